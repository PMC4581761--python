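"""Interface salt-bridge enumeration and persistence statistics.

A salt bridge is a cationic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2;
optionally His ND1/NE2) apposed to an anionic side-chain oxygen (Asp
OD1/OD2; Glu OE1/OE2) across the ligand/receptor interface.  Bridges are
seeded from the reference structure, their minimum N-O distance is sampled
at a fixed frame stride along the trajectory, and persistence is summarised
as the median sampled distance together with the occupancy: the fraction of
samples with distance strictly below a cutoff (3.5 A by default), printed as
a percentage to one decimal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import StructureModel, Trajectory

__all__ = [
    "SaltBridgePair",
    "SaltBridgeStat",
    "CATION_ATOMS",
    "ANION_ATOMS",
    "find_salt_bridges",
    "bridge_distance_series",
    "bridge_statistics",
    "default_stride",
]

#: Side-chain nitrogen atoms carrying the positive charge.
CATION_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}

#: Histidine nitrogens, included only on request (protonation-dependent).
HIS_ATOMS: dict[str, tuple[str, ...]] = {"HIS": ("ND1", "NE2")}

#: Side-chain carboxylate oxygens carrying the negative charge.
ANION_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


@dataclass(frozen=True)
class SaltBridgePair:
    """One interface bridge: cation residue vs anion residue with the
    topology indices of their charged atoms."""

    cation_residue: tuple[str, int, str]
    cation_atoms: tuple[int, ...]
    anion_residue: tuple[str, int, str]
    anion_atoms: tuple[int, ...]
    cation_side: str = "ligand"
    anion_side: str = "receptor"

    def label(self) -> str:
        c, a = self.cation_residue, self.anion_residue
        return f"{c[0]}{c[1]}-{a[0]}{a[1]}"


@dataclass(frozen=True)
class SaltBridgeStat:
    """Median sampled N-O distance (A) and cutoff occupancy for one bridge."""

    pair: SaltBridgePair | None
    median_distance: float
    occupancy: float
    n_samples: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")
        if self.median_distance <= 0:
            raise ValueError("median distance must be positive")

    @property
    def occupancy_pct(self) -> float:
        """Occupancy as a percentage rounded to one decimal (table style)."""
        return round(100.0 * self.occupancy, 1)


def _charged_atoms(model: StructureModel, chains: set[str],
                   table: dict[str, tuple[str, ...]]):
    """Per residue: indices of this residue's charged atoms from ``table``."""
    out = []
    for rid, atom_ids in model.residues():
        if rid[0] not in chains:
            continue
        resname = model.atoms[atom_ids[0]].residue_name
        wanted = table.get(resname)
        if not wanted:
            continue
        idx = tuple(i for i in atom_ids if model.atoms[i].name in wanted)
        if idx:
            out.append((rid, idx))
    return out


def find_salt_bridges(model: StructureModel,
                      ligand_chains: list[str] | None = None,
                      receptor_chains: list[str] | None = None,
                      seed_cutoff: float = 4.0,
                      include_histidine: bool = False) -> list[SaltBridgePair]:
    """Enumerate cross-interface salt bridges in a reference structure.

    A (cation residue, anion residue) pair is reported when the minimum
    N-O distance across its charged atoms is below ``seed_cutoff``; both
    orientations (ligand cation / receptor anion and vice versa) are
    scanned.  Results are ordered by the ligand-side residue then the
    receptor-side residue.
    """
    if ligand_chains is None:
        ligand_chains = model.chains_with_role("ligand_alpha", "ligand_beta")
    if receptor_chains is None:
        receptor_chains = model.chains_with_role("receptor")
    lig, rec = set(ligand_chains), set(receptor_chains)
    if lig & rec:
        raise ValueError("ligand and receptor chain sets overlap")

    cat_table = dict(CATION_ATOMS)
    if include_histidine:
        cat_table.update(HIS_ATOMS)

    coords = model.coords
    pairs: list[tuple[tuple, SaltBridgePair]] = []
    any_opposed = False
    for cat_chains, an_chains, cat_side, an_side in (
            (lig, rec, "ligand", "receptor"), (rec, lig, "receptor", "ligand")):
        cations = _charged_atoms(model, cat_chains, cat_table)
        anions = _charged_atoms(model, an_chains, ANION_ATOMS)
        if not cations or not anions:
            continue
        any_opposed = True
        for crid, cidx in cations:
            for arid, aidx in anions:
                d = np.linalg.norm(coords[list(cidx)][:, None, :]
                                   - coords[list(aidx)][None, :, :], axis=2)
                if float(d.min()) < seed_cutoff:
                    lig_key = crid if cat_side == "ligand" else arid
                    rec_key = arid if cat_side == "ligand" else crid
                    pairs.append(((lig_key, rec_key),
                                  SaltBridgePair(crid, cidx, arid, aidx,
                                                 cat_side, an_side)))
    if not pairs and not any_opposed:
        warnings.warn("no charged residues in opposable cation/anion roles "
                      "across the interface; no salt bridges possible",
                      stacklevel=2)
    pairs.sort(key=lambda kv: kv[0])
    return [p for _, p in pairs]


def default_stride(frame_spacing_ps: float, sample_interval_ps: float = 2.0) -> int:
    """Frame stride reproducing 'every 1000th 2 fs step' = one sample / 2 ps."""
    return max(1, int(np.ceil(sample_interval_ps / frame_spacing_ps)))


def bridge_distance_series(traj: Trajectory, pair: SaltBridgePair,
                           stride: int = 1) -> np.ndarray:
    """Minimum cation-N / anion-O distance (A) at every ``stride``-th frame."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = traj.topology.n_atoms
    for i in pair.cation_atoms + pair.anion_atoms:
        if not 0 <= i < n:
            raise IndexError(f"bridge atom index {i} missing from topology")
    cat = np.asarray(pair.cation_atoms, dtype=int)
    an = np.asarray(pair.anion_atoms, dtype=int)
    frames = traj.frames[::stride]
    diff = frames[:, cat, None, :] - frames[:, None, an, :]
    d = np.linalg.norm(diff, axis=3)
    return d.reshape(d.shape[0], -1).min(axis=1)


def bridge_statistics(series: np.ndarray, cutoff: float = 3.5,
                      pair: SaltBridgePair | None = None) -> SaltBridgeStat:
    """Median distance and strict-inequality occupancy over sampled frames.

    The median of an even-length series is the mean of the central pair;
    occupancy counts samples with distance strictly below ``cutoff``.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty distance series")
    median = float(np.median(series))
    occ = float(np.count_nonzero(series < cutoff)) / series.size
    return SaltBridgeStat(pair, median, occ, int(series.size))
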