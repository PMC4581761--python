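"""Shrake-Rupley solvent-accessible surface area and glycoform differencing.

Each atom is given a sphere of radius ``r_vdw + probe`` dotted with a
deterministic golden-spiral point set; the accessible fraction is the share
of dots not buried inside any neighbour's expanded sphere, and the atom's
SASA is that fraction times the sphere area.  Per-residue values sum heavy
atoms only by default.  Trajectory averages skip an initial equilibration
fraction of frames, and glycoform difference profiles highlight residues
whose mean SASA changes by more than a cutoff (40 A^2 by default) relative
to a baseline system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureModel, Trajectory

__all__ = [
    "SasaProfile",
    "SasaDifference",
    "default_radii",
    "atom_sasa",
    "sasa_structure",
    "sasa_trajectory",
    "sasa_difference",
    "sphere_points",
]


def default_radii() -> dict[str, float]:
    """Per-element van der Waals radii (A) shipped with the package."""
    text = resources.files("gfdyn.data").joinpath("vdw_radii.json").read_text()
    return {k: float(v) for k, v in json.loads(text)["radii"].items()}


@dataclass
class SasaProfile:
    """Per-residue mean SASA (A^2) for one system."""

    residue_ids: list[tuple[str, int, str]]
    mean_sasa: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mean_sasa = np.asarray(self.mean_sasa, dtype=float)
        if len(self.residue_ids) != self.mean_sasa.shape[0]:
            raise ValueError("residue_ids and mean_sasa must align")
        if np.any(self.mean_sasa < -1e-9):
            raise ValueError("SASA cannot be negative")

    @property
    def total_sasa(self) -> float:
        return float(self.mean_sasa.sum())


@dataclass
class SasaDifference:
    """System-minus-baseline per-residue SASA deltas (A^2)."""

    residue_ids: list[tuple[str, int, str]]
    delta: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)

    @property
    def highlighted(self) -> np.ndarray:
        return np.abs(self.delta) > self.cutoff

    def highlighted_residues(self) -> list[tuple[str, int, str]]:
        return [rid for rid, h in zip(self.residue_ids, self.highlighted) if h]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _atom_radii(model: StructureModel, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(model.n_atoms)
    for i, a in enumerate(model.atoms):
        key = a.element.upper()
        if key not in radii:
            raise KeyError(f"no van der Waals radius for element {a.element!r}")
        out[i] = radii[key]
    return out


def atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = 1.4,
              n_points: int = 960) -> np.ndarray:
    """Per-atom Shrake-Rupley SASA (A^2) for arbitrary spheres."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    expanded = radii + probe
    dots = sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.zeros(n)
    r_max = float(expanded.max())
    for i in range(n):
        ri = expanded[i]
        neigh = [j for j in tree.query_ball_point(coords[i], ri + r_max)
                 if j != i]
        pts = coords[i] + ri * dots
        if neigh:
            neigh = np.asarray(neigh, dtype=int)
            d2 = np.sum((pts[:, None, :] - coords[neigh][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (expanded[neigh] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * ri * ri
    return out


def sasa_structure(model: StructureModel, radii: dict[str, float] | None = None,
                   probe: float = 1.4, n_points: int = 960,
                   include_hydrogens: bool = False,
                   coords: np.ndarray | None = None,
                   exclude_resnames: tuple[str, ...] = ("GLX", "HOH"),
                   label: str = "") -> SasaProfile:
    """Per-residue SASA of one structure.

    All atoms shadow the surface, but residues named in
    ``exclude_resnames`` (pseudo-glycan occluders, waters) act only as
    occluders and are left out of the profile; per-residue sums cover
    heavy atoms unless ``include_hydrogens``.
    """
    if radii is None:
        radii = default_radii()
    atom_r = _atom_radii(model, radii)
    xyz = model.coords if coords is None else np.asarray(coords, dtype=float)
    per_atom = atom_sasa(xyz, atom_r, probe=probe, n_points=n_points)
    rids, values = [], []
    for rid, atom_ids in model.residues():
        if model.atoms[atom_ids[0]].residue_name in exclude_resnames:
            continue
        keep = [i for i in atom_ids
                if include_hydrogens or model.atoms[i].element != "H"]
        rids.append(rid)
        values.append(per_atom[keep].sum() if keep else 0.0)
    return SasaProfile(rids, np.asarray(values), label=label)


def sasa_trajectory(traj: Trajectory, radii: dict[str, float] | None = None,
                    probe: float = 1.4, n_points: int = 960,
                    skip_fraction: float = 0.125, stride: int = 1,
                    label: str = "") -> SasaProfile:
    """Per-residue SASA averaged over the post-equilibration window.

    Frames before ``skip_fraction`` of the trajectory are discarded (the
    5-of-40 ns analog), the rest sampled every ``stride`` frames.
    """
    if not 0.0 <= skip_fraction < 1.0:
        raise ValueError("skip_fraction must lie in [0, 1)")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    start = int(np.floor(skip_fraction * traj.n_frames))
    frame_ids = range(start, traj.n_frames, stride)
    if len(frame_ids) == 0:
        raise ValueError("post-skip window contains no frames")
    acc = None
    rids = None
    for k in frame_ids:
        prof = sasa_structure(traj.topology, radii, probe, n_points,
                              coords=traj.frames[k])
        if acc is None:
            acc = prof.mean_sasa.copy()
            rids = prof.residue_ids
        else:
            acc += prof.mean_sasa
    return SasaProfile(rids, acc / len(frame_ids), label=label)


def sasa_difference(system: SasaProfile, baseline: SasaProfile,
                    cutoff: float = 40.0) -> SasaDifference:
    """System-minus-baseline deltas; |delta| strictly above ``cutoff`` is
    highlighted."""
    if system.residue_ids != baseline.residue_ids:
        raise ValueError("SASA profiles cover different residue lists")
    return SasaDifference(list(system.residue_ids),
                          system.mean_sasa - baseline.mean_sasa, cutoff)
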