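"""MM-GBSA energy machinery: molecular-mechanics terms, Generalized-Born
polar solvation, the SASA-linear nonpolar term, and snapshot averaging.

The total free energy follows the end-point decomposition

    GBTOT = E_int + E_ele + E_vdw + GBSOL,      GBSOL = G_pol + G_nonpol

with gas-phase molecular mechanics (harmonic bonds/angles, cosine
dihedrals, Coulomb with k_e = 332.0636 kcal*A/(mol*e^2), Lennard-Jones 12-6
with Lorentz-Berthelot combining, no cutoff), a pairwise Generalized-Born
polar term (HCT pairwise descreening by default, OBC-II optional) between
an interior dielectric of 1 and a solvent dielectric of 80, and the
empirical nonpolar term G_nonpol = gamma*SASA + beta with
gamma = 0.00542 kcal/(mol*A^2) and beta = 0.92 kcal/mol.  The
conformational-entropy term is deliberately not modelled; requesting it is
a configuration error.

Binding mode uses the single-trajectory approximation: receptor and ligand
coordinates are extracted from the complex frames, so intra-molecular
bonded terms cancel exactly in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ForceFieldTable, Selection, StructureModel, Trajectory
from . import sasa as _sasa

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyModelConfig",
    "EnergyComponents",
    "EnergySummary",
    "bonded_energy",
    "nonbonded_energy",
    "gb_born_radii",
    "gb_polar_energy",
    "nonpolar_energy",
    "snapshot_energy",
    "mmgbsa_summary",
    "binding_components",
]

#: Electrostatic conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0636

#: Radius offset (A) used by the OBC-II effective-radius rescaling.
_OBC_OFFSET = 0.09
#: Floor (A) applied when descreening would drive a Born radius negative.
_BORN_FLOOR = 0.1


@dataclass(frozen=True)
class EnergyModelConfig:
    """Physical constants and model switches for the energy kernels."""

    interior_dielectric: float = 1.0
    solvent_dielectric: float = 80.0
    gamma: float = 0.00542
    beta: float = 0.92
    coulomb_constant: float = COULOMB_CONSTANT
    gb_model: str = "HCT"
    scale_ele_14: float = 1.0 / 1.2
    scale_lj_14: float = 0.5
    include_entropy: bool = False
    sasa_n_points: int = 960
    sasa_probe: float = 1.4

    def __post_init__(self) -> None:
        if self.interior_dielectric <= 0 or self.solvent_dielectric <= 0:
            raise ValueError("dielectric constants must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if self.gb_model not in ("HCT", "OBC-II"):
            raise ValueError(f"unknown GB model {self.gb_model!r}")
        if self.include_entropy:
            raise ValueError("conformational entropy is not modelled; "
                             "include_entropy must stay False")


@dataclass(frozen=True)
class EnergyComponents:
    """One snapshot's energy ledger (kcal/mol).

    ``gbsol`` and ``gbtot`` are derived sums, so the ledger identities
    GBSOL = G_pol + G_nonpol and GBTOT = INT + ELE + VDW + GBSOL hold by
    construction.
    """

    internal: float
    electrostatic: float
    vdw: float
    gb_polar: float
    nonpolar: float

    @property
    def gbsol(self) -> float:
        return self.gb_polar + self.nonpolar

    @property
    def gbtot(self) -> float:
        return self.internal + self.electrostatic + self.vdw + self.gbsol

    def as_dict(self) -> dict[str, float]:
        return {"INT": self.internal, "ELE": self.electrostatic,
                "VDW": self.vdw, "GBSOL": self.gbsol, "GBTOT": self.gbtot}

    def __sub__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(self.internal - other.internal,
                                self.electrostatic - other.electrostatic,
                                self.vdw - other.vdw,
                                self.gb_polar - other.gb_polar,
                                self.nonpolar - other.nonpolar)


@dataclass
class EnergySummary:
    """Component means and standard deviations over snapshots."""

    mean: EnergyComponents
    sd: dict[str, float]
    n_snapshots: int
    label: str = ""

    def table_rows(self) -> dict[str, tuple[float, float]]:
        m = self.mean.as_dict()
        return {k: (m[k], self.sd[k]) for k in ("INT", "ELE", "VDW", "GBSOL", "GBTOT")}


# ---------------------------------------------------------------------------
# Molecular-mechanics kernels


def bonded_energy(coords: np.ndarray, ff: ForceFieldTable) -> float:
    """Harmonic bond/angle plus cosine dihedral energy (kcal/mol).

    E = sum k_b (r - r0)^2 + sum k_a (theta - theta0)^2
        + sum V [1 + cos(n*phi - phase)]
    """
    coords = np.asarray(coords, dtype=float)
    e = 0.0
    for i, j, kb, r0 in ff.bonds:
        r = float(np.linalg.norm(coords[j] - coords[i]))
        e += kb * (r - r0) ** 2
    for i, j, k, ka, t0 in ff.angles:
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        theta = float(np.arccos(np.clip(cosang, -1.0, 1.0)))
        e += ka * (theta - t0) ** 2
    for i, j, k, l, v, per, phase in ff.dihedrals:
        b1 = coords[j] - coords[i]
        b2 = coords[k] - coords[j]
        b3 = coords[l] - coords[k]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
            raise ValueError(f"degenerate dihedral {(i, j, k, l)}: collinear atoms")
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))
        e += v * (1.0 + np.cos(per * phi - phase))
    return float(e)


def _exclusion_maps(ff: ForceFieldTable):
    """(excluded pair set, 1-4 scaled pair set) from the bonded lists."""
    excluded: set[tuple[int, int]] = set()
    for i, j, *_ in ff.bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, _, k, *_ in ff.angles:
        excluded.add((min(i, k), max(i, k)))
    scaled: set[tuple[int, int]] = set()
    for i, _, _, l, *_ in ff.dihedrals:
        key = (min(i, l), max(i, l))
        if key not in excluded:
            scaled.add(key)
    return excluded, scaled


def nonbonded_energy(coords: np.ndarray, ff: ForceFieldTable,
                     config: EnergyModelConfig | None = None,
                     pair_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Gas-phase (electrostatic, van der Waals) energies in kcal/mol.

    All unique pairs interact (no cutoff) except 1-2/1-3 exclusions; 1-4
    pairs are scaled by the configured factors.  ``pair_mask`` (n, n,
    boolean) optionally restricts the summed pairs, e.g. to
    inter-molecular interactions.
    """
    if config is None:
        config = EnergyModelConfig()
    coords = np.asarray(coords, dtype=float)
    n = ff.n_atoms
    if coords.shape != (n, 3):
        raise ValueError(f"coords must be ({n}, 3)")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    iu, ju = np.triu_indices(n, k=1)
    r = d[iu, ju]
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident atoms: zero interatomic distance")

    excluded, scaled = _exclusion_maps(ff)
    scale = np.ones(r.shape)
    scale_lj = np.ones(r.shape)
    for m, (i, j) in enumerate(zip(iu, ju)):
        key = (int(i), int(j))
        if key in excluded:
            scale[m] = scale_lj[m] = 0.0
        elif key in scaled:
            scale[m] = config.scale_ele_14
            scale_lj[m] = config.scale_lj_14
    if pair_mask is not None:
        keep = np.asarray(pair_mask, dtype=bool)[iu, ju]
        scale = scale * keep
        scale_lj = scale_lj * keep

    qq = ff.charge[iu] * ff.charge[ju]
    ele = float(np.sum(scale * config.coulomb_constant * qq / r))

    sig = 0.5 * (ff.lj_sigma[iu] + ff.lj_sigma[ju])
    eps = np.sqrt(ff.lj_epsilon[iu] * ff.lj_epsilon[ju])
    sr6 = (sig / r) ** 6
    lj = float(np.sum(scale_lj * 4.0 * eps * (sr6 ** 2 - sr6)))
    return ele, lj


# ---------------------------------------------------------------------------
# Generalized-Born polar solvation


def _hct_integral(r: np.ndarray, s: np.ndarray, rho: float) -> np.ndarray:
    """Pairwise descreening integral of atom *i* (intrinsic radius ``rho``)
    by neighbours at distances ``r`` with scaled radii ``s``."""
    out = np.zeros_like(r)
    U = r + s
    active = rho < U
    if not np.any(active):
        return out
    r_, s_, U_ = r[active], s[active], U[active]
    L_ = np.maximum(rho, np.abs(r_ - s_))
    term = (1.0 / L_ - 1.0 / U_
            + (r_ / 4.0) * (1.0 / U_ ** 2 - 1.0 / L_ ** 2)
            + (1.0 / (2.0 * r_)) * np.log(L_ / U_)
            + (s_ ** 2 / (4.0 * r_)) * (1.0 / L_ ** 2 - 1.0 / U_ ** 2))
    I = 0.5 * term
    # atom i fully engulfed by the descreening sphere of j
    engulfed = rho < (s_ - r_)
    I = I + np.where(engulfed, 1.0 / rho - 1.0 / L_, 0.0)
    out[active] = I
    return out


def gb_born_radii(coords: np.ndarray, ff: ForceFieldTable,
                  model: str = "HCT") -> np.ndarray:
    """Effective Born radii (A).

    HCT: 1/R_eff = 1/R - I with the intrinsic radius used directly, so an
    isolated atom recovers its input radius (and the Born formula) exactly.
    OBC-II: the standard tanh rescaling with a 0.09 A offset.  Radii driven
    non-positive by descreening are clamped to a small floor.
    """
    coords = np.asarray(coords, dtype=float)
    n = ff.n_atoms
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    radii = ff.gb_radius
    offset = _OBC_OFFSET if model == "OBC-II" else 0.0
    rho = radii - offset
    scaled = ff.gb_scale * rho
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        I = float(np.sum(_hct_integral(d[i, mask], scaled[mask], rho[i])))
        if model == "HCT":
            inv = 1.0 / rho[i] - I
            out[i] = 1.0 / inv if inv > 0 else _BORN_FLOOR
        elif model == "OBC-II":
            psi = I * rho[i]
            # OBC-II coefficients alpha, beta, gamma
            inner = 1.0 * psi - 0.8 * psi ** 2 + 4.85 * psi ** 3
            inv = 1.0 / rho[i] - np.tanh(inner) / radii[i]
            out[i] = 1.0 / inv if inv > 0 else _BORN_FLOOR
        else:
            raise ValueError(f"unknown GB model {model!r}")
    return out


def gb_polar_energy(coords: np.ndarray, ff: ForceFieldTable,
                    config: EnergyModelConfig | None = None,
                    pair_mask: np.ndarray | None = None,
                    born_radii: np.ndarray | None = None) -> float:
    """Pairwise Generalized-Born polar solvation energy (kcal/mol).

    G_pol = -k_e/2 (1/eps_in - 1/eps_out) sum_ij q_i q_j / f_GB with
    f_GB = sqrt(r^2 + R_i R_j exp(-r^2 / (4 R_i R_j))); the double sum
    includes the i = j self terms (the Born limit for a single ion).
    """
    if config is None:
        config = EnergyModelConfig()
    coords = np.asarray(coords, dtype=float)
    if born_radii is None:
        born_radii = gb_born_radii(coords, ff, model=config.gb_model)
    R = np.asarray(born_radii, dtype=float)
    q = ff.charge
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    RR = R[:, None] * R[None, :]
    f = np.sqrt(d2 + RR * np.exp(-d2 / (4.0 * RR)))
    qq = q[:, None] * q[None, :]
    terms = qq / f
    if pair_mask is not None:
        # keep self terms; restrict cross terms to the mask
        mask = np.asarray(pair_mask, dtype=bool) | np.eye(len(q), dtype=bool)
        terms = terms * mask
    tau = 1.0 / config.interior_dielectric - 1.0 / config.solvent_dielectric
    return float(-0.5 * config.coulomb_constant * tau * terms.sum())


def nonpolar_energy(sasa_total: float, config: EnergyModelConfig | None = None) -> float:
    """Nonpolar solvation term gamma*SASA + beta (kcal/mol)."""
    if config is None:
        config = EnergyModelConfig()
    if sasa_total < 0:
        raise ValueError("SASA cannot be negative")
    return config.gamma * sasa_total + config.beta


# ---------------------------------------------------------------------------
# Snapshot assembly and trajectory summaries


def snapshot_energy(model: StructureModel, coords: np.ndarray,
                    ff: ForceFieldTable,
                    config: EnergyModelConfig | None = None,
                    selection: Selection | None = None) -> EnergyComponents:
    """All energy components of one snapshot, optionally for a subset."""
    if config is None:
        config = EnergyModelConfig()
    coords = np.asarray(coords, dtype=float)
    if selection is not None:
        idx = selection.indices
        sub_model = StructureModel([model.atoms[i] for i in idx],
                                   dict(model.chain_roles))
        sub_ff = ff.subset(idx)
        sub_coords = coords[idx]
    else:
        sub_model, sub_ff, sub_coords = model, ff, coords

    internal = bonded_energy(sub_coords, sub_ff)
    ele, vdw = nonbonded_energy(sub_coords, sub_ff, config)
    gpol = gb_polar_energy(sub_coords, sub_ff, config)
    prof = _sasa.sasa_structure(sub_model, probe=config.sasa_probe,
                                n_points=config.sasa_n_points,
                                coords=sub_coords, exclude_resnames=())
    gnp = nonpolar_energy(prof.total_sasa, config)
    return EnergyComponents(internal, ele, vdw, gpol, gnp)


def _summarise(components: list[EnergyComponents], label: str) -> EnergySummary:
    arr = {k: np.array([c.as_dict()[k] for c in components])
           for k in ("INT", "ELE", "VDW", "GBSOL", "GBTOT")}
    gpol = np.array([c.gb_polar for c in components])
    gnp = np.array([c.nonpolar for c in components])
    mean = EnergyComponents(float(arr["INT"].mean()), float(arr["ELE"].mean()),
                            float(arr["VDW"].mean()), float(gpol.mean()),
                            float(gnp.mean()))
    sd = {k: float(v.std(ddof=0)) for k, v in arr.items()}
    return EnergySummary(mean, sd, len(components), label=label)


def snapshot_indices(n_frames: int, frame_spacing: float,
                     snapshot_interval: float) -> np.ndarray:
    """Frame indices sampled every ``snapshot_interval`` ps of simulated
    time (the k-th, 2k-th, ... frames), e.g. 40 snapshots from a 40 ns
    trajectory at 1 ns intervals."""
    if snapshot_interval < frame_spacing:
        raise ValueError("snapshot_interval must be >= frame_spacing")
    k = int(round(snapshot_interval / frame_spacing))
    idx = np.arange(k - 1, n_frames, k)
    if idx.size == 0:
        raise ValueError("snapshot interval longer than the trajectory")
    return idx


def mmgbsa_summary(traj: Trajectory, ff: ForceFieldTable,
                   config: EnergyModelConfig | None = None,
                   snapshot_interval: float = 1000.0,
                   mode: str = "absolute",
                   selection: Selection | None = None,
                   label: str = ""):
    """Snapshot-averaged MM-GBSA summary.

    ``mode='absolute'`` returns one :class:`EnergySummary` of the selected
    atoms (the whole complex by default), matching the published reporting
    convention of absolute complex energies.  ``mode='binding'`` returns a
    dict with ``complex``, ``receptor``, ``ligand`` and ``delta``
    summaries under the single-trajectory approximation (parts cut from
    the complex frames; the per-snapshot difference is summarised).
    """
    if config is None:
        config = EnergyModelConfig()
    model = traj.topology
    idx = snapshot_indices(traj.n_frames, traj.frame_spacing, snapshot_interval)

    if mode == "absolute":
        comps = [snapshot_energy(model, traj.frames[k], ff, config, selection)
                 for k in idx]
        return _summarise(comps, label or "absolute")
    if mode != "binding":
        raise ValueError(f"unknown mode {mode!r}")

    lig_chains = model.chains_with_role("ligand_alpha", "ligand_beta")
    rec_chains = model.chains_with_role("receptor")
    if not lig_chains or not rec_chains:
        raise ValueError("binding mode needs ligand and receptor chain roles")
    lig_idx = tuple(i for i, a in enumerate(model.atoms) if a.chain_id in lig_chains)
    rec_idx = tuple(i for i, a in enumerate(model.atoms) if a.chain_id in rec_chains)
    both_idx = tuple(sorted(lig_idx + rec_idx))
    sels = {"complex": Selection("complex", both_idx),
            "receptor": Selection("receptor", rec_idx),
            "ligand": Selection("ligand", lig_idx)}

    per_part: dict[str, list[EnergyComponents]] = {k: [] for k in sels}
    deltas: list[EnergyComponents] = []
    for k in idx:
        snap = {name: snapshot_energy(model, traj.frames[k], ff, config, sel)
                for name, sel in sels.items()}
        for name, c in snap.items():
            per_part[name].append(c)
        deltas.append(snap["complex"] - snap["receptor"] - snap["ligand"])
    out = {name: _summarise(comps, f"{label}:{name}" if label else name)
           for name, comps in per_part.items()}
    out["delta"] = _summarise(deltas, f"{label}:delta" if label else "delta")
    return out


def binding_components(model: StructureModel, coords: np.ndarray,
                       ff: ForceFieldTable,
                       config: EnergyModelConfig | None = None) -> EnergyComponents:
    """Single-snapshot binding difference (complex - receptor - ligand)."""
    lig = model.chains_with_role("ligand_alpha", "ligand_beta")
    rec = model.chains_with_role("receptor")
    lig_idx = tuple(i for i, a in enumerate(model.atoms) if a.chain_id in lig)
    rec_idx = tuple(i for i, a in enumerate(model.atoms) if a.chain_id in rec)
    both = Selection("complex", tuple(sorted(lig_idx + rec_idx)))
    c = snapshot_energy(model, coords, ff, config, both)
    r = snapshot_energy(model, coords, ff, config, Selection("receptor", rec_idx))
    l = snapshot_energy(model, coords, ff, config, Selection("ligand", lig_idx))
    return c - r - l
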