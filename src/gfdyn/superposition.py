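"""Rigid-body superposition, RMSD time series and residue shift classes.

RMSD here always means: optimally superpose the selected atoms of a frame
onto the same atoms of a reference (proper rotation only, no reflection),
then take the root-mean-square of the residual displacements.  Per-residue
shift classification compares the time-averaged post-superposition structure
against the reference and crosses the shift flag with interface membership,
reproducing the four-way contact/shifted labelling used for
hormone-receptor interface maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import (BACKBONE_ATOMS, Selection, StructureModel,
                           Trajectory, make_selection)

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "ResidueShiftClass",
    "DegenerateGeometryError",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "classify_residue_shifts",
]


class DegenerateGeometryError(ValueError):
    """Too few points or rank-deficient covariance for a unique rotation."""


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal proper rotation + translation and the residual RMSD (A).

    ``mobile @ rotation.T + translation`` best matches the reference.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        det = float(np.linalg.det(self.rotation))
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation must be proper (det=+1), got det={det}")
        if self.rmsd < 0:
            raise ValueError("rmsd cannot be negative")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (A) against a fixed reference."""

    times: np.ndarray
    values: np.ndarray
    reference_label: str = "first_frame"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values cannot be negative")


@dataclass(frozen=True)
class ResidueShiftClass:
    """Shift/interface classification of one residue.

    ``class_label`` follows the interface-map legend: residues in receptor
    contact are *contact*, residues whose settled backbone displacement
    exceeds the threshold are *shifted*, both together *contact+shifted*.
    """

    residue_id: tuple[str, int, str]
    max_backbone_shift: float
    is_shifted: bool
    is_interface: bool

    @property
    def class_label(self) -> str:
        if self.is_interface and self.is_shifted:
            return "contact+shifted"
        if self.is_interface:
            return "contact"
        if self.is_shifted:
            return "shifted"
        return "neither"


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted least-squares rigid superposition (Kabsch, proper rotation).

    Parameters
    ----------
    mobile, reference
        (n, 3) coordinate arrays, n >= 3, not all collinear.
    weights
        Optional non-negative per-point weights.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    mu_p = w @ P
    mu_q = w @ Q
    Pc = P - mu_p
    Qc = Q - mu_q
    H = (Pc * w[:, None]).T @ Qc
    # rank < 2 leaves the rotation about the degenerate axis undetermined
    if np.linalg.matrix_rank(H, tol=1e-10) < 2:
        raise DegenerateGeometryError("rank-deficient covariance (collinear points?)")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_q - R @ mu_p
    moved = Pc @ R.T
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - Qc) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    """Apply a fitted rotation/translation to any coordinate array."""
    return np.asarray(coords, dtype=float) @ result.rotation.T + result.translation


def rmsd_series(traj: Trajectory, selection: Selection,
                reference: StructureModel | np.ndarray | None = None,
                reference_label: str | None = None) -> RmsdSeries:
    """RMSD of ``selection`` per frame after superposing onto the reference.

    ``reference`` may be a structure sharing the trajectory topology, a raw
    (n_atoms, 3) coordinate array, or None for the first frame.  Values are
    invariant to any rigid motion applied uniformly to a frame.
    """
    idx = selection.indices
    if reference is None:
        ref_coords = traj.frames[0]
        label = reference_label or "first_frame"
    elif isinstance(reference, StructureModel):
        if reference.n_atoms != traj.topology.n_atoms:
            raise ValueError("reference structure does not match trajectory topology")
        ref_coords = reference.coords
        label = reference_label or "external_structure"
    else:
        ref_coords = np.asarray(reference, dtype=float)
        label = reference_label or "external_coords"
    if idx.max() >= ref_coords.shape[0]:
        raise ValueError("selection indices exceed reference atom count")
    ref_sel = ref_coords[idx]
    values = np.array([kabsch_superpose(traj.frames[k][idx], ref_sel).rmsd
                       for k in range(traj.n_frames)])
    return RmsdSeries(traj.times, values, label)


def classify_residue_shifts(traj: Trajectory, reference: StructureModel,
                            ligand_selection: Selection,
                            partner_selection: Selection,
                            shift_threshold: float = 1.5,
                            contact_cutoff: float = 4.5,
                            skip_fraction: float = 0.125) -> list[ResidueShiftClass]:
    """Per-residue settled backbone shift and interface membership.

    For each ligand residue the frames after the equilibration skip are
    superposed (on the ligand selection's backbone) onto the reference, the
    post-superposition coordinates are time-averaged, and the residue's
    shift is the maximum displacement of its backbone atoms between that
    mean structure and the reference.  A residue is *interface* when any of
    its heavy atoms lies within ``contact_cutoff`` A of the partner
    selection in the reference structure.
    """
    if shift_threshold <= 0:
        raise ValueError("shift_threshold must be positive (A)")
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive (A)")
    lig_idx = set(int(i) for i in ligand_selection.indices)
    if lig_idx & set(int(i) for i in partner_selection.indices):
        raise ValueError("ligand and partner selections must be disjoint")

    topo = traj.topology
    ref_coords = reference.coords
    # fit on the whole complex backbone so a local shift cannot drag the frame
    all_idx = np.concatenate([ligand_selection.indices, partner_selection.indices])
    fit_idx = np.array([i for i in all_idx
                        if topo.atoms[i].name in BACKBONE_ATOMS], dtype=int)
    if fit_idx.size < 3:
        fit_idx = all_idx

    start = int(np.floor(skip_fraction * traj.n_frames))
    start = min(start, traj.n_frames - 1)
    ref_fit = ref_coords[fit_idx]
    mean_coords = np.zeros_like(ref_coords)
    window = range(start, traj.n_frames)
    for k in window:
        fit = kabsch_superpose(traj.frames[k][fit_idx], ref_fit)
        mean_coords += apply_superposition(traj.frames[k], fit)
    mean_coords /= len(window)

    partner_heavy = np.array([i for i in partner_selection.indices
                              if topo.atoms[i].element != "H"], dtype=int)
    tree = cKDTree(ref_coords[partner_heavy]) if partner_heavy.size else None

    lig_chains = {topo.atoms[i].chain_id for i in ligand_selection.indices}
    out: list[ResidueShiftClass] = []
    for rid, atom_ids in topo.residues():
        if rid[0] not in lig_chains:
            continue
        atom_ids = [i for i in atom_ids if i in lig_idx]
        if not atom_ids:
            continue
        bb = [i for i in atom_ids if topo.atoms[i].name in BACKBONE_ATOMS]
        probe = bb if bb else atom_ids
        disp = np.linalg.norm(mean_coords[probe] - ref_coords[probe], axis=1)
        shift = float(disp.max())
        heavy = [i for i in atom_ids if topo.atoms[i].element != "H"]
        if tree is not None and heavy:
            dmin = float(np.min(tree.query(ref_coords[heavy], k=1)[0]))
            interface = dmin < contact_cutoff
        else:
            interface = False
        out.append(ResidueShiftClass(rid, shift, shift > shift_threshold, interface))
    return out


def shifted_fraction(classes: list[ResidueShiftClass]) -> float:
    """Fraction of residues flagged as shifted."""
    if not classes:
        return 0.0
    return sum(c.is_shifted for c in classes) / len(classes)


def detect_shift_frame(series: RmsdSeries) -> int:
    """Locate an abrupt, sustained RMSD increase (0-based frame index).

    Scans all split points and returns the one maximising the difference
    of means between the two sides — the standard single change-point
    estimator for a step in the mean.
    """
    v = np.asarray(series.values, dtype=float)
    if v.size < 3:
        raise ValueError("need at least 3 frames to locate a shift")
    best_k, best_gap = 1, -np.inf
    csum = np.cumsum(v)
    total = csum[-1]
    for k in range(1, v.size):
        gap = abs((total - csum[k - 1]) / (v.size - k) - csum[k - 1] / k)
        if gap > best_gap:
            best_gap, best_k = gap, k
    return best_k


def default_ligand_partner(model: StructureModel) -> tuple[Selection, Selection]:
    """Ligand (hormone) vs receptor selections from the chain role map."""
    lig = model.chains_with_role("ligand_alpha", "ligand_beta")
    rec = model.chains_with_role("receptor")
    if not lig or not rec:
        raise ValueError("model needs both ligand and receptor chain roles")
    lig_sel = make_selection(model, "chain " + ",".join(lig), name="ligand")
    rec_sel = make_selection(model, "chain " + ",".join(rec), name="receptor")
    return lig_sel, rec_sel
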