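"""Per-residue RMSF profiles, glycoform difference profiles and flexibility bands.

RMSF is computed about the window-mean structure: frames in the analysis
window are superposed onto their mean (iterated twice: mean, superpose,
re-mean), and each atom's fluctuation is the root-mean-square displacement
from the converged mean.  Profiles are reported per residue at the
alpha-carbon.  Difference profiles flag residues whose absolute RMSF change
from a baseline system exceeds a threshold (0.50 A for glycoform-vs-baseline
comparisons, 1.0 A for bound-vs-free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Selection, Trajectory
from .superposition import apply_superposition, kabsch_superpose

__all__ = [
    "RmsfProfile",
    "RmsfDifference",
    "FlexibilityBand",
    "BAND_EDGES",
    "rmsf_profile",
    "rmsf_difference",
    "flexibility_bands",
    "bound_vs_free_comparison",
]

#: Right-closed flexibility band edges in A: <=1 blue, (1,2] cyan, (2,3] green,
#: (3,4] yellow, (4,5] brown, >5 red.
BAND_EDGES: tuple[tuple[float, str], ...] = (
    (1.0, "blue"),
    (2.0, "cyan"),
    (3.0, "green"),
    (4.0, "yellow"),
    (5.0, "brown"),
    (np.inf, "red"),
)


@dataclass
class RmsfProfile:
    """Per-residue alpha-carbon RMSF (A) for one system."""

    residue_ids: list[tuple[str, int, str]]
    rmsf: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if len(self.residue_ids) != self.rmsf.shape[0]:
            raise ValueError("residue_ids and rmsf must align")
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF cannot be negative")

    @property
    def mean_rmsf(self) -> float:
        """Arithmetic per-residue mean (A), the headline flexibility number."""
        return float(self.rmsf.mean())


@dataclass
class RmsfDifference:
    """System-minus-baseline RMSF deltas with threshold flags."""

    residue_ids: list[tuple[str, int, str]]
    delta: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if len(self.residue_ids) != self.delta.shape[0]:
            raise ValueError("residue_ids and delta must align")

    @property
    def flagged(self) -> np.ndarray:
        return np.abs(self.delta) > self.threshold

    def flagged_residues(self) -> list[tuple[str, int, str]]:
        return [rid for rid, f in zip(self.residue_ids, self.flagged) if f]


@dataclass(frozen=True)
class FlexibilityBand:
    residue_id: tuple[str, int, str]
    band: str


def rmsf_profile(traj: Trajectory, calpha: Selection,
                 window: tuple[int, int] | None = None,
                 label: str = "") -> RmsfProfile:
    """Alpha-carbon RMSF about the window-mean structure.

    Parameters
    ----------
    traj
        Trajectory to analyse.
    calpha
        Selection of one atom per residue (normally ``calpha``); the
        superposition fit set and the reported atoms coincide.
    window
        Half-open frame range ``(start, stop)``; default skips the first
        12.5% of frames (the equilibration analog) and uses the rest.
    """
    if window is None:
        start = int(np.floor(0.125 * traj.n_frames))
        window = (start, traj.n_frames)
    start, stop = window
    if not 0 <= start < stop <= traj.n_frames:
        raise ValueError(f"window {window} outside 0..{traj.n_frames}")
    if stop - start < 2:
        raise ValueError("RMSF needs at least 2 frames in the window")

    idx = calpha.indices
    frames = traj.frames[start:stop, idx, :]
    mean = frames.mean(axis=0)
    # two rounds: superpose on current mean, then re-mean
    for _ in range(2):
        fitted = np.empty_like(frames)
        for k in range(frames.shape[0]):
            fit = kabsch_superpose(frames[k], mean)
            fitted[k] = apply_superposition(frames[k], fit)
        mean = fitted.mean(axis=0)
    sq = np.sum((fitted - mean) ** 2, axis=2)
    rmsf = np.sqrt(sq.mean(axis=0))

    rids = [traj.topology.atoms[i].residue_id for i in idx]
    return RmsfProfile(rids, rmsf, label=label)


def rmsf_difference(system: RmsfProfile, baseline: RmsfProfile,
                    threshold: float = 0.50) -> RmsfDifference:
    """System-minus-baseline per-residue deltas, flagged above ``threshold``."""
    if system.residue_ids != baseline.residue_ids:
        raise ValueError("RMSF profiles cover different residue lists")
    return RmsfDifference(list(system.residue_ids),
                          system.rmsf - baseline.rmsf, threshold)


def bound_vs_free_comparison(bound: RmsfProfile, free: RmsfProfile,
                             threshold: float = 1.0) -> RmsfDifference:
    """Bound-minus-free difference profile (negative deltas = rigidified)."""
    return rmsf_difference(bound, free, threshold=threshold)


def _band_for(value: float) -> str:
    for edge, band in BAND_EDGES:
        if value <= edge:
            return band
    return "red"


def flexibility_bands(profile: RmsfProfile) -> list[FlexibilityBand]:
    """Map each residue's RMSF onto the six-colour flexibility scale."""
    if profile.rmsf.size == 0:
        raise ValueError("empty RMSF profile")
    return [FlexibilityBand(rid, _band_for(float(v)))
            for rid, v in zip(profile.residue_ids, profile.rmsf)]
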