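"""Toy two-chain complexes and trajectories with known ground truth.

The generator stands in for production molecular dynamics: it emits a
simplified hormone/receptor complex (two extended chains of four-atom
backbone residues, charged side-chain tips at planted salt-bridge
positions, optional inert pseudo-glycan occluder spheres), a complete
force-field table for it, and i.i.d. Gaussian-jitter trajectories with
three kinds of planted signal:

* a per-residue fluctuation amplitude (RMSF ground truth: an isotropic
  per-coordinate sigma gives RMSF = sqrt(3)*sigma),
* an optional abrupt conformational shift applied to a residue region from
  a given frame onward (RMSD change-point ground truth),
* two-state Markov open/closed dynamics for each planted salt bridge whose
  stationary closed fraction equals the requested occupancy.

Bridge tip atoms follow the two-state geometry exactly (no jitter on top),
so planted occupancies are recovered to binomial sampling error.  Frames
are independent given the event schedule; dynamical realism is explicitly
out of scope.  Bonded reference values (r0, theta0, dihedral phase) are
taken from the built geometry, so the reference structure has zero
internal strain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .structure_io import (AtomRecord, ForceFieldTable, StructureModel,
                           Trajectory, write_forcefield, write_pdb,
                           write_trajectory)

__all__ = [
    "PlantedBridge",
    "ShiftEvent",
    "Occluder",
    "SyntheticSpec",
    "build_toy_complex",
    "sample_trajectory",
    "paper_analog_suite",
]

_CA_SPACING = 3.8       # A between consecutive alpha-carbons
_CHAIN_GAP = 12.0       # A between the two backbone axes
_TIP_Y = 4.5            # A from the ligand axis to the cation tip

# backbone offsets from CA, chosen non-planar so angles/dihedrals are sane
_BB_OFFSETS = {
    "N": np.array([-1.25, 0.60, 0.20]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.25, 0.60, -0.20]),
    "O": np.array([1.30, 1.80, -0.30]),
}


@dataclass(frozen=True)
class PlantedBridge:
    """A designed interface salt bridge with two-state distance dynamics."""

    ligand_res: int
    receptor_res: int
    target_occupancy: float
    closed_distance: float = 2.8
    open_distance: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target_occupancy must lie in [0, 1]")
        if self.open_distance <= self.closed_distance:
            raise ValueError("open_distance must exceed closed_distance")


@dataclass(frozen=True)
class ShiftEvent:
    """Persistent displacement of a residue region from one frame onward."""

    frame: int
    residues: tuple[tuple[str, int], ...]
    displacement: tuple[float, float, float]


@dataclass(frozen=True)
class Occluder:
    """Pseudo-glycan spheres stacked over an attachment residue."""

    chain: str
    resseq: int
    n_spheres: int = 1


@dataclass
class SyntheticSpec:
    """Complete recipe for one toy system; a fixed seed gives bit-identical
    output."""

    n_ligand_residues: int = 12
    n_receptor_residues: int = 14
    planted_bridges: list[PlantedBridge] = field(default_factory=list)
    sigma: float = 0.3
    sigma_overrides: dict[tuple[str, int], float] = field(default_factory=dict)
    shift_event: ShiftEvent | None = None
    occluders: list[Occluder] = field(default_factory=list)
    n_frames: int = 200
    frame_spacing: float = 100.0
    switching_rate: float = 0.8
    seed: int = 0
    label: str = "toy"

    def __post_init__(self) -> None:
        for b in self.planted_bridges:
            if not 1 <= b.ligand_res <= self.n_ligand_residues:
                raise ValueError(f"bridge ligand residue {b.ligand_res} out of range")
            if not 1 <= b.receptor_res <= self.n_receptor_residues:
                raise ValueError(f"bridge receptor residue {b.receptor_res} out of range")
        if not 0.0 < self.switching_rate <= 1.0:
            raise ValueError("switching_rate must lie in (0, 1]")


def _residue_atoms(chain: str, resseq: int, resname: str, ca: np.ndarray,
                   flip: bool, serial0: int) -> list[AtomRecord]:
    sign = -1.0 if flip else 1.0
    atoms = []
    for k, name in enumerate(("N", "CA", "C", "O")):
        off = _BB_OFFSETS[name] * np.array([1.0, sign, 1.0])
        xyz = ca + off
        atoms.append(AtomRecord(serial0 + k, name, name[0], resname, chain,
                                resseq, tuple(float(v) for v in xyz)))
    return atoms


def _tip_positions(bridge: PlantedBridge, distance: float,
                   open_state: bool = False) -> dict[str, np.ndarray]:
    """Cation/anion tip coordinates for a given N-O1 separation.

    The closed state points the carboxylate straight at the cation; the
    open state swings it diagonally (+x) so the displaced tip clears both
    backbones."""
    x = _CA_SPACING * (bridge.ligand_res - 1)
    nz = np.array([x, _TIP_Y, 0.0])
    direction = np.array([0.8, 0.6, 0.0]) if open_state else np.array([0.0, 1.0, 0.0])
    od1 = nz + distance * direction
    od2 = od1 + np.array([1.10, 0.60, 0.0])
    return {"NZ": nz, "OD1": od1, "OD2": od2}


def build_toy_complex(spec: SyntheticSpec) -> tuple[StructureModel, ForceFieldTable]:
    """Construct the reference structure and its force-field table.

    Chain A is the hormone analog (role ``ligand_alpha``), chain R the
    receptor analog; planted bridges are LYS(NZ)/ASP(OD1,OD2) pairs built
    at their closed distance.  Occluder spheres are chargeless ``GLX``
    residues with element ``X``.
    """
    bridges_by_lig = {b.ligand_res: b for b in spec.planted_bridges}
    bridges_by_rec = {b.receptor_res: b for b in spec.planted_bridges}

    atoms: list[AtomRecord] = []
    serial = 1
    for r in range(1, spec.n_ligand_residues + 1):
        ca = np.array([_CA_SPACING * (r - 1), 0.0, 0.0])
        resname = "LYS" if r in bridges_by_lig else "GLY"
        res = _residue_atoms("A", r, resname, ca, flip=False, serial0=serial)
        serial += len(res)
        atoms.extend(res)
        if r in bridges_by_lig:
            tip = _tip_positions(bridges_by_lig[r], bridges_by_lig[r].closed_distance)
            atoms.append(AtomRecord(serial, "NZ", "N", "LYS", "A", r,
                                    tuple(float(v) for v in tip["NZ"])))
            serial += 1
    for r in range(1, spec.n_receptor_residues + 1):
        ca = np.array([_CA_SPACING * (r - 1) + 1.9, _CHAIN_GAP, 0.0])
        resname = "ASP" if r in bridges_by_rec else "GLY"
        res = _residue_atoms("R", r, resname, ca, flip=True, serial0=serial)
        serial += len(res)
        atoms.extend(res)
        if r in bridges_by_rec:
            tip = _tip_positions(bridges_by_rec[r], bridges_by_rec[r].closed_distance)
            for name in ("OD1", "OD2"):
                atoms.append(AtomRecord(serial, name, "O", "ASP", "R", r,
                                        tuple(float(v) for v in tip[name])))
                serial += 1
    for occ in spec.occluders:
        base_ca = None
        for a in atoms:
            if a.chain_id == occ.chain and a.residue_seq == occ.resseq and a.name == "CA":
                base_ca = np.array(a.coords)
                break
        if base_ca is None:
            raise ValueError(f"occluder attachment {occ.chain}/{occ.resseq} not found")
        # glycans point away from the interface: -y for the ligand chain.
        # one sphere sits under the attachment residue; larger glycans use a
        # flanking pair (stronger occlusion) plus a stalk of further spheres.
        direction = -1.0 if occ.chain == "A" else 1.0
        if occ.n_spheres == 1:
            offsets = [(0.0, 2.8, 0.0)]
        else:
            offsets = [(0.0, 2.8, 1.8), (0.0, 2.8, -1.8),
                       (0.0, 6.2, 0.0), (0.0, 9.6, 0.0)][:occ.n_spheres]
        for k, (dx, dy, dz) in enumerate(offsets):
            xyz = base_ca + np.array([dx, direction * dy, dz])
            atoms.append(AtomRecord(serial, f"X{k + 1}", "X", "GLX", occ.chain,
                                    1000 + occ.resseq, tuple(float(v) for v in xyz)))
            serial += 1

    model = StructureModel(atoms, {"A": "ligand_alpha", "R": "receptor"})
    ff = _build_forcefield(model)
    return model, ff


_ATOM_PARAMS = {
    # name -> (charge e, lj_sigma A, lj_epsilon kcal/mol, gb_radius A, gb_scale)
    "N": (-0.30, 3.25, 0.17, 1.55, 0.80),
    "CA": (0.10, 3.40, 0.11, 1.70, 0.72),
    "C": (0.40, 3.40, 0.11, 1.70, 0.72),
    "O": (-0.20, 2.96, 0.21, 1.52, 0.85),
    "NZ": (1.00, 3.25, 0.17, 1.55, 0.80),
    "OD1": (-0.50, 2.96, 0.21, 1.52, 0.85),
    "OD2": (-0.50, 2.96, 0.21, 1.52, 0.85),
}
_OCCLUDER_PARAMS = (0.0, 5.0, 0.05, 3.0, 0.72)


def _dihedral_angle(p0, p1, p2, p3) -> float:
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(np.dot(m1, n2), np.dot(n1, n2)))


def _build_forcefield(model: StructureModel) -> ForceFieldTable:
    coords = model.coords
    n = model.n_atoms
    charge = np.zeros(n)
    sigma = np.zeros(n)
    eps = np.zeros(n)
    gb_r = np.zeros(n)
    gb_s = np.zeros(n)
    for i, a in enumerate(model.atoms):
        params = _OCCLUDER_PARAMS if a.element == "X" else _ATOM_PARAMS[a.name]
        charge[i], sigma[i], eps[i], gb_r[i], gb_s[i] = params

    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(model.atoms):
        by_res.setdefault(a.residue_id, {})[a.name] = i

    bonds: list[tuple[int, int, float, float]] = []
    angles: list[tuple[int, int, int, float, float]] = []
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = []

    def add_bond(i: int, j: int, kb: float = 300.0) -> None:
        bonds.append((i, j, kb, float(np.linalg.norm(coords[j] - coords[i]))))

    def add_angle(i: int, j: int, k: int, ka: float = 50.0) -> None:
        v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
        t0 = float(np.arccos(np.clip(np.dot(v1, v2)
                                     / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                                     -1.0, 1.0)))
        angles.append((i, j, k, ka, t0))

    ordered = [rid for rid, _ in model.residues()]
    for rid in ordered:
        names = by_res[rid]
        if "CA" not in names:  # occluder residue: spheres chained to the
            # attachment residue's CA (the glycosidic-link analog), with
            # angles excluding the nearest backbone contacts
            xs = sorted(names.values())
            for a_i, b_i in zip(xs, xs[1:]):
                add_bond(a_i, b_i, kb=100.0)
            host = by_res.get((rid[0], rid[1] - 1000, ""))
            if host is not None:
                add_bond(host["CA"], xs[0], kb=100.0)
                add_angle(host["N"], host["CA"], xs[0])
                add_angle(host["C"], host["CA"], xs[0])
                if len(xs) > 1:
                    add_angle(host["CA"], xs[0], xs[1])
            continue
        add_bond(names["N"], names["CA"])
        add_bond(names["CA"], names["C"])
        add_bond(names["C"], names["O"])
        add_angle(names["N"], names["CA"], names["C"])
        add_angle(names["CA"], names["C"], names["O"])
        for tip in ("NZ", "OD1"):
            if tip in names:
                add_bond(names["CA"], names[tip], kb=100.0)
                add_angle(names["N"], names["CA"], names[tip])
                add_angle(names["C"], names["CA"], names[tip])
        if "OD2" in names:
            add_bond(names["OD1"], names["OD2"], kb=100.0)
            add_angle(names["CA"], names["OD1"], names["OD2"])

    # peptide bonds and a backbone dihedral per junction, phased so the
    # built geometry sits at the cosine minimum (zero reference strain)
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev[0] != nxt[0] or "CA" not in by_res[prev] or "CA" not in by_res[nxt]:
            continue
        if nxt[1] != prev[1] + 1:
            continue
        c_i, n_j = by_res[prev]["C"], by_res[nxt]["N"]
        add_bond(c_i, n_j)
        add_angle(by_res[prev]["CA"], c_i, n_j)
        add_angle(by_res[prev]["O"], c_i, n_j)
        add_angle(c_i, n_j, by_res[nxt]["CA"])
        p = (by_res[prev]["N"], by_res[prev]["CA"], c_i, n_j)
        phi0 = _dihedral_angle(*(coords[i] for i in p))
        phase = (2.0 * phi0 - np.pi) % (2.0 * np.pi)
        dihedrals.append((*p, 0.5, 2, phase))

    return ForceFieldTable(charge, sigma, eps, gb_r, gb_s, bonds, angles, dihedrals)


def sample_trajectory(model: StructureModel, spec: SyntheticSpec) -> Trajectory:
    """Draw a trajectory with the spec's planted signals (seeded, exact)."""
    rng = np.random.default_rng(spec.seed)
    ref = model.coords
    n_atoms = model.n_atoms

    sigma_atom = np.full(n_atoms, spec.sigma)
    for i, a in enumerate(model.atoms):
        key = (a.chain_id, a.residue_seq)
        if key in spec.sigma_overrides:
            sigma_atom[i] = spec.sigma_overrides[key]

    tip_index: dict[tuple[int, str], int] = {}
    for i, a in enumerate(model.atoms):
        if a.name in ("NZ", "OD1", "OD2"):
            tip_index[(a.residue_seq, a.name)] = i
    bridge_atoms: set[int] = set()
    for b in spec.planted_bridges:
        bridge_atoms.add(tip_index[(b.ligand_res, "NZ")])
        bridge_atoms.add(tip_index[(b.receptor_res, "OD1")])
        bridge_atoms.add(tip_index[(b.receptor_res, "OD2")])

    shift_mask = np.zeros(n_atoms, dtype=bool)
    if spec.shift_event is not None:
        wanted = set(spec.shift_event.residues)
        for i, a in enumerate(model.atoms):
            if (a.chain_id, a.residue_seq) in wanted:
                shift_mask[i] = True

    # two-state Markov chains, one per bridge, stationary closed fraction p
    w = spec.switching_rate
    states = np.empty((len(spec.planted_bridges), spec.n_frames), dtype=bool)
    for bi, b in enumerate(spec.planted_bridges):
        p = b.target_occupancy
        s = rng.random() < p
        for k in range(spec.n_frames):
            u = rng.random()
            if s:
                s = not (u < w * (1.0 - p))
            else:
                s = u < w * p
            states[bi, k] = s

    frames = np.empty((spec.n_frames, n_atoms, 3))
    for k in range(spec.n_frames):
        noise = rng.normal(0.0, 1.0, size=(n_atoms, 3)) * sigma_atom[:, None]
        frame = ref + noise
        if spec.shift_event is not None and k >= spec.shift_event.frame:
            frame[shift_mask] += np.asarray(spec.shift_event.displacement)
        for bi, b in enumerate(spec.planted_bridges):
            closed = bool(states[bi, k])
            dist = b.closed_distance if closed else b.open_distance
            tip = _tip_positions(b, dist, open_state=not closed)
            frame[tip_index[(b.ligand_res, "NZ")]] = tip["NZ"]
            frame[tip_index[(b.receptor_res, "OD1")]] = tip["OD1"]
            frame[tip_index[(b.receptor_res, "OD2")]] = tip["OD2"]
        frames[k] = frame
    return Trajectory(model, frames, spec.frame_spacing)


def _suite_specs(n_frames: int, frame_spacing: float, seed: int) -> list[SyntheticSpec]:
    bridges_dg = [PlantedBridge(2, 2, 0.965), PlantedBridge(5, 5, 0.997),
                  PlantedBridge(8, 8, 1.0), PlantedBridge(11, 11, 0.998)]
    bridges_hypo = [PlantedBridge(2, 2, 0.779), PlantedBridge(5, 5, 0.971),
                    PlantedBridge(8, 8, 1.0), PlantedBridge(11, 11, 1.0)]
    bridges_full = [PlantedBridge(2, 2, 0.619), PlantedBridge(5, 5, 0.995),
                    PlantedBridge(8, 8, 0.906), PlantedBridge(11, 11, 0.998)]
    base = dict(n_ligand_residues=12, n_receptor_residues=14,
                n_frames=n_frames, frame_spacing=frame_spacing)
    shift = ShiftEvent(frame=n_frames // 5,
                       residues=tuple(("A", r) for r in (3, 4)),
                       displacement=(0.0, 0.0, 3.0))
    small, large = 1, 3

    def occl(n_spheres: int, sites: list[int]) -> list[Occluder]:
        return [Occluder("A", s, n_spheres) for s in sites]

    return [
        SyntheticSpec(**base, planted_bridges=bridges_dg, seed=seed,
                      label="dg_analog"),
        SyntheticSpec(**base, planted_bridges=bridges_dg, seed=seed + 1,
                      occluders=occl(small, [3, 9]), label="hypo_small_analog"),
        SyntheticSpec(**base, planted_bridges=bridges_dg, seed=seed + 2,
                      occluders=occl(small, [3, 6, 9, 12]), label="full_small_analog"),
        SyntheticSpec(**base, planted_bridges=bridges_hypo, seed=seed + 3,
                      occluders=occl(large, [3, 9]), shift_event=shift,
                      label="hypo_large_analog"),
        SyntheticSpec(**base, planted_bridges=bridges_full, seed=seed + 4,
                      occluders=occl(large, [3, 6, 9, 12]), label="full_large_analog"),
    ]


def paper_analog_suite(outdir: str | Path, n_frames: int = 400,
                       frame_spacing: float = 100.0, seed: int = 0,
                       write_files: bool = True) -> dict[str, dict]:
    """Five toy systems mirroring the published design matrix.

    One baseline without occluders, two lightly occluded systems (2 and 4
    small pseudo-glycans), and two heavily occluded systems (2 and 4 large
    pseudo-glycans); the 2-large analog additionally carries the abrupt
    conformational-shift event.  Occupancies of the four planted interface
    bridges differ across the baseline and the two heavy systems the way
    the published persistence table does.

    Returns ``{name: {"spec", "model", "ff", "trajectory", paths...}}``;
    with ``write_files`` each system's PDB, trajectory, parameter file and
    spec YAML land in ``outdir``.
    """
    outdir = Path(outdir)
    if write_files:
        outdir.mkdir(parents=True, exist_ok=True)
    suite: dict[str, dict] = {}
    for sys_spec in _suite_specs(n_frames, frame_spacing, seed):
        model, ff = build_toy_complex(sys_spec)
        traj = sample_trajectory(model, sys_spec)
        entry: dict = {"spec": sys_spec, "model": model, "ff": ff,
                       "trajectory": traj}
        if write_files:
            stem = outdir / sys_spec.label
            write_pdb(model, f"{stem}.pdb")
            write_trajectory(traj, f"{stem}_traj.pdb", fmt="pdb")
            write_forcefield(ff, model, f"{stem}.ff")
            with open(f"{stem}.yaml", "w") as fh:
                yaml.safe_dump(_spec_to_dict(sys_spec), fh, sort_keys=False)
            entry.update(structure_path=f"{stem}.pdb",
                         trajectory_path=f"{stem}_traj.pdb",
                         forcefield_path=f"{stem}.ff")
        suite[sys_spec.label] = entry
    return suite


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    return {
        "label": spec.label,
        "n_ligand_residues": spec.n_ligand_residues,
        "n_receptor_residues": spec.n_receptor_residues,
        "planted_bridges": [
            {"ligand_res": b.ligand_res, "receptor_res": b.receptor_res,
             "target_occupancy": b.target_occupancy,
             "closed_distance": b.closed_distance,
             "open_distance": b.open_distance}
            for b in spec.planted_bridges],
        "sigma": spec.sigma,
        "sigma_overrides": {f"{c}:{r}": v
                            for (c, r), v in spec.sigma_overrides.items()},
        "shift_event": None if spec.shift_event is None else {
            "frame": spec.shift_event.frame,
            "residues": [list(r) for r in spec.shift_event.residues],
            "displacement": list(spec.shift_event.displacement)},
        "occluders": [{"chain": o.chain, "resseq": o.resseq,
                       "n_spheres": o.n_spheres} for o in spec.occluders],
        "n_frames": spec.n_frames,
        "frame_spacing": spec.frame_spacing,
        "switching_rate": spec.switching_rate,
        "seed": spec.seed,
    }


def spec_from_dict(data: dict) -> SyntheticSpec:
    """Inverse of the YAML emitted by :func:`paper_analog_suite`."""
    ev = data.get("shift_event")
    return SyntheticSpec(
        n_ligand_residues=data.get("n_ligand_residues", 12),
        n_receptor_residues=data.get("n_receptor_residues", 14),
        planted_bridges=[PlantedBridge(b["ligand_res"], b["receptor_res"],
                                       b["target_occupancy"],
                                       b.get("closed_distance", 2.8),
                                       b.get("open_distance", 6.0))
                         for b in data.get("planted_bridges", [])],
        sigma=data.get("sigma", 0.3),
        sigma_overrides={(k.split(":")[0], int(k.split(":")[1])): float(v)
                         for k, v in data.get("sigma_overrides", {}).items()},
        shift_event=None if ev is None else ShiftEvent(
            ev["frame"], tuple((c, int(r)) for c, r in ev["residues"]),
            tuple(ev["displacement"])),
        occluders=[Occluder(o["chain"], o["resseq"], o.get("n_spheres", 1))
                   for o in data.get("occluders", [])],
        n_frames=data.get("n_frames", 200),
        frame_spacing=data.get("frame_spacing", 100.0),
        switching_rate=data.get("switching_rate", 0.8),
        seed=data.get("seed", 0),
        label=data.get("label", "toy"),
    )
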