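"""Structures, trajectories, force-field tables and atom selections.

This module defines the in-memory containers shared by every analysis stage
and the three plain-text dialects the package reads and writes:

* PDB ``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``TER`` records (single
  structures and multi-model trajectories),
* a whitespace-separated ``x y z`` frame format for compact trajectories,
* a sectioned key-value force-field parameter dialect carrying per-atom
  charges, Lennard-Jones and Generalized-Born parameters plus bonded terms.

Grammars for the two repo dialects are documented in ``docs/formats.md``.
Residue identity is the triple ``(chain_id, residue_seq, icode)`` taken
verbatim from the file; nothing is renumbered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Trajectory",
    "ForceFieldTable",
    "Selection",
    "PdbParseError",
    "FrameMismatchError",
    "CoverageError",
    "EmptySelectionError",
    "BACKBONE_ATOMS",
    "CHAIN_ROLES",
    "read_pdb",
    "write_pdb",
    "read_trajectory",
    "write_trajectory",
    "make_selection",
    "read_forcefield",
    "write_forcefield",
]

#: Heavy-atom protein backbone (hydrogens are never part of "backbone" here).
BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Valid chain role labels.
CHAIN_ROLES = ("ligand_alpha", "ligand_beta", "receptor", "other")


class PdbParseError(ValueError):
    """A PDB record could not be parsed; the message names the line."""


class FrameMismatchError(ValueError):
    """A trajectory frame has the wrong number of atoms."""


class CoverageError(ValueError):
    """A force-field file does not cover every atom of the model."""


class EmptySelectionError(ValueError):
    """A selection expression matched no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    coords: tuple[float, float, float]
    icode: str = ""

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element symbol")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


@dataclass
class StructureModel:
    """An ordered set of atoms with per-chain role labels.

    ``chain_roles`` maps each chain id to one of :data:`CHAIN_ROLES`; chains
    not present in the map default to ``"other"``.
    """

    atoms: list[AtomRecord]
    chain_roles: dict[str, str] = field(default_factory=dict)
    n_models_in_source: int = 1

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("a StructureModel needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within one model")
        for cid in self.chain_ids:
            self.chain_roles.setdefault(cid, "other")
        for cid, role in self.chain_roles.items():
            if role not in CHAIN_ROLES:
                raise ValueError(f"unknown role {role!r} for chain {cid!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions, Angstroms."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (shape (n, 3))."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coords shape ({self.n_atoms}, 3), got {coords.shape}")
        atoms = [
            AtomRecord(a.serial, a.name, a.element, a.residue_name, a.chain_id,
                       a.residue_seq, tuple(float(x) for x in xyz), a.icode)
            for a, xyz in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, dict(self.chain_roles))

    def residues(self) -> list[tuple[tuple[str, int, str], list[int]]]:
        """Residues in file order as (residue_id, atom index list)."""
        out: list[tuple[tuple[str, int, str], list[int]]] = []
        index: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            rid = a.residue_id
            if rid not in index:
                index[rid] = []
                out.append((rid, index[rid]))
            index[rid].append(i)
        return out

    def chains_with_role(self, *roles: str) -> list[str]:
        return [c for c in self.chain_ids if self.chain_roles.get(c, "other") in roles]


@dataclass
class Trajectory:
    """Ordered coordinate frames over one topology.

    ``frames`` is a (n_frames, n_atoms, 3) array in Angstroms and
    ``frame_spacing`` the time between successive frames in picoseconds.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_spacing: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise FrameMismatchError(
                f"frames carry {self.frames.shape[1]} atoms, "
                f"topology has {self.topology.n_atoms}")
        if self.frame_spacing <= 0:
            raise ValueError("frame_spacing must be positive (ps)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps; the first frame is at one spacing."""
        return self.frame_spacing * np.arange(1, self.n_frames + 1)

    @property
    def total_time(self) -> float:
        """Total simulated time in ps (n_frames x frame_spacing)."""
        return self.n_frames * self.frame_spacing


@dataclass
class ForceFieldTable:
    """Per-atom nonbonded/GB parameters and bonded term lists.

    Arrays are aligned with the topology's atom order.  Bonded terms
    reference 0-based atom indices.  Units: charge e, lj_sigma A,
    lj_epsilon kcal/mol, gb_radius A, k_b kcal/mol/A^2, k_a kcal/mol/rad^2,
    barrier kcal/mol, phase rad.
    """

    charge: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    gb_radius: np.ndarray
    gb_scale: np.ndarray
    bonds: list[tuple[int, int, float, float]] = field(default_factory=list)
    angles: list[tuple[int, int, int, float, float]] = field(default_factory=list)
    dihedrals: list[tuple[int, int, int, int, float, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("charge", "lj_sigma", "lj_epsilon", "gb_radius", "gb_scale"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.n_atoms
        if any(arr.shape != (n,) for arr in
               (self.lj_sigma, self.lj_epsilon, self.gb_radius, self.gb_scale)):
            raise ValueError("per-atom parameter arrays must share one length")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be non-negative")
        if np.any(self.gb_radius <= 0):
            raise ValueError("gb_radius must be positive")
        for b in self.bonds:
            self._check_indices(b[:2], n, "bond")
        for a in self.angles:
            self._check_indices(a[:3], n, "angle")
        for d in self.dihedrals:
            self._check_indices(d[:4], n, "dihedral")
            if int(d[5]) < 1:
                raise ValueError("dihedral periodicity must be >= 1")

    @staticmethod
    def _check_indices(idx, n: int, kind: str) -> None:
        for i in idx:
            if not 0 <= int(i) < n:
                raise IndexError(f"{kind} references atom index {i} outside 0..{n - 1}")

    @property
    def n_atoms(self) -> int:
        return int(np.asarray(self.charge).shape[0])

    def subset(self, indices: np.ndarray) -> "ForceFieldTable":
        """Parameters restricted to ``indices``; bonded terms fully inside
        the subset are kept and re-indexed, terms crossing it are dropped."""
        indices = np.asarray(indices, dtype=int)
        remap = {int(old): new for new, old in enumerate(indices)}
        keep = set(remap)

        def inside(ids):
            return all(int(i) in keep for i in ids)

        return ForceFieldTable(
            charge=self.charge[indices],
            lj_sigma=self.lj_sigma[indices],
            lj_epsilon=self.lj_epsilon[indices],
            gb_radius=self.gb_radius[indices],
            gb_scale=self.gb_scale[indices],
            bonds=[(remap[i], remap[j], kb, r0)
                   for i, j, kb, r0 in self.bonds if inside((i, j))],
            angles=[(remap[i], remap[j], remap[k], ka, t0)
                    for i, j, k, ka, t0 in self.angles if inside((i, j, k))],
            dihedrals=[(remap[i], remap[j], remap[k], remap[l], v, n_, ph)
                       for i, j, k, l, v, n_, ph in self.dihedrals if inside((i, j, k, l))],
        )


@dataclass(frozen=True)
class Selection:
    """A named, ordered, duplicate-free set of atom indices into a topology."""

    name: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise ValueError("selection indices must be unique")

    def __len__(self) -> int:
        return len(self.atom_indices)

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.atom_indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading/writing


def _parse_atom_line(line: str, lineno: int) -> AtomRecord | None:
    """Parse one ATOM/HETATM line; None for skipped altlocs."""
    altloc = line[16:17].strip()
    if altloc not in ("", "A"):
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        residue_seq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the atom-name convention: first alphabetic character
        element = next((c for c in name if c.isalpha()), "C").upper()
    return AtomRecord(serial, name, element, residue_name, chain_id,
                      residue_seq, (x, y, z), icode)


def read_pdb(path: str | Path) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations other than blank/'A' are dropped.  The number of
    MODEL records seen in the file is reported on
    ``StructureModel.n_models_in_source``.
    """
    atoms: list[AtomRecord] = []
    n_models = 0
    in_first_model = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                n_models += 1
                in_first_model = n_models == 1
            elif rec == "ENDMDL":
                in_first_model = False
            elif rec in ("ATOM  ", "HETATM") and in_first_model:
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    atoms.append(atom)
    if not atoms:
        raise PdbParseError(f"{path}: no atoms found")
    model = StructureModel(atoms)
    model.n_models_in_source = max(n_models, 1)
    return model


def _format_atom_line(a: AtomRecord, coords) -> str:
    name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
    return (f"ATOM  {a.serial:>5d} {name:<4.4s} {a.residue_name:<3.3s} "
            f"{a.chain_id:1.1s}{a.residue_seq:>4d}{a.icode:<1.1s}   "
            f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
            f"  1.00  0.00          {a.element:>2.2s}")


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB file (coordinates to 3 decimals)."""
    lines = [_format_atom_line(a, a.coords) for a in model.atoms]
    lines += ["TER", "END", ""]
    Path(path).write_text("\n".join(lines))


def read_trajectory(path: str | Path, topology: StructureModel,
                    spacing_ps: float) -> Trajectory:
    """Read a trajectory: multi-model PDB or the xyz frame dialect.

    The format is sniffed from the first non-blank line: PDB record names
    select the PDB reader, anything else the plain-coordinate reader.  Every
    frame must carry exactly ``topology.n_atoms`` atoms.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
    if first[:6] in ("MODEL ", "ATOM  ", "HETATM", "REMARK", "TER   ", "HEADER"):
        frames = _read_pdb_frames(path)
    else:
        frames = _read_xyz_frames(path)
    n = topology.n_atoms
    for k, fr in enumerate(frames):
        if len(fr) != n:
            raise FrameMismatchError(f"frame {k}: expected {n} atoms, got {len(fr)}")
    if not frames:
        raise FrameMismatchError(f"{path}: no frames found")
    return Trajectory(topology, np.asarray(frames, dtype=float), spacing_ps)


def _read_pdb_frames(path: str | Path) -> list[list[tuple[float, float, float]]]:
    frames: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] | None = None
    saw_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                current = []
            elif rec == "ENDMDL":
                if current is not None:
                    frames.append(current)
                current = None
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    if saw_model:
                        continue  # atoms outside MODEL blocks in a multi-model file
                    current = []
                atom = _parse_atom_line(line, lineno)
                if atom is not None:
                    current.append(atom.coords)
    if current:
        frames.append(current)
    return frames


def _read_xyz_frames(path: str | Path) -> list[list[tuple[float, float, float]]]:
    """Frame dialect: ``n_atoms comment...`` header then n_atoms ``x y z`` rows."""
    frames: list[list[tuple[float, float, float]]] = []
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    pos = 0
    while pos < len(lines):
        try:
            n = int(lines[pos].split()[0])
        except ValueError:
            raise PdbParseError(f"frame header expected at block starting {lines[pos]!r}")
        block = lines[pos + 1: pos + 1 + n]
        frame = []
        for row in block:
            parts = row.split()
            frame.append((float(parts[0]), float(parts[1]), float(parts[2])))
        frames.append(frame)
        pos += 1 + n
    return frames


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB (``fmt='pdb'``) or xyz frames."""
    path = Path(path)
    if fmt == "pdb":
        lines: list[str] = []
        for k in range(traj.n_frames):
            lines.append(f"MODEL {k + 1:>8d}")
            lines.extend(_format_atom_line(a, xyz)
                         for a, xyz in zip(traj.topology.atoms, traj.frames[k]))
            lines.append("ENDMDL")
        lines += ["END", ""]
        path.write_text("\n".join(lines))
    elif fmt == "xyz":
        lines = []
        for k in range(traj.n_frames):
            lines.append(f"{traj.topology.n_atoms} frame {k}")
            lines.extend(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in traj.frames[k])
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# Selections


def make_selection(model: StructureModel, spec: str, name: str | None = None) -> Selection:
    """Build a named atom selection from a small expression language.

    Clauses joined by ``and`` intersect; each clause is one of::

        all | calpha | backbone | heavy | protein
        chain <id>[,<id>...]
        resseq <n> | resseq <lo>-<hi>
        name <atom-name>[,<atom-name>...]
        role <role>[,<role>...]

    Raises :class:`EmptySelectionError` when no atom matches (every
    downstream stage needs at least one atom).
    """
    mask = np.ones(model.n_atoms, dtype=bool)
    for clause in [c.strip() for c in spec.split(" and ")]:
        if not clause:
            continue
        parts = clause.split()
        key = parts[0].lower()
        if key == "all":
            pass
        elif key == "calpha":
            mask &= np.array([a.name == "CA" for a in model.atoms])
        elif key == "backbone":
            mask &= np.array([a.name in BACKBONE_ATOMS for a in model.atoms])
        elif key == "heavy":
            mask &= np.array([a.element != "H" for a in model.atoms])
        elif key == "protein":
            mask &= np.array([a.residue_name != "GLX" for a in model.atoms])
        elif key == "chain":
            wanted = set(",".join(parts[1:]).split(","))
            mask &= np.array([a.chain_id in wanted for a in model.atoms])
        elif key == "resseq":
            arg = parts[1]
            if "-" in arg[1:]:  # range; a leading '-' alone is a negative number
                cut = arg.index("-", 1)
                lo_i, hi_i = int(arg[:cut]), int(arg[cut + 1:])
            else:
                lo_i = hi_i = int(arg)
            mask &= np.array([lo_i <= a.residue_seq <= hi_i for a in model.atoms])
        elif key == "name":
            wanted = set(",".join(parts[1:]).split(","))
            mask &= np.array([a.name in wanted for a in model.atoms])
        elif key == "role":
            wanted = set(",".join(parts[1:]).split(","))
            chains = {c for c in model.chain_ids
                      if model.chain_roles.get(c, "other") in wanted}
            mask &= np.array([a.chain_id in chains for a in model.atoms])
        else:
            raise ValueError(f"unknown selection clause {clause!r}")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise EmptySelectionError(f"selection {spec!r} matched no atoms")
    return Selection(name or spec, tuple(int(i) for i in idx))


# ---------------------------------------------------------------------------
# Force-field parameter dialect


def read_forcefield(path: str | Path, model: StructureModel) -> ForceFieldTable:
    """Read the sectioned key-value parameter dialect (docs/formats.md).

    ``[atoms]`` rows are keyed by ``chain resseq atom_name`` and must cover
    every atom of ``model``; bonded sections reference atom serial numbers.
    """
    sections: dict[str, list[list[str]]] = {"atoms": [], "bonds": [], "angles": [], "dihedrals": []}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip().lower()
                if current not in sections:
                    raise ValueError(f"line {lineno}: unknown section [{current}]")
                continue
            if current is None:
                raise ValueError(f"line {lineno}: data before any section header")
            sections[current].append(line.split())

    key_to_index: dict[tuple[str, int, str], int] = {}
    serial_to_index: dict[int, int] = {}
    for i, a in enumerate(model.atoms):
        key_to_index[(a.chain_id, a.residue_seq, a.name)] = i
        serial_to_index[a.serial] = i

    n = model.n_atoms
    charge = np.full(n, np.nan)
    sigma = np.full(n, np.nan)
    eps = np.full(n, np.nan)
    gb_r = np.full(n, np.nan)
    gb_s = np.full(n, np.nan)
    for row in sections["atoms"]:
        chain, resseq, name = row[0], int(row[1]), row[2]
        idx = key_to_index.get((chain, resseq, name))
        if idx is None:
            continue  # parameters for atoms absent from this model are ignored
        charge[idx], sigma[idx], eps[idx], gb_r[idx], gb_s[idx] = map(float, row[3:8])
    missing = [model.atoms[i] for i in np.flatnonzero(np.isnan(charge))]
    if missing:
        desc = ", ".join(f"{a.chain_id}/{a.residue_seq}/{a.name}" for a in missing[:10])
        raise CoverageError(f"force-field file misses {len(missing)} atoms: {desc}")

    def serial(tok: str, lineno_hint: str) -> int:
        s = int(tok)
        if s not in serial_to_index:
            raise IndexError(f"{lineno_hint} references unknown atom serial {s}")
        return serial_to_index[s]

    bonds = [(serial(r[0], "bond"), serial(r[1], "bond"), float(r[2]), float(r[3]))
             for r in sections["bonds"]]
    angles = [(serial(r[0], "angle"), serial(r[1], "angle"), serial(r[2], "angle"),
               float(r[3]), float(r[4])) for r in sections["angles"]]
    dihedrals = [(serial(r[0], "dihedral"), serial(r[1], "dihedral"),
                  serial(r[2], "dihedral"), serial(r[3], "dihedral"),
                  float(r[4]), int(r[5]), float(r[6])) for r in sections["dihedrals"]]
    return ForceFieldTable(charge, sigma, eps, gb_r, gb_s, bonds, angles, dihedrals)


def write_forcefield(ff: ForceFieldTable, model: StructureModel, path: str | Path) -> None:
    """Write the parameter dialect for ``model`` (inverse of read_forcefield)."""
    idx_to_serial = [a.serial for a in model.atoms]
    lines = ["[atoms]", "# chain resseq name charge lj_sigma lj_epsilon gb_radius gb_scale"]
    for i, a in enumerate(model.atoms):
        lines.append(f"{a.chain_id} {a.residue_seq} {a.name} "
                     f"{ff.charge[i]:.6f} {ff.lj_sigma[i]:.6f} {ff.lj_epsilon[i]:.6f} "
                     f"{ff.gb_radius[i]:.6f} {ff.gb_scale[i]:.6f}")
    lines.append("[bonds]")
    for i, j, kb, r0 in ff.bonds:
        lines.append(f"{idx_to_serial[i]} {idx_to_serial[j]} {kb:.6f} {r0:.6f}")
    lines.append("[angles]")
    for i, j, k, ka, t0 in ff.angles:
        lines.append(f"{idx_to_serial[i]} {idx_to_serial[j]} {idx_to_serial[k]} {ka:.6f} {t0:.6f}")
    lines.append("[dihedrals]")
    for i, j, k, l, v, per, ph in ff.dihedrals:
        lines.append(f"{idx_to_serial[i]} {idx_to_serial[j]} {idx_to_serial[k]} "
                     f"{idx_to_serial[l]} {v:.6f} {per} {ph:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
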