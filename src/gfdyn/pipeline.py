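"""Glycoform-comparison pipeline: one config in, a report bundle out.

Runs every analysis stage (RMSD, residue shift classes, RMSF + flexibility
bands, salt-bridge persistence, SASA averaging, MM-GBSA summary) for each
configured system, then differences every non-baseline system against the
baseline (RMSF and SASA per residue, GBTOT pairwise), writes CSV reports
plus a text summary, and records a manifest with input/output checksums so
an unchanged config reproduces identical bytes.

The module also carries the published reference component table for the
five glycoform systems (``load_reference_energy_table``) used by the
table-ledger validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import EnergyModelConfig, EnergySummary, mmgbsa_summary
from .fluctuation import flexibility_bands, rmsf_difference, rmsf_profile
from .saltbridges import (bridge_distance_series, bridge_statistics,
                          default_stride, find_salt_bridges)
from .sasa import sasa_difference, sasa_trajectory
from .structure_io import (make_selection, read_forcefield, read_pdb,
                           read_trajectory)
from .superposition import classify_residue_shifts, rmsd_series

__all__ = [
    "RunConfig",
    "SystemConfig",
    "RunManifest",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "compare_energies",
    "validate_energy_table",
    "load_reference_energy_table",
]

log = logging.getLogger("gfdyn")


class ConfigError(ValueError):
    """The run configuration is invalid; nothing was computed."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class SystemConfig:
    name: str
    structure: str
    trajectory: str
    forcefield: str
    chain_roles: dict[str, str]
    frame_spacing: float = 100.0


@dataclass
class Thresholds:
    shift: float = 1.5          # A, settled backbone shift
    rmsf_diff: float = 0.50     # A, glycoform RMSF difference flag
    bridge_cutoff: float = 3.5  # A, salt-bridge occupancy cutoff
    sasa_diff: float = 40.0     # A^2, SASA difference highlight
    contact: float = 4.5        # A, heavy-atom interface contact

    def validate(self) -> None:
        for name, v in vars(self).items():
            if v <= 0:
                raise ConfigError(f"threshold {name} must be positive, got {v}")


@dataclass
class RunConfig:
    systems: list[SystemConfig]
    baseline: str
    output_dir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    skip_fraction: float = 0.125
    sasa_stride: int = 10
    snapshot_interval: float = 1000.0
    energy_mode: str = "absolute"
    energy: EnergyModelConfig = field(default_factory=EnergyModelConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            systems = [SystemConfig(name=s["name"], structure=s["structure"],
                                    trajectory=s["trajectory"],
                                    forcefield=s["forcefield"],
                                    chain_roles=dict(s.get("chain_roles", {})),
                                    frame_spacing=float(s.get("frame_spacing", 100.0)))
                       for s in data["systems"]]
            thresholds = Thresholds(**data.get("thresholds", {}))
            energy = EnergyModelConfig(**data.get("energy", {}))
            cfg = cls(systems=systems, baseline=data["baseline"],
                      output_dir=data["output_dir"], thresholds=thresholds,
                      skip_fraction=float(data.get("skip_fraction", 0.125)),
                      sasa_stride=int(data.get("sasa_stride", 10)),
                      snapshot_interval=float(data.get("snapshot_interval", 1000.0)),
                      energy_mode=data.get("energy_mode", "absolute"),
                      seed=int(data.get("seed", 0)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.systems:
            raise ConfigError("no systems configured")
        names = [s.name for s in self.systems]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate system names")
        if self.baseline not in names:
            raise ConfigError(f"baseline {self.baseline!r} not among systems {names}")
        self.thresholds.validate()
        if not 0.0 <= self.skip_fraction < 1.0:
            raise ConfigError("skip_fraction must lie in [0, 1)")
        if self.energy_mode not in ("absolute", "binding"):
            raise ConfigError(f"unknown energy mode {self.energy_mode!r}")
        for s in self.systems:
            for path in (s.structure, s.trajectory, s.forcefield):
                if not Path(path).exists():
                    raise ConfigError(f"system {s.name}: missing input file {path}")

    def canonical_dict(self) -> dict:
        return {
            "systems": [{**vars(s)} for s in self.systems],
            "baseline": self.baseline,
            "thresholds": vars(self.thresholds),
            "skip_fraction": self.skip_fraction,
            "sasa_stride": self.sasa_stride,
            "snapshot_interval": self.snapshot_interval,
            "energy_mode": self.energy_mode,
            "energy": {k: getattr(self.energy, k)
                       for k in ("interior_dielectric", "solvent_dielectric",
                                 "gamma", "beta", "gb_model")},
            "seed": self.seed,
        }


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], elapsed: float,
               ok: bool = True) -> None:
        self.stages[stage] = {
            "outputs": {str(p): _sha256(p) for p in outputs},
            "elapsed_s": round(elapsed, 4),
            "ok": ok,
        }

    def write(self, path: Path) -> None:
        payload = {"config_hash": self.config_hash, "version": self.version,
                   "stages": self.stages}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _load_system(sys_cfg: SystemConfig):
    model = read_pdb(sys_cfg.structure)
    for chain, role in sys_cfg.chain_roles.items():
        model.chain_roles[chain] = role
    traj = read_trajectory(sys_cfg.trajectory, model, sys_cfg.frame_spacing)
    ff = read_forcefield(sys_cfg.forcefield, model)
    return model, traj, ff


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages for every system plus cross-system differences."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    canon = json.dumps(config.canonical_dict(), sort_keys=True)
    manifest = RunManifest(hashlib.sha256(canon.encode()).hexdigest(),
                           __version__)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)

    rmsf_profiles: dict[str, object] = {}
    sasa_profiles: dict[str, object] = {}
    summaries: dict[str, EnergySummary] = {}
    try:
        for sys_cfg in config.systems:
            _run_system(sys_cfg, config, outdir, manifest,
                        rmsf_profiles, sasa_profiles, summaries)
        _run_differences(config, outdir, manifest,
                         rmsf_profiles, sasa_profiles, summaries)
    finally:
        manifest.write(outdir / "manifest.json")
        log.removeHandler(fh)
        fh.close()
    return manifest


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            self.outputs: list[Path] = []
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = time.perf_counter() - self.t0
            ok = exc_type is None
            manifest.record(name, self.outputs, elapsed, ok=ok)
            log.info("stage %s: %s (%.2fs)", name, "ok" if ok else "FAILED", elapsed)
            if not ok:
                raise StageError(f"stage {name} failed: {exc}") from exc
            return False
    return _Ctx()


def _run_system(sys_cfg: SystemConfig, config: RunConfig, outdir: Path,
                manifest: RunManifest, rmsf_profiles, sasa_profiles,
                summaries) -> None:
    name = sys_cfg.name
    model, traj, ff = _load_system(sys_cfg)
    lig_chains = model.chains_with_role("ligand_alpha", "ligand_beta")
    rec_chains = model.chains_with_role("receptor")
    lig_expr = "chain " + ",".join(lig_chains)
    rec_expr = "chain " + ",".join(rec_chains)

    with _stage(manifest, f"{name}:rmsd") as st:
        # glycoform preset: RMSD over the hormone backbone only
        sel = make_selection(model, f"backbone and {lig_expr}", name="ligand_backbone")
        series = rmsd_series(traj, sel, reference=None)
        df = pd.DataFrame({"time_ps": series.times, "rmsd_A": series.values})
        p = outdir / f"{name}_rmsd.csv"
        df.to_csv(p, index=False, float_format="%.4f")
        st.outputs.append(p)

    with _stage(manifest, f"{name}:shifts") as st:
        lig_sel = make_selection(model, lig_expr, name="ligand")
        rec_sel = make_selection(model, rec_expr, name="receptor")
        classes = classify_residue_shifts(
            traj, model, lig_sel, rec_sel,
            shift_threshold=config.thresholds.shift,
            contact_cutoff=config.thresholds.contact,
            skip_fraction=config.skip_fraction)
        df = pd.DataFrame([{"chain": c.residue_id[0], "resseq": c.residue_id[1],
                            "shift_A": round(c.max_backbone_shift, 4),
                            "interface": c.is_interface, "class": c.class_label}
                           for c in classes])
        p = outdir / f"{name}_shifts.csv"
        df.to_csv(p, index=False)
        st.outputs.append(p)

    with _stage(manifest, f"{name}:rmsf") as st:
        calpha = make_selection(model, "calpha", name="calpha")
        start = int(np.floor(config.skip_fraction * traj.n_frames))
        prof = rmsf_profile(traj, calpha, window=(start, traj.n_frames), label=name)
        bands = {b.residue_id: b.band for b in flexibility_bands(prof)}
        df = pd.DataFrame([{"chain": rid[0], "resseq": rid[1],
                            "rmsf_A": round(float(v), 4), "band": bands[rid]}
                           for rid, v in zip(prof.residue_ids, prof.rmsf)])
        p = outdir / f"{name}_rmsf.csv"
        df.to_csv(p, index=False)
        st.outputs.append(p)
        rmsf_profiles[name] = prof

    with _stage(manifest, f"{name}:bridges") as st:
        pairs = find_salt_bridges(model, lig_chains, rec_chains)
        stride = default_stride(traj.frame_spacing)
        rows = []
        for pair in pairs:
            series = bridge_distance_series(traj, pair, stride=stride)
            stat = bridge_statistics(series, cutoff=config.thresholds.bridge_cutoff,
                                     pair=pair)
            rows.append({"cation_chain": pair.cation_residue[0],
                         "cation_res": pair.cation_residue[1],
                         "anion_chain": pair.anion_residue[0],
                         "anion_res": pair.anion_residue[1],
                         "median_A": round(stat.median_distance, 2),
                         "occupancy_pct": stat.occupancy_pct,
                         "n_samples": stat.n_samples})
        p = outdir / f"{name}_bridges.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        st.outputs.append(p)

    with _stage(manifest, f"{name}:sasa") as st:
        prof = sasa_trajectory(traj, skip_fraction=config.skip_fraction,
                               stride=config.sasa_stride,
                               n_points=config.energy.sasa_n_points, label=name)
        df = pd.DataFrame([{"chain": rid[0], "resseq": rid[1],
                            "sasa_A2": round(float(v), 3)}
                           for rid, v in zip(prof.residue_ids, prof.mean_sasa)])
        p = outdir / f"{name}_sasa.csv"
        df.to_csv(p, index=False)
        st.outputs.append(p)
        sasa_profiles[name] = prof

    with _stage(manifest, f"{name}:energy") as st:
        summary = mmgbsa_summary(traj, ff, config.energy,
                                 snapshot_interval=config.snapshot_interval,
                                 mode=config.energy_mode, label=name)
        if isinstance(summary, dict):
            report = summary["delta"]
        else:
            report = summary
        rows = [{"component": k, "mean": round(m, 2), "sd": round(s, 2),
                 "formatted": f"{m:.2f} ({s:.2f})"}
                for k, (m, s) in report.table_rows().items()]
        p = outdir / f"{name}_energy.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        st.outputs.append(p)
        summaries[name] = report


def _run_differences(config: RunConfig, outdir: Path, manifest: RunManifest,
                     rmsf_profiles, sasa_profiles, summaries) -> None:
    base = config.baseline
    others = [s.name for s in config.systems if s.name != base]

    with _stage(manifest, "differences") as st:
        for name in others:
            diff = rmsf_difference(rmsf_profiles[name], rmsf_profiles[base],
                                   threshold=config.thresholds.rmsf_diff)
            df = pd.DataFrame([{"chain": rid[0], "resseq": rid[1],
                                "delta_A": round(float(d), 4), "flagged": bool(f)}
                               for rid, d, f in zip(diff.residue_ids, diff.delta,
                                                    diff.flagged)])
            p = outdir / f"{name}_vs_{base}_rmsf_diff.csv"
            df.to_csv(p, index=False)
            st.outputs.append(p)

            sdiff = sasa_difference(sasa_profiles[name], sasa_profiles[base],
                                    cutoff=config.thresholds.sasa_diff)
            df = pd.DataFrame([{"chain": rid[0], "resseq": rid[1],
                                "delta_A2": round(float(d), 3),
                                "highlighted": bool(h)}
                               for rid, d, h in zip(sdiff.residue_ids, sdiff.delta,
                                                    sdiff.highlighted)])
            p = outdir / f"{name}_vs_{base}_sasa_diff.csv"
            df.to_csv(p, index=False)
            st.outputs.append(p)

    with _stage(manifest, "energy_comparison") as st:
        table = compare_energies(list(summaries.values()))
        p = outdir / "energy_comparison.csv"
        table.to_csv(p, index=False, float_format="%.2f")
        st.outputs.append(p)

        lines = [f"gfdyn {__version__} summary", ""]
        for name, summ in summaries.items():
            rows = summ.table_rows()
            lines.append(f"[{name}] n_snapshots={summ.n_snapshots}")
            for comp, (m, s) in rows.items():
                lines.append(f"  {comp:6s} {m:12.2f} ({s:.2f})")
            lines.append("")
        for name in (s.name for s in config.systems):
            if name in rmsf_profiles:
                lines.append(f"mean RMSF {name}: {_fmt(rmsf_profiles[name].mean_rmsf)} A")
        p = outdir / "summary.txt"
        p.write_text("\n".join(lines) + "\n")
        st.outputs.append(p)


def compare_energies(summaries, labels: list[str] | None = None) -> pd.DataFrame:
    """Pairwise GBTOT differences with independence-propagated sd.

    Accepts :class:`EnergySummary` objects or ``(label, mean, sd)``
    triples; returns one row per unordered pair with the difference
    (first minus second), its magnitude, and sqrt(sd_a^2 + sd_b^2).
    """
    entries: list[tuple[str, float, float]] = []
    for i, s in enumerate(summaries):
        if isinstance(s, EnergySummary):
            m, sd = s.table_rows()["GBTOT"]
            entries.append((s.label or f"system{i}", m, sd))
        else:
            entries.append((str(s[0]), float(s[1]), float(s[2])))
    if labels is not None:
        entries = [(lab, m, sd) for lab, (_, m, sd) in zip(labels, entries)]
    if len(entries) < 2:
        raise ValueError("need at least two summaries to compare")
    rows = []
    for (la, ma, sa), (lb, mb, sb) in combinations(entries, 2):
        diff = ma - mb
        rows.append({"system_a": la, "system_b": lb,
                     "gbtot_a": ma, "gbtot_b": mb,
                     "difference": diff, "magnitude": abs(diff),
                     "sd": float(np.hypot(sa, sb))})
    return pd.DataFrame(rows)


def load_reference_energy_table() -> pd.DataFrame:
    """Published MM-GBSA component table for the five glycoform systems."""
    text = resources.files("gfdyn.data").joinpath("reference_energy_table.csv")
    with resources.as_file(text) as p:
        return pd.read_csv(p)


def validate_energy_table(table: pd.DataFrame, tolerance: float = 0.02) -> pd.DataFrame:
    """Check GBTOT = INT + ELE + VDW + GBSOL per row within ``tolerance``.

    ``table`` is either wide (columns system, INT, ELE, VDW, GBSOL, GBTOT;
    one row per system) or the pipeline's long per-system layout (columns
    component, mean); returns a frame with the residual and a pass flag
    per system.
    """
    if {"component", "mean"} <= set(table.columns):
        by = dict(zip(table["component"], table["mean"]))
        table = pd.DataFrame([{"system": "table", **by}])
    required = {"system", "INT", "ELE", "VDW", "GBSOL", "GBTOT"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    resid = (table["INT"] + table["ELE"] + table["VDW"] + table["GBSOL"]
             - table["GBTOT"])
    return pd.DataFrame({"system": table["system"],
                         "residual": resid.round(6),
                         "passed": resid.abs() <= tolerance})
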