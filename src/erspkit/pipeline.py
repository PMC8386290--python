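"""Config-driven end-to-end orchestration and file I/O.

Stages: simulate (or load) epoched EEG → Hanning-taper ERSP per subject ×
condition → per-subject S3−S1 difference matrices → trial-sufficiency
diagnostics → per-band cluster permutation tests → cluster-mean extraction →
vocabulary regression.  Each stage is an importable function so persisted
intermediates can be re-analysed in isolation; ``run_pipeline`` composes
them and writes a manifest.

File formats: epochs live in an HDF5 container (one group per subject ×
condition, channel names / sampling rate / onset index as attributes),
electrode layouts in ``.sfp``-style text (``label x y z`` per line),
behavior tables as TSV, cluster results and the run manifest as JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import (NeighborGraph, PermutationResult, SubjectDifference,
                      cluster_mean_extract, subject_difference,
                      triangulation_neighbors)
from .reliability import ReliabilityMap, mean_median_agreement, trial_count_reliability
from .simulate import (ChannelLayout, Cohort, EpochSet, SimulationConfig,
                       make_layout, simulate_cohort)
from .spectral import (DEFAULT_BANDS, BandSpec, FrequencyGrid, TFR,
                       baseline_db, hanning_tfr)
from .stats import DEFAULT_TERMS, RegressionFit, ols_fit

log = logging.getLogger("erspkit")


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class PipelineConfig:
    """End-to-end run settings (YAML-loadable)."""

    mode: str = "simulate"                 # "simulate" | "load"
    seed: int | None = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    epochs_path: str | None = None         # load mode
    layout_path: str | None = None
    behavior_path: str | None = None
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)
    baseline_window: tuple[float, float] = (-0.5, 0.0)
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    n_perm: int = 1000
    cluster_alpha: float = 0.05
    cycles: float = 3.0
    t_cap: float = 0.5
    decim_ms: float = 2.0
    reliability_electrode: str = "CP1"
    reliability_counts: list[int] | None = None
    reliability_draws: int = 50
    regression_terms: tuple[str, ...] = DEFAULT_TERMS
    layout_channels: list[str] | None = None  # simulate on a montage subset
    save_epochs: bool = False
    save_null: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "simulate" and self.seed is None:
            raise ValueError("seed is mandatory in simulate mode")
        fmin, fmax = self.grid.f_min, self.grid.f_max
        for b in self.bands:
            if b.f_lo < fmin - 1e-9 or b.f_hi > fmax + 1e-9:
                raise ValueError(f"band {b.name} outside frequency grid")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw = dict(raw)
        if "simulation" in kw and isinstance(kw["simulation"], dict):
            sim = dict(kw["simulation"])
            if "effects" in sim:
                from .simulate import EffectSpec
                sim["effects"] = tuple(
                    EffectSpec(**{**e, "channels": tuple(e["channels"]),
                                  "time_window": tuple(e["time_window"])})
                    for e in sim["effects"])
            if "behavior" in sim and isinstance(sim["behavior"], dict):
                from .simulate import BehaviorLink
                sim["behavior"] = BehaviorLink(**sim["behavior"])
            if "epoch_window" in sim:
                sim["epoch_window"] = tuple(sim["epoch_window"])
            kw["simulation"] = SimulationConfig(**sim)
        if "grid" in kw and isinstance(kw["grid"], dict):
            kw["grid"] = FrequencyGrid(**kw["grid"])
        if "bands" in kw:
            kw["bands"] = tuple(
                b if isinstance(b, BandSpec) else BandSpec(**b) for b in kw["bands"])
        if "baseline_window" in kw:
            kw["baseline_window"] = tuple(kw["baseline_window"])
        if "regression_terms" in kw:
            kw["regression_terms"] = tuple(kw["regression_terms"])
        return cls(**kw)

    def to_dict(self) -> dict:
        def enc(o):
            if isinstance(o, (FrequencyGrid, BandSpec)):
                return {k: getattr(o, k) for k in o.__dataclass_fields__}
            if isinstance(o, SimulationConfig):
                d = {k: getattr(o, k) for k in o.__dataclass_fields__}
                d["effects"] = [
                    {**{k: getattr(e, k) for k in e.__dataclass_fields__},
                     "channels": list(e.channels),
                     "time_window": list(e.time_window)}
                    for e in o.effects]
                d["behavior"] = {k: getattr(o.behavior, k)
                                 for k in o.behavior.__dataclass_fields__}
                d["epoch_window"] = list(o.epoch_window)
                return d
            return o
        d = {k: enc(getattr(self, k)) for k in self.__dataclass_fields__}
        d["grid"] = enc(self.grid)
        d["bands"] = [enc(b) for b in self.bands]
        d["baseline_window"] = list(self.baseline_window)
        d["regression_terms"] = list(self.regression_terms)
        return d


# ---------------------------------------------------------------------------
# File I/O

def write_layout(layout: ChannelLayout, path: str | Path) -> None:
    """Write electrodes as .sfp-style text: ``label x y z`` per line."""
    lines = [f"{n}\t{p[0]:.6f}\t{p[1]:.6f}\t{p[2]:.6f}"
             for n, p in zip(layout.channel_names, layout.positions)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path: str | Path) -> ChannelLayout:
    """Read a whitespace-delimited ``label x y z`` electrode file; header or
    comment lines that do not parse as coordinates are skipped with a log
    message."""
    names, pos = [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if len(parts) != 4:
            if line.strip():
                log.info("layout %s: skipping line %d: %r", path, ln, line)
            continue
        try:
            xyz = [float(v) for v in parts[1:]]
        except ValueError:
            log.info("layout %s: skipping header line %d: %r", path, ln, line)
            continue
        names.append(parts[0])
        pos.append(xyz)
    if len(names) < 3:
        raise ValueError(f"layout file {path} has fewer than 3 channels")
    return ChannelLayout(tuple(names), np.array(pos))


def write_epochs(cohort_epochs: dict, layout: ChannelLayout,
                 path: str | Path) -> None:
    """Persist a cohort of EpochSets to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["channel_names"] = json.dumps(list(layout.channel_names))
        f.create_dataset("layout_positions", data=layout.positions)
        for (sid, cond), ep in sorted(cohort_epochs.items()):
            g = f.create_group(f"{sid}/{cond}")
            g.create_dataset("data", data=ep.data, compression="gzip",
                             compression_opts=1)
            g.attrs["subject_id"] = sid
            g.attrs["group"] = ep.group
            g.attrs["condition"] = cond
            g.attrs["sampling_rate"] = ep.sfreq
            g.attrs["t0_index"] = ep.t0_index


def read_epochs(path: str | Path) -> tuple[dict, ChannelLayout]:
    """Load a cohort of EpochSets from an HDF5 container."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        if "channel_names" not in f.attrs or "layout_positions" not in f:
            raise ValueError(f"{path}: missing channel_names/layout_positions")
        names = tuple(json.loads(f.attrs["channel_names"]))
        layout = ChannelLayout(names, np.asarray(f["layout_positions"]))
        for sid in f:
            if sid == "layout_positions":
                continue
            for cond in f[sid]:
                g = f[f"{sid}/{cond}"]
                for attr in ("sampling_rate", "t0_index", "group"):
                    if attr not in g.attrs:
                        raise ValueError(f"{path}: {sid}/{cond} missing {attr}")
                data = np.asarray(g["data"])
                if data.shape[1] != len(names):
                    raise ValueError(
                        f"{path}: {sid}/{cond} has {data.shape[1]} channels, "
                        f"layout has {len(names)}")
                out[(sid, cond)] = EpochSet(
                    sid, str(g.attrs["group"]), cond, data,
                    float(g.attrs["sampling_rate"]), int(g.attrs["t0_index"]),
                    layout)
    return out, layout


def write_behavior(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Stages

def stage_differences(epochs: dict, config: PipelineConfig) -> list[SubjectDifference]:
    """Trial-averaged ERSP per condition, then S3 − S1 per subject."""
    sids = sorted({k[0] for k in epochs})
    diffs = []
    for sid in sids:
        if (sid, "S1") not in epochs or (sid, "S3") not in epochs:
            raise ValueError(f"subject {sid}: missing S1 or S3 epochs")
        ersp = {}
        for cond in ("S1", "S3"):
            tfr = hanning_tfr(epochs[(sid, cond)], config.grid,
                              cycles=config.cycles, t_cap=config.t_cap,
                              decim_ms=config.decim_ms, average=True)
            ersp[cond] = baseline_db(tfr, config.baseline_window)
        diffs.append(subject_difference(ersp["S3"], ersp["S1"], sid,
                                        epochs[(sid, "S1")].group))
    return diffs


def stage_reliability(epochs: dict, config: PipelineConfig,
                      seed: int | np.random.SeedSequence | None = None) -> dict:
    """Mean–median agreement and the frequency-by-trial-count map for the
    subject with the fewest trials (worst case), at the configured electrode."""
    electrode = config.reliability_electrode
    candidates = {k: v for k, v in epochs.items() if k[1] == "S1"}
    key = min(candidates, key=lambda k: candidates[k].n_trials)
    ep = candidates[key]
    if electrode not in ep.layout.channel_names:
        raise ValueError(f"reliability electrode {electrode!r} not in layout")
    tfr = hanning_tfr(ep, config.grid, cycles=config.cycles,
                      t_cap=config.t_cap, decim_ms=max(config.decim_ms, 10.0),
                      channels=[electrode])
    rel_map = trial_count_reliability(
        tfr, electrode, counts=config.reliability_counts,
        n_draws=config.reliability_draws, seed=seed)
    mm = mean_median_agreement(tfr)
    return {"subject_id": key[0], "n_trials": ep.n_trials,
            "mean_median_r": mm, "map": rel_map}


def stage_cluster(diffs: list[SubjectDifference], neighbors: NeighborGraph,
                  config: PipelineConfig,
                  seed: int | None = None) -> dict:
    """Per-band cluster permutation tests (group A vs group B)."""
    from .cluster import permutation_test
    ga = [d for d in diffs if d.group == "A"]
    gb = [d for d in diffs if d.group == "B"]
    results = {}
    for band in config.bands:
        results[band.name] = permutation_test(
            ga, gb, neighbors, band=band, n_perm=config.n_perm,
            cluster_alpha=config.cluster_alpha, seed=seed)
    return results


def stage_extract(diffs: list[SubjectDifference], results: dict,
                  behavior: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Append one cluster-mean column per band to the behavior table.

    Uses the most massive significant cluster per band; bands without a
    significant cluster contribute no column (and hence drop out of the
    regression), mirroring the extract-only-significant-clusters rule."""
    table = behavior.copy()
    by_id = {d.subject_id: d for d in diffs}
    for band_name, res in results.items():
        sig = res.significant(alpha)
        if not sig:
            continue
        best = max(sig, key=lambda c: abs(c.mass))
        table[band_name] = np.array([cluster_mean_extract(by_id[sid], best)
                                     for sid in table["subject_id"]])
    return table


def stage_regress(table: pd.DataFrame, config: PipelineConfig) -> RegressionFit:
    terms = tuple(t for t in config.regression_terms if t in table.columns)
    return ols_fit(table, outcome="vocabulary", terms=terms)


# ---------------------------------------------------------------------------
# End-to-end run

def _stage_seed(master: int | None, label: str) -> np.random.SeedSequence:
    idx = {"simulate": 0, "reliability": 1, "cluster": 2}[label]
    return np.random.SeedSequence(entropy=(0 if master is None else master, 1000 + idx))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run the full analysis and write reports into ``outdir``.

    Outputs: per-band cluster JSON (plus null distributions when
    ``save_null``), reliability TSV/JSON, the cluster-mean-augmented
    behavior TSV, the regression TSV, and a run manifest.  Idempotent given
    config + seed (manifest timings aside).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {}

    t0 = time.perf_counter()
    if config.mode == "simulate":
        sim_layout = (make_layout(62).subset(config.layout_channels)
                      if config.layout_channels else None)
        cohort = simulate_cohort(config.simulation, layout=sim_layout)
        epochs, layout, behavior = cohort.epochs, cohort.layout, cohort.behavior
        if config.save_epochs:
            write_epochs(epochs, layout, outdir / "epochs.h5")
            write_layout(layout, outdir / "layout.sfp")
    else:
        if not (config.epochs_path and config.behavior_path):
            raise ValueError("load mode needs epochs_path and behavior_path")
        epochs, layout = read_epochs(config.epochs_path)
        if config.layout_path:
            file_layout = read_layout(config.layout_path)
            if tuple(file_layout.channel_names) != tuple(layout.channel_names):
                raise ValueError("layout file channels do not match epochs container")
            layout = file_layout
        behavior = read_behavior(config.behavior_path)
        present = sorted({k[0] for k in epochs})
        missing = set(present) - set(behavior["subject_id"])
        if missing:
            raise ValueError(f"behavior table missing subjects: {sorted(missing)}")
    write_behavior(behavior, outdir / "behavior.tsv")
    timings["inputs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    rel = stage_reliability(epochs, config, seed=_stage_seed(config.seed, "reliability"))
    rel["map"].to_frame().to_csv(outdir / "reliability_map.tsv", sep="\t",
                                 float_format="%.6f")
    rel_meta = {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in rel.items() if k != "map"}
    rel_meta.update(electrode=config.reliability_electrode,
                    n_draws=config.reliability_draws)
    (outdir / "reliability.json").write_text(json.dumps(rel_meta, indent=2, sort_keys=True))
    report["reliability"] = rel_meta
    timings["reliability"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    diffs = stage_differences(epochs, config)
    timings["ersp"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    neighbors = triangulation_neighbors(layout)
    seed_int = int(_stage_seed(config.seed, "cluster").generate_state(1)[0] % (2**31))
    results = stage_cluster(diffs, neighbors, config, seed=seed_int)
    cluster_report = {b: r.to_dict() for b, r in results.items()}
    (outdir / "clusters.json").write_text(
        json.dumps(cluster_report, indent=2, sort_keys=True))
    if config.save_null:
        np.savetxt(outdir / "null_max_mass.tsv",
                   np.column_stack([results[b].null_max_mass for b in results]),
                   delimiter="\t", header="\t".join(results), comments="")
    report["clusters"] = cluster_report
    timings["cluster"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    band_results = {b: r for b, r in results.items() if b in ("theta", "alpha", "beta")}
    table = stage_extract(diffs, band_results, behavior, alpha=config.cluster_alpha)
    write_behavior(table, outdir / "behavior_with_clusters.tsv")
    fit = stage_regress(table, config)
    fit.to_frame().to_csv(outdir / "regression.tsv", sep="\t", index=False,
                          float_format="%.6f")
    report["regression"] = {
        "terms": fit.terms,
        "coefficients": fit.coefficients.tolist(),
        "p_values": fit.p_values.tolist(),
        "r_squared": fit.r_squared,
    }
    timings["regression"] = time.perf_counter() - t0

    manifest = {
        "erspkit_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = manifest
    return report
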