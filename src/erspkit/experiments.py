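"""Reproducibility experiments exercising the pipeline end to end.

Each function runs one self-contained study-scale check — the worked
trial-count t test, permutation-null calibration, Monte-Carlo vs exact
enumeration agreement, injected-effect recovery, regression coverage, and
the reliability-map invariants — and returns plain numbers.  Problem sizes
are scaled to run on a single CPU in minutes; see the methods note for the
exact sizes and why they were chosen.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import SubjectDifference, permutation_test, triangulation_neighbors, \
    cluster_mean_extract
from .pipeline import PipelineConfig, stage_cluster, stage_differences
from .reliability import trial_count_reliability
from .simulate import (EffectSpec, SimulationConfig, make_layout,
                       simulate_behavior, simulate_cohort)
from .spectral import BandSpec, FrequencyGrid, TFR
from .stats import ols_fit, pooled_ttest_from_summary


def trial_count_ttest() -> dict:
    """Pooled two-sample t test of the retained-trial-count summaries
    (38.32 ± 5.13 vs 25.64 ± 7.33, n = 22 per group)."""
    out = pooled_ttest_from_summary(38.32, 5.13, 22, 25.64, 7.33, 22)
    return {"t": out.t, "df": out.df, "p": out.p}


def _null_fields(rng, layout, n_subjects, freqs, times, group):
    return [SubjectDifference(
        f"{group}{i}", group,
        rng.standard_normal((layout.n_channels, len(freqs), len(times))),
        tuple(layout.channel_names), freqs, times)
        for i in range(n_subjects)]


def null_familywise_rate(seed: int, n_replicates: int = 200,
                         n_subjects: int = 8, n_perm: int = 500) -> dict:
    """Familywise false-positive rate of 'any cluster with p < 0.05' under
    the null: two groups of 8 exchangeable subjects, 8 channels × 9 theta
    bins × 50 time steps per subject."""
    layout = make_layout(8)
    neighbors = triangulation_neighbors(layout)
    freqs = 4.0 + 0.5 * np.arange(9)
    times = 0.02 * np.arange(50)
    root = np.random.SeedSequence(entropy=(seed, 2))
    hits = 0
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        ga = _null_fields(rng, layout, n_subjects, freqs, times, "A")
        gb = _null_fields(rng, layout, n_subjects, freqs, times, "B")
        perm_seed = int(rng.integers(2**31))
        res = permutation_test(ga, gb, neighbors, n_perm=n_perm,
                               seed=perm_seed)
        hits += any(c.p_value < 0.05 for c in res.clusters)
    return {"rate": hits / n_replicates, "n_replicates": n_replicates}


def mc_vs_exact(seed: int, n_perm: int = 2000) -> dict:
    """Monte-Carlo vs exhaustive-enumeration cluster p for 4 vs 4 subjects
    on a 3-channel grid (70 distinct splits).  Returns the largest
    discrepancy in units of the binomial 3-SE band."""
    layout = make_layout(3)
    neighbors = triangulation_neighbors(layout)
    freqs = np.array([4.0, 5.0, 6.0])
    times = 0.01 * np.arange(4)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 3)))
    ga = [SubjectDifference(f"a{i}", "A",
                            rng.standard_normal((3, 3, 4)) + 1.3,
                            tuple(layout.channel_names), freqs, times)
          for i in range(4)]
    gb = _null_fields(rng, layout, 4, freqs, times, "B")
    exact = permutation_test(ga, gb, neighbors, method="exact")
    mc = permutation_test(ga, gb, neighbors, n_perm=n_perm,
                          seed=int(rng.integers(2**31)))
    if not exact.clusters:
        raise RuntimeError("fixture produced no clusters")
    gaps, ratios = [], []
    for ce, cm in zip(exact.clusters, mc.clusters):
        se = np.sqrt(max(ce.p_value * (1 - ce.p_value), 1e-6) / n_perm)
        gap = abs(cm.p_value - ce.p_value)
        gaps.append(gap)
        ratios.append(gap / (3 * se + 1.5 / (n_perm + 1)))
    return {"p_exact": exact.clusters[0].p_value,
            "p_mc": mc.clusters[0].p_value,
            "max_gap": max(gaps), "max_gap_over_3se": max(ratios),
            "n_splits": exact.n_perm, "n_perm": n_perm}


RECOVERY_CHANNELS = ["CZ", "C2", "C1", "CP1", "CPZ", "CP2", "P1", "PZ"]
RECOVERY_INJECTED = ("CZ", "CP1", "CPZ")


def theta_recovery(seed: int, n_replicates: int = 20, delta_db: float = 1.5,
                   n_subjects: int = 22, n_perm: int = 500) -> dict:
    """Injected-effect recovery: +1.5 dB non-phase-locked theta at three
    central-parietal channels, 0.5–0.7 s, group A only, 22 vs 22 subjects
    with study-default trial counts.  Reports the fraction of replicates
    with a significant positive theta cluster overlapping the injected
    points, and the mean extracted cluster mean for group A."""
    eff = (EffectSpec("theta", 4.0, 8.0, RECOVERY_INJECTED, (0.5, 0.7),
                      delta_db_group_a=delta_db),)
    root = np.random.SeedSequence(entropy=(seed, 4))
    detections = 0
    recovered: list[float] = []
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rep_seed = int(np.random.default_rng(ss).integers(2**31))
        sim = SimulationConfig(seed=rep_seed, n_subjects_per_group=n_subjects,
                               effects=eff)
        cfg = PipelineConfig(seed=rep_seed, simulation=sim,
                             grid=FrequencyGrid(3, 10, 0.5),
                             bands=(BandSpec("theta", 4, 8),),
                             n_perm=n_perm, decim_ms=10.0,
                             layout_channels=RECOVERY_CHANNELS)
        layout = make_layout(62).subset(RECOVERY_CHANNELS)
        cohort = simulate_cohort(sim, layout=layout)
        diffs = stage_differences(cohort.epochs, cfg)
        neighbors = triangulation_neighbors(layout)
        res = stage_cluster(diffs, neighbors, cfg, seed=rep_seed % (2**31))["theta"]
        sig = [c for c in res.significant(0.05) if c.sign > 0]
        hit = None
        for c in sig:
            member_ok = any(
                c.ch_names[ci] in RECOVERY_INJECTED
                and 4.0 <= f <= 8.0 and 0.5 <= t < 0.7
                for ci, f, t in zip(c.channels, c.freqs, c.times))
            if member_ok:
                hit = c
                break
        if hit is not None:
            detections += 1
            means_a = [cluster_mean_extract(d, hit) for d in diffs
                       if d.group == "A"]
            recovered.append(float(np.mean(means_a)))
    return {"detection_rate": detections / n_replicates,
            "mean_recovered_db": float(np.mean(recovered)) if recovered else float("nan"),
            "injected_db": delta_db, "n_replicates": n_replicates}


def regression_recovery(seed: int, n_replicates: int = 100,
                        beta_link: float = 13.82) -> dict:
    """OLS recovery of the vocabulary/beta-power link on synthetic cohorts
    (n = 44): 95% CI coverage of the generating coefficient across
    replicates, plus exact recovery in the noiseless case."""
    root = np.random.SeedSequence(entropy=(seed, 5))
    terms = ("age", "gender", "dual_language", "working_memory", "reading",
             "true_beta_change")
    covered = 0
    for rep, ss in enumerate(root.spawn(n_replicates)):
        rng = np.random.default_rng(ss)
        cfg = SimulationConfig(seed=int(rng.integers(2**31)), effects=())
        subjects = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(44)],
            "group": ["A"] * 22 + ["B"] * 22,
            "true_beta_change": np.concatenate([
                rng.normal(0.8, 0.3, 22), rng.normal(0.0, 0.3, 22)]),
        })
        table = simulate_behavior(cfg, subjects, seed=int(rng.integers(2**31)))
        fit = ols_fit(table, terms=terms)
        lo, hi = fit.conf_int("true_beta_change")
        covered += lo <= beta_link <= hi
    # noiseless identity
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 6)))
    from .simulate import BehaviorLink
    cfg0 = SimulationConfig(
        seed=0, effects=(),
        behavior=BehaviorLink(band_coefs={"beta": beta_link}, residual_sd=0.0))
    subjects = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(44)],
        "group": ["A"] * 22 + ["B"] * 22,
        "true_beta_change": rng.normal(0.4, 0.3, 44),
    })
    table0 = simulate_behavior(cfg0, subjects, seed=3)
    fit0 = ols_fit(table0, terms=terms)
    return {"ci_coverage": covered / n_replicates,
            "noiseless_abs_error": abs(fit0.coef("true_beta_change") - beta_link),
            "beta_link": beta_link, "n_replicates": n_replicates}


def reliability_checks(seed: int, n_trials: int = 25) -> dict:
    """Frequency-by-trial-count map invariants on a simulated worse-learner
    subject at electrode CP1: full-subset column equals 1 and mean r is
    non-decreasing in subset size (tolerance 0.02)."""
    from .spectral import hanning_tfr
    layout = make_layout(62).subset(["CP1", "CZ", "CPZ", "PZ"])
    cfg = SimulationConfig(seed=seed, effects=())
    ep_seed = np.random.SeedSequence(entropy=(seed, 7))
    from .simulate import simulate_epochs
    ep = simulate_epochs(cfg, "worst", "B", "S1", seed=ep_seed,
                         n_trials=n_trials, layout=layout)
    tfr = hanning_tfr(ep, FrequencyGrid(4, 12, 1.0), decim_ms=10,
                      channels=["CP1"])
    counts = [1, 3, 6, 12, 18, n_trials]
    # enough subset draws per cell that Monte-Carlo error sits well inside
    # the 0.02 monotonicity tolerance
    m = trial_count_reliability(tfr, "CP1", counts=counts, n_draws=400,
                                seed=np.random.SeedSequence(entropy=(seed, 8)))
    full_dev = float(np.abs(m.correlations[:, -1] - 1.0).max())
    steps = np.diff(m.correlations, axis=1)
    return {"full_subset_max_dev": full_dev,
            "min_monotone_step": float(steps.min()),
            "mean_r_k1": float(m.correlations[:, 0].mean())}
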