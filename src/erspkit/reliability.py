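"""Trial-sufficiency diagnostics for trial-averaged spectral power.

Two complementary checks of whether enough artifact-free trials were
retained per subject:

1. **Mean–median agreement** — with clean data, no outliers and enough
   trials, the across-trial mean and median of dB power agree; a single
   Pearson r over all (channel, frequency, time) points quantifies this.
2. **Frequency-by-trial-count reliability map** — for each frequency, the
   power time course averaged over a random k-trial subset is correlated
   with the all-trial average; repeating over subset sizes and frequencies
   yields a map showing how many trials a stable estimate needs.  The
   diagnostic is usually run at a single representative electrode
   (e.g. CP1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import TFR


@dataclass
class ReliabilityMap:
    """Mean subset-vs-full correlation per frequency × trial count."""

    frequencies: np.ndarray
    trial_counts: np.ndarray
    correlations: np.ndarray  # freqs × counts
    n_draws: int
    electrode: str
    n_trials_total: int

    def __post_init__(self) -> None:
        if self.correlations.shape != (len(self.frequencies), len(self.trial_counts)):
            raise ValueError("correlation matrix shape mismatch")
        if np.nanmax(np.abs(self.correlations)) > 1.0 + 1e-9:
            raise ValueError("correlations outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.correlations,
                            index=pd.Index(self.frequencies, name="frequency_hz"),
                            columns=pd.Index(self.trial_counts, name="n_trials"))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero variance in correlation input")
    return float(np.dot(a, b) / (na * nb))


def mean_median_agreement(tfr: TFR, per_channel: bool = False):
    """Pearson r between across-trial mean and median power.

    Mean and median are taken over trials at every valid (channel,
    frequency, time) point; one r is computed across all points pooled over
    channels (default) or per channel.
    """
    if not tfr.per_trial:
        raise ValueError("per-trial TFR required")
    if tfr.data.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    mean = tfr.data.mean(axis=0)
    median = np.median(tfr.data, axis=0)
    valid = np.isfinite(mean) & np.isfinite(median)
    if per_channel:
        out = {}
        for i, name in enumerate(tfr.ch_names):
            v = valid[i]
            if v.sum() < 2:
                raise ValueError(f"channel {name}: fewer than 2 valid points")
            out[name] = _pearson(mean[i][v], median[i][v])
        return out
    if valid.sum() < 2:
        raise ValueError("fewer than 2 valid points")
    return _pearson(mean[valid], median[valid])


def trial_count_reliability(
    tfr: TFR,
    electrode: str,
    counts: list[int] | None = None,
    n_draws: int = 50,
    seed: int | np.random.SeedSequence | None = None,
) -> ReliabilityMap:
    """Subset-average vs full-average power correlation per frequency.

    For each frequency and each subset size ``k``, ``n_draws`` random
    k-subsets of trials are drawn without replacement; the subset-mean power
    time course is correlated with the all-trial mean time course and the
    mean r is stored.  ``k`` equal to the full trial count yields r = 1 by
    construction.  Deterministic given ``seed``.
    """
    if not tfr.per_trial:
        raise ValueError("per-trial TFR required")
    if electrode not in tfr.ch_names:
        raise ValueError(f"electrode {electrode!r} not in TFR channels")
    ci = tfr.ch_names.index(electrode)
    x = tfr.data[:, ci]  # trials × freqs × times
    n_trials = x.shape[0]
    if counts is None:
        counts = sorted(set(range(1, n_trials + 1, max(1, n_trials // 10))) | {n_trials})
    counts = sorted(set(int(k) for k in counts))
    if counts[0] < 1 or counts[-1] > n_trials:
        raise ValueError(f"subset sizes must lie in [1, {n_trials}]")

    rng = np.random.default_rng(seed)
    valid = np.isfinite(x).all(axis=0)  # freqs × times
    full_mean = x.mean(axis=0)
    corr = np.empty((x.shape[1], len(counts)))
    for fi in range(x.shape[1]):
        v = valid[fi]
        if v.sum() < 2:
            corr[fi] = np.nan
            continue
        ref = full_mean[fi][v]
        if np.ptp(ref) == 0:
            raise ValueError(f"constant time course at {tfr.freqs[fi]:g} Hz")
        xf = x[:, fi][:, v]
        for ki, k in enumerate(counts):
            if k == n_trials:
                corr[fi, ki] = 1.0
                continue
            rs = np.empty(n_draws)
            for d in range(n_draws):
                sub = rng.choice(n_trials, size=k, replace=False)
                rs[d] = _pearson(xf[sub].mean(axis=0), ref)
            corr[fi, ki] = rs.mean()
    return ReliabilityMap(tfr.freqs.copy(), np.array(counts), corr,
                          n_draws, electrode, n_trials)
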