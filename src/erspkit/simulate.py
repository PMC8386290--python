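"""Synthetic epoched-EEG cohorts with known oscillatory effects.

The generator emulates a two-group word-learning study design: two cohorts
of children (better / worse learners), two conditions per subject (the
target word at its first and third sentence presentation, S1 and S3),
unequal retained-trial counts between groups, 1/f background EEG plus
ongoing alpha, and non-phase-locked band-limited power changes between
conditions at chosen electrodes and latencies.  A behavioral table links a
vocabulary-like outcome linearly to the injected band changes.

Effects are injected as multiplicative gain on the band-limited component
of the background signal so the ERSP dB change between conditions is
controlled directly: a requested change of ``d`` dB scales the band
component by ``10**(d/20)`` inside the effect window.  The gain plateau is
padded by half the spectral analysis window at the band's low edge so that
time-frequency estimates anywhere inside the nominal window see the full
change; because the background phase is random per trial the injected
activity averages out of the time-domain ERP (induced, not evoked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Electrode layout

# 62-channel 10-10 montage (Neuroscan-style: T/FT/TP for the temporal row,
# CB1/CB2 below the occiput).  Coordinates are parameterised by an
# anterior-posterior coordinate u (front negative) and a signed lateral
# coordinate v, mapped onto a unit sphere about the vertex.
_ROW_U = {
    "FP": -0.80, "AF": -0.65, "F": -0.50, "FC": -0.25, "C": 0.00,
    "CP": 0.25, "P": 0.50, "PO": 0.65, "O": 0.80, "CB": 0.90,
}

_MONTAGE_62: list[tuple[str, float, float]] = []


def _add_row(row: str, entries: list[tuple[str, float]]) -> None:
    u = _ROW_U[row]
    for name, v in entries:
        _MONTAGE_62.append((name, u, v))


_add_row("FP", [("FP1", -0.20), ("FPZ", 0.0), ("FP2", 0.20)])
_add_row("AF", [("AF3", -0.30), ("AF4", 0.30)])
_add_row("F", [("F7", -0.80), ("F5", -0.60), ("F3", -0.40), ("F1", -0.20),
               ("FZ", 0.0), ("F2", 0.20), ("F4", 0.40), ("F6", 0.60), ("F8", 0.80)])
_add_row("FC", [("FT7", -0.90), ("FC5", -0.60), ("FC3", -0.40), ("FC1", -0.20),
                ("FCZ", 0.0), ("FC2", 0.20), ("FC4", 0.40), ("FC6", 0.60), ("FT8", 0.90)])
_add_row("C", [("T7", -1.00), ("C5", -0.60), ("C3", -0.40), ("C1", -0.20),
               ("CZ", 0.0), ("C2", 0.20), ("C4", 0.40), ("C6", 0.60), ("T8", 1.00)])
_add_row("CP", [("TP7", -0.90), ("CP5", -0.60), ("CP3", -0.40), ("CP1", -0.20),
                ("CPZ", 0.0), ("CP2", 0.20), ("CP4", 0.40), ("CP6", 0.60), ("TP8", 0.90)])
_add_row("P", [("P7", -0.80), ("P5", -0.60), ("P3", -0.40), ("P1", -0.20),
               ("PZ", 0.0), ("P2", 0.20), ("P4", 0.40), ("P6", 0.60), ("P8", 0.80)])
_add_row("PO", [("PO7", -0.70), ("PO5", -0.50), ("PO3", -0.30), ("POZ", 0.0),
                ("PO4", 0.30), ("PO6", 0.50), ("PO8", 0.70)])
_add_row("O", [("O1", -0.25), ("OZ", 0.0), ("O2", 0.25)])
_add_row("CB", [("CB1", -0.45), ("CB2", 0.45)])

assert len(_MONTAGE_62) == 62


def _uv_to_xyz(u: float, v: float) -> np.ndarray:
    """Map (anterior-posterior, lateral) plane coordinates to the sphere."""
    r = math.hypot(u, v)
    theta = r * math.radians(80.0)  # vertex distance; widest rows near ears
    if r == 0:
        return np.array([0.0, 0.0, 1.0])
    # x: toward the right ear, y: toward the nose, z: up
    return np.array([
        math.sin(theta) * v / r,
        math.sin(theta) * (-u) / r,
        math.cos(theta),
    ])


@dataclass(frozen=True)
class ChannelLayout:
    """Named electrodes with 3D unit-sphere positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3)

    def __post_init__(self) -> None:
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms <= 0):
            raise ValueError("positions must have positive norm")
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 1e-9:
            raise ValueError("coincident channel positions")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)

    def subset(self, names: list[str]) -> "ChannelLayout":
        idx = [self.index(n) for n in names]
        return ChannelLayout(tuple(names), self.positions[idx])


def make_layout(n_channels: int = 62) -> ChannelLayout:
    """Build an electrode layout.

    ``n_channels = 62`` returns the named 10-10 montage; other sizes return
    generically named channels (``CH01`` …) on a Fibonacci hemisphere
    lattice, which is convenient for small test geometries.
    """
    if n_channels < 3:
        raise ValueError("need at least 3 channels (triangulation undefined below that)")
    if n_channels == 62:
        names = tuple(name for name, _, _ in _MONTAGE_62)
        pos = np.array([_uv_to_xyz(u, v) for _, u, v in _MONTAGE_62])
        return ChannelLayout(names, pos)
    k = np.arange(n_channels)
    golden = (1 + 5 ** 0.5) / 2
    z = 1.0 - 0.9 * (k + 0.5) / n_channels  # keep points on the upper cap
    phi = 2 * np.pi * k / golden
    r = np.sqrt(1 - z**2)
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = tuple(f"CH{i + 1:02d}" for i in range(n_channels))
    return ChannelLayout(names, pos)


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class EffectSpec:
    """A band-limited, spatially localised condition effect.

    ``delta_db_group_a`` / ``delta_db_group_b`` give the S1→S3 power change
    in dB for each group; ``subject_sd_db`` adds between-subject variation
    around the group mean (the per-subject realized change is what the
    behavioral link consumes).
    """

    name: str
    f_lo: float
    f_hi: float
    channels: tuple[str, ...]
    time_window: tuple[float, float]
    delta_db_group_a: float = 0.0
    delta_db_group_b: float = 0.0
    subject_sd_db: float = 0.0
    phase_locked: bool = False

    def __post_init__(self) -> None:
        if not (3.0 <= self.f_lo < self.f_hi <= 80.0):
            raise ValueError(f"effect {self.name}: band must lie in [3, 80] Hz")
        t0, t1 = self.time_window
        if not (0.0 <= t0 < t1 <= 1.0):
            raise ValueError(f"effect {self.name}: time window must lie in [0, 1] s")


@dataclass(frozen=True)
class BehaviorLink:
    """Linear link from realized band changes (dB) to the outcome score."""

    intercept: float = 60.0
    band_coefs: dict = field(default_factory=lambda: {"beta": 13.82})
    age_coef: float = -1.98
    gender_coef: float = 0.70
    dual_language_coef: float = -0.74
    working_memory_coef: float = 0.37
    reading_coef: float = 0.59
    residual_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual SD must be non-negative")


def default_effects() -> tuple[EffectSpec, ...]:
    """Study-mimicking scenario: theta and beta increases in group A (better
    learners), alpha decrease in group B, at the reported electrodes and
    latencies.  Magnitudes are chosen to be detectable at n = 22 per group."""
    return (
        EffectSpec("theta", 4.0, 8.0,
                   ("CZ", "C2", "CP1", "CPZ", "CP2", "P1"),
                   (0.556, 0.652), delta_db_group_a=1.0, subject_sd_db=0.3),
        EffectSpec("alpha", 9.0, 12.0,
                   ("AF4", "F4", "F6", "F8", "FC6", "FT8", "CZ", "C2", "T8",
                    "CP1", "CPZ", "CP2", "CP4", "TP8", "PZ", "P2", "P4", "P6",
                    "P8", "POZ", "PO4", "PO6", "PO8", "O2", "CB2"),
                   (0.524, 0.972), delta_db_group_b=-1.0, subject_sd_db=0.3),
        EffectSpec("beta", 13.0, 19.0,
                   ("TP7", "CP5", "P7", "P5", "P3", "P1", "PO7", "PO5", "PO3", "O1"),
                   (0.108, 0.300), delta_db_group_a=0.8, subject_sd_db=0.2),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level generator settings.

    Trial-count defaults reproduce the study's retained-trial statistics
    (group A mean 38.32, SD 5.13; group B mean 25.64, SD 7.33); epoching is
    −500 to +1000 ms around target-word onset at 1000 Hz.
    """

    seed: int = 0
    n_subjects_per_group: int = 22
    trial_mean_a: float = 38.32
    trial_sd_a: float = 5.13
    trial_mean_b: float = 25.64
    trial_sd_b: float = 7.33
    sfreq: float = 1000.0
    epoch_window: tuple[float, float] = (-0.5, 1.0)
    pink_exponent: float = 1.0
    noise_amp: float = 15.0       # µV RMS of the 1/f background
    alpha_amp: float = 5.0        # µV amplitude of ongoing 10 Hz alpha
    effects: tuple[EffectSpec, ...] = field(default_factory=default_effects)
    behavior: BehaviorLink = field(default_factory=BehaviorLink)
    # analysis-window parameters used to pad effect plateaus
    cycles: float = 3.0
    t_cap: float = 0.5

    def __post_init__(self) -> None:
        if self.epoch_window != (-0.5, 1.0):
            raise ValueError("epoch window is fixed at [-0.5, 1.0] s")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")

    @property
    def n_samples(self) -> int:
        return int(round((self.epoch_window[1] - self.epoch_window[0]) * self.sfreq)) + 1

    @property
    def t0_index(self) -> int:
        return int(round(-self.epoch_window[0] * self.sfreq))


@dataclass
class EpochSet:
    """One subject × condition block of epoched EEG (µV)."""

    subject_id: str
    group: str            # "A" (better learners) or "B" (worse learners)
    condition: str        # "S1" or "S3"
    data: np.ndarray      # trials × channels × samples
    sfreq: float
    t0_index: int
    layout: ChannelLayout

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 3 or d.shape[0] < 1:
            raise ValueError("data must be non-empty trials × channels × samples")
        if d.shape[1] != self.layout.n_channels:
            raise ValueError("channel count does not match layout")
        if not (0 <= self.t0_index < d.shape[2]):
            raise ValueError("t0_index out of range")
        self.data = d

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return (np.arange(self.data.shape[2]) - self.t0_index) / self.sfreq


# ---------------------------------------------------------------------------
# Signal synthesis

def _pink_noise(rng: np.random.Generator, n_trials: int, n_ch: int,
                n_samp: int, exponent: float, amp: float, sfreq: float) -> np.ndarray:
    """1/f^χ noise with random spectral phase, scaled to RMS ≈ ``amp`` µV."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sfreq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_trials, n_ch, len(freqs)))
            + 1j * rng.standard_normal((n_trials, n_ch, len(freqs)))) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=-1)
    # expected variance of irfft of the shaped complex-gaussian spectrum
    expected_var = 4.0 * np.sum(shape**2) / n_samp**2
    return x * (amp / math.sqrt(expected_var))


def _gain_profile(times: np.ndarray, window: tuple[float, float],
                  pad: float, ramp: float = 0.05) -> np.ndarray:
    """Smooth 0→1→0 plateau covering ``window`` padded by ``pad`` seconds.

    The plateau never extends before t = 0 so the baseline stays untouched.
    """
    t0 = max(0.0, window[0] - pad)
    t1 = min(times[-1], window[1] + pad)
    prof = np.zeros_like(times)
    flat = (times >= t0) & (times <= t1)
    prof[flat] = 1.0
    up = (times >= t0 - ramp) & (times < t0)
    prof[up] = 0.5 * (1 + np.cos(np.pi * (t0 - times[up]) / ramp))
    down = (times > t1) & (times <= t1 + ramp)
    prof[down] = 0.5 * (1 + np.cos(np.pi * (times[down] - t1) / ramp))
    prof[times < 0] = 0.0
    return prof


def _band_component(x: np.ndarray, f_lo: float, f_hi: float, sfreq: float) -> np.ndarray:
    """Band-limited component of ``x`` (last axis = time) via FFT masking."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec = np.fft.rfft(x, axis=-1)
    mask = (freqs >= f_lo) & (freqs <= f_hi)
    spec[..., ~mask] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _draw_trial_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    return max(1, int(round(rng.normal(mean, sd))))


def realized_delta(effect: EffectSpec, group: str,
                   rng: np.random.Generator) -> float:
    """Per-subject S1→S3 change in dB for one effect (group mean + jitter)."""
    base = effect.delta_db_group_a if group == "A" else effect.delta_db_group_b
    return base + (effect.subject_sd_db * rng.standard_normal() if effect.subject_sd_db else 0.0)


def simulate_epochs(
    config: SimulationConfig,
    subject_id: str,
    group: str,
    condition: str,
    seed: int | np.random.SeedSequence,
    n_trials: int | None = None,
    effect_deltas: dict | None = None,
    layout: ChannelLayout | None = None,
) -> EpochSet:
    """Generate one subject × condition EpochSet.

    ``effect_deltas`` maps effect name → realized S1→S3 change in dB for
    this subject; when omitted, group means are used.  The S3 condition
    carries the gain ``10**(delta/20)`` on the effect band; S1 is unscaled,
    so the between-condition ERSP difference equals ``delta`` dB.
    """
    if group not in ("A", "B"):
        raise ValueError("group must be 'A' or 'B'")
    if condition not in ("S1", "S3"):
        raise ValueError("condition must be 'S1' or 'S3'")
    layout = layout or make_layout(62)
    rng = np.random.default_rng(seed)
    if n_trials is None:
        mean, sd = ((config.trial_mean_a, config.trial_sd_a) if group == "A"
                    else (config.trial_mean_b, config.trial_sd_b))
        n_trials = _draw_trial_count(rng, mean, sd)
    n_samp = config.n_samples
    times = (np.arange(n_samp) - config.t0_index) / config.sfreq

    x = _pink_noise(rng, n_trials, layout.n_channels, n_samp,
                    config.pink_exponent, config.noise_amp, config.sfreq)
    if config.alpha_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_trials, layout.n_channels, 1))
        x += config.alpha_amp * np.cos(2 * np.pi * 10.0 * times[None, None, :] + phase)

    for eff in config.effects:
        delta = (effect_deltas or {}).get(
            eff.name,
            eff.delta_db_group_a if group == "A" else eff.delta_db_group_b,
        )
        if condition != "S3" or delta == 0.0:
            continue
        ch_idx = [layout.index(c) for c in eff.channels if c in layout.channel_names]
        if not ch_idx:
            continue
        gain = 10.0 ** (delta / 20.0)
        # Pad the modulation in time by half the analysis window and in
        # frequency by the Hann taper's half-power half-width (~0.72/T Hz)
        # so spectral estimates inside the nominal band/window see the full
        # requested change rather than a resolution-diluted one.
        t_win = min(config.cycles / eff.f_lo, config.t_cap)
        pad = 0.5 * t_win
        f_lo = max(0.5, eff.f_lo - 0.72 / t_win)
        f_hi = eff.f_hi + 0.72 / min(config.cycles / eff.f_hi, config.t_cap)
        prof = _gain_profile(times, eff.time_window, pad)
        if eff.phase_locked:
            band = _band_component(x[:, ch_idx, :], f_lo, f_hi, config.sfreq)
            p_band = band.var(axis=-1).mean()
            amp = math.sqrt(max(0.0, 2.0 * p_band * (10 ** (delta / 10.0) - 1.0)))
            fc = 0.5 * (eff.f_lo + eff.f_hi)
            burst = amp * prof * np.cos(2 * np.pi * fc * times)
            x[:, ch_idx, :] += burst[None, None, :]
        else:
            band = _band_component(x[:, ch_idx, :], f_lo, f_hi, config.sfreq)
            x[:, ch_idx, :] += (gain - 1.0) * prof[None, None, :] * band

    return EpochSet(subject_id, group, condition, x, config.sfreq,
                    config.t0_index, layout)


# ---------------------------------------------------------------------------
# Behavioral table

def simulate_behavior(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    seed: int | np.random.SeedSequence,
) -> pd.DataFrame:
    """Generate the per-subject behavioral table.

    ``subjects`` must carry ``subject_id``, ``group`` and one
    ``true_<band>_change`` column per effect (the realized dB changes the
    outcome is linked to).  Covariate distributions follow the study's
    demographics: age uniform on [8, 15], gender and dual-language Bernoulli
    with the reported cohort proportions, digit-span and reading scores
    Gaussian, word-learning accuracy separated by group.
    """
    link = config.behavior
    rng = np.random.default_rng(seed)
    n = len(subjects)
    df = subjects.reset_index(drop=True).copy()
    df["age"] = rng.uniform(8.0, 15.0, n)
    df["gender"] = rng.binomial(1, 28 / 44, n)           # 1 = female
    df["dual_language"] = rng.binomial(1, 36 / 44, n)
    df["working_memory"] = np.clip(rng.normal(7.9, 2.0, n), 2.0, 14.0)
    df["reading"] = rng.normal(91.0, 12.5, n)
    acc_mean = np.where(df["group"] == "A", 0.75, 0.51)
    acc_sd = np.where(df["group"] == "A", 0.07, 0.09)
    df["word_learning_accuracy"] = np.clip(rng.normal(acc_mean, acc_sd), 0.0, 1.0)

    vocab = (
        link.intercept
        + link.age_coef * df["age"]
        + link.gender_coef * df["gender"]
        + link.dual_language_coef * df["dual_language"]
        + link.working_memory_coef * df["working_memory"]
        + link.reading_coef * df["reading"]
    )
    for band, coef in link.band_coefs.items():
        col = f"true_{band}_change"
        if col in df.columns:
            vocab = vocab + coef * df[col]
    if link.residual_sd > 0:
        vocab = vocab + rng.normal(0.0, link.residual_sd, n)
    df["vocabulary"] = vocab
    return df


# ---------------------------------------------------------------------------
# Cohort assembly

@dataclass
class Cohort:
    """A full simulated study: epochs per subject × condition, behavior
    table, layout, and the realized per-subject effect magnitudes."""

    epochs: dict            # (subject_id, condition) -> EpochSet
    behavior: pd.DataFrame
    layout: ChannelLayout
    config: SimulationConfig

    def subjects(self) -> list[tuple[str, str]]:
        ids = sorted({k[0] for k in self.epochs})
        return [(sid, self.epochs[(sid, "S1")].group) for sid in ids]


def simulate_cohort(config: SimulationConfig,
                    layout: ChannelLayout | None = None) -> Cohort:
    """Simulate the whole two-group cohort deterministically from the seed.

    Trial counts are drawn once per subject and shared between S1 and S3
    (the study's per-condition counts are nearly identical).  Each subject's
    realized effect magnitudes feed both the EEG injection and the
    behavioral link.
    """
    layout = layout or make_layout(62)
    root = np.random.SeedSequence(config.seed)
    epochs: dict = {}
    rows = []
    for gi, group in enumerate(("A", "B")):
        mean, sd = ((config.trial_mean_a, config.trial_sd_a) if group == "A"
                    else (config.trial_mean_b, config.trial_sd_b))
        for si in range(config.n_subjects_per_group):
            sid = f"sub-{group}{si + 1:02d}"
            ss = np.random.SeedSequence(entropy=(config.seed, gi, si))
            meta_rng = np.random.default_rng(ss.spawn(1)[0])
            n_trials = _draw_trial_count(meta_rng, mean, sd)
            deltas = {eff.name: realized_delta(eff, group, meta_rng)
                      for eff in config.effects}
            s1_seed, s3_seed = np.random.SeedSequence(
                entropy=(config.seed, gi, si, 1)).spawn(2)
            epochs[(sid, "S1")] = simulate_epochs(
                config, sid, group, "S1", s1_seed,
                n_trials=n_trials, effect_deltas=deltas, layout=layout)
            epochs[(sid, "S3")] = simulate_epochs(
                config, sid, group, "S3", s3_seed,
                n_trials=n_trials, effect_deltas=deltas, layout=layout)
            row = {"subject_id": sid, "group": group, "n_trials": n_trials}
            row.update({f"true_{k}_change": v for k, v in deltas.items()})
            rows.append(row)
    subjects = pd.DataFrame(rows)
    behavior = simulate_behavior(
        config, subjects, np.random.SeedSequence(entropy=(config.seed, 97)))
    return Cohort(epochs, behavior, layout, config)
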