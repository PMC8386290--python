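"""Hanning-taper time-frequency decomposition and dB baseline correction.

Power is estimated by convolving each epoch with a Hann-windowed complex
exponential at every frequency of an evenly spaced grid (default 3–80 Hz in
0.5 Hz steps) and squaring the magnitude of the analytic amplitude.  The
window is frequency-adaptive (``cycles / f`` seconds, capped at ``t_cap``)
so low frequencies keep valid estimates inside short epochs.  Edge samples
where the window would run off the epoch are marked invalid (NaN), never
zero-filled.

The event-related spectral perturbation (ERSP) is the trial-averaged power
expressed in decibels relative to the mean power in a pre-stimulus baseline
window: ``ERSP(c, f, t) = 10 * log10(P(c, f, t) / mean_baseline P(c, f))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import next_fast_len
from scipy.signal.windows import hann


@dataclass(frozen=True)
class FrequencyGrid:
    """Evenly spaced analysis frequencies in Hz.

    The default grid runs from 3 to 80 Hz in steps of 0.5 Hz.
    """

    f_min: float = 3.0
    f_max: float = 80.0
    step: float = 0.5

    def __post_init__(self) -> None:
        if not (3.0 <= self.f_min < self.f_max <= 80.0):
            raise ValueError(
                f"grid must satisfy 3 <= f_min < f_max <= 80, got "
                f"[{self.f_min}, {self.f_max}]"
            )
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = (self.f_max - self.f_min) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("f_max - f_min must be an integer number of steps")

    @property
    def frequencies(self) -> np.ndarray:
        n = int(round((self.f_max - self.f_min) / self.step)) + 1
        return self.f_min + self.step * np.arange(n)

    @property
    def n_freqs(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, e.g. theta 4–8 Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (3.0 <= self.f_lo < self.f_hi <= 80.0):
            raise ValueError(
                f"band {self.name}: need 3 <= f_lo < f_hi <= 80, "
                f"got [{self.f_lo}, {self.f_hi}]"
            )


#: Canonical analysis bands.
DEFAULT_BANDS = (
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 9.0, 12.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma", 30.0, 80.0),
)


@dataclass
class TFR:
    """Time-frequency representation.

    ``data`` is ``(trials, channels, freqs, times)`` when ``per_trial`` is
    true, else ``(channels, freqs, times)``.  Units are raw power (µV²)
    unless ``is_db`` is set, in which case values are dB relative to the
    baseline recorded in ``baseline_window``.  Invalid (edge) estimates are
    NaN.
    """

    data: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    ch_names: list[str]
    per_trial: bool
    is_db: bool = False
    cycles: float = 3.0
    t_cap: float = 0.5
    baseline_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        expected = 4 if self.per_trial else 3
        if self.data.ndim != expected:
            raise ValueError(
                f"data must have {expected} dims, got {self.data.ndim}"
            )
        if self.data.shape[-1] != len(self.times):
            raise ValueError("time axis mismatch")
        if self.data.shape[-2] != len(self.freqs):
            raise ValueError("frequency axis mismatch")
        if self.data.shape[-3] != len(self.ch_names):
            raise ValueError("channel axis mismatch")

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def average_trials(self) -> "TFR":
        """Mean over the trial axis (raw power only)."""
        if not self.per_trial:
            return self
        if self.is_db:
            raise ValueError("average raw power before dB conversion")
        return replace(self, data=self.data.mean(axis=0), per_trial=False)


def _taper_kernel(freq: float, sfreq: float, cycles: float, t_cap: float):
    """Hann-windowed complex exponential, normalised so a unit-amplitude
    sinusoid at ``freq`` yields analytic amplitude 1 (power 1/2)."""
    dur = min(cycles / freq, t_cap)
    n = int(round(dur * sfreq))
    n += (n + 1) % 2  # odd length so the kernel is centred
    w = hann(n, sym=True)
    t = (np.arange(n) - n // 2) / sfreq
    kernel = w * np.exp(-2j * np.pi * freq * t)
    return 2.0 * kernel / w.sum(), n


def hanning_tfr(
    epochs,
    grid: FrequencyGrid | None = None,
    cycles: float = 3.0,
    t_cap: float = 0.5,
    decim_ms: float = 2.0,
    channels: list[str] | None = None,
    average: bool = False,
) -> TFR:
    """Per-trial (or trial-averaged) raw power via Hanning-taper convolution.

    Parameters
    ----------
    epochs
        An :class:`~erspkit.simulate.EpochSet` (or any object with ``data``
        shaped trials × channels × samples, ``sfreq``, ``t0_index`` and
        ``layout.channel_names``).
    grid
        Analysis frequencies; defaults to 3–80 Hz in 0.5 Hz steps.
    cycles, t_cap
        Window length per frequency is ``min(cycles / f, t_cap)`` seconds.
    decim_ms
        Output time step in milliseconds (power is computed at full rate
        and subsampled).
    channels
        Optional channel-name subset (keeps memory bounded for per-trial
        diagnostics).
    average
        If true, accumulate the trial mean instead of storing per-trial
        power (memory-friendly path for ERSP computation).
    """
    grid = grid or FrequencyGrid()
    data = np.asarray(epochs.data, dtype=np.float64)
    if data.ndim != 3 or data.shape[0] < 1:
        raise ValueError("epochs.data must be a non-empty trials × channels × samples array")
    sfreq = float(epochs.sfreq)
    names = list(epochs.layout.channel_names)
    if channels is not None:
        idx = [names.index(c) for c in channels]
        data = data[:, idx, :]
        names = list(channels)
    n_trials, n_ch, n_samp = data.shape

    step = max(1, int(round(decim_ms * sfreq / 1000.0)))
    out_idx = np.arange(0, n_samp, step)
    times = (out_idx - epochs.t0_index) / sfreq
    freqs = grid.frequencies

    shape = (n_ch, len(freqs), len(out_idx))
    if average:
        out = np.zeros(shape)
    else:
        out = np.empty((n_trials,) + shape)

    flat = data.reshape(n_trials * n_ch, n_samp)
    # one forward FFT of the data, reused for every frequency's kernel
    max_win = int(round(min(cycles / freqs[0], t_cap) * sfreq)) + 2
    nfft = next_fast_len(n_samp + max_win - 1)
    data_fft = np.fft.fft(flat, nfft, axis=1)
    for fi, f in enumerate(freqs):
        kernel, n_win = _taper_kernel(f, sfreq, cycles, t_cap)
        half = n_win // 2
        if n_win > n_samp:
            power = np.full((n_trials, n_ch, len(out_idx)), np.nan)
        else:
            k_fft = np.fft.fft(kernel, nfft)
            amp = np.fft.ifft(data_fft * k_fft, axis=1)[:, half:half + n_samp]
            power = 0.5 * np.abs(amp) ** 2
            power[:, :half] = np.nan
            if half:
                power[:, -half:] = np.nan
            power = power[:, out_idx].reshape(n_trials, n_ch, len(out_idx))
        if average:
            out[:, fi, :] = power.mean(axis=0)
        else:
            out[:, :, fi, :] = power

    return TFR(
        data=out,
        times=times,
        freqs=freqs,
        ch_names=names,
        per_trial=not average,
        cycles=cycles,
        t_cap=t_cap,
    )


def baseline_db(tfr: TFR, baseline_window: tuple[float, float] = (-0.5, 0.0)) -> TFR:
    """Convert trial-averaged raw power to dB re the pre-stimulus baseline.

    The baseline is the mean of valid power estimates with
    ``baseline_window[0] <= t < baseline_window[1]`` per channel and
    frequency.  Raises if any channel × frequency has no valid baseline
    estimate or a non-positive baseline mean.
    """
    if tfr.per_trial:
        tfr = tfr.average_trials()
    if tfr.is_db:
        raise ValueError("TFR is already baseline-corrected")
    t0, t1 = baseline_window
    mask = (tfr.times >= t0) & (tfr.times < t1)
    if not mask.any():
        raise ValueError("baseline window contains no time points")
    base = tfr.data[..., mask]
    n_valid = np.isfinite(base).sum(axis=-1)
    if (n_valid == 0).any():
        c, f = np.argwhere(n_valid == 0)[0]
        raise ValueError(
            f"no valid baseline estimate for channel {tfr.ch_names[c]} "
            f"at {tfr.freqs[f]:g} Hz"
        )
    with np.errstate(invalid="ignore"):
        base_mean = np.nanmean(base, axis=-1)
    if (base_mean <= 0).any():
        c, f = np.argwhere(base_mean <= 0)[0]
        raise ValueError(
            f"non-positive baseline power for channel {tfr.ch_names[c]} "
            f"at {tfr.freqs[f]:g} Hz"
        )
    db = 10.0 * np.log10(tfr.data / base_mean[..., None])
    return replace(tfr, data=db, is_db=True, baseline_window=(t0, t1))


def band_select(tfr: TFR, band: BandSpec) -> TFR:
    """Restrict a TFR to the frequency bins inside ``band`` (inclusive).

    No averaging over frequency is performed: clusters may span frequency
    sub-ranges, so bin resolution is preserved.
    """
    mask = (tfr.freqs >= band.f_lo - 1e-9) & (tfr.freqs <= band.f_hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.name} selects no frequency bins")
    return replace(
        tfr,
        data=tfr.data[..., mask, :].copy(),
        freqs=tfr.freqs[mask].copy(),
    )
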