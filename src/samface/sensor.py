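"""Sensor-level evoked and induced analysis.

Evoked responses are characterized by the event-related field (ERF, the
trial average after 1–30 Hz filtering and 150-ms pre-stimulus baseline
correction) and its global field power (GFP, the RMS across sensors); time
windows of interest (TWOIs) fall between successive local minima of the GFP.

Induced responses are characterized by Hilbert amplitude spectrograms —
narrow-band (4 Hz) filtering at 1-Hz-spaced centre frequencies, analytic
signal magnitude per trial, trial averaging, percent change against the
-1…0 s baseline — and time–frequency windows of interest (TFWOIs) are
contiguous regions in which a Wilcoxon signed-rank test across participants
(FDR-corrected over the full time × frequency × sensor family) marks many
sensors significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from samface.containers import EpochSet

__all__ = [
    "ERF",
    "Spectrogram",
    "TWOI",
    "TFWOI",
    "bandpass",
    "erf",
    "gfp",
    "find_twois",
    "hilbert_spectrogram",
    "sensor_count_map",
    "select_tfwois",
    "reject_epochs",
]


@dataclass
class ERF:
    """Trial-averaged field: channels × time, with the baseline window used."""

    data: np.ndarray  # (n_channels, n_times)
    time: np.ndarray
    sfreq: float
    baseline: tuple[float, float]


@dataclass
class TWOI:
    """Evoked time window of interest, seconds relative to stimulus onset."""

    t_start: float
    t_end: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("TWOI start must precede end")


@dataclass
class TFWOI:
    """Induced time–frequency window of interest (Hz × seconds)."""

    f_lo: float
    f_hi: float
    t_start: float
    t_end: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end or self.f_lo >= self.f_hi:
            raise ValueError("TFWOI bounds must be increasing")


@dataclass
class Spectrogram:
    """Percent amplitude change: frequencies × times (× sensors).

    ``values[f, t, s]`` is the percent change of the trial-averaged analytic
    amplitude at frequency ``freqs[f]`` and time ``time[t]`` relative to that
    frequency's mean amplitude over the baseline interval.
    """

    values: np.ndarray  # (n_freq, n_times, n_sensors) or (n_freq, n_times)
    freqs: np.ndarray
    time: np.ndarray
    baseline: tuple[float, float] = (-1.0, 0.0)


def _butter_sos(f_lo: float, f_hi: float, sfreq: float, order: int):
    nyq = sfreq / 2.0
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"invalid band [{f_lo}, {f_hi}] Hz")
    if f_hi >= nyq:
        raise ValueError(f"band edge {f_hi} Hz at or above Nyquist ({nyq} Hz)")
    if f_lo <= 0:
        return scipy.signal.butter(order, f_hi / nyq, btype="lowpass", output="sos")
    return scipy.signal.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass", output="sos")


def bandpass(
    x: np.ndarray,
    sfreq: float,
    f_lo: float,
    f_hi: float,
    order: int = 3,
    bidirectional: bool = True,
    axis: int = -1,
) -> np.ndarray:
    """IIR Butterworth band-pass; bi-directional (zero-phase) by default.

    With ``f_lo <= 0`` the filter degenerates to a low-pass.  The forward–
    backward pass squares the magnitude response and cancels the phase
    response, so filtered transients stay aligned with the input.
    """
    sos = _butter_sos(f_lo, f_hi, sfreq, order)
    x = np.asarray(x, dtype=float)
    if bidirectional:
        return scipy.signal.sosfiltfilt(sos, x, axis=axis)
    return scipy.signal.sosfilt(sos, x, axis=axis)


def _mirror_pad(x: np.ndarray, n_pad: int, axis: int = -1) -> np.ndarray:
    pad = [(0, 0)] * x.ndim
    pad[axis] = (n_pad, n_pad)
    return np.pad(x, pad, mode="reflect")


def filter_epochs(
    epochs: EpochSet,
    f_lo: float,
    f_hi: float,
    order: int = 3,
    pad_seconds: float = 0.5,
    chunk: int = 25,
) -> EpochSet:
    """Zero-phase band-pass of every trial, mirror-padded to tame edge transients.

    Trials are processed in chunks to bound the working set; the explicit
    mirror pad replaces scipy's default odd extension, so ``padtype=None``.
    """
    n_pad = int(round(pad_seconds * epochs.sfreq))
    sos = _butter_sos(f_lo, f_hi, epochs.sfreq, order)
    out = np.empty_like(epochs.data)
    for start in range(0, epochs.n_trials, chunk):
        sl = slice(start, min(start + chunk, epochs.n_trials))
        padded = _mirror_pad(epochs.data[sl], n_pad)
        filt = scipy.signal.sosfiltfilt(sos, padded, axis=-1, padtype=None)
        out[sl] = filt[..., n_pad : n_pad + epochs.n_times]
    return EpochSet(
        data=out, sfreq=epochs.sfreq, time=epochs.time, labels=epochs.labels, sensors=epochs.sensors
    )


def erf(
    epochs: EpochSet,
    condition: str | None = None,
    baseline: tuple[float, float] = (-0.15, 0.0),
) -> ERF:
    """Trial average for a condition, baseline-corrected per channel.

    The channel means over the baseline window (default the 150 ms before
    stimulus onset) are subtracted from the average.
    """
    mask = epochs.select(condition)
    if not mask.any():
        raise ValueError(f"no trials for condition {condition!r}")
    avg = epochs.data[mask].mean(axis=0)
    bmask = epochs.time_mask(*baseline)
    avg = avg - avg[:, bmask].mean(axis=1, keepdims=True)
    return ERF(data=avg, time=epochs.time, sfreq=epochs.sfreq, baseline=baseline)


def gfp(erf_obj: ERF | np.ndarray) -> np.ndarray:
    """Global field power: RMS of the field across sensors at each time point."""
    data = erf_obj.data if isinstance(erf_obj, ERF) else np.asarray(erf_obj, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1:
        raise ValueError("GFP needs a channels x time matrix")
    return np.sqrt(np.mean(data**2, axis=0))


def find_twois(
    gfp_ts: np.ndarray,
    time: np.ndarray,
    search_window: tuple[float, float] = (0.05, 0.4),
    smooth_samples: int = 5,
    min_separation: float = 0.02,
) -> list[TWOI]:
    """Partition the post-stimulus GFP into windows bounded by local minima.

    The GFP is pre-smoothed with a short moving average and local minima
    separated by at least ``min_separation`` seconds are located inside the
    search window; successive minima delimit the returned windows.  An empty
    list (with a warning) is returned when no internal minima exist.
    """
    gfp_ts = np.asarray(gfp_ts, dtype=float)
    time = np.asarray(time, dtype=float)
    if search_window[0] < time[0] or search_window[1] > time[-1]:
        raise ValueError("search window outside epoch")
    if smooth_samples > 1:
        kernel = np.ones(smooth_samples) / smooth_samples
        smoothed = np.convolve(gfp_ts, kernel, mode="same")
    else:
        smoothed = gfp_ts
    sfreq = 1.0 / np.median(np.diff(time))
    distance = max(1, int(round(min_separation * sfreq)))
    in_win = (time >= search_window[0]) & (time <= search_window[1])
    seg = smoothed[in_win]
    seg_t = time[in_win]
    minima, _ = scipy.signal.find_peaks(-seg, distance=distance)
    if len(minima) == 0:
        warnings.warn("no GFP local minima in search window; no TWOIs defined")
        return []
    bounds = list(seg_t[minima])
    edges = bounds + [search_window[1]]
    twois = []
    for i in range(len(edges) - 1):
        twois.append(TWOI(t_start=float(edges[i]), t_end=float(edges[i + 1]), label=f"twoi{i}"))
    return twois


def hilbert_spectrogram(
    epochs: EpochSet,
    condition: str | None = None,
    freqs: np.ndarray | None = None,
    bandwidth: float = 4.0,
    baseline: tuple[float, float] = (-1.0, 0.0),
    order: int = 3,
    pad_seconds: float = 0.5,
    percent_change: bool = True,
) -> Spectrogram:
    """Trial-averaged Hilbert amplitude spectrogram, percent change vs. baseline.

    For every centre frequency the data are band-passed to a ``bandwidth``-Hz
    band, the analytic-signal magnitude is taken per trial, magnitudes are
    averaged across trials, and the average is expressed as percent change
    relative to the mean amplitude over ``baseline`` at that frequency.

    Default frequencies are 2–160 Hz in 1-Hz steps, truncated (with a
    warning) when the sampling rate cannot support the top of the sweep.
    """
    if freqs is None:
        freqs = np.arange(2.0, 161.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    nyq = epochs.sfreq / 2.0
    max_f = nyq - bandwidth / 2.0 - 1.0
    if freqs.max() > max_f:
        warnings.warn(
            f"truncating frequency sweep at {max_f:.0f} Hz for sfreq {epochs.sfreq} Hz"
        )
        freqs = freqs[freqs <= max_f]
    mask = epochs.select(condition)
    if not mask.any():
        raise ValueError(f"no trials for condition {condition!r}")
    data = epochs.data[mask]
    n_pad = int(round(pad_seconds * epochs.sfreq))
    if epochs.n_times + 2 * n_pad < 3 * order * 2:
        raise ValueError("epoch too short for filter transients")
    padded = _mirror_pad(data, n_pad)
    bmask = epochs.time_mask(*baseline)
    n_freq = len(freqs)
    out = np.empty((n_freq, epochs.n_times, epochs.n_channels))
    for i, f in enumerate(freqs):
        lo = max(f - bandwidth / 2.0, 0.0)
        hi = f + bandwidth / 2.0
        filt = bandpass(padded, epochs.sfreq, lo, hi, order=order)
        amp = np.abs(scipy.signal.hilbert(filt, axis=-1))[..., n_pad : n_pad + epochs.n_times]
        mean_amp = amp.mean(axis=0)  # channels x time
        out[i] = mean_amp.T
    if percent_change:
        base = out[:, bmask, :].mean(axis=1, keepdims=True)
        out = 100.0 * (out - base) / base
    return Spectrogram(values=out, freqs=freqs, time=epochs.time, baseline=baseline)


def sensor_count_map(
    spectrograms: list[Spectrogram],
    q: float = 0.05,
) -> np.ndarray:
    """Count, per time–frequency point, sensors with a nonzero median response.

    A two-sided Wilcoxon signed-rank test of median percent change = 0 across
    participants is run at every frequency × time × sensor point; the
    resulting p-values are FDR-corrected (Benjamini–Hochberg) pooled over the
    whole family, and the significant sensors are counted per (frequency,
    time) cell.  Points where every participant is exactly zero are
    untestable and counted non-significant.
    """
    from samface.stats import fdr_correct, wilcoxon_signed_rank

    if len(spectrograms) < 6:
        raise ValueError("signed-rank sensor counting needs at least 6 participants")
    stack = np.stack([s.values for s in spectrograms])  # (n_subj, F, T, S)
    n_subj, F, T, S = stack.shape
    flat = stack.reshape(n_subj, -1)
    n_tests = flat.shape[1]
    p = np.ones(n_tests)
    testable = ~np.all(flat == 0, axis=0)

    # fast exact path for columns with no zeros and no tied magnitudes (the
    # typical continuous-data case): W+ from vectorized ranks against one
    # shared exact null CDF, identical to the per-column exact test
    absf = np.abs(flat)
    sorted_abs = np.sort(absf, axis=0)
    fast = testable & np.all(flat != 0, axis=0) & np.all(np.diff(sorted_abs, axis=0) > 0, axis=0)
    if fast.any():
        ranks = scipy.stats.rankdata(absf[:, fast], axis=0)
        wplus = np.rint(np.sum(ranks * (flat[:, fast] > 0), axis=0)).astype(int)
        cdf = _signed_rank_null_cdf(n_subj)
        m_total = n_subj * (n_subj + 1) // 2
        p[fast] = np.minimum(1.0, 2.0 * cdf[np.minimum(wplus, m_total - wplus)])

    for j in np.nonzero(testable & ~fast)[0]:
        p[j] = wilcoxon_signed_rank(flat[:, j])
    reject = fdr_correct(p, q=q) & testable
    return reject.reshape(F, T, S).sum(axis=2)


def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the Wilcoxon W+ statistic for sample size ``n``.

    W+ under the null is the sum of a uniformly random subset of the ranks
    1..n; the counts follow from a dynamic program over the ranks.
    """
    m_total = n * (n + 1) // 2
    counts = np.zeros(m_total + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] = counts[r:] + counts[: m_total + 1 - r]
    return np.cumsum(counts) / 2.0**n


def select_tfwois(
    count_map: np.ndarray,
    freqs: np.ndarray,
    time: np.ndarray,
    n_sensors: int,
    min_sensor_fraction: float = 0.1,
    min_area: int = 10,
) -> list[TFWOI]:
    """Bounding boxes of contiguous supra-threshold regions of the count map.

    Cells whose significant-sensor count reaches ``min_sensor_fraction`` of
    the array are thresholded, 4-connected components are labelled, and
    components of at least ``min_area`` cells are reported as their bounding
    time–frequency rectangles.
    """
    from scipy.ndimage import label as cc_label

    count_map = np.asarray(count_map)
    thr = min_sensor_fraction * n_sensors
    supra = count_map >= thr
    if not supra.any():
        return []
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    labels, n_comp = cc_label(supra, structure=structure)
    df = float(freqs[1] - freqs[0]) if len(freqs) > 1 else 1.0
    dt = float(time[1] - time[0]) if len(time) > 1 else 1.0
    out = []
    for k in range(1, n_comp + 1):
        fs, ts = np.where(labels == k)
        if len(fs) < min_area:
            continue
        f_lo, f_hi = float(freqs[fs.min()]), float(freqs[fs.max()])
        t0, t1 = float(time[ts.min()]), float(time[ts.max()])
        # a component one bin tall or wide still spans that bin's extent
        if f_hi == f_lo:
            f_hi = f_lo + df
        if t1 == t0:
            t1 = t0 + dt
        out.append(
            TFWOI(f_lo=f_lo, f_hi=f_hi, t_start=t0, t_end=t1, label=f"tfwoi{len(out)}")
        )
    return out


def reject_epochs(epochs: EpochSet, peak_to_peak: float) -> EpochSet:
    """Drop trials whose peak-to-peak amplitude exceeds a threshold on any channel.

    Automated stand-in for manual artifact inspection; disabled (not called)
    by default for synthetic data.
    """
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    keep = (ptp <= peak_to_peak).all(axis=1)
    if keep.all():
        return epochs
    return EpochSet(
        data=epochs.data[keep],
        sfreq=epochs.sfreq,
        time=epochs.time,
        labels=epochs.labels[keep],
        sensors=epochs.sensors,
    )
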