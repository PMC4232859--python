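"""SAM scalar beamformer: covariance, weights with orientation search, source power.

The beamformer forms, per voxel, the spatial filter

    w = C^-1 l / (l' C^-1 l),      l = L @ eta,

where C is the (regularized) band-limited data covariance, L the two-column
tangential leadfield and eta the source orientation.  SAM is a *scalar*
beamformer: eta is set per voxel by a non-linear search maximizing the
unit-gain source power S(eta) = 1 / (l' C^-1 l); a dense angular grid search
is the normative implementation here, and the equivalent minimum-eigenvector
solution of L' C^-1 L is available as a cross-check.

Source measures follow the two response families: evoked power is the mean
square of the trial-averaged virtual timeseries in a window (with a jackknife
standard error, since power is computed after averaging), induced amplitude
is the per-trial mean analytic-signal magnitude (standard error from the
across-trial standard deviation).  Both are baseline-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg.blas
import scipy.signal

from samface.containers import EpochSet, VolumetricImage
from samface.forward import Leadfield
from samface.sensor import filter_epochs

__all__ = [
    "Covariance",
    "SpatialFilter",
    "compute_covariance",
    "sam_weights",
    "sam_weights_all",
    "source_power_image",
    "virtual_sensor",
    "evoked_measures",
    "induced_measures",
]


@dataclass
class Covariance:
    """Band-limited sensor covariance with its provenance."""

    matrix: np.ndarray  # (n_channels, n_channels)
    band: tuple[float, float]
    window: tuple[float, float]
    n_trials: int
    mu: float  # regularization fraction of the mean diagonal

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    def inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.matrix)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance singular (mu={self.mu}); increase regularization"
            ) from exc


def compute_covariance(
    epochs: EpochSet,
    band: tuple[float, float],
    window: tuple[float, float] | None = None,
    mu: float = 0.05,
    order: int = 4,
    condition: str | None = None,
    filter_data: bool = True,
) -> Covariance:
    """Covariance of band-passed, unaveraged trial data.

    Each trial is filtered with a bidirectional Butterworth of the given
    order (4 by default for source analysis), the selected window of every
    selected trial is concatenated *without averaging*, and the channel
    covariance is formed.  Diagonal (Tikhonov) regularization adds
    ``mu * mean(diag) * I``.  Pass ``filter_data=False`` when the epochs are
    already filtered to ``band``.
    """
    filtered = filter_epochs(epochs, band[0], band[1], order=order) if filter_data else epochs
    tmask = (
        np.ones(epochs.n_times, dtype=bool) if window is None else epochs.time_mask(*window)
    )
    sel = epochs.select(condition)
    data = filtered.data[sel][:, :, tmask]
    n_trials, n_ch, n_t = data.shape
    stacked = data.transpose(1, 0, 2).reshape(n_ch, -1)
    n_samples = stacked.shape[1]
    if n_samples <= n_ch and mu == 0:
        raise ValueError(
            f"covariance singular: {n_samples} samples for {n_ch} channels with no regularization"
        )
    stacked = stacked - stacked.mean(axis=1, keepdims=True)
    # rank-k update (syrk) does half the flops of a general matmul here
    tri = scipy.linalg.blas.dsyrk(1.0 / (n_samples - 1), stacked)
    C = np.triu(tri) + np.triu(tri, 1).T
    if mu > 0:
        C = C + mu * np.mean(np.diag(C)) * np.eye(n_ch)
    C = 0.5 * (C + C.T)
    win = (float(epochs.time[0]), float(epochs.time[-1])) if window is None else window
    return Covariance(matrix=C, band=band, window=win, n_trials=n_trials, mu=mu)


@dataclass
class SpatialFilter:
    """Beamformer weights and optimized orientations for a voxel set."""

    weights: np.ndarray  # (n_vox, n_channels)
    orientation: np.ndarray  # (n_vox, 2) unit vectors in the tangential basis
    power: np.ndarray  # (n_vox,) unit-gain source power 1/(l' C^-1 l)
    leadfield: Leadfield
    cov: Covariance

    @property
    def n_voxels(self) -> int:
        return len(self.weights)


def _orientation_grid(A: np.ndarray, step_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Minimize eta' A eta over unit 2-vectors by dense angular search.

    ``A`` is (..., 2, 2) symmetric; orientations are eta(theta) =
    (cos theta, sin theta) for theta in [0, 180) degrees.  Returns unit
    orientations and the minimized quadratic form.
    """
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    c, s = np.cos(thetas), np.sin(thetas)
    a = A[..., 0, 0]
    b = A[..., 0, 1]
    d = A[..., 1, 1]
    # quadratic form for every angle: shape (..., n_angles)
    q = (
        a[..., None] * c**2
        + 2.0 * b[..., None] * c * s
        + d[..., None] * s**2
    )
    best = np.argmin(q, axis=-1)
    eta = np.stack([c[best], s[best]], axis=-1)
    qmin = np.take_along_axis(q, best[..., None], axis=-1)[..., 0]
    return eta, qmin


def _orientation_eig(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form orientation: eigenvector of A for its smallest eigenvalue."""
    w, v = np.linalg.eigh(A)
    eta = v[..., :, 0]
    return eta, w[..., 0]


def sam_weights(
    leadfield_voxel: np.ndarray,
    cov: Covariance,
    method: str = "grid",
    step_deg: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Weights, orientation and unit-gain power for one voxel.

    ``leadfield_voxel`` is the (n_channels, 2) tangential leadfield.  The
    orientation eta maximizes S(eta) = 1/(l' C^-1 l); ``method='grid'`` is
    the dense angular search (the non-linear search of the scalar
    beamformer), ``method='eig'`` the minimum-eigenvector closed form.
    Returns ``(w, eta, S)`` with w' l = 1 at l = L @ eta.
    """
    L = np.asarray(leadfield_voxel, dtype=float)
    if L.ndim != 2 or L.shape[1] != 2:
        raise ValueError("leadfield must be (n_channels, 2)")
    Ci = cov.inverse()
    CiL = Ci @ L
    A = L.T @ CiL
    if method == "grid":
        eta, q = _orientation_grid(A, step_deg)
    elif method == "eig":
        eta, q = _orientation_eig(A)
    else:
        raise ValueError(f"unknown orientation method {method!r}")
    if q <= 0 or not np.isfinite(q):
        raise np.linalg.LinAlgError("numerically singular covariance at voxel")
    w = (CiL @ eta) / q
    return w, eta, float(1.0 / q)


def sam_weights_all(
    leadfield: Leadfield,
    cov: Covariance,
    method: str = "grid",
    step_deg: float = 1.0,
) -> SpatialFilter:
    """Vectorized SAM weights for every valid voxel of a leadfield grid.

    Invalid voxels (outside their governing sphere) get zero weights and NaN
    power so downstream images stay aligned with the grid.
    """
    L = leadfield.lf  # (n_vox, n_ch, 2)
    n_vox, n_ch, _ = L.shape
    Ci = cov.inverse()
    Lr = L.transpose(1, 0, 2).reshape(n_ch, n_vox * 2)
    CiL = (Ci @ Lr).reshape(n_ch, n_vox, 2).transpose(1, 0, 2)
    A = np.einsum("vci,vcj->vij", L, CiL)
    valid = leadfield.valid & (np.abs(np.linalg.det(A)) > 0)
    if method == "grid":
        eta, q = _orientation_grid(A[valid], step_deg)
    elif method == "eig":
        eta, q = _orientation_eig(A[valid])
    else:
        raise ValueError(f"unknown orientation method {method!r}")
    weights = np.zeros((n_vox, n_ch))
    orientation = np.zeros((n_vox, 2))
    power = np.full(n_vox, np.nan)
    lv = np.einsum("vik,vk->vi", CiL[valid], eta)
    weights[valid] = lv / q[:, None]
    orientation[valid] = eta
    power[valid] = 1.0 / q
    return SpatialFilter(
        weights=weights, orientation=orientation, power=power, leadfield=leadfield, cov=cov
    )


def _default_induced_baseline(
    window: tuple[float, float], epochs: EpochSet | None = None
) -> tuple[float, float]:
    """Baseline of equal length ending 200 ms before stimulus onset.

    If the epoch's pre-stimulus span is shorter than the window, the baseline
    is clamped to the available span (with a warning), since a matched-length
    baseline is preferred but not possible.
    """
    length = window[1] - window[0]
    start = -0.2 - length
    if epochs is not None and start < epochs.time[0]:
        warnings.warn(
            "pre-stimulus span shorter than analysis window; "
            "baseline clamped to epoch start",
            UserWarning,
        )
        start = float(epochs.time[0])
    return (start, -0.2)


def _project_trials(
    weights: np.ndarray, epochs: EpochSet, trial_mask: np.ndarray, sample_mask: np.ndarray,
    analytic: bool = False, chunk: int | None = None,
):
    """Yield per-trial virtual timeseries (chunked): (chunk, n_vox, n_samples).

    With ``chunk=None`` the chunk size is chosen so the projected block stays
    around 200 MB, keeping peak memory flat as the voxel count grows.
    """
    idx = np.nonzero(trial_mask)[0]
    n_vox = weights.shape[0]
    if chunk is None:
        itemsize = 16 if analytic else 8
        per_trial = max(1, n_vox * int(sample_mask.sum()) * itemsize)
        chunk = int(max(1, min(16, 2 * 10**8 // per_trial)))
    for start in range(0, len(idx), chunk):
        sel = idx[start : start + chunk]
        block = epochs.data[sel][:, :, :]
        if analytic:
            block = scipy.signal.hilbert(block, axis=-1)
        block = block[:, :, sample_mask]
        n_tr, n_ch, n_s = block.shape
        flat = block.transpose(1, 0, 2).reshape(n_ch, n_tr * n_s)
        proj = (weights @ flat).reshape(n_vox, n_tr, n_s).transpose(1, 0, 2)
        yield sel, proj


def evoked_measures(
    filters: SpatialFilter,
    epochs: EpochSet,
    condition: str,
    window: tuple[float, float],
    baseline: tuple[float, float] = (-0.15, 0.0),
    chunk: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected evoked source power and its jackknife SE, per voxel.

    The measure X is the mean square of the trial-averaged virtual timeseries
    within ``window`` minus the same quantity over ``baseline`` (the 150 ms
    before onset by default).  Because power is computed after trial
    averaging, the SE is a leave-one-trial-out jackknife, evaluated with
    closed-form leave-one-out sums so no per-trial volume is materialized.
    """
    tmask = epochs.select(condition)
    n = int(tmask.sum())
    if n < 2:
        raise ValueError("evoked measures need at least 2 trials")
    wmask = epochs.time_mask(*window)
    bmask = epochs.time_mask(*baseline)
    smask = wmask | bmask
    w_in = wmask[smask]
    b_in = bmask[smask]
    n_vox = filters.n_voxels
    # accumulate T = sum of trials, B_i = sum_w T x_i, C_i = sum_w x_i^2
    total = np.zeros((n_vox, int(smask.sum())))
    sum_sq_w = np.zeros((n, n_vox))
    sum_sq_b = np.zeros((n, n_vox))
    row_of = {t: i for i, t in enumerate(np.nonzero(tmask)[0])}
    for sel, proj in _project_trials(filters.weights, epochs, tmask, smask, analytic=False, chunk=chunk):
        total += proj.sum(axis=0)
        rows = [row_of[t] for t in sel]
        sum_sq_w[rows] = (proj[:, :, w_in] ** 2).sum(axis=2)
        sum_sq_b[rows] = (proj[:, :, b_in] ** 2).sum(axis=2)
    # cross terms need sum_w T x_i, so a second projection pass once T is complete
    # (recomputing projections is cheaper than materializing per-trial volumes)
    cross_w = np.zeros((n, n_vox))
    cross_b = np.zeros((n, n_vox))
    for sel, proj in _project_trials(filters.weights, epochs, tmask, smask, analytic=False, chunk=chunk):
        rows = [row_of[t] for t in sel]
        cross_w[rows] = np.einsum("tvs,vs->tv", proj[:, :, w_in], total[:, w_in])
        cross_b[rows] = np.einsum("tvs,vs->tv", proj[:, :, b_in], total[:, b_in])
    nw = int(w_in.sum())
    nb = int(b_in.sum())
    tot_sq_w = (total[:, w_in] ** 2).sum(axis=1)
    tot_sq_b = (total[:, b_in] ** 2).sum(axis=1)
    # full-sample measure
    Xw = tot_sq_w / (n**2 * nw)
    Xb = tot_sq_b / (n**2 * nb)
    X = Xw - Xb
    # leave-one-out: sum_w ((T - x_i)/(n-1))^2
    loo_w = (tot_sq_w[None, :] - 2.0 * cross_w + sum_sq_w) / ((n - 1) ** 2 * nw)
    loo_b = (tot_sq_b[None, :] - 2.0 * cross_b + sum_sq_b) / ((n - 1) ** 2 * nb)
    theta = loo_w - loo_b  # (n, n_vox)
    se = np.sqrt((n - 1) / n * np.sum((theta - theta.mean(axis=0)) ** 2, axis=0))
    return X, se


def induced_measures(
    filters: SpatialFilter,
    epochs: EpochSet,
    condition: str,
    window: tuple[float, float],
    baseline: tuple[float, float] | None = None,
    chunk: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-corrected induced amplitude and its SE, per voxel.

    Per trial, the analytic-signal magnitude of the virtual timeseries (the
    Hilbert envelope of the band-passed projection — the analytic transform
    commutes with the spatial projection, so it is applied in sensor space)
    is averaged within ``window``; the baseline is an equal-length window
    ending 200 ms before onset unless given.  X is the across-trial mean of
    the window-minus-baseline amplitude, the SE its standard deviation over
    sqrt(n_trials).
    """
    if baseline is None:
        baseline = _default_induced_baseline(window, epochs)
    tmask = epochs.select(condition)
    n = int(tmask.sum())
    if n < 2:
        raise ValueError("induced measures need at least 2 trials")
    wmask = epochs.time_mask(*window)
    bmask = epochs.time_mask(*baseline)
    smask = wmask | bmask
    w_in = wmask[smask]
    b_in = bmask[smask]
    n_vox = filters.n_voxels
    theta = np.zeros((n, n_vox))
    row_of = {t: i for i, t in enumerate(np.nonzero(tmask)[0])}
    for sel, proj in _project_trials(filters.weights, epochs, tmask, smask, analytic=True, chunk=chunk):
        mag = np.abs(proj)
        rows = [row_of[t] for t in sel]
        theta[rows] = mag[:, :, w_in].mean(axis=2) - mag[:, :, b_in].mean(axis=2)
    X = theta.mean(axis=0)
    se = theta.std(axis=0, ddof=1) / np.sqrt(n)
    return X, se


def source_power_image(
    filters: SpatialFilter,
    epochs: EpochSet,
    condition: str,
    window: tuple[float, float],
    measure: str = "induced",
    baseline: tuple[float, float] | None = None,
) -> tuple[VolumetricImage, VolumetricImage]:
    """(active, baseline) volumetric source images for one condition.

    ``measure='evoked'``: mean power of the trial-averaged virtual timeseries
    in each window.  ``measure='induced'``: across-trial mean of the mean
    analytic-signal magnitude in each window.  Baselines default to the
    150 ms before onset (evoked) or an equal-length window ending 200 ms
    before onset (induced).
    """
    if measure not in ("evoked", "induced"):
        raise ValueError(f"unknown measure {measure!r}")
    if baseline is None:
        baseline = (-0.15, 0.0) if measure == "evoked" else _default_induced_baseline(window, epochs)
    tmask = epochs.select(condition)
    if not tmask.any():
        raise ValueError(f"no trials for condition {condition!r}")
    wmask = epochs.time_mask(*window)
    bmask = epochs.time_mask(*baseline)
    smask = wmask | bmask
    w_in = wmask[smask]
    b_in = bmask[smask]
    n_vox = filters.n_voxels
    if measure == "evoked":
        avg = epochs.data[tmask].mean(axis=0)[:, smask]
        proj = filters.weights @ avg
        act = (proj[:, w_in] ** 2).mean(axis=1)
        base = (proj[:, b_in] ** 2).mean(axis=1)
    else:
        act = np.zeros(n_vox)
        base = np.zeros(n_vox)
        n = int(tmask.sum())
        for _, proj in _project_trials(filters.weights, epochs, tmask, smask, analytic=True):
            mag = np.abs(proj)
            act += mag[:, :, w_in].mean(axis=2).sum(axis=0)
            base += mag[:, :, b_in].mean(axis=2).sum(axis=0)
        act /= n
        base /= n
    grid = filters.leadfield.grid
    return (
        VolumetricImage.from_flat(grid, act, semantics="power"),
        VolumetricImage.from_flat(grid, base, semantics="power"),
    )


def virtual_sensor(
    weights: np.ndarray,
    epochs: EpochSet,
    condition: str | None = None,
    twoi: tuple[float, float] | None = None,
    flip_polarity: bool = False,
) -> np.ndarray:
    """Per-trial virtual timeseries at one location: (n_trials, n_times).

    With ``flip_polarity`` the whole set of trials is negated when the
    maximal absolute deflection of the trial average inside ``twoi`` is
    negative — the scalar beamformer's orientation sign is arbitrary, so
    evoked displays are conventionally shown peak-positive.
    """
    weights = np.asarray(weights, dtype=float)
    tmask = epochs.select(condition)
    ts = np.einsum("c,tcs->ts", weights, epochs.data[tmask])
    if flip_polarity:
        if twoi is None:
            raise ValueError("polarity flip needs a TWOI")
        wmask = epochs.time_mask(*twoi)
        avg = ts.mean(axis=0)[wmask]
        peak = avg[np.argmax(np.abs(avg))]
        if peak < 0:
            ts = -ts
    return ts
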