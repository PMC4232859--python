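"""Participant-level Welch-t statistics and group-level nonparametric inference.

Participant images contrast the face and scrambled response measures with
Welch's unequal-variance t computed from per-condition standard errors (a
jackknife over trials for evoked power, which is a nonlinear functional of
the trial average).  Group inference uses a one-sample sign-flip permutation
test on the participant t images, with family-wise error control by the
maximum-statistic distribution and optional Gaussian variance smoothing
(pseudo-t) for focal sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import scipy.stats

from samface.containers import GridSpec, VolumetricImage

__all__ = [
    "welch_t",
    "jackknife_se",
    "wilcoxon_signed_rank",
    "fdr_correct",
    "permutation_group_test",
    "peak_table",
    "PermutationResult",
]


def welch_t(xf: float, xs: float, sf: float, ss: float):
    """Welch's unequal-variance t from two means and their standard errors.

        t = (xf - xs) / sqrt(sf^2 + ss^2)

    Accepts arrays (broadcast elementwise).  Undefined when both standard
    errors are zero.
    """
    xf, xs, sf, ss = (np.asarray(v, dtype=float) for v in (xf, xs, sf, ss))
    if np.any(sf < 0) or np.any(ss < 0):
        raise ValueError("standard errors must be non-negative")
    denom = np.sqrt(sf**2 + ss**2)
    if np.any(denom == 0):
        raise ZeroDivisionError("Welch t undefined: both standard errors are zero")
    t = (xf - xs) / denom
    return float(t) if t.ndim == 0 else t


def jackknife_se(trials: np.ndarray, statistic: Callable[[np.ndarray], float]) -> float:
    """Leave-one-out jackknife standard error of a statistic of the trial set.

    ``statistic`` maps the (n_trials, ...) array to a scalar; the SE is

        sqrt((n-1)/n * sum_i (theta_{-i} - mean(theta_{-i}))^2)

    For the plain mean this reduces to the classical SD/sqrt(n).
    """
    trials = np.asarray(trials, dtype=float)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least 2 trials")
    loo = np.array([statistic(np.delete(trials, i, axis=0)) for i in range(n)])
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def jackknife_se_mean_functional(
    trials: np.ndarray, functional: Callable[[np.ndarray], np.ndarray]
) -> np.ndarray:
    """Vectorized jackknife SE of ``functional`` applied to leave-one-out trial means.

    ``trials`` is (n_trials, ...); the leave-one-out means are formed in one
    pass from the total sum, and ``functional`` maps each mean (same trailing
    shape) to per-voxel scalars, stacked as (n_trials, n_out).  Used for
    evoked source power, where the statistic is a quadratic functional of the
    trial-averaged virtual timeseries.
    """
    trials = np.asarray(trials, dtype=float)
    n = trials.shape[0]
    if n < 2:
        raise ValueError("jackknife needs at least 2 trials")
    total = trials.sum(axis=0)
    loo = np.stack([functional((total - trials[i]) / (n - 1)) for i in range(n)])
    return np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))


def wilcoxon_signed_rank(values: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p for median zero.

    Exact null distribution for n <= 25 without ties; normal approximation
    with zero/tie handling otherwise.  All-zero samples are undefined.
    """
    values = np.asarray(values, dtype=float)
    nonzero = values[values != 0]
    if len(nonzero) == 0:
        raise ValueError("signed-rank test undefined for all-zero sample")
    n = len(nonzero)
    has_ties = len(np.unique(np.abs(nonzero))) < n
    if n <= 25 and not has_ties:
        res = scipy.stats.wilcoxon(values, zero_method="wilcox", mode="exact")
    else:
        res = scipy.stats.wilcoxon(
            values, zero_method="wilcox", mode="approx", correction=True
        )
    return float(res.pvalue)


def fdr_correct(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask over the pooled family."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = (np.arange(1, m + 1) / m) * q
    below = ranked <= thresh
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject.reshape(np.shape(pvalues))


def _smooth_variance(var_flat: np.ndarray, grid: GridSpec, sigma_mm: float) -> np.ndarray:
    """Gaussian-smooth a variance image within the mask, edge-renormalized.

    The kernel (sigma in mm, truncated at 3 sigma) is applied to the
    zero-filled variance volume and divided by the smoothed mask so voxels
    near the boundary are not biased low.
    """
    from scipy.ndimage import gaussian_filter

    sigma_vox = sigma_mm / (grid.spacing * 1000.0)
    vol = np.zeros(grid.shape)
    vol[grid.mask] = var_flat
    sm = gaussian_filter(vol, sigma=sigma_vox, truncate=3.0)
    norm = gaussian_filter(grid.mask.astype(float), sigma=sigma_vox, truncate=3.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sm / norm
    return out[grid.mask]


@dataclass
class PermutationResult:
    """Output of the sign-flip group test."""

    stat: VolumetricImage  # observed group statistic (t or pseudo-t)
    p_voxel: VolumetricImage  # uncorrected permutation p
    p_fwe: VolumetricImage  # max-statistic corrected p
    n_permutations: int
    exhaustive: bool


def _group_stat(images: np.ndarray, grid: GridSpec | None, sigma_mm: float | None) -> np.ndarray:
    """One-sample t (or pseudo-t under variance smoothing) across participants."""
    n = images.shape[0]
    mean = images.mean(axis=0)
    var = images.var(axis=0, ddof=1)
    if sigma_mm is not None and grid is not None and sigma_mm > 0:
        var = _smooth_variance(var, grid, sigma_mm)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    # zero mean over zero variance is a true zero; zero variance alone is a
    # degenerate +-inf kept for the permutation comparisons
    return np.where(np.isnan(t), 0.0, t)


def permutation_group_test(
    images: list[VolumetricImage] | np.ndarray,
    n_perm: int = 5000,
    variance_smoothing_sigma_mm: float | None = None,
    seed: int | None = None,
    grid: GridSpec | None = None,
    two_sided: bool = False,
) -> PermutationResult:
    """Sign-flip maximum-statistic permutation test across participants.

    The observed statistic per voxel is the one-sample t of the participant
    images (pseudo-t when ``variance_smoothing_sigma_mm`` is given: the
    variance image is convolved with a Gaussian kernel before forming the
    denominator).  The null is built by randomly flipping the sign of each
    participant's whole image — exchangeable under the hypothesis of no
    condition difference — and recomputing the statistic; when ``2^n`` does
    not exceed ``n_perm`` the full flip set is enumerated instead.

    Monte-Carlo p-values use the add-one convention (1 + exceedances) /
    (n_perm + 1); exhaustive p-values are exact counts over the ``2^n`` flips
    (which include the identity).  Family-wise-corrected p-values come from
    the distribution of the maximum statistic over the mask, with >= in the
    comparison.  The test is one-sided in the statistic by default (contrast
    direction is chosen by the caller); with ``two_sided`` statistics are
    compared in absolute value.
    """
    if isinstance(images, (list, tuple)):
        if len(images) < 2:
            raise ValueError("group test needs at least 2 participants")
        grid = images[0].grid
        for im in images:
            if im.grid.shape != grid.shape or not np.array_equal(im.grid.mask, grid.mask):
                raise ValueError("participant images must share grid and mask")
        flat = np.stack([im.flat() for im in images])
    else:
        flat = np.asarray(images, dtype=float)
        if flat.ndim != 2:
            raise ValueError("array input must be (n_participants, n_voxels)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_subj, n_vox = flat.shape
    if n_vox == 0:
        raise ValueError("empty mask")

    obs = _group_stat(flat, grid, variance_smoothing_sigma_mm)
    mag = np.abs(obs) if two_sided else obs

    exhaustive = 2**n_subj <= n_perm
    if exhaustive:
        signs = np.array(
            [[1.0 if (i >> b) & 1 == 0 else -1.0 for b in range(n_subj)] for i in range(2**n_subj)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    count_vox = np.zeros(n_vox)
    count_max = np.zeros(n_vox)
    for s in signs:
        perm_stat = _group_stat(flat * s[:, None], grid, variance_smoothing_sigma_mm)
        perm_mag = np.abs(perm_stat) if two_sided else perm_stat
        count_vox += perm_mag >= mag
        count_max += perm_mag.max() >= mag
    if exhaustive:
        n_eff = len(signs)
        p_vox = count_vox / n_eff
        p_fwe = count_max / n_eff
    else:
        p_vox = (1.0 + count_vox) / (len(signs) + 1.0)
        p_fwe = (1.0 + count_max) / (len(signs) + 1.0)

    if grid is None:
        grid = GridSpec(origin=np.zeros(3), spacing=0.004, shape=(n_vox, 1, 1))
    mk = lambda v, sem: VolumetricImage.from_flat(grid, v, semantics=sem)
    sem = "pseudo-t" if variance_smoothing_sigma_mm else "t"
    big = np.finfo(float).max
    return PermutationResult(
        stat=mk(np.clip(obs, -big, big), sem),
        p_voxel=mk(p_vox, "p"),
        p_fwe=mk(p_fwe, "p"),
        n_permutations=len(signs),
        exhaustive=exhaustive,
    )


def peak_table(
    stat: VolumetricImage,
    p_voxel: VolumetricImage | None = None,
    p_fwe: VolumetricImage | None = None,
    threshold: float = 0.0,
    minima: bool = True,
) -> pd.DataFrame:
    """Table of supra-threshold local extrema of a statistic image.

    A voxel is a local maximum (minimum) when its value is >= (<=) all of its
    26-connected in-mask neighbours and |value| exceeds ``threshold``.  Rows
    carry millimetre coordinates and any supplied p-values, sorted by
    descending |statistic| with coordinate-lexicographic tie-breaking.
    """
    grid = stat.grid
    vol = stat.values
    mask = grid.mask
    rows = []
    offsets = [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
    idx = np.argwhere(mask)
    shape = grid.shape
    for v in idx:
        val = vol[tuple(v)]
        if abs(val) <= threshold:
            continue
        is_max = True
        is_min = True
        for off in offsets:
            w = v + off
            if np.any(w < 0) or np.any(w >= shape) or not mask[tuple(w)]:
                continue
            nb = vol[tuple(w)]
            if nb > val:
                is_max = False
            if nb < val:
                is_min = False
            if not is_max and not (minima and is_min):
                break
        if is_max or (minima and is_min):
            pos_mm = (grid.origin + v * grid.spacing) * 1000.0
            row = {
                "x_mm": pos_mm[0],
                "y_mm": pos_mm[1],
                "z_mm": pos_mm[2],
                "stat": val,
                "kind": "max" if is_max else "min",
            }
            if p_voxel is not None:
                row["p_unc"] = p_voxel.values[tuple(v)]
            if p_fwe is not None:
                row["p_fwe"] = p_fwe.values[tuple(v)]
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df) == 0:
        return df
    df["absstat"] = df["stat"].abs()
    df = df.sort_values(
        by=["absstat", "x_mm", "y_mm", "z_mm"], ascending=[False, True, True, True]
    ).drop(columns="absstat")
    return df.reset_index(drop=True)
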