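"""Bivariate linear Granger causality with Geweke's influence measure.

For a seed series x and a target series y, two nested autoregressions of
the target are fitted by ordinary least squares on the same aligned
samples:

* restricted:  y_t = c + sum_k a_k y_{t-k} + e_t            (own lags only)
* full:        y_t = c + sum_k a_k y_{t-k} + sum_k b_k x_{t-k} + e_t

The directed influence is Geweke's log variance ratio

    F_{x -> y} = ln( sigma^2_restricted / sigma^2_full ),

in nats, with residual variances taken as RSS / (T - p) on both models so
the ratio is well defined.  F is non-negative (nested OLS) and invariant
to rescaling either series.  Significance is assessed against a
permutation null obtained by reshuffling the *target* series' time
indices (500 reshuffles by default), which destroys all temporal
dependence while preserving the marginal distribution.

Model order is selected with the Schwarz criterion on the bivariate full
model; the canonical order for these data is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VARFit",
    "InfluencePair",
    "InfluenceMaps",
    "PermutationResult",
    "granger_pair",
    "select_order",
    "influence_maps",
    "permutation_pvalue",
    "DEFAULT_N_PERM",
]

#: Canonical number of permutation reshuffles.
DEFAULT_N_PERM = 500

#: Relative determinant threshold below which a (standardized) full-model
#: Gram matrix is treated as collinear / degenerate.
_DET_TOL = 1e-10


@dataclass
class VARFit:
    """Nested least-squares fits of one target series.

    ``restricted_coefficients`` is ``[intercept, own-lag 1..p]``;
    ``full_coefficients`` is ``[intercept, own-lag 1..p, other-lag 1..p]``.
    Residual variances are RSS / n_effective with ``n_effective = T - p``.
    """

    order: int
    restricted_coefficients: np.ndarray
    full_coefficients: np.ndarray
    restricted_residual_variance: float
    full_residual_variance: float
    n_effective: int

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.restricted_residual_variance < 0 or self.full_residual_variance < 0:
            raise ValueError("residual variances must be non-negative")
        if self.full_residual_variance > self.restricted_residual_variance + 1e-12:
            raise ValueError("nested fits: full variance cannot exceed restricted")


@dataclass
class InfluencePair:
    """The two Geweke measures for one seed/target pair (nats)."""

    f_seed_to_target: float
    f_target_to_seed: float


@dataclass
class InfluenceMaps:
    """Voxel-wise influence maps for one subject and one seed.

    ``map_from_seed`` holds F_{seed -> voxel} and ``map_to_seed`` holds
    F_{voxel -> seed}; out-of-mask and degenerate voxels carry NaN.
    """

    map_from_seed: np.ndarray
    map_to_seed: np.ndarray
    brain_mask: np.ndarray
    seed_label: str = "seed"

    def __post_init__(self) -> None:
        if self.map_from_seed.shape != self.map_to_seed.shape:
            raise ValueError("map grids must be congruent")
        if self.brain_mask.shape != self.map_from_seed.shape:
            raise ValueError("mask grid must match map grid")


@dataclass
class PermutationResult:
    """Observed influence, permutation null samples, and add-one p-value."""

    observed: float
    null_samples: np.ndarray
    p_value: float

    @property
    def n_perm(self) -> int:
        return self.null_samples.size


def _samples(series) -> np.ndarray:
    arr = getattr(series, "samples", series)
    return np.asarray(arr, dtype=float)


def _lagged_design(target: np.ndarray, source: np.ndarray | None, p: int):
    """Response ``target[p:]`` and design [1, target lags, (source lags)]."""
    n_t = target.size
    y = target[p:]
    cols = [np.ones(n_t - p)]
    for lag in range(1, p + 1):
        cols.append(target[p - lag : n_t - lag])
    if source is not None:
        for lag in range(1, p + 1):
            cols.append(source[p - lag : n_t - lag])
    return y, np.column_stack(cols)


def _ols(design: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return beta, float(resid @ resid), rank


def _fit_direction(source: np.ndarray, target: np.ndarray, p: int) -> tuple[VARFit, float]:
    """Nested fits of ``target`` and the influence F_{source -> target}."""
    y, x_r = _lagged_design(target, None, p)
    _, x_f = _lagged_design(target, source, p)
    beta_r, rss_r, rank_r = _ols(x_r, y)
    beta_f, rss_f, rank_f = _ols(x_f, y)
    if rank_f < x_f.shape[1] or rank_r < x_r.shape[1]:
        warnings.warn(
            "near-singular lag design: minimum-norm solution used", stacklevel=3
        )
    n_eff = y.size
    tiny = np.finfo(float).tiny
    # nested OLS guarantees rss_f <= rss_r up to round-off
    rss_f = min(max(rss_f, tiny), rss_r)
    f_val = float(np.log(max(rss_r, tiny) / rss_f))
    fit = VARFit(
        order=p,
        restricted_coefficients=beta_r,
        full_coefficients=beta_f,
        restricted_residual_variance=rss_r / n_eff,
        full_residual_variance=rss_f / n_eff,
        n_effective=n_eff,
    )
    return fit, f_val


def granger_pair(x, y, p: int = 1) -> tuple[VARFit, VARFit, InfluencePair]:
    """Bidirectional Geweke influence between two series.

    Returns ``(fit_of_y, fit_of_x, InfluencePair)`` where ``fit_of_y`` is
    the nested autoregression of the target y (yielding F_{x->y}) and
    ``fit_of_x`` the autoregression of x (yielding F_{y->x}).  All four
    models are fitted by OLS on the same ``T - p`` aligned samples.
    """
    xs, ys = _samples(x), _samples(y)
    if xs.size != ys.size:
        raise ValueError("series must have equal length")
    if xs.size < p + 10:
        raise ValueError(f"need at least p + 10 = {p + 10} samples")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("constant series: Granger influence undefined")
    fit_y, f_xy = _fit_direction(xs, ys, p)
    fit_x, f_yx = _fit_direction(ys, xs, p)
    return fit_y, fit_x, InfluencePair(f_xy, f_yx)


def select_order(x, y, p_max: int = 1) -> int:
    """Model order minimizing the Schwarz criterion of the bivariate VAR.

    For each candidate order p in 1..p_max the full bivariate model
    (each series on p lags of both, plus intercepts) is fitted on the same
    ``n = T - p_max`` aligned samples, and

        SC(p) = ln det(Sigma_p) + k * ln(n) / n

    is evaluated with Sigma_p the 2x2 residual covariance and
    k = 2 * (1 + 2p) the number of estimated coefficients.
    """
    xs, ys = _samples(x), _samples(y)
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    n_t = xs.size
    if n_t <= 10 * p_max:
        raise ValueError("series too short for requested p_max")
    n = n_t - p_max
    best_p, best_sc = 1, np.inf
    for p in range(1, p_max + 1):
        cols = [np.ones(n)]
        for lag in range(1, p + 1):
            cols.append(xs[p_max - lag : n_t - lag])
            cols.append(ys[p_max - lag : n_t - lag])
        design = np.column_stack(cols)
        resp = np.column_stack([xs[p_max:], ys[p_max:]])
        beta, *_ = np.linalg.lstsq(design, resp, rcond=None)
        resid = resp - design @ beta
        sigma = resid.T @ resid / n
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            logdet = -np.inf
        k = 2 * (1 + 2 * p)
        sc = logdet + k * np.log(n) / n
        if sc < best_sc - 1e-12:
            best_sc, best_p = sc, p
    return best_p


def _standardize_cols(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (a - a.mean(axis=0)) / sd


def _batched_f_to_targets(
    source: np.ndarray, targets: np.ndarray, assume_standardized: bool = False
) -> np.ndarray:
    """Vectorized order-1 F_{source -> column} for a (T, V) stack of targets.

    Columns are standardized first (F is scale-invariant), so a fixed
    determinant threshold detects collinear/degenerate columns, which are
    returned as NaN.  ``assume_standardized`` skips the (allocation-heavy)
    standardization when the caller guarantees unit-scale columns, e.g.
    permutations of an already-standardized series.
    """
    src = (source - source.mean()) / (source.std() or 1.0)
    tgt = targets if assume_standardized else _standardize_cols(targets)
    y_t, y_l = tgt[1:], tgt[:-1]
    x_l = src[:-1]
    n = y_t.shape[0]

    s_y = y_l.sum(0)
    s_yy = np.einsum("tv,tv->v", y_l, y_l)
    s_t = y_t.sum(0)
    s_yt = np.einsum("tv,tv->v", y_l, y_t)
    s_tt = np.einsum("tv,tv->v", y_t, y_t)
    s_x = x_l.sum()
    s_xx = x_l @ x_l
    s_xy = y_l.T @ x_l
    s_xt = y_t.T @ x_l

    n_v = targets.shape[1]
    gram_r = np.empty((n_v, 2, 2))
    gram_r[:, 0, 0] = n
    gram_r[:, 0, 1] = gram_r[:, 1, 0] = s_y
    gram_r[:, 1, 1] = s_yy
    rhs_r = np.stack([s_t, s_yt], axis=1)

    gram_f = np.empty((n_v, 3, 3))
    gram_f[:, 0, 0] = n
    gram_f[:, 0, 1] = gram_f[:, 1, 0] = s_y
    gram_f[:, 0, 2] = gram_f[:, 2, 0] = s_x
    gram_f[:, 1, 1] = s_yy
    gram_f[:, 1, 2] = gram_f[:, 2, 1] = s_xy
    gram_f[:, 2, 2] = s_xx
    rhs_f = np.stack([s_t, s_yt, s_xt], axis=1)

    det_r = gram_r[:, 0, 0] * gram_r[:, 1, 1] - gram_r[:, 0, 1] ** 2
    det_f = np.linalg.det(gram_f)
    scale = float(n) ** 3
    bad = (np.abs(det_f) < _DET_TOL * scale) | (np.abs(det_r) < _DET_TOL * n**2)
    # keep solves well-posed on the flagged entries; results overwritten with NaN
    gram_f[bad] = np.eye(3)
    rhs_f[bad] = 0.0
    gram_r[bad] = np.eye(2)
    rhs_r[bad] = 0.0

    beta_r = np.linalg.solve(gram_r, rhs_r[..., None])[..., 0]
    beta_f = np.linalg.solve(gram_f, rhs_f[..., None])[..., 0]
    rss_r = np.maximum(s_tt - np.einsum("vk,vk->v", beta_r, rhs_r), 0.0)
    rss_f = np.maximum(s_tt - np.einsum("vk,vk->v", beta_f, rhs_f), 0.0)
    rss_f = np.minimum(rss_f, rss_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = np.log(rss_r / rss_f)
    f_vals[bad | ~np.isfinite(f_vals)] = np.nan
    return f_vals


def _batched_f_from_sources(sources: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Vectorized order-1 F_{column -> target} for a (T, V) stack of sources."""
    tgt = (target - target.mean()) / (target.std() or 1.0)
    src = _standardize_cols(sources)
    y_t, y_l = tgt[1:], tgt[:-1]
    x_l = src[:-1]
    n = y_t.size

    # restricted model is shared by every column
    design_r = np.column_stack([np.ones(n), y_l])
    _, rss_r, _ = _ols(design_r, y_t)

    s_y, s_yy = y_l.sum(), y_l @ y_l
    s_t, s_yt = y_t.sum(), y_l @ y_t
    s_tt = y_t @ y_t
    s_x = x_l.sum(0)
    s_xx = np.einsum("tv,tv->v", x_l, x_l)
    s_xy = x_l.T @ y_l
    s_xt = x_l.T @ y_t

    n_v = sources.shape[1]
    gram_f = np.empty((n_v, 3, 3))
    gram_f[:, 0, 0] = n
    gram_f[:, 0, 1] = gram_f[:, 1, 0] = s_y
    gram_f[:, 0, 2] = gram_f[:, 2, 0] = s_x
    gram_f[:, 1, 1] = s_yy
    gram_f[:, 1, 2] = gram_f[:, 2, 1] = s_xy
    gram_f[:, 2, 2] = s_xx
    rhs_f = np.stack([np.full(n_v, s_t), np.full(n_v, s_yt), s_xt], axis=1)

    det_f = np.linalg.det(gram_f)
    bad = np.abs(det_f) < _DET_TOL * float(n) ** 3
    gram_f[bad] = np.eye(3)
    rhs_f[bad] = 0.0

    beta_f = np.linalg.solve(gram_f, rhs_f[..., None])[..., 0]
    rss_f = np.maximum(s_tt - np.einsum("vk,vk->v", beta_f, rhs_f), 0.0)
    rss_f = np.minimum(rss_f, rss_r)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_vals = np.log(rss_r / rss_f)
    f_vals[bad | ~np.isfinite(f_vals)] = np.nan
    return f_vals


def influence_maps(
    seed, cleaned_volume: np.ndarray, brain_mask: np.ndarray, p: int = 1,
    seed_label: str = "seed",
) -> InfluenceMaps:
    """Voxel-wise bidirectional influence between a seed series and a volume.

    ``cleaned_volume`` is a 4-D ``(X, Y, Z, T)`` array of preprocessed
    series.  Constant or collinear voxels (e.g. a voxel identical to the
    seed) are flagged as NaN; out-of-mask voxels carry NaN.  The fast
    vectorized path covers order 1; higher orders fall back to per-voxel
    :func:`granger_pair` fits.
    """
    seed_s = _samples(seed)
    mask = np.asarray(brain_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    if cleaned_volume.shape[:3] != mask.shape:
        raise ValueError("volume and mask grids differ")
    if cleaned_volume.shape[3] != seed_s.size:
        raise ValueError("voxel series length differs from seed length")

    data = np.asarray(cleaned_volume, dtype=float)[mask].T  # (T, V)
    if p == 1:
        f_from = _batched_f_to_targets(seed_s, data)
        f_to = _batched_f_from_sources(data, seed_s)
        const = data.std(axis=0) == 0
        f_from[const] = np.nan
        f_to[const] = np.nan
    else:
        n_v = data.shape[1]
        f_from = np.full(n_v, np.nan)
        f_to = np.full(n_v, np.nan)
        for v in range(n_v):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("error")
                    _, _, pair = granger_pair(seed_s, data[:, v], p)
            except (ValueError, Warning):
                continue
            f_from[v] = pair.f_seed_to_target
            f_to[v] = pair.f_target_to_seed

    map_from = np.full(mask.shape, np.nan)
    map_to = np.full(mask.shape, np.nan)
    map_from[mask] = f_from
    map_to[mask] = f_to
    return InfluenceMaps(map_from, map_to, mask, seed_label)


def permutation_pvalue(
    x,
    y,
    p: int = 1,
    direction: str = "x_to_y",
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
) -> PermutationResult:
    """Permutation significance of one directed influence.

    The null distribution is obtained by uniformly reshuffling the time
    indices of the *target* series (the source is untouched) and
    recomputing F; the p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (n_perm + 1)`` and never returns 0.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if direction not in ("x_to_y", "y_to_x"):
        raise ValueError("direction must be 'x_to_y' or 'y_to_x'")
    xs, ys = _samples(x), _samples(y)
    source, target = (xs, ys) if direction == "x_to_y" else (ys, xs)
    _, observed = _fit_direction(source, target, p)

    rng = np.random.default_rng(rng_seed)
    if p == 1:
        perms = np.empty((target.size, n_perm))
        for k in range(n_perm):
            perms[:, k] = target[rng.permutation(target.size)]
        nulls = _batched_f_to_targets(source, perms)
        nulls = np.where(np.isfinite(nulls), nulls, 0.0)
    else:
        nulls = np.empty(n_perm)
        for k in range(n_perm):
            shuffled = target[rng.permutation(target.size)]
            _, nulls[k] = _fit_direction(source, shuffled, p)
    p_val = (1.0 + np.count_nonzero(nulls >= observed)) / (n_perm + 1.0)
    return PermutationResult(observed=observed, null_samples=nulls, p_value=p_val)


def permutation_null_maps(
    seed,
    cleaned_volume: np.ndarray,
    brain_mask: np.ndarray,
    direction: str = "from_seed",
    n_perm: int = DEFAULT_N_PERM,
    rng_seed: int = 0,
    pooled: bool = False,
    voxel_sample: int | None = None,
    chunk_voxels: int = 16,
) -> np.ndarray | float:
    """Per-voxel permutation null mean for one map direction (order 1).

    For ``direction="from_seed"`` the target is each voxel (reshuffled
    independently per voxel and per permutation); for ``"to_seed"`` the
    target is the seed.  Returns a 3-D map of per-voxel null means (NaN
    outside the mask), or a single pooled scalar when ``pooled=True``
    (null samples pooled across voxels).  ``voxel_sample`` restricts the
    computation to a random subset of in-mask voxels — only meaningful
    together with ``pooled=True``.
    """
    seed_s = _samples(seed)
    mask = np.asarray(brain_mask).astype(bool)
    data = np.asarray(cleaned_volume, dtype=float)[mask].T  # (T, V)
    rng = np.random.default_rng(rng_seed)
    if voxel_sample is not None and voxel_sample < data.shape[1]:
        if not pooled:
            raise ValueError("voxel_sample requires pooled=True")
        cols = rng.choice(data.shape[1], size=voxel_sample, replace=False)
        data = data[:, cols]
    n_t, n_v = data.shape
    means = np.empty(n_v)
    if direction == "from_seed":
        # standardize once: a permutation has the same marginal mean/sd as
        # the original column, so the batched fit can skip re-scaling
        data_std = _standardize_cols(data)
        for start in range(0, n_v, chunk_voxels):
            block = data_std[:, start : start + chunk_voxels]
            n_b = block.shape[1]
            # (n_b * n_perm, T): each row one independent reshuffle of a voxel
            tiled = np.repeat(block.T, n_perm, axis=0)
            stacked = rng.permuted(tiled, axis=1).T
            f_vals = _batched_f_to_targets(seed_s, stacked, assume_standardized=True)
            f_vals = np.where(np.isfinite(f_vals), f_vals, 0.0)
            means[start : start + n_b] = f_vals.reshape(n_b, n_perm).mean(axis=1)
    elif direction == "to_seed":
        acc = np.zeros(n_v)
        for _ in range(n_perm):
            shuffled = seed_s[rng.permutation(n_t)]
            f_vals = _batched_f_from_sources(data, shuffled)
            acc += np.where(np.isfinite(f_vals), f_vals, 0.0)
        means = acc / n_perm
    else:
        raise ValueError("direction must be 'from_seed' or 'to_seed'")
    if pooled:
        return float(means.mean())
    out = np.full(mask.shape, np.nan)
    out[mask] = means
    return out
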