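"""Group-level inference on influence maps and behavioral tables.

Covers: per-group mean maps, Benjamini-Hochberg FDR thresholding,
group significance masks with a minimum cluster extent (default 10
voxels), patient-vs-control two-sample t maps restricted to the union
analysis mask, post-hoc cluster-mean Pearson correlations with clinical
scores, and the summary-statistic tests used for behavioral tables
(pooled two-sample t from printed means/SDs, tie-corrected
Kruskal-Wallis on binary category counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SubjectRecord",
    "GroupStatMap",
    "ClusterResult",
    "group_mean_map",
    "fdr_threshold",
    "significance_mask_for_group",
    "union_analysis_mask",
    "two_sample_t_map",
    "extract_clusters",
    "pooled_t_summary",
    "kruskal_wallis_binary",
    "cluster_correlation",
    "table1_summary",
]

GROUP_LABELS = ("SAD", "HC")

#: Continuous clinical scores summarized in the behavioral table.
SCORE_COLUMNS = (
    "age",
    "education",
    "lsas_total",
    "lsas_fear",
    "lsas_avoidance",
    "hamd",
    "hama",
    "stai_t",
    "stai_s_pre",
    "stai_s_post",
)


@dataclass
class SubjectRecord:
    """Group membership and clinical scores for one subject."""

    subject_id: str
    group: str
    lsas_total: float = np.nan
    lsas_fear: float = np.nan
    lsas_avoidance: float = np.nan
    hamd: float = np.nan
    hama: float = np.nan
    stai_t: float = np.nan
    stai_s_pre: float = np.nan
    stai_s_post: float = np.nan
    sex: str = "male"
    age: float = np.nan
    education: float = np.nan

    def __post_init__(self) -> None:
        if self.group not in GROUP_LABELS:
            raise ValueError(f"group must be one of {GROUP_LABELS}")


@dataclass
class GroupStatMap:
    """Voxel-wise t / p maps with the FDR decision attached."""

    t_values: np.ndarray
    p_values: np.ndarray
    fdr_threshold: float
    significance_mask: np.ndarray
    analysis_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.significance_mask & ~self.analysis_mask):
            raise ValueError("significant voxels must lie inside the analysis mask")


@dataclass
class ClusterResult:
    """One surviving cluster from a group contrast."""

    voxels: np.ndarray  # (k, 3) integer indices
    size: int
    direction: str  # "increased" (patients > controls) or "decreased"
    peak_index: tuple[int, int, int]
    per_subject_means: np.ndarray | None = None
    correlations: dict = field(default_factory=dict)


def _stack(maps) -> np.ndarray:
    arr = np.asarray([np.asarray(m, dtype=float) for m in maps])
    if arr.ndim != 4:
        raise ValueError("expected a stack of congruent 3-D maps")
    return arr


def group_mean_map(maps) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise mean over subjects, ignoring flagged (NaN) voxels.

    Returns ``(mean_map, coverage)`` where ``coverage`` counts the
    subjects contributing at each voxel.
    """
    arr = _stack(maps)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    coverage = np.isfinite(arr).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(arr, axis=0)
    return mean, coverage


def fdr_threshold(p_values, q: float = 0.05) -> tuple[float, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Sorts the m p-values ascending, finds the largest i with
    ``p_(i) <= i * q / m``, and returns ``(cutoff, flags)`` where
    ``cutoff`` is that p-value (0.0 when no rejection) and ``flags`` marks
    ``p <= cutoff`` in the original order.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    order = np.sort(p)
    m = p.size
    crit = q * np.arange(1, m + 1) / m
    passing = np.nonzero(order <= crit)[0]
    cutoff = float(order[passing[-1]]) if passing.size else 0.0
    return cutoff, p <= cutoff if passing.size else np.zeros(m, dtype=bool)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def filter_clusters(
    binary_map: np.ndarray, min_cluster_size: int = 10, connectivity: int = 26
) -> np.ndarray:
    """Remove connected components smaller than ``min_cluster_size`` voxels."""
    binary_map = np.asarray(binary_map).astype(bool)
    labels, n_lab = ndimage.label(binary_map, structure=_connectivity_structure(connectivity))
    if n_lab == 0:
        return np.zeros_like(binary_map)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n_lab + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_cluster_size
    return keep[labels]


def significance_mask_for_group(
    subject_maps,
    q: float = 0.05,
    min_cluster_size: int = 10,
    connectivity: int = 26,
    method: str = "t_vs_null",
    null_mean: float | np.ndarray = 0.0,
    subject_p_maps=None,
) -> np.ndarray:
    """Group significance mask from subject-level influence evidence.

    Two variants are provided (how the original group maps were thresholded
    is under-specified; neither claims to be canonical):

    * ``"t_vs_null"`` (default): per voxel, a one-sided one-sample t of the
      subjects' F values against ``null_mean`` (a scalar, or a 3-D map of
      pooled permutation-null means).
    * ``"fisher"``: Fisher's combination of per-subject permutation
      p-values (``subject_p_maps`` required), referred to chi-square with
      2 S degrees of freedom.

    The voxel-level p map is FDR-thresholded at ``q`` and components
    smaller than ``min_cluster_size`` are removed.
    """
    if method == "t_vs_null":
        arr = _stack(subject_maps)
        n = np.isfinite(arr).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
        mu0 = np.asarray(null_mean, dtype=float)
        valid = (n >= 2) & (sd > 0)
        t_map = np.full(mean.shape, np.nan)
        t_map[valid] = (mean[valid] - np.broadcast_to(mu0, mean.shape)[valid]) / (
            sd[valid] / np.sqrt(n[valid])
        )
        p_map = np.full(mean.shape, np.nan)
        p_map[valid] = stats.t.sf(t_map[valid], df=n[valid] - 1)
    elif method == "fisher":
        if subject_p_maps is None:
            raise ValueError("fisher method needs subject_p_maps")
        parr = _stack(subject_p_maps)
        n = np.isfinite(parr).sum(axis=0)
        valid = n >= 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            chi = -2.0 * np.nansum(np.log(np.clip(parr, 1e-300, 1.0)), axis=0)
        p_map = np.full(parr.shape[1:], np.nan)
        p_map[valid] = stats.chi2.sf(chi[valid], df=2 * n[valid])
    else:
        raise ValueError("method must be 't_vs_null' or 'fisher'")

    finite = np.isfinite(p_map)
    sig = np.zeros(p_map.shape, dtype=bool)
    if finite.any():
        _, flags = fdr_threshold(p_map[finite], q)
        sig[finite] = flags
    return filter_clusters(sig, min_cluster_size, connectivity)


def union_analysis_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxels significant in either group (the between-group analysis mask)."""
    return np.asarray(mask_a).astype(bool) | np.asarray(mask_b).astype(bool)


def two_sample_t_map(
    sad_maps,
    hc_maps,
    analysis_mask: np.ndarray,
    q: float = 0.05,
    variant: str = "pooled",
) -> GroupStatMap:
    """Voxel-wise two-tailed two-sample t map (patients minus controls).

    Restricted to ``analysis_mask``; degenerate voxels (fewer than 2
    finite subjects per group, or zero pooled variance) are flagged NaN
    and excluded from the FDR correction.  ``variant="pooled"`` uses the
    pooled-variance Student t with ``n1 + n2 - 2`` df; ``"welch"`` the
    unequal-variance form.
    """
    a = _stack(sad_maps)
    b = _stack(hc_maps)
    mask = np.asarray(analysis_mask).astype(bool)
    if a.shape[1:] != mask.shape or b.shape[1:] != mask.shape:
        raise ValueError("map grids do not match the analysis mask")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")

    n1 = np.isfinite(a).sum(axis=0)
    n2 = np.isfinite(b).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        v1, v2 = np.nanvar(a, axis=0, ddof=1), np.nanvar(b, axis=0, ddof=1)

    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    df_map = np.full(mask.shape, np.nan)
    valid = mask & (n1 >= 2) & (n2 >= 2)
    if variant == "pooled":
        df = n1 + n2 - 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        valid = valid & (sp2 > 0)
        df_map[valid] = df[valid]
    elif variant == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(v1 / n1 + v2 / n2)
            df = (v1 / n1 + v2 / n2) ** 2 / (
                (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
            )
        valid = valid & (se > 0)
        df_map[valid] = df[valid]
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    t_map[valid] = (m1[valid] - m2[valid]) / se[valid]
    p_map[valid] = 2.0 * stats.t.sf(np.abs(t_map[valid]), df=df_map[valid])

    finite = mask & np.isfinite(p_map)
    sig = np.zeros(mask.shape, dtype=bool)
    cutoff = 0.0
    if finite.any():
        cutoff, flags = fdr_threshold(p_map[finite], q)
        sig[finite] = flags
    return GroupStatMap(
        t_values=t_map,
        p_values=p_map,
        fdr_threshold=cutoff,
        significance_mask=sig,
        analysis_mask=mask,
    )


def extract_clusters(
    stat_map: GroupStatMap, min_cluster_size: int = 10, connectivity: int = 26
) -> list[ClusterResult]:
    """Surviving signed clusters of a thresholded group contrast.

    Positive-t (increased in patients) and negative-t (decreased) voxels
    are clustered separately; components below ``min_cluster_size`` are
    dropped.  Clusters are sorted by decreasing size.
    """
    structure = _connectivity_structure(connectivity)
    clusters: list[ClusterResult] = []
    for sign, name in ((1, "increased"), (-1, "decreased")):
        signed = stat_map.significance_mask & (sign * stat_map.t_values > 0)
        labels, n_lab = ndimage.label(signed, structure=structure)
        for lab in range(1, n_lab + 1):
            voxels = np.argwhere(labels == lab)
            if voxels.shape[0] < min_cluster_size:
                continue
            t_here = stat_map.t_values[tuple(voxels.T)]
            peak = voxels[np.argmax(np.abs(t_here))]
            clusters.append(
                ClusterResult(
                    voxels=voxels,
                    size=voxels.shape[0],
                    direction=name,
                    peak_index=tuple(int(i) for i in peak),
                )
            )
    clusters.sort(key=lambda c: -c.size)
    return clusters


def pooled_t_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, int]:
    """Pooled-variance two-sample two-tailed t from summary statistics.

    Returns ``(t, p, df)`` with ``df = n1 + n2 - 2``.  When both SDs are
    zero and the means equal, t is defined as 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0, df
        return float(np.sign(mean1 - mean2) * np.inf), 0.0, df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p), df


def kruskal_wallis_binary(
    group_a: tuple[int, int], group_b: tuple[int, int]
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis test on a 2-group binary category table.

    ``group_a`` and ``group_b`` give counts per category (e.g.
    male/female).  Midranks are assigned to the two tied blocks, the H
    statistic is divided by the tie correction
    ``1 - sum(t^3 - t) / (N^3 - N)``, and p comes from the chi-square
    survival function with 1 df.  With every observation in one category
    the test is degenerate and ``(0.0, 1.0)`` is returned with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.shape != (2,) or b.shape != (2,) or np.any(a < 0) or np.any(b < 0):
        raise ValueError("expected non-negative counts for two categories per group")
    tot = a + b
    n_tot = tot.sum()
    if n_tot < 3:
        raise ValueError("need at least 3 observations in total")
    if np.any(tot == 0):
        warnings.warn("all observations in one category: degenerate test", stacklevel=2)
        return 0.0, 1.0
    # midranks of the two tied blocks (category 0 first)
    midranks = np.array([(tot[0] + 1) / 2.0, tot[0] + (tot[1] + 1) / 2.0])
    n_a, n_b = a.sum(), b.sum()
    mean_a = (a @ midranks) / n_a
    mean_b = (b @ midranks) / n_b
    grand = (n_tot + 1) / 2.0
    h = 12.0 / (n_tot * (n_tot + 1)) * (
        n_a * (mean_a - grand) ** 2 + n_b * (mean_b - grand) ** 2
    )
    tie = 1.0 - (tot**3 - tot).sum() / (n_tot**3 - n_tot)
    if tie <= 0:
        warnings.warn("complete ties: degenerate test", stacklevel=2)
        return 0.0, 1.0
    h /= tie
    return float(h), float(stats.chi2.sf(h, df=1))


def cluster_correlation(
    cluster: ClusterResult,
    subject_maps,
    records: pd.DataFrame,
    score: str = "lsas_avoidance",
    per_group: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Pearson correlation of cluster-mean influence with a clinical score.

    Cluster means are the per-subject average influence over the cluster's
    voxels (NaN voxels ignored).  Correlations are computed separately per
    group (the study's convention) and flagged significant at the
    uncorrected ``alpha``.  Zero-variance scores or means yield
    ``r = p = nan``.  ``records`` rows must align with ``subject_maps``.
    """
    arr = _stack(subject_maps)
    if len(records) != arr.shape[0]:
        raise ValueError("records and subject maps are misaligned")
    idx = tuple(cluster.voxels.T)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(arr[:, idx[0], idx[1], idx[2]], axis=1)
    cluster.per_subject_means = means

    out: dict[str, dict] = {}
    groups = records["group"].unique() if per_group else ["all"]
    for grp in groups:
        sel = np.ones(len(records), dtype=bool) if grp == "all" else (
            records["group"] == grp
        ).to_numpy()
        x = means[sel]
        y = records.loc[sel, score].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            out[str(grp)] = {"r": np.nan, "p": np.nan, "n": int(x.size),
                             "significant": False}
            continue
        r, p = stats.pearsonr(x, y)
        out[str(grp)] = {"r": float(r), "p": float(p), "n": int(x.size),
                         "significant": bool(p < alpha)}
    cluster.correlations[score] = out
    return out


def table1_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Behavioral summary table: group means +- SD, pooled t and p per score,
    plus the Kruskal-Wallis p for the sex composition."""
    rows = []
    sad = records[records["group"] == "SAD"]
    hc = records[records["group"] == "HC"]
    counts_sad = ((sad["sex"] == "male").sum(), (sad["sex"] == "female").sum())
    counts_hc = ((hc["sex"] == "male").sum(), (hc["sex"] == "female").sum())
    _, kw_p = kruskal_wallis_binary(counts_sad, counts_hc)
    rows.append(
        {
            "measure": "sex (male/female)",
            "sad": f"{counts_sad[0]}/{counts_sad[1]}",
            "hc": f"{counts_hc[0]}/{counts_hc[1]}",
            "t": np.nan,
            "p": kw_p,
        }
    )
    for col in SCORE_COLUMNS:
        if col not in records.columns:
            continue
        a = sad[col].dropna()
        b = hc[col].dropna()
        if len(a) < 2 or len(b) < 2:
            continue
        t, p, _ = pooled_t_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        rows.append(
            {
                "measure": col,
                "sad": f"{a.mean():.2f} +- {a.std(ddof=1):.2f}",
                "hc": f"{b.mean():.2f} +- {b.std(ddof=1):.2f}",
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
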