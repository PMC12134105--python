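"""Matrix statistics for two-group (tumor vs. healthy) proteomics designs.

Implements the Perseus-style downstream toolchain: valid-value filtering,
per-column median centering, missing-value imputation from a downshifted
normal distribution, classic pooled-variance / paired Student t tests, the
SAM-style S0-moderated statistic with permutation-based FDR, and
Benjamini-Hochberg adjustment.

Conventions
-----------
Matrices are pandas DataFrames, features in rows and samples in columns, on a
log2 scale (redox L/H ratios are log2-transformed before testing so that the
multiplicative measurement model becomes additive).  ``mean_diff`` is always
tumor minus healthy in log2 units; for redox ratios a *negative* difference
therefore means a lower Cys_red/Cys_ox ratio — i.e. more oxidation — in tumor.

The moderated statistic follows the SAM convention: S0 is added to the
standard error in the denominator, ``s0_stat = mean_diff / (se + s0)``, which
damps the significance of features with tiny variance.  p-values always come
from the unmoderated Student statistic; S0 only enters the permutation FDR.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleMeta

__all__ = [
    "FilterSpec",
    "ImputeSpec",
    "filter_valid",
    "valid_mask",
    "log2_matrix",
    "median_center",
    "impute_downshift",
    "two_group_test",
    "permutation_fdr",
    "bh_adjust",
]

RESULT_COLUMNS = [
    "mean_diff",
    "t_stat",
    "s0_stat",
    "p_value",
    "q_value",
    "significant",
    "direction",
    "n_tumor",
    "n_healthy",
]


@dataclass(frozen=True)
class FilterSpec:
    """Valid-value filter: keep features observed in at least ``min_fraction``
    of the samples of *each* group (redox default 0.30) or of *any* one group
    (LFQ default 0.60).  Thresholds are inclusive and evaluated against each
    group's own sample count."""

    min_fraction: float
    mode: Literal["each_group", "any_group"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_fraction <= 1.0:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.mode not in ("each_group", "any_group"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


REDOX_FILTER = FilterSpec(min_fraction=0.30, mode="each_group")
LFQ_FILTER = FilterSpec(min_fraction=0.60, mode="any_group")


@dataclass(frozen=True)
class ImputeSpec:
    """Downshifted-normal imputation parameters, in units of the per-column
    observed standard deviation (defaults: width 0.3, downshift 1.8)."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError("width must be > 0")
        if self.downshift < 0:
            raise ValueError("downshift must be >= 0")


def _group_columns(
    matrix: pd.DataFrame, meta: Iterable[SampleMeta]
) -> tuple[list[str], list[str]]:
    meta = list(meta)
    tumor = [m.sample_id for m in meta if m.group == "tumor"]
    healthy = [m.sample_id for m in meta if m.group == "healthy"]
    missing = [s for s in tumor + healthy if s not in matrix.columns]
    if missing:
        raise ValueError(f"samples in metadata but not in matrix: {missing}")
    if not tumor or not healthy:
        raise ValueError("both groups must be present in the metadata")
    return tumor, healthy


def valid_mask(
    matrix: pd.DataFrame, meta: Iterable[SampleMeta], spec: FilterSpec
) -> pd.Series:
    """Boolean per-feature retention mask for the valid-value rule."""
    tumor, healthy = _group_columns(matrix, meta)
    frac_t = matrix[tumor].notna().sum(axis=1) / len(tumor)
    frac_h = matrix[healthy].notna().sum(axis=1) / len(healthy)
    if spec.mode == "each_group":
        keep = (frac_t >= spec.min_fraction) & (frac_h >= spec.min_fraction)
    else:
        keep = (frac_t >= spec.min_fraction) | (frac_h >= spec.min_fraction)
    return keep


def filter_valid(
    matrix: pd.DataFrame, meta: Iterable[SampleMeta], spec: FilterSpec
) -> pd.DataFrame:
    keep = valid_mask(matrix, meta, spec)
    if not keep.any():
        warnings.warn("valid-value filter retained no features")
    return matrix.loc[keep]


def log2_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2-transform a matrix of positive ratios/intensities (NaN preserved)."""
    if ((matrix <= 0) & matrix.notna()).any().any():
        raise ValueError("matrix contains non-positive values; cannot log2")
    return np.log2(matrix)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each column's median (over observed values)."""
    medians = matrix.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = list(medians.index[medians.isna()])
        raise ValueError(f"all-missing column(s): {empty}")
    return matrix.sub(medians, axis=1)


def impute_downshift(matrix: pd.DataFrame, spec: ImputeSpec) -> pd.DataFrame:
    """Replace missing cells with draws from a downshifted normal.

    Column-wise: missing values in column c are drawn from
    Normal(m_c - downshift * s_c, (width * s_c)^2) where m_c and s_c are the
    column's observed mean and SD.  Columns with fewer than 3 observed values
    fall back to the global mean/SD with a warning.  Observed cells are never
    touched; output is reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    values = matrix.to_numpy(dtype=float, copy=True)
    observed = ~np.isnan(values)
    global_mean = float(np.nanmean(values))
    global_sd = float(np.nanstd(values, ddof=1))
    fallback_cols = []
    for j in range(values.shape[1]):
        col = values[:, j]
        obs = observed[:, j]
        n_missing = int((~obs).sum())
        if n_missing == 0:
            continue
        if obs.sum() >= 3:
            m = float(col[obs].mean())
            s = float(col[obs].std(ddof=1))
        else:
            m, s = global_mean, global_sd
            fallback_cols.append(matrix.columns[j])
        col[~obs] = rng.normal(
            loc=m - spec.downshift * s, scale=spec.width * s, size=n_missing
        )
    if fallback_cols:
        warnings.warn(
            f"column(s) {fallback_cols} had <3 observed values; imputed from "
            "global mean/SD"
        )
    return pd.DataFrame(values, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# Two-group tests


def _unpaired_stats(
    x: np.ndarray, y: np.ndarray, s0: float
) -> tuple[np.ndarray, ...]:
    """Vectorized pooled-variance Student t over rows, NaN-aware."""
    nx = np.sum(~np.isnan(x), axis=1).astype(float)
    ny = np.sum(~np.isnan(y), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mx = np.nanmean(x, axis=1)
        my = np.nanmean(y, axis=1)
        vx = np.nanvar(x, axis=1, ddof=1)
        vy = np.nanvar(y, axis=1, ddof=1)
    ok = (nx >= 2) & (ny >= 2)
    diff = mx - my
    dof = nx + ny - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / dof
        se = np.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        t = diff / se
        s0_stat = diff / (se + s0)
    # degenerate zero-variance features
    zero_se = ok & (se == 0)
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * np.inf
    if s0 == 0:
        s0_stat[zero_se & (diff == 0)] = 0.0
        s0_stat[zero_se & (diff != 0)] = t[zero_se & (diff != 0)]
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(dof, 1))
    p[zero_se & (diff == 0)] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    bad = ~ok
    for arr in (diff, t, s0_stat, p):
        arr[bad] = np.nan
    return diff, t, s0_stat, p, nx, ny


def _paired_stats(d: np.ndarray, s0: float) -> tuple[np.ndarray, ...]:
    """Vectorized one-sample t on per-pair differences, NaN-aware."""
    n = np.sum(~np.isnan(d), axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        md = np.nanmean(d, axis=1)
        sd = np.nanstd(d, axis=1, ddof=1)
    ok = n >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = sd / np.sqrt(n)
        t = md / se
        s0_stat = md / (se + s0)
    zero_se = ok & (se == 0)
    t[zero_se & (md == 0)] = 0.0
    t[zero_se & (md != 0)] = np.sign(md[zero_se & (md != 0)]) * np.inf
    if s0 == 0:
        s0_stat[zero_se & (md == 0)] = 0.0
        s0_stat[zero_se & (md != 0)] = t[zero_se & (md != 0)]
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 1, 1))
    p[zero_se & (md == 0)] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    bad = ~ok
    for arr in (md, t, s0_stat, p):
        arr[bad] = np.nan
    return md, t, s0_stat, p, n, n


def _paired_differences(
    matrix: pd.DataFrame, meta: Iterable[SampleMeta]
) -> np.ndarray:
    """Per-pair tumor-minus-healthy difference columns (NaN where incomplete)."""
    meta = list(meta)
    tumor_by_pair = {m.pair_key: m.sample_id for m in meta if m.group == "tumor"}
    healthy_by_pair = {m.pair_key: m.sample_id for m in meta if m.group == "healthy"}
    pairs = [k for k in tumor_by_pair if k in healthy_by_pair]
    if len(pairs) < 2:
        raise ValueError("paired test needs at least 2 complete pairs")
    t_cols = [tumor_by_pair[k] for k in pairs]
    h_cols = [healthy_by_pair[k] for k in pairs]
    return (
        matrix[t_cols].to_numpy(dtype=float)
        - matrix[h_cols].to_numpy(dtype=float)
    )


def two_group_test(
    matrix: pd.DataFrame,
    meta: Iterable[SampleMeta],
    s0: float = 0.0,
    paired: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided Student t test between tumor and healthy.

    Unpaired uses the classic pooled-variance statistic; paired tests the
    per-pair differences.  Returns a DataFrame indexed by feature with
    ``mean_diff`` (tumor - healthy, log2 units), ``t_stat``, the S0-moderated
    ``s0_stat``, the unmoderated ``p_value`` and a ``direction`` call;
    features with insufficient observations get NaN results.
    """
    meta = list(meta)
    if paired:
        d = _paired_differences(matrix, meta)
        diff, t, s0_stat, p, n_t, n_h = _paired_stats(d, s0)
    else:
        tumor, healthy = _group_columns(matrix, meta)
        x = matrix[tumor].to_numpy(dtype=float)
        y = matrix[healthy].to_numpy(dtype=float)
        diff, t, s0_stat, p, n_t, n_h = _unpaired_stats(x, y, s0)

    direction = np.where(diff > 0, "up_tumor", "up_healthy")
    result = pd.DataFrame(
        {
            "mean_diff": diff,
            "t_stat": t,
            "s0_stat": s0_stat,
            "p_value": p,
            "q_value": np.nan,
            "significant": False,
            "direction": direction,
            "n_tumor": n_t,
            "n_healthy": n_h,
        },
        index=matrix.index,
    )
    result.loc[np.isnan(diff), "direction"] = ""
    return result


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# SAM-style permutation FDR


def _sam_q_values(obs: np.ndarray, perm_stats: list[np.ndarray]) -> np.ndarray:
    """Median-based SAM q-values from observed and permuted |statistics|.

    For each feature's |stat| cutoff c: q = median over permutations of the
    number of null statistics >= c, divided by the number of observed
    statistics >= c; clipped to [0, 1] and monotonized so q never decreases
    as significance decreases.
    """
    finite = ~np.isnan(obs)
    abs_obs = np.abs(obs[finite])
    order = np.argsort(abs_obs)  # ascending
    sorted_abs = abs_obs[order]
    n_obs = abs_obs.size
    # observed counts >= cutoff
    obs_counts = n_obs - np.searchsorted(sorted_abs, sorted_abs, side="left")
    null_counts = np.empty((len(perm_stats), n_obs))
    for b, ps in enumerate(perm_stats):
        ps_abs = np.sort(np.abs(ps[~np.isnan(ps)]))
        null_counts[b] = ps_abs.size - np.searchsorted(ps_abs, sorted_abs, side="left")
    med_null = np.median(null_counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        q_sorted = np.clip(med_null / obs_counts, 0.0, 1.0)
    # monotonize: in ascending |stat| order q must be non-increasing, i.e. a
    # more significant feature never exceeds the q of a less significant one
    q_sorted = np.minimum.accumulate(q_sorted)
    q_finite = np.empty(n_obs)
    q_finite[order] = q_sorted
    q = np.full(obs.shape, np.nan)
    q[finite] = q_finite
    return q


def _unpaired_permutations(
    n_total: int, n_tumor: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index sets assigning ``n_tumor`` of ``n_total`` columns to 'tumor'."""
    n_distinct = math.comb(n_total, n_tumor)
    if n_distinct <= n_perm:
        return [
            np.array(c, dtype=int)
            for c in itertools.combinations(range(n_total), n_tumor)
        ]
    perms = []
    for _ in range(n_perm):
        perms.append(rng.permutation(n_total)[:n_tumor])
    return perms


def permutation_fdr(
    matrix: pd.DataFrame,
    meta: Iterable[SampleMeta],
    s0: float = 0.1,
    n_perm: int = 250,
    seed: int = 0,
    threshold_q: float = 0.05,
    paired: bool = False,
) -> pd.DataFrame:
    """S0-moderated two-group test with SAM-style permutation q-values.

    Null statistics are generated by permuting group labels (unpaired) or by
    random sign flips of the per-pair differences (paired).  If the number of
    distinct permutations does not exceed ``n_perm``, all of them are
    enumerated exhaustively.  ``significant`` marks features with
    q < ``threshold_q``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    meta = list(meta)
    rng = np.random.default_rng(seed)
    result = two_group_test(matrix, meta, s0=s0, paired=paired)

    if paired:
        d = _paired_differences(matrix, meta)
        n_pairs = d.shape[1]
        n_distinct = 2 ** n_pairs
        if n_distinct <= n_perm:
            signs_iter = [
                np.array(s, dtype=float)
                for s in itertools.product((1.0, -1.0), repeat=n_pairs)
            ]
        else:
            signs_iter = [
                rng.choice((1.0, -1.0), size=n_pairs) for _ in range(n_perm)
            ]
        perm_stats = [
            _paired_stats(d * signs[None, :], s0)[2] for signs in signs_iter
        ]
    else:
        tumor, healthy = _group_columns(matrix, meta)
        cols = tumor + healthy
        data = matrix[cols].to_numpy(dtype=float)
        n_total, n_tumor = len(cols), len(tumor)
        perm_stats = []
        for idx in _unpaired_permutations(n_total, n_tumor, n_perm, rng):
            mask = np.zeros(n_total, dtype=bool)
            mask[idx] = True
            perm_stats.append(
                _unpaired_stats(data[:, mask], data[:, ~mask], s0)[2]
            )

    q = _sam_q_values(result["s0_stat"].to_numpy(), perm_stats)
    result = result.copy()
    result["q_value"] = q
    result["significant"] = (q < threshold_q) & ~np.isnan(q)
    return result
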