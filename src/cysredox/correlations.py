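"""Pairwise association analyses across pipeline outputs.

Links per-patient quantities from different stages — protein abundance, site
oxidation, modification frequency, thiol ratios, clinical covariates such as
SUVmax — by complete-case intersection on patient identifiers.  No imputation
is performed here; each panel reports the number of pairs it actually used.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationResult", "correlate", "correlation_panel"]


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n: int


def correlate(
    x: pd.Series,
    y: pd.Series,
    method: str = "pearson",
    log_x: bool = False,
    log_y: bool = False,
) -> CorrelationResult:
    """Correlation between two per-patient value series.

    The series are intersected on their index (patient id) and reduced to
    complete cases; at least 3 pairs are required.  ``log_x``/``log_y``
    log2-transform the corresponding variable first (non-positive values
    become missing).  Pearson p-values use the usual t approximation;
    Spearman p-values are exact at small n and approximate at large n, as
    provided by scipy.
    """
    x = pd.Series(x, dtype=float)
    y = pd.Series(y, dtype=float)
    if log_x:
        x = np.log2(x.mask(x <= 0))
    if log_y:
        y = np.log2(y.mask(y <= 0))
    joined = pd.concat([x, y], axis=1, join="inner", keys=["x", "y"]).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >= 3 complete pairs, got {n}")
    xv = joined["x"].to_numpy()
    yv = joined["y"].to_numpy()
    if np.allclose(xv, xv[0]) or np.allclose(yv, yv[0]):
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        res = sps.pearsonr(xv, yv)
    elif method == "spearman":
        res = sps.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), n)


def correlation_panel(
    spec: Sequence[tuple],
    data: Mapping[str, pd.Series],
) -> pd.DataFrame:
    """Batch correlations: one row per requested pair.

    ``spec`` entries are ``(x_name, y_name)`` or
    ``(x_name, y_name, method, log_x, log_y)``; names must resolve in
    ``data``.  A pair with fewer than 3 complete cases or a constant vector
    is flagged (``ok=False``) rather than failing the whole panel.
    """
    rows = []
    for entry in spec:
        x_name, y_name = entry[0], entry[1]
        method = entry[2] if len(entry) > 2 else "pearson"
        log_x = entry[3] if len(entry) > 3 else False
        log_y = entry[4] if len(entry) > 4 else False
        for name in (x_name, y_name):
            if name not in data:
                raise ValueError(f"unresolvable variable name {name!r}")
        try:
            r, p, n = correlate(
                data[x_name], data[y_name], method=method, log_x=log_x, log_y=log_y
            )
            ok = True
        except ValueError:
            r, p, n, ok = np.nan, np.nan, 0, False
        rows.append(
            {
                "x": x_name,
                "y": y_name,
                "method": method,
                "r": r,
                "p_value": p,
                "n": n,
                "ok": ok,
            }
        )
    return pd.DataFrame(rows)
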