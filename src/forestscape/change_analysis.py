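"""Forest-cover change rates, explanatory power, and variation partitioning.

Per cell and period pair this module derives the change in forest cover
and in every road indicator, then asks three questions the way landscape
studies usually do:

* how much of the variance in the change rate each road indicator explains
  on its own (simple linear regression, adjusted R² in percent);
* how the main-road and secondary-road indicator groups share that
  explained variance (variation partitioning of adjusted R² from the
  group-wise and combined multiple regressions);
* whether cells that start with low forest cover lose cover faster
  (regression of the change rate on initial cover).

The change rate is expressed per decade by default: ΔNFC / (Δt / 10 yr).
Raw ΔNFC and the relative change ΔNFC / NFC(t1) are available as variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .road_metrics import ROAD_CLASSES

__all__ = [
    "INDICATORS",
    "RegressionSummary",
    "PartitionResult",
    "change_rate",
    "simple_regression",
    "multiple_regression",
    "indicator_power",
    "variation_partition",
    "nfc_vs_rate_slope",
]

#: the eight road-indicator columns whose deltas are screened
INDICATORS = tuple(
    f"{metric}_{cls}" for cls in ROAD_CLASSES for metric in ("SRL", "DNR", "NON", "MND")
)


@dataclass(frozen=True)
class RegressionSummary:
    """OLS summary: slope of the (first) predictor, fit statistics."""

    slope: float
    intercept: float
    r2: float
    adj_r2_pct: float
    f_stat: float
    p_value: float
    n: int
    n_predictors: int = 1


@dataclass(frozen=True)
class PartitionResult:
    """Adjusted-R² variation partition between two predictor groups.

    ``unique_*`` and ``shared`` follow the standard partition algebra and
    satisfy ``unique_main + unique_secondary + shared = combined`` exactly.
    All components are in percent, like the adjusted R² they derive from.
    """

    adj_r2_main: float
    adj_r2_secondary: float
    adj_r2_combined: float
    p_main: float
    p_secondary: float
    p_combined: float

    @property
    def unique_main(self) -> float:
        return self.adj_r2_combined - self.adj_r2_secondary

    @property
    def unique_secondary(self) -> float:
        return self.adj_r2_combined - self.adj_r2_main

    @property
    def shared(self) -> float:
        return self.adj_r2_main + self.adj_r2_secondary - self.adj_r2_combined


def change_rate(
    table: pd.DataFrame,
    t1: str,
    t2: str,
    *,
    years: float = 20.0,
    mode: str = "per_decade",
) -> pd.DataFrame:
    """Per-cell change record between two periods.

    Parameters
    ----------
    table
        Cell table indexed by (cell_id, period) with ``NFC`` and the road
        indicator columns.
    t1, t2
        Start and end period labels (both must be present).
    years
        Elapsed time between the two periods, used by the per-decade rate.
    mode
        ``per_decade`` (default): rate = ΔNFC / (years / 10);
        ``raw``: rate = ΔNFC; ``relative``: rate = ΔNFC / NFC(t1), cells
        with NFC(t1) = 0 dropped.

    Returns a DataFrame indexed by cell id with ``nfc_t1``, ``nfc_t2``,
    ``d_nfc``, ``rate`` and a ``d_<indicator>`` column per road indicator.
    """
    periods = set(table.index.get_level_values("period"))
    for t in (t1, t2):
        if t not in periods:
            raise ValueError(f"period {t!r} absent from the cell table")
    a = table.xs(t1, level="period")
    b = table.xs(t2, level="period")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    out = pd.DataFrame(index=common.rename("cell_id"))
    out["nfc_t1"] = a["NFC"]
    out["nfc_t2"] = b["NFC"]
    out["d_nfc"] = b["NFC"] - a["NFC"]
    if mode == "per_decade":
        if years <= 0:
            raise ValueError("years must be positive")
        out["rate"] = out["d_nfc"] / (years / 10.0)
    elif mode == "raw":
        out["rate"] = out["d_nfc"]
    elif mode == "relative":
        out = out[out["nfc_t1"] > 0]
        a, b = a.loc[out.index], b.loc[out.index]
        out["rate"] = out["d_nfc"] / out["nfc_t1"]
    else:
        raise ValueError(f"unknown change-rate mode {mode!r}")
    for col in INDICATORS:
        if col in a.columns:
            out[f"d_{col}"] = b[col] - a[col]
    return out


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float, float, int]:
    """Closed-form OLS with intercept: (coefs, r2, adj_r2, f, p_value).

    Collinear columns are dropped greedily (with a warning) before
    solving the normal equations, so the predictor count entering the
    adjusted-R² penalty reflects the effective design.
    """
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        keep = [0]
        for j in range(1, design.shape[1]):
            trial = design[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
        warnings.warn(
            f"dropped {design.shape[1] - len(keep)} collinear column(s) from the design",
            stacklevel=3,
        )
        design = design[:, keep]
    p = design.shape[1] - 1
    if p < 1:
        raise ValueError("design matrix has no informative predictor")
    if n < p + 2:
        raise ValueError("too few observations for the number of predictors")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response is constant")
    r2 = 1.0 - ss_res / ss_tot
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if ss_res <= 1e-14 * ss_tot:
        f = np.inf
        p_value = 0.0
    else:
        f = ((ss_tot - ss_res) / p) / (ss_res / (n - p - 1))
        p_value = float(stats.f.sf(f, p, n - p - 1))
    return beta, r2, adj_r2, f, p_value, p


def simple_regression(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> RegressionSummary:
    """Ordinary least squares of y on a single predictor x."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(xv) < 3:
        raise ValueError("need at least three observations")
    if np.ptp(xv) == 0:
        raise ValueError("predictor is constant (degenerate design)")
    beta, r2, adj_r2, f, p_value, p = _ols(xv[:, None], yv)
    return RegressionSummary(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=r2,
        adj_r2_pct=100.0 * adj_r2,
        f_stat=float(f),
        p_value=p_value,
        n=len(xv),
        n_predictors=p,
    )


def multiple_regression(X: pd.DataFrame | np.ndarray, y: np.ndarray | pd.Series) -> RegressionSummary:
    """OLS of y on several predictors; slope reported for the first one."""
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if Xv.ndim != 2 or Xv.shape[0] != len(yv):
        raise ValueError("X must be (n, p) aligned with y")
    beta, r2, adj_r2, f, p_value, p = _ols(Xv, yv)
    return RegressionSummary(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r2=r2,
        adj_r2_pct=100.0 * adj_r2,
        f_stat=float(f),
        p_value=p_value,
        n=len(yv),
        n_predictors=p,
    )


def indicator_power(changes: pd.DataFrame) -> pd.DataFrame:
    """Explanatory power of each road-indicator change, one at a time.

    For every ``d_<indicator>`` column present, regress the change rate on
    it and report slope, adjusted R² (%), F and p.  Indicators that are
    entirely missing or constant are skipped with a warning.
    """
    rows = {}
    for col in INDICATORS:
        d = f"d_{col}"
        if d not in changes.columns:
            continue
        sub = changes[[d, "rate"]].dropna()
        if len(sub) < 3 or np.ptp(sub[d].to_numpy()) == 0:
            warnings.warn(f"indicator {col} skipped (missing or constant)", stacklevel=2)
            continue
        s = simple_regression(sub[d], sub["rate"])
        rows[col] = {
            "slope": s.slope,
            "adj_r2_pct": s.adj_r2_pct,
            "f_stat": s.f_stat,
            "p_value": s.p_value,
            "n": s.n,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("indicator")


def variation_partition(changes: pd.DataFrame) -> PartitionResult:
    """Main-road vs secondary-road variation partition of adjusted R².

    Three multiple regressions of the change rate — on the four main-road
    deltas, the four secondary-road deltas, and all eight — give the
    group-wise and combined adjusted R² (%); unique and shared components
    follow by the partition algebra.
    """
    main_cols = [f"d_{m}_main" for m in ("SRL", "DNR", "NON", "MND")]
    sec_cols = [f"d_{m}_secondary" for m in ("SRL", "DNR", "NON", "MND")]
    needed = main_cols + sec_cols + ["rate"]
    missing = [c for c in needed if c not in changes.columns]
    if missing:
        raise ValueError(f"change table lacks column(s): {missing}")
    sub = changes[needed].dropna()
    y = sub["rate"]

    def _group_fit(cols: list[str]) -> tuple[float, float]:
        """(adjusted R² %, p) for one predictor group.

        A group whose columns are all constant (e.g. a road class frozen
        between the two periods) explains nothing: adjusted R² 0, p 1.
        """
        informative = [c for c in cols if np.ptp(sub[c].to_numpy()) > 0]
        if not informative:
            warnings.warn(
                "all predictors constant in one partition group; "
                "its explained variance is zero", stacklevel=3,
            )
            return 0.0, 1.0
        s = multiple_regression(sub[informative], y)
        return s.adj_r2_pct, s.p_value

    r2_main, p_main = _group_fit(main_cols)
    r2_sec, p_sec = _group_fit(sec_cols)
    r2_all, p_all = _group_fit(main_cols + sec_cols)
    return PartitionResult(
        adj_r2_main=r2_main,
        adj_r2_secondary=r2_sec,
        adj_r2_combined=r2_all,
        p_main=p_main,
        p_secondary=p_sec,
        p_combined=p_all,
    )


def nfc_vs_rate_slope(
    table: pd.DataFrame, t1: str, t2: str, *, years: float = 20.0, mode: str = "per_decade"
) -> RegressionSummary:
    """Regression of the change rate on initial forest cover.

    A positive slope means cells with low initial cover lose cover faster
    (their rates are more negative) — the site-specific vulnerability
    pattern.
    """
    changes = change_rate(table, t1, t2, years=years, mode=mode)
    return simple_regression(changes["nfc_t1"], changes["rate"])
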