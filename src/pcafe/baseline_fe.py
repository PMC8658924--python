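"""Per-probe linear-regression feature extraction (the comparison method).

Each probe's expression is regressed on time in hours; two-sided slope
p-values are BH-adjusted across probes and probes with adjusted p strictly
below the threshold are selected.  Raw expression values are used by default;
``standardize_first=True`` applies the per-sample standardization of the PCA
pipeline beforehand (the two choices give different selections, so reports
record which was used).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_fe import standardize
from .io_geo import ExpressionMatrix
from .stats import bh_adjust, ols_slope_test_matrix

__all__ = ["BaselineResult", "BaselineTable", "run_linreg_fe"]


@dataclass
class BaselineResult:
    """One probe's regression-on-time fit."""

    probe_id: str
    intercept: float
    slope: float
    p_value: float
    adjusted_p: float
    selected: bool


@dataclass
class BaselineTable:
    """Column-wise container for all probes' fits.

    ``statistic`` is the squared slope t-statistic analogue used when the
    table is written through the shared probe-report schema; here it is
    derived from the p-value's inverse mapping and kept as ``slope/se``
    squared for direct comparability with the chi-squared report column.
    """

    probe_ids: list[str]
    intercept: np.ndarray
    slope: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    standardize_first: bool = False

    @property
    def selected_probe_ids(self) -> list[str]:
        return [
            pid for pid, sel in zip(self.probe_ids, self.selected) if bool(sel)
        ]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))

    def to_rows(self) -> list[BaselineResult]:
        return [
            BaselineResult(
                probe_id=pid,
                intercept=float(self.intercept[i]),
                slope=float(self.slope[i]),
                p_value=float(self.p_value[i]),
                adjusted_p=float(self.adjusted_p[i]),
                selected=bool(self.selected[i]),
            )
            for i, pid in enumerate(self.probe_ids)
        ]


def run_linreg_fe(
    m: ExpressionMatrix,
    alpha_probe: float = 0.01,
    standardize_first: bool = False,
) -> BaselineTable:
    """OLS of each probe on time, BH across probes, strict threshold selection."""
    if m.n_samples < 3:
        raise ValueError("need at least 3 samples")
    t = np.asarray(m.time_h, dtype=np.float64)
    if np.unique(t).size < 2:
        raise ValueError("all time values are identical")
    values = standardize(m).values if standardize_first else m.values
    intercept, slope, p = ols_slope_test_matrix(values, t)
    adjusted = bh_adjust(p)
    # squared t statistic recovered from the fit for report comparability
    t_center = t - t.mean()
    sxx = float(t_center @ t_center)
    resid = values - intercept[:, None] - slope[:, None] * t[None, :]
    rss = np.einsum("ij,ij->i", resid, resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = rss / ((t.size - 2) * sxx)
        tsq = np.where(se2 > 0, slope**2 / se2, np.inf)
    return BaselineTable(
        probe_ids=m.probe_ids,
        intercept=intercept,
        slope=slope,
        statistic=tsq,
        p_value=p,
        adjusted_p=adjusted,
        selected=adjusted < alpha_probe,
        standardize_first=standardize_first,
    )
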