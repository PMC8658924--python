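"""PCA-based unsupervised feature extraction.

The pipeline: standardize each sample column of the expression matrix (zero
mean, sum of squares equal to the probe count), take the thin SVD, regress
each sample-loading vector on time to find the time-associated components
(BH-adjusted slope p below ``alpha_component``), then score every probe by the
chi-squared statistic of its standardized scores on those components and
select probes with BH-adjusted p below ``alpha_probe``.

Conventions fixed here for reproducibility:

* components are 1-based and ordered by descending singular value;
* each probe-score vector is oriented so its largest-magnitude entry is
  positive (all reported quantities are invariant to this choice);
* ``sigma`` in the probe statistic is by default the root-mean-square of the
  probe-score vector (a population SD about zero; the scores of a
  column-centered matrix have mean ~ 0, so the mean-subtracted SD differs
  negligibly — both are available via ``sigma_mode``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_geo import ExpressionMatrix
from .stats import bh_adjust, chi2_upper_tail, ols_slope_test

__all__ = [
    "StandardizedMatrix",
    "DecompositionResult",
    "ComponentTimeAssociation",
    "ProbeScoreTable",
    "PcaFeResult",
    "standardize",
    "decompose",
    "associate_components_with_time",
    "score_probes",
    "run_pca_fe",
]

NO_COMPONENT_STATUS = "no time-associated component"


@dataclass
class StandardizedMatrix:
    """Column-standardized expression values plus pass-through metadata.

    Invariants (checked on construction): each sample column sums to ~0 and
    has a sum of squares of ~``n_probes``.
    """

    values: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]
    condition: list[str]
    time_h: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.time_h = np.asarray(self.time_h, dtype=np.float64)
        n = self.n_probes
        col_sums = self.values.sum(axis=0)
        if np.any(np.abs(col_sums) > 1e-8 * n):
            raise ValueError("standardized columns must sum to zero")
        col_sq = np.einsum("ij,ij->j", self.values, self.values)
        if np.any(np.abs(col_sq - n) > 1e-6 * n):
            raise ValueError(
                f"standardized columns must have sum of squares {n}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class DecompositionResult:
    """Thin SVD of a standardized matrix.

    ``probe_scores[:, l]`` is the probe-score vector (left singular vector)
    and ``sample_loadings[:, l]`` the sample-loading vector (right singular
    vector) of component ``l + 1``; singular values are nonincreasing.
    """

    singular_values: np.ndarray
    probe_scores: np.ndarray
    sample_loadings: np.ndarray
    probe_ids: list[str]
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.singular_values.size


@dataclass
class ComponentTimeAssociation:
    """OLS fit of one component's sample loadings on time."""

    component: int  # 1-based
    intercept: float
    slope: float
    p_value: float
    adjusted_p: float = float("nan")
    selected: bool = False


@dataclass
class ProbeScoreTable:
    """Per-probe chi-squared scores and BH selection."""

    probe_ids: list[str]
    statistic: np.ndarray
    p_value: np.ndarray
    adjusted_p: np.ndarray
    selected: np.ndarray
    sigma: dict[int, float] = field(default_factory=dict)  # per used component
    df: int = 0

    @property
    def selected_probe_ids(self) -> list[str]:
        return [
            pid for pid, sel in zip(self.probe_ids, self.selected) if bool(sel)
        ]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.selected))


def standardize(m: ExpressionMatrix) -> StandardizedMatrix:
    """Standardize each sample column: zero mean, sum of squares = n_probes.

    Equivalent to dividing the centered column by its population standard
    deviation across probes.  Raises if any column has zero variance, naming
    the offending sample.
    """
    x = m.values
    centered = x - x.mean(axis=0, keepdims=True)
    ss = np.einsum("ij,ij->j", centered, centered)
    zero = np.nonzero(ss == 0.0)[0]
    if zero.size:
        raise ValueError(
            f"zero-variance sample column(s): {[m.sample_ids[j] for j in zero]}"
        )
    scaled = centered * np.sqrt(m.n_probes / ss)
    return StandardizedMatrix(
        values=scaled,
        probe_ids=m.probe_ids,
        sample_ids=m.sample_ids,
        condition=m.condition,
        time_h=m.time_h,
    )


def decompose(sm: StandardizedMatrix) -> DecompositionResult:
    """Thin SVD with a deterministic sign convention.

    Each probe-score column is oriented so its largest-magnitude entry is
    positive; the matching sample-loading column is flipped with it, so the
    reconstruction is unchanged.
    """
    if not np.all(np.isfinite(sm.values)):
        raise ValueError("matrix contains non-finite values")
    u, s, vt = np.linalg.svd(sm.values, full_matrices=False)
    v = vt.T
    for ell in range(s.size):
        anchor = np.argmax(np.abs(u[:, ell]))
        if u[anchor, ell] < 0:
            u[:, ell] = -u[:, ell]
            v[:, ell] = -v[:, ell]
    return DecompositionResult(
        singular_values=s,
        probe_scores=u,
        sample_loadings=v,
        probe_ids=sm.probe_ids,
        sample_ids=sm.sample_ids,
    )


def _time_axis(time_h: np.ndarray, time_scale: str) -> np.ndarray:
    if time_scale == "hours":
        return np.asarray(time_h, dtype=np.float64)
    if time_scale == "log2_hours":
        t = np.asarray(time_h, dtype=np.float64)
        if np.any(t <= 0):
            raise ValueError("log2_hours requires strictly positive times")
        return np.log2(t)
    raise ValueError(f"unknown time_scale {time_scale!r}")


def associate_components_with_time(
    d: DecompositionResult,
    time_h,
    alpha_component: float = 0.05,
    time_scale: str = "hours",
) -> list[ComponentTimeAssociation]:
    """Regress every sample-loading vector on time; BH-adjust across components.

    A component is selected when its BH-adjusted two-sided slope p-value is
    strictly below ``alpha_component``.
    """
    t = _time_axis(np.asarray(time_h, dtype=np.float64), time_scale)
    if t.size != d.sample_loadings.shape[0]:
        raise ValueError("time vector length must match the number of samples")
    if t.size < 3:
        raise ValueError("need at least 3 samples")
    if np.unique(t).size < 2:
        raise ValueError("all time values are identical")
    associations = []
    for ell in range(d.n_components):
        fit = ols_slope_test(d.sample_loadings[:, ell], t)
        associations.append(
            ComponentTimeAssociation(
                component=ell + 1,
                intercept=fit.intercept,
                slope=fit.slope,
                p_value=fit.p_value,
            )
        )
    adjusted = bh_adjust([a.p_value for a in associations])
    for a, adj in zip(associations, adjusted):
        a.adjusted_p = float(adj)
        a.selected = bool(adj < alpha_component)
    return associations


def score_probes(
    d: DecompositionResult,
    selected_components: list[int],
    alpha_probe: float = 0.01,
    sigma_mode: str = "rms",
) -> ProbeScoreTable:
    """Chi-squared probe scores over the selected components.

    For each selected component ``l`` the probe scores are standardized by
    ``sigma_l`` (root mean square by default, mean-subtracted SD with
    ``sigma_mode="sd"``); the statistic is the sum of squares of the
    standardized scores and is referred to the upper tail of a chi-squared
    distribution with df equal to the number of selected components.  BH
    adjustment is across probes; selection uses strict ``< alpha_probe``.
    """
    if not selected_components:
        raise ValueError(
            "no time-associated component: probe scoring requires at least one "
            "selected component (an empty selection at pipeline level means no "
            "probes are selected, not an exception)"
        )
    if sigma_mode not in ("rms", "sd"):
        raise ValueError(f"sigma_mode must be 'rms' or 'sd', got {sigma_mode!r}")
    n_probes = d.probe_scores.shape[0]
    statistic = np.zeros(n_probes)
    sigma: dict[int, float] = {}
    for ell in selected_components:
        if not 1 <= ell <= d.n_components:
            raise ValueError(f"component index {ell} out of range")
        u = d.probe_scores[:, ell - 1]
        s = float(np.sqrt(np.mean(u**2)) if sigma_mode == "rms" else np.std(u))
        if s <= 0:
            raise ValueError(f"component {ell} has zero-spread probe scores")
        sigma[ell] = s
        statistic += (u / s) ** 2
    df = len(selected_components)
    p = chi2_upper_tail(statistic, df=df)
    adjusted = bh_adjust(p)
    return ProbeScoreTable(
        probe_ids=d.probe_ids,
        statistic=statistic,
        p_value=np.asarray(p),
        adjusted_p=adjusted,
        selected=adjusted < alpha_probe,
        sigma=sigma,
        df=df,
    )


@dataclass
class PcaFeResult:
    """Everything produced by one end-to-end run."""

    standardized: StandardizedMatrix
    decomposition: DecompositionResult
    associations: list[ComponentTimeAssociation]
    scores: ProbeScoreTable | None
    status: str  # "ok" or NO_COMPONENT_STATUS

    @property
    def selected_components(self) -> list[int]:
        return [a.component for a in self.associations if a.selected]

    @property
    def selected_probe_ids(self) -> list[str]:
        if self.scores is None:
            return []
        return self.scores.selected_probe_ids


def run_pca_fe(
    m: ExpressionMatrix,
    alpha_component: float = 0.05,
    alpha_probe: float = 0.01,
    time_scale: str = "hours",
    single_component: bool = False,
    sigma_mode: str = "rms",
) -> PcaFeResult:
    """Standardize, decompose, find time-associated components, score probes.

    With ``single_component=True`` only the most significant passing component
    is used for probe scoring (ties broken by component index).  When no
    component passes, the result carries an empty probe selection and the
    status string ``"no time-associated component"`` rather than raising.
    """
    sm = standardize(m)
    d = decompose(sm)
    associations = associate_components_with_time(
        d, m.time_h, alpha_component=alpha_component, time_scale=time_scale
    )
    chosen = [a.component for a in associations if a.selected]
    if single_component and len(chosen) > 1:
        best = min(
            (a for a in associations if a.selected),
            key=lambda a: (a.adjusted_p, a.component),
        )
        chosen = [best.component]
    if not chosen:
        return PcaFeResult(sm, d, associations, None, NO_COMPONENT_STATUS)
    scores = score_probes(
        d, chosen, alpha_probe=alpha_probe, sigma_mode=sigma_mode
    )
    return PcaFeResult(sm, d, associations, scores, "ok")
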