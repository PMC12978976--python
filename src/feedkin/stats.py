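"""Paired utensil-condition statistics.

The study design is fully paired: every participant performs the task once
with chopsticks and once with a spoon, and each kinematic metric is compared
between conditions with the Wilcoxon signed-rank test, separately per sex.
This module implements the test in the convention of the original analysis
software (SPSS): zero differences dropped, midranks on tied absolute
differences, tie-corrected variance, asymptotic z with **no** continuity
correction, two-sided normal p. The effect size is

    r = z / sqrt(N),   N = 2 * n_pairs (total observation count),

categorized as below-small (< 0.3), small (0.3-0.5), medium (0.5-0.6) or
large (>= 0.6) on |r|. Descriptives are medians with IQRs; quartiles use the
SPSS HAVERAGE rule (positions at (n+1)p) by default, switchable to the
simple linear rule.

The model-level interface follows the estimator/results pattern:
``ConditionComparison(data, ...).fit()`` returns a
:class:`ConditionComparisonResults` holding one :class:`WilcoxonResult` per
(metric, phase, stratum) with a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import UndefinedTestError, ValidationError

log = logging.getLogger(__name__)

#: |r| category bounds: small at 0.3, medium at 0.5, large at 0.6.
R_CATEGORY_BOUNDS = ((0.6, "large"), (0.5, "medium"), (0.3, "small"))

_QUANTILE_METHODS = {"haverage": "weibull", "linear": "linear"}


def median_iqr(values, rule: str = "haverage") -> tuple[float, float, float]:
    """(median, Q1, Q3) with the chosen quantile rule.

    ``haverage`` interpolates at positions (n+1)p (SPSS HAVERAGE); ``linear``
    is the numpy default.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("median_iqr: empty input")
    if rule not in _QUANTILE_METHODS:
        raise ValidationError(f"unknown quantile rule {rule!r}")
    method = _QUANTILE_METHODS[rule]
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75], method=method)
    return float(med), float(q1), float(q3)


@dataclass(frozen=True)
class PairedSample:
    """One paired metric series: a = chopsticks, b = spoon, one value per
    participant."""

    values_a: np.ndarray
    values_b: np.ndarray
    metric: str = ""
    stratum: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=float)
        b = np.asarray(self.values_b, dtype=float)
        if len(a) != len(b):
            raise ValidationError(
                f"paired sample lengths differ: {len(a)} vs {len(b)}")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    @property
    def n_pairs(self) -> int:
        return len(self.values_a)


def signed_rank_statistics(d: np.ndarray) -> tuple[float, float, int]:
    """(W+, variance-corrected z, n_nonzero) from paired differences.

    W+ is the sum of ranks of positive differences after dropping zeros;
    z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - sum(t^3 - t)/48).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= float(((counts.astype(float) ** 3 - counts).sum()) / 48.0)
    if var <= 0:
        raise UndefinedTestError("zero variance in signed-rank statistic")
    z = (w_plus - mean) / math.sqrt(var)
    return w_plus, z, n


def wilcoxon_signed_rank_z(s: PairedSample, min_pairs: int = 5
                           ) -> tuple[float, float, int]:
    """(z, two-sided p, n_nonzero) for a paired sample.

    Differences are a - b, so z is negative when condition a ranks below
    condition b. ``min_pairs`` is the floor below which the asymptotic
    approximation is flagged (a warning, not an error).
    """
    d = s.values_a - s.values_b
    _, z, n_nonzero = signed_rank_statistics(d)
    if n_nonzero < min_pairs:
        log.warning("only %d nonzero pairs; asymptotic z is unreliable", n_nonzero)
    p = 2.0 * float(norm.sf(abs(z)))
    return z, min(p, 1.0), n_nonzero


def effect_size_r(z: float, n_pairs: int) -> float:
    """Effect size r = z / sqrt(2 * n_pairs).

    N counts observations, two per participant in the paired design.
    """
    if n_pairs < 1:
        raise ValidationError("n_pairs must be >= 1")
    return z / math.sqrt(2 * n_pairs)


def categorize_r(r: float) -> str:
    """Magnitude category of |r|: below_small / small / medium / large."""
    if not np.isfinite(r):
        raise ValidationError("r must be finite")
    a = abs(r)
    for bound, label in R_CATEGORY_BOUNDS:
        if a >= bound:
            return label
    return "below_small"


@dataclass(frozen=True)
class WilcoxonResult:
    """Paired-comparison output for one metric in one stratum."""

    metric: str
    phase: str
    stratum: str
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]
    z: float
    p_two_sided: float
    r: float
    category: str
    n_pairs: int
    n_nonzero: int
    significant: bool


def compare_pair(s: PairedSample, phase: str = "", alpha: float = 0.05,
                 quantile_rule: str = "haverage") -> WilcoxonResult:
    """Full Wilcoxon comparison of one paired sample."""
    z, p, n_nonzero = wilcoxon_signed_rank_z(s)
    r = effect_size_r(z, s.n_pairs)
    med_a, q1a, q3a = median_iqr(s.values_a, quantile_rule)
    med_b, q1b, q3b = median_iqr(s.values_b, quantile_rule)
    return WilcoxonResult(
        metric=s.metric,
        phase=phase,
        stratum=s.stratum,
        median_a=med_a,
        iqr_a=(q1a, q3a),
        median_b=med_b,
        iqr_b=(q1b, q3b),
        z=z,
        p_two_sided=p,
        r=r,
        category=categorize_r(r),
        n_pairs=s.n_pairs,
        n_nonzero=n_nonzero,
        significant=p < alpha,
    )


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------

def _holm(pvals: list[float]) -> list[float]:
    order = np.argsort(pvals)
    m = len(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adj[idx] = min(1.0, running)
    return adj.tolist()


class ConditionComparison:
    """Paired condition-comparison model over a tidy metrics table.

    Parameters
    ----------
    data : DataFrame with one row per (participant, condition, metric[, phase]).
    value_col, metric_col, phase_col, condition_col, participant_col, stratum_col :
        column names; ``phase_col``/``stratum_col`` may be absent from the data.
    conditions : (a, b) pair; differences are a - b.
    alpha : per-test significance level (no multiplicity correction by
        default, matching the per-test .05 convention; ``holm=True`` adjusts
        p values within each stratum).
    """

    def __init__(self, data: pd.DataFrame, value_col: str = "value",
                 metric_col: str = "metric", phase_col: str = "phase",
                 condition_col: str = "condition",
                 participant_col: str = "participant_id",
                 stratum_col: str = "sex",
                 conditions: tuple[str, str] = ("chopsticks", "spoon"),
                 alpha: float = 0.05, quantile_rule: str = "haverage",
                 holm: bool = False):
        if not 0 < alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        self.data = data.copy()
        self.value_col = value_col
        self.metric_col = metric_col
        self.phase_col = phase_col if phase_col in data.columns else None
        self.condition_col = condition_col
        self.participant_col = participant_col
        self.stratum_col = stratum_col if stratum_col in data.columns else None
        self.conditions = conditions
        self.alpha = alpha
        self.quantile_rule = quantile_rule
        self.holm = holm

    def fit(self) -> "ConditionComparisonResults":
        df = self.data
        group_cols = [self.metric_col]
        if self.phase_col:
            group_cols.append(self.phase_col)
        if self.stratum_col:
            group_cols.append(self.stratum_col)

        results: list[WilcoxonResult] = []
        dropped: list[str] = []
        cond_a, cond_b = self.conditions
        for keys, grp in df.groupby(group_cols, sort=True, dropna=False):
            if not isinstance(keys, tuple):
                keys = (keys,)
            info = dict(zip(group_cols, keys))
            wide = grp.pivot_table(index=self.participant_col,
                                   columns=self.condition_col,
                                   values=self.value_col, aggfunc="first")
            if cond_a not in wide.columns or cond_b not in wide.columns:
                continue
            paired = wide[[cond_a, cond_b]].dropna()
            lost = sorted(set(wide.index) - set(paired.index))
            if lost:
                dropped.extend(str(x) for x in lost)
                log.warning("dropping unpaired participants %s for %s", lost, info)
            if len(paired) == 0:
                continue
            sample = PairedSample(
                values_a=paired[cond_a].to_numpy(),
                values_b=paired[cond_b].to_numpy(),
                metric=str(info[self.metric_col]),
                stratum=str(info.get(self.stratum_col, "")) if self.stratum_col else "",
            )
            try:
                res = compare_pair(sample,
                                   phase=str(info.get(self.phase_col, "")) if self.phase_col else "",
                                   alpha=self.alpha, quantile_rule=self.quantile_rule)
            except UndefinedTestError:
                log.warning("identical conditions for %s; test undefined, skipped", info)
                continue
            results.append(res)

        if self.holm and results:
            adj = _holm([r.p_two_sided for r in results])
            results = [
                WilcoxonResult(**{**r.__dict__, "p_two_sided": p,
                                  "significant": p < self.alpha})
                for r, p in zip(results, adj)
            ]
        return ConditionComparisonResults(model=self, results=results,
                                          dropped_participants=dropped)


@dataclass
class ConditionComparisonResults:
    """Fitted paired-comparison results with a tabular view."""

    model: ConditionComparison
    results: list[WilcoxonResult]
    dropped_participants: list[str] = field(default_factory=list)

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "metric": r.metric,
                    "phase": r.phase,
                    "stratum": r.stratum,
                    "median_a": r.median_a,
                    "q1_a": r.iqr_a[0],
                    "q3_a": r.iqr_a[1],
                    "median_b": r.median_b,
                    "q1_b": r.iqr_b[0],
                    "q3_b": r.iqr_b[1],
                    "z": r.z,
                    "p": r.p_two_sided,
                    "r": r.r,
                    "category": r.category,
                    "n_pairs": r.n_pairs,
                    "significant": r.significant,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable comparison table, one block per stratum."""
        a, b = self.model.conditions
        lines = ["Paired condition comparison (Wilcoxon signed-rank)",
                 f"conditions: a={a}, b={b}; alpha={self.model.alpha}", ""]
        tab = self.table
        if tab.empty:
            lines.append("(no results)")
            return "\n".join(lines)
        for stratum, grp in tab.groupby("stratum", sort=True):
            lines.append(f"stratum: {stratum or '(all)'}")
            header = (f"{'metric':<28}{'phase':<7}{'a: median (IQR)':<24}"
                      f"{'b: median (IQR)':<24}{'z':>8}{'p':>8}{'r':>8}  category")
            lines.append(header)
            lines.append("-" * len(header))
            for _, row in grp.iterrows():
                med_a = f"{row.median_a:.2f} ({row.q1_a:.2f} to {row.q3_a:.2f})"
                med_b = f"{row.median_b:.2f} ({row.q1_b:.2f} to {row.q3_b:.2f})"
                star = "*" if row.significant else " "
                lines.append(
                    f"{row.metric:<28}{row.phase:<7}{med_a:<24}{med_b:<24}"
                    f"{row.z:>8.3f}{row.p:>8.3f}{row.r:>8.3f}  {row.category}{star}"
                )
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compare_conditions(data: pd.DataFrame, stratum: str | None = None,
                       **kwargs) -> pd.DataFrame:
    """Functional wrapper: fit a :class:`ConditionComparison`, return its table."""
    if stratum is not None:
        stratum_col = kwargs.get("stratum_col", "sex")
        data = data[data[stratum_col] == stratum]
    return ConditionComparison(data, **kwargs).fit().table
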