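"""Treatment comparisons for replicated mesocosm experiments.

Replicate summaries are arithmetic mean ± standard error (SE).  Treatment
effects are assessed per size class or per plankton group with independent
two-sample t-tests at α = 0.05: variance homogeneity (Levene) decides
between the pooled-variance and Welch variants, and Shapiro–Wilk normality
is attached as a diagnostic flag without switching the test.  A
summary-statistics form of the t-test reproduces published p-values from
printed means and SEs alone.

No multiple-testing correction is applied across size classes — each class
is tested at α on its own, matching the per-class reporting convention this
mirrors — so reports carry the expected false-positive count to keep that
choice transparent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TreatmentDesign:
    """Mapping of mesocosm id → treatment arm."""

    assignment: Dict[str, str]

    def __post_init__(self):
        arms = set(self.assignment.values())
        if arms != {"control", "high_co2"}:
            raise ValueError("design needs both a control and a high_co2 arm")

    @property
    def control(self) -> Tuple[str, ...]:
        return tuple(m for m, t in self.assignment.items() if t == "control")

    @property
    def high_co2(self) -> Tuple[str, ...]:
        return tuple(m for m, t in self.assignment.items() if t == "high_co2")


def default_design() -> TreatmentDesign:
    """The 5 + 5 mesocosm design: controls M1, M3, M5, M9, M10."""
    control = ("M1", "M3", "M5", "M9", "M10")
    high = ("M2", "M4", "M6", "M7", "M8")
    return TreatmentDesign(
        assignment={**{m: "control" for m in control}, **{m: "high_co2" for m in high}}
    )


def summarize(values: Sequence[float]) -> Tuple[float, float]:
    """Arithmetic mean and standard error of replicate measurements.

    SE = sample standard deviation (ddof 1) / sqrt(n); needs n ≥ 2.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two replicate values")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class ClassComparison:
    """Two-arm comparison for one size class or plankton group."""

    label: str
    mean_control: float
    se_control: float
    mean_treatment: float
    se_treatment: float
    t_statistic: float
    df: float
    p_value: float
    significant: bool
    test_variant: str  # "pooled" or "welch"
    levene_p: Optional[float] = None
    shapiro_p_control: Optional[float] = None
    shapiro_p_treatment: Optional[float] = None
    normality_ok: Optional[bool] = None
    degenerate: bool = False


def _shapiro_p(values: np.ndarray) -> Optional[float]:
    if np.ptp(values) == 0:
        return None  # constant sample: normality test undefined
    return float(_sps.shapiro(values).pvalue)


def per_class_ttest(
    control: Sequence[float],
    treatment: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    label: str = "",
) -> ClassComparison:
    """Independent two-sample t-test with assumption checks.

    Levene's test at α decides pooled vs Welch.  Shapiro–Wilk p-values for
    each arm are recorded as diagnostics only.  If both arms are constant
    and equal, the comparison is degenerate: t = 0, p = 1, flagged.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if c.size < 2 or t.size < 2:
        raise ValueError("need at least two values per arm")
    mean_c, se_c = summarize(c)
    mean_t, se_t = summarize(t)

    if np.ptp(c) == 0 and np.ptp(t) == 0:
        if mean_c == mean_t:
            return ClassComparison(
                label=label,
                mean_control=mean_c,
                se_control=se_c,
                mean_treatment=mean_t,
                se_treatment=se_t,
                t_statistic=0.0,
                df=float(c.size + t.size - 2),
                p_value=1.0,
                significant=False,
                test_variant="pooled",
                degenerate=True,
            )
        raise ValueError("zero variance in both arms with unequal means")

    levene_p = float(_sps.levene(c, t, center="median").pvalue)
    equal_var = levene_p >= alpha
    res = _sps.ttest_ind(c, t, equal_var=equal_var)
    df = float(c.size + t.size - 2) if equal_var else float(res.df)
    p = float(res.pvalue)
    sh_c, sh_t = _shapiro_p(c), _shapiro_p(t)
    normality_ok = None
    checked = [p_ for p_ in (sh_c, sh_t) if p_ is not None]
    if checked:
        normality_ok = all(p_ >= alpha for p_ in checked)
    return ClassComparison(
        label=label,
        mean_control=mean_c,
        se_control=se_c,
        mean_treatment=mean_t,
        se_treatment=se_t,
        t_statistic=float(res.statistic),
        df=df,
        p_value=p,
        significant=bool(p < alpha),
        test_variant="pooled" if equal_var else "welch",
        levene_p=levene_p,
        shapiro_p_control=sh_c,
        shapiro_p_treatment=sh_t,
        normality_ok=normality_ok,
    )


def ttest_from_summary(
    mean1: float,
    se1: float,
    n1: int,
    mean2: float,
    se2: float,
    n2: int,
    df_rule: str = "pooled",
) -> Tuple[float, float, float]:
    """Two-sample t-test from printed means and standard errors.

    t = (mean1 − mean2) / sqrt(se1² + se2²); df is n1 + n2 − 2 under the
    pooled rule or Welch–Satterthwaite from the SEs otherwise.  Returns
    (t, df, two-sided p).
    """
    if se1 < 0 or se2 < 0:
        raise ValueError("standard errors must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per arm")
    denom_sq = se1 * se1 + se2 * se2
    if denom_sq == 0:
        if mean1 == mean2:
            return 0.0, float(n1 + n2 - 2), 1.0
        raise ValueError("zero standard errors with unequal means")
    t = (mean1 - mean2) / np.sqrt(denom_sq)
    if df_rule == "pooled":
        df = float(n1 + n2 - 2)
    elif df_rule == "welch":
        df = denom_sq**2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
    else:
        raise ValueError("df_rule must be 'pooled' or 'welch'")
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return float(t), float(df), p


def correlation_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two measurement series."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant input has no defined correlation")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def compare_by_class(
    values: pd.DataFrame,
    design: TreatmentDesign,
    class_column: str = "group",
    value_column: str = "biomass_mg_per_l",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Run :func:`per_class_ttest` for every class in a long-format table.

    ``values`` must have one row per (mesocosm, class) with columns
    ``mesocosm``, ``class_column`` and ``value_column``.  Mesocosms absent
    from a class are treated as zero measurements (the class was not
    detected there), so each test always uses the full design.  The result
    carries one row per class plus the expected false-positive count
    ``alpha × n_classes`` in the attrs, since no multiplicity correction is
    applied.
    """
    rows = []
    for cls, sub in values.groupby(class_column, observed=True):
        by_meso = sub.set_index("mesocosm")[value_column]
        c = np.array([by_meso.get(m, 0.0) for m in design.control], dtype=float)
        t = np.array([by_meso.get(m, 0.0) for m in design.high_co2], dtype=float)
        cmp_ = per_class_ttest(c, t, alpha=alpha, label=str(cls))
        rows.append(
            {
                "class": cmp_.label,
                "mean_control": cmp_.mean_control,
                "se_control": cmp_.se_control,
                "mean_high_co2": cmp_.mean_treatment,
                "se_high_co2": cmp_.se_treatment,
                "t": cmp_.t_statistic,
                "df": cmp_.df,
                "p": cmp_.p_value,
                "significant": cmp_.significant,
                "test_variant": cmp_.test_variant,
                "levene_p": cmp_.levene_p,
                "normality_ok": cmp_.normality_ok,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["expected_false_positives"] = alpha * len(out)
    return out
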