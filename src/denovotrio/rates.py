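"""Mutation-rate estimation from calls, callability and parental ages.

Two cohort-level rates are reported.  With n_f the number of de novo
mutations found in family f and S_f = sum_x C_f(x) the family's callable-site
sum, the per-position-per-generation rate is

    rate_PPPG = sum_f n_f / (2 * sum_f S_f)

(the factor 2 counts the two parental genomes surveyed per trio), and with
p_f / m_f the paternal and maternal ages at conception the per-position-
per-year rate is

    rate_PPPY = sum_f n_f / sum_f ((p_f + m_f) * S_f).

Confidence intervals are Wilson score intervals on the count with the
denominator treated as fixed.  The parental-age model is an ordinary
least-squares regression of per-family counts on both parental ages jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .core import CONTEXT_CLASSES, KIND_DEL, KIND_INS, KIND_SNV, Family


@dataclass(frozen=True)
class RateEstimate:
    """A rate with its Wilson interval, all in per-position units."""

    numerator: float
    denominator: float
    rate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rate <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass(frozen=True)
class ParentalAgeModel:
    intercept: float
    paternal_slope: float
    paternal_se: float
    paternal_p: float
    maternal_slope: float
    maternal_se: float
    maternal_p: float


def wilson_ci(successes: float, trials: float,
              level: float = 0.95) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    low, high = proportion_confint(successes, trials, alpha=1 - level,
                                   method="wilson")
    # boundary counts: the Wilson interval is exactly one-sided there
    if successes == 0:
        low = 0.0
    if successes == trials:
        high = 1.0
    return float(low), float(high)


def _rate_with_ci(numerator: float, denominator: float,
                  level: float = 0.95) -> RateEstimate:
    if denominator <= 0:
        raise ValueError("rate denominator must be positive")
    low, high = wilson_ci(numerator, denominator, level)
    return RateEstimate(numerator=numerator, denominator=denominator,
                        rate=numerator / denominator, ci_low=low, ci_high=high)


def rate_pppg(counts: pd.Series | dict, callability: pd.DataFrame,
              level: float = 0.95) -> RateEstimate:
    """Per-position-per-generation rate.

    ``counts`` maps family_id to its mutation count n_f; ``callability``
    is the per-family table with a ``snv_callable_sum``-style column named
    ``callable_sum`` or ``snv_callable_sum``/``indel_callable_sum``.
    """
    counts = pd.Series(counts)
    sums = _callable_series(callability)
    _check_families(counts, sums)
    return _rate_with_ci(float(counts.sum()), 2.0 * float(sums.sum()), level)


def rate_pppy(counts: pd.Series | dict, callability: pd.DataFrame,
              families: list[Family], level: float = 0.95) -> RateEstimate:
    """Per-position-per-year rate, weighting each family's callable sum by
    the summed parental generation interval p_f + m_f."""
    counts = pd.Series(counts)
    sums = _callable_series(callability)
    _check_families(counts, sums)
    ages = {f.family_id: f.father_age + f.mother_age for f in families}
    missing = [fid for fid in sums.index if fid not in ages]
    if missing:
        raise ValueError(f"missing parental ages for families {missing[:3]}")
    denom = float(sum(ages[fid] * sums[fid] for fid in sums.index))
    return _rate_with_ci(float(counts.sum()), denom, level)


def _callable_series(callability: pd.DataFrame, column: str | None = None) -> pd.Series:
    df = callability
    if column is None:
        for cand in ("callable_sum", "snv_callable_sum"):
            if cand in df.columns:
                column = cand
                break
        else:
            raise ValueError("no callable-sum column found")
    return df.set_index("family_id")[column]


def _check_families(counts: pd.Series, sums: pd.Series) -> None:
    extra = set(counts.index) - set(sums.index)
    if extra:
        raise ValueError(f"counts given for families without callability: "
                         f"{sorted(extra)[:3]}")


def family_counts(calls: pd.DataFrame, families: list[Family],
                  kind: str | None = KIND_SNV) -> pd.Series:
    """Per-family call counts (zero-filled), optionally restricted by kind."""
    sel = calls if kind is None else calls[calls["kind"] == kind]
    counts = sel.groupby("family_id").size()
    return counts.reindex([f.family_id for f in families], fill_value=0)


def parental_age_regression(counts: pd.Series | np.ndarray,
                            father_ages: np.ndarray,
                            mother_ages: np.ndarray) -> ParentalAgeModel:
    """OLS fit of per-family counts on both parental ages jointly."""
    y = np.asarray(counts, dtype=float)
    f = np.asarray(father_ages, dtype=float)
    m = np.asarray(mother_ages, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 families for the age regression")
    X = sm.add_constant(np.column_stack([f, m]))
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("parental ages are collinear or constant")
    fit = sm.OLS(y, X).fit()
    return ParentalAgeModel(
        intercept=float(fit.params[0]),
        paternal_slope=float(fit.params[1]), paternal_se=float(fit.bse[1]),
        paternal_p=float(fit.pvalues[1]),
        maternal_slope=float(fit.params[2]), maternal_se=float(fit.bse[2]),
        maternal_p=float(fit.pvalues[2]))


def poisson_age_regression(counts, father_ages, mother_ages) -> ParentalAgeModel:
    """Poisson-GLM (identity link) alternative to the OLS fit."""
    y = np.asarray(counts, dtype=float)
    X = sm.add_constant(np.column_stack([np.asarray(father_ages, float),
                                         np.asarray(mother_ages, float)]))
    fit = sm.GLM(y, X, family=sm.families.Poisson(
        link=sm.families.links.Identity())).fit()
    return ParentalAgeModel(
        intercept=float(fit.params[0]),
        paternal_slope=float(fit.params[1]), paternal_se=float(fit.bse[1]),
        paternal_p=float(fit.pvalues[1]),
        maternal_slope=float(fit.params[2]), maternal_se=float(fit.bse[2]),
        maternal_p=float(fit.pvalues[2]))


# ---------------------------------------------------------------------------
# stratified (Table-1 style) rates
# ---------------------------------------------------------------------------

TRANSITION_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in TRANSITION_PAIRS


def stratified_rate_table(calls: pd.DataFrame, callability: pd.DataFrame,
                          families: list[Family],
                          level: float = 0.95) -> pd.DataFrame:
    """Per-(context, change-type) PPPY rates with Wilson intervals.

    SNV cells use the per-context callable sums as denominators; insertion
    and deletion rows use the indel callable sum.  The deletion:insertion
    count ratio is attached to the frame as ``table.attrs['del_ins_ratio']``.
    """
    ages = {f.family_id: f.father_age + f.mother_age for f in families}
    per_fam = callability.set_index("family_id")
    rows = []
    snvs = calls[calls["kind"] == KIND_SNV]
    for ctx in CONTEXT_CLASSES:
        denom = float(sum(ages[fid] * per_fam.loc[fid, f"callable_{ctx}"]
                          for fid in per_fam.index))
        sub = snvs[snvs["context_class"] == ctx]
        ts = int(sum(is_transition(r, a) for r, a in
                     zip(sub["ref_allele"], sub["alt_allele"])))
        tv = len(sub) - ts
        for change, n in (("transition", ts), ("transversion", tv),
                          ("all", len(sub))):
            if denom <= 0:
                raise ValueError(f"zero callable denominator for context {ctx}")
            est = _rate_with_ci(n, denom, level) if n or denom else None
            rows.append(("SNV", ctx, change, n, est.rate, est.ci_low,
                         est.ci_high))
    indel_denom = float(sum(ages[fid] * per_fam.loc[fid, "indel_callable_sum"]
                            for fid in per_fam.index))
    n_ins = int((calls["kind"] == KIND_INS).sum())
    n_del = int((calls["kind"] == KIND_DEL).sum())
    for kind, n in ((KIND_INS, n_ins), (KIND_DEL, n_del)):
        est = _rate_with_ci(n, indel_denom, level)
        rows.append((kind, "all", "all", n, est.rate, est.ci_low, est.ci_high))

    table = pd.DataFrame(rows, columns=["kind", "context_class", "change",
                                        "count", "rate_pppy", "ci_low", "ci_high"])
    table.attrs["del_ins_ratio"] = (n_del / n_ins) if n_ins else np.inf
    return table


def deletion_insertion_ratio(calls: pd.DataFrame) -> float:
    n_del = int((calls["kind"] == KIND_DEL).sum())
    n_ins = int((calls["kind"] == KIND_INS).sum())
    if n_ins == 0:
        raise ValueError("no insertions observed; ratio undefined")
    return n_del / n_ins


def round_sig(x: float, digits: int = 3) -> float:
    """Round to significant digits, matching reported-rate formatting."""
    if x == 0:
        return 0.0
    from math import floor, log10
    return round(x, -int(floor(log10(abs(x)))) + digits - 1)
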