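"""Statistical layer: normality testing and between-region comparisons.

Heterogeneity of the membrane is assessed on the per-quadrat mean D_lat
values. Under spatial homogeneity the quadrat means are normally distributed
(central limit theorem over the many trajectory segments per quadrat), so a
one-sample Kolmogorov-Smirnov test against a normal distribution with
sample-estimated mean and SD provides the normal / not-normal verdict.

Note on the KS variant: testing against a normal whose parameters were
estimated from the same sample makes the standard KS p-value conservative
(too large); the Lilliefors correction is available via
``ks_normality(..., variant="lilliefors")`` but is not the default, because
the default reproduces the procedure the quadrat method was validated with.

Pairwise comparisons between groups of quadrats (regions, cells) use
Student's t with Welch's unequal-variance correction when both groups pass
the normality check, and the Mann-Whitney U test when at least one does not.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .quadrat import QuadratResult

__all__ = [
    "KSNormality",
    "WelchResult",
    "MannWhitneyResult",
    "PairwiseComparison",
    "HeterogeneityReport",
    "ks_normality",
    "welch_t",
    "welch_t_from_stats",
    "mann_whitney",
    "choose_pairwise_test",
    "summarize",
]

DEFAULT_ALPHA = 0.05


class KSNormality(NamedTuple):
    D: float
    pvalue: float
    verdict: str           # "normal" | "not-normal"
    n: int


class WelchResult(NamedTuple):
    t: float
    df: float
    pvalue: float


class MannWhitneyResult(NamedTuple):
    U: float
    pvalue: float


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    test: str              # "welch_t" | "mann_whitney"
    statistic: float
    pvalue: float
    df: Optional[float] = None


@dataclass
class HeterogeneityReport:
    """Summary of a set of per-quadrat D_lat values.

    ``mean`` is the mean of the quadrat means and ``sd`` their sample
    standard deviation; ``ks`` is None when the sample is too small to test
    (flagged in ``notes``).
    """

    values: np.ndarray
    n: int
    mean: float
    sd: float
    ks: Optional[KSNormality]
    alpha: float = DEFAULT_ALPHA
    groups: dict[str, "HeterogeneityReport"] = field(default_factory=dict)
    comparisons: list[PairwiseComparison] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def verdict(self) -> Optional[str]:
        return self.ks.verdict if self.ks is not None else None

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "alpha": self.alpha,
            "ks_D": self.ks.D if self.ks else None,
            "ks_p": self.ks.pvalue if self.ks else None,
            "verdict": self.verdict,
            "notes": list(self.notes),
        }
        if self.groups:
            out["groups"] = {k: v.to_dict() for k, v in self.groups.items()}
        if self.comparisons:
            out["comparisons"] = [
                {"a": c.group_a, "b": c.group_b, "test": c.test,
                 "statistic": c.statistic, "df": c.df, "p": c.pvalue}
                for c in self.comparisons
            ]
        return out


# ---------------------------------------------------------------------------


def ks_normality(values, alpha: float = DEFAULT_ALPHA,
                 variant: str = "fitted") -> KSNormality:
    """One-sample KS test of normality.

    variant "fitted" (default): KS against a normal with mean and SD
    estimated from the sample; exact finite-n null distribution for
    n <= 100, asymptotic Kolmogorov law otherwise. This reproduces the
    uncorrected procedure and is conservative. variant "lilliefors": the
    estimated-parameter correction (statsmodels).
    """
    values = np.asarray(values, float)
    n = values.size
    if n < 8:
        raise ValueError("need at least 8 values for the KS normality test")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("constant sample: KS against a fitted normal is undefined")
    if variant == "fitted":
        mode = "exact" if n <= 100 else "asymp"
        res = sps.kstest(values, "norm", args=(values.mean(), sd), mode=mode)
        D, p = float(res.statistic), float(res.pvalue)
    elif variant == "lilliefors":
        from statsmodels.stats.diagnostic import lilliefors
        D, p = lilliefors(values, dist="norm", pvalmethod="table")
        D, p = float(D), float(p)
    else:
        raise ValueError("variant must be 'fitted' or 'lilliefors'")
    verdict = "normal" if p >= alpha else "not-normal"
    return KSNormality(D, p, verdict, n)


def welch_t(a, b) -> WelchResult:
    """Two-sided Welch t test (unequal variances, Satterthwaite df)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    return welch_t_from_stats(a.mean(), a.std(ddof=1), a.size,
                              b.mean(), b.std(ddof=1), b.size)


def welch_t_from_stats(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> WelchResult:
    """Welch t from summary statistics (printed means/SDs/sample sizes)."""
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se2 = v1 + v2
    if se2 == 0:
        return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
    t = (mean1 - mean2) / np.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U (tie-corrected normal approximation; exact
    for small samples without ties)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return MannWhitneyResult(float(res.statistic), float(res.pvalue))


def choose_pairwise_test(verdict_a: str, verdict_b: str) -> str:
    """Pure selection rule: Welch t when both groups are normal, otherwise
    Mann-Whitney U."""
    return ("welch_t" if verdict_a == "normal" and verdict_b == "normal"
            else "mann_whitney")


# ---------------------------------------------------------------------------


def _report_for_values(values: np.ndarray, alpha: float,
                       ks_variant: str) -> HeterogeneityReport:
    n = values.size
    mean = float(values.mean()) if n else float("nan")
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    notes: list[str] = []
    ks = None
    if n >= 8 and sd > 0:
        ks = ks_normality(values, alpha, ks_variant)
    else:
        notes.append(f"insufficient data for KS normality test (n={n})")
    return HeterogeneityReport(values, n, mean, sd, ks, alpha, notes=notes)


def summarize(
    results: Sequence[QuadratResult],
    groups: Optional[Mapping[tuple[int, int], str]] = None,
    group_cells: Optional[Mapping[str, Iterable[tuple[int, int]]]] = None,
    alpha: float = DEFAULT_ALPHA,
    ks_variant: str = "fitted",
) -> HeterogeneityReport:
    """Build the heterogeneity report from quadrat results.

    ``groups`` maps cell -> label (one group per cell); ``group_cells`` maps
    label -> iterable of cells and allows overlapping groups (e.g. regions
    sharing a boundary column of cells). When groups are given, per-group
    reports and pairwise comparisons are added; each pairwise test is Welch's
    t if both groups pass the KS normality check and Mann-Whitney U
    otherwise.
    """
    included = {r.cell: r for r in results if r.included}
    if not included:
        raise ValueError("no included quadrats")
    values = np.array([r.D_lat for r in included.values()])
    report = _report_for_values(values, alpha, ks_variant)

    membership: dict[str, list[float]] = {}
    if group_cells is not None:
        for label, cells in group_cells.items():
            membership[label] = [included[c].D_lat for c in cells if c in included]
    elif groups is not None:
        for cell, label in groups.items():
            if cell in included:
                membership.setdefault(label, []).append(included[cell].D_lat)
    for label in sorted(membership):
        report.groups[label] = _report_for_values(
            np.asarray(membership[label], float), alpha, ks_variant)
    labels = sorted(report.groups)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ra, rb = report.groups[la], report.groups[lb]
            if ra.n < 2 or rb.n < 2:
                continue
            va = ra.verdict or "not-normal"
            vb = rb.verdict or "not-normal"
            test = choose_pairwise_test(va, vb)
            if test == "welch_t":
                w = welch_t(ra.values, rb.values)
                report.comparisons.append(
                    PairwiseComparison(la, lb, test, w.t, w.pvalue, w.df))
            else:
                m = mann_whitney(ra.values, rb.values)
                report.comparisons.append(
                    PairwiseComparison(la, lb, test, m.U, m.pvalue))
    return report
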