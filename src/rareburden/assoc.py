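"""Staged case-control association statistics on carrier counts.

Implements the association stage of the discovery workflow: stage-1 triage
(advance only variants absent from first-stage controls), per-stratum 2x2
carrier statistics (odds ratio with Woolf log-OR confidence interval,
uncorrected Pearson chi-square), Mantel-Haenszel meta-analysis across cohorts
(common odds ratio, Robins-Breslow-Greenland variance for the CI, MH
chi-square test with continuity correction) and Bonferroni correction over
the number of variants taken to stage 2.

Minor allele frequencies are computed from carrier counts under the
heterozygous-carrier assumption: MAF = carriers / (2 * N determined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "stage1_triage",
    "maf_from_carriers",
    "odds_ratio",
    "woolf_ci",
    "pearson_chisq",
    "mantel_haenszel_or",
    "rbg_ci",
    "mantel_haenszel_test",
    "bonferroni",
    "build_association_report",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @classmethod
    def from_carriers(
        cls, case_carriers: int, n_cases: int, control_carriers: int, n_controls: int
    ) -> "ContingencyTable":
        if case_carriers > n_cases or control_carriers > n_controls:
            raise ValueError("carrier count exceeds determined sample count")
        return cls(
            a=case_carriers,
            b=n_cases - case_carriers,
            c=control_carriers,
            d=n_controls - control_carriers,
        )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected(self, amount: float = 0.5) -> tuple[float, float, float, float]:
        return (self.a + amount, self.b + amount, self.c + amount, self.d + amount)


def stage1_triage(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split candidate variants by first-stage control carriers.

    Variants with at least one stage-1 control carrier are dropped; variants
    with zero control carriers advance to expanded genotyping.  Returns
    ``(advance, drop)`` DataFrames; ``counts`` needs a ``control_carriers``
    column (one row per variant).
    """
    advance = counts[counts["control_carriers"] == 0]
    drop = counts[counts["control_carriers"] > 0]
    return advance.reset_index(drop=True), drop.reset_index(drop=True)


def maf_from_carriers(carriers: int, n_determined: int) -> float:
    """MAF under the all-heterozygous assumption: carriers / (2 N)."""
    if n_determined <= 0:
        raise ValueError("n_determined must be positive")
    if not 0 <= carriers <= n_determined:
        raise ValueError("carriers must be between 0 and n_determined")
    return carriers / (2.0 * n_determined)


def odds_ratio(t: ContingencyTable, zero_cell: str = "haldane") -> float:
    """Sample odds ratio (a d) / (b c).

    ``zero_cell`` policy when any cell is zero: "haldane" adds 0.5 to every
    cell (Haldane-Anscombe); "none" returns ``inf`` when ``b c = 0`` (or 0
    when ``a d = 0``).
    """
    if t.has_zero_cell():
        if zero_cell == "haldane":
            a, b, c, d = t.corrected()
            return (a * d) / (b * c)
        if zero_cell == "none":
            if t.b * t.c == 0:
                return math.inf if t.a * t.d > 0 else math.nan
            return (t.a * t.d) / (t.b * t.c)
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")
    return (t.a * t.d) / (t.b * t.c)


def woolf_ci(
    t: ContingencyTable, level: float = 0.95, zero_cell: str = "haldane"
) -> tuple[float, float]:
    """Woolf log-odds-ratio confidence interval.

    ``exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d))``; a zero cell is handled
    by the same policy as :func:`odds_ratio` ("none" raises instead).
    """
    if t.has_zero_cell():
        if zero_cell == "none":
            raise ValueError("zero cell: cannot compute Woolf CI without correction")
        a, b, c, d = t.corrected()
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se))


def pearson_chisq(
    t: ContingencyTable, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square test (1 df) on a 2x2 table.

    ``X2 = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``; with ``continuity`` the
    Yates correction subtracts n/2 from ``|ad - bc|`` (floored at 0).  A zero
    margin yields (0, 1) by convention.
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2)
    chi2 = n * diff**2 / denom
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _check_strata(strata: Sequence[ContingencyTable]) -> None:
    if len(strata) == 0:
        raise ValueError("at least one stratum is required")


def mantel_haenszel_or(strata: Sequence[ContingencyTable]) -> float:
    """Mantel-Haenszel common odds ratio: sum(a_i d_i/n_i) / sum(b_i c_i/n_i)."""
    _check_strata(strata)
    num = sum(t.a * t.d / t.n for t in strata)
    den = sum(t.b * t.c / t.n for t in strata)
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def rbg_ci(
    strata: Sequence[ContingencyTable], level: float = 0.95
) -> tuple[float, float]:
    """Robins-Breslow-Greenland CI for the MH common odds ratio.

    With per-stratum P_i=(a_i+d_i)/n_i, Q_i=(b_i+c_i)/n_i, R_i=a_i d_i/n_i,
    S_i=b_i c_i/n_i, the variance of ln OR_MH is

        sum(P R)/(2 (sum R)^2) + sum(P S + Q R)/(2 sum R sum S)
        + sum(Q S)/(2 (sum S)^2)

    and the interval is ``exp(ln OR_MH +- z sqrt(V))``.
    """
    _check_strata(strata)
    P = np.array([(t.a + t.d) / t.n for t in strata])
    Q = np.array([(t.b + t.c) / t.n for t in strata])
    R = np.array([t.a * t.d / t.n for t in strata])
    S = np.array([t.b * t.c / t.n for t in strata])
    sum_r, sum_s = R.sum(), S.sum()
    if sum_r == 0 or sum_s == 0:
        raise ValueError("MH odds ratio degenerate (sum R or sum S is zero)")
    var = (
        (P * R).sum() / (2 * sum_r**2)
        + ((P * S).sum() + (Q * R).sum()) / (2 * sum_r * sum_s)
        + (Q * S).sum() / (2 * sum_s**2)
    )
    or_mh = sum_r / sum_s
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return (math.exp(math.log(or_mh) - half), math.exp(math.log(or_mh) + half))


def mantel_haenszel_test(
    strata: Sequence[ContingencyTable], continuity: bool = True
) -> tuple[float, float]:
    """Mantel-Haenszel chi-square test (1 df) across strata.

    ``X2 = (max(0, |sum a_i - sum E_i| - 1/2))^2 / sum V_i`` with the
    hypergeometric mean ``E_i = (a_i+b_i)(a_i+c_i)/n_i`` and variance
    ``V_i = (a_i+b_i)(c_i+d_i)(a_i+c_i)(b_i+d_i) / (n_i^2 (n_i - 1))``.
    The 1/2 continuity term is omitted when ``continuity=False``.
    """
    _check_strata(strata)
    sum_a = sum(t.a for t in strata)
    sum_e = 0.0
    sum_v = 0.0
    for t in strata:
        n = t.n
        if n <= 1:
            continue
        r1, r2 = t.a + t.b, t.c + t.d
        c1, c2 = t.a + t.c, t.b + t.d
        sum_e += r1 * c1 / n
        sum_v += r1 * r2 * c1 * c2 / (n**2 * (n - 1))
    if sum_v == 0:
        return 0.0, 1.0
    diff = abs(sum_a - sum_e)
    if continuity:
        diff = max(0.0, diff - 0.5)
    chi2 = diff**2 / sum_v
    return chi2, float(stats.chi2.sf(chi2, df=1))


def bonferroni(p: float, n_tests: int = 7) -> float:
    """Bonferroni-corrected p value: min(1, p * n_tests)."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


REPORT_COLUMNS = [
    "variant", "gene", "stratum", "cases_determined", "case_carriers",
    "controls_determined", "control_carriers", "maf_cases", "maf_controls",
    "odds_ratio", "ci_low", "ci_high", "p", "p_bonferroni", "zero_cell_corrected",
]


def build_association_report(
    counts: pd.DataFrame, n_tests: int | None = None
) -> pd.DataFrame:
    """Build the per-variant association report across strata.

    ``counts`` needs columns ``variant``, ``stratum``, ``cases_determined``,
    ``case_carriers``, ``controls_determined``, ``control_carriers`` (and
    optionally ``gene``); one row per variant per stratum, stratum order as
    first encountered.  Per-stratum rows use the sample odds ratio, Woolf CI
    and uncorrected Pearson chi-square; when a variant has more than one
    stratum a "combined" row is appended with the Mantel-Haenszel common OR,
    RBG confidence interval, continuity-corrected MH chi-square p and pooled
    MAFs.  Bonferroni correction multiplies by ``n_tests`` (default: number
    of distinct variants in ``counts``).
    """
    required = {
        "variant", "stratum", "cases_determined", "case_carriers",
        "controls_determined", "control_carriers",
    }
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table lacks columns: {sorted(missing)}")
    variants = list(dict.fromkeys(counts["variant"]))
    if n_tests is None:
        n_tests = len(variants)
    rows = []
    for variant in variants:
        sub = counts[counts["variant"] == variant]
        gene = sub["gene"].iloc[0] if "gene" in sub.columns else ""
        strata: list[ContingencyTable] = []
        for row in sub.itertuples(index=False):
            t = ContingencyTable.from_carriers(
                int(row.case_carriers), int(row.cases_determined),
                int(row.control_carriers), int(row.controls_determined),
            )
            strata.append(t)
            chi2, p = pearson_chisq(t, continuity=False)
            lo, hi = woolf_ci(t)
            rows.append({
                "variant": variant, "gene": gene, "stratum": row.stratum,
                "cases_determined": int(row.cases_determined),
                "case_carriers": int(row.case_carriers),
                "controls_determined": int(row.controls_determined),
                "control_carriers": int(row.control_carriers),
                "maf_cases": maf_from_carriers(
                    int(row.case_carriers), int(row.cases_determined)),
                "maf_controls": maf_from_carriers(
                    int(row.control_carriers), int(row.controls_determined)),
                "odds_ratio": odds_ratio(t),
                "ci_low": lo, "ci_high": hi,
                "p": p, "p_bonferroni": bonferroni(p, n_tests),
                "zero_cell_corrected": t.has_zero_cell(),
            })
        if len(strata) > 1:
            cases = int(sub["cases_determined"].sum())
            controls = int(sub["controls_determined"].sum())
            case_car = int(sub["case_carriers"].sum())
            ctrl_car = int(sub["control_carriers"].sum())
            _, p_mh = mantel_haenszel_test(strata, continuity=True)
            lo, hi = rbg_ci(strata)
            rows.append({
                "variant": variant, "gene": gene, "stratum": "combined",
                "cases_determined": cases, "case_carriers": case_car,
                "controls_determined": controls, "control_carriers": ctrl_car,
                "maf_cases": maf_from_carriers(case_car, cases),
                "maf_controls": maf_from_carriers(ctrl_car, controls),
                "odds_ratio": mantel_haenszel_or(strata),
                "ci_low": lo, "ci_high": hi,
                "p": p_mh, "p_bonferroni": bonferroni(p_mh, n_tests),
                "zero_cell_corrected": any(t.has_zero_cell() for t in strata),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
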