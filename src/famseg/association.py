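"""Case-control allelic association and cohort genotype utilities.

The allelic (2n-allele) test is used deliberately: family findings are
intersected with the cohort through *unadjusted* single-SNP associations,
so no covariates and no multiple-testing correction are applied here.
Provided statistics: allelic odds ratio with Woolf 95% CI (Haldane-
Anscombe +0.5 correction when a cell is zero), Pearson chi-square (1 df,
no Yates by default) and two-sided Fisher exact p-values, Hardy-Weinberg
equilibrium chi-square, minor-allele frequency, and carrier fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from famseg.pedio import MISSING

__all__ = [
    "AssociationResult",
    "HWEResult",
    "allele_counts",
    "odds_ratio_test",
    "hwe_chi2",
    "maf",
    "carrier_fraction",
    "allelic_association",
]


@dataclass
class AssociationResult:
    """Allelic 2x2 association summary.

    ``allele_table`` rows are (case, control), columns (risk, other).
    """

    allele_table: np.ndarray
    odds_ratio: float
    ci95: tuple[float, float]
    p_chi2: float
    p_fisher: float
    continuity_corrected: bool
    or_defined: bool = True
    maf_cases: float | None = None
    maf_controls: float | None = None
    maf_overall: float | None = None
    hwe_p_controls: float | None = None


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    p: float
    degenerate: bool = False


def allele_counts(genotypes: Sequence[int] | np.ndarray,
                  status: Sequence[str]) -> np.ndarray:
    """Build the allelic 2x2 table [[case_risk, case_other],
    [control_risk, control_other]] from dosages and case/control labels.

    Missing dosages are dropped pairwise; a group with no genotyped
    samples raises.
    """
    d = np.asarray(genotypes)
    st = np.asarray(status)
    if d.shape != st.shape:
        raise ValueError("genotypes and status differ in length")
    bad = set(st) - {"case", "control"}
    if bad:
        raise ValueError(f"unknown status label(s): {sorted(bad)}")
    table = np.zeros((2, 2), dtype=np.int64)
    for row, label in enumerate(("case", "control")):
        present = st == label
        grp = d[present & (d != MISSING)]
        if present.any() and len(grp) == 0:
            raise ValueError(f"all genotypes missing in group {label!r}")
        risk = int(grp.sum())
        table[row] = (risk, 2 * len(grp) - risk)
    return table


def odds_ratio_test(table: np.ndarray | Sequence[Sequence[int]],
                    correction: Literal["auto", "always", "never"] = "auto",
                    yates: bool = False) -> AssociationResult:
    """Allelic odds ratio with Woolf CI and chi-square / Fisher p-values.

    With ``correction='auto'`` the Haldane-Anscombe +0.5 is added to every
    cell iff the table contains a zero (only for the OR and its CI; the
    chi-square and Fisher tests always use the raw counts).  A table with
    two zero cells in one row or column leaves the OR undefined
    (``or_defined=False``).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    a, b, c, d = t.ravel()

    undefined = any(
        row.sum() == 0 for row in t) or any(col.sum() == 0 for col in t.T)
    corrected = (correction == "always" or
                 (correction == "auto" and (t == 0).any()))
    ta, tb, tc, td = (a, b, c, d)
    if corrected:
        ta, tb, tc, td = a + 0.5, b + 0.5, c + 0.5, d + 0.5

    if undefined:
        oratio, ci = float("nan"), (float("nan"), float("nan"))
    else:
        oratio = (ta * td) / (tb * tc)
        se = np.sqrt(1 / ta + 1 / tb + 1 / tc + 1 / td)
        ci = (float(np.exp(np.log(oratio) - 1.96 * se)),
              float(np.exp(np.log(oratio) + 1.96 * se)))

    if undefined or t.sum() == 0:
        p_chi2 = float("nan")
    else:
        chi2, p_chi2, _, _ = stats.chi2_contingency(t, correction=yates)
        p_chi2 = float(p_chi2)
    p_fisher = float(stats.fisher_exact(np.asarray(table))[1])
    return AssociationResult(
        allele_table=np.asarray(table, dtype=np.int64),
        odds_ratio=float(oratio), ci95=ci, p_chi2=p_chi2,
        p_fisher=p_fisher, continuity_corrected=bool(corrected),
        or_defined=not undefined)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """1-df chi-square of observed genotype counts against Hardy-Weinberg
    expectations at the sample allele frequency.

    A monomorphic sample returns chi2=0, p=1, flagged degenerate.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("negative genotype count")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty genotype counts")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return HWEResult(chi2=0.0, p=1.0, degenerate=True)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return HWEResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)))


def maf(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Minor-allele frequency from genotype counts (A counted)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype counts")
    freq = (2 * n_AA + n_Aa) / (2 * n)
    return min(freq, 1.0 - freq)


def carrier_fraction(genotypes: Sequence[int] | np.ndarray,
                     allele: Literal["ref", "alt"] = "alt") -> float:
    """Fraction of genotyped individuals carrying >= 1 copy of ``allele``."""
    d = np.asarray(genotypes)
    d = d[d != MISSING]
    if len(d) == 0:
        raise ValueError("no genotyped individuals")
    if allele == "alt":
        return float((d >= 1).mean())
    if allele == "ref":
        return float((d <= 1).mean())
    raise ValueError(f"allele must be 'ref' or 'alt', got {allele!r}")


def allelic_association(genotypes: Sequence[int] | np.ndarray,
                        status: Sequence[str],
                        correction: Literal["auto", "always", "never"] = "auto",
                        ) -> AssociationResult:
    """Full single-SNP association: table, OR/CI, p-values, group MAFs and
    control HWE, from dosages and case/control labels."""
    d = np.asarray(genotypes)
    st = np.asarray(status)
    table = allele_counts(d, st)
    res = odds_ratio_test(table, correction=correction)

    def group_maf(mask: np.ndarray) -> float:
        grp = d[mask & (d != MISSING)]
        n_aa = int((grp == 2).sum())
        n_het = int((grp == 1).sum())
        n_rr = int((grp == 0).sum())
        return maf(n_aa, n_het, n_rr)

    res.maf_cases = group_maf(st == "case")
    res.maf_controls = group_maf(st == "control")
    res.maf_overall = group_maf(np.ones_like(d, dtype=bool))
    ctrl = d[(st == "control") & (d != MISSING)]
    res.hwe_p_controls = hwe_chi2(int((ctrl == 2).sum()),
                                  int((ctrl == 1).sum()),
                                  int((ctrl == 0).sum())).p
    return res
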