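"""Cohort-level statistics: mutation spectra, association tests, signatures.

Covers the statistics behind the KIT-mutant seminoma subtype: substitution
spectrum fractions (with the CpG-context C>T deamination readout), the
cryptorchidism odds ratio for dual KIT+RAS-mutant seminomas, chi-square
association tests, immune signature scoring against methylation-based
lymphocyte estimates, and two-group comparisons (Mann-Whitney / t test).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .types import ContingencyTable2x2, SomaticMutation, SpectrumProfile, SUBSTITUTION_CLASSES

#: 2x2 reconstructions of the dual KIT+RAS-mutant seminoma vs cryptorchidism
#: association in the TCGA TGCT cohort. Rows = dual-mutant exposure, columns
#: = cryptorchidism history; counts: 6 dual-mutant seminomas (4 cryptorchid)
#: and 17 cryptorchid seminomas in total. The presets differ in the
#: denominator of seminomas with known cryptorchidism status: 66 of 72
#: samples have recorded status ("complete_records"), while the cohort
#: summary reports 68 patients ("reported_total").
CRYPTORCHIDISM_TABLES: dict[str, ContingencyTable2x2] = {
    "complete_records": ContingencyTable2x2(a=4, b=2, c=13, d=47),
    "reported_total": ContingencyTable2x2(a=4, b=2, c=13, d=49),
}

#: Cryptorchidism history by histology in the TCGA TGCT cohort
#: (seminoma 17/68 vs NSGCT 5/65), as a 2x2 table.
CRYPTORCHIDISM_BY_HISTOLOGY = ContingencyTable2x2(a=17, b=51, c=5, d=60)


def spectrum_profile(mutations: Sequence[SomaticMutation],
                     sample_id: str | None = None) -> SpectrumProfile:
    """Substitution-class fractions for one sample's mutations.

    ``ct_at_cpg_fraction`` is the share of all mutations that are C>T with a
    3' guanine (CpG context). An empty mutation set yields NaN fractions.
    """
    if sample_id is None:
        sample_id = mutations[0].sample_id if mutations else ""
    n = len(mutations)
    if n == 0:
        return SpectrumProfile(
            sample_id=sample_id,
            fractions={c: float("nan") for c in SUBSTITUTION_CLASSES},
            ct_at_cpg_fraction=float("nan"), n_mutations=0)
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    ct_cpg = 0
    for m in mutations:
        counts[m.substitution] += 1
        if m.substitution == "C>T" and m.context[2] == "G":
            ct_cpg += 1
    return SpectrumProfile(
        sample_id=sample_id,
        fractions={c: counts[c] / n for c in SUBSTITUTION_CLASSES},
        ct_at_cpg_fraction=ct_cpg / n,
        n_mutations=n)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    haldane_corrected: bool


def odds_ratio(table: ContingencyTable2x2,
               confidence: float = 0.95) -> OddsRatioResult:
    """Sample odds ratio ad/(bc) with a Wald confidence interval.

    CI = exp(ln(OR) +/- z * sqrt(1/a + 1/b + 1/c + 1/d)). When any cell is
    zero the Haldane 0.5 continuity correction is applied to every cell and
    flagged in the result. Two zero cells in a cross pattern leave the odds
    ratio undefined and raise :class:`ValidationError`.
    """
    a, b, c, d = table.cells
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        raise ValidationError("odds ratio undefined: zero cells in a cross pattern")
    haldane = any(x == 0 for x in table.cells)
    if haldane:
        a, b, c, d = (x + 0.5 for x in table.cells)
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + confidence / 2)
    return OddsRatioResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        haldane_corrected=haldane)


def chi_square_2x2(table: ContingencyTable2x2,
                   continuity_correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square (1 df) for a 2x2 table; uncorrected by default."""
    a, b, c, d = table.cells
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValidationError("chi-square undefined: zero row or column margin")
    res = stats.chi2_contingency([[a, b], [c, d]],
                                 correction=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def immune_signature_scores(expression: pd.DataFrame,
                            gene_sets: Mapping[str, Iterable[str]],
                            ) -> pd.DataFrame:
    """Score immune gene-set expression per sample.

    Each gene is median-centered across the cohort first; a signature's
    score in a sample is the median of its member genes' centered values.
    Returns a signatures x samples DataFrame; signatures with no genes in
    the matrix are skipped with a warning.
    """
    centered = expression.sub(expression.median(axis=1), axis=0)
    rows = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in centered.index]
        if not present:
            warnings.warn(f"signature {name!r}: no member genes in expression "
                          "matrix; skipped", stacklevel=2)
            continue
        rows[name] = centered.loc[present].median(axis=0)
    return pd.DataFrame(rows).T


def group_compare(values: Sequence[float], labels: Sequence,
                  test: str = "mann_whitney",
                  exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided two-group comparison.

    ``mann_whitney`` uses the exact null distribution when both groups have
    at most ``exact_max_n`` observations, and the tie-corrected normal
    approximation otherwise; ``t_test`` is Welch-free pooled Student's t.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(f"need exactly 2 groups, got {len(uniq)}")
    x = values[labels == uniq[0]]
    y = values[labels == uniq[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each group needs >= 2 observations")
    if test == "mann_whitney":
        method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if test == "t_test":
        res = stats.ttest_ind(x, y)
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown test {test!r}")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """FDR-adjusted p values (Benjamini-Hochberg); batch-use helper only."""
    return multipletests(pvalues, method="fdr_bh")[1]
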