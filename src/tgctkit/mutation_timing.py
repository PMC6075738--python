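"""Mutation multiplicity and timing relative to WGD and i(12p).

Multiplicity (s_q) is the inferred number of mutated allele copies per tumor
cell, computed from the tumor variant allele fraction (TVAF), the arm total
copy number (CN) and the tumor purity p:

    s_q = TVAF * (CN * p + 2 * (1 - p)) / p

A mutation present on a single copy before a doubling is carried to
multiplicity 2 by the WGD (and to major-allele multiplicity by an i(12p)
that duplicates its haplotype), whereas a mutation acquired afterwards sits
on one copy. Rounding s_q to the nearest integer therefore times mutations
against WGD and, for 12p mutations, against i(12p) formation.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import binomtest

from .exceptions import UsageError, ValidationError
from .types import (
    AllelicSegment,
    I12pCall,
    MultiplicityCall,
    SampleMeta,
    SomaticMutation,
)

#: Maximum |s_q - round(s_q)| for an integer multiplicity call.
DEFAULT_MULTIPLICITY_TOL = 0.35
#: Cancer-cell-fraction threshold separating clonal from subclonal.
CCF_CLONAL_THRESHOLD = 0.8
#: Maximum |RNA VAF - DNA VAF| consistent with clonal expression.
RNA_DNA_VAF_TOL = 0.2


def compute_multiplicity(tvaf: float, total_cn: int, purity: float) -> float:
    """Mutation multiplicity s_q = TVAF*(CN*purity + 2*(1-purity))/purity."""
    if not (0.0 <= tvaf <= 1.0):
        raise ValueError(f"tvaf={tvaf} outside [0, 1]")
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity={purity} outside (0, 1]")
    if total_cn <= 0:
        raise ValueError(f"total_cn={total_cn} must be positive")
    return tvaf * (total_cn * purity + 2.0 * (1.0 - purity)) / purity


def expected_tvaf(m: int, total_cn: int, purity: float) -> float:
    """Expected TVAF of a clonal mutation on ``m`` of ``total_cn`` copies.

    Exact inverse of :func:`compute_multiplicity`:
    TVAF = m*purity / (CN*purity + 2*(1-purity)).
    """
    if purity <= 0 or purity > 1:
        raise ValueError(f"purity={purity} outside (0, 1]")
    if total_cn <= 0:
        raise ValueError(f"total_cn={total_cn} must be positive")
    if m < 0 or m > total_cn:
        raise ValueError(f"multiplicity m={m} outside [0, total_cn={total_cn}]")
    return m * purity / (total_cn * purity + 2.0 * (1.0 - purity))


def _nearest_int(x: float) -> int:
    return int(math.floor(x + 0.5))


def classify_vs_wgd(s_q: float, major_cn: int, minor_cn: int, wgd_count: int,
                    tol: float = DEFAULT_MULTIPLICITY_TOL) -> str:
    """Classify a mutation's timing relative to whole-genome doubling.

    Returns one of ``before_wgd``, ``after_wgd``, ``ambiguous``, ``na``.
    ``na`` when no WGD occurred; ``ambiguous`` when s_q is not within ``tol``
    of an integer, or the rounded multiplicity is 0 or exceeds the major
    allele count (no consistent clonal configuration).
    """
    if wgd_count < 0:
        raise ValidationError(f"wgd_count={wgd_count} must be >= 0")
    if wgd_count == 0:
        return "na"
    m = _nearest_int(s_q)
    if abs(s_q - m) > tol:
        return "ambiguous"
    if m == 1:
        return "after_wgd"
    if m >= 2 and m <= major_cn:
        return "before_wgd"
    return "ambiguous"


def classify_vs_i12p(s_q: float, i12p_call: I12pCall, arm: str,
                     tol: float = DEFAULT_MULTIPLICITY_TOL) -> str:
    """Classify a 12p mutation's timing relative to i(12p) formation.

    A mutation on the duplicated haplotype before/during i(12p) formation is
    amplified to multiplicity >= 2; one acquired afterwards sits on a single
    copy. Only valid for 12p mutations in samples with an i(12p) call.
    """
    if arm != "12p":
        raise UsageError(f"i(12p) timing applies to 12p mutations only, got {arm!r}")
    if not i12p_call.present:
        raise UsageError("i(12p) timing requires an i(12p)-positive sample")
    m = _nearest_int(s_q)
    if abs(s_q - m) > tol:
        return "na"
    return "after" if m <= 1 else "before_or_during"


def assess_clonality(tvaf_dna: float, rna_vaf: Optional[float], depth: int,
                     total_cn: int, purity: float,
                     ccf_threshold: float = CCF_CLONAL_THRESHOLD,
                     rna_tol: float = RNA_DNA_VAF_TOL,
                     confidence: float = 0.95) -> str:
    """Flag a mutation clonal/subclonal/unknown from DNA/RNA VAF concordance.

    The cancer cell fraction (CCF) is s_q divided by the nearest positive
    integer multiplicity, capped at 1. ``clonal`` requires CCF >= threshold
    and, when an RNA VAF is available, DNA/RNA VAF agreement within
    ``rna_tol``. ``subclonal`` requires the CCF point estimate below the
    threshold with the binomial (Clopper-Pearson) confidence interval on the
    VAF excluding it; otherwise ``unknown`` (e.g. shallow depth).
    """
    if depth <= 0:
        raise ValidationError(f"depth={depth} must be positive")
    s_q = compute_multiplicity(tvaf_dna, total_cn, purity)
    m = max(1, _nearest_int(s_q))
    ccf = min(s_q / m, 1.0)
    rna_consistent = rna_vaf is None or abs(rna_vaf - tvaf_dna) <= rna_tol
    if ccf >= ccf_threshold and rna_consistent:
        return "clonal"
    if ccf < ccf_threshold:
        # CCF is linear in TVAF, so scale the VAF CI to a CCF CI.
        alt = int(round(tvaf_dna * depth))
        ci = binomtest(alt, depth).proportion_ci(confidence_level=confidence)
        scale = (total_cn * purity + 2.0 * (1.0 - purity)) / (purity * m)
        if min(ci.high * scale, 1.0) < ccf_threshold:
            return "subclonal"
    return "unknown"


def time_mutations(mutations: Iterable[SomaticMutation],
                   segments: Sequence[AllelicSegment],
                   samples: Sequence[SampleMeta],
                   wgd_counts: Mapping[str, int],
                   i12p_calls: Mapping[str, I12pCall],
                   tol: float = DEFAULT_MULTIPLICITY_TOL) -> list[MultiplicityCall]:
    """Run the full multiplicity/timing pipeline over a mutation table.

    Mutations in samples with missing purity, or on arms with no segment,
    yield NaN s_q with ``na``/``unknown`` classifications rather than errors
    (mirroring cohort members excluded from timing for low purity).
    """
    seg_index = {(s.sample_id, s.arm): s for s in segments}
    purity = {s.sample_id: s.purity for s in samples}
    calls = []
    for mut in mutations:
        p = purity.get(mut.sample_id)
        seg = seg_index.get((mut.sample_id, mut.arm))
        if p is None or seg is None or seg.total_cn == 0:
            calls.append(MultiplicityCall(
                sample_id=mut.sample_id, gene=mut.gene, s_q=float("nan"),
                nearest_integer_m=0, timing_vs_wgd="na", timing_vs_i12p="na",
                clonal="unknown"))
            continue
        s_q = compute_multiplicity(mut.tvaf, seg.total_cn, p)
        wgd = wgd_counts.get(mut.sample_id, 0)
        vs_wgd = classify_vs_wgd(s_q, seg.major_cn, seg.minor_cn, wgd, tol=tol)
        i12p = i12p_calls.get(mut.sample_id)
        if mut.arm == "12p" and i12p is not None and i12p.present:
            vs_i12p = classify_vs_i12p(s_q, i12p, mut.arm, tol=tol)
        else:
            vs_i12p = "na"
        clonal = assess_clonality(mut.tvaf, mut.rna_vaf, mut.depth,
                                  seg.total_cn, p)
        calls.append(MultiplicityCall(
            sample_id=mut.sample_id, gene=mut.gene, s_q=s_q,
            nearest_integer_m=max(0, _nearest_int(s_q)),
            timing_vs_wgd=vs_wgd, timing_vs_i12p=vs_i12p, clonal=clonal))
    return calls
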