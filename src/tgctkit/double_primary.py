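"""Concordance analysis for metachronous double-primary tumors.

A few percent of TGCT patients develop a second primary in the
contralateral testicle. This module compares the two tumors of one patient:
somatic mutation overlap (typically empty, consistent with mutations being
late events) and per-platform correlation of molecular profiles computed on
the shared feature set.
"""
from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .types import PairConcordance, SomaticMutation


def _mutation_keys(mutations: Sequence[SomaticMutation]) -> set[tuple]:
    # arm-granular model: identity at gene + substitution + context
    return {(m.gene, m.substitution, m.context) for m in mutations}


def pair_concordance(patient_id: str,
                     mutations_t1: Sequence[SomaticMutation],
                     mutations_t2: Sequence[SomaticMutation],
                     platform_matrices: Mapping[str, pd.DataFrame],
                     sample_t1: str, sample_t2: str,
                     method: str = "pearson") -> PairConcordance:
    """Compare two primary tumors of one patient across platforms.

    ``platform_matrices`` maps platform name to a features x samples matrix
    containing columns for both tumors; platforms missing either tumor are
    skipped with a warning. Correlations use features non-missing in both
    tumors.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown correlation method {method!r}")
    k1, k2 = _mutation_keys(mutations_t1), _mutation_keys(mutations_t2)
    correlations: dict[str, float] = {}
    for platform, matrix in platform_matrices.items():
        if sample_t1 not in matrix.columns or sample_t2 not in matrix.columns:
            warnings.warn(f"platform {platform!r}: missing sample for patient "
                          f"{patient_id}; skipped", stacklevel=2)
            continue
        pair = matrix[[sample_t1, sample_t2]].dropna()
        if len(pair) < 3:
            warnings.warn(f"platform {platform!r}: < 3 shared features; "
                          "skipped", stacklevel=2)
            continue
        if method == "pearson":
            r = stats.pearsonr(pair[sample_t1], pair[sample_t2]).statistic
        else:
            r = stats.spearmanr(pair[sample_t1], pair[sample_t2]).statistic
        correlations[platform] = float(r)
    return PairConcordance(
        patient_id=patient_id,
        shared_mutations=len(k1 & k2),
        mutations_t1_only=len(k1 - k2),
        mutations_t2_only=len(k2 - k1),
        platform_correlation=correlations)
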