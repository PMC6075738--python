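"""Arm-level somatic copy-number event calling.

TGCT genomes are hyper-triploid: essentially every tumor has undergone at
least one whole-genome doubling (WGD), followed by histology-specific arm
losses, and nearly all carry at least one isochromosome 12p. This module
calls WGD count, i(12p) presence, 12q LOH, arm gains/losses relative to
ploidy, and a frequency/aneuploidy-based early-late ordering of arm events.
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .types import (
    ARM_LENGTHS_MB,
    AllelicSegment,
    ArmEventCall,
    GenomeDoublingCall,
    I12pCall,
)

#: Minimum number of arms for genome-wide ploidy/WGD inference.
MIN_ARMS_FOR_WGD = 10
#: Minimum group size for the arm-event ordering table.
MIN_GROUP_SIZE = 5


def infer_wgd_count(segments: Sequence[AllelicSegment]) -> GenomeDoublingCall:
    """Call the number of whole-genome doublings for one sample.

    One WGD is called when the genome-length-weighted fraction of arms with
    major copy number >= 2 exceeds 0.5; a second WGD when the fraction with
    major >= 3 exceeds 0.5. Ploidy is the length-weighted mean total copy
    number over arms.
    """
    if not segments:
        raise ValidationError("empty segment set")
    if len(segments) < MIN_ARMS_FOR_WGD:
        raise ValidationError(
            f"need >= {MIN_ARMS_FOR_WGD} arms for WGD inference, got {len(segments)}"
        )
    sample_ids = {s.sample_id for s in segments}
    if len(sample_ids) != 1:
        raise ValidationError(f"segments span multiple samples: {sorted(sample_ids)}")
    weights = np.array([ARM_LENGTHS_MB[s.arm] for s in segments])
    majors = np.array([s.major_cn for s in segments])
    totals = np.array([s.total_cn for s in segments])
    wsum = weights.sum()
    f2 = float(weights[majors >= 2].sum() / wsum)
    f3 = float(weights[majors >= 3].sum() / wsum)
    wgd = 0
    if f2 > 0.5:
        wgd = 1
        if f3 > 0.5:
            wgd = 2
    return GenomeDoublingCall(
        sample_id=segments[0].sample_id,
        wgd_count=wgd,
        ploidy=float((weights * totals).sum() / wsum),
        fraction_major_ge2=f2,
        fraction_major_ge3=f3,
    )


def detect_i12p(segments: Sequence[AllelicSegment]) -> I12pCall:
    """Call isochromosome 12p from one sample's chromosome-12 allelic profile.

    An i(12p) duplicates the p arm of one chromosome-12 homolog, so its
    signature is a 12p excess over 12q on both the total and the major
    haplotype: present iff total(12p) - total(12q) >= 1 and
    major(12p) - major(12q) >= 1. 12q LOH is a zero minor allele on 12q.
    """
    by_arm = {s.arm: s for s in segments if s.arm in ("12p", "12q")}
    if "12p" not in by_arm or "12q" not in by_arm:
        raise ValidationError("both 12p and 12q segments are required")
    p, q = by_arm["12p"], by_arm["12q"]
    present = (p.total_cn - q.total_cn >= 1) and (p.major_cn - q.major_cn >= 1)
    return I12pCall(
        sample_id=p.sample_id,
        present=present,
        n_12p_copies=p.total_cn,
        n_12q_copies=q.total_cn,
        loh_12q=(q.minor_cn == 0),
    )


def call_arm_events(segments: Sequence[AllelicSegment], ploidy: float,
                    ) -> list[ArmEventCall]:
    """Call arm gains/losses relative to the rounded sample ploidy.

    delta = total_cn - round(ploidy); loss at delta <= -1, gain at >= +1.
    """
    if ploidy <= 0:
        raise ValidationError(f"ploidy must be positive, got {ploidy}")
    baseline = int(np.floor(ploidy + 0.5))
    calls = []
    for seg in segments:
        delta = seg.total_cn - baseline
        direction = "loss" if delta <= -1 else ("gain" if delta >= 1 else "neutral")
        calls.append(ArmEventCall(
            sample_id=seg.sample_id, arm=seg.arm, direction=direction,
            total_cn=seg.total_cn, delta_vs_ploidy=float(seg.total_cn - ploidy),
        ))
    return calls


def order_arm_events(calls: Iterable[ArmEventCall],
                     groups: Mapping[str, str],
                     min_group_size: int = MIN_GROUP_SIZE) -> pd.DataFrame:
    """Rank arm events within groups by an early/late timing score.

    Events arising early are both frequent in the group and present in
    samples of every aneuploidy level, whereas late events are confined to
    genomes that have already accumulated many arm changes. The score for
    event ``e`` (an (arm, direction) pair) in group ``g`` is::

        timing_score = freq(e) / (1 + burden(e))

    where ``freq`` is the carrier fraction within the group and ``burden``
    the median, over carriers, of each carrier's total non-neutral arm
    count. Higher score = inferred earlier; ranks are assigned per group
    descending, with ties broken by higher frequency then arm name.

    Groups smaller than ``min_group_size`` are skipped with a warning.
    """
    df = pd.DataFrame(
        [(c.sample_id, c.arm, c.direction) for c in calls],
        columns=["sample_id", "arm", "direction"],
    )
    if df.empty:
        raise ValidationError("no arm event calls supplied")
    df["group"] = df["sample_id"].map(groups)
    df = df.dropna(subset=["group"])
    burden = (
        df[df["direction"] != "neutral"].groupby("sample_id").size()
        .reindex(df["sample_id"].unique(), fill_value=0)
    )
    rows = []
    for group, gdf in sorted(df.groupby("group"), key=lambda kv: kv[0]):
        samples = gdf["sample_id"].unique()
        if len(samples) < min_group_size:
            warnings.warn(
                f"group {group!r} has {len(samples)} samples "
                f"(< {min_group_size}); skipped", stacklevel=2)
            continue
        events = gdf[gdf["direction"] != "neutral"]
        for (arm, direction), edf in events.groupby(["arm", "direction"]):
            carriers = edf["sample_id"].unique()
            freq = len(carriers) / len(samples)
            med_burden = float(np.median(burden.loc[carriers]))
            rows.append((group, arm, direction, len(carriers), freq,
                         med_burden, freq / (1.0 + med_burden)))
    table = pd.DataFrame(rows, columns=[
        "group", "arm", "direction", "n_carriers", "frequency",
        "median_burden", "timing_score",
    ])
    if table.empty:
        return table.assign(rank=pd.Series(dtype=int))
    # deterministic rank: score desc, then frequency desc, then arm name
    table = table.sort_values(
        ["group", "timing_score", "frequency", "arm"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = table.groupby("group").cumcount() + 1
    return table
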