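"""Readers and writers for the toolkit's tabular formats.

All tables are UTF-8 TSV with a single header row; missing values are
serialised as ``NA``. The mutation table is a MAF-subset dialect (arm-level
coordinates, read counts, trinucleotide context); the segment table is a
SEG-like dialect extended with major/minor allelic copy-number columns.
Writer/reader pairs are bit-exact round trips on valid inputs.
"""
from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import pandas as pd

from .exceptions import FormatError, ValidationError
from .types import (
    AllelicSegment,
    BetaMatrix,
    COMPONENT_HISTOLOGIES,
    CHROMATIN_REGIONS,
    PROBE_CONTEXTS,
    SampleMeta,
    SomaticMutation,
)

_NA = "NA"

MUTATION_COLUMNS = (
    "sample_id", "gene", "arm", "alt_count", "ref_count",
    "tvaf", "context", "substitution", "rna_vaf",
)
_MUTATION_REQUIRED = (
    "sample_id", "gene", "arm", "alt_count", "ref_count", "context", "substitution",
)
SEGMENT_COLUMNS = ("sample_id", "arm", "major_cn", "minor_cn")
SAMPLE_COLUMNS = (
    "sample_id", "histology", "kit_status", "ras_status", "cryptorchidism",
    "purity", "ploidy",
) + tuple(f"frac_{h}" for h in COMPONENT_HISTOLOGIES)
PROBE_COLUMNS = (
    "probe_id", "context", "region", "imprinted_dmr",
    "lymphocyte_signature", "lymphocyte_ref_beta", "promoter_of_gene",
)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_NA], keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _fmt(value) -> str:
    """Serialise one cell; repr() of floats round-trips bit-exactly."""
    if value is None:
        return _NA
    if isinstance(value, float):
        return _NA if math.isnan(value) else repr(value)
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def _write_rows(path, columns: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------- mutations

def read_mutations(path) -> list[SomaticMutation]:
    """Read a mutation TSV; ``tvaf`` is computed from counts when absent."""
    df = _read_tsv(path, _MUTATION_REQUIRED)
    out: list[SomaticMutation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        alt, ref = int(row.alt_count), int(row.ref_count)
        if alt < 0 or ref < 0:
            raise ValidationError(f"{path}: negative read counts on row {i}")
        try:
            out.append(SomaticMutation(
                sample_id=row.sample_id,
                gene=row.gene,
                arm=row.arm,
                alt_count=alt,
                ref_count=ref,
                context=row.context,
                substitution=row.substitution,
                tvaf=_opt_float(getattr(row, "tvaf", None)),
                rna_vaf=_opt_float(getattr(row, "rna_vaf", None)),
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_mutations(path, mutations: Iterable[SomaticMutation]) -> None:
    _write_rows(path, MUTATION_COLUMNS, (
        (m.sample_id, m.gene, m.arm, m.alt_count, m.ref_count,
         m.tvaf, m.context, m.substitution, m.rna_vaf)
        for m in mutations
    ))


# ----------------------------------------------------------------- segments

def read_segments(path) -> list[AllelicSegment]:
    """Read an extended SEG TSV; arms must be unique within a sample."""
    df = _read_tsv(path, SEGMENT_COLUMNS)
    seen: set[tuple[str, str]] = set()
    out: list[AllelicSegment] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.sample_id, row.arm)
        if key in seen:
            raise ValidationError(f"{path}: duplicate (sample, arm) {key} on row {i}")
        seen.add(key)
        try:
            out.append(AllelicSegment(
                sample_id=row.sample_id, arm=row.arm,
                major_cn=int(row.major_cn), minor_cn=int(row.minor_cn),
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_segments(path, segments: Iterable[AllelicSegment]) -> None:
    _write_rows(path, SEGMENT_COLUMNS, (
        (s.sample_id, s.arm, s.major_cn, s.minor_cn) for s in segments
    ))


def segments_by_sample(segments: Iterable[AllelicSegment]) -> dict[str, list[AllelicSegment]]:
    """Group a flat segment collection by sample id (insertion-ordered)."""
    out: dict[str, list[AllelicSegment]] = {}
    for seg in segments:
        out.setdefault(seg.sample_id, []).append(seg)
    return out


# -------------------------------------------------------------- sample meta

def read_sample_meta(path) -> list[SampleMeta]:
    df = _read_tsv(path, SAMPLE_COLUMNS)
    out: list[SampleMeta] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        fractions = {}
        for hist in COMPONENT_HISTOLOGIES:
            value = _opt_float(getattr(row, f"frac_{hist}"))
            if value:
                fractions[hist] = value
        try:
            out.append(SampleMeta(
                sample_id=row.sample_id,
                histology=row.histology,
                component_fractions=fractions,
                kit_status=row.kit_status,
                ras_status=row.ras_status,
                cryptorchidism=row.cryptorchidism,
                purity=_opt_float(row.purity),
                ploidy=_opt_float(row.ploidy),
            ))
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return out


def write_sample_meta(path, samples: Iterable[SampleMeta]) -> None:
    _write_rows(path, SAMPLE_COLUMNS, (
        (s.sample_id, s.histology, s.kit_status, s.ras_status, s.cryptorchidism,
         s.purity, s.ploidy)
        + tuple(float(s.component_fractions.get(h, 0.0)) for h in COMPONENT_HISTOLOGIES)
        for s in samples
    ))


# ------------------------------------------------------- matrices & probes

def read_beta_matrix(path) -> BetaMatrix:
    df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False,
                     index_col=0, float_precision="round_trip")
    try:
        return BetaMatrix(df)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_beta_matrix(path, beta: BetaMatrix) -> None:
    _write_matrix(path, beta.beta, index_name="probe_id")


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples log2 expression matrix."""
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=False,
                       index_col=0, float_precision="round_trip")


def write_expression(path, expression: pd.DataFrame) -> None:
    _write_matrix(path, expression, index_name="gene")


def _write_matrix(path, df: pd.DataFrame, index_name: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([index_name, *map(str, df.columns)]) + "\n")
        for idx, row in zip(df.index, df.to_numpy()):
            fh.write(str(idx) + "\t" + "\t".join(_fmt(float(v)) for v in row) + "\n")


def read_probe_annotation(path) -> pd.DataFrame:
    """Read probe annotation, returning a DataFrame indexed by probe id."""
    df = _read_tsv(path, PROBE_COLUMNS)
    df = df.set_index("probe_id")
    df["lymphocyte_signature"] = df["lymphocyte_signature"].map(
        {"true": True, "false": False}
    )
    if df["lymphocyte_signature"].isna().any():
        raise FormatError(f"{path}: lymphocyte_signature must be true/false")
    df["lymphocyte_ref_beta"] = df["lymphocyte_ref_beta"].astype(float)
    bad_ctx = ~df["context"].isin(PROBE_CONTEXTS)
    if bad_ctx.any():
        raise ValidationError(f"{path}: unknown probe context "
                              f"{df['context'][bad_ctx].iloc[0]!r}")
    bad_reg = ~df["region"].isin(CHROMATIN_REGIONS)
    if bad_reg.any():
        raise ValidationError(f"{path}: unknown chromatin region "
                              f"{df['region'][bad_reg].iloc[0]!r}")
    missing_ref = df["lymphocyte_signature"] & df["lymphocyte_ref_beta"].isna()
    if missing_ref.any():
        raise ValidationError(
            f"{path}: signature probes require lymphocyte_ref_beta "
            f"(first offender {df.index[missing_ref][0]})"
        )
    return df


def write_probe_annotation(path, annotation: pd.DataFrame) -> None:
    cols = [c for c in PROBE_COLUMNS if c != "probe_id"]
    _write_rows(path, PROBE_COLUMNS, (
        (idx, row["context"], row["region"],
         None if pd.isna(row["imprinted_dmr"]) else row["imprinted_dmr"],
         bool(row["lymphocyte_signature"]),
         _opt_float(row["lymphocyte_ref_beta"]),
         None if pd.isna(row["promoter_of_gene"]) else row["promoter_of_gene"])
        for idx, row in annotation[cols].iterrows()
    ))
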