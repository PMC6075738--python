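"""Domain types for TGCT genome and methylome analysis.

The in-memory model is arm-granular: somatic copy number is represented as
one allelic integer record per chromosome arm, and mutations are located by
arm rather than base pair, which is the resolution every analysis in this
toolkit operates at.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

# Histologies recognised in sample metadata. "mixed" samples carry component
# fractions over the four concrete histologies.
HISTOLOGIES = ("seminoma", "EC", "teratoma", "yolk_sac", "mixed")
COMPONENT_HISTOLOGIES = ("seminoma", "EC", "teratoma", "yolk_sac")

MUTATION_STATUS = ("mutant", "wildtype", "unknown")
YES_NO_UNKNOWN = ("yes", "no", "unknown")

# Pyrimidine-centred single-base substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

PROBE_CONTEXTS = ("CpG", "CpH")
CHROMATIN_REGIONS = ("active_promoter", "poised_promoter", "heterochromatin", "other")

# Approximate arm lengths (Mb, GRCh38). The five acrocentric short arms
# (13p, 14p, 15p, 21p, 22p) carry no unique sequence on SNP arrays and are
# omitted from the arm model.
ARM_LENGTHS_MB: dict[str, float] = {
    "1p": 123.4, "1q": 125.2, "2p": 93.9, "2q": 148.4,
    "3p": 90.9, "3q": 107.4, "4p": 50.0, "4q": 140.2,
    "5p": 48.8, "5q": 132.7, "6p": 59.8, "6q": 111.0,
    "7p": 60.1, "7q": 99.2, "8p": 45.2, "8q": 99.9,
    "9p": 43.0, "9q": 95.4, "10p": 39.8, "10q": 94.0,
    "11p": 53.4, "11q": 81.7, "12p": 35.5, "12q": 97.8,
    "13q": 96.2, "14q": 89.3, "15q": 82.5,
    "16p": 36.8, "16q": 53.5, "17p": 25.1, "17q": 58.1,
    "18p": 18.5, "18q": 61.9, "19p": 26.2, "19q": 32.4,
    "20p": 28.1, "20q": 36.3, "21q": 33.9, "22q": 35.9,
    "Xp": 61.0, "Xq": 95.1,
}
ARMS = tuple(ARM_LENGTHS_MB)


def _check_fraction(name: str, value: float, allow_none: bool = False) -> None:
    if value is None:
        if allow_none:
            return
        raise ValueError(f"{name} is required")
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample clinical and composition metadata.

    ``component_fractions`` maps concrete histologies to tissue fractions
    summing to one; a pure sample maps its own histology to 1.0. ``purity``
    and ``ploidy`` may be missing (None) for low-purity samples where
    copy-number inference failed.
    """

    sample_id: str
    histology: str
    component_fractions: Mapping[str, float]
    kit_status: str = "unknown"
    ras_status: str = "unknown"
    cryptorchidism: str = "unknown"
    purity: Optional[float] = None
    ploidy: Optional[float] = None

    def __post_init__(self) -> None:
        if self.histology not in HISTOLOGIES:
            raise ValueError(f"unknown histology {self.histology!r}")
        if self.kit_status not in MUTATION_STATUS:
            raise ValueError(f"unknown kit_status {self.kit_status!r}")
        if self.ras_status not in MUTATION_STATUS:
            raise ValueError(f"unknown ras_status {self.ras_status!r}")
        if self.cryptorchidism not in YES_NO_UNKNOWN:
            raise ValueError(f"unknown cryptorchidism {self.cryptorchidism!r}")
        total = 0.0
        for hist, frac in self.component_fractions.items():
            if hist not in COMPONENT_HISTOLOGIES:
                raise ValueError(f"unknown component histology {hist!r}")
            _check_fraction(f"component_fractions[{hist}]", frac)
            total += frac
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"component fractions sum to {total}, expected 1")
        if self.purity is not None and not (0.0 < self.purity <= 1.0):
            raise ValueError(f"purity={self.purity} outside (0, 1]")
        if self.ploidy is not None and self.ploidy <= 0:
            raise ValueError(f"ploidy={self.ploidy} must be positive")


@dataclass(frozen=True)
class AllelicSegment:
    """Arm-level allelic integer copy number (major >= minor >= 0)."""

    sample_id: str
    arm: str
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValueError(
                f"{self.sample_id} {self.arm}: require major_cn >= minor_cn >= 0, "
                f"got ({self.major_cn}, {self.minor_cn})"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn


@dataclass(frozen=True)
class SomaticMutation:
    """A somatic variant with tumor read counts and trinucleotide context.

    ``tvaf`` (tumor variant allele fraction) is derived from the read counts
    when not supplied. ``context`` is the pyrimidine-centred 3-mer whose
    middle base is the reference base of ``substitution``.
    """

    sample_id: str
    gene: str
    arm: str
    alt_count: int
    ref_count: int
    context: str
    substitution: str
    tvaf: Optional[float] = None
    rna_vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError(
                f"{self.sample_id} {self.gene}: negative read counts "
                f"({self.alt_count}, {self.ref_count})"
            )
        if self.substitution not in SUBSTITUTION_CLASSES:
            raise ValueError(f"unknown substitution class {self.substitution!r}")
        ctx = self.context
        if len(ctx) != 3 or any(b not in "ACGT" for b in ctx):
            raise ValueError(f"context {ctx!r} is not a 3-mer over ACGT")
        if ctx[1] != self.substitution[0]:
            raise ValueError(
                f"context centre {ctx[1]!r} does not match substitution "
                f"reference base {self.substitution[0]!r}"
            )
        depth = self.alt_count + self.ref_count
        if self.tvaf is None:
            if depth == 0:
                raise ValueError(
                    f"{self.sample_id} {self.gene}: zero depth and no tvaf given"
                )
            object.__setattr__(self, "tvaf", self.alt_count / depth)
        else:
            _check_fraction("tvaf", self.tvaf)
            if depth > 0 and abs(self.tvaf - self.alt_count / depth) > 1e-9:
                raise ValueError(
                    f"{self.sample_id} {self.gene}: tvaf={self.tvaf} inconsistent "
                    f"with counts {self.alt_count}/{depth}"
                )
        if self.rna_vaf is not None:
            _check_fraction("rna_vaf", self.rna_vaf)

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count


@dataclass(frozen=True)
class MultiplicityCall:
    """Mutation multiplicity s_q with timing and clonality classifications."""

    sample_id: str
    gene: str
    s_q: float
    nearest_integer_m: int
    timing_vs_wgd: str  # before_wgd | after_wgd | ambiguous | na
    timing_vs_i12p: str  # before_or_during | after | na
    clonal: str  # clonal | subclonal | unknown

    def __post_init__(self) -> None:
        if not math.isnan(self.s_q) and self.s_q < 0:
            raise ValueError(f"s_q={self.s_q} must be non-negative")
        if self.timing_vs_wgd not in ("before_wgd", "after_wgd", "ambiguous", "na"):
            raise ValueError(f"bad timing_vs_wgd {self.timing_vs_wgd!r}")
        if self.timing_vs_i12p not in ("before_or_during", "after", "na"):
            raise ValueError(f"bad timing_vs_i12p {self.timing_vs_i12p!r}")
        if self.clonal not in ("clonal", "subclonal", "unknown"):
            raise ValueError(f"bad clonal flag {self.clonal!r}")


@dataclass(frozen=True)
class ArmEventCall:
    """Arm-level gain/loss call relative to sample ploidy."""

    sample_id: str
    arm: str
    direction: str  # gain | loss | neutral
    total_cn: int
    delta_vs_ploidy: float


@dataclass(frozen=True)
class GenomeDoublingCall:
    """Whole-genome doubling count inferred from major-allele copy numbers."""

    sample_id: str
    wgd_count: int
    ploidy: float
    fraction_major_ge2: float
    fraction_major_ge3: float


@dataclass(frozen=True)
class I12pCall:
    """Isochromosome 12p presence call from allelic chromosome-12 profiles."""

    sample_id: str
    present: bool
    n_12p_copies: int
    n_12q_copies: int
    loh_12q: bool


@dataclass(frozen=True)
class LymphocyteEstimate:
    """Per-sample lymphocyte fraction from methylation signature probes."""

    sample_id: str
    f: float
    n_probes_used: int

    def __post_init__(self) -> None:
        _check_fraction("f", self.f)


@dataclass(frozen=True)
class SilencingCall:
    """Promoter-hypermethylation silencing call for one (sample, gene).

    ``silenced`` is None when no unmethylated reference samples exist for the
    gene, i.e. the call is indeterminate.
    """

    sample_id: str
    gene: str
    promoter_beta_corrected: float
    expression_log2: float
    silenced: Optional[bool]


@dataclass(frozen=True)
class DensitySummary:
    """Modality summary of a beta-value distribution."""

    label: str
    peak_positions: tuple[float, ...]
    n_modes: int
    mass_above_03: float

    def __post_init__(self) -> None:
        if list(self.peak_positions) != sorted(self.peak_positions):
            raise ValueError("peak positions must be ascending")
        if self.n_modes != len(self.peak_positions):
            raise ValueError("n_modes must equal the number of peaks")


@dataclass(frozen=True)
class SpectrumProfile:
    """Per-sample substitution-class fractions.

    ``ct_at_cpg_fraction`` is the fraction of *all* mutations that are C>T
    transitions with a 3' G (CpG dinucleotide context), the readout of the
    5-methylcytosine deamination signature. Fractions are NaN when the sample
    has no mutations.
    """

    sample_id: str
    fractions: Mapping[str, float]
    ct_at_cpg_fraction: float
    n_mutations: int


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table; rows = exposure, columns = outcome: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table total must be positive")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class PairConcordance:
    """Concordance of two primary tumors from one patient."""

    patient_id: str
    shared_mutations: int
    mutations_t1_only: int
    mutations_t2_only: int
    platform_correlation: Mapping[str, float] = field(default_factory=dict)


class BetaMatrix:
    """Probes x samples DNA methylation fractions (beta values).

    Wraps a :class:`pandas.DataFrame` indexed by probe id with one column per
    sample; all non-missing entries must lie in [0, 1].
    """

    def __init__(self, beta: pd.DataFrame):
        values = beta.to_numpy(dtype=float)
        finite = values[~pd.isna(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        self.beta = beta.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    def subset(self, probes=None, samples=None) -> "BetaMatrix":
        df = self.beta
        if probes is not None:
            df = df.loc[[p for p in probes if p in df.index]]
        if samples is not None:
            df = df[[s for s in samples if s in df.columns]]
        return BetaMatrix(df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, BetaMatrix) and self.beta.equals(other.beta)

    def __repr__(self) -> str:
        return f"BetaMatrix({len(self.beta)} probes x {self.beta.shape[1]} samples)"
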