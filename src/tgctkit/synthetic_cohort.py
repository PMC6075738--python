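"""Synthetic TGCT cohort generator with recorded ground truth.

Emulates the statistical structure the analysis modules assume, so every
downstream stage is testable without controlled-access data:

* hyper-triploid genomes produced by one (occasionally two) whole-genome
  doublings followed by histology-specific arm losses applied to the minor
  haplotype;
* i(12p) in every NSGCT and ~80% of seminomas, simulated as extra copies of
  the major 12p haplotype; samples lacking i(12p) retain four 12p copies;
* seminoma lymphocyte infiltration anti-correlated with purity, mixed into
  the observed methylome as observed = f*lymphocyte_ref + (1-f)*tumor;
* archetypal tumor methylomes: KIT-mutant seminoma fully unmethylated,
  KIT-WT seminoma with a small recurrent residual set, EC with ESC-like CpG
  methylation plus CpH methylation scaling with EC content, other NSGCT
  soma-like with poised-promoter silencing gains and occasional imprinted-
  DMR methylation;
* mutations with multiplicities consistent with their drawn pre-/post-WGD
  (and pre-/post-i(12p)) timing, binomial read counts at the expected VAF;
* expression with KIT and cancer-testis antigens high in seminoma and
  immune-signature genes scaling with lymphocyte fraction.

Ground truth (purity, lymphocyte fraction, WGD count, event timings,
per-mutation multiplicity, the tumor-intrinsic beta matrix) is recorded in
:class:`CohortTruth` for recovery tests.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .mutation_timing import expected_tvaf
from .types import (
    ARMS,
    AllelicSegment,
    BetaMatrix,
    SampleMeta,
    SomaticMutation,
)

# Cohort composition of the TCGA TGCT study (72/27/16/13/9 of 137).
DEFAULT_HISTOLOGY_MIX = {
    "seminoma": 72 / 137, "EC": 27 / 137, "teratoma": 16 / 137,
    "yolk_sac": 13 / 137, "mixed": 9 / 137,
}

SILENCING_GENES = ("BRCA1", "RAD51C", "MGMT", "DNAJC15")
# Per-histology planting rates for promoter silencing (NSGCT only),
# patterned on the cohort's observed promoter-methylation frequencies.
SILENCING_RATES = {
    "EC": {"BRCA1": 0.07, "RAD51C": 0.11, "MGMT": 0.11, "DNAJC15": 0.0},
    "teratoma": {"BRCA1": 0.31, "RAD51C": 0.31, "MGMT": 0.56, "DNAJC15": 0.50},
    "yolk_sac": {"BRCA1": 0.54, "RAD51C": 0.31, "MGMT": 0.38, "DNAJC15": 0.31},
    "mixed": {"BRCA1": 0.22, "RAD51C": 0.44, "MGMT": 0.44, "DNAJC15": 0.11},
}

IMMUNE_GENES = tuple(f"IMM{i:02d}" for i in range(1, 21))
CTA_GENES = tuple(f"CTA{i:02d}" for i in range(1, 11))
N_IMPRINTED_DMRS = 8
_PROBES_PER_DMR = 5
_PROBES_PER_PROMOTER = 5

# NSGCT-favoured loss arms (seminomas preferentially lose 11q instead).
NSGCT_LOSS_ARMS = ("19q", "15q", "22q", "19p", "10q", "8p", "2q", "8q")
SEMINOMA_LOSS_ARMS = ("11q",)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for cohort simulation.

    Defaults encode the cohort archetypes: histology mix and KIT-mutation
    rate of the 137-sample cohort, i(12p) in 80% of seminomas, a second WGD
    in ~8% of samples, seminoma purity lower than NSGCT purity, lymphocyte
    fraction = 1 - purity plus Gaussian noise, and mean sequencing depth
    120x.
    """

    n_samples: int = 120
    histology_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HISTOLOGY_MIX))
    seminoma_kit_mut_rate: float = 25 / 72
    p_i12p_seminoma: float = 0.8
    p_second_wgd: float = 10 / 131
    purity_range_seminoma: tuple[float, float] = (0.2, 0.8)
    purity_range_nsgct: tuple[float, float] = (0.4, 0.95)
    lymph_noise_sd: float = 0.03
    n_probes: int = 5000
    cph_fraction: float = 0.2
    n_signature_probes: int = 200
    residual_fraction: float = 0.005  # KIT-WT seminoma residual probe set
    mean_depth: int = 120
    passenger_rate: float = 15.0  # mean passenger mutations per sample
    seminoma_kras_rate: float = 0.25
    seminoma_nras_rate: float = 0.05
    ct_fraction: float = 0.40  # C>T share of the substitution spectrum
    cpg_share_of_ct: float = 0.5  # CpG-context share among C>T
    kit_mut_cpg_depletion: float = 0.5  # multiplicative, KIT-mutant seminoma
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        total = sum(self.histology_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"histology_mix sums to {total}, expected 1")
        for name in ("seminoma_kit_mut_rate", "p_i12p_seminoma", "p_second_wgd",
                     "cph_fraction", "residual_fraction", "ct_fraction",
                     "cpg_share_of_ct", "kit_mut_cpg_depletion",
                     "seminoma_kras_rate", "seminoma_nras_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}={v} outside [0, 1]")
        n_cpg = self.n_probes - int(round(self.n_probes * self.cph_fraction))
        reserved = (self.n_signature_probes
                    + N_IMPRINTED_DMRS * _PROBES_PER_DMR
                    + len(SILENCING_GENES) * _PROBES_PER_PROMOTER)
        if n_cpg - reserved < 50:
            raise ConfigError(
                f"n_probes={self.n_probes} too small for {self.n_signature_probes} "
                "signature probes plus imprinted/promoter probe sets")
        if self.lymph_noise_sd < 0:
            raise ConfigError("lymph_noise_sd must be >= 0")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")


@dataclass
class CohortTruth:
    """Per-sample and per-mutation simulation ground truth."""

    per_sample: pd.DataFrame  # indexed by sample_id
    arm_events: pd.DataFrame  # sample_id, arm, event, timing
    mutations: pd.DataFrame  # per-mutation truth incl. multiplicity, timing
    tumor_beta: pd.DataFrame  # tumor-intrinsic beta before mixing
    silenced: pd.DataFrame  # planted (sample_id, gene) silencing
    lymphocyte_ref: pd.Series  # per-probe lymphocyte reference beta


@dataclass
class SyntheticCohort:
    samples: list[SampleMeta]
    segments: list[AllelicSegment]
    mutations: list[SomaticMutation]
    beta: BetaMatrix
    expression: pd.DataFrame
    probe_annotation: pd.DataFrame
    truth: CohortTruth


def mix_beta(tumor_beta: float, f: float, ref_beta: float) -> float:
    """Two-component mixture: f * ref_beta + (1 - f) * tumor_beta."""
    for name, v in (("tumor_beta", tumor_beta), ("f", f), ("ref_beta", ref_beta)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return f * ref_beta + (1.0 - f) * tumor_beta


def _build_probe_model(config: SimulationConfig, rng: np.random.Generator):
    """Probe annotation, lymphocyte reference and archetype base vectors."""
    n_cph = int(round(config.n_probes * config.cph_fraction))
    n_cpg = config.n_probes - n_cph

    probe_ids, context, region, dmr, promoter = [], [], [], [], []
    sig_flag = []

    def add(n, ctx, reg, dmr_name=None, gene=None, sig=False):
        start = len(probe_ids)
        for i in range(n):
            probe_ids.append(f"{'cg' if ctx == 'CpG' else 'ch'}{start + i:06d}")
            context.append(ctx)
            region.append(reg)
            dmr.append(dmr_name)
            promoter.append(gene)
            sig_flag.append(sig)

    add(config.n_signature_probes, "CpG", "other", sig=True)
    for d in range(1, N_IMPRINTED_DMRS + 1):
        add(_PROBES_PER_DMR, "CpG", "other", dmr_name=f"DMR_{d}")
    for gene in SILENCING_GENES:
        add(_PROBES_PER_PROMOTER, "CpG", "poised_promoter", gene=gene)
    n_rest = n_cpg - len(probe_ids)
    n_active = int(round(0.3 * n_rest))
    n_hetero = int(round(0.4 * n_rest))
    add(n_active, "CpG", "active_promoter")
    add(n_hetero, "CpG", "heterochromatin")
    add(n_rest - n_active - n_hetero, "CpG", "other")
    add(n_cph, "CpH", "other")

    ann = pd.DataFrame({
        "context": context, "region": region, "imprinted_dmr": dmr,
        "lymphocyte_signature": sig_flag,
        "promoter_of_gene": promoter,
    }, index=pd.Index(probe_ids, name="probe_id"))

    n = len(ann)
    is_cph = (ann["context"] == "CpH").to_numpy()
    is_sig = np.asarray(sig_flag)
    is_dmr = ann["imprinted_dmr"].notna().to_numpy()
    is_prom = ann["promoter_of_gene"].notna().to_numpy()
    is_active = (ann["region"] == "active_promoter").to_numpy()
    is_hetero = (ann["region"] == "heterochromatin").to_numpy()
    is_other = (~is_cph & ~is_sig & ~is_dmr & ~is_prom & ~is_active & ~is_hetero)

    # "other" CpG probes split into soma-unmethylated and soma-methylated
    other_state_high = is_other & (rng.random(n) < 0.5)

    ref = np.zeros(n)
    ref[is_sig] = rng.uniform(0.85, 1.0, is_sig.sum())
    ref[is_dmr] = rng.uniform(0.45, 0.55, is_dmr.sum())
    ref[is_prom] = rng.uniform(0.01, 0.08, is_prom.sum())
    ref[is_active] = rng.uniform(0.01, 0.10, is_active.sum())
    ref[is_hetero] = rng.uniform(0.75, 0.98, is_hetero.sum())
    ref[is_other] = rng.uniform(0.01, 0.10, is_other.sum())
    ref[other_state_high] = rng.uniform(0.70, 0.95, other_state_high.sum())
    ref[is_cph] = 0.0
    ann["lymphocyte_ref_beta"] = ref

    sig_tumor = np.zeros(n)
    sig_tumor[is_sig] = rng.uniform(0.0, 0.04, is_sig.sum())

    # archetype tumor-intrinsic base vectors
    sem = np.zeros(n)  # seminoma: globally unmethylated
    sem += sig_tumor

    ec = np.zeros(n)
    ec[is_active] = 0.02
    ec[is_hetero] = rng.uniform(0.75, 0.95, is_hetero.sum())
    ec[is_other] = 0.03
    ec[other_state_high] = rng.uniform(0.75, 0.95, other_state_high.sum())
    ec[is_prom] = 0.15
    ec[is_dmr] = 0.02
    ec[is_cph] = rng.uniform(0.15, 0.35, is_cph.sum())
    ec[is_sig] = sig_tumor[is_sig]

    soma = np.zeros(n)
    soma[is_active] = 0.04
    soma[is_hetero] = rng.uniform(0.78, 0.98, is_hetero.sum())
    soma[is_other] = 0.05
    soma[other_state_high] = rng.uniform(0.75, 0.98, other_state_high.sum())
    soma[is_prom] = 0.05
    soma[is_dmr] = 0.02
    soma[is_cph] = 0.01
    soma[is_sig] = sig_tumor[is_sig]

    # recurrent residual set of the KIT-WT seminoma archetype
    pool = np.flatnonzero(is_other | is_hetero)
    n_residual = min(len(pool), int(round(config.residual_fraction * n)))
    residual_idx = rng.choice(pool, size=n_residual, replace=False)

    archetypes = {"seminoma": sem, "EC": ec, "teratoma": soma, "yolk_sac": soma}
    return ann, archetypes, residual_idx


def _draw_components(histology: str, rng: np.random.Generator) -> dict[str, float]:
    if histology == "seminoma":
        return {"seminoma": 1.0}
    if histology == "mixed":
        frac = rng.dirichlet(np.ones(3))
        return dict(zip(("EC", "teratoma", "yolk_sac"), map(float, frac)))
    second = {"EC": "teratoma", "teratoma": "yolk_sac", "yolk_sac": "teratoma"}
    main = float(rng.uniform(0.7, 1.0)) if rng.random() < 0.5 else 1.0
    comps = {histology: main}
    if main < 1.0:
        comps[second[histology]] = 1.0 - main
    return comps


# post-WGD copies lost per arm: (P(L=1), P(L=2)); remainder keeps both copies
_LOSS_PROBS = {
    "seminoma": {"base": (0.50, 0.17), "favored": (0.70, 0.20)},
    "nsgct": {"base": (0.48, 0.30), "favored": (0.60, 0.38)},
}
_P_PRE_WGD_LOSS = 0.05
_P_PRE_WGD_LOSS_12Q = 0.02


def _simulate_segments(sample_id: str, histology: str, wgd_count: int,
                       i12p: bool, rng: np.random.Generator):
    """Allelic arm profile: diploid -> pre-WGD losses -> WGD(s) -> post-WGD
    minor-haplotype losses -> i(12p) gain of the major 12p haplotype."""
    is_sem = histology == "seminoma"
    probs = _LOSS_PROBS["seminoma" if is_sem else "nsgct"]
    favored = SEMINOMA_LOSS_ARMS if is_sem else NSGCT_LOSS_ARMS
    base_cn = 2 ** wgd_count
    segments, events = [], []
    i12p_k = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2])) if i12p else 0
    for arm in ARMS:
        major = minor = base_cn
        if arm != "12p":
            p_pre = _P_PRE_WGD_LOSS_12Q if arm == "12q" else _P_PRE_WGD_LOSS
            if rng.random() < p_pre:
                minor = 0
                events.append((sample_id, arm, "loss", "pre_wgd"))
            else:
                p1, p2 = probs["favored"] if arm in favored else probs["base"]
                u = rng.random()
                lost = (1 if u < p1 else (2 if u < p1 + p2 else 0))
                lost += 2 * (wgd_count - 1)  # second WGD genomes shed more
                if lost > 0:
                    minor = max(0, minor - lost)
                    events.append((sample_id, arm, "loss", "post_wgd"))
        if arm == "12p" and i12p:
            major += i12p_k
            events.append((sample_id, arm, "gain", "post_wgd"))
        segments.append(AllelicSegment(sample_id=sample_id, arm=arm,
                                       major_cn=major, minor_cn=minor))
    return segments, events, i12p_k


_DRIVER_SPECS = {  # gene -> (arm, substitution, context)
    "KIT": ("4q", "T>A", "CTG"),
    "KRAS": ("12p", "C>A", "CCA"),
    "NRAS": ("1p", "C>A", "ACA"),
}


def _draw_context(substitution: str, at_cpg: bool,
                  rng: np.random.Generator) -> str:
    five = rng.choice(list("ACGT"))
    if substitution.startswith("C"):
        three = "G" if at_cpg else rng.choice(list("ACT"))
        return f"{five}C{three}"
    return f"{five}T{rng.choice(list('ACGT'))}"


def _simulate_mutation(sample_id: str, gene: str, arm: str, m: int,
                       substitution: str, context: str, seg_index, purity,
                       mean_depth, rng, with_rna: bool):
    seg = seg_index[arm]
    evaf = expected_tvaf(m, seg.total_cn, purity)
    depth = max(1, int(rng.poisson(mean_depth)))
    alt = int(rng.binomial(depth, evaf))
    tvaf = alt / depth
    rna = float(np.clip(tvaf + rng.normal(0, 0.03), 0, 1)) if with_rna else None
    mut = SomaticMutation(
        sample_id=sample_id, gene=gene, arm=arm, alt_count=alt,
        ref_count=depth - alt, context=context, substitution=substitution,
        rna_vaf=rna)
    return mut, evaf, seg


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with recorded ground truth.

    A single RNG stream is seeded from the config; per-sample substreams are
    derived by sample counter so sample-level draws are reproducible under
    reordering.
    """
    rng_global = np.random.default_rng([config.rng_seed, 1_000_003])
    annotation, archetypes, residual_idx = _build_probe_model(config, rng_global)
    ref = annotation["lymphocyte_ref_beta"].to_numpy()
    n_probes = len(annotation)

    samples: list[SampleMeta] = []
    segments: list[AllelicSegment] = []
    mutations: list[SomaticMutation] = []
    arm_event_rows, mut_rows, sil_rows, truth_rows = [], [], [], []
    beta_cols, tumor_cols, expr_cols = {}, {}, {}

    histologies = list(config.histology_mix)
    mix_p = np.array([config.histology_mix[h] for h in histologies])

    for i in range(config.n_samples):
        rng = np.random.default_rng([config.rng_seed, 2_000_000 + i])
        sample_id = f"S{i + 1:03d}"
        histology = str(rng.choice(histologies, p=mix_p))
        comps = _draw_components(histology, rng)
        is_sem = histology == "seminoma"
        kit_mut = is_sem and rng.random() < config.seminoma_kit_mut_rate
        kras_mut = is_sem and rng.random() < config.seminoma_kras_rate
        nras_mut = is_sem and rng.random() < config.seminoma_nras_rate
        lo, hi = (config.purity_range_seminoma if is_sem
                  else config.purity_range_nsgct)
        purity = float(rng.uniform(lo, hi))
        f = float(np.clip((1.0 - purity) + rng.normal(0, config.lymph_noise_sd),
                          0.0, 1.0))
        wgd_count = 2 if rng.random() < config.p_second_wgd else 1
        i12p = (not is_sem) or rng.random() < config.p_i12p_seminoma
        if is_sem:
            p_crypt = 0.40 if kit_mut else 0.15
        else:
            p_crypt = 0.08
        crypt = "yes" if rng.random() < p_crypt else "no"

        segs, events, i12p_k = _simulate_segments(
            sample_id, histology, wgd_count, i12p, rng)
        seg_index = {s.arm: s for s in segs}
        segments.extend(segs)
        arm_event_rows.extend(events)
        ploidy = float(np.mean([s.total_cn for s in segs]))

        # ----- mutations -----------------------------------------------
        def emit(gene, arm, m, sub, ctx, vs_wgd, vs_i12p, with_rna):
            mut, evaf, seg = _simulate_mutation(
                sample_id, gene, arm, m, sub, ctx, seg_index, purity,
                config.mean_depth, rng, with_rna)
            mutations.append(mut)
            mut_rows.append((sample_id, gene, arm, m, seg.total_cn,
                             seg.major_cn, evaf, vs_wgd, vs_i12p, "clonal"))

        base_m = 2 ** wgd_count
        if kit_mut:
            arm, sub, ctx = _DRIVER_SPECS["KIT"]
            if rng.random() < 0.4:  # pre-WGD activation
                emit("KIT", arm, base_m, sub, ctx, "before_wgd", "na", True)
            else:
                emit("KIT", arm, 1, sub, ctx, "after_wgd", "na", True)
        if kras_mut:
            arm, sub, ctx = _DRIVER_SPECS["KRAS"]
            if i12p and rng.random() < 0.4:
                # on the haplotype duplicated by i(12p): multiplicity rides
                # both the doubling(s) and the isochromosome gain
                emit("KRAS", arm, base_m + i12p_k, sub, ctx,
                     "before_wgd", "before_or_during", True)
            else:
                emit("KRAS", arm, 1, sub, ctx, "after_wgd",
                     "after" if i12p else "na", True)
        if nras_mut:
            arm, sub, ctx = _DRIVER_SPECS["NRAS"]
            emit("NRAS", arm, 1, sub, ctx, "after_wgd", "na", True)

        p_cpg = config.cpg_share_of_ct * (
            config.kit_mut_cpg_depletion if kit_mut else 1.0)
        n_passengers = int(rng.poisson(config.passenger_rate))
        other_classes = [c for c in ("C>A", "C>G", "T>A", "T>C", "T>G")]
        passenger_arms = [a for a in ARMS if a != "12p"]
        for j in range(n_passengers):
            arm = str(rng.choice(passenger_arms))
            if rng.random() < config.ct_fraction:
                sub = "C>T"
                ctx = _draw_context(sub, rng.random() < p_cpg, rng)
            else:
                sub = str(rng.choice(other_classes))
                ctx = _draw_context(sub, False, rng)
            if rng.random() < 0.25:  # pre-WGD passenger
                m, vs_wgd = base_m, "before_wgd"
            else:
                m, vs_wgd = 1, "after_wgd"
            emit(f"PSG{i:03d}_{j:03d}", arm, m, sub, ctx, vs_wgd, "na", False)

        # ----- methylome ------------------------------------------------
        tumor = np.zeros(n_probes)
        for hist, frac in comps.items():
            vec = archetypes[hist]
            if hist == "seminoma" and not kit_mut:
                vec = vec.copy()
                present = rng.random(len(residual_idx)) < 0.8
                vec[residual_idx[present]] = 0.7
            tumor = tumor + frac * vec
        silenced_genes = []
        if histology in SILENCING_RATES:
            for gene in SILENCING_GENES:
                if rng.random() < SILENCING_RATES[histology][gene]:
                    probes = annotation.index.get_indexer(
                        annotation.index[annotation["promoter_of_gene"] == gene])
                    tumor[probes] = rng.uniform(0.72, 0.85, len(probes))
                    silenced_genes.append(gene)
                    sil_rows.append((sample_id, gene))
        ec_frac = comps.get("EC", 0.0)
        if histology in ("teratoma", "yolk_sac") or (
                histology == "mixed" and ec_frac < 0.5):
            if rng.random() < 0.4:  # GNAS-like methylated imprinted DMR
                probes = annotation.index.get_indexer(
                    annotation.index[annotation["imprinted_dmr"] == "DMR_1"])
                tumor[probes] = rng.uniform(0.72, 0.85, len(probes))
        tumor = np.clip(tumor + rng.normal(0, 0.01, n_probes), 0.0, 1.0)
        tumor_cols[sample_id] = tumor
        beta_cols[sample_id] = f * ref + (1.0 - f) * tumor

        # ----- expression ----------------------------------------------
        sem_frac = comps.get("seminoma", 0.0)
        expr = {}
        expr["KIT"] = 4.0 + 4.0 * sem_frac + (1.0 if kit_mut else 0.0) \
            + rng.normal(0, 0.5)
        expr["KRAS"] = 5.0 + rng.normal(0, 0.5)
        for g in IMMUNE_GENES:
            expr[g] = 2.0 + 5.0 * f + rng.normal(0, 0.3)
        for g in CTA_GENES:
            expr[g] = 3.0 + 3.0 * sem_frac + rng.normal(0, 0.5)
        for g in SILENCING_GENES:
            expr[g] = 8.0 + rng.normal(0, 0.5) - (6.0 if g in silenced_genes else 0.0)
        for g in range(20):
            expr[f"BG{g:02d}"] = 5.0 + rng.normal(0, 1.0)
        expr_cols[sample_id] = expr

        samples.append(SampleMeta(
            sample_id=sample_id, histology=histology,
            component_fractions=comps,
            kit_status="mutant" if kit_mut else "wildtype",
            ras_status="mutant" if (kras_mut or nras_mut) else "wildtype",
            cryptorchidism=crypt, purity=purity, ploidy=ploidy))
        truth_rows.append((sample_id, histology, purity, f, wgd_count,
                           bool(i12p), i12p_k, ec_frac, sem_frac, kit_mut,
                           kras_mut or nras_mut))

    probe_index = annotation.index
    sample_ids = [s.sample_id for s in samples]
    truth = CohortTruth(
        per_sample=pd.DataFrame(
            truth_rows,
            columns=["sample_id", "histology", "true_purity",
                     "true_lymph_fraction", "wgd_count", "i12p_present",
                     "i12p_extra_copies", "ec_fraction", "seminoma_fraction",
                     "kit_mutant", "ras_mutant"],
        ).set_index("sample_id"),
        arm_events=pd.DataFrame(
            arm_event_rows, columns=["sample_id", "arm", "event", "timing"]),
        mutations=pd.DataFrame(
            mut_rows, columns=["sample_id", "gene", "arm", "true_multiplicity",
                               "total_cn", "major_cn", "expected_tvaf",
                               "timing_vs_wgd", "timing_vs_i12p", "clonal"]),
        tumor_beta=pd.DataFrame(tumor_cols, index=probe_index)[sample_ids],
        silenced=pd.DataFrame(sil_rows, columns=["sample_id", "gene"]),
        lymphocyte_ref=annotation["lymphocyte_ref_beta"].copy(),
    )
    expression = pd.DataFrame(expr_cols)[sample_ids]
    expression.index.name = "gene"
    return SyntheticCohort(
        samples=samples,
        segments=segments,
        mutations=mutations,
        beta=BetaMatrix(pd.DataFrame(beta_cols, index=probe_index)[sample_ids]),
        expression=expression,
        probe_annotation=annotation,
        truth=truth,
    )
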