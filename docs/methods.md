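# Methods

This note documents the models, parameter choices and numerical decisions
behind `tgctkit`, and what the synthetic cohort does and does not
emulate.

## Data model

All analyses are arm-granular. Copy number is one allelic integer record
per chromosome arm (major ≥ minor ≥ 0) over the 41 non-acrocentric arms;
mutations are located by arm, not base pair. This matches the resolution
of every inference the toolkit performs — WGD, i(12p), arm events and
arm-level multiplicity — and deliberately excludes focal (sub-arm)
events, which belong to GISTIC-class tooling. Tables are UTF-8 TSV with
one header row and `NA` for missing values; floats are serialised with
`repr` and parsed in round-trip mode so writer/reader pairs are bit-exact.

## Mutation multiplicity and timing

Multiplicity is the closed form
`s_q = TVAF * (CN*p + 2*(1-p)) / p` with purity `p` in (0, 1] and arm
total copy number `CN ≥ 1`; `expected_tvaf` is its exact inverse and the
two compose to the identity at machine precision.

Timing against WGD rounds `s_q` to the nearest integer `m*` and requires
`|s_q - m*| ≤ 0.35` (configurable). `m* = 1` → after WGD; `2 ≤ m* ≤
major_cn` → before WGD; anything else (including `m* = 0` and `m*`
exceeding the major allele count) is ambiguous, because no clonal
configuration supports it. The 0.35 default keeps binomial TVAF noise at
120× depth from flipping calls between adjacent integers: at typical
purities the s_q standard error is ≈ 0.2, so a definite-but-wrong call
needs a > 3σ excursion while most borderline draws land in the ambiguous
band instead. Accuracy is therefore reported over non-ambiguous calls,
with the ambiguous rate reported alongside.

For 12p mutations in i(12p)-positive samples, `m* ≤ 1` places the
mutation after i(12p) formation and `m* ≥ 2` before or during it (the
isochromosome duplicates one haplotype's p arm, amplifying any mutation
already on it). Clonality uses the cancer cell fraction `CCF = s_q /
max(1, m*)` capped at 1: clonal requires CCF ≥ 0.8 plus DNA/RNA VAF
agreement within 0.2 when RNA is available; subclonal requires the
Clopper-Pearson interval on the VAF (scaled linearly to CCF) to exclude
0.8; everything else — notably shallow depth — is unknown.

## Copy-number events

WGD count: one doubling when the genome-length-weighted fraction of arms
with major ≥ 2 exceeds 0.5, two when the major ≥ 3 fraction exceeds 0.5.
The 0.5 thresholds follow the standard major-allele-fraction convention.
Ploidy is the length-weighted mean total copy number (identical to the
unweighted mean on uniform genomes).

i(12p): present iff `total(12p) - total(12q) ≥ 1` and `major(12p) -
major(12q) ≥ 1`. Requiring the excess on the major haplotype
distinguishes a true isochromosome from 12q loss alone. 12q LOH is
`minor(12q) = 0`.

Arm events: `delta = total - round(ploidy)`, loss at ≤ -1, gain at ≥ +1.

Arm-event ordering: the published analysis orders events from their
frequency and the aneuploidy level of their carriers; the exact statistic
is not printed, so this toolkit instantiates the idea as
`timing_score = freq / (1 + median carrier burden)` (burden = a carrier's
count of non-neutral arms), ranked descending per group with ties broken
by frequency then arm name. The formula is isolated behind one function
so it can be replaced; its testable contract is rank order (early events
planted across all burden levels outrank late events confined to
high-burden genomes), not score values. Groups under 5 samples are
skipped.

## Methylation deconvolution

The bulk methylome is a two-component mixture, `beta_obs = f*ref +
(1-f)*t`, with `f` the lymphocyte fraction, `ref` the lymphocyte
reference beta per probe and `t` the tumor-intrinsic beta. The estimator
is a LUMP-style ratio of means over lymphocyte-specific signature probes,
`f = clip(mean(obs)/mean(ref), 0, 1)`, requiring ≥ 20 usable probes. The
correction inverts the mixture, `t = clip((obs - f*ref)/(1-f), 0, 1)`;
negative pre-clip mass diagnoses f overestimation and is logged. `f = 1`
leaves no tumor signal and is a domain error.

Downstream defaults (all configurable): a probe is methylated at
corrected beta ≥ 0.3; recurrence means ≥ 10% of samples; imprinted-DMR
bands are erased < 0.15, biparental 0.35–0.65, methylated > 0.65, with
gap values assigned the nearest state and flagged; CpH scores use a
lymphocyte CpH reference of 0 (lymphocytes lack CpH methylation).
Silencing requires mean corrected promoter beta ≥ 0.3 *and* expression at
or below the 25th percentile of samples whose promoter is unmethylated
(< 0.1); genes without unmethylated reference samples yield indeterminate
calls. Density summaries use a Gaussian KDE with absolute bandwidth 0.03
on [0, 1] with boundary reflection (implemented as a 2048-bin histogram
smoothed with a mirrored Gaussian filter); modes are peaks with
prominence ≥ 5% of the maximum density, so boundary peaks at 0 and 1
register and noise wiggles do not.

## Cohort statistics

Odds ratios are the sample `ad/bc` with a Wald interval; the Haldane 0.5
correction is applied only when a cell is zero and flagged. The
cryptorchidism tables ship as two named presets because the published
counts support two denominators: 66 seminomas with recorded status (OR
7.23) and the 68 reported in the cohort summary (OR 7.54). Chi-square is
uncorrected Pearson by default (continuity correction by flag).
Mann-Whitney uses the exact null up to n = 20 per group and the
tie-corrected normal approximation beyond. Signature scores
median-center each gene across the cohort and take the per-sample median
over member genes. A Benjamini-Hochberg helper is provided for batch use
but not applied by default: the in-scope claims are single targeted
comparisons.

Double-primary concordance keys mutation identity on (gene,
substitution, context) — the arm-granular model has no base-pair
positions, a documented limitation — and correlates each platform on the
features non-missing in both tumors.

## Synthetic cohort

The generator encodes the study conditions; its defaults are not tuning
knobs. Histology mix 72:27:16:13:9 (seminoma : EC : teratoma : yolk sac :
mixed), seminoma KIT-mutation rate 25/72, i(12p) in 100% of NSGCTs and
80% of seminomas, a second WGD in 10/131 of samples, purity Uniform(0.2,
0.8) for seminoma and Uniform(0.4, 0.95) for NSGCT, lymphocyte fraction
`(1 - purity) + N(0, 0.03)` clipped to [0, 1], 5,000 probes (20% CpH, 200
lymphocyte signature probes), mean depth 120×.

Genomes start diploid; rare pre-WGD losses (5% per arm, 2% for 12q so
that 12q LOH stays rare) zero the minor haplotype and are doubled by the
WGD; post-WGD losses remove one or two copies from the minor haplotype
with histology-specific probabilities (NSGCTs lose more, preferentially
19q/15q/22q/19p/10q/8p/2q/8q; seminomas preferentially 11q). Restricting
losses to the minor haplotype keeps major-allele counts consistent with
the WGD count by construction, which is what makes 100% truth agreement a
meaningful noise-free contract rather than a coincidence. The loss
probabilities were chosen once to land cohort ploidy medians near the
archetypal 3.1 (seminoma) vs 2.8 (NSGCT). i(12p) adds 1–3 copies of the
major 12p haplotype; 12p itself is never lost, so i(12p)-negative genomes
retain ≥ 4 copies of 12p.

Mutations: KIT (4q) only in seminomas, pre-WGD with probability 0.4
(multiplicity 2^wgd) else post-WGD; KRAS (12p) either on the haplotype
later duplicated by i(12p) (multiplicity 2^wgd + k, before/during i(12p))
or post-WGD (multiplicity 1, after i(12p)); NRAS (1p) post-WGD;
passengers (Poisson mean 15 per sample, never on 12p) pre-WGD with
probability 0.25. Read counts are binomial at the expected VAF
`m*p/(CN*p + 2(1-p))` with Poisson depth. The substitution spectrum puts
0.40 on C>T; half of C>T falls in CpG context, multiplied by 0.5 in
KIT-mutant seminomas to emulate the deamination-signature depletion
(drivers carry fixed hotspot-like contexts and slightly dilute the
cohort-level C>T share below 0.40).

Methylomes: per-probe lymphocyte references are Uniform(0.85, 1) at
signature probes, ≈ 0.5 at imprinted DMRs, and soma-like bimodal
elsewhere (CpH reference 0). Tumor archetypes: KIT-mutant seminoma all ≈
0; KIT-WT seminoma ≈ 0 plus a recurrent residual set of 0.5% of probes at
beta 0.7 present in 80% of samples (the residual set size is a free
parameter; the published statement bounds it below 1% and a heatmap-scale
figure puts it at 0.5%); EC is ESC-like on CpG with CpH betas
Uniform(0.15, 0.35) (mean 0.25); teratoma/yolk sac are soma-like with
poised-promoter silencing gains planted at histology-specific rates and
occasional methylation of one imprinted DMR. Mixed samples combine
archetypes by Dirichlet component fractions, so CpH methylation scales
with EC content by construction. Per-sample Gaussian jitter (sd 0.01) is
added before mixing, and the emitted observed matrix is computed exactly
from the stored truth components, so re-mixing reproduces it to machine
precision.

Expression is a small gene panel: KIT and cancer-testis antigen genes
increase with seminoma fraction, twenty immune genes scale linearly with
the lymphocyte fraction, silencing genes drop by 6 log2 units when
silenced, plus background genes.

Randomness: one seed per cohort; each sample draws from a substream
keyed by (seed, sample index), so sample-level draws are reproducible
when the cohort grows or reorders.

What the simulation does *not* emulate — and hence what passing tests do
not show about real data: integer copy numbers are noise-free (no
segmentation or purity-estimation error feeding the CN inputs);
lymphocyte contamination is the only non-tumor component (no stromal or
second-immune fractions); signature probes are perfectly
lymphocyte-specific up to a small uniform tumor background; the
substitution model is 6-class with a single CpG-context parameter rather
than a full trinucleotide signature mixture; and arm losses are
independent across arms, without the co-occurrence structure of real
karyotypes. Recovery metrics on real arrays will be worse than the
near-ceiling values measured here; the tests establish correctness of
the inference rules, not field performance.

## Problem sizes and determinism

The default test cohort is 120 samples × 5,000 probes (seed fixed),
generated once per session and shared across tests; replicate-based
checks (arm-event ordering, ploidy separation, CpG-depletion detection)
use 20–100 seeded replicates at reduced probe counts since only
copy-number or mutation structure is exercised. The acceptance script
regenerates everything from its `--seed` argument and finishes in a few
seconds. The full pipeline is deterministic: fixed config and seed give
byte-identical reports.
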