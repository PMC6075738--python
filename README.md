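# tgctkit

An inference toolkit for testicular germ cell tumor (TGCT) genomics and
epigenomics. TGCTs are hyper-triploid tumors with very few somatic
mutations; essentially all of them have undergone whole-genome doubling
(WGD), nearly all carry an isochromosome 12p (i(12p)), and seminomas in
particular are heavily infiltrated by lymphocytes and globally
unmethylated. `tgctkit` implements the bespoke inference layer these
properties demand, for analysts working with arm-level allelic copy
number, somatic mutation tables, and methylation array beta values:

- **Mutation-multiplicity timing.** The multiplicity of a mutation — the
  number of mutated allele copies per tumor cell — is computed from the
  tumor variant allele fraction (TVAF), arm total copy number CN, and
  purity p as

  ```
  s_q = TVAF * (CN * p + 2 * (1 - p)) / p
  ```

  A mutation with s_q ≈ 2 on a doubled genome predates the WGD; s_q ≈ 1
  postdates it. For 12p mutations (e.g. *KRAS*), s_q ≥ 2 places the
  mutation before or during i(12p) formation. DNA/RNA VAF concordance and
  a binomial confidence interval on the cancer cell fraction classify
  clonality.
- **Copy-number event calling.** WGD count from length-weighted
  major-allele fractions, i(12p) from the 12p-over-12q excess on total and
  major copy number, 12q LOH, arm gains/losses relative to ploidy, and a
  frequency/aneuploidy timing score that ranks arm events early-to-late
  within histology groups.
- **Methylation deconvolution.** The bulk methylome is modelled as a
  two-component mixture, `beta_obs = f * beta_lymphocyte + (1 - f) *
  beta_tumor`. The lymphocyte fraction `f` is estimated from
  lymphocyte-specific signature probes (ratio of means) and the mixture is
  inverted to recover tumor-intrinsic beta values. On top of the
  correction: density/modality summaries, recurrent residual methylation
  in seminomas, CpH (non-CpG) methylation scores that quantify embryonal
  carcinoma content, imprinted-DMR states, and promoter
  epigenetic-silencing calls gated on expression.
- **Cohort statistics.** Substitution spectra with the CpG-context C>T
  deamination readout, odds ratios with Wald intervals (including the
  reconstructed dual *KIT*+*RAS*-mutant seminoma vs cryptorchidism
  tables), chi-square tests, exact Mann-Whitney comparisons, immune
  signature scoring, and double-primary concordance.
- **Synthetic cohorts.** `generate_cohort` simulates all of the above
  jointly — copy-number, mutations with read counts, methylome mixtures,
  expression — with full ground truth recorded, so every stage has a
  closed testing loop.

## Worked example

```python
from tgctkit import (SimulationConfig, generate_cohort, compute_multiplicity,
                     classify_vs_wgd, odds_ratio, ContingencyTable2x2,
                     estimate_lymphocyte_fraction)
import numpy as np, pandas as pd

# A mutation at TVAF 0.6 on a 4-copy arm in an 80%-pure tumor:
s_q = compute_multiplicity(tvaf=0.6, total_cn=4, purity=0.8)
print(f"s_q = {s_q:.2f} -> {classify_vs_wgd(s_q, major_cn=3, minor_cn=1, wgd_count=1)}")

# Cryptorchidism odds ratio for dual KIT+RAS-mutant seminomas
# (4/2 cryptorchid/not among dual mutants; 13/47 among the rest):
res = odds_ratio(ContingencyTable2x2(a=4, b=2, c=13, d=47))
print(f"OR = {res.odds_ratio:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.1f})")

# Lymphocyte deconvolution on a simulated 120-sample cohort:
cohort = generate_cohort(SimulationConfig(n_samples=120, rng_seed=1))
est = estimate_lymphocyte_fraction(cohort.beta, cohort.probe_annotation)
f_hat = pd.Series({e.sample_id: e.f for e in est})
truth = cohort.truth.per_sample
r = np.corrcoef(f_hat[truth.index], truth["true_purity"])[0, 1]
print(f"Pearson r(lymphocyte fraction, purity) = {r:.3f} over {len(truth)} samples")
```

prints

```
s_q = 2.70 -> before_wgd
OR = 7.23 (95% CI 1.19-44.0)
Pearson r(lymphocyte fraction, purity) = -0.988 over 120 samples
```

The multiplicity of 2.7 rounds to 3 = the major allele count, placing the
mutation before the doubling; the odds ratio reproduces the published
association between dual-mutant seminomas and cryptorchidism; and the
methylation-based lymphocyte estimate is nearly perfectly anti-correlated
with tumor purity, as expected when infiltration is the dominant
non-tumor component.

## Command line

The `tgctkit` console script wires the stages together:

```sh
tgctkit simulate --out cohort/ --seed 7
tgctkit cn-events --segments cohort/segments.tsv --meta cohort/samples.tsv --out cn/
tgctkit time-mutations --mutations cohort/mutations.tsv \
    --segments cohort/segments.tsv --meta cohort/samples.tsv --out timing.tsv
tgctkit deconvolve --beta cohort/beta.tsv --probes cohort/probes.tsv --out deconv/
tgctkit full-run --config run.yaml --out results/
```

`full-run` takes a YAML config with either a `simulate:` block or an
`inputs:` block of file paths, runs every stage, and writes stage TSVs
plus a versioned `report.json` that echoes all thresholds and the seed;
identical config and seed give byte-identical reports.

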