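"""End-to-end orchestration: simulate or load a cohort, run every stage,
write TSV outputs and a machine-readable JSON report.

The report echoes every threshold and the seed (provenance block), and a
fixed config + seed yields byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io_formats as io
from . import copy_number_events as cne
from . import methylation_deconv as md
from . import mutation_timing as mt
from . import cohort_stats as cs
from .exceptions import ConfigError
from .synthetic_cohort import (
    CTA_GENES, IMMUNE_GENES, SimulationConfig, SyntheticCohort, generate_cohort,
)
from .types import BetaMatrix, SampleMeta, SomaticMutation

REPORT_SCHEMA_VERSION = 1

DEFAULT_THRESHOLDS = {
    "multiplicity_tol": mt.DEFAULT_MULTIPLICITY_TOL,
    "ccf_clonal_threshold": mt.CCF_CLONAL_THRESHOLD,
    "methylated_beta": md.METHYLATED_BETA,
    "recurrence_fraction": md.RECURRENCE_FRACTION,
    "imprint_erased_max": md.IMPRINT_ERASED_MAX,
    "density_bandwidth": md.DENSITY_BANDWIDTH,
    "silencing_expression_quantile": 0.25,
}


@dataclass
class RunConfig:
    """Full-run configuration: either a simulation block or input paths."""

    simulate: Optional[dict] = None
    inputs: Optional[dict] = None
    thresholds: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        cfg = cls(
            simulate=raw.get("simulate"),
            inputs=raw.get("inputs"),
            thresholds=dict(raw.get("thresholds", {})),
            seed=int(raw.get("seed", 0)),
        )
        if cfg.simulate is None and cfg.inputs is None:
            raise ConfigError("config needs a 'simulate' block or 'inputs' paths")
        if cfg.simulate is not None and cfg.inputs is not None:
            raise ConfigError("give either 'simulate' or 'inputs', not both")
        unknown = set(cfg.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigError(f"unknown thresholds: {sorted(unknown)}")
        return cfg


def load_inputs(paths: Mapping[str, str]):
    required = ("mutations", "segments", "samples", "beta", "probes", "expression")
    missing = [k for k in required if k not in paths]
    if missing:
        raise ConfigError(f"inputs block missing paths: {missing}")
    return (
        io.read_sample_meta(paths["samples"]),
        io.read_segments(paths["segments"]),
        io.read_mutations(paths["mutations"]),
        io.read_beta_matrix(paths["beta"]),
        io.read_probe_annotation(paths["probes"]),
        io.read_expression(paths["expression"]),
    )


def write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_sample_meta(out_dir / "samples.tsv", cohort.samples)
    io.write_segments(out_dir / "segments.tsv", cohort.segments)
    io.write_mutations(out_dir / "mutations.tsv", cohort.mutations)
    io.write_beta_matrix(out_dir / "beta.tsv", cohort.beta)
    io.write_probe_annotation(out_dir / "probes.tsv", cohort.probe_annotation)
    io.write_expression(out_dir / "expression.tsv", cohort.expression)
    truth = {
        "per_sample": cohort.truth.per_sample.reset_index().to_dict("records"),
        "mutations": cohort.truth.mutations.to_dict("records"),
    }
    (out_dir / "truth.json").write_text(
        json.dumps(truth, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _is_nsgct(sample: SampleMeta) -> bool:
    return sample.histology != "seminoma"


def run_copy_number(samples: Sequence[SampleMeta], segments) -> dict:
    by_sample = io.segments_by_sample(segments)
    wgd_calls, i12p_calls, arm_calls = {}, {}, []
    for sid, segs in by_sample.items():
        call = cne.infer_wgd_count(segs)
        wgd_calls[sid] = call
        i12p_calls[sid] = cne.detect_i12p(segs)
        arm_calls.extend(cne.call_arm_events(segs, call.ploidy))
    groups = {s.sample_id: ("NSGCT" if _is_nsgct(s) else "seminoma")
              for s in samples}
    ordering = cne.order_arm_events(arm_calls, groups)
    return {"wgd": wgd_calls, "i12p": i12p_calls, "arm_events": arm_calls,
            "ordering": ordering}


def run_methylation(beta: BetaMatrix, annotation, expression,
                    thresholds: Mapping) -> dict:
    estimates = md.estimate_lymphocyte_fraction(beta, annotation)
    fractions = md.mixture_fractions(estimates)
    corrected = md.correct_beta_matrix(beta, fractions, annotation)
    cph = md.cph_score(beta, annotation, fractions)
    imprinting = md.imprinting_survey(beta, annotation, fractions)
    silencing = md.call_epigenetic_silencing(
        corrected, annotation, expression,
        beta_threshold=thresholds["methylated_beta"],
        expression_quantile=thresholds["silencing_expression_quantile"])
    return {"estimates": estimates, "fractions": fractions,
            "corrected": corrected, "cph": cph, "imprinting": imprinting,
            "silencing": silencing}


def full_run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the report dict and writes
    ``report.json`` plus stage TSVs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    thresholds = {**DEFAULT_THRESHOLDS, **config.thresholds}

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("rng_seed", config.seed)
        sim = SimulationConfig(**sim_kwargs)
        cohort = generate_cohort(sim)
        write_cohort(cohort, out_dir / "cohort")
        samples, segments, mutations = (cohort.samples, cohort.segments,
                                        cohort.mutations)
        beta, annotation, expression = (cohort.beta, cohort.probe_annotation,
                                        cohort.expression)
    else:
        samples, segments, mutations, beta, annotation, expression = \
            load_inputs(config.inputs)

    # --- copy-number events -------------------------------------------
    cn = run_copy_number(samples, segments)
    pd.DataFrame(
        [(c.sample_id, c.wgd_count, c.ploidy, c.fraction_major_ge2,
          c.fraction_major_ge3) for c in cn["wgd"].values()],
        columns=["sample_id", "wgd_count", "ploidy", "fraction_major_ge2",
                 "fraction_major_ge3"],
    ).to_csv(out_dir / "wgd_calls.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.sample_id, c.present, c.n_12p_copies, c.n_12q_copies, c.loh_12q)
         for c in cn["i12p"].values()],
        columns=["sample_id", "present", "n_12p_copies", "n_12q_copies",
                 "loh_12q"],
    ).to_csv(out_dir / "i12p_calls.tsv", sep="\t", index=False)
    cn["ordering"].to_csv(out_dir / "arm_event_ordering.tsv", sep="\t",
                          index=False)

    # --- mutation timing ----------------------------------------------
    wgd_counts = {sid: c.wgd_count for sid, c in cn["wgd"].items()}
    timing = mt.time_mutations(mutations, segments, samples, wgd_counts,
                               cn["i12p"], tol=thresholds["multiplicity_tol"])
    pd.DataFrame(
        [(t.sample_id, t.gene, t.s_q, t.nearest_integer_m, t.timing_vs_wgd,
          t.timing_vs_i12p, t.clonal) for t in timing],
        columns=["sample_id", "gene", "s_q", "nearest_integer_m",
                 "timing_vs_wgd", "timing_vs_i12p", "clonal"],
    ).to_csv(out_dir / "multiplicity_calls.tsv", sep="\t", index=False)

    # --- methylation ---------------------------------------------------
    meth = run_methylation(beta, annotation, expression, thresholds)
    fractions = meth["fractions"]
    pd.DataFrame(
        [(e.sample_id, e.f, e.n_probes_used) for e in meth["estimates"]],
        columns=["sample_id", "f", "n_probes_used"],
    ).to_csv(out_dir / "lymphocyte_estimates.tsv", sep="\t", index=False)
    meth["cph"].rename_axis("sample_id").to_frame().to_csv(
        out_dir / "cph_scores.tsv", sep="\t")
    meth["imprinting"].to_csv(out_dir / "imprinting.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(c.sample_id, c.gene, c.promoter_beta_corrected, c.expression_log2,
          c.silenced) for c in meth["silencing"]],
        columns=["sample_id", "gene", "promoter_beta_corrected",
                 "expression_log2", "silenced"],
    ).to_csv(out_dir / "silencing_calls.tsv", sep="\t", index=False)

    # --- cohort statistics ---------------------------------------------
    by_sample_muts: dict[str, list[SomaticMutation]] = {}
    for m in mutations:
        by_sample_muts.setdefault(m.sample_id, []).append(m)
    spectra = {s.sample_id: cs.spectrum_profile(
        by_sample_muts.get(s.sample_id, []), s.sample_id) for s in samples}

    report_stats: dict = {}
    sem_ids = [s.sample_id for s in samples if not _is_nsgct(s)]
    nsgct_ids = [s.sample_id for s in samples if _is_nsgct(s)]
    ploidies = {sid: c.ploidy for sid, c in cn["wgd"].items()}
    if len(sem_ids) >= 2 and len(nsgct_ids) >= 2:
        values = [ploidies[sid] for sid in sem_ids + nsgct_ids]
        labels = ["seminoma"] * len(sem_ids) + ["NSGCT"] * len(nsgct_ids)
        stat, p = cs.group_compare(values, labels, "mann_whitney")
        report_stats["ploidy_mw"] = {
            "seminoma_median": float(np.median([ploidies[s] for s in sem_ids])),
            "nsgct_median": float(np.median([ploidies[s] for s in nsgct_ids])),
            "statistic": stat, "p": p}
    kit_mut_sem = [s.sample_id for s in samples
                   if s.histology == "seminoma" and s.kit_status == "mutant"]
    others = [s.sample_id for s in samples if s.sample_id not in set(kit_mut_sem)]
    ct_cpg = {sid: sp.ct_at_cpg_fraction for sid, sp in spectra.items()
              if sp.n_mutations > 0}
    if sum(sid in ct_cpg for sid in kit_mut_sem) >= 2 and \
            sum(sid in ct_cpg for sid in others) >= 2:
        vals, labs = zip(*[(ct_cpg[sid], sid in set(kit_mut_sem))
                           for sid in ct_cpg])
        stat, p = cs.group_compare(list(vals), list(labs), "mann_whitney")
        report_stats["ct_at_cpg_kit_mut_vs_rest"] = {"statistic": stat, "p": p}

    # cryptorchidism vs dual KIT+RAS mutation among seminomas
    dual = {s.sample_id: (s.kit_status == "mutant" and s.ras_status == "mutant")
            for s in samples if s.histology == "seminoma"}
    crypt = {s.sample_id: s.cryptorchidism for s in samples
             if s.histology == "seminoma" and s.cryptorchidism != "unknown"}
    cells = [0, 0, 0, 0]
    for sid, c in crypt.items():
        row = 0 if dual.get(sid) else 1
        col = 0 if c == "yes" else 1
        cells[2 * row + col] += 1
    if all(x > 0 for x in cells):
        from .types import ContingencyTable2x2
        res = cs.odds_ratio(ContingencyTable2x2(*cells))
        report_stats["cryptorchidism_or"] = {
            "table": cells, "odds_ratio": res.odds_ratio,
            "ci": [res.ci_low, res.ci_high]}

    # immune signature score vs methylation-based lymphocyte fraction
    scores = cs.immune_signature_scores(
        expression, {"immune": list(IMMUNE_GENES), "cta": list(CTA_GENES)})
    if "immune" in scores.index:
        shared = [s for s in scores.columns if s in fractions]
        r = stats.pearsonr(scores.loc["immune", shared],
                           [fractions[s] for s in shared]).statistic
        report_stats["immune_score_vs_f_pearson_r"] = float(r)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": thresholds,
        "n_samples": len(samples),
        "n_mutations": len(mutations),
        "wgd_counts": {sid: c.wgd_count for sid, c in cn["wgd"].items()},
        "i12p_prevalence": float(np.mean(
            [c.present for c in cn["i12p"].values()])),
        "mean_lymphocyte_fraction": float(np.mean(list(fractions.values()))),
        "n_silenced_calls": int(sum(bool(c.silenced)
                                    for c in meth["silencing"])),
        "stats": report_stats,
    }
    (out_dir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=_json_default))
    return report
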