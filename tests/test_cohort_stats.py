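import math

import numpy as np
import pytest

from tgctkit.cohort_stats import (
    CRYPTORCHIDISM_BY_HISTOLOGY,
    CRYPTORCHIDISM_TABLES,
    chi_square_2x2,
    group_compare,
    immune_signature_scores,
    odds_ratio,
    spectrum_profile,
)
from tgctkit.exceptions import ValidationError
from tgctkit.types import ContingencyTable2x2, SomaticMutation

import pandas as pd


def mut(sub, ctx, sample="S1"):
    return SomaticMutation(sample_id=sample, gene="G", arm="1p",
                           alt_count=10, ref_count=10, context=ctx,
                           substitution=sub)


class TestSpectrum:
    def test_counting(self):
        muts = ([mut("C>T", "ACG")] * 2 + [mut("C>T", "ACA")] * 2
                + [mut("T>A", "ATA")] * 6)
        profile = spectrum_profile(muts)
        assert profile.fractions["C>T"] == pytest.approx(0.4)
        assert profile.ct_at_cpg_fraction == pytest.approx(0.2)
        assert sum(profile.fractions.values()) == pytest.approx(1.0)

    def test_single_class(self):
        profile = spectrum_profile([mut("T>A", "ATA")] * 3)
        assert profile.fractions["T>A"] == 1.0
        assert profile.ct_at_cpg_fraction == 0.0

    def test_empty_profile(self):
        profile = spectrum_profile([], sample_id="S9")
        assert profile.n_mutations == 0
        assert all(math.isnan(v) for v in profile.fractions.values())

    def test_cpg_fraction_bounded_by_ct_fraction(self, rng):
        subs = ["C>T", "C>A", "T>C"]
        muts = [mut(s, f"A{s[0]}{t}") for s, t in
                zip(rng.choice(subs, 60), rng.choice(list("ACGT"), 60))
                if not (s[0] == "T" and t not in "ACGT")]
        profile = spectrum_profile(muts)
        assert profile.ct_at_cpg_fraction <= profile.fractions["C>T"] + 1e-12


class TestOddsRatio:
    def test_cryptorchidism_reconstruction(self):
        res = odds_ratio(CRYPTORCHIDISM_TABLES["complete_records"])
        assert res.odds_ratio == pytest.approx(7.2308, abs=1e-3)
        assert res.ci_low == pytest.approx(1.189, abs=0.01)
        assert res.ci_high == pytest.approx(43.96, abs=0.05)

    @pytest.mark.parametrize("cells,expected", [
        ((1, 1, 1, 1), 1.0), ((2, 1, 1, 2), 4.0)])
    def test_arithmetic(self, cells, expected):
        assert odds_ratio(ContingencyTable2x2(*cells)).odds_ratio == \
            pytest.approx(expected)

    def test_symmetry_invariants(self):
        table = ContingencyTable2x2(4, 2, 13, 47)
        swapped_both = ContingencyTable2x2(47, 13, 2, 4)
        row_swapped = ContingencyTable2x2(13, 47, 4, 2)
        base = odds_ratio(table).odds_ratio
        assert odds_ratio(swapped_both).odds_ratio == pytest.approx(base)
        assert odds_ratio(row_swapped).odds_ratio == pytest.approx(1 / base)

    def test_haldane_correction_flagged(self):
        res = odds_ratio(ContingencyTable2x2(0, 5, 5, 5))
        assert res.haldane_corrected
        assert res.odds_ratio == pytest.approx(0.5 * 5.5 / (5.5 * 5.5))

    def test_cross_zero_pattern_undefined(self):
        with pytest.raises(ValidationError):
            odds_ratio(ContingencyTable2x2(0, 5, 5, 0))


class TestChiSquare:
    def test_cryptorchidism_by_histology(self):
        stat, p = chi_square_2x2(CRYPTORCHIDISM_BY_HISTOLOGY)
        assert stat == pytest.approx(7.211, abs=0.001)
        assert p == pytest.approx(0.0072, abs=0.0005)

    def test_proportional_table_is_zero(self):
        stat, _ = chi_square_2x2(ContingencyTable2x2(10, 20, 5, 10))
        assert stat == pytest.approx(0.0)

    def test_perfect_separation(self):
        stat, _ = chi_square_2x2(ContingencyTable2x2(10, 0, 0, 10))
        assert stat == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestGroupCompare:
    def test_identical_tiny_groups(self):
        _, p = group_compare([1, 1, 1, 1, 1, 1], ["a"] * 3 + ["b"] * 3)
        assert p == 1.0

    def test_separated_groups_exact(self):
        values = [1, 2, 3, 4, 5, 10, 11, 12, 13, 14]
        labels = ["a"] * 5 + ["b"] * 5
        _, p = group_compare(values, labels)
        assert p == pytest.approx(2 / 252)

    def test_t_test(self, rng):
        values = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
        labels = ["a"] * 30 + ["b"] * 30
        _, p = group_compare(values, labels, test="t_test")
        assert p < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([1, 2, 3], ["a", "a", "a"])

    def test_simulated_ploidy_separation(self):
        """Seminoma vs NSGCT ploidy medians separate decisively at cohort
        scale in >=95% of seeded replicates."""
        from tgctkit.copy_number_events import infer_wgd_count
        from tgctkit.io_formats import segments_by_sample
        from tgctkit.synthetic_cohort import SimulationConfig, generate_cohort
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            cohort = generate_cohort(SimulationConfig(
                n_samples=130, n_probes=800, n_signature_probes=60,
                passenger_rate=0.0, rng_seed=500 + rep))
            hist = cohort.truth.per_sample["histology"]
            ploidy = {sid: infer_wgd_count(segs).ploidy for sid, segs in
                      segments_by_sample(cohort.segments).items()}
            values = [ploidy[s] for s in hist.index]
            labels = (hist == "seminoma").tolist()
            _, p = group_compare(values, labels)
            rejections += p < 1e-4
        assert rejections >= 0.95 * n_reps

    def test_kit_mutant_cpg_depletion_detected(self):
        """The planted CpG-context C>T depletion in KIT-mutant seminoma is
        detected at alpha=0.01 in >=90% of seeded replicates."""
        from tgctkit.synthetic_cohort import SimulationConfig, generate_cohort
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            cohort = generate_cohort(SimulationConfig(
                n_samples=120, n_probes=800, n_signature_probes=60,
                rng_seed=900 + rep))
            truth = cohort.truth.per_sample
            by_sample = {}
            for m in cohort.mutations:
                by_sample.setdefault(m.sample_id, []).append(m)
            values, labels = [], []
            for sid, muts in by_sample.items():
                profile = spectrum_profile(muts, sid)
                if profile.n_mutations >= 5:
                    values.append(profile.ct_at_cpg_fraction)
                    labels.append(bool(truth.loc[sid, "kit_mutant"]))
            _, p = group_compare(values, labels)
            rejections += p < 0.01
        assert rejections >= 0.90 * n_reps


class TestImmuneScores:
    def test_single_gene_signature_is_centered_value(self):
        expr = pd.DataFrame({"S1": [5.0], "S2": [7.0], "S3": [9.0]},
                            index=["GENE"])
        scores = immune_signature_scores(expr, {"sig": ["GENE"]})
        assert scores.loc["sig", "S1"] == pytest.approx(-2.0)
        assert scores.loc["sig", "S2"] == pytest.approx(0.0)

    def test_constant_genes_score_zero(self):
        expr = pd.DataFrame(np.full((3, 4), 2.5), index=["A", "B", "C"],
                            columns=list("WXYZ"))
        scores = immune_signature_scores(expr, {"sig": ["A", "B", "C"]})
        assert (scores.loc["sig"] == 0).all()

    def test_empty_overlap_skipped_with_warning(self):
        expr = pd.DataFrame({"S1": [1.0]}, index=["A"])
        with pytest.warns(UserWarning, match="skipped"):
            scores = immune_signature_scores(expr, {"sig": ["MISSING"]})
        assert scores.empty

    def test_immune_score_tracks_lymphocyte_fraction(self, default_cohort):
        from tgctkit.synthetic_cohort import IMMUNE_GENES
        truth = default_cohort.truth.per_sample
        scores = immune_signature_scores(
            default_cohort.expression, {"immune": list(IMMUNE_GENES)})
        r = np.corrcoef(scores.loc["immune", truth.index],
                        truth["true_lymph_fraction"])[0, 1]
        assert r >= 0.9
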