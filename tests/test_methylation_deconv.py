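import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgctkit.exceptions import EstimationError, ValidationError
from tgctkit.methylation_deconv import (
    call_epigenetic_silencing,
    correct_beta,
    correct_beta_matrix,
    cph_score,
    density_summary,
    estimate_lymphocyte_fraction,
    imprinting_survey,
    residual_methylation_fraction,
)
from tgctkit.synthetic_cohort import mix_beta
from tgctkit.types import BetaMatrix


def make_annotation(n, signature=None, context="CpG", ref=0.9, dmr=None,
                    gene=None):
    sig = np.zeros(n, dtype=bool)
    if signature is not None:
        sig[signature] = True
    return pd.DataFrame({
        "context": [context] * n,
        "region": ["other"] * n,
        "imprinted_dmr": [dmr] * n,
        "lymphocyte_signature": sig,
        "lymphocyte_ref_beta": [ref] * n,
        "promoter_of_gene": [gene] * n,
    }, index=pd.Index([f"cg{i}" for i in range(n)], name="probe_id"))


class TestLymphocyteEstimate:
    def _estimate(self, sig_beta, ref):
        ann = make_annotation(30, signature=slice(None), ref=ref)
        beta = BetaMatrix(pd.DataFrame({"S1": [sig_beta] * 30}, index=ann.index))
        (est,) = estimate_lymphocyte_fraction(beta, ann)
        return est

    def test_pure_tumor(self):
        assert self._estimate(0.0, 0.9).f == 0.0

    def test_pure_lymphocyte(self):
        assert self._estimate(0.9, 0.9).f == pytest.approx(1.0)

    def test_half_mixture(self):
        assert self._estimate(0.45, 0.9).f == pytest.approx(0.5)

    def test_too_few_probes_rejected(self):
        ann = make_annotation(10, signature=slice(None))
        beta = BetaMatrix(pd.DataFrame({"S1": [0.5] * 10}, index=ann.index))
        with pytest.raises(EstimationError):
            estimate_lymphocyte_fraction(beta, ann)


class TestCorrectBeta:
    @pytest.mark.parametrize("obs,f,ref,expected", [
        (0.5, 0.5, 1.0, 0.0),
        (0.8, 0.0, 0.3, 0.8),  # identity at f=0
        (0.6, 0.4, 0.9, 0.4),
        (0.1, 0.4, 0.9, 0.0),  # clipped at the floor
    ])
    def test_examples(self, obs, f, ref, expected):
        assert correct_beta(obs, f, ref) == pytest.approx(expected)

    def test_f_one_is_domain_error(self):
        with pytest.raises(ValueError):
            correct_beta(0.5, 1.0, 0.9)

    @settings(max_examples=200, deadline=None)
    @given(t=st.floats(0, 1), f=st.floats(0, 0.99), r=st.floats(0, 1))
    def test_mixture_round_trip(self, t, f, r):
        assert correct_beta(mix_beta(t, f, r), f, r) == pytest.approx(
            t, abs=1e-12)

    @pytest.mark.parametrize("args", [(0.5, -0.1, 1.0), (1.2, 0.5, 0.5),
                                      (0.5, 0.5, 1.5)])
    def test_mix_beta_rejects_out_of_range(self, args):
        with pytest.raises(ValueError):
            mix_beta(*args)

    def test_matrix_correction_matches_scalar(self, rng):
        ann = make_annotation(100, ref=0.6)
        obs = rng.uniform(0, 1, (100, 2))
        beta = BetaMatrix(pd.DataFrame(obs, index=ann.index,
                                       columns=["S1", "S2"]))
        out = correct_beta_matrix(beta, {"S1": 0.3, "S2": 0.0}, ann)
        expected = np.array([[correct_beta(v, f, 0.6) for v, f in
                              zip(row, (0.3, 0.0))] for row in obs])
        np.testing.assert_allclose(out.beta.to_numpy(), expected, atol=1e-12)


class TestDensity:
    def test_soma_like_bimodal(self, rng):
        vals = np.concatenate([
            np.clip(rng.normal(0.03, 0.02, 800), 0, 1),
            np.clip(rng.normal(0.93, 0.03, 800), 0, 1)])
        summary = density_summary(vals)
        assert summary.n_modes == 2
        assert summary.peak_positions[0] < 0.1
        assert summary.peak_positions[-1] > 0.85

    def test_unmethylated_unimodal_near_zero(self, rng):
        vals = np.clip(rng.normal(0.02, 0.015, 2000), 0, 1)
        summary = density_summary(vals)
        assert summary.n_modes == 1
        assert summary.peak_positions[0] < 0.05
        assert summary.mass_above_03 < 0.01

    def test_constant_zeros_single_boundary_peak(self):
        summary = density_summary(np.zeros(600))
        assert summary.n_modes == 1
        assert summary.peak_positions[0] < 0.01

    def test_too_few_values_rejected(self):
        with pytest.raises(EstimationError):
            density_summary(np.zeros(100))


class TestResidualMethylation:
    def test_all_zero(self):
        beta = BetaMatrix(pd.DataFrame(np.zeros((100, 4)),
                                       index=[f"cg{i}" for i in range(100)]))
        assert residual_methylation_fraction(beta) == 0.0

    def test_counting(self):
        values = np.zeros((5000, 6))
        values[:50, :] = 0.9  # 50 probes methylated in every sample
        beta = BetaMatrix(pd.DataFrame(values,
                                       index=[f"cg{i}" for i in range(5000)]))
        assert residual_methylation_fraction(beta) == pytest.approx(0.01)

    def test_single_sample_rejected(self):
        beta = BetaMatrix(pd.DataFrame(np.zeros((100, 1)),
                                       index=[f"cg{i}" for i in range(100)]))
        with pytest.raises(ValidationError):
            residual_methylation_fraction(beta)


class TestCphScore:
    def test_zero_cph_scores_zero(self):
        ann = make_annotation(60, context="CpH", ref=0.0)
        beta = BetaMatrix(pd.DataFrame({"S1": np.zeros(60)}, index=ann.index))
        assert cph_score(beta, ann, {"S1": 0.3})["S1"] == 0.0

    def test_mixing_correction(self):
        # tumor CpH 0.25 observed through 20% lymphocytes -> 0.2 observed
        ann = make_annotation(60, context="CpH", ref=0.0)
        beta = BetaMatrix(pd.DataFrame({"S1": np.full(60, 0.2)},
                                       index=ann.index))
        assert cph_score(beta, ann, {"S1": 0.2})["S1"] == pytest.approx(0.25)

    def test_no_cph_probes_rejected(self):
        ann = make_annotation(60, context="CpG")
        beta = BetaMatrix(pd.DataFrame({"S1": np.zeros(60)}, index=ann.index))
        with pytest.raises(EstimationError):
            cph_score(beta, ann, {"S1": 0.0})

    def test_tracks_simulated_ec_fraction(self, default_cohort, default_deconv):
        truth = default_cohort.truth.per_sample
        scores = cph_score(default_cohort.beta,
                           default_cohort.probe_annotation,
                           default_deconv["fractions"])
        r = np.corrcoef(scores[truth.index], truth["ec_fraction"])[0, 1]
        assert r >= 0.8


class TestImprinting:
    def _survey(self, mean, f=0.0):
        ann = make_annotation(5, ref=0.5, dmr="DMR_X")
        beta = BetaMatrix(pd.DataFrame(
            {"S1": np.full(5, mix_beta(mean, f, 0.5))}, index=ann.index))
        return imprinting_survey(beta, ann, {"S1": f}).iloc[0]

    @pytest.mark.parametrize("mean,state", [
        (0.02, "erased"), (0.5, "biparental"), (0.8, "methylated")])
    def test_bands(self, mean, state):
        row = self._survey(mean)
        assert row["state"] == state
        assert not row["boundary"]

    def test_gap_value_flagged_nearest(self):
        row = self._survey(0.2)
        assert row["state"] == "erased" and row["boundary"]

    def test_lymphocyte_signal_removed_by_correction(self):
        # tumor fully erased, half lymphocytes: observed DMR beta ~0.25
        row = self._survey(0.0, f=0.5)
        assert row["state"] == "erased"

    def test_simulated_seminomas_erased_after_correction(
            self, default_cohort, default_deconv):
        truth = default_cohort.truth.per_sample
        survey = imprinting_survey(default_cohort.beta,
                                   default_cohort.probe_annotation,
                                   default_deconv["fractions"])
        sem = survey[survey["sample_id"].isin(
            truth.index[truth["histology"] == "seminoma"])]
        assert (sem["state"] == "erased").all()


class TestSilencing:
    def _setup(self, test_beta, test_expr):
        n = 5
        ann = make_annotation(n, ref=0.05, gene="BRCA1")
        cols = {f"R{i}": np.full(n, 0.02) for i in range(8)}  # references
        cols["T1"] = np.full(n, test_beta)
        beta = BetaMatrix(pd.DataFrame(cols, index=ann.index))
        expr = pd.DataFrame(
            {**{f"R{i}": [8.0 + 0.1 * i] for i in range(8)},
             "T1": [test_expr]}, index=["BRCA1"])
        return call_epigenetic_silencing(beta, ann, expr)

    def test_methylated_and_low_expression_silenced(self):
        calls = {c.sample_id: c for c in self._setup(0.7, 2.0)}
        assert calls["T1"].silenced is True

    def test_unmethylated_never_silenced(self):
        calls = {c.sample_id: c for c in self._setup(0.05, 2.0)}
        assert calls["T1"].silenced is False

    def test_methylated_but_expressed_not_silenced(self):
        calls = {c.sample_id: c for c in self._setup(0.7, 9.0)}
        assert calls["T1"].silenced is False

    def test_no_reference_samples_unknown(self):
        n = 5
        ann = make_annotation(n, ref=0.05, gene="BRCA1")
        beta = BetaMatrix(pd.DataFrame(
            {"T1": np.full(n, 0.7), "T2": np.full(n, 0.8)}, index=ann.index))
        expr = pd.DataFrame({"T1": [2.0], "T2": [3.0]}, index=["BRCA1"])
        calls = call_epigenetic_silencing(beta, ann, expr)
        assert all(c.silenced is None for c in calls)

    def test_specific_to_nsgct_archetypes(self, default_cohort, default_deconv):
        """Silencing was planted only in NSGCTs; calls must not leak into
        seminomas and must recover every planted event."""
        calls = call_epigenetic_silencing(
            default_deconv["corrected"], default_cohort.probe_annotation,
            default_cohort.expression)
        called = {(c.sample_id, c.gene) for c in calls if c.silenced}
        planted = set(map(tuple, default_cohort.truth.silenced.to_numpy()))
        truth = default_cohort.truth.per_sample
        seminomas = set(truth.index[truth["histology"] == "seminoma"])
        assert not {s for s, _ in called} & seminomas
        assert called == planted


class TestCohortRecovery:
    def test_estimated_f_anticorrelates_with_purity(self, default_cohort,
                                                    default_deconv):
        truth = default_cohort.truth.per_sample
        f_hat = pd.Series({e.sample_id: e.f
                           for e in default_deconv["estimates"]})
        r = np.corrcoef(f_hat[truth.index], truth["true_purity"])[0, 1]
        assert r <= -0.90

    def test_f_recovered_within_rmse(self, default_cohort, default_deconv):
        truth = default_cohort.truth.per_sample
        f_hat = pd.Series({e.sample_id: e.f
                           for e in default_deconv["estimates"]})
        rmse = float(np.sqrt(np.mean(
            (f_hat[truth.index] - truth["true_lymph_fraction"]) ** 2)))
        assert rmse <= 0.05
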