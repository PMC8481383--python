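"""Descriptives, design coding, mixed-model fits and contrasts.

The reference fits for the mixed models were computed with lme4 (glmer /
lmer, ML) on a seed-fixed synthetic corpus and frozen here as independent
oracle values.
"""

import numpy as np
import pandas as pd
import pytest

from turntimes.synthetic import CorpusGenSpec, gen_conversation_corpus
from turntimes.transitions import extract_corpus_transitions, transitions_to_frame
from turntimes.stats import (
    ModelDesign,
    build_design,
    describe,
    fit_overlap_glmm,
    fit_transition_lmm,
    kde_modes,
    lrt,
    marginal_contrasts,
)


@pytest.fixture(scope="module")
def oracle_frame():
    """Kept transitions of the corpus the lme4 oracle fits were run on."""
    corpus, _ = gen_conversation_corpus(
        CorpusGenSpec(n_conversations={2: 6, 3: 6}, minutes=3.0, seed=11)
    )
    kept, *_ = extract_corpus_transitions(corpus)
    return transitions_to_frame(kept)


class TestDescribe:
    def test_symmetric_set(self):
        s = describe([1, 2, 3, 4, 5])
        assert s.mean == 3 and s.median == 3 and s.mad == 1

    def test_singleton(self):
        s = describe([5.0])
        assert s.mean == s.median == 5.0
        assert s.sd == 0.0 and not s.sd_defined
        assert s.mad == 0.0 and s.modes == [5.0]

    def test_normal_sample_single_mode_near_mean(self):
        x = np.random.default_rng(1).normal(300, 50, 10_000)
        s = describe(x)
        assert len(s.modes) == 1
        assert s.modes[0] == pytest.approx(300, abs=5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            describe([])


class TestKDEModes:
    def test_separated_mixture_two_modes(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(10, 1, 5000)])
        modes = sorted(kde_modes(x))
        assert len(modes) == 2
        assert modes[0] == pytest.approx(0, abs=0.5)
        assert modes[1] == pytest.approx(10, abs=0.5)

    def test_unimodal_sample_one_mode(self):
        x = np.random.default_rng(3).normal(0, 1, 10_000)
        assert len(kde_modes(x)) == 1

    def test_constant_data(self):
        assert kde_modes([7.0] * 10) == [7.0]

    def test_modes_within_data_range(self):
        x = np.random.default_rng(4).exponential(100, 2000)
        for m in kde_modes(x):
            assert x.min() <= m <= x.max()


class TestDesign:
    def test_lmm_coding_dyadic_qr_gap_row(self):
        frame = pd.DataFrame(
            {
                "group_size": [2], "type": ["QR"], "transition_ms": [150.0],
                "next_speaker": ["s1"],
            }
        )
        d = build_design(frame, response="transition")
        row = d.exog.iloc[0]
        assert row["gap:group_size"] == 0.5
        assert row["gap:type_qr"] == 0.5
        assert row["ovl:group_size"] == 0.0  # nested out of the overlap level
        assert row["overlap"] == 0.0

    def test_sum_contrasts_balance_to_zero(self):
        frame = pd.DataFrame(
            {
                "group_size": [2, 2, 3, 3],
                "type": ["QR", "nonQR", "QR", "nonQR"],
                "transition_ms": [100.0, 100.0, 100.0, 100.0],
                "next_speaker": list("abcd"),
            }
        )
        d = build_design(frame, response="overlap")
        assert d.exog["group_size"].sum() == 0.0
        assert d.exog["type_qr"].sum() == 0.0
        assert d.exog["gs_x_qr"].sum() == 0.0

    def test_glmm_response_is_overlap_indicator(self):
        frame = pd.DataFrame(
            {
                "group_size": [2, 2], "type": ["QR", "QR"],
                "transition_ms": [-10.0, 25.0], "next_speaker": ["a", "b"],
            }
        )
        d = build_design(frame, response="overlap")
        assert list(d.endog) == [1, 0]


class TestLMM:
    # lme4::lmer (ML) on the oracle corpus
    LME4_PARAMS = {
        "const": 365.36323,
        "overlap": -640.94237,
        "gap:group_size": 49.69516,
        "ovl:group_size": -14.75750,
        "gap:type_qr": -26.96438,
        "ovl:type_qr": 48.04554,
        "gap:gs_x_qr": 29.28092,
        "ovl:gs_x_qr": -31.48438,
    }
    LME4_LOGLIK = -2375.68

    def test_matches_lme4_oracle(self, oracle_frame):
        fit = fit_transition_lmm(build_design(oracle_frame, "transition"))
        for term, ref in self.LME4_PARAMS.items():
            assert fit.params.loc[term, "estimate"] == pytest.approx(
                ref, abs=1.0
            ), term
        assert fit.loglik == pytest.approx(self.LME4_LOGLIK, abs=0.5)

    def test_shift_equivariance(self, oracle_frame):
        d = build_design(oracle_frame, "transition")
        fit = fit_transition_lmm(d)
        shifted = ModelDesign(
            kind=d.kind, endog=d.endog + 500.0, exog=d.exog,
            exog_re=d.exog_re, groups=d.groups, frame=d.frame,
        )
        fit2 = fit_transition_lmm(shifted)
        assert fit2.params.loc["const", "estimate"] - fit.params.loc[
            "const", "estimate"
        ] == pytest.approx(500.0, abs=1e-4)
        for term in self.LME4_PARAMS:
            if term == "const":
                continue
            assert fit2.params.loc[term, "estimate"] == pytest.approx(
                fit.params.loc[term, "estimate"], abs=1e-4
            )

    def test_single_group_raises(self):
        frame = pd.DataFrame(
            {
                "group_size": [2, 2], "type": ["QR", "nonQR"],
                "transition_ms": [10.0, 20.0], "next_speaker": ["a", "a"],
            }
        )
        with pytest.raises(ValueError, match="grouping"):
            fit_transition_lmm(build_design(frame, "transition"))


class TestGLMM:
    # lme4::glmer (Laplace) on the oracle corpus
    LME4_PARAMS = [-0.8770529, -0.1359580, -0.2883346, 1.0639957]
    LME4_SE = [0.1260867, 0.2521750, 0.2521735, 0.5043609]
    LME4_LOGLIK = -223.5536

    def test_matches_lme4_oracle(self, oracle_frame):
        fit = fit_overlap_glmm(build_design(oracle_frame, "overlap"))
        np.testing.assert_allclose(
            fit.params["estimate"].to_numpy(), self.LME4_PARAMS, atol=1e-3
        )
        np.testing.assert_allclose(
            fit.params["se"].to_numpy(), self.LME4_SE, atol=2e-3
        )
        assert fit.loglik == pytest.approx(self.LME4_LOGLIK, abs=1e-2)
        # lme4 reports this fit as singular too (zero RE variance)
        assert fit.singular

    def test_single_group_raises(self):
        frame = pd.DataFrame(
            {
                "group_size": [2, 2], "type": ["QR", "nonQR"],
                "transition_ms": [-10.0, 20.0], "next_speaker": ["a", "a"],
            }
        )
        with pytest.raises(ValueError, match="grouping"):
            fit_overlap_glmm(build_design(frame, "overlap"))


class TestLRT:
    def test_identical_fits_chi2_zero(self, oracle_frame):
        fit = fit_transition_lmm(build_design(oracle_frame, "transition"))
        chi2, df, p = lrt(fit, fit)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_overlap_expansion_df_and_power(self, oracle_frame):
        reduced = fit_transition_lmm(
            build_design(oracle_frame, "transition", include_overlap=False)
        )
        full = fit_transition_lmm(build_design(oracle_frame, "transition"))
        chi2, df, p = lrt(reduced, full)
        # 4 extra fixed effects + 3 extra random (co)variances
        assert df == 7
        assert df == full.n_params - reduced.n_params
        assert chi2 > 0
        assert p < 0.001

    def test_different_data_raises(self, oracle_frame):
        full = fit_transition_lmm(build_design(oracle_frame, "transition"))
        smaller = fit_transition_lmm(
            build_design(oracle_frame.iloc[:-5], "transition")
        )
        with pytest.raises(ValueError, match="identical data"):
            lrt(smaller, full)


class TestMarginalContrasts:
    def test_decomposition_algebra(self, oracle_frame):
        fit = fit_overlap_glmm(build_design(oracle_frame, "overlap"))
        by_label = {c.label: c for c in marginal_contrasts(fit)}
        gs = fit.params.loc["group_size", "estimate"]
        inter = fit.params.loc["gs_x_qr", "estimate"]
        assert by_label["group_size within QR"].estimate == pytest.approx(
            gs + 0.5 * inter
        )
        assert by_label["group_size within nonQR"].estimate == pytest.approx(
            gs - 0.5 * inter
        )

    def test_releveled_refit_agrees(self, oracle_frame):
        """The within-nonQR contrast equals the group-size coefficient of a
        refit in which transition type is dummy-coded with nonQR as the
        reference level (pure reparameterization)."""
        d = build_design(oracle_frame, "overlap")
        fit = fit_overlap_glmm(d)
        within_nonqr = next(
            c for c in marginal_contrasts(fit)
            if c.label == "group_size within nonQR"
        )
        qr_dummy = (d.exog["type_qr"] + 0.5).to_numpy()  # 1 for QR, 0 nonQR
        gs = d.exog["group_size"].to_numpy()
        exog2 = pd.DataFrame(
            {
                "const": 1.0,
                "group_size": gs,
                "type_qr": qr_dummy,
                "gs_x_qr": gs * qr_dummy,
            }
        )
        d2 = ModelDesign(
            kind="glmm", endog=d.endog, exog=exog2, exog_re=d.exog_re,
            groups=d.groups, frame=d.frame,
        )
        fit2 = fit_overlap_glmm(d2)
        assert fit2.params.loc["group_size", "estimate"] == pytest.approx(
            within_nonqr.estimate, abs=1e-3
        )
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-4)

    def test_missing_interaction_raises(self, oracle_frame):
        fit = fit_overlap_glmm(build_design(oracle_frame, "overlap"))
        fit.params = fit.params.drop(index="gs_x_qr")
        with pytest.raises(ValueError, match="gs_x_qr"):
            marginal_contrasts(fit)
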