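"""Design matrix, covariance blocks, GLS fit and network augmentation."""

import math

import numpy as np
import pytest

import nmadesign as nd
from nmadesign.data import DataValidationError
from nmadesign.nma import EstimationError, build_covariance, build_design_matrix
from conftest import brute_force_gls


class TestDesignMatrix:
    def test_basic_comparison_single_plus_one(self):
        records = [nd.ContrastRecord("S1", "A", "B", 0.5, 0.3)]
        dm = build_design_matrix(nd.assemble_network(records, "A"))
        assert dm.matrix.tolist() == [[1.0]]
        assert dm.columns == ("B",)

    def test_functional_comparison_plus_minus_pair(self, chain_network):
        dm = build_design_matrix(chain_network)
        # row 2 is the B-C study: mu_BC = mu_AC - mu_AB
        b, c = dm.columns.index("B"), dm.columns.index("C")
        assert dm.matrix[1, b] == -1.0
        assert dm.matrix[1, c] == 1.0

    def test_three_arm_study_contributes_two_rows(self, three_arm_study):
        network = nd.Network(studies=(three_arm_study,), baseline="A")
        dm = build_design_matrix(network)
        assert dm.matrix.shape == (2, 2)

    def test_rows_have_valid_entry_pattern(self, brd_like_network):
        dm = build_design_matrix(brd_like_network)
        for row in dm.matrix:
            plus, minus = np.sum(row == 1), np.sum(row == -1)
            assert plus == 1 and minus in (0, 1)
            assert np.all(np.isin(row, (-1.0, 0.0, 1.0)))


class TestCovariance:
    def test_two_arm_scalar_block(self):
        records = [nd.ContrastRecord("S1", "A", "B", 0.5, 0.3)]
        cov = build_covariance(nd.assemble_network(records, "A"))
        assert cov.blocks[0] == pytest.approx(np.array([[0.09]]))

    def test_three_arm_offdiagonal_is_shared_arm_variance(self):
        # equal arms n=100, p=0.5: per-arm variance 1/(100*0.25) = 0.04
        study = nd.Study(
            study_id="S1",
            arms=tuple(nd.ArmRecord("S1", t, 50, 100) for t in "ABZ"),
        )
        cov = build_covariance(nd.Network(studies=(study,), baseline="A"))
        assert cov.blocks[0] == pytest.approx(np.array([[0.08, 0.04], [0.04, 0.08]]))

    def test_contrast_level_three_arm_reconstruction(self):
        # pairwise variances built from per-arm variances v_A, v_B, v_Z
        v = {"A": 0.02, "B": 0.05, "Z": 0.03}
        records = [
            nd.ContrastRecord("S1", "A", "B", 0.1, math.sqrt(v["A"] + v["B"])),
            nd.ContrastRecord("S1", "A", "Z", 0.2, math.sqrt(v["A"] + v["Z"])),
            nd.ContrastRecord("S1", "B", "Z", 0.1, math.sqrt(v["B"] + v["Z"])),
        ]
        study = nd.Study(study_id="S1", contrasts=tuple(records))
        cov = build_covariance(nd.Network(studies=(study,), baseline="A"))
        assert cov.blocks[0] == pytest.approx(
            np.array([[v["A"] + v["B"], v["A"]], [v["A"], v["A"] + v["Z"]]])
        )

    def test_inconsistent_pairwise_variances_rejected(self):
        # implied off-diagonal breaks positive definiteness
        records = [
            nd.ContrastRecord("S1", "A", "B", 0.1, 0.1),
            nd.ContrastRecord("S1", "A", "Z", 0.2, 0.1),
            nd.ContrastRecord("S1", "B", "Z", 0.1, 1.0),
        ]
        study = nd.Study(study_id="S1", contrasts=tuple(records))
        with pytest.raises(DataValidationError, match="S1"):
            build_covariance(nd.Network(studies=(study,), baseline="A"))


class TestFit:
    def test_single_study_is_identity(self):
        records = [nd.ContrastRecord("S1", "A", "B", 2.007, 0.3)]
        fit = nd.fit_fixed_effects_nma(nd.assemble_network(records, "A"))
        assert fit.estimate("A", "B") == pytest.approx(2.007)
        assert nd.contrast_variance(fit, "A", "B") == pytest.approx(0.09)

    def test_two_studies_inverse_variance_pool(self):
        records = [
            nd.ContrastRecord("S1", "A", "B", 1.0, 0.5),
            nd.ContrastRecord("S2", "A", "B", 2.0, 0.5),
        ]
        fit = nd.fit_fixed_effects_nma(nd.assemble_network(records, "A"))
        assert fit.estimate("A", "B") == pytest.approx(1.5)
        assert nd.contrast_variance(fit, "A", "B") == pytest.approx(0.125)

    def test_chain_adds_estimates_and_variances(self, chain_network):
        fit = nd.fit_fixed_effects_nma(chain_network)
        assert fit.estimate("A", "C") == pytest.approx(2.007 - 0.5)
        assert nd.contrast_variance(fit, "A", "C") == pytest.approx(0.09 + 0.16)

    def test_matches_normal_equation_oracle(self, brd_like_network):
        fit = nd.fit_fixed_effects_nma(brd_like_network)
        mu, cov = brute_force_gls(brd_like_network)
        np.testing.assert_allclose(fit.mu_b_hat, mu, rtol=1e-10)
        np.testing.assert_allclose(fit.cov_mu_b, cov, rtol=1e-9, atol=1e-14)

    def test_small_networks_match_oracle(self, chain_network, three_arm_study):
        for network in (
            chain_network,
            nd.Network(studies=(three_arm_study,), baseline="A"),
        ):
            fit = nd.fit_fixed_effects_nma(network)
            mu, cov = brute_force_gls(network)
            np.testing.assert_allclose(fit.mu_b_hat, mu, rtol=1e-10)
            np.testing.assert_allclose(fit.cov_mu_b, cov, rtol=1e-10)

    def test_disconnected_network_refused(self):
        s1 = nd.Study("S1", contrasts=(nd.ContrastRecord("S1", "A", "B", 0.1, 0.2),))
        s2 = nd.Study("S2", contrasts=(nd.ContrastRecord("S2", "C", "D", 0.1, 0.2),))
        network = nd.Network(studies=(s1, s2), baseline="A")
        with pytest.raises(EstimationError, match="disconnected"):
            nd.fit_fixed_effects_nma(network)

    def test_contrast_variance_degenerate_and_symmetric(self, brd_like_fit):
        assert nd.contrast_variance(brd_like_fit, "ENFO", "ENFO") == pytest.approx(0.0)
        assert nd.contrast_variance(brd_like_fit, "ENFO", "TULA") == pytest.approx(
            nd.contrast_variance(brd_like_fit, "TULA", "ENFO")
        )
        with pytest.raises(EstimationError):
            nd.contrast_variance(brd_like_fit, "ENFO", "NOPE")

    def test_baseline_invariance(self, brd_like_network):
        """Refitting under a different baseline leaves every pairwise
        contrast variance unchanged."""
        fit_nc = nd.fit_fixed_effects_nma(brd_like_network)
        alt = nd.Network(studies=brd_like_network.studies, baseline="ENFO")
        fit_enfo = nd.fit_fixed_effects_nma(alt)
        for pair in [("NC", "ENFO"), ("CEFTS", "TULA"), ("NC", "OXY")]:
            assert nd.contrast_variance(fit_nc, *pair) == pytest.approx(
                nd.contrast_variance(fit_enfo, *pair), rel=1e-9
            )
            assert fit_nc.estimate(*pair) == pytest.approx(
                fit_enfo.estimate(*pair), rel=1e-9
            )

    def test_information_monotonicity(self, brd_like_network):
        """Adding any study never increases a contrast variance."""
        fit_full = nd.fit_fixed_effects_nma(brd_like_network)
        reduced = nd.Network(
            studies=brd_like_network.studies[:-1], baseline="NC"
        )
        fit_reduced = nd.fit_fixed_effects_nma(reduced)
        pairs = [("NC", "ENFO"), ("NC", "CEFTS"), ("ENFO", "TULA")]
        for pair in pairs:
            assert nd.contrast_variance(fit_full, *pair) <= nd.contrast_variance(
                fit_reduced, *pair
            ) + 1e-12


class TestAugment:
    def make_trial(self, allocation=(800, 800, 800), events=(540, 180, 190)):
        labels = ("NC", "ENFO", "ZNEW")
        return nd.Study(
            study_id="NEW",
            arms=tuple(
                nd.ArmRecord("NEW", t, r, n)
                for t, r, n in zip(labels, events, allocation)
            ),
        )

    def test_bookkeeping(self, brd_like_network):
        augmented = nd.augment_network(brd_like_network, self.make_trial())
        assert augmented.n_treatments == 14
        assert augmented.n_studies == 99

    def test_rejects_multiple_novel_treatments(self, brd_like_network):
        bad = nd.Study(
            study_id="NEW",
            arms=(
                nd.ArmRecord("NEW", "NC", 5, 10),
                nd.ArmRecord("NEW", "Z1", 5, 10),
                nd.ArmRecord("NEW", "Z2", 5, 10),
            ),
        )
        with pytest.raises(DataValidationError, match="novel"):
            nd.augment_network(brd_like_network, bad)

    def test_refit_variance_matches_closed_form(self, brd_like_network, brd_sigma2_exg):
        """Central cross-validation: the augmented GLS variance of the
        Z-vs-reference contrast equals the closed-form borrowing formula at
        the realized arm proportions, to 1e-10 relative tolerance."""
        trial = self.make_trial()
        augmented = nd.augment_network(brd_like_network, trial)
        fit = nd.fit_fixed_effects_nma(augmented)
        gls_var = nd.contrast_variance(fit, "ENFO", "ZNEW")

        v = {a.treatment: 1 / a.events + 1 / (a.total - a.events) for a in trial.arms}
        closed = (
            v["ENFO"]
            + v["ZNEW"]
            - v["ENFO"] ** 2 / (brd_sigma2_exg + v["NC"] + v["ENFO"])
        )
        assert gls_var == pytest.approx(closed, rel=1e-10)

    def test_huge_external_variance_recovers_standalone(self, brd_sigma2_exg):
        """A nearly uninformative network leaves the trial's own variance."""
        trial = self.make_trial()
        # single-study 'network' with enormous se on the A-B comparison
        weak = nd.assemble_network(
            [nd.ContrastRecord("S1", "NC", "ENFO", -2.0, 1e6)], "NC"
        )
        fit = nd.fit_fixed_effects_nma(nd.augment_network(weak, trial))
        v = {a.treatment: 1 / a.events + 1 / (a.total - a.events) for a in trial.arms}
        standalone = v["ENFO"] + v["ZNEW"]
        assert nd.contrast_variance(fit, "ENFO", "ZNEW") == pytest.approx(
            standalone, rel=1e-6
        )
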