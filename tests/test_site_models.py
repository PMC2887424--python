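import numpy as np
import pytest

from codonscan import (
    CodonModelParams,
    FitOptions,
    SimulationSpec,
    SiteClassSpec,
    fit_model,
    fit_site_models,
    gy94_generator,
    likelihood_ratio_test,
    neb_site_posteriors,
    parse_newick,
    simulate_alignment,
    site_log_likelihood,
)
from codonscan.codon_align import CodonAlignment
from codonscan.seqio import STANDARD_CODE
from codonscan.site_models import (
    ModelError,
    PruningEngine,
    SiteModelFit,
    _CodeTables,
    build_site_class_matrices,
    pi_array,
)

from .conftest import simulate_m0
from .oracles import brute_force_log_likelihood

UNIFORM = pi_array("uniform")


class TestGenerator:
    def test_rows_sum_to_zero_and_rate_is_one(self):
        Q = gy94_generator(CodonModelParams(2.0, 0.5, UNIFORM))
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        assert -(UNIFORM * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(61) * 5)
        Q = gy94_generator(CodonModelParams(3.0, 0.4, pi))
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_omega_zero_removes_nonsynonymous_rates(self):
        Q = gy94_generator(CodonModelParams(2.0, 0.0, UNIFORM))
        tables = _CodeTables.get(STANDARD_CODE)
        nonsyn = tables.single & ~tables.synonymous
        assert np.all(Q[nonsyn] == 0.0)

    def test_degenerate_pi_rejected(self):
        bad = UNIFORM.copy()
        bad[0] = 0.0
        bad[1] += UNIFORM[0]
        with pytest.raises(ModelError, match="positive"):
            gy94_generator(CodonModelParams(2.0, 0.5, bad))

    def test_multifurcating_tree_rejected(self):
        tree = parse_newick("((a:1,b:1,c:1):1,d:1,e:1);")
        aln = CodonAlignment([(n, "ATG") for n in "abcde"])
        with pytest.raises(ModelError, match="binary"):
            PruningEngine(tree, aln, pi="uniform")

    def test_label_mismatch_rejected(self, two_taxon_tree):
        aln = CodonAlignment([("a", "ATG"), ("zzz", "ATG")])
        with pytest.raises(ModelError, match="names"):
            PruningEngine(two_taxon_tree, aln, pi="uniform")


class TestLikelihood:
    def test_zero_branch_lengths_give_log_pi_for_identical_rows(self):
        tree = parse_newick("(a:1e-9,b:1e-9);")
        aln = CodonAlignment([("a", "ATGAAATGT"), ("b", "ATGAAATGT")])
        lnl = site_log_likelihood(tree, aln, SiteClassSpec.m0(0.5), 2.0, pi="uniform")
        assert lnl == pytest.approx(3 * np.log(1 / 61), abs=1e-4)

    def test_two_leaf_likelihood_matches_closed_form(self):
        from codonscan.site_models import _Spectral

        tree = parse_newick("(a:0.17,b:0.23);")
        aln = CodonAlignment([("a", "ATGAAATGTCTG"), ("b", "ACGAAATGCCTA")])
        kappa, omega = 2.5, 0.4
        (Q,) = build_site_class_matrices(np.array([1.0]), np.array([omega]), kappa, UNIFORM)
        P = _Spectral(Q, UNIFORM).transition_matrix(0.4)  # t1 + t2, reversibility
        tables = _CodeTables.get(STANDARD_CODE)
        expected = 0.0
        for i in range(0, 12, 3):
            s1 = tables.index[aln.rows[0][1][i : i + 3]]
            s2 = tables.index[aln.rows[1][1][i : i + 3]]
            expected += np.log(UNIFORM[s1] * P[s1, s2])
        got = site_log_likelihood(tree, aln, SiteClassSpec.m0(omega), kappa, pi="uniform")
        assert got == pytest.approx(expected, abs=1e-10)

    def test_mixture_of_identical_classes_equals_single_class(self, four_taxon_tree):
        aln, _ = simulate_m0(four_taxon_tree, 40, omega=0.3, seed=2)
        m0 = site_log_likelihood(four_taxon_tree, aln, SiteClassSpec.m0(0.3), 2.0, pi="uniform")
        degenerate = SiteClassSpec(
            "M1a", np.array([0.5, 0.5]), np.array([0.3, 0.3])
        )
        mix = site_log_likelihood(four_taxon_tree, aln, degenerate, 2.0, pi="uniform")
        assert mix == pytest.approx(m0, abs=1e-9)

    def test_gap_codons_are_missing_data(self, two_taxon_tree):
        full = CodonAlignment([("a", "ATGAAA"), ("b", "ATGAAG")])
        gapped = CodonAlignment([("a", "ATGAAA---"), ("b", "ATGAAG---")])
        spec = SiteClassSpec.m0(0.5)
        # a fully gapped column contributes a likelihood-1 factor (sum over states)
        lnl_full = site_log_likelihood(two_taxon_tree, full, spec, 2.0, pi="uniform")
        lnl_gap = site_log_likelihood(two_taxon_tree, gapped, spec, 2.0, pi="uniform")
        assert lnl_gap == pytest.approx(lnl_full, abs=1e-9)

    def test_pruning_matches_state_enumeration(self):
        rng = np.random.default_rng(7)
        tree = parse_newick("(a:0.2,b:0.3,(c:0.15,d:0.25):0.1);")
        aln, _ = simulate_m0(tree, 4, omega=0.5, seed=13)
        for _ in range(3):
            kappa = rng.uniform(1.0, 4.0)
            omega = rng.uniform(0.05, 2.0)
            spec = SiteClassSpec.m0(omega)
            got = site_log_likelihood(tree, aln, spec, kappa, pi="uniform")
            Qs = build_site_class_matrices(spec.probs, spec.omegas, kappa, UNIFORM)
            expected = brute_force_log_likelihood(
                tree, aln, spec.probs, spec.omegas, kappa, UNIFORM, Qs
            )
            assert got == pytest.approx(expected, abs=1e-8)

    def test_rerooting_invariance(self):
        """The pulley principle: the same unrooted tree rooted two ways gives
        the same likelihood under the reversible model."""
        t1 = parse_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.1):0.05);")
        t2 = parse_newick("(a:0.1,b:0.2,(c:0.3,d:0.1):0.1);")
        aln, _ = simulate_m0(t2, 60, omega=0.4, seed=17)
        spec = SiteClassSpec.m1a(0.6, 0.2)
        l1 = site_log_likelihood(t1, aln, spec, 2.0, pi="uniform")
        l2 = site_log_likelihood(t2, aln, spec, 2.0, pi="uniform")
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestFitting:
    def test_m8_never_fits_worse_than_m7(self, four_taxon_tree):
        spec = SimulationSpec(
            tree=four_taxon_tree,
            n_codons=120,
            kappa=2.0,
            site_classes=SiteClassSpec.m2a(0.7, 0.1, 0.1, 3.0),
            pi="uniform",
            seed=31,
        )
        aln, _ = simulate_alignment(spec)
        options = FitOptions(freqs="uniform", n_starts=1, seed=0)
        fits, lrts = fit_site_models(aln, four_taxon_tree, ("M7", "M8"), options)
        assert fits["M8"].lnL >= fits["M7"].lnL - 1e-6
        (m7m8,) = [r for r in lrts if r.null_model == "M7"]
        assert m7m8.statistic >= 0.0

    def test_neutral_data_pushes_m1a_to_the_neutral_boundary(self, four_taxon_tree):
        aln, _ = simulate_m0(four_taxon_tree, 200, omega=1.0, seed=37)
        options = FitOptions(freqs="uniform", n_starts=1, seed=0)
        fits, lrts = fit_site_models(aln, four_taxon_tree, ("M1a", "M2a"), options)
        p1 = 1.0 - fits["M1a"].spec.params["p0"]
        assert p1 > 0.5  # most weight on the omega = 1 class
        (lrt,) = [r for r in lrts if (r.null_model, r.alt_model) == ("M1a", "M2a")]
        assert lrt.p_value > 0.05


class TestLRT:
    def _fit(self, model, lnl, nparams):
        return SiteModelFit(
            model_id=model,
            lnL=lnl,
            kappa=2.0,
            spec=SiteClassSpec.m0(0.5),
            branch_lengths=np.array([0.1]),
            tree=parse_newick("(a:0.1,b:0.1);"),
            pi=UNIFORM,
            converged=True,
            n_free_params=nparams,
        )

    def test_equal_likelihoods_give_zero_statistic_p_one(self):
        res = likelihood_ratio_test(self._fit("M1a", -100.0, 3), self._fit("M2a", -100.0, 5))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi2_df2_critical_value(self):
        res = likelihood_ratio_test(
            self._fit("M7", -100.0, 3), self._fit("M8", -100.0 + 5.99 / 2, 5)
        )
        assert res.df == 2
        assert res.p_value == pytest.approx(0.05, abs=0.001)

    def test_slightly_negative_statistic_clamped(self):
        res = likelihood_ratio_test(
            self._fit("M1a", -100.0, 3), self._fit("M2a", -100.0000004, 5)
        )
        assert res.statistic == 0.0

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ModelError, match="nested"):
            likelihood_ratio_test(self._fit("M2a", -10.0, 5), self._fit("M7", -9.0, 3))


@pytest.fixture(scope="module")
def m2a_fit():
    tree = parse_newick("(a:0.25,b:0.25,(c:0.25,d:0.25):0.1);")
    spec = SimulationSpec(
        tree=tree,
        n_codons=150,
        kappa=2.0,
        site_classes=SiteClassSpec.m2a(0.6, 0.2, 0.1, 4.0),
        pi="uniform",
        seed=41,
    )
    aln, omegas = simulate_alignment(spec)
    fit = fit_model(aln, tree, "M2a", FitOptions(freqs="uniform", n_starts=1, seed=0))
    return fit, aln, omegas


class TestPosteriors:
    def test_class_posteriors_sum_to_one(self, m2a_fit):
        fit, aln, _ = m2a_fit
        posteriors = neb_site_posteriors(fit, aln)
        assert len(posteriors) == aln.ncodons
        for p in posteriors:
            assert p.class_posteriors.sum() == pytest.approx(1.0, abs=1e-9)
            assert p.posterior_mean_omega >= 0

    def test_true_positive_sites_get_higher_posterior_omega(self, m2a_fit):
        fit, aln, omegas = m2a_fit
        posteriors = neb_site_posteriors(fit, aln)
        means = np.array([p.posterior_mean_omega for p in posteriors])
        assert np.median(means[omegas > 1]) > np.median(means[omegas < 1])

    def test_m7_fit_flags_no_positive_sites(self, four_taxon_tree):
        aln, _ = simulate_m0(four_taxon_tree, 80, omega=0.5, seed=43)
        fit = fit_model(
            aln, four_taxon_tree, "M7", FitOptions(freqs="uniform", n_starts=1, seed=0)
        )
        posteriors = neb_site_posteriors(fit, aln)
        assert not any(p.flagged_positive for p in posteriors)
        assert all(p.p_positive == 0.0 for p in posteriors)
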