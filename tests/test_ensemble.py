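"""Random-parameter sampling, ensemble simulation and phenotype calling."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from emtcircuits.circuits import (
    CircuitError,
    ConfigurationError,
    Edge,
    RegulatoryNetwork,
    load_fixture,
)
from emtcircuits.ensemble import (
    DEFAULT_RANGES,
    EnsembleResult,
    SamplingRanges,
    bimodal_threshold,
    call_phenotypes,
    pca_summary,
    perturb,
    phenotype_fractions,
    run_ensemble,
    sample_parameters,
)


@pytest.fixture(scope="module")
def grhl2_net():
    return load_fixture("core_emt_elf3_grhl2")[0]


class TestSampling:
    def test_draws_within_ranges_and_deterministic(self, grhl2_net):
        s1 = sample_parameters(grhl2_net, n_sets=500, seed=3)
        s2 = sample_parameters(grhl2_net, n_sets=500, seed=3)
        assert np.array_equal(s1.g, s2.g) and np.array_equal(s1.a0, s2.a0)
        r = DEFAULT_RANGES
        assert s1.g.min() >= r.production[0] and s1.g.max() <= r.production[1]
        assert s1.k.min() >= r.degradation[0] and s1.k.max() <= r.degradation[1]
        assert s1.nh.min() >= 1 and s1.nh.max() <= 6
        is_act = np.array([e.sign == "activation" for e in grhl2_net.edges])
        assert s1.lam[:, is_act].min() >= 1.0
        assert s1.lam[:, ~is_act].max() <= 1.0
        assert s1.lam[:, ~is_act].min() >= 1.0 / r.fold_change[1]

    def test_marginals_match_declared_distributions(self, grhl2_net):
        """KS check of the sampled production-rate marginal against its
        declared uniform distribution at n = 10,000."""
        s = sample_parameters(grhl2_net, n_sets=10_000, seed=1)
        ks = sstats.kstest(s.g[:, 0], "uniform", args=(1.0, 99.0))
        assert ks.pvalue > 1e-3
        ks_k = sstats.kstest(s.k[:, 2], "uniform", args=(0.1, 0.9))
        assert ks_k.pvalue > 1e-3

    def test_sequence_protocol_and_provenance(self, grhl2_net):
        s = sample_parameters(grhl2_net, n_sets=10, seed=5)
        assert len(s) == 10
        pset = s[3]
        assert pset.provenance == "sampled(seed=5, index=3)"
        assert set(pset.production) == set(grhl2_net.dynamic_nodes)
        assert set(pset.hill) == {e.key for e in grhl2_net.edges}

    def test_half_functional_rule_scales_with_regulation(self, grhl2_net):
        """A heavily repressed regulator (miR200) gets much lower edge
        thresholds than an activated one (ELF3)."""
        med = DEFAULT_RANGES.node_medians(grhl2_net)
        assert med["miR200"] < med["SNAIL"] < med["ELF3"]
        spec_rule = SamplingRanges(threshold_rule="unregulated-median")
        med_u = spec_rule.node_medians(grhl2_net)
        assert len(set(med_u.values())) == 1  # unregulated: same for all

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            SamplingRanges(production=(10.0, 1.0))
        with pytest.raises(ValueError):
            SamplingRanges(threshold_rule="nope")


class TestRunEnsemble:
    def test_monostable_model_gives_one_row_per_set(self):
        net = RegulatoryNetwork("single", ["X"], [])
        res = run_ensemble(net, n_sets=40, n_inits=10, seed=0)
        assert res.n_solutions == 40
        assert np.all(res.multistability == 1)
        # steady state of an unregulated node is g/k
        s = sample_parameters(net, n_sets=40, seed=0)
        assert np.allclose(np.sort(res.raw["X"]), np.sort(s.g[:, 0] / s.k[:, 0]), rtol=1e-3)

    def test_control_z_columns_standardised(self, grhl2_ensemble):
        z = grhl2_ensemble.z
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-9)
        assert grhl2_ensemble.converged_fraction > 0.95

    def test_emt_score_and_elf3_bimodal(self, grhl2_ensemble):
        emt = (grhl2_ensemble.z["ZEB"] - grhl2_ensemble.z["miR200"]).to_numpy()
        thr, modes = bimodal_threshold(emt)
        assert modes[0] < thr < modes[1]
        thr_e, modes_e = bimodal_threshold(grhl2_ensemble.z["ELF3"].to_numpy())
        assert modes_e[0] < thr_e < modes_e[1]

    def test_emt_score_anticorrelates_with_elf3(self, grhl2_ensemble):
        emt = grhl2_ensemble.z["ZEB"] - grhl2_ensemble.z["miR200"]
        rho, p = sstats.spearmanr(emt, grhl2_ensemble.z["ELF3"])
        assert rho < -0.3 and p < 1e-10

    def test_elf3_correlates_more_strongly_than_klf4(self, grhl2_ensemble):
        """ELF3 outranks KLF4 in |Spearman rho| against both the epithelial
        (GRHL2 + miR200) and mesenchymal (ZEB + SNAIL + SLUG) scores."""
        z = grhl2_ensemble.z
        epi = z["GRHL2"] + z["miR200"]
        mes = z["ZEB"] + z["SNAIL"] + z["SLUG"]
        for score in (epi, mes):
            rho_elf3 = abs(sstats.spearmanr(score, z["ELF3"]).statistic)
            rho_klf4 = abs(sstats.spearmanr(score, z["KLF4"]).statistic)
            assert rho_elf3 > rho_klf4

    def test_fraction_stability_under_doubled_sampling(self, grhl2_net):
        """E/M fractions move by < 2 pp when n_sets doubles."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f = {}
            for n in (1500, 3000):
                res = run_ensemble(grhl2_net, n_sets=n, n_inits=20, seed=21)
                calls = call_phenotypes(res)
                f[n] = phenotype_fractions(calls, weights=res.set_weights)["E"]
        assert abs(f[3000] - f[1500]) < 0.02

    def test_numpy_and_numba_kernels_agree(self, grhl2_net):
        kw = dict(n_sets=30, n_inits=5, seed=9)
        a = run_ensemble(grhl2_net, use_numba=False, **kw)
        b = run_ensemble(grhl2_net, use_numba=True, **kw)
        assert a.n_solutions == b.n_solutions
        assert np.allclose(a.raw.to_numpy(), b.raw.to_numpy(), rtol=1e-6)


def _toy_result(z: pd.DataFrame) -> EnsembleResult:
    n = len(z)
    raw = pd.DataFrame(np.exp2(z.to_numpy()), columns=z.columns)
    return EnsembleResult(
        "toy", raw, z, np.arange(n), np.ones(n, dtype=int),
        pd.Series(0.0, index=z.columns), pd.Series(1.0, index=z.columns),
        seed=0, n_sets=n, n_inits=1, converged_fraction=1.0,
    )


class TestPhenotypeCalling:
    def test_separated_mixture_recovers_ground_truth(self):
        rng = np.random.default_rng(4)
        n = 400
        truth = np.repeat(["E", "M"], n // 2)
        zeb = np.where(truth == "M", 2.0, -2.0) + 0.3 * rng.standard_normal(n)
        mir = -zeb + 0.2 * rng.standard_normal(n)
        elf3 = np.where(truth == "E", 1.5, -1.5) + 0.3 * rng.standard_normal(n)
        res = _toy_result(pd.DataFrame({"ZEB": zeb, "miR200": mir, "ELF3": elf3}))
        calls = call_phenotypes(res)
        assert (calls["phenotype"] == truth).mean() == 1.0
        assert set(calls.attrs["thresholds"]) == {"emt_score", "ELF3"}

    def test_unimodal_distribution_is_an_error(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame({"ZEB": rng.standard_normal(300), "miR200": rng.standard_normal(300)})
        with pytest.raises(CircuitError, match="unimodal"):
            call_phenotypes(_toy_result(z))

    def test_tertile_scheme_splits_three_ways(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame({"ZEB": rng.standard_normal(300), "miR200": rng.standard_normal(300)})
        calls = call_phenotypes(_toy_result(z), scheme="emt_tertile")
        counts = calls["phenotype"].value_counts()
        assert set(counts.index) == {"E", "H", "M"}
        assert counts.max() - counts.min() <= 2

    def test_fractions_sum_to_one_with_weights(self, grhl2_ensemble):
        calls = call_phenotypes(grhl2_ensemble)
        frac = phenotype_fractions(calls, weights=grhl2_ensemble.set_weights)
        assert frac.sum() == pytest.approx(1.0)
        assert set(frac.index) <= {"E", "M"}


class TestPCA:
    def test_two_point_clusters_put_all_variance_on_pc1(self):
        z = pd.DataFrame(
            np.vstack([np.tile([1.0, 2.0], (20, 1)), np.tile([-1.0, -2.0], (20, 1))]),
            columns=["a", "b"],
        )
        p = pca_summary(_toy_result(z))
        assert p.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_row_permutation_leaves_spectrum_unchanged(self, grhl2_ensemble):
        p1 = pca_summary(grhl2_ensemble)
        rng = np.random.default_rng(0)
        shuffled = grhl2_ensemble.z.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p2 = pca_summary(_toy_result(shuffled))
        assert np.allclose(p1.explained_variance_ratio, p2.explained_variance_ratio, atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame({"a": rng.standard_normal(50), "b": rng.standard_normal(50), "c": 0.0})
        with pytest.warns(UserWarning, match="constant"):
            p = pca_summary(_toy_result(z))
        assert p.dropped == ("c",)
        assert "c" not in p.loadings.columns


class TestPerturbation:
    def test_unit_fold_matches_control(self, grhl2_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exp = perturb(grhl2_net, "ELF3", "OE", 1.0, n_sets=400, n_inits=10,
                          n_replicates=2, seed=3)
        assert np.allclose(exp.control_fractions, exp.perturbed_fractions, atol=1e-12)
        assert (exp.p_values == 1.0).all()

    def test_fractions_sum_to_one_per_replicate(self, grhl2_net):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            exp = perturb(grhl2_net, "ELF3", "OE", 20.0, n_sets=400, n_inits=10,
                          n_replicates=2, seed=3)
        assert np.allclose(exp.control_fractions.sum(axis=1), 1.0)
        assert np.allclose(exp.perturbed_fractions.sum(axis=1), 1.0)

    def test_invalid_target_and_fold(self, grhl2_net):
        with pytest.raises(ConfigurationError):
            perturb(grhl2_net, "NOTANODE", "OE", 2.0, n_sets=10, n_inits=2)
        with pytest.raises(ValueError):
            perturb(grhl2_net, "ELF3", "OE", 0.5, n_sets=10, n_inits=2)
        with pytest.raises(ValueError):
            perturb(grhl2_net, "ELF3", "UP", 2.0, n_sets=10, n_inits=2)
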