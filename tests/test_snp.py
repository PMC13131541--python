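"""SNP scans, inheritance-model selection, and linkage disequilibrium."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuro1c import snp
from neuro1c import synthetic as syn


class TestWMW:
    def test_exact_separated_triplets(self):
        # C(6,3)=20 arrangements; both fully separated orderings are extreme
        assert snp.wmw_group_test([0, 0, 0], [2, 2, 2]) == pytest.approx(0.1)

    def test_constant_data_p_one(self):
        assert snp.wmw_group_test([1, 1, 1], [1, 1, 1]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(snp.SNPAnalysisError):
            snp.wmw_group_test([], [1, 2])

    def test_asymptotic_close_to_exact_continuous(self, rng):
        worst = 0.0
        for _ in range(60):
            a, b = rng.normal(size=8), rng.normal(size=8)
            exact = snp._wmw_exact_p(a, b)
            asym = float(stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic").pvalue)
            worst = max(worst, abs(exact - asym))
        assert worst < 0.02

    def test_exact_matches_scipy_exact(self, rng):
        for _ in range(20):
            a, b = rng.normal(size=7), rng.normal(size=6)
            assert snp._wmw_exact_p(a, b) == pytest.approx(
                float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue), abs=1e-12)


class TestSubgroupScan:
    def test_frequency_summary_counts(self):
        g = pd.DataFrame({"s": [0, 0, 1, 1, 2]}, dtype=float,
                         index=list("abcde"))
        groups = pd.Series(["x"] * 5, index=g.index)
        f = snp.genotype_frequencies(g["s"])
        assert f == {"het_pct": 40.0, "hm_pct": 20.0}

    def test_planted_enrichment_detected(self):
        hits = 0
        n_sims = 25
        for s in range(n_sims):
            rng = np.random.default_rng(s)
            n = 30
            g_hi = rng.binomial(2, 0.40, n).astype(float)
            g_lo = rng.binomial(2, 0.05, n).astype(float)
            null = rng.binomial(2, 0.2, (2 * n, 30)).astype(float)
            G = pd.DataFrame(null, columns=[f"n{i}" for i in range(30)])
            G["hit"] = np.concatenate([g_hi, g_lo])
            groups = pd.Series(["A"] * n + ["B"] * n)
            scan = snp.snp_subgroup_scan(G, groups, {"AvB": (("A",), ("B",))})
            hits += scan.set_index("snp").loc["hit", "q"] <= 0.1
        assert hits >= 0.8 * n_sims

    def test_null_scan_rarely_significant(self, rng):
        G = pd.DataFrame(rng.binomial(2, 0.3, (80, 200)).astype(float),
                         columns=[f"s{i}" for i in range(200)])
        groups = pd.Series(["A"] * 40 + ["B"] * 40)
        scan = snp.snp_subgroup_scan(G, groups, {"AvB": (("A",), ("B",))})
        assert (scan["q"] <= 0.1).mean() < 0.05

    def test_empty_side_skipped(self, rng):
        G = pd.DataFrame({"s": rng.binomial(2, 0.3, 10).astype(float)})
        groups = pd.Series(["A"] * 10)
        with pytest.warns(UserWarning, match="empty side"):
            scan = snp.snp_subgroup_scan(G, groups, {"AvB": (("A",), ("B",))})
        assert len(scan) == 0


class TestInheritanceModel:
    def test_recessive_truth_selected(self):
        hits = 0
        n_sims = 30
        for s in range(n_sims):
            rng = np.random.default_rng(s)
            g = rng.binomial(2, 0.3, 150).astype(float)
            covs = pd.DataFrame({"age": rng.normal(80, 8, 150)})
            y = 1.5 * (g == 2) + rng.normal(size=150)
            hits += snp.choose_inheritance_model(g, y, covs).model == "recessive"
        assert hits >= 0.8 * n_sims

    def test_additive_truth_beats_alternatives(self):
        counts = {"additive": 0, "dominant": 0, "recessive": 0}
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            g = rng.binomial(2, 0.3, 200).astype(float)
            covs = pd.DataFrame({"age": rng.normal(80, 8, 200)})
            y = 0.8 * g + rng.normal(size=200)
            counts[snp.choose_inheritance_model(g, y, covs).model] += 1
        assert counts["additive"] > counts["dominant"]
        assert counts["additive"] > counts["recessive"]

    def test_constant_response_ties_break_to_additive(self, rng):
        g = rng.binomial(2, 0.4, 100).astype(float)
        while not (g == 2).any():
            g = rng.binomial(2, 0.4, 100).astype(float)
        covs = pd.DataFrame({"age": np.linspace(60, 90, 100)})
        fit = snp.choose_inheritance_model(g, np.full(100, 3.0), covs)
        assert fit.model == "additive"
        assert max(fit.bic.values()) == min(fit.bic.values())
        assert fit.p == 1.0

    def test_no_homozygote_drops_recessive(self, rng):
        g = (rng.random(100) < 0.3).astype(float)  # only 0/1
        covs = pd.DataFrame({"age": rng.normal(80, 5, 100)})
        fit = snp.choose_inheritance_model(g, rng.normal(size=100), covs)
        assert "recessive" not in fit.bic

    def test_equal_penalties_reduce_bic_to_likelihood(self, rng):
        """All three codings have one SNP parameter, so the BIC ranking must
        equal the likelihood ranking."""
        import statsmodels.api as sm
        g = rng.binomial(2, 0.4, 120).astype(float)
        covs = pd.DataFrame({"age": rng.normal(80, 5, 120)})
        y = 0.5 * g + rng.normal(size=120)
        fit = snp.choose_inheritance_model(g, y, covs)
        lls = {}
        for model in ("dominant", "recessive", "additive"):
            x = snp.inheritance_coding(g, model)
            X = sm.add_constant(covs.assign(_snp=x))
            lls[model] = sm.OLS(y, X).fit().llf
        assert max(lls, key=lls.get) == min(fit.bic, key=fit.bic.get)


class TestHaplotypeEM:
    def test_no_double_het_equals_counting(self):
        g1 = np.array([0, 0, 1, 2, 2, 0, 1], float)
        g2 = np.array([0, 1, 0, 0, 2, 2, 2], float)
        est = snp.estimate_haplotypes_em(g1, g2)
        # direct phase-unambiguous haplotype counting
        assert np.allclose(est.sum(), 1.0, atol=1e-12)
        counts = np.zeros(4)
        pairs = {(0, 0): (0, 0), (0, 1): (0, 1), (0, 2): (1, 1),
                 (1, 0): (0, 2), (1, 2): (1, 3), (2, 0): (2, 2),
                 (2, 1): (2, 3), (2, 2): (3, 3)}
        for a, b in zip(g1.astype(int), g2.astype(int)):
            h1, h2 = pairs[(a, b)]
            counts[h1] += 1
            counts[h2] += 1
        assert np.allclose(est, counts / counts.sum())

    def test_known_pool_recovered(self):
        rng = np.random.default_rng(5)
        freqs = np.array([0.5, 0.2, 0.2, 0.1])
        h1 = rng.choice(4, 10_000, p=freqs)
        h2 = rng.choice(4, 10_000, p=freqs)
        alle = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        g1 = alle[h1, 0] + alle[h2, 0]
        g2 = alle[h1, 1] + alle[h2, 1]
        est = snp.estimate_haplotypes_em(g1, g2)
        assert np.max(np.abs(est - freqs)) < 0.01

    def test_em_loglik_nondecreasing(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            g1 = rng.binomial(2, 0.4, 60).astype(float)
            g2 = np.clip(g1 + rng.integers(-1, 2, 60), 0, 2).astype(float)
            _, history = snp.estimate_haplotypes_em(g1, g2, return_history=True)
            assert (np.diff(history) >= -1e-9).all()

    def test_minimum_informative_subjects(self):
        with pytest.raises(snp.SNPAnalysisError):
            snp.estimate_haplotypes_em([0, 1], [1, 0])


class TestLDStats:
    def test_identical_loci_complete_coupling(self, rng):
        g = rng.binomial(2, 0.3, 400).astype(float)
        r = snp.ld_stats(g, g)
        assert r.Dprime == pytest.approx(1.0, abs=1e-9)
        assert r.r == pytest.approx(1.0, abs=1e-9)
        assert r.phase == "coupling"

    def test_repulsion_simulation(self):
        subj = syn.generate_subjects(
            syn.CohortConfig(group_sizes={"HC-CN": 1000}, seed=3))
        G = syn.generate_genotypes(
            subj, [syn.SNPSpec("a", 0.3), syn.SNPSpec("b", 0.25)],
            [syn.LDSpec(("a", "b"), 1.0, "repulsion")], seed=4)
        r = snp.ld_stats(G["a"], G["b"])
        assert r.Dprime > 0.99
        assert r.phase == "repulsion"

    def test_monomorphic_rejected(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(snp.SNPAnalysisError):
            snp.ld_stats(g, np.zeros(100))

    def test_allele_swap_preserves_dprime_magnitude(self, rng):
        g1 = rng.binomial(2, 0.3, 500).astype(float)
        g2 = np.clip(g1 + rng.integers(-1, 2, 500), 0, 2).astype(float)
        a = snp.ld_stats(g1, g2)
        b = snp.ld_stats(2 - g1, g2)
        assert a.Dprime == pytest.approx(b.Dprime, abs=1e-9)
        assert a.r == pytest.approx(-b.r, abs=1e-9)

    def test_independent_loci_p_roughly_uniform(self):
        ps = []
        for s in range(40):
            rng = np.random.default_rng(s)
            g1 = rng.binomial(2, 0.3, 800).astype(float)
            g2 = rng.binomial(2, 0.3, 800).astype(float)
            ps.append(snp.ld_stats(g1, g2).p)
        assert 0.2 < np.mean(ps) < 0.8
        assert (np.asarray(ps) < 0.05).mean() < 0.2


class TestSNPMetaboliteAssoc:
    def _data(self, seed=0, n=160):
        rng = np.random.default_rng(seed)
        G = pd.DataFrame({
            "risky": rng.binomial(2, 0.4, n).astype(float),
            "null1": rng.binomial(2, 0.3, n).astype(float),
            "null2": rng.binomial(2, 0.3, n).astype(float),
        })
        covs = pd.DataFrame({"age": rng.normal(80, 8, n)})
        y = pd.Series(1.2 * (G["risky"] == 2) + rng.normal(size=n))
        return G, y, covs

    def test_planted_recessive_hcy_raiser_labelled_risk(self):
        hits = 0
        for s in range(20):
            G, y, covs = self._data(seed=s)
            t = snp.snp_metabolite_assoc(G, y, covs, metabolite_kind="Hcy")
            row = t.set_index("snp").loc["risky"]
            hits += (row["direction"] == "risk") and (row["model"] == "recessive")
        assert hits >= 16

    def test_sign_flip_swaps_direction_labels(self):
        G, y, covs = self._data(seed=3)
        up = snp.snp_metabolite_assoc(G, y, covs, metabolite_kind="Hcy")
        dn = snp.snp_metabolite_assoc(G, -y, covs, metabolite_kind="Hcy")
        flip = {"risk": "protective", "protective": "risk"}
        assert list(dn["direction"]) == [flip[d] for d in up["direction"]]

    def test_betaine_direction_convention(self):
        G, y, covs = self._data(seed=4)
        hcy = snp.snp_metabolite_assoc(G, y, covs, metabolite_kind="Hcy")
        bet = snp.snp_metabolite_assoc(G, y, covs, metabolite_kind="betaine")
        flip = {"risk": "protective", "protective": "risk"}
        assert list(bet["direction"]) == [flip[d] for d in hcy["direction"]]

    def test_exclusion_mask_drops_subjects(self):
        G, y, covs = self._data(seed=5)
        mask = np.zeros(len(y), bool)
        mask[:40] = True
        t = snp.snp_metabolite_assoc(G, y, covs, exclude_mask=mask)
        assert len(t) == 3  # still one row per SNP, fitted on the remainder
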