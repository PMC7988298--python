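"""PCA, differential codon testing, enrichment and consistency counting."""

import numpy as np
import pandas as pd
import pytest

import sdatools as st
from sdatools.cohort import _running_es

from oracles import oracle_enrichment_score


def make_matrix(values, samples=None, codons=None, condition=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    codons = codons or sorted(st.SENSE_CODONS[: len(values[0])])
    return st.SDAMatrix(pd.DataFrame(values, index=samples, columns=codons), condition)


class TestPCA:
    def test_planted_single_axis_dominates_pc1(self):
        cfg = st.SimConfig(
            seed=3,
            factor_codons=("AGA", "CCA", "GGT", "ACT"),
            factor_strength=1.5,
            n_samples_per_condition=10,
        )
        cohort = st.generate_cohort(cfg)
        matrix = st.cohort_sda_matrix(cohort)
        res = st.pca_sda(matrix, n_components=3)
        share = st.planted_variance_share(cohort, matrix)
        assert res.explained_variance_ratio[0] >= share > 0.3
        # planted codons dominate PC1 loadings (wobble spillover onto
        # synonymous neighbors sharing a decoder is expected)
        top6 = set(
            res.loadings.loc["PC1"].abs().sort_values(ascending=False).index[:6]
        )
        assert set(cfg.factor_codons) <= top6

    def test_sample_duplication_leaves_loadings_unchanged(self, null_matrix):
        res1 = st.pca_sda(null_matrix, n_components=2)
        doubled = st.SDAMatrix(
            pd.concat(
                [
                    null_matrix.values,
                    null_matrix.values.set_axis(
                        [f"{s}_dup" for s in null_matrix.samples]
                    ),
                ]
            )
        )
        res2 = st.pca_sda(doubled, n_components=2)
        np.testing.assert_allclose(
            res1.loadings.to_numpy(), res2.loadings.to_numpy(), atol=1e-8
        )

    def test_all_constant_matrix_is_flagged_degenerate(self):
        m = make_matrix([[1.5] * 10] * 4)
        res = st.pca_sda(m, n_components=2)
        assert res.degenerate
        assert np.all(res.explained_variance_ratio == 0)

    def test_explained_variance_nonincreasing_and_bounded(self, null_matrix):
        res = st.pca_sda(null_matrix)
        ev = res.explained_variance_ratio
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() <= 1 + 1e-9

    def test_full_reconstruction_exact(self, null_matrix):
        res = st.pca_sda(null_matrix)
        X = np.log2(null_matrix.values.to_numpy())
        approx = (
            res.scores.to_numpy() @ res.loadings.to_numpy()
            + res.codon_means.to_numpy()
        )
        np.testing.assert_allclose(approx, X, atol=1e-8)

    def test_too_many_components_is_error(self, null_matrix):
        with pytest.raises(ValueError):
            st.pca_sda(null_matrix, n_components=len(null_matrix.samples) + 1)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError):
            st.pca_sda(make_matrix([[1.0, 2.0], [2.0, 1.0]]))


class TestCorrelateComponent:
    def test_self_correlation_is_one(self):
        scores = {f"s{i}": float(i) for i in range(8)}
        r, p = st.correlate_component(scores, scores)
        assert r == pytest.approx(1.0)
        r, _ = st.correlate_component(scores, {k: -v for k, v in scores.items()})
        assert r == pytest.approx(-1.0)

    def test_constant_marker_flagged_undefined(self):
        scores = {f"s{i}": float(i) for i in range(5)}
        with pytest.warns(UserWarning):
            r, p = st.correlate_component(scores, {k: 1.0 for k in scores})
        assert np.isnan(r) and np.isnan(p)

    def test_pearson_optional(self):
        scores = {f"s{i}": float(i) for i in range(6)}
        marker = {k: 2 * v + 1 for k, v in scores.items()}
        r, _ = st.correlate_component(scores, marker, method="pearson")
        assert r == pytest.approx(1.0)

    def test_planted_factor_sign_recovered_across_seeds(self):
        ok = 0
        for seed in range(20):
            cfg = st.SimConfig(
                seed=seed,
                n_genes=60,
                mean_cds_codons=120,
                n_samples_per_condition=8,
                factor_codons=("AGA", "CCA", "GGT", "ACT"),
                factor_strength=1.0,
                marker_effect=1.0,
            )
            cohort = st.generate_cohort(cfg)
            res = st.pca_sda(st.cohort_sda_matrix(cohort), n_components=1)
            r, _ = st.correlate_component(
                res.scores["PC1"], st.marker_expression(cohort)
            )
            ok += r > 0
        assert ok >= 19


class TestDifferentialCodonTest:
    def test_planted_shift_direction_and_bh_invariants(self):
        cfg = st.SimConfig(
            seed=21,
            n_genes=80,
            mean_cds_codons=150,
            planted_effects=(st.PlantedEffect("AGA", 2.0, st.Side.SUPPLY),),
            n_samples_per_condition=10,
        )
        matrix = st.cohort_sda_matrix(st.generate_cohort(cfg))
        results = st.differential_codon_test(matrix, "A", "B")
        by_codon = {r.codon: r for r in results}
        assert by_codon["AGA"].direction is st.Direction.FAVORED_IN_B
        assert by_codon["AGA"].q < 0.05
        # BH invariants: q >= p, q monotone in the rank of p
        ordered = sorted(results, key=lambda r: r.p)
        assert all(r.q >= r.p - 1e-15 for r in results)
        assert all(a.q <= b.q + 1e-15 for a, b in zip(ordered, ordered[1:]))
        # direction always consistent with the effect sign
        for r in results:
            if r.effect > 0:
                assert r.direction is st.Direction.FAVORED_IN_B
            elif r.effect < 0:
                assert r.direction is st.Direction.FAVORED_IN_A

    def test_missing_condition_label_is_error(self, null_matrix):
        m = st.SDAMatrix(null_matrix.values, {s: "A" for s in null_matrix.samples})
        with pytest.raises(ValueError):
            st.differential_codon_test(m, "A", "B")

    def test_t_test_variant_agrees_on_strong_effect(self):
        cfg = st.SimConfig(
            seed=22,
            n_genes=60,
            mean_cds_codons=120,
            planted_effects=(st.PlantedEffect("AGA", 3.0, st.Side.SUPPLY),),
            n_samples_per_condition=8,
        )
        matrix = st.cohort_sda_matrix(st.generate_cohort(cfg))
        for variant in ("wilcoxon", "t"):
            res = st.differential_codon_test(matrix, "A", "B", test=variant)
            assert {r.codon for r in res if r.q < 0.01} >= {"AGA"}


class TestPrerankedEnrichment:
    @staticmethod
    def ranking(n=200, seed=0):
        rng = np.random.default_rng(seed)
        return {f"g{i:03d}": float(v) for i, v in enumerate(rng.normal(0, 1, n))}

    def test_matches_walking_oracle(self):
        scores = self.ranking(seed=1)
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        gene_set = {g for g, _ in ranked[5:40:3]}
        for expo in (0.0, 1.0, 2.0):
            res = st.preranked_enrichment(
                scores, gene_set, n_perm=9, seed=0, weight_exponent=expo
            )
            assert res.es == pytest.approx(
                oracle_enrichment_score(ranked, gene_set, expo)
            )

    def test_top_block_enriched_at_floor_p(self):
        scores = self.ranking(seed=2)
        top = {g for g, _ in sorted(scores.items(), key=lambda kv: -kv[1])[:20]}
        res = st.preranked_enrichment(scores, top, n_perm=999, seed=5)
        assert res.es > 0.8
        assert res.p == pytest.approx(1 / 1000)

    def test_reversed_ranking_flips_es_sign(self):
        scores = self.ranking(seed=3)
        gene_set = set(list(scores)[:25])
        fwd = st.preranked_enrichment(scores, gene_set, n_perm=9, seed=1)
        rev = st.preranked_enrichment(
            {g: -v for g, v in scores.items()}, gene_set, n_perm=9, seed=1
        )
        assert rev.es == pytest.approx(-fwd.es)

    def test_same_seed_reproduces_p_exactly(self):
        scores = self.ranking(seed=4)
        gene_set = set(list(scores)[10:60:2])
        r1 = st.preranked_enrichment(scores, gene_set, n_perm=499, seed=7)
        r2 = st.preranked_enrichment(scores, gene_set, n_perm=499, seed=7)
        assert (r1.es, r1.p) == (r2.es, r2.p)
        assert r1.p >= 1 / 500

    def test_accepts_gene_score_objects(self, small_cds):
        scores = st.rcu_scores(small_cds, "AGA")
        padding = {f"x{i}": 0.01 * i for i in range(10)}
        all_scores = {s.gene_id: s.score for s in scores} | padding
        res = st.preranked_enrichment(all_scores, {"arg_rich", "x1", "x2"}, n_perm=99, seed=0)
        assert -1 <= res.es <= 1

    def test_degenerate_sets_rejected(self):
        scores = self.ranking(n=20, seed=5)
        with pytest.raises(ValueError):
            st.preranked_enrichment(scores, {"g000"}, n_perm=9, seed=0)
        with pytest.raises(ValueError):
            st.preranked_enrichment(scores, set(scores), n_perm=9, seed=0)

    def test_es_bounded(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = {f"g{i}": float(v) for i, v in enumerate(rng.normal(0, 1, 50))}
            gene_set = set(rng.choice(list(scores), size=10, replace=False))
            res = st.preranked_enrichment(scores, gene_set, n_perm=9, seed=0)
            assert -1 - 1e-12 <= res.es <= 1 + 1e-12


class TestCountConsistentChanges:
    @staticmethod
    def planted_results(seed):
        cfg = st.SimConfig(
            seed=seed,
            n_genes=60,
            mean_cds_codons=120,
            planted_effects=(st.PlantedEffect("AGA", 2.5, st.Side.SUPPLY),),
            n_samples_per_condition=10,
        )
        matrix = st.cohort_sda_matrix(st.generate_cohort(cfg))
        return st.differential_codon_test(matrix, "A", "B")

    def test_same_effect_in_all_cohorts(self):
        results = {f"c{i}": self.planted_results(100 + i) for i in range(5)}
        n_a, n_b, tested = st.count_consistent_changes(results, "AGA")
        assert (n_a, n_b, tested) == (0, 5, 5)

    def test_single_cohort_degenerate_case(self):
        res = self.planted_results(200)
        n_a, n_b, tested = st.count_consistent_changes({"only": res}, "AGA")
        hit = next(r for r in res if r.codon == "AGA")
        assert tested == 1
        assert (n_b == 1) == (hit.q < 0.05 and hit.direction is st.Direction.FAVORED_IN_B)

    def test_untested_codon_excluded_from_denominator(self):
        res = self.planted_results(201)
        pruned = [r for r in res if r.codon != "AGA"]
        counts = st.count_consistent_changes({"full": res, "pruned": pruned}, "AGA")
        assert counts[2] == 1
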