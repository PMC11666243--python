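"""Hit rules, the combined effect/confidence score, and preranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoscreen import scoring


def _stats(lfc, fdr):
    return pd.DataFrame({"gene": [f"g{i}" for i in range(len(lfc))],
                         "lfc": lfc, "fdr": fdr})


class TestVolcanoHitCall:
    @pytest.mark.parametrize("lfc,fdr,expected", [
        (1.0, 0.05, "up"),      # product exactly at the threshold hyperbola
        (-0.5, 0.2, "none"),    # product ~0.35 below threshold
        (-2.0, 0.01, "down"),   # product 4 above threshold
    ])
    def test_worked_examples(self, lfc, fdr, expected):
        out = scoring.volcano_hit_call(_stats([lfc], [fdr]))
        assert out.iloc[0] == expected

    def test_plain_fdr_rule(self):
        out = scoring.fdr_hit_call(_stats([1.0, -1.0, 2.0],
                                          [0.01, 0.04, 0.5]))
        assert out.tolist() == ["up", "down", "none"]

    @given(lfc=st.floats(0.01, 10), fdr=st.floats(1e-6, 1.0),
           shrink=st.floats(0.1, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_fdr_and_effect(self, lfc, fdr, shrink):
        """Lowering FDR or raising |LFC| never turns a hit into a non-hit."""
        base = scoring.volcano_hit_call(_stats([lfc], [fdr])).iloc[0]
        better = scoring.volcano_hit_call(
            _stats([lfc / shrink], [fdr * shrink])).iloc[0]
        if base == "up":
            assert better == "up"

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2])
    def test_alpha_out_of_range(self, alpha):
        with pytest.raises(ValueError):
            scoring.volcano_hit_call(_stats([1.0], [0.5]), alpha=alpha)


class TestPrerankScore:
    def test_null_gene_scores_zero(self):
        out = scoring.prerank_score(_stats([0.0, 1.0], [1.0, 0.5]))
        assert out.loc[0, "score"] == 0.0

    def test_equally_weighted_standardized_terms(self):
        # table built so both sample SDs are exactly 1; the (-2, 0.01) gene
        # then scores (2/1 + 2/1) * (-1) = -4
        other_lfc = -2.0 + np.sqrt(2.0)
        other_fdr = 10.0 ** (np.sqrt(2.0) - 2.0)
        out = scoring.prerank_score(_stats([-2.0, other_lfc],
                                           [0.01, other_fdr]))
        assert np.std(out["lfc"], ddof=1) == pytest.approx(1.0)
        assert np.std(out["nlfdr"], ddof=1) == pytest.approx(1.0)
        assert out.loc[0, "score"] == pytest.approx(-4.0)

    def test_three_gene_hand_computation(self):
        lfc = np.array([1.0, -1.0, 0.0])
        fdr = np.array([0.1, 0.1, 1.0])
        out = scoring.prerank_score(_stats(lfc, fdr))
        nlfdr = np.log10(1 / fdr)
        s_lfc, s_nl = np.std(lfc, ddof=1), np.std(nlfdr, ddof=1)
        expected = (np.abs(lfc) / s_lfc + nlfdr / s_nl) * np.array([1, -1, 1])
        np.testing.assert_allclose(out["score"], expected)

    def test_sign_matches_lfc(self, gene_stats_table):
        out = scoring.prerank_score(gene_stats_table)
        nz = out["lfc"] != 0
        assert (np.sign(out.loc[nz, "score"]) == np.sign(out.loc[nz, "lfc"])).all()

    def test_invariant_to_positive_lfc_rescaling(self, gene_stats_table):
        a = scoring.prerank_score(gene_stats_table)
        scaled = gene_stats_table.assign(lfc=gene_stats_table["lfc"] * 7.3)
        b = scoring.prerank_score(scaled)
        np.testing.assert_allclose(a["score"], b["score"])

    def test_fdr_floor_keeps_score_finite(self):
        out = scoring.prerank_score(_stats([1.0, -1.0], [0.0, 0.5]),
                                    fdr_floor=1e-12)
        assert np.isfinite(out["score"]).all()

    def test_degenerate_constant_column_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            scoring.prerank_score(_stats([1.0, 1.0], [0.1, 0.2]))


def brute_force_es(ranked_scores, hit_mask, p=1.0):
    """Independent oracle: explicit step-by-step running sum."""
    total = sum(abs(s) ** p for s, h in zip(ranked_scores, hit_mask) if h)
    n_miss = len(ranked_scores) - int(np.sum(hit_mask))
    running, best = 0.0, 0.0
    for s, h in zip(ranked_scores, hit_mask):
        if h:
            running += (abs(s) ** p / total) if total > 0 else 1.0 / np.sum(hit_mask)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGseaPrerank:
    def _random_instance(self, rng, n_max=50, set_max=10):
        n = int(rng.integers(8, n_max + 1))
        genes = [f"g{i:03d}" for i in range(n)]
        scores = pd.DataFrame({"gene": genes,
                               "score": rng.standard_normal(n)})
        k = int(rng.integers(2, min(set_max, n - 1) + 1))
        members = list(rng.choice(genes, size=k, replace=False))
        return scores, members

    def test_es_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            scores, members = self._random_instance(rng)
            res = scoring.gsea_prerank(scores, {"s": members}, n_perm=5,
                                       min_size=2, seed=0)
            ranked = scores.sort_values(["score", "gene"],
                                        ascending=[False, True])
            mask = ranked["gene"].isin(members).to_numpy()
            expected = brute_force_es(ranked["score"].to_numpy(), mask)
            assert res.loc[0, "es"] == pytest.approx(expected, abs=1e-9)

    def test_es_matches_reference_implementation(self):
        """Cross-check against gseapy's prerank ES on random small instances."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, members = self._random_instance(rng, n_max=40, set_max=8)
            rnk = scores.sort_values("score", ascending=False).reset_index(drop=True)
            ref = gseapy.prerank(rnk=rnk, gene_sets={"s": members},
                                 permutation_num=4, min_size=2, max_size=50,
                                 weight=1, seed=1, outdir=None, no_plot=True,
                                 threads=1)
            expected = float(ref.res2d.loc[0, "ES"])
            res = scoring.gsea_prerank(scores, {"s": members}, n_perm=4,
                                       min_size=2, seed=0)
            assert res.loc[0, "es"] == pytest.approx(expected, abs=1e-9)

    def test_sign_flip_negates_es(self, rng):
        scores, members = self._random_instance(rng)
        res = scoring.gsea_prerank(scores, {"s": members}, n_perm=10,
                                   min_size=2, seed=0)
        flipped = scores.assign(score=-scores["score"])
        res_f = scoring.gsea_prerank(flipped, {"s": members}, n_perm=10,
                                     min_size=2, seed=0)
        assert res_f.loc[0, "es"] == pytest.approx(-res.loc[0, "es"], abs=1e-12)

    def test_null_scores_give_unit_mean_abs_nes(self):
        rng = np.random.default_rng(31)
        genes = [f"g{i:03d}" for i in range(200)]
        scores = pd.DataFrame({"gene": genes,
                               "score": rng.standard_normal(200)})
        sets = {f"s{j}": list(rng.choice(genes, 15, replace=False))
                for j in range(30)}
        res = scoring.gsea_prerank(scores, sets, n_perm=300, seed=5)
        assert res["nes"].abs().mean() == pytest.approx(1.0, abs=0.15)

    def test_enriched_set_found_significant(self, rng):
        n = 300
        genes = [f"g{i:03d}" for i in range(n)]
        score = rng.standard_normal(n)
        score[:20] += 3.0  # a strongly positive regulon
        scores = pd.DataFrame({"gene": genes, "score": score})
        sets = {"regulon": genes[:20],
                **{f"null{j}": list(rng.choice(genes[20:], 20, replace=False))
                   for j in range(5)}}
        res = scoring.gsea_prerank(scores, sets, n_perm=500, seed=6)
        best = res.iloc[0]
        assert best["name"] == "regulon"
        assert best["es"] > 0 and best["fdr"] < 0.05

    def test_set_outside_size_bounds_dropped(self, rng):
        scores, members = self._random_instance(rng, n_max=30)
        res = scoring.gsea_prerank(scores, {"tiny": members[:1]}, n_perm=5,
                                   min_size=2, seed=0)
        assert res.empty

    def test_set_covering_all_genes_rejected(self):
        scores = pd.DataFrame({"gene": ["a", "b", "c"],
                               "score": [2.0, 1.0, -1.0]})
        with pytest.raises(ValueError, match="covers all"):
            scoring.gsea_prerank(scores, {"all": ["a", "b", "c"]},
                                 n_perm=5, min_size=2, seed=0)

    def test_leading_edge_members_are_top_ranked_set_genes(self):
        scores = pd.DataFrame({"gene": [f"g{i}" for i in range(20)],
                               "score": np.linspace(3, -3, 20)})
        members = ["g0", "g1", "g2", "g15"]
        res = scoring.gsea_prerank(scores, {"s": members}, n_perm=10,
                                   min_size=2, seed=0)
        le = res.loc[0, "leading_edge"]
        assert set(le) <= set(members)
        assert {"g0", "g1", "g2"} <= set(le)
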