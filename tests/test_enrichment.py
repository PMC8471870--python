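import numpy as np
import pandas as pd
import pytest

from xspecies_nash.enrichment import (
    gsea_es,
    gsea_permutation,
    rank_by_lfc,
    top50_pathways,
)
from xspecies_nash.io_formats import FormatError, GeneSetCollection


def ranked_series(stats: dict) -> pd.Series:
    table = pd.DataFrame({"gene": list(stats), "log2fc": list(stats.values())})
    return rank_by_lfc(table)


def brute_force_es(ranked: pd.Series, members: set, exponent: float):
    """Independent oracle: explicit per-position running sum.

    Returns (es, pos_extreme, neg_extreme) so callers can detect the
    degenerate case where the positive and negative extrema tie in
    magnitude (the signed result is then decided by float rounding).
    """
    genes = list(ranked.index)
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    hit_w = [abs(ranked.iloc[i]) ** exponent if hits[i] else 0.0 for i in range(n)]
    total = sum(hit_w)
    if total == 0:
        hit_w = [1.0 if h else 0.0 for h in hits]
        total = float(k)
    running, best, pos, neg = 0.0, 0.0, 0.0, 0.0
    for i in range(n):
        running += hit_w[i] / total if hits[i] else -1.0 / (n - k)
        pos = max(pos, running)
        neg = min(neg, running)
        if abs(running) > abs(best):
            best = running
    return best, pos, neg


class TestRankByLfc:
    def test_descending_order(self):
        r = ranked_series({"a": 1.0, "b": 3.0, "c": -2.0})
        assert list(r.index) == ["b", "a", "c"]

    def test_ties_broken_by_gene_id(self):
        r = ranked_series({"zeta": 1.0, "alpha": 1.0})
        assert list(r.index) == ["alpha", "zeta"]

    def test_duplicate_genes_rejected(self):
        table = pd.DataFrame({"gene": ["a", "a"], "log2fc": [1.0, 2.0]})
        with pytest.raises(FormatError, match="duplicate"):
            rank_by_lfc(table)

    def test_empty_table_rejected(self):
        with pytest.raises(FormatError, match="empty"):
            rank_by_lfc(pd.DataFrame({"gene": [], "log2fc": []}))


class TestGseaEs:
    def test_worked_unweighted_example(self):
        # N=5, members at ranks 1 and 3: deviations 1/2, 1/6, 2/3, 1/3, 0
        r = ranked_series({"g1": 5.0, "g2": 4.0, "g3": 3.0, "g4": 2.0, "g5": 1.0})
        es, leading = gsea_es(r, {"g1", "g3"}, weight_exponent=0)
        assert es == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert leading == ["g1", "g3"]

    def test_single_member_at_top_is_maximal(self):
        r = ranked_series({"g1": 5.0, "g2": 4.0, "g3": 3.0})
        es, leading = gsea_es(r, {"g1"}, weight_exponent=0)
        assert es == pytest.approx(1.0)
        assert leading == ["g1"]

    def test_set_at_bottom_is_negative_with_trailing_leading_edge(self):
        r = ranked_series({f"g{i}": 10.0 - i for i in range(10)})
        es, leading = gsea_es(r, {"g8", "g9"}, weight_exponent=1)
        assert es < 0
        assert set(leading) == {"g8", "g9"}

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        for trial in range(500):
            n = int(rng.integers(3, 51))
            stats = rng.normal(size=n) * rng.uniform(0.1, 5)
            genes = [f"t{trial}_g{i}" for i in range(n)]
            r = ranked_series(dict(zip(genes, stats)))
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            exponent = float(rng.choice([0.0, 1.0, 2.0]))
            es, _ = gsea_es(r, members, exponent)
            expected, pos, neg = brute_force_es(r, members, exponent)
            assert abs(es) == pytest.approx(abs(expected), abs=1e-12)
            if abs(pos) - abs(neg) > 1e-9 or abs(neg) - abs(pos) > 1e-9:
                # sign is only well defined when the extrema do not tie
                assert es == pytest.approx(expected, abs=1e-12)

    def test_reversing_ranked_list_negates_es(self, rng):
        genes = [f"g{i}" for i in range(30)]
        stats = rng.normal(size=30)
        r = ranked_series(dict(zip(genes, stats)))
        members = set(rng.choice(genes, size=8, replace=False))
        es, _ = gsea_es(r, members, 1.0)
        reversed_r = r.iloc[::-1]
        es_rev, _ = gsea_es(reversed_r, members, 1.0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_no_member_present_rejected(self):
        r = ranked_series({"a": 1.0, "b": 0.5})
        with pytest.raises(FormatError, match="no gene-set member"):
            gsea_es(r, {"zzz"})

    def test_whole_universe_set_rejected(self):
        r = ranked_series({"a": 1.0, "b": 0.5})
        with pytest.raises(FormatError, match="whole"):
            gsea_es(r, {"a", "b"})


class TestGseaPermutation:
    def _ranked_null(self, rng, n=400):
        genes = [f"g{i}" for i in range(n)]
        return ranked_series(dict(zip(genes, rng.normal(size=n))))

    def test_same_seed_gives_identical_table(self, rng):
        r = self._ranked_null(rng)
        coll = GeneSetCollection({"S": frozenset(list(r.index[:20]))})
        a = gsea_permutation(r, coll, n_perm=200, seed=5)
        b = gsea_permutation(r, coll, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_concordant_and_discordant_sets(self, rng):
        # strong planted shift: members at the top in A; at the bottom in B
        genes = [f"g{i}" for i in range(500)]
        members = frozenset(genes[:30])
        base = rng.normal(0, 0.3, 500)
        up = base.copy()
        up[:30] += 3.0
        down = base.copy()
        down[:30] -= 3.0
        coll = GeneSetCollection({"PLANTED": members})
        res_a = gsea_permutation(ranked_series(dict(zip(genes, up))), coll, n_perm=500, seed=1)
        res_b = gsea_permutation(ranked_series(dict(zip(genes, down))), coll, n_perm=500, seed=1)
        assert res_a.loc[0, "nes"] > 0
        assert res_a.loc[0, "q"] < 0.1
        assert res_b.loc[0, "nes"] < 0
        assert np.sign(res_a.loc[0, "nes"]) != np.sign(res_b.loc[0, "nes"])

    def test_small_sets_flagged_absent_and_excluded_from_q(self, rng):
        r = self._ranked_null(rng)
        coll = GeneSetCollection(
            {"TINY": frozenset(list(r.index[:2])), "OK": frozenset(list(r.index[:20]))}
        )
        res = gsea_permutation(r, coll, n_perm=200, seed=2).set_index("pathway")
        assert np.isnan(res.loc["TINY", "es"])
        assert not np.isnan(res.loc["OK", "q"])

    def test_permutation_p_values_are_valid_under_null(self, rng):
        # random sets drawn from the null itself: p should be ~uniform
        r = self._ranked_null(rng, n=600)
        genes = list(r.index)
        sets = {
            f"NULL_{i}": frozenset(rng.choice(genes, size=15, replace=False))
            for i in range(200)
        }
        res = gsea_permutation(r, GeneSetCollection(sets), n_perm=400, seed=3)
        p = res["p"].to_numpy()
        for alpha in (0.01, 0.05, 0.1):
            assert (p <= alpha).mean() <= alpha + 0.02
        # Kolmogorov-Smirnov distance against the uniform CDF
        sorted_p = np.sort(p)
        grid = np.arange(1, len(p) + 1) / len(p)
        ks = np.max(np.abs(sorted_p - grid))
        assert ks < 0.1

    def test_low_n_perm_rejected(self, rng):
        r = self._ranked_null(rng)
        coll = GeneSetCollection({"S": frozenset(list(r.index[:10]))})
        with pytest.raises(FormatError, match="n_perm"):
            gsea_permutation(r, coll, n_perm=50, seed=1)


class TestTop50:
    def _table(self, n_up, n_down, q=0.01):
        rows = []
        for i in range(n_up):
            rows.append({"pathway": f"UP{i:02d}", "nes": 3.0 - i * 0.01, "q": q})
        for i in range(n_down):
            rows.append({"pathway": f"DN{i:02d}", "nes": -3.0 + i * 0.01, "q": q})
        return pd.DataFrame(rows)

    def test_caps_at_25_per_direction(self):
        sel = top50_pathways(self._table(30, 30))
        assert len(sel.table) == 50
        assert (sel.table["direction"] == "up").sum() == 25
        assert (sel.table["direction"] == "down").sum() == 25

    def test_returns_all_when_fewer_qualify(self):
        sel = top50_pathways(self._table(4, 6))
        assert len(sel.table) == 10

    def test_q_cutoff_is_strict(self):
        table = pd.DataFrame(
            {"pathway": ["a", "b"], "nes": [2.0, 1.5], "q": [0.1, 0.0999]}
        )
        sel = top50_pathways(table, q_max=0.1)
        assert sel.names == ["b"]

    def test_keeps_most_extreme_nes(self):
        sel = top50_pathways(self._table(30, 0))
        assert sel.table["nes"].iloc[0] == pytest.approx(3.0)
        assert len(sel.table) == 25
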