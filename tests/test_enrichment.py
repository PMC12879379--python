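"""Monte Carlo enrichment, pair logic, ranking, candidate selection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from cisgrammar import enrichment as en
from cisgrammar.regions import GeneRegionMap


def make_presence(n_genes, columns):
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(False, index=pd.Index(genes, name="gene_id"), columns=columns)


class TestPresenceTable:
    def make_map(self):
        return GeneRegionMap(
            proximal={"g1": frozenset({"rP"}), "g2": frozenset({"rQ"})},
            distal={"g1": frozenset({"rD"}), "g2": frozenset()},
        )

    def test_hit_in_linked_region_sets_presence(self):
        hits = pd.DataFrame({"motif_id": ["m1"] * 3, "region_id": ["rP"] * 3})
        table = en.presence_table(self.make_map(), hits, ["m1"], "proximal")
        assert table.loc["g1", "m1"] and not table.loc["g2", "m1"]

    def test_no_hits_false(self):
        hits = pd.DataFrame({"motif_id": [], "region_id": []})
        table = en.presence_table(self.make_map(), hits, ["m1"], "both")
        assert not table.any().any()

    def test_both_is_union(self):
        hits = pd.DataFrame({"motif_id": ["m1"], "region_id": ["rD"]})
        prox = en.presence_table(self.make_map(), hits, ["m1"], "proximal")
        both = en.presence_table(self.make_map(), hits, ["m1"], "both")
        assert not prox.loc["g1", "m1"] and both.loc["g1", "m1"]

    def test_matches_nested_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(15)]
        regions = [f"r{i}" for i in range(30)]
        gmap = GeneRegionMap(
            proximal={g: frozenset(rng.choice(regions, 2)) for g in genes},
            distal={g: frozenset(rng.choice(regions, 3)) for g in genes},
        )
        motifs = ["m1", "m2"]
        hits = pd.DataFrame(
            {
                "motif_id": rng.choice(motifs, 40),
                "region_id": rng.choice(regions, 40),
            }
        )
        table = en.presence_table(gmap, hits, motifs, "both")
        for g in genes:
            linked = gmap.proximal[g] | gmap.distal[g]
            for m in motifs:
                expected = any(
                    ((hits["motif_id"] == m) & (hits["region_id"] == r)).any()
                    for r in linked
                )
                assert table.loc[g, m] == expected


class TestMcTest:
    def test_ubiquitous_motif_not_enriched(self):
        presence = pd.Series(True, index=[f"g{i}" for i in range(100)])
        res = en.mc_test(presence, [f"g{i}" for i in range(10)],
                         [f"g{i}" for i in range(10, 100)], n_iter=1000, seed=0)
        assert res.p_value == 1.0
        assert res.fold_change == pytest.approx(1.0)
        assert not res.enriched

    def test_target_only_motif_enriched(self):
        genes = [f"g{i}" for i in range(100)]
        presence = pd.Series(False, index=genes)
        presence.iloc[:5] = True
        res = en.mc_test(presence, genes[:5], genes[5:], n_iter=1000, seed=0)
        assert res.p_value == 0.0
        assert np.isinf(res.fold_change)
        assert res.enriched

    def test_zero_observed_never_enriched(self):
        genes = [f"g{i}" for i in range(50)]
        presence = pd.Series(False, index=genes)
        presence.iloc[10:40] = True
        res = en.mc_test(presence, genes[:5], genes[5:], n_iter=500, seed=0)
        assert res.observed == 0 and not res.enriched

    def test_matches_hypergeometric_tail(self):
        """MC p within +-0.01 of the exact hypergeometric tail (oracle)."""
        n_comp, n_t, frac = 500, 22, 0.3
        comp = [f"c{i}" for i in range(n_comp)]
        targets = [f"t{i}" for i in range(n_t)]
        K = int(n_comp * frac)
        rng = np.random.default_rng(0)
        for observed in (6, 10, 14):
            presence = pd.Series(
                [i < observed for i in range(n_t)] + [i < K for i in range(n_comp)],
                index=targets + comp,
            )
            res = en.mc_test(presence, targets, comp, n_iter=10_000, rng=rng)
            exact = hypergeom.sf(observed - 1, n_comp, K, n_t)
            assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_subset_and_count_samplers_agree(self):
        """Explicit gene-set sampling gives the same null distribution."""
        n_comp, n_t = 200, 20
        comp = [f"c{i}" for i in range(n_comp)]
        targets = [f"t{i}" for i in range(n_t)]
        presence = pd.Series(
            [i < 10 for i in range(n_t)] + [i < 60 for i in range(n_comp)],
            index=targets + comp,
        )
        a = en.mc_test(presence, targets, comp, n_iter=20_000, seed=1, method="count")
        b = en.mc_test(presence, targets, comp, n_iter=20_000, seed=2, method="subset")
        assert a.observed == b.observed
        assert a.null_mean == pytest.approx(b.null_mean, abs=0.1)
        assert a.p_value == pytest.approx(b.p_value, abs=0.02)

    def test_seed_reproducibility(self):
        genes = [f"g{i}" for i in range(60)]
        presence = pd.Series([i % 3 == 0 for i in range(60)], index=genes)
        r1 = en.mc_test(presence, genes[:8], genes[8:], n_iter=2000, seed=42, keep_null=True)
        r2 = en.mc_test(presence, genes[:8], genes[8:], n_iter=2000, seed=42, keep_null=True)
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)

    def test_anti_monotone_in_comparator_presence(self):
        genes = [f"g{i}" for i in range(120)]
        base = pd.Series([i % 4 == 0 for i in range(120)], index=genes)
        more = base.copy()
        more.iloc[60:90] = True
        a = en.mc_test(base, genes[:10], genes[10:], n_iter=5000, seed=3)
        b = en.mc_test(more, genes[:10], genes[10:], n_iter=5000, seed=3)
        assert b.p_value >= a.p_value

    def test_comparator_too_small_rejected(self):
        presence = pd.Series([True] * 5, index=list("abcde"))
        with pytest.raises(ValueError):
            en.mc_test(presence, list("abcd"), list("e"), n_iter=10)


class TestPairLogic:
    def test_pair_presence_requires_both(self):
        table = make_presence(3, ["m1", "m2"])
        table.loc["g0", "m1"] = True
        table.loc["g0", "m2"] = True
        table.loc["g1", "m1"] = True
        vec = en.pair_presence(table, ("m1", "m2"))
        assert vec["g0"] and not vec["g1"] and not vec["g2"]

    def test_pair_presence_matches_and_oracle(self, rng):
        table = make_presence(50, ["m1", "m2"])
        table.loc[:, "m1"] = rng.random(50) < 0.4
        table.loc[:, "m2"] = rng.random(50) < 0.4
        vec = en.pair_presence(table, ("m1", "m2"))
        np.testing.assert_array_equal(vec.to_numpy(), (table["m1"] & table["m2"]).to_numpy())

    def test_pair_universe_counts(self):
        ids = [f"m{i}" for i in range(10)]
        assert len(list(en.pair_universe(ids, "unordered"))) == 45
        assert len(list(en.pair_universe(ids, "cross"))) == 100


class TestExpressionFilter:
    agg = pd.Series({"TF1": 500.0, "TF2": 100.0, "TF3": 300.0})

    def test_low_expressed_monomer_removed(self):
        kept = en.expression_filter_tfbs(
            ["mA", "mB"], {"mA": ["TF1"], "mB": ["TF2"]}, self.agg, 237.04
        )
        assert kept == ["mA"]

    def test_dimer_needs_all_components(self):
        kept = en.expression_filter_tfbs(
            ["dim"], {"dim": ["TF1", "TF2"]}, self.agg, 237.04
        )
        assert kept == []

    def test_unmapped_retained_with_warning(self):
        with pytest.warns(UserWarning):
            kept = en.expression_filter_tfbs(["mX"], {}, self.agg, 237.04)
        assert kept == ["mX"]


class TestRankPairs:
    def r(self, subject, observed, null_mean):
        return en.EnrichmentResult(subject, "both", observed, null_mean, 0.0,
                                   1.0, True, 10, 0)

    def test_dominant_pair_first(self):
        out = en.rank_pairs([self.r("B", 10, 5.0), self.r("A", 20, 1.0)])
        assert list(out["subject"]) == ["A", "B"]

    def test_tie_breaks_lexicographically(self):
        out = en.rank_pairs([self.r("Z", 5, 2.0), self.r("A", 5, 2.0)])
        assert list(out["subject"]) == ["A", "Z"]

    def test_matches_sort_oracle(self, rng):
        results = [
            self.r(f"p{i:02d}", int(rng.integers(0, 30)), float(rng.random() * 10))
            for i in range(20)
        ]
        out = en.rank_pairs(results)
        from scipy.stats import rankdata

        obs = np.array([r.observed for r in results])
        nm = np.array([r.null_mean for r in results])
        key = rankdata(-obs) + rankdata(nm)
        oracle = [results[i].subject for i in np.lexsort(
            (np.array([r.subject for r in results]), key))]
        assert list(out["subject"]) == oracle


class TestSelectCandidates:
    def test_shared_archetype_skipped(self):
        pairs = [("A", "B"), ("C", "D")]
        arch = {"A": "x", "B": "y", "C": "x", "D": "z"}
        tfbs, _ = en.select_candidates(pairs, [], arch, set(), n_tfbs=3, n_novel=0)
        assert tfbs == ["A", "B", "D"]  # C shares archetype x with A

    def test_single_quota(self):
        tfbs, _ = en.select_candidates([("A", "B")], [], {"A": "x", "B": "y"},
                                       set(), n_tfbs=1, n_novel=0)
        assert tfbs == ["A"]

    def test_novel_restricted_to_selected_tfbs(self):
        tfbs_pairs = [("A", "B")]
        novel_pairs = [("C", "n1"), ("A", "n2"), ("B", "n3")]
        with pytest.warns(UserWarning):
            tfbs, novel = en.select_candidates(
                tfbs_pairs, novel_pairs, {"A": "x", "B": "y", "C": "z"},
                {"n1", "n2", "n3"}, n_tfbs=2, n_novel=3,
            )
        assert tfbs == ["A", "B"]
        assert novel == ["n2", "n3"]  # n1's pair lacks a selected TFBS

    def test_matches_step_simulation(self, rng):
        ids = [f"T{i}" for i in range(12)]
        arch = {t: f"a{i % 5}" for i, t in enumerate(ids)}
        pairs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(30)]
        tfbs, _ = en.select_candidates(pairs, [], arch, set(), n_tfbs=4, n_novel=0)
        # step-by-step oracle
        expect, used = [], set()
        for p in pairs:
            for m in p:
                if len(expect) >= 4:
                    break
                if m in expect or arch[m] in used:
                    continue
                expect.append(m)
                used.add(arch[m])
            if len(expect) >= 4:
                break
        assert tfbs == expect


class TestRepresentativeSite:
    def make_hits(self, entries):
        return pd.DataFrame(
            entries,
            columns=["motif_id", "region_id", "offset", "strand", "score", "p_value", "width"],
        )

    def test_most_prevalent_wins(self):
        seqs = {"r1": "AACGTTTT", "r2": "AACGTTTT", "r3": "TTTTGGGG"}
        hits = self.make_hits(
            [("m", "r1", 0, "+", 5.0, 1e-5, 4),
             ("m", "r2", 0, "+", 5.0, 1e-5, 4),
             ("m", "r3", 4, "+", 9.0, 1e-6, 4)]
        )
        assert en.representative_site("m", hits, seqs) == "AACG"

    def test_tie_breaks_on_score(self):
        seqs = {"r1": "AAAACCCC"}
        hits = self.make_hits(
            [("m", "r1", 0, "+", 12.0, 1e-5, 4), ("m", "r1", 4, "+", 10.0, 1e-5, 4)]
        )
        assert en.representative_site("m", hits, seqs) == "AAAA"

    def test_minus_strand_reverse_complemented(self):
        seqs = {"r1": "AAAATTTT"}
        hits = self.make_hits([("m", "r1", 0, "-", 5.0, 1e-5, 4)])
        assert en.representative_site("m", hits, seqs) == "TTTT"

    def test_no_hits_rejected(self):
        with pytest.raises(ValueError):
            en.representative_site("m", self.make_hits([]), {})


def test_null_calibration_small():
    """Targets drawn from the comparator pool reject at roughly the nominal rate."""
    rng = np.random.default_rng(7)
    n_comp, n_t, n_motifs = 2000, 200, 300
    comp = [f"c{i}" for i in range(n_comp)]
    rejections = 0
    for i in range(n_motifs):
        f = rng.uniform(0.2, 0.5)
        presence = pd.Series(rng.random(n_comp) < f, index=comp)
        targets = list(rng.choice(comp, n_t, replace=False))
        res = en.mc_test(presence, targets, comp, n_iter=2000, rng=rng)
        rejections += res.p_value < 0.05
    assert rejections / n_motifs == pytest.approx(0.05, abs=0.03)
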