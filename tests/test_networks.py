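"""Cis targets, module eigengene/MM/GS, hubs, BH, DE calls, ceRNA assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import (
    brute_bh,
    brute_cerna,
    brute_cis,
    brute_de,
    brute_edge_filter,
    brute_hubs,
)
from lncatlas.annotation import AnnotationSet, GenomicInterval, TranscriptModel
from lncatlas.networks import (
    InteractionEdge,
    ModuleStats,
    assemble_cerna,
    benjamini_hochberg,
    correlate_and_select,
    filter_interactions,
    find_cis_candidates,
    module_eigengene,
    module_membership_gs,
    nearest_coding_gene,
    select_de,
    select_hubs,
    top_sponges,
)
from lncatlas.quantify import ExpressionMatrix


def _gene(gid, chrom, start, end, strand="+"):
    return TranscriptModel(
        f"{gid}.t", gid, "protein_coding",
        (GenomicInterval(chrom, start, end, strand),),
    )


def _lnc(lid, chrom, start, end):
    return TranscriptModel(lid, lid, "lncRNA", (GenomicInterval(chrom, start, end),))


class TestCisCandidates:
    def test_gene_50kb_away_included_with_distance(self):
        lnc = _lnc("l", "c", 100_000, 101_000)
        ann = AnnotationSet([lnc, _gene("g", "c", 151_000, 160_000)])
        assert find_cis_candidates(lnc, ann) == [("g", 50_000)]

    def test_gene_one_mb_away_excluded(self):
        lnc = _lnc("l", "c", 0, 1000)
        ann = AnnotationSet([lnc, _gene("g", "c", 1_001_000, 1_002_000)])
        assert find_cis_candidates(lnc, ann) == []

    def test_overlapping_gene_distance_zero(self):
        lnc = _lnc("l", "c", 5000, 8000)
        ann = AnnotationSet([lnc, _gene("g", "c", 7000, 20_000)])
        assert find_cis_candidates(lnc, ann) == [("g", 0)]

    def test_random_layouts_match_brute_force(self, rng):
        for _ in range(50):
            genes = {}
            models = []
            for g in range(int(rng.integers(1, 15))):
                chrom = f"c{rng.integers(1, 3)}"
                start = int(rng.integers(0, 500_000))
                end = start + int(rng.integers(1000, 30_000))
                genes[f"g{g}"] = (chrom, start, end)
                models.append(_gene(f"g{g}", chrom, start, end))
            ls = int(rng.integers(0, 500_000))
            lnc = _lnc("l", f"c{rng.integers(1, 3)}", ls, ls + int(rng.integers(300, 5000)))
            ann = AnnotationSet(models + [lnc])
            expected = brute_cis(
                (lnc.chrom, lnc.span.start, lnc.span.end), genes, 100_000
            )
            assert find_cis_candidates(lnc, ann) == expected


class TestNearestCodingGene:
    def test_lnc_inside_gene_span(self):
        lnc = _lnc("l", "c", 5000, 6000)
        ann = AnnotationSet([lnc, _gene("g", "c", 1000, 20_000)])
        assert nearest_coding_gene(lnc, ann) == "g"

    def test_equidistant_tie_breaks_lexicographically(self):
        lnc = _lnc("l", "c", 10_000, 11_000)
        ann = AnnotationSet([
            lnc,
            _gene("gb", "c", 12_000, 13_000),
            _gene("ga", "c", 8_000, 9_000),
        ])
        assert nearest_coding_gene(lnc, ann) == "ga"

    def test_no_coding_gene_on_chrom_returns_none(self):
        lnc = _lnc("l", "c", 0, 1000)
        ann = AnnotationSet([lnc, _gene("g", "other", 0, 1000)])
        assert nearest_coding_gene(lnc, ann) is None


class TestCorrelateAndSelect:
    def _em(self, profiles):
        samples = [f"s{i}" for i in range(len(next(iter(profiles.values()))))]
        df = pd.DataFrame(profiles, index=samples).T
        df.columns = samples
        return ExpressionMatrix(df.abs(), pd.Series({s: "A" for s in samples}), "CPM")

    def test_identical_profiles_kept_with_r_one(self):
        em = self._em({"l": [1, 2, 3, 4], "g": [1, 2, 3, 4]})
        out = correlate_and_select([("l", "g", 0)], em)
        assert len(out) == 1 and np.isclose(out[0].r, 1.0)

    def test_r_exactly_point_six_is_excluded(self):
        # integer construction with Pearson r exactly 0.6
        x, y = [1, 2, 3, 4, 5], [3, 2, 1, 4, 5]
        assert stats.pearsonr(x, y).statistic == 0.6
        em = self._em({"l": x, "g": y})
        assert correlate_and_select([("l", "g", 0)], em, r_min=0.6) == []

    def test_strong_negative_correlation_is_not_a_cis_target(self):
        em = self._em({"l": [1, 2, 3, 4], "g": [4, 3, 2, 1]})
        assert correlate_and_select([("l", "g", 0)], em) == []

    def test_zero_variance_profile_dropped_with_warning(self):
        em = self._em({"l": [1, 1, 1, 1], "g": [1, 2, 3, 4]})
        with pytest.warns(UserWarning):
            assert correlate_and_select([("l", "g", 0)], em) == []

    def test_random_profiles_match_direct_covariance_formula(self, rng):
        for _ in range(30):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            em = self._em({"l": np.abs(x) + 1, "g": np.abs(y) + 1})
            xa = (np.abs(x) + 1)
            ya = (np.abs(y) + 1)
            r = np.sum((xa - xa.mean()) * (ya - ya.mean())) / np.sqrt(
                np.sum((xa - xa.mean()) ** 2) * np.sum((ya - ya.mean()) ** 2)
            )
            out = correlate_and_select([("l", "g", 0)], em, r_min=-2)
            assert np.isclose(out[0].r, r)


class TestEigengeneAndMM:
    def test_identical_features_give_mm_one(self):
        f = np.array([1.0, 2, 3, 7, 5, 6])
        df = pd.DataFrame([f, f, f], index=list("abc"), columns=list("uvwxyz"))
        eig = module_eigengene(df)
        z = (f - f.mean()) / f.std(ddof=1)
        assert np.allclose(np.abs(np.corrcoef(eig, z)[0, 1]), 1.0)
        mm, _ = module_membership_gs(f, eig.to_numpy(), np.array([1, 0, 0, 0, 0, 1.0]))
        assert np.isclose(mm, 1.0)

    def test_antisymmetric_pair_gives_plus_minus_one(self):
        f = np.array([1.0, 2, 3, 7, 5, 6])
        df = pd.DataFrame([f, -f], index=list("ab"), columns=list("uvwxyz"))
        eig = module_eigengene(df).to_numpy()
        mms = sorted(
            module_membership_gs(v, eig, np.zeros(6) + [1, 0, 0, 0, 0, 1])[0]
            for v in (f, -f)
        )
        assert np.allclose(mms, [-1.0, 1.0])

    def test_random_module_matches_svd_oracle(self, rng):
        X = rng.normal(size=(10, 6)) * 3 + 5
        df = pd.DataFrame(X, columns=[f"s{i}" for i in range(6)])
        eig = module_eigengene(df).to_numpy()
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=1, keepdims=True)
        w, v = np.linalg.eigh(Z.T @ Z)  # independent route: eigendecomposition
        lead = v[:, np.argmax(w)]
        assert np.allclose(np.abs(eig), np.abs(lead), atol=1e-8)
        # sign convention: mean correlation with member features >= 0
        corrs = [np.corrcoef(row, eig)[0, 1] for row in Z]
        assert np.mean(corrs) >= 0

    def test_constant_trait_gives_missing_gs(self):
        f = np.array([1.0, 2, 3, 4])
        _, gs = module_membership_gs(f, f, np.ones(4))
        assert gs is None

    def test_too_small_module_is_an_error(self):
        df = pd.DataFrame([[1.0, 2, 3]], columns=list("abc"))
        with pytest.raises(ValueError):
            module_eigengene(df)


class TestSelectHubs:
    def test_mm_085_gs_025_is_hub(self):
        assert select_hubs([("f", 0.85, 0.25)]) == {"f"}

    def test_mm_exactly_08_is_not_hub(self):
        assert select_hubs([("f", 0.8, 0.5)]) == set()

    def test_gs_exactly_02_is_not_hub(self):
        assert select_hubs([("f", 0.95, 0.2)]) == set()

    def test_missing_values_disqualify(self):
        assert select_hubs([("f", None, 0.5), ("g", 0.9, None)]) == set()

    def test_negative_correlations_count_by_magnitude(self):
        assert select_hubs([("f", -0.9, -0.3)]) == {"f"}

    def test_random_stats_match_literal_scan(self, rng):
        for _ in range(40):
            stats_list = [
                (f"f{i}", float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1)))
                for i in range(30)
            ]
            ms = [ModuleStats(f, "m", mm, gs, abs(mm) > 0.8 and abs(gs) > 0.2)
                  for f, mm, gs in stats_list]
            assert select_hubs(ms) == brute_hubs(stats_list)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.03]) == [0.03]

    def test_hand_evaluated_step_up(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert np.allclose(benjamini_hochberg([0.2] * 5), [0.2] * 5)

    def test_matches_quadratic_oracle_on_random_vectors(self, rng):
        for _ in range(40):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert np.allclose(benjamini_hochberg(p), brute_bh(list(p)))

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(size=25)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        # monotone in the raw ordering
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_p_is_an_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestSelectDe:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["feature", "contrast", "log2fc", "p_adj"])

    def test_lfc_one_fdr_0049_is_de(self):
        recs = select_de(self._table([("f", "c", 1.0, 0.049)]))
        assert recs[0].is_de

    def test_padj_exactly_005_is_not_de(self):
        recs = select_de(self._table([("f", "c", 2.0, 0.05)]))
        assert not recs[0].is_de

    def test_zero_lfc_tiny_p_is_not_de(self):
        recs = select_de(self._table([("f", "c", 0.0, 1e-9)]))
        assert not recs[0].is_de

    def test_random_tables_match_literal_scan(self, rng):
        for _ in range(30):
            rows = [
                (f"f{i}", "c", float(rng.normal(0, 1.5)), float(rng.uniform()))
                for i in range(50)
            ]
            got = {
                (r.feature, r.contrast) for r in select_de(self._table(rows)) if r.is_de
            }
            assert got == brute_de(rows)

    def test_raw_p_gets_bh_adjusted_per_contrast(self):
        table = pd.DataFrame(
            {
                "feature": ["a", "b", "c"],
                "contrast": ["x", "x", "x"],
                "log2fc": [2.0, 2.0, 2.0],
                "p": [0.01, 0.02, 0.03],
            }
        )
        recs = select_de(table)
        assert np.allclose([r.p_adj for r in recs], 0.03)


class TestInteractionsAndCerna:
    def test_score_150_energy_minus25_kept(self):
        kept = filter_interactions([InteractionEdge("l", "m", 150, -25)])
        assert len(kept) == 1

    def test_score_exactly_140_dropped(self):
        assert filter_interactions([InteractionEdge("l", "m", 140, -25)]) == []

    def test_energy_exactly_minus20_dropped(self):
        assert filter_interactions([InteractionEdge("l", "m", 150, -20)]) == []

    def test_missing_fields_dropped_with_warning(self):
        df = pd.DataFrame(
            {"source": ["a", "b"], "target": ["m", "m"],
             "score": [150.0, np.nan], "energy": [-25.0, -25.0]}
        )
        with pytest.warns(UserWarning):
            kept = filter_interactions(df)
        assert [e.source for e in kept] == ["a"]

    def test_random_edges_match_literal_scan(self, rng):
        for _ in range(30):
            edges = [
                (f"s{i}", f"t{i % 5}", float(rng.uniform(100, 200)),
                 float(rng.uniform(-40, -5)))
                for i in range(40)
            ]
            kept = filter_interactions(
                [InteractionEdge(*e) for e in edges]
            )
            assert {(e.source, e.target) for e in kept} == brute_edge_filter(edges)

    def test_join_case(self):
        triples = assemble_cerna(
            [InteractionEdge("L1", "miR-a", 150, -25)],
            [InteractionEdge("miR-a", "G1", 160, -30)],
        )
        assert [(t.sponge, t.mirna, t.mrna) for t in triples] == [("L1", "miR-a", "G1")]

    def test_no_shared_mirna_empty(self):
        assert assemble_cerna(
            [InteractionEdge("L1", "miR-a", 150, -25)],
            [InteractionEdge("miR-b", "G1", 160, -30)],
        ) == []

    def test_random_bipartite_tables_match_nested_loop_join(self, rng):
        for _ in range(30):
            e1 = [
                (f"L{rng.integers(0, 6)}", f"m{rng.integers(0, 4)}")
                for _ in range(15)
            ]
            e2 = [
                (f"m{rng.integers(0, 4)}", f"G{rng.integers(0, 6)}")
                for _ in range(15)
            ]
            got = assemble_cerna(
                [InteractionEdge(s, t, 150, -25) for s, t in e1],
                [InteractionEdge(s, t, 150, -25) for s, t in e2],
            )
            assert {(t.sponge, t.mirna, t.mrna) for t in got} == brute_cerna(e1, e2)
            # output deduplicated + bounded
            assert len(got) == len(set(got)) <= len(e1) * len(e2)

    def test_top_sponges_max_aggregation(self):
        edges = [
            InteractionEdge("A", "m1", 150, -25),
            InteractionEdge("A", "m2", 190, -25),
            InteractionEdge("B", "m1", 180, -25),
        ]
        assert top_sponges(edges, n=1) == ["A"]
        assert top_sponges(edges, n=1, agg="sum") == ["A"]
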