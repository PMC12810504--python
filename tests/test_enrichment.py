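"""Hypergeometric over-representation, BH-FDR and kappa term clustering."""
import itertools

import pytest

from netpharm.enrichment import (Annotation, cluster_terms, enrich, kappa,
                                 load_gmt)
from netpharm.errors import ValidationError
from netpharm.synthetic import gen_annotation, gene_universe

from .oracles import hypergeom_by_enumeration, hypergeom_upper_tail


def ann(term_id, genes, category="default"):
    return Annotation(term_id=term_id, term_name=term_id,
                      genes=frozenset(genes), category=category)


UNIVERSE20 = {f"G{i:02d}" for i in range(20)}


class TestEnrich:
    def test_term_equal_to_universe_is_null(self):
        hits = {f"G{i:02d}" for i in range(5)}
        rows = enrich(hits, [ann("T1", UNIVERSE20)], UNIVERSE20)
        assert rows.loc[0, "fold_enrichment"] == pytest.approx(1.0)
        assert rows.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exact_small_case(self):
        # N=20, n=5, K=4, k=4: p = C(4,4) C(16,1) / C(20,5) = 16/15504
        universe = sorted(UNIVERSE20)
        hits = set(universe[:5])
        term = set(universe[1:5])  # 4 genes, all hits
        rows = enrich(hits, [ann("T1", term)], UNIVERSE20)
        assert rows.loc[0, "p_value"] == pytest.approx(16 / 15504)
        assert rows.loc[0, "fold_enrichment"] == pytest.approx(4.0)

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ValidationError, match="ALIEN"):
            enrich({"ALIEN"}, [ann("T1", {"G00"})], UNIVERSE20)

    def test_p_matches_exhaustive_draw_enumeration(self):
        """Tail probability equals enumeration of every possible hit draw
        on a tiny universe."""
        universe = [f"G{i}" for i in range(10)]
        term = set(universe[:4])
        for n, k in [(3, 2), (5, 2), (5, 3), (7, 4)]:
            hits = set(universe[:k]) | set(universe[4:4 + n - k])
            rows = enrich(hits, [ann("T", term)], set(universe), min_hits=1)
            expected = hypergeom_by_enumeration(
                len(hits & term), universe, term, n)
            assert rows.loc[0, "p_value"] == pytest.approx(expected)

    def test_bh_fdr_monotone_and_bounded(self):
        universe = set(gene_universe(200))
        hits = set(sorted(universe)[:20])
        annotations, _ = gen_annotation(sorted(universe), sorted(hits),
                                        n_terms=15, seed=5)
        rows = enrich(hits, annotations, universe)
        assert (rows["fdr"] <= 1.0 + 1e-12).all()
        assert (rows["fdr"] >= rows["p_value"] - 1e-12).all()
        # within one category, FDR is nondecreasing along the p-ranking
        assert (rows["fdr"].diff().dropna() >= -1e-12).all()

    def test_planted_term_ranks_first(self):
        universe = gene_universe(1000)
        hits = universe[:50]
        found = 0
        for seed in range(10):
            annotations, truth = gen_annotation(
                universe, hits, n_terms=20, term_size_range=(80, 120),
                planted_term_effect=5.0, seed=seed)
            rows = enrich(set(hits), annotations, set(universe), min_hits=1)
            if rows.loc[0, "term_id"] == truth["planted_term"]:
                found += 1
        assert found >= 9


class TestKappa:
    def test_identical_sets(self):
        domain = {f"G{i}" for i in range(10)}
        term = {f"G{i}" for i in range(4)}
        assert kappa(term, term, domain) == pytest.approx(1.0)

    def test_complementary_halves_are_minus_one(self):
        domain = {f"G{i}" for i in range(10)}
        first = {f"G{i}" for i in range(5)}
        assert kappa(first, domain - first, domain) == pytest.approx(-1.0)

    def test_degenerate_full_agreement(self):
        domain = {f"G{i}" for i in range(4)}
        assert kappa(domain, domain, domain) == 1.0

    def test_hand_computed_2x2(self):
        # domain 8: a=2 both, b=1 only A, c=1 only B, d=4 neither
        domain = {f"G{i}" for i in range(8)}
        a_set = {"G0", "G1", "G2"}
        b_set = {"G0", "G1", "G3"}
        po = 6 / 8
        pe = (3 * 3 + 5 * 5) / 64
        expected = (po - pe) / (1 - pe)
        assert kappa(a_set, b_set, domain) == pytest.approx(expected)

    def test_symmetry(self):
        domain = {f"G{i}" for i in range(12)}
        a_set = {f"G{i}" for i in range(5)}
        b_set = {f"G{i}" for i in range(3, 9)}
        assert kappa(a_set, b_set, domain) == pytest.approx(
            kappa(b_set, a_set, domain))

    def test_tiny_domain_rejected(self):
        with pytest.raises(ValidationError):
            kappa({"A"}, {"A"}, {"A"})


class TestClusterTerms:
    def _rows(self, hits, annotations, universe):
        return enrich(hits, annotations, universe, min_hits=1)

    def test_dissimilar_terms_stay_singletons(self):
        universe = {f"G{i:02d}" for i in range(30)}
        hits = {f"G{i:02d}" for i in range(12)}
        annotations = [ann("T1", {"G00", "G01", "G02"}),
                       ann("T2", {"G05", "G06", "G07"}),
                       ann("T3", {"G09", "G10", "G11"})]
        rows = self._rows(hits, annotations, universe)
        clusters = cluster_terms(rows, annotations, domain=hits)
        assert all(len(c.members) == 1 for c in clusters)

    def test_identical_terms_merge_with_best_p_representative(self):
        universe = {f"G{i:02d}" for i in range(30)}
        hits = {f"G{i:02d}" for i in range(10)}
        shared = {"G00", "G01", "G02", "G03"}
        annotations = [ann("BIG", shared | {"G20", "G21"}),
                       ann("SMALL", shared)]
        rows = self._rows(hits, annotations, universe)
        clusters = cluster_terms(rows, annotations, domain=hits)
        assert len(clusters) == 1
        best = rows.loc[rows["p_value"].idxmin(), "term_id"]
        assert clusters[0].representative == best

    def test_two_planted_families_recovered(self):
        universe = {f"G{i:03d}" for i in range(60)}
        hits = {f"G{i:03d}" for i in range(20)}
        fam_a = {f"G{i:03d}" for i in range(8)}
        fam_b = {f"G{i:03d}" for i in range(10, 18)}
        annotations = [
            ann("A1", fam_a), ann("A2", fam_a | {"G050"}),
            ann("B1", fam_b), ann("B2", fam_b - {"G010"}),
        ]
        rows = self._rows(hits, annotations, universe)
        clusters = cluster_terms(rows, annotations, domain=hits)
        families = sorted(sorted(c.members) for c in clusters
                          if len(c.members) > 1)
        assert families == [["A1", "A2"], ["B1", "B2"]]

    def test_raising_threshold_only_refines(self):
        universe = set(gene_universe(100))
        hits = set(sorted(universe)[:30])
        annotations, _ = gen_annotation(sorted(universe), sorted(hits),
                                        n_terms=12, term_size_range=(5, 30),
                                        planted_term_effect=None, seed=9)
        rows = self._rows(hits, annotations, universe)
        coarse = cluster_terms(rows, annotations, threshold=0.2, domain=hits)
        fine = cluster_terms(rows, annotations, threshold=0.5, domain=hits)
        coarse_of = {t: i for i, c in enumerate(coarse) for t in c.members}
        # every fine cluster sits inside one coarse cluster
        for c in fine:
            assert len({coarse_of[t] for t in c.members}) == 1


def test_gmt_roundtrip(tmp_path):
    path = tmp_path / "terms.gmt.tsv"
    path.write_text("T1\tfirst term\tEGFR\tGSK3B\nT2\tsecond\toprm1\n")
    terms = load_gmt(path)
    assert terms[0].genes == {"EGFR", "GSK3B"}
    assert terms[1].genes == {"OPRM1"}
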