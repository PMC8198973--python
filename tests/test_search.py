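"""Nearest-motif search, rank clustering and private-mutation accounting."""

import numpy as np
import pytest

from mitomotif.motifs import Motif, MotifDB, condense_db
from mitomotif.notation import (
    RCRS_LENGTH,
    ReadingRange,
    Variant,
    make_haplotype,
    parse_haplotype,
)
from mitomotif.search import (
    CostedNeighbor,
    WeightTable,
    count_essential_privates,
    load_weight_table,
    neighbor_cost,
    rank_neighbors,
    search_neighbors,
)
from mitomotif.transcripts import Transcript


def _nb(cost, name="X"):
    h = make_haplotype(name, ReadingRange(1, 10), [], 10)
    return CostedNeighbor(frozenset({name}), cost, (), h, Transcript())


class TestRankClustering:
    def test_margin_rule_on_hand_computed_clusters(self):
        costs = [1.0, 1.3, 2.4, 2.6, 5.0]
        nbs = [_nb(c, f"H{i}") for i, c in enumerate(costs)]
        result = rank_neighbors(nbs, margin=0.5)
        assert sorted(nb.cost for nb in result.rank1) == [1.0, 1.3]
        assert sorted(nb.cost for nb in result.rank2) == [2.4, 2.6]

    def test_single_cost_leaves_rank2_empty(self):
        result = rank_neighbors([_nb(0.0)])
        assert len(result.rank1) == 1 and result.rank2 == ()

    def test_margin_boundary_is_inclusive(self):
        result = rank_neighbors([_nb(1.0, "A"), _nb(1.5, "B"), _nb(1.6, "C")])
        assert {sorted(nb.names)[0] for nb in result.rank1} == {"A", "B"}

    def test_ranks_are_disjoint(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            nbs = [_nb(float(c), f"H{i}")
                   for i, c in enumerate(rng.integers(0, 6, size=8))]
            r = rank_neighbors(nbs)
            ids1 = {id(nb) for nb in r.rank1}
            assert not ids1 & {id(nb) for nb in r.rank2}
            cmin = min(nb.cost for nb in nbs)
            assert all(nb.cost <= cmin + 0.5 for nb in r.rank1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_neighbors([])

    def test_mrca_estimates_per_rank(self, toy_db, toy_ref):
        rng = ReadingRange(1, toy_ref.length)
        q = make_haplotype("q", rng, [], toy_ref.length)
        nbs = search_neighbors(q, toy_db, toy_ref, rng)
        result = rank_neighbors(nbs, toy_db)
        assert result.mrca_rank1 == toy_db.mrca(result.rank1_names())
        if result.rank2:
            assert result.mrca_rank2 == toy_db.mrca(result.rank2_names())


class TestNeighborCost:
    def test_identical_query_costs_nothing(self, toy_db, toy_ref):
        m = toy_db[toy_db.names()[2]]
        q = make_haplotype("q", m.haplotype.range, m.haplotype.variants,
                           toy_ref.length)
        nb = neighbor_cost(q, m.haplotype, toy_ref)
        assert nb.cost == 0.0 and nb.privates == ()

    def test_planted_substitution_costs_its_weight(self, toy_db, toy_ref):
        m = toy_db[toy_db.names()[2]]
        extra = Variant("sub", 30, 0, "A" if toy_ref.base(30) != "A" else "G")
        q = make_haplotype("q", m.haplotype.range,
                           list(m.haplotype.variants) + [extra],
                           toy_ref.length)
        wt = WeightTable({"30": 2.5})
        nb = neighbor_cost(q, m.haplotype, toy_ref, weights=wt)
        assert nb.cost == pytest.approx(2.5)
        assert len(nb.privates) == 1

    def test_monotonicity_of_added_private(self, toy_db, toy_ref):
        """One added essential private of weight w raises the cost against
        every motif by exactly w (away from existing indels)."""
        rng = ReadingRange(1, toy_ref.length)
        base = make_haplotype("q", rng, [], toy_ref.length)
        pos = 42
        extra = Variant("sub", pos, 0, "A" if toy_ref.base(pos) != "A" else "G")
        more = make_haplotype("q2", rng, [extra], toy_ref.length)
        wt = WeightTable({str(pos): 1.75})
        for entry, _ in condense_db(toy_db, rng, toy_ref.length).entries:
            if any(abs(v.position - pos) <= 1 for v in entry.variants):
                continue
            c0 = neighbor_cost(base, entry, toy_ref, weights=wt).cost
            c1 = neighbor_cost(more, entry, toy_ref, weights=wt).cost
            assert c1 == pytest.approx(c0 + 1.75)

    def test_widening_never_increases_cost(self, toy_db, toy_ref, toy_spec):
        """Replacing a motif base by a covering IUPAC code cannot make any
        query more expensive."""
        from mitomotif.fixtures import code_for, sample_query
        from mitomotif.notation import IUPAC

        rng = np.random.default_rng(21)
        name = toy_db.names()[3]
        motif = toy_db[name]
        v = motif.haplotype.variants[0]
        widened_v = Variant("sub", v.position, 0,
                            code_for(IUPAC[v.observed] | {toy_ref.base(v.position)}))
        widened = make_haplotype(name, motif.haplotype.range,
                                 [widened_v if w.coord == v.coord else w
                                  for w in motif.haplotype.variants],
                                 toy_ref.length)
        for i in range(10):
            q, _ = sample_query(motif, toy_spec, toy_ref, rng)
            before = neighbor_cost(q, motif.haplotype, toy_ref,
                                   lv_regions=toy_spec.lv_regions).cost
            after = neighbor_cost(q, widened, toy_ref,
                                  lv_regions=toy_spec.lv_regions).cost
            assert after <= before


class TestEssentialPrivates:
    CR = ReadingRange(16024, 576)

    def test_identical_query_has_none(self, rcrs):
        m = parse_haplotype("73G 263G", self.CR, "m")
        q = parse_haplotype("73G 263G", self.CR, "q")
        assert count_essential_privates(q, m, rcrs) == 0

    def test_heteroplasmy_and_length_variant_excluded(self, rcrs):
        """Of {16093Y, 309.1C, 13500C}-style extras only the plain
        substitution counts as essential."""
        m = parse_haplotype("73G", self.CR, "m")
        q = parse_haplotype("73G 16093Y 309.1C 150C", self.CR, "q")
        # 16093Y: point heteroplasmy; 309.1C: length variant; 150C: essential
        assert count_essential_privates(q, m, rcrs) == 1

    def test_matches_set_difference_oracle_for_substitutions(self, toy_ref):
        rng = np.random.default_rng(13)
        rr = ReadingRange(1, toy_ref.length)
        for _ in range(30):
            def subs_only(sid):
                vs, used = [], set()
                for _ in range(int(rng.integers(0, 5))):
                    p = int(rng.integers(2, toy_ref.length + 1))
                    if p in used or toy_ref.base(p) == "C":
                        continue
                    used.add(p)
                    vs.append(Variant("sub", p, 0,
                                      "C"))
                return make_haplotype(sid, rr, vs, toy_ref.length)

            m, q = subs_only("m"), subs_only("q")
            oracle = len(set(q.variants) - set(m.variants)) + \
                len(set(m.variants) - set(q.variants))
            assert count_essential_privates(q, m, toy_ref,
                                            lv_regions=()) == oracle


@pytest.fixture(scope="module")
def excerpt():
    import importlib.resources as res

    with res.as_file(res.files("mitomotif.data") / "weights_excerpt.tsv") as p:
        return load_weight_table(p)


class TestWeightTies:
    """Desk-scale surrogates for the published weight-tie behaviour."""

    def _db(self):
        rng = ReadingRange(1, RCRS_LENGTH)

        def motif(name, parent, tokens):
            return Motif(name, parent, parse_haplotype(tokens, rng, name))

        return MotifDB([
            motif("L", None, ""),
            motif("M", "L", "489C 10400T"),
            motif("M29'Q", "M", "489C 10400T 13500C"),
            motif("M35", "M", "489C 10400T 12561A"),
            motif("T2b", "L", "709A 930A"),
            motif("T2b35", "T2b", "709A 930A 9843G"),
            motif("T2b8", "T2b", "709A 930A 3338C"),
        ])

    def test_equal_weights_produce_ex_aequo_rank1(self, rcrs, excerpt):
        """A haplotype equidistant from two motifs via equally weighted
        transitions (1.312 each) yields both as rank-1 neighbors."""
        db = self._db()
        rng = ReadingRange(1, RCRS_LENGTH)
        q = parse_haplotype("489C 10400T 13500C 12561A", rng, "q")
        nbs = search_neighbors(q, db, rcrs, rng, weights=excerpt)
        result = rank_neighbors(nbs, db, margin=0.25)
        assert result.rank1_names() == {"M29'Q", "M35"}
        assert result.mrca_rank1 == "M"

    def test_unequal_weights_break_the_tie(self, rcrs, excerpt):
        """With weights 1.593 vs 1.360 the cheaper diagnostic wins rank 1."""
        db = self._db()
        rng = ReadingRange(1, RCRS_LENGTH)
        q = parse_haplotype("709A 930A 9843G 3338C", rng, "q")
        nbs = search_neighbors(q, db, rcrs, rng, weights=excerpt)
        result = rank_neighbors(nbs, db, margin=0.2)
        assert result.rank1_names() == {"T2b35"}
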