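"""Ontology handling, annotation propagation and the hypergeometric test."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from mirtox import (
    Ontology,
    enrich,
    load_associations,
    load_obo,
    no_enrichment_check,
    propagate,
)

CHAIN_OBO = """format-version: 1.2

[Term]
id: T:0000001
name: root
namespace: biological_process

[Term]
id: T:0000002
name: middle
namespace: biological_process
is_a: T:0000001 ! root

[Term]
id: T:0000003
name: leaf
namespace: biological_process
alt_id: T:0000099
is_a: T:0000002 ! middle

[Term]
id: T:0000004
name: part
namespace: biological_process
relationship: part_of T:0000002 ! middle

[Term]
id: T:0000005
name: gone
is_obsolete: true
"""


def exact_hypergeom_p(k: int, M: int, K: int, n: int) -> Fraction:
    """Upper-tail hypergeometric by direct rational summation."""
    total = Fraction(0)
    for i in range(k, min(n, K) + 1):
        total += Fraction(comb(K, i) * comb(M - K, n - i), comb(M, n))
    return total


@pytest.fixture
def chain(tmp_path):
    p = tmp_path / "mini.obo"
    p.write_text(CHAIN_OBO)
    return load_obo(p)


class TestLoadObo:
    def test_chain_ancestors(self, chain):
        assert chain.ancestors("T:0000003") == {"T:0000002", "T:0000001"}

    def test_part_of_propagates(self, chain):
        assert chain.ancestors("T:0000004") == {"T:0000002", "T:0000001"}

    def test_alt_id_resolves_to_primary(self, chain):
        assert chain.resolve("T:0000099") == "T:0000003"

    def test_obsolete_excluded(self, chain):
        assert "T:0000005" not in chain.graph

    def test_cycle_rejected_with_listing(self):
        with pytest.raises(ValueError, match="cycle"):
            Ontology.from_edges(["a", "b", "c"], [("a", "b"), ("b", "c"), ("c", "a")])


class TestPropagation:
    def test_leaf_annotation_reaches_root(self, chain):
        ann = propagate({"geneA": {"T:0000003"}}, chain)
        assert ann.propagated["GENEA"] == {"T:0000003", "T:0000002", "T:0000001"}
        assert ann.direct["GENEA"] == {"T:0000003"}

    def test_root_only_annotation(self, chain):
        ann = propagate({"g": {"T:0000001"}}, chain)
        assert ann.propagated["G"] == {"T:0000001"}

    def test_unknown_term_dropped_and_counted(self, chain):
        ann = propagate({"g": {"T:0000003", "T:9999999"}}, chain)
        assert ann.n_dropped == 1

    def test_random_dag_matches_reachability_oracle(self, rng):
        n = 10
        terms = [f"t{i}" for i in range(n)]
        edges = []
        for i in range(1, n):
            for p in rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False):
                edges.append((terms[i], terms[p]))
        onto = Ontology.from_edges(terms, set(edges))
        # brute-force transitive closure
        parents = {t: {v for u, v in set(edges) if u == t} for t in terms}
        for t in terms:
            reach, frontier = set(), set(parents[t])
            while frontier:
                x = frontier.pop()
                if x not in reach:
                    reach.add(x)
                    frontier |= parents[x]
            assert onto.ancestors(t) == reach


class TestEnrich:
    @pytest.fixture
    def flat(self):
        return Ontology.from_edges(["root", "tA", "tB"], [("tA", "root"), ("tB", "root")])

    def annotations(self, onto, mapping):
        return propagate(mapping, onto)

    def test_term_covering_whole_background_p_is_one(self, flat):
        bg = [f"g{i}" for i in range(10)]
        ann = self.annotations(flat, {g: {"tA"} for g in bg})
        res = enrich(bg[:3], bg, ann, flat)
        by_id = {r.term_id: r for r in res}
        assert by_id["tA"].p_value == pytest.approx(1.0)

    def test_exact_combinatorial_value(self, flat):
        # M=10, n=3, K=3, k=3 -> C(3,3)C(7,0)/C(10,3) = 1/120
        bg = [f"g{i}" for i in range(10)]
        ann = self.annotations(
            flat, {g: ({"tA", "tB"} if g in bg[:3] else {"tB"}) for g in bg}
        )
        res = enrich(bg[:3], bg, ann, flat)
        by_id = {r.term_id: r for r in res}
        assert by_id["tA"].p_value == pytest.approx(1 / 120)

    def test_matches_rational_oracle_on_random_cases(self, flat, rng):
        for _ in range(25):
            M = int(rng.integers(8, 51))
            bg = [f"g{i}" for i in range(M)]
            K = int(rng.integers(2, M))
            n = int(rng.integers(1, M))
            members = set(rng.choice(bg, size=K, replace=False))
            query = list(rng.choice(bg, size=n, replace=False))
            ann = self.annotations(
                flat, {g: ({"tA"} if g in members else {"root"}) for g in bg}
            )
            res = enrich(query, bg, ann, flat)
            by_id = {r.term_id: r for r in res}
            k = len(members & set(query))
            expected = exact_hypergeom_p(k, M, K, n)
            assert by_id["tA"].p_value == pytest.approx(float(expected), rel=1e-9)

    def test_planted_term_ranks_first(self, rng):
        onto = Ontology.from_edges(
            ["root"] + [f"t{i}" for i in range(10)],
            [(f"t{i}", "root") for i in range(10)],
        )
        bg = [f"g{i}" for i in range(100)]
        query = bg[:10]
        mapping = {g: {"root"} for g in bg}
        for g in query[:8]:  # planted: 8/10 of query
            mapping[g] = mapping[g] | {"t0"}
        for g in rng.choice(bg[10:], size=2, replace=False):
            mapping[g] = mapping[g] | {"t0"}  # 10/100 background total
        for i in range(1, 10):
            for g in rng.choice(bg, size=10, replace=False):
                mapping[g] = mapping[g] | {f"t{i}"}
        res = enrich(query, bg, propagate(mapping, onto), onto)
        assert res[0].term_id == "t0"

    def test_adding_annotated_query_gene_never_raises_p(self, flat):
        bg = [f"g{i}" for i in range(30)]
        members = bg[:10]
        ann = self.annotations(
            flat, {g: ({"tA"} if g in members else {"root"}) for g in bg}
        )
        query = bg[5:9]  # 4 genes, all in tA
        p_small = {r.term_id: r.p_value for r in enrich(query, bg, ann, flat)}["tA"]
        p_big = {r.term_id: r.p_value for r in enrich(query + [bg[9]], bg, ann, flat)}["tA"]
        assert p_big <= p_small + 1e-12

    def test_bh_equals_definitional_step_up(self, flat, rng):
        onto = Ontology.from_edges(
            ["root"] + [f"t{i}" for i in range(15)],
            [(f"t{i}", "root") for i in range(15)],
        )
        bg = [f"g{i}" for i in range(60)]
        mapping = {g: {"root"} for g in bg}
        for i in range(15):
            for g in rng.choice(bg, size=int(rng.integers(2, 20)), replace=False):
                mapping[g] = mapping[g] | {f"t{i}"}
        res = enrich(list(rng.choice(bg, size=12, replace=False)), bg,
                     propagate(mapping, onto), onto)
        ps = [r.p_value for r in res]
        m = len(ps)
        order = np.argsort(ps, kind="stable")
        # definitional step-up: q_(i) = min_{j>=i} p_(j) * m / j
        q_def = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, ps[i] * m / (rank + 1))
            q_def[i] = running
        for i, r in enumerate(res):
            assert r.q_value == pytest.approx(q_def[i], rel=1e-9)

    def test_query_outside_background_rejected(self, flat):
        bg = ["g0", "g1"]
        ann = self.annotations(flat, {g: {"tA"} for g in bg})
        with pytest.raises(ValueError, match="STRAY"):
            enrich(["g0", "stray"], bg, ann, flat)

    def test_empty_query_rejected(self, flat):
        ann = self.annotations(flat, {"g0": {"tA"}})
        with pytest.raises(ValueError):
            enrich([], ["g0"], ann, flat)

    def test_deterministic_tie_break_by_term_id(self, flat):
        bg = [f"g{i}" for i in range(12)]
        ann = self.annotations(flat, {g: {"tA", "tB"} for g in bg[:6]}
                               | {g: {"root"} for g in bg})
        res = enrich(bg[:4], bg, ann, flat)
        tied = [r.term_id for r in res if r.p_value == res[0].p_value]
        assert tied == sorted(tied)


class TestNoEnrichmentCheck:
    def test_empty_results_true(self):
        assert no_enrichment_check([])

    def test_significant_term_false(self, rng):
        onto = Ontology.from_edges(["root", "t"], [("t", "root")])
        bg = [f"g{i}" for i in range(200)]
        mapping = {g: {"root"} for g in bg}
        for g in bg[:10]:
            mapping[g] = mapping[g] | {"t"}
        res = enrich(bg[:10], bg, propagate(mapping, onto), onto)
        assert not no_enrichment_check(res, alpha=0.05)

    def test_type_i_calibration_on_permuted_queries(self, rng):
        # random annotations, random queries: FDR control should leave
        # >= 90% of permutations without any significant term
        onto = Ontology.from_edges(
            ["root"] + [f"t{i}" for i in range(12)],
            [(f"t{i}", "root") for i in range(12)],
        )
        bg = [f"g{i}" for i in range(80)]
        mapping = {g: {"root"} for g in bg}
        for i in range(12):
            for g in rng.choice(bg, size=12, replace=False):
                mapping[g] = mapping[g] | {f"t{i}"}
        ann = propagate(mapping, onto)
        clean = 0
        runs = 100
        for _ in range(runs):
            query = list(rng.choice(bg, size=10, replace=False))
            clean += no_enrichment_check(enrich(query, bg, ann, onto), alpha=0.05)
        assert clean >= 0.90 * runs


class TestLoadAssociations:
    def test_two_column_tsv(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("gene\tterm\ng1\tT:0000001\ng1\tT:0000002\ng2\tT:0000001\n")
        assoc = load_associations(p)
        assert assoc == {"G1": {"T:0000001", "T:0000002"}, "G2": {"T:0000001"}}

    def test_gaf_columns(self, tmp_path):
        cols = ["DB", "ID", "Sym", "Qual", "T:0000001", "Ref", "Ev", "With", "Aspect",
                "Name", "Syn", "Type", "Taxon", "Date", "Assigned"]
        p = tmp_path / "a.gaf"
        line = "\t".join(cols).replace("Sym", "actb", 1)
        p.write_text("!gaf-version: 2.2\n" + line + "\n")
        assoc = load_associations(p)
        assert assoc == {"ACTB": {"T:0000001"}}
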