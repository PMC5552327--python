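import math

import numpy as np
import pytest

from traitlink.ontology import (
    LinTermSimilarity,
    OntologyError,
    OntologyTerm,
    OntologyGraph,
    lin_similarity,
    make_term_similarity,
    parse_obo,
    propagate_annotations,
    read_annotation_tsv,
    read_gaf,
)

from _oracles import lin_bruteforce, random_dag_and_corpus
from conftest import make_graph

MINI_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: a
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: b
namespace: biological_process
is_a: GO:0000002 ! a
"""


class TestParseObo:
    def test_three_stanza_chain(self, tmp_path):
        path = tmp_path / "mini.obo"
        path.write_text(MINI_OBO)
        graph = parse_obo(str(path))
        assert len(graph) == 3
        assert graph.roots == {"BP": "GO:0000001"}
        assert graph.terms["GO:0000003"].parent_ids == {"GO:0000002"}
        assert graph.terms["GO:0000002"].parent_ids == {"GO:0000001"}

    def test_obsolete_term_flagged_and_excluded(self, tmp_path):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000009\nname: gone\n"
            "namespace: biological_process\nis_obsolete: true\n"
        )
        path = tmp_path / "obs.obo"
        path.write_text(obo)
        graph = parse_obo(str(path))
        assert graph.terms["GO:0000009"].obsolete
        with pytest.raises(OntologyError):
            graph.ancestors("GO:0000009")

    def test_cross_namespace_parent_is_fatal(self, tmp_path):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000010\nname: mf\n"
            "namespace: molecular_function\nis_a: GO:0000001\n"
        )
        path = tmp_path / "xns.obo"
        path.write_text(obo)
        with pytest.raises(OntologyError, match="cross-namespace"):
            parse_obo(str(path))

    def test_missing_namespace_is_fatal(self, tmp_path):
        path = tmp_path / "nons.obo"
        path.write_text("[Term]\nid: GO:1\nname: x\n")
        with pytest.raises(OntologyError, match="namespace"):
            parse_obo(str(path))

    def test_cycle_is_fatal_and_named(self):
        with pytest.raises(OntologyError, match="cycle"):
            make_graph({"a": ["b"], "b": ["a"]})

    def test_part_of_becomes_parent_edge(self, tmp_path):
        obo = MINI_OBO + (
            "\n[Term]\nid: GO:0000004\nname: p\n"
            "namespace: biological_process\n"
            "is_a: GO:0000001 ! root\n"
            "relationship: part_of GO:0000002 ! a\n"
        )
        path = tmp_path / "po.obo"
        path.write_text(obo)
        graph = parse_obo(str(path))
        assert graph.terms["GO:0000004"].parent_ids == {
            "GO:0000001", "GO:0000002",
        }
        graph_no = parse_obo(str(path), part_of=False)
        assert graph_no.terms["GO:0000004"].parent_ids == {"GO:0000001"}


class TestAncestors:
    def test_root_is_its_own_closure(self, chain_graph):
        assert chain_graph.ancestors("root") == {"root"}

    def test_chain(self, chain_graph):
        assert chain_graph.ancestors("c") == {"root", "a", "b", "c"}

    def test_diamond(self, diamond_graph):
        # oracle: enumerate paths d->b->a and d->c->a
        assert diamond_graph.ancestors("d") == {"a", "b", "c", "d"}

    def test_unknown_term(self, chain_graph):
        with pytest.raises(KeyError):
            chain_graph.ancestors("nope")


class TestPropagate:
    def test_leaf_annotation_propagates_up(self, chain_graph):
        corpus = propagate_annotations(chain_graph, {"g1": {"c"}})
        assert corpus.propagated["g1"] == {"root", "a", "b", "c"}
        assert corpus.direct["g1"] == {"c"}

    def test_ic_zero_for_universal_term(self, chain_graph):
        corpus = propagate_annotations(
            chain_graph, {"g1": {"a"}, "g2": {"a"}}
        )
        assert corpus.ic["root"] == 0.0
        assert corpus.ic["a"] == 0.0

    def test_ic_formula(self, chain_graph):
        # 8 genes, 4 carry term a: ic(a) = -ln(4/8) = ln 2
        direct = {f"g{i}": {"a"} for i in range(4)}
        direct |= {f"h{i}": {"root"} for i in range(4)}
        corpus = propagate_annotations(chain_graph, direct)
        assert corpus.n_annotated_genes == 8
        assert corpus.ic["a"] == pytest.approx(math.log(2), abs=1e-12)

    def test_obsolete_annotation_dropped_with_warning(self, caplog):
        graph = make_graph({"r": [], "x": ["r"]}, obsolete={"dead"} | set())
        graph = OntologyGraph(
            list(graph.terms.values())
            + [OntologyTerm("dead", "dead", "BP", frozenset(), True)]
        )
        corpus = propagate_annotations(graph, {"g1": {"x", "dead"}})
        assert corpus.direct["g1"] == {"x"}

    def test_gene_without_terms_excluded(self, chain_graph):
        corpus = propagate_annotations(chain_graph, {"g1": {"a"}, "g2": set()})
        assert corpus.n_annotated_genes == 1
        assert "g2" not in corpus.propagated

    def test_mixed_namespaces_rejected(self):
        graph = OntologyGraph([
            OntologyTerm("b_root", "b", "BP"),
            OntologyTerm("m_root", "m", "MF"),
        ])
        with pytest.raises(OntologyError, match="mixed"):
            propagate_annotations(graph, {"g": {"b_root", "m_root"}})

    def test_unknown_term_rejected(self, chain_graph):
        with pytest.raises(OntologyError, match="unknown term"):
            propagate_annotations(chain_graph, {"g": {"zzz"}})

    def test_idempotence_and_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            parents, direct = random_dag_and_corpus(rng)
            graph = make_graph(parents)
            corpus = propagate_annotations(graph, direct)
            # idempotence: re-propagating the propagated sets changes nothing
            again = propagate_annotations(graph, corpus.propagated)
            assert again.propagated == corpus.propagated
            # parent count >= child count along every edge
            for term, term_parents in parents.items():
                if term not in corpus.term_gene_count:
                    continue
                for parent in term_parents:
                    assert (corpus.term_gene_count[parent]
                            >= corpus.term_gene_count[term])


class TestLinSimilarity:
    @pytest.fixture
    def chain_corpus(self, chain_graph):
        # root:8 genes, a:4, b:2 after propagation
        direct = {f"g{i}": {"root"} for i in range(4)}
        direct |= {f"a{i}": {"a"} for i in range(2)}
        direct |= {f"b{i}": {"b"} for i in range(2)}
        return propagate_annotations(chain_graph, direct)

    def test_self_similarity_is_one(self, chain_graph, chain_corpus):
        assert lin_similarity(chain_corpus, chain_graph, "a", "a") == 1.0

    def test_root_similarity_is_zero(self, chain_graph, chain_corpus):
        assert lin_similarity(chain_corpus, chain_graph, "root", "b") == 0.0

    def test_chain_value(self, chain_graph, chain_corpus):
        # ic(a)=ln2, ic(b)=ln4; MICA of (a,b) is a => 2 ln2 / (ln2 + ln4) = 2/3
        value = lin_similarity(chain_corpus, chain_graph, "a", "b")
        assert value == pytest.approx(2 / 3, abs=1e-12)

    def test_cross_namespace_rejected(self):
        graph = OntologyGraph([
            OntologyTerm("b_root", "b", "BP"),
            OntologyTerm("m_root", "m", "MF"),
        ])
        corpus = propagate_annotations(graph, {"g": {"b_root"}}, namespace="BP")
        with pytest.raises(OntologyError, match="cross-namespace"):
            lin_similarity(corpus, graph, "b_root", "m_root")

    def test_unannotated_term_rejected(self, chain_graph):
        corpus = propagate_annotations(chain_graph, {"g": {"a"}})
        with pytest.raises(OntologyError, match="no annotated genes"):
            lin_similarity(corpus, chain_graph, "a", "c")

    def test_both_root_degenerate_pair_returns_zero(self):
        graph = make_graph({"r": [], "x": ["r"], "y": ["r"]})
        corpus = propagate_annotations(graph, {"g1": {"x", "y"}})
        # every term annotates the single gene: all ICs are 0
        assert lin_similarity(corpus, graph, "x", "y") == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            parents, direct = random_dag_and_corpus(rng)
            graph = make_graph(parents)
            corpus = propagate_annotations(graph, direct)
            annotated = sorted(corpus.term_gene_count)
            pick = rng.choice(len(annotated), size=min(8, len(annotated)),
                              replace=False)
            chosen = [annotated[int(i)] for i in pick]
            for t1 in chosen:
                for t2 in chosen:
                    expected = lin_bruteforce(parents, direct, t1, t2)
                    got = lin_similarity(corpus, graph, t1, t2)
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_similarity_matrix_properties(self):
        rng = np.random.default_rng(3)
        parents, direct = random_dag_and_corpus(rng)
        graph = make_graph(parents)
        corpus = propagate_annotations(graph, direct)
        termsim = LinTermSimilarity(corpus, graph)
        terms = sorted(corpus.term_gene_count)[:12]
        for t1 in terms:
            for t2 in terms:
                v = termsim(t1, t2)
                assert 0.0 <= v <= 1.0
                assert v == termsim(t2, t1)
                if t1 == t2 and corpus.ic[t1] > 0:
                    assert v == 1.0


class TestRegistry:
    def test_default_lin_registered(self, chain_graph):
        corpus = propagate_annotations(
            chain_graph, {"g": {"b"}, "h": {"root"}}
        )
        termsim = make_term_similarity("lin", corpus, chain_graph)
        assert termsim("b", "b") == 1.0

    def test_unknown_name_rejected(self, chain_graph):
        corpus = propagate_annotations(chain_graph, {"g": {"b"}})
        with pytest.raises(KeyError, match="registered"):
            make_term_similarity("ism", corpus, chain_graph)


class TestReaders:
    def test_two_column_tsv_with_header(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("gene_id\tterm_id\ng1\tGO:1\ng1\tGO:2\ng2\tGO:1\n")
        assert read_annotation_tsv(str(path)) == {
            "g1": {"GO:1", "GO:2"}, "g2": {"GO:1"},
        }

    def test_gaf_aspect_filter_and_not_qualifier(self, tmp_path):
        row = ("DB\t{gene}\tsym\t{qual}\t{term}\tREF\tIEA\t\t{aspect}\t"
               "desc\t\tprotein\ttaxon:39947\t20200101\tSRC")
        lines = [
            "!gaf-version: 2.1",
            row.format(gene="g1", qual="", term="GO:1", aspect="P"),
            row.format(gene="g1", qual="NOT", term="GO:2", aspect="P"),
            row.format(gene="g2", qual="", term="GO:3", aspect="F"),
        ]
        path = tmp_path / "a.gaf"
        path.write_text("\n".join(lines) + "\n")
        assert read_gaf(str(path), "BP") == {"g1": {"GO:1"}}
        assert read_gaf(str(path), "MF") == {"g2": {"GO:3"}}
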