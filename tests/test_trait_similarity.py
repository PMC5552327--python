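import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from traitlink.pipeline import run_similarity_pipeline
from traitlink.synthetic_data import benchmark_spec, generate_dataset
from traitlink.trait_similarity import (
    best_match_average,
    build_similarity_matrix,
    f_bp,
    f_bp_per_trait,
    ks_two_sample,
    matrix_from_frame,
    max_similarity_links,
    similarity_matrix,
    term_sets_from_links,
)


class DictSim:
    """Term similarity from an explicit symmetric table (self-sim 1)."""

    def __init__(self, table):
        self.table = table

    def __call__(self, a, b):
        if a == b:
            return 1.0
        return self.table.get((a, b), self.table.get((b, a), 0.0))


class TestBestMatchAverage:
    def test_identical_sets_give_one(self):
        sim = DictSim({})
        assert best_match_average({"a", "b"}, {"a", "b"}, sim) == 1.0

    def test_singletons(self):
        sim = DictSim({("a", "b"): 0.37})
        assert best_match_average({"a"}, {"b"}, sim) == pytest.approx(0.37)

    def test_hand_computed_asymmetric_sets(self):
        # X={a,b}, Y={a}: 0.5 * [ (1 + sim(b,a))/2 + 1 ]
        sim = DictSim({("a", "b"): 0.4})
        expected = 0.5 * ((1 + 0.4) / 2 + 1)
        assert best_match_average({"a", "b"}, {"a"}, sim) == pytest.approx(expected)

    def test_one_directional_variant(self):
        sim = DictSim({("a", "b"): 0.4})
        forward = best_match_average({"a", "b"}, {"a"}, sim, symmetric=False)
        assert forward == pytest.approx((1 + 0.4) / 2)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            best_match_average(set(), {"a"}, DictSim({}))

    @given(
        st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6),
        st.sets(st.sampled_from("abcdefgh"), min_size=1, max_size=6),
        st.integers(min_value=0, max_value=10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetry_property(self, xs, ys, seed):
        rng = np.random.default_rng(seed)
        table = {
            (a, b): float(rng.random())
            for a, b in itertools.combinations(sorted(set("abcdefgh")), 2)
        }
        sim = DictSim(table)
        assert best_match_average(xs, ys, sim) == pytest.approx(
            best_match_average(ys, xs, sim), abs=1e-12
        )

    def test_monotonicity_adding_identical_term(self):
        sim = DictSim({("a", "b"): 0.2, ("a", "c"): 0.1, ("b", "c"): 0.5})
        xs = {"a", "b"}
        before = best_match_average(xs, {"c"}, sim, symmetric=False)
        after = best_match_average(xs, {"c", "a"}, sim, symmetric=False)
        assert after >= before


@pytest.fixture(scope="module")
def pipeline_outputs():
    dataset = generate_dataset(benchmark_spec(), 21)
    traits, resources = dataset.load()
    return dataset, resources, run_similarity_pipeline(traits, resources)


class TestSimilarityMatrix:
    def test_symmetric_unit_diagonal_in_range(self, pipeline_outputs):
        _, _, outputs = pipeline_outputs
        for ns in ("BP", "MF"):
            matrix = outputs.matrices[ns]
            assert matrix is not None
            assert np.allclose(matrix.values, matrix.values.T)
            assert np.allclose(np.diag(matrix.values), 1.0)
            assert matrix.values.min() >= 0.0
            assert matrix.values.max() <= 1.0 + 1e-12

    def test_identical_link_sets_give_similarity_exactly_one(
        self, pipeline_outputs
    ):
        _, resources, outputs = pipeline_outputs
        links = outputs.links["BP"]
        term_sets, types = term_sets_from_links(links, "BP")
        some_trait = sorted(term_sets)[0]
        term_sets["clone"] = frozenset(term_sets[some_trait])
        types["clone"] = types[some_trait]
        matrix = build_similarity_matrix(
            term_sets, types, "BP", resources.termsims["BP"]
        )
        assert matrix.similarity(some_trait, "clone") == 1.0
        frame = matrix.to_frame()
        row = frame[
            (frame["trait_a"] == "clone") | (frame["trait_b"] == "clone")
        ]
        pair = row[(row["trait_a"] == some_trait) | (row["trait_b"] == some_trait)]
        assert bool(pair["identical_term_sets"].iloc[0])

    def test_too_few_traits_rejected(self, pipeline_outputs):
        _, resources, outputs = pipeline_outputs
        links = [l for l in outputs.links["BP"]
                 if l.trait_id == outputs.links["BP"][0].trait_id]
        with pytest.raises(ValueError, match="need >= 2"):
            similarity_matrix(
                links, resources.corpora["BP"], resources.graphs["BP"], "BP"
            )

    def test_three_trait_toy_matches_hand_computation(self):
        sim = DictSim({("a", "b"): 0.5, ("a", "c"): 0.2, ("b", "c"): 0.8})
        term_sets = {"t1": frozenset({"a"}), "t2": frozenset({"b"}),
                     "t3": frozenset({"a", "c"})}
        types = {"t1": "macroscopic", "t2": "metabolite", "t3": "expression"}
        matrix = build_similarity_matrix(term_sets, types, "BP", sim)
        assert matrix.similarity("t1", "t2") == pytest.approx(0.5)
        # t1 vs t3: forward mean over {a}: max(1, .2)=1; backward: (1+.2)/2
        assert matrix.similarity("t1", "t3") == pytest.approx(
            0.5 * (1.0 + (1.0 + 0.2) / 2)
        )
        # t2 vs t3: forward max(.5,.8)=.8; backward (.5+.8)/2
        assert matrix.similarity("t2", "t3") == pytest.approx(
            0.5 * (0.8 + (0.5 + 0.8) / 2)
        )

    def test_sim_max_excludes_diagonal(self):
        sim = DictSim({("a", "b"): 0.5})
        term_sets = {"t1": frozenset({"a"}), "t2": frozenset({"b"})}
        types = {"t1": "macroscopic", "t2": "metabolite"}
        matrix = build_similarity_matrix(term_sets, types, "BP", sim)
        assert matrix.sim_max == pytest.approx(0.5)

    def test_long_form_roundtrip(self, pipeline_outputs):
        _, _, outputs = pipeline_outputs
        matrix = outputs.matrices["BP"]
        rebuilt = matrix_from_frame(matrix.to_frame())
        assert rebuilt.trait_ids == matrix.trait_ids
        assert np.allclose(rebuilt.values, matrix.values)


class TestMaxSimilarityLinks:
    def _matrix(self):
        sim = DictSim({("a", "b"): 0.9, ("a", "c"): 0.3, ("b", "c"): 0.2})
        term_sets = {"m1": frozenset({"a"}), "m2": frozenset({"b"}),
                     "x1": frozenset({"c"})}
        types = {"m1": "macroscopic", "m2": "macroscopic", "x1": "metabolite"}
        return build_similarity_matrix(term_sets, types, "BP", sim), types

    def test_one_link_per_present_category(self):
        matrix, types = self._matrix()
        links = max_similarity_links(matrix, types)
        by_source = {}
        for link in links:
            by_source.setdefault(link.source, []).append(link)
        assert len(by_source["m1"]) == 2  # macroscopic + metabolite
        assert len(by_source["x1"]) == 1  # only macroscopic available

    def test_target_maximizes_similarity(self):
        matrix, types = self._matrix()
        links = {(l.source, l.target_category): l.target
                 for l in max_similarity_links(matrix, types)}
        assert links[("m1", "macroscopic")] == "m2"
        assert links[("x1", "macroscopic")] == "m1"

    def test_tie_broken_by_smaller_trait_id(self):
        sim = DictSim({})
        term_sets = {"a": frozenset({"x"}), "b": frozenset({"x"}),
                     "c": frozenset({"x"})}
        types = dict.fromkeys(term_sets, "macroscopic")
        matrix = build_similarity_matrix(term_sets, types, "BP", sim)
        links = {l.source: l.target for l in max_similarity_links(matrix, types)}
        assert links["c"] == "a"  # ties at 1.0, smallest id wins
        assert links["b"] == "a"

    def test_planted_clusters_pair_within_group(self):
        dataset = generate_dataset(benchmark_spec(), 31)
        traits, resources = dataset.load()
        outputs = run_similarity_pipeline(traits, resources)
        truth = dataset.ground_truth
        groups = truth.drop_duplicates("trait_id").set_index("trait_id")["group"]
        for ns in ("BP", "MF"):
            matrix = outputs.matrices[ns]
            links = max_similarity_links(matrix)
            hits = misses = 0
            for link in links:
                if link.source not in groups.index:
                    continue
                if link.target not in groups.index:
                    continue
                expected_partner = groups[link.source]
                if link.target_category == matrix.trait_types[link.source]:
                    if groups[link.target] == expected_partner:
                        hits += 1
                    else:
                        misses += 1
            assert hits > 0


class TestFBP:
    @pytest.mark.parametrize("bp,mf,expected", [
        (10, 10, 0.5),
        (7, 0, 1.0),
        (0, 3, 0.0),
    ])
    def test_values(self, bp, mf, expected):
        assert f_bp(bp, mf) == expected

    def test_zero_links_undefined(self):
        with pytest.raises(ValueError):
            f_bp(0, 0)

    def test_per_trait_table(self):
        dataset = generate_dataset(benchmark_spec(), 17)
        traits, resources = dataset.load()
        outputs = run_similarity_pipeline(traits, resources)
        table = f_bp_per_trait(outputs.all_links)
        assert ((table["f_bp"] >= 0) & (table["f_bp"] <= 1)).all()
        assert (table["n_bp"] + table["n_mf"] >= 1).all()


class TestKS:
    def test_identical_samples_zero_statistic(self):
        d, _ = ks_two_sample([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0

    def test_disjoint_supports_statistic_one(self):
        d, p = ks_two_sample([0.0, 0.1, 0.2], [0.8, 0.9, 1.0])
        assert d == 1.0
        assert p < 0.2

    def test_hand_computed_example(self):
        d, _ = ks_two_sample([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert d == pytest.approx(1 / 3)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([0.1], [0.2, 0.3])
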