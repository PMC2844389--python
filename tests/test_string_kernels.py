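"""Spectrum / subsequence / gap-weighted / walk-weighted kernels vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from walkernel.path_extract import PathString
from walkernel.string_kernels import (
    KernelSpec,
    classify_subsequence,
    gap_weighted_kernel,
    instance_kernel,
    spectrum_kernel,
    subsequence_kernel,
    walk_weighted_kernel,
)

from conftest import make_path_string
from oracles import (
    brute_gap_weighted,
    brute_spectrum,
    brute_subsequence,
    brute_walk_weighted,
)

ALPHABET = ("a", "b", "c", "d")


def _rand_string(rng, n):
    return [rng.choice(ALPHABET) for _ in range(n)]


class TestClosedForms:
    def test_spectrum_self_kernel_counts_windows(self):
        s = ["a", "b", "c", "d", "e"]
        assert spectrum_kernel(s, s, 3) == 3.0

    def test_disjoint_alphabets_score_zero(self):
        assert spectrum_kernel(["a", "b", "c"], ["x", "y", "z"], 3) == 0.0
        assert subsequence_kernel(["a", "b", "c"], ["x", "y", "z"], 3) == 0.0

    def test_subsequence_self_kernel_is_binomial(self):
        s = ["a", "b", "c", "d", "e"]
        assert subsequence_kernel(s, s, 3) == 10.0  # C(5,3)

    def test_strings_shorter_than_p_score_zero(self):
        assert subsequence_kernel(["a", "b"], ["a", "b", "c"], 3) == 0.0
        assert gap_weighted_kernel(["a"], ["a", "b", "c"], 3, 0.5) == 0.0

    def test_single_occurrence_gap_value(self):
        s = ["a", "b", "c"]
        assert gap_weighted_kernel(s, s, 3, 0.5) == pytest.approx(0.5**6)
        assert gap_weighted_kernel(s, s, 3, 0.5) == pytest.approx(0.015625)

    def test_walk_weighted_alternating_self_pair(self):
        ps = PathString(("n1", "e1", "n2", "e2", "n3"), ("n", "e", "n", "e", "n"), "lexical")
        # 1 e-walk pair * 3 + 2 v-walk pairs * 2 + 7 gapped pairs * 1
        assert walk_weighted_kernel(ps, ps) == 14.0


class TestOracleEquivalence:
    def test_dp_kernels_match_brute_force(self, rng):
        for _ in range(150):
            s = _rand_string(rng, rng.randint(1, 9))
            t = _rand_string(rng, rng.randint(1, 9))
            assert spectrum_kernel(s, t, 3) == brute_spectrum(s, t, 3)
            assert subsequence_kernel(s, t, 3) == brute_subsequence(s, t, 3)
            lam = rng.choice([0.3, 0.5, 0.9, 1.0])
            assert gap_weighted_kernel(s, t, 3, lam) == pytest.approx(
                brute_gap_weighted(s, t, 3, lam), abs=1e-10
            )

    def test_walk_weighted_matches_enumeration(self, rng):
        for _ in range(80):
            ps = make_path_string(rng, rng.choice([1, 3, 5, 7, 9]))
            pt = make_path_string(rng, rng.choice([1, 3, 5, 7, 9]))
            lam = rng.choice([0.5, 1.0])
            policy = rng.choice(["noncontig", "min"])
            assert walk_weighted_kernel(ps, pt, (3.0, 2.0, 1.0), lam, policy) == pytest.approx(
                brute_walk_weighted(ps, pt, (3.0, 2.0, 1.0), lam, policy), abs=1e-10
            )

    @settings(derandomize=True, max_examples=60)
    @given(
        s=st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=8),
        t=st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=8),
        lam=st.sampled_from([0.25, 0.5, 1.0]),
    )
    def test_gap_weighted_properties(self, s, t, lam):
        k = gap_weighted_kernel(s, t, 3, lam)
        assert k == pytest.approx(gap_weighted_kernel(t, s, 3, lam))  # symmetry
        assert k == pytest.approx(brute_gap_weighted(s, t, 3, lam), abs=1e-10)


class TestStatedIdentities:
    def test_lambda_one_equals_subsequence(self, rng):
        for _ in range(300):
            s = _rand_string(rng, rng.randint(1, 12))
            t = _rand_string(rng, rng.randint(1, 12))
            assert abs(gap_weighted_kernel(s, t, 3, 1.0) - subsequence_kernel(s, t, 3)) < 1e-10

    def test_unit_weights_collapse_walk_weighted_to_subsequence(self, rng):
        for _ in range(100):
            ps = make_path_string(rng, rng.choice([3, 5, 7, 9]))
            pt = make_path_string(rng, rng.choice([3, 5, 7, 9]))
            assert walk_weighted_kernel(ps, pt, (1.0, 1.0, 1.0)) == pytest.approx(
                subsequence_kernel(ps.symbols, pt.symbols, 3)
            )

    def test_gapped_match_bridges_differing_middle_noun(self):
        """A gapped pair like stimulate-obj(DN)~comp_from(DN) must match even
        when the intervening noun differs between the two strings."""

        def ps(noun):
            return PathString(
                ("NE", "obj(UP)", "stimulate", "obj(DN)", noun, "comp_from(DN)", "NE"),
                ("n", "e", "n", "e", "n", "e", "n"),
                "lexical",
            )

        a, b = ps("transcription"), ps("expression")
        matched = brute_walk_weighted(a, b)
        assert walk_weighted_kernel(a, b) == matched > 0
        # the shared structure is invisible to a purely contiguous comparison
        # around the differing noun, but the gapped triple still matches
        assert subsequence_kernel(a.symbols, b.symbols, 3) > 0


class TestOrderings:
    def test_kernel_family_ordering_on_random_pairs(self, rng):
        for _ in range(100):
            ps = make_path_string(rng, rng.choice([3, 5, 7, 9, 11]))
            pt = make_path_string(rng, rng.choice([3, 5, 7, 9, 11]))
            s, t = ps.symbols, pt.symbols
            spec_v = spectrum_kernel(s, t, 3)
            sub_v = subsequence_kernel(s, t, 3)
            assert spec_v <= sub_v
            assert walk_weighted_kernel(ps, pt) >= sub_v  # weights >= 1
            for lam in (0.3, 0.7, 1.0):
                assert gap_weighted_kernel(s, t, 3, lam) <= sub_v + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "indices,roles,expected",
        [
            ((2, 3, 4), ("n", "e", "e", "n", "e"), "contig_e"),
            ((0, 1, 2), ("n", "e", "n", "e", "n"), "contig_v"),
            ((0, 1, 4), ("n", "e", "n", "e", "n"), "noncontig"),
            ((0, 2, 4), ("n", "e", "n", "e", "n"), "noncontig"),
        ],
    )
    def test_examples(self, indices, roles, expected):
        assert classify_subsequence(indices, roles) == expected

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            classify_subsequence((0, 1), ("n", "e", "n"))


class TestKernelSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"name": "bogus"},
            {"name": "spectrum", "p": 0},
            {"name": "gap_weighted", "lam": 0.0},
            {"name": "gap_weighted", "lam": 1.5},
            {"name": "walk_weighted", "weights": (3.0, 2.0, 0.0)},
            {"name": "walk_weighted", "mixed_policy": "avg"},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            KernelSpec(**kwargs)

    def test_default_lambdas(self):
        assert KernelSpec("gap_weighted").resolved_lambda == 0.5
        assert KernelSpec("walk_weighted").resolved_lambda == 1.0


class TestInstanceKernel:
    def test_empty_instance_scores_zero(self, small_instances):
        empty = next((i for i in small_instances if i.is_empty), None)
        other = next(i for i in small_instances if not i.is_empty)
        if empty is None:
            pytest.skip("corpus has no disconnected pair")
        for name in ("spectrum", "walk_weighted", "extended_dependency"):
            assert instance_kernel(empty, other, KernelSpec(name)) == 0.0

    def test_recomposition_equals_manual_two_term_sum(self, small_instances):
        insts = [i for i in small_instances if not i.is_empty][:10]
        spec = KernelSpec("walk_weighted")
        for a in insts:
            for b in insts:
                manual = walk_weighted_kernel(a.lexical, b.lexical) + walk_weighted_kernel(
                    a.syntactic, b.syntactic
                )
                assert instance_kernel(a, b, spec) == pytest.approx(manual)

    def test_identical_instance_with_coinciding_variants(self):
        from walkernel.path_extract import RelationInstance, DependencyList

        ps = PathString(("a", "r(UP)", "b"), ("n", "e", "n"), "lexical")
        dl = DependencyList(symbols=("a", "b"), subcats=((None, "r(UP)"), ("r(UP)", None)),
                            children=((), (("r(UP)", 0),)))
        inst = RelationInstance(
            doc_id="d", sent_id="s", e1="x", e2="y", label="O",
            lexical=ps, syntactic=ps, word_deps=dl, pos_deps=dl,
        )
        one_sided = spectrum_kernel(ps.symbols, ps.symbols, 3)
        assert instance_kernel(inst, inst, KernelSpec("spectrum")) == 2 * one_sided
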