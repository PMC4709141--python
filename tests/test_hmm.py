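"""HMM engine: parsing, forward/Viterbi against brute-force enumeration,
multi-emission semantics, and chunk caching."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vdjhmm.hmm import (
    ChunkCache,
    EmissionTuple,
    ModelParseError,
    ModelValidationError,
    forward,
    forward_cached,
    model_to_text,
    parse_model,
    path_log_prob,
    viterbi,
)

from conftest import CASINO_YAML, enum_forward, enum_viterbi, random_model


class TestParsing:
    def test_casino_parses_and_validates(self, casino):
        assert len(casino.states) == 2
        assert {s.name for s in casino.states} == {"F", "L"}
        assert math.isclose(sum(casino.initial_transitions.values()), 1.0)

    def test_one_state_model(self, one_state):
        assert one_state.states[0].emissions["A"] == 1.0

    @pytest.mark.parametrize(
        "mutation, message",
        [
            ("transitions: {F: 0.9, L: 0.05, END: 0.05}\n    transitions: {F: 0.85, L: 0.05}",
             "transitions"),  # row summing to 0.9
            ("init: {F: 0.5, L: 0.5}", "init"),
        ],
    )
    def test_bad_probability_rows_rejected(self, mutation, message):
        if "init" in message:
            text = CASINO_YAML.replace("init: {F: 0.5, L: 0.5}",
                                       "init: {F: 0.6, L: 0.5}")
        else:
            text = CASINO_YAML.replace("transitions: {F: 0.9, L: 0.05, END: 0.05}",
                                       "transitions: {F: 0.85, L: 0.05}")
        with pytest.raises(ModelValidationError):
            parse_model(text)

    def test_missing_key_names_offender(self):
        with pytest.raises(ModelParseError, match="alphabet"):
            parse_model("name: x\nstates: {}\ninit: {}\n")

    def test_unknown_transition_target_rejected(self):
        text = CASINO_YAML.replace("transitions: {F: 0.1, L: 0.85, END: 0.05}",
                                   "transitions: {F: 0.1, X: 0.85, END: 0.05}")
        with pytest.raises(ModelValidationError, match="X"):
            parse_model(text)

    def test_yaml_round_trip_is_stable(self, casino):
        text1 = model_to_text(casino)
        text2 = model_to_text(parse_model(text1))
        assert text1 == text2


class TestForward:
    def test_single_path_model(self, one_state):
        # init(1) * emit(1) * self(0.5) * emit(1) * end(0.5)
        lp = forward(one_state, EmissionTuple.of("AA"))
        assert math.isclose(lp, math.log(0.25), abs_tol=1e-12)

    def test_casino_matches_enumeration(self, casino):
        obs = "31511624"
        lp = forward(casino, EmissionTuple.of(obs))
        assert math.isclose(lp, enum_forward(casino, (obs,)), abs_tol=1e-9)

    def test_pair_emission_matches_enumeration(self, casino):
        obs = ("315116", "315116")
        lp = forward(casino, EmissionTuple(obs))
        assert math.isclose(lp, enum_forward(casino, obs), abs_tol=1e-9)

    def test_k2_identical_sequences_equal_squared_emissions(self, casino):
        # P_k2(x, x) under emissions e equals P_k1(x) under e^2: emissions
        # enter the path products squared either way.  The transformed model
        # is the engine itself with its emission table doubled in log space
        # (squared emissions do not sum to 1, so the copy bypasses parsing).
        import copy

        lp2 = forward(casino, EmissionTuple.of("315116", "315116"))
        squared = copy.copy(casino)
        squared._compiled = copy.copy(casino.compiled())
        squared._compiled.log_emit = 2.0 * casino.compiled().log_emit
        lp1 = forward(squared, EmissionTuple.of("315116"))
        assert math.isclose(lp1, lp2, abs_tol=1e-9)

    def test_symbol_outside_alphabet_rejected(self, casino):
        with pytest.raises(ValueError, match="alphabet"):
            forward(casino, EmissionTuple.of("31X116"))

    def test_ambiguity_symbol_is_uninformative(self, one_state):
        lp_n = forward(one_state, EmissionTuple.of("AN"))
        lp_a = forward(one_state, EmissionTuple.of("AA"))
        assert math.isclose(lp_n, lp_a, abs_tol=1e-12)


class TestViterbi:
    def test_single_path_model(self, one_state):
        res = viterbi(one_state, EmissionTuple.of("AAA"))
        assert res.path == ["s", "s", "s"]
        assert math.isclose(res.log_prob, math.log(0.125), abs_tol=1e-12)

    def test_loaded_run_prefers_loaded_state(self, casino):
        res = viterbi(casino, EmissionTuple.of("666666"))
        assert res.path == ["L"] * 6

    def test_matches_enumeration_with_lexicographic_ties(self, casino):
        for obs in ("315116", "666111", "123456"):
            want_lp, want_path = enum_viterbi(casino, (obs,))
            got = viterbi(casino, EmissionTuple.of(obs))
            assert math.isclose(got.log_prob, want_lp, abs_tol=1e-9)
            assert got.path == want_path

    def test_tie_breaks_lexicographic(self):
        # two interchangeable states: every path has equal probability
        text = """
name: tie
alphabet: [A]
init: {a: 0.5, b: 0.5}
states:
  a:
    emissions: {A: 1.0}
    transitions: {a: 0.25, b: 0.25, END: 0.5}
  b:
    emissions: {A: 1.0}
    transitions: {a: 0.25, b: 0.25, END: 0.5}
"""
        model = parse_model(text)
        res = viterbi(model, EmissionTuple.of("AAA"))
        assert res.path == ["a", "a", "a"]

    def test_path_log_prob_matches_enumeration(self, casino):
        from conftest import enum_path_prob

        obs = "3151"
        for path in itertools.product(["F", "L"], repeat=4):
            want = enum_path_prob(casino, (obs,), list(path))
            got = path_log_prob(casino, EmissionTuple.of(obs), list(path))
            assert math.isclose(math.exp(got), want, rel_tol=1e-9)


class TestOracleEquivalence:
    """Random small models vs explicit path enumeration."""

    @pytest.mark.parametrize("seed", range(5))
    def test_forward_and_viterbi_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_states=3, alphabet="ABCD")
        for L in (1, 2, 4, 6):
            obs = "".join(rng.choice(list("ABCD"), size=L))
            assert math.isclose(
                forward(model, EmissionTuple.of(obs)),
                enum_forward(model, (obs,)),
                abs_tol=1e-9,
            )
            want_lp, want_path = enum_viterbi(model, (obs,))
            got = viterbi(model, EmissionTuple.of(obs))
            assert math.isclose(got.log_prob, want_lp, abs_tol=1e-9)
            assert got.path == want_path

    @given(st.integers(0, 10_000), st.integers(1, 5))
    @settings(max_examples=25, deadline=None)
    def test_viterbi_never_exceeds_forward(self, seed, L):
        rng = np.random.default_rng(seed)
        model = random_model(rng, n_states=4, alphabet="AB")
        obs = "".join(rng.choice(list("AB"), size=L))
        f = forward(model, EmissionTuple.of(obs))
        v = viterbi(model, EmissionTuple.of(obs))
        assert v.log_prob <= f + 1e-9
        assert v.log_prob <= 0.0 + 1e-12  # all probabilities <= 1


class TestChunkCache:
    def test_empty_cache_equals_uncached(self, casino):
        cache = ChunkCache()
        obs = EmissionTuple.of("31511624")
        assert forward_cached(casino, obs, cache) == forward(casino, obs)

    def test_shared_prefix_reuse_is_bitwise_identical(self, casino):
        rng = np.random.default_rng(0)
        prefix = "".join(rng.choice(list("123456"), size=100))
        cache = ChunkCache()
        a = prefix + "111"
        b = prefix + "666"
        forward_cached(casino, EmissionTuple.of(a), cache)
        got = forward_cached(casino, EmissionTuple.of(b), cache)
        assert cache.reused_columns >= 100
        assert got == forward(casino, EmissionTuple.of(b))

    def test_repeated_query_hits_cache(self, casino):
        cache = ChunkCache()
        obs = EmissionTuple.of("315116")
        first = forward_cached(casino, obs, cache)
        again = forward_cached(casino, obs, cache)
        assert first == again
        assert cache.hits >= 1

    def test_lru_eviction_respects_capacity(self, casino):
        cache = ChunkCache(capacity=2)
        for obs in ("111", "222", "333", "444"):
            forward_cached(casino, EmissionTuple.of(obs), cache)
        assert len(cache._store) == 2

    def test_cache_keyed_by_model_name(self, casino, one_state):
        cache = ChunkCache()
        forward_cached(casino, EmissionTuple.of("1111"), cache)
        # a different model must not reuse those columns
        val = forward_cached(one_state, EmissionTuple.of("AAAA"), cache)
        assert val == forward(one_state, EmissionTuple.of("AAAA"))


class TestEmissionTuple:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            EmissionTuple(("AB", "ABC"))

    def test_zero_sequences_rejected(self):
        with pytest.raises(ValueError):
            EmissionTuple(())

    def test_window(self):
        t = EmissionTuple.of("ABCDEF", "GHIJKL")
        assert t.window(1, 4).sequences == ("BCD", "HIJ")
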