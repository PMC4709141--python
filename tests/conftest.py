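"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from vdjhmm.annotator import _ModelCache
from vdjhmm.germline import GermlineAllele, GermlineSet
from vdjhmm.hmm import HMMModel, HMMState, parse_model
from vdjhmm.simulate import example_parameter_set, synthetic_germline_set

CASINO_YAML = """
name: casino
alphabet: ["1", "2", "3", "4", "5", "6"]
init: {F: 0.5, L: 0.5}
states:
  F:
    emissions: {"1": 0.1666666666666667, "2": 0.1666666666666667,
                "3": 0.1666666666666667, "4": 0.1666666666666667,
                "5": 0.1666666666666666, "6": 0.1666666666666666}
    transitions: {F: 0.9, L: 0.05, END: 0.05}
  L:
    emissions: {"1": 0.1, "2": 0.1, "3": 0.1, "4": 0.1, "5": 0.1, "6": 0.5}
    transitions: {F: 0.1, L: 0.85, END: 0.05}
"""

ONE_STATE_YAML = """
name: one
alphabet: [A, C, G, T]
init: {s: 1.0}
states:
  s:
    emissions: {A: 1.0, C: 0.0, G: 0.0, T: 0.0}
    transitions: {s: 0.5, END: 0.5}
"""


@pytest.fixture(scope="session")
def casino() -> HMMModel:
    return parse_model(CASINO_YAML)


@pytest.fixture(scope="session")
def one_state() -> HMMModel:
    return parse_model(ONE_STATE_YAML)


@pytest.fixture(scope="session")
def germline() -> GermlineSet:
    return synthetic_germline_set()


@pytest.fixture(scope="session")
def true_params(germline):
    return example_parameter_set(germline)


# ---------------------------------------------------------------------------
# Independent oracles


def enum_path_prob(model: HMMModel, sequences, path) -> float:
    """Linear-space probability of one explicit path, straight from the
    model's dictionaries (no DP, no log space, no compiled arrays)."""
    p = model.initial_transitions.get(path[0], 0.0)
    for i, name in enumerate(path):
        state = model.state(name)
        for seq in sequences:
            p *= state.emissions.get(seq[i], 0.0)
        if i + 1 < len(path):
            p *= state.transitions.get(path[i + 1], 0.0)
    return p * model.state(path[-1]).transitions.get("END", 0.0)


def enum_forward(model: HMMModel, sequences) -> float:
    """Brute-force forward log probability by explicit path enumeration."""
    names = [s.name for s in model.states]
    L = len(sequences[0])
    total = sum(
        enum_path_prob(model, sequences, path)
        for path in itertools.product(names, repeat=L)
    )
    return math.log(total) if total > 0 else float("-inf")


def enum_viterbi(model: HMMModel, sequences):
    """Brute-force best path: max probability, ties to the lexicographically
    smallest state-name sequence."""
    names = [s.name for s in model.states]
    L = len(sequences[0])
    best_p, best_path = -1.0, None
    for path in sorted(itertools.product(names, repeat=L)):
        p = enum_path_prob(model, sequences, path)
        if p > best_p * (1 + 1e-12):
            best_p, best_path = p, path
    return (math.log(best_p) if best_p > 0 else float("-inf")), list(best_path)


def random_model(rng: np.random.Generator, n_states=3, alphabet="ABCD"):
    """A random fully-connected model with END mass on every state."""
    names = [f"s{i}" for i in range(n_states)]
    states = []
    for name in names:
        e = rng.dirichlet(np.ones(len(alphabet)))
        t = rng.dirichlet(np.ones(n_states + 1))
        states.append(
            HMMState(
                name,
                {a: float(p) for a, p in zip(alphabet, e)},
                {**{m: float(p) for m, p in zip(names, t[:-1])},
                 "END": float(t[-1])},
            )
        )
    init = rng.dirichlet(np.ones(n_states))
    return HMMModel(
        "random", list(alphabet), states,
        {m: float(p) for m, p in zip(names, init)},
    )


def tiny_germline(seed: int = 7) -> GermlineSet:
    """A 2V/2D/1J set with genes of at most 12 bases."""
    rng = np.random.default_rng(seed)

    def rnd(n):
        return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))

    alleles = {}
    for name, seg, ln in [
        ("IGHV9-1*01", "V", 11),
        ("IGHV9-1*02", "V", 12),
        ("IGHD9-9*01", "D", 8),
        ("IGHD8-8*01", "D", 7),
        ("IGHJ9*01", "J", 10),
    ]:
        alleles[name] = GermlineAllele(name, seg, rnd(ln))
    return GermlineSet(alleles)


def build_monolithic(germline: GermlineSet, params) -> HMMModel:
    """Explicitly stitch every per-allele HMM into one monolithic model.

    Allele usage enters at the junctions: start -> q_V * V entries, V exits
    -> q_D * D entries, D exits -> q_J * J entries, J exits -> END.  Used as
    the oracle for the factorization identity.
    """
    cache = _ModelCache(germline, params)
    states, init = [], {}

    def pref(a, s):
        return f"{a}|{s}"

    q = params.q_g
    for seg, nxt in (("V", "D"), ("D", "J"), ("J", None)):
        for a in germline.segment_alleles(seg):
            m = cache.get(a).model
            for st in m.states:
                trans = {}
                for t, p in st.transitions.items():
                    if t == "END":
                        if nxt is None:
                            trans["END"] = p
                        else:
                            for a2 in germline.segment_alleles(nxt):
                                m2 = cache.get(a2).model
                                for t2, p2 in m2.initial_transitions.items():
                                    key = pref(a2, t2)
                                    trans[key] = (
                                        trans.get(key, 0.0)
                                        + p * q[nxt][a2] * p2
                                    )
                    else:
                        trans[pref(a, t)] = p
                states.append(HMMState(pref(a, st.name), dict(st.emissions), trans))
            if seg == "V":
                for t, p2 in m.initial_transitions.items():
                    init[pref(a, t)] = init.get(pref(a, t), 0.0) + q["V"][a] * p2
    model = HMMModel("monolithic", ["A", "C", "G", "T"], states, init)
    model.validate()
    return model


def random_read(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
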