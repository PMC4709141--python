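"""General-purpose hidden Markov model engine with multi-sequence emission.

The engine runs the classical forward and Viterbi dynamic programs on a model
described as plain data (and serializable to/from YAML), generalized so that a
single hidden path simultaneously emits ``k >= 1`` aligned symbol sequences
(``k = 2`` is the usual pair HMM).  All arithmetic is carried out in log space;
path sums use a numerically stable log-sum-exp.

Start and end are silent pseudo-states: ``HMMModel.initial_transitions`` holds
the start-state row and each state may carry a transition to the reserved
target ``"END"``.  The ambiguity symbol ``"N"`` is emitted with probability 1
by every state, so it contributes no information to either algorithm.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "END",
    "AMBIGUOUS",
    "HMMState",
    "HMMModel",
    "EmissionTuple",
    "PathResult",
    "ChunkCache",
    "ModelError",
    "ModelParseError",
    "ModelValidationError",
    "parse_model",
    "model_to_text",
    "forward",
    "forward_table",
    "forward_cached",
    "viterbi",
]

#: reserved transition target for the silent end state
END = "END"
#: symbol emitted with probability one from every state
AMBIGUOUS = "N"

_PROB_TOL = 1e-9


class ModelError(Exception):
    """Base class for model description problems."""


class ModelParseError(ModelError):
    """The text description does not conform to the schema."""


class ModelValidationError(ModelError):
    """The parsed model violates a probabilistic invariant."""


@dataclass
class HMMState:
    """One hidden state: categorical emissions plus outgoing transitions.

    ``emissions`` may be empty only for silent states, which this engine does
    not support beyond the implicit start/end; every reachable state here
    emits.  ``transitions`` maps successor state names (or ``"END"``) to
    probabilities.
    """

    name: str
    emissions: dict[str, float]
    transitions: dict[str, float]

    def validate(self, alphabet: list[str], state_names: set[str]) -> None:
        if self.emissions:
            missing = set(self.emissions) - set(alphabet)
            if missing:
                raise ModelValidationError(
                    f"state {self.name!r}: emission symbols {sorted(missing)} "
                    f"not in alphabet"
                )
            tot = sum(self.emissions.values())
            if abs(tot - 1.0) > _PROB_TOL:
                raise ModelValidationError(
                    f"state {self.name!r}: emissions sum to {tot!r}, not 1"
                )
        tot = sum(self.transitions.values())
        if abs(tot - 1.0) > _PROB_TOL:
            raise ModelValidationError(
                f"state {self.name!r}: transitions sum to {tot!r}, not 1"
            )
        for target in self.transitions:
            if target != END and target not in state_names:
                raise ModelValidationError(
                    f"state {self.name!r}: transition target {target!r} "
                    f"is not a state"
                )


@dataclass
class HMMModel:
    """A validated HMM: alphabet, states, and start-state transitions."""

    name: str
    alphabet: list[str]
    states: list[HMMState]
    initial_transitions: dict[str, float]
    _compiled: "_CompiledHMM | None" = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> None:
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ModelValidationError(f"model {self.name!r}: duplicate state names")
        name_set = set(names)
        tot = sum(self.initial_transitions.values())
        if abs(tot - 1.0) > _PROB_TOL:
            raise ModelValidationError(
                f"model {self.name!r}: initial transitions sum to {tot!r}, not 1"
            )
        for target in self.initial_transitions:
            if target not in name_set:
                raise ModelValidationError(
                    f"model {self.name!r}: initial transition target {target!r} "
                    f"is not a state"
                )
        for state in self.states:
            state.validate(self.alphabet, name_set)

    def state(self, name: str) -> HMMState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    def compiled(self) -> "_CompiledHMM":
        # models are treated as immutable once built; the compiled form is
        # cached on first use
        if self._compiled is None:
            self._compiled = _CompiledHMM(self)
        return self._compiled


@dataclass(frozen=True)
class EmissionTuple:
    """k aligned symbol sequences emitted along one shared hidden path."""

    sequences: tuple[str, ...]

    def __post_init__(self):
        if len(self.sequences) < 1:
            raise ValueError("EmissionTuple needs at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths {sorted(lengths)}")

    @classmethod
    def of(cls, *seqs: str) -> "EmissionTuple":
        return cls(tuple(seqs))

    @property
    def k(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences[0])

    def window(self, start: int, stop: int) -> "EmissionTuple":
        """The same k-tuple restricted to columns [start, stop)."""
        return EmissionTuple(tuple(s[start:stop] for s in self.sequences))


@dataclass
class PathResult:
    """A Viterbi result: the state path and its joint log probability."""

    path: list[str]
    log_prob: float


class _CompiledHMM:
    """Dense log-space arrays for the DP recursions."""

    def __init__(self, model: HMMModel):
        model.validate()
        self.model = model
        self.names = [s.name for s in model.states]
        self.index = {n: i for i, n in enumerate(self.names)}
        # state indices in lexicographic name order, for deterministic
        # tie-breaking during Viterbi path reconstruction
        self.lex_order = sorted(range(len(self.names)), key=lambda i: self.names[i])
        n = len(self.names)
        a = len(model.alphabet)
        self.sym_index = {str(s): j for j, s in enumerate(model.alphabet)}
        with np.errstate(divide="ignore"):
            self.log_init = np.full(n, -np.inf)
            for name, p in model.initial_transitions.items():
                self.log_init[self.index[name]] = np.log(p) if p > 0 else -np.inf
            self.log_trans = np.full((n, n), -np.inf)
            self.log_end = np.full(n, -np.inf)
            self.log_emit = np.full((n, a), -np.inf)
            for i, state in enumerate(model.states):
                for target, p in state.transitions.items():
                    lp = np.log(p) if p > 0 else -np.inf
                    if target == END:
                        self.log_end[i] = lp
                    else:
                        self.log_trans[i, self.index[target]] = lp
                for sym, p in state.emissions.items():
                    self.log_emit[i, self.sym_index[str(sym)]] = (
                        np.log(p) if p > 0 else -np.inf
                    )

    def emission_matrix(self, obs: EmissionTuple) -> np.ndarray:
        """(L, n) combined log emission: sum over the k sequences."""
        L = len(obs)
        n = len(self.names)
        E = np.zeros((L, n))
        lookup = self.sym_index
        for seq in obs.sequences:
            idx = np.empty(L, dtype=np.intp)
            for i, sym in enumerate(seq):
                if sym == AMBIGUOUS:
                    idx[i] = -1  # emitted with probability 1 everywhere
                    continue
                j = lookup.get(sym)
                if j is None:
                    raise ValueError(
                        f"symbol {sym!r} at position {i} is not in the "
                        f"alphabet of model {self.model.name!r}"
                    )
                idx[i] = j
            valid = idx >= 0
            if valid.all():
                E += self.log_emit[:, idx].T
            elif valid.any():
                E[valid] += self.log_emit[:, idx[valid]].T
        return E


def _lse_step(prev: np.ndarray, log_trans: np.ndarray) -> np.ndarray:
    """out[s] = logsumexp_r prev[r] + log_trans[r, s]."""
    M = prev[:, None] + log_trans
    mx = M.max(axis=0)
    finite = np.isfinite(mx)
    out = np.full_like(mx, -np.inf)
    if finite.any():
        Mf = M[:, finite]
        out[finite] = mx[finite] + np.log(np.exp(Mf - mx[finite]).sum(axis=0))
    return out


def _logsumexp(v: np.ndarray) -> float:
    m = v.max()
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.exp(v - m).sum()))


def forward_table(model: HMMModel, obs: EmissionTuple) -> np.ndarray:
    """Full forward DP table F of shape (L, n_states), in log space.

    ``F[i, s]`` is the log probability of emitting the first ``i + 1``
    columns of ``obs`` and being in state ``s`` at column ``i`` (end
    transition not included).
    """
    c = model.compiled()
    E = c.emission_matrix(obs)
    L = len(obs)
    F = np.empty((L, len(c.names)))
    F[0] = c.log_init + E[0]
    for i in range(1, L):
        F[i] = E[i] + _lse_step(F[i - 1], c.log_trans)
    return F


def forward(model: HMMModel, obs: EmissionTuple) -> float:
    """Multi-emission forward log probability, summed over all state paths."""
    c = model.compiled()
    F = forward_table(model, obs)
    return _logsumexp(F[-1] + c.log_end)


def viterbi(model: HMMModel, obs: EmissionTuple) -> PathResult:
    """Maximum-probability state path and its log probability.

    Ties are broken in favor of the lexicographically smallest sequence of
    state names, reconstructed front-to-first using a backward
    best-completion table.
    """
    c = model.compiled()
    E = c.emission_matrix(obs)
    L = len(obs)
    n = len(c.names)
    # B[i, s]: best log prob of completing the path from state s at column i
    # (including the final END transition, excluding emission at column i)
    B = np.empty((L, n))
    B[L - 1] = c.log_end
    for i in range(L - 2, -1, -1):
        B[i] = (c.log_trans + (E[i + 1] + B[i + 1])[None, :]).max(axis=1)
    start_scores = c.log_init + E[0] + B[0]
    total = float(start_scores.max())
    if not np.isfinite(total):
        raise ValueError(
            f"no state path with nonzero probability for model {model.name!r}"
        )
    atol = 1e-8 * max(1.0, abs(total))
    path_idx: list[int] = []
    acc = 0.0  # log prob of the committed prefix (init + emissions + transitions)
    for i in range(L):
        if i == 0:
            cand = c.log_init + E[0] + B[0]
        else:
            prev = path_idx[-1]
            cand = acc + c.log_trans[prev] + E[i] + B[i]
        best = None
        for s in c.lex_order:
            if cand[s] >= total - atol:
                best = s
                break
        assert best is not None
        if i == 0:
            acc = float(c.log_init[best] + E[0, best])
        else:
            acc = float(acc + c.log_trans[path_idx[-1], best] + E[i, best])
        path_idx.append(best)
    return PathResult([c.names[i] for i in path_idx], total)


def path_log_prob(model: HMMModel, obs: EmissionTuple, path: list[str]) -> float:
    """Joint log probability of one explicit state path and the emissions.

    Includes the start transition into ``path[0]`` and the END transition
    out of ``path[-1]``; returns ``-inf`` for paths with a zero-probability
    step.
    """
    c = model.compiled()
    if len(path) != len(obs):
        raise ValueError("path length must equal observation length")
    E = c.emission_matrix(obs)
    idx = [c.index[s] for s in path]
    total = float(c.log_init[idx[0]] + E[0, idx[0]])
    for i in range(1, len(idx)):
        total += float(c.log_trans[idx[i - 1], idx[i]] + E[i, idx[i]])
    return total + float(c.log_end[idx[-1]])


class ChunkCache:
    """LRU cache of forward DP tables keyed by model name and prefix content.

    Two observations that agree on their first ``p`` columns (across all
    ``k`` sequences) have identical first ``p`` DP columns, so a cached table
    lets :func:`forward_cached` recompute only the suffix.
    """

    def __init__(self, capacity: int = 32):
        self.capacity = capacity
        self._store: OrderedDict[tuple, np.ndarray] = OrderedDict()
        self.hits = 0
        self.reused_columns = 0

    @staticmethod
    def _key(model: HMMModel, obs: EmissionTuple) -> tuple:
        return (model.name, obs.sequences)

    def longest_prefix(
        self, model: HMMModel, obs: EmissionTuple
    ) -> tuple[int, np.ndarray | None]:
        """Length of the longest cached shared prefix and its DP columns."""
        best_len, best_table = 0, None
        for (mname, seqs), table in self._store.items():
            if mname != model.name or len(seqs) != obs.k:
                continue
            p = 0
            limit = min(len(seqs[0]), len(obs))
            while p < limit and all(
                s[p] == o[p] for s, o in zip(seqs, obs.sequences)
            ):
                p += 1
            if p > best_len:
                best_len, best_table = p, table
        return best_len, best_table

    def put(self, model: HMMModel, obs: EmissionTuple, table: np.ndarray) -> None:
        key = self._key(model, obs)
        self._store[key] = table
        self._store.move_to_end(key)
        while len(self._store) > self.capacity:
            self._store.popitem(last=False)


def forward_cached(
    model: HMMModel, obs: EmissionTuple, cache: ChunkCache
) -> float:
    """Forward log probability, reusing cached DP columns of shared prefixes.

    Bit-for-bit identical to :func:`forward`: the recursion is resumed from
    the cached columns, which are themselves the product of the identical
    column-by-column recursion.
    """
    c = model.compiled()
    key = ChunkCache._key(model, obs)
    cached = cache._store.get(key)
    if cached is not None and cached.shape[0] == len(obs):
        cache._store.move_to_end(key)
        cache.hits += 1
        cache.reused_columns += len(obs)
        return _logsumexp(cached[-1] + c.log_end)
    p, table = cache.longest_prefix(model, obs)
    E = c.emission_matrix(obs)
    L = len(obs)
    F = np.empty((L, len(c.names)))
    if p > 0 and table is not None:
        F[:p] = table[:p]
        cache.hits += 1
        cache.reused_columns += p
    else:
        p = 0
    if p == 0:
        F[0] = c.log_init + E[0]
        p = 1
    for i in range(p, L):
        F[i] = E[i] + _lse_step(F[i - 1], c.log_trans)
    cache.put(model, obs, F)
    return _logsumexp(F[-1] + c.log_end)


# ---------------------------------------------------------------------------
# YAML serialization


def parse_model(text: str) -> HMMModel:
    """Parse a YAML model description and validate it.

    Schema: top-level mapping with keys ``name``, ``alphabet`` (list of
    symbols), ``init`` (state name -> probability), and ``states`` (state
    name -> {``emissions``, ``transitions``}).  Probabilities are decimals;
    transition targets may include ``"END"``.
    """
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ModelParseError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ModelParseError("model description must be a mapping")
    for key in ("name", "alphabet", "states", "init"):
        if key not in doc:
            raise ModelParseError(f"missing required key {key!r}")
    alphabet = [str(s) for s in doc["alphabet"]]
    if not isinstance(doc["states"], dict):
        raise ModelParseError("key 'states' must map state names to definitions")
    states = []
    for name, body in doc["states"].items():
        if not isinstance(body, dict) or "transitions" not in body:
            raise ModelParseError(f"state {name!r}: missing key 'transitions'")
        emissions = {
            str(k): float(v) for k, v in (body.get("emissions") or {}).items()
        }
        transitions = {
            str(k): float(v) for k, v in body["transitions"].items()
        }
        states.append(HMMState(str(name), emissions, transitions))
    init = {str(k): float(v) for k, v in doc["init"].items()}
    model = HMMModel(str(doc["name"]), alphabet, states, init)
    model.validate()
    return model


def model_to_text(model: HMMModel) -> str:
    """Serialize a model to YAML; stable under parse/emit round trips."""
    doc = {
        "name": model.name,
        "alphabet": list(model.alphabet),
        "init": {k: float(v) for k, v in sorted(model.initial_transitions.items())},
        "states": {
            s.name: {
                "emissions": {k: float(v) for k, v in sorted(s.emissions.items())},
                "transitions": {
                    k: float(v) for k, v in sorted(s.transitions.items())
                },
            }
            for s in model.states
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)
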