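"""Three-state pair hidden Markov model: sampling, Viterbi, forward/backward,
and posterior match probabilities.

The model has hidden states M (emits an aligned symbol pair into both
sequences), I_x (emits into x only) and I_y (emits into y only).  Two
topologies are supported: ``full`` (transitions allowed between the two
insertion states, which makes distinct state paths map to the same
alignment) and ``no_ix_iy`` (I_x <-> I_y transitions blocked).

Generative semantics
--------------------
An explicit END is reachable from every state with per-state termination
probability tau(s), and from the virtual START with probability
``tau_start = sum_s start(s) * tau(s)`` (so a model with tau = 1 everywhere
generates the empty pair).  The probability of a non-empty path
``s_1 .. s_n`` is::

    (1 - tau_start) * start(s_1) * prod_k a(s_k, s_{k+1}) * tau(s_n) * emissions

with ``sum_t a(s, t) + tau(s) = 1`` for every state.

All dynamic programming runs in log space (log-sum-exp), which keeps the
recursions finite far beyond the length ~100 regime where probability-space
recursion underflows; observation probabilities of length-80 protein pairs
are of order 1e-230.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .seqtypes import BioSequence, PairwiseAlignment
from .substitution import (
    JointSubstitutionModel,
    _expand,
    build_default_joint_model,
)

STATE_M, STATE_IX, STATE_IY = 0, 1, 2
STATE_NAMES = ("M", "Ix", "Iy")

DEFAULT_DELTA = 0.02
DEFAULT_EPSILON = 0.7
DEFAULT_TAU = 0.01


@dataclass(frozen=True)
class PairHMMParams:
    """Pair-HMM parameter set.

    ``transitions[s, t]`` is the probability of moving from state ``s`` to
    ``t`` (state order M, I_x, I_y); ``terminate[s]`` the probability of
    ending at ``s``; each row of ``transitions`` plus ``terminate`` sums
    to 1.  ``insert_emission`` defaults to the match model's marginals.
    """

    topology: str
    transitions: np.ndarray
    start_dist: np.ndarray
    terminate: np.ndarray
    match_emission: JointSubstitutionModel
    insert_emission: np.ndarray | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.transitions, dtype=float)
        start = np.asarray(self.start_dist, dtype=float)
        tau = np.asarray(self.terminate, dtype=float)
        if A.shape != (3, 3) or start.shape != (3,) or tau.shape != (3,):
            raise ValueError("transitions must be 3x3; start/terminate length 3")
        if np.any(A < 0) or np.any(start < 0) or np.any(tau < 0):
            raise ValueError("probabilities must be nonnegative")
        rows = A.sum(axis=1) + tau
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("each transition row plus terminate must sum to 1")
        if abs(start.sum() - 1.0) > 1e-9:
            raise ValueError("start distribution must sum to 1")
        if self.topology not in ("full", "no_ix_iy"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "no_ix_iy" and (
            A[STATE_IX, STATE_IY] != 0 or A[STATE_IY, STATE_IX] != 0
        ):
            raise ValueError("no_ix_iy topology forbids I_x <-> I_y transitions")
        ins = self.insert_emission
        if ins is None:
            ins = self.match_emission.marginal
        ins = np.asarray(ins, dtype=float)
        if ins.shape != (len(self.match_emission.alphabet),):
            raise ValueError("insert emission length must match alphabet size")
        object.__setattr__(self, "transitions", A)
        object.__setattr__(self, "start_dist", start)
        object.__setattr__(self, "terminate", tau)
        object.__setattr__(self, "insert_emission", ins)

    @property
    def tau_start(self) -> float:
        """Termination probability before any emission."""
        return float(self.start_dist @ self.terminate)

    @classmethod
    def from_gap_params(
        cls,
        delta: float = DEFAULT_DELTA,
        epsilon: float = DEFAULT_EPSILON,
        tau: float = DEFAULT_TAU,
        topology: str = "full",
        match_emission: JointSubstitutionModel | None = None,
        insert_emission: np.ndarray | None = None,
    ) -> "PairHMMParams":
        """Build a ProbCons-like parameter set from gap-open ``delta``,
        gap-extend ``epsilon`` and a single shared termination ``tau``.

        Start distribution is ``(1 - 2*delta, delta, delta)``.  In the
        ``full`` topology the I_x -> I_y switch probability equals ``delta``.
        """
        if match_emission is None:
            match_emission = build_default_joint_model("protein")
        switch = delta if topology == "full" else 0.0
        A = np.array(
            [
                [1.0 - 2.0 * delta - tau, delta, delta],
                [1.0 - epsilon - switch - tau, epsilon, switch],
                [1.0 - epsilon - switch - tau, switch, epsilon],
            ]
        )
        if np.any(A < 0):
            raise ValueError("inconsistent gap parameters (negative transition)")
        start = np.array([1.0 - 2.0 * delta, delta, delta])
        return cls(
            topology=topology,
            transitions=A,
            start_dist=start,
            terminate=np.full(3, tau),
            match_emission=match_emission,
            insert_emission=insert_emission,
        )

    def swap_xy(self) -> "PairHMMParams":
        """Mirror the model: exchange the roles of I_x and I_y."""
        perm = [STATE_M, STATE_IY, STATE_IX]
        return PairHMMParams(
            topology=self.topology,
            transitions=self.transitions[np.ix_(perm, perm)],
            start_dist=self.start_dist[perm],
            terminate=self.terminate[perm],
            match_emission=self.match_emission,
            insert_emission=self.insert_emission,
        )


@dataclass(frozen=True)
class StatePath:
    """An ordered hidden-state sequence over {M, I_x, I_y}."""

    states: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.states)

    def names(self) -> str:
        return "".join(STATE_NAMES[s] for s in self.states)

    def emitted_lengths(self) -> tuple[int, int]:
        """(L, M_y) implied by the path: M+I_x symbols in x, M+I_y in y."""
        st = np.asarray(self.states, dtype=int) if self.states else np.empty(0, int)
        L = int(np.sum(st == STATE_M) + np.sum(st == STATE_IX))
        My = int(np.sum(st == STATE_M) + np.sum(st == STATE_IY))
        return L, My

    def alignment(self) -> PairwiseAlignment:
        """The pairwise alignment encoded by the M columns of the path."""
        pairs, i, j = [], 0, 0
        for s in self.states:
            if s == STATE_M:
                i += 1
                j += 1
                pairs.append((i, j))
            elif s == STATE_IX:
                i += 1
            else:
                j += 1
        return PairwiseAlignment(pairs, (i, j))


@dataclass(frozen=True)
class SimulatedPair:
    """A sampled sequence pair with its generating path and true alignment."""

    x: BioSequence
    y: BioSequence
    truth: PairwiseAlignment
    path: StatePath
    seed: int

    def __post_init__(self) -> None:
        if self.path.emitted_lengths() != (len(self.x), len(self.y)):
            raise ValueError("path and sequence lengths are inconsistent")
        if self.path.alignment().pair_set() != self.truth.pair_set():
            raise ValueError("truth does not equal the M columns of the path")


def sample_pair(
    params: PairHMMParams, rng_seed: int, min_len: int = 0
) -> SimulatedPair:
    """Sample an aligned sequence pair from the generative model.

    Resamples until both sequences reach ``min_len``.  Deterministic for a
    fixed seed.
    """
    if np.all(params.terminate == 0):
        raise ValueError("non-terminating model: all termination probabilities are 0")
    if min_len > 0 and params.tau_start >= 1.0:
        raise ValueError("model terminates immediately but min_len > 0")
    rng = np.random.default_rng(rng_seed)
    model = params.match_emission
    K = len(model.alphabet)
    joint_flat = model.joint.ravel()
    ins = params.insert_emission / params.insert_emission.sum()
    kind = model.alphabet_kind

    while True:
        states: list[int] = []
        xs: list[str] = []
        ys: list[str] = []
        # START: terminate before any emission with probability tau_start
        if rng.random() < params.tau_start:
            pass
        else:
            s = int(rng.choice(3, p=params.start_dist))
            while True:
                states.append(s)
                if s == STATE_M:
                    k = int(rng.choice(K * K, p=joint_flat))
                    xs.append(model.alphabet[k // K])
                    ys.append(model.alphabet[k % K])
                elif s == STATE_IX:
                    xs.append(model.alphabet[int(rng.choice(K, p=ins))])
                else:
                    ys.append(model.alphabet[int(rng.choice(K, p=ins))])
                move = rng.random()
                if move < params.terminate[s]:
                    break
                p_next = params.transitions[s] / params.transitions[s].sum()
                s = int(rng.choice(3, p=p_next))
        if len(xs) >= min_len and len(ys) >= min_len:
            path = StatePath(tuple(states))
            x = BioSequence("x", "".join(xs) or "", kind) if xs else _empty(kind, "x")
            y = BioSequence("y", "".join(ys) or "", kind) if ys else _empty(kind, "y")
            return SimulatedPair(
                x=x, y=y, truth=path.alignment(), path=path, seed=rng_seed
            )


def _empty(kind: str, name: str) -> BioSequence:
    seq = BioSequence.__new__(BioSequence)
    object.__setattr__(seq, "id", name)
    object.__setattr__(seq, "residues", "")
    object.__setattr__(seq, "alphabet_kind", kind)
    return seq


# ---------------------------------------------------------------------------
# log-space parameter preparation shared by the DP routines


def _check_alphabet(x: BioSequence, y: BioSequence, params: PairHMMParams) -> None:
    kind = params.match_emission.alphabet_kind
    for seq in (x, y):
        if seq.alphabet_kind != kind:
            raise ValueError(
                f"sequence {seq.id!r} has alphabet {seq.alphabet_kind!r} but the "
                f"model expects {kind!r}"
            )
        if len(seq) == 0:
            raise ValueError(f"sequence {seq.id!r} is empty")


def _log_params(params: PairHMMParams):
    with np.errstate(divide="ignore"):
        ltr = np.log(params.transitions)
        lstart = np.log(params.start_dist * (1.0 - params.tau_start))
        ltau = np.log(params.terminate)
    return ltr, lstart, ltau


def _weights(model: JointSubstitutionModel, seq: BioSequence) -> np.ndarray:
    return np.stack([_expand(model, s) for s in seq.residues])


def _emission_logs(x: BioSequence, y: BioSequence, params: PairHMMParams):
    model = params.match_emission
    wx = _weights(model, x)
    wy = _weights(model, y)
    ins = params.insert_emission
    with np.errstate(divide="ignore"):
        lem_m = np.log(wx @ model.joint @ wy.T)
        lem_x = np.log(wx @ ins)
        lem_y = np.log(wy @ ins)
    return lem_m, lem_x, lem_y, wx, wy


def forward_total_prob(
    x: BioSequence, y: BioSequence, params: PairHMMParams
) -> float:
    """log P(x, y): total observation probability over all state paths.

    Uses a constant-memory rolling recursion, finite for sequences of length
    10,000 and beyond.
    """
    _check_alphabet(x, y, params)
    ltr, lstart, ltau = _log_params(params)
    model = params.match_emission
    wx = _weights(model, x)
    XA = wx @ model.joint  # (L, K)
    YW = _weights(model, y)  # (M, K)
    ins = params.insert_emission
    with np.errstate(divide="ignore"):
        lem_x = np.log(wx @ ins)
        lem_y = np.log(YW @ ins)
    return float(
        _kernels.forward_rolling(XA, YW, lem_x, lem_y, ltr, lstart, ltau)
    )


def backward_total_prob(
    x: BioSequence, y: BioSequence, params: PairHMMParams
) -> float:
    """log P(x, y) computed from the backward recursion (cross-check)."""
    _check_alphabet(x, y, params)
    ltr, lstart, ltau = _log_params(params)
    lem_m, lem_x, lem_y, _, _ = _emission_logs(x, y, params)
    B = _kernels.backward_full(lem_m, lem_x, lem_y, ltr, ltau)
    first = np.array(
        [
            lstart[STATE_M] + lem_m[0, 0] + B[STATE_M, 1, 1],
            lstart[STATE_IX] + lem_x[0] + B[STATE_IX, 1, 0],
            lstart[STATE_IY] + lem_y[0] + B[STATE_IY, 0, 1],
        ]
    )
    m = first.max()
    return float(m + np.log(np.exp(first - m).sum()))


def posterior_match_probs(
    x: BioSequence, y: BioSequence, params: PairHMMParams
) -> np.ndarray:
    """L x M matrix of posterior symbol alignment probabilities
    P(x_i ~ y_j | x, y), from the forward-backward recursions."""
    _check_alphabet(x, y, params)
    ltr, lstart, ltau = _log_params(params)
    lem_m, lem_x, lem_y, _, _ = _emission_logs(x, y, params)
    F, ltotal = _kernels.forward_full(lem_m, lem_x, lem_y, ltr, lstart, ltau)
    B = _kernels.backward_full(lem_m, lem_x, lem_y, ltr, ltau)
    post = np.exp(F[STATE_M, 1:, 1:] + B[STATE_M, 1:, 1:] - ltotal)
    return np.clip(post, 0.0, 1.0)


def viterbi_align(
    x: BioSequence, y: BioSequence, params: PairHMMParams
) -> tuple[StatePath, PairwiseAlignment, float]:
    """Most probable single state path, its alignment, and its log probability.

    Tie-break in the traceback prefers M, then I_x, then I_y.
    """
    _check_alphabet(x, y, params)
    ltr, lstart, ltau = _log_params(params)
    lem_m, lem_x, lem_y, _, _ = _emission_logs(x, y, params)
    states, logp = _kernels.viterbi_full(lem_m, lem_x, lem_y, ltr, lstart, ltau)
    path = StatePath(tuple(int(s) for s in states))
    return path, path.alignment(), float(logp)


# ---------------------------------------------------------------------------
# brute-force reference (tiny inputs only; used as an in-package oracle for
# the worked Viterbi example and available to tests)


def enumerate_state_paths(L: int, My: int):
    """Yield every state path emitting exactly L symbols into x and My into y.

    Guarded to tiny problems (L + My <= 10); exponential enumeration.
    """
    if L + My > 10:
        raise ValueError("state-path enumeration is limited to L + M <= 10")
    n_min, n_max = max(L, My), L + My
    for n in range(n_min, n_max + 1):
        for path in itertools.product((STATE_M, STATE_IX, STATE_IY), repeat=n):
            st = StatePath(path)
            if st.emitted_lengths() == (L, My):
                yield st


def path_log_prob(
    path: StatePath, x: BioSequence, y: BioSequence, params: PairHMMParams
) -> float:
    """log P(path, x, y) under the generative semantics (tiny-input oracle)."""
    if path.emitted_lengths() != (len(x), len(y)):
        return -np.inf
    model = params.match_emission
    ins = params.insert_emission
    logp = np.log1p(-params.tau_start)
    i = j = 0
    prev = None
    for s in path.states:
        if prev is None:
            logp += np.log(params.start_dist[s])
        else:
            if params.transitions[prev, s] == 0:
                return -np.inf
            logp += np.log(params.transitions[prev, s])
        if s == STATE_M:
            logp += np.log(
                model.joint[model.index(x[i + 1]), model.index(y[j + 1])]
            )
            i += 1
            j += 1
        elif s == STATE_IX:
            logp += np.log(ins[model.index(x[i + 1])])
            i += 1
        else:
            logp += np.log(ins[model.index(y[j + 1])])
            j += 1
        prev = s
    if params.terminate[prev] == 0:
        return -np.inf
    return float(logp + np.log(params.terminate[prev]))
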