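"""Pair-HMM: parameter invariants, generative sampling, and the DP
recursions checked against exhaustive path enumeration."""

import numpy as np
import pytest

from mpalign import (
    BioSequence,
    backward_total_prob,
    build_nucleotide_model,
    forward_total_prob,
    posterior_match_probs,
    sample_pair,
    viterbi_align,
)
from mpalign.pairhmm import (
    STATE_IX,
    STATE_IY,
    STATE_M,
    PairHMMParams,
    StatePath,
)

from conftest import random_seq
from oracles import all_paths, brute_forward, brute_posterior, brute_viterbi


def test_transition_rows_plus_terminate_sum_to_one(toy_params, protein_params):
    for p in (toy_params, protein_params):
        assert np.allclose(p.transitions.sum(axis=1) + p.terminate, 1.0)
        assert p.start_dist.sum() == pytest.approx(1.0)


def test_no_ix_iy_topology_blocks_insert_switches(nt_model):
    p = PairHMMParams.from_gap_params(
        0.1, 0.4, 0.1, "no_ix_iy", match_emission=nt_model
    )
    assert p.transitions[STATE_IX, STATE_IY] == 0
    assert p.transitions[STATE_IY, STATE_IX] == 0
    bad = p.transitions.copy()
    bad[STATE_IX, STATE_IY] = 0.05
    bad[STATE_IX, STATE_IX] -= 0.05
    with pytest.raises(ValueError, match="no_ix_iy"):
        PairHMMParams(
            "no_ix_iy", bad, p.start_dist, p.terminate, nt_model
        )


def test_inconsistent_gap_params_rejected(nt_model):
    with pytest.raises(ValueError):
        PairHMMParams.from_gap_params(0.3, 0.9, 0.2, match_emission=nt_model)


class TestSampling:
    def test_same_seed_same_output(self, toy_params):
        a = sample_pair(toy_params, 99, 3)
        b = sample_pair(toy_params, 99, 3)
        assert a.x.residues == b.x.residues
        assert a.y.residues == b.y.residues
        assert a.path.states == b.path.states

    def test_truth_is_match_columns(self, toy_params):
        sp = sample_pair(toy_params, 5, 4)
        assert sp.truth.pair_set() == sp.path.alignment().pair_set()
        ii = [i for i, _ in sp.truth.pairs]
        jj = [j for _, j in sp.truth.pairs]
        assert ii == sorted(set(ii)) and jj == sorted(set(jj))

    def test_immediate_termination_gives_empty_pair(self, nt_model):
        p = PairHMMParams(
            "full",
            np.zeros((3, 3)),
            np.array([1.0, 0.0, 0.0]),
            np.ones(3),
            nt_model,
        )
        sp = sample_pair(p, 1, 0)
        assert len(sp.x) == len(sp.y) == len(sp.path) == 0

    def test_nonterminating_model_rejected(self, nt_model):
        A = np.array([[0.8, 0.1, 0.1], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5]])
        p = PairHMMParams(
            "full", A, np.array([1.0, 0, 0]), np.zeros(3), nt_model
        )
        with pytest.raises(ValueError, match="non-terminating"):
            sample_pair(p, 1, 0)

    def test_match_state_fraction_matches_absorbing_chain(self, toy_params):
        """Mean number of M states over sampled paths agrees with the exact
        expectation from absorbing-chain linear algebra within 3 SE."""
        A = toy_params.transitions
        start = toy_params.start_dist
        # expected visits to each state: v = (1 - tau_start) * start' (I-A)^-1
        visits = (1.0 - toy_params.tau_start) * start @ np.linalg.inv(
            np.eye(3) - A
        )
        expected_m = visits[STATE_M]
        counts = np.array(
            [
                sum(1 for s in sample_pair(toy_params, seed, 0).path.states
                    if s == STATE_M)
                for seed in range(10_000)
            ]
        )
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - expected_m) < 3 * se


@pytest.mark.parametrize("topology", ["full", "no_ix_iy"])
def test_forward_matches_enumeration(nt_model, rng, topology):
    params = PairHMMParams.from_gap_params(
        0.12, 0.35, 0.15, topology, match_emission=nt_model
    )
    for _ in range(30):
        L = int(rng.integers(1, 4))
        M = int(rng.integers(1, 4))
        x = random_seq(rng, nt_model, L, "x")
        y = random_seq(rng, nt_model, M, "y")
        lp = forward_total_prob(x, y, params)
        assert lp <= 0.0
        assert lp == pytest.approx(np.log(brute_forward(x, y, params)), abs=1e-10)


def test_forward_equals_backward(toy_params, protein_params, rng):
    x = random_seq(rng, toy_params.match_emission, 12, "x")
    y = random_seq(rng, toy_params.match_emission, 9, "y")
    assert forward_total_prob(x, y, toy_params) == pytest.approx(
        backward_total_prob(x, y, toy_params), abs=1e-8
    )
    px = random_seq(rng, protein_params.match_emission, 40, "px")
    py = random_seq(rng, protein_params.match_emission, 35, "py")
    assert forward_total_prob(px, py, protein_params) == pytest.approx(
        backward_total_prob(px, py, protein_params), abs=1e-8
    )


def test_alphabet_mismatch_rejected(toy_params):
    x = BioSequence("x", "ACDEF", "protein")
    y = BioSequence("y", "ACGT", "nucleotide")
    with pytest.raises(ValueError, match="alphabet"):
        forward_total_prob(x, y, toy_params)


def test_posterior_matches_enumeration(toy_params, rng):
    """Forward-backward posterior equals path-enumeration posterior on all
    random pairs with L + M <= 8 (randomized property, 100 cases)."""
    nt = toy_params.match_emission
    for _ in range(100):
        L = int(rng.integers(1, 5))
        M = int(rng.integers(1, min(8 - L, 4) + 1))
        x = random_seq(rng, nt, L, "x")
        y = random_seq(rng, nt, M, "y")
        post = posterior_match_probs(x, y, toy_params)
        brute = brute_posterior(x, y, toy_params)
        np.testing.assert_allclose(post, brute, atol=1e-10)
        assert np.all(post >= 0) and np.all(post <= 1)
        assert np.all(post.sum(axis=1) <= 1 + 1e-9)
        assert np.all(post.sum(axis=0) <= 1 + 1e-9)


def test_posterior_transpose_symmetry(toy_params, rng):
    nt = toy_params.match_emission
    x = random_seq(rng, nt, 10, "x")
    y = random_seq(rng, nt, 7, "y")
    post_xy = posterior_match_probs(x, y, toy_params)
    post_yx = posterior_match_probs(y, x, toy_params.swap_xy())
    np.testing.assert_allclose(post_yx, post_xy.T, atol=1e-12)


def test_viterbi_matches_enumeration(toy_params, rng):
    nt = toy_params.match_emission
    for _ in range(40):
        L = int(rng.integers(1, 5))
        M = int(rng.integers(1, 5))
        x = random_seq(rng, nt, L, "x")
        y = random_seq(rng, nt, M, "y")
        path, aln, lp = viterbi_align(x, y, toy_params)
        _, best_p = brute_viterbi(x, y, toy_params)
        assert lp == pytest.approx(np.log(best_p), abs=1e-10)
        assert lp <= forward_total_prob(x, y, toy_params) + 1e-12
        assert aln.pair_set() == path.alignment().pair_set()


def test_viterbi_recovers_worked_example():
    """x=AACCG vs y=CCGTT under match-rewarding nucleotide parameters: the
    optimal path is IxIxMMMIyIy, aligning CCG to CCG as {(3,1),(4,2),(5,3)}
    (cross-checked against the enumeration oracle)."""
    nt = build_nucleotide_model(0.1)
    params = PairHMMParams.from_gap_params(
        0.2, 0.5, 0.1, "full", match_emission=nt
    )
    x = BioSequence("x", "AACCG", "nucleotide")
    y = BioSequence("y", "CCGTT", "nucleotide")
    path, aln, lp = viterbi_align(x, y, params)
    best_path, best_p = brute_viterbi(x, y, params)
    assert lp == pytest.approx(np.log(best_p), abs=1e-10)
    assert aln.pairs == ((3, 1), (4, 2), (5, 3))
    assert path.names() == "IxIxMMMIyIy"


def test_state_path_ambiguity_of_full_topology(nt_model):
    """For x=AAACGG, y=AAATTA the alignment {(1,1),(2,2),(3,3)} is produced
    by many distinct full-topology paths (MMM then any interleaving of
    3 I_x and 3 I_y), but by none under no_ix_iy, which cannot place
    insertions in both sequences side by side."""
    import itertools

    from oracles import path_probability

    full = PairHMMParams.from_gap_params(
        0.1, 0.4, 0.1, "full", match_emission=nt_model
    )
    blocked = PairHMMParams.from_gap_params(
        0.1, 0.4, 0.1, "no_ix_iy", match_emission=nt_model
    )
    x = BioSequence("x", "AAACGG", "nucleotide")
    y = BioSequence("y", "AAATTA", "nucleotide")
    target = {(1, 1), (2, 2), (3, 3)}
    n_full = n_blocked = 0
    for tail in set(itertools.permutations([STATE_IX] * 3 + [STATE_IY] * 3)):
        path = (STATE_M, STATE_M, STATE_M) + tail
        assert StatePath(path).alignment().pair_set() == frozenset(target)
        if path_probability(path, x, y, full) > 0:
            n_full += 1
        if path_probability(path, x, y, blocked) > 0:
            n_blocked += 1
    assert n_full == 20  # C(6,3) interleavings, all allowed
    assert n_blocked == 0  # the printed alignment is impossible


def test_no_nan_inf_for_long_sequences(protein_params, rng):
    """Log-space recursion stays finite far beyond the length ~100 regime
    where probability-space forward underflows."""
    x = random_seq(rng, protein_params.match_emission, 2000, "x")
    y = random_seq(rng, protein_params.match_emission, 2000, "y")
    lp = forward_total_prob(x, y, protein_params)
    assert np.isfinite(lp) and lp < 0


def test_length80_observation_probability_regime(protein_params, rng):
    """Observation probabilities of length-80 protein pairs are astronomically
    small (log10 around -230, sanity band -280..-180)."""
    vals = []
    for k in range(5):
        x = random_seq(rng, protein_params.match_emission, 80, f"x{k}")
        y = random_seq(rng, protein_params.match_emission, 80, f"y{k}")
        vals.append(forward_total_prob(x, y, protein_params) / np.log(10))
    mean = np.mean(vals)
    assert -280 < mean < -180
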