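"""HMM engine: state composition, supervised MLE, decoding vs brute force."""

import itertools
import math

import numpy as np
import pytest

from vcgh.hmm import (
    ALPHABET, COMPAT, N_STATES, STATES, DecodingError, HmmParams,
    PosteriorTrack, call_posterior, compose_paths, decompose_path, posterior,
    sample, state_index, train_mle, viterbi,
)

from conftest import random_params


def enumerate_all_paths(params, obs):
    """Independent oracle: exhaust all 3^n symbol-compatible state paths.

    Returns (best log joint prob, per-position state marginals).
    """
    best = -math.inf
    marg = np.zeros((len(obs), N_STATES))
    total = 0.0
    for path in itertools.product(*(COMPAT[b] for b in obs)):
        p = params.initial[path[0]]
        for a, b in zip(path, path[1:]):
            p *= params.transition[a, b]
        total += p
        for t, s in enumerate(path):
            marg[t, s] += p
        if p > 0:
            best = max(best, math.log(p))
    return best, marg / total


class TestStateSpace:
    def test_nine_states_three_symbols(self):
        assert len(STATES) == 9
        assert len(set(STATES)) == 9
        assert ALPHABET == ("H", "L", "M")

    def test_canonical_order(self):
        assert STATES == ("H+", "L+", "M+", "H-", "L-", "M-",
                          "Ho", "Lo", "Mo")

    @pytest.mark.parametrize("sym,lab", [("H", "+"), ("M", "o"), ("L", "-")])
    def test_compose_is_definitional(self, sym, lab):
        idx = compose_paths(np.array([sym]), np.array([lab]))[0]
        assert STATES[idx] == f"{sym}{lab}"
        assert idx == state_index(sym, lab)

    def test_compose_decompose_roundtrip(self):
        rng = np.random.default_rng(0)
        syms = rng.choice(list("HLM"), size=50)
        labs = rng.choice(list("+-o"), size=50)
        s2, l2 = decompose_path(compose_paths(syms, labs))
        assert (s2 == syms).all() and (l2 == labs).all()

    def test_compose_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            compose_paths(np.array(["H"]), np.array(["+", "o"]))


class TestTrainMle:
    def test_toy_corpus_hand_counts(self):
        # sample A: Mo,Mo,H+,H+  sample B: Mo,Lo,Lo,Mo -- transitions from Mo:
        # Mo->Mo, Mo->H+, Mo->Lo each once; both chains start at Mo
        a = compose_paths(np.array(list("MMHH")), np.array(list("oo++")))
        b = compose_paths(np.array(list("MLLM")), np.array(list("oooo")))
        params = train_mle([a, b], pseudocount=0.0)
        mo, ho, lo = (state_index("M", "o"), state_index("H", "+"),
                      state_index("L", "o"))
        assert params.transition[mo, mo] == pytest.approx(1 / 3)
        assert params.transition[mo, ho] == pytest.approx(1 / 3)
        assert params.transition[mo, lo] == pytest.approx(1 / 3)
        assert params.initial[mo] == 1.0

    def test_unseen_state_row_uniform_with_pseudocount(self):
        a = compose_paths(np.array(["M", "M"]), np.array(["o", "o"]))
        params = train_mle([a], pseudocount=1.0)
        hp = state_index("H", "+")
        np.testing.assert_allclose(params.transition[hp], 1 / 9)

    def test_rows_stochastic_after_training(self):
        rng = np.random.default_rng(3)
        paths = [rng.integers(0, 9, size=20) for _ in range(5)]
        for c in (0.0, 0.5, 2.0):
            p = train_mle(paths, pseudocount=c)
            np.testing.assert_allclose(p.transition.sum(axis=1), 1, atol=1e-12)
            assert p.initial.sum() == pytest.approx(1, abs=1e-12)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_mle([])

    def test_parameter_recovery_from_sampled_paths(self):
        """Retraining on 200 sampled length-500 paths recovers transitions
        within binomial sampling error (+/-0.02)."""
        rng = np.random.default_rng(42)
        truth = random_params(rng)
        paths = [sample(truth, 500, rng)[0] for _ in range(200)]
        est = train_mle(paths, pseudocount=0.0)
        assert np.abs(est.transition - truth.transition).max() < 0.02


class TestViterbi:
    def test_length_one_is_initial_argmax(self):
        rng = np.random.default_rng(1)
        params = random_params(rng)
        path, logp = viterbi(params, ["H"])
        compat = COMPAT["H"]
        best = compat[np.argmax(params.initial[compat])]
        assert path[0] == best
        assert logp == pytest.approx(math.log(params.initial[best]))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        params = random_params(rng)
        n = int(rng.integers(2, 9))
        obs = rng.choice(list("HLM"), size=n)
        _, logp = viterbi(params, obs)
        best, _ = enumerate_all_paths(params, obs)
        assert logp == pytest.approx(best, abs=1e-10)

    def test_concentrated_normal_subchain(self):
        # transitions keep mass on staying in Mo; all-M obs decodes all Mo
        mo = state_index("M", "o")
        trans = np.full((9, 9), 0.01 / 8)
        trans[:, mo] = 0.99
        init = np.full(9, 0.01 / 8)
        init[mo] = 0.99
        params = HmmParams(chrom="c", initial=init, transition=trans)
        path, _ = viterbi(params, list("MMMMM"))
        assert (path == mo).all()

    def test_zero_probability_instructs_pseudocount(self):
        a = compose_paths(np.array(["M", "M"]), np.array(["o", "o"]))
        params = train_mle([a], pseudocount=0.0)
        with pytest.raises(DecodingError, match="pseudocount"):
            viterbi(params, list("MH"))

    def test_viterbi_dominates_posterior_path(self):
        """The Viterbi path's joint probability is an upper bound over all
        paths, including the concatenated posterior-argmax path."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            params = random_params(rng)
            obs = rng.choice(list("HLM"), size=12)
            _, logp = viterbi(params, obs)
            track = posterior(params, obs)
            lab_idx = np.argmax(track.marginals, axis=1)
            b = [state_index(o, "+-o"[a]) for o, a in zip(obs, lab_idx)]
            joint = math.log(params.initial[b[0]])
            for x, y in zip(b, b[1:]):
                joint += math.log(params.transition[x, y])
            assert logp >= joint - 1e-12


class TestPosterior:
    def test_length_one_uniform_initial(self):
        params = HmmParams(chrom="c", initial=np.full(9, 1 / 9),
                           transition=np.full((9, 9), 1 / 9))
        track = posterior(params, ["H"])
        np.testing.assert_allclose(track.marginals[0], 1 / 3)

    @pytest.mark.parametrize("trial", range(20))
    def test_marginals_match_enumeration(self, trial):
        rng = np.random.default_rng(200 + trial)
        params = random_params(rng)
        n = int(rng.integers(2, 9))
        obs = rng.choice(list("HLM"), size=n)
        track = posterior(params, obs)
        _, marg = enumerate_all_paths(params, obs)
        for t, b in enumerate(obs):
            for a, lab in enumerate("+-o"):
                assert track.marginals[t, a] == pytest.approx(
                    marg[t, state_index(b, lab)], abs=1e-10)

    def test_marginals_normalized(self):
        rng = np.random.default_rng(9)
        params = random_params(rng)
        track = posterior(params, rng.choice(list("HLM"), size=200))
        np.testing.assert_allclose(track.marginals.sum(axis=1), 1, atol=1e-9)


class TestCallPosterior:
    def test_simple_thresholds(self):
        track = PosteriorTrack(np.array([[0.7, 0.1, 0.2],
                                         [0.55, 0.05, 0.40],
                                         [0.5, 0.5, 0.0]]), 0.0)
        assert list(call_posterior(track, 0.6)) == ["+", "o", "o"]
        assert list(call_posterior(track, 0.5)) == ["+", "+", "o"]

    def test_cutoff_range_enforced(self):
        track = PosteriorTrack(np.array([[1.0, 0.0, 0.0]]), 0.0)
        with pytest.raises(ValueError):
            call_posterior(track, 0.4)

    def test_calls_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(11)
        m = rng.dirichlet(np.ones(3), size=500)
        track = PosteriorTrack(m, 0.0)
        counts = [(call_posterior(track, c) != "o").sum()
                  for c in (0.5, 0.6, 0.7, 0.8, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSample:
    def test_degenerate_chain(self):
        mo = state_index("M", "o")
        init = np.zeros(9)
        init[mo] = 1.0
        params = HmmParams(chrom="c", initial=init, transition=np.eye(9))
        path, syms = sample(params, 10, seed=0)
        assert (path == mo).all() and (syms == "M").all()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(2)
        params = random_params(rng)
        p1, s1 = sample(params, 50, seed=123)
        p2, s2 = sample(params, 50, seed=123)
        p3, _ = sample(params, 50, seed=124)
        assert (p1 == p2).all() and (s1 == s2).all()
        assert (p1 != p3).any()

    def test_empirical_transition_frequencies(self):
        rng = np.random.default_rng(8)
        params = random_params(rng)
        path, _ = sample(params, 100_000, seed=5)
        for k in range(9):
            idx = np.flatnonzero(path[:-1] == k)
            n = len(idx)
            freq = np.bincount(path[idx + 1], minlength=9) / n
            sigma = np.sqrt(params.transition[k] *
                            (1 - params.transition[k]) / n)
            assert (np.abs(freq - params.transition[k])
                    <= 3 * sigma + 1e-9).all()

    def test_length_validated(self):
        params = random_params(np.random.default_rng(0))
        with pytest.raises(ValueError):
            sample(params, 0, seed=0)
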