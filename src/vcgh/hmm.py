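"""The 9-state per-chromosome HMM.

Hidden states are composite (expression symbol, CNA status) pairs in the
canonical order H+, L+, M+, H-, L-, M-, Ho, Lo, Mo.  Emissions are
structurally degenerate: state (b, alpha) emits symbol b with probability 1,
so an observed symbol is compatible with exactly three states (one per CNA
status).  Training is supervised maximum likelihood on composed
symbol/label paths with additive (pseudocount) smoothing; decoding is
Viterbi or scaled forward-backward, in natural-log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LABELS, SYMBOLS

# canonical composite-state order: symbol varies fastest within each CNA block
STATES: tuple[str, ...] = tuple(f"{b}{a}" for a in LABELS for b in SYMBOLS)
ALPHABET: tuple[str, ...] = SYMBOLS  # (H, L, M)
N_STATES = len(STATES)  # 9

_SYM_IDX = {b: i for i, b in enumerate(SYMBOLS)}
_LAB_IDX = {a: i for i, a in enumerate(LABELS)}

# state index -> (symbol index, label index); and the emission indicator
STATE_SYMBOL = np.array([_SYM_IDX[s[0]] for s in STATES])
STATE_LABEL = np.array([_LAB_IDX[s[1]] for s in STATES])
EMISSION = np.zeros((N_STATES, len(ALPHABET)))
EMISSION[np.arange(N_STATES), STATE_SYMBOL] = 1.0

# states compatible with each observed symbol, in canonical order
COMPAT = {b: np.flatnonzero(STATE_SYMBOL == _SYM_IDX[b]) for b in SYMBOLS}


class DecodingError(RuntimeError):
    pass


def state_index(symbol: str, label: str) -> int:
    return 3 * _LAB_IDX[label] + _SYM_IDX[symbol]


def compose_paths(symbols: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Superimpose a symbol column on a CNA column into composite-state indices."""
    symbols = np.asarray(symbols)
    labels = np.asarray(labels)
    if symbols.shape != labels.shape:
        raise ValueError(
            f"symbol/label length mismatch: {symbols.shape} vs {labels.shape}")
    sym = np.vectorize(_SYM_IDX.get)(symbols)
    lab = np.vectorize(_LAB_IDX.get)(labels)
    return 3 * lab + sym


def decompose_path(path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`compose_paths`: state indices -> (symbols, labels)."""
    path = np.asarray(path)
    syms = np.array(SYMBOLS, dtype="<U1")[STATE_SYMBOL[path]]
    labs = np.array(LABELS, dtype="<U1")[STATE_LABEL[path]]
    return syms, labs


@dataclass
class HmmParams:
    """Initial and transition distributions for one chromosome's HMM.

    The emission matrix is fixed degenerate and shared by every instance.
    """

    chrom: str
    initial: np.ndarray     # (9,)
    transition: np.ndarray  # (9, 9) row-stochastic

    def __post_init__(self):
        self.initial = np.asarray(self.initial, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.initial.shape != (N_STATES,) or \
                self.transition.shape != (N_STATES, N_STATES):
            raise ValueError("parameter shape mismatch")
        if (self.initial < 0).any() or (self.transition < 0).any():
            raise ValueError("negative probability")
        if abs(self.initial.sum() - 1) > 1e-12:
            raise ValueError("initial distribution does not sum to 1")
        rows = self.transition.sum(axis=1)
        if np.abs(rows - 1).max() > 1e-12:
            raise ValueError("transition rows do not sum to 1")

    @property
    def emission(self) -> np.ndarray:
        return EMISSION

    def __eq__(self, other) -> bool:
        return (isinstance(other, HmmParams) and self.chrom == other.chrom
                and np.array_equal(self.initial, other.initial)
                and np.array_equal(self.transition, other.transition))


@dataclass
class TrainingCounts:
    A: np.ndarray        # 9x9 transition counts
    N_start: np.ndarray  # chain-start counts per state
    n_paths: int


def count_paths(paths: list[np.ndarray]) -> TrainingCounts:
    A = np.zeros((N_STATES, N_STATES))
    N_start = np.zeros(N_STATES)
    for p in paths:
        p = np.asarray(p)
        N_start[p[0]] += 1
        np.add.at(A, (p[:-1], p[1:]), 1)
    return TrainingCounts(A=A, N_start=N_start, n_paths=len(paths))


def train_mle(paths: list[np.ndarray], chrom: str = "",
              pseudocount: float = 0.5) -> HmmParams:
    """Supervised MLE with additive smoothing.

    a_kl = (A_kl + c) / sum_l' (A_kl' + c);  pi(l) = (N_l + c) / (N + 9c).
    Emissions stay degenerate regardless of counts.
    """
    if not paths:
        raise ValueError("empty training path collection")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = count_paths(paths)
    A = counts.A + pseudocount
    rows = A.sum(axis=1)
    trans = np.empty_like(A)
    for k in range(N_STATES):
        if rows[k] == 0:  # unreachable at c=0 with no outgoing transitions
            trans[k] = 1.0 / N_STATES
        else:
            trans[k] = A[k] / rows[k]
    denom = counts.n_paths + N_STATES * pseudocount
    if denom == 0:
        initial = np.full(N_STATES, 1.0 / N_STATES)
    else:
        initial = (counts.N_start + pseudocount) / denom
    return HmmParams(chrom=chrom, initial=initial, transition=trans)


def _obs_indices(obs) -> np.ndarray:
    obs = np.asarray(obs, dtype="<U1")
    if obs.size == 0:
        raise ValueError("empty observation sequence")
    bad = ~np.isin(obs, SYMBOLS)
    if bad.any():
        raise ValueError(f"invalid observation symbol {obs[bad][0]!r}")
    return np.vectorize(_SYM_IDX.get)(obs)


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


def viterbi(params: HmmParams, obs) -> tuple[np.ndarray, float]:
    """Most probable composite-state path for an observed symbol sequence.

    Returns (state-index path, log joint probability).  Ties broken toward
    the earlier state in canonical order.
    """
    b = _obs_indices(obs)
    L = len(b)
    log_pi = _log(params.initial)
    log_A = _log(params.transition)
    log_E = _log(EMISSION)  # 0 / -inf

    delta = log_pi + log_E[:, b[0]]
    back = np.zeros((L, N_STATES), dtype=np.intp)
    for t in range(1, L):
        cand = delta[:, None] + log_A  # (from, to)
        back[t] = np.argmax(cand, axis=0)  # first max -> canonical tie-break
        delta = cand[back[t], np.arange(N_STATES)] + log_E[:, b[t]]
    best = int(np.argmax(delta))
    logp = float(delta[best])
    if not np.isfinite(logp):
        raise DecodingError(
            "all state paths have zero probability; retrain with a positive "
            "pseudocount")
    path = np.empty(L, dtype=np.intp)
    path[-1] = best
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


@dataclass
class PosteriorTrack:
    """Per-probe marginal posterior over CNA labels (+, -, o)."""

    marginals: np.ndarray  # (L, 3) columns ordered (+, -, o)
    log_likelihood: float

    def __post_init__(self):
        if np.abs(self.marginals.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("posterior marginals do not sum to 1")


def posterior(params: HmmParams, obs) -> PosteriorTrack:
    """Scaled forward-backward; marginals over CNA labels per position."""
    b = _obs_indices(obs)
    L = len(b)
    A = params.transition
    e = EMISSION[:, b].T  # (L, 9) indicator of compatibility

    alpha = np.empty((L, N_STATES))
    scale = np.empty(L)
    a0 = params.initial * e[0]
    scale[0] = a0.sum()
    if scale[0] == 0:
        raise DecodingError(
            "zero-probability observation; retrain with a positive pseudocount")
    alpha[0] = a0 / scale[0]
    for t in range(1, L):
        at = (alpha[t - 1] @ A) * e[t]
        scale[t] = at.sum()
        if scale[t] == 0:
            raise DecodingError(
                "zero-probability observation; retrain with a positive "
                "pseudocount")
        alpha[t] = at / scale[t]

    beta = np.empty((L, N_STATES))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (A @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    # with degenerate emissions only one state per label is compatible:
    # marginal for label a at t is gamma at state (obs_t, a)
    marg = np.empty((L, 3))
    for a in range(3):
        marg[:, a] = gamma[np.arange(L), 3 * a + b]
    return PosteriorTrack(marginals=marg,
                          log_likelihood=float(np.log(scale).sum()))


def call_posterior(track: PosteriorTrack, cutoff: float) -> np.ndarray:
    """Threshold posterior CNA marginals into per-probe labels.

    ``+`` where P(+) >= cutoff, ``-`` where P(-) >= cutoff, else ``o``;
    an exact 0.5/0.5 tie at cutoff 0.5 stays neutral.
    """
    if not 0.5 <= cutoff <= 1:
        raise ValueError("posterior cutoff must lie in [0.5, 1]")
    m = track.marginals
    out = np.full(len(m), "o", dtype="<U1")
    out[(m[:, 0] >= cutoff) & (m[:, 0] > m[:, 1])] = "+"
    out[(m[:, 1] >= cutoff) & (m[:, 1] > m[:, 0])] = "-"
    return out


def sample(params: HmmParams, length: int,
           seed: int | np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling: (state-index path, emitted symbol array)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    path = np.empty(length, dtype=np.intp)
    path[0] = rng.choice(N_STATES, p=params.initial)
    for t in range(1, length):
        path[t] = rng.choice(N_STATES, p=params.transition[path[t - 1]])
    syms, _ = decompose_path(path)
    return path, syms
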