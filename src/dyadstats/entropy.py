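"""Entropy-rate unpredictability of sensory-signal state sequences.

The stream of distinct signal-combination states is treated as a realisation
of a first-order discrete-state Markov process.  Because consecutive
duplicates are collapsed before estimation, self-transitions are
structurally impossible: the transition count matrix has a zero diagonal,
and the entropy rate of an 8-state process is bounded by log2(7) ≈ 2.807
bits per transition.  High entropy means the next signal combination is
hard to predict from the current one (unpredictable caregiving); zero
entropy means a perfectly repetitive transition pattern.

The statistic is the plug-in estimate

    H = − Σ_i π_i Σ_j p_ij log2 p_ij,

with ``p_ij`` the row-normalised transition frequencies and ``π`` the
empirical origin-state frequencies by default (well defined for short,
possibly non-ergodic observed chains).  The stationary distribution of the
estimated matrix and a Miller–Madow bias correction are available as
options.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import StateSequence

__all__ = [
    "TransitionModel",
    "EntropyResult",
    "SessionEntropyRecord",
    "InsufficientDataError",
    "estimate_transition_model",
    "entropy_rate",
    "max_entropy",
    "entropy_from_sequence",
]

N_STATES = 8


class InsufficientDataError(ValueError):
    """The sequence has no transitions, so no transition structure exists."""


@dataclass
class TransitionModel:
    """Visit-weighted first-order Markov transition estimates.

    ``counts[i, j]`` is the number of observed i→j transitions (diagonal
    structurally zero).  ``probs`` holds the maximum-likelihood row
    normalisation over visited origin states; unvisited rows are zero.
    ``origin_dist`` is the empirical origin-state frequency π.
    """

    counts: np.ndarray
    probs: np.ndarray
    origin_dist: np.ndarray

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def visited_origins(self) -> np.ndarray:
        return np.flatnonzero(self.counts.sum(axis=1) > 0)

    @property
    def n_states_visited(self) -> int:
        seen = (self.counts.sum(axis=1) > 0) | (self.counts.sum(axis=0) > 0)
        return int(seen.sum())

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the estimated chain on its visited states.

        Computed as the leading left eigenvector of the visited-state
        submatrix; meaningful when that submatrix is irreducible.
        """
        vis = self.visited_origins
        P = self.probs[np.ix_(vis, vis)]
        # renormalise rows in case some mass leads out of the visited-origin set
        rs = P.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        P = P / rs
        w, v = np.linalg.eig(P.T)
        k = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        full = np.zeros(N_STATES)
        full[vis] = pi
        return full


@dataclass
class EntropyResult:
    """Entropy rate in bits per transition, with data-sufficiency diagnostics."""

    entropy_bits: float
    n_transitions: int
    n_states_visited: int
    flagged_low_data: bool


@dataclass
class SessionEntropyRecord:
    dyad_id: str | None
    age_point: str | None
    entropy_bits: float
    n_transitions: int
    flagged_low_data: bool


def estimate_transition_model(seq: StateSequence, n_states: int = N_STATES) -> TransitionModel:
    """Tally ordered state pairs into a transition model.

    Raises :class:`InsufficientDataError` when the sequence contains no
    transition (fewer than two distinct-state visits).
    """
    idx = np.asarray(seq.indices, dtype=int)
    if idx.size < 2:
        raise InsufficientDataError(
            f"sequence has {max(idx.size - 1, 0)} transitions; at least 1 required"
        )
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    np.add.at(counts, (idx[:-1], idx[1:]), 1)
    if np.any(np.diag(counts)):
        raise ValueError("self-transitions present; collapse the sequence first")
    row = counts.sum(axis=1)
    total = row.sum()
    probs = np.zeros((n_states, n_states))
    nz = row > 0
    probs[nz] = counts[nz] / row[nz, None]
    origin = row / total
    return TransitionModel(counts=counts, probs=probs, origin_dist=origin)


def _row_entropies(probs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log2(probs), 0.0)
    return -terms.sum(axis=1)


def entropy_rate(
    model: TransitionModel,
    origin: str = "empirical",
    bias_correction: str | None = None,
    min_transitions: int = 10,
) -> EntropyResult:
    """Entropy rate H = −Σ_i π_i Σ_j p_ij log2 p_ij of a transition model.

    Parameters
    ----------
    origin : {"empirical", "stationary"}
        Whether π is the empirical origin-state frequency (default) or the
        stationary distribution of the estimated matrix.
    bias_correction : {None, "miller-madow"}
        Optional Miller–Madow correction adding (m_i − 1)/(2 N_i ln 2) to
        each visited row's conditional entropy (m_i observed destination
        cells, N_i row count).
    min_transitions : int
        Sessions with fewer transitions are flagged (never dropped here).
    """
    if origin == "empirical":
        pi = model.origin_dist
    elif origin == "stationary":
        pi = model.stationary_distribution()
    else:
        raise ValueError(f"unknown origin mode {origin!r}")

    h_rows = _row_entropies(model.probs)
    if bias_correction == "miller-madow":
        row_n = model.counts.sum(axis=1)
        m = (model.counts > 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(row_n > 0, (m - 1) / (2.0 * np.maximum(row_n, 1) * np.log(2)), 0.0)
        h_rows = h_rows + corr
    elif bias_correction is not None:
        raise ValueError(f"unknown bias_correction {bias_correction!r}")

    H = float(np.dot(pi, h_rows))
    H = max(H, 0.0)
    n = model.n_transitions
    return EntropyResult(
        entropy_bits=H,
        n_transitions=n,
        n_states_visited=model.n_states_visited,
        flagged_low_data=n < min_transitions,
    )


def max_entropy(n_states: int) -> float:
    """Upper bound of the entropy rate: log2(n_states − 1) bits.

    With self-transitions excluded each state has ``n_states − 1`` possible
    destinations; for the 8 signal-combination states this is
    log2(7) ≈ 2.807 bits.
    """
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")
    return float(np.log2(n_states - 1))


def entropy_from_sequence(
    seq: StateSequence,
    dyad_id: str | None = None,
    age_point: str | None = None,
    origin: str = "empirical",
    bias_correction: str | None = None,
    min_transitions: int = 10,
) -> SessionEntropyRecord:
    """Estimate the transition model and entropy rate of one session's sequence."""
    try:
        model = estimate_transition_model(seq)
    except InsufficientDataError as err:
        who = f" (dyad {dyad_id}, age {age_point})" if dyad_id else ""
        raise InsufficientDataError(str(err) + who) from None
    res = entropy_rate(
        model, origin=origin, bias_correction=bias_correction, min_transitions=min_transitions
    )
    return SessionEntropyRecord(
        dyad_id=dyad_id,
        age_point=age_point,
        entropy_bits=res.entropy_bits,
        n_transitions=res.n_transitions,
        flagged_low_data=res.flagged_low_data,
    )
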