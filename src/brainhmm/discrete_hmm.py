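"""Discrete hidden Markov models: supervised estimation, scaled forward
likelihood, Baum-Welch re-estimation, ancestral sampling and an empirical
symmetrized Kullback-Leibler divergence.

A model is lambda = (A, B, pi): an N x N transition matrix over hidden
states, an N x M emission matrix over observable symbols, and an initial
state distribution.  Throughout this package the initial distribution is
held fixed at uniform (for two states, 0.5/0.5) and is never re-estimated —
the hidden states here index coarse regularity regimes whose starting slice
carries no group information.

The divergence between two models is the Monte-Carlo estimate

    D(l1, l2) = (1 / T2) * log[ P(O_l2 | l1) / P(O_l2 | l2) ]

with O_l2 a sequence sampled from l2 — how well l1 explains data generated
by l2, relative to l2 itself — symmetrized as D_s = (D(l1,l2) + D(l2,l1))/2
and mapped to a dissimilarity d = 1 - exp(D_s) in [0, 1).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DiscreteHMM",
    "KldResult",
    "BaumWelchResult",
    "estimate_supervised",
    "forward_log_likelihood",
    "baum_welch",
    "sample",
    "kld",
]

_ROW_ATOL = 1e-8


@dataclass
class DiscreteHMM:
    """lambda = (A, B, pi) with N hidden states and M observable symbols."""

    A: np.ndarray
    B: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError(f"A must be square, got {self.A.shape}")
        if self.B.shape[0] != n:
            raise ValueError(f"B has {self.B.shape[0]} rows, expected N={n}")
        if self.pi.shape != (n,):
            raise ValueError(f"pi has shape {self.pi.shape}, expected ({n},)")
        for name, mat in (("A", self.A), ("B", self.B)):
            if (mat < 0).any():
                raise ValueError(f"{name} has negative entries")
            sums = mat.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_ATOL)
            if bad.size:
                raise ValueError(
                    f"row {bad[0]} of {name} sums to {sums[bad[0]]!r}, expected 1"
                )
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > _ROW_ATOL:
            raise ValueError(f"pi must be a distribution, got {self.pi!r}")

    @property
    def N(self) -> int:
        return self.A.shape[0]

    @property
    def M(self) -> int:
        return self.B.shape[1]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"N": self.N, "M": self.M, "A": self.A.tolist(),
             "B": self.B.tolist(), "pi": self.pi.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DiscreteHMM":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(A=payload["A"], B=payload["B"], pi=payload["pi"])


def estimate_supervised(
    state_sequences: Sequence[np.ndarray],
    observation_sequences: Sequence[np.ndarray],
    N: int,
    M: int,
    pseudocount: float = 1e-3,
) -> DiscreteHMM:
    """Count-based estimation from paired (state, observation) sequences.

    a_ij = (pseudocount + #transitions i->j) / row total;
    b_j(k) = (pseudocount + #emissions of k in state j) / row total.
    The initial distribution is uniform, not estimated.  A state with no
    counts and zero pseudocount gets a uniform row (logged).
    """
    if len(state_sequences) != len(observation_sequences):
        raise ValueError("state and observation sequence lists differ in length")
    if not state_sequences:
        raise ValueError("need at least one sequence")
    trans = np.zeros((N, N))
    emis = np.zeros((N, M))
    for q, o in zip(state_sequences, observation_sequences):
        q = np.asarray(q, dtype=int)
        o = np.asarray(o, dtype=int)
        if q.shape != o.shape:
            raise ValueError("paired sequences must have equal length")
        if q.size and (q.min() < 0 or q.max() >= N):
            raise ValueError(f"state index out of range [0, {N})")
        if o.size and (o.min() < 0 or o.max() >= M):
            raise ValueError(f"symbol index out of range [0, {M})")
        np.add.at(trans, (q[:-1], q[1:]), 1.0)
        np.add.at(emis, (q, o), 1.0)
    A = trans + pseudocount
    B = emis + pseudocount
    for name, mat in (("A", A), ("B", B)):
        totals = mat.sum(axis=1)
        zero = totals == 0
        if zero.any():
            log.info("%s rows %s unobserved; set uniform", name, np.flatnonzero(zero))
            mat[zero] = 1.0
            totals = mat.sum(axis=1)
        mat /= totals[:, None]
    return DiscreteHMM(A=A, B=B, pi=np.full(N, 1.0 / N))


def forward_log_likelihood(hmm: DiscreteHMM, observations: np.ndarray) -> float:
    """log P(O | lambda) by the scaled forward recursion.

    Per-step normalization with log accumulation; exact log of the full
    path sum.  A zero-probability sequence returns -inf.
    """
    o = np.asarray(observations, dtype=int)
    if o.size == 0:
        raise ValueError("empty observation sequence")
    if o.min() < 0 or o.max() >= hmm.M:
        raise ValueError(f"symbol out of range [0, {hmm.M})")
    alpha = hmm.pi * hmm.B[:, o[0]]
    s = alpha.sum()
    if s == 0:
        return float("-inf")
    logp = np.log(s)
    alpha /= s
    for t in range(1, o.size):
        alpha = (alpha @ hmm.A) * hmm.B[:, o[t]]
        s = alpha.sum()
        if s == 0:
            return float("-inf")
        logp += np.log(s)
        alpha /= s
    return float(logp)


def _forward_backward(hmm: DiscreteHMM, o: np.ndarray):
    """Scaled forward/backward passes; returns (alpha_hat, beta_hat, scales, logp)."""
    T, N = o.size, hmm.N
    alpha = np.empty((T, N))
    scales = np.empty(T)
    alpha[0] = hmm.pi * hmm.B[:, o[0]]
    scales[0] = alpha[0].sum()
    if scales[0] == 0:
        return None
    alpha[0] /= scales[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ hmm.A) * hmm.B[:, o[t]]
        scales[t] = alpha[t].sum()
        if scales[t] == 0:
            return None
        alpha[t] /= scales[t]
    beta = np.empty((T, N))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (hmm.A @ (hmm.B[:, o[t + 1]] * beta[t + 1])) / scales[t + 1]
    return alpha, beta, scales, float(np.log(scales).sum())


@dataclass
class BaumWelchResult:
    """Re-estimated model plus the per-iteration log-likelihood trace."""

    model: DiscreteHMM
    log_likelihoods: list[float]

    @property
    def n_iter(self) -> int:
        return len(self.log_likelihoods)


def baum_welch(
    hmm: DiscreteHMM,
    observation_sequences: Sequence[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-6,
) -> BaumWelchResult:
    """EM re-estimation of A and B; pi stays fixed at its current value.

    Expectations are summed over sequences (each treated as independent).
    Stops when the total log-likelihood improves by less than ``tol`` or
    after ``max_iter`` iterations.  The log-likelihood is non-decreasing
    across iterations (EM monotonicity).
    """
    seqs = [np.asarray(o, dtype=int) for o in observation_sequences]
    if not seqs:
        raise ValueError("need at least one observation sequence")
    model = hmm
    trace: list[float] = []
    for it in range(max_iter):
        a_num = np.zeros((model.N, model.N))
        b_num = np.zeros((model.N, model.M))
        total_ll = 0.0
        for o in seqs:
            fb = _forward_backward(model, o)
            if fb is None:
                raise ValueError(
                    f"zero-probability sequence at iteration {it}; "
                    "use a pseudocount in the starting model"
                )
            alpha, beta, scales, logp = fb
            total_ll += logp
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            if o.size > 1:
                # xi summed over t without materializing the (T, N, N) array
                w = (beta[1:] * model.B[:, o[1:]].T) / scales[1:, None]
                a_num += model.A * (alpha[:-1].T @ w)
            np.add.at(b_num.T, o, gamma)
        if not np.isfinite(total_ll):
            raise ValueError(f"non-finite log-likelihood at iteration {it}")
        trace.append(total_ll)
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            break
        a_tot = a_num.sum(axis=1, keepdims=True)
        b_tot = b_num.sum(axis=1, keepdims=True)
        A = np.where(a_tot > 0, a_num / np.where(a_tot > 0, a_tot, 1.0),
                     1.0 / model.N)
        B = np.where(b_tot > 0, b_num / np.where(b_tot > 0, b_tot, 1.0),
                     1.0 / model.M)
        model = DiscreteHMM(A=A, B=B, pi=model.pi)
    return BaumWelchResult(model=model, log_likelihoods=trace)


def sample(
    hmm: DiscreteHMM, T: int, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral sampling: a hidden state path and its observation sequence."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum_a = np.cumsum(hmm.A, axis=1)
    states = np.empty(T, dtype=int)
    u = rng.random(T)
    states[0] = int(np.searchsorted(np.cumsum(hmm.pi), u[0], side="right"))
    for t in range(1, T):
        states[t] = int(np.searchsorted(cum_a[states[t - 1]], u[t], side="right"))
    np.clip(states, 0, hmm.N - 1, out=states)
    cum_b = np.cumsum(hmm.B, axis=1)
    obs = (rng.random(T)[:, None] >= cum_b[states]).sum(axis=1)
    np.clip(obs, 0, hmm.M - 1, out=obs)
    return states, obs.astype(int)


@dataclass
class KldResult:
    """Empirical symmetrized divergence between two HMMs.

    ``d_12``/``d_21`` are the directed Monte-Carlo divergences, ``d_s``
    their mean, ``d_kl = 1 - exp(d_s)`` the dissimilarity actually compared
    (0 for identical models, approaching 1 as models diverge).
    """

    d_12: float
    d_21: float
    d_s: float
    d_kl: float
    T1: int
    T2: int
    seed: int
    flagged: bool = False


def kld(
    hmm1: DiscreteHMM,
    hmm2: DiscreteHMM,
    T1: int = 2000,
    T2: int = 2000,
    seed: int = 0,
) -> KldResult:
    """Monte-Carlo symmetrized Kullback-Leibler dissimilarity of two HMMs.

    One sequence is sampled from each model with the same seed (common
    random numbers), so identical models give exactly 0 and, for T1 == T2,
    the result is exactly symmetric in its arguments.  A -inf likelihood
    flags the result and maps d_kl to 1.
    """
    if hmm1.M != hmm2.M:
        raise ValueError(f"models disagree on symbol count: {hmm1.M} != {hmm2.M}")
    _, o2 = sample(hmm2, T2, seed)
    _, o1 = sample(hmm1, T1, seed)
    d_12 = (forward_log_likelihood(hmm1, o2) - forward_log_likelihood(hmm2, o2)) / T2
    d_21 = (forward_log_likelihood(hmm2, o1) - forward_log_likelihood(hmm1, o1)) / T1
    flagged = not (np.isfinite(d_12) and np.isfinite(d_21))
    d_s = (d_12 + d_21) / 2.0
    d_kl = 1.0 if not np.isfinite(d_s) else 1.0 - float(np.exp(d_s))
    if flagged:
        log.warning("non-finite directed divergence (d12=%s, d21=%s)", d_12, d_21)
    return KldResult(
        d_12=d_12, d_21=d_21, d_s=d_s, d_kl=d_kl, T1=T1, T2=T2,
        seed=seed if isinstance(seed, int) else -1, flagged=flagged,
    )
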