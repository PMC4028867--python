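"""Linde-Buzo-Gray (LBG) vector quantization.

A codebook of J prototype vectors is grown by binary splitting: start from
the global centroid, perturb every code vector into the pair c(1 ± eps),
then run Lloyd iterations (nearest-neighbor assignment + centroid update)
until the relative drop in average distortion falls below a tolerance, and
repeat until the requested size is reached.  The distortion is

    D = (1 / (T K)) * sum_t || y_t - Q(y_t) ||^2

i.e. the mean squared Euclidean distance to the assigned code vector,
normalized by the feature dimension K.

Feature vectors may optionally be z-scored per dimension before
quantization (the scaler is stored with the codebook and applied again at
encoding time) so that no single dimension dominates the Euclidean metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Codebook", "lbg_codebook", "encode", "distortion"]


@dataclass
class Codebook:
    """LBG codebook: J prototype vectors of dimension K plus optional scaler."""

    code_vectors: np.ndarray  # (J, K)
    training_distortion: float
    scale_mean: np.ndarray | None = None
    scale_sd: np.ndarray | None = None
    ladder_distortions: list[float] = field(default_factory=list)
    iteration_trace: list[float] = field(default_factory=list)

    @property
    def J(self) -> int:
        return self.code_vectors.shape[0]

    @property
    def K(self) -> int:
        return self.code_vectors.shape[1]

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(vectors, dtype=float))
        if x.shape[1] != self.K:
            raise ValueError(f"vectors have dimension {x.shape[1]}, codebook K={self.K}")
        if self.scale_mean is not None:
            x = (x - self.scale_mean) / self.scale_sd
        return x

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "J": self.J,
            "K": self.K,
            "scaler": None
            if self.scale_mean is None
            else {"mean": self.scale_mean.tolist(), "sd": self.scale_sd.tolist()},
            "code_vectors": self.code_vectors.tolist(),
            "training_distortion": self.training_distortion,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Codebook":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        scaler = payload.get("scaler")
        return cls(
            code_vectors=np.asarray(payload["code_vectors"], dtype=float),
            training_distortion=float(payload["training_distortion"]),
            scale_mean=None if scaler is None else np.asarray(scaler["mean"], float),
            scale_sd=None if scaler is None else np.asarray(scaler["sd"], float),
        )


def _sq_dists(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, (T, J); computed via the norm expansion."""
    d = (
        (x * x).sum(axis=1)[:, None]
        + (c * c).sum(axis=1)[None, :]
        - 2.0 * (x @ c.T)
    )
    np.maximum(d, 0.0, out=d)
    return d


def _assign_distortion(x: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    d = _sq_dists(x, c)
    assign = d.argmin(axis=1)
    dist = float(d[np.arange(x.shape[0]), assign].mean() / x.shape[1])
    return assign, dist


def _lloyd(
    x: np.ndarray,
    c: np.ndarray,
    tol: float,
    max_iter: int,
    rng: np.random.Generator,
    trace: list[float],
) -> tuple[np.ndarray, float]:
    prev = None
    assign, dist = _assign_distortion(x, c)
    trace.append(dist)
    for _ in range(max_iter):
        if prev is not None and (prev - dist) <= tol * max(prev, np.finfo(float).tiny):
            break
        prev = dist
        new_c = c.copy()
        counts = np.bincount(assign, minlength=c.shape[0])
        for j in range(c.shape[0]):
            if counts[j] > 0:
                new_c[j] = x[assign == j].mean(axis=0)
        empties = np.flatnonzero(counts == 0)
        if empties.size:
            biggest = int(np.argmax(counts))
            members = np.flatnonzero(assign == biggest)
            for j in empties:
                new_c[j] = x[rng.choice(members)]
        c = new_c
        assign, dist = _assign_distortion(x, c)
        trace.append(dist)
    return c, dist


def lbg_codebook(
    vectors: np.ndarray,
    J: int,
    epsilon: float = 0.01,
    tol: float = 1e-6,
    max_iter: int = 100,
    seed: int = 0,
    standardize: bool = False,
) -> Codebook:
    """Design a size-J codebook by binary splitting + Lloyd iterations.

    ``J`` must be a power of 2 (the doubling scheme) and no larger than the
    number of training vectors.  The seeded RNG is used only to re-seed
    empty cells from a random member of the most populous cell.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2:
        raise ValueError("vectors must be a (T, K) array")
    if J < 1 or (J & (J - 1)) != 0:
        raise ValueError(f"codebook size J={J} must be a power of 2")
    if x.shape[0] < J:
        raise ValueError(f"{x.shape[0]} training vectors < requested J={J}")

    scale_mean = scale_sd = None
    if standardize:
        scale_mean = x.mean(axis=0)
        scale_sd = x.std(axis=0)
        scale_sd = np.where(scale_sd == 0, 1.0, scale_sd)
        x = (x - scale_mean) / scale_sd

    rng = np.random.default_rng(seed)
    trace: list[float] = []
    ladder: list[float] = []
    c = x.mean(axis=0, keepdims=True)
    _, dist = _assign_distortion(x, c)
    trace.append(dist)
    ladder.append(dist)
    while c.shape[0] < J:
        c = np.concatenate([c * (1 + epsilon), c * (1 - epsilon)], axis=0)
        c, dist = _lloyd(x, c, tol, max_iter, rng, trace)
        ladder.append(dist)
    return Codebook(
        code_vectors=c,
        training_distortion=dist,
        scale_mean=scale_mean,
        scale_sd=scale_sd,
        ladder_distortions=ladder,
        iteration_trace=trace,
    )


def encode(vectors: np.ndarray, codebook: Codebook) -> np.ndarray:
    """Index of the nearest code vector (squared Euclidean) for each vector.

    Ties resolve to the lowest index.
    """
    x = codebook.transform(vectors)
    return _sq_dists(x, codebook.code_vectors).argmin(axis=1)


def distortion(vectors: np.ndarray, codebook: Codebook) -> float:
    """Average distortion D of a vector set under a codebook."""
    x = codebook.transform(vectors)
    if x.shape[0] == 0:
        raise ValueError("empty vector set")
    _, dist = _assign_distortion(x, codebook.code_vectors)
    return dist
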