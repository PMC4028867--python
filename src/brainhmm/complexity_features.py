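"""Per-series complexity features: sample entropy, regularity dimension, semivariogram.

A cortical boundary distance series is treated as a 1-D signal.  Its
irregularity is summarized two ways:

* **Sample entropy** (SampEn) — the negative log of the conditional
  probability that two subsequences that match for ``m`` points (within a
  tolerance ``r``, Chebyshev distance, self-matches excluded) still match
  when extended by one point.  Lower values mean a more regular signal.
* **Regularity dimension** — the rate at which SampEn grows with
  ``log(1/r)`` as the tolerance shrinks.  It is realized here as a local
  least-squares slope of the SampEn profile over a descending tolerance
  grid, giving a fixed-length feature vector per slice.
* **Semivariogram** — half the average squared difference of series values
  separated by lag ``h`` (in boundary-traversal index steps), capturing the
  spatial autocorrelation structure of the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_R_GRID",
    "FeatureError",
    "SampEnParams",
    "RegularityProfile",
    "SemivariogramProfile",
    "sample_entropy",
    "sample_entropy_profile",
    "local_slopes",
    "regularity_profile",
    "semivariogram",
]

#: Descending tolerance grid, 1.0 down to 0.05 in steps of 0.05 (20 values),
#: in units of the standardized series' standard deviation.
DEFAULT_R_GRID = np.round(np.arange(20, 0, -1) * 0.05, 2)


class FeatureError(ValueError):
    """A series cannot yield a usable feature vector."""


@dataclass(frozen=True)
class SampEnParams:
    """Sample-entropy parameters.

    ``m`` is the embedding (template) length, ``r`` the match tolerance in
    units of the standardized series' standard deviation.
    """

    m: int = 2
    r: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _template_chebyshev(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Chebyshev distances between templates of length m and m+1.

    Both matrices are indexed over the N-m templates starting at
    0..N-m-1 (the standard convention, so the m- and (m+1)-length counts
    run over the same template set).
    """
    n = x.size
    n_templates = n - m
    d = np.abs(x[:, None] - x[None, :])
    dm = d[:n_templates, :n_templates].copy()
    for k in range(1, m):
        np.maximum(dm, d[k : k + n_templates, k : k + n_templates], out=dm)
    dm1 = np.maximum(dm, d[m : m + n_templates, m : m + n_templates])
    return dm, dm1


def sample_entropy(
    series: np.ndarray,
    m: int = 2,
    r: float = 0.2,
    standardize: bool = True,
) -> float:
    """SampEn(m, r, N) = -ln(A^m(r) / B^m(r)).

    ``B`` counts ordered template pairs (i != j) of length ``m`` whose
    Chebyshev distance is <= ``r``; ``A`` counts the same for length
    ``m + 1``.  Returns ``nan`` ("undefined") when either count is zero or
    the series is shorter than ``m + 2``.
    """
    x = np.asarray(series, dtype=float)
    if x.size <= m + 1:
        return float("nan")
    if standardize:
        x = _standardize(x)
    dm, dm1 = _template_chebyshev(x, m)
    n_templates = dm.shape[0]
    # ordered pairs, self-matches excluded
    b = int((dm <= r).sum()) - n_templates
    a = int((dm1 <= r).sum()) - n_templates
    if a == 0 or b == 0:
        return float("nan")
    return -np.log(a / b)


def sample_entropy_profile(
    series: np.ndarray, m: int = 2, r_grid: np.ndarray = DEFAULT_R_GRID
) -> np.ndarray:
    """SampEn evaluated on a tolerance grid, sharing one distance computation."""
    x = np.asarray(series, dtype=float)
    r_grid = np.asarray(r_grid, dtype=float)
    if x.size <= m + 1:
        return np.full(r_grid.size, np.nan)
    x = _standardize(x)
    dm, dm1 = _template_chebyshev(x, m)
    n_templates = dm.shape[0]
    out = np.empty(r_grid.size)
    for k, r in enumerate(r_grid):
        b = int((dm <= r).sum()) - n_templates
        a = int((dm1 <= r).sum()) - n_templates
        out[k] = -np.log(a / b) if (a > 0 and b > 0) else np.nan
    return out


def local_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares slope of y against x over every 3-point sliding window.

    Returns one slope per interior point of ``x`` (length ``len(x) - 2``).
    Windows containing non-finite y yield ``nan``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a sliding slope")
    slopes = np.empty(x.size - 2)
    for k in range(1, x.size - 1):
        xw = x[k - 1 : k + 2]
        yw = y[k - 1 : k + 2]
        if not np.all(np.isfinite(yw)):
            slopes[k - 1] = np.nan
            continue
        xc = xw - xw.mean()
        slopes[k - 1] = (xc @ (yw - yw.mean())) / (xc @ xc)
    return slopes


@dataclass
class RegularityProfile:
    """Regularity-dimension feature vector for one series.

    ``sampen_values`` holds the raw SampEn profile over ``r_grid`` (``nan``
    where undefined); ``sampen_filled`` carries the last finite value into
    undefined entries so downstream vector quantization sees a fixed-length
    vector; ``dr_values`` are 3-point sliding-window slopes of SampEn
    against ``log(1/r)`` at the interior grid points, computed from the
    filled profile; ``dr_finite`` marks slopes whose full window was
    genuinely finite; ``imputed`` flags whether any carrying occurred.
    """

    r_grid: np.ndarray
    sampen_values: np.ndarray
    sampen_filled: np.ndarray
    dr_values: np.ndarray
    dr_finite: np.ndarray
    imputed: bool = False


def regularity_profile(
    series: np.ndarray, m: int = 2, r_grid: np.ndarray = DEFAULT_R_GRID
) -> RegularityProfile:
    """SampEn profile over a descending tolerance grid plus local slopes.

    Raises :class:`FeatureError` when fewer than 3 grid points have a
    finite SampEn (the slope windows would all be undefined).
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if r_grid.size < 3:
        raise FeatureError("r_grid must have at least 3 values")
    if np.any(r_grid <= 0) or np.any(np.diff(r_grid) >= 0):
        raise FeatureError("r_grid must be strictly descending and positive")
    raw = sample_entropy_profile(series, m=m, r_grid=r_grid)
    finite = np.isfinite(raw)
    if finite.sum() < 3:
        raise FeatureError(
            f"only {int(finite.sum())} finite SampEn values on the grid; need >= 3"
        )
    filled = raw.copy()
    # carry the last finite value toward small r (grid is descending)
    last = None
    for k in range(filled.size):
        if np.isfinite(filled[k]):
            last = filled[k]
        elif last is not None:
            filled[k] = last
    # leading undefined entries (before any finite value) take the first finite
    first = filled[np.isfinite(filled)][0]
    filled[~np.isfinite(filled)] = first
    log_inv_r = np.log(1.0 / r_grid)
    dr = local_slopes(log_inv_r, filled)
    dr_finite = np.array(
        [finite[k - 1 : k + 2].all() for k in range(1, r_grid.size - 1)]
    )
    return RegularityProfile(
        r_grid=r_grid,
        sampen_values=raw,
        sampen_filled=filled,
        dr_values=dr,
        dr_finite=dr_finite,
        imputed=bool((~finite).any()),
    )


@dataclass
class SemivariogramProfile:
    """Experimental semivariogram of one series over integer lags 1..K.

    gamma(h) = (1 / (2 N(h))) * sum_i (x_i - x_{i+h})^2 with N(h) = L - h
    (non-circular index-lag pairing, raw data units).
    """

    h_grid: np.ndarray
    gamma_values: np.ndarray
    pair_counts: np.ndarray
    truncated: bool = False


def semivariogram(series: np.ndarray, k_h: int = 100) -> SemivariogramProfile:
    """Experimental semivariogram over lags 1..k_h.

    If the series is too short for the requested maximum lag, the lag range
    is truncated to ``L - 1`` and the profile flagged; callers that need a
    fixed feature dimension should exclude truncated profiles.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise FeatureError(f"series of length {x.size} has no lag pairs")
    if k_h < 1:
        raise ValueError(f"k_h must be >= 1, got {k_h}")
    truncated = x.size <= k_h
    k = min(k_h, x.size - 1)
    h_grid = np.arange(1, k + 1)
    gamma = np.empty(k)
    counts = np.empty(k, dtype=int)
    for i, h in enumerate(h_grid):
        diff = x[h:] - x[:-h]
        counts[i] = diff.size
        gamma[i] = 0.5 * np.mean(diff * diff)
    return SemivariogramProfile(
        h_grid=h_grid, gamma_values=gamma, pair_counts=counts, truncated=truncated
    )
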