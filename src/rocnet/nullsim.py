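"""Brownian-bridge Monte Carlo nulls for the screening and network statistics.

Under independence of a factor and the disease label, the centred empirical
ROC process ``sqrt(n) * (R_hat(t) - t)`` converges to ``B1(t) +
sqrt(lambda) * B2(t)`` where ``B1``, ``B2`` are independent Brownian bridges
and ``lambda = n/m`` is the diseased-to-healthy sample-size ratio.  The
screening statistic ``S_A = sqrt(n)|AUC - 1/2|`` is the absolute integral of
that process, so its null distribution is simulated by drawing bridges on a
uniform grid; ``integral of B(t) dt`` is Gaussian with variance 1/12, hence
the exact null of ``S_A`` is half-normal with scale ``sqrt((1+lambda)/12)``
— a closed form the simulator is validated against.

For a pair of factors with equal population ROC curves, each estimated
curve deviates from the common curve by an independent copy of the limit
process scaled by ``1/sqrt(n)``; the null of the pairwise curve distance
(and of the correlation weight derived from it) is simulated from four
independent bridges, with the common baseline curve fixed at the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .roc import CORRELATION_FORMS, DISTANCE_METRICS, roc_correlation

_CHUNK = 2000  # bridge paths simulated per block to bound memory


@dataclass(frozen=True)
class BridgePath:
    """One Brownian-bridge sample path on a uniform grid over [0, 1]."""

    grid: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class NullSample:
    """Sorted Monte-Carlo draws of a statistic under its null.

    ``statistic`` is ``"s_a"`` for the screening statistic or ``"r_ij"``
    for the pairwise correlation weight; ``n_diseased`` applies to the
    latter only.
    """

    statistic: str
    lambda_ratio: float
    n_sim: int
    values: np.ndarray
    seed: int
    n_diseased: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size != self.n_sim:
            raise InvalidInputError("null sample must hold n_sim draws")
        if np.any(np.diff(vals) < 0):
            raise InvalidInputError("null draws must be sorted ascending")
        object.__setattr__(self, "values", vals)

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        """Interpolated quantile of the sorted draws, q in [0, 1]."""
        if np.any((np.asarray(q) < 0) | (np.asarray(q) > 1)):
            raise ConfigurationError("quantile level must lie in [0, 1]")
        out = np.quantile(self.values, q)
        return float(out) if np.isscalar(q) else out


def _bridge_block(n_paths: int, G: int, rng: np.random.Generator) -> np.ndarray:
    """(n_paths, G+1) bridge values: W(t_k) - t_k W(1), increments Var 1/G."""
    increments = rng.standard_normal((n_paths, G)) / np.sqrt(G)
    walk = np.cumsum(increments, axis=1)
    paths = np.empty((n_paths, G + 1))
    paths[:, 0] = 0.0
    paths[:, 1:] = walk
    t = np.arange(G + 1) / G
    paths -= t[None, :] * paths[:, -1][:, None]
    paths[:, -1] = 0.0  # exact endpoint despite rounding
    return paths


def simulate_bridge(G: int, rng_seed: int) -> BridgePath:
    """One Brownian bridge on ``G + 1`` equally spaced points of [0, 1].

    Built as ``B(t) = W(t) - t W(1)`` from a standard random walk with
    Gaussian increments of variance ``1/G``; endpoints are exactly zero and
    the same seed reproduces the same path bit-for-bit.
    """
    if G < 2:
        raise InvalidInputError(f"bridge grid needs G >= 2, got {G}")
    rng = np.random.default_rng(rng_seed)
    values = _bridge_block(1, G, rng)[0]
    return BridgePath(grid=np.arange(G + 1) / G, values=values)


def null_sa(
    lambda_ratio: float, n_sim: int = 1000, G: int = 1000, seed: int = 0
) -> NullSample:
    """Monte-Carlo null of the screening statistic ``S_A``.

    Each draw is ``|integral of (B1(t) + sqrt(lambda) B2(t)) dt|`` with the
    integral taken by the trapezoid rule on the grid.
    """
    if lambda_ratio <= 0 or n_sim < 1 or G < 2:
        raise InvalidInputError("lambda_ratio, n_sim and G must be positive (G >= 2)")
    rng = np.random.default_rng(seed)
    sqrt_lam = np.sqrt(lambda_ratio)
    draws = np.empty(n_sim)
    for start in range(0, n_sim, _CHUNK):
        stop = min(start + _CHUNK, n_sim)
        b1 = _bridge_block(stop - start, G, rng)
        b2 = _bridge_block(stop - start, G, rng)
        combined = b1 + sqrt_lam * b2
        draws[start:stop] = np.abs(np.trapezoid(combined, dx=1.0 / G, axis=1))
    return NullSample(
        statistic="s_a",
        lambda_ratio=float(lambda_ratio),
        n_sim=n_sim,
        values=np.sort(draws),
        seed=seed,
    )


def p_value(observed: float, null: NullSample, add_one: bool = False) -> float:
    """Monte-Carlo p-value: fraction of null draws at or above ``observed``.

    The raw exceedance fraction can be exactly 0; with ``add_one`` the
    positively biased estimate ``(1 + count) / (1 + n_sim)`` is returned
    instead, which never vanishes.
    """
    if not np.isfinite(observed) or observed < 0:
        raise InvalidInputError(f"observed statistic must be finite and nonnegative, got {observed}")
    count = null.n_sim - int(np.searchsorted(null.values, observed, side="left"))
    if add_one:
        return (1 + count) / (1 + null.n_sim)
    return count / null.n_sim


def null_rij(
    lambda_ratio: float,
    n_diseased: int,
    n_sim: int = 1000,
    G: int = 1000,
    seed: int = 0,
    metric: str = "l1",
    form: str = "inv1p",
) -> NullSample:
    """Monte-Carlo null of the pairwise correlation weight ``r_ij``.

    Under curve equality each factor's estimated ROC is the common curve
    plus ``delta(t) = (B_a(t) + sqrt(lambda) B_b(t)) / sqrt(n)`` with its
    own independent bridges, so the pairwise curve distance reduces to the
    distance between two independent such deviation processes on the grid;
    each draw maps through :func:`rocnet.roc.roc_correlation`.
    """
    if lambda_ratio <= 0 or n_diseased < 1 or n_sim < 1 or G < 2:
        raise InvalidInputError("lambda_ratio, n_diseased, n_sim and G must be positive (G >= 2)")
    if metric not in DISTANCE_METRICS:
        raise ConfigurationError(f"unknown ROC distance metric {metric!r}; choose from {DISTANCE_METRICS}")
    if form not in CORRELATION_FORMS:
        raise ConfigurationError(f"unknown correlation form {form!r}; choose from {CORRELATION_FORMS}")
    rng = np.random.default_rng(seed)
    sqrt_lam = np.sqrt(lambda_ratio)
    scale = 1.0 / np.sqrt(n_diseased)
    dists = np.empty(n_sim)
    for start in range(0, n_sim, _CHUNK):
        stop = min(start + _CHUNK, n_sim)
        k = stop - start
        delta_i = (_bridge_block(k, G, rng) + sqrt_lam * _bridge_block(k, G, rng)) * scale
        delta_j = (_bridge_block(k, G, rng) + sqrt_lam * _bridge_block(k, G, rng)) * scale
        diff = delta_i - delta_j
        if metric == "l1":
            d = np.trapezoid(np.abs(diff), dx=1.0 / G, axis=1)
        elif metric == "l2":
            d = np.sqrt(np.trapezoid(diff * diff, dx=1.0 / G, axis=1))
        elif metric == "sup":
            d = np.max(np.abs(diff), axis=1)
        else:  # auc_diff
            d = np.abs(np.trapezoid(diff, dx=1.0 / G, axis=1))
        dists[start:stop] = d
    draws = np.sort([roc_correlation(float(d), form) for d in dists])
    return NullSample(
        statistic="r_ij",
        lambda_ratio=float(lambda_ratio),
        n_sim=n_sim,
        values=draws,
        seed=seed,
        n_diseased=int(n_diseased),
    )


def edge_threshold(null: NullSample, beta: float, tail: str = "upper") -> float:
    """Quantile threshold for zeroing weak network edges.

    With the default ``tail="upper"`` the threshold is the ``(1 - beta)``
    quantile of the ``r_ij`` null, so shrinking ``beta`` raises the
    threshold and prunes the network harder.  ``tail="lower"`` returns the
    ``beta`` quantile instead, the retention-probability reading under
    which a pair with truly equal curves is kept with probability
    ``1 - beta``.
    """
    if not 0 < beta < 1:
        raise ConfigurationError(f"beta must lie strictly between 0 and 1, got {beta}")
    if tail not in ("upper", "lower"):
        raise ConfigurationError(f"tail must be 'upper' or 'lower', got {tail!r}")
    q = 1.0 - beta if tail == "upper" else beta
    return float(null.quantile(q))
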