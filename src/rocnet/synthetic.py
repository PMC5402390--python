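"""Two-group synthetic data with known structure, for testing every stage.

The generator emulates the structure of a two-group pollutant survey: ``k``
correlated factors measured in a diseased group of ``n`` samples and a
healthy group of ``m`` samples, with per-factor location shifts (0 marks a
null factor), optional block correlation through a Gaussian copula, heavy
tails, and sporadic gross outliers.  It is a test harness: it makes no
attempt to mimic actual pollutant concentration distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .errors import ConfigurationError

MARGINALS = ("normal", "lognormal", "t3")


def _marginal_dist(marginal: str):
    if marginal == "normal":
        return stats.norm()
    if marginal == "lognormal":
        return stats.lognorm(s=1.0)
    if marginal == "t3":
        return stats.t(df=3)
    raise ConfigurationError(f"unsupported marginal {marginal!r}; choose from {MARGINALS}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic two-group dataset.

    Parameters
    ----------
    k, n, m
        Number of factors, diseased-group size, healthy-group size.
    shifts
        Per-factor location shift added to the diseased group; length k.
    blocks
        Optional block label per factor (length k); factors sharing a label
        get pairwise copula correlation ``rho``.
    rho
        Within-block latent Gaussian correlation, |rho| < 1.
    marginal
        Base marginal law: ``normal``, ``lognormal`` (log-sd 1) or ``t3``.
    outlier_fraction
        Fraction of cells replaced by draws at 10x the marginal scale.
    seed
        Seed for the dedicated random stream.
    """

    k: int
    n: int
    m: int
    shifts: tuple = ()
    blocks: tuple | None = None
    rho: float = 0.0
    marginal: str = "normal"
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError(f"k must be >= 1, got {self.k}")
        if self.n < 2 or self.m < 2:
            raise ConfigurationError(f"group sizes n, m must be >= 2, got n={self.n}, m={self.m}")
        shifts = tuple(float(s) for s in (self.shifts or (0.0,) * self.k))
        if len(shifts) != self.k:
            raise ConfigurationError(f"shifts must have length k={self.k}, got {len(shifts)}")
        object.__setattr__(self, "shifts", shifts)
        if self.blocks is not None:
            blocks = tuple(self.blocks)
            if len(blocks) != self.k:
                raise ConfigurationError(f"blocks must have length k={self.k}, got {len(blocks)}")
            object.__setattr__(self, "blocks", blocks)
        if not abs(self.rho) < 1:
            raise ConfigurationError(f"rho must satisfy |rho| < 1, got {self.rho}")
        if self.marginal not in MARGINALS:
            raise ConfigurationError(f"unsupported marginal {self.marginal!r}; choose from {MARGINALS}")
        if not 0.0 <= self.outlier_fraction <= 0.2:
            raise ConfigurationError(
                f"outlier_fraction must lie in [0, 0.2], got {self.outlier_fraction}"
            )

    def correlation(self) -> np.ndarray:
        """Latent Gaussian correlation matrix implied by the block labels."""
        corr = np.eye(self.k)
        if self.blocks is not None and self.rho != 0.0:
            labels = np.asarray(self.blocks)
            same = labels[:, None] == labels[None, :]
            corr = np.where(same, self.rho, 0.0)
            np.fill_diagonal(corr, 1.0)
        return corr


def generate(spec: SyntheticSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Draw one dataset: (observations, labels) with diseased rows labelled 1.

    Healthy rows follow the base law (Gaussian copula with the block
    correlation, then the chosen marginal); diseased rows are the same law
    with factor j's location raised by ``shifts[j]``.  When
    ``outlier_fraction > 0`` that fraction of cells is replaced by
    independent draws from the centred marginal scaled by 10.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n + spec.m
    chol = np.linalg.cholesky(spec.correlation())
    z = rng.standard_normal((total, spec.k)) @ chol.T
    if spec.marginal == "normal":
        x = z
    else:
        dist = _marginal_dist(spec.marginal)
        x = dist.ppf(stats.norm.cdf(z))
    x[: spec.n] += np.asarray(spec.shifts)[None, :]
    if spec.outlier_fraction > 0.0:
        mask = rng.random((total, spec.k)) < spec.outlier_fraction
        x[mask] = 10.0 * _marginal_dist(spec.marginal).rvs(size=int(mask.sum()), random_state=rng)
    obs = pd.DataFrame(
        x,
        index=[f"S{i + 1}" for i in range(total)],
        columns=[f"F{j + 1}" for j in range(spec.k)],
    )
    labels = pd.Series(
        np.concatenate([np.ones(spec.n, dtype=int), np.zeros(spec.m, dtype=int)]),
        index=obs.index,
        name="label",
    )
    return obs, labels


def population_auc(marginal: str, delta: float) -> float:
    """P(U > V) for V from the base marginal and U the same law shifted by delta.

    Closed form ``Phi(delta / sqrt(2))`` for the normal marginal; numeric
    integration otherwise (the marginals are continuous, so ties carry no
    mass).
    """
    if marginal == "normal":
        return float(stats.norm.cdf(delta / np.sqrt(2.0)))
    dist = _marginal_dist(marginal)
    lo, hi = dist.support()
    val, _ = integrate.quad(lambda y: dist.pdf(y) * dist.sf(y - delta), lo, hi)
    return float(val)
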