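"""Multi-factor screening: per-factor AUC tests plus parametric baselines.

The screen computes, for every factor column, the empirical AUC, the
statistic ``S_A = sqrt(n)|AUC - 1/2|`` and a Monte-Carlo p-value against the
Brownian-bridge null.  All factors in one dataset share the same group
sizes, hence the same ``lambda = n/m``, so a single simulated null sample is
drawn once and reused across factors.

Two comparators the method is usually benchmarked against are included:
one-factor-at-a-time logistic regression (Wald test on the slope) and the
absolute Pearson correlation matrix with a significance-test cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .errors import InvalidInputError
from .nullsim import NullSample, null_sa, p_value
from .roc import TwoGroupSample, auc, empirical_roc

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningTable:
    """Per-factor screening results at significance level ``alpha``.

    ``frame`` has one row per factor, input order preserved, with columns
    ``factor, auc, s_a, p_value, significant``.
    """

    frame: pd.DataFrame
    alpha: float
    null: NullSample

    @property
    def significant_factors(self) -> list[str]:
        return self.frame.loc[self.frame["significant"], "factor"].tolist()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def split_groups(data: pd.DataFrame, labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the observation table into diseased (label 1) and healthy (label 0)."""
    lab = np.asarray(labels)
    if lab.shape[0] != data.shape[0]:
        raise InvalidInputError(
            f"labels length {lab.shape[0]} does not match {data.shape[0]} samples"
        )
    if not set(np.unique(lab)) <= {0, 1}:
        raise InvalidInputError(f"labels must be binary 0/1, found values {sorted(set(lab))}")
    if len(np.unique(lab)) < 2:
        raise InvalidInputError("single-class labels: both diseased (1) and healthy (0) samples are required")
    return data.loc[lab == 1], data.loc[lab == 0]


def _numeric_column(data: pd.DataFrame, name: str) -> np.ndarray:
    col = data[name]
    if not np.issubdtype(col.dtype, np.number):
        raise InvalidInputError(f"factor column {name!r} is not numeric")
    return col.to_numpy(dtype=float)


def screen_factors(
    data: pd.DataFrame,
    labels,
    alpha: float = 0.05,
    n_sim: int = 1000,
    G: int = 1000,
    seed: int = 0,
    null: NullSample | None = None,
    bh_correction: bool = False,
) -> ScreeningTable:
    """Screen every factor column for association with the disease label.

    One null sample of ``S_A`` at ``lambda = n/m`` is simulated (or taken
    from ``null``) and shared by all factors.  ``significant`` flags
    ``p_value < alpha``; with ``bh_correction`` the flag is based on
    Benjamini-Hochberg adjusted p-values instead (the raw p-values are
    still reported).
    """
    diseased, healthy = split_groups(data, labels)
    lam = diseased.shape[0] / healthy.shape[0]
    if null is None:
        null = null_sa(lam, n_sim=n_sim, G=G, seed=seed)
    elif not np.isclose(null.lambda_ratio, lam):
        raise InvalidInputError(
            f"null sample simulated at lambda={null.lambda_ratio} does not match data lambda={lam}"
        )
    rows = []
    for name in data.columns:
        sample = TwoGroupSample(
            factor_name=str(name),
            diseased_values=_numeric_column(diseased, name),
            healthy_values=_numeric_column(healthy, name),
        )
        a = auc(empirical_roc(sample))
        s_a = float(np.sqrt(sample.n) * abs(a - 0.5))
        rows.append((str(name), a, s_a, p_value(s_a, null)))
    frame = pd.DataFrame(rows, columns=["factor", "auc", "s_a", "p_value"])
    if bh_correction:
        frame["significant"] = multipletests(frame["p_value"], alpha=alpha, method="fdr_bh")[0]
    else:
        frame["significant"] = frame["p_value"] < alpha
    return ScreeningTable(frame=frame, alpha=alpha, null=null)


def univariate_logistic_baseline(data: pd.DataFrame, labels, alpha: float = 0.05) -> list[str]:
    """Factors selected by one-covariate logistic regressions at level alpha.

    Each factor is regressed on its own against the binary label; a factor
    is selected when the slope's two-sided Wald p-value falls below alpha.
    Non-convergent fits (typically perfect separation) are logged and left
    unselected.
    """
    diseased, healthy = split_groups(data, labels)  # validates labels
    y = np.asarray(labels, dtype=float)
    selected = []
    for name in data.columns:
        x = sm.add_constant(_numeric_column(data, name))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                warnings.simplefilter("error", RuntimeWarning)
                fit = sm.Logit(y, x).fit(disp=0)
            if not fit.mle_retvals.get("converged", False):
                raise PerfectSeparationError("logistic fit did not converge")
            if fit.pvalues[1] < alpha:
                selected.append(str(name))
        except (PerfectSeparationError, PerfectSeparationWarning, RuntimeWarning,
                np.linalg.LinAlgError) as exc:
            logger.warning("logistic fit failed for factor %r (%s); left unselected", name, exc)
    return selected


def pearson_adjacency(data: pd.DataFrame, level: float = 0.05) -> pd.DataFrame:
    """Absolute Pearson correlation matrix with a significance cutoff.

    Correlations are pooled over all samples; entries whose two-sided
    correlation-test p-value is at or above ``level`` are zeroed, as is the
    diagonal.  Zero-variance columns are zeroed entirely with a warning.
    """
    if data.shape[0] < 3:
        raise InvalidInputError("Pearson adjacency requires at least 3 samples")
    names = [str(c) for c in data.columns]
    x = np.column_stack([_numeric_column(data, c) for c in data.columns])
    k = x.shape[1]
    out = np.zeros((k, k))
    constant = np.std(x, axis=0) == 0
    for j in np.nonzero(constant)[0]:
        warnings.warn(f"factor {names[j]!r} has zero variance; its correlations are zeroed")
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            r, p = stats.pearsonr(x[:, i], x[:, j])
            if p < level:
                out[i, j] = out[j, i] = abs(r)
    return pd.DataFrame(out, index=names, columns=names)
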