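"""Two-group differential expression on normalized feature-by-sample matrices.

The central object is :class:`ExpressionMatrix`: a features x samples table of
normalized expression values together with a sample -> group mapping for a
two-group design (a "case" group, e.g. lesions that progressed to cancer, and
a "control" group that did not).  Differential expression is scored per
feature with a two-sample t-test; the full vector of signed t-scores is kept
because downstream module scoring averages t over module members regardless
of individual significance.

Probe-level matrices are collapsed to features by averaging probe rows, and
missing values can be filled by row means or by a k-nearest-rows scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"


@dataclass
class ExpressionMatrix:
    """Normalized expression values plus a sample-group annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Features x samples matrix.  The index holds feature identifiers
        (gene symbols or miRNA names), columns hold sample identifiers.
    groups : pandas.Series
        Maps each sample identifier to its group label.  Exactly the
        samples in ``values.columns`` must be covered.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        self.validate()

    def validate(self, require_complete: bool = False) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise InputError(f"duplicate feature identifiers: {list(dupes)[:5]}")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate sample identifiers")
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()]
            raise InputError(f"samples without a group label: {list(missing)[:5]}")
        if require_complete and self.values.isna().any().any():
            raise InputError("matrix contains missing values; impute first")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, label: str) -> list[str]:
        """Sample identifiers belonging to group ``label``."""
        return list(self.groups.index[self.groups == label])


def collapse_probes(
    matrix: ExpressionMatrix, probe_to_feature: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to features by averaging probe rows.

    Probes absent from the map are dropped (the count is logged).  Each
    feature row is the arithmetic mean of all probe rows mapped to it.
    """
    mapped = matrix.values.index.intersection(pd.Index(probe_to_feature.keys()))
    if len(mapped) == 0:
        raise InputError("no probe in the matrix appears in the probe-to-feature map")
    n_dropped = len(matrix.values.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = matrix.values.loc[mapped]
    features = pd.Index([probe_to_feature[p] for p in mapped], name="feature_id")
    collapsed = sub.groupby(features).mean()
    return ExpressionMatrix(values=collapsed, groups=matrix.groups)


def impute_missing(
    matrix: ExpressionMatrix, method: str = "mean", k: int = 10
) -> ExpressionMatrix:
    """Fill missing cells by row means or by averaging the k nearest rows.

    ``method='mean'`` replaces each missing cell with the mean of the row's
    observed cells.  ``method='knn'`` replaces it with the mean of the same
    cell in the ``k`` rows nearest by Euclidean distance over co-observed
    columns (distance normalized by the number of shared columns so rows
    with different overlap are comparable); only rows observed at the target
    column are candidate neighbors.
    """
    values = matrix.values
    fully_missing = values.index[values.isna().all(axis=1)]
    if len(fully_missing):
        raise InputError(
            f"features with no observed values cannot be imputed: {list(fully_missing)}"
        )
    if not values.isna().any().any():
        return matrix
    if method == "mean":
        row_means = values.mean(axis=1)
        filled = values.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    elif method == "knn":
        filled = _impute_knn(values, k)
    else:
        raise ConfigurationError(f"unknown imputation method: {method!r}")
    return ExpressionMatrix(values=filled, groups=matrix.groups)


def _impute_knn(values: pd.DataFrame, k: int) -> pd.DataFrame:
    if k < 1:
        raise ConfigurationError("k must be >= 1 for knn imputation")
    X = values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    out = X.copy()
    n = X.shape[0]
    for i in range(n):
        missing_cols = np.where(~obs[i])[0]
        if missing_cols.size == 0:
            continue
        # mean squared difference over co-observed columns, per candidate row
        dists = np.full(n, np.inf)
        for j in range(n):
            if j == i:
                continue
            shared = obs[i] & obs[j]
            if not shared.any():
                continue
            diff = X[i, shared] - X[j, shared]
            dists[j] = float(np.mean(diff * diff))
        for col in missing_cols:
            candidates = np.where(obs[:, col] & np.isfinite(dists))[0]
            if candidates.size == 0:
                out[i, col] = np.nanmean(X[i])  # fall back to the row mean
                continue
            order = candidates[np.argsort(dists[candidates], kind="stable")]
            nearest = order[:k]
            out[i, col] = float(np.mean(X[nearest, col]))
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def differential_test(
    matrix: ExpressionMatrix,
    case: str,
    control: str,
    alpha: float = 0.01,
    variant: str = "pooled",
    correction: str | None = None,
) -> pd.DataFrame:
    """Per-feature two-sample t-test of ``case`` versus ``control`` samples.

    The sign convention is fixed: ``t_score > 0`` means the feature is higher
    in the case group, reported as direction ``up``.  ``variant='pooled'``
    is the classical equal-variance Student test; ``variant='welch'`` drops
    the equal-variance assumption.  No multiple-testing correction is applied
    by default; ``correction='bh'`` adds Benjamini-Hochberg q-values and
    bases ``is_significant`` on them.

    Features whose two groups are both constant cannot be tested: they are
    flagged ``degenerate`` and assigned t = signed infinity with P = 0 when
    the group means differ, and t = 0 with P = 1 when they are equal.

    Returns
    -------
    pandas.DataFrame
        Indexed by feature, with columns ``t_score``, ``p_value``,
        ``direction``, ``is_significant`` and ``degenerate`` (plus
        ``q_value`` under BH correction).  Every feature is retained.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0,1), got {alpha}")
    if variant not in ("pooled", "welch"):
        raise ConfigurationError(f"unknown t-test variant: {variant!r}")
    matrix.validate(require_complete=True)
    case_samples = matrix.group_samples(case)
    control_samples = matrix.group_samples(control)
    for label, samples in ((case, case_samples), (control, control_samples)):
        if len(samples) < 2:
            raise InputError(f"group {label!r} has {len(samples)} samples; need >= 2")

    X = matrix.values[case_samples].to_numpy(dtype=float)
    Y = matrix.values[control_samples].to_numpy(dtype=float)
    res = stats.ttest_ind(X, Y, axis=1, equal_var=(variant == "pooled"))
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    mean_diff = X.mean(axis=1) - Y.mean(axis=1)
    degenerate = (X.var(axis=1) == 0) & (Y.var(axis=1) == 0)
    if degenerate.any():
        differs = degenerate & (mean_diff != 0)
        equal = degenerate & (mean_diff == 0)
        t[differs] = np.sign(mean_diff[differs]) * np.inf
        p[differs] = 0.0
        t[equal] = 0.0
        p[equal] = 1.0

    out = pd.DataFrame(
        {
            "t_score": t,
            "p_value": p,
            "direction": np.where(t < 0, DOWN, UP),
            "degenerate": degenerate,
        },
        index=matrix.feature_ids.rename("feature_id"),
    )
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        out["is_significant"] = out["q_value"] < alpha
    elif correction is None:
        out["is_significant"] = out["p_value"] < alpha
    else:
        raise ConfigurationError(f"unknown correction: {correction!r}")
    n_sig = int(out["is_significant"].sum())
    logger.info(
        "differential_test: %d/%d features significant at alpha=%g (%s)",
        n_sig, len(out), alpha, variant,
    )
    return out
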