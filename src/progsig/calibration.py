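"""Population-based risk groups and score standardization.

Published risk-group cutoffs do not transfer across platforms or
normalizations, so groups are recalibrated on the studied cohort: a
fixed proportion of the population is assigned to each risk group via
empirical quantile cutoffs, optionally per stratum (e.g. separate ER+
and ER- cutoffs). Standardization puts a score on unit-SD scale over
exactly the sample set entering a model fit, so hazard ratios read as
"per one standard deviation".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

GLOBAL_CONTEXT = "__all__"


def _type1_quantile(sorted_vals: np.ndarray, p: float) -> float:
    """Nearest-rank (type-1) empirical quantile: the ceil(n*p)-th order statistic."""
    n = len(sorted_vals)
    k = max(int(np.ceil(n * p)), 1)
    return float(sorted_vals[k - 1])


def percentile_cutoffs(
    scores: pd.Series,
    proportions: Sequence[float],
    stratum_labels: pd.Series | None = None,
) -> dict[str, list[float]]:
    """Quantile cutoffs putting the requested proportion in each group.

    ``proportions`` are ordered low-risk to high-risk and must sum to 1.
    Nearest-rank quantiles make group counts exact integers on distinct
    scores. With ``stratum_labels``, cutoffs are computed separately per
    stratum; otherwise a single context keyed :data:`GLOBAL_CONTEXT`.
    """
    proportions = list(proportions)
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError(f"proportions must sum to 1, got {sum(proportions)}")
    if any(p <= 0 for p in proportions):
        raise ValueError("each group proportion must be positive")
    scores = scores.dropna()
    if stratum_labels is None:
        contexts = {GLOBAL_CONTEXT: scores}
    else:
        labels = stratum_labels.reindex(scores.index)
        contexts = {str(s): scores[labels == s] for s in labels.dropna().unique()}
    out: dict[str, list[float]] = {}
    for ctx, vals in contexts.items():
        arr = np.sort(vals.to_numpy(dtype=float))
        if len(arr) == 0 or arr[0] == arr[-1]:
            raise ValueError(f"scores degenerate (all identical) in context {ctx!r}")
        cum = np.cumsum(proportions)[:-1]
        out[ctx] = [_type1_quantile(arr, p) for p in cum]
    return out


@dataclass
class RiskGroupAssignment:
    """Risk-group label per sample plus the cutoffs that produced them."""

    labels: pd.Series  # group label per sample (pd.NA where unscorable)
    cutoffs: dict[str, list[float]]
    group_order: list[str]  # low -> high risk
    context: str  # "cohort" or the stratum column used

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.group_order, fill_value=0)

    def write(self, path, *, sep: str = "\t") -> None:
        self.labels.rename("risk_group").to_csv(path, sep=sep, index_label="sample_id")


def assign_groups(
    scores: pd.Series,
    cutoffs: dict[str, list[float]] | Sequence[float],
    labels: Sequence[str],
    stratum_labels: pd.Series | None = None,
) -> RiskGroupAssignment:
    """Assign ordered risk-group labels given ascending cutoffs.

    A score <= the first cutoff gets the first (lowest-risk) label; ties
    at a cutoff deterministically go to the lower-risk group. With
    per-stratum cutoffs, each sample is binned by its own stratum's
    cutoffs.
    """
    if not isinstance(cutoffs, dict):
        cutoffs = {GLOBAL_CONTEXT: list(cutoffs)}
    labels = list(labels)
    for ctx, cuts in cutoffs.items():
        if len(labels) != len(cuts) + 1:
            raise ValueError(
                f"context {ctx!r}: {len(labels)} labels require {len(labels) - 1} cutoffs, "
                f"got {len(cuts)}"
            )
        if any(cuts[i] > cuts[i + 1] for i in range(len(cuts) - 1)):
            raise ValueError(f"context {ctx!r}: cutoffs must be ascending")

    out = pd.Series(pd.NA, index=scores.index, dtype=object)
    for sid, val in scores.items():
        if pd.isna(val):
            continue
        if stratum_labels is None:
            ctx = GLOBAL_CONTEXT
        else:
            ctx = stratum_labels.get(sid)
            if ctx is None or pd.isna(ctx) or str(ctx) not in cutoffs:
                continue
            ctx = str(ctx)
        cuts = cutoffs[ctx]
        idx = int(np.searchsorted(np.asarray(cuts), val, side="left"))
        out.loc[sid] = labels[idx]
    context = "cohort" if stratum_labels is None else "stratified"
    return RiskGroupAssignment(out, dict(cutoffs), labels, context)


def standardize(scores: pd.Series, context_mask: pd.Series | None = None) -> pd.Series:
    """Center and scale to unit sample SD over the context samples.

    The context is the exact sample set entering the subsequent model
    fit (e.g. the ER+ samples at risk in one follow-up interval); SD is
    the ddof=1 sample standard deviation. Samples outside the context
    are returned as NaN.
    """
    if context_mask is not None:
        mask = context_mask.reindex(scores.index).fillna(False).astype(bool)
    else:
        mask = pd.Series(True, index=scores.index)
    vals = scores[mask].dropna()
    if vals.nunique() < 2:
        raise ValueError("cannot standardize: fewer than 2 distinct scores in context")
    mu, sd = float(vals.mean()), float(vals.std(ddof=1))
    out = pd.Series(np.nan, index=scores.index, dtype=float)
    out[vals.index] = (vals - mu) / sd
    return out
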