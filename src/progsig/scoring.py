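"""Continuous risk scores and subtype calls for every signature archetype.

All scorers return per-sample scores oriented so that a higher score
means higher risk (the definition's ``risk_direction`` is applied), and
handle missing expression pairwise: correlations drop missing genes per
sample, weighted sums renormalize weights over the observed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix
from .signatures import MappedSignature, SignatureDefinition, map_signature

CorrMethod = Literal["pearson", "spearman"]

MIN_SHARED_GENES = 3


def _corr_with_centroids(
    x: np.ndarray, centroids: np.ndarray, method: CorrMethod
) -> np.ndarray:
    """Correlate one sample vector (len g, may contain NaN) with each centroid column."""
    out = np.full(centroids.shape[1], np.nan)
    for k in range(centroids.shape[1]):
        c = centroids[:, k]
        mask = ~np.isnan(x) & ~np.isnan(c)
        if mask.sum() < MIN_SHARED_GENES:
            continue
        xv, cv = x[mask], c[mask]
        if method == "spearman":
            xv, cv = rankdata(xv), rankdata(cv)
        xv = xv - xv.mean()
        cv = cv - cv.mean()
        denom = np.sqrt((xv**2).sum() * (cv**2).sum())
        if denom == 0:
            continue
        out[k] = float(np.clip((xv * cv).sum() / denom, -1.0, 1.0))
    return out


def centroid_correlations(
    expr: ExpressionMatrix,
    mapped: MappedSignature,
    method: CorrMethod | None = None,
) -> pd.DataFrame:
    """Per-sample correlation to each class centroid (samples x classes).

    Computed on the signature's matched genes only; genes missing in a
    sample are dropped pairwise, and a sample sharing fewer than
    3 genes with a centroid gets a missing correlation.
    """
    sig = mapped.definition
    if method is None:
        method = sig.subtype_correlation
    classes = sig.class_order
    genes = [g for g in mapped.matched if g in sig.centroids[classes[0]]]
    centroid_mat = np.array(
        [[sig.centroids[cls][g] for cls in classes] for g in genes], dtype=float
    )
    X = expr.values.reindex(genes).to_numpy()  # genes x samples
    rows = [_corr_with_centroids(X[:, j], centroid_mat, method) for j in range(X.shape[1])]
    return pd.DataFrame(rows, index=expr.sample_ids, columns=classes)


def classify_nearest_centroid(
    correlations: pd.DataFrame, *, ambiguity_margin: float = 1e-8
) -> pd.DataFrame:
    """Assign each sample the class with the highest centroid correlation.

    Ties (margin below ``ambiguity_margin``) break to the first class in
    declared order and are flagged ``ambiguous``. Samples with no valid
    correlation are called ``unknown``.
    """
    calls, ambiguous = [], []
    vals = correlations.to_numpy()
    classes = list(correlations.columns)
    for row in vals:
        if np.isnan(row).all():
            calls.append("unknown")
            ambiguous.append(False)
            continue
        best = int(np.nanargmax(row))
        calls.append(classes[best])
        others = np.delete(row, best)
        margin = row[best] - np.nanmax(others) if others.size and not np.isnan(others).all() else np.inf
        ambiguous.append(bool(margin < ambiguity_margin))
    return pd.DataFrame(
        {"call": calls, "ambiguous": ambiguous}, index=correlations.index
    )


def ror_linear(correlations: pd.DataFrame, coefficients: dict[str, float]) -> pd.Series:
    """Risk-of-relapse score: linear combination of centroid correlations."""
    if set(coefficients) != set(correlations.columns):
        raise ValueError(
            f"coefficient classes {sorted(coefficients)} do not match "
            f"correlation classes {sorted(correlations.columns)}"
        )
    coef = np.array([coefficients[c] for c in correlations.columns])
    return pd.Series(correlations.to_numpy() @ coef, index=correlations.index)


def centroid_risk(
    expr: ExpressionMatrix,
    mapped: MappedSignature,
    method: CorrMethod | None = None,
) -> pd.Series:
    """Risk score from correlation to a reference (good-prognosis) centroid.

    ``risk_direction = -1`` reverses the correlation so that samples most
    similar to the good-prognosis profile get the lowest score.
    """
    sig = mapped.definition
    corr = centroid_correlations(expr, mapped, method or sig.ror_correlation)
    return sig.risk_direction * corr[sig.reference_class]


def _entries_for_stratum(sig: SignatureDefinition, stratum: Optional[str]):
    return [
        g
        for g in sig.genes
        if not g.is_reference and (g.stratum is None or g.stratum == stratum)
    ]


def weighted_sum(
    expr: ExpressionMatrix,
    mapped: MappedSignature,
    stratum_labels: pd.Series | None = None,
) -> pd.Series:
    """Weighted sum of gene expression, per sample.

    For stratified definitions (different gene sets per patient
    stratum), each sample is scored with its own stratum's genes;
    samples with no stratum label get a missing score. When some of a
    sample's genes are unobserved, the sum over observed genes is
    rescaled by total/observed absolute weight so scores stay on a
    comparable scale.
    """
    sig = mapped.definition
    matched = set(mapped.matched)
    out = pd.Series(np.nan, index=expr.sample_ids, dtype=float)
    if sig.stratified and stratum_labels is None:
        raise ValueError(f"signature {sig.name!r} is stratified but no stratum labels given")

    strata: pd.Series
    if stratum_labels is None:
        strata = pd.Series(None, index=expr.sample_ids, dtype=object)
    else:
        strata = stratum_labels.reindex(expr.sample_ids)

    cache: dict[object, tuple[list[str], np.ndarray]] = {}
    for sid in expr.sample_ids:
        stratum = strata.loc[sid]
        if sig.stratified and (stratum is None or pd.isna(stratum)):
            continue
        key = stratum if not pd.isna(stratum) else None
        if key not in cache:
            entries = [g for g in _entries_for_stratum(sig, key) if g.gene_id in matched]
            cache[key] = (
                [g.gene_id for g in entries],
                np.array([g.weight for g in entries], dtype=float),
            )
        genes, weights = cache[key]
        if not genes:
            continue
        x = expr.values.loc[genes, sid].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        if not obs.any():
            continue
        total_w = np.abs(weights).sum()
        obs_w = np.abs(weights[obs]).sum()
        if total_w == 0:
            out.loc[sid] = 0.0
            continue
        if obs_w == 0:
            continue
        out.loc[sid] = float((weights[obs] * x[obs]).sum() * (total_w / obs_w))
    return out


def difference_of_means(
    expr: ExpressionMatrix,
    mapped: MappedSignature,
    *,
    rescale: bool = True,
) -> pd.Series:
    """Mean(up-set) - mean(down-set) per sample, optionally range-rescaled.

    The raw contrast depends on the platform's intensity scale, so by
    default the cohort's raw scores are linearly mapped onto [-1, +1]
    around the cohort midpoint (an invariant scale, genomic-grade-index
    style); the applied offset/scale is recorded in ``.attrs``.
    """
    sig = mapped.definition
    matched = set(mapped.matched)
    up = [g.gene_id for g in sig.genes if g.group == "up" and g.gene_id in matched]
    down = [g.gene_id for g in sig.genes if g.group == "down" and g.gene_id in matched]
    if not up or not down:
        raise ValueError(
            f"signature {sig.name!r}: empty {'up' if not up else 'down'}-set after mapping"
        )
    up_mean = expr.values.loc[up].mean(axis=0, skipna=True)
    down_mean = expr.values.loc[down].mean(axis=0, skipna=True)
    raw = (up_mean - down_mean).astype(float)
    raw.index = expr.sample_ids
    if not rescale:
        return raw
    lo, hi = float(raw.min()), float(raw.max())
    mid, half = (hi + lo) / 2.0, (hi - lo) / 2.0
    scaled = (raw - mid) / half if half > 0 else raw * 0.0
    scaled.attrs["rescale"] = {"midpoint": mid, "half_range": half}
    return scaled


def grouped_threshold(expr: ExpressionMatrix, mapped: MappedSignature) -> pd.Series:
    """Unscaled recurrence-score style evaluation.

    Per sample: (1) subtract the mean of the reference genes (when the
    definition declares any) from every gene value, (2) average each
    group's member genes, (3) clip group values to their declared
    bounds, (4) score = intercept + sum of weight x group value.
    """
    sig = mapped.definition
    matched = set(mapped.matched)
    ref_genes = [g.gene_id for g in sig.genes if g.is_reference and g.gene_id in matched]
    members: dict[str, list[str]] = {}
    for g in sig.genes:
        if g.is_reference or g.gene_id not in matched:
            continue
        members.setdefault(g.group, []).append(g.gene_id)
    for grp in sig.groups:
        if not members.get(grp):
            raise ValueError(f"signature {sig.name!r}: group {grp!r} has no mapped genes")

    vals = expr.values
    if ref_genes:
        ref_mean = vals.loc[ref_genes].mean(axis=0, skipna=True)
        vals = vals - ref_mean  # broadcast over genes
    score = pd.Series(sig.intercept, index=expr.sample_ids, dtype=float)
    for grp, spec in sig.groups.items():
        gval = vals.loc[members[grp]].mean(axis=0, skipna=True).astype(float)
        if spec.clip_low is not None:
            gval = gval.clip(lower=spec.clip_low)
        if spec.clip_high is not None:
            gval = gval.clip(upper=spec.clip_high)
        score = score + spec.weight * gval
    score.index = expr.sample_ids
    return score


@dataclass
class ScoreTable:
    """Per-sample continuous risk scores, one column per signature.

    ``subtype_calls`` and ``correlations`` are filled for
    ``centroid_subtype`` signatures; ``status`` records per-signature
    success or the failure reason (partial results are allowed).
    """

    scores: pd.DataFrame  # index sample_id, columns signature names
    subtype_calls: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return self.scores.index.tolist()

    @property
    def signatures(self) -> list[str]:
        return self.scores.columns.tolist()

    def write(self, path: str | Path, *, sep: str = "\t") -> None:
        out = self.scores.copy()
        for col in self.subtype_calls.columns:
            out[f"subtype:{col}"] = self.subtype_calls[col]
        out.to_csv(path, sep=sep, index_label="sample_id", na_rep="NA")


def score_signature(
    expr: ExpressionMatrix,
    mapped: MappedSignature,
    stratum_labels: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series | None, pd.DataFrame | None]:
    """Dispatch one mapped signature to its archetype scorer.

    Returns (oriented score, subtype call or None, centroid correlations
    or None).
    """
    sig = mapped.definition
    if sig.archetype == "centroid_subtype":
        corr_sub = centroid_correlations(expr, mapped, sig.subtype_correlation)
        calls = classify_nearest_centroid(corr_sub)["call"]
        corr_ror = (
            corr_sub
            if sig.ror_correlation == sig.subtype_correlation
            else centroid_correlations(expr, mapped, sig.ror_correlation)
        )
        score = sig.risk_direction * ror_linear(corr_ror, sig.ror_coefficients)
        return score, calls, corr_sub
    if sig.archetype == "centroid_risk":
        return centroid_risk(expr, mapped), None, None
    if sig.archetype == "weighted_sum":
        return sig.risk_direction * weighted_sum(expr, mapped, stratum_labels), None, None
    if sig.archetype == "difference_of_means":
        return sig.risk_direction * difference_of_means(expr, mapped), None, None
    if sig.archetype == "grouped_threshold":
        return sig.risk_direction * grouped_threshold(expr, mapped), None, None
    raise ValueError(f"unknown archetype {sig.archetype!r}")


def score_all(
    expr: ExpressionMatrix,
    signatures: list[SignatureDefinition],
    clinical=None,
    *,
    min_coverage: float = 0.5,
    stratum_column: str = "er_status",
) -> ScoreTable:
    """Score every signature on the cohort; failures are recorded, not fatal.

    Stratified signatures draw their per-sample stratum from the
    clinical table's ``stratum_column`` (ER status by default).
    """
    stratum_labels = None
    if clinical is not None:
        cdf = clinical.indexed() if hasattr(clinical, "indexed") else clinical
        stratum_labels = cdf[stratum_column].reindex(expr.sample_ids)

    scores = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    calls = pd.DataFrame(index=scores.index)
    correlations: dict[str, pd.DataFrame] = {}
    status: dict[str, str] = {}
    for sig in signatures:
        try:
            mapped = map_signature(sig, expr, min_coverage=min_coverage)
            score, call, corr = score_signature(expr, mapped, stratum_labels)
        except (ValueError, KeyError) as err:
            status[sig.name] = f"failed: {err}"
            continue
        scores[sig.name] = score
        if call is not None:
            calls[sig.name] = call
        if corr is not None:
            correlations[sig.name] = corr
        status[sig.name] = "ok"
    return ScoreTable(scores=scores, subtype_calls=calls, correlations=correlations, status=status)
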