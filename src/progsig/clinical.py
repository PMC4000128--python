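"""Clinical follow-up tables and receptor-status imputation.

Follow-up is distant-metastasis-free survival (DMFS): time in years from
diagnosis to first distant metastasis, censored at last follow-up
otherwise. Covariates are the standard breast-cancer prognostic factors
(ER/HER2 status, tumor size category, node status, histological grade)
plus cohort label and a systemic-treatment flag; unknown values are kept
as the explicit category ``"unknown"``, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COLUMNS = [
    "sample_id",
    "time_years",
    "event",
    "er_status",
    "her2_status",
    "size_cat",
    "node",
    "grade",
    "cohort",
    "systemic_treatment",
]

UNKNOWN = "unknown"

_ALLOWED = {
    "er_status": {"positive", "negative", UNKNOWN},
    "her2_status": {"positive", "negative", UNKNOWN},
    "size_cat": {"pT1", "pT2", "pT3-4", UNKNOWN},
    "node": {"positive", "negative", UNKNOWN},
    "grade": {"1", "2", "3", UNKNOWN},
    "systemic_treatment": {"yes", "no", UNKNOWN},
}


@dataclass
class ClinicalTable:
    """Validated per-sample survival records as a DataFrame.

    One row per sample with the columns in :data:`COLUMNS`. ``time_years``
    is nonnegative, ``event`` is 0/1 (1 = distant metastasis observed),
    and every categorical column takes only its declared levels with
    ``"unknown"`` as the explicit missing category.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df = df[COLUMNS]
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        df["time_years"] = pd.to_numeric(df["time_years"])
        if (df["time_years"] < 0).any() or df["time_years"].isna().any():
            bad = df.loc[(df["time_years"] < 0) | df["time_years"].isna(), "sample_id"]
            raise ValueError(f"negative or missing follow-up time for samples {bad.tolist()[:5]}")
        ev = pd.to_numeric(df["event"])
        if not ev.isin([0, 1]).all():
            bad = df.loc[~ev.isin([0, 1]), "sample_id"]
            raise ValueError(f"event indicator outside {{0,1}} for samples {bad.tolist()[:5]}")
        df["event"] = ev.astype(int)
        for col, allowed in _ALLOWED.items():
            vals = df[col].astype(str).where(df[col].notna(), UNKNOWN)
            vals = vals.replace({"nan": UNKNOWN, "": UNKNOWN, "NA": UNKNOWN})
            bad = ~vals.isin(allowed)
            if bad.any():
                raise ValueError(
                    f"column {col!r}: unexpected levels {sorted(vals[bad].unique())} "
                    f"(allowed: {sorted(allowed)})"
                )
            df[col] = vals
        df["cohort"] = df["cohort"].astype(str).where(df["cohort"].notna(), UNKNOWN)
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    def indexed(self) -> pd.DataFrame:
        """Return the table indexed by sample_id (for alignment with scores)."""
        return self.data.set_index("sample_id")


def read_clinical(path: str | Path, *, sep: str = "\t") -> ClinicalTable:
    """Read and validate a clinical TSV with the columns in :data:`COLUMNS`."""
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=["NA", ""])
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path, *, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False)


@dataclass
class ReceptorImputation:
    """Per-sample positive/negative calls from a marker-gene mixture fit."""

    labels: pd.Series  # "positive" / "negative", indexed like the input
    posterior_positive: pd.Series
    fallback: bool  # True when the mixture collapsed and a median split was used
    means: tuple[float, float]  # (negative-component mean, positive-component mean)


def impute_receptor_status(
    marker_values: pd.Series | np.ndarray,
    *,
    seed: int | None = None,
    max_iter: int = 500,
) -> ReceptorImputation:
    """Call receptor status from a marker gene's expression (e.g. ESR1, ERBB2).

    Fits a two-component equal-variance Gaussian mixture to the marker
    expression and assigns samples with posterior > 0.5 for the
    higher-mean component as positive. IHC-negative and IHC-positive
    tumors form well-separated modes for ESR1/ERBB2, which is what the
    mixture captures. If the components collapse (indistinguishable
    means or a vanishing component), falls back to a median split and
    sets ``fallback=True``.

    Deterministic: initialized at the lower/upper quartiles, so the fit
    does not depend on ``seed`` (accepted for interface stability).
    """
    values = pd.Series(marker_values).astype(float)
    if len(values) < 20:
        raise ValueError(f"need >= 20 samples to fit a mixture, got {len(values)}")
    x = values.to_numpy()
    if np.isnan(x).any():
        raise ValueError("marker values must not contain missing entries")
    spread = x.max() - x.min()
    if spread == 0:
        return _median_fallback(values)

    # Two-component equal-variance EM, quartile-initialized: deterministic
    # and exactly equivariant under affine maps x -> a*x + b (a > 0).
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    sigma = max(np.std(x) / 2, 1e-12 * spread)
    w = np.array([0.5, 0.5])
    ll_old = -np.inf
    for _ in range(max_iter):
        log_dens = -0.5 * ((x[:, None] - mu[None, :]) / sigma) ** 2 - np.log(sigma)
        log_num = np.log(w)[None, :] + log_dens
        log_norm = np.logaddexp(log_num[:, 0], log_num[:, 1])
        resp = np.exp(log_num - log_norm[:, None])
        ll = log_norm.sum()
        nk = resp.sum(axis=0)
        if nk.min() < 1e-10:
            return _median_fallback(values)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum() / len(x)
        sigma = max(np.sqrt(var), 1e-12 * spread)
        if abs(ll - ll_old) < 1e-10 * len(x):
            break
        ll_old = ll

    if abs(mu[1] - mu[0]) < 1e-6 * spread:
        return _median_fallback(values)
    hi = int(np.argmax(mu))
    post_positive = pd.Series(resp[:, hi], index=values.index)
    labels = pd.Series(
        np.where(post_positive > 0.5, "positive", "negative"), index=values.index
    )
    lo = 1 - hi
    return ReceptorImputation(labels, post_positive, False, (float(mu[lo]), float(mu[hi])))


def _median_fallback(values: pd.Series) -> ReceptorImputation:
    med = float(values.median())
    labels = pd.Series(np.where(values > med, "positive", "negative"), index=values.index)
    post = pd.Series((values > med).astype(float), index=values.index)
    return ReceptorImputation(labels, post, True, (med, med))
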