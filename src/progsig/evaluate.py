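"""Time- and stratum-resolved prognostic evaluation of risk scores.

The central question this module answers: how does a signature's
standardized hazard ratio for distant-metastasis-free survival change
with follow-up time, and does it differ between ER-positive and
ER-negative disease? Follow-up is split into intervals (default 0-5,
5-10, >10 years); within each (interval, stratum) cell the cohort is
restricted to subjects still at risk, the score re-standardized over
exactly those subjects, and a univariate Cox model fitted.

:class:`SignatureSurvivalModel` is the statsmodels-style entry point:
build it from a score table and a clinical table, call ``fit()``, and
read C-index/PVE, full-follow-up standardized HRs, proportional-hazards
diagnostics, and the per-interval HR table off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import standardize
from .clinical import ClinicalTable
from .survival import (
    CoxResult,
    concordance,
    cox_fit,
    ph_test,
    pve,
    restrict_interval,
)

DEFAULT_INTERVALS: tuple[tuple[float, float], ...] = ((0.0, 5.0), (5.0, 10.0), (10.0, math.inf))

MULTIVARIATE_SETS: dict[str, list[str]] = {
    "signature": [],
    "signature+size": ["size"],
    "signature+grade": ["grade"],
    "signature+size+node+grade": ["size", "node", "grade"],
}


def _check_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    ivals = [(float(a), float(b)) for a, b in intervals]
    if not ivals or ivals[0][0] != 0:
        raise ValueError("intervals must start at 0")
    for (a, b), (c, _) in zip(ivals, ivals[1:]):
        if not (a < b and b == c):
            raise ValueError(f"intervals must be ascending and contiguous, got {ivals}")
    if not math.isinf(ivals[-1][1]) and ivals[-1][0] >= ivals[-1][1]:
        raise ValueError(f"bad final interval {ivals[-1]}")
    return ivals


def _interval_label(lower: float, upper: float) -> str:
    if math.isinf(upper):
        return f">{lower:g} yr"
    return f"{lower:g}-{upper:g} yr"


@dataclass
class IntervalEffectTable:
    """Per (interval x stratum) standardized hazard ratios.

    One row per cell: numbers at risk and events, the HR per one SD of
    the score with 95% CI and p, plus a note when the cell could not be
    fitted (e.g. zero events). The at-risk counts are non-increasing
    across successive intervals within a stratum.
    """

    data: pd.DataFrame

    COLUMNS = [
        "signature",
        "stratum",
        "interval",
        "lower",
        "upper",
        "n_risk",
        "n_event",
        "hr",
        "ci_low",
        "ci_high",
        "p",
        "note",
    ]

    def __post_init__(self) -> None:
        self.data = self.data[self.COLUMNS].reset_index(drop=True)
        for (sig, stratum), grp in self.data.groupby(["signature", "stratum"]):
            ordered = grp.sort_values("lower")["n_risk"].to_numpy()
            if (np.diff(ordered) > 0).any():
                raise ValueError(
                    f"n_risk increases across intervals for {sig!r}/{stratum!r}"
                )
        if (self.data["n_event"] > self.data["n_risk"]).any():
            raise ValueError("n_event exceeds n_risk")

    def cell(self, signature: str, stratum: str, interval: str) -> pd.Series:
        sel = self.data[
            (self.data["signature"] == signature)
            & (self.data["stratum"] == stratum)
            & (self.data["interval"] == interval)
        ]
        if len(sel) != 1:
            raise KeyError((signature, stratum, interval))
        return sel.iloc[0]

    def write(self, path: str | Path, *, sep: str = "\t") -> None:
        self.data.to_csv(path, sep=sep, index=False, na_rep="NA")


def interval_effects(
    score: pd.Series,
    clinical: ClinicalTable,
    intervals: Sequence[tuple[float, float]] = DEFAULT_INTERVALS,
    stratify_by: Optional[str] = "er_status",
    *,
    signature_name: str = "score",
    strata_values: Optional[Sequence[str]] = None,
    cohort_adjust: bool = False,
) -> IntervalEffectTable:
    """Standardized HR of one score per follow-up interval and stratum.

    For each cell: subjects whose follow-up ended before the interval
    are excluded, subjects still at risk at its end are censored there,
    the score is re-standardized over the restricted sample, and a
    univariate Cox model is fitted. Cells with no events (or too little
    variation) are reported with a missing HR and an explanatory note
    rather than dropped.
    """
    ivals = _check_intervals(intervals)
    cdf = clinical.indexed()
    score = score.reindex(cdf.index)

    if stratify_by is None:
        strata = {"all": pd.Series(True, index=cdf.index)}
    else:
        col = cdf[stratify_by]
        values = strata_values or [v for v in col.unique() if v != "unknown"]
        strata = {str(v): col == v for v in values}

    rows = []
    for stratum, mask in strata.items():
        sub = cdf[mask & score.notna()]
        s_sub = score[sub.index]
        for lower, upper in ivals:
            t_r, e_r, included = restrict_interval(
                sub["time_years"].to_numpy(), sub["event"].to_numpy(), lower, min(upper, np.inf)
            )
            ids = sub.index[included]
            row = {
                "signature": signature_name,
                "stratum": stratum,
                "interval": _interval_label(lower, upper),
                "lower": lower,
                "upper": upper,
                "n_risk": int(included.sum()),
                "n_event": int(e_r.sum()),
                "hr": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
                "note": "",
            }
            if row["n_event"] == 0:
                row["note"] = "no events in interval"
                rows.append(row)
                continue
            try:
                z = standardize(s_sub.loc[ids])
                X = pd.DataFrame({signature_name: z.to_numpy()})
                fit = cox_fit(
                    X,
                    t_r,
                    e_r,
                    strata=sub.loc[ids, "cohort"].to_numpy() if cohort_adjust else None,
                )
            except ValueError as err:
                row["note"] = f"fit failed: {err}"
                rows.append(row)
                continue
            row["hr"] = fit.hr(signature_name)
            row["ci_low"], row["ci_high"] = fit.ci(signature_name)
            row["p"] = fit.p(signature_name)
            rows.append(row)
    return IntervalEffectTable(pd.DataFrame(rows))


def _encode_covariates(cdf: pd.DataFrame, which: list[str]) -> pd.DataFrame:
    """Reference-level dummy coding: pT1, node-negative and grade 1 are baseline."""
    out = pd.DataFrame(index=cdf.index)
    if "size" in which:
        out["size_pT2"] = (cdf["size_cat"] == "pT2").astype(float)
        out["size_pT3-4"] = (cdf["size_cat"] == "pT3-4").astype(float)
    if "node" in which:
        out["node_positive"] = (cdf["node"] == "positive").astype(float)
    if "grade" in which:
        out["grade_2"] = (cdf["grade"] == "2").astype(float)
        out["grade_3"] = (cdf["grade"] == "3").astype(float)
    return out


_UNKNOWN_FILTERS = {"size": "size_cat", "node": "node", "grade": "grade"}


def multivariate_effects(
    score: pd.Series,
    clinical: ClinicalTable,
    covariate_sets: dict[str, list[str]] = MULTIVARIATE_SETS,
    stratify_by: Optional[str] = None,
    stratum_value: Optional[str] = None,
    *,
    signature_name: str = "score",
    cohort_adjust: bool = False,
) -> dict[str, CoxResult]:
    """Cox models of the score adjusted for size / node / grade.

    Each named covariate set adds clinical factors (dummy-coded against
    pT1 / node-negative / grade-1 reference levels) to the standardized
    score. Samples with unknown levels of a used factor are dropped for
    that model only; the score is re-standardized over each model's
    estimation sample.
    """
    cdf = clinical.indexed()
    if stratify_by is not None:
        if stratum_value is None:
            raise ValueError("stratum_value required when stratify_by is set")
        cdf = cdf[cdf[stratify_by] == stratum_value]
    score = score.reindex(cdf.index)

    results: dict[str, CoxResult] = {}
    for model_name, factors in covariate_sets.items():
        bad = [f for f in factors if f not in _UNKNOWN_FILTERS]
        if bad:
            raise ValueError(f"unknown covariate factors {bad}")
        keep = score.notna()
        for f in factors:
            keep &= cdf[_UNKNOWN_FILTERS[f]] != "unknown"
        sub = cdf[keep]
        z = standardize(score[sub.index])
        X = _encode_covariates(sub, factors)
        # a level absent from this estimation sample leaves a constant dummy
        X = X.loc[:, X.nunique() > 1]
        X.insert(0, signature_name, z[sub.index].to_numpy())
        results[model_name] = cox_fit(
            X.reset_index(drop=True),
            sub["time_years"].to_numpy(),
            sub["event"].to_numpy(),
            strata=sub["cohort"].to_numpy() if cohort_adjust else None,
        )
    return results


# ---------------------------------------------------------------------------
# Model / Results objects


class SignatureSurvivalModel:
    """Evaluate signature risk scores against a censored survival endpoint.

    Parameters
    ----------
    scores : pandas.DataFrame
        Continuous risk scores, index sample_id, one column per
        signature (a :class:`~progsig.scoring.ScoreTable`'s ``scores``).
    clinical : ClinicalTable
        Follow-up times, event indicators and covariates.
    intervals : sequence of (lower, upper)
        Contiguous follow-up windows starting at 0; the last upper bound
        may be ``inf``.
    stratify_by : str or None
        Clinical column defining the strata (default ER status);
        ``None`` evaluates the whole cohort as one stratum.
    cohort_adjust : bool
        Give each cohort its own baseline hazard in every Cox fit.
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        clinical: ClinicalTable,
        *,
        intervals: Sequence[tuple[float, float]] = DEFAULT_INTERVALS,
        stratify_by: Optional[str] = "er_status",
        cohort_adjust: bool = False,
        ph_transform: str = "km",
    ):
        if hasattr(scores, "scores"):  # accept a ScoreTable directly
            scores = scores.scores
        self.scores = scores
        self.clinical = clinical
        self.intervals = _check_intervals(intervals)
        self.stratify_by = stratify_by
        self.cohort_adjust = cohort_adjust
        self.ph_transform = ph_transform

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, signature_columns: Sequence[str], **kwargs
    ) -> "SignatureSurvivalModel":
        """Build from one flat frame holding both scores and clinical columns."""
        clin = ClinicalTable(df.reset_index(drop=True))
        scores = df.set_index(df["sample_id"].astype(str))[list(signature_columns)]
        return cls(scores, clin, **kwargs)

    def fit(self) -> "SignatureSurvivalResults":
        cdf = self.clinical.indexed()
        perf_rows = []
        ph_rows = []
        interval_tables = []
        for sig in self.scores.columns:
            s = self.scores[sig].reindex(cdf.index)
            ok = s.notna()
            sub, s_sub = cdf[ok], s[ok]
            # whole-follow-up discrimination and explained variation
            cres = concordance(
                s_sub.to_numpy(), sub["time_years"].to_numpy(), sub["event"].to_numpy()
            )
            z = standardize(s_sub)
            fit = cox_fit(
                pd.DataFrame({sig: z.to_numpy()}),
                sub["time_years"].to_numpy(),
                sub["event"].to_numpy(),
                strata=sub["cohort"].to_numpy() if self.cohort_adjust else None,
            )
            perf_rows.append(
                {
                    "signature": sig,
                    "n": len(sub),
                    "n_event": int(sub["event"].sum()),
                    "c_index": cres.c,
                    "c_low": cres.ci_low,
                    "c_high": cres.ci_high,
                    "pve": pve(fit),
                    "hr_per_sd": fit.hr(sig),
                    "hr_low": fit.ci(sig)[0],
                    "hr_high": fit.ci(sig)[1],
                    "p": fit.p(sig),
                }
            )
            # per-stratum full-follow-up PH diagnostics
            strata = (
                {"all": pd.Series(True, index=sub.index)}
                if self.stratify_by is None
                else {
                    str(v): sub[self.stratify_by] == v
                    for v in sub[self.stratify_by].unique()
                    if v != "unknown"
                }
            )
            for stratum, mask in strata.items():
                strat = sub[mask]
                try:
                    zs = standardize(s_sub[strat.index])
                    sfit = cox_fit(
                        pd.DataFrame({sig: zs.to_numpy()}),
                        strat["time_years"].to_numpy(),
                        strat["event"].to_numpy(),
                    )
                    ph = ph_test(sfit, transform=self.ph_transform)
                    ph_rows.append(
                        {
                            "signature": sig,
                            "stratum": stratum,
                            "rho": float(ph.rho.iloc[0]),
                            "p": float(ph.p.iloc[0]),
                        }
                    )
                except ValueError as err:
                    ph_rows.append(
                        {"signature": sig, "stratum": stratum, "rho": np.nan, "p": np.nan}
                    )
            interval_tables.append(
                interval_effects(
                    s,
                    self.clinical,
                    self.intervals,
                    self.stratify_by,
                    signature_name=sig,
                    cohort_adjust=self.cohort_adjust,
                ).data
            )
        return SignatureSurvivalResults(
            model=self,
            performance=pd.DataFrame(perf_rows).set_index("signature"),
            ph=pd.DataFrame(ph_rows),
            intervals=IntervalEffectTable(pd.concat(interval_tables, ignore_index=True)),
        )


@dataclass
class SignatureSurvivalResults:
    """Fitted evaluation: discrimination, explained variation, time trends."""

    model: SignatureSurvivalModel
    performance: pd.DataFrame  # per signature: C-index, PVE, standardized HR
    ph: pd.DataFrame  # per signature x stratum: Schoenfeld rho, p
    intervals: IntervalEffectTable

    def summary(self) -> str:
        lines = ["Signature survival evaluation", "=" * 64]
        perf = self.performance.copy()
        lines.append("\nUnivariate performance (whole follow-up):")
        lines.append(
            perf[["n", "n_event", "c_index", "c_low", "c_high", "pve", "hr_per_sd", "p"]]
            .round(4)
            .to_string()
        )
        lines.append("\nProportional-hazards diagnostics (Schoenfeld rho, p):")
        lines.append(self.ph.round(4).to_string(index=False))
        lines.append("\nStandardized HR per follow-up interval and stratum:")
        cols = ["signature", "stratum", "interval", "n_risk", "n_event", "hr", "ci_low", "ci_high", "p"]
        lines.append(self.intervals.data[cols].round(4).to_string(index=False))
        return "\n".join(lines)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.performance.to_csv(outdir / "performance.tsv", sep="\t", na_rep="NA")
        self.ph.to_csv(outdir / "ph_tests.tsv", sep="\t", index=False, na_rep="NA")
        self.intervals.write(outdir / "interval_effects.tsv")
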