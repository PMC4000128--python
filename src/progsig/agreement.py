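"""Cross-signature agreement: score correlations, subtype confusion, kappa.

Different signatures largely track a shared proliferation axis, so
their continuous risk scores correlate strongly; this module quantifies
that agreement (pairwise-complete correlation matrix), and compares
subtype callers via confusion matrices and Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats


def score_correlation_matrix(
    scores: pd.DataFrame,
    method: Literal["pearson", "spearman"] = "pearson",
    *,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete correlation matrix of signature scores.

    Signatures can fail coverage on different samples, so each pair uses
    the samples where both scores exist; pairs with fewer than
    ``min_pairs`` complete observations get a missing entry. Returns
    (correlations, n-per-pair).
    """
    corr = scores.corr(method=method, min_periods=min_pairs)
    notna = scores.notna().astype(int)
    n = pd.DataFrame(
        notna.T.to_numpy() @ notna.to_numpy(),
        index=scores.columns,
        columns=scores.columns,
    )
    np.fill_diagonal(corr.values, 1.0)
    return corr, n


def subtype_confusion(
    calls_a: pd.Series,
    calls_b: pd.Series,
    class_order: list[str],
) -> pd.DataFrame:
    """Confusion matrix of two subtype callers on shared samples.

    Rows are caller A, columns caller B, in the declared class order.
    Samples called ``unknown`` by either are excluded from the matrix
    and reported in the ``unknown`` margin attribute (``.attrs``).
    """
    shared = calls_a.index.intersection(calls_b.index)
    if len(shared) == 0:
        raise ValueError("callers share no samples")
    a = calls_a.loc[shared]
    b = calls_b.loc[shared]
    known = (a != "unknown") & (b != "unknown")
    mat = pd.crosstab(a[known], b[known]).reindex(
        index=class_order, columns=class_order, fill_value=0
    )
    mat.index.name = "caller_a"
    mat.columns.name = "caller_b"
    mat.attrs["n_unknown"] = int((~known).sum())
    return mat


@dataclass
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_observed: float
    p_expected: float


def cohens_kappa(confusion: pd.DataFrame, *, alpha: float = 0.05) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    CI from the standard asymptotic variance (Fleiss-Cohen-Everitt).
    Degenerate margins with expected agreement 1 leave kappa undefined.
    """
    M = confusion.to_numpy(dtype=float)
    n = M.sum()
    if n < 1:
        raise ValueError("empty confusion matrix")
    P = M / n
    po = np.trace(P)
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    pe = float(row @ col)
    if abs(1 - pe) < 1e-12:
        raise ValueError("expected agreement is 1: kappa undefined")
    kappa = (po - pe) / (1 - pe)
    # asymptotic variance of kappa-hat (Fleiss, Cohen & Everitt 1969)
    k = M.shape[0]
    a = sum(
        P[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(k)
    )
    b = (1 - kappa) ** 2 * sum(
        P[i, j] * (col[i] + row[j]) ** 2 for i in range(k) for j in range(k) if i != j
    )
    c = (kappa - pe * (1 - kappa)) ** 2
    var = (a + b - c) / (n * (1 - pe) ** 2)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return KappaResult(
        kappa=float(kappa),
        se=se,
        ci_low=float(kappa - z * se),
        ci_high=float(min(kappa + z * se, 1.0)),
        p_observed=float(po),
        p_expected=pe,
    )


@dataclass
class AgreementReport:
    """Pairwise score correlations plus subtype-caller agreement."""

    correlations: pd.DataFrame
    n_pairs: pd.DataFrame
    confusion: pd.DataFrame | None = None
    kappa: KappaResult | None = None

    def pair_table(self) -> pd.DataFrame:
        """Flat (signature_a, signature_b, correlation, n) table, upper triangle."""
        rows = []
        sigs = self.correlations.columns.tolist()
        for i, a in enumerate(sigs):
            for b in sigs[i + 1 :]:
                rows.append(
                    {
                        "signature_a": a,
                        "signature_b": b,
                        "correlation": self.correlations.loc[a, b],
                        "n": int(self.n_pairs.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.correlations.to_csv(outdir / "score_correlations.tsv", sep="\t", na_rep="NA")
        self.pair_table().to_csv(outdir / "score_correlation_pairs.tsv", sep="\t", index=False)
        if self.confusion is not None:
            self.confusion.to_csv(outdir / "subtype_confusion.tsv", sep="\t")
        if self.kappa is not None:
            pd.DataFrame([self.kappa.__dict__]).to_csv(
                outdir / "subtype_kappa.tsv", sep="\t", index=False
            )


def agreement_report(
    scores: pd.DataFrame,
    calls_a: pd.Series | None = None,
    calls_b: pd.Series | None = None,
    class_order: list[str] | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
) -> AgreementReport:
    """Assemble the full agreement report for a score table."""
    corr, n = score_correlation_matrix(scores, method)
    confusion = kappa = None
    if calls_a is not None and calls_b is not None:
        if class_order is None:
            raise ValueError("class_order required with subtype calls")
        confusion = subtype_confusion(calls_a, calls_b, class_order)
        kappa = cohens_kappa(confusion)
    return AgreementReport(corr, n, confusion, kappa)
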