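"""Synthetic breast-cancer cohort generator with full ground truth.

The generator emulates the statistical structure the evaluation stack
assumes, so every downstream stage is testable without external data:

* two ER strata with different risk biology: in ER-positive disease a
  shared latent *proliferation* factor drives both the signature scores
  and the hazard; in ER-negative disease the hazard is driven by an
  independent *hypoxia* factor that only a hypoxia-like signature reads;
* nine synthetic signature definitions covering every scoring archetype,
  mutually correlated through their loadings on the shared factor
  (two scores with loadings l1, l2 and specific-factor SD sigma have
  population correlation l1*l2 / sqrt((l1^2+sigma^2)(l2^2+sigma^2)));
* survival times from a piecewise-exponential model whose log-hazard
  adds beta(t) * (standardized latent driver) within each stratum, with
  a strong early effect that vanishes late (the time-decay pattern);
* independent right-censoring: exponential random censoring plus
  administrative censoring at the follow-up horizon;
* grade and tumor size cut from the proliferation factor, so adjusting
  for them attenuates signature effects (a testable mediation path).

All randomness flows from one seed through named sub-streams, so
expression, survival and censoring are independently reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalTable
from .matrix import ExpressionMatrix
from .signatures import CalibrationSpec, GeneEntry, GroupSpec, SignatureDefinition

LOG2 = math.log(2.0)

Segment = tuple[float, float, float]  # (start, end, value); end may be inf

SUBTYPES = ["normal", "luma", "lumb", "her2", "basal"]

# risk-of-relapse coefficients per subtype: the LumA/LumB contrast carries the
# proliferation axis, HER2-enriched and basal-like add fixed excess risk
ROR_COEF = {"normal": 0.0, "luma": -0.15, "lumb": 0.15, "her2": 0.05, "basal": 0.10}

SUBTYPE_PROBS = {
    "positive": {"normal": 0.15, "luma": 0.45, "lumb": 0.30, "her2": 0.07, "basal": 0.03},
    "negative": {"normal": 0.10, "luma": 0.05, "lumb": 0.10, "her2": 0.25, "basal": 0.50},
}

# shared-proliferation loading per signature; hypoxia_sum instead loads on
# the independent hypoxia factor with the same magnitude
DEFAULT_LOADINGS = {
    "proliferation_sum": 0.90,
    "er_stratified_sum": 0.85,
    "grade_index": 0.90,
    "recurrence_groups": 0.85,
    "endocrine_groups": 0.80,
    "hypoxia_sum": 0.90,
}

COHORTS = ["uppsala", "stockholm", "oxford", "brussels", "msk", "ucsf"]


def _validate_schedule(name: str, segments: list[Segment], horizon: float) -> None:
    if not segments:
        raise ValueError(f"{name}: empty schedule")
    if segments[0][0] != 0:
        raise ValueError(f"{name}: schedule must start at 0")
    for (a, b, _), (c, _, _) in zip(segments, segments[1:]):
        if not (a < b and b == c):
            raise ValueError(f"{name}: schedule segments must tile contiguously")
    if segments[-1][1] < horizon:
        raise ValueError(f"{name}: schedule must cover the censoring horizon")


@dataclass
class SimulationConfig:
    """Generating parameters of the synthetic cohort.

    Defaults mirror the structure of a meta-cohort of ~900 breast
    tumors with ~76% ER-positive disease, 15-year administrative
    follow-up, and a prognostic effect of one standard deviation of
    the latent driver of HR = 2 (ER+) / 1.5 (ER-) during the first five
    years and none afterwards.
    """

    seed: int
    n_samples: int = 912
    er_positive_fraction: float = 692 / 912

    # expression / latent-factor structure
    centroid_pool_size: int = 60
    centroid_scale: float = 1.5  # SD of centroid patterns (log2 units)
    centroid_noise_sd: float = 0.8
    proliferation_shift: float = 0.8  # shift along the LumA->LumB axis per SD of P
    genes_per_sum_signature: int = 20
    noise_sd: float = 0.5  # per-gene measurement noise (log2 units)
    specific_sd: float = 0.45  # signature-specific factor SD
    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    n_filler_genes: int = 200

    # survival model, per ER stratum
    baseline_hazard: dict[str, list[Segment]] = field(
        default_factory=lambda: {
            "positive": [(0.0, 5.0, 0.035), (5.0, 10.0, 0.015), (10.0, math.inf, 0.005)],
            "negative": [(0.0, 5.0, 0.065), (5.0, 10.0, 0.012), (10.0, math.inf, 0.008)],
        }
    )
    beta_schedule: dict[str, list[Segment]] = field(
        default_factory=lambda: {
            "positive": [(0.0, 5.0, LOG2), (5.0, math.inf, 0.0)],
            "negative": [(0.0, 5.0, math.log(1.5)), (5.0, math.inf, 0.0)],
        }
    )
    hazard_driver: dict[str, str] = field(
        default_factory=lambda: {"positive": "proliferation", "negative": "hypoxia"}
    )
    admin_censor_years: float = 15.0
    random_censoring_rate: float = 0.015  # per year

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 <= self.er_positive_fraction <= 1:
            raise ValueError("er_positive_fraction must be in [0, 1]")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        for st in ("positive", "negative"):
            _validate_schedule(
                f"baseline_hazard[{st}]", self.baseline_hazard[st], self.admin_censor_years
            )
            _validate_schedule(
                f"beta_schedule[{st}]", self.beta_schedule[st], self.admin_censor_years
            )
            if any(v < 0 for _, _, v in self.baseline_hazard[st]):
                raise ValueError("baseline hazard rates must be nonnegative")


@dataclass
class GroundTruth:
    """Per-sample generating quantities, aligned to sample ids."""

    table: pd.DataFrame  # sample_id, er_status, subtype, proliferation, hypoxia, driver_z
    beta_schedule: dict[str, list[Segment]]
    baseline_hazard: dict[str, list[Segment]]

    def write(self, path: str | Path, *, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False)


@dataclass
class SimulatedCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    signatures: list[SignatureDefinition]
    truth: GroundTruth

    def __iter__(self):
        return iter((self.expression, self.clinical, self.signatures, self.truth))


# ---------------------------------------------------------------------------
# hazard segments


def _merge_segments(base: list[Segment], beta: list[Segment]) -> list[tuple[float, float, float, float]]:
    """Merge baseline and effect schedules into (start, end, lambda0, beta) pieces."""
    cuts = sorted({a for a, _, _ in base} | {a for a, _, _ in beta} | {math.inf})
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        lam = next(v for s, e, v in base if s <= a < e)
        bet = next(v for s, e, v in beta if s <= a < e)
        out.append((a, b, lam, bet))
    return out


def _piecewise_exponential_times(
    rng: np.random.Generator,
    z: np.ndarray,
    segments: list[tuple[float, float, float, float]],
) -> np.ndarray:
    """Invert the piecewise-constant cumulative hazard at Exp(1) draws."""
    target = rng.exponential(1.0, len(z))
    t = np.full(len(z), math.inf)
    remaining = target.copy()
    done = np.zeros(len(z), dtype=bool)
    for a, b, lam, bet in segments:
        if lam == 0:
            continue
        rate = lam * np.exp(bet * z)
        length = b - a
        seg_haz = rate * length  # inf * finite handled below
        within = ~done & (remaining <= seg_haz if math.isfinite(length) else ~done)
        t[within] = a + remaining[within] / rate[within]
        done |= within
        if math.isfinite(length):
            remaining = remaining - np.where(done, 0.0, rate * length)
    return t


# ---------------------------------------------------------------------------
# main generator


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate expression, clinical records, signature definitions and truth.

    Deterministic for a given config (same seed -> identical output).
    """
    ss = np.random.SeedSequence(config.seed)
    r_expr, r_surv, r_cens, r_clin = (np.random.default_rng(s) for s in ss.spawn(4))
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # --- strata, subtypes, latent factors -------------------------------
    er = np.where(r_clin.random(n) < config.er_positive_fraction, "positive", "negative")
    subtype = np.empty(n, dtype=object)
    for st in ("positive", "negative"):
        idx = np.flatnonzero(er == st)
        probs = [SUBTYPE_PROBS[st][k] for k in SUBTYPES]
        subtype[idx] = r_clin.choice(SUBTYPES, size=len(idx), p=probs)
    P = r_expr.standard_normal(n)  # proliferation
    H = r_expr.standard_normal(n)  # hypoxia

    genes: dict[str, np.ndarray] = {}
    signatures: list[SignatureDefinition] = []

    # --- centroid gene pool ---------------------------------------------
    pool = [f"CEN_G{j:03d}" for j in range(config.centroid_pool_size)]
    C = r_expr.normal(0.0, config.centroid_scale, size=(config.centroid_pool_size, len(SUBTYPES)))
    k_idx = np.array([SUBTYPES.index(s) for s in subtype])
    v = C[:, SUBTYPES.index("lumb")] - C[:, SUBTYPES.index("luma")]
    # unit per-gene RMS, so proliferation_shift is in log2 units per SD of P
    v = v / np.linalg.norm(v) * math.sqrt(len(v))
    pool_expr = (
        8.0
        + C[:, k_idx]
        + config.proliferation_shift * v[:, None] * P[None, :]
        + r_expr.normal(0.0, config.centroid_noise_sd, size=(len(pool), n))
    )
    for j, g in enumerate(pool):
        genes[g] = pool_expr[j]

    def centroid_dict(gene_subset: list[str]) -> dict[str, dict[str, float]]:
        rows = [pool.index(g) for g in gene_subset]
        return {
            cls: {g: float(8.0 + C[r, SUBTYPES.index(cls)]) for g, r in zip(gene_subset, rows)}
            for cls in SUBTYPES
        }

    signatures.append(
        SignatureDefinition(
            name="subtype_a",
            archetype="centroid_subtype",
            class_order=SUBTYPES,
            centroids=centroid_dict(pool),
            ror_coefficients=ROR_COEF,
            subtype_correlation="spearman",
            ror_correlation="pearson",
            provenance="synthetic",
        )
    )
    signatures.append(
        SignatureDefinition(
            name="subtype_b",
            archetype="centroid_subtype",
            class_order=SUBTYPES,
            centroids=centroid_dict(pool[35:]),
            ror_coefficients=ROR_COEF,
            subtype_correlation="spearman",
            ror_correlation="pearson",
            provenance="synthetic",
        )
    )
    good_panel = pool[:30]
    signatures.append(
        SignatureDefinition(
            name="good_prognosis_centroid",
            archetype="centroid_risk",
            class_order=SUBTYPES,
            centroids=centroid_dict(good_panel),
            reference_class="luma",
            risk_direction=-1,
            ror_correlation="pearson",
            provenance="synthetic",
        )
    )

    # --- latent-factor signature panels ---------------------------------
    def factor_genes(prefix: str, m: int, scores: np.ndarray, signs: np.ndarray) -> list[str]:
        names = [f"{prefix}_G{j:02d}" for j in range(m)]
        base = r_expr.normal(8.0, 1.0, size=m)
        noise = r_expr.normal(0.0, config.noise_sd, size=(m, n))
        for j, g in enumerate(names):
            genes[g] = base[j] + signs[j] * scores + noise[j]
        return names

    def true_score(name: str, factor: np.ndarray) -> np.ndarray:
        l = config.loadings[name]
        u = r_expr.standard_normal(n)
        return l * factor + config.specific_sd * u

    m = config.genes_per_sum_signature

    t_prolif = true_score("proliferation_sum", P)
    signs = np.where(r_expr.random(m) < 0.7, 1.0, -1.0)
    names = factor_genes("PRF", m, t_prolif, signs)
    signatures.append(
        SignatureDefinition(
            name="proliferation_sum",
            archetype="weighted_sum",
            genes=[GeneEntry(gene_id=g, weight=float(s) / m) for g, s in zip(names, signs)],
            provenance="synthetic",
        )
    )

    t_strat = true_score("er_stratified_sum", P)
    t_strat_neg = 0.6 * H + config.specific_sd * r_expr.standard_normal(n)
    signs_p = np.ones(15)
    names_p = factor_genes("STP", 15, t_strat, signs_p)
    signs_n = np.ones(5)
    names_n = factor_genes("STN", 5, t_strat_neg, signs_n)
    entries = [
        GeneEntry(gene_id=g, weight=1.0 / 15, stratum="positive") for g in names_p
    ] + [GeneEntry(gene_id=g, weight=1.0 / 5, stratum="negative") for g in names_n]
    signatures.append(
        SignatureDefinition(
            name="er_stratified_sum",
            archetype="weighted_sum",
            genes=entries,
            calibration={
                "positive": CalibrationSpec(labels=["good", "poor"], proportions=[0.30, 0.70]),
                "negative": CalibrationSpec(labels=["good", "poor"], proportions=[0.22, 0.78]),
            },
            provenance="synthetic",
        )
    )

    t_grade = true_score("grade_index", P)
    up = factor_genes("GGU", 10, t_grade, np.ones(10))
    down = factor_genes("GGD", 10, -t_grade, np.ones(10))
    signatures.append(
        SignatureDefinition(
            name="grade_index",
            archetype="difference_of_means",
            genes=[GeneEntry(gene_id=g, group="up") for g in up]
            + [GeneEntry(gene_id=g, group="down") for g in down],
            calibration={
                "all": CalibrationSpec(labels=["low", "high"], proportions=[1 / 3, 2 / 3])
            },
            provenance="synthetic",
        )
    )

    def grouped(name: str, factor: np.ndarray, n_main: int, n_anti: int, n_ref: int,
                labels_props) -> None:
        t = true_score(name, factor)
        main = factor_genes(name[:3].upper() + "M", n_main, t, np.ones(n_main))
        anti = factor_genes(name[:3].upper() + "A", n_anti, -0.5 * t, np.ones(n_anti))
        ref = factor_genes(name[:3].upper() + "R", n_ref, np.zeros(n), np.ones(n_ref))
        entries = (
            [GeneEntry(gene_id=g, group="main") for g in main]
            + [GeneEntry(gene_id=g, group="anti") for g in anti]
            + [GeneEntry(gene_id=g, is_reference=True) for g in ref]
        )
        signatures.append(
            SignatureDefinition(
                name=name,
                archetype="grouped_threshold",
                genes=entries,
                groups={
                    "main": GroupSpec(weight=1.0, clip_low=-6.0, clip_high=6.0),
                    "anti": GroupSpec(weight=-0.8),
                },
                intercept=0.0,
                calibration=(
                    {"all": CalibrationSpec(labels=list(labels_props[0]), proportions=list(labels_props[1]))}
                ),
                provenance="synthetic",
            )
        )

    grouped(
        "recurrence_groups", P, 6, 4, 4,
        (("low", "intermediate", "high"), (0.51, 0.22, 0.27)),
    )
    grouped("endocrine_groups", P, 5, 3, 3, (("low", "high"), (0.75, 0.25)))

    t_hyp = true_score("hypoxia_sum", H)
    hyp_names = factor_genes("HYP", 15, t_hyp, np.ones(15))
    signatures.append(
        SignatureDefinition(
            name="hypoxia_sum",
            archetype="weighted_sum",
            genes=[GeneEntry(gene_id=g, weight=1.0 / 15) for g in hyp_names],
            provenance="synthetic",
        )
    )

    # --- marker genes and filler ----------------------------------------
    her2 = np.where(
        r_clin.random(n) < np.where(subtype == "her2", 0.60, 0.08), "positive", "negative"
    )
    genes["ESR1"] = 8.0 + np.where(er == "positive", 1.5, -1.5) + r_expr.normal(0, 0.5, n)
    genes["ERBB2"] = 8.0 + np.where(her2 == "positive", 1.8, 0.0) + r_expr.normal(0, 0.5, n)
    filler_base = r_expr.normal(8.0, 1.0, size=config.n_filler_genes)
    filler = filler_base[:, None] + r_expr.normal(0.0, 1.0, size=(config.n_filler_genes, n))
    for j in range(config.n_filler_genes):
        genes[f"FIL_G{j:03d}"] = filler[j]

    expression = ExpressionMatrix(
        pd.DataFrame(genes, index=sample_ids).T.astype(float)
    )

    # --- survival --------------------------------------------------------
    driver_z = np.zeros(n)
    times = np.zeros(n)
    factors = {"proliferation": P, "hypoxia": H}
    for st in ("positive", "negative"):
        mask = er == st
        if mask.sum() < 2:
            continue
        x = factors[config.hazard_driver[st]][mask]
        z = (x - x.mean()) / x.std(ddof=1)
        driver_z[mask] = z
        segs = _merge_segments(config.baseline_hazard[st], config.beta_schedule[st])
        times[mask] = _piecewise_exponential_times(r_surv, z, segs)
    if config.random_censoring_rate > 0:
        c_rand = r_cens.exponential(1.0 / config.random_censoring_rate, n)
    else:
        c_rand = np.full(n, math.inf)
    censor = np.minimum(c_rand, config.admin_censor_years)
    event = (times <= censor).astype(int)
    obs_time = np.minimum(times, censor)
    if event.sum() == 0:
        warnings.warn("configuration yields zero events; downstream fits will fail")

    # --- clinical covariates from the proliferation factor ---------------
    grade_latent = P + r_clin.normal(0.0, 0.6, n)
    g_sd = math.sqrt(1 + 0.6**2)
    from scipy.stats import norm as _norm

    g_cuts = _norm.ppf([0.25, 0.60], scale=g_sd)
    grade = np.where(grade_latent < g_cuts[0], "1", np.where(grade_latent < g_cuts[1], "2", "3"))
    size_latent = 0.5 * P + r_clin.normal(0.0, 1.0, n)
    s_sd = math.sqrt(0.25 + 1.0)
    s_cuts = _norm.ppf([0.55, 0.90], scale=s_sd)
    size = np.where(size_latent < s_cuts[0], "pT1", np.where(size_latent < s_cuts[1], "pT2", "pT3-4"))
    node = np.where(r_clin.random(n) < 0.45, "positive", "negative")
    treat = np.where(r_clin.random(n) < 0.57, "yes", "no")
    cohort = r_clin.choice(COHORTS, size=n, p=[0.25, 0.18, 0.2, 0.12, 0.12, 0.13])

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "time_years": obs_time,
                "event": event,
                "er_status": er,
                "her2_status": her2,
                "size_cat": size,
                "node": node,
                "grade": grade,
                "cohort": cohort,
                "systemic_treatment": treat,
            }
        )
    )

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "sample_id": sample_ids,
                "er_status": er,
                "subtype": subtype,
                "proliferation": P,
                "hypoxia": H,
                "driver_z": driver_z,
                "latent_event_time": times,
            }
        ),
        beta_schedule=config.beta_schedule,
        baseline_hazard=config.baseline_hazard,
    )
    return SimulatedCohort(expression, clinical, signatures, truth)


# ---------------------------------------------------------------------------
# expectations


def _event_probability(z: float, segs, mu: float, tau: float) -> float:
    """P(event observed before random/administrative censoring) given z."""
    p = 0.0
    surv = 1.0  # P(T > a, C_rand > a)
    for a, b, lam0, bet in segs:
        if a >= tau:
            break
        end = min(b, tau)
        lam = lam0 * math.exp(bet * z)
        total = lam + mu
        if total > 0:
            p += surv * (lam / total) * (1.0 - math.exp(-total * (end - a)))
            surv *= math.exp(-total * (end - a))
    return p


def expected_event_count(config: SimulationConfig, truth: GroundTruth | None = None) -> float:
    """Expected number of observed events under the generating model.

    With ``truth`` supplied, conditions on the simulated driver values;
    otherwise integrates over a standard-normal driver with
    Gauss-Hermite quadrature. Used to sanity-check simulations (the
    empirical count is binomial around this value).
    """
    mu = config.random_censoring_rate
    tau = config.admin_censor_years
    total = 0.0
    if truth is not None:
        tab = truth.table
        for st in ("positive", "negative"):
            segs = _merge_segments(config.baseline_hazard[st], config.beta_schedule[st])
            for z in tab.loc[tab["er_status"] == st, "driver_z"]:
                total += _event_probability(float(z), segs, mu, tau)
        return total
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    weights = weights / weights.sum()
    for st, frac in (
        ("positive", config.er_positive_fraction),
        ("negative", 1.0 - config.er_positive_fraction),
    ):
        n_st = config.n_samples * frac
        segs = _merge_segments(config.baseline_hazard[st], config.beta_schedule[st])
        p = sum(w * _event_probability(float(zk), segs, mu, tau) for zk, w in zip(nodes, weights))
        total += n_st * p
    return total
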