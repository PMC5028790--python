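"""Hypothesis-driven health-outcome models and AICc multimodel inference.

A fixed set of ten hypotheses (H0-H8, with H7 split into a rank-by-sex
and a certainty-by-sex variant) relates each health outcome to sex, age
class, dominance rank (proportion outranked, 0-1) and dominance
certainty (DC, 0.5-1), up to the full sex x rank x DC interaction.
Outcomes are fit as log-link GLMMs with a group (cage) random intercept:
negative binomial for IL-6, TNF-alpha and diarrhea bout counts, gamma
for CRP.  Blood outcomes control for sample-processing order; CRP
additionally controls for IL-6; diarrhea carries a log observation-days
offset.

Model comparison follows standard information-theoretic practice:
AICc, dAICc, model likelihood L = exp(-dAICc/2), Akaike weights, and
evidence ratios (best weight / comparison weight).  When the best model
holds < 0.90 of the weight, all models within dAICc <= 5 (except the
null) form the candidate set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import patsy

from .glmm import GLMMResult, fit_glmm

HYPOTHESIS_TERMS: dict[str, str] = {
    "H0": "",
    "H1": "sex + age_cat",
    "H2": "sex + age_cat + rank",
    "H3": "sex + age_cat + dc",
    "H4": "sex + age_cat + rank + dc",
    "H5": "sex + age_cat + rank + dc + rank:dc",
    "H6": "sex + age_cat + rank + dc + rank:age_cat",
    "H7a": "sex + age_cat + rank + dc + rank:sex",
    "H7b": "sex + age_cat + rank + dc + dc:sex",
    "H8": ("sex + age_cat + rank + dc + rank:dc + rank:sex + dc:sex"
           " + rank:dc:sex"),
}

OUTCOME_FAMILY = {
    "crp": "gamma",
    "il6": "negbin",
    "tnfa": "negbin",
    "diarrhea": "negbin",
}

OUTCOME_CONTROLS = {
    "crp": "sampling_order + il6",
    "il6": "sampling_order",
    "tnfa": "sampling_order",
    "diarrhea": "",
}

OUTCOME_COLUMN = {
    "crp": "crp",
    "il6": "il6",
    "tnfa": "tnfa",
    "diarrhea": "diarrhea_bouts",
}

WEIGHT_THRESHOLD = 0.90
DELTA_AICC_MAX = 5.0


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    hypothesis: str
    outcome: str

    def __post_init__(self):
        if self.hypothesis not in HYPOTHESIS_TERMS:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if self.outcome not in OUTCOME_FAMILY:
            raise ValueError(f"unknown outcome {self.outcome!r}")

    @property
    def family(self) -> str:
        return OUTCOME_FAMILY[self.outcome]

    @property
    def formula_rhs(self) -> str:
        controls = OUTCOME_CONTROLS[self.outcome]
        terms = HYPOTHESIS_TERMS[self.hypothesis]
        parts = [p for p in (controls, terms) if p]
        rhs = " + ".join(parts) if parts else "1"
        # sex/age enter as treatment-coded categoricals: males and adults
        # (6-12 y) are the referent levels
        rhs = rhs.replace("sex", "C(sex, Treatment('M'))")
        rhs = rhs.replace("age_cat", "C(age_cat, Treatment('6-12'))")
        return rhs


def fit_outcome_model(
    data: pd.DataFrame, spec: ModelSpec, seed: int = 0
) -> GLMMResult:
    """Fit one hypothesis for one outcome on the per-animal table.

    ``data`` needs columns: the outcome, ``sex``, ``age_cat``, ``rank``,
    ``dc``, ``group_id``, plus ``sampling_order``/``il6`` for blood
    outcomes and ``observation_days`` for diarrhea.  The fit itself is
    deterministic; ``seed`` is accepted for interface stability.
    """
    ycol = OUTCOME_COLUMN[spec.outcome]
    needed = [ycol, "group_id"]
    if spec.outcome == "diarrhea":
        needed.append("observation_days")
    df = data.dropna(subset=[c for c in needed if c in data.columns]).copy()
    if df["group_id"].nunique() < 2:
        raise ValueError("random intercept needs at least 2 groups")
    X = patsy.dmatrix(spec.formula_rhs, df, return_type="dataframe")
    y = df[ycol].to_numpy(dtype=float)
    offset = None
    if spec.outcome == "diarrhea":
        days = df["observation_days"].to_numpy(dtype=float)
        if (days <= 0).any():
            raise ValueError("observation_days must be positive for diarrhea")
        offset = np.log(days)
    names = [_clean_term(t) for t in X.columns]
    return fit_glmm(
        y, X.to_numpy(), df["group_id"].to_numpy(),
        family=spec.family, offset=offset, param_names=names,
    )


def _clean_term(term: str) -> str:
    """Readable coefficient names: C(sex, Treatment('M'))[T.F] -> sex[F]."""
    out = term.replace("C(sex, Treatment('M'))", "sex")
    out = out.replace("C(age_cat, Treatment('6-12'))", "age_cat")
    out = out.replace("[T.", "[")
    return out


def selection_table(fits: dict[str, GLMMResult]) -> pd.DataFrame:
    """Selection table (AICc, dAICc, L, Akaike weight, evidence ratio)."""
    aicc = {h: f.aicc for h, f in fits.items() if f.converged}
    if len(aicc) < 2:
        raise ValueError("need at least 2 converged fits")
    return selection_from_aicc(aicc)


def selection_from_aicc(aicc: dict[str, float]) -> pd.DataFrame:
    """Selection arithmetic from AICc values alone."""
    best = min(aicc.values())
    return selection_from_deltas({h: a - best for h, a in aicc.items()},
                                 aicc=aicc)


def selection_from_deltas(
    deltas: dict[str, float], aicc: dict[str, float] | None = None
) -> pd.DataFrame:
    """Selection arithmetic from dAICc values alone.

    L = exp(-dAICc/2); w = L / sum(L); evidence ratio = w_best / w.
    """
    hyps = sorted(deltas, key=lambda h: deltas[h])
    d = np.array([deltas[h] for h in hyps], dtype=float)
    if d.min() < -1e-9:
        raise ValueError("dAICc values must be nonnegative")
    lik = np.exp(-0.5 * d)
    w = lik / lik.sum()
    table = pd.DataFrame({
        "hypothesis": hyps,
        "aicc": [aicc[h] for h in hyps] if aicc else np.nan,
        "delta_aicc": d,
        "likelihood": lik,
        "weight": w,
        "evidence_ratio": w[0] / w,
    })
    return table.set_index("hypothesis")


def candidate_set(
    table: pd.DataFrame,
    weight_threshold: float = WEIGHT_THRESHOLD,
    delta_max: float = DELTA_AICC_MAX,
    null_hypothesis: str = "H0",
) -> list[str]:
    """Models retained for inference.

    A single best model is kept when it carries >= 90% of the Akaike
    weight; otherwise all models within dAICc <= 5 are kept.  The null
    model is excluded from multi-model candidate sets — it can sit
    within dAICc <= 5 purely by its parsimony penalty while carrying no
    explanatory terms to interpret.
    """
    ordered = table.sort_values("delta_aicc")
    best = ordered.index[0]
    if ordered["weight"].iloc[0] >= weight_threshold:
        return [best]
    keep = [h for h in ordered.index[ordered["delta_aicc"] <= delta_max]
            if h != null_hypothesis]
    return keep


@dataclasses.dataclass
class EffectSize:
    """Multiplicative (fold) change of an outcome for a predictor shift."""

    predictor: str
    delta: float
    moderators: dict[str, float]
    effective_slope: float
    fold_change: float  # multiplicative factor, exp(slope * delta)

    @property
    def magnitude(self) -> float:
        """Fold change expressed as a number >= 1."""
        return self.fold_change if self.fold_change >= 1 else 1.0 / self.fold_change

    @property
    def direction(self) -> str:
        if np.isclose(self.fold_change, 1.0):
            return "no change"
        return "increase" if self.fold_change > 1 else "decrease"

    def describe(self) -> str:
        if self.direction == "no change":
            return "no change"
        return f"{self.magnitude:.2f} times {self.direction}"


def fold_change(
    coefficients: dict[str, float],
    predictor: str,
    delta: float,
    moderators: dict[str, float] | None = None,
) -> EffectSize:
    """Fold change in the outcome when ``predictor`` shifts by ``delta``.

    On the log link, the effective slope of a predictor is its main
    effect plus every interaction coefficient involving it, each
    evaluated at the supplied moderator values (interaction terms are
    named ``a:b``).  The fold change is exp(effective slope x delta).
    """
    moderators = dict(moderators or {})
    slope = 0.0
    found = False
    for term, beta in coefficients.items():
        parts = term.split(":")
        if predictor not in parts:
            continue
        found = True
        factor = 1.0
        for other in parts:
            if other == predictor:
                continue
            if other not in moderators:
                raise ValueError(
                    f"term {term!r} needs a value for moderator {other!r}"
                )
            factor *= moderators[other]
        slope += beta * factor
    if not found:
        raise ValueError(f"predictor {predictor!r} not in coefficients")
    return EffectSize(
        predictor=predictor,
        delta=delta,
        moderators=moderators,
        effective_slope=slope,
        fold_change=float(np.exp(slope * delta)),
    )


def fit_hypothesis_set(
    data: pd.DataFrame,
    outcome: str,
    hypotheses: list[str] | None = None,
    seed: int = 0,
) -> dict[str, GLMMResult]:
    """Fit the full hypothesis set for one outcome."""
    hyps = hypotheses or list(HYPOTHESIS_TERMS)
    fits = {}
    for h in hyps:
        fits[h] = fit_outcome_model(data, ModelSpec(h, outcome), seed=seed)
    return fits
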