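"""End-to-end orchestration: ingest -> dominance -> ranking -> models.

A run is driven by a serializable :class:`RunConfig` (YAML on disk) and
produces a per-animal rank/certainty table, per-outcome AICc selection
tables, coefficient tables, candidate sets, effect-size summaries and a
machine-readable manifest.  Deterministic stages are bit-identical under
the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
import time

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dominance import infer_dominance
from .health_models import (
    HYPOTHESIS_TERMS,
    OUTCOME_FAMILY,
    ModelSpec,
    candidate_set,
    fit_outcome_model,
    fold_change,
    selection_table,
)
from .observations import (
    build_winloss,
    diarrhea_summary,
    preprocess_biomarkers,
    read_events,
    read_health,
    read_subjects,
)
from .ranking import (
    categorize_certainty,
    find_lowest_cost_order,
    node_removal_sensitivity,
    proportion_outranked,
)
from .synthetic import make_paper_regime_study

log = logging.getLogger("domcert")

PRESETS = ("paper-regime",)


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    events: str | None = None
    subjects: str | None = None
    health: str | None = None
    preset: str | None = None
    seed: int = 0
    max_path_len: int = 3
    indirect_beta: float = 0.5
    prior: float = 1.0
    anneal_seed: int = 0
    outcomes: tuple[str, ...] = ("crp", "il6", "tnfa", "diarrhea")
    hypotheses: tuple[str, ...] = tuple(HYPOTHESIS_TERMS)
    outdir: str = "domcert_run"

    def __post_init__(self):
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        bad = [o for o in self.outcomes if o not in OUTCOME_FAMILY]
        if bad:
            raise ValueError(f"unknown outcome name(s): {bad}")
        bad = [h for h in self.hypotheses if h not in HYPOTHESIS_TERMS]
        if bad:
            raise ValueError(f"unknown hypothesis id(s): {bad}")
        if self.preset is None and not (
            self.events and self.subjects and self.health
        ):
            raise ValueError("either a preset or all three input paths required")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def rank_certainty_table(
    events, subjects: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """Per-animal dominance inference, run group by group."""
    rows = []
    for g, roster in subjects.groupby("group_id", sort=True):
        ids = list(roster["animal_id"])
        group_events = [
            e for e in events
            if e.actor_id in set(ids) and e.recipient_id in set(ids)
        ]
        W = build_winloss(group_events, ids)
        res = infer_dominance(
            W, max_len=config.max_path_len,
            beta=config.indirect_beta, prior=config.prior,
        )
        order = find_lowest_cost_order(res.dp, res.ids, seed=config.anneal_seed)
        prop = proportion_outranked(order)
        dc = dict(zip(res.ids, res.dc))
        cats = categorize_certainty(dc).categories if len(ids) >= 10 else {
            a: "moderate" for a in ids
        }
        t = res.transitivity.t
        for a in ids:
            rows.append({
                "animal_id": a,
                "group_id": g,
                "ordinal_rank": order.ordinal(a),
                "rank": prop[a],
                "dc": dc[a],
                "certainty_category": cats[a],
                "group_transitivity": t,
            })
    return pd.DataFrame(rows)


def sensitivity_by_betweenness(
    events, subjects: pd.DataFrame, config: RunConfig
) -> dict:
    """DC stability under removal of the highest-, median- and
    lowest-betweenness animal of each group's aggression network."""
    import networkx as nx

    report: dict = {}
    kwargs = dict(max_len=config.max_path_len, beta=config.indirect_beta,
                  prior=config.prior)
    for g, roster in subjects.groupby("group_id", sort=True):
        ids = list(roster["animal_id"])
        W = build_winloss(
            [e for e in events
             if e.actor_id in set(ids) and e.recipient_id in set(ids)],
            ids,
        )
        G = nx.from_numpy_array((W.counts > 0).astype(int),
                                create_using=nx.DiGraph)
        bc = nx.betweenness_centrality(G)
        ranked = sorted(bc, key=bc.get)
        picks = {ids[ranked[-1]], ids[ranked[len(ranked) // 2]],
                 ids[ranked[0]]}
        rep = node_removal_sensitivity(W, sorted(picks), **kwargs)
        report[str(g)] = rep.correlations
    return report


def assemble_model_table(
    subjects: pd.DataFrame, ranks: pd.DataFrame, health: pd.DataFrame
) -> pd.DataFrame:
    """Merge covariates, dominance estimates and health outcomes."""
    df = subjects.merge(
        ranks[["animal_id", "rank", "dc", "ordinal_rank",
               "certainty_category"]],
        on="animal_id", how="left",
    )
    df = df.rename(columns={"age_category": "age_cat"})
    if health is not None and len(health):
        df = df.merge(diarrhea_summary(health), on="animal_id", how="left")
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the artifact dictionary.

    Writes CSV/JSON artifacts plus a run manifest under
    ``config.outdir``.
    """
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    timings = {}
    try:
        t0 = time.time()
        if config.preset == "paper-regime":
            log.info("simulating preset study (seed=%d)", config.seed)
            study = make_paper_regime_study(seed=config.seed)
            events, subjects, health = study.events, study.subjects, study.health
        else:
            log.info("reading inputs")
            events = read_events(config.events)
            subjects = read_subjects(config.subjects)
            health = read_health(config.health)
        timings["ingest"] = time.time() - t0

        t0 = time.time()
        subjects = preprocess_biomarkers(subjects)
        ranks = rank_certainty_table(events, subjects, config)
        timings["dominance"] = time.time() - t0
        log.info("dominance inference done (%.1fs)", timings["dominance"])

        table = assemble_model_table(subjects, ranks, health)
        ranks_path = outdir / "rank_certainty.csv"
        ranks.to_csv(ranks_path, index=False)
        table.to_csv(outdir / "model_table.csv", index=False)

        t0 = time.time()
        sensitivity = sensitivity_by_betweenness(events, subjects, config)
        with open(outdir / "sensitivity.json", "w") as fh:
            json.dump(sensitivity, fh, indent=2)
        timings["sensitivity"] = time.time() - t0

        t0 = time.time()
        selections, candidates, effects, coeffs = {}, {}, {}, []
        for outcome in config.outcomes:
            fits = {}
            for h in config.hypotheses:
                try:
                    fits[h] = fit_outcome_model(table, ModelSpec(h, outcome))
                except ValueError as exc:
                    log.warning("%s/%s failed: %s", outcome, h, exc)
            sel = selection_table(fits)
            selections[outcome] = sel
            sel.to_csv(outdir / f"selection_{outcome}.csv")
            cand = candidate_set(sel)
            candidates[outcome] = cand
            for h in cand:
                fit = fits[h]
                for name, beta, se in zip(fit.param_names, fit.params, fit.se):
                    coeffs.append({
                        "outcome": outcome, "hypothesis": h, "term": name,
                        "coef": beta, "se": se,
                    })
            effects[outcome] = _effect_report(fits, cand)
            log.info("%s: best=%s candidates=%s", outcome, sel.index[0], cand)
        timings["models"] = time.time() - t0

        pd.DataFrame(coeffs).to_csv(outdir / "coefficients.csv", index=False)
        with open(outdir / "candidate_sets.json", "w") as fh:
            json.dump(candidates, fh, indent=2)
        with open(outdir / "effect_sizes.json", "w") as fh:
            json.dump(effects, fh, indent=2)
        manifest = {
            "package_version": __version__,
            "config": config.to_dict(),
            "seeds": {"simulation": config.seed, "annealing": config.anneal_seed},
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
            "n_events": len(events),
            "n_subjects": len(subjects),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return {
            "ranks": ranks,
            "model_table": table,
            "sensitivity": sensitivity,
            "selections": selections,
            "candidates": candidates,
            "effects": effects,
            "manifest": manifest,
        }
    finally:
        log.removeHandler(handler)
        handler.close()


def _effect_report(fits, cand: list[str]) -> dict:
    """Fold changes for the standard predictor shifts, per candidate model."""
    report = {}
    for h in cand:
        coefs = fits[h].coef_dict()
        entry = {}
        mods = {}
        if any(":" in t and "dc" in t.split(":") for t in coefs):
            mods["rank"] = 0.5
        if any(":" in t and "sex[F]" in t.split(":") for t in coefs):
            mods["sex[F]"] = 0.0  # evaluated for the referent (males)
        if "dc" in coefs:
            try:
                entry["dc_minus_0.10"] = fold_change(
                    coefs, "dc", -0.10, {**mods, "rank": 0.5} if "rank" in mods
                    else mods).fold_change
            except ValueError:
                pass
        if "rank" in coefs:
            rmods = dict(mods)
            rmods.pop("rank", None)
            if any(":" in t and "rank" in t.split(":") for t in coefs):
                rmods["dc"] = 0.85
            try:
                entry["rank_plus_0.25"] = fold_change(
                    coefs, "rank", 0.25, rmods).fold_change
            except ValueError:
                pass
        report[h] = entry
    return report
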