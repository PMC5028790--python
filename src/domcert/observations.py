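"""Raw study records: agonistic events, health checks, subject covariates.

This module is the ingest layer of the pipeline.  It parses dyadic
agonistic-interaction records, builds the directed win/loss count matrix
that the dominance machinery consumes, counts diarrhea bouts from
twice-weekly health checks, and applies the standard preprocessing to
serum biomarkers (assay detection floor, high-CRP flagging).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

AGGRESSION_CATEGORIES = ("threat", "mild", "moderate", "intense")
SUBMISSION_CATEGORIES = (
    "freeze/turn away",
    "move away",
    "run away <6m",
    "run away >6m",
    "crouch",
    "none",
)

#: Assay sensitivity floor for the cytokine multiplex (pg/mL).  Values
#: strictly below this are unquantifiable and assigned ``CYTOKINE_ASSIGNED``.
CYTOKINE_DETECTION_LIMIT = 1.6
CYTOKINE_ASSIGNED = 1.0
#: CRP above this (mg/L) suggests acute infection; such animals are flagged
#: but retained.
CRP_FLAG_THRESHOLD = 10.0

EVENT_COLUMNS = ("date", "actor", "recipient", "aggression", "submission")


class RecordError(ValueError):
    """Raised when an input file violates the documented schema."""


@dataclasses.dataclass(frozen=True)
class AgonisticEvent:
    """One directed aggressive interaction (actor aggresses recipient)."""

    timestamp: _dt.date
    actor_id: str
    recipient_id: str
    aggression_category: str
    submission_category: str = "none"

    def __post_init__(self) -> None:
        if self.actor_id == self.recipient_id:
            raise RecordError(
                f"self-directed event for animal {self.actor_id!r}"
            )
        if self.aggression_category not in AGGRESSION_CATEGORIES:
            raise RecordError(
                f"unknown aggression category {self.aggression_category!r}"
            )
        if self.submission_category not in SUBMISSION_CATEGORIES:
            raise RecordError(
                f"unknown submission category {self.submission_category!r}"
            )


@dataclasses.dataclass
class WinLossMatrix:
    """Square matrix of directed win counts: row actor beats column recipient."""

    ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n = len(self.ids)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match ids")
        if (self.counts < 0).any():
            raise ValueError("negative win counts")
        if np.diag(self.counts).any():
            raise ValueError("nonzero diagonal in win/loss matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    def total(self) -> float:
        return float(self.counts.sum())

    def index_of(self, animal_id: str) -> int:
        return self.ids.index(animal_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)

    def drop(self, animal_id: str) -> "WinLossMatrix":
        """Return a copy with one animal (row and column) removed."""
        i = self.index_of(animal_id)
        keep = [j for j in range(self.n) if j != i]
        return WinLossMatrix(
            [self.ids[j] for j in keep], self.counts[np.ix_(keep, keep)]
        )


def read_events(path) -> list[AgonisticEvent]:
    """Read agonistic events from a CSV file.

    The file must carry the header columns ``date, actor, recipient,
    aggression, submission`` (ISO-8601 dates).  Any malformed row is
    reported with its line number and the whole read fails: silent
    partial ingest of behavioural data is never acceptable.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise RecordError(f"events file missing required columns: {missing}")
    events: list[AgonisticEvent] = []
    problems: list[str] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            ts = _dt.date.fromisoformat(str(getattr(row, "date"))[:10])
            events.append(
                AgonisticEvent(
                    timestamp=ts,
                    actor_id=getattr(row, "actor"),
                    recipient_id=getattr(row, "recipient"),
                    aggression_category=getattr(row, "aggression"),
                    submission_category=getattr(row, "submission") or "none",
                )
            )
        except (RecordError, ValueError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise RecordError(
            "invalid event rows:\n" + "\n".join(problems)
        )
    return events


def build_winloss(
    events: Iterable[AgonisticEvent],
    subjects: Sequence[str] | pd.DataFrame,
    include_categories: Sequence[str] | None = None,
) -> WinLossMatrix:
    """Tally directed wins into an N x N count matrix.

    Every aggressive event is a win for the actor, whether or not a
    submission was recorded; by default all aggression severities are
    retained.  ``subjects`` fixes the node set (and matrix order), so
    animals that never interacted still appear with all-zero rows.
    """
    if isinstance(subjects, pd.DataFrame):
        ids = list(subjects["animal_id"])
    else:
        ids = list(subjects)
    if len(set(ids)) != len(ids):
        raise RecordError("duplicate animal ids in subjects")
    index = {a: i for i, a in enumerate(ids)}
    counts = np.zeros((len(ids), len(ids)))
    unknown: set[str] = set()
    for ev in events:
        if include_categories is not None and (
            ev.aggression_category not in include_categories
        ):
            continue
        try:
            counts[index[ev.actor_id], index[ev.recipient_id]] += 1
        except KeyError:
            unknown.update(
                a for a in (ev.actor_id, ev.recipient_id) if a not in index
            )
    if unknown:
        raise RecordError(f"events reference unknown animal ids: {sorted(unknown)}")
    return WinLossMatrix(ids, counts)


def count_diarrhea_bouts(observations: pd.DataFrame) -> tuple[int, int]:
    """Count diarrhea bouts and observed days for one animal.

    A bout is a maximal run of consecutive *observation* days with liquid
    stool; it ends only at an observed day without liquid stool.  Days on
    which the animal was absent neither extend nor break a run.

    Parameters
    ----------
    observations
        Rows for a single animal, sorted by date, with boolean columns
        ``observed`` and ``liquid_stool``.
    """
    if len(observations) == 0:
        return 0, 0
    obs = observations.loc[observations["observed"].astype(bool)]
    flags = obs["liquid_stool"].astype(bool).to_numpy()
    if (observations["liquid_stool"].astype(bool)
            & ~observations["observed"].astype(bool)).any():
        raise RecordError("liquid stool recorded on an unobserved day")
    # bouts = number of 0->1 transitions in the observed-day flag sequence
    bouts = int(flags[0]) + int((flags[1:] & ~flags[:-1]).sum()) if len(flags) else 0
    return bouts, int(len(flags))


AGE_CATEGORIES = ("3", "4-5", "6-12", "13+")
AGE_REFERENT = "6-12"  # adults


def age_category(age_years: float) -> str:
    """Bin age in years into juvenile / subadult / adult / geriatric classes.

    The study colony contained no animal younger than three, so ages
    below 3 are rejected rather than silently binned.
    """
    if age_years < 3:
        raise ValueError(f"age {age_years} below study minimum of 3 years")
    if age_years < 4:
        return "3"
    if age_years < 6:
        return "4-5"
    if age_years < 13:
        return "6-12"
    return "13+"


def preprocess_biomarkers(subjects: pd.DataFrame) -> pd.DataFrame:
    """Apply assay-floor substitution and high-CRP flagging.

    Cytokine values (IL-6, TNF-alpha) strictly below the 1.6 pg/mL assay
    sensitivity are assigned 1; a value of exactly 1.6 is kept.  CRP
    above 10 is flagged (possible acute infection) but the animal is
    retained.  Returns a copy; the input is not modified.
    """
    out = subjects.copy()
    for col in ("il6", "tnfa", "crp"):
        if col in out.columns:
            vals = out[col].astype(float)
            if (vals.dropna() < 0).any():
                raise RecordError(f"negative {col} concentration")
    for col in ("il6", "tnfa"):
        if col in out.columns:
            vals = out[col].astype(float)
            out[col] = vals.where(
                ~(vals < CYTOKINE_DETECTION_LIMIT), CYTOKINE_ASSIGNED
            )
    if "crp" in out.columns:
        out["crp_over_10"] = out["crp"].astype(float) > CRP_FLAG_THRESHOLD
    return out


def read_subjects(path) -> pd.DataFrame:
    """Read the subject roster CSV (animal_id, sex, age, group_id, ...)."""
    df = pd.read_csv(path, dtype={"animal_id": str, "group_id": str})
    required = {"animal_id", "sex", "age", "group_id"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"subjects file missing required columns: {sorted(missing)}")
    bad_sex = set(df["sex"]) - {"M", "F"}
    if bad_sex:
        raise RecordError(f"unknown sex codes: {sorted(bad_sex)}")
    if "age_category" not in df.columns:
        df["age_category"] = [age_category(a) for a in df["age"].astype(float)]
    return df


def read_health(path) -> pd.DataFrame:
    """Read twice-weekly health observations (animal_id, date, observed, liquid_stool)."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    required = {"animal_id", "date", "observed", "liquid_stool"}
    missing = required - set(df.columns)
    if missing:
        raise RecordError(f"health file missing required columns: {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["observed"] = df["observed"].astype(bool)
    df["liquid_stool"] = df["liquid_stool"].astype(bool)
    if (df["liquid_stool"] & ~df["observed"]).any():
        raise RecordError("liquid stool recorded on an unobserved day")
    return df.sort_values(["animal_id", "date"]).reset_index(drop=True)


def diarrhea_summary(health: pd.DataFrame) -> pd.DataFrame:
    """Per-animal diarrhea bout counts and observed-day totals."""
    rows = []
    for animal, grp in health.groupby("animal_id", sort=True):
        bouts, days = count_diarrhea_bouts(grp.sort_values("date"))
        rows.append({"animal_id": animal, "diarrhea_bouts": bouts,
                     "observation_days": days})
    return pd.DataFrame(rows, columns=["animal_id", "diarrhea_bouts",
                                       "observation_days"])
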