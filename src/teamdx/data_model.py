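"""Domain types, label vocabularies, and deterministic variable transforms.

The unit of observation is one rater x lesion x session trial.  Raters give a
three-level diagnosis (collapsed from a five-level forced choice), a
confidence level, and -- in the assisted session only -- their reading of the
AI output and of its confidence.  Ground truth (histology) is binary and
lesion-level, as is the algorithmically decoded AI label.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "Session",
    "RawChoice",
    "Diagnosis",
    "Confidence",
    "PerceivedAiDx",
    "AiConfidence",
    "AlgorithmicAiDx",
    "Histology",
    "Expertise",
    "TrialRecord",
    "Cohort",
    "CohortValidationError",
    "map_judgment",
    "confidence_score",
    "score_to_belief",
    "is_correct",
    "agreement",
    "validate_cohort",
    "COHORT_COLUMNS",
]


class Session(enum.StrEnum):
    S1 = "S1"
    S2 = "S2"


class RawChoice(enum.StrEnum):
    ADENOMA = "Adenoma"
    HYPERPLASTIC = "Hyperplastic"
    SSL = "SSL"
    CARCINOMA = "Carcinoma"
    UNCERTAIN = "Uncertain"


class Diagnosis(enum.StrEnum):
    ADENOMA = "Adenoma"
    NON_ADENOMA = "NonAdenoma"
    UNCERTAIN = "Uncertain"


class Confidence(enum.StrEnum):
    VERY_LOW = "VeryLow"
    LOW = "Low"
    HIGH = "High"
    VERY_HIGH = "VeryHigh"
    UNCERTAIN = "Uncertain"


class PerceivedAiDx(enum.StrEnum):
    ADENOMA = "Adenoma"
    NON_ADENOMA = "NonAdenoma"
    UNCERTAIN = "Uncertain"
    NOT_NOTICED = "NotNoticed"


class AiConfidence(enum.StrEnum):
    VERY_LOW = "VeryLow"
    LOW = "Low"
    HIGH = "High"
    VERY_HIGH = "VeryHigh"


class AlgorithmicAiDx(enum.StrEnum):
    ADENOMA = "Adenoma"
    NON_ADENOMA = "NonAdenoma"
    UNDETERMINED = "Undetermined"


class Histology(enum.StrEnum):
    ADENOMA = "Adenoma"
    NON_ADENOMA = "NonAdenoma"


class Expertise(enum.StrEnum):
    EXPERT = "Expert"
    NON_EXPERT = "NonExpert"


#: Canonical long-format CSV column order; empty string marks structurally
#: absent fields (e.g. perceived AI fields in S1 rows).
COHORT_COLUMNS = (
    "rater_id",
    "lesion_id",
    "session",
    "raw_choice",
    "diagnosis",
    "confidence",
    "perceived_ai_dx",
    "perceived_ai_conf",
    "algorithmic_ai_dx",
    "histology",
    "expertise",
)

_DETERMINATE = (Diagnosis.ADENOMA.value, Diagnosis.NON_ADENOMA.value)

_RAW_TO_DIAGNOSIS = {
    RawChoice.ADENOMA.value: Diagnosis.ADENOMA,
    RawChoice.CARCINOMA.value: Diagnosis.ADENOMA,
    RawChoice.HYPERPLASTIC.value: Diagnosis.NON_ADENOMA,
    RawChoice.SSL.value: Diagnosis.NON_ADENOMA,
    RawChoice.UNCERTAIN.value: Diagnosis.UNCERTAIN,
}

# The 1..9 belief score: 9 = strong belief in adenoma, 1 = strong belief in
# non-adenoma, 5 = uncertain.  Monotone and symmetric around 5; invertible
# everywhere except at 5 (which collapses to Uncertain/Uncertain).
_CONF_ORDER = (
    Confidence.VERY_LOW.value,
    Confidence.LOW.value,
    Confidence.HIGH.value,
    Confidence.VERY_HIGH.value,
)
_SCORE = {
    (Diagnosis.ADENOMA.value, Confidence.VERY_LOW.value): 6,
    (Diagnosis.ADENOMA.value, Confidence.LOW.value): 7,
    (Diagnosis.ADENOMA.value, Confidence.HIGH.value): 8,
    (Diagnosis.ADENOMA.value, Confidence.VERY_HIGH.value): 9,
    (Diagnosis.UNCERTAIN.value, Confidence.UNCERTAIN.value): 5,
    (Diagnosis.NON_ADENOMA.value, Confidence.VERY_LOW.value): 4,
    (Diagnosis.NON_ADENOMA.value, Confidence.LOW.value): 3,
    (Diagnosis.NON_ADENOMA.value, Confidence.HIGH.value): 2,
    (Diagnosis.NON_ADENOMA.value, Confidence.VERY_HIGH.value): 1,
}
_SCORE_INV = {v: k for k, v in _SCORE.items()}


def map_judgment(raw_choice: Union[RawChoice, str]) -> Diagnosis:
    """Collapse the five-level forced choice onto the three-level diagnosis.

    Adenoma and Carcinoma map to Adenoma; Hyperplastic and SSL map to
    NonAdenoma; Uncertain is preserved.
    """
    key = str(raw_choice)
    try:
        return _RAW_TO_DIAGNOSIS[key]
    except KeyError:
        raise ValueError(f"unknown raw choice: {key!r}") from None


def confidence_score(
    diagnosis: Union[Diagnosis, str], confidence: Union[Confidence, str]
) -> int:
    """Belief score in 1..9 (9 = certain adenoma, 1 = certain non-adenoma).

    Raises ``ValueError`` when the diagnosis/confidence pair violates the
    record invariant (Uncertain in one field but not the other).
    """
    key = (str(diagnosis), str(confidence))
    try:
        return _SCORE[key]
    except KeyError:
        raise ValueError(
            f"invalid diagnosis/confidence pair: {key[0]!r}, {key[1]!r}"
        ) from None


def score_to_belief(score: int) -> tuple[Diagnosis, Confidence]:
    """Inverse of :func:`confidence_score`; 5 maps to (Uncertain, Uncertain)."""
    try:
        dx, conf = _SCORE_INV[int(score)]
    except (KeyError, ValueError):
        raise ValueError(f"score must be an integer in 1..9, got {score!r}") from None
    return Diagnosis(dx), Confidence(conf)


def is_correct(
    diagnosis: Union[Diagnosis, str], histology: Union[Histology, str]
) -> bool:
    """Whether a diagnosis matches the binary ground truth.

    Uncertain diagnoses can never match and therefore count as incorrect.
    """
    hist = str(histology)
    if hist not in _DETERMINATE:
        raise ValueError(f"histology must be determinate, got {hist!r}")
    return str(diagnosis) == hist


def agreement(md_dx: Union[Diagnosis, str], ai_dx) -> Optional[bool]:
    """Label agreement between a rater diagnosis and an AI label.

    Returns ``None`` (undefined) when the AI label is indeterminate
    (Uncertain / NotNoticed / Undetermined); callers must state their own
    exclusion policy for those trials.  A rater ``Uncertain`` never matches a
    determinate AI label.
    """
    ai = str(ai_dx)
    if ai not in _DETERMINATE:
        return None
    return str(md_dx) == ai


@dataclass(frozen=True, slots=True)
class TrialRecord:
    """One rater x lesion x session observation with record-level invariants."""

    rater_id: str
    lesion_id: str
    session: Session
    diagnosis: Diagnosis
    confidence: Confidence
    histology: Histology
    algorithmic_ai_dx: AlgorithmicAiDx
    expertise: Expertise
    raw_choice: Optional[RawChoice] = None
    perceived_ai_dx: Optional[PerceivedAiDx] = None
    perceived_ai_conf: Optional[AiConfidence] = None

    def __post_init__(self) -> None:
        if (self.confidence == Confidence.UNCERTAIN) != (
            self.diagnosis == Diagnosis.UNCERTAIN
        ):
            raise ValueError(
                "confidence must be Uncertain iff diagnosis is Uncertain "
                f"(got diagnosis={self.diagnosis!s}, confidence={self.confidence!s})"
            )
        if self.session == Session.S1:
            if self.perceived_ai_dx is not None or self.perceived_ai_conf is not None:
                raise ValueError("S1 records carry no perceived AI fields")
        else:
            if self.perceived_ai_dx is None:
                raise ValueError("S2 records must carry perceived_ai_dx")
            determinate = self.perceived_ai_dx in (
                PerceivedAiDx.ADENOMA,
                PerceivedAiDx.NON_ADENOMA,
            )
            if determinate != (self.perceived_ai_conf is not None):
                raise ValueError(
                    "perceived_ai_conf present iff perceived_ai_dx is determinate "
                    f"(got {self.perceived_ai_dx!s}, {self.perceived_ai_conf!s})"
                )
        if self.raw_choice is not None:
            if map_judgment(self.raw_choice) != self.diagnosis:
                raise ValueError(
                    f"raw_choice {self.raw_choice!s} maps to "
                    f"{map_judgment(self.raw_choice)!s}, not {self.diagnosis!s}"
                )

    def to_row(self) -> dict[str, str]:
        def s(x) -> str:
            return "" if x is None else str(x)

        return {
            "rater_id": self.rater_id,
            "lesion_id": self.lesion_id,
            "session": str(self.session),
            "raw_choice": s(self.raw_choice),
            "diagnosis": str(self.diagnosis),
            "confidence": str(self.confidence),
            "perceived_ai_dx": s(self.perceived_ai_dx),
            "perceived_ai_conf": s(self.perceived_ai_conf),
            "algorithmic_ai_dx": str(self.algorithmic_ai_dx),
            "histology": str(self.histology),
            "expertise": str(self.expertise),
        }


class CohortValidationError(ValueError):
    """Raised when trial records violate the cohort contract.

    Carries the full list of violations, each with row coordinates, so a
    caller can report every problem at once.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "\n  ".join(self.errors[:25])
        more = "" if len(self.errors) <= 25 else f"\n  ... {len(self.errors) - 25} more"
        super().__init__(f"cohort validation failed ({len(self.errors)} problems):\n  {preview}{more}")


@dataclass(frozen=True)
class Cohort:
    """A validated set of trial records plus rater/lesion metadata.

    ``df`` is the long-format table with exactly one row per
    (rater, lesion, session); construct via :func:`validate_cohort`.
    """

    df: pd.DataFrame
    raters: Mapping[str, str]   # rater_id -> expertise
    lesions: Mapping[str, str]  # lesion_id -> histology

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)

    @property
    def n_trials(self) -> int:
        """Rater x lesion trial count (per session)."""
        return self.n_raters * self.n_lesions

    def session(self, which: Union[Session, str]) -> pd.DataFrame:
        return self.df[self.df["session"] == str(which)]

    def subset_raters(self, rater_ids: Iterable[str]) -> "Cohort":
        ids = set(rater_ids)
        df = self.df[self.df["rater_id"].isin(ids)].reset_index(drop=True)
        return Cohort(
            df=df,
            raters={r: e for r, e in self.raters.items() if r in ids},
            lesions=dict(self.lesions),
        )

    def records(self) -> list[TrialRecord]:
        out = []
        for row in self.df.itertuples(index=False):
            out.append(
                TrialRecord(
                    rater_id=row.rater_id,
                    lesion_id=row.lesion_id,
                    session=Session(row.session),
                    raw_choice=RawChoice(row.raw_choice) if row.raw_choice else None,
                    diagnosis=Diagnosis(row.diagnosis),
                    confidence=Confidence(row.confidence),
                    perceived_ai_dx=(
                        PerceivedAiDx(row.perceived_ai_dx) if row.perceived_ai_dx else None
                    ),
                    perceived_ai_conf=(
                        AiConfidence(row.perceived_ai_conf) if row.perceived_ai_conf else None
                    ),
                    algorithmic_ai_dx=AlgorithmicAiDx(row.algorithmic_ai_dx),
                    histology=Histology(row.histology),
                    expertise=Expertise(row.expertise),
                )
            )
        return out


_VOCAB = {
    "session": {e.value for e in Session},
    "raw_choice": {e.value for e in RawChoice} | {""},
    "diagnosis": {e.value for e in Diagnosis},
    "confidence": {e.value for e in Confidence},
    "perceived_ai_dx": {e.value for e in PerceivedAiDx} | {""},
    "perceived_ai_conf": {e.value for e in AiConfidence} | {""},
    "algorithmic_ai_dx": {e.value for e in AlgorithmicAiDx},
    "histology": {e.value for e in Histology},
    "expertise": {e.value for e in Expertise},
}


def _as_dataframe(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [
            r.to_row() if isinstance(r, TrialRecord) else dict(r) for r in records
        ]
        df = pd.DataFrame(rows)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing column(s): {', '.join(missing)}"])
    df = df[list(COHORT_COLUMNS)].copy()
    for c in COHORT_COLUMNS:
        df[c] = df[c].fillna("").astype(str)
    return df


def validate_cohort(records) -> Cohort:
    """Validate trial records and assemble a :class:`Cohort`.

    ``records`` may be an iterable of :class:`TrialRecord` (or dicts) or a
    long-format DataFrame with the :data:`COHORT_COLUMNS`.  Every violation is
    collected and reported with row coordinates; nothing is imputed.
    """
    df = _as_dataframe(records)
    errors: list[str] = []

    # vocabulary membership
    for col, vocab in _VOCAB.items():
        bad = ~df[col].isin(vocab)
        for i in df.index[bad][:50]:
            errors.append(f"row {i}: invalid {col} value {df.at[i, col]!r}")
    if errors:
        raise CohortValidationError(errors)

    is_s1 = df["session"] == Session.S1.value
    is_s2 = ~is_s1

    # duplicate cells
    dup = df.duplicated(subset=["rater_id", "lesion_id", "session"], keep=False)
    if dup.any():
        cells = df.loc[dup, ["rater_id", "lesion_id", "session"]].drop_duplicates()
        for t in cells.itertuples(index=False):
            errors.append(
                f"duplicate record for (rater={t.rater_id}, lesion={t.lesion_id}, "
                f"session={t.session})"
            )

    # completeness: each rater x lesion must have both sessions
    cell_counts = df.groupby(["rater_id", "lesion_id"])["session"].nunique()
    incomplete = cell_counts[cell_counts < 2]
    for (r, l) in incomplete.index[:50]:
        errors.append(f"missing session record(s) for (rater={r}, lesion={l})")

    # confidence/diagnosis invariant
    bad_conf = (df["confidence"] == Confidence.UNCERTAIN.value) != (
        df["diagnosis"] == Diagnosis.UNCERTAIN.value
    )
    for i in df.index[bad_conf][:50]:
        errors.append(
            f"row {i}: confidence={df.at[i, 'confidence']!r} inconsistent with "
            f"diagnosis={df.at[i, 'diagnosis']!r}"
        )

    # session structure of perceived AI fields
    s1_with_ai = is_s1 & ((df["perceived_ai_dx"] != "") | (df["perceived_ai_conf"] != ""))
    for i in df.index[s1_with_ai][:50]:
        errors.append(f"row {i}: S1 record carries perceived AI fields")
    s2_missing = is_s2 & (df["perceived_ai_dx"] == "")
    for i in df.index[s2_missing][:50]:
        errors.append(f"row {i}: S2 record lacks perceived_ai_dx")
    determinate_ai = df["perceived_ai_dx"].isin(
        [PerceivedAiDx.ADENOMA.value, PerceivedAiDx.NON_ADENOMA.value]
    )
    bad_pconf = is_s2 & (determinate_ai != (df["perceived_ai_conf"] != ""))
    for i in df.index[bad_pconf][:50]:
        errors.append(
            f"row {i}: perceived_ai_conf must be present iff perceived_ai_dx is "
            f"determinate (got dx={df.at[i, 'perceived_ai_dx']!r}, "
            f"conf={df.at[i, 'perceived_ai_conf']!r})"
        )

    # lesion-level consistency
    for col in ("histology", "algorithmic_ai_dx"):
        per_lesion = df.groupby("lesion_id")[col].nunique()
        for l in per_lesion[per_lesion > 1].index:
            errors.append(f"lesion {l}: inconsistent {col} across records")
    per_rater = df.groupby("rater_id")["expertise"].nunique()
    for r in per_rater[per_rater > 1].index:
        errors.append(f"rater {r}: inconsistent expertise across records")

    if errors:
        raise CohortValidationError(errors)

    raters = (
        df.drop_duplicates("rater_id").set_index("rater_id")["expertise"].to_dict()
    )
    lesions = (
        df.drop_duplicates("lesion_id").set_index("lesion_id")["histology"].to_dict()
    )
    df = df.sort_values(["rater_id", "lesion_id", "session"], kind="mergesort")
    return Cohort(df=df.reset_index(drop=True), raters=raters, lesions=lesions)
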