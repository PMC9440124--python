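"""Confidence-calibration and agreement analyses.

Accuracy stratified by confidence level (own diagnosis in each session, or
the perceived AI diagnosis), opinion-switch rates on disagreement trials, AI
accuracy under the standard (determinate-only) and conservative conventions,
and perceived-vs-algorithmic / inter-rater agreement proportions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import (
    AiConfidence,
    AlgorithmicAiDx,
    Cohort,
    Confidence,
    Diagnosis,
    PerceivedAiDx,
    Session,
)
from .endpoints import _paired

__all__ = [
    "CalibrationTable",
    "accuracy_by_confidence",
    "switch_rate_by_confidence",
    "ai_accuracy",
    "perceived_vs_algorithmic_agreement",
    "interrater_ai_agreement",
    "weighted_overall",
]

_CONF_LEVELS = ("VeryLow", "Low", "High", "VeryHigh")
_DET = (Diagnosis.ADENOMA.value, Diagnosis.NON_ADENOMA.value)
# perceived-AI "Uncertain" and "NotNoticed" are pooled as indeterminate
_AI_INDET = (
    PerceivedAiDx.UNCERTAIN.value,
    PerceivedAiDx.NOT_NOTICED.value,
    AlgorithmicAiDx.UNDETERMINED.value,
)


@dataclass
class CalibrationTable:
    """Per-confidence-level proportions with an overall summary row.

    ``cells`` maps confidence level -> (proportion, n); ``overall`` may use a
    larger denominator than the cell sum (e.g. uncertain-diagnosis trials are
    scored in the overall but belong to no cell).
    """

    stratifier: str
    cells: dict[str, tuple[float, int]]
    overall: tuple[float, int]

    def to_dict(self) -> dict:
        return {
            "stratifier": self.stratifier,
            "cells": {k: {"proportion": p, "n": n} for k, (p, n) in self.cells.items()},
            "overall": {"proportion": self.overall[0], "n": self.overall[1]},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def weighted_overall(cells: dict[str, tuple[float, int]], denominator: int) -> float:
    """Reassemble an overall proportion from per-cell (proportion, n) pairs.

    Trials outside the cells contribute zero to the numerator (they are
    scored as errors), so the overall is sum(p_k * n_k) / denominator.
    """
    num = sum(p * n for p, n in cells.values())
    return num / denominator


def accuracy_by_confidence(cohort: Cohort, target: str = "S1") -> CalibrationTable:
    """Accuracy per confidence level for one session, or for the perceived AI.

    For ``S1``/``S2`` the overall row covers every rater x lesion trial with
    Uncertain diagnoses counted wrong; the four cells cover the determinate
    confidence levels only.  For ``ai_perceived`` the standard convention
    applies: indeterminate / not-noticed AI readings are excluded from both
    the cells and the overall.
    """
    if target in ("S1", "S2"):
        df = cohort.session(target)
        correct = (df["diagnosis"] == df["histology"]).to_numpy()
        conf = df["confidence"]
        cells = {}
        for lev in _CONF_LEVELS:
            m = (conf == lev).to_numpy()
            if m.sum():
                cells[lev] = (float(correct[m].mean()), int(m.sum()))
        overall = (float(correct.mean()), int(len(df)))
        return CalibrationTable(f"human_conf_{target}", cells, overall)
    if target == "ai_perceived":
        df = cohort.session(Session.S2)
        det = df["perceived_ai_dx"].isin(_DET)
        df = df[det]
        correct = (df["perceived_ai_dx"] == df["histology"]).to_numpy()
        conf = df["perceived_ai_conf"]
        cells = {}
        for lev in _CONF_LEVELS:
            m = (conf == lev).to_numpy()
            if m.sum():
                cells[lev] = (float(correct[m].mean()), int(m.sum()))
        overall = (float(correct.mean()), int(len(df)))
        return CalibrationTable("ai_conf", cells, overall)
    raise ValueError(f"target must be 'S1', 'S2' or 'ai_perceived', got {target!r}")


def switch_rate_by_confidence(cohort: Cohort, stratifier: str = "ai_conf") -> CalibrationTable:
    """How often raters switch to the AI label after disagreeing with it.

    Candidates are (rater, lesion) pairs with a determinate perceived AI label
    whose S1 diagnosis differs from it (an S1 ``Uncertain`` counts as
    disagreement).  The proportion is the fraction whose S2 diagnosis equals
    the AI label; cells stratify by S1 human confidence
    (``stratifier="human_conf_S1"``) or perceived AI confidence (``"ai_conf"``).
    """
    if stratifier not in ("human_conf_S1", "ai_conf"):
        raise ValueError(f"unknown stratifier {stratifier!r}")
    pair = _paired(cohort)
    ai = pair["perceived_ai_dx_s2"]
    cand = ai.isin(_DET) & (pair["diagnosis_s1"] != ai)
    pair = pair[cand]
    if pair.empty:
        raise ValueError(
            "no disagreement candidates: every determinate perceived AI label "
            "matches the S1 diagnosis (or none is determinate)"
        )
    switched = (pair["diagnosis_s2"] == pair["perceived_ai_dx_s2"]).to_numpy()
    strat = (
        pair["confidence_s1"] if stratifier == "human_conf_S1" else pair["perceived_ai_conf_s2"]
    )
    cells = {}
    for lev in _CONF_LEVELS:
        m = (strat == lev).to_numpy()
        if m.sum():
            cells[lev] = (float(switched[m].mean()), int(m.sum()))
    overall = (float(switched.mean()), int(len(pair)))
    return CalibrationTable(stratifier, cells, overall)


def ai_accuracy(
    cohort: Cohort, basis: str = "perceived", convention: str = "s"
) -> tuple[float, int]:
    """AI accuracy under the standard (``s``) or conservative (``u``) convention.

    ``s``: correct determinate judgments / determinate judgments.
    ``u``: correct determinate judgments / all rater x lesion trials
    (indeterminate and not-noticed outputs count as errors).  The algorithmic
    basis evaluates the lesion-level label once per rater x lesion trial so
    the two bases share a denominator.
    """
    if convention not in ("s", "u"):
        raise ValueError(f"convention must be 's' or 'u', got {convention!r}")
    df = cohort.session(Session.S2)
    if basis == "perceived":
        label = df["perceived_ai_dx"]
    elif basis == "algorithmic":
        label = df["algorithmic_ai_dx"]
    else:
        raise ValueError(f"basis must be 'perceived' or 'algorithmic', got {basis!r}")
    det = label.isin(_DET).to_numpy()
    correct = (label == df["histology"]).to_numpy() & det
    if convention == "s":
        n = int(det.sum())
        return (float(correct.sum() / n) if n else float("nan"), n)
    n = int(len(df))
    return (float(correct.sum() / n), n)


def perceived_vs_algorithmic_agreement(
    cohort: Cohort, exclude_uncertain: bool = False
) -> tuple[float, int]:
    """Agreement between the rater's reading of the AI and the algorithmic label.

    Inclusive mode counts a trial as agreeing when both sides carry the same
    determinate label or both are indeterminate (perceived Uncertain /
    NotNoticed vs algorithmic Undetermined are pooled).  With
    ``exclude_uncertain`` trials where either side is indeterminate are
    dropped before comparing labels.
    """
    df = cohort.session(Session.S2)
    perc = df["perceived_ai_dx"]
    alg = df["algorithmic_ai_dx"]
    p_det = perc.isin(_DET).to_numpy()
    a_det = alg.isin(_DET).to_numpy()
    same_label = (perc == alg).to_numpy()
    if exclude_uncertain:
        keep = p_det & a_det
        n = int(keep.sum())
        return (float(same_label[keep].mean()) if n else float("nan"), n)
    agree = np.where(p_det & a_det, same_label, ~p_det & ~a_det)
    return float(agree.mean()), int(len(df))


def interrater_ai_agreement(
    cohort: Cohort, exclude_uncertain: bool = False
) -> tuple[float, int]:
    """Average pairwise agreement of perceived AI labels across raters.

    For every rater pair: the fraction of lesions on which the two perceived
    AI labels agree (indeterminate readings pooled); with
    ``exclude_uncertain`` the lesions where either rater's reading is
    indeterminate are dropped for that pair.  Returns the mean over pairs and
    the number of pairs.
    """
    if cohort.n_raters < 2:
        raise ValueError("need at least 2 raters for pairwise agreement")
    df = cohort.session(Session.S2)
    wide = df.pivot(index="lesion_id", columns="rater_id", values="perceived_ai_dx")
    # pool the indeterminate classes
    pooled = wide.replace(
        {PerceivedAiDx.UNCERTAIN.value: "_indet", PerceivedAiDx.NOT_NOTICED.value: "_indet"}
    )
    raters = list(pooled.columns)
    props = []
    for a, b in combinations(raters, 2):
        la, lb = pooled[a], pooled[b]
        if exclude_uncertain:
            keep = (la != "_indet") & (lb != "_indet")
            if keep.sum() == 0:
                continue
            props.append(float((la[keep] == lb[keep]).mean()))
        else:
            props.append(float((la == lb).mean()))
    if not props:
        raise ValueError("no rater pair has comparable lesions after exclusions")
    return float(np.mean(props)), len(props)
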