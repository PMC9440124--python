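"""Pre-registered endpoint datasets and odds-ratio estimates.

Four endpoints, each a session odds ratio from the crossed random-intercepts
logistic model:

* influence   -- odds of rater-AI label agreement, S2 vs S1 (the S1 diagnosis
                 is compared against the AI label shown in S2 for the same
                 lesion); tested against 1.
* accuracy    -- odds of a correct diagnosis, S2 vs S1, all trials; tested
                 against 1.
* effectiveness -- accuracy odds ratio on the pairs where the AI advice was
                 correct; tested against 1.
* safety      -- accuracy odds ratio on the pairs where the AI advice was
                 wrong; tested against 0.3 (one-sided, greater).

AI correctness/agreement can be judged against the rater's own reading of the
device (``ai_basis="perceived"``, the default) or the algorithmic lesion-level
label (``"algorithmic"``).  Pairs with an indeterminate AI label are excluded
and logged, never silently scored.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_model import Cohort, Diagnosis, Expertise, Session
from .glmm import GlmmFit, GlmmSettings, fit_crossed_logistic, test_one_sided, wald_interval

__all__ = [
    "ENDPOINT_NAMES",
    "ENDPOINT_BOUNDS",
    "EndpointRows",
    "EndpointEstimate",
    "EmptySubsetError",
    "build_influence_rows",
    "build_accuracy_rows",
    "estimate_endpoint",
    "estimate_endpoints",
    "report_reciprocal_safety",
]

ENDPOINT_NAMES = ("influence", "accuracy", "effectiveness", "safety")

#: Pre-registered one-sided test bounds (all direction "greater").
ENDPOINT_BOUNDS = {
    "influence": 1.0,
    "accuracy": 1.0,
    "effectiveness": 1.0,
    "safety": 0.3,
}

_DET = (Diagnosis.ADENOMA.value, Diagnosis.NON_ADENOMA.value)


class EmptySubsetError(ValueError):
    """An endpoint subset is empty after exclusions; carries the counts."""

    def __init__(self, message: str, exclusions: dict):
        self.exclusions = dict(exclusions)
        super().__init__(f"{message}; exclusions: {self.exclusions}")


@dataclass
class EndpointRows:
    """Model-ready rows for one endpoint plus a full exclusion log."""

    name: str
    rows: pd.DataFrame  # columns: y, session, rater_id, lesion_id
    exclusions: dict[str, int]
    ai_basis: str
    n_candidate_pairs: int

    @property
    def n_pairs(self) -> int:
        return len(self.rows) // 2


@dataclass
class EndpointEstimate:
    """One endpoint odds ratio with CI and pre-registered test decision."""

    name: str
    or_value: float
    ci_low: float
    ci_high: float
    log_or: float
    se: float
    subgroup: str               # all | expert | nonexpert
    test_bound: float
    p_one_sided: float
    z: float = math.nan
    n_obs: int = 0
    n_pairs: int = 0
    sigma_rater: float = math.nan
    sigma_lesion: float = math.nan
    converged: bool = True
    ai_basis: str = "perceived"
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def reject(self) -> bool:
        return self.p_one_sided < 0.05

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "subgroup": self.subgroup,
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_or": self.log_or,
            "se": self.se,
            "test_bound": self.test_bound,
            "z": self.z,
            "p_one_sided": self.p_one_sided,
            "n_obs": self.n_obs,
            "n_pairs": self.n_pairs,
            "sigma_rater": self.sigma_rater,
            "sigma_lesion": self.sigma_lesion,
            "converged": self.converged,
            "ai_basis": self.ai_basis,
            "exclusions": dict(self.exclusions),
        }


def _paired(cohort: Cohort) -> pd.DataFrame:
    """One row per (rater, lesion) with both sessions' fields side by side."""
    df = cohort.df
    s1 = df[df["session"] == Session.S1.value]
    s2 = df[df["session"] == Session.S2.value]
    pair = s1.merge(
        s2,
        on=["rater_id", "lesion_id", "histology", "algorithmic_ai_dx", "expertise"],
        suffixes=("_s1", "_s2"),
        validate="one_to_one",
    )
    return pair


def _ai_label(pair: pd.DataFrame, ai_basis: str) -> pd.Series:
    if ai_basis == "perceived":
        return pair["perceived_ai_dx_s2"]
    if ai_basis == "algorithmic":
        return pair["algorithmic_ai_dx"]
    raise ValueError(f"ai_basis must be 'perceived' or 'algorithmic', got {ai_basis!r}")


def _stack_sessions(pair: pd.DataFrame, y1: pd.Series, y2: pd.Series) -> pd.DataFrame:
    base = pair[["rater_id", "lesion_id"]]
    rows = pd.concat(
        [
            base.assign(session=0, y=y1.astype(int).to_numpy()),
            base.assign(session=1, y=y2.astype(int).to_numpy()),
        ],
        ignore_index=True,
    )
    return rows[["y", "session", "rater_id", "lesion_id"]]


def build_influence_rows(cohort: Cohort, ai_basis: str = "perceived") -> EndpointRows:
    """Agreement-with-AI outcomes for both sessions, per retained pair.

    For each (rater, lesion): ``y_S2`` is agreement of the S2 diagnosis with
    the AI label, ``y_S1`` is agreement of the S1 diagnosis with that same
    (S2-shown) AI label.  Pairs whose AI label is indeterminate are excluded
    and logged.  A rater ``Uncertain`` diagnosis counts as disagreement.
    """
    pair = _paired(cohort)
    if ai_basis == "perceived" and (pair["perceived_ai_dx_s2"] == "").any():
        raise ValueError("cohort lacks perceived AI fields; cannot use ai_basis='perceived'")
    ai = _ai_label(pair, ai_basis)
    det = ai.isin(_DET)
    exclusions = {
        f"ai_label_{lab}": int(n)
        for lab, n in ai[~det].value_counts().items()
    }
    kept = pair[det]
    ai = ai[det]
    y1 = kept["diagnosis_s1"].to_numpy() == ai.to_numpy()
    y2 = kept["diagnosis_s2"].to_numpy() == ai.to_numpy()
    rows = _stack_sessions(kept, pd.Series(y1), pd.Series(y2))
    if rows.empty:
        raise EmptySubsetError("no pairs with a determinate AI label", exclusions)
    return EndpointRows(
        name="influence",
        rows=rows,
        exclusions=exclusions,
        ai_basis=ai_basis,
        n_candidate_pairs=len(pair),
    )


def build_accuracy_rows(
    cohort: Cohort, subset: str = "all", ai_basis: str = "perceived"
) -> EndpointRows:
    """Correct-diagnosis outcomes for both sessions, optionally on AI subsets.

    ``subset``: ``all`` (accuracy endpoint), ``ai_correct`` (effectiveness) or
    ``ai_wrong`` (safety).  Subset membership is judged per (rater, lesion)
    pair from the AI label under ``ai_basis`` against histology; pairs with an
    indeterminate AI label are excluded from both AI subsets.  Both session
    records of a pair share the pair's membership.
    """
    if subset not in ("all", "ai_correct", "ai_wrong"):
        raise ValueError(f"unknown subset {subset!r}")
    pair = _paired(cohort)
    name = {"all": "accuracy", "ai_correct": "effectiveness", "ai_wrong": "safety"}[subset]
    exclusions: dict[str, int] = {}
    if subset == "all":
        kept = pair
    else:
        ai = _ai_label(pair, ai_basis)
        det = ai.isin(_DET)
        exclusions["ai_indeterminate"] = int((~det).sum())
        ai_correct = det & (ai == pair["histology"])
        keep = ai_correct if subset == "ai_correct" else (det & ~ai_correct)
        other = "ai_wrong" if subset == "ai_correct" else "ai_correct"
        exclusions[other] = int((det & ~keep).sum())
        kept = pair[keep]
    y1 = kept["diagnosis_s1"].to_numpy() == kept["histology"].to_numpy()
    y2 = kept["diagnosis_s2"].to_numpy() == kept["histology"].to_numpy()
    if kept.empty:
        raise EmptySubsetError(f"subset {subset!r} is empty after exclusions", exclusions)
    rows = _stack_sessions(kept, pd.Series(y1), pd.Series(y2))
    return EndpointRows(
        name=name,
        rows=rows,
        exclusions=exclusions,
        ai_basis=ai_basis,
        n_candidate_pairs=len(pair),
    )


def build_endpoint_rows(
    cohort: Cohort, name: str, ai_basis: str = "perceived"
) -> EndpointRows:
    if name == "influence":
        return build_influence_rows(cohort, ai_basis=ai_basis)
    subset = {"accuracy": "all", "effectiveness": "ai_correct", "safety": "ai_wrong"}[name]
    return build_accuracy_rows(cohort, subset=subset, ai_basis=ai_basis)


def estimate_endpoint(
    cohort: Cohort,
    name: str,
    ai_basis: str = "perceived",
    subgroup: str = "all",
    settings: Optional[GlmmSettings] = None,
    level: float = 0.95,
) -> EndpointEstimate:
    """Build one endpoint's rows, fit the GLMM, and attach CI and test."""
    if name not in ENDPOINT_NAMES:
        raise ValueError(f"unknown endpoint {name!r}")
    target = cohort
    if subgroup != "all":
        want = Expertise.EXPERT.value if subgroup == "expert" else Expertise.NON_EXPERT.value
        ids = [r for r, e in cohort.raters.items() if e == want]
        if not ids:
            raise ValueError(f"no raters in subgroup {subgroup!r}")
        target = cohort.subset_raters(ids)
    ep = build_endpoint_rows(target, name, ai_basis=ai_basis)
    try:
        fit = fit_crossed_logistic(ep.rows, settings=settings)
    except Exception as exc:
        raise RuntimeError(f"endpoint {name!r} ({subgroup}): GLMM fit failed: {exc}") from exc
    lo, hi = wald_interval(fit, level=level)
    bound = ENDPOINT_BOUNDS[name]
    z, p = test_one_sided(fit, bound=bound, direction="greater")
    return EndpointEstimate(
        name=name,
        or_value=math.exp(fit.log_or),
        ci_low=lo,
        ci_high=hi,
        log_or=fit.log_or,
        se=fit.se_log_or,
        subgroup=subgroup,
        test_bound=bound,
        p_one_sided=p,
        z=z,
        n_obs=fit.n_obs,
        n_pairs=ep.n_pairs,
        sigma_rater=fit.sigma_rater,
        sigma_lesion=fit.sigma_lesion,
        converged=fit.converged,
        ai_basis=ai_basis,
        exclusions=ep.exclusions,
    )


def estimate_endpoints(
    cohort: Cohort,
    ai_basis: str = "perceived",
    settings: Optional[GlmmSettings] = None,
    subgroups: bool = True,
    level: float = 0.95,
) -> dict[str, dict[str, EndpointEstimate]]:
    """All four endpoints, overall and (optionally) per expertise subgroup.

    Subgroup estimates come from separate fits restricted to each group.
    Returns ``{subgroup: {endpoint: EndpointEstimate}}``; fit failures are
    re-raised naming the endpoint.
    """
    groups = ["all"]
    if subgroups:
        present = set(cohort.raters.values())
        if Expertise.EXPERT.value in present:
            groups.append("expert")
        if Expertise.NON_EXPERT.value in present:
            groups.append("nonexpert")
    out: dict[str, dict[str, EndpointEstimate]] = {}
    for g in groups:
        out[g] = {}
        for name in ENDPOINT_NAMES:
            out[g][name] = estimate_endpoint(
                cohort, name, ai_basis=ai_basis, subgroup=g, settings=settings, level=level
            )
    return out


def report_reciprocal_safety(estimate: EndpointEstimate) -> float:
    """Odds ratio for following *incorrect* AI advice: 1 / safety OR, 2 dp."""
    if estimate.name != "safety":
        raise ValueError(f"expected the safety endpoint, got {estimate.name!r}")
    return round(1.0 / estimate.or_value, 2)


def estimates_to_json(est: dict[str, dict[str, EndpointEstimate]], **kw) -> str:
    return json.dumps(
        {g: {n: e.to_dict() for n, e in d.items()} for g, d in est.items()}, **kw
    )
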