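"""Synthetic cohorts from a latent-evidence belief-integration model.

Each lesion carries a signed latent truth (+1 adenoma, -1 non-adenoma) and a
difficulty; each rater a discriminability (skill).  Unassisted (S1) evidence
is Gaussian around (skill - difficulty) * sign, the diagnosis is the sign of
the evidence outside a small uncertain band, and confidence is a monotone bin
of |evidence| -- so confidence is calibrated by construction.  The AI emits
its own latent evidence, abstaining below a threshold.  Assisted (S2)
evidence is a confidence-weighted combination of the rater's S1 evidence and
the perceived AI label, each weighted by its (perceived) confidence level:
zero AI weight reproduces under-reliance, zero human weight over-reliance,
and the default weights a calibrated in-between.

Default numeric values were frozen from large-sample calibration runs so
that the AI's determinate accuracy sits near 0.85 with roughly 14%
indeterminate outputs, and the full endpoint pipeline lands in the plausible
range of the study-scale analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .data_model import Cohort, validate_cohort
from .endpoints import ENDPOINT_NAMES, estimate_endpoint
from .glmm import GlmmSettings, NotConvergedError, SeparationError

__all__ = [
    "GeneratorConfig",
    "simulate_ai",
    "simulate_s1",
    "integrate_beliefs",
    "generate_cohort",
    "simulate_power",
    "simulate_session_shift",
    "PowerResult",
    "ai_determinate_accuracy_closed_form",
    "ai_indeterminate_fraction_closed_form",
]

_CONF_LEVELS = ("VeryLow", "Low", "High", "VeryHigh")


def _default_weight_human() -> dict[str, float]:
    return {"Uncertain": 0.4, "VeryLow": 0.6, "Low": 0.9, "High": 1.2, "VeryHigh": 1.5}


def _default_weight_ai() -> dict[str, float]:
    return {"VeryLow": 0.15, "Low": 0.35, "High": 0.8, "VeryHigh": 1.3}


@dataclass(frozen=True)
class GeneratorConfig:
    """All generative parameters; see module docstring for the mechanism."""

    n_raters: int = 21
    n_expert: int = 10
    n_lesions: int = 504
    adenoma_prevalence: float = 0.6
    lesion_difficulty_sd: float = 0.9
    expert_skill: float = 1.2
    nonexpert_skill: float = 0.85
    rater_skill_sd: float = 0.15
    ai_skill: float = 0.8693
    ai_indeterminate_threshold: float = 0.2583
    ai_evidence_scale: float = 0.85
    misread_prob: float = 0.06
    confidence_cutpoints_human: tuple[float, float, float] = (0.25, 0.8, 1.8)
    confidence_cutpoints_ai: tuple[float, float, float] = (0.45, 0.85, 1.55)
    uncertain_band_human: float = 0.06
    expert_conf_shift: float = 0.3
    weight_human: dict[str, float] = field(default_factory=_default_weight_human)
    weight_ai: dict[str, float] = field(default_factory=_default_weight_ai)
    s2_mode: str = "integrate"          # "integrate" | "resample"
    s2_noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.n_raters < 1 or self.n_lesions < 1:
            errs.append("n_raters and n_lesions must be positive")
        if not 0 <= self.n_expert <= self.n_raters:
            errs.append("n_expert must be between 0 and n_raters")
        for name in ("adenoma_prevalence", "misread_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                errs.append(f"{name} must be in [0, 1], got {p}")
        for name in ("lesion_difficulty_sd", "rater_skill_sd", "ai_skill",
                     "ai_indeterminate_threshold", "ai_evidence_scale",
                     "uncertain_band_human", "s2_noise_sd"):
            if getattr(self, name) < 0:
                errs.append(f"{name} must be non-negative")
        for name in ("confidence_cutpoints_human", "confidence_cutpoints_ai"):
            c = tuple(getattr(self, name))
            if len(c) != 3 or not (c[0] < c[1] < c[2]):
                errs.append(f"{name} must be a strictly increasing triple, got {c}")
        if self.uncertain_band_human >= self.confidence_cutpoints_human[0]:
            errs.append("uncertain_band_human must be below the first human cutpoint")
        for name, want in (("weight_human", set(_CONF_LEVELS) | {"Uncertain"}),
                           ("weight_ai", set(_CONF_LEVELS))):
            w = getattr(self, name)
            if set(w) != want:
                errs.append(f"{name} must have weights for levels {sorted(want)}")
            elif any(v < 0 for v in w.values()):
                errs.append(f"{name} weights must be non-negative")
        if self.s2_mode not in ("integrate", "resample"):
            errs.append(f"s2_mode must be 'integrate' or 'resample', got {self.s2_mode!r}")
        if errs:
            raise ValueError("invalid generator config: " + "; ".join(errs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confidence_cutpoints_human"] = list(self.confidence_cutpoints_human)
        d["confidence_cutpoints_ai"] = list(self.confidence_cutpoints_ai)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("confidence_cutpoints_human", "confidence_cutpoints_ai"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown generator config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# closed forms used to calibrate (and to cross-check) the AI mechanism

def ai_determinate_accuracy_closed_form(skill: float, threshold: float) -> float:
    """P(correct | determinate) for evidence N(skill, 1) and abstention band."""
    from scipy.special import ndtr

    p_right = ndtr(skill - threshold)
    p_wrong = ndtr(-skill - threshold)
    return float(p_right / (p_right + p_wrong))


def ai_indeterminate_fraction_closed_form(skill: float, threshold: float) -> float:
    from scipy.special import ndtr

    return float(ndtr(threshold - skill) - ndtr(-threshold - skill))


# ---------------------------------------------------------------------------
# binning helpers

def _bin_confidence(mag: np.ndarray, cutpoints, shift=0.0) -> np.ndarray:
    c1, c2, c3 = (np.asarray(c) + shift for c in cutpoints)
    return np.select(
        [mag < c1, mag < c2, mag < c3],
        ["VeryLow", "Low", "High"],
        default="VeryHigh",
    )


def _bin_human(x: np.ndarray, config: GeneratorConfig, shift=0.0):
    mag = np.abs(x)
    uncertain = mag < config.uncertain_band_human
    diagnosis = np.where(x > 0, "Adenoma", "NonAdenoma")
    diagnosis = np.where(uncertain, "Uncertain", diagnosis)
    conf = _bin_confidence(mag, config.confidence_cutpoints_human, shift)
    conf = np.where(uncertain, "Uncertain", conf)
    return diagnosis, conf


# ---------------------------------------------------------------------------
# generative operations

def simulate_ai(hist_sign: np.ndarray, config: GeneratorConfig, rng: np.random.Generator):
    """AI labels, displayed confidence, and latent evidence per lesion.

    Evidence is N(ai_skill * sign, 1); the label abstains (``Undetermined``)
    when |evidence| falls below the indeterminate threshold; the displayed
    confidence is the AI-cutpoint bin of |evidence|.
    """
    hist_sign = np.asarray(hist_sign, dtype=float)
    e = config.ai_skill * hist_sign + rng.standard_normal(hist_sign.shape)
    det = np.abs(e) >= config.ai_indeterminate_threshold
    label = np.where(e > 0, "Adenoma", "NonAdenoma")
    label = np.where(det, label, "Undetermined")
    conf = _bin_confidence(np.abs(e), config.confidence_cutpoints_ai)
    return label, conf, e


def simulate_s1(
    skill,
    difficulty,
    hist_sign,
    config: GeneratorConfig,
    rng: np.random.Generator,
    cutpoint_shift=0.0,
):
    """Unassisted diagnoses: latent evidence, three-level label, confidence.

    ``skill``, ``difficulty``, ``hist_sign`` broadcast together; evidence is
    N((skill - difficulty) * sign, 1).
    """
    mean = (np.asarray(skill, dtype=float) - np.asarray(difficulty, dtype=float)) * np.asarray(
        hist_sign, dtype=float
    )
    x = np.asarray(mean + rng.standard_normal(np.shape(mean)))
    diagnosis, conf = _bin_human(x, config, cutpoint_shift)
    return diagnosis, conf, x


def integrate_beliefs(
    x: np.ndarray,
    human_conf: np.ndarray,
    perceived_ai_dx: np.ndarray,
    perceived_ai_conf: np.ndarray,
    config: GeneratorConfig,
    cutpoint_shift=0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Confidence-weighted combination of own evidence and perceived AI advice.

    z = w_h(own confidence) * x + w_ai(perceived AI confidence) * a, where a
    is +/- ai_evidence_scale for a determinate perceived label and 0
    otherwise (an indeterminate reading contributes nothing).  The assisted
    diagnosis and confidence reuse the S1 binning rules on z.
    """
    x = np.asarray(x, dtype=float)
    human_conf = np.asarray(human_conf, dtype=object)
    perceived_ai_dx = np.asarray(perceived_ai_dx, dtype=object)
    perceived_ai_conf = np.asarray(perceived_ai_conf, dtype=object)

    wh = np.vectorize(lambda c: config.weight_human[str(c)])(human_conf).astype(float)
    a = np.where(
        perceived_ai_dx == "Adenoma",
        config.ai_evidence_scale,
        np.where(perceived_ai_dx == "NonAdenoma", -config.ai_evidence_scale, 0.0),
    ).astype(float)
    wai = np.zeros_like(a)
    det = (perceived_ai_dx == "Adenoma") | (perceived_ai_dx == "NonAdenoma")
    if det.any():
        lookup = np.vectorize(lambda c: config.weight_ai[str(c)])
        wai[det] = lookup(perceived_ai_conf[det]).astype(float)

    z = wh * x + wai * a
    if config.s2_noise_sd > 0:
        if rng is None:
            raise ValueError("s2_noise_sd > 0 requires an rng")
        z = z + config.s2_noise_sd * rng.standard_normal(z.shape)
    diagnosis, conf = _bin_human(z, config, cutpoint_shift)
    return z, diagnosis, conf


def _perceive_ai(alg_label, displayed_conf, config, rng):
    """Rater reading of the displayed label: correct, or misread with small prob.

    The faithful reading maps ``Undetermined`` to a perceived ``Uncertain``.
    A misread replaces the faithful reading by one of the three other
    perceived options, uniformly.
    """
    base = np.where(alg_label == "Undetermined", "Uncertain", alg_label).astype(object)
    options = ("Adenoma", "NonAdenoma", "Uncertain", "NotNoticed")
    misread = rng.random(base.shape) < config.misread_prob
    pick = rng.integers(0, 3, size=base.shape)
    out = base.copy()
    idx = np.nonzero(misread)
    for i in zip(*idx):
        others = [o for o in options if o != base[i]]
        out[i] = others[pick[i]]
    det = (out == "Adenoma") | (out == "NonAdenoma")
    pconf = np.where(det, displayed_conf, "").astype(object)
    return out, pconf


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate and validate a full two-session cohort.

    Deterministic given ``config.seed``; every source of randomness draws
    from a named child stream of the seed.  The returned cohort passes
    :func:`teamdx.data_model.validate_cohort`.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("lesion", "rater", "ai", "s1", "perceive", "s2"), root.spawn(6)
        )
    }
    R, L = config.n_raters, config.n_lesions

    hist = np.where(
        streams["lesion"].random(L) < config.adenoma_prevalence, "Adenoma", "NonAdenoma"
    )
    sign = np.where(hist == "Adenoma", 1.0, -1.0)
    difficulty = config.lesion_difficulty_sd * streams["lesion"].standard_normal(L)

    expertise = np.array(
        ["Expert"] * config.n_expert + ["NonExpert"] * (R - config.n_expert)
    )
    mean_skill = np.where(
        expertise == "Expert", config.expert_skill, config.nonexpert_skill
    )
    skill = mean_skill + config.rater_skill_sd * streams["rater"].standard_normal(R)
    shift = np.where(expertise == "Expert", config.expert_conf_shift, 0.0)

    alg_label, disp_conf, _ = simulate_ai(sign, config, streams["ai"])

    diag1, conf1, x1 = simulate_s1(
        skill[:, None], difficulty[None, :], sign[None, :], config,
        streams["s1"], cutpoint_shift=shift[:, None],
    )

    perc, pconf = _perceive_ai(
        np.broadcast_to(alg_label, (R, L)).copy(),
        np.broadcast_to(disp_conf, (R, L)).copy(),
        config,
        streams["perceive"],
    )

    if config.s2_mode == "resample":
        diag2, conf2, _ = simulate_s1(
            skill[:, None], difficulty[None, :], sign[None, :], config,
            streams["s2"], cutpoint_shift=shift[:, None],
        )
    else:
        _, diag2, conf2 = integrate_beliefs(
            x1, conf1, perc, pconf, config,
            cutpoint_shift=shift[:, None], rng=streams["s2"],
        )

    rater_ids = np.array([f"R{j + 1:02d}" for j in range(R)])
    lesion_ids = np.array([f"L{i + 1:04d}" for i in range(L)])
    rr = np.repeat(rater_ids, L)
    ll = np.tile(lesion_ids, R)

    def flat(arr):
        return np.asarray(arr, dtype=object).reshape(-1)

    common = {
        "rater_id": np.concatenate([rr, rr]),
        "lesion_id": np.concatenate([ll, ll]),
        "session": np.array(["S1"] * R * L + ["S2"] * R * L),
        "raw_choice": "",
        "diagnosis": np.concatenate([flat(diag1), flat(diag2)]),
        "confidence": np.concatenate([flat(conf1), flat(conf2)]),
        "perceived_ai_dx": np.concatenate([np.full(R * L, "", dtype=object), flat(perc)]),
        "perceived_ai_conf": np.concatenate([np.full(R * L, "", dtype=object), flat(pconf)]),
        "algorithmic_ai_dx": np.concatenate([np.tile(alg_label, R)] * 2),
        "histology": np.concatenate([np.tile(hist, R)] * 2),
        "expertise": np.concatenate([np.repeat(expertise, L)] * 2),
    }
    df = pd.DataFrame(common)
    return validate_cohort(df)


# ---------------------------------------------------------------------------
# direct GLMM-scale simulation (bypasses the belief-integration mechanism)

def simulate_session_shift(
    n_raters: int,
    n_lesions: int,
    beta0: float,
    beta1: float,
    sigma_rater: float,
    sigma_lesion: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Binary outcomes drawn directly from the crossed-intercepts model.

    Used for parameter-recovery and coverage checks: the injected session
    log-odds shift ``beta1`` is the estimand.
    """
    from scipy.special import expit

    u = sigma_rater * rng.standard_normal(n_raters)
    v = sigma_lesion * rng.standard_normal(n_lesions)
    r = np.repeat(np.arange(n_raters), n_lesions)
    l = np.tile(np.arange(n_lesions), n_raters)
    rows = []
    for s in (0, 1):
        eta = beta0 + beta1 * s + u[r] + v[l]
        y = (rng.random(eta.shape) < expit(eta)).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "y": y,
                    "session": s,
                    "rater_id": [f"R{i:03d}" for i in r],
                    "lesion_id": [f"L{j:04d}" for j in l],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# simulation-based power

@dataclass
class PowerResult:
    """Per-endpoint rejection rates for the pre-registered one-sided tests."""

    n_reps: int
    alpha: float
    rejection_rate: dict[str, float]
    mc_se: dict[str, float]
    n_nonconverged: dict[str, int]
    n_failed: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_power(
    config: GeneratorConfig,
    overrides: Optional[dict] = None,
    n_reps: int = 100,
    alpha: float = 0.05,
    endpoints: Sequence[str] = ENDPOINT_NAMES,
    glmm_settings: Optional[GlmmSettings] = None,
) -> PowerResult:
    """Monte-Carlo rejection rates of the pre-registered endpoint tests.

    Each replicate generates a cohort under ``config`` (with ``overrides``
    applied) from an independent child seed, runs the endpoint pipeline, and
    records whether each one-sided test rejects at ``alpha``.  Replicates
    whose fit does not converge, or fails outright, are counted and reported
    -- never silently dropped (non-converged fits still contribute their
    p-value; failed fits are excluded from the denominator).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = replace(config, **(overrides or {}))
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.seed).spawn(n_reps)
    rej = {e: 0 for e in endpoints}
    used = {e: 0 for e in endpoints}
    nonconv = {e: 0 for e in endpoints}
    failed = {e: 0 for e in endpoints}
    for ss in seeds:
        rep_cfg = replace(cfg, seed=int(ss.generate_state(1)[0]))
        cohort = generate_cohort(rep_cfg)
        for e in endpoints:
            try:
                est = estimate_endpoint(
                    cohort, e, subgroup="all", settings=glmm_settings
                )
            except (RuntimeError, SeparationError, ValueError):
                failed[e] += 1
                continue
            if not est.converged:
                nonconv[e] += 1
            used[e] += 1
            if est.p_one_sided < alpha:
                rej[e] += 1
    rates = {e: (rej[e] / used[e] if used[e] else math.nan) for e in endpoints}
    mc_se = {
        e: (math.sqrt(rates[e] * (1 - rates[e]) / used[e]) if used[e] else math.nan)
        for e in endpoints
    }
    return PowerResult(
        n_reps=n_reps,
        alpha=alpha,
        rejection_rate=rates,
        mc_se=mc_se,
        n_nonconverged=nonconv,
        n_failed=failed,
    )
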