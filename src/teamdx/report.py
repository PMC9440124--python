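"""End-to-end pipeline and consolidated text/JSON reporting.

``run_pipeline`` goes load-or-generate -> validate -> endpoints ->
calibration -> render, writing a bundle of estimates.json, tables.json,
report.txt and exclusions.log into an output directory.  The text report only
formats numbers already present in the JSON artifacts; nothing is recomputed
by the renderer.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from . import calibration as cal
from .data_model import Cohort
from .endpoints import ENDPOINT_NAMES, estimate_endpoints
from .glmm import GlmmSettings
from .io import read_cohort_csv, write_cohort_csv
from .synthetic import GeneratorConfig, generate_cohort

log = logging.getLogger("teamdx")

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is included in the message."""


@dataclass
class RunConfig:
    """One run: exactly one input source (cohort file XOR generator config)."""

    cohort_path: Optional[Union[str, Path]] = None
    generator: Optional[GeneratorConfig] = None
    ai_basis: str = "perceived"
    out_dir: Union[str, Path] = "teamdx_out"
    seed: int = 0
    subgroups: bool = True
    glmm_settings: Optional[GlmmSettings] = None

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.generator is None):
            raise ValueError(
                "exactly one input source required: cohort_path xor generator"
            )
        if self.ai_basis not in ("perceived", "algorithmic"):
            raise ValueError(f"ai_basis must be 'perceived' or 'algorithmic'")


def _calibration_tables(cohort: Cohort) -> dict:
    tables: dict = {
        "accuracy_by_confidence": {
            t: cal.accuracy_by_confidence(cohort, t).to_dict()
            for t in ("S1", "S2", "ai_perceived")
        },
        "ai_accuracy": {},
        "agreement": {},
    }
    for basis in ("perceived", "algorithmic"):
        for conv in ("s", "u"):
            p, n = cal.ai_accuracy(cohort, basis=basis, convention=conv)
            tables["ai_accuracy"][f"{basis}_{conv}"] = {"proportion": p, "n": n}
    try:
        for strat in ("human_conf_S1", "ai_conf"):
            tables.setdefault("switch_rate", {})[strat] = cal.switch_rate_by_confidence(
                cohort, strat
            ).to_dict()
    except ValueError as exc:
        tables["switch_rate"] = {"error": str(exc)}
    for flag in (False, True):
        p, n = cal.perceived_vs_algorithmic_agreement(cohort, exclude_uncertain=flag)
        key = "excluding_uncertain" if flag else "all_trials"
        tables["agreement"][f"perceived_vs_algorithmic_{key}"] = {"proportion": p, "n": n}
    if cohort.n_raters >= 2:
        for flag in (False, True):
            p, n = cal.interrater_ai_agreement(cohort, exclude_uncertain=flag)
            key = "excluding_uncertain" if flag else "all_trials"
            tables["agreement"][f"interrater_{key}"] = {"proportion": p, "n_pairs": n}
    return tables


def _render_report(estimates: dict, tables: dict, meta: dict) -> str:
    lines = []
    lines.append("teamdx consolidated report")
    lines.append(f"seed: {meta['seed']}  ai_basis: {meta['ai_basis']}  source: {meta['source']}")
    lines.append("")
    lines.append("Endpoint odds ratios (95% CI) by subgroup")
    lines.append(f"{'endpoint':<15}{'subgroup':<11}{'OR':>7}{'CI low':>9}{'CI high':>9}{'bound':>7}{'p (1-sided)':>13}")
    for sub, d in estimates.items():
        for name in ENDPOINT_NAMES:
            if name not in d:
                continue
            e = d[name]
            lines.append(
                f"{name:<15}{sub:<11}{e['or']:>7.2f}{e['ci_low']:>9.2f}"
                f"{e['ci_high']:>9.2f}{e['test_bound']:>7.2f}{e['p_one_sided']:>13.4g}"
            )
    lines.append("")
    lines.append("Accuracy by confidence level")
    for t, tab in tables["accuracy_by_confidence"].items():
        cells = "  ".join(
            f"{k}={v['proportion']:.3f}({v['n']})" for k, v in tab["cells"].items()
        )
        ov = tab["overall"]
        lines.append(f"  {t:<13}{cells}  overall={ov['proportion']:.3f}({ov['n']})")
    if "switch_rate" in tables and "error" not in tables["switch_rate"]:
        lines.append("")
        lines.append("Switch rate on disagreement trials")
        for t, tab in tables["switch_rate"].items():
            cells = "  ".join(
                f"{k}={v['proportion']:.3f}({v['n']})" for k, v in tab["cells"].items()
            )
            ov = tab["overall"]
            lines.append(f"  {t:<13}{cells}  overall={ov['proportion']:.3f}({ov['n']})")
    lines.append("")
    lines.append("AI accuracy")
    for k, v in tables["ai_accuracy"].items():
        lines.append(f"  {k:<16}{v['proportion']:.3f} (n={v['n']})")
    lines.append("")
    lines.append("Agreement on the AI output")
    for k, v in tables["agreement"].items():
        n = v.get("n", v.get("n_pairs"))
        lines.append(f"  {k:<42}{v['proportion']:.3f} (n={n})")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns ``{"estimates": ..., "tables": ..., "paths": {...}}``.  Any stage
    failure raises :class:`PipelineError` naming the stage, and partial
    outputs are removed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {"seed": config.seed, "ai_basis": config.ai_basis}

    def stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if config.cohort_path is not None:
        meta["source"] = str(config.cohort_path)
        cohort = stage("load", read_cohort_csv, config.cohort_path)
    else:
        from dataclasses import replace

        gen = replace(config.generator, seed=config.seed)
        meta["source"] = "generator"
        cohort = stage("generate", generate_cohort, gen)
        path = out / "cohort.csv"
        stage("write_cohort", write_cohort_csv, cohort, path)
        written.append(path)

    log.info("cohort: %d raters x %d lesions", cohort.n_raters, cohort.n_lesions)
    est = stage(
        "endpoints",
        estimate_endpoints,
        cohort,
        ai_basis=config.ai_basis,
        settings=config.glmm_settings,
        subgroups=config.subgroups,
    )
    est_dict = {g: {n: e.to_dict() for n, e in d.items()} for g, d in est.items()}
    tables = stage("calibration", _calibration_tables, cohort)

    paths = {}
    artifacts = {
        "estimates.json": {"seed": config.seed, "ai_basis": config.ai_basis, "estimates": est_dict},
        "tables.json": {"seed": config.seed, "tables": tables},
    }
    for fname, payload in artifacts.items():
        p = out / fname
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)
        paths[fname] = p
    excl = out / "exclusions.log"
    with excl.open("w") as fh:
        for g, d in est_dict.items():
            for name, e in d.items():
                fh.write(f"{g}/{name}: retained_pairs={e['n_pairs']} exclusions={e['exclusions']}\n")
    written.append(excl)
    paths["exclusions.log"] = excl
    rpt = out / "report.txt"
    rpt.write_text(_render_report(est_dict, tables, meta))
    paths["report.txt"] = rpt
    return {"estimates": est_dict, "tables": tables, "paths": paths}
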