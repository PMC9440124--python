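#!/usr/bin/env python
"""Download the deposited trial records (OSF project 57smj) for the headline
reproduction targets.  Requires network access.

Downloads every file in the deposit's osfstorage to data/raw/ and, if a
tabular file with recognizable column content is found, converts it to the
package's cohort CSV contract at data/osf_cohort.csv.  The deposit's exact
schema could not be inspected in the environment where this package was
developed (no route to osf.io), so the conversion maps columns by a
best-effort name match and will stop with a clear error when a required
variable cannot be located -- in that case adapt COLUMN_CANDIDATES below.
"""

from __future__ import annotations

import json
import sys
import urllib.request
from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
RAW = REPO / "data" / "raw"
OUT = REPO / "data" / "osf_cohort.csv"
API = "https://api.osf.io/v2/nodes/57smj/files/osfstorage/?page[size]=100"

# candidate source-column names for each cohort column, matched
# case-insensitively against the downloaded table
COLUMN_CANDIDATES = {
    "rater_id": ("rater_id", "subject", "subject_id", "endoscopist", "participant"),
    "lesion_id": ("lesion_id", "lesion", "video", "video_id", "case"),
    "session": ("session",),
    "diagnosis": ("diagnosis", "judgment", "human_judgment", "response"),
    "confidence": ("confidence", "human_confidence"),
    "perceived_ai_dx": ("perceived_ai_dx", "ai_perceived", "perceived_ai", "ai_opinion"),
    "perceived_ai_conf": ("perceived_ai_conf", "ai_confidence", "perceived_ai_confidence"),
    "algorithmic_ai_dx": ("algorithmic_ai_dx", "ai_algorithmic", "algorithmic_ai", "ai_diagnosis"),
    "histology": ("histology", "ground_truth", "histologic_evaluation", "truth"),
    "expertise": ("expertise", "expert", "group"),
}


def list_files():
    with urllib.request.urlopen(API, timeout=60) as fh:
        payload = json.load(fh)
    for item in payload.get("data", []):
        attrs = item["attributes"]
        links = item["links"]
        yield attrs["name"], links.get("download") or links.get("move")


def download_all() -> list[Path]:
    RAW.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, url in list_files():
        dest = RAW / name
        if not url:
            continue
        print(f"downloading {name} ...")
        urllib.request.urlretrieve(url, dest)
        paths.append(dest)
    return paths


def convert(path: Path) -> None:
    import pandas as pd

    df = pd.read_csv(path)
    lower = {c.lower(): c for c in df.columns}
    mapping = {}
    for target, candidates in COLUMN_CANDIDATES.items():
        hit = next((lower[c] for c in candidates if c in lower), None)
        if hit is None and target not in ("perceived_ai_conf", "perceived_ai_dx"):
            raise SystemExit(
                f"could not locate a source column for {target!r} in {path.name}; "
                f"available: {sorted(df.columns)}. Adjust COLUMN_CANDIDATES."
            )
        if hit is not None:
            mapping[target] = hit
    out = df[[mapping[t] for t in mapping]].rename(
        columns={v: k for k, v in mapping.items()}
    )
    out["raw_choice"] = ""
    from teamdx.data_model import COHORT_COLUMNS, validate_cohort
    from teamdx.io import write_cohort_csv

    for col in COHORT_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    cohort = validate_cohort(out)
    write_cohort_csv(cohort, OUT)
    print(f"wrote {OUT}")


def main() -> int:
    paths = download_all()
    tables = [p for p in paths if p.suffix.lower() in (".csv", ".tsv")]
    if not tables:
        print("no tabular files found; inspect data/raw/ manually", file=sys.stderr)
        return 1
    convert(tables[0])
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
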