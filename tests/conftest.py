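import pandas as pd
import pytest

from teamdx.data_model import TrialRecord, validate_cohort


def mk_pair(
    rater,
    lesion,
    s1_dx,
    s2_dx,
    hist,
    perceived="Adenoma",
    alg=None,
    pconf="High",
    s1_conf=None,
    s2_conf=None,
    expertise="NonExpert",
):
    """Two TrialRecords (S1, S2) for one rater x lesion cell."""
    from teamdx.data_model import (
        AiConfidence,
        AlgorithmicAiDx,
        Confidence,
        Diagnosis,
        Expertise,
        Histology,
        PerceivedAiDx,
        Session,
    )

    if alg is None:
        alg = "Adenoma"  # lesion-level default; override per test when it matters
    if s1_conf is None:
        s1_conf = "Uncertain" if s1_dx == "Uncertain" else "High"
    if s2_conf is None:
        s2_conf = "Uncertain" if s2_dx == "Uncertain" else "High"
    det = perceived in ("Adenoma", "NonAdenoma")
    common = dict(
        rater_id=rater,
        lesion_id=lesion,
        histology=Histology(hist),
        algorithmic_ai_dx=AlgorithmicAiDx(alg),
        expertise=Expertise(expertise),
    )
    s1 = TrialRecord(
        session=Session.S1,
        diagnosis=Diagnosis(s1_dx),
        confidence=Confidence(s1_conf),
        **common,
    )
    s2 = TrialRecord(
        session=Session.S2,
        diagnosis=Diagnosis(s2_dx),
        confidence=Confidence(s2_conf),
        perceived_ai_dx=PerceivedAiDx(perceived),
        perceived_ai_conf=AiConfidence(pconf) if det else None,
        **common,
    )
    return [s1, s2]


def pair_cohort(specs):
    """Build and validate a cohort from a list of mk_pair keyword dicts."""
    records = []
    for spec in specs:
        records.extend(mk_pair(**spec))
    return validate_cohort(records)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort at study size, shared across tests."""
    from teamdx.synthetic import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=20240917))
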