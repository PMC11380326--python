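"""Shared fixtures: the bundled instrument, a mini instrument for toy
tables, and one seeded synthetic corpus reused across the suite."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from robdiv import (
    GeneratorConfig,
    Instrument,
    Item,
    ScoreTable,
    StudyRecord,
    generate,
    load_instrument,
    paper_preset,
)

SEED = 20240907  # fixed session seed for reproducible corpora


@pytest.fixture(scope="session")
def instrument() -> Instrument:
    return load_instrument()


@pytest.fixture(scope="session")
def paper_config(instrument):
    return paper_preset(instrument, seed=SEED)


@pytest.fixture(scope="session")
def paper_table(paper_config, instrument) -> ScoreTable:
    table = generate(paper_config, instrument)
    table.validate()
    return table


@pytest.fixture(scope="session")
def strata_table(instrument) -> ScoreTable:
    """Corpus from the preset with planted stratum effects."""
    config = paper_preset(instrument, stratum_effects=True, seed=SEED + 1)
    return generate(config, instrument)


@pytest.fixture()
def mini_instrument() -> Instrument:
    """Three items: plain RQ, RQ allowing I, one RoB item."""
    return Instrument(
        items=(
            Item(item_id="A1", kind="RQ", source_tool="ARRIVE",
                 response_domain="YN", text="toy reporting item"),
            Item(item_id="A2", kind="RQ", source_tool="CONSORT",
                 response_domain="YNI", text="toy reporting item with I"),
            Item(item_id="S1", kind="RoB", source_tool="SYRCLE",
                 response_domain="LUH", text="toy bias item"),
        ),
        name="mini", version="test",
    )


@pytest.fixture()
def mini_studies() -> list[StudyRecord]:
    return [
        StudyRecord("s1", "m1", "animal", "baseline", 1999),
        StudyRecord("s2", "m2", "human", "baseline", 2005),
        StudyRecord("s3", "m3", "animal", "treatment", 2010),
        StudyRecord("s4", "m4", "human", "treatment", 2015),
    ]


@pytest.fixture()
def toy_table(mini_instrument, mini_studies) -> ScoreTable:
    """4 studies x 3 items; A1 reported in exactly 1 of 4 studies."""
    rows = []
    a1 = {"s1": "Y", "s2": "N", "s3": "N", "s4": "N"}
    a2 = {"s1": "Y", "s2": "Y", "s3": "N", "s4": "I"}
    r1 = {"s1": "L", "s2": "U", "s3": "H", "s4": "U"}
    for sid in ("s1", "s2", "s3", "s4"):
        rows += [
            {"study_id": sid, "item_id": "A1", "value": a1[sid]},
            {"study_id": sid, "item_id": "A2", "value": a2[sid]},
            {"study_id": sid, "item_id": "S1", "value": r1[sid]},
        ]
    return ScoreTable(mini_instrument, mini_studies, pd.DataFrame(rows))
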