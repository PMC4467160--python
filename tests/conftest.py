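"""Shared fixtures: one default-scale synthetic compendium and one full
pipeline run, computed once per session and reused by many tests."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest
import yaml

from pdl1bc.integrate import PooledMatrix
from pdl1bc.markers import call_all_markers
from pdl1bc.pipeline import integrate_cohorts, run_pipeline
from pdl1bc.synth import SimConfig, SimTruth, generate_cohorts


@dataclass
class Compendium:
    config: SimConfig
    cohorts: list
    clinical: pd.DataFrame  # with subtype + marker status columns
    truth: SimTruth
    pooled: PooledMatrix
    raw_pooled: PooledMatrix
    tumors: pd.DataFrame


@pytest.fixture(scope="session")
def compendium() -> Compendium:
    """Default study conditions, seed 1, fully integrated and marker-called."""
    config = SimConfig(seed=1)
    cohorts, clinical, truth = generate_cohorts(config)
    pooled, raw_pooled, subtypes = integrate_cohorts(cohorts, truth.centroids)
    clinical = clinical.copy()
    clinical["subtype"] = subtypes.reindex(clinical.index)
    clinical = call_all_markers(pooled.matrix, clinical)
    tumors = clinical[clinical["role"] == "tumor"]
    return Compendium(config=config, cohorts=cohorts, clinical=clinical,
                      truth=truth, pooled=pooled, raw_pooled=raw_pooled,
                      tumors=tumors)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One end-to-end pipeline run on the default synthetic config."""
    base = tmp_path_factory.mktemp("pipeline")
    cfg = base / "cfg.yaml"
    cfg.write_text(yaml.safe_dump({"mode": "synth", "synth": {"seed": 1}}))
    outdir = base / "out"
    summary = run_pipeline(cfg, outdir)
    return summary, outdir
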