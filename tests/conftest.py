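"""Shared fixtures: simulated datasets and the standard pipeline run."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from circabs import events as ev
from circabs import io
from circabs.simulate import SimConfig, Simulation, simulate


@dataclass
class PipelineRun:
    """Tissue-level matrix plus the standard downstream objects."""

    sim: Simulation
    matrix: pd.DataFrame  # tissue-level RPM
    hc: pd.Series
    events: list  # high-confidence ABS events
    labels: pd.Series  # classification of high-confidence circRNAs


def run_pipeline(sim: Simulation, by="tissue") -> PipelineRun:
    per_sample = io.normalize_rpm(sim.junctions, sim.sample_sheet)
    matrix = io.average_replicates(per_sample, sim.sample_sheet, by=by)
    hc = io.filter_high_confidence(matrix)
    hc_events = ev.filter_high_confidence_events(ev.group_events(matrix.index, hc))
    labels = ev.classify_circrnas(hc_events, matrix.index[hc])
    return PipelineRun(sim=sim, matrix=matrix, hc=hc, events=hc_events, labels=labels)


@pytest.fixture(scope="session")
def default_sim() -> Simulation:
    """The reference study conditions: 5,000 circRNA loci, seed 1."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_run(default_sim) -> PipelineRun:
    return run_pipeline(default_sim)


@pytest.fixture(scope="session")
def small_sim() -> Simulation:
    return simulate(SimConfig(n_loci=400, seed=2))


@pytest.fixture(scope="session")
def small_run(small_sim) -> PipelineRun:
    return run_pipeline(small_sim)


@pytest.fixture(scope="session")
def deep_sim() -> Simulation:
    """Well-covered events (~200 reads/event/tissue) with planted PCU shifts."""
    import numpy as np

    cfg = SimConfig(
        seed=11,
        n_loci=600,
        abs_fraction=1.0,
        dual_fraction=0.0,
        abundance_mu=float(np.log(10.0)),
        abundance_sigma=0.3,
        tissue_specific_fraction=0.5,
        pcu_shift=40.0,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def deep_run(deep_sim) -> PipelineRun:
    return run_pipeline(deep_sim)
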