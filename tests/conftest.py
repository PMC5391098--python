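"""Shared fixtures: small synthetic worlds generated once per session."""

from __future__ import annotations

import pytest

from lamprof.pipeline import run_pipeline
from lamprof.simulate import (
    SimParams,
    make_genome,
    plant_integrations,
    simulate_amplicons,
)

SMALL = dict(genome_len=60_000, n_trna_genes=12, n_trna_families=6, arm_len=6_000)


@pytest.fixture(scope="session")
def small_world():
    """A 60-kb genome with 12 tRNA genes and a 12-kb two-arm palindrome."""
    params = SimParams(seed=11, **SMALL)
    refs, catalog = make_genome(params)
    return params, refs, catalog


@pytest.fixture(scope="session")
def clean_run(small_world):
    """Error-free tdna run: events, truth, reads, and the pipeline result."""
    base, refs, catalog = small_world
    params = SimParams(seed=11, n_events=25, error_rate=0.0, **SMALL)
    events, truth = plant_integrations(refs, catalog, params)
    pairs, sources = simulate_amplicons(events, refs, params)
    result = run_pipeline(pairs, refs, catalog, "tdna")
    return dict(params=params, refs=refs, catalog=catalog, events=events,
                truth=truth, pairs=pairs, sources=sources, result=result)
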