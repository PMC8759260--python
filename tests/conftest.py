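from types import SimpleNamespace

import pytest

from clockdissect.associations import (association_scan, build_design,
                                       preprocess_expression, select_core_set)
from clockdissect.pipeline import DEFAULT_CONFIG, build_clock_panel
from clockdissect.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort_truth():
    """Default synthetic cohort, shared across the suite."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def scan_bundle(cohort_truth):
    """Full association scan plus clock panel and core set on the
    default cohort."""
    cohort, truth = cohort_truth
    expr = preprocess_expression(cohort.counts, cohort.gene_coords)
    design = build_design(cohort.covariates)
    results = association_scan(cohort.beta, expr, design, cohort.cpg_coords)
    clocks = build_clock_panel(truth, cohort, DEFAULT_CONFIG, seed=5)
    core = select_core_set(results, clocks)
    return SimpleNamespace(cohort=cohort, truth=truth, expr=expr, design=design,
                           results=results, clocks=clocks, core=core)
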