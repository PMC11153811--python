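"""Shared fixtures: generated datasets at two scales.

The full-scale bundle (86 neurons, 2000 genes, default seeds) backs the
end-to-end assertions; the small config keeps per-module tests fast.
"""

from dataclasses import replace

import pytest

from lsopatch.pipeline import PipelineConfig, run_all
from lsopatch.synthdata import (
    GeneratorConfig,
    default_ephys_params,
    generate_counts,
    generate_traces,
)


@pytest.fixture(scope="session")
def bundle():
    """Full pipeline on the default study-sized dataset (seed 0)."""
    return run_all(PipelineConfig(seed=0))


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(
        n_onset=20, n_sustained=6, n_delayed=14, negcontrol_n=2,
        n_genes=600, n_markers_c1=80, n_markers_c2=40, n_housekeeping=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_counts(small_config):
    return generate_counts(small_config)


def noiseless_params():
    return {
        name: replace(p, noise_sd_mv=0.0, noise_sd_pa=0.0)
        for name, p in default_ephys_params().items()
    }


@pytest.fixture(scope="session")
def noiseless_cells():
    """A few noiseless cells of each class with their traces."""
    cfg = GeneratorConfig(
        n_onset=3, n_sustained=2, n_delayed=3, negcontrol_n=0,
        n_genes=50, n_markers_c1=5, n_markers_c2=5, n_housekeeping=5,
        seed=5, ephys_params=noiseless_params(),
    )
    cm, truth = generate_counts(cfg)
    traces = generate_traces(cfg, truth)
    return cfg, truth, traces
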