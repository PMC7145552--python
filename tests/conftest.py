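"""Shared fixtures: a reduced-scale synthetic bundle and its pipeline run."""

from __future__ import annotations

import pytest

from tecisreg.pipeline import RunConfig, run_all
from tecisreg.synthetic_data import simulate, small_config

FACTORS = ["ERa", "FoxA1", "GATA3", "AP2g"]
BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One reduced-scale synthetic bundle shared across the suite."""
    outdir = tmp_path_factory.mktemp("bundle")
    return simulate(small_config(BUNDLE_SEED), outdir)


@pytest.fixture(scope="session")
def pipeline_result(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig(
        bundle_dir=small_bundle.outdir,
        out_dir=outdir,
        factors=FACTORS,
        n_random_sites=5000,
        seed=7,
    )
    return run_all(cfg)
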