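"""Shared fixtures: a default progenitor and one full pipeline run."""

from __future__ import annotations

import json
import warnings

import pytest

from l1forge import simulate
from l1forge.pipeline import Pipeline, PipelineConfig

warnings.filterwarnings("ignore", message="clamped .* negative NJ")


@pytest.fixture(scope="session")
def default_spec():
    return simulate.ProgenitorSpec()


@pytest.fixture(scope="session")
def root_truth(default_spec):
    return simulate.simulate_progenitor(default_spec, seed=11)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run at the default study conditions
    (3-subfamily succession, 30 copies each, 5% divergence, one planted
    KZFP-site loss); shared by the end-to-end checks."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    cfg = PipelineConfig(seed=1, outdir=str(outdir), kzfp_loss_at=2)
    pipe = Pipeline(cfg)
    manifest = pipe.run_all()
    metrics = json.loads((outdir / "evaluate" / "metrics.json").read_text())
    return {"pipe": pipe, "outdir": outdir, "manifest": manifest,
            "metrics": metrics, "config": cfg}
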