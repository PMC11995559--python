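import dataclasses

import pytest

from acrip.pipeline import RunConfig
from acrip.simulate import SimConfig, simulate_annotation, simulate_expression, simulate_rip_coverage


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=60, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """One small simulated study shared across read-only tests."""
    ann = simulate_annotation(small_cfg)
    rip, truth = simulate_rip_coverage(small_cfg, ann)
    rna, protein = simulate_expression(small_cfg, ann, truth)
    return {"cfg": small_cfg, "ann": ann, "rip": rip, "truth": truth,
            "rna": rna, "protein": protein}


@pytest.fixture()
def tiny_run_cfg(tmp_path) -> RunConfig:
    cfg = RunConfig(outdir=str(tmp_path / "run"))
    return dataclasses.replace(cfg, sim=dataclasses.replace(cfg.sim, n_genes=40, seed=5))
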