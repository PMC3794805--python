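"""Shared fixtures: one full benchmark-profile pipeline run per session,
plus small generator configs for cheaper stage-level tests."""

from __future__ import annotations

import pytest

from kinfamscan.pipeline import PipelineConfig, run_pipeline
from kinfamscan.synthetic_data import (GeneratorConfig, generate_dataset,
                                       paper_profile_config)

SEED = 1


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """Full pipeline on the benchmark profile (tree built separately in a
    reduced test; bootstrap off for runtime)."""
    outdir = tmp_path_factory.mktemp("paper_run")
    cfg = PipelineConfig(seed=SEED, outdir=outdir,
                         generator=paper_profile_config(seed=SEED),
                         run_tree=False)
    report, outputs = run_pipeline(cfg)
    return {"config": cfg, "report": report, "outputs": outputs,
            "truth": outputs["dataset"].truth, "dataset": outputs["dataset"],
            "outdir": outdir}


def small_config(seed: int = SEED, **overrides) -> GeneratorConfig:
    """A fast, structurally complete generator configuration."""
    base = dict(seed=seed, n_zik=3, n_mekk=4, n_raf=5, n_decoys=12,
                near_miss_fraction=0.25, n_unexpressed=2, n_chromosomes=5,
                reads_per_sample=6000, exon_count_range=(1, 6),
                duplication_pairs=2, tandem_pairs=1,
                spacer_range=(2000, 4000),
                expression={"raf_higher_0dpa": 1, "raf_higher_3dpa": 1,
                            "rpkm_range": [5.0, 500.0],
                            "preference_ratio": 4.0,
                            "tissue_dropout": 0.15})
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())
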