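from __future__ import annotations

import pytest

from sweepscan.pipeline import RunConfig, run_scan
from sweepscan.synth import SyntheticConfig, generate_dataset


def _run_bundle(cfg: SyntheticConfig, root):
    bundle = generate_dataset(cfg, root / "bundle")
    config = RunConfig(
        vcf=str(bundle.vcf),
        popmap=str(bundle.popmap),
        gff3=str(bundle.gff3),
        fasta=str(bundle.fasta),
        pathways=str(bundle.pathways),
        out_dir=str(root / "run"),
        window_size=cfg.window_size,
        seed=1,
    )
    return cfg, bundle, run_scan(config)


@pytest.fixture(scope="session")
def iid_run(tmp_path_factory):
    """Synthetic bundle (fast i.i.d. background) + full pipeline run."""
    root = tmp_path_factory.mktemp("iid")
    return _run_bundle(SyntheticConfig(seed=42, background_mode="iid"), root)


@pytest.fixture(scope="session")
def coalescent_run(tmp_path_factory):
    """Synthetic bundle with coalescent background (the generator's default
    study conditions) + full pipeline run."""
    root = tmp_path_factory.mktemp("coal")
    return _run_bundle(SyntheticConfig(seed=7), root)
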