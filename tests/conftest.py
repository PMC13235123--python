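import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from gliascan.panel import packaged_panel
from gliascan.pipeline import RunConfig, run_pipeline, simulate_command


@pytest.fixture(scope="session")
def panel():
    return packaged_panel()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Noiseless 3-genotype dataset with truth table (depth 1500/genotype)."""
    out = tmp_path_factory.mktemp("smalldata")
    return simulate_command(
        out,
        n_genotypes=3,
        depth=1500,
        error_rate=0.0,
        pseudogene_fraction=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_run(small_dataset, tmp_path_factory):
    """Full pipeline run on the noiseless small dataset."""
    out = tmp_path_factory.mktemp("smallrun")
    config = RunConfig(
        fwd_fastq=small_dataset["fwd"],
        rev_fastq=small_dataset["rev"],
        sample_sheet=small_dataset["sample_sheet"],
        out_dir=out,
        n_reps=20,
        seed=11,
    )
    return run_pipeline(config)
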