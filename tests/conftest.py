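import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from caprimir.pipeline import PipelineConfig, run_pipeline
from caprimir.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """The default synthetic study: 2 x 2e5 reads, 30 known miRNAs,
    10 novel hairpins, 10 decoys, written to disk once per session."""
    outdir = tmp_path_factory.mktemp("synthetic")
    ds = simulate_dataset(SimulationConfig(seed=1), outdir)
    return ds, outdir


@pytest.fixture(scope="session")
def pipeline_run(dataset, tmp_path_factory):
    """The full pipeline executed over the default synthetic study."""
    ds, data_dir = dataset
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        reads_d=data_dir / "reads_D.fastq",
        reads_p=data_dir / "reads_P.fastq",
        genome_fasta=data_dir / "genome.fa",
        mature_fa=data_dir / "mature.fa",
        hairpin_fa=data_dir / "hairpin.fa",
        features_bed=data_dir / "features.bed",
        outdir=outdir,
    )
    return ds, run_pipeline(config)


def tiny_config(seed: int = 7, **overrides) -> SimulationConfig:
    """A fast configuration for determinism and error-path tests."""
    defaults = dict(
        seed=seed,
        reads_per_library=4000,
        genome_length=30_000,
        n_known_mirnas=6,
        n_novel_hairpins=2,
        n_decoy_hairpins=2,
        n_ncrna_loci=1,
        # fewer loci concentrate the lognormal abundance draws; keep the
        # planted share of the clean pool comfortably below 1
        frac_known=0.35,
        frac_ncrna=0.10,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
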