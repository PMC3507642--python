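"""Shared fixtures: a small synthetic experiment for module tests and a
default-scale run for the end-to-end recovery checks."""

from pathlib import Path

import pytest

from cistromedose.pipeline import RunConfig, run_pipeline
from cistromedose.simulate import (
    SyntheticConfig,
    generate_truth,
    write_experiment,
)


def _file_tag(label: str) -> str:
    return label.replace("+", "plus").replace("-", "minus")


def make_run_config(cfg: SyntheticConfig, data_dir: Path, **overrides) -> RunConfig:
    conds = {
        d.label: {
            "peaks": f"peaks_{_file_tag(d.label)}.bed",
            "negatives": f"negatives_{_file_tag(d.label)}.bed",
            "track": f"track_{_file_tag(d.label)}.bedgraph",
        }
        for d in cfg.doses
    }
    treated = [d.label for d in cfg.doses if d.label not in ("R1881+", "R1881-")]
    kwargs = dict(
        data_dir=str(data_dir),
        conditions=conds,
        treated_conditions=treated,
        conserved_elements="conserved_R1881plus.bed",
        bound_fasta="bound_R1881plus.fasta",
        genome_fasta="genome.fasta",
        are_pwm="are_pwm.meme",
        partner_pwm="partner_pwm.meme",
        de_table=f"de_{_file_tag(treated[-1])}.tsv",
        signatures="signatures.gmt",
        seed=cfg.seed,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """A reduced experiment for fast module-level tests."""
    return SyntheticConfig(
        seed=7, n_chroms=2, chrom_length=500_000, n_sites=200,
        n_genes=400, n_negative_peaks=60,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return generate_truth(small_config)


@pytest.fixture(scope="session")
def small_experiment_dir(small_config, tmp_path_factory) -> Path:
    outdir = tmp_path_factory.mktemp("smallexp")
    write_experiment(small_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Default study conditions (2000 sites, occupancy noise 0.02) run
    through the full pipeline; shared by the recovery checks."""
    cfg = SyntheticConfig(seed=11)
    outdir = tmp_path_factory.mktemp("defaultexp")
    truth = write_experiment(cfg, outdir)
    report = run_pipeline(make_run_config(cfg, outdir))
    return cfg, truth, report
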