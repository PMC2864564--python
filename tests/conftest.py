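import pytest

from tilecycle.pipeline import RunConfig, run_pipeline, standard_benchmark_config
from tilecycle.simulate import SimConfig


def small_config(seed: int = 3) -> RunConfig:
    """A 30-kb two-dataset run that exercises every pipeline stage quickly."""
    return RunConfig(
        sim=SimConfig(
            chrom_lengths={"chrI": 30_000},
            n_orf=10,
            n_orf_periodic=4,
            n_antisense=1,
            n_antisense_periodic=1,
            n_intergenic=1,
            n_intergenic_periodic=0,
        ),
        datasets=("cdc28", "alpha"),
        benchmark_size=4,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_run")
    cfg = small_config()
    return cfg, out, run_pipeline(cfg, out)


@pytest.fixture(scope="session")
def bench_run(tmp_path_factory):
    """The standard 500-transcript planted-truth benchmark (seed 1)."""
    out = tmp_path_factory.mktemp("bench_run")
    cfg = standard_benchmark_config(seed=1)
    return cfg, out, run_pipeline(cfg, out)
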