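import numpy as np
import pytest

from hapsomatic import somatic_caller as sc
from hapsomatic import synthbam


@pytest.fixture(scope="session")
def fx_diploid(tmp_path_factory):
    """Diploid region without somatic mutations: genotyping / haplotagging."""
    spec = synthbam.FixtureSpec(
        region_length=200_000,
        depth=40,
        read_length=10_000,
        epsilon=0.005,
        mu=0.0,
        alpha=0.5,
        decoy_rate=5e-4,
        seed=11,
    )
    return synthbam.make_fixture(spec, str(tmp_path_factory.mktemp("diploid")))


@pytest.fixture(scope="session")
def fx_tumour(tmp_path_factory):
    """50% purity tumour mixture with 20 clonal somatic SNVs."""
    spec = synthbam.FixtureSpec(
        region_length=200_000,
        depth=80,
        read_length=20_000,
        epsilon=0.005,
        n_somatic=20,
        rho=1.0,
        alpha=0.5,
        seed=7,
    )
    return synthbam.make_fixture(spec, str(tmp_path_factory.mktemp("tumour")))


@pytest.fixture(scope="session")
def tumour_run(fx_tumour):
    """Full calling pipeline output on the tumour fixture."""
    config = sc.CallerConfig(alpha=0.5)
    calls, bed, assignments = sc.call_window(
        fx_tumour.bam,
        fx_tumour.germline_vcf,
        fx_tumour.reference_fasta,
        (fx_tumour.chrom, 0, fx_tumour.region_length),
        config,
    )
    return fx_tumour, config, calls, bed, assignments


def read_truth_table(path):
    truth = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            rid, hap, tumour, strand = line.split()
            truth[rid] = (int(hap), bool(int(tumour)), strand)
    return truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
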