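import numpy as np
import pytest

from enhancerkit import CoverageTrack, Gene, GenomicInterval, Peak
from enhancerkit.simulate import scenario, simulate


def make_track(values_by_chrom, library_size=1_000_000, bin_size=1):
    return CoverageTrack(
        {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()},
        library_size=library_size,
        bin_size=bin_size,
    )


def uniform_track(chrom_sizes, value, library_size=1_000_000, bin_size=1):
    return CoverageTrack(
        {c: np.full(-(-s // bin_size), float(value)) for c, s in chrom_sizes.items()},
        library_size=library_size,
        bin_size=bin_size,
        chrom_sizes=chrom_sizes,
    )


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def uniform_track_factory():
    return uniform_track


# A reduced-scale study configuration: same architecture as the default
# scenario (clustered super-enhancer constituents among typical peaks and
# promoter sites, two zones per chromosome) on a 2 x 0.8 Mb genome so the
# suite stays fast.
SMALL = dict(
    chrom_length=800_000,
    n_genes=60,
    n_typical_peaks=60,
    n_super_clusters=6,
    n_promoter_sites=40,
    n_lineage_a=8,
    n_lineage_b=8,
)


def small_scenario(name, seed, **overrides):
    return scenario(name, seed=seed, **{**SMALL, **overrides})


@pytest.fixture(scope="session")
def small_baseline_study():
    return simulate(small_scenario("baseline", seed=101))


@pytest.fixture(scope="session")
def knockout_study():
    return simulate(
        small_scenario("tbet_knockout", seed=202, factors=("tbet", "ptefb", "med1", "brd4"))
    )
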