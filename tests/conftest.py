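import numpy as np
import pytest

from methedit.core_io import BetaMatrix, CpGSite, SampleMeta
from methedit.dmr import DMR
from methedit.simulate import SimConfig, simulate_dataset


def make_samples(spec):
    """spec: list of (construct, guide, day, replicate) tuples."""
    return [
        SampleMeta(
            sample_id=f"{c}_{g}_d{d}_r{r}",
            construct=c,
            guide=g,
            timepoint_days=d,
            replicate=r,
        )
        for c, g, d, r in spec
    ]


def make_beta(positions, values, samples, chrom="chr1"):
    sites = [CpGSite(chrom=chrom, pos=p) for p in positions]
    return BetaMatrix(sites, samples, np.asarray(values, dtype=float))


def make_dmr(chrom="chr1", positions=(100, 500), direction="hyper", mean_delta=0.2):
    return DMR(
        chrom=chrom,
        start=positions[0],
        end=positions[-1] + 1,
        cpg_positions=tuple(positions),
        direction=direction,
        mean_delta=mean_delta,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared by read-only tests."""
    return simulate_dataset(SimConfig(n_regions=300, seed=1))


@pytest.fixture
def two_group_samples():
    return make_samples(
        [("CRISPRoff", "targeting", 3, r) for r in (1, 2)]
        + [("d3A", "NTC", 3, r) for r in (1, 2)]
    )
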