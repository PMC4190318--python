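import numpy as np
import pandas as pd
import pytest

from chfmap import GenotypeMatrix, MarkerMap, SampleTable
from chfmap.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One simulated study reused across read-only tests (2k markers keeps it
    fast; the genome layout is the default 31 x 50 Mb)."""
    return simulate_study(SimConfig(seed=11, n_markers=2000))


@pytest.fixture(scope="session")
def dense_study():
    """Denser map (about 40 markers/Mb) on a smaller genome, for tests that
    need the shared autozygous segment to be resolvable."""
    cfg = SimConfig(
        seed=11,
        n_markers=8000,
        n_chromosomes=4,
        chromosome_length_bp=50_000_000,
        causal_chromosome="chr3",
    )
    return simulate_study(cfg)


def make_marker_map(positions, chrom="chr20", ref="A", alt="G"):
    n = len(positions)
    return MarkerMap(
        pd.DataFrame(
            {
                "marker_id": [f"T{j:04d}" for j in range(n)],
                "chromosome": [chrom] * n,
                "position_bp": list(positions),
                "ref_allele": [ref] * n,
                "alt_allele": [alt] * n,
            }
        )
    )


def shared_block_fixture():
    """Five cases identically homozygous over a 31-marker block spanning
    >500 kb, flanked on each side by one marker heterozygous in one case.

    Flank positions reproduce the published interval bounds
    (49,164,218 / 50,115,936) so the delineated interval is 952 kb.
    """
    inner = np.linspace(49_200_000, 50_100_000, 31).astype(int)
    positions = np.concatenate([[49_164_218], inner, [50_115_936]])
    mm = make_marker_map(positions)
    calls = np.full((5, 33), 2, dtype=np.int8)
    calls[0, 0] = 1  # left flank: het in case 1
    calls[1, 32] = 1  # right flank: het in case 2
    gm = GenotypeMatrix([f"CASE{i}" for i in range(1, 6)], calls)
    return gm, mm


def sample_table_for(gm, phenotype="affected"):
    ids = gm.sample_ids
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "phenotype": [phenotype] * len(ids),
                "breed": ["FranchesMontagnes"] * len(ids),
                "role": ["case"] * len(ids),
            }
        )
    )
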