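import numpy as np
import pandas as pd
import pytest

from cryptic_cre.intervals import RegionSet
from cryptic_cre.synth import SynthConfig, build_genome, simulate_counts


def make_regions(triples, names=None, strands=None, summits=None) -> RegionSet:
    """Build a RegionSet from (chrom, start, end) triples."""
    df = pd.DataFrame(triples, columns=["chrom", "start", "end"])
    if names is not None:
        df["name"] = names
    if strands is not None:
        df["strand"] = strands
    if summits is not None:
        df["summit"] = summits
    return RegionSet(df)


def brute_force_overlap(query: RegionSet, subject: RegionSet, min_size: int = 0):
    """All-pairs any-overlap oracle for overlap_counts."""
    k = 0
    subs = [
        s
        for s in subject.df.itertuples(index=False)
        if s.end - s.start >= min_size
    ]
    for q in query.df.itertuples(index=False):
        if any(
            s.chrom == q.chrom and s.start < q.end and s.end > q.start for s in subs
        ):
            k += 1
    return k, len(query)


@pytest.fixture(scope="session")
def default_truth():
    """The default miniature study design, seed 1."""
    return build_genome(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def default_sims(default_truth):
    return simulate_counts(default_truth)


@pytest.fixture(scope="session")
def validation_truth():
    """6v6 two-group design with clean implanted effects: the scale at
    which the differential caller's power properties are stated."""
    cfg = SynthConfig(
        seed=11,
        replicates_per_group=6,
        groups=("control", "K9A"),
        chrom_length=12_000_000,
        n_genes=2000,
        n_links=100,
        de_up_fraction=1.0,
        link_coupling=0.0,
        n_bivalent_promoters=40,
        n_k27a_bivalent_up=0,
        region_length=(1000, 3000),  # narrow: this design is never clustered
    )
    return build_genome(cfg)
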