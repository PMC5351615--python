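import numpy as np
import pandas as pd
import pytest

from epidriver import (
    PlantedEffect,
    StudyDesign,
    digest_and_index,
    generate_genome,
    plan_methylation_states,
    simulate_counts,
)
from epidriver.regions import Fragment, FragmentCatalog, GenomicInterval


def make_catalog(entries):
    """Build a catalog from (chrom, start, end, cpg_positions) tuples."""
    frags = [
        Fragment(
            id=f"{chrom}:{start}-{end}",
            interval=GenomicInterval(chrom, start, end),
            cpg_positions=list(cpgs),
        )
        for chrom, start, end, cpgs in entries
    ]
    return FragmentCatalog(frags)


def counts_frame(rows):
    """Build a per-CpG counts frame from (chrom, pos, meth, unmeth) tuples."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])


@pytest.fixture(scope="session")
def small_genome():
    genome, islands = generate_genome(
        n_chroms=1, chrom_len=60_000, ccgg_rate=0.008, cgi_blocks=2, seed=7
    )
    return genome, islands


@pytest.fixture(scope="session")
def small_catalog(small_genome):
    genome, _ = small_genome
    return digest_and_index(genome)


@pytest.fixture(scope="session")
def small_study(small_catalog):
    """A 2-pair study with planted shared DMFs and simulated counts."""
    design = StudyDesign(n_pairs=2, coverage_mean=30, seed=11)
    planted = [
        PlantedEffect("shared", "hyper", 0.5, 5),
        PlantedEffect("shared", "hypo", 0.5, 5),
    ]
    truth = plan_methylation_states(
        small_catalog, design, planted, min_cpgs_planted=3
    )
    counts = simulate_counts(truth, small_catalog, design)
    return design, truth, counts
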