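"""Shared fixtures: small deterministic genomes and site tables."""

import numpy as np
import pytest

from linkedsel.genome_data import (
    AnnotationSet,
    GeneticMap,
    GenomicInterval,
    NeutralSiteTable,
    SubstitutionSet,
)
from linkedsel.selection_effects import EffectiveSizeContext, SelectionGrid


@pytest.fixture(scope="session")
def grid():
    return SelectionGrid.default()


@pytest.fixture(scope="session")
def ctx():
    return EffectiveSizeContext(Ne=1e6)


@pytest.fixture
def const_map():
    """One 1 Mb chromosome at a constant 2 cM/Mb."""
    return GeneticMap.from_rates({"chr1": (np.array([0.0]), np.array([1e6]),
                                           np.array([2.0]))})


@pytest.fixture
def sparse_toy():
    """1 Mb toy genome with sparse selected blocks (< 1e4 selected bp):
    two annotation classes, two substitution classes, piecewise map."""
    gmap = GeneticMap.from_rates({
        "chr1": (np.array([0.0, 400_000.0, 700_000.0]),
                 np.array([400_000.0, 700_000.0, 1_000_000.0]),
                 np.array([1.0, 3.0, 0.8])),
        "chr2": (np.array([0.0]), np.array([500_000.0]), np.array([2.0])),
    })
    records = [
        GenomicInterval("chr1", 100_000, 102_000, "coding"),
        GenomicInterval("chr1", 450_000, 451_000, "coding"),
        GenomicInterval("chr1", 820_000, 821_500, "coding"),
        GenomicInterval("chr1", 300_000, 301_000, "utr"),
        GenomicInterval("chr2", 200_000, 202_500, "coding"),
    ]
    annotations = AnnotationSet.from_records(records, classes=["coding", "utr"])
    subs = SubstitutionSet.from_records(
        [("chr1", 101_000, "nonsyn"), ("chr1", 450_500, "nonsyn"),
         ("chr1", 820_700, "nonsyn"), ("chr1", 300_400, "utr_sub"),
         ("chr2", 201_000, "nonsyn")],
        classes=["nonsyn", "utr_sub"])
    rng = np.random.default_rng(11)
    pos1 = np.sort(rng.choice(1_000_000, 400, replace=False))
    pos2 = np.sort(rng.choice(500_000, 150, replace=False))
    chrom = np.array(["chr1"] * 400 + ["chr2"] * 150, dtype=object)
    pos = np.concatenate([pos1, pos2])
    n = 8
    npairs = n * (n - 1) // 2
    nd = rng.binomial(npairs, 0.02, size=len(pos))
    table = NeutralSiteTable.from_arrays(chrom, pos, nd, npairs - nd)
    return {"gmap": gmap, "annotations": annotations, "subs": subs,
            "table": table}


@pytest.fixture(scope="session")
def fullscale():
    """Default-condition synthetic run (4 x 25 Mb, seed 1), fitted combined."""
    from linkedsel.pipeline import run_synthetic_pipeline
    from linkedsel.synthetic_data import SyntheticConfig

    return run_synthetic_pipeline(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete simulated data set (2 x 6 Mb), session-cached."""
    from linkedsel.synthetic_data import SyntheticConfig, make_genome, simulate_polymorphism

    cfg = SyntheticConfig(seed=5, n_chroms=2, chrom_length_bp=6_000_000,
                          proxy_window=2000)
    genome = make_genome(cfg)
    table, truth, proxy = simulate_polymorphism(genome)
    return {"config": cfg, "genome": genome, "table": table, "truth": truth,
            "proxy": proxy}
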