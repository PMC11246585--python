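"""Shared simulated-population fixtures.

Panels are generated once per session: a small panel for unit-level checks
and a desk-scale panel (1,500 individuals x ~18k post-filter variants over
2 x 100 Mb) for the scenario-recovery tests.
"""

import numpy as np
import pytest

from hpart import annotate as an
from hpart import grm as gm
from hpart import synthpop as sp


@pytest.fixture(scope="session")
def small_panel():
    pool = sp.simulate_founder_haplotypes(
        300, 4000, [25_000_000, 25_000_000], ld_block_mean_kb=50, seed=101
    )
    return sp.gene_drop(
        pool, n_generations=2, n_sires=10, n_dams=100, offspring_per_dam=3, seed=102
    )


@pytest.fixture(scope="session")
def small_annotation(small_panel):
    _, classes = sp.layout_genome(small_panel, seed=103)
    return an.annotate_panel(small_panel, functional_class=classes)


@pytest.fixture(scope="session")
def desk_panel():
    pool = sp.simulate_founder_haplotypes(
        1100, 20_000, [100_000_000, 100_000_000], ld_block_mean_kb=50, seed=11
    )
    return sp.gene_drop(
        pool, n_generations=2, n_sires=25, n_dams=500, offspring_per_dam=3, seed=12
    )


@pytest.fixture(scope="session")
def desk_annotation(desk_panel):
    _, classes = sp.layout_genome(desk_panel, seed=13)
    return an.annotate_panel(desk_panel, functional_class=classes)


@pytest.fixture(scope="session")
def desk_tc_grms(desk_panel, desk_annotation):
    """OCR vs non-OCR GRMs (Yang rule) on the desk panel."""
    part = an.make_partition(desk_annotation, mode="noLDMS", design="TC", focal="OCR")
    return part, gm.build_grms(desk_panel, part)


@pytest.fixture(scope="session")
def desk_mc_grms(desk_panel, desk_annotation):
    """Six-functional-class GRMs (Yang rule) on the desk panel."""
    part = an.make_partition(desk_annotation, mode="noLDMS", design="MC")
    return part, gm.build_grms(desk_panel, part)


def iid_panel(n: int, m: int, seed: int, p_range=(0.1, 0.5)) -> sp.GenotypePanel:
    """Unstructured panel: binomial dosages, no LD, no relatedness."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    dosages = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    import pandas as pd

    return sp.GenotypePanel(
        dosages=dosages,
        chrom=np.ones(m, dtype=int),
        pos_bp=np.arange(1, m + 1) * 10_000,
        chrom_lengths={1: (m + 1) * 10_000},
        pedigree=pd.DataFrame(
            {"id": np.arange(n), "sire": -1, "dam": -1, "generation": 0, "sex": 0}
        ),
        sample_ids=np.arange(n),
    )
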