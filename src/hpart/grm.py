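"""Genomic relationship matrices under the two classic construction rules.

``yang``: centered *and* scaled genotypes, G = W W' / m with
w_ij = (x_ij - 2 p_j) / sqrt(2 p_j (1 - p_j)) — every variant contributes
equally regardless of MAF.  ``vanraden1``: centered genotypes only,
G = (X - 2P)(X - 2P)' / sum_j 2 p_j (1 - p_j) — common variants contribute
more.  Allele frequencies are always re-estimated from the analyzed panel.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .annotate import Partition
from .synthpop import GenotypePanel

logger = logging.getLogger(__name__)

RULES = ("yang", "vanraden1")


@dataclasses.dataclass
class GrmSet:
    """Named per-category GRMs with their variant counts and construction rule."""

    matrices: dict[str, np.ndarray]
    counts: dict[str, int]
    rule: str

    @property
    def names(self) -> list[str]:
        return list(self.matrices)

    @property
    def n_individuals(self) -> int:
        return next(iter(self.matrices.values())).shape[0]

    def __iter__(self):
        return iter(self.matrices.items())


def build_grm(
    panel: GenotypePanel,
    variant_subset: np.ndarray | None = None,
    rule: str = "yang",
) -> tuple[np.ndarray, int]:
    """GRM from a variant subset; monomorphic variants are dropped with a log
    notice (their standardized dosage is undefined). Returns (G, m_used)."""
    if rule not in RULES:
        raise ValueError(f"unknown GRM rule {rule!r}")
    idx = np.arange(panel.n_variants) if variant_subset is None else np.asarray(variant_subset)
    if idx.size == 0:
        raise ValueError("empty variant subset")
    X = panel.dosages[:, idx].astype(np.float64)
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1) & (X.var(axis=0) > 0)
    if not poly.all():
        logger.info("dropped %d monomorphic variants from GRM", int((~poly).sum()))
        X, p = X[:, poly], p[poly]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic variants in subset")
    het = 2.0 * p * (1.0 - p)
    C = X - 2.0 * p
    if rule == "yang":
        W = C / np.sqrt(het)
        G = W @ W.T / W.shape[1]
    else:
        G = C @ C.T / het.sum()
    return G, X.shape[1]


def build_grms(panel: GenotypePanel, partition: Partition, rule: str = "yang") -> GrmSet:
    """One GRM per partition group."""
    mats, counts = {}, {}
    for name, idx in zip(partition.names, partition.groups):
        G, m = build_grm(panel, idx, rule=rule)
        mats[name], counts[name] = G, m
    return GrmSet(mats, counts, rule)


def grm_offdiag_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the strictly-lower-triangle entries of two GRMs."""
    if a.shape != b.shape:
        raise ValueError("GRM dimension mismatch")
    i, j = np.tril_indices(a.shape[0], k=-1)
    return float(np.corrcoef(a[i, j], b[i, j])[0, 1])
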