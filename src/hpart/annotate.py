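"""Variant stratification: functional classes, MAF bins, LD scores and partitions.

A variant's LD score is the sum of squared dosage correlations with every
variant of the same chromosome within a physical window (including itself),
MAF bins are (0.01, 0.05], (0.05, 0.10], (0.10, 0.50], and LD-score bins are
empirical quartiles.  ``make_partition`` turns these strata into the variant
groupings fitted by the estimators: multi-component (MC, all functional
classes at once) or two-component (TC, one focal class against the rest),
optionally crossed with MAF (MS), LD (LDS) or both (LDMS) strata.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._intervals import in_intervals, merge_intervals
from .synthpop import CLASS_PRECEDENCE, GenomeLayout, GenotypePanel

logger = logging.getLogger(__name__)

MODES = ("noLDMS", "MS", "LDS", "LDMS")


@dataclasses.dataclass
class AnnotationMap:
    """Per-variant functional class, MAF bin, LD score, and LD quartile bin.

    Quartile breakpoints are computed once from the panel and frozen here so
    that phenotype simulation and estimation stratify variants identically.
    """

    functional_class: np.ndarray  # str labels
    maf_bin: np.ndarray  # {1,2,3}
    ld_score: np.ndarray  # float, >= 1 for polymorphic variants
    ld_bin: np.ndarray  # {1,2,3,4}
    maf: np.ndarray  # minor-allele frequency, kept for enrichment strata

    @property
    def n_variants(self) -> int:
        return self.functional_class.shape[0]

    def class_fractions(self) -> dict[str, float]:
        vals, counts = np.unique(self.functional_class, return_counts=True)
        return {str(v): c / self.n_variants for v, c in zip(vals, counts)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": self.functional_class,
                "maf_bin": self.maf_bin,
                "ld_score": self.ld_score,
                "ld_bin": self.ld_bin,
                "maf": self.maf,
            }
        )


@dataclasses.dataclass
class Partition:
    """Ordered, named, disjoint variant groups covering the whole panel."""

    names: list[str]
    groups: list[np.ndarray]
    mode: str
    design: str  # "MC" or "TC"
    focal: str | None = None

    def __post_init__(self) -> None:
        total = sum(g.size for g in self.groups)
        union = np.concatenate(self.groups) if self.groups else np.array([], dtype=int)
        if np.unique(union).size != total:
            raise ValueError("partition groups are not disjoint")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_sizes(self) -> dict[str, int]:
        return {n: g.size for n, g in zip(self.names, self.groups)}


def compute_ld_scores(panel: GenotypePanel, window_kb: float = 200.0) -> np.ndarray:
    """Per-variant LD score: sum of r^2 with all same-chromosome variants
    within +/- ``window_kb``, including the self term (so an isolated
    polymorphic variant scores exactly 1).

    Monomorphic variants have undefined correlations; their pairwise
    contributions are treated as 0 and a notice is logged.
    """
    X = panel.dosages.astype(np.float64)
    n, m = X.shape
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    mono = sd == 0
    if mono.any():
        logger.warning("%d monomorphic variants: r^2 contributions set to 0", int(mono.sum()))
    Z = np.zeros_like(X)
    ok = ~mono
    Z[:, ok] = (X[:, ok] - mean[ok]) / sd[ok]

    w = window_kb * 1000.0
    scores = np.ones(m)
    pos = panel.pos_bp.astype(np.int64)
    chrom = panel.chrom
    d = 1
    while d < m:
        dist = pos[d:] - pos[:-d]
        same = chrom[d:] == chrom[:-d]
        valid = same & (dist <= w)
        if not valid.any():
            if not same.any() or dist[same].min() > w:
                break
            d += 1
            continue
        r = np.einsum("ij,ij->j", Z[:, d:], Z[:, :-d]) / n
        r2 = np.where(valid, r * r, 0.0)
        scores[d:] += r2
        scores[:-d] += r2
        d += 1
    return scores


def bin_by_maf(freq: np.ndarray) -> np.ndarray:
    """MAF bins 1..3 over (0.01, 0.05], (0.05, 0.10], (0.10, 0.50].

    The 0.05 boundary belongs to bin 1, consistent with the "low MAF
    (MAF <= 0.05)" enrichment stratum used in the simulation scenarios.
    """
    p = np.asarray(freq, dtype=float)
    maf = np.minimum(p, 1.0 - p)
    if np.any(maf < 0.01 - 1e-12):
        raise ValueError("MAF below 0.01: panel should have been filtered")
    return (1 + (maf > 0.05).astype(np.int8) + (maf > 0.10).astype(np.int8)).astype(np.int8)


def bin_by_ld_quartiles(ld_score: np.ndarray) -> np.ndarray:
    """Quartile bins 1..4 from the empirical LD-score distribution.

    Breakpoints are the 25/50/75% quantiles; a score enters the next bin only
    when strictly above a breakpoint, so tied scores share the bin of the
    first occurrence and an all-equal vector collapses into bin 1.
    """
    s = np.asarray(ld_score, dtype=float)
    if s.size < 4:
        raise ValueError("need at least 4 variants to form quartiles")
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite LD scores")
    q = np.quantile(s, [0.25, 0.5, 0.75])
    if q[0] == q[2]:
        logger.warning("degenerate LD-score distribution: quartiles coincide")
    return (1 + (s > q[0]).astype(np.int8) + (s > q[1]).astype(np.int8) + (s > q[2]).astype(np.int8)).astype(np.int8)


def _merged_by_chrom(df: pd.DataFrame) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for c, sub in df.groupby("chrom"):
        out[int(c)] = merge_intervals(sub["start"].to_numpy(), sub["end"].to_numpy())
    return out


def classify_by_precedence(
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    class_intervals: dict[str, pd.DataFrame],
    order: tuple[str, ...] = CLASS_PRECEDENCE,
) -> np.ndarray:
    """Assign each 1-based position its highest-precedence containing class;
    unmatched positions become IGR."""
    pos0 = np.asarray(pos_bp, dtype=np.int64) - 1
    chrom = np.asarray(chrom)
    labels = np.full(pos0.shape, "IGR", dtype=object)
    assigned = np.zeros(pos0.shape, dtype=bool)
    for cls in order:
        if cls == "IGR" or cls not in class_intervals:
            continue
        merged = _merged_by_chrom(class_intervals[cls])
        for c, (s, e) in merged.items():
            on_c = (chrom == c) & ~assigned
            if not on_c.any():
                continue
            hit = in_intervals(pos0[on_c], s, e)
            idx = np.flatnonzero(on_c)[hit]
            labels[idx] = cls
            assigned[idx] = True
    return labels.astype(str)


def classify_layout(chrom: np.ndarray, pos_bp: np.ndarray, layout: GenomeLayout) -> np.ndarray:
    """Functional classes for variants against a simulated genome layout."""
    return classify_by_precedence(chrom, pos_bp, layout.class_intervals())


def classify_variants_from_intervals(
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    genes: pd.DataFrame,
    cds: pd.DataFrame,
    utr: pd.DataFrame,
    peaks: pd.DataFrame,
    flank_kb: float = 1.0,
) -> np.ndarray:
    """Classify variants from interval tables (``chrom``/``start``/``end``,
    0-based half-open, as produced by the GTF/BED readers in :mod:`hpart.io`).

    Precedence: OCR (peaks) beats everything; then CDS and UTR from the gene
    models; then the +/- ``flank_kb`` gene flanks (UDR); remaining in-gene
    variants are intronic (IOR) and the rest intergenic (IGR).
    """
    flank = int(flank_kb * 1000)
    if len(genes) and flank > 0:
        up = genes.assign(start=np.maximum(genes["start"] - flank, 0), end=genes["start"])
        down = genes.assign(start=genes["end"], end=genes["end"] + flank)
        udr = pd.concat([up, down], ignore_index=True)
    else:
        udr = pd.DataFrame(columns=["chrom", "start", "end"])
    return classify_by_precedence(
        chrom, pos_bp,
        {"OCR": peaks, "CDS": cds, "UTR": utr, "UDR": udr, "IOR": genes},
    )


def annotate_panel(
    panel: GenotypePanel,
    layout: GenomeLayout | None = None,
    functional_class: np.ndarray | None = None,
    window_kb: float = 200.0,
) -> AnnotationMap:
    """Build the full AnnotationMap for a panel: functional classes (from a
    layout or given directly), MAF bins, LD scores and frozen quartile bins."""
    if functional_class is None:
        if layout is None:
            raise ValueError("provide a GenomeLayout or per-variant classes")
        functional_class = classify_layout(panel.chrom, panel.pos_bp, layout)
    scores = compute_ld_scores(panel, window_kb=window_kb)
    freq = panel.freq
    return AnnotationMap(
        functional_class=np.asarray(functional_class, dtype=str),
        maf_bin=bin_by_maf(freq),
        ld_score=scores,
        ld_bin=bin_by_ld_quartiles(scores),
        maf=np.minimum(freq, 1 - freq),
    )


def _merged_labels(classes: np.ndarray, merge: dict[str, str] | None) -> np.ndarray:
    if not merge:
        return classes
    out = classes.copy()
    for old, new in merge.items():
        out[out == old] = new
    return out


def make_partition(
    annotation: AnnotationMap,
    mode: str = "noLDMS",
    design: str = "MC",
    focal: str | None = None,
    merge: dict[str, str] | None = None,
) -> Partition:
    """Variant partition for a model run.

    MC crosses every (merged) functional class with the mode's MAF/LD strata;
    TC contrasts ``focal`` against all other variants, likewise crossed.
    Empty groups are pruned with a logged notice.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    if design not in ("MC", "TC"):
        raise ValueError(f"unknown design {design!r}")
    labels = _merged_labels(annotation.functional_class, merge)
    if design == "TC":
        if focal is None or focal not in labels:
            raise ValueError(f"TC design needs an existing focal class, got {focal!r}")
        labels = np.where(labels == focal, focal, "rest")
        class_order = [focal, "rest"]
    else:
        class_order = [c for c in CLASS_PRECEDENCE if c in labels]
        class_order += sorted(set(labels) - set(class_order))

    use_maf = mode in ("MS", "LDMS")
    use_ld = mode in ("LDS", "LDMS")
    names, groups, pruned = [], [], []
    for cls in class_order:
        cls_mask = labels == cls
        for mb in [1, 2, 3] if use_maf else [None]:
            for lb in [1, 2, 3, 4] if use_ld else [None]:
                mask = cls_mask.copy()
                name = cls
                if mb is not None:
                    mask &= annotation.maf_bin == mb
                    name += f".maf{mb}"
                if lb is not None:
                    mask &= annotation.ld_bin == lb
                    name += f".ld{lb}"
                idx = np.flatnonzero(mask)
                if idx.size == 0:
                    pruned.append(name)
                    continue
                names.append(name)
                groups.append(idx)
    if pruned:
        logger.info("pruned %d empty partition groups: %s", len(pruned), pruned)
    part = Partition(names=names, groups=groups, mode=mode, design=design, focal=focal)
    if sum(g.size for g in part.groups) != annotation.n_variants:
        raise AssertionError("partition does not cover all variants")
    return part


def collapse_to_class(partition: Partition, values: np.ndarray) -> dict[str, float]:
    """Sum per-group values (e.g. variance components) back to functional
    classes, undoing the MAF/LD stratification of a partition's group names."""
    out: dict[str, float] = {}
    for name, v in zip(partition.names, values):
        cls = name.split(".")[0]
        out[cls] = out.get(cls, 0.0) + float(v)
    return out
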