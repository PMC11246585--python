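"""Livestock-like genotype panels: LD-structured founders plus pedigree gene-dropping.

The founder haplotypes come from a copy-with-mutation Markov chain along
each chromosome: every haplotype carries a latent uniform that is copied to
the next variant with a distance-dependent probability ``exp(-d/scale)`` and
redrawn otherwise, so adjacent-variant r^2 decays with distance at a
configurable block scale while per-site allele frequencies follow a
rare-skewed spectrum truncated at MAF 0.01.  Relatedness (large half-sib
families, common grand-sires) is then created explicitly by dropping the
founder haplotypes through a pedigree of successive sire/dam generations
with recombination.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from ._intervals import merge_intervals

logger = logging.getLogger(__name__)

#: Genome-wide variant proportions of the six functional classes
#: (coding, intronic, untranslated, gene flanks, intergenic, open chromatin).
TABLE1_PROPORTIONS: dict[str, float] = {
    "CDS": 0.0056,
    "IOR": 0.3014,
    "UTR": 0.0005,
    "UDR": 0.0529,
    "IGR": 0.5335,
    "OCR": 0.1061,
}

#: Variant shares of the genetic variance (percent) in the three complex
#: multi-class simulation scenarios.
COMPLEX_SCENARIO_SHARES: dict[str, dict[str, float]] = {
    "I": {"CDS": 25, "IOR": 14, "UTR": 1, "UDR": 10, "IGR": 15, "OCR": 35},
    "II": {"CDS": 15, "IOR": 10, "UTR": 0.5, "UDR": 4.5, "IGR": 10, "OCR": 60},
    "III": {"CDS": 50, "IOR": 20, "UTR": 0, "UDR": 10, "IGR": 0, "OCR": 20},
}

CLASS_PRECEDENCE = ("OCR", "CDS", "UTR", "UDR", "IOR", "IGR")


@dataclasses.dataclass
class HaplotypePool:
    """Founder haplotypes (2 per founder) with variant coordinates."""

    haplotypes: np.ndarray  # (2 * n_founders, m) uint8
    chrom: np.ndarray  # (m,) int
    pos_bp: np.ndarray  # (m,) int, 1-based
    chrom_lengths: dict[int, int]

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclasses.dataclass
class GenotypePanel:
    """Diploid dosage panel with pedigree and (optionally) phased haplotypes.

    ``dosages[i, j]`` counts copies of the alternate allele (0/1/2) for
    individual ``i`` at variant ``j``.  ``pedigree`` covers every simulated
    individual; rows of ``dosages`` correspond to ``sample_ids``.
    """

    dosages: np.ndarray  # (n, m) int8
    chrom: np.ndarray  # (m,)
    pos_bp: np.ndarray  # (m,) 1-based
    chrom_lengths: dict[int, int]
    pedigree: pd.DataFrame  # id, sire, dam, generation, sex (-1 parent = founder)
    sample_ids: np.ndarray  # (n,) ids of the dosage rows
    haplotypes: np.ndarray | None = None  # (2, n, m) uint8 for the dosage rows
    parent_haplotypes: dict[int, np.ndarray] | None = None  # id -> (2, m)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def freq(self) -> np.ndarray:
        """Alternate-allele frequency estimated from the panel itself."""
        return self.dosages.mean(axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.freq
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            chrom_lengths=self.chrom_lengths,
            pedigree=self.pedigree,
            sample_ids=self.sample_ids,
            haplotypes=None if self.haplotypes is None else self.haplotypes[:, :, idx],
            parent_haplotypes=None
            if self.parent_haplotypes is None
            else {k: v[:, idx] for k, v in self.parent_haplotypes.items()},
        )

    def filter_maf(self, min_maf: float = 0.01) -> "GenotypePanel":
        """Drop variants with realized MAF below ``min_maf`` (and monomorphics)."""
        keep = np.flatnonzero(self.maf >= min_maf)
        n_drop = self.n_variants - keep.size
        if n_drop:
            logger.info("MAF filter removed %d variants (< %g)", n_drop, min_maf)
        return self.subset_variants(keep)


@dataclasses.dataclass
class GenomeLayout:
    """Gene/peak interval structure used to assign functional classes.

    Intervals are 0-based half-open per chromosome; the io layer renders
    them 1-based inclusive for GTF output.
    """

    genes: pd.DataFrame  # chrom, start, end
    cds: pd.DataFrame
    utr: pd.DataFrame
    peaks: pd.DataFrame  # OCR intervals
    flank_bp: int
    chrom_lengths: dict[int, int]

    def class_intervals(self) -> dict[str, pd.DataFrame]:
        """Raw (unmerged) intervals per class; UDR derived from gene flanks."""
        if len(self.genes) and self.flank_bp > 0:
            up = self.genes.assign(
                start=np.maximum(self.genes["start"] - self.flank_bp, 0),
                end=self.genes["start"],
            )
            down = self.genes.assign(start=self.genes["end"], end=self.genes["end"] + self.flank_bp)
            udr = pd.concat([up, down], ignore_index=True)
        else:
            udr = pd.DataFrame(columns=["chrom", "start", "end"])
        return {
            "OCR": self.peaks,
            "CDS": self.cds,
            "UTR": self.utr,
            "UDR": udr,
            "IOR": self.genes,  # gene body; precedence carves out CDS/UTR/UDR
        }


def _spread_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` items across weights."""
    weights = np.asarray(weights, dtype=float)
    raw = total * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(raw - counts)[::-1]
        counts[order[:short]] += 1
    return counts


def _sample_positions(n: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` distinct sorted 1-based positions on [1, length]."""
    if n > length:
        raise ValueError("more variants than base pairs requested")
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=int(n * 1.2) + 16))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def _maf_spectrum(n: int, alpha: float, rng: np.random.Generator,
                  lo: float = 0.01, hi: float = 0.5) -> np.ndarray:
    """Draw MAFs from a density proportional to maf^-alpha on [lo, hi]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return lo * (hi / lo) ** u
    a, b = lo ** (1 - alpha), hi ** (1 - alpha)
    return (a + u * (b - a)) ** (1.0 / (1 - alpha))


def simulate_founder_haplotypes(
    n_founders: int,
    n_variants: int,
    chrom_lengths: dict[int, int] | list[int],
    ld_block_mean_kb: float = 50.0,
    maf_alpha: float = 1.0,
    ld_scale_log10_sd: float = 0.6,
    ld_region_mb: float = 5.0,
    seed: int = 0,
) -> HaplotypePool:
    """Simulate ``2 * n_founders`` haplotypes with distance-decaying LD.

    Each haplotype carries a latent uniform along the chromosome; at each
    step the uniform is copied with probability ``exp(-d / scale)`` (d the
    inter-variant distance, scale around ``ld_block_mean_kb``) and redrawn
    otherwise.  The allele at variant j is the indicator ``U < p_j``, so
    marginal frequencies follow the target spectrum while copied uniforms
    generate positive LD between nearby variants.

    The copy scale varies regionally: each ``ld_region_mb`` segment gets a
    log-normal multiplier (log10 SD ``ld_scale_log10_sd``), emulating the
    recombination-rate variation and selective sweeps that give livestock
    genomes genuinely low- and high-LD regions; set the SD to 0 for a
    homogeneous genome.
    """
    if n_founders < 2 or n_variants < 1:
        raise ValueError("need n_founders >= 2 and n_variants >= 1")
    if isinstance(chrom_lengths, (list, tuple, np.ndarray)):
        chrom_lengths = {i + 1: int(L) for i, L in enumerate(chrom_lengths)}
    rng = np.random.default_rng(seed)

    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = _spread_counts(n_variants, lengths)

    chrom_arr = np.concatenate([np.full(k, c) for c, k in zip(chroms, per_chrom)])
    pos = np.concatenate(
        [_sample_positions(k, chrom_lengths[c], rng) for c, k in zip(chroms, per_chrom)]
    )

    maf = _maf_spectrum(n_variants, maf_alpha, rng)
    flip = rng.random(n_variants) < 0.5
    p = np.where(flip, 1.0 - maf, maf)

    # per-variant copy scale from regional multipliers
    region_bp = max(int(ld_region_mb * 1e6), 1)
    scale_bp = np.full(n_variants, ld_block_mean_kb * 1000.0)
    if ld_block_mean_kb > 0 and ld_scale_log10_sd > 0:
        for c in chroms:
            on_c = chrom_arr == c
            n_regions = chrom_lengths[c] // region_bp + 1
            mult = 10.0 ** rng.normal(0.0, ld_scale_log10_sd, size=n_regions)
            scale_bp[on_c] *= mult[pos[on_c] // region_bp]

    n_hap = 2 * n_founders
    haps = np.empty((n_hap, n_variants), dtype=np.uint8)
    u = rng.random(n_hap)
    prev_chrom = None
    prev_pos = 0
    for j in range(n_variants):
        if chrom_arr[j] != prev_chrom:
            u = rng.random(n_hap)
        elif scale_bp[j] > 0:
            c = np.exp(-(pos[j] - prev_pos) / scale_bp[j])
            redraw = rng.random(n_hap) >= c
            u = np.where(redraw, rng.random(n_hap), u)
        else:
            u = rng.random(n_hap)
        haps[:, j] = u < p[j]
        prev_chrom, prev_pos = chrom_arr[j], pos[j]

    return HaplotypePool(haps, chrom_arr, pos, dict(chrom_lengths))


def _chrom_slices(chrom: np.ndarray) -> list[tuple[int, slice]]:
    out = []
    start = 0
    for c in pd.unique(chrom):
        n = int(np.sum(chrom == c))
        out.append((int(c), slice(start, start + n)))
        start += n
    return out


def _gamete(
    haps: np.ndarray,
    slices: list[tuple[int, slice]],
    pos: np.ndarray,
    chrom_lengths: dict[int, int],
    cm_per_mb: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant gamete from a parent's (2, m) haplotype pair."""
    out = np.empty(haps.shape[1], dtype=np.uint8)
    for c, sl in slices:
        morgans = chrom_lengths[c] / 1e6 * cm_per_mb / 100.0
        n_x = rng.poisson(morgans)
        start = rng.integers(0, 2)
        if n_x == 0:
            out[sl] = haps[start, sl]
            continue
        xo = np.sort(rng.integers(1, chrom_lengths[c] + 1, size=n_x))
        source = (start + np.searchsorted(xo, pos[sl])) % 2
        seg = haps[:, sl]
        out[sl] = np.where(source == 0, seg[0], seg[1])
    return out


def gene_drop(
    pool: HaplotypePool,
    n_generations: int = 2,
    n_sires: int = 25,
    n_dams: int = 500,
    offspring_per_dam: int = 3,
    cm_per_mb: float = 1.0,
    seed: int = 0,
    min_maf: float = 0.01,
    keep_lineage: bool = True,
) -> GenotypePanel:
    """Drop founder haplotypes through a sire/dam pedigree; return the final generation.

    Each generation samples ``n_sires`` males and ``n_dams`` females from the
    previous one; every dam is mated to one random sire and produces
    ``offspring_per_dam`` offspring, so the design creates large paternal
    half-sib families (on average ``n_dams / n_sires * offspring_per_dam``
    offspring per sire).  Founder/offspring sexes alternate deterministically
    so that the demanded numbers of parents are available whenever they are
    feasible at all.  Variants with realized MAF below ``min_maf`` in the
    final generation are removed.
    """
    if min(n_generations, n_sires, n_dams, offspring_per_dam) < 1:
        raise ValueError("pedigree counts must be positive")
    if pool.n_variants < 1:
        raise ValueError("empty haplotype pool")
    rng = np.random.default_rng(seed)
    m = pool.n_variants
    slices = _chrom_slices(pool.chrom)

    # generation 0: founders, sexes alternating (0 = male, 1 = female)
    n_f = pool.n_founders
    haps = pool.haplotypes.reshape(n_f, 2, m)
    ids = np.arange(n_f)
    sex = ids % 2
    ped_rows = [
        {"id": int(i), "sire": -1, "dam": -1, "generation": 0, "sex": int(sex[i])}
        for i in ids
    ]
    hap_store: dict[int, np.ndarray] = {int(i): haps[i] for i in ids}
    next_id = n_f

    cur_ids, cur_sex = ids, sex
    for gen in range(1, n_generations + 1):
        males = cur_ids[cur_sex == 0]
        females = cur_ids[cur_sex == 1]
        if males.size < n_sires or females.size < n_dams:
            raise ValueError(
                f"generation {gen}: need {n_sires} sires / {n_dams} dams, "
                f"have {males.size} males / {females.size} females"
            )
        sires = rng.choice(males, size=n_sires, replace=False)
        dams = rng.choice(females, size=n_dams, replace=False)
        mate = rng.integers(0, n_sires, size=n_dams)

        new_ids = []
        for d_i, dam in enumerate(dams):
            sire = sires[mate[d_i]]
            for _ in range(offspring_per_dam):
                pat = _gamete(hap_store[int(sire)], slices, pool.pos_bp, pool.chrom_lengths, cm_per_mb, rng)
                mat = _gamete(hap_store[int(dam)], slices, pool.pos_bp, pool.chrom_lengths, cm_per_mb, rng)
                hap_store[next_id] = np.stack([pat, mat])
                ped_rows.append(
                    {"id": next_id, "sire": int(sire), "dam": int(dam),
                     "generation": gen, "sex": next_id % 2}
                )
                new_ids.append(next_id)
                next_id += 1
        cur_ids = np.array(new_ids)
        cur_sex = cur_ids % 2

    pedigree = pd.DataFrame(ped_rows)
    final_ids = cur_ids
    final_haps = np.stack([hap_store[int(i)] for i in final_ids])  # (n, 2, m)
    dosages = final_haps.sum(axis=1).astype(np.int8)

    parent_ids = set()
    final_set = set(int(i) for i in final_ids)
    for row in ped_rows:
        if row["id"] in final_set:
            parent_ids.update((row["sire"], row["dam"]))
    parent_haps = {pid: hap_store[pid] for pid in parent_ids if pid >= 0}

    panel = GenotypePanel(
        dosages=dosages,
        chrom=pool.chrom.copy(),
        pos_bp=pool.pos_bp.copy(),
        chrom_lengths=dict(pool.chrom_lengths),
        pedigree=pedigree,
        sample_ids=final_ids,
        haplotypes=np.transpose(final_haps, (1, 0, 2)).copy(),
        parent_haplotypes=parent_haps if keep_lineage else None,
    )
    return panel.filter_maf(min_maf) if min_maf > 0 else panel


def check_mendelian(panel: GenotypePanel) -> bool:
    """Replay transmissions: every haplotype must be a mosaic of its parent's two.

    Requires ``panel.haplotypes`` and ``panel.parent_haplotypes``.
    """
    if panel.haplotypes is None or panel.parent_haplotypes is None:
        raise ValueError("panel lacks stored haplotypes for Mendelian replay")
    ped = panel.pedigree.set_index("id")
    for row, ind in enumerate(panel.sample_ids):
        sire, dam = int(ped.loc[int(ind), "sire"]), int(ped.loc[int(ind), "dam"])
        if sire < 0:
            continue
        for hap_i, parent in ((0, sire), (1, dam)):
            child = panel.haplotypes[hap_i, row]
            ph = panel.parent_haplotypes[parent]
            if not np.all((child == ph[0]) | (child == ph[1])):
                return False
    return True


def _place_genes(
    chrom_lengths: dict[int, int],
    n_genes: int,
    mean_len: float,
    cds_frac: float,
    utr_frac: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place non-overlapping genes with internal UTR/CDS/intron structure."""
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = _spread_counts(n_genes, lengths)

    gene_rows, cds_rows, utr_rows = [], [], []
    for c, k in zip(chroms, per_chrom):
        if k == 0:
            continue
        L = chrom_lengths[c]
        glens = np.maximum(rng.gamma(4.0, mean_len / 4.0, size=k), 600).astype(np.int64)
        overflow = glens.sum() - int(L * 0.98)
        if overflow > 0:  # genome nearly saturated; shrink proportionally
            glens = (glens * (L * 0.98) / glens.sum()).astype(np.int64)
        free = L - glens.sum()
        gaps = rng.dirichlet(np.ones(k + 1)) * free
        starts = (np.cumsum(gaps[:-1]) + np.cumsum(np.concatenate([[0], glens[:-1]]))).astype(np.int64)
        for s, g in zip(starts, glens):
            e = s + int(g)
            gene_rows.append((c, int(s), e))
            utr_len = int(round(g * utr_frac))
            cds_len = int(round(g * cds_frac))
            u5 = utr_len // 2
            u3 = utr_len - u5
            if u5 > 0:
                utr_rows.append((c, int(s), int(s) + u5))
            if u3 > 0:
                utr_rows.append((c, e - u3, e))
            interior_s, interior_e = int(s) + u5, e - u3
            if cds_len > 0 and interior_e > interior_s:
                n_ex = max(1, int(round(g / 3000)))
                ex_lens = _spread_counts(cds_len, np.ones(n_ex))
                # exons evenly spaced through the interior
                span = interior_e - interior_s
                anchors = np.linspace(0, max(span - ex_lens.max(), 0), n_ex).astype(np.int64)
                for a, el in zip(anchors, ex_lens):
                    if el > 0:
                        cs = interior_s + int(a)
                        cds_rows.append((c, cs, min(cs + int(el), interior_e)))
    cols = ["chrom", "start", "end"]
    return (
        pd.DataFrame(gene_rows, columns=cols),
        pd.DataFrame(cds_rows, columns=cols),
        pd.DataFrame(utr_rows, columns=cols),
    )


def layout_genome(
    panel: GenotypePanel,
    class_proportions: dict[str, float] | None = None,
    seed: int = 0,
    flank_bp: int = 1000,
    mean_peak_bp: int = 2000,
) -> tuple[GenomeLayout, np.ndarray]:
    """Lay out genes and open-chromatin peaks so that realized per-class variant
    proportions approximate the targets, and classify the panel's variants.

    Targets are fractions of variants per class (any missing mass goes to
    IGR, the intergenic remainder).  Annotations are contiguous intervals,
    so neighboring variants of different classes are in LD — the confounding
    regime the estimators are evaluated under.  Overlaps are resolved by the
    precedence OCR > CDS > UTR > UDR > IOR > IGR.
    """
    from .annotate import classify_layout  # late import; annotate depends on types here

    props = dict(class_proportions or TABLE1_PROPORTIONS)
    props.setdefault("IGR", 0.0)
    unknown = set(props) - set(CLASS_PRECEDENCE)
    if unknown:
        raise ValueError(f"unknown annotation classes: {sorted(unknown)}")
    explicit = sum(v for k, v in props.items() if k != "IGR")
    if explicit + props["IGR"] > 1.0 + 1e-9:
        raise ValueError("class proportions sum to more than 1")
    if any(v < 0 for v in props.values()):
        raise ValueError("class proportions must be non-negative")
    rng = np.random.default_rng(seed)

    L = sum(panel.chrom_lengths.values())
    ocr_t = props.get("OCR", 0.0)
    cds_t, utr_t, ior_t, udr_t = (props.get(k, 0.0) for k in ("CDS", "UTR", "IOR", "UDR"))
    genic_t = cds_t + utr_t + ior_t
    inflation = 1.0 / max(1.0 - ocr_t, 1e-9)

    eff_flank = flank_bp if udr_t > 0 else 0
    if genic_t + udr_t > 0:
        gene_span = genic_t * inflation * L
        if udr_t > 0:
            n_genes = max(1, int(round(udr_t * inflation * L / (2 * flank_bp))))
        else:
            n_genes = max(1, int(round(gene_span / 12_000)))
        mean_len = gene_span / n_genes if gene_span > 0 else 2 * flank_bp
        cds_frac = cds_t / genic_t if genic_t > 0 else 0.0
        utr_frac = utr_t / genic_t if genic_t > 0 else 0.0
        genes, cds, utr = _place_genes(panel.chrom_lengths, n_genes, mean_len, cds_frac, utr_frac, rng)
    else:
        genes = cds = utr = pd.DataFrame(columns=["chrom", "start", "end"])

    peak_rows = []
    if ocr_t > 0:
        # Poisson-coverage correction: random peaks overlap, so place enough
        # that the merged span hits the target fraction.
        lam = -np.log(max(1.0 - ocr_t, 1e-9))
        for c, Lc in panel.chrom_lengths.items():
            n_pk = max(1, int(round(lam * Lc / mean_peak_bp)))
            plens = np.maximum(rng.gamma(3.0, mean_peak_bp / 3.0, size=n_pk), 100).astype(np.int64)
            starts = rng.integers(0, Lc, size=n_pk)
            ends = np.minimum(starts + plens, Lc)
            s, e = merge_intervals(starts, ends)
            peak_rows.append(pd.DataFrame({"chrom": c, "start": s, "end": e}))
    peaks = (
        pd.concat(peak_rows, ignore_index=True)
        if peak_rows
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )

    layout = GenomeLayout(
        genes=genes, cds=cds, utr=utr, peaks=peaks,
        flank_bp=eff_flank, chrom_lengths=dict(panel.chrom_lengths),
    )
    classes = classify_layout(panel.chrom, panel.pos_bp, layout)
    return layout, classes


def sample_genome_subset(
    panel: GenotypePanel,
    n_positions: int = 200,
    half_width_kb: float = 500.0,
    seed: int = 0,
) -> tuple[GenotypePanel, np.ndarray]:
    """Random genomic windows: sample positions, keep all variants within
    ``half_width_kb`` of each; overlapping windows are merged so the selected
    span can fall short of ``n_positions * 2 * half_width_kb``.

    Returns the subset panel and the kept variant indices (for remapping
    annotations built on the parent panel).
    """
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    rng = np.random.default_rng(seed)
    chroms = sorted(panel.chrom_lengths)
    lengths = np.array([panel.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    hw = int(half_width_kb * 1000)

    pick_c = rng.choice(len(chroms), size=n_positions, p=probs)
    keep = np.zeros(panel.n_variants, dtype=bool)
    for ci in range(len(chroms)):
        n_c = int(np.sum(pick_c == ci))
        if n_c == 0:
            continue
        centers = rng.integers(1, panel.chrom_lengths[chroms[ci]] + 1, size=n_c)
        s, e = merge_intervals(np.maximum(centers - hw, 0), centers + hw)
        on_c = panel.chrom == chroms[ci]
        pos = panel.pos_bp
        idx = np.searchsorted(s, pos, side="right") - 1
        hit = (idx >= 0) & on_c
        hit[hit] &= pos[hit] < e[idx[hit]] + 1
        keep |= hit
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("sampled windows contain no variants")
    return panel.subset_variants(idx), idx
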