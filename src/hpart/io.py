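"""Readers and writers for the standard interchange formats.

PLINK bed/bim/fam (variant-major 2-bit bed with magic-byte validation),
GCTA-layout binary GRMs (single-precision lower-triangle stream), Ensembl
GTF via pyranges, BED peak intervals, and plain TSV tables for annotations
and phenotypes.  External text coordinates are 1-based inclusive (GTF) or
0-based half-open (BED); everything internal is 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import AnnotationMap
from .grm import GrmSet
from .synthpop import GenomeLayout, GenotypePanel

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes, variant-major: 00=hom A1 (dosage 2), 10=het, 11=hom A2, 01=missing
_CODE_FROM_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FROM_CODE = np.array([2, -1, 1, 0], dtype=np.int8)  # -1 marks missing


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write bed/bim/fam; the alternate allele is A1 so dosages round-trip."""
    prefix = Path(prefix)
    n, m = panel.n_individuals, panel.n_variants
    bim = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "id": [f"v{c}_{p}" for c, p in zip(panel.chrom, panel.pos_bp)],
            "cm": 0.0,
            "pos": panel.pos_bp,
            "a1": "A",
            "a2": "C",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.sample_ids,
            "iid": panel.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    bytes_per_var = (n + 3) // 4
    out = np.zeros((m, bytes_per_var), dtype=np.uint8)
    codes = np.empty((m, n), dtype=np.uint8)
    for dos, code in _CODE_FROM_DOSAGE.items():
        codes[panel.dosages.T == dos] = code
    for k in range(4):
        cols = codes[:, k::4]
        out[:, : cols.shape[1]] |= cols << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a bed/bim/fam triplet into a panel.

    Missing genotypes are mean-imputed (rounded) with a logged count;
    structural problems (bad magic bytes, truncated bed, fam/bed mismatch)
    raise rather than being silently repaired.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"bad bed magic bytes {raw[:3]!r} at offset 0")
    bytes_per_var = (n + 3) // 4
    expected = 3 + bytes_per_var * m
    if len(raw) != expected:
        raise ValueError(f"truncated/oversized bed: {len(raw)} bytes, expected {expected}")
    data = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, bytes_per_var)
    codes = np.empty((m, bytes_per_var * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    dosages = _DOSAGE_FROM_CODE[codes[:, :n]].T.astype(np.float64)

    missing = dosages < 0
    if missing.any():
        logger.info("mean-imputing %d missing genotypes", int(missing.sum()))
        col_mean = np.where(missing, np.nan, dosages).astype(float)
        means = np.nanmean(col_mean, axis=0)
        dosages = np.where(missing, np.round(means), dosages)

    chrom = bim["chrom"].to_numpy()
    chrom_lengths = {int(c): int(bim.loc[bim["chrom"] == c, "pos"].max()) for c in pd.unique(chrom)}
    pedigree = pd.DataFrame(
        {"id": fam["iid"], "sire": -1, "dam": -1, "generation": 0, "sex": fam["sex"]}
    )
    return GenotypePanel(
        dosages=dosages.astype(np.int8),
        chrom=chrom,
        pos_bp=bim["pos"].to_numpy(),
        chrom_lengths=chrom_lengths,
        pedigree=pedigree,
        sample_ids=fam["iid"].to_numpy(),
    )


def write_grm_gcta(G: np.ndarray, ids: np.ndarray, m_variants: int, prefix: str | Path) -> None:
    """GCTA binary GRM layout: lower triangle (diagonal included) as float32
    in ``.grm.bin``, pair-wise variant counts in ``.grm.N.bin``, ids in
    ``.grm.id``."""
    prefix = Path(prefix)
    n = G.shape[0]
    i, j = np.tril_indices(n)
    G[i, j].astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(i.size, m_variants, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": ids, "iid": ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_gcta(prefix: str | Path) -> tuple[np.ndarray, np.ndarray, int]:
    """Read a GCTA binary GRM; returns (G, ids, m_variants)."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep="\t", header=None)[1].to_numpy()
    n = ids.size
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if tri.size != n * (n + 1) // 2:
        raise ValueError(f"GRM stream has {tri.size} entries for {n} ids")
    G = np.zeros((n, n))
    i, j = np.tril_indices(n)
    G[i, j] = tri
    G[j, i] = tri
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    m = int(counts[0]) if counts.size else 0
    return G, ids, m


def write_grm_set(grms: GrmSet, ids: np.ndarray, out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, G in grms:
        prefix = out_dir / name
        write_grm_gcta(G, ids, grms.counts[name], prefix)
        written.append(prefix)
    return written


def write_annotation(annotation: AnnotationMap, variant_ids: np.ndarray, path: str | Path) -> None:
    df = annotation.to_frame()
    df.insert(0, "variant_id", variant_ids)
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> AnnotationMap:
    df = pd.read_csv(path, sep="\t")
    return AnnotationMap(
        functional_class=df["class"].to_numpy(dtype=str),
        maf_bin=df["maf_bin"].to_numpy(dtype=np.int8),
        ld_score=df["ld_score"].to_numpy(dtype=float),
        ld_bin=df["ld_bin"].to_numpy(dtype=np.int8),
        maf=df["maf"].to_numpy(dtype=float),
    )


def write_phenotypes(sample_ids: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids, "y": y}).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_phenotypes(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, names=["fid", "iid", "y"])
    return df["iid"].to_numpy(), df["y"].to_numpy(dtype=float)


def read_gtf_intervals(path: str | Path) -> dict[str, pd.DataFrame]:
    """Ensembl-dialect GTF -> internal 0-based half-open interval tables for
    gene bodies, CDS and UTR features."""
    import pyranges as pr

    gr = pr.read_gtf(str(path)).df
    if gr.empty:
        raise ValueError(f"no GTF records parsed from {path}")
    out = {}
    for key, feats in (("genes", ["gene"]), ("cds", ["CDS"]),
                       ("utr", ["UTR", "five_prime_utr", "three_prime_utr"])):
        sub = gr[gr["Feature"].isin(feats)]
        out[key] = pd.DataFrame(
            {
                "chrom": pd.to_numeric(sub["Chromosome"], errors="coerce").fillna(0).astype(int),
                "start": sub["Start"].astype(np.int64),
                "end": sub["End"].astype(np.int64),
            }
        ).reset_index(drop=True)
    return out


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """BED (0-based half-open) peak intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"BED file {path} needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    if (out["end"] <= out["start"]).any():
        bad = int((out["end"] <= out["start"]).sum())
        raise ValueError(f"BED file {path}: {bad} intervals with end <= start")
    return out


def write_layout_gtf(layout: GenomeLayout, path: str | Path) -> None:
    """Render the simulated gene models as Ensembl-style GTF (1-based inclusive)."""
    rows = []
    for g_i, g in layout.genes.iterrows():
        attrs = f'gene_id "SIM{g_i:06d}";'
        rows.append((g["chrom"], "hpart", "gene", g["start"] + 1, g["end"], ".", "+", ".", attrs))
    for _, r in layout.cds.iterrows():
        rows.append((r["chrom"], "hpart", "CDS", r["start"] + 1, r["end"], ".", "+", ".", 'gene_id "NA";'))
    for _, r in layout.utr.iterrows():
        rows.append((r["chrom"], "hpart", "UTR", r["start"] + 1, r["end"], ".", "+", ".", 'gene_id "NA";'))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_layout_bed(layout: GenomeLayout, path: str | Path) -> None:
    """Render the open-chromatin peaks as BED (0-based half-open)."""
    layout.peaks[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)
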