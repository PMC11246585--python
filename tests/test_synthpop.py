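"""Population simulator: LD structure, pedigree transmission, genome layout."""

import numpy as np
import pytest

from hpart import synthpop as sp
from hpart.annotate import classify_by_precedence
from hpart.grm import build_grm

import pandas as pd


def adjacent_r2(haps: np.ndarray) -> np.ndarray:
    """Mean r^2 between consecutive variant pairs (polymorphic only)."""
    h = haps.astype(float)
    out = []
    for j in range(h.shape[1] - 1):
        a, b = h[:, j], h[:, j + 1]
        if a.std() == 0 or b.std() == 0:
            continue
        out.append(np.corrcoef(a, b)[0, 1] ** 2)
    return np.array(out)


class TestFounderHaplotypes:
    def test_no_ld_limit_gives_independent_sites(self):
        pool = sp.simulate_founder_haplotypes(
            500, 400, [4_000_000], ld_block_mean_kb=0.0, seed=1
        )
        r2 = adjacent_r2(pool.haplotypes)
        # E[r^2] under independence is ~1/(2*n_founders)
        assert r2.mean() < 3.0 / 1000

    def test_seeded_determinism(self):
        a = sp.simulate_founder_haplotypes(100, 5000, [10_000_000], seed=7)
        b = sp.simulate_founder_haplotypes(100, 5000, [10_000_000], seed=7)
        assert np.array_equal(a.haplotypes, b.haplotypes)
        assert np.array_equal(a.pos_bp, b.pos_bp)

    def test_adjacent_r2_matches_two_site_chain_oracle(self):
        """Adjacent-pair r^2 of the copy-with-mutation chain must match a
        brute-force two-site simulation of the same chain (matched copy
        probability and allele frequencies, pair by pair)."""
        scale_kb = 50.0
        pool = sp.simulate_founder_haplotypes(
            4000, 150, [5_000_000], ld_block_mean_kb=scale_kb,
            ld_scale_log10_sd=0.0, seed=6,
        )
        h = pool.haplotypes.astype(float)
        freq = h.mean(axis=0)
        rng = np.random.default_rng(7)
        panel_r2, oracle_r2 = [], []
        for j in range(h.shape[1] - 1):
            p1, p2 = freq[j], freq[j + 1]
            if min(p1, 1 - p1, p2, 1 - p2) < 0.05:
                continue  # skip near-monomorphic pairs (noisy r^2)
            c = np.exp(-(pool.pos_bp[j + 1] - pool.pos_bp[j]) / (scale_kb * 1000))
            panel_r2.append(np.corrcoef(h[:, j], h[:, j + 1])[0, 1] ** 2)
            u1 = rng.random(10_000)
            carry = rng.random(10_000) < c
            u2 = np.where(carry, u1, rng.random(10_000))
            a1, a2 = (u1 < p1).astype(float), (u2 < p2).astype(float)
            oracle_r2.append(np.corrcoef(a1, a2)[0, 1] ** 2)
        assert len(panel_r2) > 20
        assert np.mean(panel_r2) == pytest.approx(np.mean(oracle_r2), abs=0.03)

    def test_rare_skewed_spectrum_truncated(self):
        pool = sp.simulate_founder_haplotypes(400, 3000, [30_000_000], seed=2)
        freq = pool.haplotypes.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        assert (maf[maf > 0] < 0.05).mean() > 0.25  # rare-heavy
        assert pool.pos_bp.min() >= 1

    def test_positions_strictly_increasing_within_chromosome(self):
        pool = sp.simulate_founder_haplotypes(50, 2000, [5_000_000, 5_000_000], seed=3)
        for c in (1, 2):
            pos = pool.pos_bp[pool.chrom == c]
            assert np.all(np.diff(pos) > 0)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            sp.simulate_founder_haplotypes(1, 100, [1_000_000], seed=0)
        with pytest.raises(ValueError):
            sp.simulate_founder_haplotypes(10, 0, [1_000_000], seed=0)


class TestGeneDrop:
    def test_offspring_is_sum_of_parental_gametes_without_recombination(self):
        pool = sp.simulate_founder_haplotypes(2, 200, [2_000_000], seed=4)
        panel = sp.gene_drop(
            pool, n_generations=1, n_sires=1, n_dams=1, offspring_per_dam=3,
            cm_per_mb=0.0, seed=5, min_maf=0.0,
        )
        haps = pool.haplotypes.reshape(2, 2, -1)
        for row in range(panel.n_individuals):
            pat, mat = panel.haplotypes[0, row], panel.haplotypes[1, row]
            assert any(np.array_equal(pat, haps[0][i]) for i in range(2))
            assert any(np.array_equal(mat, haps[1][i]) for i in range(2))
            assert np.array_equal(panel.dosages[row], (pat + mat).astype(np.int8))

    def test_mendelian_replay(self, small_panel):
        assert sp.check_mendelian(small_panel)

    def test_half_sib_relatedness_near_quarter(self, small_panel):
        """Realized GRM of known paternal half-sibs averages near 0.25."""
        G, _ = build_grm(small_panel)
        ped = small_panel.pedigree.set_index("id")
        ids = small_panel.sample_ids
        sire = ped.loc[ids, "sire"].to_numpy()
        dam = ped.loc[ids, "dam"].to_numpy()
        vals = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if sire[i] == sire[j] and dam[i] != dam[j]:
                    vals.append(G[i, j])
        assert len(vals) > 50
        assert np.mean(vals) == pytest.approx(0.25, abs=0.08)

    def test_fewer_sires_increase_mean_relatedness(self):
        pool = sp.simulate_founder_haplotypes(200, 2000, [20_000_000], seed=8)
        few = sp.gene_drop(pool, 1, n_sires=3, n_dams=60, offspring_per_dam=2, seed=9)
        many = sp.gene_drop(pool, 1, n_sires=60, n_dams=60, offspring_per_dam=2, seed=9)
        def mean_offdiag(panel):
            G, _ = build_grm(panel)
            n = G.shape[0]
            return (G.sum() - np.trace(G)) / (n * n - n)
        assert mean_offdiag(few) > mean_offdiag(many)

    def test_maf_filter_invariant(self, small_panel):
        assert small_panel.maf.min() >= 0.01
        assert small_panel.freq.min() >= 0.01 and small_panel.freq.max() <= 0.99

    def test_seeded_determinism(self):
        pool = sp.simulate_founder_haplotypes(50, 500, [5_000_000], seed=10)
        a = sp.gene_drop(pool, 1, n_sires=5, n_dams=20, offspring_per_dam=2, seed=11)
        b = sp.gene_drop(pool, 1, n_sires=5, n_dams=20, offspring_per_dam=2, seed=11)
        assert np.array_equal(a.dosages, b.dosages)

    def test_infeasible_pedigree_raises(self):
        pool = sp.simulate_founder_haplotypes(10, 100, [1_000_000], seed=12)
        with pytest.raises(ValueError, match="sires"):
            sp.gene_drop(pool, 1, n_sires=20, n_dams=2, offspring_per_dam=1, seed=0)


class TestGenomeLayout:
    def test_realized_class_proportions_near_targets(self, desk_panel, desk_annotation):
        fracs = desk_annotation.class_fractions()
        for cls, target in sp.TABLE1_PROPORTIONS.items():
            if target * desk_panel.n_variants < 200:
                continue  # tiny classes are Poisson-noise dominated
            assert abs(fracs[cls] - target) / target < 0.15, (cls, fracs[cls], target)

    def test_ocr_span_close_to_target(self, desk_panel):
        layout, _ = sp.layout_genome(desk_panel, seed=13)
        from hpart._intervals import total_span
        span = sum(
            total_span(sub["start"].to_numpy(), sub["end"].to_numpy())
            for _, sub in layout.peaks.groupby("chrom")
        )
        genome = sum(desk_panel.chrom_lengths.values())
        assert span / genome == pytest.approx(0.106, abs=0.02)

    def test_single_class_takes_everything(self, small_panel):
        _, classes = sp.layout_genome(small_panel, {"OCR": 1.0}, seed=1)
        assert set(classes) == {"OCR"}

    def test_intergenic_remainder_between_genes(self):
        genes = pd.DataFrame({"chrom": [1, 1], "start": [1000, 50_000], "end": [2000, 60_000]})
        labels = classify_by_precedence(
            np.array([1, 1, 1]), np.array([25_000, 1500, 55_000]),
            {"IOR": genes},
        )
        assert list(labels) == ["IGR", "IOR", "IOR"]

    def test_rejects_overfull_proportions(self, small_panel):
        with pytest.raises(ValueError):
            sp.layout_genome(small_panel, {"OCR": 0.7, "IOR": 0.5}, seed=0)


class TestGenomeSubset:
    def test_whole_chromosome_window_is_identity(self, small_panel):
        one_chrom = small_panel.subset_variants(
            np.flatnonzero(small_panel.chrom == 1)
        )
        subset, idx = sp.sample_genome_subset(
            one_chrom, n_positions=50, half_width_kb=30_000, seed=1
        )
        assert subset.n_variants == one_chrom.n_variants

    def test_overlapping_windows_merge_without_duplicates(self, small_panel):
        subset, idx = sp.sample_genome_subset(small_panel, 30, half_width_kb=500, seed=2)
        assert np.unique(idx).size == idx.size
        assert np.all(np.diff(idx) > 0)  # order preserved

    def test_selected_span_below_naive_total(self, desk_panel):
        """Many windows overlap or hit chromosome ends, so the selected span
        is below n_positions * 2 * half_width."""
        subset, idx = sp.sample_genome_subset(desk_panel, 200, half_width_kb=500, seed=3)
        frac = subset.n_variants / desk_panel.n_variants
        naive = 200 * 1_000_000 / sum(desk_panel.chrom_lengths.values())
        assert frac < naive
        assert subset.n_variants > 0
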