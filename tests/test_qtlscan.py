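import numpy as np
import pandas as pd
import pytest

from radsexscan.qtlscan import (binary_lod, fisher_exact_2x2, haplotype_sex_table,
                                lod_scan, lod_support_interval, permutation_threshold)
from radsexscan.simcross import GenotypeMatrix


def brute_force_lod(males, totals, step=1e-4):
    """Independent oracle: maximize each class's binomial likelihood on a grid.

    The grid includes the 0 and 1 endpoints (with the 0*ln 0 = 0 limit) so
    classes that are all-male or all-female reach their exact boundary MLE.
    """
    from scipy.special import xlogy
    grid = np.concatenate([[0.0], np.arange(step, 1.0, step), [1.0]])
    ll1 = 0.0
    for m, t in zip(males, totals):
        ll1 += (xlogy(m, grid) + xlogy(t - m, 1 - grid)).max()
    big_m, big_t = sum(males), sum(totals)
    ll0 = (xlogy(big_m, grid) + xlogy(big_t - big_m, 1 - grid)).max()
    return (ll1 - ll0) / np.log(10)


def _gm_from_classes(classes, chrom="chr1", spacing_cm=10.0):
    """Wrap a (markers x individuals) collapsed-class array as a GenotypeMatrix."""
    classes = np.asarray(classes, dtype=np.int8)
    m, n = classes.shape
    mat = np.where(classes >= 1, 1, 0).astype(np.int8)
    pat = np.where(classes == 2, 1, 0).astype(np.int8)
    mat[classes < 0] = -1
    pat[classes < 0] = -1
    markers = pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(m)],
        "chrom": chrom,
        "pos_bp": np.arange(1, m + 1) * 1_000_000,
        "cM_female": np.arange(m) * spacing_cm,
        "cM_male": np.arange(m) * spacing_cm,
        "allele1": "A", "allele2": "C", "diagnostic": True,
    })
    return GenotypeMatrix(markers=markers, sample_ids=[f"s{i}" for i in range(n)],
                          maternal=mat, paternal=pat)


def _sheet(sexes):
    return pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(sexes))],
                         "family": "A", "generation": "F2", "sex": sexes})


class TestBinaryLod:
    def test_identical_sex_ratios_give_zero(self):
        classes = ["a"] * 40 + ["b"] * 40
        sexes = (["male"] * 20 + ["female"] * 20) * 2
        lod, _ = binary_lod(classes, sexes)
        assert lod == pytest.approx(0.0, abs=1e-12)

    def test_sex_locus_table_reproduces_published_peak(self):
        # 70 C/C all male; 12 of 75 C/G male: single-marker LOD vs the
        # interval-mapped 28.78 within the declared 0.05 budget
        classes = ["CC"] * 70 + ["CG"] * 75
        sexes = ["male"] * 70 + ["male"] * 12 + ["female"] * 63
        lod, phat = binary_lod(classes, sexes)
        assert lod == pytest.approx(28.78, abs=0.05)
        assert phat["CC"] == 1.0
        assert phat["CG"] == pytest.approx(12 / 75)

    def test_sex_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        classes = rng.integers(0, 3, 60)
        sexes = np.where(rng.random(60) < 0.4, "male", "female")
        flipped = np.where(sexes == "male", "female", "male")
        assert binary_lod(classes, sexes)[0] == pytest.approx(
            binary_lod(classes, flipped)[0], abs=1e-10)

    def test_single_class_returns_zero_with_warning(self):
        lod, _ = binary_lod(["x"] * 10, ["male"] * 6 + ["female"] * 4)
        assert lod == 0.0

    def test_matches_brute_force_penetrance_grid(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(2, 5))
            totals = rng.integers(1, 60, size=k)
            males = np.array([rng.integers(0, t + 1) for t in totals])
            classes = np.repeat(np.arange(k), totals)
            sexes = np.concatenate([
                ["male"] * m + ["female"] * (t - m) for m, t in zip(males, totals)])
            lod, _ = binary_lod(classes, sexes)
            assert lod == pytest.approx(brute_force_lod(males, totals), abs=1e-3)


class TestPermutationThreshold:
    def _null_gm(self, seed, n_markers=40, n_ind=80):
        rng = np.random.default_rng(seed)
        return _gm_from_classes(rng.integers(0, 3, (n_markers, n_ind)))

    def test_identical_seed_identical_thresholds(self):
        gm = self._null_gm(1)
        sheet = _sheet(["male"] * 40 + ["female"] * 40)
        t1 = permutation_threshold(gm, sheet, n_perm=200, seed=9)
        t2 = permutation_threshold(gm, sheet, n_perm=200, seed=9)
        assert t1 == t2

    def test_ten_percent_threshold_not_above_five_percent(self):
        gm = self._null_gm(2)
        sheet = _sheet(["male"] * 40 + ["female"] * 40)
        t = permutation_threshold(gm, sheet, n_perm=300, seed=10)
        assert t[0.90] <= t[0.95]

    def test_monomorphic_markers_give_zero_thresholds(self):
        gm = _gm_from_classes(np.zeros((5, 40), dtype=int))
        sheet = _sheet(["male"] * 20 + ["female"] * 20)
        t = permutation_threshold(gm, sheet, n_perm=200, seed=11)
        assert t[0.95] == 0.0 and t[0.90] == 0.0

    def test_too_few_permutations_rejected(self):
        gm = self._null_gm(3)
        with pytest.raises(ValueError):
            permutation_threshold(gm, _sheet(["male"] * 40 + ["female"] * 40), n_perm=50)


class TestSupportInterval:
    def _scan(self, lods, chrom="chr1"):
        m = len(lods)
        return pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(m)], "chrom": chrom,
            "pos_bp": np.arange(1, m + 1) * 1_000_000,
            "cM": np.arange(m, dtype=float), "LOD": lods,
        })

    def test_triangular_profile_hand_trace(self):
        # peak 10 at index 4; LOD >= 8.5 on indices 3..5; one flank beyond
        scan = self._scan([6, 7, 8, 9, 10, 9, 8, 7, 6, 5])
        iv = lod_support_interval(scan, threshold=3.0, drop=1.5)
        assert len(iv) == 1
        assert (iv[0].cm_lo, iv[0].cm_hi) == (2.0, 6.0)

    def test_terminal_peak_clamps_at_chromosome_end(self):
        scan = self._scan([1, 1, 1, 5, 20])
        iv = lod_support_interval(scan, threshold=3.0, drop=1.5)[0]
        assert iv.cm_hi == 4.0 and iv.bp_hi == 5_000_000
        assert iv.cm_lo == 3.0  # the run is the peak alone; one marker beyond

    def test_zero_drop_keeps_flanking_pair_only(self):
        scan = self._scan([1, 2, 9, 2, 1])
        iv = lod_support_interval(scan, threshold=3.0, drop=0.0)[0]
        assert (iv.cm_lo, iv.cm_hi) == (1.0, 3.0)

    def test_no_peak_above_threshold_gives_empty_list(self):
        assert lod_support_interval(self._scan([1, 2, 1]), threshold=5.0) == []


class TestHaplotypeSexTable:
    def test_published_single_locus_percent_male(self):
        classes = np.array([[0] * 70 + [1] * 75])
        gm = _gm_from_classes(classes)
        sheet = _sheet(["male"] * 70 + ["male"] * 12 + ["female"] * 63)
        tab = haplotype_sex_table(gm, sheet, ["m0"]).set_index("class")
        assert tab.loc["G1G1", "percent_male"] == 100.0
        assert tab.loc["G1G2", "percent_male"] == pytest.approx(16.0)
        assert "G2G2" not in tab.index  # empty class omitted

    def test_two_marker_joint_classes_recover_penetrance(self, tiny_sim, tiny_config):
        gm = tiny_sim.genotypes
        sar_chrom, sar_pos = tiny_config.sex_model.loci[0]
        sar_id = gm.markers.loc[(gm.markers["chrom"] == sar_chrom)
                                & (gm.markers["pos_bp"] == sar_pos), "marker_id"].iloc[0]
        other = gm.markers["marker_id"].iloc[0]
        tab = haplotype_sex_table(gm, tiny_sim.sample_sheet, [sar_id, other])
        assert tab["class"].str.contains(r"\|").all()
        g1g1 = tab[tab["class"].str.startswith("G1G1|")]
        assert (g1g1["percent_male"] == 100.0).all()
        totals = tab["n_male"].sum() + tab["n_female"].sum()
        assert totals == len(tiny_sim.sample_sheet)

    def test_counts_sum_to_family_total(self, tiny_sim):
        gm = tiny_sim.genotypes
        tab = haplotype_sex_table(gm, tiny_sim.sample_sheet, [gm.markers["marker_id"].iloc[3]])
        assert tab["n_male"].sum() + tab["n_female"].sum() == len(tiny_sim.sample_sheet)


class TestFisherExact:
    def test_diagonal_table_enumeration(self):
        # margins (3,3)/(3,3): the two extreme tables each have prob 1/20
        assert fisher_exact_2x2([[3, 0], [0, 3]]) == pytest.approx(0.1)

    def test_no_association_gives_one(self):
        assert fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_transpose_invariance(self):
        t = np.array([[8, 2], [3, 7]])
        assert fisher_exact_2x2(t) == pytest.approx(fisher_exact_2x2(t.T))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [1, 2]])


class TestLodScan:
    def test_detects_simulated_sex_locus(self, tiny_sim, tiny_config):
        scan = lod_scan(tiny_sim.genotypes, tiny_sim.sample_sheet)
        peak = scan.loc[scan["LOD"].idxmax()]
        assert peak["chrom"] == tiny_config.sex_model.loci[0][0]
        thr = permutation_threshold(tiny_sim.genotypes, tiny_sim.sample_sheet,
                                    n_perm=300, seed=4)
        assert peak["LOD"] > thr[0.95]
        iv = lod_support_interval(scan, thr[0.95])
        assert len(iv) >= 1
        hit = [v for v in iv if v.chrom == peak["chrom"]][0]
        assert hit.cm_lo <= peak["cM"] <= hit.cm_hi
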