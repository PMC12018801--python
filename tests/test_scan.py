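import numpy as np
import pandas as pd
import pytest

from dynaqtl.haplotypes import HaplotypeProbabilities
from dynaqtl.scan import (
    credible_interval,
    find_peaks,
    founder_coefficients,
    kinship_loco,
    permutation_threshold,
    run_scan,
    scan_lmm,
)
from dynaqtl.simulate import QtlSpec, plant_qtl

from conftest import haley_knott_lod


@pytest.fixture(scope="module")
def phenotype_with_qtl(panel, rils_and_mosaics):
    rils, mosaics = rils_and_mosaics
    effects = {f: 1.0 for f in panel.founder_ids}
    effects["F7"] = -7.0
    spec = QtlSpec("1", 75_000_000, effects, 0.25)
    g = plant_qtl(mosaics, spec, panel, other_variance=1.0)
    rng = np.random.default_rng(77)
    y = pd.Series(g + rng.normal(0, 1, len(g)), index=rils.ril_ids)
    return y, spec


class TestKinship:
    def test_identical_rils_entry_equals_diagonal(self, hap_probs):
        probs2 = hap_probs.probs.copy()
        probs2[1] = probs2[0]  # duplicate RIL
        hp = HaplotypeProbabilities(
            probs2, hap_probs.ril_ids, hap_probs.founder_ids, hap_probs.gmap
        )
        kin = kinship_loco(hp)["1"]
        assert np.isclose(kin[0, 1], kin[0, 0])

    def test_positive_semidefinite(self, hap_probs):
        for _c, k in kinship_loco(hap_probs).matrices.items():
            assert np.allclose(k, k.T)
            assert np.linalg.eigvalsh(k).min() >= -1e-8

    def test_mean_diagonal_one(self, hap_probs):
        for k in kinship_loco(hap_probs).matrices.values():
            assert np.isclose(np.diag(k).mean(), 1.0)

    def test_loco_exclusion_brute_force(self, hap_probs):
        """LOCO matrix equals a from-scratch product over off-chromosome markers."""
        kin = kinship_loco(hap_probs)["1"]
        n = hap_probs.probs.shape[0]
        idx2 = hap_probs.gmap.marker_indices("2")
        x = hap_probs.probs[:, idx2, :].reshape(n, -1)
        raw = x @ x.T
        oracle = raw * n / np.trace(raw)
        assert np.allclose(kin, oracle, atol=1e-10)

    def test_single_chromosome_rejected(self, hap_probs):
        idx = hap_probs.gmap.marker_indices("1")
        gm1 = type(hap_probs.gmap)(hap_probs.gmap.table.iloc[idx].reset_index(drop=True))
        hp = HaplotypeProbabilities(
            hap_probs.probs[:, idx, :], hap_probs.ril_ids, hap_probs.founder_ids, gm1
        )
        with pytest.raises(ValueError, match="2 chromosomes"):
            kinship_loco(hp)


class TestScan:
    def test_matches_haley_knott_oracle_without_kinship(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        scan, _ = scan_lmm(hap_probs, y, None, use_kinship=False)
        yv = y.loc[hap_probs.ril_ids].to_numpy()
        rng = np.random.default_rng(0)
        for mi in rng.choice(hap_probs.gmap.n_markers, 15, replace=False):
            oracle = haley_knott_lod(hap_probs.probs[:, mi, :], yv)
            assert abs(scan["lod"].iloc[mi] - oracle) < 1e-8

    def test_duplicate_marker_identical_lod(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        probs2 = hap_probs.probs.copy()
        probs2[:, 5, :] = probs2[:, 4, :]
        hp = HaplotypeProbabilities(probs2, hap_probs.ril_ids, hap_probs.founder_ids, hap_probs.gmap)
        scan, _ = scan_lmm(hp, y, kinship_loco(hp))
        assert np.isclose(scan["lod"].iloc[4], scan["lod"].iloc[5], atol=1e-10)

    def test_lod_invariant_to_affine_phenotype(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        kin = kinship_loco(hap_probs)
        a, _ = scan_lmm(hap_probs, y, kin)
        b, _ = scan_lmm(hap_probs, 3.0 * y + 11.0, kin)
        assert np.allclose(a["lod"], b["lod"], atol=1e-6)

    def test_lod_nonnegative(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        scan, _ = scan_lmm(hap_probs, y, kinship_loco(hap_probs))
        assert (scan["lod"] >= 0).all()

    def test_detects_planted_qtl(self, hap_probs, phenotype_with_qtl):
        y, spec = phenotype_with_qtl
        res = run_scan(hap_probs, y, kinship_loco(hap_probs), n_perm=150, seed=9)
        assert len(res.peaks) >= 1
        assert res.peaks.iloc[0]["chrom"] == "1"
        lo, hi = res.intervals["1"]
        assert lo <= spec.pos_bp <= hi


class TestPermutations:
    def test_seed_reproducibility(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        kin = kinship_loco(hap_probs)
        t1 = permutation_threshold(hap_probs, y, kin, n_perm=120, seed=5)
        t2 = permutation_threshold(hap_probs, y, kin, n_perm=120, seed=5)
        assert t1 == t2

    def test_quantile_monotone(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        kin = kinship_loco(hap_probs)
        t95, maxima = permutation_threshold(
            hap_probs, y, kin, n_perm=120, quantile=0.95, seed=6, return_maxima=True
        )
        t100 = float(np.quantile(maxima, 1.0))
        assert t100 >= t95
        assert t100 == maxima.max()

    def test_too_few_permutations_rejected(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        with pytest.raises(ValueError):
            permutation_threshold(hap_probs, y, None, n_perm=50, seed=1)


class TestPeaksAndIntervals:
    def _scan_frame(self, lods, chrom="1"):
        m = len(lods)
        return pd.DataFrame(
            {
                "chrom": chrom,
                "marker": [f"m{i}" for i in range(m)],
                "bp": np.arange(1, m + 1) * 1000,
                "lod": lods,
            }
        )

    def test_no_peak_below_threshold(self):
        peaks = find_peaks(self._scan_frame([1.0, 2.0, 1.5]), threshold=3.0)
        assert peaks.empty

    def test_single_spike(self):
        peaks = find_peaks(self._scan_frame([0.1, 9.0, 0.2]), threshold=3.0)
        assert len(peaks) == 1 and peaks.iloc[0]["marker"] == "m1"

    def test_tie_breaks_to_smallest_bp(self):
        peaks = find_peaks(self._scan_frame([5.0, 5.0, 1.0]), threshold=3.0)
        assert peaks.iloc[0]["marker"] == "m0"

    def test_interval_concentrated_mass(self):
        scan = self._scan_frame([0.0, 0.0, 40.0, 0.0, 0.0])
        lo, hi = credible_interval(scan, "1", prob=0.95)
        assert (lo, hi) == (2000, 4000)  # flanking-marker span

    def test_interval_flat_lod_covers_chromosome(self):
        scan = self._scan_frame([2.0] * 40)
        lo, hi = credible_interval(scan, "1", prob=0.95)
        covered = ((scan["bp"] >= lo) & (scan["bp"] <= hi)).mean()
        assert covered >= 0.95

    def test_interval_contains_peak_and_marker_endpoints(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        scan, _ = scan_lmm(hap_probs, y, kinship_loco(hap_probs))
        lo, hi = credible_interval(scan, "1")
        sub = scan[scan["chrom"] == "1"]
        peak_bp = sub.loc[sub["lod"].idxmax(), "bp"]
        assert lo <= peak_bp <= hi
        assert lo in sub["bp"].to_numpy() and hi in sub["bp"].to_numpy()


class TestFounderCoefficients:
    def test_sign_recovery_and_zero_sum(self, hap_probs, phenotype_with_qtl):
        y, spec = phenotype_with_qtl
        kin = kinship_loco(hap_probs)["1"]
        coefs = founder_coefficients(
            hap_probs, y, kin, "1", (70_000_000, 80_000_000)
        )
        assert np.allclose(coefs.sum(axis=0), 0.0, atol=1e-8)
        assert (coefs.loc["F7"] < 0).all()  # planted negative founder

    def test_label_permutation_symmetry(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        perm = np.array([2, 0, 1, 3, 4, 5, 7, 6])
        hp = HaplotypeProbabilities(
            hap_probs.probs[:, :, perm],
            hap_probs.ril_ids,
            [hap_probs.founder_ids[j] for j in perm],
            hap_probs.gmap,
        )
        a = founder_coefficients(hap_probs, y, None, "1", (70_000_000, 80_000_000))
        b = founder_coefficients(hp, y, None, "1", (70_000_000, 80_000_000))
        assert np.allclose(a.loc[b.index].to_numpy(), b.to_numpy(), atol=1e-8)

    def test_null_trait_coefficients_small(self, hap_probs, phenotype_with_qtl):
        y, _ = phenotype_with_qtl
        rng = np.random.default_rng(123)
        y_null = pd.Series(rng.normal(0, 1, len(y)), index=y.index)
        kin = kinship_loco(hap_probs)["1"]
        c_null = founder_coefficients(hap_probs, y_null, kin, "1", (70_000_000, 80_000_000))
        c_qtl = founder_coefficients(hap_probs, y, kin, "1", (70_000_000, 80_000_000))
        assert np.abs(c_null.to_numpy()).mean() < 0.5 * np.abs(c_qtl.to_numpy()).mean()
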