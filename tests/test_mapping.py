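"""Tests of kinship, heritability, genome scans, haplotype effects, peaks,
permutations, FDR, and variant association."""

import numpy as np
import pandas as pd
import pytest

from cmqtl import simulate as sim
from cmqtl import mapping


def ols_lod_oracle(G_at_marker, y, X0=None):
    """Independent plain-least-squares LOD at one marker."""
    n = y.size
    X0 = np.ones((n, 1)) if X0 is None else X0
    A = np.column_stack([X0, G_at_marker])
    b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ b0) ** 2))
    b1, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    rss1 = float(np.sum((y - A @ b1) ** 2))
    return (n / 2.0) * np.log10(rss0 / rss1)


class TestKinship:
    def test_identical_individuals(self, small_map):
        _, gp = sim.simulate_do_genoprobs(2, small_map, seed=1)
        gp.dosage[1] = gp.dosage[0]
        K = mapping.calc_kinship(gp).overall
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)

    def test_matches_double_loop_oracle(self):
        mm = sim.simulate_marker_map(1, 4, 20_000_000, seed=2)
        _, gp = sim.simulate_do_genoprobs(3, mm, seed=3)
        K = mapping.calc_kinship(gp).overall
        q = gp.dosage / 2.0
        for i in range(3):
            for j in range(3):
                expected = sum(
                    q[i, f, m] * q[j, f, m] for f in range(8) for m in range(4)
                ) / 4.0
                assert K[i, j] == pytest.approx(expected, abs=1e-12)

    def test_unrelated_mean_off_diagonal(self, small_map):
        _, gp = sim.simulate_do_genoprobs(500, small_map, seed=4)
        K = mapping.calc_kinship(gp).overall
        off = K[~np.eye(500, dtype=bool)]
        assert abs(off.mean() - 1.0 / 8.0) < 0.02

    def test_psd_and_bounded(self, small_genoprobs):
        K = mapping.calc_kinship(small_genoprobs).overall
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() > -1e-10
        assert K.min() >= 0 and K.max() <= 1 + 1e-12
        assert np.all(np.diag(K) > 0)

    def test_loco_excludes_focal_chromosome(self):
        mm = sim.simulate_marker_map(2, 10, 50_000_000, seed=5)
        _, gp = sim.simulate_do_genoprobs(20, mm, seed=6)
        km = mapping.calc_kinship(gp, loco=True)
        idx2 = mm.chrom_index("2")
        q = gp.dosage[:, :, idx2].reshape(20, -1) / 2.0
        expected = q @ q.T / idx2.size
        np.testing.assert_allclose(km.loco["1"], expected, atol=1e-12)

    def test_loco_single_chromosome_rejected(self):
        mm = sim.simulate_marker_map(1, 10, 50_000_000, seed=7)
        _, gp = sim.simulate_do_genoprobs(5, mm, seed=8)
        with pytest.raises(ValueError, match="LOCO"):
            mapping.calc_kinship(gp, loco=True)


@pytest.fixture(scope="module")
def kin(small_genoprobs):
    K = mapping.calc_kinship(small_genoprobs).overall
    L = np.linalg.cholesky(K + 1e-8 * np.eye(K.shape[0]))
    return K, L


@pytest.fixture(scope="module")
def locus_data(small_genoprobs):
    rng = np.random.default_rng(16)
    eff = np.asarray(sim.biallelic_effects())
    m = 8
    g = small_genoprobs.dosage[:, :, m] @ eff
    g = (g - g.mean()) / g.std() * np.sqrt(0.4)
    y = g + rng.standard_normal(small_genoprobs.n_individuals) * np.sqrt(0.6)
    marker = small_genoprobs.marker_map.df["marker_id"].iloc[m]
    return marker, m, y, eff


class TestHeritability:
    def test_noiseless_genetic_trait(self, kin):
        K, L = kin
        g = L @ np.random.default_rng(0).standard_normal(K.shape[0])
        est = mapping.estimate_heritability(g, K)
        assert est.h2 >= 0.95

    def test_null_trait_low_h2(self):
        # long founder segments give the strong relatedness contrasts that
        # make h2 well identified (independent mosaics understate the
        # sibling structure of a real outbred population)
        mm = sim.simulate_marker_map(5, 100, 100_000_000, seed=11)
        _, gp = sim.simulate_do_genoprobs(300, mm, recomb_rate_per_cm=0.01, seed=31)
        K = mapping.calc_kinship(gp).overall
        low = 0
        n_sim = 50
        for s in range(n_sim):
            y = np.random.default_rng(100 + s).standard_normal(300)
            low += mapping.estimate_heritability(y, K).h2 < 0.1
        assert low >= 0.9 * n_sim

    def test_recovery_at_half(self):
        mm = sim.simulate_marker_map(3, 40, 100_000_000, seed=9)
        _, gp = sim.simulate_do_genoprobs(400, mm, seed=10)
        K = mapping.calc_kinship(gp).overall
        L = np.linalg.cholesky(K + 1e-8 * np.eye(400))
        ests = []
        for s in range(60):
            rng = np.random.default_rng(200 + s)
            y = np.sqrt(0.5) * (L @ rng.standard_normal(400)) + np.sqrt(0.5) * rng.standard_normal(400)
            ests.append(mapping.estimate_heritability(y, K).h2)
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_constant_phenotype_rejected(self, kin):
        K, _ = kin
        with pytest.raises(ValueError, match="constant"):
            mapping.estimate_heritability(np.ones(K.shape[0]), K)


class TestGenomeScan:
    def test_matches_ols_oracle_without_kinship(self, small_genoprobs):
        rng = np.random.default_rng(11)
        n = small_genoprobs.n_individuals
        y = rng.standard_normal(n)
        scan = mapping.genome_scan(small_genoprobs, y)
        for m in range(0, small_genoprobs.n_markers, 7):
            oracle = ols_lod_oracle(small_genoprobs.dosage[:, :, m], y)
            assert scan.lod.iloc[m, 0] == pytest.approx(oracle, abs=1e-8)

    def test_lod_is_likelihood_ratio(self, small_genoprobs):
        """2 ln(10) LOD equals the Gaussian likelihood-ratio statistic."""
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        n = small_genoprobs.n_individuals
        y = rng.standard_normal(n)
        scan = mapping.genome_scan(small_genoprobs, y)
        m = 13
        X0 = np.ones((n, 1))
        A = np.column_stack([X0, small_genoprobs.dosage[:, :-1, m]])
        ll0 = sm.OLS(y, X0).fit().llf
        ll1 = sm.OLS(y, A).fit().llf
        assert 2 * np.log(10) * scan.lod.iloc[m, 0] == pytest.approx(
            2 * (ll1 - ll0), abs=1e-6
        )

    def test_invariance_to_shift_and_scale(self, small_genoprobs):
        rng = np.random.default_rng(13)
        y = rng.standard_normal(small_genoprobs.n_individuals)
        km = mapping.calc_kinship(small_genoprobs, loco=True)
        base = mapping.genome_scan(small_genoprobs, y, kinship=km).lod
        shifted = mapping.genome_scan(small_genoprobs, 3.0 * y + 7.0, kinship=km).lod
        np.testing.assert_allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-6)

    def test_covariates_and_missing_phenotypes(self, small_genoprobs):
        rng = np.random.default_rng(14)
        n = small_genoprobs.n_individuals
        y = rng.standard_normal(n)
        y[:5] = np.nan
        cov = pd.DataFrame({"sex": rng.choice(["F", "M"], n)})
        scan = mapping.genome_scan(small_genoprobs, pd.Series(y, name="t"), cov)
        keep = np.isfinite(y)
        sexd = (cov["sex"] == "M").to_numpy(dtype=float)[keep]
        X0 = np.column_stack([np.ones(keep.sum()), sexd])
        oracle = ols_lod_oracle(small_genoprobs.dosage[keep][:, :, 3], y[keep], X0)
        assert scan.lod.iloc[3, 0] == pytest.approx(oracle, abs=1e-8)

    def test_planted_qtl_recovered(self, small_genoprobs):
        rng = np.random.default_rng(15)
        eff = np.asarray(sim.biallelic_effects())
        m = 20
        g = small_genoprobs.dosage[:, :, m] @ eff
        g = (g - g.mean()) / g.std() * np.sqrt(0.3)
        y = g + rng.standard_normal(small_genoprobs.n_individuals) * np.sqrt(0.7)
        km = mapping.calc_kinship(small_genoprobs, loco=True)
        scan = mapping.genome_scan(small_genoprobs, y, kinship=km)
        peak_marker = scan.lod.iloc[:, 0].idxmax()
        peak_chrom = small_genoprobs.marker_map.df.set_index("marker_id").loc[
            peak_marker, "chromosome"
        ]
        assert peak_chrom == small_genoprobs.marker_map.df["chromosome"].iloc[m]


class TestHaplotypeEffects:
    def test_matches_dense_mme_oracle(self, small_genoprobs, locus_data):
        marker, m, y, _ = locus_data
        tau = 0.7
        hev = mapping.haplotype_blup_effects(small_genoprobs, marker, y, tau=tau)
        n = y.size
        X = np.ones((n, 1))
        G = small_genoprobs.dosage[:, :, m]
        C = np.block([[X.T @ X, X.T @ G], [G.T @ X, G.T @ G + np.eye(8) / tau]])
        sol = np.linalg.solve(C, np.concatenate([X.T @ y, G.T @ y]))
        u = sol[1:] - sol[1:].mean()
        np.testing.assert_allclose(hev.effects, u, atol=1e-8)

    def test_no_shrinkage_limit_is_least_squares(self, small_genoprobs, locus_data):
        marker, m, y, _ = locus_data
        hev = mapping.haplotype_blup_effects(small_genoprobs, marker, y, tau=1e10)
        n = y.size
        A = np.column_stack([np.ones((n, 1)), small_genoprobs.dosage[:, :, m]])
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        u = beta[1:] - beta[1:].mean()
        np.testing.assert_allclose(hev.effects, u, atol=1e-5)

    def test_full_shrinkage_limit_is_zero(self, small_genoprobs, locus_data):
        marker, _, y, _ = locus_data
        hev = mapping.haplotype_blup_effects(small_genoprobs, marker, y, tau=1e-12)
        np.testing.assert_allclose(hev.effects, 0.0, atol=1e-6)

    def test_null_trait_flagged_zero_variance(self, small_genoprobs):
        y = np.random.default_rng(17).standard_normal(small_genoprobs.n_individuals)
        marker = small_genoprobs.marker_map.df["marker_id"].iloc[0]
        hev = mapping.haplotype_blup_effects(small_genoprobs, marker, y)
        if hev.zero_variance:
            assert np.allclose(hev.effects, 0.0)

    def test_recovers_planted_effect_pattern(self, small_genoprobs, locus_data):
        marker, _, y, eff = locus_data
        km = mapping.calc_kinship(small_genoprobs, loco=True)
        hev = mapping.haplotype_blup_effects(small_genoprobs, marker, y, kinship=km)
        assert hev.effects.mean() == pytest.approx(0.0, abs=1e-8)
        assert np.corrcoef(hev.effects, eff)[0, 1] > 0.8


class TestPeaks:
    @staticmethod
    def scan_from_profile(profiles):
        """Build a ScanResult from a dict chromosome -> LOD array."""
        rows, lods = [], []
        for chrom, arr in profiles.items():
            for i, v in enumerate(arr):
                rows.append(
                    {
                        "marker_id": f"c{chrom}_m{i}",
                        "chromosome": chrom,
                        "position_bp": (i + 1) * 1_000_000,
                        "position_cm": (i + 1) * 0.5,
                    }
                )
                lods.append(v)
        mm = sim.MarkerMap(pd.DataFrame(rows))
        lod = pd.DataFrame({"t": lods}, index=mm.df["marker_id"].to_numpy())
        return mapping.ScanResult(lod, mm)

    def test_all_below_threshold_empty(self):
        scan = self.scan_from_profile({"1": [1.0, 2.0, 3.0]})
        assert mapping.find_peaks(scan, threshold=7.5).empty

    def test_support_interval_spans_drop(self):
        profile = [1, 2, 6, 8, 9, 8.2, 6.5, 2, 1]
        scan = self.scan_from_profile({"1": profile})
        peaks = mapping.find_peaks(scan, threshold=7.5, drop=1.5)
        assert len(peaks) == 1
        pk = peaks.iloc[0]
        assert pk.lod == 9.0 and pk.position_bp == 5_000_000
        # markers with LOD >= 7.5: indices 3..5
        assert pk.ci_lo_bp == 4_000_000 and pk.ci_hi_bp == 6_000_000
        assert pk.ci_lo_bp <= pk.position_bp <= pk.ci_hi_bp

    def test_two_chromosomes_two_peaks(self):
        scan = self.scan_from_profile({"1": [8, 9, 8], "2": [7, 8.5, 7], "3": [1, 2, 1]})
        peaks = mapping.find_peaks(scan, threshold=7.5)
        assert len(peaks) == 2
        assert list(peaks["chromosome"]) == ["1", "2"]
        top = mapping.find_peaks(scan, threshold=7.5, genome_wide_max=True)
        assert len(top) == 1 and top.iloc[0].chromosome == "1"

    def test_exact_tie_takes_first_marker(self):
        scan = self.scan_from_profile({"1": [8.0, 9.0, 9.0, 8.0]})
        pk = mapping.find_peaks(scan, threshold=7.5).iloc[0]
        assert pk.marker_id == "c1_m1"


class TestPermutationsAndFdr:
    def test_deterministic_given_seed(self, small_genoprobs):
        y = np.random.default_rng(18).standard_normal(small_genoprobs.n_individuals)
        a = mapping.permutation_null(small_genoprobs, y, n_perm=20, seed=5)
        b = mapping.permutation_null(small_genoprobs, y, n_perm=20, seed=5)
        np.testing.assert_array_equal(a.max_lods, b.max_lods)

    def test_zero_permutations_rejected(self, small_genoprobs):
        y = np.random.default_rng(19).standard_normal(small_genoprobs.n_individuals)
        with pytest.raises(ValueError):
            mapping.permutation_null(small_genoprobs, y, n_perm=0)

    def test_kinship_permutations_run(self, small_genoprobs):
        y = np.random.default_rng(20).standard_normal(small_genoprobs.n_individuals)
        km = mapping.calc_kinship(small_genoprobs, loco=True)
        null = mapping.permutation_null(small_genoprobs, y, kinship=km, n_perm=5, seed=1)
        assert null.max_lods.shape == (5,) and (null.max_lods >= 0).all()

    def test_fdr_vacuous_q_discovers_everything(self):
        null = mapping.NullDistribution(np.array([1.0, 2.0, 3.0]), 0, 3)
        obs = np.array([0.5, 1.5, 2.5])
        thr, flags = mapping.fdr_threshold(null, obs, q=1.0)
        assert thr == 0.5 and flags.all()

    def test_fdr_no_signal_no_discoveries(self):
        null = mapping.NullDistribution(np.linspace(5, 9, 100), 0, 100)
        obs = np.array([1.0, 2.0, 3.0])
        thr, flags = mapping.fdr_threshold(null, obs, q=0.1)
        assert np.isinf(thr) and not flags.any()

    def test_fdr_matches_exhaustive_search(self):
        rng = np.random.default_rng(21)
        null = mapping.NullDistribution(rng.gumbel(3.0, 1.0, 1000), 0, 1000)
        obs = np.concatenate([rng.gumbel(3.0, 1.0, 7), [8.5, 9.0, 10.0]])
        q = 0.10
        thr, flags = mapping.fdr_threshold(null, obs, q)
        # exhaustive oracle over all candidate thresholds
        best = np.inf
        m = obs.size
        for t in np.sort(obs):
            tail = np.mean(null.max_lods >= t)
            n_disc = np.sum(obs >= t)
            if n_disc and m * tail / n_disc <= q:
                best = t
                break
        assert thr == pytest.approx(best)
        np.testing.assert_array_equal(flags, obs >= best)


class TestSnpAssociation:
    def test_monomorphic_flagged(self, small_genoprobs):
        y = np.random.default_rng(22).standard_normal(small_genoprobs.n_individuals)
        variants = pd.DataFrame(
            {
                "variant_id": ["v1", "v2"],
                "chromosome": ["1", "1"],
                "position_bp": [5_000_000, 6_000_000],
                "sdp": ["11111111", "00000000"],
            }
        )
        out = mapping.snp_association(small_genoprobs, variants, y)
        assert out["monomorphic"].all() and (out["lod"] == 0).all()

    def test_collapsed_dosage_matches_ols_oracle(self, small_genoprobs):
        rng = np.random.default_rng(23)
        n = small_genoprobs.n_individuals
        y = rng.standard_normal(n)
        mm = small_genoprobs.marker_map
        pos = int(mm.df["position_bp"].iloc[4]) + 10  # nearest marker: index 4
        variants = pd.DataFrame(
            {
                "variant_id": ["v1"],
                "chromosome": [mm.df["chromosome"].iloc[4]],
                "position_bp": [pos],
                "sdp": ["11001010"],
            }
        )
        out = mapping.snp_association(small_genoprobs, variants, y)
        mask = np.array([ch == "1" for ch in "11001010"])
        v = small_genoprobs.dosage[:, mask, 4].sum(axis=1)
        oracle = ols_lod_oracle(v[:, None], y)
        assert out["lod"].iloc[0] == pytest.approx(oracle, abs=1e-8)

    def test_causal_sdp_wins_among_random_sdps(self, small_genoprobs):
        rng = np.random.default_rng(24)
        n = small_genoprobs.n_individuals
        mm = small_genoprobs.marker_map
        m = 10
        causal = "11110000"
        mask = np.array([ch == "1" for ch in causal])
        sdps = {causal}
        while len(sdps) < 50:
            s = "".join(rng.choice(["0", "1"], 8))
            if s not in ("00000000", "11111111"):
                sdps.add(s)
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(sdps))],
                "chromosome": mm.df["chromosome"].iloc[m],
                "position_bp": int(mm.df["position_bp"].iloc[m]),
                "sdp": sorted(sdps),
            }
        )
        complement = "00001111"  # dosage 2 - v: an identical 1-df test
        wins = 0
        n_sim = 20
        for s in range(n_sim):
            r2 = np.random.default_rng(500 + s)
            g = small_genoprobs.dosage[:, mask, m].sum(axis=1)
            g = (g - g.mean()) / g.std() * np.sqrt(0.3)
            y = g + r2.standard_normal(n) * np.sqrt(0.7)
            out = mapping.snp_association(small_genoprobs, variants, y)
            wins += out.loc[out["lod"].idxmax(), "sdp"] in (causal, complement)
        assert wins >= 0.9 * n_sim


class TestMarkerLod:
    def test_single_locus_matches_oracle(self, small_genoprobs):
        rng = np.random.default_rng(25)
        y = rng.standard_normal(small_genoprobs.n_individuals)
        G = small_genoprobs.dosage[:, :, 2]
        assert mapping.marker_lod(G, y) == pytest.approx(ols_lod_oracle(G, y), abs=1e-10)
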