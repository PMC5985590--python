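"""Tests of EHH/iHS/nSL, standardization, H statistics, windowed pi,
the CLR scan and window enrichment, each against hand counts or
brute-force oracles."""

import itertools

import numpy as np
import pytest

from aspenscan.core import HaplotypeMatrix
from aspenscan.haplostats import (BackgroundSFS, clr_scan, ehh,
                                  h_statistics, ihs_unstandardized,
                                  nsl_unstandardized,
                                  standardize_by_frequency,
                                  sweep_transformed_sfs,
                                  window_enrichment, windowed_pi)


def hap(rows, positions, L):
    return HaplotypeMatrix(alleles=np.asarray(rows, dtype=np.int8),
                           positions=np.asarray(positions),
                           region_length=L)


def _ehh_bruteforce(a, carriers, core, x):
    """Pairwise-count EHH from core to column x inclusive."""
    lo, hi = (x, core) if x < core else (core, x)
    n = len(carriers)
    hom = 0
    for i, j in itertools.combinations(carriers, 2):
        if np.array_equal(a[i, lo:hi + 1], a[j, lo:hi + 1]):
            hom += 1
    return hom / (n * (n - 1) / 2)


class TestEhh:
    def test_core_value_is_one_and_hand_count(self):
        a = [[1, 0, 0], [1, 0, 0], [1, 1, 1], [1, 1, 1], [0, 0, 1],
             [0, 1, 0]]
        H = hap(a, [10, 20, 30], 40)
        cu = ehh(H, 0, 1)
        # two identical pairs among four carriers: (1+1)/C(4,2) = 1/3
        assert cu.right_ehh[0] == pytest.approx(1 / 3)
        assert cu.right_ehh[1] == pytest.approx(1 / 3)
        assert cu.carrier_count == 4

    def test_all_carriers_distinct_gives_zero(self):
        a = [[1, 0, 0], [1, 1, 0], [1, 0, 1], [0, 0, 0]]
        H = hap(a, [5, 10, 15], 20)
        cu = ehh(H, 0, 1)
        assert cu.right_ehh[0] == pytest.approx(1 / 3)  # one shared pair? no:
        # carriers rows 0,1,2; at col 1 alleles 0,1,0 -> pair (0,2) shares
        assert cu.right_ehh[1] == 0.0

    def test_monotone_nonincreasing_and_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, (12, 30))
        a[:, 15] = rng.permutation([1] * 6 + [0] * 6)
        H = hap(a, np.arange(1, 31) * 10, 400)
        cu = ehh(H, 15, 1)
        carriers = np.where(a[:, 15] == 1)[0]
        right = [_ehh_bruteforce(a, carriers, 15, x) for x in range(16, 30)]
        left = [_ehh_bruteforce(a, carriers, 15, x)
                for x in range(14, -1, -1)]
        assert np.allclose(cu.right_ehh, right)
        assert np.allclose(cu.left_ehh, left)
        assert np.all(np.diff(cu.right_ehh) <= 1e-12)
        assert np.all(np.diff(cu.left_ehh) <= 1e-12)

    def test_too_few_carriers(self):
        H = hap([[1, 0], [0, 0], [0, 1]], [1, 2], 10)
        with pytest.raises(ValueError):
            ehh(H, 0, 1)


def _ihs_bruteforce(H, j):
    """Direct trapezoid-integrated EHH for one core SNP."""
    a = H.alleles
    pos = H.positions.astype(float)
    m = H.n_sites
    out = {}
    for al in (0, 1):
        carriers = np.where(a[:, j] == al)[0]
        total = 0.0
        for direction in (-1, 1):
            cols = (range(j - 1, -1, -1) if direction < 0
                    else range(j + 1, m))
            prev_e, prev_d = 1.0, 0.0
            for x in cols:
                e = _ehh_bruteforce(a, carriers, j, x)
                d = abs(pos[x] - pos[j])
                total += 0.5 * (prev_e + e) * (d - prev_d)
                prev_e, prev_d = e, d
                if e < 0.05:
                    break
            else:
                return None  # hit the edge
        out[al] = total
    if out[0] == 0 or out[1] == 0:
        return None
    return np.log(out[0] / out[1])


class TestIhs:
    def test_symmetric_configuration_gives_zero(self):
        # derived and ancestral carriers have mirror-identical haplotypes
        block = np.array([[0, 0, 1, 0, 0],
                          [1, 0, 1, 0, 1],
                          [0, 1, 1, 1, 0],
                          [1, 1, 1, 1, 1]])
        mirror = block.copy()
        mirror[:, 2] = 0
        a = np.vstack([block, mirror])
        H = hap(a, [100, 200, 300, 400, 500], 600)
        res = ihs_unstandardized(H, min_maf=0.04)
        core = 2
        assert res["ihs"][core] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 2, (8, 40))
        H = hap(a, np.sort(rng.choice(np.arange(1, 4000), 40,
                                      replace=False)), 4000)
        res = ihs_unstandardized(H)
        checked = 0
        for j in range(40):
            row = res.iloc[j]
            if row["reason"] in ("maf", "carriers"):
                continue
            oracle = _ihs_bruteforce(H, j)
            if oracle is None:
                assert row["reason"] in ("edge", "zero_ihh")
            else:
                assert row["ihs"] == pytest.approx(oracle, abs=1e-10)
                checked += 1
        assert checked >= 3

    def test_sign_flips_with_polarity_swap(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 2, (10, 30))
        H = hap(a, np.arange(1, 31) * 50, 1600)
        res = ihs_unstandardized(H)
        Hf = hap(1 - a, H.positions, 1600)
        resf = ihs_unstandardized(Hf)
        both = np.isfinite(res["ihs"]) & np.isfinite(resf["ihs"])
        assert both.any()
        assert np.allclose(res["ihs"][both], -resf["ihs"][both], atol=1e-10)


def _nsl_bruteforce(a, j):
    def mean_l(members):
        tot, cnt = 0, 0
        m = a.shape[1]
        for x, y in itertools.combinations(members, 2):
            left = j
            while left > 0 and a[x, left - 1] == a[y, left - 1]:
                left -= 1
            right = j
            while right < m - 1 and a[x, right + 1] == a[y, right + 1]:
                right += 1
            tot += right - left + 1
            cnt += 1
        return tot / cnt

    anc = np.where(a[:, j] == 0)[0]
    der = np.where(a[:, j] == 1)[0]
    if len(anc) < 2 or len(der) < 2:
        return None
    return np.log(mean_l(anc) / mean_l(der))


class TestNsl:
    def test_position_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, (10, 20))
        H1 = hap(a, np.arange(1, 21) * 10, 300)
        H2 = hap(a, np.arange(1, 21) * 100, 3000)
        r1 = nsl_unstandardized(H1)["nsl"]
        r2 = nsl_unstandardized(H2)["nsl"]
        assert np.allclose(r1.dropna(), r2.dropna())

    def test_matches_pairwise_bruteforce(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 2, (8, 15))
        H = hap(a, np.arange(1, 16) * 7, 120)
        res = nsl_unstandardized(H)
        for j in range(15):
            oracle = _nsl_bruteforce(a, j)
            row = res.iloc[j]
            if row["reason"]:
                continue
            assert row["nsl"] == pytest.approx(oracle, abs=1e-10)


class TestStandardize:
    def test_bin_moments(self):
        rng = np.random.default_rng(0)
        sc = rng.normal(size=400)
        fr = rng.uniform(0, 1, 400)
        st = standardize_by_frequency(sc, fr, n_bins=10)
        bins = np.clip((fr * 10).astype(int), 0, 9)
        for b in range(10):
            v = st[(bins == b) & np.isfinite(st)]
            if v.size:
                assert abs(v.mean()) < 1e-10
                assert v.std() == pytest.approx(1.0, abs=1e-10)

    def test_binning_matches_floor_oracle(self):
        rng = np.random.default_rng(1)
        sc = rng.normal(size=200)
        fr = rng.uniform(0, 1, 200)
        st = standardize_by_frequency(sc, fr, n_bins=100)
        oracle_bins = np.minimum((fr * 100).astype(int), 99)
        for b in np.unique(oracle_bins):
            sel = oracle_bins == b
            if sel.sum() >= 2:
                v = (sc[sel] - sc[sel].mean()) / sc[sel].std()
                assert np.allclose(st[sel], v)
            else:
                assert np.all(np.isnan(st[sel]))

    def test_sparse_bins_missing(self):
        st = standardize_by_frequency([1.0], [0.5], 100)
        assert np.isnan(st[0])


class TestHStatistics:
    def test_identical_haplotypes(self):
        H = hap(np.ones((6, 4)), [5, 10, 15, 20], 100)
        pw, _ = h_statistics(H, snp_window=4)
        row = pw.iloc[0]
        assert (row.H1, row.H2, row.H12, row.H2H1) == (1.0, 0.0, 1.0, 0.0)

    def test_ten_distinct_haplotypes_hand_count(self):
        H = hap(np.eye(10), np.arange(1, 11) * 10, 200)
        pw, _ = h_statistics(H, snp_window=10)
        row = pw.iloc[0]
        assert row.H1 == pytest.approx(0.1)
        assert row.H12 == pytest.approx(0.12)
        assert row.H2 == pytest.approx(0.09)
        assert row.H2H1 == pytest.approx(0.9)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, (12, 50))
        H1 = hap(a, np.arange(1, 51) * 100, 6000)
        H2 = hap(a[rng.permutation(12)], H1.positions, 6000)
        p1, _ = h_statistics(H1, snp_window=25)
        p2, _ = h_statistics(H2, snp_window=25)
        assert np.allclose(p1[["H1", "H12", "H2H1"]].to_numpy(),
                           p2[["H1", "H12", "H2H1"]].to_numpy())


class TestWindowedPi:
    def test_two_haplotypes_k_over_w(self):
        a = np.zeros((2, 3), dtype=np.int8)
        a[1] = 1  # differ at 3 sites
        H = hap(a, [100, 200, 300], 1000)
        df = windowed_pi(H, window=1000, step=1000)
        assert df.iloc[0]["pi"] == pytest.approx(3 / 1000)

    def test_identical_zero(self):
        H = hap(np.ones((4, 2)), [10, 20], 100)
        df = windowed_pi(H, window=100, step=100)
        assert df.iloc[0]["pi"] == 0.0

    def test_neutral_mean_matches_theta(self):
        from aspenscan.simulate import simulate_neutral_haplotypes

        vals = []
        for sd in range(150):
            H = simulate_neutral_haplotypes(0.004, 0.001, 5000, 10, sd)
            df = windowed_pi(H, window=5000, step=5000)
            vals.append(df.iloc[0]["pi"])
        assert np.mean(vals) == pytest.approx(0.004, rel=0.10)

    def test_low_callable_windows_excluded(self):
        H = hap(np.ones((4, 2)), [10, 20], 100)
        df = windowed_pi(H, window=50, step=50,
                         callable_fraction=[0.05, 1.0])
        assert len(df) == 1


def _clr_bruteforce(positions, counts, n, bg, grid_pos, alphas, L):
    """Dense-grid likelihood evaluation with explicit spectra."""
    pb = bg.probs()
    sup = bg.support()
    sel = np.isin(counts, sup)
    positions, counts = positions[sel], counts[sel]
    lp0 = np.log(pb[counts]).sum()
    best = 0.0
    for alpha in alphas:
        lp = 0.0
        for pos, b in zip(positions, counts):
            q = sweep_transformed_sfs(bg, 1 - np.exp(-alpha * abs(pos - grid_pos)))
            lp += np.log(max(q[b], 1e-300))
        best = max(best, lp - lp0)
    return 2 * best


@pytest.fixture(scope="module")
def background():
    rng = np.random.default_rng(0)
    n = 10
    weights = 1.0 / np.arange(1, n)
    draws = rng.choice(np.arange(1, n), size=2000,
                       p=weights / weights.sum())
    return BackgroundSFS.from_derived_counts(draws, n)


class TestClr:
    def test_nesting_full_escape_returns_background(self, background):
        q = sweep_transformed_sfs(background, 1.0)
        assert np.allclose(q, background.probs(), atol=1e-8)

    def test_null_behavior(self, background):
        """Sites drawn iid from the background give small CLR."""
        rng = np.random.default_rng(1)
        pb = background.probs()
        sup = background.support()
        maxima = []
        for _ in range(30):
            m = 150
            pos = np.sort(rng.integers(1, 50_000, m))
            counts = rng.choice(sup, size=m, p=pb[sup])
            df = clr_scan(pos, counts, background.n, background, 50_000,
                          grid_spacing=5000, n_alpha=16)
            maxima.append(df["clr"].median())
        assert np.median(maxima) < 3.0

    def test_matches_bruteforce_grid_oracle(self, background):
        rng = np.random.default_rng(2)
        m = 30
        pos = np.sort(rng.choice(np.arange(1, 10_000), m, replace=False))
        sup = background.support()
        pb = background.probs()
        counts = rng.choice(sup, size=m, p=pb[sup])
        alphas = np.geomspace(1e-6, 1e-1, 20)
        df = clr_scan(pos, counts, background.n, background, 10_000,
                      grid_spacing=5000, n_alpha=20,
                      alpha_range=(1e-6, 1e-1), ad_cutoff=50.0)
        for _, row in df.iterrows():
            oracle = _clr_bruteforce(pos, counts, background.n, background,
                                     row["grid_pos"], alphas, 10_000)
            assert row["clr"] == pytest.approx(oracle, abs=2e-2)

    def test_nonnegative(self, background):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.integers(1, 20_000, 50))
        counts = rng.integers(1, background.n, 50)
        df = clr_scan(pos, counts, background.n, background, 20_000)
        assert (df["clr"] >= 0).all()

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            BackgroundSFS(counts=np.zeros(11), n=10)


class TestWindowEnrichment:
    def test_all_below_threshold(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(-1, 1, 500)
        pos = np.sort(rng.choice(np.arange(1, 1_400_000), 500,
                                 replace=False))
        df = window_enrichment(scores, pos, min_snps=100)
        assert (df["proportion"] == 0).all()

    def test_small_windows_excluded(self):
        scores = np.ones(99) * 3
        pos = np.arange(1, 100)
        df = window_enrichment(scores, pos, min_snps=100)
        assert len(df) == 0

    def test_enriched_window_ranks_top(self):
        rng = np.random.default_rng(1)
        n_win, per = 12, 150
        scores, pos, chroms = [], [], []
        for w in range(n_win):
            s = rng.normal(0, 1, per)
            if w == 5:
                s[:60] = 4.0  # planted enrichment
            scores.append(s)
            pos.append(w * 700_000 + np.sort(rng.choice(
                np.arange(1, 700_000), per, replace=False)))
            chroms += ["chr"] * per
        df = window_enrichment(np.concatenate(scores), np.concatenate(pos),
                               np.array(chroms))
        top = df.sort_values("proportion").iloc[-1]
        assert top["start"] == 5 * 700_000 + 1
        assert top["quantile"] == 1.0
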