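import itertools

import numpy as np
import pandas as pd
import pytest

from coevoscan import selscan, simgen
from coevoscan.genio import (
    GenotypeMatrix,
    HaplotypeMatrix,
    SamplePanel,
    VariantRecord,
    interpolate_cm,
)


def wc_fst_oracle(g_a, g_b):
    """Independent scalar WC-1984 theta-hat, written straight from the paper's
    component definitions (a, b, c) with explicit loops over populations."""
    pops = []
    for g in (g_a, g_b):
        g = np.asarray([x for x in g if x >= 0], dtype=float)
        n = len(g)
        p = g.sum() / (2 * n)
        h = np.mean(g == 1)
        pops.append((n, p, h))
    r = 2
    nbar = sum(n for n, _, _ in pops) / r
    nc = (r * nbar - sum(n**2 for n, _, _ in pops) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p, _ in pops) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p, _ in pops) / ((r - 1) * nbar)
    hbar = sum(n * h for n, _, h in pops) / (r * nbar)
    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c) if (a + b + c) != 0 else np.nan


def _two_pop_gm(g_a, g_b):
    g_a, g_b = np.asarray(g_a, np.int8), np.asarray(g_b, np.int8)
    n = len(g_a) + len(g_b)
    samples = [f"s{i}" for i in range(n)]
    gm = GenotypeMatrix(
        samples,
        [VariantRecord("1", 100, "v0", "A", "G")],
        np.concatenate([g_a, g_b])[:, None],
    )
    panel = SamplePanel(
        pd.DataFrame(
            {
                "sample": samples,
                "population": ["A"] * len(g_a) + ["B"] * len(g_b),
                "sex": ["unknown"] * n,
            }
        )
    )
    return gm, panel


class TestSiteFst:
    def test_identical_counts_give_nonpositive_fst(self):
        g = [0] * 5 + [1] * 6 + [2] * 4
        gm, panel = _two_pop_gm(g, g)
        fst = selscan.site_fst(gm, panel, "A", "B")["fst"].iloc[0]
        assert fst <= 0

    def test_complete_fixation_is_one(self):
        gm, panel = _two_pop_gm([0] * 20, [2] * 20)
        fst = selscan.site_fst(gm, panel, "A", "B")["fst"].iloc[0]
        assert fst == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_in_both_is_undefined(self):
        gm, panel = _two_pop_gm([0] * 10, [0] * 10)
        out = selscan.site_fst(gm, panel, "A", "B")
        assert not out["defined"].iloc[0]
        assert np.isnan(out["fst"].iloc[0])

    def test_matches_independent_oracle(self, rng):
        for _ in range(300):
            na, nb = rng.integers(5, 40, size=2)
            pa, pb = rng.uniform(0.05, 0.95, size=2)
            g_a = rng.binomial(2, pa, na)
            g_b = rng.binomial(2, pb, nb)
            gm, panel = _two_pop_gm(g_a, g_b)
            got = selscan.site_fst(gm, panel, "A", "B")["fst"].iloc[0]
            want = wc_fst_oracle(g_a, g_b)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_unknown_population_is_error(self):
        gm, panel = _two_pop_gm([0, 1], [1, 2])
        with pytest.raises(Exception, match="C"):
            selscan.site_fst(gm, panel, "A", "C")


class TestPbs:
    def test_closed_form_hand_value(self):
        out = selscan.pbs([0.1], [0.2], [0.05])
        # (-log(0.9) - log(0.8) + log(0.95)) / 2 computed by hand
        assert out["pbs_a"].iloc[0] == pytest.approx(0.138606, abs=1e-6)

    def test_symmetric_fst_gives_equal_branches(self):
        for f in (0.0, 0.1, 0.5):
            out = selscan.pbs([f], [f], [f])
            t = -np.log(1 - f)
            for col in ("pbs_a", "pbs_b", "pbs_c"):
                assert out[col].iloc[0] == pytest.approx(t / 2, abs=1e-12)

    def test_branch_sum_identity(self, rng):
        f = rng.uniform(0, 0.9, size=(50, 3))
        out = selscan.pbs(f[:, 0], f[:, 1], f[:, 2])
        t_sum = (-np.log(1 - f)).sum(axis=1) / 2
        np.testing.assert_allclose(
            out[["pbs_a", "pbs_b", "pbs_c"]].sum(axis=1), t_sum, atol=1e-10
        )

    def test_undefined_fst_propagates(self):
        out = selscan.pbs([np.nan], [0.1], [0.1])
        assert not out["defined"].iloc[0]

    def test_negative_fst_clamped_and_fixation_capped(self):
        out = selscan.pbs([-0.2], [-0.1], [0.0])
        assert out["pbs_a"].iloc[0] == 0.0
        capped = selscan.pbs([1.0], [0.0], [0.0])
        assert np.isfinite(capped["pbs_a"].iloc[0])


class TestNormalizePbs:
    def test_zero_and_unit_cases(self):
        df = pd.DataFrame({"pbs_a": [0.0, 1.0], "pbs_b": [0.0, 0.0], "pbs_c": [0.0, 0.0]})
        out = selscan.normalize_pbs(df)
        assert out["pbs_a_norm"].tolist() == [0.0, 0.5]

    def test_normalized_below_raw_when_any_branch_positive(self, rng):
        raw = rng.uniform(0, 2, size=(100, 3))
        df = pd.DataFrame(raw, columns=["pbs_a", "pbs_b", "pbs_c"])
        out = selscan.normalize_pbs(df)
        assert (out["pbs_a_norm"] < out["pbs_a"]).all()

    def test_monotone_in_own_branch(self, rng):
        b, c = 0.3, 0.7
        grid = np.linspace(0, 3, 50)
        df = pd.DataFrame({"pbs_a": grid, "pbs_b": b, "pbs_c": c})
        out = selscan.normalize_pbs(df)
        assert (np.diff(out["pbs_a_norm"]) > 0).all()


class TestEmpiricalThreshold:
    def test_values_1_to_100(self):
        thr, p = selscan.empirical_threshold(np.arange(1, 101), q=0.95)
        assert 95 < thr < 96
        assert p[-1] == pytest.approx(1 / 100)  # the maximum

    def test_matches_sort_and_count_oracle(self, rng):
        vals = rng.normal(size=500)
        thr, p = selscan.empirical_threshold(vals, q=0.95)
        assert thr == pytest.approx(np.quantile(vals, 0.95))
        for k in rng.integers(0, 500, size=20):
            assert p[k] == pytest.approx(np.mean(vals >= vals[k]))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            selscan.empirical_threshold([np.nan])


def _hm_from_array(haps, positions=None):
    haps = np.asarray(haps, dtype=np.uint8)
    m = haps.shape[1]
    positions = positions if positions is not None else 100 * (np.arange(m) + 1)
    variants = [
        VariantRecord("1", int(p), f"v{j}", "A", "G", ancestral="A")
        for j, p in enumerate(positions)
    ]
    samples = [f"s{i}" for i in range(haps.shape[0] // 2)]
    return HaplotypeMatrix(samples, variants, haps, polarized=True)


def ehh_pairwise_oracle(haps, core, allele):
    """EHH by brute-force enumeration of haplotype pairs identical from the
    core out to each position (inclusive)."""
    carriers = [h for h in haps if h[core] == allele]
    n = len(carriers)
    m = len(haps[0])
    out = np.zeros(m)
    denom = n * (n - 1) / 2
    for x in range(m):
        lo, hi = (min(core, x), max(core, x))
        ident = 0
        for h1, h2 in itertools.combinations(carriers, 2):
            if all(h1[k] == h2[k] for k in range(lo, hi + 1)):
                ident += 1
        out[x] = ident / denom
    return out


class TestEhh:
    def test_identical_core_haplotypes_give_one_everywhere(self):
        haps = np.tile([0, 1, 0, 1, 1], (6, 1))
        hm = _hm_from_array(haps)
        _, e = selscan.ehh_curve(hm, 2, 0)
        np.testing.assert_allclose(e, 1.0)

    def test_two_plus_two_split_gives_one_third(self):
        # 4 core haplotypes split into two classes of 2 at the next column
        haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
        hm = _hm_from_array(haps)
        _, e = selscan.ehh_curve(hm, 0, 0)
        assert e[1] == pytest.approx(1 / 3)

    def test_matches_pairwise_identity_oracle(self, rng):
        haps = rng.integers(0, 2, size=(20, 12)).astype(np.uint8)
        haps[:, 5] = np.repeat([0, 1], 10)  # both alleles well represented
        hm = _hm_from_array(haps)
        for allele in (0, 1):
            _, e = selscan.ehh_curve(hm, 5, allele)
            want = ehh_pairwise_oracle(haps.tolist(), 5, allele)
            np.testing.assert_allclose(e, want, atol=1e-12)

    def test_non_increasing_away_from_core(self, neutral_panel):
        hm, _ = neutral_panel
        daf = hm.derived_allele_freq()
        core = int(np.argmin(np.abs(daf - 0.5)))
        for allele in (0, 1):
            _, e = selscan.ehh_curve(hm, core, allele)
            assert (np.diff(e[core:]) <= 1e-12).all()
            assert (np.diff(e[core::-1]) <= 1e-12).all()
            assert e[core] == 1.0

    def test_fewer_than_two_carriers_is_error(self):
        haps = np.zeros((4, 3), dtype=np.uint8)
        haps[0, 1] = 1
        with pytest.raises(ValueError):
            selscan.ehh_curve(_hm_from_array(haps), 1, 1)


class TestIntegrateIhh:
    def test_rectangle(self):
        cm = np.array([0.0, 0.25, 0.5])
        area, boundary = selscan.integrate_ihh(cm, np.ones(3), cutoff=0.05)
        assert area == pytest.approx(0.5)
        assert boundary  # cutoff never reached

    def test_triangle(self):
        cm = np.linspace(0, 1, 11)
        e = np.linspace(1, 0, 11)
        area, boundary = selscan.integrate_ihh(cm, e, cutoff=0.0)
        assert area == pytest.approx(0.5)
        assert not boundary

    def test_cutoff_crossing_interpolated(self):
        # EHH drops 1 -> 0.04 over 1 cM; crossing at 0.05 is interpolated
        area, boundary = selscan.integrate_ihh(
            np.array([0.0, 1.0]), np.array([1.0, 0.04]), cutoff=0.05
        )
        xc = (1 - 0.05) / (1 - 0.04)
        assert area == pytest.approx(0.5 * (1 + 0.05) * xc)
        assert not boundary

    def test_matches_independent_numerical_integrator(self, rng):
        for _ in range(50):
            k = rng.integers(3, 20)
            cm = np.concatenate([[0], np.sort(rng.uniform(0, 2, k))])
            e = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, k))[::-1]])
            cutoff = rng.uniform(0, 0.3)
            got, _ = selscan.integrate_ihh(cm, e, cutoff)
            # oracle: truncate at interpolated crossing, then trapezoid rule
            below = np.flatnonzero(e < cutoff)
            if below.size:
                j = below[0]
                frac = (e[j - 1] - cutoff) / (e[j - 1] - e[j])
                xs = np.concatenate([cm[:j], [cm[j - 1] + frac * (cm[j] - cm[j - 1])]])
                ys = np.concatenate([e[:j], [cutoff]])
            else:
                xs, ys = cm, e
            assert got == pytest.approx(np.trapezoid(ys, xs), abs=1e-10)


class TestIhsScan:
    def test_symmetric_haplotype_structure_gives_zero(self):
        # derived carriers are a mirrored copy of ancestral carriers
        rng = np.random.default_rng(5)
        block = rng.integers(0, 2, size=(6, 9)).astype(np.uint8)
        block[:, 4] = 0
        mirror = block.copy()
        mirror[:, 4] = 1
        hm = _hm_from_array(np.vstack([block, mirror]))
        gmap = simgen.GeneticMap.uniform(1, 2000, cm_per_mb=1000.0)
        scan = selscan.ihs_scan(hm, gmap, maf_min=0.05, n_bins=5)
        row = scan[scan.pos == hm.positions[4]]
        assert row["uihs"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_bin_moments_after_standardization(self, neutral_panel):
        hm, gmap = neutral_panel
        scan = selscan.ihs_scan(hm, gmap, n_bins=20)
        std = scan[scan.standardized]
        assert len(std) > 200
        g = std.groupby("bin")["ihs"]
        ok = g.count() >= 2
        assert g.mean()[ok].abs().max() < 0.05
        assert g.std(ddof=1)[ok].between(0.9, 1.1).all()

    def test_maf_bounds_respected(self, neutral_panel):
        hm, gmap = neutral_panel
        scan = selscan.ihs_scan(hm, gmap, maf_min=0.2)
        assert scan["daf"].between(0.2, 0.8).all()

    def test_sweep_site_outlies_neutral_reference(self, neutral_panel):
        hm_neutral, gmap_neutral = neutral_panel
        ref = selscan.ihs_scan(hm_neutral, gmap_neutral, n_bins=20)
        thr = np.quantile(np.abs(ref["ihs"]), 0.95)
        hits = 0
        for seed in (11, 12, 13):
            hs, gmap, pos = simgen.simulate_sweep(
                n_samples=40, sequence_length=800_000, s=0.05, seed=seed
            )
            j = list(hs.positions).index(pos)
            cm = interpolate_cm(gmap, hs.positions)
            vals = {}
            for name, allele in (("a", 0), ("d", 1)):
                sub = hs.haplotypes[hs.haplotypes[:, j] == allele]
                l, _ = selscan._ihh_one_side(sub, cm, hs.positions, j, -1, 0.05, 200_000)
                r, _ = selscan._ihh_one_side(sub, cm, hs.positions, j, +1, 0.05, 200_000)
                vals[name] = l + r
            uihs = np.log(vals["a"] / vals["d"])
            target = pd.DataFrame(
                {"daf": [hs.derived_allele_freq()[j]], "uihs": [uihs]}
            )
            z = selscan.standardize_ihs(target, reference=ref, n_bins=20)["ihs"].iloc[0]
            hits += abs(z) > thr
        assert hits >= 2
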