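import numpy as np
import pytest

from gwaselect.io_formats import GeneticMap
from gwaselect.selection_haplotype import (EhhProfile, IhsStandardization,
                                           ehh_profile, empirical_threshold,
                                           ihs_scan, integrate_ihh)
from gwaselect.synthetic_data import (SelectedSite, SimulationConfig,
                                      simulate_populations)
from tests.conftest import make_panel


def brute_force_ehh(haps, core, allele, cutoff=0.05):
    """Materialize extended haplotype substrings and count equal pairs."""
    carriers = np.flatnonzero(haps[:, core] == allele)
    n_c = len(carriers)
    denom = n_c * (n_c - 1) / 2.0
    result = {}
    for direction in (-1, +1):
        sites, values = [], []
        j = core + direction
        truncated = True
        while 0 <= j < haps.shape[1]:
            lo, hi = (j, core + 1) if direction < 0 else (core, j + 1)
            strings = [tuple(haps[c, lo:hi]) for c in carriers]
            counts = {}
            for s in strings:
                counts[s] = counts.get(s, 0) + 1
            pairs = sum(c * (c - 1) // 2 for c in counts.values())
            ehh = pairs / denom
            sites.append(j)
            values.append(ehh)
            if ehh < cutoff:
                truncated = False
                break
            j += direction
        result[direction] = (sites, values, truncated)
    return result


def _profile_against_brute_force(panel, gmap, core, allele):
    prof = ehh_profile(panel, gmap, core, allele)
    brute = brute_force_ehh(panel.haplotypes, core, allele)
    cm = gmap.interpolate(panel.positions)
    for direction in (-1, +1):
        sites, values, truncated = brute[direction]
        dist, ehh = prof.side(direction)
        np.testing.assert_array_equal(
            dist[1:], np.abs(cm[sites] - cm[core]))
        assert list(ehh[1:]) == values  # exact float equality
        trunc_flag = (prof.truncated_left if direction < 0
                      else prof.truncated_right)
        assert trunc_flag == truncated


class TestEhhProfile:
    def test_offset_zero_is_one(self, small_panel, uniform_map):
        gmap = uniform_map(small_panel.positions)
        prof = ehh_profile(small_panel, gmap, 5, 1)
        assert prof.ehh[prof.offsets_cm == 0][0] == 1.0

    def test_combinatorial_count_example(self, uniform_map):
        # 4 carriers of the core allele (column 0); two flank steps split
        # them into extended-haplotype groups {2, 1, 1}
        haps = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 1],
            [0, 0, 0],
            [0, 1, 1],
        ], dtype=np.uint8)
        panel = make_panel(haps)
        gmap = uniform_map(panel.positions)
        prof = ehh_profile(panel, gmap, 0, 1)
        right = prof.side(+1)[1]
        # step 1: flank alleles [0,0,1,1] -> groups {2,2} -> 2*C(2,2)/C(4,2)
        assert right[1] == pytest.approx(2 / 6)
        # step 2: strings (0,0),(0,0),(1,0),(1,1) -> groups {2,1,1} -> 1/6
        assert right[2] == pytest.approx(1 / 6)

    def test_shared_haplotype_keeps_ehh_at_one(self, uniform_map):
        haps = np.tile(np.array([[1, 1, 1, 1]], dtype=np.uint8), (6, 1))
        haps = np.vstack([haps, np.zeros((2, 4), dtype=np.uint8)])
        panel = make_panel(haps)
        prof = ehh_profile(panel, uniform_map(panel.positions), 2, 1)
        assert np.all(prof.ehh == 1.0)
        assert prof.truncated_left and prof.truncated_right

    def test_fewer_than_two_carriers_is_error(self, uniform_map):
        haps = np.zeros((6, 3), dtype=np.uint8)
        haps[0, 1] = 1
        panel = make_panel(haps)
        with pytest.raises(ValueError, match="carrier"):
            ehh_profile(panel, uniform_map(panel.positions), 1, 1)

    def test_oracle_equivalence_on_random_panels(self, rng, uniform_map):
        for _ in range(30):
            n_hap = 2 * rng.integers(3, 16)
            n_sites = rng.integers(5, 64)
            haps = (rng.random((n_hap, n_sites))
                    < rng.uniform(0.2, 0.8, n_sites)).astype(np.uint8)
            panel = make_panel(haps)
            gmap = uniform_map(panel.positions)
            core = int(rng.integers(n_sites))
            for allele in (0, 1):
                if np.sum(haps[:, core] == allele) < 2:
                    continue
                _profile_against_brute_force(panel, gmap, core, allele)


class TestIntegrateIhh:
    def _profile(self, offsets, ehh, trunc=False):
        return EhhProfile(core_id="v", core_allele=1,
                          offsets_cm=np.asarray(offsets, dtype=float),
                          ehh=np.asarray(ehh, dtype=float),
                          truncated_left=trunc, truncated_right=trunc)

    def test_hand_trapezoid(self):
        prof = self._profile([0.0, 0.1, 0.2], [1.0, 0.5, 0.04])
        assert integrate_ihh(prof) == pytest.approx(0.075 + 0.027)

    def test_rectangle(self):
        prof = self._profile([0.0, 0.2, 0.4], [1.0, 1.0, 1.0], trunc=True)
        assert integrate_ihh(prof) == pytest.approx(0.4)

    def test_symmetric_profile_doubles_one_side(self):
        prof = self._profile([-0.2, -0.1, 0.0, 0.1, 0.2],
                             [0.04, 0.5, 1.0, 0.5, 0.04])
        assert integrate_ihh(prof) == pytest.approx(2 * (0.075 + 0.027))

    def test_integration_stops_at_first_subcutoff_point(self):
        prof = self._profile([0.0, 0.1, 0.2, 0.3], [1.0, 0.5, 0.04, 0.01])
        assert integrate_ihh(prof) == pytest.approx(0.075 + 0.027)

    def test_non_monotone_profile_is_error(self):
        prof = self._profile([0.0, 0.1, 0.2], [1.0, 0.4, 0.6])
        with pytest.raises(ValueError, match="non-increasing"):
            integrate_ihh(prof)


class TestEmpiricalThreshold:
    def test_order_statistics_example(self, rng):
        scores = rng.uniform(-2, 2, size=999)
        scores = np.append(scores, 5.0)
        res = empirical_threshold(scores)
        assert 2.0 < res.cutoff <= 5.0
        assert res.n_hits == 1

    def test_constant_scores(self):
        res = empirical_threshold(np.full(2000, 1.5))
        assert res.cutoff == pytest.approx(1.5)
        assert res.n_hits == 0

    def test_median_quantile(self, rng):
        scores = rng.normal(0, 1, size=100_000)
        res = empirical_threshold(scores, quantile=0.5)
        assert res.cutoff == pytest.approx(np.median(np.abs(scores)), abs=1e-9)

    def test_small_input_warns(self):
        with pytest.warns(UserWarning, match="tail"):
            empirical_threshold(np.arange(10.0))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            empirical_threshold(np.array([]))


@pytest.fixture(scope="module")
def neutral_scan():
    cfg = SimulationConfig(n_diploid={"A": 150}, n_sites=400,
                           sequence_length=400_000, recombination_rate=1e-6,
                           generations=80, seed=77,
                           initial_frequency_range=(0.1, 0.9))
    panel = simulate_populations(cfg)[0]["A"]
    gmap = GeneticMap.uniform(panel.positions, cm_per_bp=1e-4)
    result = ihs_scan(panel, gmap, np.zeros(panel.n_sites, dtype=int))
    return panel, gmap, result


class TestIhsScan:
    def test_low_daf_sites_excluded(self, neutral_scan):
        panel, _, result = neutral_scan
        low = result[result["daf"] < 0.05]
        assert (low["flag"] == "low_daf").all()
        assert low["ihs_s"].isna().all()

    def test_bins_follow_daf(self, neutral_scan):
        _, _, result = neutral_scan
        ok = result[result["ihs_s"].notna()]
        np.testing.assert_array_equal(ok["bin"],
                                      np.clip((ok["daf"] // 0.05).astype(int), 0, 19))

    def test_standardization_self_consistency(self, neutral_scan):
        _, _, result = neutral_scan
        ok = result[result["ihs_s"].notna()]
        assert abs(ok["ihs_s"].mean()) < 0.15
        assert 0.85 < ok["ihs_s"].std() < 1.15

    def test_label_swap_negates_unstandardized_score(self, neutral_scan):
        panel, gmap, result = neutral_scan
        flipped = ihs_scan(panel, gmap, np.ones(panel.n_sites, dtype=int))
        both = result.merge(flipped, on="id", suffixes=("_a", "_b"))
        both = both.dropna(subset=["ihs_u_a", "ihs_u_b"])
        assert len(both) > 50
        np.testing.assert_allclose(both["ihs_u_b"], -both["ihs_u_a"],
                                   rtol=1e-9)

    def test_gaussian_p_matches_score(self, neutral_scan):
        from scipy import stats
        _, _, result = neutral_scan
        ok = result[result["ihs_s"].notna()]
        np.testing.assert_allclose(
            ok["p"], 2 * stats.norm.sf(np.abs(ok["ihs_s"])), rtol=1e-9)

    def test_reference_standardization_reproduces_self(self, neutral_scan):
        panel, gmap, result = neutral_scan
        ok = result[(result["flag"] == "") & result["ihs_u"].notna()]
        ref = IhsStandardization.fit(ok["bin"].to_numpy(),
                                     ok["ihs_u"].to_numpy())
        again = ihs_scan(panel, gmap, np.zeros(panel.n_sites, dtype=int),
                         reference=ref)
        np.testing.assert_allclose(again["ihs_s"].dropna(),
                                   result["ihs_s"].dropna(), rtol=1e-9)

    def test_no_usable_sites_is_error(self, uniform_map):
        haps = np.zeros((8, 5), dtype=np.uint8)
        haps[0] = 1  # daf 0.125 but every profile trivially truncated
        panel = make_panel(haps)
        with pytest.raises(ValueError):
            ihs_scan(panel, uniform_map(panel.positions),
                     np.zeros(5, dtype=int))
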