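import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevonet.alignment import Alignment
from coevonet.connectivity import (
    FamilySummary,
    bin_and_average,
    classify_hcc_lcc,
    cohort_regression,
    degree_ci_regression,
    environment_contrast,
    family_summary,
    linear_fit,
    sample_null_pairs,
    site_degrees,
    stratified_regression,
)
from coevonet.conservation import normalize_profile
from coevonet.scoring import SignificantPair
from coevonet.secondary import EnvironmentAnnotation
from coevonet.structure import Atom, ColumnResidueMap, Residue, StructureModel


def pairs_of(coords):
    return [SignificantPair(i, j, "MIp", 5.0) for i, j in coords]


class TestSiteDegrees:
    def test_counting(self):
        deg = site_degrees(pairs_of([(1, 9), (1, 12), (9, 20)]))
        assert deg == {1: 2, 9: 2, 12: 1, 20: 1}

    def test_empty(self):
        assert site_degrees([]) == {}

    def test_handshake_identity(self):
        ps = pairs_of([(1, 9), (1, 17), (9, 17)])
        deg = site_degrees(ps)
        assert sum(deg.values()) == 2 * len(ps)

    @settings(max_examples=50, deadline=None)
    @given(
        st.sets(
            st.tuples(st.integers(0, 30), st.integers(0, 30)).map(
                lambda t: (min(t), max(t))
            ).filter(lambda t: t[0] < t[1]),
            max_size=40,
        )
    )
    def test_handshake_property(self, coords):
        deg = site_degrees(pairs_of(sorted(coords)))
        assert sum(deg.values()) == 2 * len(coords)

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError):
            site_degrees(pairs_of([(1, 9), (1, 9)]))


class TestHccLcc:
    @pytest.mark.parametrize("degree,label", [(1, "LCC"), (3, "LCC"), (4, "HCC")])
    def test_boundary_at_three(self, degree, label):
        assert classify_hcc_lcc({5: degree})[5] == label

    def test_partition(self):
        deg = {c: d for c, d in enumerate([1, 2, 3, 4, 5, 6], start=1)}
        labels = classify_hcc_lcc(deg)
        assert len(labels) == len(deg)
        assert sum(v == "HCC" for v in labels.values()) == 3


class TestBinning:
    def test_width_one(self):
        s = bin_and_average([1, 1, 2, 5], [0.5, 0.7, 1.0, 2.0], 1)
        assert s.labels == ["1", "2", "5"]
        assert list(s.n) == [2, 1, 1]
        assert np.allclose(s.mean_y, [0.6, 1.0, 2.0])

    def test_width_five(self):
        s = bin_and_average([1, 1, 2, 5], [0.5, 0.7, 1.0, 2.0], 5)
        assert s.labels == ["1-5"]
        assert s.n[0] == 4 and s.mean_y[0] == pytest.approx(1.05)

    def test_single_item(self):
        s = bin_and_average([3], [1.5], 1)
        assert list(s.n) == [1] and s.mean_y[0] == 1.5

    def test_counts_conserved(self, rng):
        x = rng.integers(1, 40, size=100)
        s = bin_and_average(x, rng.normal(size=100), 5)
        assert s.n.sum() == 100

    def test_bad_width(self):
        with pytest.raises(ValueError):
            bin_and_average([1], [1], 0)


class TestLinearFit:
    def test_exact_line(self):
        r = linear_fit(bin_and_average([1, 2, 3], [1, 2, 3], 1))
        assert r.slope == pytest.approx(1.0) and r.r_squared == pytest.approx(1.0)

    def test_flat_y_convention(self):
        r = linear_fit(bin_and_average([1, 2, 3], [5, 5, 5], 1))
        assert r.slope == 0.0 and r.r_squared == 0.0

    def test_hand_computed_ols(self):
        # x=(1,2,3), y=(2,4,5): slope 1.5, R^2 = 27/28
        r = linear_fit(bin_and_average([1, 2, 3], [2, 4, 5], 1))
        assert r.slope == pytest.approx(1.5)
        assert r.r_squared == pytest.approx(27 / 28)

    def test_zero_x_variance_errors(self):
        from coevonet.connectivity import BinnedSeries

        degenerate = BinnedSeries(
            1, ["1", "1"], np.array([1, 1]), np.array([2.0, 2.0]),
            np.array([1.0, 3.0]),
        )
        with pytest.raises(ValueError, match="variance"):
            linear_fit(degenerate)
        with pytest.raises(ValueError, match="bins"):
            linear_fit(bin_and_average([2, 2], [1, 3], 5))

    def test_order_invariance(self, rng):
        x = rng.integers(1, 20, 50)
        y = rng.normal(size=50)
        r1 = linear_fit(bin_and_average(x, y, 5))
        perm = rng.permutation(50)
        r2 = linear_fit(bin_and_average(x[perm], y[perm], 5))
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.r_squared == pytest.approx(r2.r_squared)


def collinear_beads(n, spacing=3.8):
    return StructureModel(
        "A",
        [
            Residue(k + 1, "", "ALA",
                    {"CA": Atom("CA", "C", np.array([k * spacing, 0.0, 0.0]))})
            for k in range(n)
        ],
    )


class TestNullSampling:
    def _setup(self):
        # compact chain: many pairs within 10 A at |i-j| > 6
        from coevonet.synthetic import compact_chain

        s = compact_chain(30, seed=8)
        m = ColumnResidueMap({c: c for c in range(30)}, 1.0)
        return s, m

    def test_determinism_under_seed(self):
        s, m = self._setup()
        sig = pairs_of([(0, 10)])
        e1 = sample_null_pairs(m, s, sig, n_pairs=3, n_draws=4, seed=9)
        e2 = sample_null_pairs(m, s, sig, n_pairs=3, n_draws=4, seed=9)
        assert e1.draws == e2.draws

    def test_constraints_hold(self):
        s, m = self._setup()
        sig = pairs_of([(0, 10), (3, 13)])
        sig_sites = {0, 10, 3, 13}
        ens = sample_null_pairs(m, s, sig, n_pairs=4, n_draws=10, seed=2)
        from coevonet.structure import distance_matrix

        d = distance_matrix(s)
        for draw in ens.draws:
            for i, j in draw:
                assert j - i > 6
                assert d[i, j] < 10.0
                assert (i, j) not in {(0, 10), (3, 13)}
                assert i not in sig_sites  # anchors are non-coevolved

    def test_pool_exhaustion_errors(self):
        s, m = self._setup()
        with pytest.raises(ValueError, match="eligible"):
            sample_null_pairs(m, s, pairs_of([(0, 10)]), n_pairs=10**6, seed=0)


class TestEnvironmentContrast:
    def _profile(self, ci):
        p = normalize_profile(np.arange(len(ci), dtype=float), np.zeros(len(ci), bool))
        p.ci[:] = ci
        return p

    def _env(self, buried):
        n = len(buried)
        return EnvironmentAnnotation(
            relative_accessibility=np.where(buried, 0.01, 0.5),
            buried=np.asarray(buried, bool),
            ss_class=np.array(["helix"] * n, dtype=object),
            hbonded=np.ones(n, bool),
        )

    def test_delta_ci_hand_example(self):
        # sites 0..3 accessible; 0,1 are HCC (degree 4), 2,3 LCC
        pairs = pairs_of(
            [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4), (2, 4)]
        )
        ci = [1.2, 1.0, 0.8, 0.6, 0.0]
        m = ColumnResidueMap({c: c for c in range(5)}, 1.0)
        env = self._env([False] * 5)
        ec = environment_contrast(pairs, m, env, self._profile(ci), "burial")
        deg = site_degrees(pairs)
        assert deg[0] == 4 and deg[1] == 4  # HCC sites
        assert ec.delta_ci["ACC_ACC"] == pytest.approx(
            np.mean([1.2, 1.0]) - np.mean([0.8, 0.6, 0.0])
        )

    def test_all_accessible_no_bur_bur(self):
        pairs = pairs_of([(0, 1)])
        m = ColumnResidueMap({0: 0, 1: 1}, 1.0)
        ec = environment_contrast(
            pairs, m, self._env([False, False]), self._profile([1.0, 0.5]), "burial"
        )
        assert "BUR_BUR" not in ec.pair_counts

    def test_mixed_pair_classified(self):
        pairs = pairs_of([(0, 1)])
        m = ColumnResidueMap({0: 0, 1: 1}, 1.0)
        ec = environment_contrast(
            pairs, m, self._env([False, True]), self._profile([1.0, 0.5]), "burial"
        )
        assert ec.pair_counts == {"MIXED": 1}

    def test_missing_class_side_reported_none(self):
        pairs = pairs_of([(0, 1)])  # both degree 1 -> LCC only
        m = ColumnResidueMap({0: 0, 1: 1}, 1.0)
        ec = environment_contrast(
            pairs, m, self._env([False, False]), self._profile([1.0, 0.5]), "burial"
        )
        assert ec.delta_ci["ACC_ACC"] is None


class TestFamilyAndCohort:
    def _profile(self, ci):
        p = normalize_profile(np.arange(len(ci), dtype=float), np.zeros(len(ci), bool))
        p.ci[:] = ci
        return p

    def test_family_summary_distinct_sites(self):
        p = self._profile([0.1] * 21)
        s = family_summary("F", "MIp", pairs_of([(1, 9), (1, 12)]), p, {0, 1, 2})
        assert s.n_coevolved_sites == 3 and s.n_pairs == 2

    def test_empty_family_still_summarised(self):
        p = self._profile([0.5, 0.5, 0.5])
        s = family_summary("F", "MIp", [], p, {0, 1, 2})
        assert s.n_pairs == 0 and s.mean_ci == pytest.approx(0.5)

    def test_cohort_negative_trend_recovered(self):
        summaries = [
            FamilySummary(f"F{k}", "MIp", k, 5 * k, 2.0 - 0.04 * (5 * k))
            for k in range(1, 21)
        ]
        reg = cohort_regression(summaries, bin_width=5)
        assert reg.slope < 0 and reg.r_squared > 0.9

    def test_identical_families_error(self):
        summaries = [FamilySummary(f"F{k}", "MIp", 3, 10, 0.5) for k in range(5)]
        with pytest.raises(ValueError):
            cohort_regression(summaries, bin_width=40)

    def test_two_bins_exact_line(self):
        summaries = [
            FamilySummary("A", "M", 1, 10, 1.0),
            FamilySummary("B", "M", 1, 90, 0.2),
        ]
        reg = cohort_regression(summaries, bin_width=40)
        assert reg.r_squared == pytest.approx(1.0)


class TestStratifiedRegression:
    def _go(self, rows):
        return pd.DataFrame(rows, columns=["family_id", "domain", "label"])

    def _summaries(self, ids, slope):
        return [
            FamilySummary(fid, "MIp", 1, 10 * (k + 1), 1.0 + slope * 10 * (k + 1))
            for k, fid in enumerate(ids)
        ]

    def test_opposite_trends_recovered(self):
        neg_ids = [f"N{k}" for k in range(6)]
        pos_ids = [f"P{k}" for k in range(6)]
        summaries = self._summaries(neg_ids, -0.05) + self._summaries(pos_ids, +0.05)
        go = self._go(
            [(f, "molecular function", "catalysis") for f in neg_ids]
            + [(f, "molecular function", "transport") for f in pos_ids]
        )
        table = stratified_regression(summaries, go, "molecular function",
                                      bin_width=10, min_families=5)
        by_class = table.set_index("class")
        assert by_class.loc["catalysis", "slope"] < 0
        assert by_class.loc["transport", "slope"] > 0

    def test_small_class_omitted(self):
        ids = [f"F{k}" for k in range(6)]
        summaries = self._summaries(ids, -0.05)
        go = self._go(
            [(f, "d", "big") for f in ids] + [("F0", "d", "tiny")]
        )
        table = stratified_regression(summaries, go, "d", bin_width=10)
        assert set(table["class"]) == {"big"}

    def test_multilabel_family_in_both(self):
        ids = [f"F{k}" for k in range(6)]
        summaries = self._summaries(ids, -0.05)
        rows = [(f, "d", "one") for f in ids] + [(f, "d", "two") for f in ids]
        table = stratified_regression(summaries, self._go(rows), "d",
                                      bin_width=10, min_families=5)
        assert set(table["class"]) == {"one", "two"}


class TestDegreeCiRegression:
    def test_positive_trend(self):
        p = normalize_profile(np.arange(30, dtype=float), np.zeros(30, bool))
        degrees = {c: 1 + c // 6 for c in range(30)}
        reg = degree_ci_regression(degrees, p, bin_width=1)
        assert reg.slope > 0
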