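"""d' distances, clustering, cross-reactivity, dose-series summaries."""

import math

import numpy as np
import pandas as pd
import pytest

import cleavekit as ck
from cleavekit.errors import ConfigurationError, InputError, UndefinedDistanceError
from cleavekit.profiling import (
    DosePoint,
    dprime_matrix,
    linkage_to_newick,
)


def _matrix(fc, se, sensors=None, conditions=None):
    fc = pd.DataFrame(fc, index=sensors, columns=conditions, dtype=float)
    se = pd.DataFrame(se, index=fc.index, columns=fc.columns, dtype=float)
    return ck.ResponseMatrix(fc, se)


class TestDprime:
    def test_identical_profiles_give_zero(self):
        m = _matrix([[2.0, 3.0], [2.0, 3.0]], [[0.1, 0.1], [0.1, 0.1]])
        assert ck.dprime(m, m.sensors[0], m.sensors[1]) == 0.0

    def test_single_condition_arithmetic(self):
        # |log 4 - log 1| / sqrt(0.04 + 0.04) = 4.90 to 2 d.p.
        m = _matrix([[4.0], [1.0]], [[0.2], [0.2]])
        d = ck.dprime(m, 0, 1)
        assert d == pytest.approx(math.log(4) / math.sqrt(0.08), rel=1e-12)
        assert d == pytest.approx(4.90, abs=0.005)

    def test_symmetry_and_self_distance(self, rng):
        m = _matrix(
            np.exp(rng.normal(0, 1, (6, 4))), rng.uniform(0.05, 0.3, (6, 4))
        )
        dm = dprime_matrix(m)
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)

    def test_matches_brute_force_on_random_matrix(self, rng):
        fc = np.exp(rng.normal(0, 1, (10, 5)))
        se = rng.uniform(0.05, 0.5, (10, 5))
        m = _matrix(fc, se)
        dm = dprime_matrix(m)
        for i in range(10):
            for j in range(10):
                expect = max(
                    abs(math.log(fc[i, v]) - math.log(fc[j, v]))
                    / math.sqrt(se[i, v] ** 2 + se[j, v] ** 2)
                    for v in range(5)
                )
                if i == j:
                    expect = 0.0
                assert dm.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_missing_cells_excluded_from_max(self):
        m = _matrix([[4.0, np.nan], [1.0, 100.0]], [[0.2, np.nan], [0.2, 0.1]])
        assert ck.dprime(m, 0, 1) == pytest.approx(math.log(4) / math.sqrt(0.08))

    def test_no_shared_conditions_is_an_error(self):
        m = _matrix([[4.0, np.nan], [np.nan, 2.0]], [[0.2, np.nan], [np.nan, 0.2]])
        with pytest.raises(UndefinedDistanceError):
            ck.dprime(m, 0, 1)


class TestClusterSensors:
    def test_identical_sensors_merge(self):
        m = _matrix([[2.0, 5.0], [2.0, 5.0]], [[0.1] * 2] * 2, sensors=["a", "b"])
        res = ck.cluster_sensors(m, cutoff=3.0)
        assert res.labels["a"] == res.labels["b"]

    def test_planted_archetypes_recovered(self, rng):
        # 3 archetypes x 4 sensors; within-archetype d' < 1, between > 6
        base = np.array([[8.0, 1.0, 1.0], [1.0, 8.0, 1.0], [1.0, 1.0, 8.0]])
        fc, names = [], []
        for arch in range(3):
            for rep in range(4):
                fc.append(base[arch] * np.exp(rng.normal(0, 0.02, 3)))
                names.append(f"a{arch}r{rep}")
        m = _matrix(np.array(fc), np.full((12, 3), 0.15), sensors=names)
        res = ck.cluster_sensors(m, cutoff=3.0)
        assert res.labels.nunique() == 3
        for arch in range(3):
            labs = {res.labels[f"a{arch}r{i}"] for i in range(4)}
            assert len(labs) == 1

    def test_complete_linkage_bounds_within_cluster_dprime(self, rng):
        fc = np.exp(rng.normal(0, 0.8, (8, 4)))
        m = _matrix(fc, np.full((8, 4), 0.2))
        cutoff = 4.0
        res = ck.cluster_sensors(m, cutoff=cutoff)
        dm = dprime_matrix(m)
        for lab in res.labels.unique():
            members = list(res.labels.index[res.labels == lab])
            for i in members:
                for j in members:
                    assert dm.loc[i, j] <= cutoff + 1e-9

    def test_singleton_sensor_is_own_cluster(self):
        m = _matrix([[2.0]], [[0.1]], sensors=["only"])
        res = ck.cluster_sensors(m, cutoff=3.0)
        assert res.labels["only"] == 1
        assert res.representatives == {1: "only"}

    def test_representative_is_highest_abundance(self):
        m = _matrix([[2.0, 5.0], [2.0, 5.0]], [[0.1] * 2] * 2, sensors=["a", "b"])
        res = ck.cluster_sensors(m, cutoff=3.0, abundance={"a": 0.1, "b": 0.9})
        assert set(res.representatives.values()) == {"b"}

    def test_nonpositive_cutoff_rejected(self):
        m = _matrix([[2.0]], [[0.1]])
        with pytest.raises(ConfigurationError):
            ck.cluster_sensors(m, cutoff=0.0)

    def test_newick_export_parses(self):
        from io import StringIO

        from Bio import Phylo

        m = _matrix(
            [[2.0, 1.0], [2.1, 1.0], [1.0, 9.0]],
            [[0.1] * 2] * 3,
            sensors=["a", "b", "c"],
        )
        res = ck.cluster_sensors(m, cutoff=3.0)
        nwk = linkage_to_newick(res.linkage, m.sensors)
        tree = Phylo.read(StringIO(nwk), "newick")
        assert {t.name for t in tree.get_terminals()} == {"a", "b", "c"}


class TestCrossReactivity:
    def test_single_responder(self):
        m = _matrix([[5.0, 1.0]], [[0.1, 0.1]], sensors=["s"], conditions=["x", "y"])
        xr = ck.cross_reactivity(m, f_grid=[2.0])
        assert xr.sensor_xr.loc["s", 2.0] == 1
        assert xr.compound_xr.loc["x", 2.0] == 1
        assert np.isnan(xr.compound_xr.loc["y", 2.0])

    def test_compound_takes_min_over_sensors(self):
        fc = [[5.0, 5.0, 5.0], [5.0, 1.0, 1.0]]  # s1 XR=3, s2 XR=1
        m = _matrix(fc, [[0.1] * 3] * 2, sensors=["s1", "s2"], conditions=list("xyz"))
        xr = ck.cross_reactivity(m, f_grid=[2.0])
        assert xr.compound_xr.loc["x", 2.0] == 1  # via the selective sensor

    def test_matches_brute_force_on_random_matrix(self, rng):
        fc = np.exp(rng.normal(0.3, 0.8, (20, 15)))
        m = _matrix(fc, np.full((20, 15), 0.1))
        grid = [1.5, 2.0, 4.0]
        xr = ck.cross_reactivity(m, f_grid=grid)
        for f in grid:
            for i in range(20):
                assert xr.sensor_xr.iloc[i][f] == int((fc[i] >= f).sum())
            for j in range(15):
                responders = [i for i in range(20) if fc[i, j] >= f]
                want = (
                    min(int((fc[i] >= f).sum()) for i in responders)
                    if responders
                    else np.nan
                )
                got = xr.compound_xr.iloc[j][f]
                assert (np.isnan(got) and isinstance(want, float)) or got == want

    def test_curve_monotonicity(self, rng):
        fc = np.exp(rng.normal(0.3, 0.8, (10, 12)))
        m = _matrix(fc, np.full((10, 12), 0.1))
        grid = [1.5, 2.0, 3.0, 5.0]
        xr = ck.cross_reactivity(m, f_grid=grid)
        cum = xr.cumulative_counts(c_grid=[1, 2, 5, 10])
        # non-decreasing in C for fixed f
        assert (cum.diff(axis=1).iloc[:, 1:] >= 0).all().all()
        # the number of compounds with any responder shrinks as f rises
        n_defined = xr.compound_xr.notna().sum(axis=0)
        assert (n_defined.diff().iloc[1:] <= 0).all()


class TestMinDetectableConcentration:
    def _series(self, points, companions=()):
        return ck.DoseSeries(
            "s1", "cX",
            [DosePoint(c, fc, ci) for c, fc, ci in points],
            companions=list(companions),
        )

    def test_lowest_qualifying_concentration(self):
        s = self._series(
            [
                (10.0, 6.0, (4.0, 9.0)),
                (1.0, 4.0, (2.5, 6.0)),
                (0.1, 2.5, (1.5, 4.0)),
                (0.025, 2.1, (1.2, 3.6)),
                (0.012, 1.4, (0.8, 2.4)),
            ]
        )
        res = ck.min_detectable_concentration(s, fc_threshold=2.0)
        assert res.min_concentration_um == pytest.approx(0.025)
        assert res.fc_at_max == 6.0

    def test_ci_lower_bound_gate(self):
        # fc crosses 2 but its CI still includes 1: not detected there
        s = self._series([(10.0, 2.5, (0.9, 6.0))])
        res = ck.min_detectable_concentration(s)
        assert res.min_concentration_um is None

    def test_never_reaching_threshold_reports_none(self):
        s = self._series([(10.0, 1.8, (1.2, 2.6)), (5.0, 1.4, (0.9, 2.0))])
        assert ck.min_detectable_concentration(s).min_concentration_um is None

    def test_companion_masking(self):
        m = _matrix(
            [[5.0, 3.0]], [[0.1, 0.1]], sensors=["s1"], conditions=["cX", "cY"]
        )
        s = self._series([(10.0, 5.0, (3.0, 8.0))], companions=["cY"])
        res = ck.min_detectable_concentration(s, single_compound_matrix=m)
        assert res.masked and "cY" in res.mask_reason

    def test_increasing_concentrations_rejected(self):
        with pytest.raises(InputError):
            self._series([(1.0, 2.0, (1.5, 3.0)), (2.0, 2.0, (1.5, 3.0))])

    def test_within_one_dilution_of_analytic_threshold(self, rng):
        # simulated two-fold dilution series from the saturating response
        # model: the crossing is found within one dilution step of the
        # concentration where FC(x) = 2
        from cleavekit.cleaveseq import fold_change_frame
        from cleavekit.synthetic import TargetResponse

        t = TargetResponse(fc_max=8.0, ec50_um=1.0)
        x_star = t.ec50_um / (t.fc_max - 2.0)  # FC(x)=2 analytically
        depth, c0 = 5000, 0.6
        concs = [10.0 / 2**i for i in range(12)]
        pts = []
        for x in concs:
            odds = (c0 / (1 - c0)) / t.fold_change(x)
            c = odds / (1 + odds)
            a_ref = rng.binomial(depth, c0)
            a_test = rng.binomial(depth, c)
            f = fold_change_frame(a_ref, depth - a_ref, a_test, depth - a_test).iloc[0]
            pts.append((x, float(f.fc), (float(f.ci95_lo), float(f.ci95_hi))))
        res = ck.min_detectable_concentration(self._series(pts))
        assert res.min_concentration_um is not None
        assert x_star / 2 <= res.min_concentration_um <= x_star * 2
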