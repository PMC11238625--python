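import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from coabund import (
    ValidationError,
    build_consensus_profile,
    complete_partners,
    compute_zscores,
    euclidean_distance,
    rank_by_distance,
    select_candidates,
    select_threshold,
)
from coabund.matching import (
    REASON_MISSING_PROFILE,
    REASON_ZERO_VARIANCE,
    DistanceTable,
    SelectionResult,
    ZScoreMatrix,
)
from conftest import make_matrix
from naive import naive_euclid, naive_zscore_row


def zmatrix(values, protein_ids=None, excluded=None):
    """Construct a ZScoreMatrix directly (for consensus/median unit tests)."""
    values = np.asarray(values, dtype=float)
    ids = protein_ids or [f"P{i + 1}" for i in range(values.shape[0])]
    z = pd.DataFrame(values, index=ids, columns=[f"s{j + 1}" for j in range(values.shape[1])])
    return ZScoreMatrix(z=z, excluded=excluded or {})


def table_from(distances, reference_ids=()):
    """Build a ranked DistanceTable from a {protein_id: distance} dict."""
    items = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    frame = pd.DataFrame(
        {
            "protein_id": [k for k, _ in items],
            "distance": [v for _, v in items],
            "rank": np.arange(1, len(items) + 1),
            "is_reference": [k in set(reference_ids) for k, _ in items],
        }
    )
    return DistanceTable(frame=frame)


class TestComputeZscores:
    def test_known_row(self):
        """z of [1,2,3,4]: mean 2.5, sample sd sqrt(5/3)."""
        m = make_matrix([[1, 2, 3, 4], [2, 4, 8, 16]])
        z = compute_zscores(m)
        np.testing.assert_allclose(
            z.z.loc["P1"],
            [-1.161895, -0.387298, 0.387298, 1.161895],
            atol=1e-6,
        )

    def test_constant_row_excluded_zero_variance(self):
        m = make_matrix([[5, 5, 5, 5], [1, 2, 3, 4]])
        z = compute_zscores(m)
        assert z.excluded == {"P1": REASON_ZERO_VARIANCE}
        assert "P1" not in z.protein_ids

    def test_cell_at_row_mean_maps_to_zero(self):
        m = make_matrix([[1.0, 3.0, 2.0, 6.0]])  # mean 3 at s2
        z = compute_zscores(m)
        assert z.z.loc["P1", "s2"] == pytest.approx(0.0, abs=1e-12)

    def test_population_convention(self):
        m = make_matrix([[1, 2, 3, 4]])
        z = compute_zscores(m, sd_convention="population")
        sd_pop = np.std([1, 2, 3, 4])
        assert z.z.loc["P1", "s1"] == pytest.approx((1 - 2.5) / sd_pop)

    def test_missing_row_mu_sigma_over_present_samples(self):
        m = make_matrix([[1, np.nan, 3, 4], [1, 2, 3, 4]])
        z = compute_zscores(m, min_present_fraction=0.5)
        present = z.z.loc["P1"].dropna()
        assert present.mean() == pytest.approx(0.0, abs=1e-9)
        assert present.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_excess_missing_excluded(self):
        m = make_matrix([[1, np.nan, np.nan, np.nan], [1, 2, 3, 4]])
        z = compute_zscores(m, min_present_fraction=0.5)
        assert "P1" in z.excluded

    def test_log_transform_makes_nonpositive_missing(self):
        m = make_matrix([[0.0, 2, 4, 8], [1, 2, 3, 4]])
        z = compute_zscores(m, transform="log2", min_present_fraction=0.5)
        assert np.isnan(z.z.loc["P1", "s1"])

    def test_fewer_than_two_samples_is_error(self):
        values = pd.DataFrame(
            [[1.0]],
            index=pd.Index(["P1"], name="protein_id"),
            columns=["s1"],
        )
        from coabund import AbundanceMatrix, SampleDesign

        design = SampleDesign(
            pd.DataFrame(
                {"sample_id": ["s1", "s2"], "condition": ["c", "c"], "replicate": [1, 2]}
            )
        )
        with pytest.raises(ValidationError):
            m = AbundanceMatrix(values=values, design=design)

    def test_all_rows_excluded_is_error(self):
        m = make_matrix([[3, 3, 3, 3]])
        with pytest.raises(ValidationError, match="all rows"):
            compute_zscores(m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            (5, 8),
            elements=st.floats(0.1, 1e4, allow_nan=False),
        )
    )
    def test_retained_rows_standardised(self, arr):
        """Every retained row has mean 0 and sample sd 1 within 1e-9."""
        m = make_matrix(arr)
        try:
            z = compute_zscores(m)
        except ValidationError:
            return  # all rows degenerate; nothing to check
        means = z.z.mean(axis=1)
        sds = z.z.std(axis=1, ddof=1)
        np.testing.assert_allclose(means, 0.0, atol=1e-9)
        np.testing.assert_allclose(sds, 1.0, atol=1e-9)


class TestZscoreOracle:
    def test_matches_naive_recomputation(self):
        """Standardisation agrees with a pure-Python oracle on a random 50x18 matrix."""
        rng = np.random.default_rng(42)
        arr = rng.lognormal(3, 1, size=(50, 18))
        z = compute_zscores(make_matrix(arr))
        for i, pid in enumerate([f"P{k + 1}" for k in range(50)]):
            expected = naive_zscore_row(list(arr[i]))
            np.testing.assert_allclose(z.z.loc[pid], expected, atol=1e-9)


class TestConsensusProfile:
    def test_single_reference_equals_that_row(self):
        z = zmatrix([[0.3, -1.2, 0.9]])
        cons = build_consensus_profile(z, ["P1"])
        np.testing.assert_array_equal(cons.values, z.z.loc["P1"])

    def test_odd_count_median(self):
        z = zmatrix([[0.0], [1.0], [5.0]])
        cons = build_consensus_profile(z, ["P1", "P2", "P3"])
        assert cons.values.iloc[0] == 1.0

    def test_even_count_midpoint(self):
        z = zmatrix([[0.0], [1.0], [3.0], [10.0]])
        cons = build_consensus_profile(z, ["P1", "P2", "P3", "P4"])
        assert cons.values.iloc[0] == 2.0

    def test_empty_reference_set_is_error(self):
        z = zmatrix([[0.1, 0.2]])
        with pytest.raises(ValidationError, match="empty"):
            build_consensus_profile(z, [])

    def test_excluded_reference_is_error_naming_subunit(self):
        z = zmatrix([[0.1, 0.2]], excluded={"NUO9": REASON_ZERO_VARIANCE})
        with pytest.raises(ValidationError, match="NUO9"):
            build_consensus_profile(z, ["P1", "NUO9"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        hnp.arrays(float, (6, 10), elements=st.floats(-5, 5, allow_nan=False))
    )
    def test_consensus_bounded_by_reference_range(self, arr):
        z = zmatrix(arr)
        cons = build_consensus_profile(z, z.protein_ids)
        assert (cons.values >= arr.min(axis=0) - 1e-12).all()
        assert (cons.values <= arr.max(axis=0) + 1e-12).all()


class TestEuclideanDistance:
    def test_identical_vectors_zero(self):
        assert euclidean_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_3_4_5_triangle(self):
        assert euclidean_distance([0.0, 0.0], [3.0, 4.0]) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ValidationError, match="length"):
            euclidean_distance([1.0], [1.0, 2.0])

    def test_missing_values_rejected(self):
        with pytest.raises(ValidationError, match="missing"):
            euclidean_distance([np.nan, 1.0], [0.0, 1.0])

    vec = st.lists(st.floats(-50, 50, allow_nan=False), min_size=4, max_size=4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(vec, vec, vec)
    def test_metric_properties(self, x, y, z):
        """Non-negativity, symmetry, identity, triangle inequality."""
        dxy = euclidean_distance(x, y)
        assert dxy >= 0
        assert dxy == pytest.approx(euclidean_distance(y, x))
        assert euclidean_distance(x, x) == 0.0
        assert dxy <= euclidean_distance(x, z) + euclidean_distance(z, y) + 1e-9

    def test_matches_naive_on_random_profiles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x, y = rng.normal(size=(2, 18))
            assert euclidean_distance(x, y) == pytest.approx(
                naive_euclid(list(x), list(y)), abs=1e-9
            )


class TestRankByDistance:
    def test_ties_broken_by_protein_id(self):
        m = make_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1]], ["B", "A", "C"])
        z = compute_zscores(m)
        cons = build_consensus_profile(z, ["A"])
        table = rank_by_distance(z, cons, ["A"])
        assert list(table.frame["protein_id"]) == ["A", "B", "C"]
        assert list(table.frame["rank"]) == [1, 2, 3]

    def test_reference_rows_flagged(self):
        m = make_matrix([[1, 2, 3, 4], [4, 1, 2, 8]])
        z = compute_zscores(m)
        cons = build_consensus_profile(z, ["P1"])
        table = rank_by_distance(z, cons, ["P1"])
        flags = dict(zip(table.frame["protein_id"], table.frame["is_reference"]))
        assert flags == {"P1": True, "P2": False}

    def test_incomplete_profile_excluded(self):
        m = make_matrix([[1, 2, 3, 4], [1, np.nan, 3, 4]])
        z = compute_zscores(m, min_present_fraction=0.5)
        cons = build_consensus_profile(z, ["P1"])
        table = rank_by_distance(z, cons, ["P1"])
        assert table.excluded["P2"] == REASON_MISSING_PROFILE
        assert "P2" not in table

    def test_scale_shift_invariance(self):
        """a -> alpha*a + beta leaves the z row, distance and rank unchanged."""
        rng = np.random.default_rng(11)
        base = rng.lognormal(2, 0.5, size=(6, 12))
        m1 = make_matrix(base)
        transformed = base.copy()
        transformed[3] = 7.3 * transformed[3] + 11.0
        m2 = make_matrix(transformed)
        refs = ["P1", "P2"]
        t1 = rank_by_distance(
            compute_zscores(m1), build_consensus_profile(compute_zscores(m1), refs), refs
        )
        t2 = rank_by_distance(
            compute_zscores(m2), build_consensus_profile(compute_zscores(m2), refs), refs
        )
        f1 = t1.frame.set_index("protein_id")
        f2 = t2.frame.set_index("protein_id")
        assert f1.loc["P4", "distance"] == pytest.approx(f2.loc["P4", "distance"], abs=1e-9)
        assert (f1["rank"] == f2["rank"]).all()

    def test_added_noise_does_not_shrink_expected_distance(self):
        """Mean distance over seeds is non-decreasing in added profile noise."""
        rng = np.random.default_rng(5)
        base = rng.lognormal(2, 0.5, size=(5, 12))
        refs = ["P1", "P2", "P3"]

        def mean_distance(noise_sd, n_seeds=30):
            total = 0.0
            for seed in range(n_seeds):
                arr = base.copy()
                noise_rng = np.random.default_rng(100 + seed)
                arr[4] = arr[4] * np.exp(noise_rng.normal(0, noise_sd, 12))
                z = compute_zscores(make_matrix(arr))
                cons = build_consensus_profile(z, refs)
                t = rank_by_distance(z, cons, refs)
                total += t.distance_of("P5")
            return total / n_seeds

        d0, d1, d2 = mean_distance(0.0), mean_distance(0.5), mean_distance(1.5)
        assert d0 <= d1 + 1e-9
        assert d1 <= d2 + 0.05  # sampling slack at finite seeds


class TestThresholdAndSelection:
    def test_auto_threshold_is_max_reference_distance(self):
        table = table_from({"N1": 0.41, "N2": 0.91, "N3": 2.21, "X": 1.5}, ["N1", "N2", "N3"])
        assert select_threshold(table, ["N1", "N2", "N3"]) == 2.21

    def test_fixed_passes_value_through(self):
        table = table_from({"A": 1.0}, [])
        assert select_threshold(table, [], mode="fixed", fixed_value=2.22) == 2.22

    def test_fixed_without_value_is_error(self):
        table = table_from({"A": 1.0}, [])
        with pytest.raises(ValidationError):
            select_threshold(table, [], mode="fixed")

    def test_degenerate_single_reference_at_zero(self):
        table = table_from({"R": 0.0, "A": 0.0, "B": 0.1}, ["R"])
        thr = select_threshold(table, ["R"])
        assert thr == 0.0
        sel = select_candidates(table, thr, mode="auto")
        assert sel.selected_ids == ("A",)

    def test_auto_selection_inclusive(self):
        table = table_from({"A": 0.5, "B": 2.3, "R": 1.0}, ["R"])
        thr = select_threshold(table, ["R"])
        sel = select_candidates(table, thr, mode="auto")
        assert sel.selected_ids == ("A",)
        assert sel.reference_passing == ("R",)

    def test_fixed_selection_strict(self):
        """Fixed mode means literally 'distance smaller than' the cut-off."""
        table = table_from({"A": 2.21, "B": 2.22, "C": 2.30}, [])
        sel = select_candidates(table, 2.22, mode="fixed")
        assert sel.selected_ids == ("A",)

    def test_threshold_below_everything_gives_empty_selection(self):
        table = table_from({"A": 0.5, "R": 1.0}, ["R"])
        sel = select_candidates(table, 0.1, mode="fixed")
        assert sel.selected_ids == ()

    def test_include_reference_flag(self):
        table = table_from({"A": 0.5, "R": 1.0}, ["R"])
        sel = select_candidates(table, 1.0, mode="auto", include_reference=True)
        assert set(sel.selected_ids) == {"A", "R"}

    def test_auto_mode_admits_all_reference_subunits(self):
        rng = np.random.default_rng(8)
        dists = {f"N{i}": float(d) for i, d in enumerate(rng.uniform(0, 3, 10))}
        dists.update({f"X{i}": float(d) for i, d in enumerate(rng.uniform(0, 6, 30))})
        refs = [f"N{i}" for i in range(10)]
        table = table_from(dists, refs)
        thr = select_threshold(table, refs)
        sel = select_candidates(table, thr, mode="auto", include_reference=True)
        assert set(refs) <= set(sel.selected_ids)


class TestCompletePartners:
    def _selection(self, ids):
        return SelectionResult(threshold=2.21, mode="auto", selected_ids=tuple(ids))

    def test_partner_added_with_distance_and_trigger(self):
        table = table_from({"ACL20267": 2.07, "ACL20268": 2.45}, [])
        sel = complete_partners(self._selection(["ACL20267"]), table, [("ACL20267", "ACL20268")])
        (comp,) = sel.partner_completed
        assert comp.partner_id == "ACL20268"
        assert comp.trigger_id == "ACL20267"
        assert comp.distance == pytest.approx(2.45)
        assert sel.selected_ids == ("ACL20267",)

    def test_empty_map_is_identity(self):
        table = table_from({"A": 1.0}, [])
        sel = self._selection(["A"])
        assert complete_partners(sel, table, []) == sel

    def test_unselected_trigger_adds_nothing(self):
        table = table_from({"A": 1.0, "B": 2.0}, [])
        sel = complete_partners(self._selection(["X"]), table, [("A", "B")])
        assert sel.partner_completed == ()

    def test_partner_absent_from_table_skipped_with_warning(self, caplog):
        table = table_from({"A": 1.0}, [])
        with caplog.at_level("WARNING"):
            sel = complete_partners(self._selection(["A"]), table, [("A", "GHOST")])
        assert sel.partner_completed == ()
        assert "GHOST" in caplog.text

    def test_already_selected_partner_not_duplicated(self):
        table = table_from({"A": 1.0, "B": 1.5}, [])
        sel = complete_partners(self._selection(["A", "B"]), table, [("A", "B")])
        assert sel.partner_completed == ()
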