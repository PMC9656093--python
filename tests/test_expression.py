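"""Peak matching, spectral clustering, quantitation, series statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tagglyco.expression import (
    DEFAULT_IS_MZ,
    PeakMatch,
    aggregate_series,
    analyze_inputs,
    benjamini_hochberg,
    cluster_across_experiments,
    match_peaks,
    quantify,
    welch_p,
    zero_cut,
)
from tagglyco.glycans import GlycanList
from tagglyco.plate import CalibrationSpot, CategorySpot, Peak, PeakList, SpotInput


def peaklist(name, mzs, area=100.0):
    return PeakList(name, [Peak(mz, area) for mz in mzs])


class TestMatchPeaks:
    def test_single_candidate_within_tolerance(self, glycan_list):
        matches = match_peaks(peaklist("e1", [1362.50]), glycan_list, 0.2)
        assert len(matches) == 1
        texts = [c.composition_text for c in matches[0].candidates]
        assert texts == ["(Hex)2 + (Man)3(GlcNAc)2"]

    def test_unmatched_peak_dropped(self, glycan_list):
        assert match_peaks(peaklist("e1", [1000.0]), glycan_list, 0.2) == []

    def test_isobaric_candidates_both_kept(self, glycan_list):
        """A hexose-rich and a GlcA-bearing composition 0.074 Da apart share
        one observed peak; neither is arbitrated away."""
        matches = match_peaks(peaklist("e1", [2010.73]), glycan_list, 0.2)
        texts = {c.composition_text for c in matches[0].candidates}
        assert "(Hex)6 + (Man)3(GlcNAc)2" in texts
        assert "(HexNAc)3 (Fuc)1 (GlcA)1 + (Man)3(GlcNAc)2" in texts

    def test_all_deltas_within_tolerance(self, glycan_list):
        matches = match_peaks(peaklist("e1", [1362.5, 2010.73, 2432.93]),
                              glycan_list, 0.2)
        for m in matches:
            assert all(abs(d) <= 0.2 for d in m.deltas)

    def test_empty_list_is_error(self, registry):
        with pytest.raises(ValueError, match="empty"):
            match_peaks(peaklist("e1", [1362.5]), GlycanList([], "x", "y"), 0.2)

    @given(st.lists(st.floats(1300, 3300), min_size=1, max_size=20),
           st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_tolerance_monotonicity(self, glycan_list, mzs, t1, t2):
        """Candidate sets can only grow with the tolerance."""
        lo, hi = sorted((t1, t2))
        small = {m.observed_mz: {c.composition_id for c in m.candidates}
                 for m in match_peaks(peaklist("e", mzs), glycan_list, lo)}
        big = {m.observed_mz: {c.composition_id for c in m.candidates}
               for m in match_peaks(peaklist("e", mzs), glycan_list, hi)}
        for mz, cands in small.items():
            assert cands <= big[mz]

    def test_matches_equal_brute_force_all_pairs(self, glycan_list):
        """Oracle: direct all-pairs |delta| <= tolerance scan."""
        rng = np.random.default_rng(7)
        entries = glycan_list.entries
        for _ in range(5):
            mzs = rng.uniform(1300, 3300, size=15)
            tol = float(rng.uniform(0.05, 0.4))
            got = {round(m.observed_mz, 6): {c.composition_id for c in m.candidates}
                   for m in match_peaks(peaklist("e", mzs), glycan_list, tol)}
            want = {}
            for mz in mzs:
                cands = {e.composition_id for e in entries
                         if abs(mz - e.theoretical_mz) <= tol}
                if cands:
                    want[round(float(mz), 6)] = cands
            assert got == want


def pm(exp, mz):
    return PeakMatch(exp, mz, 100.0, [], [])


class TestClustering:
    def test_replicate_peaks_merge_with_arithmetic_mean(self):
        clusters = cluster_across_experiments(
            [pm("a", 1362.48), pm("b", 1362.52), pm("c", 1362.50)], 0.2)
        assert len(clusters) == 1
        assert clusters[0].mean_observed_mz == pytest.approx(1362.50)
        assert set(clusters[0].members) == {"a", "b", "c"}

    def test_distant_peaks_stay_separate(self):
        clusters = cluster_across_experiments([pm("a", 1362.5), pm("a", 1735.7)], 0.2)
        assert len(clusters) == 2

    def test_ids_dense_ascending_mean(self):
        clusters = cluster_across_experiments(
            [pm("a", 2000.0), pm("a", 1362.5), pm("b", 1362.5)], 0.2)
        assert [c.spectral_id for c in clusters] == [1, 2]
        assert clusters[0].mean_observed_mz < clusters[1].mean_observed_mz

    def test_same_experiment_twice_seeds_new_cluster(self):
        clusters = cluster_across_experiments(
            [pm("a", 1362.48), pm("a", 1362.52), pm("b", 1362.50)], 0.2)
        assert len(clusters) == 2
        assert sum(len(c.members) for c in clusters) == 3

    def test_matched_peak_count_conserved(self):
        rng = np.random.default_rng(11)
        matches = [pm(f"e{i%4}", float(rng.uniform(1000, 1010)))
                   for i in range(40)]
        clusters = cluster_across_experiments(matches, 0.2)
        assert sum(len(c.members) for c in clusters) == len(matches)

    def test_cluster_span_bounded_by_twice_tolerance(self):
        rng = np.random.default_rng(13)
        matches = [pm(f"e{i}", float(rng.uniform(1000, 1002))) for i in range(60)]
        for c in cluster_across_experiments(matches, 0.2):
            mzs = [m.observed_mz for m in c.members.values()]
            assert max(mzs) - min(mzs) <= 2 * 0.2 + 1e-12

    def test_matches_connected_components_oracle(self):
        """On inputs whose components are tight (span <= tolerance) and hold
        at most one peak per experiment, clusters = connected components of
        the |dm/z| <= tolerance graph (union-find oracle)."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            k = int(rng.integers(2, 7))
            centers = np.sort(rng.uniform(1000, 3000, size=k))
            centers = centers[np.diff(centers, prepend=0) > 1.0]
            matches = []
            for ci, c in enumerate(centers):
                for e in range(int(rng.integers(1, 5))):
                    matches.append(pm(f"e{e}", float(c + rng.uniform(-0.1, 0.1))))
            tol = 0.2
            # union-find oracle over the threshold graph
            parent = list(range(len(matches)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(matches)):
                for j in range(i + 1, len(matches)):
                    if abs(matches[i].observed_mz - matches[j].observed_mz) <= tol:
                        parent[find(i)] = find(j)
            n_components = len({find(i) for i in range(len(matches))})
            clusters = cluster_across_experiments(matches, tol)
            assert len(clusters) == n_components


class TestQuantify:
    def test_ratio_rule(self):
        assert quantify(1000.0, 500.0, 20.0) == pytest.approx(40.0)
        assert quantify(0.0, 500.0, 20.0) == 0.0

    def test_scale_invariance(self):
        assert quantify(1000.0, 500.0, 20.0) == pytest.approx(
            quantify(2000.0, 1000.0, 20.0))

    def test_invalid_standard_rejected(self):
        with pytest.raises(ValueError):
            quantify(1.0, 0.0, 20.0)
        with pytest.raises(ValueError):
            quantify(1.0, 1.0, -1.0)


class TestSeriesStats:
    def test_mean_sd_cv_closed_form(self, glycan_list):
        inputs = []
        for i, area in enumerate([100.0, 200.0]):
            inputs.append(SpotInput(f"e{i}", f"A{i+1}", CategorySpot(1, "s"),
                                    {"is_pmol": 20.0, "tolerance_da": 0.2},
                                    [Peak(1362.48, area), Peak(DEFAULT_IS_MZ, 1000.0)]))
        table = analyze_inputs(inputs, glycan_list)
        df = aggregate_series(table)
        row = df.iloc[0]
        # amounts are 2 and 4 pmol
        assert row["mean:s"] == pytest.approx(3.0)
        assert row["sd:s"] == pytest.approx(math.sqrt(2), abs=1e-4)
        assert row["cv%:s"] == pytest.approx(100 * math.sqrt(2) / 3, abs=1e-2)

    def test_hand_computed_sample_sd(self):
        vals = np.array([10.0, 20.0, 30.0])
        assert vals.std(ddof=1) == pytest.approx(10.0)
        assert 100 * vals.std(ddof=1) / vals.mean() == pytest.approx(50.0)

    def test_single_experiment_series_has_nan_sd(self, glycan_list):
        inputs = [SpotInput("e0", "A1", CategorySpot(1, "only"),
                            {"is_pmol": 20.0},
                            [Peak(1362.48, 100.0), Peak(DEFAULT_IS_MZ, 1000.0)])]
        df = aggregate_series(analyze_inputs(inputs, glycan_list))
        assert math.isnan(df.iloc[0]["sd:only"])


class TestWelch:
    def test_identical_series_p_one(self):
        assert welch_p([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_clearly_different_series(self):
        p = welch_p([0, 0, 0, 0], [10, 10.1, 9.9, 10.2])
        assert p < 0.001
        # oracle: Welch statistic + t CDF by hand
        a = np.array([0, 0, 0, 0.0])
        b = np.array([10, 10.1, 9.9, 10.2])
        se = math.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        t = (a.mean() - b.mean()) / se
        nu = (a.var(ddof=1) / 4 + b.var(ddof=1) / 4) ** 2 / (
            (a.var(ddof=1) / 4) ** 2 / 3 + (b.var(ddof=1) / 4) ** 2 / 3)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t), nu), rel=1e-9)

    def test_symmetric_in_arguments(self):
        a, b = [1.0, 2, 3], [2.0, 4, 6]
        assert welch_p(a, b) == pytest.approx(welch_p(b, a))

    def test_bh_adjustment_monotone_capped(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.9, 0.04])
        assert (np.diff(adj[np.argsort([0.01, 0.02, 0.9, 0.04])]) >= -1e-12).all()
        assert (adj <= 1.0).all()


class TestAnalyzePipeline:
    def _inputs(self, areas, is_area=1000.0, label="s"):
        out = []
        for i, area in enumerate(areas):
            peaks = [Peak(DEFAULT_IS_MZ, is_area)]
            if area is not None:
                peaks.append(Peak(1362.48, area))
            out.append(SpotInput(f"e{i}", f"A{i+1}", CategorySpot(1, label),
                                 {"is_pmol": 20.0, "tolerance_da": 0.2}, peaks))
        return out

    def test_absent_peak_is_zero_not_missing(self, glycan_list):
        table = analyze_inputs(self._inputs([100.0, None]), glycan_list)
        assert table.amounts("e1").iloc[0] == 0.0

    def test_missing_internal_standard_flags_experiment(self, glycan_list):
        inputs = self._inputs([100.0, 100.0])
        inputs[1] = SpotInput("e1", "A2", CategorySpot(1, "s"),
                              {"is_pmol": 20.0, "tolerance_da": 0.2},
                              [Peak(1362.48, 100.0)])  # no IS peak
        table = analyze_inputs(inputs, glycan_list)
        assert table.invalid_experiments == ["e1"]
        assert math.isnan(table.amounts("e1").iloc[0])
        assert table.amounts("e0").iloc[0] == pytest.approx(2.0)

    def test_internal_standard_peak_not_annotated(self, glycan_list):
        inputs = self._inputs([None])
        table = analyze_inputs(inputs, glycan_list)
        assert len(table.data) == 0

    def test_zero_cut_drops_all_zero_rows_idempotently(self, glycan_list):
        inputs = self._inputs([100.0, None])
        # second glycan present in neither experiment never appears at all,
        # so build a row that is zero everywhere via a peak in no experiment
        table = analyze_inputs(inputs, glycan_list)
        df = table.data.copy()
        zero_row = df.iloc[[0]].copy()
        zero_row[[c for c in df.columns if c.startswith("pmol:")]] = 0.0
        df2 = pd.concat([df, zero_row], ignore_index=True)
        cut = zero_cut(df2)
        assert len(cut) == len(df2) - 1
        assert zero_cut(cut).equals(cut)
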