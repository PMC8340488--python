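import numpy as np
import pandas as pd
import pytest

from sporesig import synthetic
from sporesig.metagenome import (
    CoverageSummary,
    MappingSummary,
    abundance_compare,
    aitchison_contribution,
    calibrate,
    call_presence,
    permutation_equalized,
    prevalence,
    rpkm,
    summarize_coverage,
)

from oracles import aitchison_contributions_naive, equalized_fraction_exhaustive


def _summary(breadth, cv, genome="g", sample="s"):
    return CoverageSummary(genome, sample, breadth, 1.0 if breadth else 0.0, cv)


class TestCoverageSummary:
    def test_uniform_depth(self):
        s = summarize_coverage(np.full(100, 5))
        assert s.breadth == 1.0
        assert s.mean_depth == 5.0
        assert s.depth_cv == 0.0

    def test_all_zeros(self):
        s = summarize_coverage(np.zeros(50))
        assert s.breadth == 0.0
        assert s.mean_depth == 0.0

    def test_matches_naive_loop(self, rng):
        vec = rng.poisson(2, size=300)
        s = summarize_coverage(vec)
        covered = [d for d in vec if d >= 1]
        assert s.breadth == pytest.approx(len(covered) / 300)
        assert s.mean_depth == pytest.approx(np.mean(covered))
        assert s.depth_cv == pytest.approx(np.std(covered) / np.mean(covered))

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            summarize_coverage(np.array([]))


class TestCalibration:
    def test_constant_cv_gives_constant_threshold(self):
        summaries = [_summary(0.6 + 0.01 * (i % 40), 0.5) for i in range(200)]
        calib = calibrate(summaries)
        assert np.allclose(calib.cv_thresholds, 0.5)

    def test_outlier_capped_by_percentile(self, rng):
        # 100 points in one bin, one extreme outlier: the 99th percentile
        # stays far below the outlier
        cvs = list(rng.uniform(0.2, 0.4, size=99)) + [10.0]
        summaries = [_summary(0.905, cv) for cv in cvs]
        calib = calibrate(summaries)
        assert calib.threshold_for(0.905) < 2.0
        assert calib.threshold_for(0.905) == pytest.approx(
            np.percentile(cvs, 99), abs=1e-12
        )

    def test_thresholds_equal_bruteforce_percentile_per_bin(self, rng):
        breadths = rng.uniform(0.6, 1.0, size=500)
        cvs = rng.uniform(0, 1, size=500)
        summaries = [_summary(b, c) for b, c in zip(breadths, cvs)]
        calib = calibrate(summaries)
        for i in range(40):
            lo, hi = 0.60 + 0.01 * i, 0.60 + 0.01 * (i + 1)
            members = [
                c
                for b, c in zip(breadths, cvs)
                if (lo <= b < hi) or (i == 39 and b >= lo)
            ]
            if members:
                assert calib.cv_thresholds[i] == pytest.approx(
                    np.percentile(members, 99), abs=1e-12
                )

    def test_empty_bins_inherit_nearest(self):
        summaries = [_summary(0.605, 0.3)] * 120 + [_summary(0.995, 0.7)] * 120
        calib = calibrate(summaries)
        assert calib.threshold_for(0.62) == pytest.approx(0.3)
        assert calib.threshold_for(0.97) == pytest.approx(0.7)

    def test_no_usable_summaries_rejected(self):
        with pytest.raises(ValueError):
            calibrate([_summary(0.5, 0.1)])


class TestPresenceRule:
    @pytest.fixture()
    def calib(self):
        return calibrate([_summary(0.6 + 0.399 * (i / 199), 0.5) for i in range(200)])

    def test_breadth_below_cutoff_never_present(self, calib):
        assert not call_presence(_summary(0.59, 0.0), calib)

    def test_breadth_above_with_low_cv_present(self, calib):
        assert call_presence(_summary(0.61, 0.1), calib)

    def test_cv_above_threshold_absent(self, calib):
        assert not call_presence(_summary(0.61, 0.9), calib)

    def test_monotone_in_breadth_at_fixed_cv(self, calib):
        calls = [
            call_presence(_summary(b, 0.2), calib)
            for b in np.linspace(0.0, 1.0, 101)
        ]
        # once present, stays present as breadth grows
        first_true = calls.index(True)
        assert all(calls[first_true:])


class TestRpkm:
    def test_unit_case(self):
        assert rpkm(MappingSummary("g", "s", 100, 1.0, 1_000_000)) == pytest.approx(100.0)

    def test_hand_evaluated_case(self):
        assert rpkm(MappingSummary("g", "s", 500, 2000.0, 10_000_000)) == pytest.approx(
            0.025
        )

    def test_zero_reads_zero_rpkm(self):
        assert rpkm(MappingSummary("g", "s", 0, 5.0, 1000)) == 0.0

    def test_scaling_properties(self):
        base = rpkm(MappingSummary("g", "s", 100, 10.0, 10_000))
        doubled_trc = rpkm(MappingSummary("g", "s", 100, 10.0, 20_000))
        assert doubled_trc == pytest.approx(base / 2)
        joint = rpkm(MappingSummary("g", "s", 300, 10.0, 30_000))
        assert joint == pytest.approx(rpkm(MappingSummary("g", "s", 100, 10.0, 10_000)))
        half_gl = rpkm(MappingSummary("g", "s", 100, 5.0, 10_000))
        assert half_gl == pytest.approx(2 * base)

    def test_zero_trc_rejected(self):
        with pytest.raises(ValueError):
            rpkm(MappingSummary("g", "s", 0, 1.0, 0))


def _species_calls(n_sf, n_fsf):
    return pd.DataFrame(
        {
            "genome_id": [f"sf{i}" for i in range(n_sf)]
            + [f"fsf{i}" for i in range(n_fsf)],
            "sporulation_class": ["SF"] * n_sf + ["FSF"] * n_fsf,
        }
    )


class TestPrevalenceAbundance:
    def test_species_present_everywhere(self):
        calls = _species_calls(1, 1)
        presence = pd.DataFrame(
            [[True] * 4, [False] * 4],
            index=["sf0", "fsf0"],
            columns=[f"s{i}" for i in range(4)],
        )
        df, _ = prevalence(presence, calls)
        out = df.set_index("genome_id")
        assert out.loc["sf0", "prevalence"] == 1.0
        assert out.loc["fsf0", "prevalence"] == 0.0

    def test_identical_prevalences_p_near_one(self, rng):
        calls = _species_calls(10, 10)
        mat = np.tile(rng.random(30) < 0.5, (20, 1))
        presence = pd.DataFrame(
            mat, index=calls["genome_id"], columns=[f"s{i}" for i in range(30)]
        )
        _, test = prevalence(presence, calls)
        assert test.p_value > 0.9

    def test_strictly_more_than_min_samples_retained(self):
        calls = _species_calls(2, 2)
        samples = [f"s{i}" for i in range(30)]
        presence = pd.DataFrame(False, index=calls["genome_id"], columns=samples)
        presence.iloc[0, :10] = True  # exactly 10 -> excluded
        presence.iloc[1, :11] = True  # 11 -> kept
        presence.iloc[2, :15] = True
        presence.iloc[3, :20] = True
        rpkm_matrix = pd.DataFrame(
            1.0, index=calls["genome_id"], columns=samples
        )
        df, _ = abundance_compare(rpkm_matrix, presence, calls, min_samples=10)
        assert "sf0" not in set(df["genome_id"])
        assert "sf1" in set(df["genome_id"])

    def test_median_rpkm_over_present_samples_only(self):
        calls = _species_calls(1, 1)
        samples = [f"s{i}" for i in range(12)]
        presence = pd.DataFrame(True, index=calls["genome_id"], columns=samples)
        presence.loc["sf0", samples[6:]] = False
        presence.loc["sf0", samples[:6]] = True
        presence.loc["fsf0"] = True
        rpkm_matrix = pd.DataFrame(0.0, index=calls["genome_id"], columns=samples)
        rpkm_matrix.loc["sf0", samples[:6]] = [1, 2, 3, 4, 5, 6]
        rpkm_matrix.loc["sf0", samples[6:]] = 99.0  # absent samples must be ignored
        rpkm_matrix.loc["fsf0"] = 2.0
        presence.loc["sf0"] = [True] * 6 + [False] * 6
        df, _ = abundance_compare(rpkm_matrix, presence, calls, min_samples=5)
        out = df.set_index("genome_id")
        assert out.loc["sf0", "median_rpkm"] == pytest.approx(3.5)

    def test_all_filtered_rejected(self):
        calls = _species_calls(1, 1)
        presence = pd.DataFrame(
            False, index=calls["genome_id"], columns=["s0", "s1"]
        )
        rpkm_matrix = pd.DataFrame(0.0, index=presence.index, columns=presence.columns)
        with pytest.raises(ValueError):
            abundance_compare(rpkm_matrix, presence, calls)


class TestPermutation:
    def test_all_sf_above_fsf_gives_one(self):
        calls = _species_calls(10, 5)
        prev = pd.Series(
            list(np.linspace(0.8, 0.9, 10)) + list(np.linspace(0.1, 0.2, 5)),
            index=calls["genome_id"],
        )
        assert permutation_equalized(prev, calls, n_perm=200, seed=1) == 1.0

    def test_seed_reproducible(self):
        calls = _species_calls(12, 6)
        rng = np.random.default_rng(5)
        prev = pd.Series(rng.random(18), index=calls["genome_id"])
        a = permutation_equalized(prev, calls, n_perm=500, seed=99)
        b = permutation_equalized(prev, calls, n_perm=500, seed=99)
        assert a == b

    def test_converges_to_exhaustive_enumeration(self):
        # C(9, 4) = 126 subsets: exact fraction computable
        calls = _species_calls(9, 4)
        rng = np.random.default_rng(13)
        prev = pd.Series(rng.random(13), index=calls["genome_id"])
        exact = equalized_fraction_exhaustive(prev.iloc[:9], prev.iloc[9:])
        approx = permutation_equalized(prev, calls, n_perm=1000, seed=3)
        assert abs(approx - exact) <= 0.03

    def test_more_fsf_than_sf_rejected(self):
        calls = _species_calls(2, 5)
        prev = pd.Series(np.linspace(0, 1, 7), index=calls["genome_id"])
        with pytest.raises(ValueError):
            permutation_equalized(prev, calls)


class TestAitchison:
    def test_duplicate_samples_no_diversity(self):
        calls = _species_calls(2, 2)
        mat = pd.DataFrame(
            np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 3)),
            index=calls["genome_id"],
            columns=["s0", "s1", "s2"],
        )
        with pytest.raises(ValueError, match="identical"):
            aitchison_contribution(mat, calls)

    def test_clr_scale_invariance(self, rng):
        calls = _species_calls(3, 3)
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(6, 5)),
            index=calls["genome_id"],
            columns=[f"s{i}" for i in range(5)],
        )
        base = aitchison_contribution(mat, calls)
        scaled = mat.copy()
        scaled["s0"] *= 10.0  # per-sample scaling must not change shares
        out = aitchison_contribution(scaled, calls)
        np.testing.assert_allclose(
            base["contribution"].to_numpy(), out["contribution"].to_numpy(), atol=1e-12
        )

    def test_matches_naive_double_loop(self, rng):
        calls = _species_calls(2, 2)
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(4, 3)),
            index=calls["genome_id"],
            columns=["s0", "s1", "s2"],
        )
        out = aitchison_contribution(mat, calls)
        expected = aitchison_contributions_naive(mat.to_numpy())
        np.testing.assert_allclose(out["contribution"].to_numpy(), expected, atol=1e-12)

    def test_shares_sum_to_one(self, rng):
        calls = _species_calls(5, 5)
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(10, 6)),
            index=calls["genome_id"],
            columns=[f"s{i}" for i in range(6)],
        )
        out = aitchison_contribution(mat, calls)
        assert (out["contribution"] >= 0).all()
        assert out["contribution"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_dead_species_dropped_with_warning(self, rng):
        calls = _species_calls(2, 2)
        mat = pd.DataFrame(
            rng.lognormal(0, 1, size=(4, 3)),
            index=calls["genome_id"],
            columns=["s0", "s1", "s2"],
        )
        mat.loc["fsf1"] = 0.0
        with pytest.warns(UserWarning, match="absent everywhere"):
            out = aitchison_contribution(mat, calls)
        assert "fsf1" not in set(out["genome_id"])


class TestGeneratorRecovery:
    def test_planted_directions_recovered(self):
        classes = {f"sf{i}": "SF" for i in range(25)}
        classes.update({f"fsf{i}": "FSF" for i in range(25)})
        meta = synthetic.make_metagenomes(
            classes, n_samples=120, genome_length=1500, seed=42
        )
        calib = calibrate(meta.summaries)
        species = sorted(classes)
        samples = sorted({s.sample_id for s in meta.summaries})
        presence = pd.DataFrame(False, index=species, columns=samples)
        for s in meta.summaries:
            presence.loc[s.genome_id, s.sample_id] = call_presence(s, calib)
        calls = pd.DataFrame(
            {"genome_id": species, "sporulation_class": [classes[s] for s in species]}
        )
        prev_df, prev_test = prevalence(presence, calls)
        sf_med = prev_df.query("sporulation_class == 'SF'")["prevalence"].median()
        fsf_med = prev_df.query("sporulation_class == 'FSF'")["prevalence"].median()
        assert sf_med > fsf_med  # planted direction: SF more prevalent
        assert prev_test.p_value < 0.01

        meta.mapping["rpkm"] = [
            rpkm(MappingSummary(r.genome_id, r.sample_id, int(r.rs), float(r.gl_kb), int(r.trc)))
            for r in meta.mapping.itertuples()
        ]
        rpkm_matrix = meta.mapping.pivot(
            index="genome_id", columns="sample_id", values="rpkm"
        ).loc[species, samples]
        abund_df, abund_test = abundance_compare(rpkm_matrix, presence, calls)
        sf_ab = abund_df.query("sporulation_class == 'SF'")["median_rpkm"].median()
        fsf_ab = abund_df.query("sporulation_class == 'FSF'")["median_rpkm"].median()
        assert fsf_ab > sf_ab  # planted direction: FSF more abundant
        assert abund_test.p_value < 0.01
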