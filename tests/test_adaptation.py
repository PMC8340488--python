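import numpy as np
import pandas as pd
import pytest

from sporesig import synthetic
from sporesig.adaptation import (
    cazyme_family,
    cazyme_filter,
    cazyme_summary,
    class_comparison,
    domain_enrichment,
    enrichment_frame,
    genome_feature_compare,
    known_function_fraction,
    paralog_percent,
    pool_replicates,
    substrate_comparison,
)
from sporesig.types import HomologyHit

from oracles import fisher_p_enumeration, hochberg_by_definition


def _calls(n_sf, n_fsf):
    return pd.DataFrame(
        {
            "genome_id": [f"sf{i}" for i in range(n_sf)]
            + [f"fsf{i}" for i in range(n_fsf)],
            "sporulation_class": ["SF"] * n_sf + ["FSF"] * n_fsf,
        }
    )


class TestDomainEnrichment:
    def test_all_sf_no_fsf_domain_is_sf_enriched(self):
        calls = _calls(10, 10)
        ann = pd.DataFrame(
            {"genome_id": [f"sf{i}" for i in range(10)], "domain_id": "D1"}
        )
        results = [r for r in domain_enrichment(ann, calls) if r.group == "SF"]
        (r,) = results
        expected = float(fisher_p_enumeration(10, 0, 0, 10, "greater"))
        assert r.p_raw == pytest.approx(expected, abs=1e-12)
        assert r.enriched  # single domain: adjusted == raw < 0.05

    def test_equal_fractions_not_enriched(self):
        calls = _calls(10, 10)
        ann = pd.DataFrame(
            {
                "genome_id": [f"sf{i}" for i in range(5)]
                + [f"fsf{i}" for i in range(5)],
                "domain_id": "D1",
            }
        )
        for r in domain_enrichment(ann, calls):
            assert not r.enriched

    def test_hochberg_adjustment_matches_definition(self, rng):
        calls = _calls(8, 8)
        rows = []
        for d in range(6):
            for g in calls["genome_id"]:
                if rng.random() < 0.5:
                    rows.append({"genome_id": g, "domain_id": f"D{d}"})
        results = domain_enrichment(pd.DataFrame(rows), calls)
        for group in ("SF", "FSF"):
            sub = [r for r in results if r.group == group]
            adj = hochberg_by_definition([r.p_raw for r in sub])
            assert [r.p_adjusted for r in sub] == pytest.approx(list(adj), abs=1e-12)

    def test_planted_enriched_domains_recovered(self):
        sf = [f"sf{i}" for i in range(50)]
        fsf = [f"fsf{i}" for i in range(50)]
        recovered = []
        for seed in range(20):
            ann, _, truth = synthetic.make_domain_tables(
                sf, fsf, n_domains=200, n_enriched_per_group=30, seed=seed
            )
            calls = pd.DataFrame(
                {"genome_id": sf + fsf, "sporulation_class": ["SF"] * 50 + ["FSF"] * 50}
            )
            df = enrichment_frame(domain_enrichment(ann, calls))
            hits_sf = set(df.query("group == 'SF' and enriched")["domain_id"])
            recovered.append(len(hits_sf & set(truth["enriched_sf"])))
        assert np.mean(recovered) >= 27  # >= 90% of 30 planted, 20-seed average


class TestClassComparison:
    def test_absent_class_p_one(self):
        cmp = class_comparison(
            ["a", "b"], ["c", "d"], {"a": "X", "b": "X", "c": "X", "d": "X"}
        ).set_index("functional_class")
        assert cmp.loc["X", "p_value"] == pytest.approx(1.0)

    def test_known_function_fractions_from_set_sizes(self):
        # enriched sets of the published size with the published known counts
        sf = [f"s{i}" for i in range(489)]
        fsf = [f"f{i}" for i in range(272)]
        class_map = {d: "known" for d in sf[:450]}
        class_map.update({d: None for d in sf[450:]})
        class_map.update({d: "known" for d in fsf[:225]})
        class_map.update({d: None for d in fsf[225:]})
        assert round(100 * known_function_fraction(fsf, class_map)) == 83
        assert round(100 * known_function_fraction(sf, class_map)) == 92

    def test_four_class_fixture_matches_enumeration(self):
        sf = ["a1", "a2", "b1", "c1"]
        fsf = ["a3", "b2", "b3", "d1"]
        class_map = {
            "a1": "A", "a2": "A", "a3": "A",
            "b1": "B", "b2": "B", "b3": "B",
            "c1": "C", "d1": "D",
        }
        cmp = class_comparison(sf, fsf, class_map).set_index("functional_class")
        for cls in "ABCD":
            a = sum(1 for d in sf if class_map[d] == cls)
            b = sum(1 for d in fsf if class_map[d] == cls)
            expected = float(
                fisher_p_enumeration(a, b, len(sf) - a, len(fsf) - b, "two-sided")
            )
            assert cmp.loc[cls, "p_value"] == pytest.approx(expected, abs=1e-9)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            class_comparison([], ["x"], {})


class TestParalogs:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ({"A": 3, "B": 1}, 50.0),
            ({"A": 1, "B": 1, "C": 1}, 0.0),
            ({"A": 2, "B": 2}, 50.0),
        ],
    )
    def test_excess_copy_definition(self, counts, expected):
        assert paralog_percent(counts) == pytest.approx(expected)

    def test_multicopy_domain_mode(self):
        # 1 of 2 distinct domains is multi-copy
        assert paralog_percent({"A": 3, "B": 1}, mode="multicopy_domains") == 50.0

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            paralog_percent({})


def _caz_hit(fam="GH13", aln=100, e=1e-6, cov=0.5, genome="g1"):
    return HomologyHit(f"{fam}.hmm", genome, 0.0, aln, e, cov)


class TestCazymeFilter:
    @pytest.mark.parametrize(
        "aln, e, cov, kept",
        [
            (100, 1e-6, None, True),  # strict clause
            (90, 5e-4, 0.35, True),  # relaxed clause
            (80, 1e-9, 0.9, False),  # alignment not > 80
            (100, 5e-4, 0.2, False),  # relaxed clause coverage fails
            (100, 5e-3, 0.9, False),  # both e-value clauses fail
        ],
    )
    def test_filter_rules(self, aln, e, cov, kept):
        hits = [_caz_hit(aln=aln, e=e, cov=cov)]
        assert (len(cazyme_filter(hits)) == 1) is kept

    def test_excluded_families_dropped(self):
        hits = [_caz_hit(fam=f) for f in ("AA3", "GT2", "CE10", "CE1", "GH5", "PL9")]
        kept = {cazyme_family(h.query_id) for h in cazyme_filter(hits)}
        assert kept == {"CE1", "GH5", "PL9"}

    def test_missing_coverage_fails_relaxed_clause(self):
        with pytest.warns(UserWarning, match="hmm_coverage"):
            assert cazyme_filter([_caz_hit(e=5e-4, cov=None)]) == []

    def test_idempotent(self, rng):
        hits = [
            _caz_hit(
                fam=rng.choice(["GH1", "AA2", "CE10", "PL5"]),
                aln=int(rng.integers(60, 200)),
                e=float(10.0 ** -rng.uniform(2, 8)),
                cov=float(rng.uniform(0, 1)),
            )
            for _ in range(50)
        ]
        once = cazyme_filter(hits)
        assert cazyme_filter(once) == once

    def test_family_label_parsing(self):
        assert cazyme_family("GH13_31.hmm") == "GH13"
        assert cazyme_family("PL1.hmm") == "PL1"
        assert cazyme_family("CBM20") == "CBM20"


class TestCazymeSummary:
    def test_counts_and_welch(self):
        calls = _calls(2, 2)
        hits = (
            [_caz_hit(genome="sf0", fam=f) for f in ("GH1", "GH2", "GH2")]
            + [_caz_hit(genome="sf1", fam=f) for f in ("GH1", "PL1", "CE1", "CE2")]
            + [_caz_hit(genome="fsf0", fam="GH1")]
            + [_caz_hit(genome="fsf1", fam="GH3")]
        )
        profiles, tests = cazyme_summary(hits, calls)
        prof = profiles.set_index("genome_id")
        assert prof.loc["sf0", "total_cazymes"] == 3
        assert prof.loc["sf0", "n_families"] == 2
        assert prof.loc["fsf1", "total_cazymes"] == 1
        assert (profiles["n_families"] <= profiles["total_cazymes"] + (profiles["total_cazymes"] == 0)).all()
        assert "total_cazymes" in tests

    def test_identical_groups_p_one(self):
        calls = _calls(2, 2)
        hits = [_caz_hit(genome=g, fam="GH1") for g in calls["genome_id"]]
        _, tests = cazyme_summary(hits, calls)
        assert tests["total_cazymes"].p_value == pytest.approx(1.0)

    def test_planted_group_difference_detected(self):
        sig = 0
        for seed in range(20):
            classes = {f"sf{i}": "SF" for i in range(30)}
            classes.update({f"fsf{i}": "FSF" for i in range(30)})
            hits, _ = synthetic.make_cazyme_hits(classes, seed=seed)
            calls = pd.DataFrame(
                {
                    "genome_id": list(classes),
                    "sporulation_class": list(classes.values()),
                }
            )
            _, tests = cazyme_summary(cazyme_filter(hits), calls)
            if tests["total_cazymes"].p_value < 1e-6:
                sig += 1
        assert sig == 20


class TestSubstrates:
    def test_all_sf_vs_none_gives_one_in_35(self):
        growth = pd.DataFrame(
            {f"sf{i}": [True] for i in range(4)} | {f"fsf{i}": [False] for i in range(4)},
            index=["glycerol"],
        )
        classes = {f"sf{i}": "SF" for i in range(4)} | {
            f"fsf{i}": "FSF" for i in range(4)
        }
        out = substrate_comparison(growth, classes)
        assert out["p_value"].iloc[0] == pytest.approx(1 / 35, abs=1e-9)

    def test_grown_by_all_p_one(self):
        growth = pd.DataFrame(
            {c: [True] for c in ("sf0", "sf1", "fsf0", "fsf1")}, index=["maltose"]
        )
        classes = {"sf0": "SF", "sf1": "SF", "fsf0": "FSF", "fsf1": "FSF"}
        assert substrate_comparison(growth, classes)["p_value"].iloc[0] == pytest.approx(1.0)

    def test_fixture_matches_enumeration(self, rng):
        isolates = [f"sf{i}" for i in range(4)] + [f"fsf{i}" for i in range(4)]
        classes = {i: ("SF" if i.startswith("sf") else "FSF") for i in isolates}
        growth = pd.DataFrame(
            rng.random((10, 8)) < 0.5, index=[f"s{i}" for i in range(10)], columns=isolates
        )
        out = substrate_comparison(growth, classes).set_index("substrate")
        for s in growth.index:
            a = int(growth.loc[s, isolates[:4]].sum())
            b = int(growth.loc[s, isolates[4:]].sum())
            expected = float(fisher_p_enumeration(a, b, 4 - a, 4 - b, "two-sided"))
            assert out.loc[s, "p_value"] == pytest.approx(expected, abs=1e-9)

    def test_majority_pooling_ties_to_false(self):
        growth = pd.DataFrame(
            {"iso1_r1": [True, True], "iso1_r2": [False, True]},
            index=["s1", "s2"],
        )
        pooled = pool_replicates(growth, {"iso1_r1": "iso1", "iso1_r2": "iso1"})
        assert not pooled.loc["s1", "iso1"]  # 1 of 2 votes: tie -> False
        assert pooled.loc["s2", "iso1"]


class TestGenomeFeatures:
    def test_identical_distributions(self):
        meta = pd.DataFrame(
            {
                "genome_id": ["a", "b", "c", "d"],
                "genome_length_bp": [3_000_000, 3_500_000, 3_000_000, 3_500_000],
                "gene_count": [2800, 3200, 2800, 3200],
            }
        )
        calls = pd.DataFrame(
            {"genome_id": ["a", "b", "c", "d"], "sporulation_class": ["SF", "SF", "FSF", "FSF"]}
        )
        out = genome_feature_compare(meta, calls)
        assert out["size_reduction_percent"] == pytest.approx(0.0)
        assert out["size_test"].p_value == pytest.approx(1.0)
        assert out["spearman_sf"] == pytest.approx(1.0)

    def test_planted_36_percent_reduction(self, genome_set):
        from conftest import calls_from_truth

        meta = genome_set.metadata_frame()
        out = genome_feature_compare(meta, calls_from_truth(genome_set))
        assert out["size_reduction_percent"] == pytest.approx(36.0, abs=4.0)
        assert out["size_test"].p_value < 1e-6
        assert out["spearman_sf"] > 0.9
        assert out["spearman_fsf"] > 0.9

    def test_tiny_group_rejected(self):
        meta = pd.DataFrame(
            {"genome_id": ["a", "b"], "genome_length_bp": [1, 2], "gene_count": [1, 2]}
        )
        calls = pd.DataFrame(
            {"genome_id": ["a", "b"], "sporulation_class": ["SF", "FSF"]}
        )
        with pytest.raises(ValueError):
            genome_feature_compare(meta, calls)
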