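"""eSNV inclusion filters, capture regions, sample exclusion and TMB."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import esnvsig as es
from esnvsig.errors import ConfigurationError, ParseError, UndefinedTMBError
from esnvsig.filtering import CaptureRegion, variant_passes
from esnvsig.variants import VariantRecord


def rec(qs=0.5, dp=30, af=0.001, pos=100, ref="C", alt="T", sample="S"):
    return VariantRecord(
        sample_id=sample, chrom="chrS", pos=pos, ref=ref, alt=alt,
        quality_score=qs, depth=dp, population_af=af,
    )


class TestCaptureRegion:
    def test_direct_threshold(self):
        df = pd.DataFrame({"chrom": "chrS", "pos": [1, 2, 3, 4], "depth": [25, 19, 20, 21]})
        region = es.compute_capture_region(df, min_depth=20)
        assert region.size == 3
        assert set(region.positions.tolist()) == {1, 3, 4}

    def test_all_zero_depth(self):
        df = pd.DataFrame({"chrom": "chrS", "pos": [1, 2], "depth": [0, 0]})
        assert es.compute_capture_region(df).size == 0

    def test_file_with_and_without_header(self, tmp_path):
        p1 = tmp_path / "a.coverage.tsv"
        p1.write_text("chrom\tpos\tdepth\nchrS\t10\t20\nchrS\t11\t19\n")
        p2 = tmp_path / "b.coverage.tsv"
        p2.write_text("chrS\t10\t20\nchrS\t11\t19\n")
        assert es.compute_capture_region(p1).size == 1
        assert es.compute_capture_region(p2).size == 1
        assert es.compute_capture_region(p1).sample_id == "a"

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chrS\t10\t20\nchrS\toops\t30\n")
        with pytest.raises(ParseError) as exc:
            es.compute_capture_region(p)
        assert exc.value.line_number == 2


class TestSampleExclusion:
    def test_boundary_five_million(self):
        regions = [
            CaptureRegion("A", 4_999_999),
            CaptureRegion("B", 5_000_000),
        ]
        kept, excluded = es.exclude_low_coverage_samples(regions)
        assert kept == ["B"] and excluded == ["A"]

    def test_empty_input(self):
        assert es.exclude_low_coverage_samples([]) == ([], [])

    def test_large_regions_all_kept(self):
        regions = [CaptureRegion(s, 10_000_000) for s in "ABC"]
        kept, excluded = es.exclude_low_coverage_samples(regions)
        assert kept == list("ABC") and excluded == []


class TestFilterEsnvs:
    def test_passing_record_kept(self):
        report = es.filter_esnvs([rec()], set())
        assert len(report.kept) == 1 and report.n_removed == 0

    def test_depth_exactly_ten_removed(self):
        # the rule is strictly greater than 10
        report = es.filter_esnvs([rec(dp=10)], set())
        assert report.removed_by_rule["low_depth"] == 1
        assert len(es.filter_esnvs([rec(dp=11)], set()).kept) == 1

    def test_quality_and_af_boundaries_are_strict(self):
        assert es.filter_esnvs([rec(qs=0.10)], set()).removed_by_rule["low_quality"] == 1
        assert es.filter_esnvs([rec(af=0.02)], set()).removed_by_rule["common_population"] == 1
        assert len(es.filter_esnvs([rec(af=0.0199)], set()).kept) == 1

    def test_missing_af_treated_as_novel(self):
        assert len(es.filter_esnvs([rec(af=None)], set()).kept) == 1

    def test_pon_membership_removes(self):
        r = rec()
        report = es.filter_esnvs([r], {r.site_key})
        assert report.removed_by_rule["pon_recurrent"] == 1

    def test_first_failing_rule_attribution(self):
        # fails both quality and depth; attributed to quality (first in order)
        report = es.filter_esnvs([rec(qs=0.01, dp=5)], set())
        assert report.removed_by_rule == {
            "low_quality": 1, "low_depth": 0, "common_population": 0, "pon_recurrent": 0,
        }

    def test_brute_force_oracle_agreement(self):
        """On random records, the report matches an independent
        per-record rule evaluation exactly."""
        rng = np.random.default_rng(42)
        pon = {("chrS", 7, "C", "T")}
        records = []
        for i in range(50):
            records.append(
                rec(
                    qs=float(rng.uniform(0, 0.3)),
                    dp=int(rng.integers(1, 30)),
                    af=None if rng.random() < 0.3 else float(rng.uniform(0, 0.05)),
                    pos=int(rng.integers(1, 15)),
                )
            )
        report = es.filter_esnvs(records, pon)
        expected_kept, expected_removed = [], dict.fromkeys(es.filtering.FILTER_RULES, 0)
        for r in records:
            if not r.quality_score > 0.10:
                expected_removed["low_quality"] += 1
            elif not r.depth > 10:
                expected_removed["low_depth"] += 1
            elif r.population_af is not None and not r.population_af < 0.02:
                expected_removed["common_population"] += 1
            elif r.site_key in pon:
                expected_removed["pon_recurrent"] += 1
            else:
                expected_kept.append(r)
        assert report.kept == expected_kept
        assert report.removed_by_rule == expected_removed

    @given(
        qs=st.lists(st.floats(0, 1, allow_nan=False), min_size=0, max_size=30),
        q_min=st.floats(0, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_partition_and_monotonicity(self, qs, q_min):
        records = [rec(qs=q, dp=50, af=None, pos=i + 1) for i, q in enumerate(qs)]
        report = es.filter_esnvs(records, set(), q_min=q_min)
        assert len(report.kept) + report.n_removed == len(records)
        # raising the threshold never keeps more
        stricter = es.filter_esnvs(records, set(), q_min=min(1.0, q_min + 0.1))
        assert len(stricter.kept) <= len(report.kept)


class TestTMB:
    @pytest.mark.parametrize(
        "n,bases,expected",
        [(50, 10_000_000, 5.0), (0, 5_000_000, 0.0), (575, 100_000_000, 5.75)],
    )
    def test_arithmetic(self, n, bases, expected):
        assert es.compute_tmb(n, bases) == pytest.approx(expected)

    def test_zero_capture_undefined(self):
        with pytest.raises(UndefinedTMBError):
            es.compute_tmb(5, 0)


class TestPanelOfNormals:
    def test_recurrence_threshold(self):
        a = rec(pos=5, sample="N1")
        b = rec(pos=5, sample="N2")
        private = rec(pos=9, sample="N1")
        pon = es.build_panel_of_normals([[a, private], [b], []])
        assert pon == {a.site_key}

    def test_duplicates_within_one_normal_count_once(self):
        a = rec(pos=5, sample="N1")
        pon = es.build_panel_of_normals([[a, a], []])
        assert pon == set()

    def test_invalid_recurrence(self):
        with pytest.raises(ConfigurationError):
            es.build_panel_of_normals([], min_recurrence=0)


def test_vcf_round_trip(tmp_path):
    """Records written by the deterministic emitter are read back
    identically through pysam."""
    records = [
        rec(pos=10, af=0.001),
        rec(pos=5, af=None, ref="A", alt="G"),
        rec(pos=10, ref="C", alt="G", af=0.001),
    ]
    path = tmp_path / "S.vcf"
    es.write_vcf(records, path, chrom="chrS", chrom_length=1000)
    back = es.read_vcf(path, sample_id="S")
    assert sorted(back, key=lambda r: (r.pos, r.alt)) == sorted(
        records, key=lambda r: (r.pos, r.alt)
    )
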