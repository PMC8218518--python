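"""Synthetic cohort generator: determinism, fidelity and planted artifacts."""

import filecmp

import numpy as np
import pytest

import esnvsig as es
from esnvsig.errors import ConfigurationError, DataError
from esnvsig.filtering import variant_passes
from esnvsig.simulate import make_hotspot_table, _ContextIndex


class TestGenerateReference:
    def test_deterministic(self):
        a = es.generate_reference(10_000, 0.5, seed=1)
        b = es.generate_reference(10_000, 0.5, seed=1)
        assert a == b and len(a) == 10_000 and set(a) <= set("ACGT")

    def test_gc_concentration(self):
        # binomial sd at n=200k is ~0.001, so 0.02 is a >10-sigma band
        seq = es.generate_reference(200_000, 0.41, seed=7)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.39 <= gc <= 0.43

    def test_extreme_gc(self):
        seq = es.generate_reference(10_000, 0.99, seed=1)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc >= 0.96

    @pytest.mark.parametrize("length,gc", [(5_000, 0.5), (10_000, 0.0), (10_000, 1.0)])
    def test_invalid_config(self, length, gc):
        with pytest.raises(ConfigurationError):
            es.generate_reference(length, gc, seed=0)


class TestSimulateCohort:
    def test_clean_counts_match_config(self, small_cohort):
        cfg = small_cohort.config
        for j, s in enumerate(cfg.sample_ids):
            assert len(small_cohort.clean_variants[s]) == cfg.mutations_per_sample[j]

    def test_channel_roundtrip_fidelity(self, small_cohort):
        """Recomputing every clean variant's channel from the reference
        reproduces the drawn 96-profile: columns sum to the mutation
        counts with zero skips and no REF mismatches."""
        cfg = small_cohort.config
        pm = es.build_profiles(
            small_cohort.clean_variants, small_cohort.reference, sample_ids=cfg.sample_ids
        )
        assert (pm.counts.sum(axis=0).to_numpy() == cfg.mutations_per_sample).all()
        assert sum(pm.skipped.values()) == 0

    def test_clean_variants_pass_all_filters(self, small_cohort):
        pon = small_cohort.panel_of_normals
        for recs in small_cohort.clean_variants.values():
            assert all(variant_passes(r, pon) is None for r in recs)

    def test_manifest_tmb_exact(self, small_cohort):
        man = small_cohort.manifest
        sizes = np.array([man.capture_sizes[s] for s in man.sample_ids], dtype=float)
        expected = man.true_counts.to_numpy() / sizes * 1e6
        np.testing.assert_array_equal(man.true_tmb.to_numpy(), expected)

    def test_coverage_files_yield_configured_capture(self, small_cohort):
        sample = small_cohort.config.sample_ids[0]
        region = es.compute_capture_region(small_cohort.coverage[sample], min_depth=20)
        assert region.size == small_cohort.capture_sizes[sample]

    def test_pure_signature_profile_cosine(self, catalog):
        ids = ["P1"]
        cfg = es.SimulationConfig(
            sample_ids=ids,
            signature_names=["SBS_POLE_like"],
            mixture_weights=[[1.0]],
            mutations_per_sample=[1000],
            hotspot_samples=[],
            filter_failure_counts={},
            n_normals=0,
            pon_artifact_count=0,
            seed=3,
        )
        cohort = es.simulate_cohort(cfg, catalog=catalog)
        pm = es.build_profiles(cohort.clean_variants, cohort.reference, sample_ids=ids)
        v = pm.counts["P1"].to_numpy(dtype=float)
        w = catalog.matrix["SBS_POLE_like"].to_numpy()
        assert es.cosine_similarity(v, w) >= 0.95

    def test_zero_mutation_sample_is_valid(self, catalog, tmp_path):
        cfg = es.SimulationConfig(
            sample_ids=["Z1"],
            signature_names=["SBS_flat"],
            mixture_weights=[[1.0]],
            mutations_per_sample=[0],
            hotspot_samples=[],
            filter_failure_counts={},
            n_normals=0,
            pon_artifact_count=0,
            seed=0,
        )
        cohort = es.simulate_cohort(cfg, catalog=catalog, out_dir=tmp_path)
        assert cohort.clean_variants["Z1"] == []
        recs = es.read_vcf(tmp_path / "vcf" / "Z1.vcf")
        assert recs == []
        pm = es.build_profiles(cohort.clean_variants, cohort.reference, sample_ids=["Z1"])
        assert pm.counts["Z1"].sum() == 0

    def test_byte_identical_rerun(self, catalog, tmp_path):
        cfg = es.default_cohort_config(n_samples=4, n_hypermutated=1, seed=9)
        es.simulate_cohort(cfg, catalog=catalog, out_dir=tmp_path / "a")
        es.simulate_cohort(cfg, catalog=catalog, out_dir=tmp_path / "b")
        for rel in ["reference.fasta", "pon.tsv", "hotspots.tsv", "manifest.json"]:
            assert filecmp.cmp(tmp_path / "a" / rel, tmp_path / "b" / rel, shallow=False)
        for s in cfg.sample_ids:
            assert filecmp.cmp(
                tmp_path / "a" / "vcf" / f"{s}.vcf",
                tmp_path / "b" / "vcf" / f"{s}.vcf",
                shallow=False,
            )

    def test_config_invariants(self):
        with pytest.raises(ConfigurationError):
            es.SimulationConfig(
                sample_ids=["A"],
                signature_names=["SBS_flat"],
                mixture_weights=[[0.9]],  # does not sum to 1
                mutations_per_sample=[5],
                seed=0,
            )
        with pytest.raises(ConfigurationError):
            es.SimulationConfig(
                sample_ids=["A"],
                signature_names=["SBS_flat"],
                mixture_weights=[[1.0]],
                mutations_per_sample=[5],
                reference_length=5_000,
                seed=0,
            )


class TestInjectFilterFailures:
    def _clean(self, small_cohort, sample):
        return list(small_cohort.clean_variants[sample])

    def test_counts_by_construction(self, small_cohort):
        sample = small_cohort.config.sample_ids[0]
        clean = self._clean(small_cohort, sample)
        counts = {"low_quality": 3, "common_population": 2}
        aug, labels = es.inject_filter_failures(
            clean, counts, small_cohort.panel_of_normals, seed=4,
            reference=small_cohort.reference,
        )
        assert len(aug) == len(clean) + 5 and len(labels) == 5
        report = es.filter_esnvs(aug, small_cohort.panel_of_normals)
        assert len(report.kept) == len(clean)
        assert report.removed_by_rule["low_quality"] == 3
        assert report.removed_by_rule["common_population"] == 2

    def test_each_failure_fails_only_its_own_rule(self, small_cohort):
        sample = small_cohort.config.sample_ids[1]
        clean = self._clean(small_cohort, sample)
        counts = {"low_quality": 2, "low_depth": 2, "common_population": 2, "pon_recurrent": 2}
        aug, labels = es.inject_filter_failures(
            clean, counts, small_cohort.panel_of_normals, seed=5,
            reference=small_cohort.reference,
        )
        planted = {(l["pos"], l["failure_class"]) for l in labels}
        for rec in aug[len(clean):]:
            rule = es.filtering.variant_passes(rec, small_cohort.panel_of_normals)
            assert (rec.pos, rule) in planted

    def test_empty_map_is_identity(self, small_cohort):
        sample = small_cohort.config.sample_ids[0]
        clean = self._clean(small_cohort, sample)
        aug, labels = es.inject_filter_failures(
            clean, {}, small_cohort.panel_of_normals, seed=0, reference=small_cohort.reference
        )
        assert aug == clean and labels == []

    def test_unknown_class_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError):
            es.inject_filter_failures(
                [], {"bogus": 1}, set(), seed=0, reference=small_cohort.reference
            )


class TestSpikeHotspots:
    def test_spiked_sample_reports_hit(self, small_cohort):
        hits = es.check_hotspots(small_cohort.variants, small_cohort.hotspot_table)
        hyper = set(small_cohort.config.hotspot_samples)
        for s in small_cohort.config.sample_ids:
            assert (len(hits[s]) >= 1) == (s in hyper)

    def test_empty_sample_ids_is_identity(self, small_cohort):
        before = {s: list(v) for s, v in small_cohort.variants.items()}
        after, spiked = es.spike_hotspots(
            before, small_cohort.hotspot_table, [], reference=small_cohort.reference
        )
        assert after == before and spiked == []

    def test_two_spikes_two_hits(self, small_cohort):
        variants = {"X": []}
        after, _ = es.spike_hotspots(
            variants, small_cohort.hotspot_table, ["X", "X"],
            reference=small_cohort.reference, seed=1,
        )
        hits = es.check_hotspots(after, small_cohort.hotspot_table)
        assert len(hits["X"]) == 2

    def test_ref_mismatch_rejected(self, small_cohort):
        table = small_cohort.hotspot_table.table.copy()
        row = table.iloc[0]
        table.loc[table.index[0], "ref"] = {"A": "C", "C": "A", "G": "T", "T": "G"}[row.ref]
        bad = es.HotspotTable(table)
        with pytest.raises(DataError):
            es.spike_hotspots({"X": []}, bad, ["X"], reference=small_cohort.reference)

    def test_hotspot_contexts_are_pole_characteristic(self, small_cohort):
        """Hotspot loci sit in TCT / TCG contexts (the signature-10
        defining substitutions)."""
        seq = small_cohort.reference
        for r in small_cohort.hotspot_table.table.itertuples():
            assert seq[r.pos - 2 : r.pos + 1] in ("TCT", "TCG")


def test_panel_of_normals_recurrence(small_cohort):
    """Every panel site occurs in >= 2 synthetic normals; private normal
    variants stay out."""
    from collections import Counter

    counts = Counter()
    for normal in small_cohort.normal_variant_sets:
        for key in {r.site_key for r in normal}:
            counts[key] += 1
    for key in small_cohort.panel_of_normals:
        assert counts[key] >= 2
    for key, n in counts.items():
        assert (key in small_cohort.panel_of_normals) == (n >= 2)
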