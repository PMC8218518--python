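"""Shared fixtures: synthetic catalogs, cohorts and one full pipeline run.

Expensive fixtures are session-scoped so the signature-recovery cohort
and the end-to-end pipeline are each computed once per test session.
"""

from __future__ import annotations

import numpy as np
import pytest

import esnvsig as es


@pytest.fixture(scope="session")
def catalog() -> es.ReferenceCatalog:
    return es.synthetic_signature_catalog()


@pytest.fixture(scope="session")
def small_cohort(catalog):
    """A 12-sample cohort with 2 hypermutated samples, fully in memory."""
    cfg = es.default_cohort_config(n_samples=12, n_hypermutated=2, seed=1)
    return es.simulate_cohort(cfg, catalog=catalog)


@pytest.fixture(scope="session")
def recovery_cohort(catalog):
    """Three known signatures, 200 samples x 500 mutations: the
    parameter-recovery setting for de novo extraction."""
    names = ["SBS_POLE_like", "SBS_aging_like", "SBS_tobacco_like"]
    rng = np.random.default_rng(11)
    n = 200
    cfg = es.SimulationConfig(
        sample_ids=[f"T{i:03d}" for i in range(n)],
        signature_names=names,
        mixture_weights=rng.dirichlet(np.ones(3), size=n),
        mutations_per_sample=[500] * n,
        hotspot_samples=[],
        filter_failure_counts={},
        n_normals=0,
        pon_artifact_count=0,
        seed=11,
    )
    cohort = es.simulate_cohort(cfg, catalog=catalog)
    profiles = es.build_profiles(
        cohort.clean_variants, cohort.reference, sample_ids=cfg.sample_ids
    )
    return cohort, profiles


@pytest.fixture(scope="session")
def recovery_factorization(recovery_cohort):
    _, profiles = recovery_cohort
    return es.nmf_factorize(profiles, rank=3, seed=5)


@pytest.fixture(scope="session")
def full_run(tmp_path_factory):
    """One default-condition pipeline run: 195 samples, 6 planted
    hypermutated with spiked hotspots, written to disk and re-read."""
    out = tmp_path_factory.mktemp("full_run")
    config = es.RunConfig(out_dir=str(out), seed=1)
    result = es.run_pipeline(config)
    manifest = es.GroundTruthManifest.from_json(out / "sim" / "manifest.json")
    return result, manifest
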