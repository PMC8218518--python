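"""End-to-end orchestration: simulate -> filter -> profile -> extract ->
match -> call -> stats, with provenance and per-stage logging.

A run is driven by a :class:`RunConfig` (YAML-loadable; unknown keys are
rejected so a typo cannot silently fall back to a default). In synthetic
mode the simulator writes a complete input set first and the later stages
consume the *files*, exercising the same code paths as a real-data run.
Re-running with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import (
    HotspotTable,
    assemble_calls,
    check_hotspots,
    identify_pole_signature,
    signature_tmb,
)
from .errors import ConfigurationError, EsnvSigError
from .filtering import compute_capture_region, exclude_low_coverage_samples, filter_esnvs
from .matching import ReferenceCatalog, match_to_catalog
from .nmf import Factorization, nmf_factorize, reconstruction_similarity
from .profiles import ProfileMatrix, build_profiles
from .simulate import default_cohort_config, simulate_cohort
from .stats import compare_cohort
from .variants import read_site_table, read_vcf, write_vcf

logger = logging.getLogger("esnvsig")


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters for one reproducible run.

    With no input paths the synthetic cohort is generated; supplying
    ``vcf_dir``/``coverage_dir``/``fasta`` (and friends) switches to real
    inputs. ``min_capture`` defaults to a value scaled to the synthetic
    genome; for real RNA-seq data set it to 5_000_000 (the published
    exclusion rule).
    """

    out_dir: str = "run"
    seed: int = 0
    # synthetic-cohort study conditions
    n_samples: int = 195
    n_hypermutated: int = 6
    reference_length: int = 100_000
    # real-data inputs (all-or-nothing; None -> simulate)
    vcf_dir: str | None = None
    coverage_dir: str | None = None
    fasta: str | None = None
    pon: str | None = None
    catalog: str | None = None
    hotspots: str | None = None
    annotations: str | None = None
    # filtering
    q_min: float = 0.10
    depth_min: int = 10
    af_max: float = 0.02
    min_depth: int = 20
    min_capture: int = 10_000
    # factorization
    rank: int = 4
    restarts: int = 30
    max_iter: int = 2000
    tol: float = 1e-6
    # matching / calling
    pole_name: str = "SBS_POLE_like"
    min_similarity: float = 0.8
    threshold: float | None = None
    fence_k: float = 1.5
    histotype: str = "endometrioid"

    def __post_init__(self) -> None:
        if not 0 <= self.q_min <= 1 or not 0 <= self.af_max <= 1:
            raise ConfigurationError("q_min and af_max must lie in [0,1]")
        if self.depth_min < 0 or self.min_depth < 0 or self.min_capture < 0:
            raise ConfigurationError("depth/capture thresholds must be >= 0")
        if self.rank < 1 or self.restarts < 1 or self.max_iter < 1:
            raise ConfigurationError("rank, restarts and max_iter must be >= 1")
        if not 0 <= self.min_similarity <= 1:
            raise ConfigurationError("min_similarity must lie in [0,1]")
        if self.fence_k < 0:
            raise ConfigurationError("fence_k must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config {path} must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


@dataclasses.dataclass
class RunResult:
    """Objects a caller usually wants back after :func:`run_pipeline`."""

    out_dir: Path
    calls: pd.DataFrame
    stats: dict
    factorization: Factorization
    profiles: ProfileMatrix
    match_similarity: pd.DataFrame
    provenance: dict


def _setup_logging(out: Path) -> logging.Handler:
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(fmt)
    logger.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler(sys.stderr)
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    logger.setLevel(logging.INFO)
    return fh


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Any stage failure is re-raised as its package exception with the
    stage name; outputs written before the failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = _setup_logging(out)
    counts: dict = {}
    try:
        # ------------------------------------------------ stage: simulate
        if config.vcf_dir is None:
            sim_dir = out / "sim"
            sim_cfg = default_cohort_config(
                n_samples=config.n_samples,
                n_hypermutated=config.n_hypermutated,
                reference_length=config.reference_length,
                seed=config.seed,
            )
            cohort = simulate_cohort(sim_cfg, out_dir=sim_dir)
            logger.info(
                "simulate: %d samples, %d hypermutated, reference %d bp",
                config.n_samples,
                config.n_hypermutated,
                config.reference_length,
            )
            vcf_dir = sim_dir / "vcf"
            coverage_dir = sim_dir / "coverage"
            fasta = sim_dir / "reference.fasta"
            pon_path = sim_dir / "pon.tsv"
            catalog_path = sim_dir / "catalog.tsv"
            hotspot_path = sim_dir / "hotspots.tsv"
            annotation_path = sim_dir / "annotations.tsv"
        else:
            if config.coverage_dir is None or config.fasta is None:
                raise ConfigurationError("real-data mode needs vcf_dir, coverage_dir and fasta")
            vcf_dir = Path(config.vcf_dir)
            coverage_dir = Path(config.coverage_dir)
            fasta = Path(config.fasta)
            pon_path = Path(config.pon) if config.pon else None
            catalog_path = Path(config.catalog) if config.catalog else None
            hotspot_path = Path(config.hotspots) if config.hotspots else None
            annotation_path = Path(config.annotations) if config.annotations else None

        # -------------------------------------------------- stage: filter
        pon = read_site_table(pon_path) if pon_path else set()
        regions = [
            compute_capture_region(p, min_depth=config.min_depth)
            for p in sorted(coverage_dir.glob("*.tsv"))
        ]
        kept_ids, excluded_ids = exclude_low_coverage_samples(regions, config.min_capture)
        capture_sizes = {r.sample_id: r.size for r in regions}
        kept_variants = {}
        reports = []
        for sample in kept_ids:
            recs = read_vcf(vcf_dir / f"{sample}.vcf", sample_id=sample)
            rep = filter_esnvs(
                recs, pon, q_min=config.q_min, depth_min=config.depth_min, af_max=config.af_max
            )
            kept_variants[sample] = rep.kept
            reports.append(
                {"sample_id": sample, "input": len(recs), "kept": len(rep.kept), **rep.removed_by_rule}
            )
        report_df = pd.DataFrame(reports)
        report_df.to_csv(out / "filter_report.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"sample_id": s, "capture_bases": capture_sizes[s]} for s in kept_ids]
        ).to_csv(out / "capture_sizes.tsv", sep="\t", index=False)
        filt_dir = out / "filtered"
        filt_dir.mkdir(exist_ok=True)
        with open(fasta) as fhh:
            chrom = fhh.readline().strip().lstrip(">").split()[0]
        ref_len = sum(len(l.strip()) for l in open(fasta) if not l.startswith(">"))
        for sample in kept_ids:
            write_vcf(kept_variants[sample], filt_dir / f"{sample}.vcf", chrom, ref_len)
        counts["filter"] = {
            "samples_in": len(regions),
            "samples_excluded_low_coverage": len(excluded_ids),
            "variants_kept": int(report_df["kept"].sum()),
            "variants_removed": int(report_df["input"].sum() - report_df["kept"].sum()),
        }
        logger.info("filter: %s", counts["filter"])

        # ------------------------------------------------ stage: profiles
        profiles = build_profiles(kept_variants, fasta, sample_ids=kept_ids)
        profiles.to_tsv(out / "profiles.tsv")
        counts["profile"] = {
            "total_mutations": int(profiles.counts.to_numpy().sum()),
            "skipped": int(sum(profiles.skipped.values())),
        }
        logger.info("profile: %s", counts["profile"])

        # ------------------------------------------------- stage: extract
        fac = nmf_factorize(
            profiles,
            rank=config.rank,
            n_restarts=config.restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            seed=config.seed,
        )
        fac.W.to_csv(out / "signatures.tsv", sep="\t", index_label="channel")
        fac.H.round(6).to_csv(out / "contributions.tsv", sep="\t", index_label="signature")
        pd.DataFrame({"iteration": range(1, len(fac.objective_trace) + 1),
                      "kl_divergence": fac.objective_trace}).to_csv(
            out / "objective_trace.tsv", sep="\t", index=False
        )
        cos, _ = reconstruction_similarity(profiles, fac.W, fac.H)
        median_cos = float(pd.Series(cos).median())
        if median_cos < 0.8:
            logger.warning(
                "extract: low median reconstruction cosine %.3f; rank %d may be too small",
                median_cos,
                config.rank,
            )
        counts["extract"] = {
            "rank": config.rank,
            "final_kl": float(fac.objective_trace[-1]),
            "median_reconstruction_cosine": median_cos,
            "dropped_zero_samples": len(fac.dropped_samples),
        }
        logger.info("extract: %s", counts["extract"])

        # --------------------------------------------------- stage: match
        if catalog_path is None:
            raise ConfigurationError("a reference catalog is required for matching")
        catalog = ReferenceCatalog.from_tsv(catalog_path)
        match = match_to_catalog(fac.W, catalog)
        match.similarity.round(6).to_csv(out / "match_similarity.tsv", sep="\t", index_label="signature")
        counts["match"] = {
            "best": {s: [n, round(v, 4)] for s, (n, v) in zip(fac.signature_names, match.best_match)}
        }
        logger.info("match: %s", counts["match"])

        # ---------------------------------------------------- stage: call
        pole = identify_pole_signature(
            match, pole_name=config.pole_name, min_similarity=config.min_similarity
        )
        tmb = signature_tmb(fac.H, capture_sizes)
        hotspots = HotspotTable.from_tsv(hotspot_path) if hotspot_path else None
        hits = check_hotspots(kept_variants, hotspots) if hotspots else {}
        calls = assemble_calls(tmb, pole, hits, k=config.fence_k, threshold=config.threshold)
        calls.round(6).to_csv(out / "calls.tsv", sep="\t", index=False)
        counts["call"] = {
            "pole_signature": pole.name if pole.found else None,
            "pole_similarity": None if not pole.found else round(pole.similarity, 4),
            "threshold": None if calls.empty else float(calls["threshold"].iloc[0]),
            "n_outliers": int(calls["outlier"].sum()),
            "n_hotspot_positive": int((calls["n_hotspots"] > 0).sum()),
        }
        logger.info("call: %s", counts["call"])

        # --------------------------------------------------- stage: stats
        stats: dict = {}
        if annotation_path is not None:
            ann = pd.read_csv(annotation_path, sep="\t")
            stats = compare_cohort(calls, ann, histotype=config.histotype)
            (out / "stats.json").write_text(json.dumps(stats, indent=1))
            logger.info("stats: %s", {k: v for k, v in stats.items() if not isinstance(v, dict)})

        provenance = {
            "package": "esnvsig",
            "version": __version__,
            "seed": config.seed,
            "config": {
                k: v for k, v in dataclasses.asdict(config).items() if not isinstance(v, Path)
            },
            "stage_counts": counts,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
        return RunResult(
            out_dir=out,
            calls=calls,
            stats=stats,
            factorization=fac,
            profiles=profiles,
            match_similarity=match.similarity,
            provenance=provenance,
        )
    except EsnvSigError:
        logger.exception("pipeline halted")
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()
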