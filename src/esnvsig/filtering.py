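"""Expressed-SNV inclusion filters, capture regions and mutation burden.

An eSNV is retained when it has a quality score strictly above ``q_min``
(default 0.10), read depth strictly above ``depth_min`` (default 10), a
population allele frequency strictly below ``af_max`` (default 0.02, with
absence treated as novel), and is not a recurrent artifact from the panel
of normals. Removed variants are attributed to the *first* failing rule
in that order, so the per-rule counts partition the input.

The capture region of a sample — the TMB denominator — is the set of
positions with coverage at or above ``min_depth`` (default 20x); samples
whose capture region spans fewer than 5,000,000 positions are excluded
from analysis. TMB is variants per capture base times 1e6 (mut/Mb).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError, UndefinedTMBError
from .variants import SiteKey, VariantRecord

#: Filter rules in attribution order.
FILTER_RULES: tuple[str, ...] = ("low_quality", "low_depth", "common_population", "pon_recurrent")


@dataclasses.dataclass
class CaptureRegion:
    """Positions of one sample with coverage >= the depth cutoff.

    ``size`` (the number of such positions, in bases) is the TMB
    denominator. ``positions`` may be dropped (None) after the size is
    known, to save memory on large cohorts.
    """

    sample_id: str
    size: int
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.positions is not None and self.size != len(self.positions):
            raise ValueError("size must equal the number of positions")


@dataclasses.dataclass
class FilterReport:
    """Outcome of :func:`filter_esnvs` for one variant set."""

    kept: list[VariantRecord]
    removed_by_rule: dict[str, int]

    @property
    def n_removed(self) -> int:
        return sum(self.removed_by_rule.values())


def compute_capture_region(
    coverage: str | Path | pd.DataFrame,
    min_depth: int = 20,
    sample_id: str | None = None,
) -> CaptureRegion:
    """Capture region from a per-base coverage table.

    ``coverage`` is a 3-column (chrom, pos, depth) TSV path or an
    equivalent DataFrame; a header row is optional. Positions with depth
    >= ``min_depth`` are in the region.
    """
    if isinstance(coverage, (str, Path)):
        path = Path(coverage)
        if sample_id is None:
            sample_id = path.stem.removesuffix(".coverage")
        try:
            df = pd.read_csv(
                path,
                sep="\t",
                comment="#",
                names=["chrom", "pos", "depth"],
                header=0 if _has_header(path) else None,
                dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
            )
        except (ValueError, pd.errors.ParserError):
            raise _locate_bad_coverage_line(path) from None
    else:
        df = coverage.copy()
        df.columns = ["chrom", "pos", "depth"][: len(df.columns)]
        if sample_id is None:
            sample_id = "sample"
    if (df["depth"] < 0).any():
        bad = int(df.index[df["depth"] < 0][0]) + 1
        raise ParseError("negative depth in coverage table", line_number=bad)
    covered = df.loc[df["depth"] >= min_depth, "pos"].to_numpy()
    covered = np.unique(covered)
    return CaptureRegion(sample_id=sample_id, size=int(covered.size), positions=covered)


def _has_header(path: Path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    return len(fields) >= 2 and not fields[1].lstrip("-").isdigit()


def _locate_bad_coverage_line(path: Path) -> ParseError:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if i == 1 and _has_header(path):
                continue
            if len(fields) != 3 or not fields[1].isdigit() or not fields[2].lstrip("-").isdigit():
                return ParseError(f"malformed coverage row in {path.name}", line_number=i)
    return ParseError(f"could not parse coverage table {path.name}")


def exclude_low_coverage_samples(
    regions: Sequence[CaptureRegion],
    min_positions: int = 5_000_000,
) -> tuple[list[str], list[str]]:
    """Split samples into (kept, excluded) by capture-region size.

    A sample is excluded iff its capture region covers fewer than
    ``min_positions`` bases (default five million).
    """
    kept = [r.sample_id for r in regions if r.size >= min_positions]
    excluded = [r.sample_id for r in regions if r.size < min_positions]
    return kept, excluded


def variant_passes(
    rec: VariantRecord,
    panel_of_normals: frozenset[SiteKey] | set[SiteKey],
    q_min: float = 0.10,
    depth_min: int = 10,
    af_max: float = 0.02,
) -> str | None:
    """Return None if the record passes all filters, else the first failing rule."""
    if not rec.quality_score > q_min:
        return "low_quality"
    if not rec.depth > depth_min:
        return "low_depth"
    if rec.population_af is not None and not rec.population_af < af_max:
        return "common_population"
    if rec.site_key in panel_of_normals:
        return "pon_recurrent"
    return None


def filter_esnvs(
    variants: Iterable[VariantRecord],
    panel_of_normals: set[SiteKey] | frozenset[SiteKey] = frozenset(),
    q_min: float = 0.10,
    depth_min: int = 10,
    af_max: float = 0.02,
) -> FilterReport:
    """Apply the eSNV inclusion filters to a variant set.

    Thresholds follow the published rules literally: quality strictly
    greater than ``q_min``, depth strictly greater than ``depth_min``
    (a record at exactly depth 10 is removed), population AF strictly
    less than ``af_max`` with a missing AF treated as novel.
    """
    if not 0 <= q_min <= 1:
        raise ConfigurationError(f"q_min must be in [0,1], got {q_min}")
    if depth_min < 0:
        raise ConfigurationError(f"depth_min must be >= 0, got {depth_min}")
    if not 0 <= af_max <= 1:
        raise ConfigurationError(f"af_max must be in [0,1], got {af_max}")
    kept: list[VariantRecord] = []
    removed = {rule: 0 for rule in FILTER_RULES}
    for rec in variants:
        rule = variant_passes(rec, panel_of_normals, q_min=q_min, depth_min=depth_min, af_max=af_max)
        if rule is None:
            kept.append(rec)
        else:
            removed[rule] += 1
    return FilterReport(kept=kept, removed_by_rule=removed)


def build_panel_of_normals(
    normal_variant_sets: Sequence[Iterable[VariantRecord]],
    min_recurrence: int = 2,
) -> set[SiteKey]:
    """Recurrent sites across normal-tissue variant sets.

    A site enters the panel when it appears in at least ``min_recurrence``
    distinct normals (2 is the minimal meaning of "recurrent"). Duplicate
    observations within one normal count once.
    """
    if min_recurrence < 1:
        raise ConfigurationError("min_recurrence must be >= 1")
    counts: dict[SiteKey, int] = {}
    for normal in normal_variant_sets:
        for key in {rec.site_key for rec in normal}:
            counts[key] = counts.get(key, 0) + 1
    return {key for key, n in counts.items() if n >= min_recurrence}


def compute_tmb(n_variants: int, capture_bases: int) -> float:
    """Tumor mutation burden in mutations per megabase.

    ``n_variants / capture_bases * 1e6``. A zero-sized capture region
    makes TMB undefined; such samples should have been excluded upstream.
    """
    if capture_bases <= 0:
        raise UndefinedTMBError(
            f"TMB undefined for capture size {capture_bases}; sample should have been excluded"
        )
    if n_variants < 0:
        raise ConfigurationError("variant count must be >= 0")
    return n_variants / capture_bases * 1e6
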