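"""POLE hypermutation calling from signature contributions.

Each sample's NMF contribution (mutation counts per signature) is
converted to a per-signature TMB by dividing by the sample's capture
size. The extracted signature that best resembles the catalog's POLE
signature (COSMIC signature 10 in the v2 catalog) is identified, and
samples whose POLE-signature TMB lies above the upper Tukey fence
Q3 + 1.5 * IQR are called hypermutated outliers. Calls are cross-checked
against expressed POLE exonuclease-domain hotspot mutations (P286R,
S297F, V411L, A456P in the human gene).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, InsufficientDataError
from .matching import MatchResult
from .variants import VariantRecord

logger = logging.getLogger(__name__)


def signature_tmb(H: pd.DataFrame, capture_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Per-sample, per-signature TMB (mut/Mb): H[k, s] / capture_bases[s] * 1e6."""
    missing = [s for s in H.columns if s not in capture_sizes]
    if missing:
        raise ConfigurationError(f"missing capture size for sample(s): {missing}")
    sizes = np.array([capture_sizes[s] for s in H.columns], dtype=float)
    if (sizes <= 0).any():
        bad = [s for s, z in zip(H.columns, sizes) if z <= 0]
        raise ConfigurationError(f"non-positive capture size for sample(s): {bad}")
    return H / sizes * 1e6


@dataclasses.dataclass
class PoleSignature:
    """Which extracted signature corresponds to the POLE process."""

    found: bool
    index: int | None = None
    name: str | None = None
    similarity: float | None = None


def identify_pole_signature(
    match: MatchResult,
    pole_name: str = "COSMIC_10",
    min_similarity: float = 0.8,
) -> PoleSignature:
    """Pick the extracted signature closest to the catalog's POLE column.

    Returns a no-POLE-signature outcome (``found=False``) when no
    extracted signature reaches ``min_similarity``; downstream calling
    then reports zero POLE-driven samples rather than guessing.
    """
    if pole_name not in match.similarity.columns:
        raise ConfigurationError(f"catalog has no column named {pole_name!r}")
    sims = match.similarity[pole_name].to_numpy()
    idx = int(np.argmax(sims))  # tie -> lower index
    if (sims == sims[idx]).sum() > 1:
        logger.info("tie for best %s similarity (%.4f); keeping lower index", pole_name, sims[idx])
    if sims[idx] < min_similarity:
        return PoleSignature(found=False)
    return PoleSignature(
        found=True,
        index=idx,
        name=str(match.similarity.index[idx]),
        similarity=float(sims[idx]),
    )


class TukeyFenceCaller(BaseEstimator):
    """Boxplot-rule outlier caller (scikit-learn estimator style).

    ``fit`` computes the fences Q1 - k*IQR and Q3 + k*IQR with
    linear-interpolation quantiles; ``predict`` flags values strictly
    above the upper fence. Hypermutation is one-sided, so only the upper
    fence triggers calls; ``lower_outliers_`` is informational.

    Parameters
    ----------
    k : float, default 1.5
        Whisker multiplier.
    threshold : float or None
        Fixed override for the upper fence (e.g. a published 5 mut/Mb
        cutoff); when set, ``fit`` only records it.
    """

    def __init__(self, k: float = 1.5, threshold: float | None = None):
        self.k = k
        self.threshold = threshold

    def fit(self, X, y=None):
        values = np.asarray(X, dtype=float).ravel()
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            self.lower_fence_ = -np.inf
            return self
        if values.size < 4:
            raise InsufficientDataError(
                f"need >= 4 values for a Tukey fence, got {values.size}"
            )
        q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
        iqr = q3 - q1
        self.threshold_ = float(q3 + self.k * iqr)
        self.lower_fence_ = float(q1 - self.k * iqr)
        return self

    def predict(self, X) -> np.ndarray:
        values = np.asarray(X, dtype=float).ravel()
        return values > self.threshold_

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def call_outliers(
    values: Sequence[float] | np.ndarray,
    k: float = 1.5,
    threshold: float | None = None,
) -> tuple[float, np.ndarray]:
    """Upper-fence outlier calls for a vector of per-sample TMB values.

    Returns ``(threshold, flags)`` where ``threshold`` is
    Q3 + k*IQR (or the fixed override) and ``flags[i]`` is True iff
    ``values[i]`` is strictly above it. Order-invariant: the flag of a
    value does not depend on where it sits in the input.
    """
    caller = TukeyFenceCaller(k=k, threshold=threshold).fit(values)
    return caller.threshold_, caller.predict(values)


@dataclasses.dataclass
class HotspotTable:
    """POLE hotspot coordinates: gene, protein change, chrom, pos, ref, alt."""

    table: pd.DataFrame

    _COLUMNS = ("gene", "protein_change", "chrom", "pos", "ref", "alt")

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"hotspot table missing column(s): {missing}")
        keys = list(zip(self.table.chrom, self.table.pos, self.table.ref, self.table.alt))
        if len(set(keys)) != len(keys):
            raise ConfigurationError("hotspot table has duplicate (chrom,pos,ref,alt) rows")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HotspotTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def site_map(self) -> dict[tuple[str, int, str, str], str]:
        return {
            (r.chrom, int(r.pos), r.ref, r.alt): r.protein_change
            for r in self.table.itertuples()
        }


#: One hotspot hit: (protein label, position, ref, alt).
HotspotHit = tuple[str, int, str, str]


def check_hotspots(
    variants_by_sample: Mapping[str, Iterable[VariantRecord]],
    hotspots: HotspotTable,
) -> dict[str, list[HotspotHit]]:
    """Exact (chrom, pos, ref, alt) hotspot matches among filtered variants."""
    site_map = hotspots.site_map()
    hits: dict[str, list[HotspotHit]] = {}
    for sample, records in variants_by_sample.items():
        found = [
            (site_map[rec.site_key], rec.pos, rec.ref, rec.alt)
            for rec in records
            if rec.site_key in site_map
        ]
        hits[sample] = sorted(found, key=lambda h: h[1])
    return hits


@dataclasses.dataclass
class SampleCall:
    """Per-sample POLE call."""

    sample_id: str
    pole_signature_name: str | None
    pole_tmb: float
    outlier: bool
    threshold_used: float
    hotspot_hits: list[HotspotHit]


def assemble_calls(
    tmb: pd.DataFrame,
    pole: PoleSignature,
    hotspot_hits: Mapping[str, list[HotspotHit]],
    k: float = 1.5,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Combine signature TMB, the POLE signature and hotspot evidence.

    Returns a table with one row per sample: POLE-signature TMB, the
    fence used, the outlier flag (all False when no extracted signature
    matched the POLE catalog entry) and semicolon-joined hotspot labels.
    """
    samples = list(tmb.columns)
    if pole.found:
        values = tmb.iloc[pole.index].to_numpy()
        fence, flags = call_outliers(values, k=k, threshold=threshold)
    else:
        values = np.zeros(len(samples))
        fence, flags = np.inf, np.zeros(len(samples), dtype=bool)
    rows = []
    for i, s in enumerate(samples):
        hits = hotspot_hits.get(s, [])
        rows.append(
            {
                "sample_id": s,
                "pole_signature": pole.name if pole.found else "",
                "pole_tmb": float(values[i]),
                "threshold": fence,
                "outlier": bool(flags[i]),
                "hotspots": ";".join(h[0] for h in hits),
                "n_hotspots": len(hits),
            }
        )
    return pd.DataFrame(rows)
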