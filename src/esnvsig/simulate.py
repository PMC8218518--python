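"""Synthetic cohorts with known signature mixtures and planted artifacts.

This module generates everything the downstream pipeline consumes — a
reference sequence, per-sample site-level VCFs, per-base coverage tables,
a panel of normals, a hotspot table and clinical annotations — together
with a ground-truth manifest, so that signature extraction, filtering and
POLE calling can be validated end to end without any external data.

Each sample's mutations are drawn hierarchically: first a per-signature
count from the sample's mixture weights, then 96-channel counts from each
signature's channel distribution, and finally each mutation is placed
uniformly at an unused reference position whose trinucleotide context
(after pyrimidine-strand collapse) matches the drawn channel, so that
recomputing channels from the written FASTA + VCF reproduces the draw
exactly. Clean variants carry annotations that pass every inclusion
filter; planted failures each violate exactly one filter; hypermutated
samples additionally receive filter-passing POLE hotspot variants.

Scale note: the default cohort mirrors a 195-sample study with six
hypermutated POLE-like samples, on a deliberately small (100 kb) genome
so that dense per-base coverage files stay desk-sized; TMB arithmetic is
scale-free, so mutation counts are chosen to keep the hypermutated /
background burden contrast realistic.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, complement, revcomp
from .errors import ConfigurationError, DataError, SimulationError
from .filtering import FILTER_RULES, build_panel_of_normals
from .matching import ReferenceCatalog
from .calling import HotspotTable
from .variants import SiteKey, VariantRecord, write_site_table, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: POLE exonuclease-domain hotspot labels and the channel each is planted at
#: (TCT>TAT and TCG>TTG are the signature-10-defining substitutions).
_HOTSPOT_SPECS = (
    ("P286R", "TCT", "A"),
    ("S297F", "TCG", "T"),
    ("V411L", "TCT", "A"),
    ("A456P", "TCG", "T"),
)


def generate_reference(
    length: int, gc_content: float, seed: int, path: str | Path | None = None, chrom: str = "chrS"
) -> str:
    """Random A/C/G/T sequence of ``length`` bases with the given GC fraction.

    Bases are i.i.d.; the empirical GC fraction concentrates around
    ``gc_content`` (within 0.02 for length >= 100 kb). Deterministic for
    a fixed seed. Optionally written as a FASTA file.
    """
    if length < 10_000:
        raise ConfigurationError(f"reference length must be >= 10000, got {length}")
    if not 0 < gc_content < 1:
        raise ConfigurationError(f"gc_content must be in (0,1), got {gc_content}")
    rng = np.random.default_rng(seed)
    is_gc = rng.random(length) < gc_content
    is_first = rng.random(length) < 0.5
    codes = np.where(is_gc, np.where(is_first, 2, 1), np.where(is_first, 0, 3))
    seq = _BASES[codes].tobytes().decode("ascii")
    if path is not None:
        write_fasta(seq, path, chrom=chrom)
    return seq


def write_fasta(seq: str, path: str | Path, chrom: str = "chrS", width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``mixture_weights`` is n_samples x K over ``signature_names`` (rows
    sum to 1); ``filter_failure_counts`` are applied per sample.
    """

    sample_ids: list[str]
    signature_names: list[str]
    mixture_weights: np.ndarray
    mutations_per_sample: np.ndarray
    reference_length: int = 100_000
    gc_content: float = 0.41
    capture_fraction: float = 0.5
    n_normals: int = 6
    pon_artifact_count: int = 20
    filter_failure_counts: dict[str, int] = dataclasses.field(default_factory=dict)
    hotspot_samples: list[str] = dataclasses.field(default_factory=list)
    chrom: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        self.mutations_per_sample = np.asarray(self.mutations_per_sample, dtype=int)
        n, k = self.mixture_weights.shape
        if n != len(self.sample_ids) or k != len(self.signature_names):
            raise ConfigurationError("mixture_weights must be n_samples x n_signatures")
        if not np.allclose(self.mixture_weights.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("mixture_weights rows must sum to 1")
        if (self.mixture_weights < 0).any():
            raise ConfigurationError("mixture_weights must be non-negative")
        if len(self.mutations_per_sample) != n:
            raise ConfigurationError("mutations_per_sample must have one entry per sample")
        if (self.mutations_per_sample < 0).any():
            raise ConfigurationError("mutation counts must be >= 0")
        if self.reference_length < 10_000:
            raise ConfigurationError("reference_length must be >= 10000")
        if not 0 < self.capture_fraction <= 1:
            raise ConfigurationError("capture_fraction must be in (0,1]")
        unknown = set(self.filter_failure_counts) - set(FILTER_RULES)
        if unknown:
            raise ConfigurationError(f"unknown filter-failure class(es): {sorted(unknown)}")
        if any(c < 0 for c in self.filter_failure_counts.values()):
            raise ConfigurationError("filter-failure counts must be >= 0")
        missing = set(self.hotspot_samples) - set(self.sample_ids)
        if missing:
            raise ConfigurationError(f"hotspot_samples not in cohort: {sorted(missing)}")
        if self.filter_failure_counts.get("pon_recurrent", 0) > 0 and (
            self.n_normals < 2 or self.pon_artifact_count < 1
        ):
            raise ConfigurationError("pon_recurrent failures require a panel of normals")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


def synthetic_signature_catalog(
    names: Sequence[str] = ("SBS_POLE_like", "SBS_aging_like", "SBS_tobacco_like", "SBS_flat"),
    seed: int = 2021,
) -> ReferenceCatalog:
    """A small synthetic reference catalog of 96-channel signatures.

    These are synthetic stand-ins constructed to have the *character* of
    well-known mutational processes, not the published COSMIC v2 values:
    the POLE-like column concentrates mass on T[C>A]T and T[C>T]G (the
    substitutions that define the POLE-exonuclease signature), the
    aging-like column on C>T at CpG contexts, the tobacco-like column on
    broad C>A, and the flat column is near-uniform. Columns sum to 1 and
    are pairwise well separated, which makes them recoverable by NMF.
    """
    rng = np.random.default_rng(seed)
    idx = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}
    cols = {}
    for name in names:
        low = name.lower()
        w = np.zeros(96)
        if "pole" in low:
            # TCT>TAT dominant, TCG>TTG secondary — the exonuclease-
            # deficiency character, kept strongly C>A-weighted so the
            # signature stays identifiable against the CpG aging process
            w[idx["T[C>A]T"]] = 0.45
            w[idx["T[C>A]G"]] = 0.08
            w[idx["C[C>A]T"]] = 0.06
            w[idx["T[C>T]G"]] = 0.10
            w[idx["T[C>T]T"]] = 0.04
            w += rng.dirichlet(np.full(96, 0.4)) * 0.27
        elif "aging" in low:
            for five in "ACGT":
                w[idx[f"{five}[C>T]G"]] = 0.15
            w += rng.dirichlet(np.full(96, 0.5)) * 0.40
        elif "tobacco" in low:
            for five in "ACGT":
                for three in "ACGT":
                    w[idx[f"{five}[C>A]{three}"]] = rng.uniform(0.02, 0.07)
            w += rng.dirichlet(np.full(96, 0.5)) * 0.25
        else:  # flat
            w = rng.dirichlet(np.full(96, 25.0))
        cols[name] = w / w.sum()
    matrix = pd.DataFrame(cols, index=list(CHANNEL_LABELS))
    return ReferenceCatalog(matrix=matrix)


def default_cohort_config(
    n_samples: int = 195,
    n_hypermutated: int = 6,
    signature_names: Sequence[str] = (
        "SBS_POLE_like",
        "SBS_aging_like",
        "SBS_tobacco_like",
        "SBS_flat",
    ),
    reference_length: int = 100_000,
    seed: int = 0,
) -> SimulationConfig:
    """The default study conditions: a 195-sample cohort, six hypermutated.

    Hypermutated samples draw 400-900 mutations at 75-90% POLE-like
    weight; background samples draw ~200 mutations with a low POLE-like
    contribution whose per-sample expected count is uniform on [0, 48]
    (negative controls in real cohorts show a nonzero POLE attribution
    floor; a compact, light-tailed null keeps the boxplot fence a
    meaningful separator rather than an artifact of a skewed null).
    The burden contrast between the groups is roughly an order of
    magnitude, as in POLE-driven tumors.
    """
    if not 0 <= n_hypermutated <= n_samples:
        raise ConfigurationError("n_hypermutated must be between 0 and n_samples")
    rng = np.random.default_rng(seed)
    width = len(str(n_samples))
    sample_ids = [f"S{i + 1:0{width}d}" for i in range(n_samples)]
    hyper = sorted(rng.choice(n_samples, size=n_hypermutated, replace=False).tolist())
    k = len(signature_names)
    pole_k = next(i for i, n in enumerate(signature_names) if "pole" in n.lower())
    weights = np.zeros((n_samples, k))
    mutations = np.zeros(n_samples, dtype=int)
    for i in range(n_samples):
        rest = rng.dirichlet(np.full(k - 1, 3.0))
        if i in hyper:
            pole_w = rng.uniform(0.75, 0.90)
            mutations[i] = rng.integers(400, 901)
        else:
            mutations[i] = rng.poisson(200)
            pole_w = min(0.5, rng.uniform(0.0, 48.0) / max(mutations[i], 1))
        weights[i, pole_k] = pole_w
        weights[i, [j for j in range(k) if j != pole_k]] = rest * (1 - pole_w)
    return SimulationConfig(
        sample_ids=sample_ids,
        signature_names=list(signature_names),
        mixture_weights=weights,
        mutations_per_sample=mutations,
        reference_length=reference_length,
        gc_content=0.41,
        capture_fraction=0.5,
        n_normals=6,
        pon_artifact_count=20,
        filter_failure_counts={
            "low_quality": 3,
            "low_depth": 3,
            "common_population": 2,
            "pon_recurrent": 2,
        },
        hotspot_samples=[sample_ids[i] for i in hyper],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# placement machinery


class _ContextIndex:
    """Positions of each forward-strand trinucleotide in the reference."""

    def __init__(self, seq: str):
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        enc = lut[codes]
        tri = 16 * enc[:-2] + 4 * enc[1:-1] + enc[2:]
        order = np.argsort(tri, kind="stable")
        starts = np.searchsorted(tri[order], np.arange(65))
        centres = order + 2  # 1-based centre position of each window
        self._by_code: list[np.ndarray] = [
            np.sort(centres[starts[c] : starts[c + 1]]) for c in range(64)
        ]

    @staticmethod
    def encode(trinuc: str) -> int:
        m = {"A": 0, "C": 1, "G": 2, "T": 3}
        a, b, c = (m[x] for x in trinuc)
        return 16 * a + 4 * b + c

    def positions(self, trinuc: str, lo: int, hi: int) -> np.ndarray:
        """Centre positions (1-based, within [lo, hi]) matching ``trinuc``."""
        arr = self._by_code[self.encode(trinuc)]
        i0, i1 = np.searchsorted(arr, [lo, hi + 1])
        return arr[i0:i1]


def _parse_channel(label: str) -> tuple[str, str, str]:
    """Label "A[C>T]G" -> (pyrimidine context "ACG", ref "C", alt "T")."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def _place_channel(
    label: str,
    count: int,
    ctx_index: _ContextIndex,
    seq: str,
    lo: int,
    hi: int,
    blocked: set[int],
    rng: np.random.Generator,
) -> list[tuple[int, str, str]]:
    """Choose ``count`` distinct positions realizing ``label``; returns
    (pos, ref, alt) triples on the genomic (forward) strand."""
    ctx, ref, alt = _parse_channel(label)
    fwd = ctx_index.positions(ctx, lo, hi)
    rev = ctx_index.positions(revcomp(ctx), lo, hi)
    cands = np.concatenate([fwd, rev])
    if blocked:
        cands = cands[~np.isin(cands, np.fromiter(blocked, dtype=np.int64))]
    if len(cands) < count:
        raise SimulationError(
            f"cannot place {count} mutation(s) for channel {label}: only "
            f"{len(cands)} unused matching context position(s) in the capture region"
        )
    chosen = rng.choice(cands, size=count, replace=False)
    out = []
    fwd_set = set(fwd.tolist())
    for pos in chosen.tolist():
        if pos in fwd_set:
            out.append((pos, ref, alt))
        else:
            out.append((pos, complement(ref), complement(alt)))
    return out


def _clean_annotations(rng: np.random.Generator) -> tuple[float, int, float | None]:
    qs = float(rng.uniform(0.15, 1.0))
    dp = int(rng.integers(11, 200))
    af = None if rng.random() < 0.5 else float(rng.uniform(0.0, 0.019))
    return qs, dp, af


def inject_filter_failures(
    variants: list[VariantRecord],
    failure_counts: Mapping[str, int],
    panel_of_normals: set[SiteKey] | Sequence[SiteKey],
    seed: int | np.random.Generator,
    reference: str = "",
    chrom: str = "chrS",
    blocked: set[int] | None = None,
) -> tuple[list[VariantRecord], list[dict]]:
    """Add records that each fail exactly one inclusion filter.

    Returns the augmented variant list and the planted-failure labels
    (one dict per added record, with its site and failure class). An
    empty ``failure_counts`` returns the input unchanged.
    """
    unknown = set(failure_counts) - set(FILTER_RULES)
    if unknown:
        raise ConfigurationError(f"unknown filter-failure class(es): {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    used_in_sample = {v.pos for v in variants}  # one record per position per sample
    blocked = set(blocked or ()) | used_in_sample
    sample_id = variants[0].sample_id if variants else "sample"
    pon_sites = sorted(panel_of_normals)
    augmented = list(variants)
    labels: list[dict] = []

    def random_site() -> tuple[int, str, str]:
        if not reference:
            raise ConfigurationError("a reference sequence is required to place failures")
        for _ in range(10_000):
            pos = int(rng.integers(2, len(reference)))
            if pos in blocked:
                continue
            ref = reference[pos - 1]
            if ref not in "ACGT":
                continue
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            return pos, ref, alt
        raise SimulationError("could not find a free position for a planted failure")

    for rule in FILTER_RULES:  # deterministic order
        for _ in range(int(failure_counts.get(rule, 0))):
            qs, dp, af = _clean_annotations(rng)
            if rule == "low_quality":
                pos, ref, alt = random_site()
                qs = float(rng.uniform(0.0, 0.10))
            elif rule == "low_depth":
                pos, ref, alt = random_site()
                dp = int(rng.integers(1, 11))
            elif rule == "common_population":
                pos, ref, alt = random_site()
                af = float(rng.uniform(0.02, 0.5))
            else:  # pon_recurrent: reuse a panel site this sample has not used yet
                free = [s for s in pon_sites if s[1] not in used_in_sample]
                if not free:
                    raise SimulationError("no free panel-of-normals site to plant")
                _, pos, ref, alt = free[int(rng.integers(len(free)))]
            blocked.add(pos)
            used_in_sample.add(pos)
            rec = VariantRecord(
                sample_id=sample_id,
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                quality_score=qs,
                depth=dp,
                population_af=af,
            )
            augmented.append(rec)
            labels.append(
                {
                    "sample": sample_id,
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "failure_class": rule,
                }
            )
    return augmented, labels


def make_hotspot_table(
    seq: str, chrom: str, rng: np.random.Generator, ctx_index: _ContextIndex | None = None
) -> HotspotTable:
    """Choose four loci on the synthetic reference to stand in for the
    POLE exonuclease hotspots (labels P286R/S297F/V411L/A456P)."""
    ctx_index = ctx_index or _ContextIndex(seq)
    used: set[int] = set()
    rows = []
    for label, ctx, alt in _HOTSPOT_SPECS:
        cands = ctx_index.positions(ctx, 2, len(seq) - 1)
        cands = cands[~np.isin(cands, np.fromiter(used, dtype=np.int64))] if used else cands
        if len(cands) == 0:
            raise SimulationError(f"reference has no free {ctx} context for hotspot {label}")
        pos = int(rng.choice(cands))
        used.add(pos)
        rows.append(
            {
                "gene": "POLE",
                "protein_change": label,
                "chrom": chrom,
                "pos": pos,
                "ref": ctx[1],
                "alt": alt,
            }
        )
    return HotspotTable(pd.DataFrame(rows))


def spike_hotspots(
    variants: dict[str, list[VariantRecord]],
    hotspot_table: HotspotTable,
    sample_ids: Sequence[str],
    reference: str | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, list[VariantRecord]], list[dict]]:
    """Give each named sample one filter-passing hotspot variant.

    Hotspots are assigned cyclically through the table rows, so with six
    samples and four hotspots two pairs of samples share a hotspot.
    Returns the augmented variant map and the spike manifest entries.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = hotspot_table.table
    if reference is not None:
        for r in table.itertuples():
            if reference[int(r.pos) - 1] != r.ref:
                raise DataError(
                    f"hotspot {r.protein_change} ref mismatch at {r.chrom}:{r.pos}: "
                    f"table says {r.ref}, reference has {reference[int(r.pos) - 1]}"
                )
    out = {s: list(v) for s, v in variants.items()}
    spiked: list[dict] = []
    for i, sample in enumerate(sample_ids):
        row = table.iloc[i % len(table)]
        qs, dp, _ = _clean_annotations(rng)
        rec = VariantRecord(
            sample_id=sample,
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            quality_score=qs,
            depth=dp,
            population_af=None,
        )
        out.setdefault(sample, []).append(rec)
        spiked.append(
            {
                "sample": sample,
                "pos": int(row.pos),
                "ref": str(row.ref),
                "alt": str(row.alt),
                "protein_label": str(row.protein_change),
            }
        )
    return out, spiked


# ---------------------------------------------------------------------------
# ground truth + top-level simulation


@dataclasses.dataclass
class GroundTruthManifest:
    """Everything the generator knows that the pipeline must rediscover."""

    signature_names: list[str]
    sample_ids: list[str]
    true_signatures: pd.DataFrame  # 96 x K
    true_weights: pd.DataFrame  # K x N mixture weights
    true_counts: pd.DataFrame  # K x N realized mutation counts
    true_tmb: pd.DataFrame  # K x N mut/Mb
    capture_sizes: dict[str, int]
    spiked_hotspots: list[dict]
    planted_failures: list[dict]

    @property
    def hypermutated_samples(self) -> list[str]:
        return sorted({h["sample"] for h in self.spiked_hotspots})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_names": self.signature_names,
            "sample_ids": self.sample_ids,
            "true_signatures": self.true_signatures.to_dict(orient="list"),
            "true_weights": self.true_weights.to_dict(orient="list"),
            "true_counts": self.true_counts.astype(int).to_dict(orient="list"),
            "true_tmb": self.true_tmb.to_dict(orient="list"),
            "capture_sizes": self.capture_sizes,
            "spiked_hotspots": self.spiked_hotspots,
            "planted_failures": self.planted_failures,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        sigs = pd.DataFrame(d["true_signatures"], index=list(CHANNEL_LABELS))

        def mk(key: str) -> pd.DataFrame:
            return pd.DataFrame(
                {s: d[key][s] for s in d["sample_ids"]}, index=d["signature_names"]
            )

        return cls(
            signature_names=d["signature_names"],
            sample_ids=d["sample_ids"],
            true_signatures=sigs,
            true_weights=mk("true_weights"),
            true_counts=mk("true_counts"),
            true_tmb=mk("true_tmb"),
            capture_sizes={k: int(v) for k, v in d["capture_sizes"].items()},
            spiked_hotspots=d["spiked_hotspots"],
            planted_failures=d["planted_failures"],
        )


@dataclasses.dataclass
class SimulatedCohort:
    """In-memory result of :func:`simulate_cohort` (plus file paths if written)."""

    config: SimulationConfig
    reference: str
    catalog: ReferenceCatalog
    variants: dict[str, list[VariantRecord]]  # everything written to the VCFs
    clean_variants: dict[str, list[VariantRecord]]
    capture_windows: dict[str, tuple[int, int]]  # sample -> (start, size), 1-based
    panel_of_normals: set[SiteKey]
    normal_variant_sets: list[list[VariantRecord]]
    hotspot_table: HotspotTable
    manifest: GroundTruthManifest
    annotations: pd.DataFrame
    coverage: dict[str, pd.DataFrame] = dataclasses.field(default_factory=dict)
    out_dir: Path | None = None

    @property
    def capture_sizes(self) -> dict[str, int]:
        return {s: size for s, (_, size) in self.capture_windows.items()}


def _simulate_annotations(
    sample_ids: Sequence[str], hyper: set[str], rng: np.random.Generator
) -> pd.DataFrame:
    """Clinical annotations: hypermutated samples are endometrioid with
    early onset; the background mirrors a mixed ovarian-cancer cohort."""
    histologies = ["serous", "endometrioid", "clear_cell", "mucinous", "other"]
    probs = [0.60, 0.22, 0.08, 0.05, 0.05]
    rows = []
    for s in sample_ids:
        if s in hyper:
            hist = "endometrioid"
            age = int(np.clip(round(rng.normal(48, 2)), 25, 90))
            stage = str(rng.choice(["I", "I", "III"]))
            grade = int(rng.integers(1, 4))
        else:
            hist = str(rng.choice(histologies, p=probs))
            age = int(np.clip(round(rng.normal(61, 12)), 20, 95))
            stage = str(rng.choice(["I", "II", "III", "IV"], p=[0.23, 0.08, 0.52, 0.17]))
            grade = int(rng.choice([1, 2, 3], p=[0.10, 0.13, 0.77]))
        rows.append(
            {"sample_id": s, "age_years": age, "histology": hist, "stage": stage, "grade": grade}
        )
    return pd.DataFrame(rows)


def _simulate_normals(
    seq: str,
    chrom: str,
    n_normals: int,
    artifact_count: int,
    blocked: set[int],
    rng: np.random.Generator,
) -> tuple[list[list[VariantRecord]], set[SiteKey], set[int]]:
    """Normal-tissue variant sets containing recurrent artifacts.

    Each artifact site appears in >= 2 normals (the minimal meaning of
    "recurrent"); each normal also has a few private sites that must NOT
    enter the panel.
    """
    if n_normals < 2 or artifact_count < 1:
        return [[] for _ in range(max(n_normals, 0))], set(), set()
    positions: set[int] = set()
    artifacts: list[SiteKey] = []
    while len(artifacts) < artifact_count:
        pos = int(rng.integers(2, len(seq)))
        if pos in blocked or pos in positions:
            continue
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        positions.add(pos)
        artifacts.append((chrom, pos, ref, alt))
    normals: list[list[VariantRecord]] = [[] for _ in range(n_normals)]
    for key in artifacts:
        carriers = rng.choice(n_normals, size=int(rng.integers(2, n_normals + 1)), replace=False)
        for i in carriers:
            normals[i].append(
                VariantRecord(
                    sample_id=f"N{i + 1}",
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    quality_score=0.5,
                    depth=40,
                )
            )
    for i in range(n_normals):  # private, non-recurrent noise
        for _ in range(5):
            pos = int(rng.integers(2, len(seq)))
            if pos in blocked or pos in positions:
                continue
            positions.add(pos)
            ref = seq[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            normals[i].append(
                VariantRecord(
                    sample_id=f"N{i + 1}",
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    quality_score=0.5,
                    depth=40,
                )
            )
    pon = build_panel_of_normals(normals, min_recurrence=2)
    return normals, pon, positions


def simulate_cohort(
    config: SimulationConfig,
    catalog: ReferenceCatalog | None = None,
    reference: str | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Generate a full synthetic cohort under ``config``.

    Deterministic: identical (config, seed) give byte-identical outputs.
    When ``out_dir`` is given, writes reference.fasta, vcf/<sample>.vcf,
    coverage/<sample>.coverage.tsv, pon.tsv, hotspots.tsv, catalog.tsv,
    annotations.tsv and manifest.json.
    """
    if catalog is None:
        catalog = synthetic_signature_catalog(names=tuple(config.signature_names))
    missing = set(config.signature_names) - set(catalog.names)
    if missing:
        raise ConfigurationError(f"catalog lacks signature(s): {sorted(missing)}")
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(5 + config.n_samples)
    ref_stream, hs_stream, spike_stream, pon_stream, ann_stream = streams[:5]
    sample_streams = streams[5:]
    if reference is None:
        ref_seed = int(ref_stream.generate_state(1)[0] % (2**31))
        reference = generate_reference(config.reference_length, config.gc_content, seed=ref_seed)
    L = len(reference)
    chrom = config.chrom
    ctx_index = _ContextIndex(reference)

    hotspot_table = make_hotspot_table(reference, chrom, np.random.default_rng(hs_stream), ctx_index)
    hotspot_positions = set(int(p) for p in hotspot_table.table["pos"])
    normals, pon, pon_positions = _simulate_normals(
        reference,
        chrom,
        config.n_normals,
        config.pon_artifact_count,
        hotspot_positions,
        np.random.default_rng(pon_stream),
    )
    reserved = hotspot_positions | pon_positions

    sig_matrix = catalog.matrix[config.signature_names]
    K = len(config.signature_names)
    window_size = int(round(config.capture_fraction * L))
    clean_variants: dict[str, list[VariantRecord]] = {}
    all_variants: dict[str, list[VariantRecord]] = {}
    capture_windows: dict[str, tuple[int, int]] = {}
    coverage: dict[str, pd.DataFrame] = {}
    true_counts = np.zeros((K, config.n_samples), dtype=int)
    planted_failures: list[dict] = []

    for j, (sample, stream) in enumerate(zip(config.sample_ids, sample_streams)):
        rng = np.random.default_rng(stream)
        start = int(rng.integers(1, L - window_size + 2)) if window_size < L else 1
        lo, hi = start, start + window_size - 1
        capture_windows[sample] = (start, window_size)
        # hierarchical draw: per-signature counts, then per-channel counts
        counts_k = rng.multinomial(int(config.mutations_per_sample[j]), config.mixture_weights[j])
        true_counts[:, j] = counts_k
        channel_counts = np.zeros(96, dtype=int)
        for k in range(K):
            if counts_k[k]:
                channel_counts += rng.multinomial(counts_k[k], sig_matrix.iloc[:, k].to_numpy())
        blocked = set(reserved)
        recs: list[VariantRecord] = []
        lo_p, hi_p = max(lo, 2), min(hi, L - 1)  # placed variants need both flanks
        for c in np.nonzero(channel_counts)[0]:
            for pos, ref, alt in _place_channel(
                CHANNEL_LABELS[c],
                int(channel_counts[c]),
                ctx_index,
                reference,
                lo_p,
                hi_p,
                blocked,
                rng,
            ):
                blocked.add(pos)
                qs, dp, af = _clean_annotations(rng)
                recs.append(
                    VariantRecord(
                        sample_id=sample,
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        quality_score=qs,
                        depth=dp,
                        population_af=af,
                    )
                )
        clean_variants[sample] = recs
        augmented, labels = inject_filter_failures(
            recs or [],
            config.filter_failure_counts,
            pon,
            rng,
            reference=reference,
            chrom=chrom,
            blocked=blocked,
        )
        for lab in labels:
            lab["sample"] = sample
        planted_failures.extend(labels)
        # failure records injected into an empty sample need the right id
        augmented = [
            dataclasses.replace(r, sample_id=sample) if r.sample_id != sample else r
            for r in augmented
        ]
        all_variants[sample] = augmented
        # dense coverage: the capture window at >= 20x, a flank below 20x
        flank = 30
        f_lo = max(1, lo - flank)
        f_hi = min(L, hi + flank)
        pos_arr = np.arange(f_lo, f_hi + 1)
        depth = np.where(
            (pos_arr >= lo) & (pos_arr <= hi),
            rng.integers(20, 120, size=pos_arr.size),
            rng.integers(0, 20, size=pos_arr.size),
        )
        coverage[sample] = pd.DataFrame({"chrom": chrom, "pos": pos_arr, "depth": depth})

    hyper = list(config.hotspot_samples)
    all_variants, spiked = spike_hotspots(
        all_variants,
        hotspot_table,
        hyper,
        reference=reference,
        seed=np.random.default_rng(spike_stream),
    )

    capture_sizes = {s: size for s, (_, size) in capture_windows.items()}
    true_tmb = true_counts / np.array([capture_sizes[s] for s in config.sample_ids]) * 1e6
    manifest = GroundTruthManifest(
        signature_names=list(config.signature_names),
        sample_ids=list(config.sample_ids),
        true_signatures=sig_matrix.copy(),
        true_weights=pd.DataFrame(
            config.mixture_weights.T, index=config.signature_names, columns=config.sample_ids
        ),
        true_counts=pd.DataFrame(
            true_counts, index=config.signature_names, columns=config.sample_ids
        ),
        true_tmb=pd.DataFrame(true_tmb, index=config.signature_names, columns=config.sample_ids),
        capture_sizes=capture_sizes,
        spiked_hotspots=spiked,
        planted_failures=planted_failures,
    )
    annotations = _simulate_annotations(
        config.sample_ids, set(hyper), np.random.default_rng(ann_stream)
    )
    cohort = SimulatedCohort(
        config=config,
        reference=reference,
        catalog=catalog,
        variants=all_variants,
        clean_variants=clean_variants,
        capture_windows=capture_windows,
        panel_of_normals=pon,
        normal_variant_sets=normals,
        hotspot_table=hotspot_table,
        manifest=manifest,
        annotations=annotations,
        coverage=coverage,
        out_dir=None,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir), coverage)
        cohort.out_dir = Path(out_dir)
    return cohort


def _write_cohort(cohort: SimulatedCohort, out: Path, coverage: dict[str, pd.DataFrame]) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "vcf").mkdir(exist_ok=True)
    (out / "coverage").mkdir(exist_ok=True)
    chrom = cohort.config.chrom
    write_fasta(cohort.reference, out / "reference.fasta", chrom=chrom)
    for sample, recs in cohort.variants.items():
        write_vcf(recs, out / "vcf" / f"{sample}.vcf", chrom=chrom, chrom_length=len(cohort.reference))
    for sample, df in coverage.items():
        df.to_csv(out / "coverage" / f"{sample}.coverage.tsv", sep="\t", index=False)
    write_site_table(cohort.panel_of_normals, out / "pon.tsv")
    cohort.hotspot_table.to_tsv(out / "hotspots.tsv")
    cohort.catalog.to_tsv(out / "catalog.tsv")
    cohort.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    cohort.manifest.to_json(out / "manifest.json")
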