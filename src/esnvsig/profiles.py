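"""Build 96-channel mutational profiles from filtered variants.

The profile matrix counts each sample's variants over the 96
substitution-in-context channels (rows, fixed catalog order; see
:mod:`esnvsig.channels`). Counts, not proportions, are stored so the
mutation-count scale survives factorization and can be converted to
mutations per megabase downstream; proportion views are derived.

Variants whose trinucleotide context cannot be resolved (an N base, or a
position at the very edge of the reference with no flanking base) are
skipped and tallied per sample rather than guessed, so column sums plus
skips always equal the input variant count.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

from .channels import CHANNEL_LABELS, channel_index
from .errors import AmbiguousContextError, DataError
from .variants import VariantRecord


@dataclasses.dataclass
class ProfileMatrix:
    """96 x N mutation-count matrix plus per-sample skip tallies.

    ``counts`` is a DataFrame indexed by the 96 channel labels with one
    column per sample.
    """

    counts: pd.DataFrame
    skipped: dict[str, int]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def channel_labels(self) -> list[str]:
        return list(self.counts.index)

    def proportions(self) -> pd.DataFrame:
        """Per-sample channel proportions (zero columns stay zero)."""
        totals = self.counts.sum(axis=0)
        safe = totals.replace(0, 1)
        return self.counts / safe

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="channel")
        if list(df.index) != list(CHANNEL_LABELS):
            raise DataError(f"profile matrix {path} rows are not in catalog channel order")
        return cls(counts=df, skipped={})


class _SequenceSource:
    """Uniform access to a reference by path, pyfaidx handle, dict or str."""

    def __init__(self, reference):
        self._fasta = None
        self._seqs = None
        if isinstance(reference, pyfaidx.Fasta):
            self._fasta = reference
        elif isinstance(reference, Mapping):
            self._seqs = {k: str(v).upper() for k, v in reference.items()}
        elif isinstance(reference, Path):
            self._fasta = pyfaidx.Fasta(str(reference))
        elif isinstance(reference, str):
            # a bare A/C/G/T(/N) string is a single-contig sequence, else a path
            probe = reference[:512].upper()
            if probe and set(probe) <= set("ACGTN"):
                self._seqs = {None: reference.upper()}
            else:
                self._fasta = pyfaidx.Fasta(reference)
        else:
            raise TypeError(f"unsupported reference type {type(reference)!r}")

    def length(self, chrom: str) -> int:
        if self._fasta is not None:
            return len(self._fasta[chrom])
        seqs = self._seqs
        return len(seqs[chrom if chrom in seqs else None])

    def context(self, chrom: str, pos: int) -> str:
        """Trinucleotide (pos-1, pos, pos+1), 1-based; raises at edges."""
        if pos < 2 or pos + 1 > self.length(chrom):
            raise AmbiguousContextError(f"no flanking base at {chrom}:{pos}")
        if self._fasta is not None:
            return str(self._fasta[chrom][pos - 2 : pos + 1]).upper()
        seqs = self._seqs
        seq = seqs[chrom if chrom in seqs else None]
        return seq[pos - 2 : pos + 1]


def build_profiles(
    variants_by_sample: Mapping[str, Iterable[VariantRecord]],
    reference,
    sample_ids: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Assemble the cohort 96 x N count matrix.

    Parameters
    ----------
    variants_by_sample : mapping of sample id -> filtered variant records
    reference : FASTA path, ``pyfaidx.Fasta``, chrom->sequence mapping, or
        a bare sequence string for single-contig data.
    sample_ids : column order; defaults to the mapping's key order.

    Raises
    ------
    DataError
        If a variant's REF base disagrees with the reference sequence —
        that is a corrupt input, not a skippable ambiguity.
    """
    source = _SequenceSource(reference)
    if sample_ids is None:
        sample_ids = list(variants_by_sample.keys())
    counts = np.zeros((96, len(sample_ids)), dtype=np.int64)
    skipped: dict[str, int] = {s: 0 for s in sample_ids}
    for j, sample in enumerate(sample_ids):
        for rec in variants_by_sample.get(sample, ()):
            try:
                ctx = source.context(rec.chrom, rec.pos)
            except AmbiguousContextError:
                skipped[sample] += 1
                continue
            if ctx[1] != rec.ref:
                raise DataError(
                    f"REF mismatch at {rec.chrom}:{rec.pos} in sample {sample}: "
                    f"VCF says {rec.ref}, reference has {ctx[1]}"
                )
            try:
                k = channel_index(ctx, rec.ref, rec.alt)
            except AmbiguousContextError:
                skipped[sample] += 1
                continue
            counts[k, j] += 1
    df = pd.DataFrame(counts, index=list(CHANNEL_LABELS), columns=list(sample_ids))
    return ProfileMatrix(counts=df, skipped=skipped)
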