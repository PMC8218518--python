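"""The 96 single-base-substitution channels and pyrimidine-strand collapse.

A mutational signature is a probability distribution over 96 channels: the
six pyrimidine-reference substitution classes (C>A, C>G, C>T, T>A, T>C,
T>G) crossed with the 4 x 4 possible flanking bases. Substitutions observed
with a purine reference base (A or G) are reverse-complemented onto the
pyrimidine strand before classification, so e.g. an A>C at context "TAG"
is the same channel as a T>G at "CTA".

Channel ordering is fixed to the standard catalog row order: substitution
blocks in the order above; within a block the 5' flank varies slowest and
the 3' flank fastest, each in A, C, G, T order. Channel 0 is "A[C>A]A",
channel 95 is "T[T>G]T".
"""

from __future__ import annotations

from .errors import AmbiguousContextError

BASES = "ACGT"
PYRIMIDINES = "CT"
SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTIONS)}


def complement(base: str) -> str:
    """Watson-Crick complement of a single base."""
    return _COMPLEMENT[base]


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _make_labels() -> tuple[str, ...]:
    labels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return tuple(labels)


#: The 96 channel labels in fixed catalog order, e.g. "A[C>A]A" ... "T[T>G]T".
CHANNEL_LABELS: tuple[str, ...] = _make_labels()

_LABEL_INDEX = {lab: i for i, lab in enumerate(CHANNEL_LABELS)}


def channel_index(context: str, ref: str, alt: str) -> int:
    """Map a substitution in its trinucleotide context to a channel in [0, 95].

    Parameters
    ----------
    context : str
        The three reference bases centred on the mutated base;
        ``context[1]`` must equal ``ref``.
    ref, alt : str
        The reference and alternate base of the substitution.

    If ``ref`` is a purine the substitution and its context are
    reverse-complemented first (pyrimidine-strand collapse).

    Raises
    ------
    AmbiguousContextError
        If the context is not three A/C/G/T bases (the caller should skip
        the variant and tally it, not guess).
    ValueError
        If ``context[1] != ref`` or ``ref == alt``.
    """
    context = context.upper()
    ref = ref.upper()
    alt = alt.upper()
    if len(context) != 3 or any(b not in _BASE_INDEX for b in context):
        raise AmbiguousContextError(f"unresolvable trinucleotide context {context!r}")
    if alt not in _BASE_INDEX:
        raise AmbiguousContextError(f"non-ACGT alternate base {alt!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} is not centred on ref base {ref!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are both {ref!r}")
    if ref not in PYRIMIDINES:
        context = revcomp(context)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    sub = _SUB_INDEX[f"{ref}>{alt}"]
    return 16 * sub + 4 * _BASE_INDEX[context[0]] + _BASE_INDEX[context[2]]


def channel_label(index: int) -> str:
    """Label ("A[C>A]A" style) for a channel index."""
    return CHANNEL_LABELS[index]


def label_to_index(label: str) -> int:
    """Inverse of :func:`channel_label`."""
    return _LABEL_INDEX[label]
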