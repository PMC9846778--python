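"""Canonical SBS-96 trinucleotide mutation-context schema.

Single-base substitutions are classified on the pyrimidine strand into six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each flanked by one of
the four bases on the 5' and 3' side, giving 96 categories written as e.g.
``A[C>A]A``. The canonical ordering used throughout this package is the
COSMIC file ordering: substitution class first, then 5' flank, then 3'
flank, each alphabetically. This module is the single source of truth for
that ordering.
"""

from __future__ import annotations

SUBSTITUTION_CLASSES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: The 96 context labels in canonical (COSMIC) order.
SBS96_CONTEXTS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in _BASES
    for three in _BASES
)

_CONTEXT_INDEX = {label: i for i, label in enumerate(SBS96_CONTEXTS)}

N_CONTEXTS = 96


class ContextSchemaError(ValueError):
    """Raised when a set of context labels does not form a valid SBS-96 schema."""


def validate_context_labels(labels) -> list[int]:
    """Check that *labels* is a permutation of the 96 canonical contexts.

    Returns the permutation ``perm`` such that ``labels[perm[i]]`` is the
    i-th canonical context, i.e. an index array that reorders data stored in
    *labels* order into canonical order.
    """
    labels = list(labels)
    if len(labels) != N_CONTEXTS:
        raise ContextSchemaError(
            f"expected {N_CONTEXTS} context labels, got {len(labels)}"
        )
    seen = set()
    for lab in labels:
        if lab not in _CONTEXT_INDEX:
            raise ContextSchemaError(f"unrecognised SBS-96 context label: {lab!r}")
        if lab in seen:
            raise ContextSchemaError(f"duplicate context label: {lab!r}")
        seen.add(lab)
    position = {lab: i for i, lab in enumerate(labels)}
    return [position[lab] for lab in SBS96_CONTEXTS]


def substitution_class(label: str) -> str:
    """Return the substitution class (e.g. ``"C>A"``) of a context label."""
    return label[2:5]
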