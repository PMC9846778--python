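"""Containers and TSV I/O for SBS-96 signature tables and mutational catalogues.

Two tabular dialects are supported, both plain tab-separated text:

* **Signature table** (COSMIC SBS dialect): first column ``Type`` holding the
  96 context labels, one column per signature. Profiles are renormalised on
  read so that files expressed as probabilities or percentages are treated
  alike.
* **Catalogue table**: first column the context label, one integer column per
  sample.

Internally, signatures are stored *signatures x 96* (each row a probability
profile over the canonical context order) and catalogues *96 x samples*
(integer counts). Converters between the two orientations are explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contexts import N_CONTEXTS, SBS96_CONTEXTS, validate_context_labels

__all__ = [
    "SignatureMatrix",
    "MutationalCatalogue",
    "DEFAULT_ARTEFACT_SIGNATURES",
    "read_signature_table",
    "write_signature_table",
    "read_catalogue",
    "write_catalogue",
    "filter_artefact_signatures",
]

#: Signatures annotated "Possible sequencing artefact" in COSMIC v3.3.
#: Reconstructed from the public COSMIC signature annotations; always
#: overridable by the caller.
DEFAULT_ARTEFACT_SIGNATURES: tuple[str, ...] = (
    "SBS27",
    "SBS43",
    "SBS45",
    "SBS46",
    "SBS47",
    "SBS48",
    "SBS49",
    "SBS50",
    "SBS51",
    "SBS52",
    "SBS53",
    "SBS54",
    "SBS55",
    "SBS56",
    "SBS57",
    "SBS58",
    "SBS59",
    "SBS60",
    "SBS95",
)


class FormatError(ValueError):
    """Malformed input table (labels missing, duplicated or unparseable)."""


@dataclass
class SignatureMatrix:
    """A set of SBS-96 signature profiles, one per row.

    Attributes
    ----------
    names : list of str
        Unique signature identifiers (e.g. ``"SBS1"``).
    values : ndarray of shape (n_signatures, 96)
        Nonnegative profiles in canonical context order, each row summing
        to 1.
    """

    names: list[str]
    values: np.ndarray
    contexts: tuple[str, ...] = field(default=SBS96_CONTEXTS, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_CONTEXTS:
            raise ValueError(
                f"signature matrix must be (n, {N_CONTEXTS}); got {self.values.shape}"
            )
        if len(self.names) != self.values.shape[0]:
            raise ValueError("number of names does not match number of rows")
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if np.any(self.values < 0):
            raise ValueError("signature profiles must be nonnegative")
        row_sums = self.values.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("signature profiles must have positive total mass")
        if not np.allclose(row_sums, 1.0, atol=1e-8):
            raise ValueError("signature rows must be L1-normalised to 1 (+-1e-8)")

    @property
    def n_signatures(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Contexts-as-rows DataFrame in the COSMIC orientation."""
        return pd.DataFrame(
            self.values.T, index=list(self.contexts), columns=self.names
        ).rename_axis("Type")

    @classmethod
    def from_profiles(cls, names, profiles) -> "SignatureMatrix":
        """Build from raw nonnegative profiles, renormalising each row."""
        profiles = np.asarray(profiles, dtype=float)
        sums = profiles.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValueError("cannot normalise an all-zero profile")
        return cls(list(names), profiles / sums)

    def select(self, names) -> "SignatureMatrix":
        """Sub-matrix restricted to *names*, in the given order."""
        index = {n: i for i, n in enumerate(self.names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown signature names: {missing}")
        rows = [index[n] for n in names]
        return SignatureMatrix(list(names), self.values[rows])


@dataclass
class MutationalCatalogue:
    """A 96 x samples matrix of somatic mutation counts."""

    sample_ids: list[str]
    counts: np.ndarray
    contexts: tuple[str, ...] = field(default=SBS96_CONTEXTS, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != N_CONTEXTS:
            raise ValueError(
                f"catalogue must be ({N_CONTEXTS}, n_samples); got {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                raise ValueError("catalogue counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise ValueError("catalogue counts must be nonnegative")
        if len(self.sample_ids) != counts.shape[1]:
            raise ValueError("number of sample ids does not match number of columns")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def total_mutations(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.contexts), columns=self.sample_ids
        ).rename_axis("MutationType")


def _read_context_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("expected a context column plus at least one data column")
    labels = df.iloc[:, 0].astype(str).tolist()
    try:
        perm = validate_context_labels(labels)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc
    data = df.iloc[:, 1:]
    return data.iloc[perm].set_axis(list(SBS96_CONTEXTS), axis=0)


def read_signature_table(path, dialect: str = "cosmic_v3") -> SignatureMatrix:
    """Read a COSMIC-dialect SBS TSV into a :class:`SignatureMatrix`.

    Rows are reordered to canonical context order and each signature column
    is renormalised to sum to 1 (published files vary between probabilities
    and percentages), then transposed into the signatures-as-rows internal
    convention.
    """
    if dialect != "cosmic_v3":
        raise ValueError(f"unknown signature-table dialect: {dialect!r}")
    data = _read_context_table(path)
    values = data.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("signature table contains negative entries")
    return SignatureMatrix.from_profiles(list(data.columns), values.T)


def write_signature_table(sig: SignatureMatrix, path) -> None:
    """Write a signature matrix in the COSMIC TSV dialect (contexts as rows)."""
    sig.to_frame().to_csv(path, sep="\t", float_format="%.18g")


def read_catalogue(path) -> MutationalCatalogue:
    """Read a catalogue TSV (context rows, integer sample columns)."""
    data = _read_context_table(path)
    values = data.to_numpy()
    if not np.all(values == np.floor(np.asarray(values, dtype=float))):
        raise ValueError("catalogue cells must be integers")
    return MutationalCatalogue(list(data.columns), np.asarray(values, dtype=np.int64))


def write_catalogue(cat: MutationalCatalogue, path) -> None:
    """Write a catalogue TSV; ``read_catalogue`` round-trips it bit-exactly."""
    cat.to_frame().to_csv(path, sep="\t")


def filter_artefact_signatures(
    sig: SignatureMatrix, exclude=DEFAULT_ARTEFACT_SIGNATURES
) -> SignatureMatrix:
    """Drop the named artefact signatures, preserving the order of the rest.

    Names in *exclude* that are absent from *sig* trigger a warning listing
    them (they are reported, never silently ignored). Removing every
    signature is an error.
    """
    exclude = list(exclude)
    present = set(sig.names)
    unknown = [n for n in exclude if n not in present]
    if unknown:
        warnings.warn(
            f"exclusion list contains signatures absent from the matrix: {unknown}",
            UserWarning,
            stacklevel=2,
        )
    excluded = set(exclude)
    keep = [n for n in sig.names if n not in excluded]
    if not keep:
        raise ValueError("artefact filtering removed every signature")
    return sig.select(keep)
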