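"""Nucleotide alignment container, file I/O, and site classification.

Alignments are held as a small integer matrix (taxa x sites) over the alphabet
A=0, C=1, G=2, T=3, with every IUPAC ambiguity code, gap, or unknown character
mapped to a single missing-state code. All statistics downstream exclude
missing cells from nucleotide counts and base frequencies.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlignmentFormatError,
    DuplicateLabelError,
    EmptyInputError,
    UndefinedCompositionError,
)

__all__ = [
    "MISSING",
    "Alignment",
    "SiteCounts",
    "BaseComposition",
    "read_alignment",
    "write_alignment",
    "site_counts",
    "site_count_matrix",
    "informative_mask",
    "base_frequencies",
]

#: Integer code for a missing / ambiguous / gap state.
MISSING = 4

_ALPHABET = "ACGT"

# 'U' is read as T so RNA-style files are usable; every other non-ACGT symbol
# (IUPAC ambiguity codes, '-', '?', '.', 'N', ...) is missing data.
_CHAR_TO_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_CHAR_TO_CODE["U"] = 3

_CODE_TO_CHAR = np.array(list(_ALPHABET + "-"))


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), MISSING, dtype=np.uint8)
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    for ch, code in _CHAR_TO_CODE.items():
        out[arr == ord(ch)] = code
    return out


@dataclass(eq=False)
class Alignment:
    """A taxon-labelled nucleotide matrix.

    Attributes
    ----------
    taxa:
        Ordered, unique, non-empty taxon labels.
    states:
        ``(n_taxa, n_sites)`` uint8 matrix with values in ``{0..3, MISSING}``.
    """

    taxa: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        self.taxa = tuple(self.taxa)
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise AlignmentFormatError("states must be a 2-D matrix")
        if len(self.taxa) != self.states.shape[0]:
            raise AlignmentFormatError("number of labels does not match matrix rows")
        if any(not t for t in self.taxa):
            raise AlignmentFormatError("empty taxon label")
        if len(set(self.taxa)) != len(self.taxa):
            raise DuplicateLabelError("duplicate taxon labels")
        if self.states.size and self.states.max() > MISSING:
            raise AlignmentFormatError("state codes out of range")

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @classmethod
    def from_sequences(cls, pairs) -> "Alignment":
        """Build from an iterable of ``(label, sequence-string)`` pairs."""
        pairs = list(pairs)
        if not pairs:
            raise EmptyInputError("no sequences")
        labels = [str(lab) for lab, _ in pairs]
        seqs = [str(s) for _, s in pairs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        states = np.vstack([_encode(s) for s in seqs]) if seqs[0] else np.zeros(
            (len(seqs), 0), dtype=np.uint8
        )
        return cls(tuple(labels), states)

    def sequence(self, index: int) -> str:
        """Decoded sequence string for one taxon; missing cells become ``-``."""
        return "".join(_CODE_TO_CHAR[self.states[index]])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.states, other.states)


@dataclass(frozen=True)
class SiteCounts:
    """Nucleotide counts (A, C, G, T) at one alignment column."""

    counts: np.ndarray
    n_obs: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.counts.shape != (4,) or (self.counts < 0).any():
            raise ValueError("counts must be a non-negative 4-vector")
        if int(self.counts.sum()) != self.n_obs:
            raise ValueError("n_obs must equal sum(counts)")


@dataclass(frozen=True)
class BaseComposition:
    """Pooled nucleotide frequencies over a set of alignment columns."""

    p: np.ndarray
    source: str = "all_sites"
    n_effective: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p must be a 4-simplex")


# ---------------------------------------------------------------------------
# File I/O (Bio.AlignIO behind the scenes)
# ---------------------------------------------------------------------------

_EXT_FORMAT = {
    ".fa": "fasta",
    ".fas": "fasta",
    ".fasta": "fasta",
    ".fna": "fasta",
    ".phy": "phylip",
    ".phylip": "phylip",
    ".nex": "nexus",
    ".nexus": "nexus",
    ".nxs": "nexus",
}

_BIO_FORMAT = {"fasta": "fasta", "phylip": "phylip-relaxed", "nexus": "nexus"}


def _sniff_format(path: str) -> str:
    with open(path, "r", errors="replace") as fh:
        for line in fh:
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                return "fasta"
            if stripped.startswith("#"):
                return "nexus"
            if stripped.split()[0].isdigit():
                return "phylip"
            break
    raise AlignmentFormatError(f"cannot determine alignment format of {path!r}")


def read_alignment(path: str, format: str = "auto") -> Alignment:
    """Read a nucleotide alignment from FASTA, relaxed PHYLIP, or NEXUS.

    ``format='auto'`` resolves by file extension, then by content sniffing
    (``>`` record marker, ``#NEXUS`` header, or a numeric PHYLIP header line).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise EmptyInputError(f"empty file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = _EXT_FORMAT.get(os.path.splitext(path)[1].lower()) or _sniff_format(path)
    if fmt not in _BIO_FORMAT:
        raise ValueError(f"unknown format {format!r}")
    try:
        msa = AlignIO.read(path, _BIO_FORMAT[fmt])
    except ValueError as exc:
        msg = str(exc).lower()
        if "no records" in msg or "empty" in msg:
            raise EmptyInputError(f"no sequences in {path}") from exc
        raise AlignmentFormatError(f"cannot parse {path!r} as {fmt}: {exc}") from exc
    return Alignment.from_sequences((rec.id, str(rec.seq)) for rec in msa)


def write_alignment(aln: Alignment, path: str, format: str = "fasta") -> None:
    """Write an alignment; missing states are emitted as ``-``.

    Round-trips through :func:`read_alignment` preserve labels and the
    encoded state matrix for all three formats (relaxed PHYLIP keeps
    full-length names rather than truncating at 10 characters).
    """
    fmt = format.lower()
    if fmt not in _BIO_FORMAT:
        raise ValueError(f"unknown format {format!r}")
    records = [
        SeqRecord(Seq(aln.sequence(i)), id=label, description="",
                  annotations={"molecule_type": "DNA"})
        for i, label in enumerate(aln.taxa)
    ]
    msa = MultipleSeqAlignment(records)
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, _BIO_FORMAT[fmt])


# ---------------------------------------------------------------------------
# Per-site statistics
# ---------------------------------------------------------------------------


def site_count_matrix(aln: Alignment) -> np.ndarray:
    """``(n_sites, 4)`` matrix of per-column A/C/G/T counts (missing excluded)."""
    return np.stack(
        [(aln.states == k).sum(axis=0) for k in range(4)], axis=1
    ).astype(np.int64)


def site_counts(aln: Alignment, site_index: int) -> SiteCounts:
    """Nucleotide counts at one (0-based) column."""
    if not 0 <= site_index < aln.n_sites:
        raise IndexError(f"site index {site_index} out of range [0, {aln.n_sites})")
    col = aln.states[:, site_index]
    counts = np.array([(col == k).sum() for k in range(4)], dtype=np.int64)
    return SiteCounts(counts, int(counts.sum()))


def informative_mask(aln: Alignment) -> np.ndarray:
    """Boolean vector marking parsimony-informative columns.

    A column is informative when at least two distinct nucleotides each occur
    in at least two sequences; missing states never contribute.
    """
    counts = site_count_matrix(aln)
    return (counts >= 2).sum(axis=1) >= 2


def base_frequencies(
    aln: Alignment, mask: np.ndarray | None = None, source: str | None = None
) -> BaseComposition:
    """Pooled nucleotide frequencies over selected columns.

    Frequencies are tallied over every non-missing cell of the selected
    columns.  ``n_effective`` records the modal per-column observation count
    (ties resolved toward the larger count), which is the taxon count used as
    ``n`` in the full-saturation entropy.
    """
    counts = site_count_matrix(aln)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (aln.n_sites,):
            raise ValueError("mask length must equal n_sites")
        counts = counts[mask]
        if source is None:
            source = "informative_sites"
    if source is None:
        source = "all_sites"
    total = counts.sum()
    if total == 0:
        raise UndefinedCompositionError("selected sites contain no non-missing states")
    n_obs = counts.sum(axis=1)
    n_obs = n_obs[n_obs > 0]
    values, freq = np.unique(n_obs, return_counts=True)
    # modal n_obs; on ties prefer the larger (more complete) column class
    n_eff = int(values[np.nonzero(freq == freq.max())[0][-1]])
    return BaseComposition(counts.sum(axis=0) / total, source=source, n_effective=n_eff)
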