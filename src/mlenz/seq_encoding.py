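"""Raw protein encodings: sequence one-hot, PSSM profile, domain presence.

A protein instance is represented by three raw encodings that are fed to
separate branches of the network:

* an ``L x 20`` one-hot matrix of the amino-acid sequence itself,
* an ``L x 20`` position-specific scoring matrix (PSSM) capturing
  evolutionary information, read from a PSI-BLAST ASCII profile and scaled
  to ``[0, 1]``,
* a fixed-length binary vector marking which entries of a functional-domain
  vocabulary (e.g. Pfam families reported by HMMER) are hit.

Columns of both ``L x 20`` matrices follow the fixed alphabetical residue
ordering :data:`AMINO_ACIDS` ('A' is column 0, 'C' is column 1, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Fixed column ordering of the 20 standard amino acids (alphabetical by
#: one-letter code). Persisted with trained models; never reorder.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Canonical substitutes for ambiguous/non-standard residue codes, applied
#: only when a caller opts in (``map_nonstandard=True``). 'X' has no single
#: canonical substitute and always raises.
NONSTANDARD_MAP = {"B": "D", "Z": "E", "U": "C", "O": "K", "J": "L"}


class EncodingError(ValueError):
    """Raised when a raw input violates an encoding contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the 20 standard residues."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise EncodingError(f"record {self.id!r}: empty sequence")
        for ch in self.sequence:
            if ch not in _AA_INDEX:
                raise EncodingError(
                    f"record {self.id!r}: non-standard residue {ch!r} "
                    f"(accepted alphabet: {AMINO_ACIDS})"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OneHotMatrix:
    """``L x 20`` binary matrix; exactly one 1 per row."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[1] != 20:
            raise EncodingError(f"one-hot matrix must be L x 20, got {v.shape}")


@dataclass(frozen=True)
class PssmMatrix:
    """``L x 20`` residue profile scaled to ``[0, 1]``.

    ``source`` records provenance: ``"parsed"`` for a real PSI-BLAST
    profile, ``"fallback"`` for the degenerate one-hot profile used when no
    profile file is available.
    """

    values: np.ndarray
    source: str = "parsed"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[1] != 20:
            raise EncodingError(f"PSSM matrix must be L x 20, got {v.shape}")
        if self.source not in ("parsed", "fallback"):
            raise EncodingError(f"unknown PSSM source tag {self.source!r}")


@dataclass(frozen=True)
class DomainVector:
    """Binary presence vector over a fixed, ordered domain vocabulary."""

    values: np.ndarray
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.vocabulary),):
            raise EncodingError(
                f"domain vector length {self.values.shape} does not match "
                f"vocabulary size {len(self.vocabulary)}"
            )


@dataclass(frozen=True)
class EncodedProtein:
    """The three raw representations of one sequence, kept together."""

    one_hot: OneHotMatrix
    pssm: PssmMatrix
    domains: DomainVector

    def __post_init__(self) -> None:
        if self.one_hot.values.shape[0] != self.pssm.values.shape[0]:
            raise EncodingError(
                "one-hot and PSSM row counts differ: "
                f"{self.one_hot.values.shape[0]} vs {self.pssm.values.shape[0]}"
            )

    @property
    def length(self) -> int:
        return self.one_hot.values.shape[0]


def _normalize_sequence(seq: str, record_id: str, map_nonstandard: bool) -> str:
    seq = seq.upper()
    if not map_nonstandard:
        return seq
    out = []
    for ch in seq:
        if ch in NONSTANDARD_MAP:
            out.append(NONSTANDARD_MAP[ch])
        elif ch == "X":
            raise EncodingError(
                f"record {record_id!r}: residue 'X' has no canonical substitute"
            )
        else:
            out.append(ch)
    return "".join(out)


def read_fasta(path: str | Path, map_nonstandard: bool = False) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are upper-cased. The record id is the header token up to the
    first whitespace. With ``map_nonstandard=True`` the ambiguous codes
    B/Z/U/O/J are mapped to canonical substitutes (see
    :data:`NONSTANDARD_MAP`); otherwise any non-standard letter is an error.

    Raises
    ------
    EncodingError
        If the file contains no records, or a sequence contains a character
        outside the 20-letter alphabet after normalization.
    """
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _normalize_sequence(str(entry.seq), entry.id, map_nonstandard)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise EncodingError(f"no FASTA records found in {path}")
    return records


def one_hot_encode(record: ProteinRecord) -> OneHotMatrix:
    """Encode a sequence as an ``L x 20`` one-hot matrix.

    Row *i* has its single 1 in the column of residue *i* under the
    alphabetical ordering ``ACDEFGHIKLMNPQRSTVWY`` ('A' -> column 0,
    'C' -> column 1).
    """
    idx = np.fromiter((_AA_INDEX[ch] for ch in record.sequence), dtype=np.intp)
    m = np.zeros((len(record), 20))
    m[np.arange(len(record)), idx] = 1.0
    return OneHotMatrix(values=m)


def fallback_pssm(record: ProteinRecord) -> PssmMatrix:
    """Degenerate profile used when no PSI-BLAST PSSM is available.

    Places each position's entire frequency mass on the observed residue,
    i.e. the one-hot matrix reinterpreted as a profile.
    """
    return PssmMatrix(values=one_hot_encode(record).values, source="fallback")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def parse_pssm(
    path: str | Path, record: ProteinRecord, columns: str = "percentages"
) -> PssmMatrix:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm`` dialect).

    Each data row carries the position, the residue letter, 20 log-odds
    integers and 20 percentage columns. By default the percentage columns
    are returned divided by 100 (observed residue frequencies in [0, 1]);
    with ``columns="log_odds"`` the log-odds block is used instead, squashed
    to [0, 1] by the logistic function.

    The residue column must match ``record.sequence`` position by position
    and the number of data rows must equal the sequence length.
    """
    if columns not in ("percentages", "log_odds"):
        raise ValueError(f"columns must be 'percentages' or 'log_odds', got {columns!r}")
    rows: list[np.ndarray] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Data rows start with an integer position then a residue letter.
            if len(parts) < 2 or not parts[0].isdigit():
                continue
            if len(parts[1]) != 1 or not parts[1].isalpha():
                continue
            fields = parts[2:]
            if len(fields) < 40:
                raise EncodingError(
                    f"{path}: malformed PSSM row at line {lineno}: expected at "
                    f"least 40 numeric columns, found {len(fields)}"
                )
            try:
                numbers = np.array([float(x) for x in fields[:40]])
            except ValueError as exc:
                raise EncodingError(
                    f"{path}: malformed PSSM row at line {lineno}: {exc}"
                ) from exc
            letters.append(parts[1].upper())
            rows.append(numbers)
    if len(rows) != len(record):
        raise EncodingError(
            f"{path}: PSSM has {len(rows)} rows but record {record.id!r} "
            f"has length {len(record)}"
        )
    for pos, (letter, expected) in enumerate(zip(letters, record.sequence)):
        if letter != expected:
            raise EncodingError(
                f"{path}: residue mismatch at position {pos}: PSSM has "
                f"{letter!r}, record {record.id!r} has {expected!r}"
            )
    block = np.stack(rows)
    if columns == "percentages":
        values = block[:, 20:40] / 100.0
    else:
        values = _logistic(block[:, 0:20])
    return PssmMatrix(values=values, source="parsed")


def domain_encode(
    hits: Iterable[str], vocabulary: Sequence[str]
) -> DomainVector:
    """Encode domain hits as a binary vector over a fixed vocabulary.

    ``output[j] == 1`` iff ``vocabulary[j]`` appears among ``hits``. Hits
    outside the vocabulary are not an error: they are counted and reported
    through the warnings channel so callers can audit vocabulary coverage.
    """
    vocab = tuple(vocabulary)
    if not vocab:
        raise EncodingError("domain vocabulary must be non-empty")
    if len(set(vocab)) != len(vocab):
        raise EncodingError("domain vocabulary contains duplicate identifiers")
    hit_set = set(hits)
    unknown = hit_set - set(vocab)
    if unknown:
        warnings.warn(
            f"{len(unknown)} domain hit(s) outside the vocabulary ignored: "
            f"{sorted(unknown)[:5]}",
            stacklevel=2,
        )
    values = np.array([1.0 if d in hit_set else 0.0 for d in vocab])
    return DomainVector(values=values, vocabulary=vocab)


def parse_domain_hits(path: str | Path) -> list[str]:
    """Read domain identifiers from a plain list or an HMMER tblout table.

    Plain lists carry one identifier per line. In tblout tables comment
    lines start with ``#`` and the accession is taken from the fourth
    whitespace-separated column (falling back to the first when the row is
    too short). Returns unique identifiers in first-appearance order.
    """
    seen: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 1:
                ident = parts[0]
            else:
                # tblout: target name, accession, query name, accession, ...
                ident = parts[3] if len(parts) >= 4 and parts[3] != "-" else parts[0]
            seen.setdefault(ident, None)
    return list(seen)


def encode_protein(
    record: ProteinRecord,
    vocabulary: Sequence[str],
    pssm_path: str | Path | None = None,
    domain_hits: Iterable[str] = (),
) -> EncodedProtein:
    """Build the full three-part encoding of one record.

    Uses the parsed PSSM when a profile path is given, the degenerate
    one-hot fallback otherwise.
    """
    pssm = parse_pssm(pssm_path, record) if pssm_path is not None else fallback_pssm(record)
    return EncodedProtein(
        one_hot=one_hot_encode(record),
        pssm=pssm,
        domains=domain_encode(domain_hits, vocabulary),
    )


@dataclass
class SearchToolDefaults:
    """Parameters used when homology/domain search is delegated to external
    tools (PSI-BLAST against SWISS-PROT, HMMER against Pfam).

    Kept as data only: this package parses search outputs, it does not run
    the searches in its tested surface.
    """

    psiblast_iterations: int = 3
    psiblast_evalue: float = 0.002
    extra_args: tuple[str, ...] = field(default_factory=tuple)


def write_vocabulary(vocabulary: Sequence[str], path: str | Path) -> None:
    """Persist a domain vocabulary as a plain text list, one id per line."""
    Path(path).write_text("".join(f"{d}\n" for d in vocabulary))


def read_vocabulary(path: str | Path) -> tuple[str, ...]:
    return tuple(
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    )
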