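"""Reading and writing of RNA sequence sets, block sets and feature matrices.

Sequences are handled as plain un-gapped RNA strings over {A, C, G, U}.
FASTA input is normalized on read: residues are uppercased, DNA-style T is
mapped to U and alignment gap characters (``-`` and ``.``) are stripped, so
that Rfam seed files exported either as RNA or DNA, gapped or un-gapped, all
yield the same in-memory dataset.  Ambiguous IUPAC codes (N, R, Y, ...) are
rejected rather than guessed at.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
_GAP_CHARS = frozenset("-.")
_INPUT_ALPHABET = frozenset("ACGUTacgut-.")


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA records, block-set rows or feature files."""


@dataclass(frozen=True)
class SequenceRecord:
    """One RNA sequence with an identifier and (possibly empty) family label."""

    id: str
    family: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"record {self.id!r}: invalid residue {sorted(bad)[0]!r} "
                f"(expected only A, C, G, U)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class FamilyDataset:
    """An ordered set of sequences sharing one family label.

    ``mean_length`` and ``length_variance`` are always recomputed from the
    current records (population variance, ddof=0), never stored stale.
    """

    family: str
    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SequenceFormatError(f"duplicate sequence id {dup!r} in family {self.family!r}")
        for r in self.records:
            if r.family != self.family:
                raise SequenceFormatError(
                    f"record {r.id!r} labeled {r.family!r} in dataset for {self.family!r}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.records], dtype=int)

    @property
    def mean_length(self) -> float:
        return float(np.mean(self.lengths))

    @property
    def length_variance(self) -> float:
        return float(np.var(self.lengths))


def normalize_residues(raw: str) -> tuple[str, int]:
    """Normalize one raw sequence string.

    Uppercases, maps T to U and strips gap characters.  Returns the cleaned
    sequence and the number of gap characters removed.  Characters outside
    the accepted input alphabet raise :class:`SequenceFormatError`.
    """
    bad = set(raw) - _INPUT_ALPHABET
    if bad:
        raise SequenceFormatError(
            f"invalid character {sorted(bad)[0]!r} (ambiguous or non-nucleotide codes are rejected)"
        )
    n_gaps = sum(raw.count(g) for g in _GAP_CHARS)
    cleaned = raw.upper().replace("T", "U").replace("-", "").replace(".", "")
    return cleaned, n_gaps


def read_fasta(path: str | Path, family_label: str) -> FamilyDataset:
    """Read a (possibly line-wrapped) multi-record FASTA file into a dataset.

    Records keep file order.  Gap characters are removed silently with a
    logged count; T is mapped to U; lowercase is uppercased.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    total_gaps = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            cleaned, n_gaps = normalize_residues(str(rec.seq))
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"{path}: record {rec.id!r}: {exc}") from exc
        total_gaps += n_gaps
        try:
            records.append(SequenceRecord(id=rec.id, family=family_label, residues=cleaned))
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"{path}: {exc}") from exc
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    if total_gaps:
        logger.info("read_fasta(%s): stripped %d gap characters", path, total_gaps)
    return FamilyDataset(family=family_label, records=records)


def write_fasta(dataset: FamilyDataset | Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA (one sequence per line)."""
    records = list(dataset)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")


# --------------------------------------------------------------------------
# Block sets
# --------------------------------------------------------------------------

_BLOCKSET_HEADER = ["family", "motif", "location", "prevalence"]


def write_blockset(blocks: Sequence, path: str | Path) -> None:
    """Write blocks as TSV with columns family, motif, location, prevalence.

    Round-trips losslessly through :func:`read_blockset`.
    """
    blocks = list(blocks)
    if not blocks:
        raise ValueError("write_blockset: empty block collection")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_BLOCKSET_HEADER)
        for b in blocks:
            writer.writerow([b.family, b.motif, b.canonical_location, repr(b.prevalence)])


def read_blockset(path: str | Path):
    """Read a block-set TSV written by :func:`write_blockset` (or hand-authored).

    Returns blocks in file order; motifs are validated over {A, C, G, U}.
    Malformed rows raise :class:`SequenceFormatError` naming the line number.
    """
    from .sbf import Block  # local import to avoid a cycle

    path = Path(path)
    blocks: list[Block] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1:
                if row != _BLOCKSET_HEADER:
                    raise SequenceFormatError(
                        f"{path}:1: expected header {_BLOCKSET_HEADER}, got {row}"
                    )
                continue
            if not row or all(not c for c in row):
                continue
            if len(row) != 4:
                raise SequenceFormatError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            family, motif, loc_s, prev_s = row
            try:
                location = int(loc_s)
                prevalence = float(prev_s)
            except ValueError as exc:
                raise SequenceFormatError(f"{path}:{lineno}: {exc}") from exc
            try:
                blocks.append(
                    Block(family=family, motif=motif, canonical_location=location,
                          prevalence=prevalence)
                )
            except ValueError as exc:
                raise SequenceFormatError(f"{path}:{lineno}: {exc}") from exc
    if not blocks:
        raise SequenceFormatError(f"{path}: no blocks found")
    return blocks


# --------------------------------------------------------------------------
# Feature matrices
# --------------------------------------------------------------------------

def _block_token(block) -> str:
    return f"{block.family}:{block.motif}:{block.canonical_location}:{block.prevalence!r}"


def _parse_block_token(token: str, where: str):
    from .sbf import Block

    parts = token.split(":")
    if len(parts) != 4:
        raise SequenceFormatError(f"{where}: malformed block column {token!r}")
    family, motif, loc_s, prev_s = parts
    return Block(family=family, motif=motif, canonical_location=int(loc_s),
                 prevalence=float(prev_s))


def write_feature_matrix(matrix, path: str | Path) -> None:
    """Write a feature matrix as TSV.

    First column is the observation id, second the true family label; the
    remaining columns, one per block in block-set order, carry 1-based
    first-occurrence locations (0 = block absent).  Block identity (family,
    motif, canonical location, prevalence) is encoded in the column headers
    so the matrix is self-describing.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["observation", "family"] + [_block_token(b) for b in matrix.block_order])
        for oid, fam, row in zip(matrix.observation_ids, matrix.families, matrix.values):
            writer.writerow([oid, fam] + [int(v) for v in row])


def read_feature_matrix(path: str | Path):
    """Read a feature matrix TSV written by :func:`write_feature_matrix`."""
    from .features import FeatureMatrix

    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SequenceFormatError(f"{path}: empty file") from None
        if len(header) < 3 or header[:2] != ["observation", "family"]:
            raise SequenceFormatError(f"{path}: malformed feature-matrix header")
        blocks = [_parse_block_token(tok, f"{path}:1") for tok in header[2:]]
        ids: list[str] = []
        families: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise SequenceFormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(row)}"
                )
            ids.append(row[0])
            families.append(row[1])
            try:
                rows.append([int(v) for v in row[2:]])
            except ValueError as exc:
                raise SequenceFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        raise SequenceFormatError(f"{path}: no observations")
    return FeatureMatrix(
        observation_ids=ids,
        families=families,
        block_order=blocks,
        values=np.array(rows, dtype=int),
    )
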