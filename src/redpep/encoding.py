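"""FASTA input and N-peptide composition feature matrices.

A sequence ``P = R1 R2 ... RL`` reduced to a ``k``-letter alphabet is
encoded as the vector of overlapping N-mer frequencies: entry ``w`` equals
``count(w) / (L - N + 1)`` so each row sums to one. Feature order is
lexicographic in the scheme's group order, giving ``k**N`` columns
(400 for the unreduced dipeptide case).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabets import ReductionScheme, reduce_sequence
from .errors import (
    EmptyDatasetError,
    EmptyMatrixError,
    EncodingError,
    FastaFormatError,
    ShortSequenceError,
)

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class ProteinRecord:
    """One labelled protein sequence (label 1 = positive class)."""

    id: str
    sequence: str
    label: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise EmptyDatasetError(f"record {self.id!r}: empty sequence")
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1")


@dataclass
class FeatureMatrix:
    """Samples-by-features composition matrix with provenance.

    ``values[i, j]`` is the frequency of N-peptide ``feature_names[j]`` in
    sample ``sample_ids[i]``; ``labels[i]`` is its binary class. The
    provenance (scheme, N) travels with the matrix so downstream models
    can refuse mismatched encodings.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray
    scheme: ReductionScheme
    n: int
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_columns(self, names: list[str]) -> "FeatureMatrix":
        """Column-subset view preserving provenance (IFS prefixes)."""
        index = {name: j for j, name in enumerate(self.feature_names)}
        try:
            cols = [index[name] for name in names]
        except KeyError as exc:
            raise EncodingError(f"unknown feature {exc.args[0]!r}") from exc
        return FeatureMatrix(
            sample_ids=list(self.sample_ids),
            feature_names=list(names),
            values=self.values[:, cols],
            labels=self.labels.copy(),
            scheme=self.scheme,
            n=self.n,
            excluded_ids=list(self.excluded_ids),
        )

    def write_tsv(self, path: str | Path) -> None:
        """Delimited text: header, sample id first column, label last."""
        with Path(path).open("w") as fh:
            fh.write("sample_id\t" + "\t".join(self.feature_names) + "\tlabel\n")
            for sid, row, lab in zip(self.sample_ids, self.values, self.labels):
                cells = "\t".join(format(v, ".10g") for v in row)
                fh.write(f"{sid}\t{cells}\t{int(lab)}\n")


def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    try:
        text_head = path.open().read(1)
    except OSError as exc:
        raise FastaFormatError(f"cannot read {path}: {exc}") from exc
    if text_head != ">":
        raise FastaFormatError(f"{path}: not FASTA (first byte is not '>')")
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(f"{path}: record {idx} ({rec.id}) is empty")
        records.append((rec.id, seq))
    return records


def read_labeled_fasta(
    positive_path: str | Path, negative_path: str | Path
) -> list[ProteinRecord]:
    """Read two FASTA files; labels follow file of origin.

    Duplicate ids across files are disambiguated with ``|pos`` / ``|neg``
    suffixes and logged.
    """
    pos = _read_fasta(positive_path)
    neg = _read_fasta(negative_path)
    if not pos and not neg:
        raise EmptyDatasetError("both FASTA files are empty")
    pos_ids = {rid for rid, _ in pos}
    clashes = pos_ids & {rid for rid, _ in neg}
    if clashes:
        logger.warning(
            "%d id(s) appear in both files; tagging with |pos / |neg: %s",
            len(clashes), sorted(clashes)[:5],
        )
    records: list[ProteinRecord] = []
    for rid, seq in pos:
        rid_out = f"{rid}|pos" if rid in clashes else rid
        records.append(ProteinRecord(rid_out, seq, POSITIVE))
    for rid, seq in neg:
        rid_out = f"{rid}|neg" if rid in clashes else rid
        records.append(ProteinRecord(rid_out, seq, NEGATIVE))
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise EmptyDatasetError(
            f"duplicate ids within one file: {dupes[:5]}"
        )
    return records


def feature_names_for(alphabet: list[str] | tuple[str, ...], n: int) -> list[str]:
    """All N-peptides over ``alphabet``, lexicographic in alphabet order."""
    return ["".join(t) for t in itertools.product(alphabet, repeat=n)]


def npeptide_composition(
    reduced: str, alphabet: list[str] | tuple[str, ...], n: int
) -> np.ndarray:
    """Overlapping N-mer frequency vector of length ``len(alphabet)**n``.

    Entry for word ``w`` is ``count(w) / (L - N + 1)``; the vector sums
    to exactly one. Raises :class:`~redpep.errors.ShortSequenceError` if
    the sequence is shorter than ``n`` and
    :class:`~redpep.errors.EncodingError` on out-of-alphabet symbols.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    length = len(reduced)
    if length < n:
        raise ShortSequenceError(
            f"sequence of length {length} shorter than N={n}"
        )
    k = len(alphabet)
    index = {label: i for i, label in enumerate(alphabet)}
    if len(index) != k:
        raise EncodingError("alphabet labels not distinct")
    counts = np.zeros(k**n, dtype=np.float64)
    try:
        codes = [index[ch] for ch in reduced]
    except KeyError as exc:
        raise EncodingError(
            f"symbol {exc.args[0]!r} outside alphabet {list(alphabet)}"
        ) from exc
    # word -> flat index via base-k positional encoding
    word = 0
    base = k ** (n - 1)
    for i, c in enumerate(codes):
        word = (word % base) * k + c
        if i >= n - 1:
            counts[word] += 1
    return counts / (length - n + 1)


def encode_dataset(
    records: list[ProteinRecord], scheme: ReductionScheme, n: int
) -> FeatureMatrix:
    """Encode labelled records into a composition matrix, in input order.

    Sequences that are shorter than ``n`` after reduction (or degenerate
    after dropping non-standard residues) are excluded and their ids
    logged; if everything is excluded an
    :class:`~redpep.errors.EmptyMatrixError` is raised.
    """
    if not records:
        raise EmptyDatasetError("no records to encode")
    alphabet = scheme.labels
    names = feature_names_for(alphabet, n)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    labels: list[int] = []
    excluded: list[str] = []
    from .errors import DegenerateSequenceError

    for rec in records:
        try:
            reduced, _ = reduce_sequence(rec.sequence, scheme, "skip")
            rows.append(npeptide_composition(reduced, alphabet, n))
        except (ShortSequenceError, DegenerateSequenceError):
            excluded.append(rec.id)
            continue
        ids.append(rec.id)
        labels.append(rec.label)
    if excluded:
        logger.info(
            "excluded %d sample(s) too short for N=%d: %s",
            len(excluded), n, excluded[:5],
        )
    if not rows:
        raise EmptyMatrixError(
            f"all {len(records)} samples excluded for scheme "
            f"size {scheme.size}, N={n}"
        )
    return FeatureMatrix(
        sample_ids=ids,
        feature_names=names,
        values=np.vstack(rows),
        labels=np.asarray(labels, dtype=np.int64),
        scheme=scheme,
        n=n,
        excluded_ids=excluded,
    )
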