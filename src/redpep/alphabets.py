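"""Reduced amino-acid alphabet schemes.

A reduction scheme is an ordered partition of the 20 standard amino acids
into ``size`` groups. Sequences are rewritten over single-character group
labels (the first letter of each group), which shrinks the alphabet while
preserving coarse physicochemical signal. A built-in family of 18 schemes
(sizes 2-19, derived by information maximization over paired contact
interactions) ships with the package; arbitrary schemes can be supplied in
dash-delimited cluster notation or loaded from a plain-text catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from .errors import (
    CatalogError,
    DegenerateSequenceError,
    PartitionError,
    ResidueError,
    SchemeParseError,
    SizeMismatchError,
)

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard codes that may appear in real FASTA data.
NONSTANDARD_CODES = frozenset("BJOUXZ")

# Built-in family: one row per size 2..19, dash-delimited cluster notation.
_BUILTIN_FAMILY_TYPE_ID = 19
_BUILTIN_CLUSTERS: tuple[tuple[int, str], ...] = (
    (2, "CFILMVWY-ADEGHKNPQRST"),
    (3, "CFILMVWY-DEGKNQS-AHPRT"),
    (4, "FWY-CILMV-DEGKNQS-AHPRT"),
    (5, "FWY-CILMV-DEGKNS-APQT-HR"),
    (6, "FWY-CILMV-DE-GKNQS-APT-HR"),
    (7, "FWY-CILMV-DE-K-GNPQS-AT-HR"),
    (8, "FWY-ILMV-C-DE-K-GNPQS-AT-HR"),
    (9, "FWY-ILMV-C-DE-K-GNQS-PT-A-HR"),
    (10, "WY-F-ILMV-C-DE-K-GNQS-PT-A-HR"),
    (11, "WY-F-ILMV-C-DE-K-G-PNQS-T-A-HR"),
    (12, "WY-F-IL-MV-C-DE-K-G-PNQS-T-A-HR"),
    (13, "WY-F-IL-MV-C-DE-K-G-P-NQS-T-A-HR"),
    (14, "W-Y-F-IL-MV-C-DE-K-G-P-NQS-T-A-HR"),
    (15, "W-Y-F-IL-MV-C-DE-K-G-P-NQS-T-A-H-R"),
    (16, "W-Y-F-IL-M-V-C-DE-K-G-P-NQS-T-A-H-R"),
    (17, "W-Y-F-I-L-M-V-C-DE-K-G-P-NQS-T-A-H-R"),
    (18, "W-Y-F-I-L-M-V-C-DE-K-G-P-N-QS-T-A-H-R"),
    (19, "W-Y-F-I-L-M-V-C-D-E-K-G-P-N-QS-T-A-H-R"),
)


@dataclass(frozen=True)
class ReductionScheme:
    """An ordered partition of the 20 standard amino acids into ``size`` groups.

    Parameters
    ----------
    type_id : int
        Scheme-family identifier.
    size : int
        Number of groups (the reduced alphabet size).
    groups : tuple of str
        The groups, in order; each is a non-empty string of standard
        one-letter codes.
    labels : tuple of str
        One single-character label per group. By convention the first
        letter of each group.
    """

    type_id: int
    size: int
    groups: tuple[str, ...]
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(g[0] for g in self.groups)
            )
        self._validate()

    def _validate(self) -> None:
        if len(self.groups) != self.size:
            raise SizeMismatchError(
                f"scheme type {self.type_id}: declared size {self.size} but "
                f"{len(self.groups)} groups"
            )
        seen: dict[str, int] = {}
        for gi, group in enumerate(self.groups):
            if not group:
                raise SchemeParseError(
                    f"scheme type {self.type_id} size {self.size}: empty group"
                )
            for aa in group:
                if aa not in STANDARD_AMINO_ACIDS:
                    raise SchemeParseError(
                        f"illegal character {aa!r} in group {group!r}"
                    )
                if aa in seen:
                    raise PartitionError(
                        f"amino acid {aa!r} assigned to more than one group "
                        f"(groups {seen[aa]} and {gi})"
                    )
                seen[aa] = gi
        missing = sorted(STANDARD_AMINO_ACIDS - seen.keys())
        if missing:
            raise PartitionError(
                "amino acid(s) unassigned: " + ", ".join(missing)
            )
        if len(set(self.labels)) != len(self.labels):
            raise PartitionError(
                f"group labels not distinct: {self.labels}"
            )

    @property
    def notation(self) -> str:
        """Dash-delimited cluster notation (round-trips through parsing)."""
        return "-".join(self.groups)

    def mapping(self) -> dict[str, str]:
        """Residue -> group-label lookup table."""
        return {
            aa: label
            for group, label in zip(self.groups, self.labels)
            for aa in group
        }

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"type{self.type_id}/size{self.size}({self.notation})"


def parse_cluster_string(
    notation: str, type_id: int, size: int
) -> ReductionScheme:
    """Parse dash-delimited cluster notation into a validated scheme.

    ``"WY-F-ILMV-C-DE-K-GNQS-PT-A-HR"`` with ``size=10`` yields ten groups
    labelled by each group's first letter. Raises
    :class:`~redpep.errors.SchemeParseError`,
    :class:`~redpep.errors.PartitionError` or
    :class:`~redpep.errors.SizeMismatchError` on invalid input.
    """
    if not notation:
        raise SchemeParseError("empty cluster notation")
    bad = set(notation) - STANDARD_AMINO_ACIDS - {"-"}
    if bad:
        raise SchemeParseError(
            f"illegal character(s) in notation: {sorted(bad)}"
        )
    tokens = notation.split("-")
    if any(not t for t in tokens):
        raise SchemeParseError(f"empty group in notation {notation!r}")
    return ReductionScheme(
        type_id=type_id, size=size, groups=tuple(tokens)
    )


def identity_scheme() -> ReductionScheme:
    """The trivial 20-singleton scheme (no reduction)."""
    return ReductionScheme(
        type_id=0, size=20, groups=tuple(sorted(STANDARD_AMINO_ACIDS))
    )


def reduce_sequence(
    sequence: str,
    scheme: ReductionScheme,
    unknown_policy: Literal["skip", "error"] = "skip",
) -> tuple[str, int]:
    """Rewrite an amino-acid sequence over the scheme's group labels.

    Input is case-normalized to uppercase. Non-standard residues
    (B, J, O, U, X, Z) are dropped under ``unknown_policy='skip'`` (the
    count of dropped residues is returned) or raise
    :class:`~redpep.errors.ResidueError` under ``'error'``.

    Returns
    -------
    (reduced, n_dropped) : tuple of str and int
    """
    if not sequence:
        raise DegenerateSequenceError("empty input sequence")
    table = scheme.mapping()
    out: list[str] = []
    dropped = 0
    for pos, aa in enumerate(sequence.upper()):
        label = table.get(aa)
        if label is not None:
            out.append(label)
        elif unknown_policy == "error":
            raise ResidueError(
                f"non-standard residue {aa!r} at position {pos}"
            )
        else:
            dropped += 1
    if not out:
        raise DegenerateSequenceError(
            f"sequence empty after skipping {dropped} non-standard residue(s)"
        )
    return "".join(out), dropped


def load_builtin_family() -> list[ReductionScheme]:
    """The bundled 18-scheme family, ordered by size 2..19."""
    return [
        parse_cluster_string(notation, _BUILTIN_FAMILY_TYPE_ID, size)
        for size, notation in _BUILTIN_CLUSTERS
    ]


def load_catalog(path: str | Path) -> list[ReductionScheme]:
    """Load schemes from a plain-text catalog.

    One record per line: ``type<ws>size<ws>cluster-notation``. Blank lines
    and ``#`` comments are ignored. Duplicate (type, size) pairs and
    invalid partitions are rejected with the offending line number.
    """
    path = Path(path)
    schemes: list[ReductionScheme] = []
    seen: set[tuple[int, int]] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise CatalogError(
                    f"{path}:{lineno}: expected 'type size clusters', "
                    f"got {len(parts)} field(s)"
                )
            try:
                type_id, size = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise CatalogError(
                    f"{path}:{lineno}: non-integer type/size"
                ) from exc
            key = (type_id, size)
            if key in seen:
                raise CatalogError(
                    f"{path}:{lineno}: duplicate scheme type {type_id} "
                    f"size {size}"
                )
            try:
                scheme = parse_cluster_string(parts[2], type_id, size)
            except (SchemeParseError, PartitionError, SizeMismatchError) as exc:
                raise type(exc)(
                    f"{path}:{lineno} (type {type_id} size {size}): {exc}"
                ) from exc
            seen.add(key)
            schemes.append(scheme)
    return schemes


def validate_family(schemes: Iterable[ReductionScheme]) -> None:
    """Re-assert the partition invariant on a collection of schemes."""
    for scheme in schemes:
        scheme._validate()
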