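"""Core domain types and nucleotide utilities for k-turn analysis.

The kink-turn (k-turn) is a widespread RNA structural motif: a duplex
containing a three-nucleotide bulge followed by tandem sheared G:A and A:G
base pairs, which kinks the helical axis to an included angle of roughly 50
degrees.  Positions within the motif are named in a signed coordinate system
counting base pairs outward from the bulge loop: negative indices belong to
the canonical (C) helix 5' of the loop on the bulged strand, positive indices
to the non-canonical (NC) helix that carries the G:A pairs.  Nucleotides on
the bulged strand take the suffix ``b``, partners on the other strand the
suffix ``n``, and the three loop nucleotides are L1, L2, L3 written 5'->3'.

This module holds that nomenclature (:class:`PairId`, :class:`KTurnAnnotation`),
the controlled vocabularies for prediction outputs (:class:`FoldingClass`,
:class:`Conformation`), and small sequence utilities shared by the scanner,
the rule engine and the fixture generators.  Sequence coordinates are always
0-based half-open; the signed k-turn labels are a separate coordinate system
mapped onto sequence indices explicitly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "KTurnError",
    "InvalidNucleotideError",
    "AnnotationError",
    "FoldingClass",
    "Conformation",
    "VALID_BASES",
    "normalize_base",
    "normalize_seq",
    "is_watson_crick",
    "is_wobble",
    "complement",
    "PairId",
    "KTurnAnnotation",
    "read_fasta",
    "write_fasta",
]


class KTurnError(Exception):
    """Base class for all errors raised by this package."""


class InvalidNucleotideError(KTurnError, ValueError):
    """A symbol outside the RNA alphabet (A, C, G, U, optionally N)."""


class AnnotationError(KTurnError, ValueError):
    """A k-turn annotation violating the motif invariants."""


VALID_BASES = frozenset("ACGUN")

_WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N"}

_warned_t = False


def normalize_base(symbol: str, *, allow_n: bool = True) -> str:
    """Validate one nucleotide symbol, upper-casing and mapping T -> U.

    DNA-alphabet input (T) is accepted and normalized to U so that FASTA
    files written with a DNA alphabet remain usable; a warning is emitted
    once per process.
    """
    global _warned_t
    if not isinstance(symbol, str) or len(symbol) != 1:
        raise InvalidNucleotideError(f"expected a single nucleotide symbol, got {symbol!r}")
    s = symbol.upper()
    if s == "T":
        if not _warned_t:
            warnings.warn("DNA alphabet detected: normalizing T to U", stacklevel=2)
            _warned_t = True
        s = "U"
    if s not in VALID_BASES or (s == "N" and not allow_n):
        raise InvalidNucleotideError(f"invalid nucleotide symbol {symbol!r}")
    return s


def normalize_seq(seq: str, *, allow_n: bool = True) -> str:
    """Normalize a whole RNA string (case folding, T->U, validation)."""
    return "".join(normalize_base(c, allow_n=allow_n) for c in seq)


def is_watson_crick(b: str, n: str) -> bool:
    """True exactly for the canonical pairs A:U, U:A, G:C, C:G.

    G:U is deliberately *not* Watson-Crick here: in the k-turn rule system it
    is a wobble pair with distinct structural consequences (a G4b:U4n wobble
    widens the major groove and facilitates ion-induced folding).
    """
    return (normalize_base(b), normalize_base(n)) in _WC_PAIRS


def is_wobble(b: str, n: str) -> bool:
    """True for the G:U / U:G wobble pair."""
    pair = (normalize_base(b), normalize_base(n))
    return pair in {("G", "U"), ("U", "G")}


def complement(seq: str) -> str:
    """Reverse complement of an RNA string under Watson-Crick rules.

    A<->U and G<->C; N maps to N.  The empty string maps to itself.
    """
    norm = normalize_seq(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(norm))


class FoldingClass(str, Enum):
    """Ion-induced folding classes (whether Mg2+ alone folds the k-turn)."""

    FOLDS = "FOLDS"
    FOLDS_WEAKLY = "FOLDS_WEAKLY"
    DOES_NOT_FOLD = "DOES_NOT_FOLD"
    INDETERMINATE = "INDETERMINATE"


class Conformation(str, Enum):
    """N3/N1 conformational classes of the folded k-turn.

    The cross-strand hydrogen bond donated by the -1n 2'-OH is accepted by
    either N3 or N1 of A2b; the choice rotates the C-helix and defines two
    structural families of roughly equal size among known k-turns.
    """

    N3 = "N3"
    N1 = "N1"
    UNKNOWN = "UNKNOWN"


@dataclass(frozen=True)
class PairId:
    """One base pair of the motif in signed k-turn coordinates.

    ``index`` is never 0: negative values count outward into the C-helix
    (-1 is the pair flanking the loop), positive values outward into the
    NC-helix (1 and 2 are the sheared G:A and A:G pairs).  ``b_base`` is the
    nucleotide on the bulged strand, ``n_base`` its partner.
    """

    index: int
    b_base: str
    n_base: str

    def __post_init__(self) -> None:
        if self.index == 0:
            raise AnnotationError("pair index 0 does not exist; indices count outward from the loop")
        object.__setattr__(self, "b_base", normalize_base(self.b_base))
        object.__setattr__(self, "n_base", normalize_base(self.n_base))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.b_base, self.n_base)

    def __str__(self) -> str:  # e.g. "-1b:-1n=C:G" abbreviated to "C:G@-1"
        return f"{self.b_base}:{self.n_base}@{self.index}"


@dataclass(frozen=True)
class KTurnAnnotation:
    """A located k-turn with every nomenclature position mapped to sequence.

    ``c_pairs`` are ordered inward-most first (index -1, then -2, ...);
    ``nc_pairs`` ordered 1, 2, 3, ...  ``loop`` holds (L1, L2, L3) 5'->3' on
    the bulged strand.  ``b_strand_span`` / ``n_strand_span`` are half-open
    0-based intervals into the source strands: the b-span covers the C-helix,
    loop and NC-helix nucleotides of the bulged strand; the n-span covers only
    the paired positions of the non-bulged strand.  ``source_ids`` names the
    two strands; a self-hybridized duplex lists the same id twice.
    """

    c_pairs: tuple[PairId, ...]
    loop: tuple[str, str, str]
    nc_pairs: tuple[PairId, ...]
    b_strand_span: tuple[int, int]
    n_strand_span: tuple[int, int]
    source_ids: tuple[str, str] = ("b", "n")

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_pairs", tuple(self.c_pairs))
        object.__setattr__(self, "nc_pairs", tuple(self.nc_pairs))
        object.__setattr__(self, "loop", tuple(normalize_base(x) for x in self.loop))
        object.__setattr__(self, "source_ids", tuple(self.source_ids))
        if len(self.loop) != 3:
            raise AnnotationError(f"k-turn loop must be exactly 3 nucleotides, got {len(self.loop)}")
        if len(self.c_pairs) < 2:
            raise AnnotationError("at least 2 C-helix pairs required")
        if len(self.nc_pairs) < 3:
            raise AnnotationError("at least 3 NC-helix pairs required")
        for rank, p in enumerate(self.c_pairs, start=1):
            if p.index != -rank:
                raise AnnotationError(
                    f"c_pairs must be ordered -1, -2, ... inward-most first; position {rank} has index {p.index}"
                )
        for rank, p in enumerate(self.nc_pairs, start=1):
            if p.index != rank:
                raise AnnotationError(
                    f"nc_pairs must be ordered 1, 2, ...; position {rank} has index {p.index}"
                )
        if self.nc_pairs[0].pair != ("G", "A"):
            raise AnnotationError(f"1b:1n must be the sheared G:A pair, got {self.nc_pairs[0]}")
        if self.nc_pairs[1].pair != ("A", "G"):
            raise AnnotationError(f"2b:2n must be the sheared A:G pair, got {self.nc_pairs[1]}")
        b_len = self.b_strand_span[1] - self.b_strand_span[0]
        n_len = self.n_strand_span[1] - self.n_strand_span[0]
        expect_b = len(self.c_pairs) + 3 + len(self.nc_pairs)
        expect_n = len(self.c_pairs) + len(self.nc_pairs)
        if b_len != expect_b:
            raise AnnotationError(f"b_strand_span length {b_len} inconsistent with {expect_b} motif nucleotides")
        if n_len != expect_n:
            raise AnnotationError(f"n_strand_span length {n_len} inconsistent with {expect_n} paired positions")
        if len(self.source_ids) != 2:
            raise AnnotationError("source_ids must name exactly two strands")

    # -- lookups ----------------------------------------------------------

    def pair_at(self, index: int) -> PairId | None:
        """Pair at a signed k-turn index, or None if not covered."""
        if index < 0:
            k = -index - 1
            return self.c_pairs[k] if k < len(self.c_pairs) else None
        if index > 0:
            k = index - 1
            return self.nc_pairs[k] if k < len(self.nc_pairs) else None
        raise AnnotationError("pair index 0 does not exist")

    @property
    def key_pairs(self) -> dict[str, tuple[str, str] | None]:
        """The rule-engine inputs: -1b:-1n, 3b:3n and 4b:4n."""
        out: dict[str, tuple[str, str] | None] = {}
        for label, idx in (("-1", -1), ("3", 3), ("4", 4)):
            p = self.pair_at(idx)
            out[label] = p.pair if p is not None else None
        return out

    def nomenclature_table(self) -> dict[str, tuple[str, str, int]]:
        """Map every position label to (strand role, base, sequence index).

        Labels follow the standard scheme: ``-3b``, ``-1n``, ``L1``, ``2b`` ...
        Sequence indices are 0-based positions in the source strands.
        """
        table: dict[str, tuple[str, str, int]] = {}
        b0, _ = self.b_strand_span
        n0, n1 = self.n_strand_span
        nc = len(self.c_pairs)
        # bulged strand 5'->3': -nc..-1, L1..L3, 1..len(nc_pairs)
        for rank, p in enumerate(self.c_pairs, start=1):  # -1 first
            table[f"{p.index}b"] = ("b", p.b_base, b0 + nc - rank)
        for i, base in enumerate(self.loop, start=1):
            table[f"L{i}"] = ("b", base, b0 + nc + i - 1)
        for rank, p in enumerate(self.nc_pairs, start=1):
            table[f"{p.index}b"] = ("b", p.b_base, b0 + nc + 3 + rank - 1)
        # non-bulged strand 5'->3' runs NC-helix outer..1, then -1..-nc outer
        k = len(self.nc_pairs)
        for rank, p in enumerate(self.nc_pairs, start=1):
            table[f"{p.index}n"] = ("n", p.n_base, n0 + k - rank)
        for rank, p in enumerate(self.c_pairs, start=1):
            table[f"{p.index}n"] = ("n", p.n_base, n0 + k + rank - 1)
        return table

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "c_pairs": [{"index": p.index, "b": p.b_base, "n": p.n_base} for p in self.c_pairs],
            "loop": list(self.loop),
            "nc_pairs": [{"index": p.index, "b": p.b_base, "n": p.n_base} for p in self.nc_pairs],
            "b_strand_span": list(self.b_strand_span),
            "n_strand_span": list(self.n_strand_span),
            "source_ids": list(self.source_ids),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KTurnAnnotation":
        return cls(
            c_pairs=tuple(PairId(p["index"], p["b"], p["n"]) for p in d["c_pairs"]),
            loop=tuple(d["loop"]),
            nc_pairs=tuple(PairId(p["index"], p["b"], p["n"]) for p in d["nc_pairs"]),
            b_strand_span=tuple(d["b_strand_span"]),
            n_strand_span=tuple(d["n_strand_span"]),
            source_ids=tuple(d.get("source_ids", ("b", "n"))),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "KTurnAnnotation":
        return cls.from_dict(json.loads(s))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (id, normalized RNA sequence) records from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_seq(str(rec.seq))))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) records to a FASTA file."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")
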