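"""Sequence-based prediction of k-turn ion-induced folding and conformation.

Whether a k-turn folds into its tightly kinked conformation on addition of
Mg2+ ions alone, and whether the folded state is N3 or N1, is governed by a
small number of key base pairs:

* 3b:3n — the pair adjacent to the tandem sheared pairs.  A Watson-Crick
  pair here gives poor or non-existent ion-induced folding (rule 1, which
  takes precedence); otherwise 3b = C (rule 2) or 3n = G (rule 3) give good
  folding.  The same pair is the major determinant of the N3/N1 conformation
  (A:G -> N3, C:C -> N1 among the cases characterized here).
* -1b:-1n — the C-helix pair flanking the loop.  C:G (the common natural
  sequence) and A:U support folding (A:U with somewhat lower apparent Mg2+
  affinity), U:A gives only weak folding, and G:C blocks ion-induced folding
  entirely.
* 4b:4n — a G:U wobble here facilitates folding: a lower apparent K_d, a
  more completely folded population, and a partial rescue of the weak-folding
  -1b:-1n = U:A background (which nonetheless remains visibly weaker, so the
  class is kept at FOLDS_WEAKLY rather than upgraded).

Every prediction carries an ordered :class:`RuleTrace` naming each rule that
fired and its effect, so a verdict is always auditable.  Combinations the
characterized rules do not cover return INDETERMINATE rather than guessing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .core import (
    Conformation,
    FoldingClass,
    KTurnAnnotation,
    KTurnError,
    is_watson_crick,
    normalize_base,
)

__all__ = [
    "RuleTrace",
    "TraceStep",
    "PredictionResult",
    "ConformationTable",
    "predict_folding",
    "predict_conformation",
    "predict",
]


class InvalidPairError(KTurnError, ValueError):
    """A base-pair argument outside the RNA alphabet."""


def _norm_pair(pair: tuple[str, str], what: str) -> tuple[str, str]:
    try:
        return (normalize_base(pair[0], allow_n=False), normalize_base(pair[1], allow_n=False))
    except (KTurnError, IndexError, TypeError) as e:
        raise InvalidPairError(f"invalid {what} pair {pair!r}: {e}") from e


@dataclass(frozen=True)
class TraceStep:
    """One fired rule: a stable id, human-readable description, effect."""

    rule_id: str
    description: str
    effect: str


@dataclass
class RuleTrace:
    """Ordered record of every decision taken for one prediction."""

    steps: list[TraceStep] = field(default_factory=list)

    def add(self, rule_id: str, description: str, effect: str) -> None:
        self.steps.append(TraceStep(rule_id, description, effect))

    def ids(self) -> list[str]:
        return [s.rule_id for s in self.steps]

    def to_list(self) -> list[dict]:
        return [
            {"rule_id": s.rule_id, "description": s.description, "effect": s.effect}
            for s in self.steps
        ]


@dataclass(frozen=True)
class PredictionResult:
    """Folding class + conformation call + qualitative Mg2+ affinity hint.

    ``affinity_hint`` is relative to the baseline background (-1b:-1n = C:G,
    no 4b:4n G:U): ``higher`` / ``lower`` / ``baseline``; ``none`` when the
    k-turn is predicted not to fold at all.
    """

    folding: FoldingClass
    conformation: Conformation
    affinity_hint: str
    trace: RuleTrace

    def __post_init__(self) -> None:
        if self.affinity_hint not in {"higher", "baseline", "lower", "none"}:
            raise KTurnError(f"invalid affinity hint {self.affinity_hint!r}")
        if self.folding is FoldingClass.DOES_NOT_FOLD and self.affinity_hint != "none":
            raise KTurnError("a non-folding k-turn has no Mg2+ affinity hint")

    def to_dict(self) -> dict:
        return {
            "folding": self.folding.value,
            "conformation": self.conformation.value,
            "affinity_hint": self.affinity_hint,
            "trace": self.trace.to_list(),
        }


# ---------------------------------------------------------------------------
# conformation table


class ConformationTable:
    """Mapping 3b:3n pair -> N3/N1 conformation, with provenance notes.

    Built-in entries cover only the pairs characterized here (A:G -> N3 from
    the crystal structure of the RAGATH-18 duplex; C:C -> N1 from the
    Actinomyces-1 k-turn in the SAM-I riboswitch).  The published assignments
    for 15/16 pairs live in earlier work and are not reproduced as built-ins;
    a user-supplied TSV (columns: pair, conformation, source) extends the
    table to any of the 16 combinations.
    """

    _BUILTIN: dict[tuple[str, str], tuple[Conformation, str]] = {
        ("A", "G"): (Conformation.N3, "built-in: crystal structure, 3b:3n = A:G standard k-turn"),
        ("C", "C"): (Conformation.N1, "built-in: crystal structure, 3b:3n = C:C k-turn"),
    }

    def __init__(self, extra: Mapping[tuple[str, str], Conformation] | None = None,
                 provenance: str = "user-supplied") -> None:
        self._table = dict(self._BUILTIN)
        if extra:
            for pair, conf in extra.items():
                self._table[_norm_pair(pair, "3b:3n")] = (Conformation(conf), provenance)

    def lookup(self, pair: tuple[str, str]) -> tuple[Conformation, str]:
        key = _norm_pair(pair, "3b:3n")
        if key in self._table:
            return self._table[key]
        return (Conformation.UNKNOWN, "not covered by built-in or user table")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConformationTable":
        """Load extensions from TSV columns pair (e.g. ``G:C``), conformation, source."""
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                b, n = row["pair"].split(":")
                key = _norm_pair((b, n), "3b:3n")
                conf = Conformation(row["conformation"].strip().upper())
                table._table[key] = (conf, row.get("source", "user TSV"))
        return table


# ---------------------------------------------------------------------------
# folding rules


def predict_folding(
    m1: tuple[str, str], p3: tuple[str, str], p4: tuple[str, str]
) -> tuple[FoldingClass, str, RuleTrace]:
    """Predict the ion-induced folding class from the three key pairs.

    Parameters are the -1b:-1n, 3b:3n and 4b:4n pairs as (b, n) tuples.
    Evaluation order (recorded step by step in the trace):

    1. ``-1b:-1n = G:C`` blocks folding outright.
    2. Rule 1: Watson-Crick 3b:3n -> DOES_NOT_FOLD, overriding rules 2-3.
    3. Rules 2/3: 3b = C or 3n = G -> FOLDS; anything else INDETERMINATE.
    4. -1b:-1n modifier: A:U keeps the class but lowers apparent affinity;
       U:A downgrades FOLDS to FOLDS_WEAKLY (and lowers affinity).
    5. 4b:4n = G:U raises apparent affinity; in a weak-folding background it
       is recorded as a partial rescue without upgrading the class.
    """
    m1 = _norm_pair(m1, "-1b:-1n")
    p3 = _norm_pair(p3, "3b:3n")
    p4 = _norm_pair(p4, "4b:4n")
    trace = RuleTrace()

    if m1 == ("G", "C"):
        trace.add(
            "M1-GC-block",
            "-1b:-1n = G:C prevents ion-induced folding in any 3b:3n background",
            "class = DOES_NOT_FOLD (terminal)",
        )
        return FoldingClass.DOES_NOT_FOLD, "none", trace

    if is_watson_crick(*p3):
        trace.add(
            "R1-3bn-WC",
            f"3b:3n = {p3[0]}:{p3[1]} is Watson-Crick: poor or non-existent "
            "folding in metal ions (rule 1, takes precedence over rules 2-3)",
            "class = DOES_NOT_FOLD (terminal)",
        )
        return FoldingClass.DOES_NOT_FOLD, "none", trace

    if p3[0] == "C" or p3[1] == "G":
        which = "3b = C (rule 2)" if p3[0] == "C" else "3n = G (rule 3)"
        rid = "R2-3b-C" if p3[0] == "C" else "R3-3n-G"
        trace.add(rid, f"{which}: good folding in response to metal ions", "class = FOLDS")
        folding = FoldingClass.FOLDS
    else:
        trace.add(
            "R0-uncharacterized",
            f"3b:3n = {p3[0]}:{p3[1]} is not covered by rules 1-3",
            "class = INDETERMINATE",
        )
        folding = FoldingClass.INDETERMINATE

    hint = "baseline"
    if m1 == ("C", "G"):
        trace.add("M1-CG", "-1b:-1n = C:G (the common natural sequence): no change", "none")
    elif m1 == ("A", "U"):
        trace.add(
            "M1-AU",
            "-1b:-1n = A:U folds almost as well but needs more Mg2+",
            "affinity_hint = lower",
        )
        hint = "lower"
    elif m1 == ("U", "A"):
        if folding is FoldingClass.FOLDS:
            trace.add(
                "M1-UA-weak",
                "-1b:-1n = U:A gives only weak ion-induced folding",
                "class FOLDS -> FOLDS_WEAKLY; affinity_hint = lower",
            )
            folding = FoldingClass.FOLDS_WEAKLY
        else:
            trace.add(
                "M1-UA-weak",
                "-1b:-1n = U:A weakens folding; base class already uncertain "
                "(low confidence: this combination is uncharacterized)",
                "affinity_hint = lower",
            )
        hint = "lower"
    else:
        trace.add(
            "M1-other",
            f"-1b:-1n = {m1[0]}:{m1[1]} is outside the characterized Watson-Crick set "
            "(low confidence)",
            "none",
        )

    if p4 == ("G", "U"):
        if folding is FoldingClass.FOLDS_WEAKLY:
            trace.add(
                "M4-GU-rescue",
                "4b:4n = G:U provides a partial rescue of the weak-folding "
                "background, but folding remains clearly weaker",
                "partial rescue noted; class stays FOLDS_WEAKLY",
            )
        else:
            trace.add(
                "M4-GU",
                "4b:4n = G:U facilitates ion-induced folding (more complete "
                "folding at lower Mg2+ concentration)",
                "affinity_hint = higher",
            )
            hint = "higher"

    return folding, hint, trace


def predict_conformation(
    p3: tuple[str, str], table: ConformationTable | None = None
) -> Conformation:
    """N3/N1 conformation from the 3b:3n pair (table lookup; UNKNOWN if absent)."""
    table = table or ConformationTable()
    conf, _ = table.lookup(p3)
    return conf


def predict(
    annotation: KTurnAnnotation, table: ConformationTable | None = None
) -> PredictionResult:
    """Full prediction (folding class + conformation) for an annotated k-turn.

    If the annotation lacks a pair at index 4 (short NC helix), the
    prediction proceeds with 4b:4n treated as non-G:U and the trace records
    the assumption.
    """
    table = table or ConformationTable()
    key = annotation.key_pairs
    m1, p3, p4 = key["-1"], key["3"], key["4"]
    if m1 is None or p3 is None:
        raise KTurnError("annotation must cover pairs -1 and 3 for prediction")
    missing_p4 = p4 is None
    if missing_p4:
        p4 = ("A", "U")  # any non-G:U pair: the modifier simply does not fire
    folding, hint, trace = predict_folding(m1, p3, p4)
    if missing_p4:
        trace.add(
            "M4-absent",
            "annotation has no pair at index 4; treated as non-G:U",
            "assumption recorded",
        )
    conf, source = table.lookup(p3)
    trace.add(
        "C-3bn-table",
        f"conformation of 3b:3n = {p3[0]}:{p3[1]}: {conf.value} ({source})",
        f"conformation = {conf.value}",
    )
    return PredictionResult(folding=folding, conformation=conf, affinity_hint=hint, trace=trace)
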