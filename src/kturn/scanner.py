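"""Locate standard k-turn motifs in duplexes and secondary structures.

A standard k-turn register is searched as: a three-nucleotide bulge on exactly
one strand, immediately 3' of which the bulged strand enters the NC-helix with
the tandem sheared pairs 1b:1n = G:A and 2b:2n = A:G; the pair 3b:3n may be
any of the 16 base combinations (it is the main determinant of folding and
conformation, not of motif identity), while pairs at index >= 4 and the
C-helix pairs must be Watson-Crick or G:U wobble to delimit genuine helices.

The scanner enumerates every bulged alignment of the two strands (both
polarities, so the bulge may sit on either input strand) and reports every
register that satisfies the minimum helix lengths, with the helices extended
maximally outward.  Overlapping registers are all reported; downstream
consumers filter.  Limitations: the bulge is strictly 3 nt (2- or 4-nt bulged
variants are not standard k-turns and are not reported) and dot-bracket input
is restricted to plain ``()`` pairs (pseudoknots rejected).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import (
    AnnotationError,
    KTurnAnnotation,
    KTurnError,
    PairId,
    is_watson_crick,
    is_wobble,
    normalize_seq,
)

__all__ = [
    "ScanConfig",
    "DotBracketError",
    "scan_duplex",
    "scan_secondary_structure",
    "build_kturn_duplex",
    "random_kturn_spec",
    "KTurnSpec",
    "parse_dot_bracket",
]


class DotBracketError(KTurnError, ValueError):
    """Malformed dot-bracket string (unbalanced or pseudoknotted)."""


#: pairs accepted in flanking helices: Watson-Crick plus G:U wobble
def _wc_or_wobble(b: str, n: str) -> bool:
    return is_watson_crick(b, n) or is_wobble(b, n)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner thresholds and pair-admissibility policy.

    Defaults mirror the canonical experimental construct: three C-helix base
    pairs, the loop, and four NC-helix base pairs.  Natural k-turns vary, so
    both minima are configurable.  ``require_3bn_any`` keeps index 3
    unconstrained (all 16 pairings occur in nature); setting it False demands
    WC/wobble there too.
    """

    min_c_pairs: int = 3
    min_nc_pairs: int = 4
    require_3bn_any: bool = True

    def __post_init__(self) -> None:
        if self.min_c_pairs < 2:
            raise ValueError("min_c_pairs must be >= 2")
        if self.min_nc_pairs < 3:
            raise ValueError("min_nc_pairs must be >= 3")

    def pair_ok(self, index: int, b: str, n: str) -> bool:
        if index == 3 and self.require_3bn_any:
            return True
        return _wc_or_wobble(b, n)


def _scan_one_polarity(
    b: str, n: str, config: ScanConfig, ids: tuple[str, str]
) -> list[KTurnAnnotation]:
    """Enumerate k-turn registers with the bulge on strand ``b``.

    Antiparallel pairing convention: if b[p] pairs n[q] then b[p+1] pairs
    n[q-1].  With the loop at b[p+1:p+4] (-1b = b[p], -1n = n[q]):

        -kb = b[p-k+1]   -kn = n[q+k-1]      (C-helix, outward 5' on b)
         jb = b[p+3+j]    jn = n[q-j]        (NC-helix, outward 3' on b)
    """
    out = []
    lb, ln = len(b), len(n)
    for p in range(lb):
        for q in range(ln):
            # sheared signature: 1b:1n = G:A, 2b:2n = A:G
            if p + 5 >= lb or q - 2 < 0:
                continue
            if not (b[p + 4] == "G" and n[q - 1] == "A" and b[p + 5] == "A" and n[q - 2] == "G"):
                continue
            # count admissible C-helix pairs outward from -1
            c_pairs: list[PairId] = []
            k = 1
            while p - k + 1 >= 0 and q + k - 1 < ln:
                bb, nb = b[p - k + 1], n[q + k - 1]
                if not _wc_or_wobble(bb, nb):
                    break
                c_pairs.append(PairId(-k, bb, nb))
                k += 1
            if len(c_pairs) < config.min_c_pairs:
                continue
            # count admissible NC-helix pairs outward from 1
            nc_pairs: list[PairId] = []
            j = 1
            while p + 3 + j < lb and q - j >= 0:
                bb, nb = b[p + 3 + j], n[q - j]
                if j <= 2 or config.pair_ok(j, bb, nb):
                    nc_pairs.append(PairId(j, bb, nb))
                    j += 1
                else:
                    break
            if len(nc_pairs) < config.min_nc_pairs:
                continue
            ncp, nnc = len(c_pairs), len(nc_pairs)
            ann = KTurnAnnotation(
                c_pairs=tuple(c_pairs),
                loop=(b[p + 1], b[p + 2], b[p + 3]),
                nc_pairs=tuple(nc_pairs),
                b_strand_span=(p - ncp + 1, p + 4 + nnc),
                n_strand_span=(q - nnc, q + ncp),
                source_ids=ids,
            )
            out.append(ann)
    return out


def scan_duplex(
    strand_b: str, strand_n: str, config: ScanConfig | None = None
) -> list[KTurnAnnotation]:
    """Find all standard k-turns in an antiparallel two-strand duplex.

    Both polarities are tried, so the bulge may sit on either strand; for a
    self-hybridizing strand pass the same sequence twice.  Annotations are
    sorted by bulged-strand span start (ties broken by strand role and n-span)
    and exact duplicates removed.  Strands too short for the minimum helix
    requirements simply yield an empty list.
    """
    if not strand_b or not strand_n:
        raise KTurnError("both strands must be non-empty")
    config = config or ScanConfig()
    sb = normalize_seq(strand_b)
    sn = normalize_seq(strand_n)
    anns = _scan_one_polarity(sb, sn, config, ("b", "n"))
    anns += _scan_one_polarity(sn, sb, config, ("n", "b"))
    seen = set()
    unique = []
    for a in sorted(anns, key=lambda a: (a.b_strand_span, a.source_ids, a.n_strand_span)):
        key = (a.source_ids, a.b_strand_span, a.n_strand_span)
        if key not in seen:
            seen.add(key)
            unique.append(a)
    return unique


# ---------------------------------------------------------------------------
# dot-bracket front end


def parse_dot_bracket(db: str) -> dict[int, int]:
    """Parse plain ``()`` dot-bracket into a symmetric pairing map.

    Only round brackets are supported; any other bracket character is taken
    as a pseudoknot annotation and rejected.
    """
    pairs: dict[int, int] = {}
    stack: list[int] = []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise DotBracketError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
        elif c == ".":
            continue
        else:
            raise DotBracketError(
                f"unsupported character {c!r} at position {i}: only '(', ')' and '.' "
                "are accepted (pseudoknots are not supported)"
            )
    if stack:
        raise DotBracketError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def scan_secondary_structure(
    seq: str, db: str, config: ScanConfig | None = None
) -> list[KTurnAnnotation]:
    """Find k-turns in a sequence with known secondary structure.

    A candidate is any 3x0 internal loop: three consecutive unpaired
    nucleotides u..u+2 whose flanks are paired with zero unpaired partners on
    the other strand (pair partners of u-1 and u+3 are adjacent).  The flanking
    pairs are then checked against the same motif signature as the duplex
    scanner, walking the pairing map outward in both directions.  Both strands
    of the structure are implicit in the map, so bulges on either strand of a
    stem are found.  Annotation spans refer to positions in ``seq`` itself
    (source id repeated).
    """
    config = config or ScanConfig()
    s = normalize_seq(seq)
    if len(s) != len(db):
        raise KTurnError(f"sequence length {len(s)} != structure length {len(db)}")
    pmap = parse_dot_bracket(db)
    out = []
    L = len(s)
    for u in range(1, L - 3):
        # 3-nt unpaired run with paired flanks
        if any(i in pmap for i in (u, u + 1, u + 2)):
            continue
        if (u - 1) not in pmap or (u + 3) not in pmap:
            continue
        if pmap[u - 1] != pmap[u + 3] + 1:  # 3x0 loop: other strand contiguous
            continue
        p, q = u - 1, pmap[u - 1]  # -1b at p pairs -1n at q
        # sheared signature on NC side
        def bpos(j: int) -> int:
            return u + 2 + j

        def npos(j: int) -> int | None:
            return pmap.get(bpos(j))

        if npos(1) is None or npos(2) is None:
            continue
        if not (s[bpos(1)] == "G" and s[npos(1)] == "A" and s[bpos(2)] == "A" and s[npos(2)] == "G"):
            continue
        # NC-helix outward: consecutive stacked pairs
        nc_pairs: list[PairId] = []
        j = 1
        prev_n = q
        while True:
            bp = bpos(j)
            if bp >= L or bp not in pmap:
                break
            np_ = pmap[bp]
            if np_ != prev_n - 1:  # must stack without further loops
                break
            bb, nb = s[bp], s[np_]
            if j > 2 and not config.pair_ok(j, bb, nb):
                break
            nc_pairs.append(PairId(j, bb, nb))
            prev_n = np_
            j += 1
        if len(nc_pairs) < config.min_nc_pairs:
            continue
        # C-helix outward
        c_pairs: list[PairId] = []
        k = 1
        prev_n = q
        while True:
            bp = p - k + 1
            if bp < 0 or bp not in pmap:
                break
            np_ = pmap[bp]
            if k > 1 and np_ != prev_n + 1:
                break
            bb, nb = s[bp], s[np_]
            if not _wc_or_wobble(bb, nb):
                break
            c_pairs.append(PairId(-k, bb, nb))
            prev_n = np_
            k += 1
        if len(c_pairs) < config.min_c_pairs:
            continue
        ncp, nnc = len(c_pairs), len(nc_pairs)
        n_hi = q + ncp  # half-open over the n-side positions
        n_lo = pmap[bpos(nnc)]  # partner of the outermost NC pair
        ann = KTurnAnnotation(
            c_pairs=tuple(c_pairs),
            loop=(s[u], s[u + 1], s[u + 2]),
            nc_pairs=tuple(nc_pairs),
            b_strand_span=(p - ncp + 1, u + 3 + nnc),
            n_strand_span=(n_lo, n_hi),
            source_ids=("seq", "seq"),
        )
        out.append(ann)
    out.sort(key=lambda a: a.b_strand_span)
    return out


# ---------------------------------------------------------------------------
# fixture generation


@dataclass(frozen=True)
class KTurnSpec:
    """Construction parameters for a synthetic k-turn duplex.

    ``c_pairs`` inward-most first ((-1b, -1n) first), ``nc_pairs`` from index
    1 outward; the first two NC pairs must be G:A and A:G.
    """

    c_pairs: tuple[tuple[str, str], ...]
    loop: tuple[str, str, str]
    nc_pairs: tuple[tuple[str, str], ...]

    def as_annotation(self) -> KTurnAnnotation:
        ncp, nnc = len(self.c_pairs), len(self.nc_pairs)
        return KTurnAnnotation(
            c_pairs=tuple(PairId(-(i + 1), b, n) for i, (b, n) in enumerate(self.c_pairs)),
            loop=self.loop,
            nc_pairs=tuple(PairId(i + 1, b, n) for i, (b, n) in enumerate(self.nc_pairs)),
            b_strand_span=(0, ncp + 3 + nnc),
            n_strand_span=(0, ncp + nnc),
        )


def build_kturn_duplex(spec: KTurnSpec) -> tuple[str, str]:
    """Build (strand_b, strand_n) whose scan recovers ``spec`` exactly.

    The bulged strand reads C-helix (outer to inner), loop, NC-helix (inner
    to outer) 5'->3'; the antiparallel partner reads the NC-helix partners
    outer-to-inner then the C-helix partners inner-to-outer.
    """
    ann = spec.as_annotation()  # validates invariants, raises AnnotationError
    b = (
        "".join(p.b_base for p in reversed(ann.c_pairs))
        + "".join(ann.loop)
        + "".join(p.b_base for p in ann.nc_pairs)
    )
    n = "".join(p.n_base for p in reversed(ann.nc_pairs)) + "".join(
        p.n_base for p in ann.c_pairs
    )
    return b, n


_WC = [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")]
_WC_GU = _WC + [("G", "U"), ("U", "G")]
_ALL16 = [(b, n) for b in "ACGU" for n in "ACGU"]


def random_kturn_spec(rng: random.Random, config: ScanConfig | None = None) -> KTurnSpec:
    """Draw a random valid k-turn spec (for round-trip property testing).

    Helix pairs are WC or G:U wobble; the 3b:3n pair is drawn from all 16
    combinations; loop bases are uniform.  Helix lengths are drawn at the
    configured minima plus 0-2 extra pairs.
    """
    config = config or ScanConfig()
    n_c = rng.randint(config.min_c_pairs, config.min_c_pairs + 2)
    n_nc = rng.randint(config.min_nc_pairs, config.min_nc_pairs + 2)
    c_pairs = tuple(rng.choice(_WC_GU) for _ in range(n_c))
    loop = tuple(rng.choice("ACGU") for _ in range(3))
    nc = [("G", "A"), ("A", "G")]
    nc.append(rng.choice(_ALL16 if config.require_3bn_any else _WC_GU))
    for _ in range(n_nc - 3):
        nc.append(rng.choice(_WC_GU))
    return KTurnSpec(c_pairs=c_pairs, loop=loop, nc_pairs=tuple(nc))
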