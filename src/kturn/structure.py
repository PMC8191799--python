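"""Geometric verification and N3/N1 classification of k-turn 3D structures.

Given atomic coordinates (PDB or mmCIF) and a mapping from k-turn position
labels to residues, this module measures the diagnostic contacts of the
motif and decides between its two conformational families:

* the tandem G:A pairs adopt the trans sugar-Hoogsteen ("sheared")
  geometry, with hydrogen bonds G N2...A N7 and A N6...G N3;
* the conserved adenines accept cross-strand hydrogen bonds from the L1 and
  -1n 2'-hydroxyl groups; the -1n O2' proton is accepted by either N3 or N1
  of A2b, defining the N3 and N1 conformations.  In the N1 conformation the
  A2b base rotates in plane and the A2b N6 - G2n N3 distance lengthens to
  roughly 5.3 A, which serves as a secondary consistency check;
* a G:U at 4b:4n forms a cis-wobble pair (G O6...U N3 and G N1...U O2);
* the flanking helix axes meet at an included angle of about 50 degrees in
  the folded k-turn.

Crystal structures at typical resolutions carry no hydrogens, so all
hydrogen-bond criteria use heavy-atom distances with a configurable cutoff
(3.5 A default).  Helix axes are estimated from base-pair midpoints by
principal direction, adequate for a kinked/unkinked call (about +-5 deg);
full helicoidal parameter fitting is out of scope.

The module also generates synthetic k-turn core geometries with a chosen
acceptor atom (N3 or N1), used for classifier validation; these are built
from idealized base geometry and are not crystallographic models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np

from .core import Conformation, KTurnError

__all__ = [
    "StructureError",
    "Atom",
    "StructureModel",
    "ResidueMap",
    "GeometryReport",
    "read_structure",
    "measure_distance",
    "detect_sheared_GA",
    "check_wobble",
    "classify_N3_N1",
    "interhelical_angle",
    "make_synthetic_kturn_core",
    "make_sheared_ga_pair",
    "make_imino_ga_pair",
    "make_wobble_gu_pair",
    "make_synthetic_duplex_helix",
]

H_BOND_CUTOFF = 3.5  # heavy-atom donor-acceptor distance, Angstrom
N1_LENGTHENED = 4.5  # A2b N6 - G2n N3 beyond this supports N1
KINK_ANGLE_MAX = 70.0  # included angles at or below this count as kinked


class StructureError(KTurnError, ValueError):
    """Invalid structural input (unknown format, missing atoms/residues)."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    resname: str
    chain: str
    resnum: int
    pos: tuple[float, float, float]

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


class StructureModel:
    """Atomic coordinates indexed by (chain, residue number, atom name).

    Atom names follow PDB nucleic-acid conventions with primes (O2', C1');
    star variants (O2*) are normalized on input.
    """

    def __init__(self, atoms: Sequence[Atom], model_id: str = "1") -> None:
        self.atoms = list(atoms)
        self.model_id = model_id
        self._index: dict[tuple[str, int], dict[str, Atom]] = {}
        for a in self.atoms:
            if not all(math.isfinite(c) for c in a.pos):
                raise StructureError(f"non-finite coordinates on atom {a}")
            self._index.setdefault((a.chain, a.resnum), {})[a.name] = a

    def residues(self) -> list[tuple[str, int]]:
        return list(self._index)

    def residue_name(self, chain: str, resnum: int) -> str:
        res = self._require_residue(chain, resnum)
        return next(iter(res.values())).resname

    def _require_residue(self, chain: str, resnum: int) -> dict[str, Atom]:
        try:
            return self._index[(chain, resnum)]
        except KeyError:
            raise StructureError(f"residue {chain}/{resnum} not present in model") from None

    def atom(self, chain: str, resnum: int, name: str) -> Atom:
        res = self._require_residue(chain, resnum)
        key = _normalize_atom_name(name)
        if key not in res:
            raise StructureError(
                f"atom {key!r} missing from residue {chain}/{resnum} ({self.residue_name(chain, resnum)})"
            )
        return res[key]

    def has_atom(self, chain: str, resnum: int, name: str) -> bool:
        res = self._index.get((chain, resnum), {})
        return _normalize_atom_name(name) in res

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """A copy under the rigid motion x -> R x + t (used in invariance tests)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        moved = [
            Atom(a.name, a.element, a.resname, a.chain, a.resnum, tuple(R @ a.xyz + t))
            for a in self.atoms
        ]
        return StructureModel(moved, model_id=self.model_id)


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'")


def read_structure(path: str | Path, fmt: str | None = None) -> StructureModel:
    """Load a PDB or mmCIF file into a :class:`StructureModel`.

    Format is inferred from the extension unless ``fmt`` ("pdb" | "mmcif")
    is given.  Multi-model files keep the first model (with a warning); for
    alternate locations the highest-occupancy altloc of each atom is kept.
    """
    path = Path(path)
    if fmt is not None:
        fmt_l = fmt.lower()
        if fmt_l == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt_l in {"mmcif", "cif"}:
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        else:
            raise StructureError(f"unknown structure format {fmt!r} (expected pdb or mmcif)")
    else:
        try:
            st = gemmi.read_structure(str(path))
        except (RuntimeError, ValueError) as e:
            raise StructureError(f"could not read structure {path}: {e}") from e
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    if len(st) > 1:
        warnings.warn(f"{path.name}: {len(st)} models present, keeping the first", stacklevel=2)
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                name = _normalize_atom_name(at.name)
                prev = best.get(name)
                if prev is None:
                    best[name] = at
                elif at.occ > prev.occ:
                    warnings.warn(
                        f"altloc on {chain.name}/{res.seqid.num} {name}: keeping highest occupancy",
                        stacklevel=2,
                    )
                    best[name] = at
                else:
                    warnings.warn(
                        f"altloc on {chain.name}/{res.seqid.num} {name}: keeping highest occupancy",
                        stacklevel=2,
                    )
            for name, at in best.items():
                atoms.append(
                    Atom(
                        name=name,
                        element=at.element.name,
                        resname=res.name.strip(),
                        chain=chain.name,
                        resnum=res.seqid.num,
                        pos=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )
    return StructureModel(atoms, model_id=str(st.name or path.stem))


# ---------------------------------------------------------------------------
# residue mapping


@dataclass
class ResidueMap:
    """Mapping from k-turn position labels to (chain, residue number).

    Labels use the standard nomenclature: ``-1n``, ``1b``, ``2b``, ``L1`` ...
    Classification requires at least -1n, 1n, 2b, 2n and L1.
    """

    entries: dict[str, tuple[str, int]] = field(default_factory=dict)

    REQUIRED_FOR_CLASSIFICATION = ("-1n", "1n", "2b", "2n", "L1")

    def __getitem__(self, label: str) -> tuple[str, int]:
        try:
            return self.entries[label]
        except KeyError:
            raise StructureError(f"label {label!r} not present in residue map") from None

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def missing_for_classification(self) -> list[str]:
        return [l for l in self.REQUIRED_FOR_CLASSIFICATION if l not in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueMap":
        """Read TSV with columns label, chain, resnum (header optional)."""
        entries = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise StructureError(f"residue map line needs 3 tab-separated fields: {line!r}")
                label, chain, resnum = parts
                if label.lower() == "label":
                    continue
                entries[label] = (chain, int(resnum))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tchain\tresnum\n")
            for label, (chain, resnum) in self.entries.items():
                fh.write(f"{label}\t{chain}\t{resnum}\n")


Selector = tuple  # (label | "chain/resnum" | (chain, resnum), atom name)


def _resolve(sel: Selector, rmap: ResidueMap | None) -> tuple[str, int, str]:
    where, atom_name = sel
    if isinstance(where, tuple):
        chain, resnum = where
        return str(chain), int(resnum), atom_name
    if rmap is not None and where in rmap:
        chain, resnum = rmap[where]
        return chain, resnum, atom_name
    if isinstance(where, str) and "/" in where:
        chain, resnum = where.split("/", 1)
        return chain, int(resnum), atom_name
    raise StructureError(f"cannot resolve residue selector {where!r}")


def measure_distance(
    model: StructureModel, sel1: Selector, sel2: Selector, rmap: ResidueMap | None = None
) -> float:
    """Euclidean distance (A) between two atoms.

    Selectors are (residue, atom-name) with the residue given as a k-turn
    label (resolved through ``rmap``), a ``"chain/resnum"`` string, or a
    (chain, resnum) tuple.  Missing atoms raise naming the selector.
    """
    c1, r1, a1 = _resolve(sel1, rmap)
    c2, r2, a2 = _resolve(sel2, rmap)
    p1 = model.atom(c1, r1, a1).xyz
    p2 = model.atom(c2, r2, a2).xyz
    return float(np.linalg.norm(p1 - p2))


# ---------------------------------------------------------------------------
# base-pair geometry checks


def _check_restype(model: StructureModel, chain: str, resnum: int, expect: str) -> None:
    name = model.residue_name(chain, resnum).upper()
    # tolerate one-letter RNA names and DNA-prefixed variants
    base = name[-1] if name else ""
    if base != expect:
        raise StructureError(f"residue {chain}/{resnum} is {name!r}, expected a {expect}")


def detect_sheared_GA(
    model: StructureModel,
    g_sel,
    a_sel,
    rmap: ResidueMap | None = None,
    cutoff: float = H_BOND_CUTOFF,
) -> dict:
    """Test a G and an A residue for the sheared (trans sugar-Hoogsteen) pair.

    The verdict requires d(G N2...A N7) <= cutoff; d(A N6...G N3) is measured
    and reported but not required, because it lengthens in the N1
    conformation of the 2b:2n pair.  ``g_sel``/``a_sel`` are residue
    selectors as accepted by :func:`measure_distance`.
    """
    gc, gr, _ = _resolve((g_sel, "N2"), rmap)
    ac, ar, _ = _resolve((a_sel, "N7"), rmap)
    _check_restype(model, gc, gr, "G")
    _check_restype(model, ac, ar, "A")
    d_n2_n7 = measure_distance(model, ((gc, gr), "N2"), ((ac, ar), "N7"))
    try:
        d_n6_n3 = measure_distance(model, ((ac, ar), "N6"), ((gc, gr), "N3"))
    except StructureError:
        d_n6_n3 = None
    return {
        "sheared": bool(d_n2_n7 <= cutoff),
        "d_GN2_AN7": d_n2_n7,
        "d_AN6_GN3": d_n6_n3,
        "cutoff": cutoff,
    }


def check_wobble(
    model: StructureModel,
    g_sel,
    u_sel,
    rmap: ResidueMap | None = None,
    cutoff: float = H_BOND_CUTOFF,
) -> dict:
    """Test a G and a U residue for the cis-wobble pair.

    Verdict true iff both nucleobase hydrogen bonds are present:
    d(G O6...U N3) <= cutoff and d(G N1...U O2) <= cutoff.
    """
    gc, gr, _ = _resolve((g_sel, "O6"), rmap)
    uc, ur, _ = _resolve((u_sel, "N3"), rmap)
    _check_restype(model, gc, gr, "G")
    _check_restype(model, uc, ur, "U")
    d_o6_n3 = measure_distance(model, ((gc, gr), "O6"), ((uc, ur), "N3"))
    d_n1_o2 = measure_distance(model, ((gc, gr), "N1"), ((uc, ur), "O2"))
    return {
        "wobble": bool(d_o6_n3 <= cutoff and d_n1_o2 <= cutoff),
        "d_GO6_UN3": d_o6_n3,
        "d_GN1_UO2": d_n1_o2,
        "cutoff": cutoff,
    }


# ---------------------------------------------------------------------------
# N3/N1 classification


@dataclass
class GeometryReport:
    """Measured k-turn geometry and the resulting conformational verdict."""

    distances: dict[str, float | None]
    sheared: dict[str, dict]
    conformation: Conformation
    notes: list[str]
    interhelical_angle_deg: float | None = None
    kinked: bool | None = None

    def to_dict(self) -> dict:
        return {
            "distances_A": self.distances,
            "sheared_pairs": self.sheared,
            "conformation": self.conformation.value,
            "notes": self.notes,
            "interhelical_angle_deg": self.interhelical_angle_deg,
            "kinked": self.kinked,
        }


def classify_N3_N1(
    model: StructureModel,
    rmap: ResidueMap,
    cutoff: float = H_BOND_CUTOFF,
    lengthened: float = N1_LENGTHENED,
) -> GeometryReport:
    """Classify a mapped k-turn as N3 or N1 from its hydrogen-bond geometry.

    Primary criterion: of d(-1n O2'...A2b N3) and d(-1n O2'...A2b N1), the
    smaller one decides, provided it is within the hydrogen-bond cutoff.
    Secondary consistency check: d(A2b N6...G2n N3) <= cutoff supports N3,
    >= ``lengthened`` supports N1 (the in-plane rotation of A2b in the N1
    conformation stretches this contact to ~5.3 A); intermediate values
    abstain.  Disagreement between the two criteria, or missing required
    atoms, yields UNKNOWN with the reason and all measured distances listed.
    The report also verifies the other conserved cross-strand bond,
    d(L1 O2'...A1n N1), and the sheared geometry of both tandem G:A pairs
    when 1b is mapped.
    """
    notes: list[str] = []
    distances: dict[str, float | None] = {}
    missing = rmap.missing_for_classification()
    if missing:
        return GeometryReport(
            distances={},
            sheared={},
            conformation=Conformation.UNKNOWN,
            notes=[f"residue map lacks required labels: {', '.join(missing)}"],
        )

    def safe(label: str, sel1, sel2) -> float | None:
        try:
            d = measure_distance(model, sel1, sel2, rmap)
        except StructureError as e:
            notes.append(f"{label}: {e}")
            d = None
        distances[label] = d
        return d

    d_n3 = safe("-1nO2'-A2bN3", ("-1n", "O2'"), ("2b", "N3"))
    d_n1 = safe("-1nO2'-A2bN1", ("-1n", "O2'"), ("2b", "N1"))
    d_n6 = safe("A2bN6-G2nN3", ("2b", "N6"), ("2n", "N3"))
    d_l1 = safe("L1O2'-A1nN1", ("L1", "O2'"), ("1n", "N1"))

    sheared: dict[str, dict] = {}
    for pair_label, g_label, a_label in (("1b:1n", "1b", "1n"), ("2b:2n", "2n", "2b")):
        if g_label in rmap and a_label in rmap:
            try:
                sheared[pair_label] = detect_sheared_GA(model, g_label, a_label, rmap, cutoff)
            except StructureError as e:
                notes.append(f"sheared check {pair_label}: {e}")

    if d_n3 is None or d_n1 is None:
        notes.append("deciding distances not both measurable")
        return GeometryReport(distances, sheared, Conformation.UNKNOWN, notes)

    if d_n3 <= d_n1 and d_n3 <= cutoff:
        primary = Conformation.N3
        notes.append(f"-1n O2' accepted by A2b N3 ({d_n3:.2f} A <= {cutoff} A)")
    elif d_n1 < d_n3 and d_n1 <= cutoff:
        primary = Conformation.N1
        notes.append(f"-1n O2' accepted by A2b N1 ({d_n1:.2f} A <= {cutoff} A)")
    else:
        notes.append(
            f"neither acceptor within H-bond range (N3 {d_n3:.2f} A, N1 {d_n1:.2f} A)"
        )
        return GeometryReport(distances, sheared, Conformation.UNKNOWN, notes)

    if d_n6 is not None:
        if d_n6 <= cutoff:
            secondary = Conformation.N3
        elif d_n6 >= lengthened:
            secondary = Conformation.N1
            notes.append(f"A2b N6 - G2n N3 lengthened to {d_n6:.2f} A (N1-like)")
        else:
            secondary = None
            notes.append(f"A2b N6 - G2n N3 = {d_n6:.2f} A: secondary check abstains")
        if secondary is not None and secondary is not primary:
            notes.append(
                f"criteria disagree: O2' acceptor says {primary.value}, "
                f"A2b N6 - G2n N3 = {d_n6:.2f} A says {secondary.value}"
            )
            return GeometryReport(distances, sheared, Conformation.UNKNOWN, notes)
    else:
        notes.append("A2b N6 - G2n N3 not measurable; secondary check skipped")

    if d_l1 is not None and d_l1 > cutoff:
        notes.append(f"cross-strand bond L1 O2' - A1n N1 not formed ({d_l1:.2f} A)")
    return GeometryReport(distances, sheared, primary, notes)


# ---------------------------------------------------------------------------
# interhelical angle

_AXIS_ATOMS = ("C1'", "P")


def _pair_midpoints(
    model: StructureModel, pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]]
) -> np.ndarray:
    mids = []
    for res1, res2 in pairs:
        pts = []
        for chain, resnum in (res1, res2):
            for name in _AXIS_ATOMS:
                if model.has_atom(chain, resnum, name):
                    pts.append(model.atom(chain, resnum, name).xyz)
                    break
            else:
                raise StructureError(
                    f"residue {chain}/{resnum} has none of the axis atoms {_AXIS_ATOMS}"
                )
        mids.append(np.mean(pts, axis=0))
    return np.asarray(mids)


def interhelical_angle(
    model: StructureModel,
    c_helix_pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]],
    nc_helix_pairs: Sequence[tuple[tuple[str, int], tuple[str, int]]],
) -> float:
    """Included angle (degrees) between the axes of two helices.

    Each helix is given as >= 3 base pairs, each a ((chain, resnum),
    (chain, resnum)) tuple ordered 5'->3' along the bulged strand.  The axis
    is the principal direction of the base-pair midpoints (C1' atoms, P as
    fallback), oriented along the pair ordering; precision is about +-5 deg,
    adequate to distinguish the tightly kinked k-turn (around 50 deg) from
    coaxial geometry.
    """
    axes = []
    for pairs in (c_helix_pairs, nc_helix_pairs):
        if len(pairs) < 3:
            raise StructureError("need >= 3 base pairs per helix for an axis estimate")
        mids = _pair_midpoints(model, pairs)
        centered = mids - mids.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        axis = vt[0]
        if np.dot(axis, mids[-1] - mids[0]) < 0:
            axis = -axis
        axes.append(axis)
    cosang = float(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0))
    return math.degrees(math.acos(cosang))


# ---------------------------------------------------------------------------
# synthetic geometry generators (idealized, for validation -- not models of
# any deposited structure)

# adenine heavy atoms in the standard base reference frame (A), base plane z=0
_ADENINE_FRAME = {
    "N9": (-1.291, 4.498, 0.0),
    "C8": (0.024, 4.897, 0.0),
    "N7": (0.877, 3.902, 0.0),
    "C5": (0.071, 2.771, 0.0),
    "C6": (0.369, 1.398, 0.0),
    "N6": (1.611, 0.909, 0.0),
    "N1": (-0.668, 0.532, 0.0),
    "C2": (-1.912, 1.023, 0.0),
    "N3": (-2.320, 2.290, 0.0),
    "C4": (-1.267, 3.124, 0.0),
}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_synthetic_kturn_core(
    conformation: Conformation | str,
    seed: int | None = None,
    h_bond: float = 2.8,
    n1_n6_n3: float = 5.3,
    jitter: float = 0.05,
) -> tuple[StructureModel, ResidueMap]:
    """Build an idealized k-turn hydrogen-bonding core with a known acceptor.

    Places a full adenine (A2b) in its standard base frame, a G2n with N2
    hydrogen-bonded to A2b N7 (sheared pair) and N3 either paired with A2b
    N6 (N3 conformation) or lengthened to ``n1_n6_n3`` A (N1 conformation,
    mimicking the in-plane rotation), a G(-1n) whose O2' sits ``h_bond`` A
    from the chosen acceptor atom and far from the rival, a U(L1) O2'
    bonded to A1n N1, and a minimal A1n.  The assembly is jittered by
    ``jitter`` A per coordinate and placed under a random rigid motion, both
    seeded.  Returns the model and its residue map; synthetic, for
    classifier validation only.
    """
    conf = Conformation(conformation)
    if conf not in (Conformation.N3, Conformation.N1):
        raise StructureError("synthetic core requires conformation N3 or N1")
    rng = np.random.default_rng(seed)
    A = {k: np.array(v) for k, v in _ADENINE_FRAME.items()}

    atoms: list[Atom] = []

    def add(name: str, resname: str, chain: str, resnum: int, pos: np.ndarray) -> None:
        elem = name[0]
        atoms.append(Atom(name, elem, resname, chain, resnum, tuple(pos)))

    # A2b: chain B residue 12
    for name, pos in A.items():
        add(name, "A", "B", 12, pos)

    # G2n: N2 on the Hoogsteen edge of A2b (bonded to N7), N3 near or far
    # from A2b N6 depending on the conformation
    n7_dir = _unit(A["N7"] - A["C5"])
    g2n_n2 = A["N7"] + h_bond * n7_dir
    n6_dir = _unit(A["N6"] - A["C6"])
    d_n6 = h_bond if conf is Conformation.N3 else n1_n6_n3
    g2n_n3 = A["N6"] + d_n6 * n6_dir
    add("N2", "G", "N", 13, g2n_n2)
    add("N3", "G", "N", 13, g2n_n3)
    add("N7", "G", "N", 13, g2n_n2 + np.array([2.3, 0.8, 0.0]))  # ring filler

    # -1n O2': near the chosen acceptor, placed on the extension of the line
    # through the rival acceptor so the rival distance is always larger
    if conf is Conformation.N3:
        o2p = A["N3"] + h_bond * _unit(A["N3"] - A["N1"])
    else:
        o2p = A["N1"] + h_bond * _unit(A["N1"] - A["N3"])
    add("O2'", "G", "N", 14, o2p)

    # A1n with its N1, and the L1 O2' hydrogen-bonded to it
    a1n_n1 = np.array([4.5, -3.5, 2.5])
    add("N1", "A", "N", 15, a1n_n1)
    add("N6", "A", "N", 15, a1n_n1 + np.array([1.2, 2.2, 0.0]))
    add("N7", "A", "N", 15, a1n_n1 + np.array([0.9, 5.6, 0.4]))
    add("O2'", "U", "B", 11, a1n_n1 + h_bond * np.array([0.0, -1.0, 0.0]))

    # G1b sheared against A1n: N2 within H-bond range of A1n N7
    add("N2", "G", "B", 13, a1n_n1 + np.array([0.9, 2.7, 0.4]))
    add("N3", "G", "B", 13, a1n_n1 + np.array([2.4, 3.4, 0.6]))

    coords = np.array([a.pos for a in atoms])
    if jitter > 0:
        coords = coords + rng.normal(0.0, jitter, size=coords.shape)
    R = _random_rotation(rng)
    t = rng.uniform(-50.0, 50.0, size=3)
    coords = coords @ R.T + t
    atoms = [
        Atom(a.name, a.element, a.resname, a.chain, a.resnum, tuple(c))
        for a, c in zip(atoms, coords)
    ]
    rmap = ResidueMap(
        {
            "2b": ("B", 12),
            "2n": ("N", 13),
            "-1n": ("N", 14),
            "1n": ("N", 15),
            "L1": ("B", 11),
            "1b": ("B", 13),
        }
    )
    return StructureModel(atoms, model_id=f"synthetic-{conf.value}"), rmap


def make_sheared_ga_pair(h_bond: float = 2.9) -> StructureModel:
    """Idealized sheared G:A pair (G N2...A N7 and A N6...G N3 at ``h_bond`` A)."""
    A = {k: np.array(v) for k, v in _ADENINE_FRAME.items()}
    atoms = [Atom(n, n[0], "A", "A", 1, tuple(p)) for n, p in A.items()]
    g_n2 = A["N7"] + h_bond * _unit(A["N7"] - A["C5"])
    g_n3 = A["N6"] + h_bond * _unit(A["N6"] - A["C6"])
    atoms.append(Atom("N2", "N", "G", "A", 2, tuple(g_n2)))
    atoms.append(Atom("N3", "N", "G", "A", 2, tuple(g_n3)))
    return StructureModel(atoms, model_id="synthetic-sheared-GA")


def make_imino_ga_pair() -> StructureModel:
    """A G:A pair in cis Watson-Crick-like (imino) geometry: N2...N7 is far.

    Approximates the imino arrangement by placing the G amino/imino edge
    against the A Watson-Crick edge; the Hoogsteen-edge N7 of A is then >5 A
    from G N2, so the sheared-pair test must reject it.
    """
    A = {k: np.array(v) for k, v in _ADENINE_FRAME.items()}
    atoms = [Atom(n, n[0], "A", "A", 1, tuple(p)) for n, p in A.items()]
    wc_dir = _unit(A["N1"] - A["C2"] + A["N1"] - A["C6"])
    g_n1 = A["N1"] + 2.9 * wc_dir
    g_n2 = g_n1 + 2.3 * _unit(np.array([-0.4, -1.0, 0.0]))
    g_n3 = g_n1 + 2.4 * _unit(np.array([-1.0, -0.4, 0.0]))
    atoms.append(Atom("N1", "N", "G", "A", 2, tuple(g_n1)))
    atoms.append(Atom("N2", "N", "G", "A", 2, tuple(g_n2)))
    atoms.append(Atom("N3", "N", "G", "A", 2, tuple(g_n3)))
    return StructureModel(atoms, model_id="synthetic-imino-GA")


def make_wobble_gu_pair(h_bond: float = 2.8, wobble: bool = True) -> StructureModel:
    """Idealized G:U pair; wobble geometry when ``wobble``, else WC-like.

    In the wobble arrangement both G O6...U N3 and G N1...U O2 sit at
    ``h_bond`` A; in the WC-like control U is shifted so that O2 moves out
    of range of G N1.
    """
    g_o6 = np.array([0.0, 0.0, 0.0])
    g_n1 = np.array([0.0, -2.3, 0.0])
    atoms = [
        Atom("O6", "O", "G", "A", 1, tuple(g_o6)),
        Atom("N1", "N", "G", "A", 1, tuple(g_n1)),
    ]
    if wobble:
        u_n3 = g_o6 + np.array([h_bond, 0.0, 0.0])
        u_o2 = g_n1 + np.array([h_bond, 0.0, 0.0])
    else:
        u_n3 = g_o6 + np.array([h_bond, 2.2, 0.0])  # shifted up: N1...O2 breaks
        u_o2 = g_n1 + np.array([h_bond, 4.4, 0.0])
    atoms.append(Atom("N3", "N", "U", "A", 2, tuple(u_n3)))
    atoms.append(Atom("O2", "O", "U", "A", 2, tuple(u_o2)))
    return StructureModel(atoms, model_id="synthetic-GU")


def make_synthetic_duplex_helix(
    n_pairs: int,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    chain_ids: tuple[str, str] = ("A", "B"),
    resnum_start: int = 1,
    rise: float = 2.81,
    twist_deg: float = 32.7,
    radius: float = 9.4,
) -> tuple[StructureModel, list[tuple[tuple[str, int], tuple[str, int]]]]:
    """Generate a simplified duplex helix for axis-estimation tests.

    Places paired C1' atoms diametrically opposite on a cylinder around the
    given axis (A-form-like rise and twist), so base-pair midpoints lie
    exactly on the axis.  Returns the model and its base-pair list in the
    form accepted by :func:`interhelical_angle`.  Purely synthetic; it
    carries no bases or backbone beyond the C1' trace.
    """
    axis = _unit(np.asarray(axis if axis is not None else [0.0, 0.0, 1.0], dtype=float))
    origin = np.asarray(origin if origin is not None else [0.0, 0.0, 0.0], dtype=float)
    # orthonormal frame around the axis
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(axis, helper))
    v = np.cross(axis, u)
    atoms: list[Atom] = []
    pairs = []
    for i in range(n_pairs):
        theta = math.radians(twist_deg) * i
        center = origin + rise * i * axis
        p1 = center + radius * (math.cos(theta) * u + math.sin(theta) * v)
        p2 = center - radius * (math.cos(theta) * u + math.sin(theta) * v)
        r1 = (chain_ids[0], resnum_start + i)
        r2 = (chain_ids[1], resnum_start + i)
        atoms.append(Atom("C1'", "C", "G", r1[0], r1[1], tuple(p1)))
        atoms.append(Atom("C1'", "C", "C", r2[0], r2[1], tuple(p2)))
        pairs.append((r1, r2))
    return StructureModel(atoms, model_id="synthetic-helix"), pairs
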