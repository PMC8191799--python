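"""Reference parameters of the characterized k-turn constructs.

Steady-state FRET titrations of 25-bp duplexes carrying a central k-turn,
5'-labelled with fluorescein (bulged strand) and Cy3 (non-bulged strand),
give a two-state folding isotherm per construct.  The table below records
the published operating points used throughout this package as generator
inputs for synthetic-data studies: the zero-ion FRET efficiency E0, the
saturating efficiency (plateau), and the apparent Kd for Mg2+-induced
folding.  The wild-type background is the archetypal Kt-7 k-turn; variants
change a single base pair.  Where a construct's own E0 was not reported it
is taken as the 0.25 of the shared Kt-7 duplex background (all constructs
are the same labelled duplex design and start from the same extended state).

``grid_uM`` is the log-spaced titration window used for synthetic
parameter-recovery studies: 1 uM-10 mM generally, extended down to 0.5 uM
for the high-affinity drum k-turn (Kd = 8 uM) so the lower baseline is
sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["TitrationReference", "TITRATION_REFERENCES", "TABLE_OF_FOUR"]


@dataclass(frozen=True)
class TitrationReference:
    """Published two-state isotherm parameters for one construct."""

    name: str
    e0: float
    plateau: float
    kd_uM: float
    grid_uM: tuple[float, float] = (1.0, 10_000.0)

    @property
    def de(self) -> float:
        return self.plateau - self.e0

    @property
    def kd_M(self) -> float:
        return self.kd_uM * 1e-6


TITRATION_REFERENCES: dict[str, TitrationReference] = {
    # wild-type Kt-7: E_FRET 0.25 -> 0.56, apparent Kd 70 uM
    "Kt7_WT": TitrationReference("Kt7_WT", e0=0.25, plateau=0.56, kd_uM=70.0),
    # -1b:-1n = U:A: weak folding, E_FRET rises only to 0.3, Kd 231 uM
    "Kt7_m1_UA": TitrationReference("Kt7_m1_UA", e0=0.25, plateau=0.30, kd_uM=231.0),
    # -1b:-1n = A:U: folds almost as well as wild type, Kd 106 uM
    "Kt7_m1_AU": TitrationReference("Kt7_m1_AU", e0=0.25, plateau=0.56, kd_uM=106.0),
    # 4b:4n = G:U: more complete folding (plateau 0.67) at lower Mg2+, Kd 44 uM
    "Kt7_4bn_GU": TitrationReference("Kt7_4bn_GU", e0=0.25, plateau=0.67, kd_uM=44.0),
    # drum k-turn: plateau ~0.6, the highest apparent affinity, Kd 8 uM
    "drum": TitrationReference("drum", e0=0.25, plateau=0.60, kd_uM=8.0,
                               grid_uM=(0.5, 10_000.0)),
    # RAGATH-18 k-turn: plateau ~0.6, Kd 33 uM
    "RAGATH-18": TitrationReference("RAGATH-18", e0=0.25, plateau=0.60, kd_uM=33.0),
}


#: key pairs (-1b:-1n, 3b:3n, 4b:4n) and confirmed behaviour of the four
#: k-turns identified among the structured bacterial intergenic RNAs
TABLE_OF_FOUR = [
    ("Actinomyces-1", ("C", "G"), ("C", "C"), ("C", "G"), "FOLDS", "N1"),
    ("drum", ("C", "G"), ("A", "G"), ("G", "U"), "FOLDS", "N3"),
    ("HOLDH", ("U", "A"), ("A", "G"), ("G", "U"), "FOLDS_WEAKLY", "N3"),
    ("RAGATH-18", ("C", "G"), ("A", "G"), ("G", "U"), "FOLDS", "N3"),
]
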