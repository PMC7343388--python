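"""Normalized basal position (NBP) from synaptic contact geometry.

An inner hair cell is bisected from its basal pole to the cuticular plate;
a fiber's contact at distance ``c`` along the radial axis from the basal pole,
on a hair cell of length ``L``, gets the signed fractional position

    NBP = s * c / L,   s = +1 (modiolar face), s = -1 (pillar face).

When a fiber makes several contacts, the most extreme position relative to the
basal pole (maximal |c/L|) is taken.  The binary face class uses the inclusive
rule: modiolar iff NBP >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Contact", "ContactGeometry", "compute_nbp", "classify_face"]

_FACES = ("modiolar", "pillar")


@dataclass(frozen=True)
class Contact:
    c: float          # distance from the basal pole along the radial axis (um)
    face: str

    def __post_init__(self):
        if self.face not in _FACES:
            raise ValueError(f"face must be one of {_FACES}, got {self.face!r}")
        if self.c < 0:
            raise ValueError("contact distance c must be >= 0")


@dataclass
class ContactGeometry:
    contacts: list = field(default_factory=list)
    hair_cell_length: float = 0.0

    def __post_init__(self):
        if self.hair_cell_length <= 0:
            raise ValueError("hair_cell_length must be positive")
        for ct in self.contacts:
            if ct.c > self.hair_cell_length:
                raise ValueError(
                    f"contact at c={ct.c} exceeds hair cell length "
                    f"{self.hair_cell_length}")


def compute_nbp(geom: ContactGeometry) -> float:
    """Signed fractional position of the most extreme contact, in [-1, 1].

    Ties between equal-magnitude modiolar and pillar contacts break toward
    modiolar, consistent with the inclusive face-class rule.
    """
    if not geom.contacts:
        raise ValueError("contact list is empty")
    best = None
    for ct in geom.contacts:
        signed = (1.0 if ct.face == "modiolar" else -1.0) * ct.c / geom.hair_cell_length
        if (best is None or abs(signed) > abs(best)
                or (abs(signed) == abs(best) and signed > best)):
            best = signed
    return float(best) + 0.0  # normalizes signed zero


def classify_face(nbp: float) -> str:
    """Binary face class: ``"modiolar"`` iff nbp >= 0, else ``"pillar"``."""
    if not -1.0 <= nbp <= 1.0:
        raise ValueError("nbp outside [-1, 1]")
    return "modiolar" if nbp >= 0 else "pillar"
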