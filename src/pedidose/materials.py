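"""Tissue materials of the stylized 5-year-old phantom.

Eight organ compositions (elemental mass percentages, density, reference
volume) follow the published paediatric organ table used by this analysis.
Four additional tissues that the table omits -- kidney, bladder wall, urine
and whole-body soft tissue -- are filled in from ICRP 89 / ICRU 46 style
reference values; see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ELEMENTS = ("H", "C", "N", "O", "Na", "P", "S", "Cl", "K")

# organ -> ([H, C, N, O, Na, P, S, Cl, K] mass %, density g/cc, volume cc)
_ORGAN_TABLE: dict[str, tuple[list[float], float, float]] = {
    "lung": ([10.3, 10.5, 3.1, 74.9, 0.2, 0.2, 0.3, 0.3, 0.1], 0.260, 980.0),
    "heart": ([10.4, 13.9, 2.9, 71.8, 0.1, 0.2, 0.2, 0.2, 0.3], 1.04, 218.0),
    "stomach": ([10.6, 11.5, 2.2, 75.1, 0.1, 0.1, 0.1, 0.2, 0.1], 1.03, 119.4),
    "liver": ([10.3, 18.6, 2.8, 67.1, 0.2, 0.2, 0.3, 0.2, 0.3], 1.05, 562.0),
    "colon": ([10.6, 11.5, 2.2, 75.1, 0.1, 0.1, 0.1, 0.2, 0.1], 1.03, 149.7),
    "small_intestine": ([10.6, 11.5, 2.2, 75.1, 0.1, 0.1, 0.1, 0.2, 0.1], 1.03, 265.0),
    "testis": ([10.6, 9.9, 2.0, 76.6, 0.2, 0.1, 0.2, 0.2, 0.2], 1.04, 1.57),
    "ovary": ([10.5, 9.3, 2.4, 76.8, 0.2, 0.2, 0.2, 0.2, 0.2], 1.04, 1.66),
}

# tissues the organ table omits (see docs/methods.md)
_SOFT_AVG = [sum(_ORGAN_TABLE[o][0][i] for o in _ORGAN_TABLE) / len(_ORGAN_TABLE)
             for i in range(len(ELEMENTS))]
_EXTRA_TISSUES: dict[str, tuple[list[float], float]] = {
    "kidney": (_SOFT_AVG, 1.05),
    "bladder_wall": (_SOFT_AVG, 1.04),
    "soft_tissue": (_SOFT_AVG, 1.04),
    "urine": ([11.19, 0.0, 0.0, 88.81, 0.0, 0.0, 0.0, 0.0, 0.0], 1.00),
}


@dataclass(frozen=True)
class Material:
    """Elemental mass fractions (percent) plus density for one tissue."""

    name: str
    mass_fractions: dict[str, float] = field(hash=False)
    density: float  # g/cc

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"material {self.name!r}: density must be > 0")
        unknown = set(self.mass_fractions) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"material {self.name!r}: unknown elements {sorted(unknown)}")
        total = sum(self.mass_fractions.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(
                f"material {self.name!r}: mass fractions sum to {total:.2f}, not 100 +- 0.5")

    @property
    def weight_fractions(self) -> dict[str, float]:
        """Mass fractions normalized to unity (for mixture-rule physics)."""
        total = sum(self.mass_fractions.values())
        return {el: w / total for el, w in self.mass_fractions.items() if w > 0}


def table_organs() -> tuple[str, ...]:
    """Names of the organs with published composition rows."""
    return tuple(_ORGAN_TABLE)


def material_from_table(name: str) -> Material:
    """Material for a published organ row or one of the defined extra tissues.

    Raises ``KeyError`` for unknown names.
    """
    key = name.lower().strip().replace(" ", "_")
    if key in _ORGAN_TABLE:
        fractions, density, _ = _ORGAN_TABLE[key]
    elif key in _EXTRA_TISSUES:
        fractions, density = _EXTRA_TISSUES[key]
    else:
        known = sorted(list(_ORGAN_TABLE) + list(_EXTRA_TISSUES))
        raise KeyError(f"unknown organ/tissue {name!r}; known: {known}")
    return Material(key, dict(zip(ELEMENTS, fractions)), density)


def reference_volume(name: str) -> float:
    """Published reference volume (cc) for a table organ."""
    key = name.lower().strip().replace(" ", "_")
    try:
        return _ORGAN_TABLE[key][2]
    except KeyError:
        raise KeyError(f"no reference volume for {name!r}") from None
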