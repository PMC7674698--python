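"""Radionuclide decay data and emission sampling.

⁹⁹ᵐTc decays with a 6.01 h half-life; its photon spectrum is dominated by the
140.5 keV gamma line (89.06% per decay) with two weak ~18 keV lines, for a
total photon yield of 0.9515 per decay.  The internal-conversion electron and
fluorescence energy of the remaining decays is not transported (see
docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Radionuclide:
    name: str
    half_life_h: float
    lines: tuple[tuple[float, float], ...]  # (energy MeV, yield % per decay)

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        if any(y < 0 for _, y in self.lines):
            raise ValueError("line yields must be >= 0")

    @property
    def decay_constant_per_min(self) -> float:
        """lambda = ln2 / (half-life in minutes)."""
        return math.log(2.0) / (self.half_life_h * 60.0)

    @property
    def photons_per_decay(self) -> float:
        return sum(y for _, y in self.lines) / 100.0

    def line_probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(energies MeV, probability of each line given a photon is emitted)."""
        e = np.array([en for en, _ in self.lines])
        y = np.array([y for _, y in self.lines])
        return e, y / y.sum()


def tc99m() -> Radionuclide:
    """⁹⁹ᵐTc: half-life 6.01 h; lines 18.3/18.4/140.5 keV."""
    return Radionuclide(
        name="Tc-99m",
        half_life_h=6.01,
        lines=((0.0183, 2.1), (0.0184, 3.99), (0.1405, 89.06)),
    )


def sample_emission(nuclide: Radionuclide, rng: np.random.Generator,
                    size: int | None = None):
    """Sample emitted photon energies (MeV), one line per emission.

    Lines are drawn with probability yield / sum(yields).
    """
    if not isinstance(rng, np.random.Generator):
        raise TypeError("sample_emission requires a seeded numpy Generator")
    energies, probs = nuclide.line_probabilities()
    idx = rng.choice(energies.size, size=size, p=probs)
    return energies[idx]
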