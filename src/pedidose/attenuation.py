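"""Photon interaction coefficients, 10-160 keV.

Elemental mass attenuation coefficients (photoelectric, incoherent, coherent;
cm^2/g) for the nine elements appearing in the phantom tissues are embedded as
a static table and combined by the standard mixture rule

    mu_type(E) = rho * sum_i w_i (mu/rho)_{i,type}(E)

with log-log interpolation on the energy grid.  How the embedded table was
constructed (Cromer-Liberman photoabsorption, closed-form Klein-Nishina
incoherent scattering, Thomas-Fermi form-factor coherent scattering) is
described in docs/methods.md.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .constants import ATTENUATION_EMAX_KEV, ATTENUATION_EMIN_KEV
from .materials import ELEMENTS, Material

INTERACTIONS = ("photoelectric", "incoherent", "coherent")


@dataclass(frozen=True)
class AttenuationTable:
    """Per-element energy grids of mass attenuation coefficients (cm^2/g)."""

    energy_kev: np.ndarray                      # (n,)
    coefficients: dict[str, np.ndarray]         # element -> (n, 3) [pe, incoh, coh]

    def elemental(self, element: str, energy_kev, interaction: str) -> np.ndarray:
        """Log-log interpolated (mu/rho) for one element (cm^2/g)."""
        col = INTERACTIONS.index(interaction)
        e = _check_energy(energy_kev)
        table = self.coefficients[element]
        return np.exp(np.interp(np.log(e), np.log(self.energy_kev),
                                np.log(np.maximum(table[:, col], 1e-300))))


_TABLE: AttenuationTable | None = None


def load_table() -> AttenuationTable:
    """The embedded elemental table (cached)."""
    global _TABLE
    if _TABLE is None:
        path = resources.files("pedidose.data") / "attenuation_10_160keV.csv"
        rows: dict[str, list[list[float]]] = {el: [] for el in ELEMENTS}
        energies: list[float] = []
        with path.open() as fh:
            for rec in csv.DictReader(fh):
                el = rec["element"]
                rows[el].append([float(rec["photoelectric"]),
                                 float(rec["incoherent"]),
                                 float(rec["coherent"])])
                if el == "H":
                    energies.append(float(rec["energy_keV"]))
        grid = np.asarray(energies)
        coeffs = {el: np.asarray(v) for el, v in rows.items()}
        if any(v.shape != (grid.size, 3) for v in coeffs.values()):
            raise ValueError("malformed attenuation table")
        _TABLE = AttenuationTable(grid, coeffs)
    return _TABLE


def _check_energy(energy_kev) -> np.ndarray:
    e = np.asarray(energy_kev, dtype=float)
    if np.any(e < ATTENUATION_EMIN_KEV - 1e-9) or np.any(e > ATTENUATION_EMAX_KEV + 1e-9):
        raise ValueError(
            f"energy out of tabulated range [{ATTENUATION_EMIN_KEV}, "
            f"{ATTENUATION_EMAX_KEV}] keV")
    return np.clip(e, ATTENUATION_EMIN_KEV, ATTENUATION_EMAX_KEV)


def mixture_mu(material: Material, energy_kev) -> dict[str, np.ndarray]:
    """Linear attenuation coefficients (1/cm) by interaction for a tissue.

    Returns a dict with keys ``photoelectric``, ``incoherent``, ``coherent``
    and ``total``; scalar input gives scalar-shaped arrays.
    """
    table = load_table()
    e = _check_energy(energy_kev)
    out = {}
    for k, col in zip(INTERACTIONS, range(3)):
        mu_rho = np.zeros_like(e, dtype=float)
        for el, w in material.weight_fractions.items():
            tab = table.coefficients[el]
            mu_rho += w * np.exp(np.interp(np.log(e), np.log(table.energy_kev),
                                           np.log(np.maximum(tab[:, col], 1e-300))))
        out[k] = material.density * mu_rho
    out["total"] = out["photoelectric"] + out["incoherent"] + out["coherent"]
    return out
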