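"""Boltzmann-weighted ensemble free energies and hydration free energy.

The electronic-structure free energies themselves (force-field or
semiempirical, with implicit solvation) are external inputs — this module is
the ensemble arithmetic on top of them: a Boltzmann-weighted ensemble free
energy per phase,

    G = -kT ln sum_i exp(-G_i / kT),

the hydration free energy as the solvated-minus-gas difference, and the
per-residue normalization used to compare peptides of different length
(hydrophobic surface energy grows with system size, so unnormalized values
conflate size with solubility).  More negative hydration free energy means
better solubility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rate_theory import BOLTZMANN_KCAL

#: 1 hartree in kcal/mol
HARTREE_TO_KCAL = 627.509


@dataclass
class PhaseFreeEnergies:
    """Per-structure free energies in solvated and gas phases (kcal/mol)."""

    G_solv: np.ndarray
    G_gas: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.G_solv = np.atleast_1d(np.asarray(self.G_solv, dtype=float))
        self.G_gas = np.atleast_1d(np.asarray(self.G_gas, dtype=float))
        if self.G_solv.shape != self.G_gas.shape:
            raise ValueError("phase lists must have equal length")
        if self.G_solv.size == 0:
            raise ValueError("empty free-energy lists")
        if not (np.all(np.isfinite(self.G_solv)) and np.all(np.isfinite(self.G_gas))):
            raise ValueError("non-finite free energies")

    @classmethod
    def from_hartree(cls, G_solv, G_gas, temperature: float = 300.0):
        return cls(
            G_solv=np.asarray(G_solv, dtype=float) * HARTREE_TO_KCAL,
            G_gas=np.asarray(G_gas, dtype=float) * HARTREE_TO_KCAL,
            temperature=temperature,
        )

    @classmethod
    def from_csv(cls, path, temperature: float = 300.0):
        """Read a table with columns: structure id, G_gas, G_solv, unit.

        ``unit`` is ``kcal`` or ``hartree`` per row; a header line is
        skipped if present.
        """
        import csv

        gas, solv = [], []
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or not row[0].strip():
                    continue
                try:
                    g, s = float(row[1]), float(row[2])
                except (ValueError, IndexError):
                    continue  # header
                unit = row[3].strip().lower() if len(row) > 3 else "kcal"
                factor = HARTREE_TO_KCAL if unit.startswith("h") else 1.0
                gas.append(g * factor)
                solv.append(s * factor)
        return cls(G_solv=solv, G_gas=gas, temperature=temperature)


def boltzmann_ensemble_G(G_list, temperature: float = 300.0) -> float:
    """Boltzmann-weighted ensemble free energy, -kT ln sum exp(-G_i/kT).

    Computed with a max-shift so arbitrarily deep minima do not overflow.
    The result is bracketed by min(G) - kT ln(n) <= G <= min(G).
    """
    G = np.atleast_1d(np.asarray(G_list, dtype=float))
    if G.size == 0:
        raise ValueError("empty free-energy list")
    kT = BOLTZMANN_KCAL * temperature
    g0 = G.min()
    return float(g0 - kT * np.log(np.exp(-(G - g0) / kT).sum()))


def hydration_free_energy(phases: PhaseFreeEnergies) -> float:
    """Hydration free energy: ensemble G(solvated) - ensemble G(gas)."""
    return (
        boltzmann_ensemble_G(phases.G_solv, phases.temperature)
        - boltzmann_ensemble_G(phases.G_gas, phases.temperature)
    )


def per_residue_normalize(value: float, n_residues: int) -> float:
    """Normalize an ensemble quantity by chain length (kcal/mol/residue)."""
    if n_residues <= 0:
        raise ValueError("n_residues must be positive")
    return value / n_residues
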