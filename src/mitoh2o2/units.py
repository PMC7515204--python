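"""Unit bridges between proteomics, per-mitochondrion concentrations and
protein-specific rates.

Per-cell protein copy numbers are converted to a per-mitochondrion molar
concentration by distributing the copies equally over the cell's mitochondria
(0.29 um^3 each, 383-882 per HeLa cell); volumetric rates (uM/s) convert to
protein-specific rates (nmol per mg protein per s) through the cellular
protein density of 2e5 mg/L, taken as invariant between organelles.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "MitoGeometry",
    "copies_to_concentration",
    "concentration_to_copies",
    "volumetric_to_specific_rate",
]


@dataclass(frozen=True)
class MitoGeometry:
    """Mitochondrial geometry and protein density of a HeLa cell."""

    volume_um3: float = 0.29
    mito_per_cell: tuple[int, int] = (383, 882)
    protein_density_mg_per_L: float = 2.0e5

    def __post_init__(self) -> None:
        lo, hi = self.mito_per_cell
        if self.volume_um3 <= 0 or self.protein_density_mg_per_L <= 0:
            raise ValueError("geometry values must be strictly positive")
        if not (0 < lo <= hi):
            raise ValueError("mitochondria-per-cell range must be positive and ordered")

    @property
    def volume_L(self) -> float:
        return self.volume_um3 * 1.0e-15


def copies_to_concentration(
    copies_per_cell: float,
    geometry: MitoGeometry = MitoGeometry(),
) -> tuple[float, float]:
    """Per-mitochondrion concentration range (uM), [C_min, C_max].

    Copies are assumed spread equally across mitochondria, so the highest
    mitochondrial count gives the lowest concentration and vice versa.
    """
    if copies_per_cell < 0:
        raise ValueError("copy number must be non-negative")
    lo_count, hi_count = geometry.mito_per_cell

    def conc(n_mito: int) -> float:
        mol = copies_per_cell / (Avogadro * n_mito)
        return mol / geometry.volume_L * 1.0e6  # mol/L -> uM

    return (conc(hi_count), conc(lo_count))


def concentration_to_copies(
    concentration_uM: float,
    n_mito: int,
    geometry: MitoGeometry = MitoGeometry(),
) -> float:
    """Inverse bridge: per-mitochondrion concentration back to copies/cell."""
    if concentration_uM < 0:
        raise ValueError("concentration must be non-negative")
    return concentration_uM * 1.0e-6 * geometry.volume_L * Avogadro * n_mito


def volumetric_to_specific_rate(
    rate_uM_per_s: float,
    protein_density_mg_per_L: float = 2.0e5,
) -> float:
    """Volumetric rate (uM/s) to a protein-specific rate (nmol/mg-protein/s).

    50 uM/s at 2e5 mg/L protein is 0.25 nmol/mg-protein/s.
    """
    if protein_density_mg_per_L <= 0:
        raise ValueError("protein density must be strictly positive")
    mol_per_L_s = rate_uM_per_s * 1.0e-6
    return mol_per_L_s / protein_density_mg_per_L * 1.0e9
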