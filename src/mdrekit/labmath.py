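"""Reaction arithmetic: molar concentrations of proteins and duplex oligos.

A protein dosed by mass is converted to molarity through its oligomeric
molecular weight (monomer mass x subunit count); a duplex oligo through
its length and an average 650 Da per base pair.  Unit bookkeeping:

    nM = ug / (kDa_total * uL) * 1e6        (protein)
    nM = ng / (bp * Da_per_bp * uL) * 1e6   (duplex)
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ProteinSpec", "molar_conc", "duplex_conc", "exact_duplex_mw"]

#: Average molecular weight of one base pair of duplex DNA, Da.
DEFAULT_MW_PER_BP = 650.0

# monoisotopic-free average masses of dNMP residues in DNA, Da
_RESIDUE_MW = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.2}
_HYDROLYSIS = 61.96  # terminal 5'-OH/3'-OH correction per strand (HPO3 + H2O)


@dataclass(frozen=True)
class ProteinSpec:
    """An enzyme preparation: monomer mass (kDa) and oligomeric state."""

    name: str
    monomer_mass: float  # kDa
    oligomer_n: int = 1

    def __post_init__(self):
        if self.monomer_mass <= 0:
            raise ValueError(f"{self.name}: monomer_mass must be positive")
        if self.oligomer_n < 1:
            raise ValueError(f"{self.name}: oligomer_n must be >= 1")

    @property
    def total_mass_kda(self) -> float:
        return self.monomer_mass * self.oligomer_n


def molar_conc(mass_ug: float, spec: ProteinSpec, volume_ul: float) -> float:
    """Molar concentration in nM of ``mass_ug`` of protein in ``volume_ul``.

    Example: 1 ug of a 24.62 kDa dimer in 30 uL is ~677 nM.
    """
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    if mass_ug < 0:
        raise ValueError("mass must be non-negative")
    return mass_ug / (spec.total_mass_kda * volume_ul) * 1e6


def duplex_conc(
    mass_ng: float,
    duplex_bp: int,
    volume_ul: float,
    mw_per_bp: float = DEFAULT_MW_PER_BP,
) -> float:
    """Molar concentration in nM of a duplex oligo dosed by mass.

    Example: 21 ng of a 60-mer duplex in 30 uL is ~18 nM at 650 Da/bp.
    """
    if volume_ul <= 0 or duplex_bp <= 0 or mw_per_bp <= 0:
        raise ValueError("volume, length and Da/bp must be positive")
    if mass_ng < 0:
        raise ValueError("mass must be non-negative")
    return mass_ng / (duplex_bp * mw_per_bp * volume_ul) * 1e6


def exact_duplex_mw(top: str, bottom: str) -> float:
    """Sequence-exact duplex MW (Da), as an alternative to 650 Da/bp."""
    mw = 0.0
    for strand in (top.upper(), bottom.upper()):
        mw += sum(_RESIDUE_MW[b] for b in strand) + _HYDROLYSIS
    return mw
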