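"""Domain-architecture classification and the methyl-pocket motif check.

Domain calls are inputs (from any annotation source); the classifier
maps an ordered domain list onto the known winged-helix fusion
families.  The pocket check scores, against a configurable set of
alignment columns, whether a wH domain carries the residues that form
the 6mA methyl pocket and the GATC base contacts (reference numbering
from the DpnI crystal structure, PDB 4kyw).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DOMAIN_VOCAB",
    "FAMILIES",
    "DomainArchitecture",
    "PocketMotifConfig",
    "classify_architecture",
    "pocket_motif_check",
]

DOMAIN_VOCAB = frozenset(
    {"PD-(D/E)XK", "wH", "PUA", "HNH", "GIY-YIG", "PLD", "NTPase", "NTD", "Mrr"}
)

#: Ordered-domain signatures of the recognized fusion families.
FAMILIES: dict[tuple[str, ...], str] = {
    ("PD-(D/E)XK", "wH"): "PD-(D/E)XK-wH",
    ("PUA", "wH", "HNH"): "PUA-wH-HNH",
    ("wH", "HNH"): "wH-HNH",
    ("wH", "GIY-YIG"): "wH-GIY-YIG",
    ("PLD", "wH"): "PLD-wH",
    ("PD-(D/E)XK", "wH", "NTPase"): "PD-(D/E)XK-wH-NTPase",
    ("NTD", "wH", "NTPase"): "NTD-wH-NTPase",
    ("wH", "Mrr", "NTPase"): "wH-Mrr-NTPase",
}


@dataclass(frozen=True)
class DomainArchitecture:
    protein_id: str
    domains: tuple[str, ...]  # ordered N- to C-terminal
    intervals: tuple[tuple[int, int] | None, ...] | None = None

    def __post_init__(self):
        if not self.domains:
            raise ValueError(f"{self.protein_id}: at least one domain required")
        unknown = [d for d in self.domains if d not in DOMAIN_VOCAB]
        if unknown:
            raise ValueError(f"{self.protein_id}: unknown domain labels {unknown}")
        object.__setattr__(self, "domains", tuple(self.domains))


def classify_architecture(arch: DomainArchitecture) -> str:
    """Family label for an ordered domain architecture.

    Exact ordered match against the known families; order matters
    (HNH-wH is not wH-HNH).  Architectures without a wH domain are
    ``no_wH``; anything else is ``unclassified``.
    """
    if "wH" not in arch.domains:
        return "no_wH"
    return FAMILIES.get(arch.domains, "unclassified")


@dataclass(frozen=True)
class PocketMotifConfig:
    """Columns of a reference alignment that must carry pocket residues.

    Each entry: (alignment column, allowed residues, role) with role in
    {methyl_pocket, base_contact}.  The default threshold 1.0 demands
    the full motif; lower thresholds admit "closely related" motifs.
    """

    entries: tuple[tuple[int, str, str], ...]
    reference_note: str = "DpnI wH, PDB 4kyw numbering"

    def __post_init__(self):
        cols = [e[0] for e in self.entries]
        if len(cols) != len(set(cols)):
            raise ValueError("alignment columns must be unique")
        for col, allowed, role in self.entries:
            if role not in ("methyl_pocket", "base_contact"):
                raise ValueError(f"unknown role {role!r}")
            if col < 0 or not allowed:
                raise ValueError("bad column/allowed set")


def pocket_motif_check(
    aligned_wH: str, config: PocketMotifConfig, threshold: float = 1.0
) -> tuple[float, bool]:
    """Fraction of configured columns carrying an allowed residue, and
    whether that fraction reaches the threshold ("motif present").

    ``aligned_wH`` is the wH sequence mapped to reference alignment
    columns; '-' gaps never match.
    """
    for col, _, _ in config.entries:
        if col >= len(aligned_wH):
            raise ValueError(f"alignment column {col} outside aligned string")
    matched = sum(
        1 for col, allowed, _ in config.entries if aligned_wH[col] in allowed
    )
    fraction = matched / len(config.entries)
    return fraction, fraction >= threshold
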