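"""Gene-neighborhood and genome-wide methylation-conflict scans.

Given an annotated genome whose gene table labels winged-helix fusion
endonucleases (``wh_fusion:<family>``) and methyltransferases
(``mtase:<spec name>``), this module asks, per fusion gene:

* does a methyltransferase sit among the nearest genes on either side
  (the defense-island test; a fusion without one is *stand-alone*)?
* does any MTase encoded anywhere on the genome create a methylation
  conflict with the fusion's reader context, and of which class?
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .motif_algebra import ConflictDecision, MTaseSpec, ReaderContext, methyl_conflict

__all__ = [
    "GeneRecord",
    "ConflictReport",
    "neighborhood_scan",
    "genome_conflict_scan",
    "summarize",
]


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene; coordinates 0-based half-open internally."""

    contig: str
    start: int
    end: int
    strand: str
    gene_id: str
    product_class: str  # "wh_fusion:<family>" | "mtase:<name>" | "other"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be +/-")
        kind = self.product_class.split(":", 1)[0]
        if kind not in ("wh_fusion", "mtase", "other"):
            raise ValueError(
                f"{self.gene_id}: unparseable product_class {self.product_class!r}"
            )

    @property
    def kind(self) -> str:
        return self.product_class.split(":", 1)[0]

    @property
    def detail(self) -> str:
        parts = self.product_class.split(":", 1)
        return parts[1] if len(parts) > 1 else ""

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class ConflictReport:
    fusion_id: str
    contig: str
    family: str
    neighbor_mtases: list[str] = field(default_factory=list)
    genome_conflicts: list[tuple[str, ConflictDecision]] = field(default_factory=list)

    @property
    def standalone(self) -> bool:
        return not self.neighbor_mtases


def _sorted_contigs(genes: list[GeneRecord]) -> dict[str, list[GeneRecord]]:
    ids = [g.gene_id for g in genes]
    dupes = [i for i, c in Counter(ids).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate gene_ids: {dupes}")
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig in by_contig:
        by_contig[contig].sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_contig


def neighborhood_scan(
    genes: list[GeneRecord],
    window_genes: int = 3,
    mode: str = "genes",
    bp_window: int = 10_000,
) -> dict[str, list[str]]:
    """MTase genes near each wH-fusion gene.

    ``mode="genes"`` (default) collects MTases among the ``window_genes``
    nearest genes on each side by rank on the same contig, truncated at
    contig edges.  ``mode="bp"`` instead collects MTases whose midpoint
    lies within ``bp_window`` bp of the fusion's midpoint (the interval
    variant of the co-occurrence tally).
    """
    if mode not in ("genes", "bp"):
        raise ValueError("mode must be 'genes' or 'bp'")
    by_contig = _sorted_contigs(genes)
    hits: dict[str, list[str]] = {}
    for contig, glist in by_contig.items():
        for i, g in enumerate(glist):
            if g.kind != "wh_fusion":
                continue
            if mode == "genes":
                lo = max(0, i - window_genes)
                window = glist[lo:i] + glist[i + 1 : i + 1 + window_genes]
            else:
                window = [
                    o
                    for o in glist
                    if o.gene_id != g.gene_id
                    and abs(o.midpoint - g.midpoint) <= bp_window
                ]
            hits[g.gene_id] = sorted(o.gene_id for o in window if o.kind == "mtase")
    return hits


def genome_conflict_scan(
    genes: list[GeneRecord],
    specs: dict[str, MTaseSpec],
    reader: ReaderContext,
    window_genes: int = 3,
) -> list[ConflictReport]:
    """Per-fusion conflict report over the whole genome.

    Every MTase gene on any contig of the genome is tested against the
    reader with :func:`methyl_conflict`; set semantics, so gene order is
    irrelevant.  Neighborhood hits use the gene-rank window.
    """
    mtase_genes = [g for g in genes if g.kind == "mtase"]
    for g in mtase_genes:
        if g.detail not in specs:
            raise KeyError(
                f"gene {g.gene_id}: no MTase spec named {g.detail!r} supplied"
            )
    neighbors = neighborhood_scan(genes, window_genes=window_genes)
    # one algebra call per distinct spec, reused across genes
    decisions = {
        name: methyl_conflict(specs[name], reader)
        for name in sorted({g.detail for g in mtase_genes})
    }
    reports = []
    for g in sorted(
        (g for g in genes if g.kind == "wh_fusion"),
        key=lambda g: (g.contig, g.start, g.gene_id),
    ):
        rep = ConflictReport(
            fusion_id=g.gene_id,
            contig=g.contig,
            family=g.detail,
            neighbor_mtases=neighbors.get(g.gene_id, []),
        )
        for mg in sorted(mtase_genes, key=lambda x: (x.contig, x.start, x.gene_id)):
            dec = decisions[mg.detail]
            if dec.conflict:
                rep.genome_conflicts.append((mg.gene_id, dec))
        reports.append(rep)
    return reports


def summarize(reports: list[ConflictReport]) -> dict:
    """Aggregate counts over fusion reports.

    Returns standalone fraction, conflict counts by type, and the
    number of fusions with a neighboring MTase.
    """
    if not reports:
        raise ValueError("need at least one report")
    n = len(reports)
    standalone = sum(r.standalone for r in reports)
    type_counts: Counter[str] = Counter()
    for r in reports:
        for _, dec in r.genome_conflicts:
            type_counts[dec.conflict_type] += 1
    return {
        "n_fusions": n,
        "n_standalone": standalone,
        "standalone_fraction": standalone / n,
        "n_with_neighbor_mtase": n - standalone,
        "n_conflicts": sum(type_counts.values()),
        "conflicts_by_type": dict(type_counts),
    }


def reports_to_frame(reports: list[ConflictReport]) -> pd.DataFrame:
    """Flat table view of conflict reports (one row per fusion)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "fusion_id": r.fusion_id,
                "contig": r.contig,
                "family": r.family,
                "standalone": r.standalone,
                "neighbor_mtases": ",".join(r.neighbor_mtases),
                "n_conflicts": len(r.genome_conflicts),
                "conflict_types": ",".join(
                    sorted({d.conflict_type for _, d in r.genome_conflicts})
                ),
            }
        )
    return pd.DataFrame(rows)
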