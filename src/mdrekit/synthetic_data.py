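"""Seeded generators for every input class the pipeline consumes.

Three generators with embedded ground truth:

* :func:`gen_genomes` — annotated genome fragments carrying wH-fusion
  genes and methyltransferase genes with known neighborhood and
  conflict status (the desk-scale stand-in for surveyed prokaryotic
  genomes);
* :func:`gen_plasmid` — circular substrates with GATC sites at exactly
  controlled spacer distances (two-site cooperativity substrates);
* :func:`gen_oligo_set` — the four duplex methylation states
  (M+/M+, M+/M-, M-/M+, M-/M-) of a 60-mer with a single GATC site,
  defaulting to the printed assay duplex.

All outputs are byte-identical for a fixed seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from importlib import resources

from .genome_scan import GeneRecord
from .methylome import MethylomeTrack, SeqRecord, apply_mtase, hemi_from_full
from .motif_algebra import (
    CapacityError,
    MTaseSpec,
    ReaderContext,
    conflict_oracle,
    mtase_from_dict,
)

__all__ = [
    "OLIGO_TOP",
    "OLIGO_BOTTOM",
    "GenomeSimConfig",
    "GroundTruth",
    "GenomeSet",
    "load_mtase_pool",
    "gen_genomes",
    "gen_plasmid",
    "gen_oligo_set",
]

# The 60-mer duplex used in the oligo digestion assays (FAM label on the
# top-strand 5' end; single GATC at 0-based 18, methylatable A at 19).
OLIGO_TOP = (
    "ACTCATGCAGGCATGCAGGATCGCAGTCAGATTTATGTGTCATATAGTACGTGATTCAAG"
)
OLIGO_BOTTOM = (
    "CTTGAATCACGTACTATATGACACATAAATCTGACTGCGATCCTGCATGCCTGCATGAGT"
)

_COMP = str.maketrans("ACGT", "TGCA")


def load_mtase_pool(path=None) -> dict[str, MTaseSpec]:
    """MTase specs from JSON; defaults to the bundled definitions."""
    if path is None:
        text = resources.files("mdrekit.data").joinpath("mtases.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)
    return {name: mtase_from_dict(d) for name, d in raw.items()}


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSimConfig:
    seed: int = 0
    n_genomes: int = 100
    genome_length: int = 20_000
    gene_count_range: tuple[int, int] = (8, 14)
    gene_length_range: tuple[int, int] = (300, 900)
    intergenic_gap: int = 20
    p_fusion_present: float = 1.0
    p_neighbor_mtase: float = 0.13
    p_conflicting_mtase: float = 0.2
    p_distal_benign_mtase: float = 0.3
    window_genes: int = 3

    def __post_init__(self):
        for p in (
            self.p_fusion_present,
            self.p_neighbor_mtase,
            self.p_conflicting_mtase,
            self.p_distal_benign_mtase,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class GroundTruth:
    """Per-genome planted labels, consistent with the emitted annotation."""

    fusion_ids: dict[str, list[str]] = field(default_factory=dict)
    standalone: dict[str, bool] = field(default_factory=dict)  # fusion_id -> flag
    conflicts: list[tuple[str, str, str]] = field(default_factory=list)
    # (fusion_id, mtase_gene_id, expected conflict type)


@dataclass
class GenomeSet:
    records: list[SeqRecord]
    genes: list[GeneRecord]
    truth: GroundTruth
    specs: dict[str, MTaseSpec]


_FUSION_FAMILIES = (
    "PD-(D/E)XK-wH",
    "PUA-wH-HNH",
    "wH-HNH",
    "wH-GIY-YIG",
    "PLD-wH",
)

_conflict_status_cache: dict[tuple[str, str, int], tuple[bool, str]] = {}


def _spec_conflict_status(
    spec: MTaseSpec, reader: ReaderContext, seed: int = 0
) -> tuple[bool, str]:
    """Conflict status of a spec against the reader, decided by the
    brute-force oracle (sampled when the concrete space is too large);
    cached per (spec, reader)."""
    key = (spec.name, str(spec.pattern) + f":{reader.methyl_index}", seed)
    if key not in _conflict_status_cache:
        try:
            dec = conflict_oracle(spec, reader, flank=len(reader.pattern))
        except CapacityError:
            dec = conflict_oracle(
                spec, reader, flank=len(reader.pattern), sample=50_000, seed=seed
            )
        _conflict_status_cache[key] = (dec.conflict, dec.conflict_type)
    return _conflict_status_cache[key]


def gen_genomes(
    config: GenomeSimConfig,
    specs: dict[str, MTaseSpec] | None = None,
    reader: ReaderContext | None = None,
) -> GenomeSet:
    """Simulate annotated genomes with planted fusion/MTase layouts.

    Genes are packed left to right with a fixed intergenic gap on
    alternating strands.  With probability ``p_neighbor_mtase`` an MTase
    is planted within the ``window_genes``-gene neighborhood of the
    fusion (the fusion is then not stand-alone); with probability
    ``p_conflicting_mtase`` a conflicting MTase is planted outside the
    window; with ``p_distal_benign_mtase`` a benign one is.  Conflict
    status of every pool spec is established with the enumeration
    oracle at generation time and recorded as ground truth.
    """
    rng = random.Random(config.seed)
    specs = dict(specs) if specs is not None else load_mtase_pool()
    reader = reader or ReaderContext.dam_gatc()

    status = {
        name: _spec_conflict_status(spec, reader, seed=config.seed % (2**31))
        for name, spec in specs.items()
    }
    conflicting = sorted(n for n, (c, _) in status.items() if c)
    benign = sorted(n for n, (c, _) in status.items() if not c)
    if not conflicting or not benign:
        raise ValueError("spec pool must contain conflicting and benign MTases")

    records: list[SeqRecord] = []
    genes: list[GeneRecord] = []
    truth = GroundTruth()

    for gi in range(config.n_genomes):
        contig = f"g{gi:04d}"
        n_genes = rng.randint(*config.gene_count_range)
        lengths = [
            rng.randint(*config.gene_length_range) for _ in range(n_genes)
        ]
        needed = 100 + sum(lengths) + config.intergenic_gap * n_genes
        if needed > config.genome_length:
            raise ValueError(
                f"{contig}: {n_genes} genes need {needed} bp "
                f"> genome_length {config.genome_length}"
            )
        seq = "".join(rng.choices("ACGT", k=config.genome_length))
        records.append(SeqRecord(contig, seq, "linear"))

        classes = ["other"] * n_genes
        truth.fusion_ids[contig] = []

        if rng.random() < config.p_fusion_present:
            fusion_i = rng.randrange(n_genes)
            family = rng.choice(_FUSION_FAMILIES)
            classes[fusion_i] = f"wh_fusion:{family}"

            window = set(
                range(max(0, fusion_i - config.window_genes),
                      min(n_genes, fusion_i + config.window_genes + 1))
            ) - {fusion_i}
            outside = sorted(set(range(n_genes)) - window - {fusion_i})

            neighbor = rng.random() < config.p_neighbor_mtase
            if neighbor and window:
                ni = rng.choice(sorted(window))
                classes[ni] = f"mtase:{rng.choice(benign + conflicting)}"

            if rng.random() < config.p_conflicting_mtase and outside:
                ci = rng.choice(outside)
                classes[ci] = f"mtase:{rng.choice(conflicting)}"

            if rng.random() < config.p_distal_benign_mtase:
                free = [i for i in outside if classes[i] == "other"]
                if free:
                    classes[rng.choice(free)] = f"mtase:{rng.choice(benign)}"

        pos = 100
        genome_genes = []
        for i in range(n_genes):
            g = GeneRecord(
                contig=contig,
                start=pos,
                end=pos + lengths[i],
                strand="+" if i % 2 == 0 else "-",
                gene_id=f"{contig}_gene{i:03d}",
                product_class=classes[i],
            )
            genome_genes.append(g)
            pos += lengths[i] + config.intergenic_gap
        genes.extend(genome_genes)

        # ground truth, derived from the layout just planted
        for g in genome_genes:
            if g.kind != "wh_fusion":
                continue
            truth.fusion_ids[contig].append(g.gene_id)
            idx = genome_genes.index(g)
            window_ids = (
                genome_genes[max(0, idx - config.window_genes): idx]
                + genome_genes[idx + 1: idx + 1 + config.window_genes]
            )
            has_neighbor = any(o.kind == "mtase" for o in window_ids)
            truth.standalone[g.gene_id] = not has_neighbor
            for o in genome_genes:
                if o.kind == "mtase":
                    is_conf, ctype = status[o.detail]
                    if is_conf:
                        truth.conflicts.append((g.gene_id, o.gene_id, ctype))

    return GenomeSet(records=records, genes=genes, truth=truth, specs=specs)


# ---------------------------------------------------------------------------
# Plasmids with controlled GATC spacing
# ---------------------------------------------------------------------------

def _count_circular(seq: str, motif: str) -> int:
    doubled = seq + seq[: len(motif) - 1]
    n = 0
    for i in range(len(seq)):
        if doubled[i : i + len(motif)] == motif:
            n += 1
    return n


def gen_plasmid(
    spacers: list[int],
    seed: int = 0,
    site: str = "GATC",
    tail: int = 50,
    max_tries: int = 1000,
) -> SeqRecord:
    """Circular plasmid with consecutive ``site`` occurrences separated
    by exactly the requested spacer lengths (bp between sites), filler
    free of further occurrences (checked across the origin)."""
    if any(s < 0 for s in spacers):
        raise ValueError("spacers must be >= 0")
    rng = random.Random(seed)
    expected = len(spacers) + 1
    for _ in range(max_tries):
        parts = [site]
        for s in spacers:
            parts.append("".join(rng.choices("ACGT", k=s)))
            parts.append(site)
        parts.append("".join(rng.choices("ACGT", k=tail)))
        seq = "".join(parts)
        if _count_circular(seq, site) == expected:
            name = "plasmid_" + "-".join(map(str, spacers)) if spacers else "plasmid_single"
            return SeqRecord(name, seq, "circular")
    raise RuntimeError("could not sample filler free of extra sites")


# ---------------------------------------------------------------------------
# Duplex oligo states
# ---------------------------------------------------------------------------

def gen_oligo_set(
    top: str = OLIGO_TOP,
    bottom: str = OLIGO_BOTTOM,
    states: tuple[str, ...] = ("M+/M+", "M+/M-", "M-/M+", "M-/M-"),
    dam: MTaseSpec | None = None,
) -> list[tuple[str, SeqRecord, MethylomeTrack]]:
    """The four methylation states of a GATC duplex.

    The duplex is represented by its top strand plus a per-strand mark
    track; marks sit on the GATC adenines (Dam positions).  Strands
    must be mutual reverse complements.
    """
    top = top.upper()
    bottom = bottom.upper()
    if bottom != top.translate(_COMP)[::-1]:
        raise ValueError("bottom strand is not the reverse complement of top")
    dam = dam or load_mtase_pool()["Dam"]
    out = []
    for state in states:
        if state not in ("M+/M+", "M+/M-", "M-/M+", "M-/M-"):
            raise ValueError(f"unknown duplex state {state!r}")
        seq = SeqRecord(f"duplex_{state.replace('/', '_')}", top, "linear")
        full = apply_mtase(seq, dam)
        if state == "M+/M+":
            track = full
        elif state == "M+/M-":
            track = hemi_from_full(full, "top")
        elif state == "M-/M+":
            track = hemi_from_full(full, "bottom")
        else:
            track = MethylomeTrack(seq_id=seq.id, marks=set())
        out.append((state, seq, track))
    return out
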