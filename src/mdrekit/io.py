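"""Readers and writers for the standard formats.

FASTA via Biopython SeqIO (substrates are strict ACGT; degenerate
letters belong in pattern files, not substrate FASTA), gene tables as
GFF3 (via gffutils) or 6-column TSV, and methylome tracks as BED-like
TSV.  Internal coordinates are 0-based half-open everywhere; 1-based
only at format boundaries.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .genome_scan import GeneRecord
from .methylome import MethylomeTrack, SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_methylome",
    "write_methylome",
]

logger = logging.getLogger("mdrekit")
if not logger.handlers:  # stderr logging, results go to files
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

MOD_CODES = ("m6A", "m4C", "m5C", "5hmC")


def read_fasta(path, topology: str = "linear") -> list[SeqRecord]:
    """Read substrate FASTA; wrapped and unwrapped dialects both accepted.

    Lowercase is uppercased with a notice; non-ACGT characters are
    rejected with a position report.  A ``circular=true`` token in the
    description flags circular topology, overriding ``topology``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.info("record %s: lowercase bases uppercased", rec.id)
        topo = topology
        if "circular=true" in rec.description.lower():
            topo = "circular"
        records.append(SeqRecord(rec.id, seq.upper(), topo))
    if not records:
        logger.warning("no records in %s", path)
    return records


def write_fasta(records: list[SeqRecord], path) -> None:
    bio = [
        BioSeqRecord(
            Seq(r.bases),
            id=r.id,
            description="circular=true" if r.topology == "circular" else "",
        )
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_gene_table(path, dialect: str | None = None) -> list[GeneRecord]:
    """Gene table from GFF3 (1-based inclusive -> 0-based half-open) or
    TSV (columns contig, start, end, strand, gene_id, product_class;
    start already 0-based half-open).  Dialect sniffed by extension when
    not given."""
    path = Path(path)
    if dialect is None:
        dialect = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_gff3(path: Path) -> list[GeneRecord]:
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        attrs = dict(feat.attributes)
        if "product_class" not in attrs:
            raise ValueError(
                f"{path}: feature {feat.id} lacks a product_class attribute"
            )
        genes.append(
            GeneRecord(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                gene_id=attrs.get("ID", [feat.id])[0],
                product_class=attrs["product_class"][0],
            )
        )
    return genes


def _read_tsv(path: Path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(cols)}")
            contig, start, end, strand, gene_id, product_class = cols
            try:
                genes.append(
                    GeneRecord(contig, int(start), int(end), strand, gene_id, product_class)
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from e
    return genes


def write_gene_table(genes: list[GeneRecord], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for g in genes:
            fh.write(
                f"{g.contig}\t{g.start}\t{g.end}\t{g.strand}\t{g.gene_id}\t{g.product_class}\n"
            )


def read_methylome(path) -> dict[str, MethylomeTrack]:
    """BED-like methylome TSV: seq_id, 0-based position, strand (+/-),
    mod code.  Bottom-strand positions are in top coordinates."""
    tracks: dict[str, MethylomeTrack] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            seq_id, pos, strand_sym, mod = cols
            if strand_sym not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be +/-")
            if mod not in MOD_CODES:
                raise ValueError(f"{path}:{lineno}: unknown mod {mod!r}")
            strand = "top" if strand_sym == "+" else "bottom"
            tracks.setdefault(seq_id, MethylomeTrack(seq_id=seq_id)).marks.add(
                (int(pos), strand, mod)
            )
    return tracks


def write_methylome(tracks: dict[str, MethylomeTrack] | MethylomeTrack, path, header: str = "") -> None:
    if isinstance(tracks, MethylomeTrack):
        tracks = {tracks.seq_id: tracks}
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for seq_id in sorted(tracks):
            for pos, strand, mod in sorted(tracks[seq_id].marks):
                sym = "+" if strand == "top" else "-"
                fh.write(f"{seq_id}\t{pos}\t{sym}\t{mod}\n")
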