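"""Methylome tracks: applying MTase specs to substrate sequences.

All marks live in top-strand coordinates: a bottom-strand m6A is stored
at the position of the paired T on the top strand, so cut-site math
needs only one coordinate system.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .motif_algebra import (
    IupacPattern,
    MTaseSpec,
    pattern_to_regex,
    revcomp_pattern,
)

__all__ = [
    "SeqRecord",
    "MethylomeTrack",
    "find_occurrences",
    "apply_mtase",
    "ecoGII_track",
    "hemi_from_full",
]

_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SeqRecord:
    """A DNA substrate: plain ACGT, linear or circular."""

    id: str
    bases: str
    topology: str = "linear"  # linear | circular

    def __post_init__(self):
        seq = self.bases.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = re.search(r"[^ACGT]", seq)
        if bad:
            raise ValueError(
                f"{self.id}: non-ACGT character {bad.group()!r} at position {bad.start()}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.id}: topology must be linear/circular")
        object.__setattr__(self, "bases", seq)

    def __len__(self) -> int:
        return len(self.bases)

    def revcomp(self) -> "SeqRecord":
        return SeqRecord(self.id, self.bases.translate(_COMP)[::-1], self.topology)


@dataclass
class MethylomeTrack:
    """Per-strand base modifications on one sequence.

    marks: set of (position, strand, mod) with position in top-strand
    coordinates.
    """

    seq_id: str
    marks: set[tuple[int, str, str]] = field(default_factory=set)

    def validate_against(self, seq: SeqRecord) -> None:
        for pos, strand, mod in self.marks:
            if not 0 <= pos < len(seq):
                raise ValueError(f"mark position {pos} outside sequence")
            if mod == "m6A":
                needed = "A" if strand == "top" else "T"
                if seq.bases[pos] != needed:
                    raise ValueError(
                        f"m6A {strand} mark at {pos} sits on "
                        f"{seq.bases[pos]!r}, expected {needed!r}"
                    )

    def has(self, pos: int, strand: str, mod: str = "m6A") -> bool:
        return (pos, strand, mod) in self.marks


def find_occurrences(seq: SeqRecord, pattern: IupacPattern) -> list[int]:
    """Start positions (top-strand coordinates) of pattern occurrences
    on the given strand orientation; circular sequences are scanned
    across the origin and origin-spanning hits reported modulo length.
    """
    L = len(seq)
    text = seq.bases
    if seq.topology == "circular" and len(pattern) > 1:
        text = text + seq.bases[: len(pattern) - 1]
    rx = pattern_to_regex(pattern)
    hits = {m.start() % L for m in re.finditer(rf"(?=({rx.pattern}))", text)}
    return sorted(hits)


def apply_mtase(
    seq: SeqRecord,
    mtase: MTaseSpec,
    completeness: float = 1.0,
    seed: int | None = None,
) -> MethylomeTrack:
    """Deposit the MTase's marks at every target occurrence on both strands.

    Bottom-strand pattern occurrences are found via the reverse
    complement; their top marks become bottom marks and vice versa, with
    indices mirrored.  ``completeness`` < 1 keeps a seeded random subset
    of the marks (partially methylated substrates such as in-vivo phage
    lambda DNA); the default deposits everything and is idempotent.
    """
    L = len(seq)
    plen = len(mtase.pattern)
    marks: set[tuple[int, str, str]] = set()

    for start in find_occurrences(seq, mtase.pattern):
        for m in mtase.marks:
            marks.add(((start + m.index) % L, m.strand, m.mod))

    rc = revcomp_pattern(mtase.pattern)
    palindromic = rc.codes == mtase.pattern.codes
    if not palindromic:
        for start in find_occurrences(seq, rc):
            for m in mtase.marks:
                # occurrence on bottom strand: pattern index i maps to top
                # coordinate start + plen-1-i, strands swap
                pos = (start + plen - 1 - m.index) % L
                strand = "bottom" if m.strand == "top" else "top"
                marks.add((pos, strand, m.mod))

    if completeness < 1.0:
        rng = random.Random(seed)
        marks = {m for m in sorted(marks) if rng.random() < completeness}

    track = MethylomeTrack(seq_id=seq.id, marks=marks)
    track.validate_against(seq)
    return track


def _polyA_positions(bases: str, letter: str, min_run: int) -> set[int]:
    out: set[int] = set()
    for m in re.finditer(rf"{letter}{{{min_run},}}", bases):
        out.update(range(m.start(), m.end()))
    return out


def ecoGII_track(seq: SeqRecord, polyA_min_run: int = 4) -> MethylomeTrack:
    """M.EcoGII-style hypermethylation: every adenine on both strands is
    m6A-marked except adenines inside a same-strand polyA run of length
    >= ``polyA_min_run``.  Bottom-strand adenines are the T positions in
    top coordinates (bottom polyA runs are top-strand T runs).
    """
    if polyA_min_run < 2:
        raise ValueError("polyA_min_run must be >= 2")
    bases = seq.bases
    if seq.topology == "circular":
        # runs may wrap the origin; scan a doubled text and fold back
        doubled = bases + bases
        skip_top = {p % len(bases) for p in _polyA_positions(doubled, "A", polyA_min_run)}
        skip_bot = {p % len(bases) for p in _polyA_positions(doubled, "T", polyA_min_run)}
    else:
        skip_top = _polyA_positions(bases, "A", polyA_min_run)
        skip_bot = _polyA_positions(bases, "T", polyA_min_run)
    marks: set[tuple[int, str, str]] = set()
    for i, b in enumerate(bases):
        if b == "A" and i not in skip_top:
            marks.add((i, "top", "m6A"))
        elif b == "T" and i not in skip_bot:
            marks.add((i, "bottom", "m6A"))
    return MethylomeTrack(seq_id=seq.id, marks=marks)


def hemi_from_full(track: MethylomeTrack, retained_strand: str) -> MethylomeTrack:
    """Replication model: keep only the retained (template) strand's marks."""
    if retained_strand not in ("top", "bottom"):
        raise ValueError("retained_strand must be top/bottom")
    return MethylomeTrack(
        seq_id=track.seq_id,
        marks={m for m in track.marks if m[1] == retained_strand},
    )
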