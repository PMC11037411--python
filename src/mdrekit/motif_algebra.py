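"""Degenerate-pattern algebra for methylation conflict analysis.

A modification-dependent restriction endonuclease (MDRE) that reads
N6-methyladenine in a sequence context (canonically Gm6ATC, the Dam
context) is in *genetic conflict* with a co-resident methyltransferase
(MTase) whenever the MTase can deposit m6A at a position that the
reader senses.  Three conflict classes are distinguished:

* ``frequent_adenine`` — a promiscuous adenine MTase (e.g. M.EcoGII)
  that methylates adenines in essentially every context, including the
  reader's;
* ``dam_like`` — an MTase whose target site *is* the reader context
  (e.g. Dam itself for a GATC reader);
* ``embedded_context`` — an MTase whose longer target site contains an
  occurrence of the reader context with the methylated adenine aligned
  (e.g. CGm6ATCG contains Gm6ATC).

The decision is made purely on the IUPAC degenerate-code algebra: the
MTase pattern (padded with N outside its span, i.e. unconstrained
genomic flanks) is aligned so that a methylated adenine falls on the
reader's sensed adenine, and the conflict exists iff every overlapping
code pair has a non-empty base-set intersection.  A brute-force
enumeration oracle over concrete sequences is provided for
verification.
"""

from __future__ import annotations

import itertools
import random
import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_SETS",
    "EMPTY",
    "IupacPattern",
    "MethylMark",
    "MTaseSpec",
    "ReaderContext",
    "ConflictDecision",
    "intersect_codes",
    "complement_code",
    "revcomp_pattern",
    "methyl_conflict",
    "classify_conflict",
    "conflict_oracle",
    "parse_pattern",
    "pattern_to_regex",
    "mtase_from_dict",
    "reader_from_string",
]

# ---------------------------------------------------------------------------
# IUPAC code algebra
# ---------------------------------------------------------------------------

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

#: Sentinel for the empty base set (disjoint intersection).
EMPTY = ""

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class InvalidCodeError(ValueError):
    """Raised for letters outside the 15-letter IUPAC alphabet."""


def _check_code(c: str) -> str:
    c = c.upper()
    if c not in IUPAC_SETS:
        raise InvalidCodeError(f"invalid IUPAC code: {c!r}")
    return c


def intersect_codes(a: str, b: str) -> str:
    """Intersection of two IUPAC codes as a code, or ``EMPTY`` if disjoint.

    Commutative, associative and idempotent; ``N`` is the identity and
    ``EMPTY`` is absorbing.
    """
    s = IUPAC_SETS[_check_code(a)] & IUPAC_SETS[_check_code(b)]
    return _SET_TO_CODE[s] if s else EMPTY


def complement_code(c: str) -> str:
    """Watson–Crick complement of a single IUPAC code."""
    return _COMPLEMENT[_check_code(c)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

_RUN_RE = re.compile(r"([ACGTRYSWKMBDHVN])_?(\d+)_?", re.IGNORECASE)


def parse_pattern(text: str, label: str = "") -> "IupacPattern":
    """Parse a pattern string, expanding run syntax like ``N7`` or ``N_7_``.

    ``GAGN7ATGC`` -> ``GAG`` + seven ``N`` + ``ATGC``.
    """
    expanded = _RUN_RE.sub(lambda m: m.group(1) * int(m.group(2)), text.strip())
    codes = [_check_code(c) for c in expanded]
    return IupacPattern(codes=codes, label=label or text.strip())


@dataclass(frozen=True)
class IupacPattern:
    """A degenerate DNA pattern over the 15-letter IUPAC alphabet."""

    codes: tuple[str, ...]
    label: str = ""

    def __init__(self, codes, label: str = ""):
        codes = tuple(_check_code(c) for c in codes)
        if not codes:
            raise ValueError("pattern must be non-empty")
        object.__setattr__(self, "codes", codes)
        object.__setattr__(self, "label", label)

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return "".join(self.codes)

    def admits(self, index: int, base: str) -> bool:
        return base.upper() in IUPAC_SETS[self.codes[index]]


def revcomp_pattern(p: IupacPattern) -> IupacPattern:
    """Reverse complement of a degenerate pattern (an involution)."""
    return IupacPattern(
        codes=[_COMPLEMENT[c] for c in reversed(p.codes)],
        label=f"revcomp({p.label})" if p.label else "",
    )


@dataclass(frozen=True)
class MethylMark:
    """A methylated position within a pattern, in top-strand coordinates.

    For an m6A mark on the top strand the code at ``index`` must admit A;
    on the bottom strand the (top-strand) code must admit T, because the
    methylated adenine is the base paired with that T.
    """

    strand: str  # "top" | "bottom"
    index: int
    mod: str = "m6A"  # m6A | m4C | m5C | 5hmC

    def __post_init__(self):
        if self.strand not in ("top", "bottom"):
            raise ValueError(f"strand must be top/bottom, got {self.strand!r}")
        if self.mod not in ("m6A", "m4C", "m5C", "5hmC"):
            raise ValueError(f"unknown modification {self.mod!r}")

    def validate_against(self, pattern: IupacPattern) -> None:
        if not 0 <= self.index < len(pattern):
            raise ValueError(f"mark index {self.index} outside pattern span")
        if self.mod == "m6A":
            needed = "A" if self.strand == "top" else "T"
            if not pattern.admits(self.index, needed):
                raise ValueError(
                    f"m6A {self.strand} mark at index {self.index}: code "
                    f"{pattern.codes[self.index]!r} does not admit {needed}"
                )


@dataclass(frozen=True)
class MTaseSpec:
    """A methyltransferase: target pattern plus its methylated positions."""

    name: str
    pattern: IupacPattern
    marks: tuple[MethylMark, ...]
    frequency_class: str = "site_specific"  # site_specific | frequent

    def __post_init__(self):
        if not self.marks:
            raise ValueError(f"MTase {self.name}: at least one mark required")
        if self.frequency_class not in ("site_specific", "frequent"):
            raise ValueError(f"bad frequency_class {self.frequency_class!r}")
        object.__setattr__(self, "marks", tuple(self.marks))
        for m in self.marks:
            m.validate_against(self.pattern)


@dataclass(frozen=True)
class ReaderContext:
    """The sequence-plus-modification context an MDRE sensor recognizes.

    The default is the Dam context: GATC with the sensed adenine at
    index 1 (Gm6ATC).
    """

    pattern: IupacPattern
    methyl_index: int = 1
    mod: str = "m6A"

    def __post_init__(self):
        if not 0 <= self.methyl_index < len(self.pattern):
            raise ValueError("methyl_index outside pattern span")
        if not self.pattern.admits(self.methyl_index, "A"):
            raise ValueError("reader code at methyl_index must admit A")

    @classmethod
    def dam_gatc(cls) -> "ReaderContext":
        return cls(pattern=parse_pattern("GATC", "GATC"), methyl_index=1, mod="m6A")


@dataclass
class ConflictDecision:
    conflict: bool
    conflict_type: str = "none"  # frequent_adenine | dam_like | embedded_context | none
    witnesses: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.conflict != (self.conflict_type != "none"):
            raise ValueError("conflict flag inconsistent with conflict_type")
        if (not self.conflict) and self.witnesses:
            raise ValueError("no-conflict decision must carry no witnesses")


# ---------------------------------------------------------------------------
# Conflict decision
# ---------------------------------------------------------------------------

def _canonical_marks(
    mtase: MTaseSpec, mod: str | None = None
) -> list[tuple[IupacPattern, int]]:
    """Canonicalize marks to top-strand adenines.

    A bottom-strand mark at top-coordinate i becomes a top-strand mark at
    index len-1-i of the reverse-complemented pattern; both strands then
    share a single alignment code path.  With ``mod`` given, marks of
    other modification types are dropped.
    """
    out = []
    rc = revcomp_pattern(mtase.pattern)
    for m in mtase.marks:
        if mod is not None and m.mod != mod:
            continue
        if m.strand == "top":
            out.append((mtase.pattern, m.index))
        else:
            out.append((rc, len(mtase.pattern) - 1 - m.index))
    return out


def _aligned_intersections(
    pattern: IupacPattern, idx: int, reader: ReaderContext
) -> list[str] | None:
    """Per-position intersection codes for the alignment placing
    reader.methyl_index on pattern position ``idx``.

    The combined window spans the union of the pattern and the aligned
    reader; pattern positions outside the reader are kept as-is, reader
    positions outside the pattern meet N.  Returns None if any
    overlapping pair is disjoint, or if the marked position cannot be A.
    """
    r = reader.pattern.codes
    offset = idx - reader.methyl_index  # reader start relative to pattern start
    lo = min(0, offset)
    hi = max(len(pattern), offset + len(r))
    merged: list[str] = []
    for pos in range(lo, hi):
        code = pattern.codes[pos] if 0 <= pos < len(pattern) else "N"
        rpos = pos - offset
        if 0 <= rpos < len(r):
            code = intersect_codes(code, r[rpos])
            if code == EMPTY:
                return None
        if pos == idx:
            # the marked base is a methylated adenine: force A
            code = intersect_codes(code, "A")
            if code == EMPTY:
                return None
        merged.append(code)
    return merged


def _witness_from_codes(codes: list[str]) -> str:
    """Resolve degenerate positions to the lexicographically smallest base."""
    return "".join(min(IUPAC_SETS[c]) for c in codes)


def classify_conflict(mtase: MTaseSpec, reader: ReaderContext) -> str:
    """Assign a conflict class; requires that a conflict exists.

    ``frequent_adenine`` for promiscuous MTases; ``dam_like`` when the
    MTase target equals the reader context (up to reverse complement)
    with a mark on the reader's sensed adenine; ``embedded_context``
    otherwise.  Returns "none" when there is in fact no conflict.
    """
    if not _conflict_exists(mtase, reader):
        return "none"
    if mtase.frequency_class == "frequent":
        return "frequent_adenine"
    rcodes = reader.pattern.codes
    for pat, idx in _canonical_marks(mtase, reader.mod):
        if pat.codes == rcodes and idx == reader.methyl_index:
            return "dam_like"
    return "embedded_context"


def _conflict_exists(mtase: MTaseSpec, reader: ReaderContext) -> bool:
    return any(
        _aligned_intersections(pat, idx, reader) is not None
        for pat, idx in _canonical_marks(mtase, reader.mod)
    )


def methyl_conflict(mtase: MTaseSpec, reader: ReaderContext) -> ConflictDecision:
    """Decide whether ``mtase`` can methylate inside the reader context.

    Each mark (bottom-strand marks canonicalized to the reverse
    complement) is aligned so the methylated adenine falls on the
    reader's sensed position; a conflict exists iff every overlapping
    IUPAC code pair intersects.  A modification-type mismatch (e.g. an
    m5C MTase against an m6A reader) is simply no conflict, not an
    error.  Witness sequences realize the per-position intersections
    with degenerate leftovers resolved to the lexicographically
    smallest base.
    """
    witnesses: list[str] = []
    for pat, idx in _canonical_marks(mtase, reader.mod):
        codes = _aligned_intersections(pat, idx, reader)
        if codes is not None:
            w = _witness_from_codes(codes)
            if w not in witnesses:
                witnesses.append(w)
    if not witnesses:
        return ConflictDecision(conflict=False)
    return ConflictDecision(
        conflict=True,
        conflict_type=classify_conflict(mtase, reader),
        witnesses=witnesses,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

class CapacityError(RuntimeError):
    """Raised when an enumeration would exceed the expansion budget."""


def pattern_to_regex(p: IupacPattern) -> re.Pattern:
    parts = []
    for c in p.codes:
        s = sorted(IUPAC_SETS[c])
        parts.append(s[0] if len(s) == 1 else "[" + "".join(s) + "]")
    return re.compile("".join(parts))


def _scan_literal(seq: str, pattern: IupacPattern) -> list[int]:
    rx = pattern_to_regex(pattern)
    return [m.start() for m in re.finditer(rf"(?=({rx.pattern}))", seq)]


def conflict_oracle(
    mtase: MTaseSpec,
    reader: ReaderContext,
    flank: int,
    max_expansions: int = 10**6,
    sample: int | None = None,
    seed: int = 0,
) -> ConflictDecision:
    """Brute-force conflict decision by literal enumeration.

    Enumerates every concrete sequence matching the MTase pattern padded
    by ``flank`` unconstrained bases per side, and checks literally
    whether any marked adenine sits on the sensed position of a reader
    occurrence (either orientation).  Flank bases farther than
    ``len(reader)-1`` from the pattern can never overlap a reader
    occurrence covering a marked (in-pattern) adenine, so only the
    inner ``min(flank, len(reader)-1)`` flank positions are enumerated.

    If the concrete space exceeds ``max_expansions``, a seeded random
    sample of ``sample`` sequences is drawn instead; with ``sample``
    unset this is a :class:`CapacityError`.
    """
    eff_flank = min(flank, len(reader.pattern) - 1)
    core = mtase.pattern.codes
    space = [sorted(IUPAC_SETS["N"])] * eff_flank
    space += [sorted(IUPAC_SETS[c]) for c in core]
    space += [sorted(IUPAC_SETS["N"])] * eff_flank
    total = 1
    for s in space:
        total *= len(s)

    if total > max_expansions and sample is None:
        raise CapacityError(
            f"{total} expansions exceed the {max_expansions} budget; "
            "pass sample= to draw a random subset"
        )

    if total <= max_expansions:
        seqs = ("".join(t) for t in itertools.product(*space))
    else:
        rng = random.Random(seed)
        seqs = ("".join(rng.choice(s) for s in space) for _ in range(sample))

    rlen = len(reader.pattern)
    j = reader.methyl_index
    rc_reader = revcomp_pattern(reader.pattern)
    r_rx = pattern_to_regex(reader.pattern)
    rc_rx = pattern_to_regex(rc_reader)
    mod_marks = [m for m in mtase.marks if m.mod == reader.mod]

    witnesses: list[str] = []
    for seq in seqs:
        sensed_top: set[int] = set()
        sensed_bottom: set[int] = set()
        for m in re.finditer(rf"(?=({r_rx.pattern}))", seq):
            sensed_top.add(m.start() + j)
        for m in re.finditer(rf"(?=({rc_rx.pattern}))", seq):
            sensed_bottom.add(m.start() + (rlen - 1 - j))
        for mark in mod_marks:
            p = eff_flank + mark.index
            base = seq[p]
            if mark.strand == "top":
                if base == "A" and p in sensed_top:
                    if seq not in witnesses:
                        witnesses.append(seq)
            else:
                if base == "T" and p in sensed_bottom:
                    if seq not in witnesses:
                        witnesses.append(seq)
    if not witnesses:
        return ConflictDecision(conflict=False)
    return ConflictDecision(
        conflict=True,
        conflict_type=classify_conflict(mtase, reader),
        witnesses=witnesses[:10],
    )


# ---------------------------------------------------------------------------
# Spec I/O helpers
# ---------------------------------------------------------------------------

def mtase_from_dict(d: dict) -> MTaseSpec:
    """Build an MTaseSpec from a JSON/YAML mapping.

    Expected keys: name, pattern (run syntax like "GAGN7ATGC" allowed),
    marks: [{strand, index, mod}], frequency_class.
    """
    try:
        pattern = parse_pattern(d["pattern"], d.get("name", ""))
        marks = tuple(
            MethylMark(strand=m["strand"], index=int(m["index"]),
                       mod=m.get("mod", "m6A"))
            for m in d["marks"]
        )
        return MTaseSpec(
            name=d["name"],
            pattern=pattern,
            marks=marks,
            frequency_class=d.get("frequency_class", "site_specific"),
        )
    except (KeyError, TypeError) as e:
        raise ValueError(f"malformed MTase spec: {d!r}") from e


def reader_from_string(text: str) -> ReaderContext:
    """Parse a reader spec string like ``GATC:1:m6A``."""
    parts = text.split(":")
    if len(parts) not in (2, 3):
        raise ValueError(f"reader spec must be PATTERN:INDEX[:MOD], got {text!r}")
    mod = parts[2] if len(parts) == 3 else "m6A"
    return ReaderContext(
        pattern=parse_pattern(parts[0]), methyl_index=int(parts[1]), mod=mod
    )
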