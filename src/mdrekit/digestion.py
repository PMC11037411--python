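"""Modification-gated restriction digestion simulation.

Enzyme models gate cleavage on the methylation state of each
recognition site (full / hemi_top / hemi_bottom / none, determined from
a :class:`~mdrekit.methylome.MethylomeTrack`) and cut with one of three
geometries:

* ``within_site`` — exact bond offsets inside the site (DpnI-like
  Gm6A↓TC, MboI-like ↓GATC);
* ``distance_range`` — a variable-distance interval of candidate bonds
  outside the site (most wH fusion endonucleases, e.g. G6mATC N1–23);
* ``nicking`` — a single-strand cut, optionally requiring a paired
  downstream site (HtuIII-like ↓NGm6ATC-N14-Gm6ATC).

Cut coordinates are 0-based bond indices in top-strand coordinates: a
cut at bond ``b`` severs the backbone between positions ``b`` and
``b+1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .methylome import MethylomeTrack, SeqRecord, find_occurrences
from .motif_algebra import ReaderContext, reader_from_string, revcomp_pattern

__all__ = [
    "WithinSite",
    "DistanceRange",
    "Nicking",
    "EnzymeModel",
    "SiteCall",
    "DigestResult",
    "call_sites",
    "predict_cuts",
    "two_site_efficiency",
    "fragment_lengths",
    "labeled_fragment_length",
    "oligo_response_matrix",
    "load_enzymes",
]

STATES = ("full", "hemi_top", "hemi_bottom", "none")
ACTIVITIES = ("high", "partial", "none")


@dataclass(frozen=True)
class WithinSite:
    """Exact cut bonds relative to site start (site-local orientation)."""

    top_cut_offset: int
    bottom_cut_offset: int


@dataclass(frozen=True)
class DistanceRange:
    """Cleavage at min_nt..max_nt beyond the site on the configured side(s)."""

    min_nt: int
    max_nt: int
    side: str = "both"  # left | right | both (site-local)

    def __post_init__(self):
        if not 0 <= self.min_nt <= self.max_nt:
            raise ValueError("need 0 <= min_nt <= max_nt")
        if self.side not in ("left", "right", "both"):
            raise ValueError("side must be left/right/both")


@dataclass(frozen=True)
class Nicking:
    """Single-strand cut at a fixed bond offset from site start.

    ``pair_spacer`` (lo, hi), if set, requires a second active site
    downstream (site-local 3' direction) with a gap in that bp range.
    """

    strand: str  # site-local top | bottom
    offset: int
    pair_spacer: tuple[int, int] | None = None


@dataclass(frozen=True)
class TwoSiteRule:
    fast_spacer: tuple[int, int]
    slow_spacers: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class EnzymeModel:
    name: str
    reader: ReaderContext
    mode: WithinSite | DistanceRange | Nicking
    response: dict  # state -> activity
    two_site: TwoSiteRule | None = None
    cofactor_note: str = ""

    def __post_init__(self):
        missing = [s for s in STATES if s not in self.response]
        if missing:
            raise ValueError(f"{self.name}: response map missing states {missing}")
        bad = [v for v in self.response.values() if v not in ACTIVITIES]
        if bad:
            raise ValueError(f"{self.name}: unknown activities {bad}")


@dataclass(frozen=True)
class SiteCall:
    seq_id: str
    site_start: int
    orientation: str  # + | -
    methylation_state: str
    activity: str


@dataclass
class DigestResult:
    seq_id: str
    enzyme: str
    kind: str  # within_site | distance_range | nicking
    ds_cuts: list[tuple[int, int]] = field(default_factory=list)  # (top, bottom) bonds
    intervals: list[tuple[int, int]] = field(default_factory=list)  # inclusive bond ranges
    nicks: list[tuple[str, int]] = field(default_factory=list)  # (strand, bond)
    completeness: str = "complete"  # complete | partial


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def _site_occurrences(seq: SeqRecord, reader: ReaderContext) -> list[tuple[int, str]]:
    """(start, orientation) of reader occurrences; palindromic readers
    report each site once, on the + orientation."""
    fwd = find_occurrences(seq, reader.pattern)
    rc = revcomp_pattern(reader.pattern)
    if rc.codes == reader.pattern.codes:
        return [(s, "+") for s in fwd]
    rev = find_occurrences(seq, rc)
    out = [(s, "+") for s in fwd] + [(s, "-") for s in rev if s not in set(fwd)]
    return sorted(out)


def _methylation_state(
    seq: SeqRecord, track: MethylomeTrack, reader: ReaderContext, start: int
) -> str:
    """State of the site at ``start`` from the marks at the two sensed
    adenine slots (genomic-strand semantics; identical for both site
    orientations)."""
    L = len(reader.pattern)
    n = len(seq)
    j = reader.methyl_index
    top_pos = (start + j) % n
    bot_pos = (start + L - 1 - j) % n
    top_ok = track.has(top_pos, "top", reader.mod)
    # the paired bottom-strand slot exists only if the site admits T there
    has_bot_slot = reader.pattern.admits(L - 1 - j, "T") or seq.bases[bot_pos] == "T"
    bot_ok = has_bot_slot and track.has(bot_pos, "bottom", reader.mod)
    if top_ok and bot_ok:
        return "full"
    if top_ok:
        return "hemi_top"
    if bot_ok:
        return "hemi_bottom"
    return "none"


def call_sites(
    seq: SeqRecord, track: MethylomeTrack, enzyme: EnzymeModel
) -> list[SiteCall]:
    """One call per reader occurrence (both orientations), with the
    activity read off the enzyme's response map."""
    if track.seq_id != seq.id:
        raise ValueError(f"track {track.seq_id!r} does not belong to {seq.id!r}")
    calls = []
    for start, orient in _site_occurrences(seq, enzyme.reader):
        state = _methylation_state(seq, track, enzyme.reader, start)
        calls.append(
            SiteCall(
                seq_id=seq.id,
                site_start=start,
                orientation=orient,
                methylation_state=state,
                activity=enzyme.response[state],
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Cut prediction
# ---------------------------------------------------------------------------

def predict_cuts(
    seq: SeqRecord, track: MethylomeTrack, enzyme: EnzymeModel
) -> DigestResult:
    """Predict cut events at every active site.

    Sites with activity ``none`` contribute nothing; any site with only
    ``partial`` activity flags the digest ``partial``.
    """
    calls = [c for c in call_sites(seq, track, enzyme) if c.activity != "none"]
    mode = enzyme.mode
    L = len(enzyme.reader.pattern)
    n = len(seq)
    kind = {WithinSite: "within_site", DistanceRange: "distance_range", Nicking: "nicking"}[
        type(mode)
    ]
    result = DigestResult(seq_id=seq.id, enzyme=enzyme.name, kind=kind)
    if any(c.activity == "partial" for c in calls):
        result.completeness = "partial"

    for c in calls:
        s = c.site_start
        if isinstance(mode, WithinSite):
            if c.orientation == "+":
                cut = (s + mode.top_cut_offset, s + mode.bottom_cut_offset)
            else:  # mirror through the site
                cut = (s + L - 2 - mode.bottom_cut_offset, s + L - 2 - mode.top_cut_offset)
            cut = (cut[0] % n, cut[1] % n) if seq.topology == "circular" else cut
            if cut not in result.ds_cuts:
                result.ds_cuts.append(cut)
        elif isinstance(mode, DistanceRange):
            end = s + L  # half-open site end
            right = (end + mode.min_nt, end + mode.max_nt)
            left = (s - 1 - mode.max_nt, s - 1 - mode.min_nt)
            sides = {"left": [left], "right": [right], "both": [left, right]}[mode.side]
            if c.orientation == "-":  # site-local sides flip
                sides = {"left": [right], "right": [left], "both": [left, right]}[mode.side]
            for iv in sides:
                if seq.topology == "circular":
                    iv = (iv[0] % n, iv[1] % n)
                if iv not in result.intervals:
                    result.intervals.append(iv)
        else:  # Nicking
            if mode.pair_spacer is not None and not _has_paired_site(
                calls, c, L, mode.pair_spacer
            ):
                continue
            if c.orientation == "+":
                nick = (mode.strand, s + mode.offset)
            else:
                flipped = "bottom" if mode.strand == "top" else "top"
                nick = (flipped, s + L - 2 - mode.offset)
            if seq.topology == "circular":
                nick = (nick[0], nick[1] % n)
            if nick not in result.nicks:
                result.nicks.append(nick)

    result.ds_cuts.sort()
    result.intervals.sort()
    result.nicks.sort()
    return result


def _has_paired_site(
    calls: list[SiteCall], site: SiteCall, site_len: int, spacer: tuple[int, int]
) -> bool:
    lo, hi = spacer
    for other in calls:
        if other is site:
            continue
        if site.orientation == "+":
            gap = other.site_start - (site.site_start + site_len)
        else:
            gap = site.site_start - (other.site_start + site_len)
        if lo <= gap <= hi:
            return True
    return False


def two_site_efficiency(spacer_bp: int, enzyme: EnzymeModel) -> str:
    """Cooperative two-site cleavage class for a given inter-site spacer.

    ``fast`` in the optimal range, ``slow`` in any slow range, otherwise
    ``unspecified`` (no rate reported for the gaps).
    """
    if enzyme.two_site is None:
        raise ValueError(f"{enzyme.name} has no two-site rule")
    if spacer_bp < 0:
        raise ValueError("spacer must be >= 0")
    lo, hi = enzyme.two_site.fast_spacer
    if lo <= spacer_bp <= hi:
        return "fast"
    for slo, shi in enzyme.two_site.slow_spacers:
        if slo <= spacer_bp <= shi:
            return "slow"
    return "unspecified"


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def fragment_lengths(
    cuts: DigestResult, seq: SeqRecord, resolve: str = "exact"
) -> list[int]:
    """Sorted fragment lengths from a digest.

    Only exact (within_site) cuts are used directly; distance-range
    digests must be resolved to interval midpoints first
    (``resolve="midpoint"``), which is flagged approximate by that
    explicit opt-in.  Cuts are placed at top-strand bonds.  A circular
    substrate with no cuts yields the full length (uncut).
    """
    if cuts.kind == "distance_range":
        if resolve != "midpoint":
            raise ValueError(
                "distance_range digests need resolve='midpoint' (approximate)"
            )
        bonds = sorted({(lo + hi) // 2 for lo, hi in cuts.intervals})
    elif cuts.kind == "nicking":
        raise ValueError("nicks do not linearize into double-strand fragments")
    else:
        bonds = sorted({top for top, _ in cuts.ds_cuts})

    n = len(seq)
    if seq.topology == "linear":
        bonds = [b for b in bonds if 0 <= b < n - 1]
        edges = [-1] + bonds + [n - 1]
        return sorted(edges[i + 1] - edges[i] for i in range(len(edges) - 1))
    # circular
    bonds = sorted({b % n for b in bonds})
    if not bonds:
        return [n]  # uncut circle
    frags = [bonds[i + 1] - bonds[i] for i in range(len(bonds) - 1)]
    frags.append(n - bonds[-1] + bonds[0])
    return sorted(frags)


def labeled_fragment_length(cuts: DigestResult, seq: SeqRecord) -> int | None:
    """Length of the fragment carrying a 5' top-strand label (e.g. FAM):
    everything up to the first top-strand cut bond.  None if uncut."""
    tops = sorted(top for top, _ in cuts.ds_cuts)
    if not tops:
        return None
    return tops[0] + 1


# ---------------------------------------------------------------------------
# Oligo response matrix
# ---------------------------------------------------------------------------

_RANK = {"none": 0, "partial": 1, "high": 2}


def oligo_response_matrix(
    duplexes: list[tuple[str, SeqRecord, MethylomeTrack]],
    enzymes: list[EnzymeModel],
) -> pd.DataFrame:
    """Activity call per (enzyme, duplex methylation state).

    Each duplex is a (state_label, sequence, track) triple carrying
    explicit per-strand marks; the matrix entry is the strongest site
    activity on that duplex.
    """
    rows = {}
    for enz in enzymes:
        row = {}
        for label, seq, track in duplexes:
            calls = call_sites(seq, track, enz)
            row[label] = (
                max((c.activity for c in calls), key=_RANK.__getitem__)
                if calls
                else "none"
            )
        rows[enz.name] = row
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Bundled enzyme definitions
# ---------------------------------------------------------------------------

def _model_from_dict(name: str, d: dict) -> EnzymeModel:
    m = d["mode"]
    mtype = m["type"]
    if mtype == "within_site":
        mode = WithinSite(int(m["top_cut_offset"]), int(m["bottom_cut_offset"]))
    elif mtype == "distance_range":
        mode = DistanceRange(int(m["min_nt"]), int(m["max_nt"]), m.get("side", "both"))
    elif mtype == "nicking":
        pair = m.get("pair_spacer")
        mode = Nicking(m["strand"], int(m["offset"]), tuple(pair) if pair else None)
    else:
        raise ValueError(f"{name}: unknown mode {mtype!r}")
    two = d.get("two_site")
    rule = (
        TwoSiteRule(
            tuple(two["fast_spacer"]),
            tuple(tuple(r) for r in two["slow_spacers"]),
        )
        if two
        else None
    )
    return EnzymeModel(
        name=name,
        reader=reader_from_string(d["reader"]),
        mode=mode,
        response=dict(d["response"]),
        two_site=rule,
        cofactor_note=d.get("cofactor_note", ""),
    )


def load_enzymes(path: str | Path | None = None) -> dict[str, EnzymeModel]:
    """Load enzyme models from JSON; defaults to the bundled config."""
    if path is None:
        text = resources.files("mdrekit.data").joinpath("enzymes.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    return {name: _model_from_dict(name, d) for name, d in raw.items()}
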