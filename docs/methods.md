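# Methods

## The problem

A modification-dependent restriction endonuclease (MDRE) that senses
N6-methyladenine (m6A) in a sequence context — here the Dam context
Gm6ATC, read by winged-helix (wH) sensor domains — can only persist in
a genome if nothing methylates that context on the host's own DNA.
mdrekit models the three computations that establish this: deciding
whether a given methyltransferase (MTase) can deposit m6A inside a
reader context, locating MTase genes near and far from the
endonuclease gene, and simulating what the enzyme does to substrates of
defined methylation state.

## Conflict algebra

An MTase is specified as an IUPAC degenerate pattern plus one or more
methyl marks, each a (strand, index, modification) triple with indices
in top-strand coordinates: a bottom-strand m6A is stored at the
position of the paired T. A reader context is a pattern plus the index
of the sensed adenine (default GATC, index 1, m6A).

The decision `methyl_conflict(mtase, reader)`:

1. Marks are canonicalized to top-strand adenines: a bottom mark at
   index *i* becomes a top mark at index *len−1−i* of the
   reverse-complemented pattern. This gives one code path and makes
   strand symmetry (`conflict(spec) == conflict(revcomp(spec))`) hold
   by construction.
2. The reader is aligned so its sensed adenine sits on the mark. There
   is exactly one such offset per mark. Pattern positions outside the
   reader, and reader positions outside the pattern, meet N
   (unconstrained genomic flank).
3. Conflict iff every overlapping code pair has a non-empty base-set
   intersection (the marked position is additionally intersected with
   A, since the methylated base is an adenine).
4. Witnesses realize the per-position intersections, resolving leftover
   degeneracy to the lexicographically smallest base — deterministic
   output, and every witness literally contains both a pattern match
   and a reader occurrence sharing the methylated position.

Classification: `frequent_adenine` if the spec is flagged promiscuous;
`dam_like` if some canonical mark makes the pattern code-identical to
the reader with the mark on the sensed adenine (identity up to reverse
complement, not mere containment — longer sites that embed the context
are the separate `embedded_context` class).

A modification-type mismatch (an m5C MTase against an m6A reader) is a
negative decision, not an error.

### The enumeration oracle

`conflict_oracle` decides the same question by brute force: enumerate
every concrete sequence matching the pattern padded by `flank`
unconstrained bases per side, scan each literally for reader
occurrences in both orientations, and check whether a marked adenine is
ever the sensed base. Flank positions farther than `len(reader)−1` from
the pattern cannot intersect a reader occurrence that covers an
in-pattern mark, so only the inner `min(flank, len(reader)−1)` flank
bases are enumerated; this keeps the space inside the 10⁶-expansion
budget for patterns with ≤3 degenerate positions while remaining a
literal enumeration of every sequence that can matter. Larger spaces
(e.g. GAGN₇ATGC) are sampled randomly with a seed; sampling is only
used where the test accepts a probabilistic negative.

One deliberate outcome: for EcoR124I-like GAAN₆RTCG (type I), both the
algebra and the oracle find a genuine GATC overlap through the
bottom-strand context (CGAYN₆TTC, Y→T, giving CGATC… witnesses). The
package reports this conflict; it is a property of the sequence
algebra, not a bug.

## Methylome tracks

`apply_mtase` finds pattern occurrences on both strands (reverse
complement for the bottom; circular substrates are scanned across the
origin with modular deduplication) and deposits every mark of the spec;
it is idempotent. Partial methylation (e.g. in-vivo phage lambda DNA)
is a seeded random subset controlled by a completeness fraction,
default 1.0 — the actual completeness of partially Dam-methylated phage
DNA is unquantified, so it is a free parameter.

`ecoGII_track` marks every adenine on both strands except inside a
same-strand homopolymer A-run of at least `polyA_min_run` bases
(default 4; the minimum length of a "polyA track" is not defined by the
enzyme's characterization, so it is configurable). Bottom-strand runs
are top-strand T-runs.

## Digestion model

Cut coordinates are 0-based bond indices in top-strand coordinates: a
cut at bond *b* severs between positions *b* and *b+1*. Site calls take
their methylation state solely from the track at the two sensed adenine
slots of each reader occurrence (positions start+j on top and
start+len−1−j on bottom); the four states full / hemi_top /
hemi_bottom / none map to activities high / partial / none through the
enzyme's response table. Hemi orientations are kept distinct because
enzymes genuinely differ there (Ahi29725I prefers full over hemi;
Apa233I cuts both).

Geometries:

* **within_site** — offsets relative to site start; DpnI-type
  Gm6A↓TC is top=bottom=+1 (blunt), MboI-type ↓GATC is top=−1,
  bottom=+3 (4-nt 5′ overhang). Reverse-orientation sites mirror
  through the site (bond s+L−2−offset, strands swapped).
* **distance_range** — one inclusive bond interval per configured
  flank, [site_end+min, site_end+max] on the right and its mirror on
  the left; intervals never overlap the site span. Fragment sizes from
  interval digests require explicit midpoint resolution and are flagged
  approximate by that opt-in. The default side is both flanks, because
  run-off data do not fix sidedness for all enzymes; HhiV4I's distance
  range (only "in the vicinity of" the site is known) is a documented
  placeholder set equal to the Ahi29725I N1–23 range.
* **nicking** — a single-strand bond at a fixed offset; HtuIII-type
  nicks one N upstream of the site (offset −2, top strand) and only at
  sites paired with a second active site downstream. Only one paired
  geometry (14-bp spacer) has been observed, so the accepted spacer
  window defaults to 5–30 bp and is configurable.

Two-site cooperativity is a lookup: spacers 13–27 bp are fast, 8–11 and
>42 bp slow, and the unmeasured gaps (<8, 12, 28–42) return
`unspecified` rather than an interpolation. Star activity at enzyme
excess is represented only as `response[none] = partial`, not as
concentration kinetics — kinetics, dose response and cation chemistry
are out of scope (cofactors ride along as metadata).

Fragment accounting: linear digests with *n* cuts give *n+1* fragments,
circular give *n* (an uncut circle reports its full length). Fragment
lengths are taken between top-strand bonds, and the 5′-label (FAM)
fragment is everything up to the first top-strand cut; lengths always
sum to the substrate length.

Eleven enzyme definitions (DpnI, MboI, DpnII, Sau3AI, BamHI, FcyTI,
Psp4BI, HhiV4I, Ahi29725I, Apa233I, HtuIII) ship as JSON and are
overridable; the response tables encode the qualitatively reported
duplex digestion behaviors and are configuration, not measurement.

## Genome scans

Neighborhoods are counted by gene rank — the `window_genes` (default 3)
nearest annotated genes on each side on the same contig, truncated at
contig edges — because co-residence claims are made in genes, not
kilobases; a base-pair window mode (default 10 kb, midpoint distance)
is provided for interval-style co-occurrence tallies. A fusion with no
MTase in its window is *stand-alone*. The genome-wide scan evaluates
`methyl_conflict` for every MTase gene on any contig of the genome
(set semantics; order-independent) and aggregates per-fusion reports.
MTase identities come from the annotation; domain prediction from
sequence is deliberately out of scope.

## Architecture and lab math

Family classification is an exact ordered match of the domain list
against the eight known wH-fusion signatures; order matters, proteins
without wH are `no_wH`, everything else `unclassified`. The pocket
motif check scores configured alignment columns (methyl-pocket and
base-contact roles, reference numbering from the DpnI structure
4kyw) against allowed residue sets; the threshold for "motif present"
defaults to 1.0, with lower values admitting closely related motifs
whose exact residue sets are not enumerated anywhere — hence
configuration.

Molarity conversions: `nM = μg / (kDa_total × μL) × 10⁶` for proteins
(oligomeric MW = monomer × subunits) and
`nM = ng / (bp × 650 × μL) × 10⁶` for duplex oligos. The 650 Da/bp
average is the default convention; a sequence-exact duplex MW is
offered as an alternative.

## Synthetic data

The genome generator emulates annotated prokaryotic genome fragments:
per genome (default 20 kb, 8–14 non-overlapping genes of 300–900 bp on
alternating strands, 20 bp gaps) a wH-fusion gene is planted, an MTase
is placed inside its 3-gene window with probability `p_neighbor_mtase`
(default 0.13, so the expected stand-alone fraction is 0.87 — the
published survey's headline rate, which itself is not desk-reproducible
from external genomes; the calibrated simulation substitutes for it), a
conflicting MTase is placed elsewhere with probability 0.2, and a
benign one with probability 0.3. Conflict status of every pool spec is
established by the enumeration oracle at generation time and embedded
as ground truth, so recovery by the scanners is exact by construction —
passing recovery tests demonstrates internal consistency of generator,
algebra and scanner, not performance on real annotation pipelines.
Real genomes differ in every way the generator ignores: GC content,
gene density, operon structure, ambiguous MTase annotations, and
pseudogenes.

Plasmid substrates carry GATC sites at exactly requested spacings, with
filler rejection-sampled until no accidental GATC occurs anywhere
(checked across the origin). The oligo generator emits the four duplex
methylation states of a 60-mer with a single GATC, defaulting to the
printed assay duplex; marks sit on the Dam positions of that site.

All generators are deterministic for a fixed seed (Python
`random.Random`); identical seeds give byte-identical files.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use 1,000 genomes for
the recovery/calibration runs (binomial 99% half-width ±2.7 points
around 87%), 30–40 random specs for the algebra/oracle sweeps, and
1,000 random substrates for fragment conservation; these sizes were
chosen so the full analysis reruns in seconds while leaving the
statistical checks well-powered. Coordinates are 0-based half-open
internally, 1-based only at format boundaries (GFF3, human-readable
text). Ties in gene ordering break by (start, end, gene_id); duplicate
gene ids are rejected.

## Known limitations

* The conflict decision is boolean; no partial or probabilistic
  scoring, and marks must be supplied (no inference of methylated
  positions from sequence).
* Enzyme response tables are qualitative (high/partial/none); no rates.
* Cleavage-position base preferences (NN/RN, NN/GN) are annotations
  only, not modeled.
* Degenerate readers are supported in site calling, but the relaxed
  Sm6ATS specificity of real wH domains beyond GATC ("star" binding
  sites) is uncharacterized and left to configuration.
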