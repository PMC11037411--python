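# mdrekit

Analysis toolkit for **N6-methyladenine-dependent (type IV) restriction
systems** — endonucleases that cleave DNA only when it carries adenine
methylation, canonically in the Dam context Gm6ATC. It is aimed at
researchers characterizing modification-dependent restriction
endonucleases (MDREs) such as the winged-helix (wH) domain fusion
enzymes: it answers, at the desk, the questions that frame such a
characterization.

* **Conflict algebra** (`motif_algebra`): can a co-resident
  methyltransferase (MTase) methylate inside the endonuclease's reader
  context and trigger self-restriction? The decision is made over IUPAC
  degenerate codes: the MTase target pattern (flanks padded with N) is
  aligned so a methylated adenine falls on the reader's sensed adenine,
  and a conflict exists iff every overlapping code pair has a non-empty
  base-set intersection. Conflicts classify as *frequent_adenine* (a
  promiscuous MTase like M.EcoGII), *dam_like* (the target *is* the
  reader context), or *embedded_context* (a longer site containing it,
  e.g. CGm6ATCG ⊃ Gm6ATC). A brute-force enumeration oracle verifies
  the algebra on small instances.
* **Methylome tracks** (`methylome`): apply MTase specifications to
  linear or circular substrates, producing per-strand m6A tracks,
  including hemi-methylated replication states and M.EcoGII
  hypermethylation (all adenines except polyA tracks).
* **Digestion simulation** (`digestion`): modification-gated cleavage
  with three geometries — within-site (Gm6A↓TC, DpnI-like), variable
  distance (G6mATC N1–23, most wH fusions), and single-strand nicking
  with a paired-site requirement (↓NGm6ATC-N14-Gm6ATC) — plus two-site
  cooperativity spacer classes, fragment prediction, and the
  duplex-oligo response matrix over the four methylation states
  M+/M+, M+/M−, M−/M+, M−/M−.
* **Genome scans** (`genome_scan`): per wH-fusion gene, find MTases in
  the gene neighborhood (defense-island test; a fusion with none is
  *stand-alone*) and evaluate methylation conflicts genome-wide.
* **Architecture & lab math** (`architecture`, `labmath`): map ordered
  domain lists to the wH fusion families (PD-(D/E)XK–wH, PUA–wH–HNH,
  wH–GIY-YIG, PLD–wH, …), score the 6mA/GATC pocket-residue motif, and
  convert reaction masses to molarities.
* **Synthetic data** (`synthetic_data`): seeded generators for
  annotated genomes with planted ground truth, circular plasmids with
  exact GATC spacings, and the four methylation states of the printed
  60-mer assay duplex.

## Worked example

```python
from mdrekit import (gen_oligo_set, load_enzymes, predict_cuts,
                     fragment_lengths, molar_conc, ProteinSpec)
from mdrekit.digestion import labeled_fragment_length

enzymes = load_enzymes()
duplexes = {label: (seq, track) for label, seq, track in gen_oligo_set()}

seq, track = duplexes["M+/M+"]           # fully methylated 60-mer duplex
res = predict_cuts(seq, track, enzymes["DpnI"])
print(res.ds_cuts)                        # [(19, 19)]
print(fragment_lengths(res, seq))         # [20, 40]
print(labeled_fragment_length(res, seq))  # 20

print(round(molar_conc(1.0, ProteinSpec("Ahi29725I", 24.62, 2), 30)))  # 677
```

The duplex carries one GATC site (0-based 18–21). DpnI-type enzymes cut
inside Gm6A↓TC, blunt, at bond 19 — so the 5′-FAM-labeled top-strand
fragment is 20 nt and the distal fragment 40 nt. MboI on the unmodified
duplex cuts ↓GATC and leaves an 18-nt labeled fragment. 1 μg of the
24.62 kDa × 2 homodimer in 30 μL is ≈677 nM.

The same operations are exposed as a CLI:

```sh
mdrekit oligo-matrix
mdrekit conc protein --ug 1 --monomer-kda 24.62 --oligomer 2 --ul 30
mdrekit simulate genomes --n 100 --seed 7 --out sim/
mdrekit conflict-scan --genes sim/genes.tsv --out reports.tsv
```

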