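# helentron-scan

Structural detection, classification and empty-site validation of
**Helentrons** and their non-autonomous partners (**HINEs** / DINE-1-like
elements) — rolling-circle transposons recognized not by homology but by
their architecture: short palindromic subterminal inverted repeats
(subTIRs) near each terminus, a small stem-loop near the 3' end, insertion
into TT dinucleotides flanked by variable T runs, and no target-site
duplication.

The toolkit covers:

* **`palindrome`** — maximal hairpin / dispersed inverted-repeat detection
  (the primitive under all structure calls; N never matches anything).
* **`structure`** — element annotation against configurable positional
  window profiles (`hine-mo`, `dine-1`, `helitron`, `proto-helentron` or a
  custom YAML), canonical Helitron terminus checks (5' TC / 3' CTRR), a
  structure-type decision table (HINE, Helentron, canonical Helitron,
  proto-Helentron, Helitron2-like, unclassified), and a whole-genome
  scanner.
* **`families`** — family assignment by shared subTIR stretch (>= 11 bp
  identical, single linkage), subfamilies by >= 80% identity over the last
  60 bp, deletion-derivative linking, and canonical naming
  (`HINE-Mo-1A.1`, `Helentron-Cq-32A`, `proto-Helentron-Pi`).
* **`sites`** — paralogous empty-site search with a chimeric 50 bp + 50 bp
  flank query (>= 90% identity over >= 90% of the query), target-site
  reports (flanking T runs, TT at the reconstructed junction, A|T junction,
  TSD scan) and boundary canonicalization policies.
* **`rep`** — six-frame ORF discovery and Rep-protein classification from
  the rolling-circle motif-2 block `(V/I)ExQxRG(S/L)(P/L)HxH`
  (S = Helentron-class, L = Helitron-class).
* **`simulate`** — a synthetic-genome generator that plants elements with
  exact ground truth (TT target sites, 2-5 terminal Ts per end, duplicated
  pre-insertion loci as empty sites, deletion derivatives, per-copy
  divergence), used by the entire test suite.

## CLI

```bash
helentron-scan simulate --length 500000 --n-elements 2 --n-copies 10 \
    --dup-fraction 0.5 --seed 1 --out-prefix scratch/sim
helentron-scan scan --genome scratch/sim.fasta --profile hine-mo \
    --gff scratch/elements.gff3 --bed scratch/elements.bed
helentron-scan classify --elements elements.fa --species Mo --out families.tsv
helentron-scan sites --genome scratch/sim.fasta --elements scratch/elements.bed \
    --out scratch/sites.tsv
helentron-scan repclass --proteins proteins.fa --out calls.tsv
helentron-scan run --genome scratch/sim.fasta --out-dir scratch/run   # full pipeline
```

Every output embeds the tool version and a hash of the run configuration.
Coordinates are 0-based half-open internally and in BED; GFF3 output is
1-based inclusive.  Minus-strand elements are annotated on the extracted
reverse complement and emitted on the forward assembly with `strand=-`.

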