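# Methods

## Gene contexts

All analyses operate on a *gene context*: the transcript-oriented string
`coding tail + stop codon + downstream UTR`. Contexts are extracted from a
genome FASTA + GFF3 pair (CDS features grouped by `Parent`, minus-strand
genes reverse-complemented, internal coordinates 0-based half-open) or read
directly from a context FASTA whose headers carry `stop_start=<int>`. Since
3'-UTR annotations are rarely available, the UTR is defined operationally as
the `utr_nt` bases downstream of the stop codon (default 150 nt, the span
routinely cloned together with a yeast ORF); scanning itself only uses the
first `window_nt` bases (default 30). The coding tail kept in the context is
`tail_nt = 30` nt (10 codons) by default — enough for shifted-frame motifs
that overlap the C-terminus and for the deletion window. Genes whose
annotated stop codon is not TAA/TAG/TGA are rejected with an error naming
the gene; genes whose CDS length is not a multiple of 3 are excluded with a
warning. N bases are retained; any codon containing N translates to `X` and
can never match a motif or a stop.

## Translation and read-through

Translation uses the standard nuclear code (all study species use it;
selenocysteine and alternative codes are out of scope). Stop-codon
read-through is modelled as the near-cognate substitutions UAA/UAG → Gln and
UGA → Arg. `readthrough_translate` bypasses at most `max_readthrough` stops
(default 1 — one ribosomal bypass per molecule is the modelled event) and
terminates at the next stop.

## Motif grammars

A grammar is one amino-acid set per tripeptide position; a tripeptide
matches when each residue is in its set, and the motif additionally requires
an immediately following stop codon. `build_grammar` takes positional unions
over training tripeptides — deterministic, order-invariant, and by
construction every training peptide matches. Three grammars are bundled:

- `search`: (S/A/C/E/I/H/Q)-(K/R/H)-(L/F) — the permissive set used for
  systematic genome scanning;
- `canonical`: (S/A/C)-(K/R/H)-(L/M) — the textbook consensus;
- `union` (default): (S/A/C/E/I/H/Q)-(K/R/H)-(L/M/F). The union is the
  default because documented cryptic termini include both Met and Phe at the
  third position (e.g. ARM and NKF); either narrower grammar is selectable.

The real 20-gene training list behind the search grammar is not public, so
the package ships a clearly-labelled synthetic placeholder TSV whose
positional unions equal the search grammar exactly; users can drop in their
own table. Context scoring is pluggable: the default scorer is the grammar
indicator; a positional add-one log-odds scorer is provided for ranking but
its values are deliberately not comparable to any external PTS1 predictor.

## The scan

For each frame f ∈ {0, +1, +2} relative to the CDS frame, the scanner walks
codon starts p on the frame's grid and reports a hit when the three codons
at p translate to a grammar-accepted tripeptide and the codon at p+9 is a
stop. Constraints:

- `motif_start = p − (first base after the stop codon)` must be below
  `window_nt`. A config switch (`offset_origin="stop_start"`) counts from
  the stop codon's first base instead, because published "N bp downstream"
  distances do not pin the origin down.
- Frame 0 starts at the first codon after the annotated stop (the stop
  itself is read through); shifted frames start at the shifted codon
  overlapping the annotated stop, so motifs may begin up to 2 bases before
  the UTR.
- A hit is *interrupted* when a same-frame stop codon lies strictly between
  the annotated stop locus and p (for frame 0: a second stop after the
  read-through). Interrupted hits are retained with a flag by default and
  both counted and excluded in summaries; `drop_interrupted` filters them.
- All qualifying hits are reported (no best-hit selection), sorted by
  (frame, motif_start).

The implied isoform for a shifted-frame hit is built as coding-frame
residues up to the shift point followed by shifted-frame residues from the
codon overlapping the stop — the precise base at which a real ribosome
slips is unknowable from sequence, so the shift is anchored at the stop
codon, the common slippage locus. The 12-residue context peptide is the last
≤ 12 residues of that isoform.

## Deletion enumeration and imprinting

`enumerate_deletions` deletes each base in an `upstream_window` (default
30 nt; the published mutagenesis covered ~100 nt around the stop, but 30
keeps enumeration local to the divergent C-terminal segment and is
configurable) before the stop and groups deletions with byte-identical
outcomes: deleting any base of a homopolymer run is one equivalence class,
so a window with maximal runs r₁…r_k plus s singletons yields k + s classes
and W events. A class *creates an in-frame motif* when the mutated
coding-frame translation terminates at a stop with a grammar-matching
terminal tripeptide. `imprinting_map` joins these classes to the +1-frame
hits carrying the same tripeptide; note that *any* upstream deletion that
does not create a premature in-frame stop maps a +1 motif into frame, so a
meaningful map restricts the window to the mutagenised segment (the bundled
6T fixture documents a 6-base window). Insertion enumeration (which would
map +2-frame hits into frame) is intentionally off by default; observed
imprinting events are deletions.

`substitutions_to_motif` examines the three coding codons immediately before
the stop. If the terminal tripeptide already fully matches the grammar it
returns nothing; otherwise it mutates one codon (default the C-terminal
one, whose residue dominates targeting strength) through its nine single-base
neighbours and keeps those that change the residue to a *different*
grammar-accepted amino acid — for a terminal Phe codon exactly the three
one-base Leu codons, the NKF\*→NKL\* evolvability route. A `position`
argument targets the first or second codon instead. Genome-wide substitution
scanning is out of scope.

`find_slippage_sites` reports maximal homopolymer runs of length ≥
`min_run` (default 3, the shortest run length with documented slippage
propensity) within `search_window` bases before the stop. Higher-order
tandem repeats are reported only through their homopolymer decomposition —
a "3 × 3 nt" stretch like AAATCCCAAA appears as three adjacent runs.

## Prevalence and conservation

`summarize_genome` reports the fraction of genes with ≥ 1 candidate
(interrupted or not) and the interrupted share under two definitions —
per hit (interrupted hits / all hits) and per gene (genes whose every hit is
interrupted / genes with a hit) — because "fraction interrupted" is
ambiguous between the two; both are emitted. `conservation_report` maps
per-species hit tables onto an ortholog table (an input; no ortholog
inference is attempted) and flags a group conserved when ≥ m species
(default 2) carry a hit, requiring the identical tripeptide by default
(frame/offset identity is reported but not required, as cross-species
offsets drift). Genes missing from the table become singleton groups with a
warning. Output ordering is deterministic and independent of species input
order.

## Synthetic benchmark

The generator emulates the minimal gene architecture the analyses need: per
gene a single-exon CDS (random sense codons, so no internal stops), a stop
codon, and a 150 nt UTR at GC 0.38 (yeast-like background; codon usage and
UTR length distributions are deliberately not modelled). Defaults: 200
genes, 20% planted with a motif (uniformly across frames, offsets drawn
from the frame-compatible positions in [0, 30)), and 40% of planted genes
interrupted by an extra same-frame stop — the interrupted share observed in
genome scans. Planted and interrupted counts are rounded deterministic
counts, not Bernoulli draws, so summary fractions equal the requested proportions
exactly. Every gene is rejection-sampled (≤ 1000 attempts, then an
*infeasible spec* error) until a scan of the candidate context returns
exactly the intended truth — planted genes exactly their one hit, background
genes none — so the truth table is exact and recovery tests are sharp:
sensitivity 1.0 with zero unplanted within-window hits is a hard
requirement, not a statistical target. An optional homopolymer run
(e.g. T×6) is written immediately before the stop of planted genes with its
maximality enforced. A minus-strand mode exists to exercise coordinate
handling. All randomness flows from the single spec seed; outputs are
byte-identical across runs.

What passing these tests does *not* show about real data: real UTRs have
non-uniform composition, real annotations have multi-exon and overlapping
genes, and real motif prevalence depends on the grammar chosen — the
benchmark certifies the machinery, not genome-wide biology.

## Pipeline and determinism

`run_pipeline` computes scan → imprint → slippage → summary (→ conservation
when an ortholog table is given) entirely in memory and writes outputs only
after every stage succeeds, so failures leave no partial files; a stage
failure raises an error naming the stage. Outputs and the log carry no
timestamps: identical config + inputs give byte-identical directories. The
run's config is echoed into the output directory.

## Numerical/edge-case choices

- Deletion class ids are `del_<base><first position>`; substitution ids
  `sub_<pos><ref>><alt>`; ties in tables are broken by stable sorts on
  (gene_id, frame/kind, position).
- A UTR shorter than the scan window triggers a warning and a truncated
  scan; a downstream region shorter than `utr_nt` gives a truncated context
  whose `utr_len` reflects the truth.
- Contexts shorter than three coding codons skip the substitution scan with
  a warning.
- Problem sizes in the test-suite benchmarks (200 genes × 3 seeds for
  recovery; 200 random contexts for oracle equivalence; 1000 random windows
  for the deletion closed form) were chosen as the smallest sizes that
  exercise every frame/offset/interruption combination.

## Known limitations

- No quantitative slippage-rate or read-through-efficiency model; hits are
  combinatorial candidates, not predicted targeting strengths.
- The external PTS1 predictor's numeric scores are not reproduced; scoring
  is pluggable and the bundled scorers are membership/log-odds only.
- PTS2 and N-terminal signals are out of scope, as are UTR inference from
  RNA-seq and ortholog inference.
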