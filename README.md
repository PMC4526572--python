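# crypticpts

Frameshift-aware discovery of cryptic peroxisomal targeting signals (PTS1)
hidden in yeast 3'-UTRs.

## The problem

A PTS1 is a C-terminal tripeptide — canonically (S/A/C)-(K/R/H)-(L/M)
immediately followed by the stop codon — that routes a protein to the
peroxisome. A gene can harbour a *cryptic* PTS1: a tripeptide+stop encoded
just downstream of (or out of frame with) its annotated stop codon, expressed
only when the ribosome reads through the stop or slips into a shifted frame,
typically at a homopolymer run. Such latent signals matter for understanding
how duplicate genes split an ancestral dual localization (e.g. the cytosolic
IDP2 / peroxisomal IDP3 pair of isocitrate dehydrogenases), and how a
transient translational error can be "imprinted" into the genome by a single
base deletion at the very site that causes the slippage.

`crypticpts` is for comparative genomicists and yeast molecular biologists
who want to scan genomes (or single gene contexts) for these signals and
analyse their mutational accessibility. It provides:

- **scanner** — searches every reading frame relative to the CDS for a
  grammar-matching tripeptide immediately followed by a stop, starting within
  a 30 bp window after the annotated stop codon. Frame 0 is reached by stop
  codon read-through (UAA/UAG decoded as Gln, UGA as Arg); frames +1/+2 by a
  frameshift at the stop. Motifs "interrupted" by an additional same-frame
  stop are flagged or filtered.
- **motif** — positional-union grammars over training tripeptides. The
  bundled modes are `search` (S/A/C/E/I/H/Q)-(K/R/H)-(L/F), `canonical`
  (S/A/C)-(K/R/H)-(L/M) and their `union` (the default).
- **frameshift** — enumerates single-base deletions upstream of the stop
  (collapsed into equivalence classes: all deletions within one homopolymer
  run are the same outcome), links them to the +1-frame hits they would put
  in frame, finds one-base substitutions that strengthen a near-miss terminal
  tripeptide (NKF\* → NKL\*), and detects slippage-prone homopolymer runs.
- **conservation** — per-genome prevalence summaries and cross-species
  conservation of hits over an ortholog table.
- **synthetic** — a generator of yeast-like genomes with planted motifs,
  interruptions and slippage runs plus an exact truth table, so the whole
  pipeline is testable without downloads.

## Worked example

```python
from crypticpts import GeneContext, scan_context
from crypticpts.frameshift import enumerate_deletions, find_slippage_sites

# coding tail "GAA", stop codon TAA, then a short 3'-UTR
ctx = GeneContext("toy", "GAATAAGTCTAAACTATAA", stop_start=3)
for h in scan_context(ctx):
    print(h.frame, h.tripeptide, h.motif_start, h.interrupted, h.isoform_tail)

events = enumerate_deletions(ctx, upstream_window=3)
print(len(events), sorted({e.equivalence_class_id for e in events}))
print([e.resulting_isoform_tail for e in events])
```

prints

```
1 SKL 1 False NKSKL
3 ['del_A1', 'del_G0']
['NKSKL', 'DKSKL', 'DKSKL']
```

i.e. one cryptic motif in the +1-shifted frame — tripeptide SKL starting one
base after the stop codon, not interrupted, with implied isoform terminus
`NKSKL` — and all three single-base deletions of the last coding codon
(two equivalence classes: deleting the G, or either A of the AA run) place
that SKL in the coding frame.

The same analyses run from the shell:

```sh
crypticpts synth --seed 7 --n-genes 200 --outdir synth/
crypticpts scan --contexts synth/contexts.fasta --out hits.tsv --summary summary.tsv
crypticpts imprint --contexts synth/contexts.fasta --out variants.tsv
crypticpts slippage --contexts synth/contexts.fasta --min-run 3 --out sites.tsv
crypticpts run --config config.yaml     # full pipeline, deterministic outputs
```

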