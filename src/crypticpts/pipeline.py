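"""One-shot pipeline: scan -> imprint -> slippage -> summarize [-> conserve].

All stages are computed in memory first and written only after every stage
has succeeded, so a failed run leaves no partial outputs. Outputs and the log
contain no timestamps; identical config + inputs give byte-identical output
directories.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .conservation import conservation_report, read_ortholog_table
from .frameshift import enumerate_deletions, find_slippage_sites, imprinting_map, substitutions_to_motif
from .motif import get_grammar
from .scanner import scan_genome
from .io_formats import write_hits, write_variants


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Serializable pipeline configuration; echoed into the output directory."""

    outdir: str
    fasta: str | None = None
    gff: str | None = None
    contexts: str | None = None
    orthologs: str | None = None
    species: str = "genome"
    grammar_mode: str = "union"
    window_nt: int = 30
    drop_interrupted: bool = False
    upstream_window: int = 30
    min_run: int = 3
    conservation_m: int = 2
    tail_nt: int = 30
    utr_nt: int = 150
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Writes hits.tsv, variants.tsv, imprinting.tsv, sites.tsv, summary.tsv,
    conservation.tsv (when an ortholog table is given), run.log and
    config.yaml. Any stage failure raises :class:`StageError` and nothing is
    written.
    """
    grammar = get_grammar(config.grammar_mode)  # config errors before any compute
    if config.contexts is None and (config.fasta is None or config.gff is None):
        raise ValueError("config needs either 'contexts' or both 'fasta' and 'gff'")

    log: list[str] = []

    try:
        hits, summary, contexts = scan_genome(
            fasta=config.fasta if config.contexts is None else None,
            gff=config.gff if config.contexts is None else None,
            contexts=config.contexts,
            grammar=grammar,
            window_nt=config.window_nt,
            drop_interrupted=config.drop_interrupted,
            tail_nt=config.tail_nt,
            utr_nt=config.utr_nt,
        )
        log.append(f"scan: {summary['n_genes_scanned']} genes, "
                   f"{summary['n_hits']} candidate hits "
                   f"({summary['n_hits_interrupted']} interrupted)")
    except Exception as exc:  # noqa: BLE001
        raise StageError("scan", exc) from exc

    try:
        variant_rows = []
        imprint_rows = []
        for ctx in contexts:
            for ev in enumerate_deletions(ctx, config.upstream_window, grammar):
                variant_rows.append(ev.to_row())
            for ev in substitutions_to_motif(ctx, grammar):
                variant_rows.append(ev.to_row())
            imprint_rows.extend(
                imprinting_map(ctx, grammar, config.upstream_window, config.window_nt)
            )
        variants = pd.DataFrame(
            variant_rows,
            columns=["gene_id", "kind", "position", "ref_base", "alt_base",
                     "equivalence_class_id", "creates_inframe_motif",
                     "resulting_isoform_tail", "resulting_seq"],
        )
        imprinting = pd.DataFrame(
            imprint_rows,
            columns=["gene_id", "frame", "motif_start", "tripeptide",
                     "hit_interrupted", "linked_classes",
                     "premature_stop_classes", "n_deletion_classes"],
        )
        for col in ("linked_classes", "premature_stop_classes"):
            if len(imprinting):
                imprinting[col] = imprinting[col].map(",".join)
        log.append(f"imprint: {len(variants)} variant events, "
                   f"{len(imprinting)} +1-frame hits mapped")
    except Exception as exc:  # noqa: BLE001
        raise StageError("imprint", exc) from exc

    try:
        site_rows = [
            {
                "gene_id": site.gene_id,
                "start": site.start,
                "end": site.end,
                "base": site.base,
                "run_length": site.run_length,
                "distance_to_stop": site.distance_to_stop,
            }
            for ctx in contexts
            for site in find_slippage_sites(ctx, config.min_run, config.upstream_window)
        ]
        sites = pd.DataFrame(
            site_rows,
            columns=["gene_id", "start", "end", "base", "run_length",
                     "distance_to_stop"],
        )
        log.append(f"slippage: {len(sites)} homopolymer sites (min_run={config.min_run})")
    except Exception as exc:  # noqa: BLE001
        raise StageError("slippage", exc) from exc

    conservation = None
    if config.orthologs is not None:
        try:
            orth = read_ortholog_table(config.orthologs)
            conservation = conservation_report(
                {config.species: hits}, orth, m=config.conservation_m
            )
            log.append(f"conserve: {len(conservation)} ortholog groups with hits")
        except Exception as exc:  # noqa: BLE001
            raise StageError("conserve", exc) from exc

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_hits(hits, outdir / "hits.tsv")
    write_variants(variants, outdir / "variants.tsv")
    imprinting.sort_values(["gene_id", "motif_start"], kind="mergesort").to_csv(
        outdir / "imprinting.tsv", sep="\t", index=False
    )
    sites.sort_values(["gene_id", "start"], kind="mergesort").to_csv(
        outdir / "sites.tsv", sep="\t", index=False
    )
    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)
    if conservation is not None:
        conservation.to_csv(outdir / "conservation.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    return outdir
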