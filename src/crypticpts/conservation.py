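"""Per-genome prevalence summaries and cross-species motif conservation.

Cryptic motifs under functional selection are expected to recur in orthologs
of related species, most stringently with the identical tripeptide. This
module aggregates per-species hit tables over an ortholog table and flags
groups whose motif is present in at least ``m`` species.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Mapping

import pandas as pd

logger = logging.getLogger("crypticpts")

ORTHOLOG_COLUMNS = ["ortholog_group_id", "species", "gene_id"]


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns ortholog_group_id, species, gene_id; pairs unique."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in ORTHOLOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ortholog table lacks columns: {missing}")
    dup = df.duplicated(subset=["species", "gene_id"])
    if dup.any():
        raise ValueError("ortholog table has duplicate (species, gene_id) pairs")
    return df[ORTHOLOG_COLUMNS]


def summarize_genome(hits: pd.DataFrame, n_genes_total: int) -> dict:
    """Prevalence summary for one genome's hit table.

    ``fraction_with_candidate`` counts genes with at least one hit,
    interrupted or not. The interrupted share is reported under two
    definitions, since "fraction interrupted" can be read per hit or per
    gene: ``fraction_interrupted_hits`` (interrupted hits / all hits) and
    ``fraction_interrupted_genes`` (genes whose every hit is interrupted /
    genes with a hit).
    """
    if n_genes_total <= 0:
        raise ValueError("n_genes_total must be positive")
    n_hits = int(len(hits))
    if n_hits == 0:
        return {
            "n_genes_scanned": n_genes_total,
            "n_genes_with_hit": 0,
            "fraction_with_candidate": 0.0,
            "n_hits": 0,
            "n_hits_interrupted": 0,
            "fraction_interrupted_hits": 0.0,
            "fraction_interrupted_genes": 0.0,
        }
    genes_with_hit = hits["gene_id"].nunique()
    n_interrupted = int(hits["interrupted"].sum())
    all_interrupted = hits.groupby("gene_id")["interrupted"].all()
    return {
        "n_genes_scanned": n_genes_total,
        "n_genes_with_hit": int(genes_with_hit),
        "fraction_with_candidate": genes_with_hit / n_genes_total,
        "n_hits": n_hits,
        "n_hits_interrupted": n_interrupted,
        "fraction_interrupted_hits": n_interrupted / n_hits,
        "fraction_interrupted_genes": float(all_interrupted.sum()) / genes_with_hit,
    }


def conservation_report(
    hits_by_species: Mapping[str, pd.DataFrame],
    orthologs: pd.DataFrame,
    m: int = 2,
    require_same_tripeptide: bool = True,
) -> pd.DataFrame:
    """Cross-species conservation of cryptic motifs within ortholog groups.

    A group is ``conserved`` when hits occur in at least ``m`` species — with
    the identical tripeptide when ``require_same_tripeptide`` (the default,
    the stringent reading under which e.g. an SHL* motif shared by all four
    post-duplication species stands out). Genes with hits but absent from the
    ortholog table become singleton groups with a logged warning. Output is
    deterministic, sorted by group id; species input order is irrelevant.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    gene_to_group = {
        (r.species, r.gene_id): r.ortholog_group_id
        for r in orthologs.itertuples(index=False)
    }
    groups: dict[str, dict] = {}
    for species in sorted(hits_by_species):
        hits = hits_by_species[species]
        for row in hits.itertuples(index=False):
            key = (species, row.gene_id)
            group = gene_to_group.get(key)
            if group is None:
                group = f"singleton:{species}:{row.gene_id}"
                logger.warning(
                    "gene %r (%s) absent from ortholog table; counted as singleton",
                    row.gene_id, species,
                )
            entry = groups.setdefault(
                group,
                {"species_tripeptides": set(), "tripeptides": Counter(),
                 "frames": set(), "genes": set()},
            )
            entry["species_tripeptides"].add((species, row.tripeptide))
            entry["tripeptides"][row.tripeptide] += 1
            entry["frames"].add(int(row.frame))
            entry["genes"].add(f"{species}:{row.gene_id}")
    rows = []
    for group_id in sorted(groups):
        entry = groups[group_id]
        species_with_hit = sorted({sp for sp, _ in entry["species_tripeptides"]})
        if require_same_tripeptide:
            tri_species: dict[str, set] = {}
            for sp, tri in entry["species_tripeptides"]:
                tri_species.setdefault(tri, set()).add(sp)
            conserved = any(len(sps) >= m for sps in tri_species.values())
        else:
            conserved = len(species_with_hit) >= m
        rows.append(
            {
                "ortholog_group_id": group_id,
                "n_species_with_hit": len(species_with_hit),
                "species_with_hit": ",".join(species_with_hit),
                "tripeptides": ",".join(
                    f"{t}:{n}" for t, n in sorted(entry["tripeptides"].items())
                ),
                "frames": ",".join(str(f) for f in sorted(entry["frames"])),
                "genes": ",".join(sorted(entry["genes"])),
                "conserved": conserved,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "ortholog_group_id", "n_species_with_hit", "species_with_hit",
            "tripeptides", "frames", "genes", "conserved",
        ],
    )
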