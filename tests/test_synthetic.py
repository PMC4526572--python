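import filecmp

import pandas as pd
import pytest

from crypticpts.frameshift import find_slippage_sites
from crypticpts.io_formats import read_context_fasta
from crypticpts.motif import UNION_GRAMMAR
from crypticpts.scanner import scan_context, scan_contexts, scan_genome
from crypticpts.synthetic import PlantSpec, generate, make_example_fixtures


def _truth_tuples(truth: pd.DataFrame) -> dict[str, set]:
    out = {}
    for row in truth.itertuples():
        out[row.gene_id] = (
            {(row.frame, row.motif_start, row.tripeptide, row.interrupted)}
            if row.planted
            else set()
        )
    return out


def test_generation_is_deterministic_under_seed(tmp_path):
    spec = PlantSpec(n_genes=40, seed=7)
    generate(spec, outdir=tmp_path / "a")
    generate(spec, outdir=tmp_path / "b")
    for name in ("genome.fasta", "genes.gff3", "contexts.fasta", "truth.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name, shallow=False)
    generate(PlantSpec(n_genes=40, seed=8), outdir=tmp_path / "c")
    assert not filecmp.cmp(
        tmp_path / "a" / "genome.fasta", tmp_path / "c" / "genome.fasta", shallow=False
    )


def test_interrupted_count_is_exact_by_construction():
    spec = PlantSpec(n_genes=80, fraction_planted=0.5, fraction_interrupted=0.5, seed=2)
    data = generate(spec)
    planted = data.truth[data.truth.planted]
    assert len(planted) == 40
    assert int(planted.interrupted.sum()) == 20


def hit_tuples_without_stop(hits):
    return {(h.frame, h.motif_start, h.tripeptide, h.interrupted) for h in hits}


def test_planted_recovery_with_truth_table():
    data = generate(PlantSpec(n_genes=60, seed=19))
    truth = _truth_tuples(data.truth)
    for ctx in data.contexts:
        assert hit_tuples_without_stop(scan_context(ctx, UNION_GRAMMAR)) == truth[ctx.gene_id]


def test_summary_fractions_equal_spec_proportions():
    spec = PlantSpec(n_genes=100, fraction_planted=0.2, fraction_interrupted=0.25, seed=3)
    data = generate(spec)
    _, summary = scan_contexts(data.contexts, UNION_GRAMMAR)
    assert summary["fraction_with_candidate"] == pytest.approx(0.2)
    assert summary["fraction_interrupted_hits"] == pytest.approx(0.25)


def test_slippage_run_planted_and_detected():
    spec = PlantSpec(n_genes=30, fraction_planted=0.5, slippage_run=("T", 6), seed=5)
    data = generate(spec)
    ctx_by_id = {c.gene_id: c for c in data.contexts}
    planted = data.truth[data.truth.planted]
    assert (planted.slippage_run_length == 6).all()
    for gene_id in planted.gene_id:
        sites = find_slippage_sites(ctx_by_id[gene_id], min_run=6)
        assert any(s.base == "T" and s.run_length == 6 for s in sites)


def test_genome_files_round_trip_through_scan(tmp_path):
    out = generate(PlantSpec(n_genes=25, seed=4, minus_strand_fraction=0.4),
                   outdir=tmp_path)
    hits, summary, _ = scan_genome(tmp_path / "genome.fasta", tmp_path / "genes.gff3")
    truth = pd.read_csv(tmp_path / "truth.tsv", sep="\t")
    planted = truth[truth.planted]
    got = {
        (r.gene_id, r.frame, r.motif_start, r.tripeptide, r.interrupted)
        for r in hits.itertuples()
    }
    expected = {
        (r.gene_id, r.frame, r.motif_start, r.tripeptide, r.interrupted)
        for r in planted.itertuples()
    }
    assert got == expected
    # the context FASTA carries the same sequences the scanner used
    ctxs = read_context_fasta(tmp_path / "contexts.fasta")
    assert len(ctxs) == 25


def test_infeasible_specs_error():
    with pytest.raises(ValueError):
        PlantSpec(offset_range=(0, 40))  # beyond the scan window
    with pytest.raises(ValueError):
        PlantSpec(fraction_planted=1.2)
    with pytest.raises(ValueError):
        generate(PlantSpec(n_genes=4, tripeptide_pool=("GGG",), seed=0))


def test_example_fixtures_written_and_reloadable(tmp_path):
    fixtures = make_example_fixtures(outdir=tmp_path)
    back = {c.gene_id: c for c in read_context_fasta(tmp_path / "examples.fasta")}
    assert set(back) == set(fixtures)
    for name, ctx in fixtures.items():
        assert back[name].seq == ctx.seq and back[name].stop_start == ctx.stop_start
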