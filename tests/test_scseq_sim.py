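"""Clonal expansion, depth, background expression, reads and run output."""

import gzip
import math

import numpy as np
import pytest
import yaml

from tcrforge import (
    CloneModel,
    DepthSpec,
    ExpressionModel,
    assign_clones,
    clone_sizes,
    fit_zipf_exponent,
    generate_reads,
    make_cells,
    merge_pseudobulk,
    sample_depth,
    simulate_background,
    simulate_run,
    write_run,
)
from tcrforge.ref_model import reverse_complement
from tcrforge.scseq_sim import error_free_read, read_count_for


# ---------------------------------------------------------------------------
# clonal expansion


def test_clone_sizes_degenerate_limits():
    assert clone_sizes(10, 50.0).tolist() == [10]  # one dominant clone
    assert clone_sizes(10, 0.0).tolist() == [1] * 10  # uniform limit
    assert clone_sizes(7, 1.5).sum() == 7


def test_rank_size_slope_recovers_exponent():
    est = fit_zipf_exponent(clone_sizes(2000, 1.2))
    assert est == pytest.approx(1.2, abs=0.15)


def test_assign_clones_shares_rearrangements(cache, bundle, rng):
    cells = make_cells(30, bundle, cache, rng)
    assign_clones(cells, CloneModel(zipf_exponent=2.0), cache, rng)
    by_clone = {}
    for cell in cells:
        by_clone.setdefault(cell.clone_id, []).append(cell)
    assert sum(len(v) for v in by_clone.values()) == 30
    for members in by_clone.values():
        first = members[0]
        for other in members[1:]:
            assert other.tra.event.cdr3_aa == first.tra.event.cdr3_aa
            assert other.trb.event.cdr3_nt == first.trb.event.cdr3_nt
            assert other.barcode != first.barcode  # barcodes stay per-cell
            assert other.tra.cell_barcode == other.barcode


# ---------------------------------------------------------------------------
# depth


def test_depth_spec_modes(rng):
    fixed = sample_depth(DepthSpec.parse("fixed:400"), rng, n=100)
    assert (fixed == 400).all()
    uniform = sample_depth(DepthSpec.parse("uniform:2:100"), rng, n=10_000)
    assert uniform.min() >= 2 and uniform.max() <= 100
    assert 49 <= uniform.mean() <= 53  # mean of U(2, 100) is 51
    with pytest.raises(ValueError):
        DepthSpec.parse("banana:1")
    with pytest.raises(ValueError):
        DepthSpec(mode="uniform", low=10, high=2)


# ---------------------------------------------------------------------------
# background expression


def _dummy_cells(n):
    class _C:  # only cell_id is consulted by the background sampler
        def __init__(self, i):
            self.cell_id = f"cell_{i:05d}"

    return [_C(i) for i in range(n)]


def test_background_scaling_fixed_point(rng):
    model = ExpressionModel.synthetic(rng, n_genes=1, dispersion=0.0)
    depths = simulate_background(model, _dummy_cells(50), rng)
    for per_gene in depths.values():
        assert per_gene[model.gene_names[0]] == pytest.approx(1.0, abs=1e-9)


def test_background_grand_mean_is_one(rng):
    model = ExpressionModel.synthetic(rng, n_genes=20, dispersion=0.5)
    depths = simulate_background(model, _dummy_cells(1000), rng)
    matrix = np.array([[depths[c][g] for g in model.gene_names] for c in depths])
    assert matrix.mean() == pytest.approx(1.0, abs=1e-6)
    assert matrix.mean(axis=0) == pytest.approx(np.ones(20), abs=1e-9)


def test_background_is_overdispersed(rng):
    model = ExpressionModel.synthetic(rng, n_genes=200, dispersion=0.5)
    depths = simulate_background(model, _dummy_cells(100), rng)
    matrix = np.array([[depths[c][g] for g in model.gene_names] for c in depths])
    assert matrix.var() / matrix.mean() > 1.0


def test_background_disabled_without_genes(rng):
    assert simulate_background(None, _dummy_cells(3), rng) == {}


def test_expression_model_from_counts(tmp_path, rng):
    import pandas as pd

    counts = pd.DataFrame(
        {"c1": [5, 0, 2], "c2": [3, 0, 4]}, index=["G1", "G2", "G3"]
    )
    path = tmp_path / "counts.tsv"
    counts.to_csv(path, sep="\t")
    model = ExpressionModel.from_counts(path, rng=rng)
    assert model.gene_names == ["G1", "G3"]  # all-zero gene dropped
    assert model.mean_depths["G1"] == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# read generation


def test_read_count_arithmetic():
    assert read_count_for(400, 600, 150, 1) == 1600
    assert read_count_for(400, 600, 150, 2) == 800
    assert read_count_for(2, 30, 150, 1) == 1  # minimum one read
    assert read_count_for(0, 600, 150, 1) == 0


def test_error_free_reads_are_template_substrings(rng):
    template = "".join("ACGT"[b] for b in rng.integers(4, size=400))
    reads = generate_reads(template, 10, 100, "PE", 0.0, rng, template_id="t")
    assert len(reads) == 2 * read_count_for(10, 400, 100, 2)
    for r in reads:
        if r.mate == 1:
            assert r.sequence == template[:100]
        else:
            assert r.sequence == reverse_complement(template)[:100]
            assert r.start == 300 and r.strand == "-"
        assert r.error_positions == ()
        assert len(r.quality) == 100


def test_error_injection_rate_and_provenance(rng):
    template = "".join("ACGT"[b] for b in rng.integers(4, size=1000))
    reads = generate_reads(template, 60, 250, "SE", 0.01, rng, template_id="t")
    n_mismatch = n_bases = 0
    for r in reads:
        clean = error_free_read(r, template)
        observed = {i for i, (a, b) in enumerate(zip(clean, r.sequence)) if a != b}
        assert observed == set(r.error_positions)  # provenance reconstructs
        n_mismatch += len(observed)
        n_bases += len(r.sequence)
    assert n_mismatch / n_bases == pytest.approx(0.01, abs=0.005)


def test_short_template_is_skipped():
    rng = np.random.default_rng(0)
    assert generate_reads("ACGT" * 10, 5, 150, "SE", 0.0, rng) == []


def test_quality_string_tracks_error_rate(rng):
    (read,) = generate_reads("A" * 200, 1, 200, "SE", 0.001, rng)
    assert read.quality == chr(33 + 30) * 200
    (read,) = generate_reads("A" * 200, 1, 200, "SE", 0.0, rng)
    assert read.quality == chr(33 + 41) * 200


# ---------------------------------------------------------------------------
# run output


@pytest.fixture()
def small_run(cache, bundle):
    rng = np.random.default_rng(77)
    cells = make_cells(5, bundle, cache, rng)
    return simulate_run(
        cells, DepthSpec(mode="fixed", value=20), 120, "PE", 0.0, rng,
        config={"seed": 77},
    )


def test_write_run_per_cell_layout(small_run, tmp_path):
    manifest = write_run(small_run, tmp_path, layout="per-cell")
    fastqs = sorted(tmp_path.glob("*_R1.fastq"))
    assert len(fastqs) == 5
    total = sum(len(v) for v in small_run.reads.values())
    assert manifest["n_reads"] == total
    n_lines = sum(
        len(p.read_text().splitlines()) for p in tmp_path.glob("*.fastq")
    )
    assert n_lines == 4 * total
    # every read id is resolvable to a template recorded in the manifest
    for path in tmp_path.glob("*_R1.fastq"):
        for line in path.read_text().splitlines()[::4]:
            template_id = line[1:].split(" ")[0].rsplit(":", 1)[0]
            assert template_id in manifest["template_lengths"]
    assert (tmp_path / "manifest.yaml").exists()
    assert (tmp_path / "ground_truth.tsv").exists()
    assert (tmp_path / "amplicons.fasta").exists()


def test_write_run_gzip_round_trip(small_run, tmp_path):
    write_run(small_run, tmp_path / "plain", layout="barcoded-merged", gzip_out=False)
    write_run(small_run, tmp_path / "zipped", layout="barcoded-merged", gzip_out=True)
    plain = (tmp_path / "plain" / "merged_R1.fastq").read_bytes()
    zipped = gzip.decompress((tmp_path / "zipped" / "merged_R1.fastq.gz").read_bytes())
    assert plain == zipped


def test_realized_depth_within_one_read_equivalent(small_run):
    for tid, template in small_run.templates.items():
        cell = small_run.template_cell[tid]
        total_nt = sum(
            len(r.sequence) for r in small_run.reads[cell] if r.template_id == tid
        )
        realized = total_nt / len(template)
        assert abs(realized - small_run.depths[tid]) <= 2 * 120 / len(template)


def test_merge_pseudobulk(tmp_path, rng):
    paths = []
    for i in range(6):
        p = tmp_path / f"cell{i}.fastq"
        p.write_text(f"@r{i}\nACGT\n+\nIIII\n")
        paths.append(p)
    out = tmp_path / "bulk.fastq"
    chosen = merge_pseudobulk(paths, 3, np.random.default_rng(3), out)
    merged = out.read_text()
    assert merged == "".join(p.read_text() for p in chosen)
    chosen2 = merge_pseudobulk(paths, 3, np.random.default_rng(3), tmp_path / "b2.fastq")
    assert [p.name for p in chosen] == [p.name for p in chosen2]

    everything = merge_pseudobulk(paths, 6, np.random.default_rng(0), tmp_path / "all.fastq")
    assert len(everything) == 6
    with pytest.raises(ValueError):
        merge_pseudobulk(paths, 7, rng, tmp_path / "x.fastq")
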