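"""From ground-truth contigs to sequencing data.

Covers clonal expansion (rank-size power law), per-contig sequencing
depth (fixed or uniform), an optional background of non-TCR transcripts
scaled to a mean depth of 1x per gene per cell, amplicon-style read
generation with i.i.d. substitution errors, FASTQ output in per-cell or
barcoded-merged layouts, and pseudo-bulk concatenation.

Read generation follows amplicon semantics: single-end reads start at the
template 5' end; for paired ends, mate 1 starts at the 5' end and mate 2
is the reverse complement anchored at the 3' end. The read count per
template is round(depth * template_len / (read_len * mates)), at least
one read for any positive depth.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .rearrange import CellTCR, assemble_contig, write_ground_truth
from .ref_model import TCRCache, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# clonal expansion


@dataclass
class CloneModel:
    """Rank-size power law for clone sizes: size(r) proportional to r^-s."""

    zipf_exponent: float = 1.5


def clone_sizes(n_cells: int, exponent: float) -> np.ndarray:
    """Deterministic integer clone sizes summing to ``n_cells``.

    The r-th largest clone is proportional to r**(-exponent), discretized
    by rounding with the clone count chosen self-consistently; the
    residual after rounding is folded into the largest clones.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    if exponent == 0:
        k = n_cells
        base = np.full(k, n_cells // k, dtype=int)
        base[: n_cells % k] += 1
        return base
    n_clones = n_cells
    sizes = np.array([n_cells])
    for _ in range(100):
        ranks = np.arange(1, n_clones + 1, dtype=float)
        weights = ranks ** (-exponent)
        sizes = np.rint(n_cells * weights / weights.sum()).astype(int)
        surviving = max(1, int((sizes > 0).sum()))
        if surviving == n_clones:
            break
        n_clones = surviving
    sizes = np.maximum(sizes[:n_clones], 1)
    deficit = n_cells - int(sizes.sum())
    i = 0
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        if sizes[i % n_clones] + step >= 1:
            sizes[i % n_clones] += step
            deficit -= step
        i += 1
    return np.sort(sizes)[::-1]


def fit_zipf_exponent(sizes: np.ndarray, min_size: int = 5) -> float:
    """Log-log rank-size regression slope (negated) over non-tiny clones."""
    sizes = np.sort(np.asarray(sizes))[::-1]
    keep = sizes >= min_size
    if keep.sum() < 3:
        raise ValueError("too few clones above min_size for a regression")
    ranks = np.arange(1, len(sizes) + 1)[keep]
    slope = np.polyfit(np.log(ranks), np.log(sizes[keep]), 1)[0]
    return float(-slope)


def assign_clones(
    cells: list[CellTCR],
    clone_model: CloneModel,
    cache: TCRCache,
    rng: np.random.Generator,
) -> list[CellTCR]:
    """Group cells into clones; clone members share both rearrangements.

    Clone sizes follow the model's power law; membership is a random
    partition. Each member's contigs are rebuilt from the clone
    representative's events with the member's own barcode.
    """
    sizes = clone_sizes(len(cells), clone_model.zipf_exponent)
    order = rng.permutation(len(cells))
    cursor = 0
    for clone_id, size in enumerate(sizes):
        members = order[cursor:cursor + size]
        cursor += size
        rep = cells[members[0]]
        for idx in members:
            cell = cells[idx]
            cell.clone_id = clone_id
            if idx != members[0]:
                cell.tra = assemble_contig(
                    rep.tra.event, cache, cell.barcode,
                    c_len=rep.tra.c_len, orient_5prime=rep.tra.is_5prime,
                )
                cell.trb = assemble_contig(
                    rep.trb.event, cache, cell.barcode,
                    c_len=rep.trb.c_len, orient_5prime=rep.trb.is_5prime,
                )
    return cells


# ---------------------------------------------------------------------------
# sequencing depth


@dataclass
class DepthSpec:
    """Per-contig sequencing depth: a constant or uniform on [low, high]."""

    mode: str = "uniform"  # fixed | uniform
    value: float = 0.0
    low: float = 2.0
    high: float = 100.0

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "uniform"):
            raise ValueError(f"unknown depth mode {self.mode!r}")
        if self.mode == "fixed" and self.value <= 0:
            raise ValueError("fixed depth must be positive")
        if self.mode == "uniform" and not 0 < self.low <= self.high:
            raise ValueError("uniform depth needs 0 < low <= high")

    @classmethod
    def parse(cls, text: str) -> "DepthSpec":
        """Parse 'fixed:400' or 'uniform:2:100'."""
        parts = text.split(":")
        if parts[0] == "fixed" and len(parts) == 2:
            return cls(mode="fixed", value=float(parts[1]))
        if parts[0] == "uniform" and len(parts) == 3:
            return cls(mode="uniform", low=float(parts[1]), high=float(parts[2]))
        raise ValueError(f"cannot parse depth spec {text!r}")


def sample_depth(spec: DepthSpec, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    if spec.mode == "fixed":
        return np.full(n, spec.value)
    return rng.uniform(spec.low, spec.high, size=n)


# ---------------------------------------------------------------------------
# background expression


@dataclass
class ExpressionModel:
    """Non-TCR transcript pool with per-gene mean depths.

    A stand-in for copula-based expression simulators: per-gene means are
    drawn log-normally (or taken from a user count table) and per-cell
    depths are gamma-Poisson (negative binomial) around them. The
    contract that matters downstream is the exact rescaling of each gene
    to a mean depth of 1x per cell.
    """

    gene_names: list[str]
    transcripts: dict[str, str]  # reverse-complemented for 5' amplification
    mean_depths: dict[str, float]
    dispersion: float = 0.5

    @classmethod
    def synthetic(
        cls,
        rng: np.random.Generator,
        n_genes: int = 200,
        transcript_len: int = 1000,
        dispersion: float = 0.5,
        lognormal_sigma: float = 1.0,
    ) -> "ExpressionModel":
        names = [f"GENE{i + 1:04d}" for i in range(n_genes)]
        transcripts = {
            name: reverse_complement(
                "".join("ACGT"[b] for b in rng.integers(4, size=transcript_len))
            )
            for name in names
        }
        means = np.exp(rng.normal(0.0, lognormal_sigma, size=n_genes))
        return cls(
            gene_names=names,
            transcripts=transcripts,
            mean_depths={n: float(m) for n, m in zip(names, means)},
            dispersion=dispersion,
        )

    @classmethod
    def from_counts(
        cls,
        counts,  # genes x cells DataFrame, or path to TSV / MatrixMarket
        transcripts: dict[str, str] | None = None,
        transcript_len: int = 1000,
        dispersion: float = 0.5,
        rng: np.random.Generator | None = None,
    ) -> "ExpressionModel":
        import pandas as pd

        if isinstance(counts, (str, Path)):
            path = Path(counts)
            if path.suffix == ".mtx":
                from scipy.io import mmread

                matrix = np.asarray(mmread(path).todense())
                counts = pd.DataFrame(
                    matrix, index=[f"GENE{i + 1:04d}" for i in range(matrix.shape[0])]
                )
            else:
                counts = pd.read_csv(path, sep="\t", index_col=0)
        means = counts.mean(axis=1)
        means = means[means > 0]
        if means.empty:
            raise ValueError("count table has no expressed genes")
        names = list(means.index.astype(str))
        if transcripts is None:
            rng = rng or np.random.default_rng(0)
            transcripts = {
                name: reverse_complement(
                    "".join("ACGT"[b] for b in rng.integers(4, size=transcript_len))
                )
                for name in names
            }
        return cls(
            gene_names=names,
            transcripts=transcripts,
            mean_depths={n: float(m) for n, m in means.items()},
            dispersion=dispersion,
        )


def simulate_background(
    expr_model: ExpressionModel | None,
    cells: list[CellTCR],
    rng: np.random.Generator,
) -> dict[str, dict[str, float]]:
    """Per-cell, per-gene background depths, scaled to a 1x mean per gene.

    Raw depths are gamma-Poisson around the model's gene means; each gene
    is then rescaled so its mean depth across cells is exactly 1x (genes
    sampled all-zero fall back to a flat 1x). Returns
    ``{cell_id: {gene: depth}}``; an empty model disables the background.
    """
    if expr_model is None or not expr_model.gene_names:
        return {}
    n_cells = len(cells)
    n_genes = len(expr_model.gene_names)
    means = np.array([expr_model.mean_depths[g] for g in expr_model.gene_names])
    phi = expr_model.dispersion
    if phi > 0:
        lam = rng.gamma(1.0 / phi, means[:, None] * phi, size=(n_genes, n_cells))
        raw = rng.poisson(lam).astype(float)
    else:
        raw = np.tile(means[:, None], (1, n_cells)).astype(float)
    gene_means = raw.mean(axis=1)
    zero = gene_means <= 0
    raw[zero, :] = 1.0
    gene_means[zero] = 1.0
    scaled = raw / gene_means[:, None]
    return {
        cell.cell_id: {
            gene: float(scaled[gi, ci]) for gi, gene in enumerate(expr_model.gene_names)
        }
        for ci, cell in enumerate(cells)
    }


# ---------------------------------------------------------------------------
# read generation


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    quality: str
    template_id: str
    start: int  # 0-based on the template's forward strand
    strand: str  # '+' or '-'
    mate: int  # 1 or 2
    error_positions: tuple[int, ...] = ()

    def provenance_comment(self) -> str:
        errors = ",".join(map(str, self.error_positions)) or "-"
        return f"template={self.template_id} start={self.start} strand={self.strand} errors={errors}"


def _phred_char(error_rate: float) -> str:
    if error_rate <= 0:
        q = 41
    else:
        q = int(round(-10.0 * math.log10(error_rate)))
    return chr(33 + min(41, max(2, q)))


def read_count_for(depth: float, template_len: int, read_len: int, mates: int) -> int:
    """round-half-away-from-zero(depth*len/(read_len*mates)), minimum 1."""
    if depth <= 0:
        return 0
    return max(1, int(math.floor(depth * template_len / (read_len * mates) + 0.5)))


def _inject_errors(
    base: np.ndarray, count: int, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    reads = np.tile(base, (count, 1))
    if error_rate <= 0:
        return reads, [()] * count
    mask = rng.random(reads.shape) < error_rate
    n_err = int(mask.sum())
    if n_err:
        # substitute with one of the three other bases, uniformly
        idx = np.searchsorted(_BASES, reads[mask])
        shift = rng.integers(1, 4, size=n_err)
        reads[mask] = _BASES[(idx + shift) % 4]
    positions = [tuple(np.flatnonzero(row).tolist()) for row in mask]
    return reads, positions


def generate_reads(
    template: str,
    depth: float,
    read_len: int,
    mode: str,
    error_rate: float,
    rng: np.random.Generator,
    template_id: str = "template",
) -> list[ReadRecord]:
    """Amplicon reads over ``template`` at the requested depth.

    Returns an empty list (a skipped template) when the template is
    shorter than the read length.
    """
    if mode not in ("SE", "PE"):
        raise ValueError(f"unknown mode {mode!r}")
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_len > len(template):
        return []
    mates = 2 if mode == "PE" else 1
    count = read_count_for(depth, len(template), read_len, mates)
    qual = _phred_char(error_rate) * read_len
    records: list[ReadRecord] = []

    fwd = np.frombuffer(template[:read_len].encode(), dtype=np.uint8).copy()
    reads1, errs1 = _inject_errors(fwd, count, error_rate, rng)
    if mates == 2:
        rc = reverse_complement(template)
        rev = np.frombuffer(rc[:read_len].encode(), dtype=np.uint8).copy()
        reads2, errs2 = _inject_errors(rev, count, error_rate, rng)
    for i in range(count):
        records.append(
            ReadRecord(
                read_id=f"{template_id}:{i}/1",
                sequence=reads1[i].tobytes().decode(),
                quality=qual,
                template_id=template_id,
                start=0,
                strand="+",
                mate=1,
                error_positions=errs1[i],
            )
        )
        if mates == 2:
            records.append(
                ReadRecord(
                    read_id=f"{template_id}:{i}/2",
                    sequence=reads2[i].tobytes().decode(),
                    quality=qual,
                    template_id=template_id,
                    start=len(template) - read_len,
                    strand="-",
                    mate=2,
                    error_positions=errs2[i],
                )
            )
    return records


def error_free_read(record: ReadRecord, template: str) -> str:
    """Reconstruct the error-free read from a record's provenance."""
    if record.strand == "+":
        return template[record.start:record.start + len(record.sequence)]
    segment = template[record.start:record.start + len(record.sequence)]
    return reverse_complement(segment)


# ---------------------------------------------------------------------------
# whole-run orchestration


@dataclass
class SimulatedRun:
    cells: list[CellTCR]
    templates: dict[str, str]  # template_id -> sequence
    template_cell: dict[str, str]  # template_id -> cell_id
    depths: dict[str, float]  # template_id -> requested depth
    reads: dict[str, list[ReadRecord]]  # cell_id -> reads
    config: dict
    n_skipped_templates: int = 0


def simulate_run(
    cells: list[CellTCR],
    depth_spec: DepthSpec,
    read_len: int,
    mode: str,
    error_rate: float,
    rng: np.random.Generator,
    background_depths: dict[str, dict[str, float]] | None = None,
    expr_model: ExpressionModel | None = None,
    config: dict | None = None,
) -> SimulatedRun:
    """Draw depths and generate reads for every contig (and background)."""
    templates: dict[str, str] = {}
    template_cell: dict[str, str] = {}
    for cell in cells:
        for contig in cell.contigs:
            tid = f"{cell.cell_id}|{contig.chain}"
            templates[tid] = contig.nt_seq
            template_cell[tid] = cell.cell_id
    tcr_ids = list(templates)
    tcr_depths = sample_depth(depth_spec, rng, n=len(tcr_ids))
    depths = {tid: float(d) for tid, d in zip(tcr_ids, tcr_depths)}

    if background_depths:
        if expr_model is None:
            raise ValueError("background depths given without an expression model")
        for cell in cells:
            for gene, depth in background_depths.get(cell.cell_id, {}).items():
                tid = f"{cell.cell_id}|{gene}"
                templates[tid] = expr_model.transcripts[gene]
                template_cell[tid] = cell.cell_id
                depths[tid] = depth

    reads: dict[str, list[ReadRecord]] = {cell.cell_id: [] for cell in cells}
    n_skipped = 0
    for tid in templates:
        if depths[tid] <= 0:
            continue
        recs = generate_reads(
            templates[tid], depths[tid], read_len, mode, error_rate, rng,
            template_id=tid,
        )
        if not recs:
            n_skipped += 1
            continue
        reads[template_cell[tid]].extend(recs)

    run_config = {
        "read_len": read_len,
        "mode": mode,
        "error_rate": error_rate,
        "depth": vars(depth_spec).copy(),
        "n_cells": len(cells),
    }
    run_config.update(config or {})
    return SimulatedRun(
        cells=cells,
        templates=templates,
        template_cell=template_cell,
        depths=depths,
        reads=reads,
        config=run_config,
        n_skipped_templates=n_skipped,
    )


def _fastq_open(path: Path, gzip_out: bool):
    if gzip_out:
        # fixed mtime so identical runs are byte-identical
        return gzip.GzipFile(filename="", mode="wb", fileobj=open(path, "wb"), mtime=0)
    return open(path, "wb")


def _write_fastq(path: Path, records: list[ReadRecord], gzip_out: bool) -> None:
    with _fastq_open(path, gzip_out) as out:
        chunks = [
            f"@{r.read_id} {r.provenance_comment()}\n{r.sequence}\n+\n{r.quality}\n"
            for r in records
        ]
        out.write("".join(chunks).encode())


def write_run(
    run: SimulatedRun,
    out_dir: str | Path,
    layout: str = "per-cell",
    gzip_out: bool = False,
) -> dict:
    """Write FASTQ files, ground truth, amplicon FASTA and a manifest.

    ``per-cell`` layout emits one FASTQ (pair) per cell named by cell id;
    ``barcoded-merged`` emits a single FASTQ (pair) for the whole run
    (barcodes live inside the contig sequence). Returns the manifest.
    """
    if layout not in ("per-cell", "barcoded-merged"):
        raise ValueError(f"unknown layout {layout!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paired = run.config["mode"] == "PE"
    suffix = ".fastq.gz" if gzip_out else ".fastq"

    fastq_files: dict[str, list[str]] = {}
    if layout == "per-cell":
        for cell in run.cells:
            recs = run.reads[cell.cell_id]
            files = []
            if paired:
                for mate in (1, 2):
                    path = out_dir / f"{cell.cell_id}_R{mate}{suffix}"
                    _write_fastq(path, [r for r in recs if r.mate == mate], gzip_out)
                    files.append(path.name)
            else:
                path = out_dir / f"{cell.cell_id}{suffix}"
                _write_fastq(path, recs, gzip_out)
                files.append(path.name)
            fastq_files[cell.cell_id] = files
    else:
        all_recs = [r for cell in run.cells for r in run.reads[cell.cell_id]]
        files = []
        if paired:
            for mate in (1, 2):
                path = out_dir / f"merged_R{mate}{suffix}"
                _write_fastq(path, [r for r in all_recs if r.mate == mate], gzip_out)
                files.append(path.name)
        else:
            path = out_dir / f"merged{suffix}"
            _write_fastq(path, all_recs, gzip_out)
            files.append(path.name)
        fastq_files["merged"] = files

    with open(out_dir / "amplicons.fasta", "w") as fasta:
        for tid, seq in run.templates.items():
            fasta.write(f">{tid}\n{seq}\n")
    write_ground_truth(run.cells, out_dir)

    manifest = {
        "config": run.config,
        "layout": layout,
        "gzip": gzip_out,
        "n_templates": len(run.templates),
        "n_skipped_templates": run.n_skipped_templates,
        "n_reads": sum(len(v) for v in run.reads.values()),
        "read_counts": {cid: len(run.reads[cid]) for cid in sorted(run.reads)},
        "template_lengths": {tid: len(seq) for tid, seq in sorted(run.templates.items())},
        "depths": {tid: run.depths[tid] for tid in sorted(run.depths)},
        "fastq_files": fastq_files,
    }
    with open(out_dir / "manifest.yaml", "w") as out:
        yaml.safe_dump(manifest, out, sort_keys=True)
    return manifest


def merge_pseudobulk(
    fastq_paths: list[str | Path],
    n_cells_select: int,
    rng: np.random.Generator,
    out: str | Path,
) -> list[Path]:
    """Concatenate a random cell subset's FASTQs into one pseudo-bulk file.

    Uniform sampling without replacement; byte-level concatenation (also
    valid for gzip members). The selection is written next to the output
    as ``<out>.selected.txt``. Oversampling is fatal.
    """
    paths = [Path(p) for p in fastq_paths]
    if n_cells_select > len(paths):
        raise ValueError(
            f"cannot select {n_cells_select} of {len(paths)} available cells"
        )
    chosen_idx = rng.choice(len(paths), size=n_cells_select, replace=False)
    chosen = [paths[i] for i in chosen_idx]
    out = Path(out)
    with open(out, "wb") as merged:
        for path in chosen:
            merged.write(path.read_bytes())
    selection_file = out.with_name(out.name + ".selected.txt")
    selection_file.write_text("".join(f"{p.name}\n" for p in chosen))
    return chosen
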