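"""Ground-truth TCR rearrangements and full-length 5' library contigs.

The generative recipe follows V(D)J recombination as seen at the protein
level: draw V and J genes from the usage model, clip germline residues at
the V-CDR3 and CDR3-J junctions, draw a CDR3 length and fill the interior
with residues from the positional composition tables, keeping the anchor
cysteine and the J-gene F/W anchor fixed. Incompatible draws (clipping
deeper than the germline allows, lengths too short for the retained
residues) are retried until a bounded budget is exhausted.

Nucleotide realization keeps germline codons for germline residues and
draws a uniform synonymous codon for sampled interior residues, so
productive junctions translate back exactly; non-productive events are
realized as frameshifts (junction length not a multiple of 3).

Contigs mirror a 5' 10X-style library: cell barcode block, clipped V,
junction, clipped J and ~50 bp of the C segment, stored reverse-
complemented for 5' amplification.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .ref_model import CODONS_BY_AA, TCRCache, reverse_complement, translate
from .stat_models import CHAINS, ModelBundle, sample_categorical

_BASES = "ACGT"
DEFAULT_C_LEN = 50
DEFAULT_BARCODE_LEN = 16


class RetryBudgetExceeded(RuntimeError):
    """The bundle cannot produce a feasible rearrangement for this cache."""


@dataclass
class RearrangementEvent:
    chain: str
    v_name: str
    j_name: str
    v_del: int
    j_del: int
    cdr3_aa: str
    productive: bool
    cdr3_nt: str = ""


@dataclass
class TCRContig:
    cell_barcode: str
    chain: str
    event: RearrangementEvent
    nt_seq: str  # final template (reverse-complemented when is_5prime)
    is_5prime: bool
    c_len: int
    umi: str = ""

    @property
    def forward_seq(self) -> str:
        """The pre-orientation (mRNA-sense) contig sequence."""
        return reverse_complement(self.nt_seq) if self.is_5prime else self.nt_seq


@dataclass
class CellTCR:
    cell_id: str
    barcode: str
    tra: TCRContig
    trb: TCRContig
    clone_id: int = 0

    @property
    def contigs(self) -> tuple[TCRContig, TCRContig]:
        return (self.tra, self.trb)


def sample_rearrangement(
    bundle: ModelBundle,
    cache: TCRCache,
    chain: str,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> RearrangementEvent:
    """Draw one rearrangement for ``chain``, retrying incompatible draws."""
    for _ in range(max_retries):
        v_name = sample_categorical(bundle.usage.v[chain], rng)
        j_name = sample_categorical(bundle.usage.j[chain], rng)
        v_del = int(sample_categorical(bundle.clip.dists[chain]["v"], rng))
        j_del = int(sample_categorical(bundle.clip.dists[chain]["j"], rng))
        length = int(sample_categorical(bundle.cdr3.length[chain], rng))

        v_seg = cache.segments[v_name]
        j_seg = cache.segments[j_name]
        v_tail = v_seg.aa_seq[cache.anchor_index[v_name] + 1:]
        j_head = j_seg.aa_seq[: cache.anchor_index[j_name]]
        if v_del > len(v_tail) or j_del > len(j_head):
            continue  # clip deeper than the germline allows
        retained_v = v_tail[: len(v_tail) - v_del]
        retained_j = j_head[j_del:]
        n_interior = length - 2 - len(retained_v) - len(retained_j)
        if n_interior < 0:
            continue  # length cannot accommodate the retained residues

        interior = "".join(
            sample_categorical(
                bundle.cdr3.regions[chain][
                    bundle.cdr3.region_of(1 + len(retained_v) + i, length)
                ],
                rng,
            )
            for i in range(n_interior)
        )
        anchor = cache.anchor_residue(j_name)
        cdr3_aa = "C" + retained_v + interior + retained_j + anchor
        productive = bool(rng.random() < bundle.p_productive)
        return RearrangementEvent(
            chain=chain,
            v_name=v_name,
            j_name=j_name,
            v_del=v_del,
            j_del=j_del,
            cdr3_aa=cdr3_aa,
            productive=productive,
        )
    raise RetryBudgetExceeded(
        f"no feasible rearrangement for {chain} within {max_retries} tries; "
        "check that the bundle's clip/length support fits the cache"
    )


def realize_nt(
    event: RearrangementEvent, cache: TCRCache, rng: np.random.Generator
) -> RearrangementEvent:
    """Pick a nucleotide realization of ``event.cdr3_aa``.

    Germline-retained residues (anchors included) keep their germline
    codons; sampled interior residues get a uniform synonymous codon.
    Non-productive events lose one random junction nucleotide, shifting
    the downstream frame.
    """
    v_seg = cache.segments[event.v_name]
    j_seg = cache.segments[event.j_name]
    v_anchor = cache.anchor_index[event.v_name]
    j_anchor = cache.anchor_index[event.j_name]
    v_tail_len = len(v_seg.aa_seq) - v_anchor - 1
    retained_v = v_tail_len - event.v_del
    j_head_len = j_anchor
    retained_j = j_head_len - event.j_del
    n_interior = len(event.cdr3_aa) - 2 - retained_v - retained_j

    codons: list[str] = [v_seg.codon(v_anchor)]
    for i in range(retained_v):
        codons.append(v_seg.codon(v_anchor + 1 + i))
    for i in range(n_interior):
        aa = event.cdr3_aa[1 + retained_v + i]
        options = CODONS_BY_AA[aa]
        codons.append(options[rng.integers(len(options))])
    for i in range(retained_j):
        codons.append(j_seg.codon(event.j_del + i))
    codons.append(j_seg.codon(j_anchor))
    cdr3_nt = "".join(codons)
    if not event.productive:
        drop = int(rng.integers(len(cdr3_nt)))
        cdr3_nt = cdr3_nt[:drop] + cdr3_nt[drop + 1:]
    return replace(event, cdr3_nt=cdr3_nt)


def clipped_v_nt(event: RearrangementEvent, cache: TCRCache) -> str:
    """V-segment nucleotides 5' of the junction (anchor codon excluded)."""
    v_seg = cache.segments[event.v_name]
    return v_seg.nt_seq[: v_seg.frame_offset + 3 * cache.anchor_index[event.v_name]]


def clipped_j_nt(event: RearrangementEvent, cache: TCRCache) -> str:
    """J-segment nucleotides 3' of the junction (anchor codon excluded)."""
    j_seg = cache.segments[event.j_name]
    start = j_seg.frame_offset + 3 * (cache.anchor_index[event.j_name] + 1)
    return j_seg.nt_seq[start:]


def assemble_contig(
    event: RearrangementEvent,
    cache: TCRCache,
    barcode: str,
    c_len: int = DEFAULT_C_LEN,
    orient_5prime: bool = True,
    umi: str = "",
) -> TCRContig:
    """Build the full mRNA contig and orient it for 5' amplification.

    Layout (mRNA sense): barcode [+ UMI] + clipped V + junction + clipped J
    + the first ``c_len`` nt of the chain's C segment, mimicking C-specific
    priming. With ``orient_5prime`` the stored template is the reverse
    complement of that sequence.
    """
    if not event.cdr3_nt:
        raise ValueError("event must be nucleotide-realized before assembly")
    c_seg = cache.c_segment(event.chain)
    if c_len > len(c_seg.nt_seq):
        raise ValueError(
            f"c_len {c_len} exceeds the {event.chain} C segment "
            f"({len(c_seg.nt_seq)} nt)"
        )
    forward = (
        barcode
        + umi
        + clipped_v_nt(event, cache)
        + event.cdr3_nt
        + clipped_j_nt(event, cache)
        + c_seg.nt_seq[:c_len]
    )
    return TCRContig(
        cell_barcode=barcode,
        chain=event.chain,
        event=event,
        nt_seq=reverse_complement(forward) if orient_5prime else forward,
        is_5prime=orient_5prime,
        c_len=c_len,
        umi=umi,
    )


def coding_frame_has_stop(event: RearrangementEvent, cache: TCRCache) -> bool:
    """True if the V-frame translation through the end of J hits a stop."""
    v_seg = cache.segments[event.v_name]
    cds = (
        clipped_v_nt(event, cache)[v_seg.frame_offset:]
        + event.cdr3_nt
        + clipped_j_nt(event, cache)
    )
    return "*" in translate(cds)


def _random_barcode(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(4, size=length))


def draw_barcodes(
    n: int,
    rng: np.random.Generator,
    length: int = DEFAULT_BARCODE_LEN,
    min_hamming: int = 0,
    max_redraws: int = 10000,
) -> list[str]:
    """Unique random barcodes, optionally separated by a Hamming distance."""
    barcodes: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(barcodes) < n:
        if attempts > max_redraws + n:
            raise RuntimeError("barcode collision budget exhausted")
        attempts += 1
        bc = _random_barcode(rng, length)
        if bc in seen:
            continue
        if min_hamming > 1 and any(
            sum(a != b for a, b in zip(bc, other)) < min_hamming for other in barcodes
        ):
            continue
        seen.add(bc)
        barcodes.append(bc)
    return barcodes


def make_cells(
    n_cells: int,
    bundle: ModelBundle,
    cache: TCRCache,
    rng: np.random.Generator,
    *,
    c_len: int = DEFAULT_C_LEN,
    orient_5prime: bool = True,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    min_hamming: int = 0,
) -> list[CellTCR]:
    """Simulate ``n_cells`` cells, each with one TRA and one TRB contig."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    barcodes = draw_barcodes(n_cells, rng, length=barcode_len, min_hamming=min_hamming)
    cells: list[CellTCR] = []
    for i, barcode in enumerate(barcodes):
        contigs = {}
        for chain in CHAINS:
            event = sample_rearrangement(bundle, cache, chain, rng)
            event = realize_nt(event, cache, rng)
            contigs[chain] = assemble_contig(
                event, cache, barcode, c_len=c_len, orient_5prime=orient_5prime
            )
        cells.append(
            CellTCR(
                cell_id=f"cell_{i:05d}",
                barcode=barcode,
                tra=contigs["TRA"],
                trb=contigs["TRB"],
                clone_id=i,
            )
        )
    return cells


# ---------------------------------------------------------------------------
# ground-truth export

TRUTH_COLUMNS = (
    "cell_id",
    "barcode",
    "chain",
    "v_call",
    "j_call",
    "junction_aa",
    "junction",
    "productive",
    "clone_id",
)


def write_ground_truth(cells: list[CellTCR], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the AIRR-style truth TSV and the annotated contig FASTA."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "ground_truth.tsv"
    fasta_path = out_dir / "contigs.fasta"
    with open(tsv_path, "w", newline="") as tsv, open(fasta_path, "w") as fasta:
        writer = csv.writer(tsv, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for cell in cells:
            for contig in cell.contigs:
                ev = contig.event
                writer.writerow(
                    [
                        cell.cell_id,
                        cell.barcode,
                        ev.chain,
                        ev.v_name,
                        ev.j_name,
                        ev.cdr3_aa,
                        ev.cdr3_nt,
                        "T" if ev.productive else "F",
                        cell.clone_id,
                    ]
                )
                header = f"{cell.cell_id}|{ev.chain}|{ev.v_name}|{ev.j_name}|{ev.cdr3_aa}"
                fasta.write(f">{header}\n{contig.nt_seq}\n")
    return tsv_path, fasta_path
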