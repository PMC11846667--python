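"""Gene-segment references and the codon-aware TCR cache.

A TCR rearrangement is assembled from germline V, J and C segments. To
simulate it at nucleotide level we need, for every segment, the reading
frame of its cDNA (found by locally aligning the three forward-frame
translations against the segment's peptide) and, for V/J segments, the
position of the conserved CDR3 anchor residue: the 3'-terminal cysteine
of the V gene, and the phenylalanine (tryptophan for TRAJ33, TRAJ38 and
TRAJ55) near the start of the J gene.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

#: J genes whose CDR3 anchor is tryptophan rather than phenylalanine.
SPECIAL_W_J = frozenset({"TRAJ33", "TRAJ38", "TRAJ55"})

#: Default mapping from segment-name prefix to (segment_type, chain).
DEFAULT_NAMING_RULES: dict[str, tuple[str, str]] = {
    "TRAV": ("V", "TRA"),
    "TRAJ": ("J", "TRA"),
    "TRAC": ("C", "TRA"),
    "TRBV": ("V", "TRB"),
    "TRBJ": ("J", "TRB"),
    "TRBC": ("C", "TRB"),
}

CACHE_SCHEMA_VERSION = 1

# codons per amino acid, standard genetic code, deterministic order
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


class FrameDetectionError(ValueError):
    """No reading frame of the cDNA aligns to the peptide above threshold."""


def subgroup_of(name: str) -> str:
    """IMGT subgroup: truncate a gene/allele name at the first '-' and '*'.

    >>> subgroup_of("TRBV6-1*01")
    'TRBV6'
    """
    return name.split("*")[0].split("-")[0]


def translate(nt_seq: str) -> str:
    """Translate a nucleotide string, dropping any trailing partial codon."""
    usable = len(nt_seq) - len(nt_seq) % 3
    return str(Seq(nt_seq[:usable]).translate())


def reverse_complement(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())


@dataclass(frozen=True)
class GeneSegment:
    """One germline V/J/C segment with its cDNA, peptide and codon frame."""

    name: str
    segment_type: str  # V | J | C
    chain: str  # TRA | TRB
    nt_seq: str
    aa_seq: str
    frame_offset: int  # nt index where codon 1 begins, in {0, 1, 2}

    @property
    def subgroup(self) -> str:
        return subgroup_of(self.name)

    @property
    def cds(self) -> str:
        return self.nt_seq[self.frame_offset:]

    def codon(self, aa_index: int) -> str:
        """Germline codon for peptide position ``aa_index`` (0-based)."""
        start = self.frame_offset + 3 * aa_index
        return self.nt_seq[start:start + 3]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "segment_type": self.segment_type,
            "chain": self.chain,
            "nt_seq": self.nt_seq,
            "aa_seq": self.aa_seq,
            "frame_offset": self.frame_offset,
        }


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_ALPHABET = set(_ALIGNER.substitution_matrix.alphabet)


def _sanitize(pep: str) -> str:
    return "".join(c if c in _ALPHABET else "X" for c in pep.upper())


def detect_frame(nt_seq: str, aa_seq: str, min_score: float = 10.0) -> tuple[int, float]:
    """Find the reading frame of ``nt_seq`` that encodes ``aa_seq``.

    Each of the three forward-frame translations is locally aligned
    (Smith-Waterman, BLOSUM62, gap open 10 / extend 1) against the
    peptide; the offset with the highest score wins, ties broken by the
    smaller offset.

    Returns ``(frame_offset, score)``; raises :class:`FrameDetectionError`
    when no frame scores at least ``min_score``.
    """
    if len(nt_seq) < 3:
        raise ValueError("nt_seq shorter than one codon")
    if not aa_seq:
        raise ValueError("empty peptide")
    target = _sanitize(aa_seq)
    best_offset, best_score = -1, -np.inf
    for offset in range(3):
        pep = _sanitize(translate(nt_seq[offset:]))
        if not pep:
            continue
        score = _ALIGNER.score(target, pep)
        if score > best_score:
            best_offset, best_score = offset, score
    if best_offset < 0 or best_score < min_score:
        raise FrameDetectionError(
            f"no reading frame aligns to the peptide (best score {best_score})"
        )
    return best_offset, float(best_score)


@dataclass
class TCRCache:
    """Frame- and anchor-annotated segment library used by the simulator."""

    segments: dict[str, GeneSegment]
    anchor_index: dict[str, int]  # peptide position of the CDR3 anchor, V and J only
    special_w_j: frozenset[str] = SPECIAL_W_J
    exclusions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.special_w_j = frozenset(self.special_w_j)

    def segments_of(self, segment_type: str, chain: str) -> list[GeneSegment]:
        return [
            s
            for s in self.segments.values()
            if s.segment_type == segment_type and s.chain == chain
        ]

    def c_segment(self, chain: str) -> GeneSegment:
        cs = self.segments_of("C", chain)
        if not cs:
            raise KeyError(f"no C segment for chain {chain}")
        return cs[0]

    def anchor_residue(self, name: str) -> str:
        seg = self.segments[name]
        return seg.aa_seq[self.anchor_index[name]]

    def expected_j_anchor(self, j_name: str) -> str:
        return "W" if subgroup_of(j_name) in self.special_w_j else "F"

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": CACHE_SCHEMA_VERSION,
            "segments": [s.to_dict() for s in self.segments.values()],
            "anchor_index": dict(sorted(self.anchor_index.items())),
            "special_w_j": sorted(self.special_w_j),
            "exclusions": list(self.exclusions),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TCRCache":
        if d.get("schema_version") != CACHE_SCHEMA_VERSION:
            raise ValueError(f"unsupported cache schema: {d.get('schema_version')}")
        segments = {s["name"]: GeneSegment(**s) for s in d["segments"]}
        return cls(
            segments=segments,
            anchor_index={k: int(v) for k, v in d["anchor_index"].items()},
            special_w_j=frozenset(d["special_w_j"]),
            exclusions=list(d.get("exclusions", [])),
        )

    @classmethod
    def load(cls, path: str | Path) -> "TCRCache":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicated segment name {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"empty reference: {path}")
    return records


def _classify(name: str, naming_rules: dict[str, tuple[str, str]]) -> tuple[str, str] | None:
    # longest matching prefix wins
    for prefix in sorted(naming_rules, key=len, reverse=True):
        if name.startswith(prefix):
            return naming_rules[prefix]
    return None


def _find_v_anchor(aa_seq: str) -> int | None:
    """V anchor = last cysteine of the V peptide."""
    idx = aa_seq.rfind("C")
    return idx if idx >= 0 else None


def _find_j_anchor(aa_seq: str, expected: str, window: int = 5) -> int | None:
    """J anchor = first expected residue within the first ``window`` positions."""
    idx = aa_seq[:window].find(expected)
    return idx if idx >= 0 else None


def build_tcr_cache(
    cdna_fasta: str | Path,
    pep_fasta: str | Path,
    naming_rules: dict[str, tuple[str, str]] | None = None,
    min_score: float = 10.0,
) -> TCRCache:
    """Pair cDNA and peptide references into an annotated segment cache.

    Segments whose name matches no naming rule, whose frame cannot be
    detected, or whose CDR3 anchor cannot be located are excluded (and
    listed in ``cache.exclusions``); an empty or duplicated reference is
    fatal.
    """
    naming_rules = naming_rules or DEFAULT_NAMING_RULES
    cdna = _read_fasta(cdna_fasta)
    pep = _read_fasta(pep_fasta)

    segments: dict[str, GeneSegment] = {}
    anchor_index: dict[str, int] = {}
    exclusions: list[str] = []
    for name in cdna:
        if name not in pep:
            exclusions.append(f"{name}: no paired peptide record")
            continue
        kind = _classify(name, naming_rules)
        if kind is None:
            exclusions.append(f"{name}: no naming rule matches")
            continue
        segment_type, chain = kind
        try:
            offset, _score = detect_frame(cdna[name], pep[name], min_score=min_score)
        except FrameDetectionError as exc:
            exclusions.append(f"{name}: {exc}")
            continue
        seg = GeneSegment(
            name=name,
            segment_type=segment_type,
            chain=chain,
            nt_seq=cdna[name],
            aa_seq=pep[name].upper(),
            frame_offset=offset,
        )
        if segment_type == "V":
            anchor = _find_v_anchor(seg.aa_seq)
            if anchor is None:
                exclusions.append(f"{name}: V segment has no cysteine anchor")
                continue
            anchor_index[name] = anchor
        elif segment_type == "J":
            expected = "W" if subgroup_of(name) in SPECIAL_W_J else "F"
            anchor = _find_j_anchor(seg.aa_seq, expected)
            if anchor is None:
                exclusions.append(
                    f"{name}: J segment lacks '{expected}' anchor in first 5 residues"
                )
                continue
            anchor_index[name] = anchor
        segments[name] = seg

    if not segments:
        raise ValueError("reference produced an empty cache")
    for line in exclusions:
        logger.warning("segment excluded: %s", line)
    return TCRCache(segments=segments, anchor_index=anchor_index, exclusions=exclusions)


# ---------------------------------------------------------------------------
# toy reference generator


def _random_peptide(rng: np.random.Generator, n: int, forbid: str = "") -> str:
    pool = [a for a in _AA20 if a not in forbid]
    return "".join(rng.choice(pool) for _ in range(n))


def _encode(rng: np.random.Generator, aa: str) -> str:
    return "".join(rng.choice(CODONS_BY_AA[a]) for a in aa)


def make_toy_reference(
    n_v: int,
    n_j: int,
    rng_seed: int,
    out_dir: str | Path,
    *,
    v_tail: int = 0,
    j_head: int = 0,
    v_core_len: int = 24,
    j_extra_len: int = 10,
    c_len_aa: int = 30,
    special_j: bool = False,
) -> tuple[Path, Path]:
    """Write a paired synthetic cDNA/peptide FASTA reference for both chains.

    Per chain, ``n_v`` V segments (random core, anchor cysteine, then
    ``v_tail`` germline residues available for junction clipping), ``n_j``
    J segments (``j_head`` clippable residues, the anchor, then a tail)
    and one C segment are produced, all in frame 0 and satisfying the
    anchor rules by construction. With ``special_j`` the first TRA J genes
    are named TRAJ33/TRAJ38/TRAJ55 and anchored on tryptophan.

    Deterministic for a given seed. Returns ``(cdna_path, pep_path)``.
    """
    if n_v < 1 or n_j < 1:
        raise ValueError("need at least one V and one J segment per chain")
    if j_head > 4:
        raise ValueError("j_head must leave the anchor within the first 5 residues")
    rng = np.random.default_rng(rng_seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries: list[tuple[str, str, str]] = []  # (name, nt, aa)
    for chain in ("TRA", "TRB"):
        for i in range(n_v):
            # tail after the anchor C must stay cysteine-free so the anchor
            # remains the last C of the peptide
            aa = (
                _random_peptide(rng, v_core_len)
                + "C"
                + _random_peptide(rng, v_tail, forbid="C")
            )
            entries.append((f"{chain}V{i + 1}", _encode(rng, aa), aa))
        special_names = ["TRAJ33", "TRAJ38", "TRAJ55"]
        for i in range(n_j):
            name = f"{chain}J{i + 1}"
            anchor = "F"
            if special_j and chain == "TRA" and i < len(special_names):
                name, anchor = special_names[i], "W"
            aa = (
                _random_peptide(rng, j_head, forbid=anchor)
                + anchor
                + _random_peptide(rng, j_extra_len)
            )
            entries.append((name, _encode(rng, aa), aa))
        aa = _random_peptide(rng, c_len_aa)
        entries.append((f"{chain}C", _encode(rng, aa), aa))

    cdna_path = out_dir / "toy_cdna.fasta"
    pep_path = out_dir / "toy_pep.fasta"
    with open(cdna_path, "w") as nt_out, open(pep_path, "w") as aa_out:
        for name, nt, aa in entries:
            nt_out.write(f">{name}\n{nt}\n")
            aa_out.write(f">{name}\n{aa}\n")
    return cdna_path, pep_path
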