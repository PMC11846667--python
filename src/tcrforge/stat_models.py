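"""Empirical distributions driving rearrangement sampling.

The simulator draws from four families of categorical distributions,
normally fitted from a large AIRR-style rearrangement table (the original
statistics came from a paired single-cell immune-profiling database):

* V and J gene usage per chain,
* amino-acid deletion ("clip") counts at the V-CDR3 and CDR3-J junctions,
* CDR3 amino-acid length (anchors included),
* positional amino-acid composition of the CDR3 interior, pooled into a
  start region (the k positions after the anchor cysteine), an end region
  (the k positions before the J anchor) and a middle region.

A :class:`ModelBundle` collects these plus the Bernoulli probability that
a rearrangement is productive, and round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .ref_model import GeneSegment, TCRCache, subgroup_of

CHAINS = ("TRA", "TRB")
JUNCTION_SIDES = ("v", "j")  # V-CDR3 and CDR3-J
BUNDLE_SCHEMA_VERSION = 1
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_SUM_TOL = 1e-6


class BundleValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# categorical helpers (plain dicts keyed by category)


def normalize(counts: Mapping) -> dict:
    total = float(sum(counts.values()))
    if total <= 0:
        raise BundleValidationError("cannot normalize an empty/zero distribution")
    return {k: v / total for k, v in sorted(counts.items())}


def check_distribution(dist: Mapping, what: str) -> None:
    if not dist:
        raise BundleValidationError(f"{what}: empty distribution")
    total = float(sum(dist.values()))
    if abs(total - 1.0) > _SUM_TOL:
        raise BundleValidationError(f"{what}: probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise BundleValidationError(f"{what}: negative probability")


def sample_categorical(dist: Mapping, rng: np.random.Generator):
    keys = list(dist.keys())
    probs = np.asarray(list(dist.values()), dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def total_variation(p: Mapping, q: Mapping) -> float:
    """TV distance between two categorical distributions, 0 on identical."""
    support = sorted(set(p) | set(q), key=str)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in support)


# ---------------------------------------------------------------------------
# model dataclasses


@dataclass
class UsageModel:
    """P(V gene) and P(J gene) per chain."""

    v: dict[str, dict[str, float]]
    j: dict[str, dict[str, float]]

    def validate(self, cache: TCRCache | None = None) -> None:
        for chain in CHAINS:
            for kind, table in (("V", self.v), ("J", self.j)):
                dist = table.get(chain)
                if dist is None:
                    raise BundleValidationError(f"usage: missing {kind} for {chain}")
                check_distribution(dist, f"usage {kind} {chain}")
                if cache is not None:
                    known = {s.name for s in cache.segments_of(kind, chain)}
                    unknown = set(dist) - known
                    if unknown:
                        raise BundleValidationError(
                            f"usage {kind} {chain}: genes absent from cache: {sorted(unknown)}"
                        )


@dataclass
class ClipModel:
    """Deleted-amino-acid counts per chain and junction side."""

    dists: dict[str, dict[str, dict[int, float]]]  # chain -> side -> {n_del: p}
    max_del: int = 12

    def validate(self) -> None:
        for chain in CHAINS:
            for side in JUNCTION_SIDES:
                dist = self.dists.get(chain, {}).get(side)
                if dist is None:
                    raise BundleValidationError(f"clip: missing {chain}/{side}")
                check_distribution(dist, f"clip {chain}/{side}")
                if any(int(k) < 0 or int(k) > self.max_del for k in dist):
                    raise BundleValidationError(
                        f"clip {chain}/{side}: support outside [0, {self.max_del}]"
                    )


@dataclass
class CDR3Model:
    """CDR3 length and pooled positional amino-acid composition."""

    length: dict[str, dict[int, float]]  # chain -> {len: p}, anchors included
    regions: dict[str, dict[str, dict[str, float]]]  # chain -> start|middle|end -> {aa: p}
    k: int = 3  # width of the start/end regions

    REGION_NAMES = ("start", "middle", "end")

    def validate(self) -> None:
        for chain in CHAINS:
            dist = self.length.get(chain)
            if dist is None:
                raise BundleValidationError(f"cdr3 length: missing {chain}")
            check_distribution(dist, f"cdr3 length {chain}")
            if any(int(k) < 5 or int(k) > 30 for k in dist):
                raise BundleValidationError(f"cdr3 length {chain}: support outside [5, 30]")
            for region in self.REGION_NAMES:
                table = self.regions.get(chain, {}).get(region)
                if table is None:
                    raise BundleValidationError(f"cdr3 regions: missing {chain}/{region}")
                check_distribution(table, f"cdr3 region {chain}/{region}")

    def region_of(self, position: int, length: int) -> str:
        """Region of CDR3 position ``position`` (0-based, anchors at 0 and L-1)."""
        if 1 <= position <= self.k:
            return "start"
        if length - 1 - self.k <= position <= length - 2:
            return "end"
        return "middle"


@dataclass
class ModelBundle:
    usage: UsageModel
    clip: ClipModel
    cdr3: CDR3Model
    p_productive: float = 1.0
    provenance: str = ""

    def validate(self, cache: TCRCache | None = None) -> None:
        self.usage.validate(cache)
        self.clip.validate()
        self.cdr3.validate()
        if not 0.0 <= self.p_productive <= 1.0:
            raise BundleValidationError("p_productive outside [0, 1]")

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "usage": {"v": self.usage.v, "j": self.usage.j},
            "clip": {"dists": self.clip.dists, "max_del": self.clip.max_del},
            "cdr3": {
                "length": self.cdr3.length,
                "regions": self.cdr3.regions,
                "k": self.cdr3.k,
            },
            "p_productive": self.p_productive,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBundle":
        if d.get("schema_version") != BUNDLE_SCHEMA_VERSION:
            raise BundleValidationError(
                f"unsupported bundle schema: {d.get('schema_version')}"
            )
        usage = UsageModel(v=d["usage"]["v"], j=d["usage"]["j"])
        clip = ClipModel(
            dists={
                chain: {side: {int(k): v for k, v in dist.items()} for side, dist in sides.items()}
                for chain, sides in d["clip"]["dists"].items()
            },
            max_del=int(d["clip"]["max_del"]),
        )
        cdr3 = CDR3Model(
            length={
                chain: {int(k): v for k, v in dist.items()}
                for chain, dist in d["cdr3"]["length"].items()
            },
            regions=d["cdr3"]["regions"],
            k=int(d["cdr3"]["k"]),
        )
        bundle = cls(
            usage=usage,
            clip=clip,
            cdr3=cdr3,
            p_productive=float(d["p_productive"]),
            provenance=d.get("provenance", ""),
        )
        bundle.validate()
        return bundle

    def __eq__(self, other) -> bool:
        return isinstance(other, ModelBundle) and self.to_dict() == other.to_dict()


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    bundle.validate()
    Path(path).write_text(json.dumps(bundle.to_dict(), indent=1, sort_keys=True))


def load_bundle(path: str | Path) -> ModelBundle:
    return ModelBundle.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# fitting


def infer_clip_lengths(
    junction_aa: str, v: GeneSegment, j: GeneSegment, cache: TCRCache
) -> tuple[int, int]:
    """Deleted germline residue counts implied by an observed junction.

    ``v_del`` counts germline V residues after the anchor cysteine that are
    absent from the junction prefix; ``j_del`` counts germline J residues
    before the anchor absent from the junction suffix. Both use a greedy
    longest-match decomposition; residues matched by neither side are
    treated as (implicitly regenerated) insertions.
    """
    if len(junction_aa) < 2:
        raise ValueError("junction shorter than 2 residues")
    core = junction_aa[1:-1]
    v_tail = v.aa_seq[cache.anchor_index[v.name] + 1:]
    j_head = j.aa_seq[: cache.anchor_index[j.name]]
    n_matched_v = 0
    while (
        n_matched_v < len(v_tail)
        and n_matched_v < len(core)
        and core[n_matched_v] == v_tail[n_matched_v]
    ):
        n_matched_v += 1
    n_matched_j = 0
    while (
        n_matched_j < len(j_head)
        and n_matched_j < len(core)
        and core[-1 - n_matched_j] == j_head[-1 - n_matched_j]
    ):
        n_matched_j += 1
    return len(v_tail) - n_matched_v, len(j_head) - n_matched_j


def _strip_allele(call: str) -> str:
    return call.split("*")[0]


def fit_bundle(
    airr_table: pd.DataFrame | str | Path,
    cache: TCRCache,
    k: int = 3,
    max_del: int = 12,
    p_productive: float = 1.0,
    provenance: str = "",
) -> ModelBundle:
    """Fit usage, clip, length and composition models from an AIRR table.

    The table needs ``v_call``, ``j_call`` and ``junction_aa`` columns.
    Rows whose genes are not in the cache, whose junction does not start
    with the anchor cysteine or end with the chain-appropriate F/W anchor,
    or whose implied clipping exceeds ``max_del`` are dropped (tallied in
    the bundle provenance). A chain with zero usable rows is fatal.
    """
    if not isinstance(airr_table, pd.DataFrame):
        airr_table = pd.read_csv(airr_table, sep="\t", dtype=str)
    required = {"v_call", "j_call", "junction_aa"}
    missing = required - set(airr_table.columns)
    if missing:
        raise ValueError(f"AIRR table lacks columns: {sorted(missing)}")

    usage_v: dict[str, dict[str, int]] = {c: {} for c in CHAINS}
    usage_j: dict[str, dict[str, int]] = {c: {} for c in CHAINS}
    lengths: dict[str, dict[int, int]] = {c: {} for c in CHAINS}
    clips: dict[str, dict[str, dict[int, int]]] = {
        c: {s: {} for s in JUNCTION_SIDES} for c in CHAINS
    }
    regions: dict[str, dict[str, dict[str, int]]] = {
        c: {r: {} for r in CDR3Model.REGION_NAMES} for c in CHAINS
    }
    region_helper = CDR3Model(length={}, regions={}, k=k)
    n_dropped = 0
    for row in airr_table.itertuples(index=False):
        v_name = _strip_allele(str(row.v_call))
        j_name = _strip_allele(str(row.j_call))
        junction = str(row.junction_aa)
        if v_name not in cache.segments or j_name not in cache.segments:
            n_dropped += 1
            continue
        chain = cache.segments[v_name].chain
        if cache.segments[j_name].chain != chain:
            n_dropped += 1
            continue
        expected_end = cache.expected_j_anchor(j_name)
        if (
            len(junction) < 5
            or len(junction) > 30
            or not junction.startswith("C")
            or not junction.endswith(expected_end)
        ):
            n_dropped += 1
            continue
        v_del, j_del = infer_clip_lengths(
            junction, cache.segments[v_name], cache.segments[j_name], cache
        )
        if v_del > max_del or j_del > max_del:
            n_dropped += 1
            continue
        usage_v[chain][v_name] = usage_v[chain].get(v_name, 0) + 1
        usage_j[chain][j_name] = usage_j[chain].get(j_name, 0) + 1
        lengths[chain][len(junction)] = lengths[chain].get(len(junction), 0) + 1
        clips[chain]["v"][v_del] = clips[chain]["v"].get(v_del, 0) + 1
        clips[chain]["j"][j_del] = clips[chain]["j"].get(j_del, 0) + 1
        for pos in range(1, len(junction) - 1):
            region = region_helper.region_of(pos, len(junction))
            aa = junction[pos]
            regions[chain][region][aa] = regions[chain][region].get(aa, 0) + 1

    for chain in CHAINS:
        if not usage_v[chain]:
            raise ValueError(
                f"no usable rearrangements for chain {chain} "
                f"({n_dropped} rows dropped overall)"
            )

    bundle = ModelBundle(
        usage=UsageModel(
            v={c: normalize(usage_v[c]) for c in CHAINS},
            j={c: normalize(usage_j[c]) for c in CHAINS},
        ),
        clip=ClipModel(
            dists={
                c: {s: normalize(clips[c][s]) for s in JUNCTION_SIDES} for c in CHAINS
            },
            max_del=max_del,
        ),
        cdr3=CDR3Model(
            length={c: normalize(lengths[c]) for c in CHAINS},
            regions={
                c: {r: normalize(regions[c][r]) for r in CDR3Model.REGION_NAMES}
                for c in CHAINS
            },
            k=k,
        ),
        p_productive=p_productive,
        provenance=provenance
        or f"fitted from {len(airr_table)} rows ({n_dropped} dropped)",
    )
    bundle.validate(cache)
    return bundle


# ---------------------------------------------------------------------------
# shipped default


def default_bundle(cache: TCRCache, p_productive: float = 1.0) -> ModelBundle:
    """Zero-input bundle for a given cache.

    Uniform V/J usage; a truncated-geometric clip distribution (ratio 0.5)
    bounded by the shortest clippable germline stretch of the chain, so
    every draw is realizable; a triangular CDR3 length distribution on
    [10, 20] peaked at 14; uniform interior composition.
    """
    usage_v, usage_j = {}, {}
    clip_dists: dict[str, dict[str, dict[int, float]]] = {}
    for chain in CHAINS:
        vs = cache.segments_of("V", chain)
        js = cache.segments_of("J", chain)
        if not vs or not js:
            raise ValueError(f"cache lacks V or J segments for {chain}")
        usage_v[chain] = normalize({s.name: 1 for s in vs})
        usage_j[chain] = normalize({s.name: 1 for s in js})
        max_v = min(len(s.aa_seq) - cache.anchor_index[s.name] - 1 for s in vs)
        max_j = min(cache.anchor_index[s.name] for s in js)
        clip_dists[chain] = {
            "v": normalize({d: 0.5 ** d for d in range(max_v + 1)}),
            "j": normalize({d: 0.5 ** d for d in range(max_j + 1)}),
        }
    length = normalize(
        {L: 5 - abs(L - 14) if abs(L - 14) < 5 else 1 for L in range(10, 21)}
    )
    uniform_aa = normalize({aa: 1 for aa in _AA20})
    return ModelBundle(
        usage=UsageModel(v=usage_v, j=usage_j),
        clip=ClipModel(dists=clip_dists, max_del=12),
        cdr3=CDR3Model(
            length={c: dict(length) for c in CHAINS},
            regions={
                c: {r: dict(uniform_aa) for r in CDR3Model.REGION_NAMES} for c in CHAINS
            },
            k=3,
        ),
        p_productive=p_productive,
        provenance="built-in default (uniform usage, truncated-geometric clips)",
    )
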