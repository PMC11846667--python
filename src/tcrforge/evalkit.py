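"""Benchmark metrics for TCR construction methods.

Cell universe and definitions: "all cells" are ground-truth cells whose
TCRs are full-length and productive; a method's "result cells" are those
for which it reports any assembly; a "true cell" has at least one
correctly assembled chain for the feature under evaluation. Sensitivity
is true/all, accuracy is true/result. V and J genes are compared at the
subgroup level (TRBV6-1*01 -> TRBV6), CDR3 at exact amino-acid identity,
and an assembled TCR (AsTCR) requires V, J and CDR3 all correct; the
"paired" chain requires both TRA and TRB correct.

Also included: candidate-read TPR/TNR against read-level ground truth and
the contig-depth estimator (total candidate-read nucleotides divided by
contig length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ref_model import subgroup_of

FEATURES = ("CDR3", "V", "J", "AsTCR")
CHAIN_SCOPES = ("TRA", "TRB", "paired")


@dataclass(frozen=True)
class ChainCall:
    v_call: str
    j_call: str
    cdr3_aa: str


@dataclass
class CellTruth:
    cell_id: str
    chains: dict[str, ChainCall]  # TRA / TRB
    full_length: bool = True
    productive: bool = True


@dataclass
class CellPrediction:
    cell_id: str
    chains: dict[str, list[ChainCall]] = field(default_factory=dict)

    @property
    def is_result(self) -> bool:
        return any(self.chains.values())


def _match_subgroup(truth_call: str, pred_call: str) -> bool:
    truth_sg = subgroup_of(truth_call)
    pred_sg = subgroup_of(pred_call)
    # a bare locus prefix (e.g. "TRBJ" with no subgroup number) never matches
    if pred_sg == pred_sg.rstrip("0123456789"):
        return False
    return truth_sg == pred_sg


def chain_correct(truth: ChainCall, pred: ChainCall, feature: str) -> bool:
    if feature == "CDR3":
        return truth.cdr3_aa == pred.cdr3_aa
    if feature == "V":
        return _match_subgroup(truth.v_call, pred.v_call)
    if feature == "J":
        return _match_subgroup(truth.j_call, pred.j_call)
    if feature == "AsTCR":
        return all(chain_correct(truth, pred, f) for f in ("CDR3", "V", "J"))
    raise ValueError(f"unknown feature {feature!r}")


def _cell_chain_true(
    truth: CellTruth, pred: CellPrediction, feature: str, chain: str
) -> bool:
    truth_call = truth.chains.get(chain)
    if truth_call is None:
        return False
    return any(
        chain_correct(truth_call, p, feature) for p in pred.chains.get(chain, [])
    )


def score_cells(
    truth: dict[str, CellTruth],
    pred: dict[str, CellPrediction],
    feature: str,
    chain: str,
) -> dict[str, str]:
    """Label each truth cell 'true', 'false' or 'no-result'.

    A cell is true when at least one predicted chain matches the truth
    under ``feature``; scope 'paired' requires both chains correct.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    if chain not in CHAIN_SCOPES:
        raise ValueError(f"unknown chain scope {chain!r}")
    labels: dict[str, str] = {}
    for cell_id, t in truth.items():
        p = pred.get(cell_id)
        if p is None or not p.is_result:
            labels[cell_id] = "no-result"
            continue
        if chain == "paired":
            ok = _cell_chain_true(t, p, feature, "TRA") and _cell_chain_true(
                t, p, feature, "TRB"
            )
        else:
            ok = _cell_chain_true(t, p, feature, chain)
        labels[cell_id] = "true" if ok else "false"
    return labels


def compute_metrics(
    truth: dict[str, CellTruth],
    pred: dict[str, CellPrediction],
    strict_universe: bool = False,
) -> pd.DataFrame:
    """Sensitivity and accuracy for every feature x chain scope.

    Returns a tidy frame with columns chain, feature, n_all, n_result,
    n_true, sensitivity, accuracy. Accuracy is NaN when there are no
    result cells. With ``strict_universe`` predictions for cells outside
    the truth universe are ignored entirely; otherwise they still count
    as result cells for accuracy.
    """
    if not truth:
        raise ValueError("empty truth set")
    n_extra_results = 0
    if not strict_universe:
        n_extra_results = sum(
            1 for cid, p in pred.items() if cid not in truth and p.is_result
        )
    rows = []
    for chain in CHAIN_SCOPES:
        for feature in FEATURES:
            labels = score_cells(truth, pred, feature, chain)
            n_all = len(labels)
            n_true = sum(1 for v in labels.values() if v == "true")
            n_result = (
                sum(1 for v in labels.values() if v != "no-result") + n_extra_results
            )
            rows.append(
                {
                    "chain": chain,
                    "feature": feature,
                    "n_all": n_all,
                    "n_result": n_result,
                    "n_true": n_true,
                    "sensitivity": n_true / n_all,
                    "accuracy": (n_true / n_result) if n_result else math.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loaders


def _reduce_multi_contig(group: pd.DataFrame) -> pd.Series:
    """Keep the contig with highest read support; ties by lexicographic CDR3."""
    ordered = group.sort_values(
        ["reads", "cdr3"], ascending=[False, True], kind="mergesort"
    )
    return ordered.iloc[0]


def load_truth(path: str | Path, dialect: str) -> dict[str, CellTruth]:
    """Read ground truth in the CellRanger CSV or simulator TSV dialect.

    CellRanger: ``filtered_contig_annotations.csv`` columns barcode,
    chain, v_gene, j_gene, cdr3, productive, full_length, reads; cells
    are filtered to full-length AND productive contigs. Simulator TSV:
    the ground-truth table written by this package (productive column,
    full length by construction).
    """
    path = Path(path)
    if dialect == "cellranger-csv":
        df = pd.read_csv(path)
        required = {
            "barcode", "chain", "v_gene", "j_gene", "cdr3", "productive", "full_length",
        }
        col_map = {"barcode": "cell_id", "v_gene": "v_call", "j_gene": "j_call", "cdr3": "cdr3"}
    elif dialect == "forge-tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"cell_id", "chain", "v_call", "j_call", "junction_aa", "productive"}
        col_map = {"junction_aa": "cdr3"}
    else:
        raise ValueError(f"unknown truth dialect {dialect!r}")
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df = df.rename(columns=col_map)
    truthy = {"true", "t", "1", "yes"}
    df["productive"] = df["productive"].astype(str).str.lower().isin(truthy)
    if "full_length" in df.columns:
        df["full_length"] = df["full_length"].astype(str).str.lower().isin(truthy)
    else:
        df["full_length"] = True
    if "reads" not in df.columns:
        df["reads"] = 0
    usable = df[df["productive"] & df["full_length"]]

    cells: dict[str, CellTruth] = {}
    for (cell_id, chain), group in usable.groupby(["cell_id", "chain"], sort=True):
        row = _reduce_multi_contig(group)
        call = ChainCall(
            v_call=str(row["v_call"]), j_call=str(row["j_call"]), cdr3_aa=str(row["cdr3"])
        )
        cells.setdefault(str(cell_id), CellTruth(cell_id=str(cell_id), chains={}))
        cells[str(cell_id)].chains[str(chain)] = call
    return cells


def load_predictions(path: str | Path) -> dict[str, CellPrediction]:
    """Read a generic prediction TSV: cell_id, chain, v_call, j_call, cdr3_aa."""
    df = pd.read_csv(path, sep="\t")
    required = {"cell_id", "chain", "v_call", "j_call", "cdr3_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    preds: dict[str, CellPrediction] = {}
    for row in df.itertuples(index=False):
        cid = str(row.cell_id)
        preds.setdefault(cid, CellPrediction(cell_id=cid))
        preds[cid].chains.setdefault(str(row.chain), []).append(
            ChainCall(
                v_call=str(row.v_call), j_call=str(row.j_call), cdr3_aa=str(row.cdr3_aa)
            )
        )
    return preds


def truth_as_predictions(truth: dict[str, CellTruth]) -> dict[str, CellPrediction]:
    """Turn a truth set into a perfect prediction set (self-evaluation)."""
    return {
        cid: CellPrediction(
            cell_id=cid, chains={chain: [call] for chain, call in t.chains.items()}
        )
        for cid, t in truth.items()
    }


# ---------------------------------------------------------------------------
# candidate reads and contig depth


def candidate_read_rates(
    truth_labels: dict[str, bool], candidates: set[str]
) -> tuple[float, float]:
    """TPR and TNR of a candidate-read selection.

    ``truth_labels`` maps read id -> True for TCR-derived reads.
    Candidates must be a subset of the labeled reads. Either rate is NaN
    when its denominator class is empty.
    """
    unknown = candidates - set(truth_labels)
    if unknown:
        raise ValueError(f"{len(unknown)} candidate reads are unlabeled")
    tcr = {r for r, is_tcr in truth_labels.items() if is_tcr}
    non_tcr = set(truth_labels) - tcr
    tpr = len(candidates & tcr) / len(tcr) if tcr else math.nan
    tnr = len(non_tcr - candidates) / len(non_tcr) if non_tcr else math.nan
    return tpr, tnr


def estimate_contig_depth(contig_len: int, read_lengths: list[int]) -> float:
    """Depth = total candidate-read nucleotides / contig length."""
    if contig_len <= 0:
        raise ValueError("contig_len must be positive")
    return sum(read_lengths) / contig_len
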