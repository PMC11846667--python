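"""Cell-level sensitivity/accuracy, candidate reads and contig depth."""

import math

import numpy as np
import pytest

from tcrforge import (
    CellPrediction,
    CellTruth,
    ChainCall,
    candidate_read_rates,
    compute_metrics,
    estimate_contig_depth,
    load_predictions,
    load_truth,
    make_cells,
    score_cells,
    truth_as_predictions,
    write_ground_truth,
)
from tcrforge.evalkit import CHAIN_SCOPES, FEATURES, chain_correct


def _cell(cid, tra=None, trb=None):
    chains = {}
    if tra:
        chains["TRA"] = ChainCall(*tra)
    if trb:
        chains["TRB"] = ChainCall(*trb)
    return CellTruth(cell_id=cid, chains=chains)


def _pred(cid, tra=None, trb=None):
    chains = {}
    if tra:
        chains["TRA"] = [ChainCall(*c) for c in tra]
    if trb:
        chains["TRB"] = [ChainCall(*c) for c in trb]
    return CellPrediction(cell_id=cid, chains=chains)


def test_chain_feature_definitions():
    truth = ChainCall("TRBV6-1", "TRBJ2-7", "CASSLGF")
    assert chain_correct(truth, ChainCall("TRBV6-2*01", "x", "y"), "V")  # subgroup
    assert not chain_correct(truth, ChainCall("TRBV7-2", "x", "y"), "V")
    assert chain_correct(truth, ChainCall("x", "TRBJ2-1", "y"), "J")
    assert chain_correct(truth, ChainCall("x", "y", "CASSLGF"), "CDR3")
    # correct CDR3 but wrong J fails the assembled-TCR conjunction
    assert not chain_correct(truth, ChainCall("TRBV6-1", "TRBJ1-1", "CASSLGF"), "AsTCR")
    assert chain_correct(truth, ChainCall("TRBV6-5", "TRBJ2-3*02", "CASSLGF"), "AsTCR")


def test_bare_locus_prediction_never_matches():
    truth = ChainCall("TRBV6-1", "TRBJ2-7", "CASSLGF")
    assert not chain_correct(truth, ChainCall("x", "TRBJ", "y"), "J")


def test_sensitivity_and_accuracy_arithmetic():
    truth = {f"c{i}": _cell(f"c{i}", tra=("TRAV1", "TRAJ1", f"CAR{i}F")) for i in range(10)}
    pred = {}
    for i in range(8):  # 8 result cells, 6 correct
        cdr3 = f"CAR{i}F" if i < 6 else "CWRONGF"
        pred[f"c{i}"] = _pred(f"c{i}", tra=[("TRAV1", "TRAJ1", cdr3)])
    report = compute_metrics(truth, pred)
    row = report[(report.chain == "TRA") & (report.feature == "CDR3")].iloc[0]
    assert row.n_all == 10 and row.n_result == 8 and row.n_true == 6
    assert row.sensitivity == pytest.approx(0.60)
    assert row.accuracy == pytest.approx(0.75)


def test_empty_predictor_has_zero_sensitivity_and_missing_accuracy():
    truth = {"c0": _cell("c0", tra=("TRAV1", "TRAJ1", "CAF"))}
    report = compute_metrics(truth, {})
    assert (report.sensitivity == 0).all()
    assert report.accuracy.isna().all()
    with pytest.raises(ValueError):
        compute_metrics({}, {})


def test_self_evaluation_identity(cache, bundle, tmp_path):
    cells = make_cells(20, bundle, cache, np.random.default_rng(4))
    tsv, _ = write_ground_truth(cells, tmp_path)
    truth = load_truth(tsv, "forge-tsv")
    assert len(truth) == 20
    report = compute_metrics(truth, truth_as_predictions(truth))
    assert (report.sensitivity == 1.0).all()
    assert (report.accuracy == 1.0).all()


def test_metrics_invariant_to_duplication_and_order():
    truth = {f"c{i}": _cell(f"c{i}", trb=("TRBV1", "TRBJ1", f"CX{i}F")) for i in range(5)}
    pred = {f"c{i}": _pred(f"c{i}", trb=[("TRBV1", "TRBJ1", f"CX{i}F")]) for i in range(3)}
    base = compute_metrics(truth, pred)
    doubled = {
        cid: _pred(cid, trb=[("TRBV1", "TRBJ1", f"CX{cid[1:]}F")] * 3) for cid in pred
    }
    reordered = dict(reversed(list(truth.items())))
    assert base.equals(compute_metrics(reordered, doubled))


# ---------------------------------------------------------------------------
# brute-force oracle for the scoring definitions


def _oracle_label(truth, pred, feature, chain):
    if pred is None or not any(pred.chains.values()):
        return "no-result"

    def ok(ch):
        t = truth.chains.get(ch)
        if t is None:
            return False
        result = False
        for p in pred.chains.get(ch, []):
            cdr3 = t.cdr3_aa == p.cdr3_aa
            v = t.v_call.split("*")[0].split("-")[0] == p.v_call.split("*")[0].split("-")[0] \
                and any(c.isdigit() for c in p.v_call.split("*")[0].split("-")[0])
            j = t.j_call.split("*")[0].split("-")[0] == p.j_call.split("*")[0].split("-")[0] \
                and any(c.isdigit() for c in p.j_call.split("*")[0].split("-")[0])
            result = result or {
                "CDR3": cdr3, "V": v, "J": j, "AsTCR": cdr3 and v and j,
            }[feature]
        return result

    chains = ("TRA", "TRB") if chain == "paired" else (chain,)
    return "true" if all(ok(c) for c in chains) else "false"


def _random_case(rng):
    genes_v = ["TRAV1", "TRAV2-1", "TRBV6-1", "TRBV6"]
    genes_j = ["TRAJ3", "TRBJ2-7", "TRBJ", "TRAJ33"]
    cdr3s = ["CAF", "CASSF", "CAW"]
    truth, pred = {}, {}
    for i in range(rng.integers(1, 6)):
        cid = f"c{i}"
        chains = {}
        for ch in ("TRA", "TRB"):
            if rng.random() < 0.8:
                chains[ch] = ChainCall(
                    rng.choice(genes_v), rng.choice(genes_j), rng.choice(cdr3s)
                )
        if not chains:
            chains["TRA"] = ChainCall("TRAV1", "TRAJ3", "CAF")
        truth[cid] = CellTruth(cell_id=cid, chains=chains)
        if rng.random() < 0.8:
            pchains = {
                ch: [
                    ChainCall(rng.choice(genes_v), rng.choice(genes_j), rng.choice(cdr3s))
                    for _ in range(rng.integers(0, 3))
                ]
                for ch in ("TRA", "TRB")
            }
            pred[cid] = CellPrediction(cell_id=cid, chains=pchains)
    return truth, pred


def test_score_cells_agrees_with_brute_force_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        truth, pred = _random_case(rng)
        for feature in FEATURES:
            for chain in CHAIN_SCOPES:
                labels = score_cells(truth, pred, feature, chain)
                expected = {
                    cid: _oracle_label(t, pred.get(cid), feature, chain)
                    for cid, t in truth.items()
                }
                assert labels == expected


# ---------------------------------------------------------------------------
# loaders


def test_cellranger_dialect_filters_and_reduces(tmp_path):
    csv = tmp_path / "filtered_contig_annotations.csv"
    csv.write_text(
        "barcode,chain,v_gene,j_gene,cdr3,productive,full_length,reads\n"
        "AAA-1,TRB,TRBV6-1,TRBJ2-7,CASSF,True,True,100\n"
        "AAA-1,TRB,TRBV7-2,TRBJ1-1,CASSG,True,True,500\n"  # higher support wins
        "BBB-1,TRA,TRAV1,TRAJ3,CAF,False,True,50\n"  # non-productive: dropped
        "CCC-1,TRA,TRAV2,TRAJ4,CAVF,True,True,10\n"
    )
    truth = load_truth(csv, "cellranger-csv")
    assert set(truth) == {"AAA-1", "CCC-1"}
    assert truth["AAA-1"].chains["TRB"].v_call == "TRBV7-2"
    with pytest.raises(ValueError, match="missing column"):
        bad = tmp_path / "bad.csv"
        bad.write_text("barcode,chain\nx,TRA\n")
        load_truth(bad, "cellranger-csv")
    with pytest.raises(ValueError, match="dialect"):
        load_truth(csv, "nope")


def test_prediction_loader_groups_chains(tmp_path):
    tsv = tmp_path / "pred.tsv"
    tsv.write_text(
        "cell_id\tchain\tv_call\tj_call\tcdr3_aa\n"
        "c0\tTRA\tTRAV1\tTRAJ3\tCAF\n"
        "c0\tTRB\tTRBV6-1\tTRBJ2-7\tCASSF\n"
    )
    preds = load_predictions(tsv)
    assert set(preds["c0"].chains) == {"TRA", "TRB"}


# ---------------------------------------------------------------------------
# candidate reads and depth


def test_candidate_read_rates_definitions():
    labels = {f"t{i}": True for i in range(10)} | {f"n{i}": False for i in range(40)}
    tcr_only = {f"t{i}" for i in range(10)}
    assert candidate_read_rates(labels, tcr_only) == (1.0, 1.0)
    tpr, tnr = candidate_read_rates(labels, set(labels))  # everything selected
    assert (tpr, tnr) == (1.0, 0.0)
    tpr, _ = candidate_read_rates({"n0": False}, set())
    assert math.isnan(tpr)
    with pytest.raises(ValueError):
        candidate_read_rates(labels, {"unknown"})


def test_candidate_rates_match_set_arithmetic_oracle():
    rng = np.random.default_rng(11)
    ids = [f"r{i}" for i in range(1000)]
    labels = {r: bool(rng.random() < 0.3) for r in ids}
    candidates = {r for r in ids if rng.random() < 0.5}
    tpr, tnr = candidate_read_rates(labels, candidates)
    tp = sum(1 for r in ids if labels[r] and r in candidates)
    tn = sum(1 for r in ids if not labels[r] and r not in candidates)
    assert tpr == tp / sum(labels.values())
    assert tnr == tn / (len(ids) - sum(labels.values()))


def test_contig_depth_estimator():
    assert estimate_contig_depth(500, [150] * 10) == pytest.approx(3.0)
    assert estimate_contig_depth(500, []) == 0.0
    with pytest.raises(ValueError):
        estimate_contig_depth(0, [150])
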