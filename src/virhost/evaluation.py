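"""Evaluation metrics and experiment harnesses.

Implements the metric suite (accuracy, rank-wise accuracy, precision,
prediction rate, macro F1, row-normalized confusion matrices) and four
harnesses: stratified k-fold cross-validation, fragment-completeness
robustness, leave-one-genus-out novel-virus evaluation with two null models,
and the family-wise homogeneity analysis.

Metric conventions: a rejected query counts as an error for accuracy but is
excluded from precision's denominator; prediction rate is the fraction of
queries receiving a (non-rejected) prediction; rank-wise accuracy is the
unweighted mean of per-taxon accuracies; layer-2 evaluation compounds layer-1
errors (a query mis-assigned at layer 1 is wrong at layer 2 too).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import OrderHostClassifier, predictions_to_frame
from .taxonomy import (
    LAYER1_LABELS,
    LAYER2_LABELS,
    MERGED_MAMMAL_LABEL,
    VirusRecord,
    dominant_label,
    host_homogeneity,
)

__all__ = [
    "MetricReport",
    "ChallengingCaseTag",
    "stratified_kfold",
    "stratified_kfold_indices",
    "compute_metrics",
    "fragment_queries",
    "cross_validate_order",
    "leave_one_genus_out",
    "null_model_1",
    "null_model_2",
    "tag_challenging_cases",
    "family_wise_analysis",
    "blast_baseline_labels",
]

_LABEL_ORDER = list(LAYER1_LABELS) + list(LAYER2_LABELS) + [MERGED_MAMMAL_LABEL]


# ---------------------------------------------------------------------------
# folds


def stratified_kfold_indices(
    labels: Sequence, k: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified k-fold over integer positions.

    Positions of each label are shuffled under the seed and dealt round-robin,
    so per-label fold sizes differ by at most one.  Labels with fewer than k
    members degrade to best-effort allocation (their members land in fewer
    than k folds) with a warning.
    """
    labels = np.asarray(labels)
    rng = np.random.RandomState(seed)
    fold_of = np.empty(len(labels), dtype=int)
    for lab in sorted(map(str, set(labels.tolist()))):
        idx = np.flatnonzero(labels.astype(str) == lab)
        if len(idx) < k:
            warnings.warn(f"label {lab!r} has {len(idx)} < {k} members; best-effort folds")
        perm = rng.permutation(idx)
        for j, pos in enumerate(perm):
            fold_of[pos] = j % k
    out = []
    for f in range(k):
        test = np.flatnonzero(fold_of == f)
        train = np.flatnonzero(fold_of != f)
        out.append((train, test))
    return out


def stratified_kfold(
    records: Sequence[VirusRecord], k: int = 5, seed: int = 0, layer: str = "layer1"
) -> list[tuple[list[VirusRecord], list[VirusRecord]]]:
    """Stratify records by host label into k disjoint train/test partitions."""
    labels = [
        (r.layer2_host if layer == "layer2" and r.layer2_host else r.layer1_host)
        for r in records
    ]
    splits = stratified_kfold_indices(labels, k=k, seed=seed)
    records = list(records)
    return [
        ([records[i] for i in train], [records[i] for i in test])
        for train, test in splits
    ]


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricReport:
    """Metric bundle for one evaluation run."""

    n_queries: int
    accuracy: float
    precision: float
    prediction_rate: float
    macro_f1: float
    order_wise_accuracy: float | None = None
    family_wise_accuracy: float | None = None
    genus_wise_accuracy: float | None = None
    confusion: pd.DataFrame | None = None
    per_taxon: dict[str, pd.Series] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "n_queries": self.n_queries,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "prediction_rate": self.prediction_rate,
            "macro_f1": self.macro_f1,
            "order_wise_accuracy": self.order_wise_accuracy,
            "family_wise_accuracy": self.family_wise_accuracy,
            "genus_wise_accuracy": self.genus_wise_accuracy,
        }
        return out


def _truth_label(record: VirusRecord, layer: str) -> str | None:
    if layer == "layer1":
        return record.layer1_host
    return record.layer2_host


def _predicted_label(row: pd.Series, layer: str) -> str | None:
    if row["rejected"]:
        return None
    if layer == "layer1":
        return row["layer1_label"]
    # layer-2 evaluation compounds layer-1 errors: a non-Chordata layer-1 call
    # for a Chordata-annotated query is simply a wrong layer-2 prediction
    if row["layer1_label"] != "Chordata":
        return row["layer1_label"]
    return row["layer2_label"] if pd.notna(row["layer2_label"]) else None


def compute_metrics(
    truth: Sequence[VirusRecord],
    predictions: pd.DataFrame | Sequence,
    layer: str = "layer1",
) -> MetricReport:
    """Score predictions against truth records for one layer.

    For layer 2, only queries carrying a layer-2 annotation enter the
    evaluation; predictions are matched to truth by query id.
    """
    if not isinstance(predictions, pd.DataFrame):
        predictions = predictions_to_frame(predictions)
    pred_by_id = predictions.set_index("id")
    rows = []
    for rec in truth:
        t = _truth_label(rec, layer)
        if t is None:
            continue
        if rec.id not in pred_by_id.index:
            raise KeyError(f"no prediction for query {rec.id!r}")
        p = _predicted_label(pred_by_id.loc[rec.id], layer)
        rows.append((rec, t, p))
    if not rows:
        raise ValueError(f"no evaluable queries at {layer}")
    n = len(rows)
    correct = np.array([t == p for _, t, p in rows])
    predicted = np.array([p is not None for _, _, p in rows])
    accuracy = correct.mean()
    prediction_rate = predicted.mean()
    precision = correct[predicted].mean() if predicted.any() else 0.0

    labels = sorted({t for _, t, _ in rows})
    f1s = []
    for lab in labels:
        tp = sum(1 for _, t, p in rows if t == lab and p == lab)
        fp = sum(1 for _, t, p in rows if t != lab and p == lab)
        fn = sum(1 for _, t, p in rows if t == lab and p != lab)
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    macro_f1 = float(np.mean(f1s))

    report = MetricReport(
        n_queries=n,
        accuracy=float(accuracy),
        precision=float(precision),
        prediction_rate=float(prediction_rate),
        macro_f1=macro_f1,
    )
    for rank, attr in (("order", "order_wise_accuracy"), ("family", "family_wise_accuracy"), ("genus", "genus_wise_accuracy")):
        taxa: dict[str, list[bool]] = {}
        ok = True
        for (rec, t, p), c in zip(rows, correct):
            taxon = getattr(rec, rank)
            if taxon is None:
                ok = False
                break
            taxa.setdefault(taxon, []).append(bool(c))
        if ok and taxa:
            per = pd.Series({tax: float(np.mean(v)) for tax, v in taxa.items()})
            report.per_taxon[rank] = per
            setattr(report, attr, float(per.mean()))

    pred_labels = sorted({p for _, _, p in rows if p is not None} | set(labels))
    conf = pd.DataFrame(0.0, index=labels, columns=pred_labels)
    for _, t, p in rows:
        if p is not None:
            conf.loc[t, p] += 1
    sums = conf.sum(axis=1)
    report.confusion = conf.div(sums.replace(0, np.nan), axis=0)
    return report


# ---------------------------------------------------------------------------
# fragment harness


def fragment_queries(
    sequences: Mapping[str, str],
    ratios: Sequence[float] = (0.90, 0.75, 0.60, 0.45),
    seed: int = 0,
) -> dict[float, dict[str, str]]:
    """One contiguous contig per sequence per completeness ratio.

    Contig length is round(ratio * L); the start position is uniform at
    random under the fixed seed, so repeated calls are identical.
    """
    rng = np.random.RandomState(seed)
    out: dict[float, dict[str, str]] = {}
    for ratio in ratios:
        contigs = {}
        for sid in sequences:
            seq = sequences[sid]
            if len(seq) < 100:
                raise ValueError(f"sequence {sid!r} shorter than 100 bp")
            length = int(round(ratio * len(seq)))
            start = int(rng.randint(0, len(seq) - length + 1))
            contigs[sid] = seq[start : start + length]
        out[ratio] = contigs
    return out


# ---------------------------------------------------------------------------
# cross-validation driver


def _assert_disjoint(train: Sequence[VirusRecord], test: Sequence[VirusRecord]) -> None:
    overlap = {r.id for r in train} & {r.id for r in test}
    if overlap:
        raise AssertionError(f"train/test leakage: {sorted(overlap)[:5]}")


def cross_validate_order(
    records: Sequence[VirusRecord],
    sequences: Mapping[str, str],
    k: int = 5,
    seed: int = 0,
    fragment_ratio: float | None = None,
    **classifier_kwargs,
) -> tuple[pd.DataFrame, dict[str, MetricReport]]:
    """Stratified k-fold cross-validation of one order's classifier.

    Returns the pooled out-of-fold predictions and metric reports per layer.
    With ``fragment_ratio`` set, test sequences are cut to that completeness
    before prediction (training always uses full-length references).
    """
    records = list(records)
    folds = stratified_kfold(records, k=k, seed=seed)
    all_preds = []
    for fold_no, (train, test) in enumerate(folds):
        _assert_disjoint(train, test)
        if not train or not test:
            continue
        clf = OrderHostClassifier(order=train[0].order, seed=seed, **classifier_kwargs)
        clf.fit({r.id: sequences[r.id] for r in train}, train)
        test_seqs = {r.id: sequences[r.id] for r in test}
        if fragment_ratio is not None:
            test_seqs = fragment_queries(test_seqs, ratios=[fragment_ratio], seed=seed + fold_no)[
                fragment_ratio
            ]
        all_preds.extend(clf.predict_queries(test_seqs))
    preds = predictions_to_frame(all_preds)
    reports = {"layer1": compute_metrics(records, preds, "layer1")}
    if any(r.layer2_host for r in records):
        reports["layer2"] = compute_metrics(records, preds, "layer2")
    return preds, reports


# ---------------------------------------------------------------------------
# leave-one-genus-out

def leave_one_genus_out(
    records: Sequence[VirusRecord],
    sequences: Mapping[str, str],
    seed: int = 0,
    genera: Sequence[str] | None = None,
    **classifier_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Novel-virus evaluation: hold out each genus in turn.

    For every genus, the order's classifier is retrained without that genus
    (homology references included), and the genus members are predicted.
    Training homology features are computed under genus-level exclusion so the
    learner cannot lean on within-genus hits that a truly novel query would
    lack.  Returns pooled predictions and a per-genus accuracy table; the
    aggregate genus-wise accuracy is the unweighted mean over genera.  A genus
    spanning its whole order is skipped with a warning (no training data
    remains).  ``genera`` optionally restricts which genera are held out (each
    still evaluated against the full remainder of its order).
    """
    records = list(records)
    by_order: dict[str, list[VirusRecord]] = {}
    for r in records:
        if r.genus is None:
            raise ValueError(f"record {r.id!r} lacks a genus annotation")
        by_order.setdefault(r.order, []).append(r)
    all_preds = []
    rows = []
    for order, recs in sorted(by_order.items()):
        held_out = sorted({r.genus for r in recs})
        if genera is not None:
            held_out = [g for g in held_out if g in set(genera)]
        for genus in held_out:
            train = [r for r in recs if r.genus != genus]
            test = [r for r in recs if r.genus == genus]
            if not train:
                warnings.warn(f"genus {genus!r} spans the whole order {order}; skipped")
                continue
            _assert_disjoint(train, test)
            clf = OrderHostClassifier(
                order=order, seed=seed, homology_exclusion="genus", **classifier_kwargs
            )
            clf.fit({r.id: sequences[r.id] for r in train}, train)
            preds = clf.predict_queries({r.id: sequences[r.id] for r in test})
            all_preds.extend(preds)
            frame = predictions_to_frame(preds).set_index("id")
            acc1 = float(
                np.mean(
                    [frame.loc[r.id, "layer1_label"] == r.layer1_host for r in test]
                )
            )
            l2_test = [r for r in test if r.layer2_host]
            acc2 = (
                float(
                    np.mean(
                        [
                            _predicted_label(frame.loc[r.id], "layer2") == r.layer2_host
                            for r in l2_test
                        ]
                    )
                )
                if l2_test
                else np.nan
            )
            rows.append(
                {"order": order, "genus": genus, "n": len(test), "accuracy_layer1": acc1, "accuracy_layer2": acc2}
            )
    per_genus = pd.DataFrame(rows)
    return predictions_to_frame(all_preds), per_genus


# ---------------------------------------------------------------------------
# null models


def null_model_1(
    train_label_distribution: Mapping[str, float], n_queries: int, seed: int = 0
) -> list[str]:
    """Random labels drawn i.i.d. from the training label distribution."""
    if not train_label_distribution:
        raise ValueError("empty label distribution")
    labels = sorted(train_label_distribution)
    weights = np.array([train_label_distribution[lab] for lab in labels], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.RandomState(seed)
    return [labels[i] for i in rng.choice(len(labels), size=n_queries, p=probs)]


def null_model_2(train_label_distribution: Mapping[str, float]) -> str:
    """The dominant training label (ties broken by the fixed taxonomy order)."""
    if not train_label_distribution:
        raise ValueError("empty label distribution")
    return dominant_label(Counter(train_label_distribution), _LABEL_ORDER)


# ---------------------------------------------------------------------------
# challenging cases


@dataclass(frozen=True)
class ChallengingCaseTag:
    """Flags marking a genus whose host tropism diverges from its relatives."""

    genus: str
    case1: bool  # dominant layer-1 host differs from the order's
    case2: bool  # dominant layer-1 host differs from the family's
    case3: bool  # members infect hosts across >= 2 layer-1 groups


def tag_challenging_cases(records: Sequence[VirusRecord]) -> list[ChallengingCaseTag]:
    """Tag every genus with the three challenging-case flags (layer-1 based)."""
    by = {"order": {}, "family": {}, "genus": {}}
    for r in records:
        for rank in by:
            taxon = getattr(r, rank)
            if taxon is None:
                raise ValueError(f"record {r.id!r} lacks a {rank} annotation")
            by[rank].setdefault(taxon, Counter())[r.layer1_host] += 1
    genus_parent: dict[str, tuple[str, str]] = {}
    for r in records:
        genus_parent[r.genus] = (r.order, r.family)
    tags = []
    for genus in sorted(genus_parent):
        order, family = genus_parent[genus]
        dom_g = dominant_label(by["genus"][genus], _LABEL_ORDER)
        dom_o = dominant_label(by["order"][order], _LABEL_ORDER)
        dom_f = dominant_label(by["family"][family], _LABEL_ORDER)
        tags.append(
            ChallengingCaseTag(
                genus=genus,
                case1=dom_g != dom_o,
                case2=dom_g != dom_f,
                case3=len(by["genus"][genus]) >= 2,
            )
        )
    return tags


# ---------------------------------------------------------------------------
# family-wise analysis


def family_wise_analysis(
    records: Sequence[VirusRecord],
    predictions: pd.DataFrame,
    threshold: float = 0.9,
) -> dict:
    """Partition families by host homogeneity r and attribute layer-1 errors.

    A family with r >= ``threshold`` (fraction of members carrying its
    dominant layer-1 host; the boundary value counts as high) is
    high-homogeneity.  Returns per-family statistics, the error counts per
    partition, and the row-normalized layer-1 confusion matrix.
    """
    by_family: dict[str, list[VirusRecord]] = {}
    for r in records:
        if r.family is None:
            raise ValueError(f"record {r.id!r} lacks a family annotation")
        by_family.setdefault(r.family, []).append(r)
    pred_by_id = predictions.set_index("id")
    rows = []
    errors = {"high": 0, "low": 0}
    for family, members in sorted(by_family.items()):
        r_value = host_homogeneity(members)
        n_err = sum(
            1
            for rec in members
            if _predicted_label(pred_by_id.loc[rec.id], "layer1") != rec.layer1_host
        )
        part = "high" if r_value >= threshold else "low"
        errors[part] += n_err
        rows.append(
            {
                "family": family,
                "n": len(members),
                "r": r_value,
                "homogeneity": part,
                "n_errors": n_err,
                "error_rate": n_err / len(members),
            }
        )
    report = compute_metrics(records, predictions, "layer1")
    return {
        "per_family": pd.DataFrame(rows),
        "errors_by_partition": errors,
        "confusion": report.confusion,
    }


# ---------------------------------------------------------------------------
# alignment-only baseline


def blast_baseline_labels(homology_table: pd.DataFrame) -> pd.Series:
    """Alignment-only baseline: the argmax host group of the homology vector.

    Ties (including the all-no-hit case) resolve to the first group in the
    table's fixed column order.
    """
    return homology_table.idxmax(axis=1)
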