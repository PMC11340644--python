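"""Hierarchical per-order host classifiers with confidence-based rejection.

One classifier is trained per virus order.  Layer 1 predicts the host branch
at kingdom/phylum rank from the concatenated feature vector X = [S | H]
(genomic traits plus per-group homology scores); when the order carries
layer-2 annotations, a second model refines Chordata predictions to host
class/order rank, with its own host-group index (so the homology dimension m
differs between layers).  Orders whose references all share one leaf host
label skip training entirely and assign that label directly.

Prediction scores are class probabilities from the underlying learner
(gradient boosting by default, with classical alternatives selectable for
architecture comparisons).  A per-order rejection cutoff, calibrated on
out-of-fold validation scores to a configurable precision target, turns
low-confidence predictions into explicit rejections.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import LabelEncoder
from sklearn.svm import SVC

from .homology import HomologyEncoder, resolve_backend
from .taxonomy import VirusRecord, order_mode, OrderMode
from .traits import FEATURE_LAYOUT_VERSION, GenomicTraitEncoder

__all__ = [
    "LEARNERS",
    "make_learner",
    "calibrate_rejection_cutoff",
    "PredictionResult",
    "OrderHostClassifier",
    "HostPredictor",
    "predictions_to_frame",
]


def _xgboost_learner(seed: int):
    from xgboost import XGBClassifier

    # library defaults plus a fixed seed; labels are integer-encoded upstream
    return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)


LEARNERS = {
    "xgboost": _xgboost_learner,
    "gbdt": lambda seed: GradientBoostingClassifier(random_state=seed),
    "rf": lambda seed: RandomForestClassifier(random_state=seed),
    "svm": lambda seed: SVC(probability=True, random_state=seed),
    "logistic": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
    "knn": lambda seed: KNeighborsClassifier(),
    "gnb": lambda seed: GaussianNB(),
}


def make_learner(name: str, seed: int):
    """Instantiate a learner by registry name with library-default parameters."""
    try:
        factory = LEARNERS[name]
    except KeyError:
        raise ValueError(f"unknown learner {name!r}; choose from {sorted(LEARNERS)}")
    return factory(seed)


def calibrate_rejection_cutoff(
    validation_scores: Sequence[tuple[float, bool]],
    target_precision: float = 0.95,
) -> tuple[float, pd.DataFrame]:
    """Smallest score cutoff achieving the target precision on validation data.

    Scans every observed top score as a candidate cutoff (accept when
    top score >= cutoff) and returns the smallest one whose precision over the
    accepted predictions reaches ``target_precision``, together with the full
    precision / prediction-rate trade-off curve.  If the target is
    unattainable the maximum observed score is returned with a warning.
    """
    if not validation_scores:
        raise ValueError("calibrate_rejection_cutoff: empty validation set")
    if target_precision <= 0:
        scores = np.array([s for s, _ in validation_scores])
        correct = np.array([c for _, c in validation_scores])
        curve = pd.DataFrame(
            {"cutoff": [0.0], "precision": [correct.mean()], "prediction_rate": [1.0]}
        )
        return 0.0, curve
    scores = np.array([s for s, _ in validation_scores], dtype=float)
    correct = np.array([bool(c) for _, c in validation_scores])
    n = len(scores)
    rows = []
    best = None
    for cutoff in np.unique(scores):
        accepted = scores >= cutoff
        n_acc = int(accepted.sum())
        precision = correct[accepted].mean() if n_acc else 1.0
        rows.append((float(cutoff), float(precision), n_acc / n))
        if best is None and precision >= target_precision:
            best = float(cutoff)
    curve = pd.DataFrame(rows, columns=["cutoff", "precision", "prediction_rate"])
    if best is None:
        best = float(scores.max())
        warnings.warn(
            f"target precision {target_precision} unattainable on validation data; "
            f"using max observed score {best:.4f}"
        )
    return best, curve


@dataclass
class PredictionResult:
    """Host prediction for one query."""

    id: str
    order: str | None
    layer1_label: str | None = None
    layer1_score: float | None = None
    layer2_label: str | None = None
    layer2_score: float | None = None
    rejected: bool = False
    note: str = ""
    layer1_scores: dict[str, float] = field(default_factory=dict)
    layer2_scores: dict[str, float] = field(default_factory=dict)


def predictions_to_frame(results: Iterable[PredictionResult]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "order": r.order,
            "layer1_label": r.layer1_label,
            "layer1_score": r.layer1_score,
            "layer2_label": r.layer2_label,
            "layer2_score": r.layer2_score,
            "rejected": r.rejected,
            "note": r.note,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "id", "order", "layer1_label", "layer1_score",
            "layer2_label", "layer2_score", "rejected", "note",
        ],
    )


class _LayerModel:
    """One trained classification layer: learner + homology encoder + labels."""

    def __init__(self, labels: list[str], direct_label: str | None = None):
        self.labels = labels
        self.direct_label = direct_label
        self.learner = None
        self.homology: HomologyEncoder | None = None
        self.cutoff = 0.0
        self.calibration_curve: pd.DataFrame | None = None

    def score_queries(self, queries: Mapping[str, str], traits: pd.DataFrame) -> pd.DataFrame:
        """Class-probability table (rows: query ids, columns: labels)."""
        if self.direct_label is not None:
            return pd.DataFrame(
                {lab: (1.0 if lab == self.direct_label else 0.0) for lab in self.labels},
                index=list(queries),
            )
        hom = self.homology.transform(queries)
        X = np.hstack([traits.loc[hom.index].to_numpy(), hom.to_numpy()])
        proba = np.asarray(self.learner.predict_proba(X), dtype=float)
        proba /= proba.sum(axis=1, keepdims=True)  # learners emit float32 sums
        return pd.DataFrame(proba, index=hom.index, columns=self.labels)


class OrderHostClassifier(BaseEstimator, ClassifierMixin):
    """Hierarchical host classifier for one virus order.

    Parameters
    ----------
    order : str
        Virus order this classifier serves.
    feature_set : {"sbias", "bias"}
        Genomic-trait layout (without / with codon-pair scores).
    learner : str
        Learner registry name (default gradient boosting, ``xgboost``).
    aligner_backend : {"auto", "blastn", "builtin"}
        Backend for homology features.
    gene_caller : {"naive_orf", "external"}
        Coding-region backend for trait features.
    seed : int
        Seeds the learner and the internal calibration folds.
    rejection_target : float
        Precision target for the per-layer rejection cutoff; 0 disables
        rejection.
    calibration_folds : int
        Internal out-of-fold split count used to collect validation scores.

    Fitted attributes (trailing underscore) include ``mode_``, ``layer1_`` and
    ``layer2_`` layer models and ``feature_layout_version_``.
    """

    def __init__(
        self,
        order: str = "?",
        feature_set: str = "sbias",
        learner: str = "xgboost",
        aligner_backend: str = "auto",
        gene_caller: str = "naive_orf",
        seed: int = 0,
        rejection_target: float = 0.0,
        calibration_folds: int = 5,
        homology_exclusion: str = "self",
    ):
        self.order = order
        self.feature_set = feature_set
        self.learner = learner
        self.aligner_backend = aligner_backend
        self.gene_caller = gene_caller
        self.seed = seed
        self.rejection_target = rejection_target
        self.calibration_folds = calibration_folds
        self.homology_exclusion = homology_exclusion

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        X: Mapping[str, str | Sequence[str]],
        y: Sequence[VirusRecord],
    ) -> "OrderHostClassifier":
        """Fit on reference sequences ``X`` (id -> sequence) and their records."""
        records = list(y)
        if not records:
            raise ValueError("no training records")
        self.mode_: OrderMode = order_mode(records)
        self.feature_layout_version_ = FEATURE_LAYOUT_VERSION
        self.aligner_backend_ = resolve_backend(self.aligner_backend)
        self.trait_encoder_ = GenomicTraitEncoder(
            feature_set=self.feature_set, gene_caller=self.gene_caller
        ).fit([])
        self.classes_ = np.unique([r.layer1_host for r in records])
        if self.mode_.mode == "direct_assign":
            self.layer1_ = None
            self.layer2_ = None
            return self
        self.traits_cache_ = self._encode_traits({r.id: X[r.id] for r in records})
        self.layer1_ = self._fit_layer(records, X, layer="layer1")
        self.layer2_ = None
        if self.mode_.mode == "two_layer":
            chordata = [r for r in records if r.layer2_host is not None]
            self.layer2_ = self._fit_layer(chordata, X, layer="layer2")
        del self.traits_cache_
        return self

    def _encode_traits(self, sequences: Mapping) -> pd.DataFrame:
        mat = self.trait_encoder_.transform(list(sequences.values()))
        return pd.DataFrame(mat, index=list(sequences), columns=self.trait_encoder_.feature_names_)

    def _fit_layer(
        self, records: list[VirusRecord], sequences: Mapping, layer: str
    ) -> _LayerModel:
        labels = {
            r.id: (r.layer1_host if layer == "layer1" else r.layer2_host) for r in records
        }
        distinct = sorted(set(labels.values()))
        if len(distinct) == 1:
            # single-label layer degrades to direct assignment
            return _LayerModel(distinct, direct_label=distinct[0])
        seqs = {r.id: sequences[r.id] for r in records}
        hom = HomologyEncoder(backend=self.aligner_backend_, scope=(self.order, layer)).fit(
            seqs, labels
        )
        # training-time exclusion keeps a virus's own sequence (or, for the
        # novel-virus setting, its whole genus) out of its homology features
        if self.homology_exclusion == "self":
            exclude = {rid: {rid} for rid in seqs}
        elif self.homology_exclusion == "genus":
            genus_of = {r.id: r.genus for r in records}
            members: dict[str | None, set[str]] = {}
            for rid, genus in genus_of.items():
                members.setdefault(genus, set()).add(rid)
            exclude = {
                rid: members[genus_of[rid]] if genus_of[rid] is not None else {rid}
                for rid in seqs
            }
        else:
            raise ValueError(f"unknown homology_exclusion {self.homology_exclusion!r}")
        H = hom.transform(seqs, exclude=exclude)
        S = self.traits_cache_.loc[H.index]
        X = np.hstack([S.to_numpy(), H.to_numpy()])
        y = np.array([labels[rid] for rid in H.index])
        enc = LabelEncoder().fit(y)
        model = _LayerModel(list(enc.classes_))
        model.homology = hom
        model.learner = make_learner(self.learner, self.seed)
        if self.rejection_target > 0:
            model.cutoff, model.calibration_curve = self._calibrate(X, y, enc)
        model.learner.fit(X, enc.transform(y))
        return model

    def _calibrate(self, X: np.ndarray, y: np.ndarray, enc: LabelEncoder):
        """Out-of-fold top scores drive the rejection-cutoff calibration."""
        from .evaluation import stratified_kfold_indices

        folds = stratified_kfold_indices(y, k=self.calibration_folds, seed=self.seed)
        points: list[tuple[float, bool]] = []
        for train_idx, test_idx in folds:
            if len(np.unique(y[train_idx])) < 2 or len(test_idx) == 0:
                continue
            learner = make_learner(self.learner, self.seed)
            sub_enc = LabelEncoder().fit(y[train_idx])
            learner.fit(X[train_idx], sub_enc.transform(y[train_idx]))
            proba = learner.predict_proba(X[test_idx])
            for row, true_lab in zip(proba, y[test_idx]):
                top = int(np.argmax(row))
                points.append((float(row[top]), sub_enc.classes_[top] == true_lab))
        if len(points) < 20:
            warnings.warn(
                f"order {self.order}: only {len(points)} validation points; "
                "rejection cutoff disabled"
            )
            return 0.0, None
        return calibrate_rejection_cutoff(points, self.rejection_target)

    # -- prediction ---------------------------------------------------------

    def predict_queries(
        self, queries: Mapping[str, str | Sequence[str]]
    ) -> list[PredictionResult]:
        """Hierarchical predictions (with rejection) for a batch of queries."""
        if self.mode_.mode == "direct_assign":
            label = self.mode_.direct_label
            l1 = label if _is_layer1(label) else "Chordata"
            l2 = None if _is_layer1(label) else label
            return [
                PredictionResult(
                    id=qid, order=self.order, layer1_label=l1, layer1_score=1.0,
                    layer2_label=l2, layer2_score=None if l2 is None else 1.0,
                    layer1_scores={l1: 1.0},
                )
                for qid in queries
            ]
        traits = self._encode_traits(queries)
        s1 = self.layer1_.score_queries(queries, traits)
        results = []
        need_l2: dict[str, PredictionResult] = {}
        for qid in queries:
            scores = s1.loc[qid]
            top_label = scores.idxmax()
            top = float(scores[top_label])
            res = PredictionResult(
                id=qid, order=self.order, layer1_scores=scores.to_dict()
            )
            if self.layer1_.direct_label is None and top < self.layer1_.cutoff:
                res.rejected = True
                res.note = "layer1 score below rejection cutoff"
            else:
                res.layer1_label = top_label
                res.layer1_score = top
                if top_label == "Chordata" and self.layer2_ is not None:
                    need_l2[qid] = res
            results.append(res)
        if need_l2:
            s2 = self.layer2_.score_queries(
                {qid: queries[qid] for qid in need_l2}, traits
            )
            for qid, res in need_l2.items():
                scores = s2.loc[qid]
                top_label = scores.idxmax()
                top = float(scores[top_label])
                res.layer2_scores = scores.to_dict()
                if self.layer2_.direct_label is None and top < self.layer2_.cutoff:
                    res.note = "layer2 score below rejection cutoff"
                else:
                    res.layer2_label = top_label
                    res.layer2_score = top
        return results

    def predict(self, X: Mapping[str, str | Sequence[str]]) -> np.ndarray:
        """Layer-1 labels for a batch of queries (sklearn-style surface)."""
        return np.array(
            [r.layer1_label for r in self.predict_queries(X)], dtype=object
        )


def _is_layer1(label: str) -> bool:
    from .taxonomy import LAYER1_LABELS

    return label in LAYER1_LABELS


class HostPredictor(BaseEstimator):
    """Bundle-level estimator: screening, routing and per-order classifiers.

    Fit on a full reference set (sequences + records); queries are routed by
    their order label to the matching :class:`OrderHostClassifier`.  Queries
    from orders absent from the bundle yield an explicit ``unsupported order``
    result rather than an exception; optionally the order of the global
    best-hit reference is used instead and the result marked
    ``order-inferred``.
    """

    def __init__(
        self,
        feature_set: str = "sbias",
        learner: str = "xgboost",
        aligner_backend: str = "auto",
        gene_caller: str = "naive_orf",
        seed: int = 0,
        rejection_target: float = 0.0,
        screen: bool = True,
        infer_order: bool = False,
    ):
        self.feature_set = feature_set
        self.learner = learner
        self.aligner_backend = aligner_backend
        self.gene_caller = gene_caller
        self.seed = seed
        self.rejection_target = rejection_target
        self.screen = screen
        self.infer_order = infer_order

    def fit(
        self, X: Mapping[str, str | Sequence[str]], y: Sequence[VirusRecord]
    ) -> "HostPredictor":
        from .taxonomy import build_default_taxonomy, screen_labels

        self.taxonomy_ = build_default_taxonomy()
        records = list(y)
        if self.screen:
            records, self.screening_report_ = screen_labels(records, taxonomy=self.taxonomy_)
        else:
            self.screening_report_ = None
        self.records_ = records
        by_order: dict[str, list[VirusRecord]] = {}
        for rec in records:
            by_order.setdefault(rec.order, []).append(rec)
        self.classifiers_ = {}
        for order, recs in sorted(by_order.items()):
            clf = OrderHostClassifier(
                order=order,
                feature_set=self.feature_set,
                learner=self.learner,
                aligner_backend=self.aligner_backend,
                gene_caller=self.gene_caller,
                seed=self.seed,
                rejection_target=self.rejection_target,
            )
            clf.fit({r.id: X[r.id] for r in recs}, recs)
            self.classifiers_[order] = clf
        self.reference_sequences_ = {r.id: X[r.id] for r in records}
        self.fingerprint_ = hashlib.sha256(
            ",".join(sorted(r.id for r in records)).encode()
        ).hexdigest()[:16]
        self.feature_layout_version_ = FEATURE_LAYOUT_VERSION
        self.aligner_backend_ = resolve_backend(self.aligner_backend)
        return self

    def predict_queries(
        self,
        queries: Mapping[str, str | Sequence[str]],
        orders: Mapping[str, str | None],
    ) -> list[PredictionResult]:
        routed: dict[str, dict[str, str]] = {}
        results: dict[str, PredictionResult] = {}
        inferred: set[str] = set()
        for qid, seq in queries.items():
            order = orders.get(qid)
            if order is None and self.infer_order:
                order = self._infer_order(seq)
                if order is not None:
                    inferred.add(qid)
            if order is None or order not in self.classifiers_:
                results[qid] = PredictionResult(
                    id=qid, order=order, rejected=True, note="unsupported order"
                )
            else:
                routed.setdefault(order, {})[qid] = seq
        for order, batch in routed.items():
            for res in self.classifiers_[order].predict_queries(batch):
                if res.id in inferred:
                    res.note = (res.note + "; " if res.note else "") + "order-inferred"
                results[res.id] = res
        return [results[qid] for qid in queries]

    def predict(
        self,
        queries: Mapping[str, str | Sequence[str]],
        orders: Mapping[str, str | None],
    ) -> pd.DataFrame:
        return predictions_to_frame(self.predict_queries(queries, orders))

    def _infer_order(self, seq: str | Sequence[str]) -> str | None:
        """Order of the global best-hit reference (fallback routing)."""
        from .homology import ReferenceGroupIndex, best_hit_scores

        by_order: dict[str, dict[str, str]] = {}
        for rec in self.records_:
            s = self.reference_sequences_[rec.id]
            by_order.setdefault(rec.order, {})[rec.id] = s if isinstance(s, str) else s[0]
        if len(by_order) < 2:
            return next(iter(by_order), None)
        index = ReferenceGroupIndex(scope=("*", "order"), groups=by_order)
        query = seq if isinstance(seq, str) else seq[0]
        scores = best_hit_scores(query, index, backend=self.aligner_backend_)
        best = max(scores, key=scores.get)
        return best if scores[best] > 1.0 else None
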