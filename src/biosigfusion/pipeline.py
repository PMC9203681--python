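"""End-to-end orchestration: windowing, FHM retention, HDPAB selection,
classification, and stratified 10-fold cross-validation.

The outer k-fold provides held-out test estimates; inside each training
fold the data are further split 8:1 (train : validation) so that together
with the 10% outer test fold the effective partition is the 80/10/10
train/validation/test scheme, with validation driving Bi-LSTM early
stopping.  Every training-derived artefact — feature normalisation
constants, the fitted fusion mixture, the retained-observation rule, the
selected feature mask, count-bin edges — is computed from training rows
only and applied unchanged to the held-out fold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import bilstm as bl
from . import fhm as fh
from . import hdpab as hd
from . import signal_features as sf
from . import zipmrm as zp
from .synthetic_data import SyntheticSpec, gen_two_class_signals

logger = logging.getLogger("biosigfusion")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything a full run needs; any field may come from a YAML file."""

    # input: either a synthetic spec or a directory of Bonn-style files
    synthetic: SyntheticSpec | None = field(default_factory=SyntheticSpec)
    input_dir: str | None = None
    window_length: int | None = None     # None -> one window per record
    overlap_fraction: float = 0.0
    # FHM
    Q_max: int = 3
    y0: float = 0.05
    g: float = 1.5
    fhm_eps: float = 1e-8
    fhm_max_iter: int = 200
    # HDPAB
    hdpab_NP: int = 12
    hdpab_iters: int = 12
    hdpab_lambda: float = 0.01
    mask_threshold: float = 0.5
    # classifiers
    classifier: str = "bilstm"           # bilstm | zipmrm | both
    hidden_size: int = 80
    learning_rate: float = 0.01
    batch_size: int = 40
    l2: float = 1e-4
    epochs: int = 40
    patience: int = 8
    zip_K: int = 2
    zip_levels: int = 8
    # cross-validation
    k: int = 10
    val_fraction: float = 1.0 / 9.0      # of the training fold -> 10% overall
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must lie in (0, 0.5)")
        if self.classifier not in ("bilstm", "zipmrm", "both"):
            raise ValueError("classifier must be bilstm, zipmrm or both")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticSpec(**raw["synthetic"])
        return cls(**raw)


@dataclass
class EvaluationReport:
    """Per-fold accuracies, confusion counts, masks and provenance."""

    fold_accuracies: dict[str, list[float]]
    mean_accuracy: dict[str, float]
    confusion: dict[str, list[list[int]]]
    selected_masks: list[list[bool]]
    feature_names: list[str]
    provenance: dict

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# CV plumbing
# ---------------------------------------------------------------------------

def kfold_split(
    n: int, k: int, seed: int, stratify_labels: Sequence | None = None
) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per index); folds are disjoint,
    exhaustive, and size-balanced to within one."""
    if n < k:
        raise ValueError("need at least k observations")
    labels = (
        np.zeros(n, dtype=int)
        if stratify_labels is None
        else np.asarray(stratify_labels)
    )
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        logger.warning(
            "a class has fewer than k members; stratification is best-effort"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((n, 1)), labels)):
        assignment[test_idx] = fold
    return assignment


def evaluate_accuracy(pred: Sequence, true: Sequence) -> float:
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError("prediction/truth length mismatch")
    return float(np.mean(pred == true))


def _fold_seed(base: int, fold: int) -> int:
    return int((base + 7919 * (fold + 1)) % (2**31 - 1))


# ---------------------------------------------------------------------------
# Single fold
# ---------------------------------------------------------------------------

def fit_fold(
    train_segments: list[sf.SignalRecord],
    test_segments: list[sf.SignalRecord],
    config: PipelineConfig,
    seed: int,
) -> dict:
    """Fit every stage on the training segments only and predict the
    held-out segments.  Returns predictions plus the training-derived
    artefacts (used by the leakage check)."""
    fm_train = sf.build_feature_matrix(train_segments)
    fm_test = sf.apply_normalization(test_segments, fm_train)
    y_train = np.asarray(fm_train.labels)
    classes = sorted(set(y_train))
    cls_index = {c: i for i, c in enumerate(classes)}

    # intensity weights from the training window matrix, aligned with the
    # rows that survived descriptor computation
    v = fh.svd_intensity(np.stack([s.samples for s in train_segments]))
    v = v[fm_train.source_mask]
    wei = fh.observation_weights(v, g=config.g)

    # FHM on the leading principal-component score of the normalised matrix
    z = _pc1_scores(fm_train.values)
    fitted = fh.select_model(
        z, wei, Q_max=config.Q_max, y0=config.y0, seed=seed,
        eps=config.fhm_eps, max_iter=config.fhm_max_iter,
    )
    retained = fitted.retained_mask.copy()
    note = ""
    kept_counts = [int((y_train[retained] == c).sum()) for c in classes]
    if retained.sum() < 10 or min(kept_counts) < 5:
        note = (
            f"retained set too small/one-class ({int(retained.sum())} rows); "
            "falling back to all training rows"
        )
        logger.info(note)
        retained = np.ones_like(retained)

    Xr = fm_train.values[retained]
    yr = y_train[retained]
    mask, history = hd.select_features(
        Xr, yr, NP=config.hdpab_NP, max_iter=config.hdpab_iters,
        lam=config.hdpab_lambda, threshold=config.mask_threshold, seed=seed,
    )

    y_int = np.array([cls_index[c] for c in yr])
    out: dict = {
        "artifacts": {
            "normalization": list(fm_train.normalization),
            "fhm_params": fitted.params.as_vector().tolist(),
            "fhm_class": fitted.model_class,
            "retained_mask": retained.tolist(),
            "selected_mask": mask.tolist(),
            "fhm_note": note,
            "hdpab_history": history.tolist(),
        },
        "classes": classes,
        "predictions": {},
    }

    if config.classifier in ("bilstm", "both"):
        Xs = bl.vectors_to_sequences(Xr[:, mask])
        strat = y_int if np.bincount(y_int).min() >= 2 else None
        Xtr, Xval, ytr, yval = train_test_split(
            Xs, y_int, test_size=config.val_fraction, random_state=seed,
            stratify=strat,
        )
        model, _ = bl.train_bilstm(
            (Xtr, ytr), (Xval, yval),
            hidden_size=config.hidden_size, lr=config.learning_rate,
            batch_size=config.batch_size, l2=config.l2,
            epochs=config.epochs, patience=config.patience, seed=seed,
        )
        pred_int, _ = bl.predict(
            model, bl.vectors_to_sequences(fm_test.values[:, mask])
        )
        out["predictions"]["bilstm"] = [classes[i] for i in pred_int]

    if config.classifier in ("zipmrm", "both"):
        counts_train, edges = zp.discretize_counts(
            Xr[:, mask], levels=config.zip_levels
        )
        clf = zp.ZIPMRMClassifier(
            K=config.zip_K, seed=seed, max_iter=60,
        ).fit(counts_train, yr)
        counts_test = zp.apply_count_bins(fm_test.values[:, mask], edges)
        out["predictions"]["zipmrm"] = list(clf.predict(counts_test))
        out["artifacts"]["bin_edges"] = edges.tolist()

    return out


def _pc1_scores(X: np.ndarray) -> np.ndarray:
    """Leading principal-component score per observation (the scalar
    normalised data point the fusion mixture models), z-scored."""
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    score = U[:, 0] * s[0]
    sd = score.std()
    return score / sd if sd > 0 else score


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def load_segments(config: PipelineConfig) -> list[sf.SignalRecord]:
    """Materialise observation windows from the configured input."""
    if config.input_dir is not None:
        records = []
        root = Path(config.input_dir)
        labels_file = root / "labels.csv"
        if labels_file.exists():
            import pandas as pd

            tab = pd.read_csv(labels_file)
            for _, row in tab.iterrows():
                records.append(
                    sf.read_bonn_txt(root / row["file"], label=str(row["label"]))
                )
        else:
            raise FileNotFoundError(f"{labels_file} not found")
    else:
        records = gen_two_class_signals(config.synthetic)
    segments = []
    for rec in records:
        wl = config.window_length or len(rec)
        segments.extend(
            sf.segment_signal(rec, wl, config.overlap_fraction)
        )
    return segments


def run_pipeline(
    config: PipelineConfig, shuffle_labels: bool = False
) -> EvaluationReport:
    """Outer stratified k-fold over observation windows; per fold the full
    FHM -> HDPAB -> classifier stack is fitted on training rows only.

    ``shuffle_labels=True`` permutes the class labels (seeded) before the
    CV, giving the chance-level permutation null.
    """
    segments = load_segments(config)
    labels = np.array([s.label for s in segments])
    if shuffle_labels:
        rng = np.random.default_rng(config.seed + 1)
        labels = rng.permutation(labels)
        segments = [
            sf.SignalRecord(s.samples, s.sampling_rate, s.channel_id, lab)
            for s, lab in zip(segments, labels)
        ]
    n = len(segments)
    assignment = kfold_split(n, config.k, config.seed, labels)

    names = (
        ["bilstm", "zipmrm"] if config.classifier == "both"
        else [config.classifier]
    )
    fold_acc: dict[str, list[float]] = {m: [] for m in names}
    classes = sorted(set(labels))
    conf = {m: np.zeros((len(classes), len(classes)), dtype=int) for m in names}
    masks = []
    feature_names = list(sf.DEFAULT_DESCRIPTORS)
    for fold in range(config.k):
        te = assignment == fold
        tr_segments = [s for s, t in zip(segments, te) if not t]
        te_segments = [s for s, t in zip(segments, te) if t]
        result = fit_fold(
            tr_segments, te_segments, config, _fold_seed(config.seed, fold)
        )
        masks.append(result["artifacts"]["selected_mask"])
        y_true = labels[te]
        for m in names:
            pred = np.asarray(result["predictions"][m])
            fold_acc[m].append(evaluate_accuracy(pred, y_true))
            for t_lab, p_lab in zip(y_true, pred):
                conf[m][classes.index(t_lab), classes.index(p_lab)] += 1
    return EvaluationReport(
        fold_accuracies={m: list(map(float, v)) for m, v in fold_acc.items()},
        mean_accuracy={m: float(np.mean(v)) for m, v in fold_acc.items()},
        confusion={m: conf[m].tolist() for m in names},
        selected_masks=masks,
        feature_names=feature_names,
        provenance={
            "seed": config.seed,
            "k": config.k,
            "n_observations": int(n),
            "classifier": config.classifier,
            "shuffled": bool(shuffle_labels),
        },
    )


# ---------------------------------------------------------------------------
# Baseline comparison harness
# ---------------------------------------------------------------------------

def compare_baselines(
    features: np.ndarray,
    labels: Sequence,
    k: int = 10,
    seed: int = 0,
):
    """Established classifiers under the same CV protocol; rows mirror the
    comparison-table layout.  A missing optional dependency skips that
    baseline with a notice."""
    import pandas as pd
    from sklearn.discriminant_analysis import (
        LinearDiscriminantAnalysis, QuadraticDiscriminantAnalysis,
    )
    from sklearn.ensemble import AdaBoostClassifier
    from sklearn.mixture import GaussianMixture
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    assignment = kfold_split(len(y), k, seed, y)

    class _GMMClassifier:
        def fit(self, X, y):
            self.classes_ = np.unique(y)
            self.models_ = {
                c: GaussianMixture(
                    n_components=1, random_state=seed
                ).fit(X[y == c])
                for c in self.classes_
            }
            return self

        def predict(self, X):
            scores = np.column_stack(
                [self.models_[c].score_samples(X) for c in self.classes_]
            )
            return self.classes_[np.argmax(scores, axis=1)]

    builders = {
        "KNN": lambda: KNeighborsClassifier(),
        "NBC": lambda: GaussianNB(),
        "Adaboost": lambda: AdaBoostClassifier(random_state=seed),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "SVM-RBF": lambda: SVC(kernel="rbf"),
        "QDA": lambda: QuadraticDiscriminantAnalysis(),
        "GMM": lambda: _GMMClassifier(),
    }
    try:
        from hmmlearn.hmm import GaussianHMM

        class _HMMClassifier:
            def fit(self, X, y):
                self.classes_ = np.unique(y)
                self.models_ = {}
                for c in self.classes_:
                    m = GaussianHMM(
                        n_components=2, n_iter=20, random_state=seed
                    )
                    m.fit(X[y == c])
                    self.models_[c] = m
                return self

            def predict(self, X):
                scores = np.column_stack(
                    [
                        [self.models_[c].score(row[None, :]) for row in X]
                        for c in self.classes_
                    ]
                )
                return self.classes_[np.argmax(scores, axis=1)]

        builders["HMM"] = lambda: _HMMClassifier()
    except ImportError:
        logger.info("hmmlearn not installed; HMM baseline skipped")

    rows = []
    for name, build in builders.items():
        accs = []
        try:
            for fold in range(k):
                te = assignment == fold
                clf = build().fit(X[~te], y[~te])
                accs.append(evaluate_accuracy(clf.predict(X[te]), y[te]))
            rows.append({"classifier": name, "accuracy": float(np.mean(accs))})
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("baseline %s failed: %s", name, exc)
    return pd.DataFrame(rows)
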