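"""Leave-one-subject-out evaluation, accuracy metrics and the shared
on-disk dataset layout.

A dataset directory contains one sub-directory per subject with a
tab-delimited ``features.tsv`` (rows = features, columns = samples) and a
``labels.tsv`` (one integer per line), plus a top-level ``manifest.json``
recording the feature dimension, class count, feature index and optional
per-subject group tags.  Subjects are ordered lexicographically by id
everywhere, so fold numbering is stable across machines.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .pdpl import PDPLParams, TrainedModel, TrainingSet, predict_batch, train

log = logging.getLogger(__name__)


@dataclass
class SubjectRecord:
    subject_id: str
    X: np.ndarray  # p x n_s
    labels: np.ndarray  # n_s ints in 1..K
    group: str | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.ndim != 2:
            raise ValueError(f"subject {self.subject_id}: X must be 2-D")
        if self.X.shape[1] != self.labels.size:
            raise ValueError(f"subject {self.subject_id}: one label per column required")


@dataclass
class FeatureDataset:
    """Per-subject feature matrices with a shared feature space and label set."""

    subjects: list[SubjectRecord]
    K: int
    feature_index: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset has no subjects")
        self.subjects = sorted(self.subjects, key=lambda s: s.subject_id)
        p = self.subjects[0].X.shape[0]
        for s in self.subjects:
            if s.X.shape[0] != p:
                raise ValueError(
                    f"subject {s.subject_id}: feature dimension {s.X.shape[0]} != {p}"
                )
            bad = (s.labels < 1) | (s.labels > self.K)
            if bad.any():
                raise ValueError(
                    f"subject {s.subject_id}: labels outside 1..{self.K}"
                )

    @property
    def p(self) -> int:
        return self.subjects[0].X.shape[0]

    @property
    def N(self) -> int:
        return len(self.subjects)


@dataclass
class LOSOResult:
    subject_ids: list[str]
    accuracies: np.ndarray
    mean: float
    std: float
    ci95: tuple[float, float]
    per_fold_seconds: list[float] = field(default_factory=list)


def group_by_class(X: np.ndarray, labels: np.ndarray, K: int) -> TrainingSet:
    """Split columns of X into K class blocks; errors if a class is empty."""
    labels = np.asarray(labels, dtype=int)
    blocks = []
    for k in range(1, K + 1):
        cols = X[:, labels == k]
        if cols.shape[1] == 0:
            raise ValueError(f"training fold contains no samples of class {k}")
        blocks.append(cols)
    return TrainingSet(blocks)


def loso_folds(ds: FeatureDataset):
    """Yield (TrainingSet, held-out SubjectRecord) pairs, one per subject."""
    if ds.N < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    for i, test in enumerate(ds.subjects):
        train_subjects = [s for j, s in enumerate(ds.subjects) if j != i]
        X = np.hstack([s.X for s in train_subjects])
        y = np.concatenate([s.labels for s in train_subjects])
        yield group_by_class(X, y, ds.K), test


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.size != truth.size:
        raise ValueError("prediction and truth lengths differ")
    if pred.size == 0:
        raise ValueError("cannot compute accuracy of zero samples")
    return float(np.mean(pred == truth))


def ci95(accs: np.ndarray) -> tuple[float, float]:
    """Student-t 95% interval over per-subject accuracies, clipped to [0, 1]."""
    accs = np.asarray(accs, dtype=float)
    n = accs.size
    if n < 2:
        raise ValueError("confidence interval needs at least 2 values")
    mean = accs.mean()
    sd = accs.std(ddof=1)
    half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return (max(0.0, mean - half), min(1.0, mean + half))


def run_loso(
    ds: FeatureDataset, params: PDPLParams, on_fold_error: str = "raise"
) -> LOSOResult:
    """Train on all-but-one subject, test on the held-out one, for every subject.

    ``on_fold_error="zero"`` scores a failing fold as accuracy 0 with a
    warning instead of propagating (used inside the GA fitness so a bad
    parameter vector cannot crash the search).
    """
    accs, ids, times = [], [], []
    for fold, (train_set, test_subject) in enumerate(loso_folds(ds)):
        t0 = time.perf_counter()
        try:
            model = train(train_set, params)
            pred = predict_batch(model, test_subject.X)
            acc = accuracy(pred, test_subject.labels)
        except Exception as exc:
            if on_fold_error != "zero":
                raise RuntimeError(
                    f"LOSO fold {fold} (subject {test_subject.subject_id}) failed: {exc}"
                ) from exc
            warnings.warn(
                f"fold for subject {test_subject.subject_id} failed ({exc}); "
                "scoring accuracy 0",
                stacklevel=2,
            )
            acc = 0.0
        dt = time.perf_counter() - t0
        log.info("fold %d subject=%s acc=%.4f (%.2fs)", fold, test_subject.subject_id, acc, dt)
        accs.append(acc)
        ids.append(test_subject.subject_id)
        times.append(dt)
    accs = np.asarray(accs)
    return LOSOResult(
        subject_ids=ids,
        accuracies=accs,
        mean=float(accs.mean()),
        std=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        ci95=ci95(accs) if accs.size > 1 else (float(accs[0]), float(accs[0])),
        per_fold_seconds=times,
    )


def summarize_by_group(
    result: LOSOResult, groups: dict[str, str]
) -> dict[str, tuple[float, float]]:
    """Group-wise (mean, std) of per-subject accuracies."""
    for sid in result.subject_ids:
        if sid not in groups:
            raise KeyError(f"no group tag for subject {sid!r}")
    out: dict[str, tuple[float, float]] = {}
    tags = sorted(set(groups[sid] for sid in result.subject_ids))
    for tag in tags:
        vals = np.array(
            [a for sid, a in zip(result.subject_ids, result.accuracies) if groups[sid] == tag]
        )
        out[tag] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return out


# ---------------------------------------------------------------------------
# On-disk dataset layout


def save_dataset(ds: FeatureDataset, path: str | Path) -> None:
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "p": ds.p,
        "K": ds.K,
        "feature_index": ds.feature_index,
        "subjects": [
            {"subject_id": s.subject_id, "group": s.group} for s in ds.subjects
        ],
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for s in ds.subjects:
        sub = root / s.subject_id
        sub.mkdir(exist_ok=True)
        np.savetxt(sub / "features.tsv", s.X, delimiter="\t")
        np.savetxt(sub / "labels.tsv", s.labels, fmt="%d")


def load_dataset(path: str | Path) -> FeatureDataset:
    root = Path(path)
    manifest = json.loads((root / "manifest.json").read_text())
    subjects = []
    for rec in manifest["subjects"]:
        sid = rec["subject_id"]
        X = np.loadtxt(root / sid / "features.tsv", delimiter="\t", ndmin=2)
        labels = np.loadtxt(root / sid / "labels.tsv", dtype=int, ndmin=1)
        subjects.append(SubjectRecord(sid, X, labels, group=rec.get("group")))
    fi = manifest.get("feature_index")
    return FeatureDataset(
        subjects,
        K=manifest["K"],
        feature_index=[tuple(t) for t in fi] if fi else None,
    )
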