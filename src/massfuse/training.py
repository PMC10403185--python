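"""Cohort splitting, five-fold cross-validation, and scoring.

The fixed test set is held out once; K-fold cross-validation rotates over the
merged train+validation pool. Every fold trains a fresh network on the other
folds, early-stops on held-out-fold AUC, contributes out-of-fold scores, and
scores the fixed test set; test-set scores are pooled by averaging P2 across
the fold models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import ScoredCohort, auc_mann_whitney
from .nn.network import MassClassifier3d, NetworkConfig, build_network
from .nn.optim import Adam, cross_entropy


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class SplitPlan:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    fold_assignments: dict[str, int]   # case_id -> fold in {1..k} over train+val
    seed: int

    def __post_init__(self) -> None:
        pools = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        if sum(len(p) for p in pools) != len(set().union(*pools)):
            raise ValueError("train/val/test must be disjoint")
        dev = set(self.train_ids) | set(self.val_ids)
        if set(self.fold_assignments) != dev:
            raise ValueError("folds must partition train+val exactly")

    @property
    def n_folds(self) -> int:
        return max(self.fold_assignments.values())

    def fold_members(self, fold: int) -> list[str]:
        return [c for c, f in self.fold_assignments.items() if f == fold]


@dataclass
class Hyperparams:
    lr: float = 1e-4
    batch_size: int = 4
    max_epochs: int = 100
    patience: int = 15
    optimizer: str = "adam"
    seed: int = 0


@dataclass
class TrainRun:
    fold: int
    config: NetworkConfig
    hyperparams: Hyperparams
    trace: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_auc: float = float("nan")


@dataclass
class TensorDataset:
    """In-memory channel tensors with binary labels (1 = malignant)."""

    case_ids: list[str]
    x: np.ndarray                # (N, C, s, s, s)
    y: np.ndarray                # (N,) in {0, 1}

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y).astype(int)
        if not (len(self.case_ids) == self.x.shape[0] == self.y.size):
            raise ValueError("case_ids, x and y must align")
        self._index = {c: i for i, c in enumerate(self.case_ids)}

    def subset(self, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [self._index[c] for c in ids]
        return self.x[idx], self.y[idx]

    @classmethod
    def from_tensor_dir(cls, tensor_dir: str | Path) -> "TensorDataset":
        from .preprocessing import ModelInputTensor
        files = sorted(Path(tensor_dir).glob("*.npz"))
        if not files:
            raise FileNotFoundError(f"no tensor files in {tensor_dir}")
        tensors = [ModelInputTensor.load(f) for f in files]
        return cls(case_ids=[t.case_id for t in tensors],
                   x=np.stack([t.channels for t in tensors]),
                   y=np.array([1 if t.label == "malignant" else 0 for t in tensors]))


def _stratified_partition(ids_by_class: dict[str, list[str]], sizes: tuple[int, ...],
                          rng: np.random.Generator) -> list[list[str]]:
    """Exact-size partition, per-class proportional within +/- 1 (largest remainder)."""
    total = sum(len(v) for v in ids_by_class.values())
    if sum(sizes) != total:
        raise ValueError(f"sizes {sizes} must sum to cohort size {total}")
    quotas = {}
    for cls_label, members in ids_by_class.items():
        ideal = np.array([len(members) * s / total for s in sizes])
        base = np.floor(ideal).astype(int)
        short = len(members) - base.sum()
        order = np.argsort(-(ideal - base), kind="stable")
        base[order[:short]] += 1
        quotas[cls_label] = base
    # repair column sums (each off by at most the number of classes)
    col = np.sum(list(quotas.values()), axis=0)
    while not np.array_equal(col, np.asarray(sizes)):
        over = int(np.argmax(col - np.asarray(sizes)))
        under = int(np.argmin(col - np.asarray(sizes)))
        donor = max(quotas, key=lambda c: quotas[c][over] - len(ids_by_class[c])
                    * sizes[over] / total)
        quotas[donor][over] -= 1
        quotas[donor][under] += 1
        col = np.sum(list(quotas.values()), axis=0)
    subsets: list[list[str]] = [[] for _ in sizes]
    for cls_label, members in ids_by_class.items():
        members = list(members)
        rng.shuffle(members)
        start = 0
        for j, q in enumerate(quotas[cls_label]):
            subsets[j].extend(members[start:start + q])
            start += q
        if any(q < 0 for q in quotas[cls_label]):
            raise ValueError(f"class {cls_label!r} has too few members to stratify")
    return subsets


def make_split(labels: dict[str, str], sizes: tuple[int, int, int], seed: int,
               n_folds: int = 5) -> SplitPlan:
    """Label-stratified train/val/test split plus stratified CV folds.

    ``labels`` maps case_id -> "benign"/"malignant" (a CohortManifest's
    ``labels()``); deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ids_by_class = {}
    for cid in sorted(labels):
        ids_by_class.setdefault(labels[cid], []).append(cid)
    train, val, test = _stratified_partition(ids_by_class, sizes, rng)
    dev = train + val
    folds: dict[str, int] = {}
    for cls_label in sorted(ids_by_class):
        members = [c for c in dev if labels[c] == cls_label]
        rng.shuffle(members)
        for i, cid in enumerate(members):
            folds[cid] = i % n_folds + 1
    return SplitPlan(train_ids=train, val_ids=val, test_ids=test,
                     fold_assignments=folds, seed=seed)


def _score(net: MassClassifier3d, x: np.ndarray, batch: int = 8) -> np.ndarray:
    """Malignant probability P2 for each row of x (eval mode)."""
    net.set_training(False)
    out = []
    for i in range(0, x.shape[0], batch):
        from .nn.layers import softmax
        out.append(softmax(net.forward(x[i:i + batch]), axis=1)[:, 1])
    return np.concatenate(out) if out else np.empty(0)


def train_model(x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray, y_val: np.ndarray,
                config: NetworkConfig, hyper: Hyperparams,
                fold: int = 0) -> tuple[MassClassifier3d, TrainRun]:
    """Train one network with early stopping on validation AUC."""
    net = build_network(config, seed=hyper.seed + 1000 * fold)
    opt = Adam(net.params(), lr=hyper.lr)
    rng = np.random.default_rng(hyper.seed + 1000 * fold + 1)
    run = TrainRun(fold=fold, config=config, hyperparams=hyper)
    best_state, best_auc, best_epoch = None, -np.inf, -1
    n = x_train.shape[0]
    for epoch in range(hyper.max_epochs):
        net.set_training(True)
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, hyper.batch_size):
            idx = order[i:i + hyper.batch_size]
            logits = net.forward(x_train[idx])
            loss, grad = cross_entropy(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"fold {fold}: non-finite loss at epoch {epoch}, batch {i}")
            opt.zero_grad()
            net.backward(grad)
            opt.step()
            losses.append(loss)
        val_scores = _score(net, x_val)
        val_auc = auc_mann_whitney(y_val, val_scores) if 0 < y_val.sum() < y_val.size \
            else float("nan")
        run.trace.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                          "val_auc": float(val_auc)})
        if np.isfinite(val_auc) and val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_state = net.state_dict()
        if epoch - best_epoch >= hyper.patience:
            break
    if best_state is not None:
        net.load_state_dict(best_state)
    run.best_epoch, run.best_val_auc = best_epoch, float(best_auc)
    return net, run


@dataclass
class CVResult:
    runs: list[TrainRun]
    oof: ScoredCohort              # pooled out-of-fold scores over train+val
    test: ScoredCohort | None      # mean-ensembled fixed test set (if any)
    per_fold_test: pd.DataFrame | None

    def oof_frame(self) -> pd.DataFrame:
        return self.oof.to_frame()


def run_cv(dataset: TensorDataset, split: SplitPlan, config: NetworkConfig,
           hyper: Hyperparams) -> CVResult:
    """Five-fold (or k-fold) CV over train+val with a fixed held-out test set."""
    labels = dict(zip(dataset.case_ids, dataset.y))
    oof_ids: list[str] = []
    oof_scores: list[float] = []
    oof_labels: list[int] = []
    runs: list[TrainRun] = []
    test_rows = []
    test_ids = list(split.test_ids)
    x_test, y_test = (dataset.subset(test_ids) if test_ids else (None, None))
    test_score_stack = []
    for fold in range(1, split.n_folds + 1):
        val_ids = sorted(split.fold_members(fold))
        train_ids = sorted(set(split.fold_assignments) - set(val_ids))
        x_tr, y_tr = dataset.subset(train_ids)
        x_va, y_va = dataset.subset(val_ids)
        net, run = train_model(x_tr, y_tr, x_va, y_va, config, hyper, fold=fold)
        runs.append(run)
        fold_scores = _score(net, x_va)
        oof_ids.extend(val_ids)
        oof_scores.extend(fold_scores.tolist())
        oof_labels.extend(int(labels[c]) for c in val_ids)
        if test_ids:
            s = _score(net, x_test)
            test_score_stack.append(s)
            for cid, sc in zip(test_ids, s):
                test_rows.append({"fold": fold, "case_id": cid,
                                  "label": int(labels[cid]), "p2": float(sc)})
    oof = ScoredCohort(case_ids=oof_ids, labels=np.array(oof_labels),
                       scores=np.array(oof_scores))
    test_cohort, per_fold = None, None
    if test_ids:
        mean_scores = np.mean(test_score_stack, axis=0)
        test_cohort = ScoredCohort(case_ids=test_ids, labels=y_test,
                                   scores=mean_scores)
        per_fold = pd.DataFrame(test_rows)
    return CVResult(runs=runs, oof=oof, test=test_cohort, per_fold_test=per_fold)


def write_scores(result: CVResult, path: str | Path, split: SplitPlan) -> Path:
    """Scores CSV: case_id, label, p1, p2, fold (fold 0 = ensembled test row)."""
    path = Path(path)
    df = result.oof.to_frame()
    df["fold"] = [split.fold_assignments[c] for c in result.oof.case_ids]
    if result.test is not None:
        t = result.test.to_frame()
        t["fold"] = 0
        df = pd.concat([df, t], ignore_index=True)
    df.to_csv(path, index=False)
    return path
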