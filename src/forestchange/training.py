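"""Automatic training extraction and consensus label-noise filtering.

Training pixels come from local windows of the SWIR difference image.  In
each window the mean μ and standard deviation σ of the valid difference
values are computed and three labels assigned:

* disturbed  — d < μ − kσ          (default k = 1.5, fixed across windows)
* regrowth   — d > μ + kσ
* no-change  — |d − μ| < 0.5σ, randomly subsampled to at most the size of
  the larger tail so the classes stay balanced.

A window contributes samples only when at least a quarter of it is valid
and both tails hold at least ``min_tail_count`` pixels; the threshold value
therefore adapts per window while the sigma-multiplier stays fixed.

Because thresholds, masks and the forest screen all make mistakes, the raw
labels are then passed through a consensus filter: a stratified n-fold
cross-validation in which four classifier families (max-margin, decision
tree, nearest-neighbour, small feed-forward network) are each trained on a
stratified 70 % subsample of the training folds and predict the held-out
fold.  A sample is discarded only when *every* family mispredicts its
label — a deliberately conservative rule that removes samples no model of
the feature space can explain rather than samples any one model dislikes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .config import PipelineConfig
from .features import DiffImage, FeatureStack
from .masking import MaskSet

logger = logging.getLogger(__name__)

LABELS = ("disturbed", "regrowth", "no-change")
LABEL_IDS = {name: i for i, name in enumerate(LABELS)}
DISTURBED, REGROWTH, NO_CHANGE = 0, 1, 2


class TrainingExtractionError(RuntimeError):
    """No window passed the sufficiency rules: no training is extractable."""


@dataclass
class LocalWindow:
    origin: tuple[int, int]
    size: tuple[int, int]
    mean: float
    std: float
    valid_count: int


@dataclass
class TrainingSet:
    rows: np.ndarray  # (n,) pixel row
    cols: np.ndarray  # (n,) pixel col
    features: np.ndarray  # (n, 6)
    labels: np.ndarray  # (n,) int label ids
    window_ids: np.ndarray  # (n,) index into `windows`
    windows: list[LocalWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.labels == i).sum()) for i, name in enumerate(LABELS)}

    def subset(self, keep: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            rows=self.rows[keep],
            cols=self.cols[keep],
            features=self.features[keep],
            labels=self.labels[keep],
            window_ids=self.window_ids[keep],
            windows=self.windows,
        )

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "row": self.rows,
                "col": self.cols,
                "label": [LABELS[i] for i in self.labels],
                "window_id": self.window_ids,
            }
        )
        from .features import FEATURE_NAMES

        for i, name in enumerate(FEATURE_NAMES):
            df[name] = self.features[:, i]
        return df


@dataclass
class FilterReport:
    removed_ids: np.ndarray  # indices into the original TrainingSet
    n_original: int
    misclassified_per_family: dict[str, int]
    fold_count: int
    train_fraction_used: float  # measured fraction of fold-train pop. per fit

    @property
    def removal_fraction(self) -> float:
        return len(self.removed_ids) / self.n_original if self.n_original else 0.0

    def to_dict(self) -> dict:
        return {
            "removed_ids": [int(i) for i in self.removed_ids],
            "n_original": self.n_original,
            "removal_fraction": self.removal_fraction,
            "misclassified_per_family": dict(self.misclassified_per_family),
            "fold_count": self.fold_count,
            "train_fraction_used": self.train_fraction_used,
        }


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def window_thresholds(mean: float, std: float, cfg: PipelineConfig):
    """(lower, upper) tail thresholds: μ ∓ kσ with the fixed multiplier k."""
    k = cfg.threshold_multiplier
    return mean - k * std, mean + k * std


def extract_training(
    diff: DiffImage,
    masks: MaskSet,
    stack: FeatureStack,
    cfg: PipelineConfig,
) -> TrainingSet:
    """Label training pixels by local-window thresholding of the difference."""
    d = diff.data
    valid = masks.valid
    h, w = d.shape
    rng = np.random.default_rng(cfg.rng_seed)
    rows_all, cols_all, labels_all, wids_all = [], [], [], []
    windows: list[LocalWindow] = []
    stride = cfg.effective_stride
    for r0 in range(0, h, stride):
        for c0 in range(0, w, stride):
            r1, c1 = min(r0 + cfg.window_size, h), min(c0 + cfg.window_size, w)
            vwin = valid[r0:r1, c0:c1]
            n_total = (r1 - r0) * (c1 - c0)
            n_valid = int(vwin.sum())
            if n_total == 0 or n_valid == 0:
                continue
            vals = d[r0:r1, c0:c1][vwin]
            mu = float(vals.mean())
            sigma = float(vals.std())
            windows.append(LocalWindow((r0, c0), (r1 - r0, c1 - c0), mu, sigma, n_valid))
            wid = len(windows) - 1
            if n_valid / n_total < cfg.window_min_valid_frac:
                continue
            if sigma == 0.0:
                continue  # degenerate window: no tails exist
            lower, upper = window_thresholds(mu, sigma, cfg)
            win = d[r0:r1, c0:c1]
            dist = vwin & (win < lower)
            regr = vwin & (win > upper)
            n_dist, n_regr = int(dist.sum()), int(regr.sum())
            if n_dist < cfg.min_tail_count or n_regr < cfg.min_tail_count:
                continue
            noch = vwin & (np.abs(win - mu) < cfg.no_change_band * sigma)
            nc_rows, nc_cols = np.nonzero(noch)
            cap = max(n_dist, n_regr)
            if len(nc_rows) > cap:
                pick = rng.choice(len(nc_rows), size=cap, replace=False)
                pick.sort()
                nc_rows, nc_cols = nc_rows[pick], nc_cols[pick]
            for mask_or_idx, label in ((dist, DISTURBED), (regr, REGROWTH)):
                rr, cc = np.nonzero(mask_or_idx)
                rows_all.append(rr + r0)
                cols_all.append(cc + c0)
                labels_all.append(np.full(len(rr), label))
                wids_all.append(np.full(len(rr), wid))
            rows_all.append(nc_rows + r0)
            cols_all.append(nc_cols + c0)
            labels_all.append(np.full(len(nc_rows), NO_CHANGE))
            wids_all.append(np.full(len(nc_rows), wid))
    if not rows_all:
        raise TrainingExtractionError(
            "no local window passed the sufficiency rules; no training extractable"
        )
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    labels = np.concatenate(labels_all).astype(np.int64)
    wids = np.concatenate(wids_all).astype(np.int64)
    if len(labels) > cfg.max_training_samples:
        pick = _stratified_subsample(
            labels, np.arange(len(labels)),
            cfg.max_training_samples / len(labels), rng,
        )
        rows, cols, labels, wids = rows[pick], cols[pick], labels[pick], wids[pick]
    ts = TrainingSet(
        rows=rows,
        cols=cols,
        features=stack.vectors(rows, cols),
        labels=labels,
        window_ids=wids,
        windows=windows,
    )
    logger.info("extracted %d training samples: %s", len(ts), ts.class_counts())
    return ts


# ---------------------------------------------------------------------------
# consensus filter
# ---------------------------------------------------------------------------

def _filter_families(cfg: PipelineConfig, seed: int) -> dict[str, object]:
    """The four filter classifier families, each behind a standardizing pipeline."""
    return {
        "svm": make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0, gamma="scale")),
        "tree": make_pipeline(
            StandardScaler(),
            DecisionTreeClassifier(max_depth=cfg.filter_tree_max_depth, random_state=seed),
        ),
        "knn": make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=cfg.filter_knn_k)),
        "mlp": make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(cfg.filter_mlp_hidden,),
                max_iter=cfg.filter_mlp_max_iter,
                random_state=seed,
            ),
        ),
    }


def _stratified_folds(labels: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Fold assignment per sample; every class is spread over the folds even
    when it holds fewer than ``n_folds`` members."""
    fold = np.empty(len(labels), dtype=np.int64)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _stratified_subsample(
    labels: np.ndarray, indices: np.ndarray, frac: float, rng: np.random.Generator
) -> np.ndarray:
    """Take ``frac`` of ``indices`` per class, without replacement, keeping the
    class distribution of the whole pool (at least one per class)."""
    out = []
    for cls in np.unique(labels[indices]):
        pool = indices[labels[indices] == cls]
        n = max(1, int(round(frac * len(pool))))
        out.append(rng.choice(pool, size=min(n, len(pool)), replace=False))
    return np.sort(np.concatenate(out))


def label_flip_experiment(
    cfg: PipelineConfig,
    n_per_class: int = 1000,
    flip_frac: float = 0.10,
    separation: float = 6.0,
) -> dict[str, float]:
    """Benchmark the consensus filter on blobs with injected label flips.

    Three well-separated Gaussian classes in the 6-feature space get
    ``flip_frac`` of their labels flipped at random; the filter is then
    asked to find them.  Returns the fraction of flipped samples removed,
    the fraction of clean samples removed, and the overall removal
    fraction.  Deterministic given ``cfg.rng_seed``.
    """
    rng = np.random.default_rng(cfg.rng_seed + 10)
    centers = np.zeros((3, 6))
    centers[0, 0] = -separation
    centers[1, 0] = +separation
    centers[2, 1] = +separation
    X = np.concatenate([rng.normal(c, 1.0, (n_per_class, 6)) for c in centers])
    y = np.repeat(np.arange(3), n_per_class)
    n = len(y)
    flipped = np.zeros(n, dtype=bool)
    idx = rng.choice(n, size=int(round(flip_frac * n)), replace=False)
    y = y.copy()
    y[idx] = (y[idx] + 1 + rng.integers(0, 2, len(idx))) % 3
    flipped[idx] = True
    ts = TrainingSet(
        rows=np.zeros(n, dtype=np.int64),
        cols=np.arange(n, dtype=np.int64),
        features=X,
        labels=y.astype(np.int64),
        window_ids=np.zeros(n, dtype=np.int64),
    )
    _, report = consensus_filter(ts, cfg)
    removed = np.zeros(n, dtype=bool)
    removed[report.removed_ids] = True
    return {
        "flip_removed_frac": float((removed & flipped).sum() / flipped.sum()),
        "clean_removed_frac": float((removed & ~flipped).sum() / (~flipped).sum()),
        "removal_fraction": report.removal_fraction,
        "fold_count": report.fold_count,
        "train_fraction_used": report.train_fraction_used,
    }


def consensus_filter(
    ts: TrainingSet, cfg: PipelineConfig
) -> tuple[TrainingSet, FilterReport]:
    """Remove samples that every filter family, cross-validated, mislabels."""
    n = len(ts)
    labels = ts.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("consensus filtering requires at least two classes")
    exempt_classes = set(int(c) for c, cnt in zip(classes, counts) if cnt < cfg.n_folds)
    for c in exempt_classes:
        logger.warning(
            "class %r has fewer than %d samples; exempted from removal",
            LABELS[c], cfg.n_folds,
        )

    rng = np.random.default_rng(cfg.rng_seed + 1)
    fold = _stratified_folds(labels, cfg.n_folds, rng)
    families = sorted(_filter_families(cfg, cfg.rng_seed).keys())
    miss = {fam: np.zeros(n, dtype=bool) for fam in families}
    frac_used: list[float] = []
    for f in range(cfg.n_folds):
        test_idx = np.nonzero(fold == f)[0]
        train_pool = np.nonzero(fold != f)[0]
        if len(test_idx) == 0 or len(np.unique(labels[train_pool])) < 2:
            continue
        models = _filter_families(cfg, cfg.rng_seed + 100 + f)
        for fam in families:
            sub = _stratified_subsample(labels, train_pool, cfg.filter_train_frac, rng)
            frac_used.append(len(sub) / len(train_pool))
            model = models[fam]
            model.fit(ts.features[sub], labels[sub])
            pred = model.predict(ts.features[test_idx])
            miss[fam][test_idx] = pred != labels[test_idx]

    miss_matrix = np.stack([miss[fam] for fam in families])  # (4, n)
    if cfg.filter_mode == "consensus":
        flagged = miss_matrix.all(axis=0)
    else:  # majority
        flagged = miss_matrix.sum(axis=0) > len(families) / 2
    for c in exempt_classes:
        flagged &= labels != c
    removed = np.nonzero(flagged)[0]
    report = FilterReport(
        removed_ids=removed,
        n_original=n,
        misclassified_per_family={fam: int(miss[fam].sum()) for fam in families},
        fold_count=cfg.n_folds,
        train_fraction_used=float(np.mean(frac_used)) if frac_used else 0.0,
    )
    filtered = ts.subset(~flagged)
    logger.info(
        "consensus filter removed %d of %d samples (%.1f%%)",
        len(removed), n, 100 * report.removal_fraction,
    )
    return filtered, report
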