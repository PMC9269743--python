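"""Nocturnal hypoglycemia prediction with synthetic-data augmentation.

A *night instance* is built from a day row anchored at 17:00: the features
are the 60 CGM readings between 17:00 and 22:00 (five pre-sleep hours) and
the binary label is derived exclusively from the 22:00-06:00 window — a
night is positive when the monitor registers at least three consecutive
readings strictly below 70 mg/dL in that window.

The classifier is a small 1-D convolutional network (the same family as
the GAN discriminator, scaled to a 60-sample input) emitting the
probability of nocturnal hypoglycemia; labels are thresholded at 0.5.

``run_protocol`` implements the evaluation discipline for augmentation
studies: repeated stratified k-fold cross-validation over the *real*
instances, with synthetic instances appended to training folds only —
test folds never contain synthetic data — and per-fold metrics
(accuracy, sensitivity, specificity, Gmean, MCC) aggregated as medians
over fold x repetition.  Patients with fewer than five positive nights
are ineligible: their test folds would be too sparse to score the
classifier meaningfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import _nn
from .cgm_io import GLUCOSE_MAX, GLUCOSE_MIN, DayMatrix
from .gan import TrainedGAN, generate_days

__all__ = [
    "NightInstance",
    "ClassifierMetrics",
    "AugmentationResult",
    "NightClassifierConfig",
    "NightClassifier",
    "label_night",
    "extract_instances",
    "build_night_classifier",
    "evaluate_predictions",
    "run_protocol",
    "augmentation_sweep",
    "MIN_EVENTS",
    "FEATURE_LEN",
    "NIGHT_LEN",
]

FEATURE_LEN = 60   # 17:00 -> 22:00 at 5-minute steps
NIGHT_LEN = 96     # 22:00 -> 06:00
MIN_EVENTS = 5     # eligibility: minimum positive nights per patient
HYPO_THRESHOLD = 70.0
MIN_RUN = 3


@dataclass
class NightInstance:
    features: np.ndarray  # 60 glucose values, mg/dL
    label: int
    provenance: str = "real"

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (FEATURE_LEN,):
            raise ValueError(f"features must have exactly {FEATURE_LEN} values")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class ClassifierMetrics:
    """Percent metrics (acc/sen/sp/gmean) plus MCC in [-1, 1]."""

    acc: float
    sen: float
    sp: float
    gmean: float
    mcc: float

    def as_array(self) -> np.ndarray:
        return np.array([self.acc, self.sen, self.sp, self.gmean, self.mcc])


@dataclass
class AugmentationResult:
    per_fold: dict = field(default_factory=dict)   # condition -> list[ClassifierMetrics]
    median: dict = field(default_factory=dict)     # condition -> ClassifierMetrics
    n_synthetic: int = 0
    repetitions: int = 0
    seeds: list = field(default_factory=list)
    excluded: bool = False
    exclusion_reason: str = ""


def label_night(night_window: np.ndarray) -> int:
    """1 iff >= 3 consecutive samples strictly below 70 mg/dL."""
    w = np.asarray(night_window, dtype=float)
    if w.ndim != 1 or len(w) != NIGHT_LEN or np.isnan(w).any():
        raise ValueError(f"night window must be {NIGHT_LEN} complete samples")
    below = w < HYPO_THRESHOLD
    run = 0
    for b in below:
        run = run + 1 if b else 0
        if run >= MIN_RUN:
            return 1
    return 0


def extract_instances(days: DayMatrix) -> list[NightInstance]:
    """Night instances from a 17:00-anchored day matrix.

    Row samples [0, 60) are the pre-sleep features; the label comes from
    samples [60, 156), i.e. 22:00-06:00.  Provenance is inherited from the
    matrix.
    """
    if days.anchor_hour != 17:
        raise ValueError("night instances require a day matrix anchored at 17:00")
    out = []
    for row in days.rows:
        out.append(NightInstance(row[:FEATURE_LEN],
                                 label_night(row[FEATURE_LEN: FEATURE_LEN + NIGHT_LEN]),
                                 provenance=days.provenance))
    return out


@dataclass(frozen=True)
class NightClassifierConfig:
    channels: tuple = (8, 16)
    kernel: int = 5
    leaky_slope: float = 0.2
    pool: int = 2
    epochs: int = 25
    batch_size: int = 32
    lr: float = 3e-3
    threshold: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.channels or self.kernel < 1 or self.epochs < 0:
            raise ValueError("invalid classifier configuration")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")


class NightClassifier:
    """1-D conv net: 60 pre-sleep readings -> P(nocturnal hypoglycemia)."""

    def __init__(self, config: NightClassifierConfig = NightClassifierConfig()):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list[_nn.Layer] = []
        c_prev, length = 1, FEATURE_LEN
        for channels in config.channels:
            layers += [_nn.Conv1D(c_prev, channels, config.kernel, rng),
                       _nn.LeakyReLU(config.leaky_slope),
                       _nn.MaxPool1D(config.pool)]
            c_prev = channels
            length //= config.pool
        layers += [_nn.Flatten(), _nn.Dense(c_prev * length, 1, rng), _nn.Sigmoid()]
        self.net = _nn.Sequential(layers).astype(np.float32)
        self._rng = rng

    @staticmethod
    def _norm(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return ((X - GLUCOSE_MIN) / (GLUCOSE_MAX - GLUCOSE_MIN) * 2.0 - 1.0)[:, None, :]

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NightClassifier":
        Xn = self._norm(X)
        y = np.asarray(y, dtype=float)
        opt = _nn.Adam(self.net.params(), lr=self.config.lr)
        n = len(Xn)
        for _ in range(self.config.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.config.batch_size):
                idx = order[start: start + self.config.batch_size]
                opt.zero_grad()
                p = self.net.forward(Xn[idx])[:, 0]
                _, dp = _nn.bce_loss(p, y[idx])
                self.net.backward(dp[:, None])
                opt.step()
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.forward(self._norm(X))[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.config.threshold).astype(int)


def build_night_classifier(config: NightClassifierConfig = NightClassifierConfig()
                           ) -> NightClassifier:
    return NightClassifier(config)


def evaluate_predictions(pred_labels: np.ndarray, true_labels: np.ndarray
                         ) -> ClassifierMetrics:
    """Confusion-matrix metrics; class 1 (hypoglycemia night) is positive."""
    yp = np.asarray(pred_labels, dtype=int)
    yt = np.asarray(true_labels, dtype=int)
    if yp.shape != yt.shape:
        raise ValueError("prediction and truth lengths differ")
    pos, neg = int((yt == 1).sum()), int((yt == 0).sum())
    if pos == 0 or neg == 0:
        missing = "sensitivity" if pos == 0 else "specificity"
        raise ValueError(f"single-class truth: {missing} undefined")
    tp = int(((yp == 1) & (yt == 1)).sum())
    tn = int(((yp == 0) & (yt == 0)).sum())
    fp = int(((yp == 1) & (yt == 0)).sum())
    fn = int(((yp == 0) & (yt == 1)).sum())
    acc = 100.0 * (tp + tn) / len(yt)
    sen = 100.0 * tp / pos
    sp = 100.0 * tn / neg
    gmean = float(np.sqrt(sen * sp))
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return ClassifierMetrics(acc, sen, sp, gmean, float(mcc))


def _median_metrics(metrics: list[ClassifierMetrics]) -> ClassifierMetrics:
    arr = np.vstack([m.as_array() for m in metrics])
    return ClassifierMetrics(*np.median(arr, axis=0))


def _as_xy(instances: list[NightInstance]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([inst.features for inst in instances])
    y = np.array([inst.label for inst in instances], dtype=int)
    return X, y


def run_protocol(real: list[NightInstance], synth: list[NightInstance] | None = None,
                 k_folds: int = 5, repetitions: int = 20, base_seed: int = 0,
                 clf_config: NightClassifierConfig = NightClassifierConfig()
                 ) -> AugmentationResult:
    """Repeated stratified k-fold comparison of real-only vs augmented training.

    Synthetic instances are appended to every training fold; test folds are
    strictly real.  Repetition ``r`` uses seed ``base_seed + r`` for both
    the fold shuffle and the classifier initialization.  Patients with
    fewer than ``MIN_EVENTS`` positive nights yield an explicit exclusion
    result.
    """
    synth = synth or []
    if any(inst.provenance != "real" for inst in real):
        raise ValueError("the evaluation pool must contain only real instances")
    X, y = _as_xy(real)
    n_events = int(y.sum())
    if n_events < MIN_EVENTS:
        return AugmentationResult(
            excluded=True,
            exclusion_reason=(f"patient has {n_events} positive nights; "
                              f"at least {MIN_EVENTS} required"))
    conditions = {"real": []}
    if synth:
        conditions["augmented"] = synth
    seeds = [base_seed + r for r in range(repetitions)]
    per_fold: dict[str, list[ClassifierMetrics]] = {c: [] for c in conditions}
    for seed in seeds:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        for train_idx, test_idx in skf.split(X, y):
            for cond, extra in conditions.items():
                X_tr, y_tr = X[train_idx], y[train_idx]
                if extra:
                    Xs, ys = _as_xy(extra)
                    X_tr = np.vstack([X_tr, Xs])
                    y_tr = np.concatenate([y_tr, ys])
                cfg = NightClassifierConfig(**{**clf_config.__dict__, "seed": seed})
                clf = NightClassifier(cfg).fit(X_tr, y_tr)
                per_fold[cond].append(
                    evaluate_predictions(clf.predict(X[test_idx]), y[test_idx]))
    return AugmentationResult(
        per_fold=per_fold,
        median={c: _median_metrics(v) for c, v in per_fold.items()},
        n_synthetic=len(synth), repetitions=repetitions, seeds=seeds)


def synthetic_instances(gan: TrainedGAN, n: int, seed: int = 0) -> list[NightInstance]:
    """Generate ``n`` synthetic nights and label them with the night rule.

    The generator must have been trained on a 17:00-anchored day matrix so
    a generated row spans both the feature and the label windows.
    """
    return extract_instances(generate_days(gan, n, seed=seed))


def augmentation_sweep(real: list[NightInstance], gan: TrainedGAN,
                       sizes: tuple = tuple(range(500, 5001, 500)),
                       k_folds: int = 5, repetitions: int = 20, base_seed: int = 0,
                       clf_config: NightClassifierConfig = NightClassifierConfig()
                       ) -> dict:
    """Median metrics as a function of synthetic training-set size.

    Returns ``{"sizes": [...], "median": {size: {condition: metrics}},
    "gains": {...}}`` where ``gains`` summarizes how the Gmean improvement
    flattens across the sweep (early vs late gain).
    """
    sizes = tuple(sizes)
    if not sizes:
        raise ValueError("need at least one sweep size")
    results: dict[int, AugmentationResult] = {}
    for i, size in enumerate(sizes):
        synth = synthetic_instances(gan, size, seed=base_seed + 1000 + i)
        results[size] = run_protocol(real, synth, k_folds=k_folds,
                                     repetitions=repetitions, base_seed=base_seed,
                                     clf_config=clf_config)
    first = results[sizes[0]]
    if first.excluded:
        return {"sizes": list(sizes), "excluded": True,
                "reason": first.exclusion_reason}
    table = {size: {cond: res.median[cond] for cond in res.median}
             for size, res in results.items()}
    gains = {}
    if len(sizes) >= 3:
        gm = {s: table[s]["augmented"].gmean for s in sizes}
        mid = sizes[len(sizes) // 2]
        gains = {"early_gain": gm[mid] - gm[sizes[0]],
                 "late_gain": gm[sizes[-1]] - gm[mid],
                 "early_span": (sizes[0], mid), "late_span": (mid, sizes[-1])}
    return {"sizes": list(sizes), "median": table, "per_fold":
            {s: results[s].per_fold for s in sizes}, "gains": gains}
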