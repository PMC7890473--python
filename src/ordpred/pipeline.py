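"""Balanced target sampling, feature assembly and classifier evaluation.

The experiment protocol, run on any univariate series:

1. encode the series into D=3, tau=1 patterns;
2. sample ``n_per_class`` target windows per pattern code (balanced,
   without replacement, seeded), each with a full epoch of ``epoch_len``
   raw values before it and a preceding pattern (PRE);
3. compute epoch features (TPS, IRR, IRR_SYM and its components) on the
   epoch only — the epoch ends at the value immediately before the
   target's first value, so it never overlaps the target;
4. fit a classifier on a stratified 64/16/20 train/validation/test split
   and report per-class and macro precision, recall and AUC against the
   chance baseline.

Three prediction tasks share the sampled targets:

* analysis "1" — predict the target pattern code (6 classes) from PRE +
  TPS + IRR + IRR_SYM;
* analyses "2a"/"2b" — predict up-wave-after-up-wave (resp. down-after-
  down) from PRE + the six IRR_SYM components;
* analysis "3" — predict whether the fourth raw value exceeds the third
  (the UP flag) from PRE + TPS + IRR + IRR_SYM.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .features import LEGAL_MASK, LEGAL_PAIRS, tps_columns
from .patterns import UPWARD_CODES, encode_series

__all__ = [
    "ANALYSES",
    "CLASSIFIERS",
    "ExperimentConfig",
    "EvaluationReport",
    "sample_targets",
    "build_labels",
    "feature_table",
    "assemble_feature_table",
    "split_indices",
    "baseline_rates",
    "run_experiment",
    "feature_influence",
]

ANALYSES = ("1", "2a", "2b", "3")

_LABEL_COLUMN = {"1": "target", "2a": "up_after_up", "2b": "down_after_down", "3": "up"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to re-run one experiment deterministically."""

    n_per_class: int = 10_000
    epoch_len: int = 60
    split: tuple[float, float, float] = (0.64, 0.16, 0.20)
    seed: int = 0
    classifier: str = "gradient-boosting"
    analysis: str = "1"
    tps_mode: str = "joint"
    alpha: float = 1.0
    classifier_params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.epoch_len < 4:
            raise ValueError("epoch_len must be >= 4")
        if len(self.split) != 3 or abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}, got {self.analysis!r}")
        if self.tps_mode not in ("joint", "conditional"):
            raise ValueError(f"tps_mode must be 'joint' or 'conditional'")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; choose from {sorted(CLASSIFIERS)}"
            )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["split"] = list(self.split)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        d = dict(d)
        if "split" in d:
            d["split"] = tuple(d["split"])
        return cls(**d)


def build_labels(series, t: int) -> dict[str, int]:
    """Labels for the target window starting at raw index ``t``.

    The length-4 stretch (v[t-1] .. v[t+2]) covers PRE and the target;
    ``up`` compares the raw fourth value against the third (ties count as
    not-up), the wave flags compare PRE's and the target's clusters.
    """
    x = np.asarray(series, dtype=float).ravel()
    if t < 1 or t + 2 >= x.size:
        raise ValueError(f"target at {t} lacks a preceding window or a full window")
    pre = int(encode_series(x[t - 1 : t + 2]).codes[0])
    target = int(encode_series(x[t : t + 3]).codes[0])
    pre_up = pre in UPWARD_CODES
    tgt_up = target in UPWARD_CODES
    return {
        "t": int(t),
        "pre": pre,
        "target": target,
        "up_after_up": int(pre_up and tgt_up),
        "down_after_down": int(not pre_up and not tgt_up),
        "up": int(x[t + 2] > x[t + 1]),
    }


def sample_targets(series, cfg: ExperimentConfig) -> pd.DataFrame:
    """Balanced sample of target windows: ``n_per_class`` per pattern code.

    Eligible positions have a full epoch, a PRE window and a complete
    target window.  Returns a dataframe with columns ``t, pre, target,
    up_after_up, down_after_down, up`` in seeded-shuffled order.
    """
    x = np.asarray(series, dtype=float).ravel()
    codes = encode_series(x).codes
    m = codes.size
    lo, hi = cfg.epoch_len, m - 1  # inclusive range of eligible target starts
    if lo > hi:
        raise ValueError(
            f"series of length {x.size} has no eligible targets for "
            f"epoch_len={cfg.epoch_len}"
        )
    rng = np.random.default_rng(cfg.seed)
    eligible = np.arange(lo, hi + 1)
    chosen: list[np.ndarray] = []
    for c in range(1, 7):
        pool = eligible[codes[eligible] == c]
        if pool.size < cfg.n_per_class:
            raise ValueError(
                f"pattern class {c} has only {pool.size} eligible positions, "
                f"need {cfg.n_per_class}"
            )
        chosen.append(rng.choice(pool, size=cfg.n_per_class, replace=False))
    t = np.concatenate(chosen)
    rng.shuffle(t)

    pre = codes[t - 1]
    target = codes[t]
    pre_up = np.isin(pre, list(UPWARD_CODES))
    tgt_up = np.isin(target, list(UPWARD_CODES))
    return pd.DataFrame(
        {
            "t": t,
            "pre": pre,
            "target": target,
            "up_after_up": (pre_up & tgt_up).astype(int),
            "down_after_down": (~pre_up & ~tgt_up).astype(int),
            "up": (x[t + 2] > x[t + 1]).astype(int),
        }
    )


# per-row counts of legal successor cells inside / outside the row's cluster
_N_IN = np.array([2, 1, 2, 2, 1, 2], dtype=float)
_N_OUT = np.array([1, 2, 1, 1, 2, 1], dtype=float)
_IN_MASK = np.zeros((6, 6), dtype=bool)
for _i in range(6):
    for _j in range(6):
        if LEGAL_MASK[_i, _j]:
            same = ((_i + 1) in UPWARD_CODES) == ((_j + 1) in UPWARD_CODES)
            _IN_MASK[_i, _j] = same


def feature_table(
    series,
    targets: pd.DataFrame,
    epoch_len: int,
    *,
    alpha: float = 1.0,
    tps_mode: str = "joint",
) -> pd.DataFrame:
    """Epoch features for every sampled target, as one wide dataframe.

    Equivalent to calling :func:`ordpred.features.extract_epoch_features`
    per target, but the series (and its reversal) are encoded once and each
    epoch's pattern/transition counts are read off slices, which keeps tens
    of thousands of epochs cheap.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    codes = encode_series(x).codes
    rev_codes = encode_series(x[::-1]).codes
    ts = targets["t"].to_numpy()
    if (ts - epoch_len < 0).any() or (ts + 2 >= n).any():
        raise ValueError("a target lacks a full epoch or a complete window")

    n_rows = ts.size
    tps = np.empty((n_rows, 18))
    irr = np.empty(n_rows)
    comps = np.empty((n_rows, 6))
    legal_flat = np.flatnonzero(LEGAL_MASK.ravel())
    in_flat = _IN_MASK.ravel()[legal_flat]
    row_of = legal_flat // 6
    in_mat = np.zeros((18, 6))  # legal cell -> its row, split by cluster side
    out_mat = np.zeros((18, 6))
    for c in range(18):
        (in_mat if in_flat[c] else out_mat)[c, row_of[c]] = 1.0

    for k, t in enumerate(ts):
        ep = codes[t - epoch_len : t - 2]  # patterns fully inside the epoch
        pair = (ep[:-1] - 1) * 6 + (ep[1:] - 1)
        counts36 = np.bincount(pair, minlength=36).astype(float)
        legal_counts = counts36[legal_flat]
        n_tr = legal_counts.sum()

        if tps_mode == "joint":
            tps[k] = legal_counts / n_tr if n_tr > 0 else 0.0
        else:
            row_tot = counts36.reshape(6, 6).sum(axis=1)
            cond = counts36.reshape(6, 6) / np.maximum(row_tot, 1)[:, None]
            tps[k] = cond.ravel()[legal_flat]

        # IRR: forward vs backward pattern distributions of the epoch
        cf = np.bincount(ep - 1, minlength=6).astype(float)
        rev_lo = n - t  # reversed-series position of the epoch's last value
        eb = rev_codes[rev_lo : rev_lo + epoch_len - 2]
        cb = np.bincount(eb - 1, minlength=6).astype(float)
        pf = (cf + alpha) / (cf + alpha).sum()
        pb = (cb + alpha) / (cb + alpha).sum()
        irr[k] = max(float(np.sum(pf * np.log(pf / pb))), 0.0)

        # IRR_SYM components: out/in cluster count ratios with Laplace alpha;
        # the ratio is invariant to row normalisation, so counts suffice
        comps[k] = (legal_counts @ out_mat + alpha * _N_OUT) / (
            legal_counts @ in_mat + alpha * _N_IN
        )

    out = pd.DataFrame(tps, columns=tps_columns())
    out.insert(0, "pre", codes[ts - 1])
    out["irr"] = irr
    out["irr_sym"] = comps.mean(axis=1)
    for c in range(6):
        out[f"irr_sym_c{c + 1}"] = comps[:, c]
    out.index = targets.index
    return out


def assemble_feature_table(
    targets: pd.DataFrame, features: pd.DataFrame, analysis: str
) -> tuple[pd.DataFrame, pd.Series]:
    """Analysis-specific design matrix (PRE one-hot encoded) and label vector."""
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}, got {analysis!r}")
    onehot = pd.get_dummies(
        pd.Categorical(features["pre"], categories=range(1, 7)), prefix="pre"
    ).astype(float)
    onehot.index = features.index
    if analysis in ("1", "3"):
        cols = tps_columns() + ["irr", "irr_sym"]
    else:
        cols = [f"irr_sym_c{c}" for c in range(1, 7)]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise KeyError(f"feature table is missing columns: {missing}")
    X = pd.concat([onehot, features[cols]], axis=1)
    y = targets[_LABEL_COLUMN[analysis]]
    return X, y


def split_indices(
    labels: pd.Series | np.ndarray,
    split: tuple[float, float, float] = (0.64, 0.16, 0.20),
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Deterministic stratified train/validation/test partition (positions)."""
    labels = np.asarray(labels)
    idx = np.arange(labels.size)
    f_train, f_val, f_test = split
    rest, test = train_test_split(
        idx, test_size=f_test, random_state=seed, stratify=labels
    )
    val_frac = f_val / (f_train + f_val)
    train, val = train_test_split(
        rest, test_size=val_frac, random_state=seed + 1, stratify=labels[rest]
    )
    return {"train": np.sort(train), "val": np.sort(val), "test": np.sort(test)}


def _make_classifier(name: str, seed: int, val_fraction: float, params: dict):
    if name == "gradient-boosting":
        kw = dict(
            n_estimators=150,
            random_state=seed,
            validation_fraction=val_fraction,
            n_iter_no_change=10,
        )
        kw.update(params)
        return GradientBoostingClassifier(**kw)
    if name == "random-forest":
        kw = dict(n_estimators=200, random_state=seed, n_jobs=1)
        kw.update(params)
        return RandomForestClassifier(**kw)
    if name == "logistic":
        kw = dict(max_iter=2000)
        kw.update(params)
        return LogisticRegression(**kw)
    if name == "decision-table":
        # rule-based stand-in: a shallow decision tree (axis-aligned rules)
        kw = dict(max_depth=6, random_state=seed)
        kw.update(params)
        return DecisionTreeClassifier(**kw)
    if name == "knn":
        kw = dict(n_neighbors=25)
        kw.update(params)
        return KNeighborsClassifier(**kw)
    raise ValueError(f"unknown classifier {name!r}")


CLASSIFIERS = ("gradient-boosting", "random-forest", "logistic", "decision-table", "knn")


@dataclass
class EvaluationReport:
    analysis: str
    classifier: str
    n_train: int
    n_val: int
    n_test: int
    precision_macro: float
    recall_macro: float
    auc_macro: float
    per_class: dict[str, dict[str, float]]
    baseline: float
    influence: list[tuple[str, float]] | None
    config: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.influence is not None:
            d["influence"] = [[f, float(s)] for f, s in self.influence]
        return d


def baseline_rates(targets: pd.DataFrame, analysis: str) -> float:
    """Chance rate: 1/k for the k-class task, positive prevalence for binary."""
    if analysis not in ANALYSES:
        raise ValueError(f"analysis must be one of {ANALYSES}, got {analysis!r}")
    y = targets[_LABEL_COLUMN[analysis]]
    if analysis == "1":
        return 1.0 / y.nunique()
    return float(np.mean(y))


def feature_influence(model, feature_names: list[str]) -> list[tuple[str, float]]:
    """Relative feature influences normalised to sum to 100, descending."""
    if not hasattr(model, "feature_importances_"):
        raise ValueError(
            f"{type(model).__name__} exposes no feature importances"
        )
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    scores = imp * 100.0 / total if total > 0 else imp
    order = np.argsort(scores)[::-1]
    return [(feature_names[i], float(scores[i])) for i in order]


def run_experiment(
    cfg: ExperimentConfig, targets: pd.DataFrame, features: pd.DataFrame
) -> EvaluationReport:
    """Fit the configured classifier and evaluate on the held-out test split.

    Boosting consumes the validation fraction for early stopping (through
    its internal validation split over train+validation rows); the other
    learners train on the training rows only.
    """
    X, y = assemble_feature_table(targets, features, cfg.analysis)
    if y.nunique() < 2:
        raise ValueError(f"labels for analysis {cfg.analysis} are single-class")
    parts = split_indices(y, cfg.split, cfg.seed)
    Xv, yv = X.to_numpy(), y.to_numpy()

    val_fraction = cfg.split[1] / (cfg.split[0] + cfg.split[1])
    model = _make_classifier(cfg.classifier, cfg.seed, val_fraction, cfg.classifier_params)
    if cfg.classifier == "gradient-boosting":
        fit_idx = np.sort(np.concatenate([parts["train"], parts["val"]]))
    else:
        fit_idx = parts["train"]
    model.fit(Xv[fit_idx], yv[fit_idx])

    test = parts["test"]
    y_true, y_pred = yv[test], model.predict(Xv[test])
    classes = np.unique(yv)
    prec, rec, _, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    proba = model.predict_proba(Xv[test])
    if classes.size == 2:
        auc = float(roc_auc_score(y_true, proba[:, 1]))
        auc_per_class = {str(c): auc for c in classes}
    else:
        auc = float(
            roc_auc_score(y_true, proba, multi_class="ovr", average="macro", labels=classes)
        )
        per = [
            float(roc_auc_score((y_true == c).astype(int), proba[:, k]))
            for k, c in enumerate(classes)
        ]
        auc_per_class = {str(c): v for c, v in zip(classes, per)}

    per_class = {
        str(c): {
            "precision": float(p),
            "recall": float(r),
            "auc": auc_per_class[str(c)],
        }
        for c, p, r in zip(classes, prec, rec)
    }
    try:
        influence = feature_influence(model, list(X.columns))
    except ValueError:
        influence = None
    return EvaluationReport(
        analysis=cfg.analysis,
        classifier=cfg.classifier,
        n_train=int(parts["train"].size),
        n_val=int(parts["val"].size),
        n_test=int(test.size),
        precision_macro=float(prec.mean()),
        recall_macro=float(rec.mean()),
        auc_macro=auc,
        per_class=per_class,
        baseline=baseline_rates(targets, cfg.analysis),
        influence=influence,
        config=cfg.to_dict(),
    )
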