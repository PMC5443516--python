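"""Cross-validated contact classifiers, descriptor selection, and the
enrichment objective.

Training is protein-level five-fold cross-validation: the proteins are split
into five equal blocks; each fold uses one block as the independent (test)
set, the next block as the monitoring set (early stopping / model
selection), and the remaining three as the training set, so every protein is
independent exactly once and no pair record ever spans roles within a fold.
Proteins declared similar are packed into the same block so homology never
leaks across roles.

Two model families are supported behind one ensemble interface:

* decision trees (scikit-learn), with node splitting forbidden below 20
  training points;
* a single-hidden-layer sigmoid network trained by full-batch gradient
  descent on the summed squared error, with gradient step ``eta`` (default
  1.7e-5) and momentum ``alpha`` (default 0), monitored on the fold's
  monitoring proteins.

The ensemble prediction is the arithmetic mean of the five members'
propensities.  Descriptor selection offers single-feature F1/information-
gain ranking, iterative input-sensitivity pruning (never more than half the
descriptors removed per stage), and, for networks, weight-derived
consistency/magnitude scores.  The ranking objective used throughout is the
enrichment of true contacts among the highest-scoring fraction of pairs and
the integral of precision over the 0.01%-0.55% fraction-predicted-positive
range.
"""

from __future__ import annotations

import json
import pickle
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.tree import DecisionTreeClassifier

META_COLUMNS = ("protein_id", "i", "j", "label")


class PlanningError(ValueError):
    """No valid protein-to-fold assignment exists."""


class TrainingError(RuntimeError):
    """A training fold is degenerate (e.g. a class is empty)."""


@dataclass
class CrossValidationPlan:
    """Per-fold (training, monitoring, independent) protein id sets."""

    folds: list[dict]
    seed: int

    def __post_init__(self) -> None:
        for fold in self.folds:
            sets = [set(fold["train"]), set(fold["monitor"]), set(fold["independent"])]
            if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
                raise PlanningError("fold role sets must be disjoint")


def make_cv_plan(
    protein_ids,
    linked_pairs=(),
    sizes: tuple[int, int, int] = (15, 5, 5),
    seed: int = 0,
    n_folds: int = 5,
) -> CrossValidationPlan:
    """Rotation plan over ``n_folds`` equal protein blocks.

    ``linked_pairs`` (sequence-similar proteins) are always co-assigned to
    one block.  ``sizes`` documents the intended (train, monitor,
    independent) counts; the protein count must be divisible into
    ``n_folds`` equal blocks after linking.
    """
    ids = list(protein_ids)
    if len(set(ids)) != len(ids):
        raise PlanningError("duplicate protein ids")
    if len(ids) % n_folds != 0:
        raise PlanningError(
            f"{len(ids)} proteins cannot be split into {n_folds} equal blocks"
        )
    block_size = len(ids) // n_folds

    # union-find over linked pairs
    parent = {p: p for p in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in linked_pairs:
        if a not in parent or b not in parent:
            raise PlanningError(f"linked pair ({a}, {b}) names an unknown protein")
        parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for p in ids:
        groups.setdefault(find(p), []).append(p)
    units = sorted(groups.values(), key=lambda u: (-len(u), u[0]))
    if any(len(u) > block_size for u in units):
        raise PlanningError("a linked group exceeds the block size; no valid assignment")

    rng = np.random.default_rng(seed)
    # place larger linked groups first (shuffled within equal sizes) so the
    # equal-block packing always succeeds when one exists for this greedy
    rng.shuffle(units)
    units.sort(key=len, reverse=True)
    blocks: list[list[str]] = [[] for _ in range(n_folds)]
    for unit in units:
        candidates = [
            b for b in range(n_folds) if len(blocks[b]) + len(unit) <= block_size
        ]
        if not candidates:
            raise PlanningError("linked groups cannot be packed into equal blocks")
        target = min(candidates, key=lambda b: (len(blocks[b]), b))
        blocks[target].extend(unit)
    folds = []
    for k in range(n_folds):
        independent = sorted(blocks[k])
        monitor = sorted(blocks[(k + 1) % n_folds])
        train = sorted(
            p for b in range(n_folds) if b not in (k, (k + 1) % n_folds) for p in blocks[b]
        )
        folds.append({"train": train, "monitor": monitor, "independent": independent})
    return CrossValidationPlan(folds=folds, seed=seed)


@dataclass
class TrainingConfig:
    """Hyper-parameters shared by both model families.

    ``eta`` multiplies the summed squared-error gradient of the network;
    ``min_node_size`` forbids decision-tree splits below that many points.
    ``objective`` picks the quantity monitored for early stopping: plain
    RMSE for initial training, average enrichment for the final stage.
    """

    eta: float = 1.7e-5
    alpha: float = 0.0
    min_node_size: int = 20
    n_hidden: int = 32
    max_epochs: int = 2000
    patience: int = 100
    objective: str = "rmse"  # or "enrichment"
    fpp_range: tuple[float, float] = (0.0001, 0.0055)
    seed: int = 0


class _ANN:
    """Single hidden layer, sigmoid activations, summed-squared-error loss."""

    def __init__(self, n_in: int, n_hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        self.W1 = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.normal(0.0, 1.0 / np.sqrt(n_hidden), size=n_hidden)
        self.b2 = 0.0

    def forward(self, X):
        H = expit(X @ self.W1 + self.b1)
        y = expit(H @ self.W2 + self.b2)
        return y, H

    def _params(self):
        return [self.W1.copy(), self.b1.copy(), self.W2.copy(), float(self.b2)]

    def _set_params(self, params):
        self.W1, self.b1, self.W2, self.b2 = (
            params[0].copy(),
            params[1].copy(),
            params[2].copy(),
            float(params[3]),
        )

    def fit(self, X, y, eta, alpha, max_epochs, patience, monitor_fn):
        """Gradient descent with momentum; keeps the best-monitored weights."""
        steps = [np.zeros_like(self.W1), np.zeros_like(self.b1), np.zeros_like(self.W2), 0.0]
        best = self._params()
        best_score = monitor_fn(self)
        stall = 0
        for _epoch in range(max_epochs):
            pred, H = self.forward(X)
            err = pred - y
            g2 = err * pred * (1.0 - pred)  # (n,)
            dW2 = H.T @ g2
            db2 = g2.sum()
            dH = np.outer(g2, self.W2)
            g1 = dH * H * (1.0 - H)
            dW1 = X.T @ g1
            db1 = g1.sum(axis=0)
            grads = [dW1, db1, dW2, db2]
            new_steps = []
            for p, g, s in zip((self.W1, self.b1, self.W2), grads[:3], steps[:3]):
                step = -eta * g + alpha * s
                p += step
                new_steps.append(step)
            step2 = -eta * grads[3] + alpha * steps[3]
            self.b2 += step2
            steps = new_steps + [step2]
            score = monitor_fn(self)
            if score < best_score - 1e-12:
                best_score = score
                best = self._params()
                stall = 0
            else:
                stall += 1
                if stall >= patience:
                    break
        self._set_params(best)
        return best_score


class ANNMember:
    """A fitted network plus the training-set standardisation."""

    def __init__(self, net: _ANN, mean: np.ndarray, scale: np.ndarray):
        self.net = net
        self.mean = mean
        self.scale = scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return self.net.forward(Z)[0]


class DTMember:
    def __init__(self, tree: DecisionTreeClassifier):
        self.tree = tree

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.tree.predict_proba(np.asarray(X, dtype=float))
        idx = list(self.tree.classes_).index(1.0)
        return proba[:, idx]


@dataclass
class ModelEnsemble:
    """Five cross-validated members; prediction = mean member propensity."""

    members: list
    model_kind: str
    feature_names: list[str]
    config: TrainingConfig
    plan: CrossValidationPlan


def _as_matrix(features, feature_names):
    if isinstance(features, pd.DataFrame):
        missing = [c for c in feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        return features[feature_names].to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"expected {len(feature_names)} feature columns, got {X.shape[1]}"
        )
    return X


def _monitor_metric(pred, y, config: TrainingConfig):
    """Lower is better; enrichment is negated."""
    if config.objective == "rmse":
        return float(np.sqrt(np.mean((pred - y) ** 2)))
    if config.objective == "enrichment":
        avg_enr, _ = enrichment_objective(pred, y, config.fpp_range)
        return -avg_enr
    raise ValueError(f"unknown objective {config.objective!r}")


def train_ensemble(
    dataset: pd.DataFrame,
    plan: CrossValidationPlan,
    model_kind: str,
    config: TrainingConfig | None = None,
    feature_names: list[str] | None = None,
) -> ModelEnsemble:
    """Fit one member per fold on that fold's training proteins.

    ``dataset`` must carry ``protein_id`` and a binary ``label`` column;
    rows with missing labels are dropped.
    """
    if model_kind not in ("dt", "ann"):
        raise ValueError("model_kind must be 'dt' or 'ann'")
    config = config or TrainingConfig()
    data = dataset.dropna(subset=["label"])
    if feature_names is None:
        feature_names = [c for c in data.columns if c not in META_COLUMNS]
    members = []
    for k, fold in enumerate(plan.folds):
        tr = data[data["protein_id"].isin(fold["train"])]
        mon = data[data["protein_id"].isin(fold["monitor"])]
        ytr = tr["label"].to_numpy(dtype=float)
        if len(np.unique(ytr)) < 2:
            raise TrainingError(f"fold {k}: training labels contain a single class")
        Xtr = tr[feature_names].to_numpy(dtype=float)
        seed_k = config.seed + k
        if model_kind == "dt":
            tree = DecisionTreeClassifier(
                min_samples_split=config.min_node_size, random_state=seed_k
            )
            tree.fit(Xtr, ytr)
            members.append(DTMember(tree))
        else:
            mean = Xtr.mean(axis=0)
            scale = Xtr.std(axis=0)
            scale[scale == 0] = 1.0
            Ztr = (Xtr - mean) / scale
            if len(mon):
                Xmon = mon[feature_names].to_numpy(dtype=float)
                Zmon = (Xmon - mean) / scale
                ymon = mon["label"].to_numpy(dtype=float)
            else:
                Zmon, ymon = Ztr, ytr
            net = _ANN(len(feature_names), config.n_hidden, seed_k)

            def monitor(n, Zmon=Zmon, ymon=ymon):
                return _monitor_metric(n.forward(Zmon)[0], ymon, config)

            net.fit(
                Ztr,
                ytr,
                eta=config.eta,
                alpha=config.alpha,
                max_epochs=config.max_epochs,
                patience=config.patience,
                monitor_fn=monitor,
            )
            members.append(ANNMember(net, mean, scale))
    return ModelEnsemble(
        members=members,
        model_kind=model_kind,
        feature_names=list(feature_names),
        config=config,
        plan=plan,
    )


def predict(ensemble: ModelEnsemble, features) -> np.ndarray:
    """Mean propensity of the ensemble members, each in [0, 1]."""
    X = _as_matrix(features, ensemble.feature_names)
    preds = np.stack([m.predict(X) for m in ensemble.members])
    return preds.mean(axis=0)


def predict_independent(ensemble: ModelEnsemble, dataset: pd.DataFrame) -> pd.DataFrame:
    """Score every protein with the one fold for which it is independent."""
    frames = []
    for member, fold in zip(ensemble.members, ensemble.plan.folds):
        rows = dataset[dataset["protein_id"].isin(fold["independent"])]
        if not len(rows):
            continue
        X = rows[ensemble.feature_names].to_numpy(dtype=float)
        out = rows[["protein_id", "i", "j"]].copy()
        out["propensity"] = member.predict(X)
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


def _entropy(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = y.mean()
    out = 0.0
    for v in (p, 1.0 - p):
        if v > 0:
            out -= v * np.log2(v)
    return out


def rank_features_f1_infogain(
    dataset: pd.DataFrame, feature_names: list[str] | None = None, rank_by: str = "f1"
) -> pd.DataFrame:
    """Best single-threshold F1 and the information gain of that split.

    Thresholds are the midpoints between consecutive distinct observed
    values; both directions ("above threshold positive" / "below threshold
    positive") are scanned.  Constant features fall back to the
    all-positive prediction (information gain 0).
    """
    data = dataset.dropna(subset=["label"])
    y = data["label"].to_numpy(dtype=float)
    if feature_names is None:
        feature_names = [c for c in data.columns if c not in META_COLUMNS]
    n_pos = y.sum()
    n = len(y)
    base_f1 = 2 * n_pos / (n + n_pos) if n else 0.0
    rows = []
    H = _entropy(y)
    for name in feature_names:
        x = data[name].to_numpy(dtype=float)
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if distinct.size == 0:
            rows.append(
                {"feature": name, "f1": base_f1, "info_gain": 0.0,
                 "threshold": np.nan, "direction": "all"}
            )
            continue
        cum_pos = np.cumsum(ys)
        best = (-1.0, np.nan, "gt")
        for cut in distinct:  # predict positive above (or below) xs[cut]
            thr = 0.5 * (xs[cut] + xs[cut + 1])
            below_pos = cum_pos[cut]
            n_below = cut + 1
            for direction in ("gt", "lt"):
                if direction == "gt":
                    tp = n_pos - below_pos
                    pred_pos = n - n_below
                else:
                    tp = below_pos
                    pred_pos = n_below
                if pred_pos == 0 or n_pos == 0:
                    f1 = 0.0
                else:
                    prec = tp / pred_pos
                    rec = tp / n_pos
                    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
                if f1 > best[0]:
                    best = (f1, thr, direction, cut)
        f1, thr, direction, cut = best
        below = ys[: cut + 1]
        above = ys[cut + 1 :]
        gain = H - (len(below) / n * _entropy(below) + len(above) / n * _entropy(above))
        rows.append(
            {"feature": name, "f1": float(f1), "info_gain": float(gain),
             "threshold": float(thr), "direction": direction}
        )
    out = pd.DataFrame(rows)
    return out.sort_values(rank_by, ascending=False, kind="mergesort").reset_index(drop=True)


def input_sensitivities(
    ensemble: ModelEnsemble, dataset: pd.DataFrame
) -> pd.Series:
    """Mean absolute response to a one-SD perturbation of each descriptor.

    Each member is probed on its own fold's monitoring proteins; responses
    average over members.
    """
    data = dataset.dropna(subset=["label"])
    names = ensemble.feature_names
    total = np.zeros(len(names))
    n_used = 0
    for member, fold in zip(ensemble.members, ensemble.plan.folds):
        rows = data[data["protein_id"].isin(fold["monitor"])]
        if not len(rows):
            continue
        X = rows[names].to_numpy(dtype=float)
        base = member.predict(X)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        for k in range(len(names)):
            Xp = X.copy()
            Xp[:, k] += sd[k]
            total[k] += np.abs(member.predict(Xp) - base).mean()
        n_used += 1
    if n_used == 0:
        raise TrainingError("no monitoring rows available for sensitivity analysis")
    return pd.Series(total / n_used, index=names)


def input_sensitivity_prune(
    dataset: pd.DataFrame,
    plan: CrossValidationPlan,
    model_kind: str,
    config: TrainingConfig | None = None,
    schedule: list[int] | None = None,
    feature_names: list[str] | None = None,
) -> list[dict]:
    """Iteratively retrain and keep the most input-sensitive descriptors.

    The default schedule scales the reference 210 -> 160 -> 130 -> 70
    progression to the starting feature count; no stage may remove more
    than half of the current descriptors.  Returns one entry per stage
    (including stage 0, the full set) with the retained features, their
    sensitivities and the trained ensemble.
    """
    config = config or TrainingConfig()
    data = dataset.dropna(subset=["label"])
    if feature_names is None:
        feature_names = [c for c in data.columns if c not in META_COLUMNS]
    current = list(feature_names)
    if schedule is None:
        n0 = len(current)
        schedule = sorted(
            {max(1, int(np.ceil(n0 * f / 210.0))) for f in (160, 130, 70)}, reverse=True
        )
        schedule = [s for s in schedule if s < n0]
    prev = len(current)
    for target in schedule:
        if target < int(np.ceil(prev / 2.0)):
            raise ValueError(
                f"schedule stage {prev} -> {target} removes more than half the descriptors"
            )
        prev = target
    stages = []
    for target in [len(current)] + list(schedule):
        keep = current[:target] if target < len(current) else current
        ensemble = train_ensemble(data, plan, model_kind, config, keep)
        sens = input_sensitivities(ensemble, data).sort_values(ascending=False)
        stages.append({"features": list(keep), "sensitivity": sens, "ensemble": ensemble})
        current = list(sens.index)  # ranked for the next stage
    return stages


def ann_weight_scores(ensemble: ModelEnsemble) -> pd.DataFrame:
    """Weight-derived descriptor scores for a network ensemble.

    The output derivative with respect to each (standardised) input is
    evaluated at the centre of the training distribution from the layer
    weights.  A descriptor is *consistent* when the derivative keeps one
    sign across all members.  The magnitude score min-max rescales each
    member's absolute derivatives into [0, 0.5], sums them per descriptor
    across members, and squares the sum.
    """
    if ensemble.model_kind != "ann":
        raise TypeError("weight-derivative scores require a network ensemble")
    derivs = []
    for member in ensemble.members:
        net = member.net
        h = expit(net.b1)
        z2 = h @ net.W2 + net.b2
        y = expit(z2)
        d = y * (1 - y) * (net.W1 * (net.W2 * h * (1 - h))[None, :]).sum(axis=1)
        derivs.append(d)
    D = np.stack(derivs)  # (members, features)
    consistent = np.all(D >= 0, axis=0) | np.all(D <= 0, axis=0)
    A = np.abs(D)
    lo = A.min(axis=1, keepdims=True)
    hi = A.max(axis=1, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = np.where(hi > lo, 0.5 * (A - lo) / span, 0.0)
    score = scaled.sum(axis=0) ** 2
    return pd.DataFrame(
        {
            "feature": ensemble.feature_names,
            "consistent": consistent,
            "score": score,
            "mean_derivative": D.mean(axis=0),
        }
    ).sort_values("score", ascending=False).reset_index(drop=True)


def precision_fpp_curve(
    predictions, labels, fpp_range=(0.0001, 0.0055), n_grid: int = 100
):
    """Precision at a uniform grid of fraction-predicted-positive values.

    At fraction ``f`` the top ``ceil(f * N)`` pairs by score count as
    predicted positive (ties broken by original order for determinism).
    """
    lo, hi = fpp_range
    if not (0.0 < lo < hi <= 1.0):
        raise ValueError("fpp_range must satisfy 0 < lo < hi <= 1")
    scores = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if scores.shape != y.shape:
        raise ValueError("predictions and labels must align")
    order = np.lexsort((np.arange(len(scores)), -scores))
    cum_tp = np.cumsum(y[order])
    N = len(y)
    f = np.linspace(lo, hi, n_grid)
    k = np.clip(np.ceil(f * N).astype(int), 1, N)
    precision = cum_tp[k - 1] / k
    return f, precision


def enrichment_objective(
    predictions, labels, fpp_range=(0.0001, 0.0055), n_grid: int = 100
) -> tuple[float, float]:
    """(average enrichment, precision integral) over the FPP range.

    Enrichment at a fraction is precision divided by the dataset base rate;
    the integral is the trapezoid rule over the precision curve.
    """
    f, precision = precision_fpp_curve(predictions, labels, fpp_range, n_grid)
    base = float(np.mean(labels))
    if base == 0.0:
        warnings.warn("no positive labels; enrichment undefined, returning 0")
        return 0.0, float(np.trapezoid(precision, f))
    enrichment = precision / base
    return float(enrichment.mean()), float(np.trapezoid(precision, f))


def save_ensemble(ensemble: ModelEnsemble, directory) -> None:
    """Versioned on-disk bundle: members, schema, config, plan."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "model_kind": ensemble.model_kind,
        "feature_names": ensemble.feature_names,
        "config": asdict(ensemble.config),
        "plan": {"folds": ensemble.plan.folds, "seed": ensemble.plan.seed},
    }
    (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
    with open(directory / "members.pkl", "wb") as fh:
        pickle.dump(ensemble.members, fh)


def load_ensemble(directory) -> ModelEnsemble:
    directory = Path(directory)
    meta = json.loads((directory / "bundle.json").read_text())
    if meta.get("format_version") != 1:
        raise ValueError("unsupported model bundle version")
    with open(directory / "members.pkl", "rb") as fh:
        members = pickle.load(fh)
    cfg = meta["config"]
    cfg["fpp_range"] = tuple(cfg["fpp_range"])
    return ModelEnsemble(
        members=members,
        model_kind=meta["model_kind"],
        feature_names=meta["feature_names"],
        config=TrainingConfig(**cfg),
        plan=CrossValidationPlan(folds=meta["plan"]["folds"], seed=meta["plan"]["seed"]),
    )
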