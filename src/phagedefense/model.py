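"""Gradient-boosting ensemble: training, scoring, attribution aggregation.

One LightGBM classifier is trained per held-out fold; the five fitted
members form the ensemble. Held-out evaluation scores each labeled gene with
the member that never saw its fold; new genomes are scored with the mean
probability across members. Scores are reported both as probabilities and
as log-odds ln(p / (1 - p)), with p clamped to [1e-9, 1 - 1e-9] so the
transform stays finite; a log-odds of 4 corresponds to p ~ 0.982 and is the
stringent prediction cutoff, log-odds 0 (p = 0.5) the permissive one.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import lightgbm as lgb
import numpy as np

from .dataset import LabeledDataset, make_validation_split
from .features import Block, feature_layout, layout_from_json, layout_to_json

P_CLAMP = 1e-9

#: base LightGBM parameters shared by every member; chosen for reproducible
#: single-threaded fits.
BASE_PARAMS: dict = {
    "objective": "binary",
    "verbosity": -1,
    "num_threads": 1,
    "deterministic": True,
    "force_row_wise": True,
}

DEFAULT_PARAMS: dict = {
    "learning_rate": 0.1,
    "num_leaves": 31,
    "n_estimators": 200,
    "min_child_samples": 10,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "reg_lambda": 0.0,
}

#: documented random/Bayesian hyperparameter search space.
SEARCH_SPACE: dict[str, tuple] = {
    "learning_rate": ("log", 0.01, 0.3),
    "num_leaves": ("int", 8, 64),
    "n_estimators": ("int", 50, 400),
    "min_child_samples": ("int", 5, 50),
    "subsample": ("float", 0.5, 1.0),
    "colsample_bytree": ("float", 0.3, 1.0),
    "reg_lambda": ("log", 1e-3, 10.0),
}


def log_odds(p: float | np.ndarray) -> float | np.ndarray:
    """ln(p / (1 - p)) with clamping so saturated probabilities stay finite."""
    p = np.clip(p, P_CLAMP, 1.0 - P_CLAMP)
    out = np.log(p / (1.0 - p))
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class PredictionRecord:
    gene_id: str
    probability: float
    log_odds: float

    @classmethod
    def from_probability(cls, gene_id: str, p: float) -> "PredictionRecord":
        return cls(gene_id=gene_id, probability=float(p), log_odds=log_odds(p))


@dataclass
class EnsembleModel:
    """k fold-trained classifiers plus the feature layout they expect."""

    members: dict[int, lgb.LGBMClassifier]  # held-out fold -> fitted model
    dim: int
    layout: list[Block]
    metadata: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.layout[-1].stop

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for fold, member in self.members.items():
            member.booster_.save_model(str(path / f"member_fold{fold}.txt"))
        meta = dict(self.metadata)
        meta.update(
            {
                "dim": self.dim,
                "folds": sorted(self.members),
                "layout": layout_to_json(self.layout),
            }
        )
        (path / "metadata.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        members: dict[int, lgb.LGBMClassifier] = {}
        for fold in meta["folds"]:
            booster = lgb.Booster(model_file=str(path / f"member_fold{fold}.txt"))
            clf = lgb.LGBMClassifier()
            clf._Booster = booster
            clf.fitted_ = True
            clf._n_classes = 2
            members[fold] = clf
        layout = layout_from_json(meta.pop("layout"))
        return cls(members=members, dim=meta.pop("dim"), layout=layout, metadata=meta)


def _member_probabilities(member: lgb.LGBMClassifier, X: np.ndarray) -> np.ndarray:
    booster = member.booster_ if hasattr(member, "booster_") else member._Booster
    return np.asarray(booster.predict(X))


def train_fold_model(
    dataset: LabeledDataset,
    held_out_fold: int,
    params: dict | None = None,
    seed: int = 0,
) -> lgb.LGBMClassifier:
    """Fit one member on every fold except ``held_out_fold``."""
    if held_out_fold not in dataset.folds:
        raise ValueError(f"fold {held_out_fold} absent from dataset")
    train = dataset.subset(dataset.fold != held_out_fold)
    if len(np.unique(train.y)) < 2:
        raise ValueError("training folds contain a single class")
    merged = {**BASE_PARAMS, **DEFAULT_PARAMS, **(params or {}), "random_state": seed}
    clf = lgb.LGBMClassifier(**merged)
    clf.fit(train.X, train.y)
    return clf


def _sample_params(rng: np.random.Generator) -> dict:
    params: dict = {}
    for name, (kind, lo, hi) in SEARCH_SPACE.items():
        if kind == "int":
            params[name] = int(rng.integers(lo, hi + 1))
        elif kind == "log":
            params[name] = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        else:
            params[name] = float(rng.uniform(lo, hi))
    return params


def _validation_ap(clf: lgb.LGBMClassifier, validation: LabeledDataset) -> float:
    from .evaluation import average_precision

    p = _member_probabilities(clf, validation.X)
    return average_precision(p, validation.y)


def tune_hyperparameters(
    train: LabeledDataset,
    validation: LabeledDataset,
    budget: int = 25,
    seed: int = 0,
    strategy: str = "random",
) -> tuple[dict, list[dict]]:
    """Search ``SEARCH_SPACE`` for the parameters maximizing validation AP.

    ``strategy="random"`` (default) is a seeded random search;
    ``strategy="bayes"`` uses optuna's TPE sampler through the same
    interface when that package is available. Returns
    ``(best_params, trial_log)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(validation) == 0:
        raise ValueError("empty validation set")
    if strategy not in ("random", "bayes"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "bayes":
        return _tune_bayes(train, validation, budget, seed)
    rng = np.random.default_rng(seed)
    trials: list[dict] = []
    best_params: dict = {}
    best_ap = -1.0
    for i in range(budget):
        params = _sample_params(rng)
        clf = _fit_on(train, params, seed)
        ap = _validation_ap(clf, validation)
        trials.append({"trial": i, "params": params, "validation_ap": ap})
        if ap > best_ap:
            best_ap, best_params = ap, params
    return best_params, trials


def _fit_on(train: LabeledDataset, params: dict, seed: int) -> lgb.LGBMClassifier:
    if len(np.unique(train.y)) < 2:
        raise ValueError("training split contains a single class")
    merged = {**BASE_PARAMS, **DEFAULT_PARAMS, **params, "random_state": seed}
    clf = lgb.LGBMClassifier(**merged)
    clf.fit(train.X, train.y)
    return clf


def _tune_bayes(train, validation, budget, seed):  # pragma: no cover - optional
    try:
        import optuna
    except ImportError as exc:
        raise ImportError(
            "strategy='bayes' requires optuna; use strategy='random'"
        ) from exc
    optuna.logging.set_verbosity(optuna.logging.WARNING)
    trials: list[dict] = []

    def objective(trial):
        params = {}
        for name, (kind, lo, hi) in SEARCH_SPACE.items():
            if kind == "int":
                params[name] = trial.suggest_int(name, lo, hi)
            elif kind == "log":
                params[name] = trial.suggest_float(name, lo, hi, log=True)
            else:
                params[name] = trial.suggest_float(name, lo, hi)
        ap = _validation_ap(_fit_on(train, params, seed), validation)
        trials.append({"trial": trial.number, "params": params, "validation_ap": ap})
        return ap

    study = optuna.create_study(
        direction="maximize", sampler=optuna.samplers.TPESampler(seed=seed)
    )
    study.optimize(objective, n_trials=budget)
    return study.best_params, trials


def train_ensemble(
    dataset: LabeledDataset,
    k: int = 5,
    budget: int = 0,
    seed: int = 0,
    validation_fraction: float = 0.1,
    shared_params: dict | None = None,
) -> EnsembleModel:
    """Train one (optionally tuned) member per held-out fold.

    With ``budget >= 1`` each member's hyperparameters are tuned on a
    component-stratified validation split carved from its training folds;
    ``budget = 0`` trains with ``DEFAULT_PARAMS`` (or ``shared_params``).
    """
    folds = dataset.folds
    if len(folds) != k:
        raise ValueError(f"dataset has folds {folds}, expected {k}")
    members: dict[int, lgb.LGBMClassifier] = {}
    member_meta: dict[str, dict] = {}
    for fold in folds:
        member_seed = seed * 1000 + fold
        params = dict(shared_params or {})
        if budget >= 1:
            train_part = dataset.subset(dataset.fold != fold)
            tr, val = make_validation_split(train_part, validation_fraction, seed=member_seed)
            params, _ = tune_hyperparameters(tr, val, budget=budget, seed=member_seed)
        members[fold] = train_fold_model(dataset, fold, params, seed=member_seed)
        member_meta[str(fold)] = {"seed": member_seed, "params": params}
    dim = (dataset.X.shape[1] - 119) // 5
    return EnsembleModel(
        members=members,
        dim=dim,
        layout=feature_layout(dim),
        metadata={"seed": seed, "budget": budget, "members": member_meta},
    )


def predict_genes(
    model: EnsembleModel,
    gene_ids: list[str],
    X: np.ndarray,
    mode: str = "ensemble",
    folds: np.ndarray | None = None,
) -> list[PredictionRecord]:
    """Score genes with the ensemble.

    ``mode="ensemble"`` (new genomes): probability is the arithmetic mean of
    the members' probabilities. ``mode="heldout"`` (evaluation protocol):
    each row is scored by the member whose held-out fold equals the row's
    fold tag, so no gene is ever scored by a model that trained on it;
    ``folds`` is required and every tag must name a member.
    """
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(f"feature matrix must be (n, {model.n_features})")
    if len(gene_ids) != X.shape[0]:
        raise ValueError("gene_ids not aligned with feature matrix")
    if mode == "ensemble":
        probs = np.mean([_member_probabilities(m, X) for m in model.members.values()], axis=0)
    elif mode == "heldout":
        if folds is None:
            raise ValueError("heldout mode requires per-row fold tags")
        folds = np.asarray(folds)
        unknown = set(int(f) for f in folds) - set(model.members)
        if unknown:
            raise ValueError(
                f"rows tagged with folds {sorted(unknown)} have no held-out member; "
                "refusing to score rows a member may have trained on"
            )
        probs = np.empty(X.shape[0])
        for fold, member in model.members.items():
            mask = folds == fold
            if mask.any():
                probs[mask] = _member_probabilities(member, X[mask])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [PredictionRecord.from_probability(g, p) for g, p in zip(gene_ids, probs)]


def predict_heldout(model: EnsembleModel, dataset: LabeledDataset) -> list[PredictionRecord]:
    """Held-out scoring of a labeled dataset (each row by its fold's member)."""
    return predict_genes(model, dataset.gene_ids, dataset.X, mode="heldout", folds=dataset.fold)


# ---------------------------------------------------------------------------
# attribution


def compute_attributions(model: EnsembleModel, X: np.ndarray, fold: int) -> np.ndarray:
    """Per-feature additive attribution values from one member's trees.

    Uses LightGBM's native tree attribution (``pred_contrib``); the trailing
    expected-value column is dropped, so each row sums to the model's raw
    margin minus its baseline.
    """
    member = model.members[fold]
    booster = member.booster_ if hasattr(member, "booster_") else member._Booster
    contrib = np.asarray(booster.predict(np.asarray(X), pred_contrib=True))
    return contrib[:, :-1]


@dataclass
class AttributionSummary:
    """Mean per-gene summed attributions by (category, window position).

    ``by_category_position`` maps ``(category, position)`` to the mean over
    genes of the per-gene sum of attribution values in that block;
    ``by_neighbor`` maps each window position to the mean summed attribution
    over every block belonging to that position.
    """

    by_category_position: dict[tuple[str, int | None], float]
    by_neighbor: dict[int, float]
    n_genes: int


def aggregate_attributions(attrib: np.ndarray, layout: list[Block]) -> AttributionSummary:
    """Aggregate an (n_genes, n_features) attribution matrix over the layout."""
    attrib = np.asarray(attrib)
    n_features = layout[-1].stop
    if attrib.ndim != 2 or attrib.shape[1] != n_features:
        raise ValueError(f"attribution matrix must be (n, {n_features})")
    by_cat: dict[tuple[str, int | None], float] = {}
    by_pos: dict[int, float] = {}
    for block in layout:
        block_sum = attrib[:, block.start : block.stop].sum(axis=1)
        key = (block.category, block.position)
        by_cat[key] = by_cat.get(key, 0.0) + float(block_sum.mean())
        if block.position is not None:
            by_pos[block.position] = by_pos.get(block.position, 0.0) + float(block_sum.mean())
    return AttributionSummary(
        by_category_position=by_cat, by_neighbor=by_pos, n_genes=attrib.shape[0]
    )
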