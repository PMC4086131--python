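"""Feature assembly, calibrated linear-margin ensemble, and prediction.

Training follows a grouped five-fold protocol: for each fold rotation,
three folds train a soft-margin linear classifier (with a cost factor
up-weighting errors on positive examples), one fold fits the Platt sigmoid
and records validation accuracy, and the remaining fold is held out for
testing.  The five validation-fitted members are kept; at prediction time
their calibrated probabilities are combined with accuracy-proportional
weights that sum to one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import LinearSVC

from varmod.conservation import ConservationScore
from varmod.core_io import Variant
from varmod.seq_features import (
    DEFAULT_CHARGE_MATRIX,
    DEFAULT_TABLES,
    sequence_feature_block,
)
from varmod.struct_features import (
    ProteinStructureContext,
    StructuralBlock,
    structural_feature_block,
)

SCHEMA_VERSION = 1

FEATURE_NAMES: tuple[str, ...] = (
    "jsd_conservation",
    "mass_ratio",
    "charge_change",
    "functional_group_change",
    "ligand_distance",
    "binding_extra_a",
    "binding_extra_b",
    "interface_distance",
    "ss8_H", "ss8_G", "ss8_I", "ss8_E", "ss8_B", "ss8_T", "ss8_S", "ss8_-",
    "ss3_helix", "ss3_sheet", "ss3_coil",
    "relative_sasa",
    "structure_missing",
    "ligand_site_missing",
    "interface_site_missing",
)

N_FEATURES = len(FEATURE_NAMES)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_J_GRID = (0.5, 1.0, 2.0, 4.0)
DEFAULT_SEED = 17


def assemble_features(
    variant: Variant,
    conservation: dict[int, ConservationScore] | list[ConservationScore],
    structural_block: StructuralBlock,
    tables=DEFAULT_TABLES,
    charge_matrix=DEFAULT_CHARGE_MATRIX,
) -> np.ndarray:
    """Concatenate all features for one variant in fixed schema order."""
    if not isinstance(conservation, dict):
        conservation = {s.position: s for s in conservation}
    cons = conservation.get(variant.pos)
    if cons is None:
        raise KeyError(
            f"no conservation score at position {variant.pos}; "
            "sequence features are mandatory"
        )
    seq_block = sequence_feature_block(variant, tables, charge_matrix)
    vec = np.concatenate(
        [[cons.score], seq_block, structural_block.as_array()]
    )
    assert vec.shape == (N_FEATURES,)
    return vec


# --------------------------------------------------------------------------
# Platt sigmoid calibration
# --------------------------------------------------------------------------

def fit_platt(
    decision_values: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 200,
    min_step: float = 1e-10,
    sigma: float = 1e-12,
) -> tuple[float, float]:
    """Fit sigmoid parameters (A, B) so P(y=1|f) = 1 / (1 + exp(A f + B)).

    Regularised maximum likelihood with the (N+1)/(N+2) target smoothing,
    solved by Newton's method with backtracking.  Falls back to
    (A, B) = (-1, 0) with a warning if the fit does not converge.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels)
    prior1 = int((y == 1).sum())
    prior0 = int((y == 0).sum())
    hi = (prior1 + 1.0) / (prior1 + 2.0)
    lo = 1.0 / (prior0 + 2.0)
    t = np.where(y == 1, hi, lo)

    a, b = 0.0, np.log((prior0 + 1.0) / (prior1 + 1.0))

    def fval(a_: float, b_: float) -> float:
        z = a_ * f + b_
        # numerically stable cross-entropy with targets t
        return float(
            np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                            (t - 1) * z + np.log1p(np.exp(z))))
        )

    obj = fval(a, b)
    for _ in range(max_iter):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)),
                     1 / (1 + np.exp(z)))
        d1 = t - p
        d2 = p * (1 - p)
        g_a = float(np.dot(f, d1))
        g_b = float(d1.sum())
        if abs(g_a) < 1e-5 and abs(g_b) < 1e-5:
            return a, b
        h11 = float(np.dot(f * f, d2)) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float(np.dot(f, d2))
        det = h11 * h22 - h21 * h21
        da = -(h22 * g_a - h21 * g_b) / det
        db = -(-h21 * g_a + h11 * g_b) / det
        gd = g_a * da + g_b * db
        step = 1.0
        while step >= min_step:
            new_a, new_b = a + step * da, b + step * db
            new_obj = fval(new_a, new_b)
            if new_obj < obj + 1e-4 * step * gd:
                a, b, obj = new_a, new_b, new_obj
                break
            step /= 2.0
        else:
            break
    else:
        z = a * f + b
        p = 1 / (1 + np.exp(np.clip(z, -500, 500)))
        if max(abs(float(np.dot(f, t - p))), abs(float((t - p).sum()))) < 1e-3:
            return a, b
    warnings.warn("Platt sigmoid fit did not converge; using A=-1, B=0")
    return -1.0, 0.0


def platt_probability(decision_values: np.ndarray, a: float, b: float) -> np.ndarray:
    # clip keeps the sigmoid strictly inside (0, 1) in double precision
    z = np.clip(a * np.asarray(decision_values, dtype=float) + b, -30, 30)
    return 1.0 / (1.0 + np.exp(z))


# --------------------------------------------------------------------------
# Ensemble members
# --------------------------------------------------------------------------

@dataclass
class CalibratedClassifier:
    """A standardised linear decision function with a Platt sigmoid."""

    coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    validation_accuracy: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    c_param: float = 1.0
    j_param: float = 1.0

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.scaler_mean) / self.scaler_scale
        return z @ self.coef + self.intercept

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return platt_probability(self.decision_function(x), self.platt_a, self.platt_b)


def _standardise_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    return mean, scale


def train_member(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    c: float = 1.0,
    j: float = 1.0,
) -> CalibratedClassifier:
    """Fit one linear member at (C, j) and calibrate it on the validation set.

    ``j`` multiplies the penalty of errors on positive examples.  Features
    are standardised with training-set statistics only.
    """
    y_train = np.asarray(y_train)
    y_val = np.asarray(y_val)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("training set must contain both labels")
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    mean, scale = _standardise_stats(np.asarray(x_train, dtype=float))
    zt = (x_train - mean) / scale
    svm = LinearSVC(
        C=c, class_weight={0: 1.0, 1: j}, dual=False, tol=1e-6, max_iter=20000
    )
    svm.fit(zt, y_train)
    member = CalibratedClassifier(
        coef=svm.coef_.ravel().astype(float),
        intercept=float(svm.intercept_[0]),
        platt_a=-1.0,
        platt_b=0.0,
        validation_accuracy=0.0,
        scaler_mean=mean,
        scaler_scale=scale,
        c_param=c,
        j_param=j,
    )
    dv = member.decision_function(x_val)
    member.platt_a, member.platt_b = fit_platt(dv, y_val)
    calls = (member.predict_proba(x_val) >= 0.5).astype(int)
    member.validation_accuracy = float((calls == y_val).mean())
    return member


def grid_optimise(
    fold_data: dict[int, tuple[np.ndarray, np.ndarray]],
    c_grid=DEFAULT_C_GRID,
    j_grid=DEFAULT_J_GRID,
) -> dict[int, tuple[float, float]]:
    """Select (C, j) per fold rotation by validation accuracy.

    Rotation for test fold t uses fold (t mod k)+1 ... as validation and
    the remaining three folds for training.  Ties break toward smaller C,
    then j closest to 1, then smaller j.
    """
    folds = sorted(fold_data)
    k = len(folds)
    best: dict[int, tuple[float, float]] = {}
    for idx, test_fold in enumerate(folds):
        val_fold = folds[(idx + 1) % k]
        train_folds = [f for f in folds if f not in (test_fold, val_fold)]
        x_tr = np.vstack([fold_data[f][0] for f in train_folds])
        y_tr = np.concatenate([fold_data[f][1] for f in train_folds])
        x_va, y_va = fold_data[val_fold]
        candidates = []
        for c in c_grid:
            for j in j_grid:
                member = train_member(x_tr, y_tr, x_va, y_va, c, j)
                candidates.append(
                    (-member.validation_accuracy, c, abs(np.log(j)), j)
                )
        candidates.sort()
        _, c_best, _, j_best = candidates[0]
        best[test_fold] = (c_best, j_best)
    return best


@dataclass(frozen=True)
class Prediction:
    variant: Variant
    probability: float
    call: str  # "functional" | "non-functional"
    member_probabilities: tuple[float, ...]


@dataclass
class EnsembleModel:
    """Five calibrated linear classifiers with accuracy-proportional weights."""

    members: list[CalibratedClassifier]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]
    threshold: float = 0.5
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.weights is None:
            acc = np.array([m.validation_accuracy for m in self.members])
            if acc.sum() == 0:
                acc = np.ones(len(self.members))
            self.weights = acc / acc.sum()
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.members):
            raise ValueError("one weight per member required")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ValueError("ensemble weights must sum to 1")

    def member_probabilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return np.column_stack([m.predict_proba(x) for m in self.members])

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Weighted, normalised final probability per row of x."""
        return self.member_probabilities(x) @ self.weights

    def combine(self, x: np.ndarray, variant: Variant) -> Prediction:
        x = np.asarray(x, dtype=float).reshape(1, -1)
        per_member = self.member_probabilities(x)[0]
        p = float(per_member @ self.weights)
        call = "functional" if p >= self.threshold else "non-functional"
        return Prediction(variant, p, call, tuple(float(v) for v in per_member))

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "schema_version": self.schema_version,
            "feature_names": list(FEATURE_NAMES),
            "threshold": self.threshold,
            "weights": self.weights.tolist(),
            "members": [
                {
                    "coef": m.coef.tolist(),
                    "intercept": m.intercept,
                    "platt_a": m.platt_a,
                    "platt_b": m.platt_b,
                    "validation_accuracy": m.validation_accuracy,
                    "scaler_mean": m.scaler_mean.tolist(),
                    "scaler_scale": m.scaler_scale.tolist(),
                    "c_param": m.c_param,
                    "j_param": m.j_param,
                }
                for m in self.members
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        payload = json.loads(text)
        if payload["schema_version"] != SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {payload['schema_version']} does not "
                f"match this build ({SCHEMA_VERSION}); refusing to predict"
            )
        members = [
            CalibratedClassifier(
                coef=np.asarray(m["coef"], dtype=float),
                intercept=float(m["intercept"]),
                platt_a=float(m["platt_a"]),
                platt_b=float(m["platt_b"]),
                validation_accuracy=float(m["validation_accuracy"]),
                scaler_mean=np.asarray(m["scaler_mean"], dtype=float),
                scaler_scale=np.asarray(m["scaler_scale"], dtype=float),
                c_param=float(m["c_param"]),
                j_param=float(m["j_param"]),
            )
            for m in payload["members"]
        ]
        return cls(
            members=members,
            weights=np.asarray(payload["weights"], dtype=float),
            threshold=float(payload["threshold"]),
            schema_version=payload["schema_version"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def train_ensemble(
    x: np.ndarray,
    y: np.ndarray,
    protein_ids: list[str],
    c_grid=DEFAULT_C_GRID,
    j_grid=DEFAULT_J_GRID,
    k: int = 5,
    seed: int = DEFAULT_SEED,
) -> EnsembleModel:
    """Grouped k-fold grid-optimised ensemble training.

    Variants from one protein never span folds.  For each rotation the
    best (C, j) is selected on the validation fold and the
    validation-calibrated member is kept, weighted by its validation
    accuracy.
    """
    from varmod.evaluation import grouped_folds_from_ids

    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    assignment = grouped_folds_from_ids(protein_ids, k=k, seed=seed)
    fold_idx = np.array([assignment[p] for p in protein_ids])
    fold_data = {
        f: (x[fold_idx == f], y[fold_idx == f]) for f in sorted(set(fold_idx))
    }
    best_params = grid_optimise(fold_data, c_grid, j_grid)
    folds = sorted(fold_data)
    members = []
    for idx, test_fold in enumerate(folds):
        val_fold = folds[(idx + 1) % len(folds)]
        train_folds = [f for f in folds if f not in (test_fold, val_fold)]
        x_tr = np.vstack([fold_data[f][0] for f in train_folds])
        y_tr = np.concatenate([fold_data[f][1] for f in train_folds])
        x_va, y_va = fold_data[val_fold]
        c, j = best_params[test_fold]
        members.append(train_member(x_tr, y_tr, x_va, y_va, c, j))
    return EnsembleModel(members=members)


def predict(
    model: EnsembleModel,
    variants: list[Variant],
    feature_matrix: np.ndarray,
) -> list[Prediction]:
    """One Prediction per variant; deterministic given model and features."""
    if len(variants) == 0:
        return []
    feature_matrix = np.atleast_2d(np.asarray(feature_matrix, dtype=float))
    if feature_matrix.shape != (len(variants), N_FEATURES):
        raise ValueError(
            f"feature matrix shape {feature_matrix.shape} does not match "
            f"({len(variants)}, {N_FEATURES})"
        )
    return [model.combine(feature_matrix[i], v) for i, v in enumerate(variants)]


# --------------------------------------------------------------------------
# High-level feature extraction pipeline
# --------------------------------------------------------------------------

def extract_feature_matrix(
    variants: list[Variant],
    conservation: dict[int, ConservationScore] | list[ConservationScore],
    context: ProteinStructureContext,
    tables=DEFAULT_TABLES,
    charge_matrix=DEFAULT_CHARGE_MATRIX,
    distance_cap: float | None = None,
) -> np.ndarray:
    """Feature matrix (n_variants x N_FEATURES) for one protein."""
    if not isinstance(conservation, dict):
        conservation = {s.position: s for s in conservation}
    rows = []
    for v in variants:
        block = structural_feature_block(context, v.pos, distance_cap)
        rows.append(assemble_features(v, conservation, block, tables, charge_matrix))
    return np.vstack(rows) if rows else np.zeros((0, N_FEATURES))


def extract_dataset_features(
    dataset,
    sasa_points: int = 960,
    distance_cap: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Run the full extraction stack over a labelled dataset.

    ``dataset`` needs ``labelled_variants``, ``alignments``, ``structures``
    and ``sites`` attributes (see the fixtures module).  Returns
    (X, y, protein_ids) with one row per labelled variant.
    """
    from varmod.conservation import conservation_track

    contexts: dict[str, ProteinStructureContext] = {}
    cons: dict[str, dict[int, ConservationScore]] = {}
    for pid, aln in dataset.alignments.items():
        cons[pid] = {s.position: s for s in conservation_track(aln)}
        contexts[pid] = ProteinStructureContext.build(
            dataset.structures.get(pid),
            dataset.sites.get(pid, []),
            sasa_points=sasa_points,
        )
    rows, labels, pids = [], [], []
    for lv in dataset.labelled_variants:
        block = structural_feature_block(
            contexts[lv.protein_id], lv.variant.pos, distance_cap
        )
        rows.append(assemble_features(lv.variant, cons[lv.protein_id], block))
        labels.append(lv.label)
        pids.append(lv.protein_id)
    x = np.vstack(rows) if rows else np.zeros((0, N_FEATURES))
    return x, np.asarray(labels, dtype=int), pids
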