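"""ReLU feed-forward property regressors (Stages 2-3).

Networks have architecture (K, p1[, p2], 1): rectified-linear hidden layers
and an identity output.  Training delegates to scikit-learn's MLPRegressor;
the fitted weights are extracted into a plain-array :class:`Predictor` so
that the forward pass is self-contained, bit-reproducible, and directly
encodable as linear constraints by the inversion module.

No input scaling is applied by default so the network consumes raw integer
descriptors; an optional min-max scaling mode folds the affine transform
into the first layer before the model is serialized or inverted, keeping
everything linear.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chemgraph import ChemGraphError, Dataset
from .descriptors import DescriptorSpace, feature_vector
from .specification import ChemSpec


class PredictorError(ChemGraphError):
    pass


def space_fingerprint(space: DescriptorSpace) -> str:
    blob = json.dumps(space.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Predictor:
    """A ReLU MLP regressor as explicit weight matrices.

    ``weights[i]`` has shape (fan_in, fan_out); hidden layers apply
    ``max(x, 0)``, the final layer is affine.
    """

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    space_fp: str = ""

    def __post_init__(self):
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        if len(self.weights) != len(self.biases):
            raise PredictorError("weights/biases length mismatch")
        if self.weights[-1].shape[1] != 1:
            raise PredictorError("output layer must have one unit")

    @property
    def K(self) -> int:
        return self.weights[0].shape[0]

    @property
    def architecture(self) -> Tuple[int, ...]:
        return tuple([self.K] + [w.shape[1] for w in self.weights])

    def predict(self, x: Sequence[float]) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.K,):
            raise PredictorError(f"input length {x.shape} != K={self.K}")
        h = x
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W + b, 0.0)
        out = h @ self.weights[-1] + self.biases[-1]
        return float(out[0])

    def predict_graph(self, G, space: DescriptorSpace) -> float:
        return self.predict(feature_vector(G, space))

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "architecture": list(self.architecture),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "space_fp": self.space_fp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Predictor":
        return cls(
            weights=[np.array(w) for w in d["weights"]],
            biases=[np.array(b) for b in d["biases"]],
            space_fp=d.get("space_fp", ""),
        )


def save_model(predictor: Predictor, space: DescriptorSpace, path) -> None:
    """Model file: weights in plain decimal text plus the space definition."""
    with open(path, "w") as fh:
        json.dump(
            {"predictor": predictor.to_dict(), "descriptor_space": space.to_dict()},
            fh,
        )
        fh.write("\n")


def load_model(path) -> Tuple[Predictor, DescriptorSpace]:
    with open(path) as fh:
        d = json.load(fh)
    return (
        Predictor.from_dict(d["predictor"]),
        DescriptorSpace.from_dict(d["descriptor_space"]),
    )


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------


def train(
    dataset: Dataset,
    space: DescriptorSpace,
    architecture: Sequence[int],
    train_seed: int = 0,
    scale_inputs: bool = False,
    solver: str = "adam",
    max_iter: int = 3000,
    tol: float = 1e-7,
    alpha: float = 1e-5,
    X: Optional[np.ndarray] = None,
    y: Optional[np.ndarray] = None,
) -> Predictor:
    """Fit a ReLU network on a data set's feature vectors.

    ``architecture`` is (K, p1[, p2], 1); its input width must equal the
    space's K.  Training is reproducible given ``train_seed``.  With
    ``scale_inputs`` the min-max affine transform is folded into the first
    layer of the returned predictor.
    """
    from sklearn.neural_network import MLPRegressor

    arch = tuple(int(a) for a in architecture)
    if len(arch) < 3 or arch[-1] != 1:
        raise PredictorError("architecture must be (K, p1[, p2], 1)")
    if arch[0] != space.K:
        raise PredictorError(f"architecture input {arch[0]} != space K {space.K}")
    if len(dataset) == 0:
        raise PredictorError("empty dataset")
    if X is None:
        X = np.array([feature_vector(G, space) for G, _ in dataset])
    if y is None:
        y = np.array(dataset.values, dtype=float)

    scale_w = np.ones(space.K)
    scale_b = np.zeros(space.K)
    Xt = X
    if scale_inputs:
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        scale_w = 1.0 / span
        scale_b = -lo / span
        Xt = X * scale_w + scale_b

    kwargs = dict(
        hidden_layer_sizes=arch[1:-1],
        activation="relu",
        solver=solver,
        alpha=alpha,
        max_iter=max_iter,
        tol=tol,
        random_state=train_seed,
    )
    if solver == "adam":
        kwargs["n_iter_no_change"] = 50
    mlp = MLPRegressor(**kwargs)
    if len(y) == 1:
        # degenerate: constant predictor at the single observed value
        weights = [np.zeros((space.K, h)) for h in arch[1:-1]]
        weights.append(np.zeros((arch[-2], 1)))
        biases = [np.zeros(h) for h in arch[1:-1]] + [np.array([y[0]])]
        return Predictor(weights, biases, space_fingerprint(space))
    mlp.fit(Xt, y)
    weights = [np.asarray(c) for c in mlp.coefs_]
    biases = [np.asarray(b) for b in mlp.intercepts_]
    # fold input scaling into the first layer: W'x + b' = W(sx + t) + b
    W0 = weights[0] * scale_w[:, None]
    b0 = biases[0] + scale_b @ weights[0]
    weights[0] = W0
    biases[0] = b0
    return Predictor(weights, biases, space_fingerprint(space))


def predict(predictor: Predictor, x: Sequence[float]) -> float:
    return predictor.predict(x)


def r_squared(
    predictor: Predictor,
    dataset: Dataset,
    space: DescriptorSpace,
    X: Optional[np.ndarray] = None,
) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot over a data set."""
    if len(dataset) < 2:
        raise PredictorError("R^2 needs at least two observations")
    y = np.array(dataset.values, dtype=float)
    if np.allclose(y, y[0]):
        raise PredictorError("R^2 undefined for a constant property")
    if X is None:
        X = np.array([feature_vector(G, space) for G, _ in dataset])
    pred = np.array([predictor.predict(x) for x in X])
    ybar = y.mean()
    return float(1.0 - np.sum((y - pred) ** 2) / np.sum((y - ybar) ** 2))


@dataclass
class CVResult:
    """Five-fold cross-validation scores over an architecture menu."""

    fold_r2: Dict[Tuple[int, ...], List[float]]
    fold_assignment: List[int]
    fold_seed: int

    def mean_r2(self, arch: Tuple[int, ...]) -> float:
        vals = self.fold_r2[arch]
        return float(np.mean(vals))

    @property
    def best_mean(self) -> float:  # t-R^2_cv over the menu
        return max(self.mean_r2(a) for a in self.fold_r2)

    @property
    def max_r2(self) -> float:  # t-R^2_max over all (arch, fold)
        return max(v for vals in self.fold_r2.values() for v in vals)


def cross_validate(
    dataset: Dataset,
    space: DescriptorSpace,
    architectures: Sequence[Sequence[int]],
    fold_seed: int = 0,
    train_seed: int = 0,
    n_folds: int = 5,
    **train_kwargs,
) -> CVResult:
    """Random n-fold partition; per-(architecture, fold) test R^2."""
    n = len(dataset)
    if n < n_folds:
        raise PredictorError(f"need at least {n_folds} entries")
    rng = np.random.default_rng(fold_seed)
    # fold membership depends only on fold_seed and n, not dataset order
    perm = rng.permutation(n)
    assignment = [0] * n
    for pos, idx in enumerate(perm):
        assignment[idx] = pos % n_folds
    X = np.array([feature_vector(G, space) for G, _ in dataset])
    y = np.array(dataset.values, dtype=float)
    out: Dict[Tuple[int, ...], List[float]] = {}
    for arch in architectures:
        arch_t = tuple(int(a) for a in arch)
        scores = []
        for fold in range(n_folds):
            test = [i for i in range(n) if assignment[i] == fold]
            tr = [i for i in range(n) if assignment[i] != fold]
            sub = Dataset(
                [dataset.graphs[i] for i in tr],
                [dataset.values[i] for i in tr],
                dataset.property_name,
            )
            model = train(
                sub, space, arch_t, train_seed=train_seed, X=X[tr], y=y[tr],
                **train_kwargs,
            )
            pred = np.array([model.predict(X[i]) for i in test])
            yt = y[test]
            scores.append(
                float(1.0 - np.sum((yt - pred) ** 2) / np.sum((yt - yt.mean()) ** 2))
            )
        out[arch_t] = scores
    return CVResult(out, assignment, fold_seed)


# ---------------------------------------------------------------------------
# Input-node reduction
# ---------------------------------------------------------------------------


def reduce_inputs(
    predictor: Predictor, space: DescriptorSpace, chem_spec: ChemSpec
) -> Tuple[Predictor, DescriptorSpace]:
    """Drop input nodes for edge-configurations and fringe codes that the
    specification does not use.

    On any graph conforming to the specification the dropped descriptors
    are zero, so the reduced network computes the same output.
    """
    keep_gamma = (
        set(space.gamma_int)
        if chem_spec.gamma_int_allowed is None
        else set(chem_spec.gamma_int_allowed)
    )
    keep_f = set(chem_spec.f_star())
    missing = [c for c in keep_f if c not in set(space.fringe_codes)]
    missing += [
        str(g) for g in keep_gamma - set(space.gamma_int)
    ]
    if missing:
        raise PredictorError(
            "specification uses codes absent from the space: " + ", ".join(sorted(missing))
        )
    keep_idx = list(range(space.ec_offset))
    gammas, codes = [], []
    for i, g in enumerate(space.gamma_int):
        if g in keep_gamma:
            keep_idx.append(space.ec_offset + i)
            gammas.append(g)
    for i, c in enumerate(space.fringe_codes):
        if c in keep_f:
            keep_idx.append(space.fc_offset + i)
            codes.append(c)
    reduced_space = DescriptorSpace(
        lambda_int=space.lambda_int,
        lambda_ex=space.lambda_ex,
        gamma_int=tuple(gammas),
        fringe_codes=tuple(codes),
        rho=space.rho,
        table=space.table,
    )
    W0 = predictor.weights[0][keep_idx, :]
    reduced = Predictor(
        [W0] + [w.copy() for w in predictor.weights[1:]],
        [b.copy() for b in predictor.biases],
        space_fingerprint(reduced_space),
    )
    return reduced, reduced_space
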