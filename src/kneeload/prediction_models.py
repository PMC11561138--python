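"""Peak-prediction models: a one-hidden-node feedforward network trained by
Levenberg-Marquardt with Bayesian regularization, and a first-order multiple
linear regression baseline.

Each of the nine loading peaks gets its own model over up to six predictors
(mass, height, age, sex, walking speed, KFA predictor). The network is

    y_hat = a * tanh(w . x + b1) + b2

on min/max-normalized inputs and output. Training minimizes
F = beta * Ed + alpha * Ew (Ed sum of squared residuals, Ew sum of squared
parameters); the evidence framework re-estimates alpha and beta during
optimization (gamma = Nw - alpha * tr(H^-1), alpha = gamma / (2 Ew),
beta = (N - gamma) / (2 Ed)), which regularizes without a validation split.
A model can be pre-trained on one dataset and fine-tuned on another by
continuing the optimization from the pre-trained weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    SingularDesignError,
    TrainingFailureError,
)
from .gait_features import RESPONSE_VARIABLES

#: Predictor columns in canonical order.
PREDICTORS = ("mass", "height", "age", "sex", "speed", "kfa")

#: The four predictor sets studied: demographics always included.
PREDICTOR_SETS: dict[str, tuple[str, ...]] = {
    "demographic": ("mass", "height", "age", "sex"),
    "demographic+kfa": ("mass", "height", "age", "sex", "kfa"),
    "demographic+speed": ("mass", "height", "age", "sex", "speed"),
    "full": PREDICTORS,
}

SERIALIZATION_VERSION = 1


def predictor_set_columns(name: str) -> tuple[str, ...]:
    try:
        return PREDICTOR_SETS[name]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown predictor set {name!r}; choose from {sorted(PREDICTOR_SETS)}"
        ) from None


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Affine map of each column onto [-1, 1] using training min/max.

    Constant columns map to 0; values outside the training range
    extrapolate beyond [-1, 1] (allowed, by design).
    """

    mins: np.ndarray
    maxs: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "MinMaxNormalizer":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[0] < 1:
            raise InvalidArgumentError("cannot fit normalization on empty data")
        mins, maxs = x.min(axis=0), x.max(axis=0)
        if np.any(maxs == mins):
            warnings.warn("constant predictor column mapped to 0", stacklevel=2)
        return cls(mins=mins, maxs=maxs)

    def _span(self) -> np.ndarray:
        span = self.maxs - self.mins
        return np.where(span > 0, span, 1.0)

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = 2.0 * (x - self.mins) / self._span() - 1.0
        return np.where(self.maxs == self.mins, 0.0, out)

    def invert(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        out = (z + 1.0) / 2.0 * self._span() + self.mins
        return np.where(self.maxs == self.mins, self.mins, out)


@dataclass(frozen=True)
class TrainingConfig:
    seed: int = 0
    max_epochs: int = 300
    tolerance: float = 1e-12  # relative objective change for convergence
    evidence_interval: int = 5  # LM iterations between alpha/beta updates
    pretrain: bool = True  # use the pre-training dataset when provided

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise InvalidArgumentError("max_epochs must be >= 1")


@dataclass
class AnnModel:
    """Trained one-hidden-node network for one response variable."""

    response: str
    predictor_set: str
    norm_in: MinMaxNormalizer
    norm_out: MinMaxNormalizer
    w: np.ndarray  # hidden weights, one per active predictor
    b1: float
    a: float  # output weight
    b2: float
    alpha: float
    beta: float
    gamma: float  # effective number of parameters
    n_iter: int = 0

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.w, [self.b1, self.a, self.b2]])

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        """Predict peak force (N) for rows of active-predictor values."""
        x = _as_matrix(x, self.predictor_set)
        if x.shape[1] != len(self.w):
            raise InvalidArgumentError(
                f"expected {len(self.w)} predictors, got {x.shape[1]}"
            )
        if not np.all(np.isfinite(x)):
            raise InvalidArgumentError("predictor values must be finite")
        z = self.norm_in.apply(x)
        y_norm = self.a * np.tanh(z @ self.w + self.b1) + self.b2
        return np.asarray(self.norm_out.invert(y_norm[:, None])).ravel()

    def to_dict(self) -> dict:
        return {
            "format_version": SERIALIZATION_VERSION,
            "kind": "ann",
            "response": self.response,
            "predictor_set": self.predictor_set,
            "norm_in": {"mins": self.norm_in.mins.tolist(),
                        "maxs": self.norm_in.maxs.tolist()},
            "norm_out": {"mins": self.norm_out.mins.tolist(),
                         "maxs": self.norm_out.maxs.tolist()},
            "w": self.w.tolist(),
            "b1": self.b1, "a": self.a, "b2": self.b2,
            "alpha": self.alpha, "beta": self.beta, "gamma": self.gamma,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        if d.get("format_version") != SERIALIZATION_VERSION or d.get("kind") != "ann":
            raise InvalidArgumentError("unrecognized ANN serialization")
        return cls(
            response=d["response"],
            predictor_set=d["predictor_set"],
            norm_in=MinMaxNormalizer(np.array(d["norm_in"]["mins"]),
                                     np.array(d["norm_in"]["maxs"])),
            norm_out=MinMaxNormalizer(np.array(d["norm_out"]["mins"]),
                                      np.array(d["norm_out"]["maxs"])),
            w=np.array(d["w"]), b1=d["b1"], a=d["a"], b2=d["b2"],
            alpha=d["alpha"], beta=d["beta"], gamma=d["gamma"],
            n_iter=d["n_iter"],
        )


@dataclass
class MlrModel:
    """First-order polynomial regression y = a*mass + b*height + c*age +
    d*sex + e*speed + f*kfa + g with zeros for inactive predictors."""

    response: str
    predictor_set: str
    coef: np.ndarray  # length 6, ordered as PREDICTORS
    intercept: float

    def predict(self, x: np.ndarray | pd.DataFrame) -> np.ndarray:
        x = _as_matrix(x, self.predictor_set)
        active = predictor_set_columns(self.predictor_set)
        coef_active = self.coef[[PREDICTORS.index(p) for p in active]]
        return x @ coef_active + self.intercept

    def to_dict(self) -> dict:
        return {
            "format_version": SERIALIZATION_VERSION,
            "kind": "mlr",
            "response": self.response,
            "predictor_set": self.predictor_set,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlrModel":
        if d.get("format_version") != SERIALIZATION_VERSION or d.get("kind") != "mlr":
            raise InvalidArgumentError("unrecognized MLR serialization")
        return cls(response=d["response"], predictor_set=d["predictor_set"],
                   coef=np.array(d["coef"]), intercept=d["intercept"])


def _as_matrix(x, predictor_set: str) -> np.ndarray:
    """Accept a DataFrame with named predictor columns or a raw matrix of
    active-predictor columns."""
    if isinstance(x, pd.DataFrame):
        cols = predictor_set_columns(predictor_set)
        return x[list(cols)].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    return np.atleast_2d(x)


def _residuals_and_jacobian(theta, z, t):
    """Residuals t - y_hat and Jacobian d r / d theta for the one-node net."""
    nw = z.shape[1]
    w, b1, a, b2 = theta[:nw], theta[nw], theta[nw + 1], theta[nw + 2]
    h = np.tanh(z @ w + b1)
    r = t - (a * h + b2)
    sech2 = 1.0 - h**2
    jac = np.empty((len(t), nw + 3))
    jac[:, :nw] = -(a * sech2)[:, None] * z
    jac[:, nw] = -a * sech2
    jac[:, nw + 1] = -h
    jac[:, nw + 2] = -1.0
    return r, jac


def _nguyen_widrow_init(n_inputs: int, rng: np.random.Generator) -> np.ndarray:
    """Deterministic bounded-uniform initialization in the Nguyen-Widrow
    spirit: hidden weights of magnitude ~0.7 with random direction."""
    w = rng.uniform(-1.0, 1.0, size=n_inputs)
    norm = np.linalg.norm(w)
    w = 0.7 * w / (norm if norm > 0 else 1.0)
    b1 = float(rng.uniform(-0.5, 0.5))
    a = float(rng.uniform(0.5, 1.0))
    b2 = float(rng.uniform(-0.1, 0.1))
    return np.concatenate([w, [b1, a, b2]])


def train_ann(
    data: pd.DataFrame,
    response: str,
    predictor_set: str = "full",
    cfg: TrainingConfig | None = None,
    init: AnnModel | None = None,
    norm_in: MinMaxNormalizer | None = None,
    norm_out: MinMaxNormalizer | None = None,
) -> AnnModel:
    """Fit the Bayesian-regularized one-node network for one response.

    ``data`` must contain the active predictor columns and the ``response``
    column. Passing ``init`` continues optimization from an existing model
    (fine-tuning); its normalization is reused so the weight space matches.
    Deterministic for a fixed config seed.
    """
    cfg = cfg or TrainingConfig()
    cols = predictor_set_columns(predictor_set)
    if len(data) < 10:
        raise InvalidArgumentError("need at least 10 training pairs")
    x = data[list(cols)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)[:, None]

    if init is not None:
        norm_in, norm_out = init.norm_in, init.norm_out
        theta = init.theta
    else:
        norm_in = norm_in or MinMaxNormalizer.fit(x)
        norm_out = norm_out or MinMaxNormalizer.fit(y)
        theta = _nguyen_widrow_init(len(cols), np.random.default_rng(cfg.seed))
    z = norm_in.apply(x)
    t = np.asarray(norm_out.apply(y)).ravel()

    n, nw = len(t), len(theta)
    alpha, beta = (init.alpha, init.beta) if init is not None else (0.01, 1.0)
    gamma = float(nw)
    mu = 1e-3
    r, jac = _residuals_and_jacobian(theta, z, t)
    ed, ew = float(r @ r), float(theta @ theta)
    objective = beta * ed + alpha * ew
    if not np.isfinite(objective):
        raise TrainingFailureError(f"non-finite initial objective {objective}")

    eye = np.eye(nw)
    n_iter = 0
    for it in range(cfg.max_epochs):
        grad = beta * (jac.T @ r) + alpha * theta
        hess = beta * (jac.T @ jac) + alpha * eye
        # One adaptive Levenberg-Marquardt step.
        improved = False
        for _ in range(30):
            try:
                step = np.linalg.solve(hess + mu * eye, -grad)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            theta_new = theta + step
            r_new, jac_new = _residuals_and_jacobian(theta_new, z, t)
            ed_new = float(r_new @ r_new)
            ew_new = float(theta_new @ theta_new)
            obj_new = beta * ed_new + alpha * ew_new
            if np.isfinite(obj_new) and obj_new < objective:
                theta, r, jac = theta_new, r_new, jac_new
                ed, ew = ed_new, ew_new
                rel_change = (objective - obj_new) / max(objective, 1e-30)
                objective = obj_new
                mu = max(mu * 0.1, 1e-12)
                improved = True
                break
            mu *= 10.0
            if mu > 1e10:
                break
        n_iter = it + 1
        if not improved:
            break

        if (it + 1) % cfg.evidence_interval == 0:
            hess = beta * (jac.T @ jac) + alpha * eye
            try:
                h_inv_trace = float(np.trace(np.linalg.inv(hess)))
            except np.linalg.LinAlgError:
                h_inv_trace = 0.0
            gamma = float(np.clip(nw - alpha * h_inv_trace, 1e-3, nw))
            alpha = gamma / max(2.0 * ew, 1e-12)
            beta = max(n - gamma, 1e-3) / max(2.0 * ed, 1e-12)
            objective = beta * ed + alpha * ew
            if not np.isfinite(objective):
                raise TrainingFailureError("non-finite objective after evidence update")
        elif improved and rel_change < cfg.tolerance:
            break

    return AnnModel(
        response=response,
        predictor_set=predictor_set,
        norm_in=norm_in,
        norm_out=norm_out,
        w=theta[: len(cols)].copy(),
        b1=float(theta[len(cols)]),
        a=float(theta[len(cols) + 1]),
        b2=float(theta[len(cols) + 2]),
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        n_iter=n_iter,
    )


def train_ann_with_pretraining(
    pretrain_data: pd.DataFrame,
    data: pd.DataFrame,
    response: str,
    predictor_set: str = "full",
    cfg: TrainingConfig | None = None,
) -> AnnModel:
    """Pre-train on one dataset, then fine-tune on another.

    Normalization is fitted on the pooled predictors/targets so the two
    phases share one weight space.
    """
    cfg = cfg or TrainingConfig()
    cols = list(predictor_set_columns(predictor_set))
    pooled_x = pd.concat([pretrain_data[cols], data[cols]]).to_numpy(dtype=float)
    pooled_y = pd.concat([pretrain_data[response], data[response]]).to_numpy(
        dtype=float
    )[:, None]
    norm_in = MinMaxNormalizer.fit(pooled_x)
    norm_out = MinMaxNormalizer.fit(pooled_y)
    pre = train_ann(pretrain_data, response, predictor_set, cfg,
                    norm_in=norm_in, norm_out=norm_out)
    return train_ann(data, response, predictor_set, cfg, init=pre)


def predict_ann(model: AnnModel, x) -> np.ndarray:
    return model.predict(x)


def fit_mlr(
    data: pd.DataFrame, response: str, predictor_set: str = "full"
) -> MlrModel:
    """Ordinary least squares fit of the first-order model."""
    cols = predictor_set_columns(predictor_set)
    x = data[list(cols)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    design = np.column_stack([x, np.ones(len(y))])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    sol, *_ = np.linalg.lstsq(design, y, rcond=None)
    coef = np.zeros(len(PREDICTORS))
    for c, v in zip(cols, sol[:-1]):
        coef[PREDICTORS.index(c)] = v
    return MlrModel(response=response, predictor_set=predictor_set,
                    coef=coef, intercept=float(sol[-1]))


def predict_mlr(model: MlrModel, x) -> np.ndarray:
    return model.predict(x)


def train_all_peaks(
    data: pd.DataFrame,
    predictor_set: str = "full",
    cfg: TrainingConfig | None = None,
    pretrain_data: pd.DataFrame | None = None,
) -> dict[str, tuple[AnnModel, MlrModel]]:
    """Train one (ANN, MLR) pair per response variable — nine of each."""
    cfg = cfg or TrainingConfig()
    models = {}
    for response in RESPONSE_VARIABLES:
        if pretrain_data is not None and cfg.pretrain:
            ann = train_ann_with_pretraining(
                pretrain_data, data, response, predictor_set, cfg
            )
        else:
            ann = train_ann(data, response, predictor_set, cfg)
        mlr = fit_mlr(data, response, predictor_set)
        models[response] = (ann, mlr)
    return models


def save_models(models: dict[str, tuple[AnnModel, MlrModel]], path) -> None:
    payload = {
        "format_version": SERIALIZATION_VERSION,
        "models": {
            resp: {"ann": ann.to_dict(), "mlr": mlr.to_dict()}
            for resp, (ann, mlr) in models.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_models(path) -> dict[str, tuple[AnnModel, MlrModel]]:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != SERIALIZATION_VERSION:
        raise InvalidArgumentError("unrecognized model file version")
    return {
        resp: (AnnModel.from_dict(d["ann"]), MlrModel.from_dict(d["mlr"]))
        for resp, d in payload["models"].items()
    }
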