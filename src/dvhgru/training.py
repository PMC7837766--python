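"""Training: EUD-weighted loss, per-organ Adam fits, k selection, baseline.

The loss is a sensitivity-weighted squared error over the DVH bins,

.. math::

    f(\\mathrm{DVH}', \\mathrm{DVH}, k)
      = \\frac{1}{n}\\sum_p \\sum_i s(D_i^{(p)}, k)\\,(D_i'^{(p)} - D_i^{(p)})^2,
    \\qquad
    s(D_i, k) = \\frac{D_i^{k-1}}{\\sum_j D_j^{k-1}},

with ``n`` the number of patients in the batch and the weights computed
from the TARGET (clinical-plan) doses and held constant — so the loss stays
a proper weighted MSE.  ``k = 1`` collapses to uniformly weighted MSE;
``k >> 1`` concentrates the penalty on the high-dose bins that dominate the
gEUD and the maximum dose of serial organs.

Per-organ models are trained full-batch with Adam.  ``grid_search_k``
replays the trial-and-error selection of ``k``: one model per candidate,
scored on a validation split by the composite
``|mu_EUD| + sigma_EUD (+ |mu_Dmax| + sigma_Dmax for serial organs)``.
The "previous method" comparison arm is a single 3-layer model trained
jointly on all organs with ``k = 1`` and an organ-identity one-hot appended
to the per-step input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import nn
from .dvh import (
    DoseVolumeHistogram,
    OARConfig,
    compute_eud,
    max_dose,
    sensitivity_weights,
)
from .cohort import PatientCase
from .predictor import (
    ModelSpec,
    TrainedModel,
    build_model,
    features_from_beams,
    monotone_repair,
    predict_batch,
)

__all__ = [
    "TrainConfig",
    "eud_weighted_loss",
    "eud_weighted_loss_grad",
    "train_oar_model",
    "KSearchResult",
    "grid_search_k",
    "BaselineModel",
    "train_previous_baseline",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one fit.

    Full-batch Adam by default (50 sequences of length 100 fit trivially in
    one batch); ``patience`` enables early stopping on the validation loss
    when a validation set is supplied.
    """

    learning_rate: float = 1e-3
    epochs: int = 400
    batch_size: int | None = None
    k: int = 1
    seed: int = 0
    patience: int | None = None
    loss_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if int(self.k) != self.k or self.k < 1:
            raise ValueError(f"k must be a positive integer, got {self.k}")
        object.__setattr__(self, "k", int(self.k))


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[None, :] if a.ndim == 1 else a


def eud_weighted_loss(
    predicted: np.ndarray, target: np.ndarray, k: float
) -> float:
    """Sensitivity-weighted squared error, averaged over patients.

    ``predicted`` and ``target`` are dose sequences, either a single
    sequence or a (patients, bins) batch.  Weights are computed per patient
    from the target doses.
    """
    pred = _as_2d(predicted)
    targ = _as_2d(target)
    if pred.shape != targ.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {targ.shape}")
    s = sensitivity_weights(targ, k)  # (B, bins), rows sum to 1
    return float(np.sum(s * (pred - targ) ** 2) / pred.shape[0])


def eud_weighted_loss_grad(
    predicted: np.ndarray, target: np.ndarray, k: float
) -> np.ndarray:
    """Gradient of :func:`eud_weighted_loss` with respect to the predictions."""
    pred = _as_2d(predicted)
    targ = _as_2d(target)
    s = sensitivity_weights(targ, k)
    g = 2.0 * s * (pred - targ) / pred.shape[0]
    return g.reshape(np.shape(predicted))


def _training_arrays(
    cases: Sequence[PatientCase],
    oar_name: str,
    spec: ModelSpec,
    extras: Sequence[np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack normalized features (B, 100, F) and targets (B, 100) for one OAR."""
    X, Y = [], []
    for i, case in enumerate(cases):
        beams, plan = case.oars[oar_name]
        X.append(
            features_from_beams(spec, beams, None if extras is None else extras[i])
        )
        t = plan.doses / spec.dose_norm
        Y.append(t[::-1] if not spec.ascending else t)
    return np.stack(X), np.stack(Y)


def _run_adam(
    model: TrainedModel,
    X: np.ndarray,
    Y: np.ndarray,
    cfg: TrainConfig,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> tuple[TrainedModel, list[float], list[float]]:
    """Full/mini-batch Adam on the EUD-weighted loss; deterministic under seeds."""
    params = model.params
    opt = nn.Adam(params, lr=cfg.learning_rate)
    drop_rng = np.random.default_rng([cfg.seed, 1])
    batch_rng = np.random.default_rng([cfg.seed, 2])
    B = X.shape[0]
    weights = sensitivity_weights(Y, cfg.k)  # constants: no gradient through s
    history: list[float] = []
    val_history: list[float] = []
    best_val = np.inf
    best_params = None
    since_best = 0
    for epoch in range(1, cfg.epochs + 1):
        if cfg.batch_size is None or cfg.batch_size >= B:
            idx_batches = [np.arange(B)]
        else:
            perm = batch_rng.permutation(B)
            idx_batches = np.array_split(perm, int(np.ceil(B / cfg.batch_size)))
        epoch_loss = 0.0
        for idx in idx_batches:
            y, cache = nn.forward(
                params,
                X[idx],
                dropout_p=model.spec.dropout_p,
                dropout_rng=drop_rng,
            )
            diff = y - Y[idx]
            s = weights[idx]
            loss = float(np.sum(s * diff**2) / len(idx))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate})"
                )
            dy = 2.0 * s * diff / len(idx)
            grads = nn.backward(params, cache, dy)
            opt.step(params, grads)
            epoch_loss += loss * len(idx) / B
        history.append(epoch_loss)
        if X_val is not None:
            yv, _ = nn.forward(params, X_val)
            vloss = eud_weighted_loss(yv, Y_val, cfg.k)
            val_history.append(vloss)
            if vloss < best_val - 1e-12:
                best_val = vloss
                best_params = params.copy()
                since_best = 0
            else:
                since_best += 1
            if cfg.patience is not None and since_best >= cfg.patience:
                break
        if epoch_loss <= cfg.loss_floor:
            break
    if cfg.patience is not None and best_params is not None:
        model.params = best_params
    return model, history, val_history


def train_oar_model(
    cases: Sequence[PatientCase],
    oar: OARConfig,
    model_spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
    val_cases: Sequence[PatientCase] | None = None,
) -> TrainedModel:
    """Train one per-organ model on its training cases.

    The loss exponent is taken from ``cfg.k`` (typically ``oar.loss_k``).
    Fully deterministic under (model seed, training seed, case order).
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    spec = model_spec or ModelSpec()
    cfg = cfg or TrainConfig(k=oar.loss_k)
    model = build_model(spec)
    model.oar_name = oar.name
    X, Y = _training_arrays(cases, oar.name, spec)
    X_val = Y_val = None
    if val_cases is not None:
        X_val, Y_val = _training_arrays(val_cases, oar.name, spec)
    model, history, val_history = _run_adam(model, X, Y, cfg, X_val, Y_val)
    model.metadata = {
        "oar": oar.name,
        "k": cfg.k,
        "epochs_run": len(history),
        "final_loss": history[-1],
        "first_loss": history[0],
        "loss_history": history,
        "val_history": val_history,
        "train_seed": cfg.seed,
        "n_train": len(cases),
    }
    return model


def _endpoint_errors(
    model: TrainedModel,
    cases: Sequence[PatientCase],
    oar: OARConfig,
) -> dict[str, np.ndarray]:
    preds = predict_batch(model, [c.oars[oar.name][0] for c in cases])
    out = {
        "eud": np.array(
            [
                compute_eud(p, oar.eud_a) - compute_eud(c.oars[oar.name][1], oar.eud_a)
                for p, c in zip(preds, cases)
            ]
        )
    }
    if oar.serial:
        out["dmax"] = np.array(
            [
                max_dose(p) - max_dose(c.oars[oar.name][1])
                for p, c in zip(preds, cases)
            ]
        )
    return out


def _mu_sigma(delta: np.ndarray) -> tuple[float, float]:
    mu = float(np.mean(delta))
    return mu, float(np.sqrt(np.mean((delta - mu) ** 2)))


@dataclass
class KSearchResult:
    """Outcome of the trial-and-error selection of the loss exponent."""

    selected_k: int
    table: list[dict]
    models: dict[int, TrainedModel]

    def objective(self, k: int) -> float:
        for row in self.table:
            if row["k"] == k:
                return row["objective"]
        raise KeyError(k)


def grid_search_k(
    cases: Sequence[PatientCase],
    oar: OARConfig,
    candidate_ks: Iterable[int],
    model_spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
    val_cases: Sequence[PatientCase] | None = None,
) -> KSearchResult:
    """Train one model per candidate k; pick the k with the best validation score.

    The score is ``|mu_EUD| + sigma_EUD``, plus ``|mu_Dmax| + sigma_Dmax``
    for serial organs, evaluated on the validation split.  Ties break toward
    the smaller k.
    """
    ks = sorted({int(k) for k in candidate_ks})
    if not ks:
        raise ValueError("candidate k set is empty")
    if val_cases is None or len(val_cases) == 0:
        raise ValueError("grid_search_k needs a validation split disjoint from training")
    cfg = cfg or TrainConfig()
    table: list[dict] = []
    models: dict[int, TrainedModel] = {}
    for k in ks:
        cfg_k = replace(cfg, k=k)
        model = train_oar_model(cases, oar, model_spec, cfg_k)
        errs = _endpoint_errors(model, val_cases, oar)
        mu_e, sd_e = _mu_sigma(errs["eud"])
        row = {"k": k, "mu_eud": mu_e, "sigma_eud": sd_e}
        objective = abs(mu_e) + sd_e
        if oar.serial:
            mu_d, sd_d = _mu_sigma(errs["dmax"])
            row.update(mu_dmax=mu_d, sigma_dmax=sd_d)
            objective += abs(mu_d) + sd_d
        row["objective"] = objective
        table.append(row)
        models[k] = model
    best = min(table, key=lambda r: (r["objective"], r["k"]))
    return KSearchResult(selected_k=best["k"], table=table, models=models)


@dataclass
class BaselineModel:
    """Jointly trained multi-organ comparison arm (3 layers, k = 1).

    A stand-in for earlier multi-organ DVH predictors: one model for all
    organs, with an organ-identity one-hot appended to the per-step input.
    """

    trained: TrainedModel
    oar_names: tuple[str, ...]

    def _one_hot(self, oar_name: str) -> np.ndarray:
        try:
            i = self.oar_names.index(oar_name)
        except ValueError:
            raise KeyError(f"baseline was not trained on OAR {oar_name!r}") from None
        v = np.zeros(len(self.oar_names))
        v[i] = 1.0
        return v

    def predict(self, beams, oar_name: str) -> DoseVolumeHistogram:
        from .predictor import predict_dvh

        return predict_dvh(self.trained, beams, extra=self._one_hot(oar_name))

    def predict_cases(
        self, cases: Sequence[PatientCase], oar_name: str
    ) -> list[DoseVolumeHistogram]:
        extra = self._one_hot(oar_name)
        return predict_batch(
            self.trained,
            [c.oars[oar_name][0] for c in cases],
            extras=[extra] * len(cases),
        )


def train_previous_baseline(
    cases: Sequence[PatientCase],
    oar_names: Sequence[str] | None = None,
    model_spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> BaselineModel:
    """Train the previous-method arm: 3 layers, uniform (k = 1) loss, all OARs jointly."""
    if len(cases) < 2:
        raise ValueError("need at least 2 training cases")
    if oar_names is None:
        oar_names = sorted(cases[0].oars)
    oar_names = tuple(oar_names)
    base = model_spec or ModelSpec()
    spec = replace(
        base, num_layers=3, n_extra_features=len(oar_names)
    )
    cfg = cfg or TrainConfig()
    if cfg.k != 1:
        raise ValueError("the previous-method baseline uses the uniform k = 1 loss")
    model = build_model(spec)
    model.oar_name = "ALL"
    X_parts, Y_parts = [], []
    for j, name in enumerate(oar_names):
        one_hot = np.zeros(len(oar_names))
        one_hot[j] = 1.0
        X, Y = _training_arrays(cases, name, spec, extras=[one_hot] * len(cases))
        X_parts.append(X)
        Y_parts.append(Y)
    X = np.concatenate(X_parts)
    Y = np.concatenate(Y_parts)
    model, history, _ = _run_adam(model, X, Y, cfg)
    model.metadata = {
        "oar": "ALL",
        "k": 1,
        "epochs_run": len(history),
        "final_loss": history[-1],
        "first_loss": history[0],
        "loss_history": history,
        "train_seed": cfg.seed,
        "n_train": len(cases) * len(oar_names),
    }
    return BaselineModel(trained=model, oar_names=oar_names)
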