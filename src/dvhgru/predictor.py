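"""GRU-based DVH predictor: model specification, inference, checkpoints.

The model consumes, at each percent-volume step ``v = 1..100%``, the nine
nonmodulated-beam doses at that volume (normalized by the prescription
dose), runs them through a stacked GRU, and emits the predicted plan dose
at the same volume through a one-unit affine head.  Dropout sits between
the recurrent output and the head and is active only during training.
Predicted curves are clipped at zero and made monotone non-increasing by a
running maximum taken from the 100%-volume tail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dvh import BeamDVHSet, DoseVolumeHistogram, N_BINS

__all__ = ["ModelSpec", "TrainedModel", "build_model", "predict_dvh", "monotone_repair"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture and preprocessing configuration.

    ``input_size`` is fixed at the nine beam features per step;
    ``n_extra_features`` adds per-step constant covariates (used by the
    jointly trained multi-organ baseline for its organ-identity one-hot).
    ``dose_norm`` is the Gy divisor applied to inputs and un-applied to
    outputs (the 70 Gy prescription by default).  ``ascending`` selects the
    direction in which the volume axis is consumed.
    """

    input_size: int = 9
    hidden_size: int = 32
    num_layers: int = 1
    dropout_p: float = 0.5
    dose_norm: float = 70.0
    seed: int = 0
    ascending: bool = True
    n_extra_features: int = 0

    def __post_init__(self) -> None:
        if self.input_size != 9:
            raise ValueError("input_size is fixed at 9 beam features per step")
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must lie in [0, 1)")
        if self.dose_norm <= 0:
            raise ValueError("dose_norm must be positive")
        if self.n_extra_features < 0:
            raise ValueError("n_extra_features must be >= 0")

    @property
    def total_input_size(self) -> int:
        return self.input_size + self.n_extra_features


@dataclass
class TrainedModel:
    """A (possibly untrained) GRU predictor with its provenance metadata."""

    spec: ModelSpec
    params: nn.GRUParams
    oar_name: str = ""
    metadata: dict = field(default_factory=dict)

    def n_parameters(self) -> int:
        return self.params.n_parameters()

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write a single-file JSON checkpoint (exact float64 round-trip)."""
        payload = {
            "format": "dvhgru-checkpoint-v1",
            "spec": asdict(self.spec),
            "oar_name": self.oar_name,
            "metadata": self.metadata,
            "weights": {
                "layers": [
                    [a.tolist() for a in layer] for layer in self.params.layers
                ],
                "w_out": self.params.w_out.tolist(),
                "b_out": float(self.params.b_out),
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "dvhgru-checkpoint-v1":
            raise ValueError(f"not a dvhgru checkpoint: {path}")
        spec = ModelSpec(**payload["spec"])
        w = payload["weights"]
        layers = [
            tuple(np.asarray(a, dtype=float) for a in layer)
            for layer in w["layers"]
        ]
        params = nn.GRUParams(
            layers=layers,
            w_out=np.asarray(w["w_out"], dtype=float),
            b_out=np.asarray(w["b_out"], dtype=float),
        )
        return cls(
            spec=spec,
            params=params,
            oar_name=payload["oar_name"],
            metadata=payload["metadata"],
        )


def build_model(spec: ModelSpec) -> TrainedModel:
    """Initialize an untrained model, deterministically under ``spec.seed``."""
    params = nn.init_params(
        spec.total_input_size, spec.hidden_size, spec.num_layers, spec.seed
    )
    return TrainedModel(spec=spec, params=params)


def monotone_repair(doses: np.ndarray) -> np.ndarray:
    """Running maximum from the 100%-volume tail; identity on monotone input."""
    return np.maximum.accumulate(doses[..., ::-1], axis=-1)[..., ::-1]


def features_from_beams(
    spec: ModelSpec, beams: BeamDVHSet, extra: np.ndarray | None = None
) -> np.ndarray:
    """(100, total_input) normalized per-step feature matrix."""
    feats = beams.feature_matrix() / spec.dose_norm  # (100, 9)
    if spec.n_extra_features:
        if extra is None or len(extra) != spec.n_extra_features:
            raise ValueError(
                f"model expects {spec.n_extra_features} extra per-step features"
            )
        feats = np.concatenate(
            [feats, np.broadcast_to(extra, (N_BINS, spec.n_extra_features))], axis=1
        )
    elif extra is not None:
        raise ValueError("model takes no extra features")
    if not spec.ascending:
        feats = feats[::-1]
    return feats


def predict_dvh(
    model: TrainedModel, beams: BeamDVHSet, extra: np.ndarray | None = None
) -> DoseVolumeHistogram:
    """Predict the plan DVH from a beam set (dropout disabled)."""
    feats = features_from_beams(model.spec, beams, extra)
    y, _ = nn.forward(model.params, feats[None, :, :])
    y = y[0]
    if not model.spec.ascending:
        y = y[::-1]
    doses = monotone_repair(np.clip(y * model.spec.dose_norm, 0.0, None))
    return DoseVolumeHistogram(doses)


def predict_batch(
    model: TrainedModel,
    beam_sets: list[BeamDVHSet],
    extras: list[np.ndarray] | None = None,
) -> list[DoseVolumeHistogram]:
    """Vectorized prediction over many beam sets."""
    feats = np.stack(
        [
            features_from_beams(
                model.spec, b, None if extras is None else extras[i]
            )
            for i, b in enumerate(beam_sets)
        ]
    )
    y, _ = nn.forward(model.params, feats)
    if not model.spec.ascending:
        y = y[:, ::-1]
    doses = monotone_repair(np.clip(y * model.spec.dose_norm, 0.0, None))
    return [DoseVolumeHistogram(d) for d in doses]
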