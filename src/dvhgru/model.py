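"""Model/Results facade over the per-organ DVH predictor.

Follows the familiar two-object pattern of statistical modelling packages:
:class:`DVHPredictionModel` holds the data and configuration, ``fit()``
returns a :class:`DVHFitResults` carrying the trained weights, the loss
history, prediction and evaluation methods, and a ``summary()`` table.

Example
-------
>>> from dvhgru import cohort, model
>>> co = cohort.generate_cohort(cohort.CohortSpec(n_patients=20, n_train=14, seed=1))
>>> m = model.DVHPredictionModel.from_cohort(co, "spinal_cord")
>>> res = m.fit()
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import Cohort, PatientCase
from .dvh import (
    BeamDVHSet,
    DoseVolumeHistogram,
    OARConfig,
    compute_eud,
    default_oar_config,
    max_dose,
)
from .evaluation import mu_sigma, prediction_errors
from .predictor import ModelSpec, TrainedModel, predict_batch, predict_dvh
from .training import (
    KSearchResult,
    TrainConfig,
    grid_search_k,
    train_oar_model,
)

__all__ = ["DVHPredictionModel", "DVHFitResults"]


class DVHPredictionModel:
    """Per-organ GRU DVH prediction model, bound to its training data.

    Parameters
    ----------
    train_cases : sequence of PatientCase
        Cases providing the beam DVH sets (features) and plan DVHs (targets).
    oar : OARConfig
        Organ configuration; supplies the default loss exponent ``k``.
    model_spec, train_config : optional
        Architecture and optimization settings; sensible defaults otherwise
        (the training loss exponent defaults to ``oar.loss_k``).
    """

    def __init__(
        self,
        train_cases: Sequence[PatientCase],
        oar: OARConfig,
        model_spec: ModelSpec | None = None,
        train_config: TrainConfig | None = None,
    ):
        if len(train_cases) < 2:
            raise ValueError("need at least 2 training cases")
        if any(oar.name not in c.oars for c in train_cases):
            raise ValueError(f"some cases lack OAR {oar.name!r}")
        self.train_cases = tuple(train_cases)
        self.oar = oar
        self.model_spec = model_spec or ModelSpec()
        self.train_config = train_config or TrainConfig(k=oar.loss_k)

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        oar_name: str,
        oar: OARConfig | None = None,
        **kwargs,
    ) -> "DVHPredictionModel":
        """Build from a generated cohort's training split."""
        return cls(
            cohort.train_cases,
            oar or default_oar_config(oar_name),
            **kwargs,
        )

    def fit(self, val_cases: Sequence[PatientCase] | None = None) -> "DVHFitResults":
        """Train with Adam on the EUD-weighted loss; returns the results object."""
        trained = train_oar_model(
            self.train_cases, self.oar, self.model_spec, self.train_config, val_cases
        )
        return DVHFitResults(model=self, trained=trained)

    def fit_k_search(
        self,
        candidate_ks: Iterable[int],
        val_cases: Sequence[PatientCase],
    ) -> tuple["DVHFitResults", KSearchResult]:
        """Trial-and-error selection of the loss exponent k on a validation split."""
        search = grid_search_k(
            self.train_cases,
            self.oar,
            candidate_ks,
            self.model_spec,
            self.train_config,
            val_cases,
        )
        return (
            DVHFitResults(model=self, trained=search.models[search.selected_k]),
            search,
        )


@dataclass
class DVHFitResults:
    """Fitted per-organ model: weights, history, prediction, evaluation."""

    model: DVHPredictionModel
    trained: TrainedModel

    @property
    def loss_history(self) -> list[float]:
        return self.trained.metadata.get("loss_history", [])

    @property
    def k(self) -> int:
        return int(self.trained.metadata.get("k", self.model.train_config.k))

    @property
    def params(self) -> list[np.ndarray]:
        return self.trained.params.flatten()

    def predict(self, beams: BeamDVHSet) -> DoseVolumeHistogram:
        """Predict the plan DVH for one beam set."""
        return predict_dvh(self.trained, beams)

    def predict_cases(
        self, cases: Sequence[PatientCase]
    ) -> list[DoseVolumeHistogram]:
        return predict_batch(
            self.trained, [c.oars[self.model.oar.name][0] for c in cases]
        )

    def endpoint_errors(
        self, cases: Sequence[PatientCase]
    ) -> dict[str, np.ndarray]:
        """delta vectors (Gy) for EUD and, for serial organs, max dose."""
        return prediction_errors(self.predict_cases(cases), cases, self.model.oar)

    def save(self, path: str | Path) -> None:
        self.trained.save(path)

    def summary(self, test_cases: Sequence[PatientCase] | None = None) -> str:
        """Human-readable fit summary; adds test-set mu/sigma when cases given."""
        oar = self.model.oar
        md = self.trained.metadata
        spec = self.trained.spec
        lines = [
            "DVH prediction fit",
            "=" * 52,
            f"OAR:            {oar.name} ({'serial' if oar.serial else 'parallel'}, a={oar.eud_a:g})",
            f"loss exponent:  k = {self.k}",
            f"architecture:   GRU layers={spec.num_layers} hidden={spec.hidden_size} "
            f"dropout={spec.dropout_p}",
            f"parameters:     {self.trained.n_parameters()}",
            f"training:       {md.get('n_train', '?')} cases, "
            f"{md.get('epochs_run', '?')} epochs, Adam lr={self.model.train_config.learning_rate:g}",
            f"loss:           {md.get('first_loss', float('nan')):.3e} (epoch 1) -> "
            f"{md.get('final_loss', float('nan')):.3e} (final)",
        ]
        if test_cases is not None:
            errs = self.endpoint_errors(test_cases)
            for endpoint, delta in errs.items():
                mu, sigma = mu_sigma(delta)
                label = "EUD " if endpoint == "eud" else "Dmax"
                lines.append(
                    f"test {label} error: mu = {mu:+.3f} Gy, sigma = {sigma:.3f} Gy "
                    f"(n={len(delta)})"
                )
        return "\n".join(lines)
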