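"""Evaluation statistics for DVH prediction.

Per test patient the prediction error of an endpoint (gEUD, or maximum dose
for serial organs) is ``delta_i = predicted - planned`` in Gy.  Summaries
follow the conventions of the evaluation protocol this package implements:

* ``mu`` is the mean of the deltas and ``sigma`` the POPULATION standard
  deviation (denominator ``n``, not ``n - 1``) — note this differs from
  most library defaults;
* paired methods are compared with a two-sided Wilcoxon signed-rank test on
  the paired deltas (exact null by enumeration for n <= 15 after dropping
  zero differences; normal approximation with tie correction above);
* agreement between predicted and planned endpoint values pooled across
  organs is summarised by ordinary least squares and the Pearson r;
* boxplot summaries use linearly interpolated quartiles and 1.5 * IQR
  whiskers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .dvh import DoseVolumeHistogram, OARConfig, compute_eud, max_dose
from .cohort import PatientCase

__all__ = [
    "prediction_errors",
    "mu_sigma",
    "wilcoxon_signed_rank",
    "pooled_regression",
    "boxplot_stats",
    "EndpointSummary",
    "EvaluationReport",
    "evaluate_predictions",
]

SIGNIFICANCE_LEVEL = 0.05


def prediction_errors(
    predictions: Sequence[DoseVolumeHistogram] | Mapping[str, DoseVolumeHistogram],
    cases: Sequence[PatientCase],
    oar: OARConfig,
) -> dict[str, np.ndarray]:
    """Per-patient endpoint errors ``delta_i = D'_i - D_i`` in Gy.

    Returns a dict with key ``"eud"`` and, for serial organs, ``"dmax"``;
    order matches the case order.
    """
    if isinstance(predictions, Mapping):
        missing = [c.patient_id for c in cases if c.patient_id not in predictions]
        if missing:
            raise ValueError(f"missing predictions for patients: {missing}")
        preds = [predictions[c.patient_id] for c in cases]
    else:
        preds = list(predictions)
        if len(preds) != len(cases):
            raise ValueError(
                f"{len(preds)} predictions for {len(cases)} cases"
            )
    plans = [c.oars[oar.name][1] for c in cases]
    out = {
        "eud": np.array(
            [compute_eud(p, oar.eud_a) - compute_eud(t, oar.eud_a) for p, t in zip(preds, plans)]
        )
    }
    if oar.serial:
        out["dmax"] = np.array(
            [max_dose(p) - max_dose(t) for p, t in zip(preds, plans)]
        )
    return out


def mu_sigma(delta: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """Mean and population standard deviation (denominator n) of the errors."""
    d = np.asarray(delta, dtype=float)
    if d.size == 0:
        raise ValueError("empty error vector")
    mu = float(d.mean())
    sigma = float(np.sqrt(np.mean((d - mu) ** 2)))
    return mu, sigma


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ranks of |d| (average ranks for ties) and the signs, zeros removed."""
    d = diffs[diffs != 0.0]
    ranks = sps.rankdata(np.abs(d))
    return ranks, np.sign(d)


def wilcoxon_signed_rank(
    delta_a: Sequence[float] | np.ndarray,
    delta_b: Sequence[float] | np.ndarray,
    use_absolute: bool = False,
) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired per-patient errors.

    Pairs are differenced patient-wise (signed errors by default; set
    ``use_absolute`` to pair |delta| instead).  Zero differences are
    discarded.  For n <= 15 remaining pairs the exact two-sided p-value is
    computed by enumerating all sign assignments of the (tie-averaged)
    ranks, ``p = 2 min(P(W+ <= w), P(W+ >= w))`` capped at 1; larger
    samples use the normal approximation with tie correction.
    """
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired error vectors must be 1-D and equal length")
    if use_absolute:
        a, b = np.abs(a), np.abs(b)
    diffs = a - b
    ranks, signs = _signed_ranks(diffs)
    m = len(ranks)
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1 (degenerate)")
        return 1.0
    w_obs = float(ranks[signs > 0].sum())
    if m <= 15:
        # exact null: each rank is + or - with probability 1/2
        w_values = np.fromiter(
            (
                sum(itertools.compress(ranks, flags))
                for flags in itertools.product((0, 1), repeat=m)
            ),
            dtype=float,
            count=2**m,
        )
        tol = 1e-9
        p_le = np.mean(w_values <= w_obs + tol)
        p_ge = np.mean(w_values >= w_obs - tol)
        return float(min(1.0, 2.0 * min(p_le, p_ge)))
    mean = m * (m + 1) / 4.0
    var = m * (m + 1) * (2 * m + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(counts**3 - counts)) / 48.0
    if var <= 0:
        warnings.warn("zero variance after tie correction; p = 1 (degenerate)")
        return 1.0
    z = (w_obs - mean) / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def pooled_regression(
    predicted: Sequence[float] | np.ndarray,
    planned: Sequence[float] | np.ndarray,
) -> tuple[float, float, float]:
    """OLS of predicted on planned endpoint values: (slope, intercept, Pearson r)."""
    x = np.asarray(planned, dtype=float)
    y = np.asarray(predicted, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need >= 2 pooled (planned, predicted) pairs")
    if np.ptp(x) == 0:
        raise ValueError("planned values are constant; correlation undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def boxplot_stats(delta: Sequence[float] | np.ndarray) -> dict:
    """Quartiles, 1.5*IQR whisker ends and outliers of an error vector.

    Quartiles use linear interpolation; whiskers extend to the most extreme
    data points within 1.5 * IQR of the box, and points beyond are outliers.
    """
    d = np.asarray(delta, dtype=float)
    if d.size == 0:
        raise ValueError("empty error vector")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = d[(d >= lo_fence) & (d <= hi_fence)]
    return {
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_lo": float(inside.min()),
        "whisker_hi": float(inside.max()),
        "outliers": np.sort(d[(d < lo_fence) | (d > hi_fence)]),
    }


@dataclass
class EndpointSummary:
    """mu/sigma summary of one (organ, endpoint) error vector."""

    oar: str
    endpoint: str  # "eud" or "dmax"
    delta: np.ndarray
    mu: float
    sigma: float
    p_value: float | None = None  # vs the comparison method, if any

    @property
    def boxplot(self) -> dict:
        return boxplot_stats(self.delta)


@dataclass
class EvaluationReport:
    """Full evaluation: per-organ endpoint summaries plus pooled agreement."""

    summaries: list[EndpointSummary]
    pooled_slope: float
    pooled_intercept: float
    pooled_r: float
    scatter: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"{'OAR':<18}{'endpoint':<10}{'mu (Gy)':>10}{'sigma (Gy)':>12}{'p':>10}",
            "-" * 60,
        ]
        for s in self.summaries:
            p = f"{s.p_value:.4f}" if s.p_value is not None else "-"
            lines.append(
                f"{s.oar:<18}{s.endpoint:<10}{s.mu:>10.3f}{s.sigma:>12.3f}{p:>10}"
            )
        lines.append("-" * 60)
        lines.append(
            f"pooled OLS: slope={self.pooled_slope:.4f} "
            f"intercept={self.pooled_intercept:.3f} Gy  r={self.pooled_r:.4f}"
        )
        return "\n".join(lines)

    def plot_scatter(self, ax=None):
        """Predicted-vs-plan endpoint scatter with the pooled OLS line (cosmetic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.array([s["plan_gy"] for s in self.scatter])
        y = np.array([s["predicted_gy"] for s in self.scatter])
        ax.scatter(x, y, s=12, alpha=0.6)
        grid = np.linspace(x.min(), x.max(), 2)
        ax.plot(grid, self.pooled_slope * grid + self.pooled_intercept, "k-",
                label=f"OLS, r = {self.pooled_r:.3f}")
        ax.plot(grid, grid, "k:", lw=0.8)
        ax.set_xlabel("original plan (Gy)")
        ax.set_ylabel("predicted (Gy)")
        ax.legend()
        return ax

    def plot_error_boxes(self, ax=None):
        """Per-(organ, endpoint) boxplot of the delta vectors, 1.5 IQR whiskers (cosmetic)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = [f"{s.oar}\n{s.endpoint}" for s in self.summaries]
        ax.boxplot([s.delta for s in self.summaries], tick_labels=labels, whis=1.5)
        ax.axhline(0.0, color="k", lw=0.8, ls=":")
        ax.set_ylabel("prediction error (Gy)")
        return ax

    def to_rows(self) -> list[dict]:
        return [
            {
                "oar": s.oar,
                "endpoint": s.endpoint,
                "mu_gy": s.mu,
                "sigma_gy": s.sigma,
                "p_value": s.p_value,
                "n": len(s.delta),
            }
            for s in self.summaries
        ]


def evaluate_predictions(
    predictions_by_oar: Mapping[str, Sequence[DoseVolumeHistogram]],
    cases: Sequence[PatientCase],
    oar_configs: Mapping[str, OARConfig],
    comparison_by_oar: Mapping[str, Sequence[DoseVolumeHistogram]] | None = None,
) -> EvaluationReport:
    """Assemble the full report for one prediction set over the test cases.

    When a comparison prediction set is given, each endpoint additionally
    carries the paired Wilcoxon p-value of this method against it.
    """
    summaries: list[EndpointSummary] = []
    pooled_pred: list[float] = []
    pooled_plan: list[float] = []
    scatter: list[dict] = []
    for oar_name in sorted(predictions_by_oar):
        oar = oar_configs[oar_name]
        preds = predictions_by_oar[oar_name]
        errs = prediction_errors(preds, cases, oar)
        comp_errs = None
        if comparison_by_oar is not None:
            comp_errs = prediction_errors(comparison_by_oar[oar_name], cases, oar)
        for endpoint, delta in errs.items():
            mu, sigma = mu_sigma(delta)
            p = None
            if comp_errs is not None:
                p = wilcoxon_signed_rank(delta, comp_errs[endpoint])
            summaries.append(
                EndpointSummary(
                    oar=oar_name, endpoint=endpoint, delta=delta, mu=mu, sigma=sigma,
                    p_value=p,
                )
            )
        for case, pred in zip(cases, preds):
            plan = case.oars[oar_name][1]
            for endpoint in errs:
                if endpoint == "eud":
                    pv = compute_eud(pred, oar.eud_a)
                    tv = compute_eud(plan, oar.eud_a)
                else:
                    pv = max_dose(pred)
                    tv = max_dose(plan)
                pooled_pred.append(pv)
                pooled_plan.append(tv)
                scatter.append(
                    {
                        "patient_id": case.patient_id,
                        "oar": oar_name,
                        "endpoint": endpoint,
                        "plan_gy": tv,
                        "predicted_gy": pv,
                    }
                )
    slope, intercept, r = pooled_regression(pooled_pred, pooled_plan)
    return EvaluationReport(
        summaries=summaries,
        pooled_slope=slope,
        pooled_intercept=intercept,
        pooled_r=r,
        scatter=scatter,
    )
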