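"""Cumulative DVH data model and gEUD math on the percent-volume grid.

A cumulative dose-volume histogram (DVH) gives, for each dose level, the
fraction of an organ's volume receiving at least that dose.  Everything in
this package works with the inverse sampling: the dose :math:`D_v` at each
percent volume :math:`v = 1\\%, 2\\%, \\dots, 100\\%` (bin width
:math:`\\Delta v = 1\\%`).  On that equal-volume grid the generalized
equivalent uniform dose (gEUD) reduces to a power mean,

.. math::

    \\mathrm{EUD} = \\Big( \\sum_j \\tfrac{\\Delta v}{100\\%}\\, D_j^a
    \\Big)^{1/a},

with the organ-specific exponent ``a`` (large for serial organs, whose
response is dominated by the maximum dose; 1 for parallel organs, whose
response tracks the mean dose).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GRID_VOLUMES",
    "N_BINS",
    "GANTRY_ANGLES",
    "DoseVolumeHistogram",
    "BeamDVHSet",
    "OARConfig",
    "DEFAULT_OAR_CONFIGS",
    "default_oar_config",
    "resample_dvh",
    "compute_eud",
    "max_dose",
    "sensitivity_weights",
]

N_BINS = 100
#: percent-volume grid: v = 1%, 2%, ..., 100%
GRID_VOLUMES = np.arange(1, N_BINS + 1, dtype=float)
#: gantry angles (degrees) of the nine nonmodulated conformal fields B1..B9
GANTRY_ANGLES = (160, 200, 240, 280, 320, 0, 40, 80, 120)

_DOSE_ATOL = 1e-9  # Gy; equality tolerance for monotonicity checks


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """Cumulative DVH sampled as dose-at-percent-volume on the 1% grid.

    ``doses[j]`` is the dose (Gy) received by at least ``(j+1)%`` of the
    organ volume.  A valid cumulative DVH is non-negative and monotone
    non-increasing in volume.
    """

    doses: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.doses, dtype=float)
        if arr.ndim != 1 or arr.shape[0] != N_BINS:
            raise ValueError(
                f"DVH must have exactly {N_BINS} dose samples, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("DVH doses must be finite")
        if np.any(arr < 0):
            j = int(np.argmax(arr < 0))
            raise ValueError(f"negative dose {arr[j]:g} Gy at v={j + 1}%")
        diffs = np.diff(arr)
        bad = diffs > _DOSE_ATOL
        if np.any(bad):
            j = int(np.argmax(bad))
            raise ValueError(
                "DVH doses must be non-increasing in volume: "
                f"doses[v={j + 1}%]={arr[j]:g} < doses[v={j + 2}%]={arr[j + 1]:g}"
            )
        object.__setattr__(self, "doses", arr)

    @property
    def volumes(self) -> np.ndarray:
        """Percent-volume grid points (1..100)."""
        return GRID_VOLUMES

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DoseVolumeHistogram):
            return NotImplemented
        return bool(np.array_equal(self.doses, other.doses))

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash(self.doses.tobytes())


@dataclass(frozen=True)
class BeamDVHSet:
    """The nine nonmodulated-beam DVHs (B1..B9) for one OAR of one patient.

    The fixed beam order corresponds to gantry angles
    160, 200, 240, 280, 320, 0, 40, 80, 120 degrees.
    """

    beams: tuple[DoseVolumeHistogram, ...]
    gantry_angles: tuple[int, ...] = GANTRY_ANGLES

    def __post_init__(self) -> None:
        beams = tuple(self.beams)
        if len(beams) != 9:
            raise ValueError(f"expected exactly 9 beam DVHs, got {len(beams)}")
        if tuple(self.gantry_angles) != GANTRY_ANGLES:
            raise ValueError(f"gantry angles must be {GANTRY_ANGLES}")
        object.__setattr__(self, "beams", beams)
        object.__setattr__(self, "gantry_angles", GANTRY_ANGLES)

    def feature_matrix(self) -> np.ndarray:
        """Beam doses stacked as a (100, 9) array: row j = the nine doses at v=(j+1)%."""
        return np.stack([b.doses for b in self.beams], axis=1)


@dataclass(frozen=True)
class OARConfig:
    """Per-organ parameters.

    Parameters
    ----------
    name : str
        Organ label.
    loss_k : int
        Sensitivity exponent ``k`` of the EUD-weighted training loss
        (``k = 1`` collapses to uniformly weighted MSE).
    eud_a : float
        gEUD exponent ``a`` used for evaluation (8 for serial organs,
        1 for parallel organs).
    serial : bool
        Whether the organ is serial, i.e. whether the maximum dose is
        reported alongside the EUD.
    dose_cap : float
        Normalization dose in Gy (the 70 Gy prescription by default).
    """

    name: str
    loss_k: int = 1
    eud_a: float = 1.0
    serial: bool = False
    dose_cap: float = 70.0

    def __post_init__(self) -> None:
        if int(self.loss_k) != self.loss_k or self.loss_k < 1:
            raise ValueError(f"loss_k must be a positive integer, got {self.loss_k}")
        object.__setattr__(self, "loss_k", int(self.loss_k))
        if self.eud_a < 1:
            raise ValueError(f"eud_a must be >= 1, got {self.eud_a}")
        if self.dose_cap <= 0:
            raise ValueError("dose_cap must be positive")


def _default_configs() -> dict[str, OARConfig]:
    # k values from the trial-and-error table; a=8 for serial organs,
    # a=1 for parallel organs; serial <=> a == 8.
    spec = {
        "brainstem": (8, 8),
        "spinal_cord": (15, 8),
        "optic_nerve_l": (3, 8),
        "optic_nerve_r": (2, 8),
        "chiasm": (1, 8),
        "larynx": (1, 1),
        "parotid_l": (1, 1),
        "parotid_r": (1, 1),
        "temporal_lobe_l": (1, 1),
        "temporal_lobe_r": (1, 1),
    }
    return {
        name: OARConfig(name=name, loss_k=k, eud_a=float(a), serial=(a == 8))
        for name, (k, a) in spec.items()
    }


#: organ -> OARConfig with the standard per-organ (k, a) defaults
DEFAULT_OAR_CONFIGS: dict[str, OARConfig] = _default_configs()


def default_oar_config(name: str) -> OARConfig:
    """Return the default :class:`OARConfig` for a known organ label."""
    try:
        return DEFAULT_OAR_CONFIGS[name]
    except KeyError:
        raise KeyError(
            f"unknown OAR {name!r}; known: {sorted(DEFAULT_OAR_CONFIGS)}"
        ) from None


def resample_dvh(samples: Iterable[tuple[float, float]]) -> DoseVolumeHistogram:
    """Resample a cumulative DVH onto the 1% percent-volume grid.

    Parameters
    ----------
    samples : iterable of (dose_gy, volume_percent)
        Points of the cumulative curve V(d): volume (in % of organ volume)
        receiving at least dose d.  The curve must be non-increasing in dose
        and its volumes must cover the grid (reach down to <= 1% and up
        to 100%).

    Returns
    -------
    DoseVolumeHistogram
        Dose at each grid volume v = 1..100%, by linear interpolation of the
        input in the volume -> dose direction.  Where several doses share the
        same volume (a flat stretch of the cumulative curve), the maximum
        dose at that volume is taken — the conservative choice for serial
        organs.
    """
    pts = np.asarray(list(samples), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (dose, volume) samples")
    order = np.argsort(pts[:, 0], kind="stable")
    dose = pts[order, 0]
    vol = pts[order, 1]
    if np.any(dose < 0):
        raise ValueError("doses must be non-negative")
    incr = np.diff(vol) > 1e-9
    if np.any(incr):
        i = int(np.argmax(incr))
        raise ValueError(
            "cumulative volume must be non-increasing in dose: "
            f"V({dose[i]:g} Gy)={vol[i]:g}% < V({dose[i + 1]:g} Gy)={vol[i + 1]:g}%"
        )
    if vol[0] < 100.0 - 1e-9 or vol[-1] > 1.0 + 1e-9:
        raise ValueError(
            f"volume range [{vol[-1]:g}%, {vol[0]:g}%] does not cover the 1..100% grid"
        )
    # invert: volume ascending; np.interp picks, within runs of equal volume,
    # the value at the first matching x — feed doses descending so that the
    # first match is the maximum dose at that volume.
    v_asc = vol[::-1]
    d_at_v = dose[::-1]
    # make v strictly usable by interp (it tolerates equal x; first wins)
    grid = np.interp(GRID_VOLUMES, v_asc, d_at_v)
    # enforce exact tie rule at grid volumes present in the input
    for gv in np.unique(v_asc):
        hits = np.isclose(GRID_VOLUMES, gv, rtol=0, atol=1e-12)
        if hits.any():
            grid[hits] = dose[np.isclose(vol, gv, rtol=0, atol=1e-12)].max()
    grid = np.maximum.accumulate(grid[::-1])[::-1]  # defensive monotone snap
    return DoseVolumeHistogram(grid)


def compute_eud(dvh: DoseVolumeHistogram, a: float) -> float:
    """Generalized equivalent uniform dose of a DVH.

    Computed as the power mean ``(mean(D_j^a))^(1/a)`` over the 100
    equal-volume dose samples; ``a = 1`` gives the mean dose, and the limit
    ``a -> inf`` approaches the maximum dose.  Evaluated in log space for
    numerical stability at large ``a``.
    """
    if a <= 0:
        raise ValueError(f"EUD exponent a must be positive, got {a}")
    d = dvh.doses
    dmax = float(d[0])
    if dmax == 0.0:
        return 0.0
    # (mean((d/dmax)^a))^(1/a) * dmax avoids overflow for large a
    ratios = d / dmax
    return float(dmax * np.mean(ratios**a) ** (1.0 / a))


def max_dose(dvh: DoseVolumeHistogram) -> float:
    """Maximum dose of a DVH: the dose at the smallest sampled volume (1%)."""
    return float(dvh.doses[0])


def sensitivity_weights(doses: Sequence[float] | np.ndarray, k: float) -> np.ndarray:
    """Dose-sensitivity weights ``s_j = D_j^(k-1) / sum_i D_i^(k-1)``.

    For ``k = 1`` the weights are uniform; for ``k > 1`` they concentrate on
    the high-dose bins, mirroring the sensitivity of the gEUD to each dose
    sample.  Weights are non-negative, sum to 1, and are invariant to
    rescaling all doses by a positive constant.
    """
    if k < 1:
        raise ValueError(f"sensitivity exponent k must be >= 1, got {k}")
    d = np.asarray(doses, dtype=float)
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    if k == 1:
        return np.full(d.shape, 1.0 / d.shape[-1])
    dmax = d.max(axis=-1, keepdims=True)
    if np.any(dmax == 0):
        raise ValueError("all-zero doses give undefined weights for k > 1")
    p = (d / dmax) ** (k - 1.0)  # scale-invariant, overflow-safe
    return p / p.sum(axis=-1, keepdims=True)
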