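"""Seeded synthetic cohort of beam/plan DVH cases.

The real inputs to this kind of knowledge-based-planning model come from a
treatment planning system: per patient and per organ at risk (OAR), the nine
DVHs produced by nonmodulated conformal fields plus the DVH of the clinical
plan.  This module substitutes a parametric family with the same statistical
structure so that training, k-selection and evaluation can run end to end
without clinical data:

* a latent per-patient anatomy factor ``x_p ~ Uniform`` scales every dose,
  emulating how favourable or unfavourable geometry shifts the whole dose
  level of an organ;
* beam ``b`` contributes the monotone curve
  ``D_b(v) = x_p * M * w_b * (1 - v/100)**gamma_b`` on the percent-volume
  grid (``M``: organ dose scale in Gy, ``w_b``: relative beam weight,
  ``gamma_b``: shape exponent — large gamma means a small-volume hot spot);
* the plan DVH is the mixture ``sum_b c_b * D_b(v)`` plus i.i.d. Gaussian
  noise, repaired to a valid monotone curve by a running maximum taken from
  the 100%-volume tail and clipped to physical bounds.

Because the noiseless plan is an exact (linear) function of the beam doses,
ground truth is known and recovery can be tested; the latent factor is kept
on each case for the same reason.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .dvh import (
    GRID_VOLUMES,
    N_BINS,
    BeamDVHSet,
    DoseVolumeHistogram,
    DEFAULT_OAR_CONFIGS,
)

__all__ = [
    "OARProfile",
    "CohortSpec",
    "PatientCase",
    "Cohort",
    "default_profiles",
    "serial_scenario",
    "generate_case",
    "generate_cohort",
]

#: plan doses may not exceed this multiple of the organ dose cap
PLAN_CAP_FACTOR = 1.2


@dataclass(frozen=True)
class OARProfile:
    """Generator parameters for one organ.

    ``base_dose`` is the organ dose scale M in Gy; ``beam_gammas`` the nine
    shape exponents; ``beam_weights`` the nine relative beam weights w_b;
    ``mix_weights`` the plan mixing weights c_b (sum 1); ``noise_gy`` the
    plan noise sd in Gy.
    """

    base_dose: float
    beam_gammas: tuple[float, ...]
    beam_weights: tuple[float, ...]
    mix_weights: tuple[float, ...]
    noise_gy: float = 1.0
    dose_cap: float = 70.0

    def __post_init__(self) -> None:
        g = tuple(float(x) for x in self.beam_gammas)
        w = tuple(float(x) for x in self.beam_weights)
        c = tuple(float(x) for x in self.mix_weights)
        if len(g) != 9 or len(w) != 9 or len(c) != 9:
            raise ValueError("beam_gammas, beam_weights, mix_weights need 9 entries each")
        if any(x <= 0 for x in g):
            raise ValueError("beam shape exponents must be positive")
        if any(x < 0 for x in c):
            raise ValueError("mixing weights must be non-negative")
        if abs(sum(c) - 1.0) > 1e-9:
            raise ValueError(f"mixing weights must sum to 1, got {sum(c):g}")
        if self.noise_gy < 0:
            raise ValueError("noise sd must be non-negative")
        if self.base_dose <= 0:
            raise ValueError("base dose must be positive")
        object.__setattr__(self, "beam_gammas", g)
        object.__setattr__(self, "beam_weights", w)
        object.__setattr__(self, "mix_weights", c)


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort.

    ``latent_range`` bounds the per-patient anatomy factor x_p; the train
    split size defaults to the 50-of-80 convention.
    """

    n_patients: int = 80
    n_train: int = 50
    seed: int = 0
    oar_profiles: Mapping[str, OARProfile] = field(default_factory=dict)
    latent_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not (1 <= self.n_train < self.n_patients):
            raise ValueError(
                f"n_train={self.n_train} must leave a non-empty test split of "
                f"{self.n_patients} patients"
            )
        lo, hi = self.latent_range
        if not (0 < lo <= hi):
            raise ValueError("latent_range must be positive and ordered")
        if not self.oar_profiles:
            object.__setattr__(self, "oar_profiles", default_profiles())

    def to_json(self) -> str:
        d = asdict(self)
        d["oar_profiles"] = {k: asdict(v) for k, v in self.oar_profiles.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["oar_profiles"] = {
            k: OARProfile(**v) for k, v in d["oar_profiles"].items()
        }
        d["latent_range"] = tuple(d["latent_range"])
        return cls(**d)


@dataclass(frozen=True)
class PatientCase:
    """One patient: per-OAR beam DVH set and plan DVH, plus the latent factor."""

    patient_id: str
    oars: Mapping[str, tuple[BeamDVHSet, DoseVolumeHistogram]]
    latent: float | None = None


@dataclass(frozen=True)
class Cohort:
    """Generated cases with a recorded, seed-reproducible train/test split."""

    spec: CohortSpec
    cases: tuple[PatientCase, ...]
    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]

    @property
    def train_cases(self) -> tuple[PatientCase, ...]:
        return tuple(self.cases[i] for i in self.train_idx)

    @property
    def test_cases(self) -> tuple[PatientCase, ...]:
        return tuple(self.cases[i] for i in self.test_idx)


def _spread(lo: float, hi: float, n: int = 9) -> tuple[float, ...]:
    return tuple(float(x) for x in np.linspace(lo, hi, n))


def default_profiles() -> dict[str, OARProfile]:
    """Default per-organ generator profiles.

    Dose scales sit in the 20-60 Gy range typical of head-and-neck OARs;
    beam shapes and weights differ across beams so the plan mixture is a
    nondegenerate function of all nine inputs.  Serial organs get one
    sharper (larger gamma) beam to carry a modest high-dose head.
    """
    fixed_w = _spread(0.7, 1.3)
    fixed_c = tuple(float(x) for x in np.linspace(1.4, 0.6, 9) / np.linspace(1.4, 0.6, 9).sum())
    profiles: dict[str, OARProfile] = {}
    scales = {
        "brainstem": 42.0,
        "spinal_cord": 34.0,
        "chiasm": 38.0,
        "optic_nerve_l": 35.0,
        "optic_nerve_r": 33.0,
        "larynx": 40.0,
        "parotid_l": 28.0,
        "parotid_r": 27.0,
        "temporal_lobe_l": 45.0,
        "temporal_lobe_r": 44.0,
    }
    for i, (name, scale) in enumerate(scales.items()):
        # deterministic per-organ variation of the beam shapes
        gammas = tuple(
            float(g) for g in 0.6 + 1.4 * (0.5 + 0.5 * np.sin(np.arange(9) + i))
        )
        serial = DEFAULT_OAR_CONFIGS[name].serial
        if serial:
            gammas = (3.0,) + gammas[1:]
        profiles[name] = OARProfile(
            base_dose=scale,
            beam_gammas=gammas,
            beam_weights=fixed_w,
            mix_weights=fixed_c,
            noise_gy=1.0,
        )
    return profiles


def serial_scenario(
    n_patients: int = 60,
    n_train: int = 40,
    seed: int = 0,
    noise_gy: float = 1.5,
) -> CohortSpec:
    """Single-organ cohort whose plans carry a heavy high-dose head.

    Beam 1 is sharp (gamma = 6) and strong, so most of its dose lands on a
    small sub-volume; the plan mixture inherits a hot head whose height
    varies patient to patient while the remaining 99% of the curve is
    dominated by the broad beams.  Under a uniformly weighted loss the model
    is rewarded for fitting the broad body of the curve; predicting the
    maximum dose is the hard part, which is exactly the regime where a
    sensitivity exponent k >> 1 in the loss should help.
    """
    gammas = (6.0, 0.6, 0.8, 1.0, 1.2, 0.7, 0.9, 1.1, 1.3)
    weights = (2.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    mix = np.array([0.45, *np.full(8, 0.55 / 8)])
    profile = OARProfile(
        base_dose=34.0,
        beam_gammas=gammas,
        beam_weights=weights,
        mix_weights=tuple(float(x) for x in mix),
        noise_gy=noise_gy,
    )
    return CohortSpec(
        n_patients=n_patients,
        n_train=n_train,
        seed=seed,
        oar_profiles={"spinal_cord": profile},
    )


def _beam_curves(profile: OARProfile, latent: float) -> np.ndarray:
    """(100, 9) beam dose matrix D_b(v) = x_p * M * w_b * (1 - v/100)^gamma_b."""
    frac = 1.0 - GRID_VOLUMES / 100.0  # (100,)
    g = np.asarray(profile.beam_gammas)
    w = np.asarray(profile.beam_weights)
    return latent * profile.base_dose * w * frac[:, None] ** g


def _monotone_repair(doses: np.ndarray) -> np.ndarray:
    """Restore monotone non-increase by a running maximum from the tail."""
    return np.maximum.accumulate(doses[::-1])[::-1]


def generate_case(
    spec: CohortSpec, patient_index: int, rng: np.random.Generator | None = None
) -> PatientCase:
    """Generate one patient case; deterministic in (spec.seed, patient_index)."""
    if rng is None:
        rng = np.random.default_rng([spec.seed, patient_index])
    lo, hi = spec.latent_range
    latent = float(rng.uniform(lo, hi))
    oars: dict[str, tuple[BeamDVHSet, DoseVolumeHistogram]] = {}
    for name, profile in spec.oar_profiles.items():
        curves = _beam_curves(profile, latent)  # (100, 9)
        beams = BeamDVHSet(
            tuple(DoseVolumeHistogram(curves[:, b]) for b in range(9))
        )
        c = np.asarray(profile.mix_weights)
        plan = curves @ c
        if profile.noise_gy > 0:
            plan = plan + rng.normal(0.0, profile.noise_gy, size=N_BINS)
        plan = _monotone_repair(plan)
        plan = np.clip(plan, 0.0, PLAN_CAP_FACTOR * profile.dose_cap)
        oars[name] = (beams, DoseVolumeHistogram(plan))
    return PatientCase(patient_id=f"P{patient_index:03d}", oars=oars, latent=latent)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full cohort and a seed-reproducible random train/test split."""
    cases = tuple(generate_case(spec, i) for i in range(spec.n_patients))
    split_rng = np.random.default_rng([spec.seed, 987654321])
    perm = split_rng.permutation(spec.n_patients)
    train_idx = tuple(sorted(int(i) for i in perm[: spec.n_train]))
    test_idx = tuple(sorted(int(i) for i in perm[spec.n_train :]))
    return Cohort(spec=spec, cases=cases, train_idx=train_idx, test_idx=test_idx)
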