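"""CSV/JSON formats tying the pipeline together.

The on-disk DVH exchange format is a long-format CSV with the exact header
``patient_id,oar,source,v_percent,dose_gy`` where ``source`` is one of
``beam1..beam9``, ``plan`` or ``prediction``; every (patient, oar, source)
group carries exactly the 100 grid bins with non-increasing doses.  Doses
are always in Gy (no cGy dialect).  Reading validates all invariants and
names the offending rows; ``read(write(x)) == x`` bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, PatientCase
from .dvh import BeamDVHSet, DoseVolumeHistogram, N_BINS

__all__ = [
    "DVH_TABLE_COLUMNS",
    "write_dvh_table",
    "read_dvh_table",
    "write_predictions",
    "read_predictions",
    "config_hash",
    "write_manifest",
]

DVH_TABLE_COLUMNS = ["patient_id", "oar", "source", "v_percent", "dose_gy"]
BEAM_SOURCES = tuple(f"beam{i}" for i in range(1, 10))


def _case_rows(case: PatientCase) -> list[tuple]:
    rows = []
    for oar_name in sorted(case.oars):
        beams, plan = case.oars[oar_name]
        for b, dvh in zip(BEAM_SOURCES, beams.beams):
            for j, dose in enumerate(dvh.doses):
                rows.append((case.patient_id, oar_name, b, j + 1, dose))
        for j, dose in enumerate(plan.doses):
            rows.append((case.patient_id, oar_name, "plan", j + 1, dose))
    return rows


def write_dvh_table(cases: Sequence[PatientCase], path: str | Path) -> None:
    """Write beam + plan DVHs of all cases, sorted by (patient, oar, source, v)."""
    rows: list[tuple] = []
    for case in sorted(cases, key=lambda c: c.patient_id):
        rows.extend(_case_rows(case))
    df = pd.DataFrame(rows, columns=DVH_TABLE_COLUMNS)
    df.to_csv(path, index=False)


def _group_to_dvh(g: pd.DataFrame, label: str) -> DoseVolumeHistogram:
    v = g["v_percent"].to_numpy()
    if len(v) != N_BINS or set(v) != set(range(1, N_BINS + 1)):
        missing = sorted(set(range(1, N_BINS + 1)) - set(v))
        dupes = sorted({int(x) for x in v[pd.Series(v).duplicated().to_numpy()]})
        detail = []
        if missing:
            detail.append(f"missing bins {missing[:5]}{'...' if len(missing) > 5 else ''}")
        if dupes:
            detail.append(f"duplicate bins {dupes[:5]}")
        raise ValueError(f"{label}: {'; '.join(detail) or f'{len(v)} rows'}")
    doses = g.sort_values("v_percent")["dose_gy"].to_numpy(dtype=float)
    try:
        return DoseVolumeHistogram(doses)
    except ValueError as e:
        raise ValueError(f"{label}: {e}") from None


def read_dvh_table(path: str | Path) -> list[PatientCase]:
    """Read and validate a DVH table into patient cases.

    Rejects missing/duplicate bins, non-monotone dose curves and incomplete
    beam sets, naming the (patient, oar, source) group concerned.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != DVH_TABLE_COLUMNS:
        raise ValueError(
            f"expected header {','.join(DVH_TABLE_COLUMNS)}, got {','.join(df.columns)}"
        )
    if df["dose_gy"].isna().any():
        bad = df.index[df["dose_gy"].isna()][0]
        raise ValueError(f"unparseable dose at data row {bad}")
    cases = []
    for pid, pgroup in df.groupby("patient_id", sort=True):
        oars: dict[str, tuple[BeamDVHSet, DoseVolumeHistogram]] = {}
        for oar_name, og in pgroup.groupby("oar", sort=True):
            sources = dict(tuple(og.groupby("source")))
            missing = [s for s in (*BEAM_SOURCES, "plan") if s not in sources]
            if missing:
                raise ValueError(f"{pid}/{oar_name}: missing sources {missing}")
            beams = tuple(
                _group_to_dvh(sources[b], f"{pid}/{oar_name}/{b}") for b in BEAM_SOURCES
            )
            plan = _group_to_dvh(sources["plan"], f"{pid}/{oar_name}/plan")
            oars[oar_name] = (BeamDVHSet(beams), plan)
        cases.append(PatientCase(patient_id=str(pid), oars=oars))
    return cases


def write_predictions(
    predictions: Mapping[str, Mapping[str, DoseVolumeHistogram]],
    path: str | Path,
) -> None:
    """Write predicted DVHs (patient -> oar -> DVH) as ``prediction`` rows."""
    rows = []
    for pid in sorted(predictions):
        for oar_name in sorted(predictions[pid]):
            for j, dose in enumerate(predictions[pid][oar_name].doses):
                rows.append((pid, oar_name, "prediction", j + 1, dose))
    pd.DataFrame(rows, columns=DVH_TABLE_COLUMNS).to_csv(path, index=False)


def read_predictions(path: str | Path) -> dict[str, dict[str, DoseVolumeHistogram]]:
    """Read a prediction table back into patient -> oar -> DVH."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != DVH_TABLE_COLUMNS:
        raise ValueError(
            f"expected header {','.join(DVH_TABLE_COLUMNS)}, got {','.join(df.columns)}"
        )
    out: dict[str, dict[str, DoseVolumeHistogram]] = {}
    for (pid, oar_name), g in df.groupby(["patient_id", "oar"], sort=True):
        out.setdefault(str(pid), {})[str(oar_name)] = _group_to_dvh(
            g, f"{pid}/{oar_name}/prediction"
        )
    return out


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serializable configuration."""
    text = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, seed: int, config: dict) -> None:
    """Record the seed and config hash every artifact needs for regeneration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
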