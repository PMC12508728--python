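"""Long-format CSV round-trips for cohorts, fits and covariates.

All tables are plain CSV; files written by the pipeline carry ``#``-prefixed
header comment lines (version, seed, config hash) and are read back with
``comment='#'``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, GeneratorConfig, ParticipantProfile
from .fitting import Marker, MarkerSeries

SERIES_COLUMNS = ["participant_id", "session_volume_L", "marker", "time_s", "value", "unit"]
COVARIATE_COLUMNS = [
    "participant_id", "age", "bmi",
    "baseline_liver_volume_mL", "baseline_spleen_volume_mL", "ivc_ao_ratio",
]


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Flatten a cohort to the long series table."""
    rec = []
    for (pid, vol), series in sorted(cohort.sessions.items()):
        for marker in Marker:
            if marker not in series:
                continue
            s = series[marker]
            for t, v in zip(s.times, s.values):
                rec.append((pid, vol, marker.value, t, v, s.unit))
    return pd.DataFrame(rec, columns=SERIES_COLUMNS)


def covariates_to_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (p.id, p.age, p.bmi, p.baseline_liver_volume,
             p.baseline_spleen_volume, p.ivc_ao_ratio)
            for p in cohort.participants
        ],
        columns=COVARIATE_COLUMNS,
    )


def frame_to_series(df: pd.DataFrame) -> dict:
    """Group a long series table back into per-session MarkerSeries maps."""
    out: dict = {}
    for (pid, vol, marker), g in df.groupby(
        ["participant_id", "session_volume_L", "marker"], sort=True
    ):
        g = g.sort_values("time_s")
        s = MarkerSeries(
            times=g["time_s"].to_numpy(dtype=float),
            values=g["value"].to_numpy(dtype=float),
            marker=Marker(marker),
            unit=str(g["unit"].iloc[0]) if "unit" in g else "",
        )
        out.setdefault((pid, float(vol)), {})[Marker(marker)] = s
    return out


def frame_to_cohort(df: pd.DataFrame, covariates: pd.DataFrame | None = None) -> Cohort:
    """Rebuild a Cohort container from long-format tables.

    Without a covariate table, placeholder mid-range covariates are attached
    (sufficient for the descriptive and fitting stages, not for the LMM).
    """
    sessions = frame_to_series(df)
    pids = sorted({pid for pid, _ in sessions})
    participants = []
    if covariates is not None:
        cov = covariates.set_index("participant_id")
        for pid in pids:
            r = cov.loc[pid]
            participants.append(
                ParticipantProfile(
                    id=pid, age=float(r["age"]), bmi=float(r["bmi"]),
                    baseline_liver_volume=float(r["baseline_liver_volume_mL"]),
                    baseline_spleen_volume=float(r["baseline_spleen_volume_mL"]),
                    ivc_ao_ratio=float(r["ivc_ao_ratio"]),
                )
            )
    else:
        for pid in pids:
            participants.append(
                ParticipantProfile(
                    id=pid, age=40.0, bmi=24.0, baseline_liver_volume=1600.0,
                    baseline_spleen_volume=200.0, ivc_ao_ratio=1.1,
                )
            )
    return Cohort(participants=participants, sessions=sessions, config=GeneratorConfig())


def config_hash(obj) -> str:
    """Short stable hash of a configuration object."""
    s = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(s.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path, seed=None, cfg_hash: str = "") -> None:
    """Write a CSV with the pipeline's provenance header comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# hydromark v{__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if cfg_hash:
            fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
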