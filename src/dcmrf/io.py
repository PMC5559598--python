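"""File formats: calibration CSV, phantom spec CSV+JSON, schedule/grid JSON,
NIfTI maps and series (via nibabel), relaxometry study CSV."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from ._exceptions import InputDomainError
from .types import AgentRelaxivity, BaselineRelaxation, CalibrationFit, ConcentrationPair

__all__ = [
    "read_calibration_series", "write_calibration_series",
    "write_calibration_report",
    "read_phantom_spec", "write_phantom_spec",
    "save_schedule", "load_schedule", "save_grid", "load_grid",
    "save_map", "load_map", "save_series", "load_series",
]


# -- calibration tables -----------------------------------------------------

def write_calibration_series(path, concentrations, r1, r2) -> None:
    """CSV with columns ``concentration_mM, R1_per_ms, R2_per_ms``."""
    pd.DataFrame({"concentration_mM": concentrations,
                  "R1_per_ms": r1, "R2_per_ms": r2}).to_csv(path, index=False)


def read_calibration_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"concentration_mM", "R1_per_ms", "R2_per_ms"}
    missing = required - set(df.columns)
    if missing:
        raise InputDomainError(f"calibration CSV missing columns {sorted(missing)}")
    return df


def write_calibration_report(path, fits) -> None:
    """Fit report CSV: ``agent, rate, slope, intercept, r_squared, p, n``.

    ``fits`` is an iterable of (agent_name, rate_label, CalibrationFit).
    """
    rows = [{"agent": agent, "rate": rate, "slope": fit.slope,
             "intercept": fit.intercept, "r_squared": fit.r_squared,
             "p": fit.p_two_tailed, "n": fit.n}
            for agent, rate, fit in fits]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- phantom spec -----------------------------------------------------------

def write_phantom_spec(csv_path, spec) -> None:
    """Vial table CSV + JSON sidecar (shape, baseline, agents).

    CSV columns: ``vial_id, gd_mM, mn_mM, cx_px, cy_px, radius_px`` with
    (cx, cy) = (col, row).  The sidecar shares the CSV stem with ``.json``.
    """
    csv_path = Path(csv_path)
    pd.DataFrame([{
        "vial_id": v.vial_id, "gd_mM": v.conc.agent_a, "mn_mM": v.conc.agent_b,
        "cx_px": v.center[1], "cy_px": v.center[0], "radius_px": v.radius,
    } for v in spec.vials]).to_csv(csv_path, index=False)
    header = {
        "image_shape": list(spec.image_shape),
        "baseline": {"T1_0": spec.baseline.T1_0, "T2_0": spec.baseline.T2_0},
        "agents": [{"name": a.name, "r1": a.r1, "r2": a.r2} for a in spec.agents],
    }
    csv_path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def read_phantom_spec(csv_path):
    from .phantom import PhantomSpec, Vial  # deferred: io <-> phantom
    csv_path = Path(csv_path)
    table = pd.read_csv(csv_path)
    header = json.loads(csv_path.with_suffix(".json").read_text())
    vials = tuple(
        Vial(vial_id=int(r.vial_id), center=(int(r.cy_px), int(r.cx_px)),
             radius=float(r.radius_px),
             conc=ConcentrationPair(float(r.gd_mM), float(r.mn_mM)))
        for r in table.itertuples())
    agents = tuple(AgentRelaxivity(a["name"], a["r1"], a["r2"])
                   for a in header["agents"])
    baseline = BaselineRelaxation(**header["baseline"])
    return PhantomSpec(image_shape=tuple(header["image_shape"]),
                       vials=vials, baseline=baseline, agents=agents)


# -- schedule / grid JSON ---------------------------------------------------

def save_schedule(path, sched) -> None:
    Path(path).write_text(json.dumps(sched.to_dict()))


def load_schedule(path):
    from .mrf import MRFSchedule
    return MRFSchedule.from_dict(json.loads(Path(path).read_text()))


def save_grid(path, grid) -> None:
    Path(path).write_text(json.dumps(grid.to_dict()))


def load_grid(path):
    from .mrf import DictionaryGrid
    return DictionaryGrid.from_dict(json.loads(Path(path).read_text()))


# -- NIfTI ------------------------------------------------------------------

def save_map(path, arr) -> None:
    """2-D/3-D map to NIfTI (identity affine, float32)."""
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4)), str(path))


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_series(path, series, magnitude_only: bool = False) -> None:
    """(rows, cols, N) signal series to 4-D NIfTI (x, y, 1, time).

    Complex data is stored as complex64 unless ``magnitude_only`` is set.
    """
    series = np.asarray(series)
    if series.ndim != 3:
        raise InputDomainError("series must be (rows, cols, timepoints)")
    data = np.abs(series).astype(np.float32) if magnitude_only \
        else series.astype(np.complex64)
    nib.save(nib.Nifti1Image(data[:, :, None, :], np.eye(4)), str(path))


def load_series(path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim != 4 or data.shape[2] != 1:
        raise InputDomainError("expected a 4-D (x, y, 1, t) series")
    return data[:, :, 0, :]
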