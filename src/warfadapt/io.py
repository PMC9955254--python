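"""File formats and run configuration.

Patient records travel as CSV with header ``day,dose_mg,inr`` (days 1-based
in files, converted to the internal 0-based grid on read and back on write).
Identified models are exported as JSON text with numerator/denominator
coefficients in descending powers of z plus provenance metadata.  Run
configurations round-trip through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adaptive import AdaptiveConfig
from .cohort import CohortConfig
from .model_core import (
    DoseResponseSeries,
    PrioriSet,
    StateSpaceModel,
    TransferFunctionModel,
)

__all__ = ["RunConfig", "read_patient_csv", "write_patient_csv",
           "export_model", "import_model", "write_event_log",
           "load_config", "save_config"]

_HEADER = ["day", "dose_mg", "inr"]


def read_patient_csv(path, patient_id: str | None = None,
                     inr_baseline: float = 1.0) -> DoseResponseSeries:
    """Read a patient record; validates the grid and forward-fills dose.

    Duplicate or non-monotone days are rejected.  Missing days are filled
    onto the unit grid: dose is forward-filled (the prescription continues
    between visits) and the last measured INR is carried forward.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if list(df.columns) != _HEADER:
        raise ValueError(f"{path}: expected header {','.join(_HEADER)}, "
                         f"got {','.join(df.columns)}")
    for i, row in df.iterrows():
        if not np.isfinite(row["day"]) or row["day"] != int(row["day"]):
            raise ValueError(f"{path}: malformed day on line {i + 2}")
        if not np.isfinite(row["dose_mg"]) or not np.isfinite(row["inr"]):
            raise ValueError(f"{path}: malformed row on line {i + 2}")
    days = df["day"].astype(int).to_numpy()
    if len(days) == 0:
        raise ValueError(f"{path}: empty record")
    dup = pd.Series(days).duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicate day {days[dup.argmax()]}")
    if np.any(np.diff(days) < 0):
        raise ValueError(f"{path}: days must increase")
    grid = np.arange(days[0], days[-1] + 1)
    df = df.set_index("day").reindex(grid)
    df["dose_mg"] = df["dose_mg"].ffill()
    df["inr"] = df["inr"].ffill()
    return DoseResponseSeries(
        patient_id=patient_id or path.stem,
        day=grid - 1,  # files are 1-based, internal grid 0-based
        dose=df["dose_mg"].to_numpy(float),
        inr=df["inr"].to_numpy(float),
        inr_baseline=inr_baseline,
    )


def write_patient_csv(series: DoseResponseSeries, path) -> None:
    df = pd.DataFrame({
        "day": series.day + 1,
        "dose_mg": series.dose,
        "inr": series.inr,
    })
    df.to_csv(path, index=False)


def export_model(model, path, *, patient_id: str = "",
                 window: tuple[int, int] | None = None,
                 priors: PrioriSet | None = None) -> None:
    """Write a model as structured text (JSON) with provenance metadata."""
    if isinstance(model, StateSpaceModel):
        tf = model.to_tf()
        order = model.order
    else:
        tf = model
        order = tf.order
    payload = {
        "num": list(map(float, tf.num)),
        "den": list(map(float, tf.den)),
        "order": int(order),
        "patient_id": patient_id,
        "window": list(window) if window is not None else None,
        "priors": asdict(priors) if priors is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def import_model(path) -> TransferFunctionModel:
    payload = json.loads(Path(path).read_text())
    return TransferFunctionModel(num=np.asarray(payload["num"]),
                                 den=np.asarray(payload["den"]))


def write_event_log(events: list, path) -> None:
    """Append-only CSV audit log of the adaptive loop (one row per event)."""
    df = pd.DataFrame(events,
                      columns=["day", "event", "O", "r", "delta_hat",
                               "prediction"])
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Everything needed to reproduce a run: priors, loop settings, cohort
    settings, seeds and the output directory."""

    priors: PrioriSet = field(
        default_factory=lambda: PrioriSet(K=10.0, r=0.95, epsilon=0.1,
                                          gamma=0.5, K_u=1.0))
    N_t: int = 7
    O_default: int = 3
    O_max: int = 5
    r_grid: tuple = (0.90, 0.95, 0.99)
    M_t_rule: str = "order"
    baseline_na: int = 6
    baseline_nb: int = 6
    baseline_nc: int = 0
    baseline_q: float = 1e-4
    baseline_r_v: float = 0.01
    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_n: int = 44
    days: int = 60
    seed: int = 0
    out_dir: str = "runs"

    def adaptive_config(self) -> AdaptiveConfig:
        return AdaptiveConfig(priors=self.priors, N_t=self.N_t,
                              O_default=self.O_default, O_max=self.O_max,
                              r_grid=tuple(self.r_grid),
                              M_t_rule=self.M_t_rule)


def save_config(cfg: RunConfig, path) -> None:
    data = asdict(cfg)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "priors" in data and isinstance(data["priors"], dict):
        data["priors"] = PrioriSet(**data["priors"])
    if "cohort" in data and isinstance(data["cohort"], dict):
        c = data["cohort"]
        for k, v in list(c.items()):
            if isinstance(v, list):
                c[k] = tuple(v)
        data["cohort"] = CohortConfig(**c)
    if "r_grid" in data:
        data["r_grid"] = tuple(data["r_grid"])
    return RunConfig(**data)
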