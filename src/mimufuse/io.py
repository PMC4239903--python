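"""Plain-text (CSV/YAML) readers and writers for traces and orientations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .quat import OrientationSeries
from .synth import MimuTrace, SensorModel

TRACE_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"]


def write_trace_csv(path, trace: MimuTrace) -> None:
    df = pd.DataFrame(np.hstack([trace.t[:, None], trace.gyro, trace.accel,
                                 trace.mag]), columns=TRACE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate: {trace.sample_rate}\n")
        df.to_csv(fh, index=False)


def read_trace_csv(path) -> MimuTrace:
    sample_rate = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# sample_rate:"):
            sample_rate = float(first.split(":", 1)[1])
    df = pd.read_csv(path, comment="#")
    t = df["t"].to_numpy()
    if sample_rate is None:
        sample_rate = 1.0 / float(np.median(np.diff(t)))
    return MimuTrace(df[["gx", "gy", "gz"]].to_numpy(),
                     df[["ax", "ay", "az"]].to_numpy(),
                     df[["mx", "my", "mz"]].to_numpy(), sample_rate,
                     meta={"source": str(path)})


def write_orientation_csv(path, series: OrientationSeries) -> None:
    df = pd.DataFrame(np.hstack([series.t[:, None], series.q]),
                      columns=["t", "qx", "qy", "qz", "qw"])
    with open(path, "w") as fh:
        fh.write(f"# frame: {series.frame}\n")
        for k, v in series.meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def read_orientation_csv(path) -> OrientationSeries:
    frame = "ulf-in-ggf"
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# frame:"):
                frame = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    q = df[["qx", "qy", "qz", "qw"]].to_numpy()
    q = q / np.linalg.norm(q, axis=1, keepdims=True)
    return OrientationSeries(df["t"].to_numpy(), q, frame=frame,
                             meta={"source": str(path)})


def load_sensor_model(path) -> SensorModel:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for key in ("gyro_bias", "mag_hard_iron", "mag_sensitivity", "reference_field"):
        if key in data:
            data[key] = tuple(data[key])
    return SensorModel(**data)


def dump_sensor_model(path, model: SensorModel) -> None:
    data = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
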