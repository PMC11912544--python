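"""File formats: protocol YAML, trace CSV, parameter/posterior JSON.

Protocol files store pressures in mmHg (the unit the experimental literature
reports); everything is converted to Pa on load.  Trace files are plain CSV
with header ``time_s,diameter_um``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml

from .distributions import Distribution, distribution_from_dict
from .model import (MMHG_PA, DiameterTrace, ExperimentProtocol, StepEvent,
                    VesselParameters)

__all__ = [
    "load_protocol",
    "save_protocol",
    "load_trace",
    "save_trace",
    "load_parameters",
    "save_parameters",
    "save_posterior",
    "load_posterior",
]


def load_protocol(path: str | Path) -> ExperimentProtocol:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    events = tuple(
        StepEvent(time=float(e["t_s"]), target=e["target"],
                  value=float(e["value_mmHg"]) * MMHG_PA)
        for e in d.get("events", []))
    in_situ = d.get("in_situ_dP_mmHg")
    return ExperimentProtocol(
        PI_base=float(d["PI_base_mmHg"]) * MMHG_PA,
        dP_base=float(d["dP_base_mmHg"]) * MMHG_PA,
        events=events,
        duration=float(d.get("duration_s", 300.0)),
        smoothing_width=float(d.get("smoothing_width_s", 2.0)),
        in_situ_dP=None if in_situ is None else float(in_situ) * MMHG_PA,
    )


def save_protocol(protocol: ExperimentProtocol, path: str | Path) -> None:
    d = {
        "PI_base_mmHg": protocol.PI_base / MMHG_PA,
        "dP_base_mmHg": protocol.dP_base / MMHG_PA,
        "duration_s": protocol.duration,
        "smoothing_width_s": protocol.smoothing_width,
        "events": [{"t_s": e.time, "target": e.target,
                    "value_mmHg": e.value / MMHG_PA} for e in protocol.events],
    }
    if protocol.in_situ_dP is not None:
        d["in_situ_dP_mmHg"] = protocol.in_situ_dP / MMHG_PA
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def load_trace(path: str | Path) -> DiameterTrace:
    df = pd.read_csv(path)
    return DiameterTrace(times=df["time_s"].to_numpy(),
                         D=df["diameter_um"].to_numpy())


def save_trace(trace: DiameterTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.times, "diameter_um": trace.D}).to_csv(
        path, index=False)


def load_parameters(path: str | Path) -> VesselParameters:
    with open(path) as fh:
        return VesselParameters(**json.load(fh))


def save_parameters(params: VesselParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(params), fh, indent=2, sort_keys=True)


def save_posterior(fits: dict[str, Distribution], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: v.to_dict() for k, v in fits.items()}, fh,
                  indent=2, sort_keys=True)


def load_posterior(path: str | Path) -> dict[str, Distribution]:
    with open(path) as fh:
        return {k: distribution_from_dict(v) for k, v in json.load(fh).items()}
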