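"""Result serialization: CSV tables, trace files, run manifests.

Output tables mirror the layouts of the study's summary tables (basal
electrophysiology per cell; minimal invading AIS parameters; directional
spatial constants), with stable column order so identical configurations
produce identical files.  A JSON manifest records the configuration hash
and package version per run.  The static literature survey of published
AIS/soma fast-Na+ densities ships as packaged reference data (it is data,
never computed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .electrotonus import ElectrotonicReport
from .experiments import CellReport, SweepResult
from .morphology import MorphometricSummary
from .solver import SimulationTrace

__all__ = ["write_report", "load_sweep_result", "load_literature_gna",
           "config_hash"]


def load_sweep_result(matrix_csv, minimal_csv):
    """Rebuild a :class:`SweepResult` from its written CSV pair."""
    from .experiments import InvasionOutcome

    df = pd.read_csv(matrix_csv)
    diameters = np.array(sorted(df["AIS diameter (um)"].unique()))
    g_values = np.array(sorted(df["g_Na (S/cm2)"].unique()))
    outcomes = [[None] * len(g_values) for _ in diameters]
    for _, row in df.iterrows():
        i = int(np.argmin(np.abs(diameters - row["AIS diameter (um)"])))
        j = int(np.argmin(np.abs(g_values - row["g_Na (S/cm2)"])))
        outcomes[i][j] = InvasionOutcome(row["outcome"])
    mdf = pd.read_csv(minimal_csv)
    minimal = None
    if len(mdf) and not mdf.iloc[0].isna().any():
        minimal = (float(mdf.iloc[0, 0]), float(mdf.iloc[0, 1]))
    return SweepResult(diameters=diameters, g_values=g_values,
                       outcomes=outcomes, minimal_pair=minimal)


def load_literature_gna() -> pd.DataFrame:
    """Published AIS and soma fast-Na+ densities from prior motoneuron models."""
    src = resources.files("axosoma").joinpath("data/literature_gna.csv")
    with resources.as_file(src) as p:
        return pd.read_csv(p)


def config_hash(obj) -> str:
    """Stable short hash of a (nested dataclass) configuration object."""

    def norm(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: norm(getattr(o, f.name))
                    for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {str(k): norm(v) for k, v in sorted(o.items())}
        if isinstance(o, (list, tuple)):
            return [norm(x) for x in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    blob = json.dumps(norm(obj), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _frame_of(objects, names=None) -> pd.DataFrame:
    first = objects[0]
    if isinstance(first, CellReport):
        cols = CellReport.CSV_COLUMNS
        rows = [o.as_row() for o in objects]
    elif isinstance(first, MorphometricSummary):
        cols = MorphometricSummary.CSV_COLUMNS
        rows = [o.as_row() for o in objects]
    elif isinstance(first, ElectrotonicReport):
        cols = ("Source", "Destination", "ln Attenuation", "Distance (um)",
                "Lambda (um)")
        rows = [[o.source, o.destination, o.X, o.distance,
                 o.effective_lambda] for o in objects]
    else:
        raise TypeError(f"no CSV layout for {type(first).__name__}")
    idx = names if names is not None else range(len(rows))
    return pd.DataFrame(rows, columns=list(cols), index=idx)


def write_report(objects, outdir, name: str = "report",
                 config=None) -> list[Path]:
    """Write result objects to ``outdir`` as CSV plus a JSON manifest.

    Accepts a list of :class:`CellReport`, :class:`MorphometricSummary` or
    :class:`ElectrotonicReport` (one table), a :class:`SweepResult`
    (outcome matrix + minimal pair), or a :class:`SimulationTrace` (time +
    site columns).  Returns the written paths.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(objects, SweepResult):
        rows = []
        for i, d in enumerate(objects.diameters):
            for j, g in enumerate(objects.g_values):
                rows.append([d, g, objects.outcomes[i][j].value])
        df = pd.DataFrame(rows, columns=["AIS diameter (um)",
                                         "g_Na (S/cm2)", "outcome"])
        p = out / f"{name}_matrix.csv"
        df.to_csv(p, index=False)
        written.append(p)
        mp = objects.minimal_pair
        df2 = pd.DataFrame(
            [[mp[0], mp[1]] if mp else [np.nan, np.nan]],
            columns=["AIS diameter (um)",
                     "Fast Na+ conductance at AIS (S/cm2)"])
        p2 = out / f"{name}_minimal.csv"
        df2.to_csv(p2, index=False)
        written.append(p2)
    elif isinstance(objects, SimulationTrace):
        df = pd.DataFrame({"t_ms": objects.t,
                           **{f"V_{k}_mV": v for k, v in objects.V.items()}})
        p = out / f"{name}_trace.csv"
        df.to_csv(p, index=False)
        written.append(p)
    else:
        objs = list(objects)
        if not objs:
            p = out / f"{name}.csv"
            pd.DataFrame().to_csv(p, index=False)
            written.append(p)
        else:
            df = _frame_of(objs)
            p = out / f"{name}.csv"
            df.to_csv(p, index=True)
            written.append(p)

    manifest = {
        "name": name,
        "config_hash": config_hash(config) if config is not None else None,
        "package": "axosoma 0.1.0",
        "written": [str(p.name) for p in written],
        "wall_time": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    mp = out / f"{name}_manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2)
    written.append(mp)
    return written
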