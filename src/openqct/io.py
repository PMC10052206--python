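"""Reading and writing the package's on-disk formats.

One CSV dialect for beat tables (header ``t,hr,sbp,dbp,mbp,lvet,pep,z0,
dzmax,trc``; empty cell = gap; UTF-8; decimal point), a YAML/JSON sidecar
for subject metadata, CSV for trends, JSON for events, complexity maps and
generator truth.  Every writer stamps a provenance block (package version,
config hash, seed) where the format allows it.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .complexity import map_to_dict
from .exceptions import ConfigurationError, InvalidInputError
from .hemodynamics import PRIMITIVE_COLUMNS, SubjectAnthropometry
from .synthetic import GeneratorTruth
from .trend import EventAnnotation, TrendPoint


def read_beats(path) -> pd.DataFrame:
    """Read a beat table CSV; empty cells become NaN gaps."""
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InvalidInputError(f"malformed beat CSV {path}: {exc}") from exc
    missing = [c for c in PRIMITIVE_COLUMNS if c not in frame.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")
    bad = frame["t"].isna()
    if bad.any():
        raise InvalidInputError(
            f"{path}: missing timestamp at row {int(np.flatnonzero(bad)[0]) + 2}")
    return frame


def write_beats(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6f")


def read_subject(path) -> tuple[SubjectAnthropometry, float]:
    """Read a subject sidecar (YAML or JSON): weight, height, sex[, cvp_assumed]."""
    text = Path(path).read_text()
    meta = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(meta, dict):
        raise ConfigurationError(f"{path}: subject sidecar must be a mapping")
    try:
        anthro = SubjectAnthropometry(weight=float(meta["weight"]),
                                      height=float(meta["height"]),
                                      sex=meta.get("sex", "male"))
    except KeyError as exc:
        raise ConfigurationError(f"{path}: subject sidecar lacks {exc}") from exc
    return anthro, float(meta.get("cvp_assumed", 6.0))


def write_subject(anthro: SubjectAnthropometry, path, cvp_assumed: float = 6.0) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"weight": anthro.weight, "height": anthro.height,
                        "sex": anthro.sex, "cvp_assumed": cvp_assumed}, fh)


def _provenance(config_hash: str | None, seed: int | None) -> dict:
    return {"package": "openqct", "version": __version__,
            "config_hash": config_hash, "seed": seed}


def trend_frame(trend: list[TrendPoint], variable_names) -> pd.DataFrame:
    """Tabular trend: times, complexity triple, beats used, profile columns."""
    rows = []
    for p in trend:
        row = {"window_end_time": p.window_end_time,
               "window_index": p.window_index,
               "C": p.state.C, "C_min": p.state.C_min,
               "C_critical": p.state.C_critical,
               "n_beats_used": p.n_beats_used}
        for name, pct in zip(variable_names, p.state.profile):
            row[f"profile_{name}"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def write_trend(trend: list[TrendPoint], variable_names, path,
                config_hash: str | None = None, seed: int | None = None) -> None:
    frame = trend_frame(trend, variable_names)
    with open(path, "w") as fh:
        fh.write(f"# {json.dumps(_provenance(config_hash, seed))}\n")
        frame.to_csv(fh, index=False, float_format="%.6f")


def read_trend(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_events(events: list[EventAnnotation], path,
                 config_hash: str | None = None, seed: int | None = None) -> None:
    payload = {"provenance": _provenance(config_hash, seed),
               "events": [{"kind": e.kind, "time": e.time, "detail": e.detail}
                          for e in events]}
    Path(path).write_text(json.dumps(payload, indent=2))


def write_map(graph: nx.Graph, path, config_hash: str | None = None,
              seed: int | None = None) -> None:
    payload = {"provenance": _provenance(config_hash, seed), **map_to_dict(graph)}
    Path(path).write_text(json.dumps(payload, indent=2))


def write_map_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    for _, _, d in g.edges(data=True):  # GraphML cannot hold None
        if d.get("mi") is None:
            d.pop("mi", None)
    nx.write_graphml(g, path)


def write_truth(truth: GeneratorTruth, path) -> None:
    payload = {"events": truth.events,
               "latents": truth.latents.to_dict(orient="list")}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path) -> GeneratorTruth:
    payload = json.loads(Path(path).read_text())
    return GeneratorTruth(events=payload["events"],
                          latents=pd.DataFrame(payload["latents"]))
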