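"""Serialization of simulation and analysis artifacts.

All artifacts are plain text: CSV for time series and summaries, JSON for
reports and manifests, DOT for transition graphs, whitespace-separated
integer grids for lattice snapshots.  Numeric output uses six significant
digits with stable column order and line endings.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, List

import networkx as nx
import numpy as np
import pandas as pd

from .census import CensusResult
from .lattice import FrequencySeries, Lattice
from .niches import TransitionRecord

__all__ = [
    "write_series",
    "read_series",
    "write_census",
    "write_transitions",
    "read_transitions",
    "write_dot",
    "write_lattice",
    "read_lattice",
]

_FREQ_COLUMNS = [f"f_T{t}" for t in range(1, 16)]


def write_series(series: FrequencySeries, path) -> None:
    """Frequency series as CSV with columns step, f_T1..f_T15."""
    df = pd.DataFrame(series.freqs, columns=_FREQ_COLUMNS)
    df.insert(0, "step", series.steps)
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def read_series(path) -> FrequencySeries:
    df = pd.read_csv(path)
    freqs = df[_FREQ_COLUMNS].to_numpy(dtype=float)
    # renormalise away the 6-digit rounding so samples sit on the simplex
    freqs = freqs / freqs.sum(axis=1, keepdims=True)
    return FrequencySeries(df["step"].to_numpy(np.int64), freqs)


def write_census(result: CensusResult, json_path, summary_csv_path=None) -> None:
    """Census report as JSON (one record per network) plus a CSV summary."""
    payload = {
        "summary": result.summary,
        "records": [
            {
                "subset": sorted(r.subset),
                "classification": r.classification,
                "leakage": sorted(map(list, r.leakage)),
                "extinct_members": sorted(r.extinct_members),
                "fixed_point": None
                if r.fixed_point is None
                else [round(float(x), 6) for x in r.fixed_point],
            }
            for r in result.records
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
    if summary_csv_path is not None:
        pd.DataFrame([result.summary]).to_csv(
            summary_csv_path, index=False, lineterminator="\n"
        )


def write_transitions(records: Iterable[TransitionRecord], path) -> None:
    """Transition records as JSON lines (one experiment per line)."""
    lines = []
    for r in records:
        d = {
            f.name: getattr(r, f.name)
            for f in dataclasses.fields(r)
            if f.name != "phases"
        }
        lines.append(json.dumps(d, default=float))
    Path(path).write_text("\n".join(lines) + "\n")


def read_transitions(path) -> List[dict]:
    return [json.loads(line) for line in Path(path).read_text().splitlines() if line]


def write_dot(graph: nx.DiGraph, path) -> None:
    """Minimal DOT writer for the niche transition diagram."""
    lines = ["digraph niches {"]
    for node, data in graph.nodes(data=True):
        thr = data.get("threshold_bits")
        label = node if thr is None or thr != thr else f"{node}\\n{thr:.2g} bits"
        lines.append(f'  "{node}" [label="{label}"];')
    for u, v, data in graph.edges(data=True):
        style = "both" if data.get("reversible") else "forward"
        lines.append(f'  "{u}" -> "{v}" [dir={style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_lattice(lattice: Lattice, path) -> None:
    """Plain-text integer grid snapshot."""
    np.savetxt(path, lattice.grid, fmt="%d")


def read_lattice(path) -> Lattice:
    return Lattice(np.loadtxt(path, dtype=np.int8))
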