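"""Readers and writers for the pipeline's on-disk formats.

Counts travel as Matrix Market plus TSV sidecars (genes.tsv: id, length bp;
cells.tsv: id); traces as one HDF5 file with groups ``/cell_<id>/<protocol>``
holding ``time`` / ``signal`` datasets and units + stimulus attributes;
ground truth as JSON.  All CSV output uses a fixed column order, UTF-8 and
6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from .datatypes import CountMatrix, GroundTruth, Trace, TraceSet

__all__ = [
    "read_counts",
    "write_counts",
    "read_traces",
    "write_traces",
    "read_truth",
    "write_truth",
    "write_csv",
    "config_hash",
]

CSV_FLOAT_FORMAT = "%.6g"


def write_counts(cm: CountMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", csc_matrix(cm.counts), field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids, "length_bp": cm.gene_lengths}).to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(out / "cells.tsv", sep="\t", index=False)


def read_counts(in_dir: str | Path) -> CountMatrix:
    src = Path(in_dir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (src / name).exists():
            raise FileNotFoundError(f"missing {name} in {src}")
    counts = np.asarray(mmread(src / "matrix.mtx").todense()).astype(np.int64)
    genes = pd.read_csv(src / "genes.tsv", sep="\t")
    cells = pd.read_csv(src / "cells.tsv", sep="\t")
    if counts.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix {counts.shape} does not match sidecars ({len(genes)}, {len(cells)})"
        )
    return CountMatrix(
        counts=counts,
        gene_ids=genes["gene_id"].to_numpy(),
        gene_lengths=genes["length_bp"].to_numpy(),
        cell_ids=cells["cell_id"].to_numpy(),
    )


def write_traces(tracesets: dict[str, TraceSet], path: str | Path, mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        for cid, ts in tracesets.items():
            grp = f.require_group(f"cell_{cid}")
            for key, tr in ts.traces.items():
                g = grp.create_group(key)
                g.create_dataset("time", data=tr.time)
                g.create_dataset("signal", data=tr.signal)
                g.attrs["units"] = tr.units
                g.attrs["sampling_rate"] = tr.sampling_rate
                g.attrs["protocol"] = tr.protocol
                for k, v in tr.params.items():
                    g.attrs[f"param_{k}"] = v


KNOWN_PROTOCOLS = {"rest", "current_step", "triangular", "vc_step", "psc"}


def read_traces(path: str | Path) -> dict[str, TraceSet]:
    out: dict[str, TraceSet] = {}
    with h5py.File(path, "r") as f:
        for name in f:
            cid = name.removeprefix("cell_")
            ts = TraceSet(cell_id=cid)
            for key in f[name]:
                g = f[name][key]
                if "units" not in g.attrs:
                    raise ValueError(f"trace {name}/{key} lacks a units attribute")
                if g.attrs["protocol"] not in KNOWN_PROTOCOLS:
                    warnings.warn(f"skipping unknown protocol {g.attrs['protocol']!r}")
                    continue
                params = {
                    k.removeprefix("param_"): g.attrs[k]
                    for k in g.attrs
                    if k.startswith("param_")
                }
                ts.traces[key] = Trace(
                    signal=g["signal"][:],
                    sampling_rate=float(g.attrs["sampling_rate"]),
                    protocol=str(g.attrs["protocol"]),
                    units=str(g.attrs["units"]),
                    params=params,
                )
            out[cid] = ts
    return out


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "cells": json.loads(truth.cells.to_json(orient="records")),
        "genes": json.loads(truth.genes.to_json(orient="records")),
        "psc_events": {
            cid: json.loads(df.to_json(orient="records"))
            for cid, df in truth.psc_events.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        cells=pd.DataFrame(payload["cells"]),
        genes=pd.DataFrame(payload["genes"]),
        psc_events={
            cid: pd.DataFrame(rows) for cid, rows in payload.get("psc_events", {}).items()
        },
    )


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=CSV_FLOAT_FORMAT, encoding="utf-8")


def config_hash(obj) -> str:
    """Stable hash of a (nested, JSON-serializable) parameter mapping."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in vars(o).items()}
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default).encode()
    return hashlib.sha256(blob).hexdigest()
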