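"""Serialization of intermediate pipeline artifacts.

Arrays go into ``.npz`` containers; axis bookkeeping goes into JSON
sidecars, so every artifact can be reloaded without re-running earlier
stages. Small summary tables are written as TSV by the pipeline itself.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .classify import FeatureSet, GcCollection
from .preprocess import BinSet
from .tensorize import Axis3Entry, WeightTensor

__all__ = [
    "save_binsets", "load_binsets",
    "save_gc", "load_gc",
    "save_weights", "load_weights",
    "save_tensor", "load_tensor",
]


def save_binsets(binsets: list[BinSet], path: str | Path) -> None:
    path = Path(path)
    arrays = {f"bins_{i}": bs.bins for i, bs in enumerate(binsets)}
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = [
        {
            "parent_bins": [[s, int(b)] for s, b in bs.parent_bins],
            "condition_sample_id": bs.condition_sample_id,
            "state": bs.state,
            "channels": bs.channels,
            "region_of": bs.region_of,
            "rate": bs.rate,
        }
        for bs in binsets
    ]
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_binsets(path: str | Path) -> list[BinSet]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        return [
            BinSet(
                bins=z[f"bins_{i}"],
                parent_bins=[(s, int(b)) for s, b in m["parent_bins"]],
                condition_sample_id=m["condition_sample_id"],
                state=m["state"],
                channels=m["channels"],
                region_of=m["region_of"],
                rate=m["rate"],
            )
            for i, m in enumerate(meta)
        ]


def save_gc(gc: GcCollection, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), gc=gc.gc, freqs=gc.freqs)
    meta = {
        "dirpairs": [list(p) for p in gc.dirpairs],
        "state": gc.state,
        "region_of": gc.region_of,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_gc(path: str | Path) -> GcCollection:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        return GcCollection(
            gc=z["gc"],
            dirpairs=[tuple(p) for p in meta["dirpairs"]],
            freqs=z["freqs"],
            state=meta["state"],
            region_of=meta["region_of"],
        )


def save_weights(
    weights: dict[tuple[str, str], tuple[np.ndarray, FeatureSet]], path: str | Path
) -> None:
    path = Path(path)
    arrays = {}
    meta = []
    for k, ((ra, rb), (W, fs)) in enumerate(weights.items()):
        arrays[f"w_{k}"] = W
        meta.append({
            "region_pair": [ra, rb],
            "columns": [[s, d, f] for s, d, f in fs.columns],
            "state": fs.state,
        })
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_weights(path: str | Path) -> dict[tuple[str, str], tuple[np.ndarray, FeatureSet]]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    out = {}
    with np.load(path.with_suffix(".npz")) as z:
        for k, m in enumerate(meta):
            ra, rb = m["region_pair"]
            fs = FeatureSet(
                features=[],
                columns=[(s, d, float(f)) for s, d, f in m["columns"]],
                state=m["state"],
                region_pair=(ra, rb),
            )
            out[(ra, rb)] = (z[f"w_{k}"], fs)
    return out


def save_tensor(tensor: WeightTensor, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=tensor.data, freqs=tensor.freqs)
    meta = {
        "axis3": [[e.dataset, e.src, e.dst, e.state] for e in tensor.axis3],
        "n_sample_pairs": tensor.n_sample_pairs,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_tensor(path: str | Path) -> WeightTensor:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as z:
        return WeightTensor(
            data=z["data"],
            axis3=[Axis3Entry(*e) for e in meta["axis3"]],
            freqs=z["freqs"],
            n_sample_pairs=meta["n_sample_pairs"],
        )
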