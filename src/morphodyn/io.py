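"""HDF5 persistence for feature tables, supervectors, and transition matrices."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import TransitionMatrix
from .features import FEATURE_BLOCKS

__all__ = [
    "save_features_h5",
    "load_features_h5",
    "save_supervectors_h5",
    "load_supervectors_h5",
    "save_transition_matrix_h5",
    "load_transition_matrix_h5",
]


def save_features_h5(path: str | Path, table: pd.DataFrame) -> None:
    """Write a per-cell feature table (raw f0..f90 + PCs + index columns).

    The feature-block layout is stored as a JSON attribute so readers can
    recover which columns are Zernike / Haralick / shape / environment.
    """
    fcols = [c for c in table.columns if c.startswith("f") and c[1:].isdigit()]
    pcols = [c for c in table.columns if c.startswith("PC")]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("raw", data=table[fcols].to_numpy(float))
        if pcols:
            fh.create_dataset("reduced", data=table[pcols].to_numpy(float))
        for col in ("frame", "cell_label"):
            fh.create_dataset(col, data=table[col].to_numpy(int))
        for col in ("treatment", "stack_id"):
            if col in table:
                fh.create_dataset(
                    col, data=np.array(table[col].astype(str), dtype=h5py.string_dtype())
                )
        fh.attrs["feature_blocks"] = json.dumps(
            {k: [v.start, v.stop] for k, v in FEATURE_BLOCKS.items()}
        )


def load_features_h5(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as fh:
        raw = fh["raw"][()]
        out = pd.DataFrame(raw, columns=[f"f{i}" for i in range(raw.shape[1])])
        if "reduced" in fh:
            red = fh["reduced"][()]
            for j in range(red.shape[1]):
                out[f"PC{j + 1}"] = red[:, j]
        for col in ("frame", "cell_label"):
            out[col] = fh[col][()]
        for col in ("treatment", "stack_id"):
            if col in fh:
                out[col] = [s.decode() for s in fh[col][()]]
    return out


def save_supervectors_h5(
    path: str | Path, supervectors: np.ndarray, index: pd.DataFrame | None = None,
    coordinates: np.ndarray | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("supervectors", data=np.asarray(supervectors, float))
        if coordinates is not None:
            fh.create_dataset("coordinates", data=np.asarray(coordinates, float))
        if index is not None:
            fh.attrs["index_json"] = index.to_json(orient="split")


def load_supervectors_h5(
    path: str | Path,
) -> tuple[np.ndarray, pd.DataFrame | None, np.ndarray | None]:
    with h5py.File(path, "r") as fh:
        X = fh["supervectors"][()]
        coords = fh["coordinates"][()] if "coordinates" in fh else None
        index = None
        if "index_json" in fh.attrs:
            import io as _io

            index = pd.read_json(_io.StringIO(fh.attrs["index_json"]), orient="split")
    return X, index, coords


def save_transition_matrix_h5(path: str | Path, tm: TransitionMatrix) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=tm.counts)
        fh.create_dataset("probabilities", data=tm.probabilities)
        fh.create_dataset("empty_rows", data=tm.empty_rows)
        if tm.centers is not None:
            fh.create_dataset("centers", data=tm.centers)


def load_transition_matrix_h5(path: str | Path) -> TransitionMatrix:
    with h5py.File(path, "r") as fh:
        return TransitionMatrix(
            counts=fh["counts"][()],
            probabilities=fh["probabilities"][()],
            centers=fh["centers"][()] if "centers" in fh else None,
            empty_rows=fh["empty_rows"][()],
        )
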