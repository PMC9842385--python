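"""Dataset container I/O.

The canonical on-disk form is a single HDF5 archive (pattern arrays and
validity masks per group and phase, subject ids, truth record) with the
scene table and the rater-level behavior table embedded as TSV text, plus
standalone TSV readers/writers for both tables and YAML/JSON round-trip
for :class:`~pisckit.synthetic.SyntheticSpec`.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synthetic import SyntheticSpec
from .types import Dataset, SceneTable

SCHEMA_VERSION = "1"

__all__ = [
    "save_dataset",
    "load_dataset",
    "read_scene_table",
    "write_scene_table",
    "read_behavior_table",
    "write_behavior_table",
    "load_spec",
    "dump_spec",
]


def _df_to_tsv_bytes(df: pd.DataFrame) -> bytes:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=False)
    return buf.getvalue().encode()


def _df_from_tsv_bytes(b: bytes) -> pd.DataFrame:
    return pd.read_csv(_io.BytesIO(b), sep="\t")


def save_dataset(dataset: Dataset, path: "str | Path") -> None:
    """Write a dataset archive; see module docstring for the layout."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        for (group, phase), arr in dataset.patterns.items():
            g = f.require_group(f"patterns/{group}/{phase}")
            g.create_dataset("patterns", data=arr)
            g.create_dataset(
                "valid", data=dataset.valid[(group, phase)].astype(np.uint8)
            )
        for group, ids in dataset.subject_ids.items():
            f.require_group("subjects").create_dataset(
                group, data=np.array(ids, dtype=h5py.string_dtype())
            )
        f.create_dataset(
            "scene_table",
            data=np.void(_df_to_tsv_bytes(dataset.scene_table.to_dataframe())),
        )
        if dataset.behavior is not None:
            f.create_dataset(
                "behavior", data=np.void(_df_to_tsv_bytes(dataset.behavior))
            )
        if dataset.truth is not None:
            t = f.require_group("truth")
            for key, val in dataset.truth.items():
                if isinstance(val, np.ndarray):
                    t.create_dataset(key, data=val)
                else:
                    t.attrs[key] = json.dumps(val)


def load_dataset(path: "str | Path") -> Dataset:
    """Load a dataset archive written by :func:`save_dataset`.

    Raises a clear error on schema mismatch or a truncated/corrupt file;
    never returns a partial object.
    """
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise ValueError(
                    f"dataset schema version {version!r} != {SCHEMA_VERSION!r}"
                )
            patterns, valid = {}, {}
            for group in f["patterns"]:
                for phase in f[f"patterns/{group}"]:
                    g = f[f"patterns/{group}/{phase}"]
                    patterns[(group, phase)] = g["patterns"][()]
                    valid[(group, phase)] = g["valid"][()].astype(bool)
            subject_ids = {
                g: [s.decode() for s in f["subjects"][g][()]]
                for g in f["subjects"]
            }
            scene_table = SceneTable.from_dataframe(
                _df_from_tsv_bytes(f["scene_table"][()].tobytes())
            )
            behavior = None
            if "behavior" in f:
                behavior = _df_from_tsv_bytes(f["behavior"][()].tobytes())
            truth = None
            if "truth" in f:
                truth = {k: f["truth"][k][()] for k in f["truth"]}
                truth.update(
                    {k: json.loads(v) for k, v in f["truth"].attrs.items()}
                )
    except OSError as exc:
        raise ValueError(f"cannot read dataset archive {path}: {exc}") from exc
    return Dataset(
        patterns=patterns,
        valid=valid,
        subject_ids=subject_ids,
        scene_table=scene_table,
        behavior=behavior,
        truth=truth,
    )


def write_scene_table(table: SceneTable, path: "str | Path") -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_scene_table(path: "str | Path") -> SceneTable:
    return SceneTable.from_dataframe(pd.read_csv(path, sep="\t"))


def write_behavior_table(table: pd.DataFrame, path: "str | Path") -> None:
    table.to_csv(path, sep="\t", index=False)


def read_behavior_table(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_spec(path: "str | Path") -> SyntheticSpec:
    """Read a SyntheticSpec from YAML (JSON is valid YAML)."""
    with open(path) as fh:
        return SyntheticSpec.from_dict(yaml.safe_load(fh))


def dump_spec(spec: SyntheticSpec, path: "str | Path") -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
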