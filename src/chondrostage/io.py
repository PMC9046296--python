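"""Reading and writing the package's on-disk formats.

Profiles travel as long-format CSV (sample_id, batch_id, stage,
indicator, round, value); feature matrices as wide CSV with a JSON
sidecar for normalization parameters; reference models as a CSV + JSON
bundle; images as multi-channel TIFF with channel names in metadata;
trajectory matrices as genes x cells CSV plus a one-column pseudotime
CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import INDICATORS, SampleProfile, StageLabel, TrajectoryMatrix
from .features import FeatureMatrix
from .staging import ReferenceModel

__all__ = [
    "write_profiles_csv",
    "read_profiles_csv",
    "write_matrix_csv",
    "read_matrix_csv",
    "save_model",
    "load_model",
    "write_image_tiff",
    "read_image_tiff",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

LONG_COLUMNS = ["sample_id", "batch_id", "stage", "indicator", "round", "value"]


def write_profiles_csv(profiles: list[SampleProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for ind in INDICATORS:
            for rnd, value in p.values[ind].items():
                rows.append(
                    (p.sample_id, p.batch_id, p.stage.value, ind, rnd, value)
                )
    pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[SampleProfile]:
    table = pd.read_csv(path)
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    profiles = []
    for sid, group in table.groupby("sample_id", sort=False):
        wide = group.pivot(index="round", columns="indicator", values="value")
        wide = wide.sort_index()
        profiles.append(
            SampleProfile(
                sample_id=str(sid),
                batch_id=str(group["batch_id"].iloc[0]),
                stage=StageLabel(group["stage"].iloc[0]),
                values=wide.reset_index(drop=True),
            )
        )
    return profiles


def write_matrix_csv(matrix: FeatureMatrix, path: str | Path) -> None:
    """Wide CSV with sample/indicator header rows plus a JSON sidecar."""
    path = Path(path)
    matrix.data.to_csv(path)
    sidecar = {
        "state": matrix.state,
        "norm_params": matrix.norm_params,
        "normalize_scope": matrix.normalize_scope,
        "sample_meta": matrix.sample_meta.reset_index().to_dict(orient="records"),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_matrix_csv(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    data = pd.read_csv(path, header=[0, 1], index_col=0)
    data.columns.names = ["sample_id", "indicator"]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    params = sidecar.get("norm_params")
    if params is not None:
        params = {k: (float(v[0]), float(v[1])) for k, v in params.items()}
    meta = pd.DataFrame(sidecar.get("sample_meta", []))
    if not meta.empty:
        meta = meta.set_index("sample_id")
    return FeatureMatrix(
        data=data,
        state=sidecar["state"],
        norm_params=params,
        sample_meta=meta,
        normalize_scope=sidecar.get("normalize_scope", "indicator"),
    )


def save_model(model: ReferenceModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_matrix_csv(model.matrix, directory / "reference_matrix.csv")
    meta = {"panel": list(model.panel), "metadata": model.metadata}
    (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_model(directory: str | Path) -> ReferenceModel:
    directory = Path(directory)
    matrix = read_matrix_csv(directory / "reference_matrix.csv")
    meta = json.loads((directory / "model.json").read_text())
    return ReferenceModel(
        matrix=matrix, panel=tuple(meta["panel"]), metadata=meta["metadata"]
    )


def write_image_tiff(
    channels: dict[str, np.ndarray],
    path: str | Path,
    pixel_size: float,
) -> None:
    names = list(channels)
    stack = np.stack([channels[n] for n in names])
    tifffile.imwrite(
        path,
        stack,
        metadata={"axes": "CYX", "channel_names": names,
                  "pixel_size_um": pixel_size},
    )


def read_image_tiff(
    path: str | Path,
    channel_map: dict[str, int] | str | Path | None = None,
) -> dict[str, np.ndarray]:
    """Read a multi-channel TIFF into a name -> array mapping.

    ``channel_map`` maps channel names to page indices and may be given
    inline or as a YAML file; if omitted, channel names stored in the
    TIFF metadata are used.
    """
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    if isinstance(channel_map, (str, Path)):
        channel_map = yaml.safe_load(Path(channel_map).read_text())
    if channel_map is None:
        names = meta.get("channel_names")
        if names is None:
            raise ValueError("no channel map given and none stored in the TIFF")
        channel_map = {n: i for i, n in enumerate(names)}
    return {name: stack[idx] for name, idx in channel_map.items()}


def write_trajectory_csv(
    matrix: TrajectoryMatrix,
    expr_path: str | Path,
    pseudotime_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    matrix.expression.to_csv(expr_path)
    matrix.pseudotime.rename("pseudotime").to_csv(pseudotime_path)
    if labels_path is not None and matrix.labels is not None:
        matrix.labels.map(lambda c: c.value).rename("pattern").to_csv(labels_path)


def read_trajectory_csv(
    expr_path: str | Path, pseudotime_path: str | Path
) -> TrajectoryMatrix:
    expr = pd.read_csv(expr_path, index_col=0)
    pt = pd.read_csv(pseudotime_path, index_col=0)["pseudotime"]
    return TrajectoryMatrix(expression=expr, pseudotime=pt)
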