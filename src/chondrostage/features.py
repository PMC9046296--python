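"""Feature-matrix capture, normalization, and batch harmonization.

Per-cell indicator measurements are captured in a matrix whose rows are
detection rounds (1..20) and whose columns are (sample, indicator)
pairs.  Per indicator, values are min-max mapped to integers in
[0, 14000] (half-up rounding), the normalization parameters are frozen
so that query samples can be projected into the reference coordinate
system, and rounds are sorted within each column so that all downstream
distances are exactly invariant to the order in which cells happened to
be measured.

Batches acquired in separate sessions are harmonized through a shared
anchor sample (the Model-P2 healthy control): a robust affine map per
batch and indicator sends the batch anchor's (median, IQR) onto the
first batch anchor's.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import INDICATORS, SampleProfile, StageLabel

__all__ = [
    "NORM_MAX",
    "FeatureMatrix",
    "assemble_matrix",
    "normalize_matrix",
    "apply_normalization",
    "sort_rounds",
    "harmonize_batches",
]

logger = logging.getLogger(__name__)

#: Upper bound of the integer normalization range.
NORM_MAX = 14000


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


@dataclass
class FeatureMatrix:
    """Rounds x (sample, indicator) value table with normalization state.

    ``data`` has a RangeIndex of rounds (1..n) and a two-level column
    MultiIndex (sample_id, indicator).  ``state`` is "raw" or
    "normalized"; after normalization ``norm_params`` maps each
    indicator to the fitted (min, max) and all values are integers in
    [0, NORM_MAX].  ``sample_meta`` carries stage and batch per sample.
    """

    data: pd.DataFrame
    state: str = "raw"
    norm_params: dict[str, tuple[float, float]] | None = None
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalize_scope: str = "indicator"

    def __post_init__(self) -> None:
        if self.state not in ("raw", "normalized"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.data.columns.nlevels != 2:
            raise ValueError("columns must be a (sample_id, indicator) MultiIndex")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.get_level_values(0).unique())

    @property
    def indicators(self) -> list[str]:
        return list(self.data.columns.get_level_values(1).unique())

    @property
    def n_rounds(self) -> int:
        return len(self.data)

    def sample_vectors(self) -> pd.DataFrame:
        """Samples x features table (indicators concatenated in panel order)."""
        blocks = []
        for sid in self.sample_ids:
            block = self.data[sid].loc[:, self.indicators].to_numpy().ravel(order="F")
            blocks.append(block)
        cols = [
            f"{ind}_r{r}"
            for ind in self.indicators
            for r in range(1, self.n_rounds + 1)
        ]
        return pd.DataFrame(blocks, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=cols)

    def stage_of(self, sample_id: str) -> StageLabel:
        if sample_id in self.sample_meta.index:
            return StageLabel(self.sample_meta.loc[sample_id, "stage"])
        return StageLabel.UNKNOWN


def assemble_matrix(profiles: list[SampleProfile]) -> FeatureMatrix:
    """Capture sample profiles into a raw feature matrix.

    Column order is deterministic: samples in input order, indicators in
    panel order.  All profiles must share the round count and indicator
    panel.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    n_rounds = profiles[0].n_rounds
    seen = set()
    columns = {}
    meta = []
    for p in profiles:
        if p.n_rounds != n_rounds:
            raise ValueError(
                f"profile {p.sample_id!r} has {p.n_rounds} rounds, expected {n_rounds}"
            )
        if p.sample_id in seen:
            raise ValueError(f"duplicate sample_id {p.sample_id!r}")
        seen.add(p.sample_id)
        for ind in INDICATORS:
            columns[(p.sample_id, ind)] = p.values[ind].to_numpy()
        meta.append(
            {"sample_id": p.sample_id, "batch_id": p.batch_id, "stage": p.stage.value}
        )
    data = pd.DataFrame(columns, index=pd.RangeIndex(1, n_rounds + 1, name="round"))
    data.columns = pd.MultiIndex.from_tuples(
        data.columns, names=["sample_id", "indicator"]
    )
    sample_meta = pd.DataFrame(meta).set_index("sample_id")
    return FeatureMatrix(data=data, state="raw", sample_meta=sample_meta)


def normalize_matrix(matrix: FeatureMatrix, scope: str = "indicator") -> FeatureMatrix:
    """Min-max normalize to integers in [0, NORM_MAX].

    With the default per-indicator scope, each indicator's (min, max)
    over all its samples and rounds maps linearly onto [0, NORM_MAX];
    ``scope="global"`` fits a single (min, max) over the whole matrix
    and stores it for every indicator.  Constant indicators map to 0
    everywhere (with a warning).  The fitted parameters are stored for
    later application to query samples.
    """
    if scope not in ("indicator", "global"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    arr = matrix.data.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("matrix contains non-finite values")

    out = matrix.data.copy()
    params: dict[str, tuple[float, float]] = {}
    if scope == "global":
        vmin, vmax = float(arr.min()), float(arr.max())
        for ind in matrix.indicators:
            params[ind] = (vmin, vmax)
    else:
        for ind in matrix.indicators:
            block = matrix.data.xs(ind, axis=1, level="indicator").to_numpy()
            params[ind] = (float(block.min()), float(block.max()))

    for ind in matrix.indicators:
        vmin, vmax = params[ind]
        cols = [c for c in matrix.data.columns if c[1] == ind]
        if vmax == vmin:
            warnings.warn(
                f"indicator {ind!r} is constant; normalized to all zeros",
                stacklevel=2,
            )
            out.loc[:, cols] = 0.0
        else:
            scaled = (out.loc[:, cols] - vmin) / (vmax - vmin) * NORM_MAX
            out.loc[:, cols] = _round_half_up(scaled.to_numpy())
    return FeatureMatrix(
        data=out,
        state="normalized",
        norm_params=params,
        sample_meta=matrix.sample_meta,
        normalize_scope=scope,
    )


def apply_normalization(
    query: SampleProfile,
    params: dict[str, tuple[float, float]],
) -> tuple[pd.DataFrame, int]:
    """Project a query profile with previously fitted (min, max) params.

    The same linear map is applied, values are rounded half-up and then
    clipped to [0, NORM_MAX]; the number of clipped entries is returned
    (values outside the fitted reference range are clipped, not
    extrapolated — the reference range defines the model's domain).
    """
    out = {}
    n_clipped = 0
    for ind in INDICATORS:
        if ind not in params:
            raise KeyError(f"no normalization parameters for indicator {ind!r}")
        vmin, vmax = params[ind]
        v = query.values[ind].to_numpy(dtype=float)
        if vmax == vmin:
            scaled = np.zeros_like(v)
        else:
            scaled = _round_half_up((v - vmin) / (vmax - vmin) * NORM_MAX)
        clipped = np.clip(scaled, 0, NORM_MAX)
        n_clipped += int(np.sum(clipped != scaled))
        out[ind] = clipped
    if n_clipped:
        logger.info("apply_normalization: clipped %d values for %s",
                    n_clipped, query.sample_id)
    frame = pd.DataFrame(out, index=query.values.index)
    return frame, n_clipped


def sort_rounds(matrix: FeatureMatrix) -> FeatureMatrix:
    """Sort values ascending within each (sample, indicator) column.

    Rounds across indicators are exchangeable (they are not matched
    cells), so sorting loses nothing and makes every downstream distance
    exactly invariant to the order of detection rounds.
    """
    data = matrix.data.copy()
    data.loc[:, :] = np.sort(matrix.data.to_numpy(), axis=0)
    return replace(matrix, data=data)


def harmonize_batches(
    batches: list[FeatureMatrix],
    anchor_sample_id: str,
) -> FeatureMatrix:
    """Merge batches through a shared anchor sample's robust affine map.

    For each batch after the first and each indicator, the affine map
    sending the batch anchor's (median, IQR) onto the first batch
    anchor's is applied to every sample of that batch.  An anchor IQR of
    zero degrades to a median shift (with a warning).  Sample ids that
    collide across batches (the anchor itself always does) are renamed
    "<sid>@<batch_id>" in the merged matrix.
    """
    if len(batches) < 2:
        raise ValueError("need at least 2 batches to harmonize")
    for i, b in enumerate(batches):
        if anchor_sample_id not in b.sample_ids:
            raise ValueError(
                f"anchor sample {anchor_sample_id!r} absent from batch index {i}"
            )
        if b.state != batches[0].state:
            raise ValueError("all batches must share the normalization state")

    def anchor_stats(b: FeatureMatrix, ind: str) -> tuple[float, float]:
        v = b.data[(anchor_sample_id, ind)].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return float(med), float(q3 - q1)

    ref = batches[0]
    merged_cols: dict[tuple[str, str], np.ndarray] = {
        c: ref.data[c].to_numpy(dtype=float) for c in ref.data.columns
    }
    meta_frames = [ref.sample_meta]
    taken = set(ref.sample_ids)

    for b in batches[1:]:
        gains_offsets = {}
        for ind in ref.indicators:
            med_r, iqr_r = anchor_stats(ref, ind)
            med_b, iqr_b = anchor_stats(b, ind)
            if iqr_b == 0.0:
                warnings.warn(
                    f"anchor IQR is zero for indicator {ind!r}; "
                    "falling back to median shift",
                    stacklevel=2,
                )
                gain = 1.0
            else:
                gain = iqr_r / iqr_b
            gains_offsets[ind] = (gain, med_r - gain * med_b)

        batch_name = (
            b.sample_meta["batch_id"].iloc[0] if "batch_id" in b.sample_meta else "b"
        )
        rename = {
            sid: (f"{sid}@{batch_name}" if sid in taken else sid)
            for sid in b.sample_ids
        }
        taken.update(rename.values())
        for (sid, ind), col in b.data.items():
            gain, offset = gains_offsets[ind]
            merged_cols[(rename[sid], ind)] = gain * col.to_numpy(dtype=float) + offset
        meta = b.sample_meta.rename(index=rename)
        meta_frames.append(meta)

    data = pd.DataFrame(merged_cols, index=ref.data.index)
    data.columns = pd.MultiIndex.from_tuples(
        data.columns, names=["sample_id", "indicator"]
    )
    return FeatureMatrix(
        data=data,
        state=ref.state,
        norm_params=ref.norm_params,
        sample_meta=pd.concat(meta_frames),
    )
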