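"""Core domain types shared across the staging and trajectory pipelines.

The staging system describes one cultured chondrocyte sample by a fixed
panel of six visual indicators — four immunostained markers (RBP4, SOD3,
IFITM3, F-actin) plus cell size and nucleus size — each measured over a
fixed number of detection rounds (one randomly selected cell per round,
20 rounds by default).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Marker channels quantified per cell (mean gray value, arbitrary units).
MARKERS: tuple[str, ...] = ("rbp4", "sod3", "ifitm3", "factin")

#: Full indicator panel used for staging, in canonical column order.
INDICATORS: tuple[str, ...] = MARKERS + ("cell_size", "nucleus_size")

#: Detection rounds per indicator per sample.
DEFAULT_N_ROUNDS: int = 20

#: Fixed column names for per-cell measurement tables.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "cell_id", "rbp4", "sod3", "ifitm3", "factin",
    "cell_area_um2", "nucleus_area_um2",
)


class StageLabel(enum.Enum):
    """Serial-passage stage of a chondrocyte sample.

    P0 denotes primary cells (cultured < 24 h); higher passage numbers
    correspond to progressively dedifferentiated cultures.  Ordering
    P0 < P2 < P4 < P8 is defined; UNKNOWN marks unstaged query samples
    and never appears in a reference model.
    """

    P0 = "P0"
    P2 = "P2"
    P4 = "P4"
    P8 = "P8"
    UNKNOWN = "UNKNOWN"

    @property
    def order(self) -> int:
        if self is StageLabel.UNKNOWN:
            raise ValueError("UNKNOWN stage has no position in the passage ordering")
        return _STAGE_ORDER[self]

    def __lt__(self, other: "StageLabel") -> bool:
        if not isinstance(other, StageLabel):
            return NotImplemented
        return self.order < other.order


_STAGE_ORDER = {StageLabel.P0: 0, StageLabel.P2: 1, StageLabel.P4: 2, StageLabel.P8: 3}

#: Reference stages in passage order.
REFERENCE_STAGES: tuple[StageLabel, ...] = (
    StageLabel.P0, StageLabel.P2, StageLabel.P4, StageLabel.P8,
)

#: Stages considered "early" vs "late" dedifferentiation (biphasic model).
EARLY_STAGES: frozenset[StageLabel] = frozenset({StageLabel.P0, StageLabel.P2})
LATE_STAGES: frozenset[StageLabel] = frozenset({StageLabel.P4, StageLabel.P8})


class PatternClass(enum.Enum):
    """Temporal archetype of a gene's expression along pseudotime.

    Five biological archetypes (immediate/gradual down, delayed/gradual
    up, tide wave) plus FLAT, a rejection class for genes without
    meaningful dynamic range, so background genes are never forced into
    one of the dynamic classes.
    """

    IMMEDIATE_DOWN = "IMMEDIATE_DOWN"
    GRADUAL_DOWN = "GRADUAL_DOWN"
    DELAYED_UP = "DELAYED_UP"
    GRADUAL_UP = "GRADUAL_UP"
    TIDE_WAVE = "TIDE_WAVE"
    FLAT = "FLAT"


#: The five dynamic (non-FLAT) archetypes, in a fixed order.
DYNAMIC_PATTERNS: tuple[PatternClass, ...] = (
    PatternClass.IMMEDIATE_DOWN,
    PatternClass.GRADUAL_DOWN,
    PatternClass.DELAYED_UP,
    PatternClass.GRADUAL_UP,
    PatternClass.TIDE_WAVE,
)


@dataclass
class SampleProfile:
    """One sample's round-by-indicator measurement block.

    Parameters
    ----------
    sample_id, batch_id : str
        Identifiers; batch distinguishes acquisition sessions.
    stage : StageLabel
        Known passage stage, or UNKNOWN for query samples.
    values : pandas.DataFrame
        Rounds (index 1..n_rounds) x indicators (columns in INDICATORS
        order).  All values finite and >= 0.
    """

    sample_id: str
    batch_id: str
    stage: StageLabel
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in INDICATORS if c not in self.values.columns]
        if missing:
            raise ValueError(
                f"profile {self.sample_id!r} missing indicators: {missing}"
            )
        self.values = self.values.loc[:, list(INDICATORS)].astype(float)
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"profile {self.sample_id!r} has non-finite values")
        if (arr < 0).any():
            raise ValueError(f"profile {self.sample_id!r} has negative values")
        self.values.index = pd.RangeIndex(1, len(self.values) + 1, name="round")

    @property
    def n_rounds(self) -> int:
        return len(self.values)


@dataclass
class TrajectoryMatrix:
    """Genes x cells expression matrix with a pseudotime ordering.

    ``expression`` holds nonnegative counts or normalized values with
    gene ids as index and cell ids as columns; ``pseudotime`` is one
    nonnegative scalar per cell (same cell ids).  ``labels`` optionally
    records the generating PatternClass per gene (simulations only).
    """

    expression: pd.DataFrame
    pseudotime: pd.Series
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if len(self.pseudotime) != self.expression.shape[1]:
            raise ValueError(
                f"pseudotime length {len(self.pseudotime)} != "
                f"number of cells {self.expression.shape[1]}"
            )
        if not self.pseudotime.index.equals(self.expression.columns):
            self.pseudotime = self.pseudotime.reindex(self.expression.columns)
            if self.pseudotime.isna().any():
                raise ValueError("pseudotime index does not match cell ids")
        if self.expression.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.pseudotime < 0).any():
            raise ValueError("pseudotime must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expression.shape[1]

    def subset(
        self,
        genes: pd.Index | None = None,
        cells: pd.Index | None = None,
    ) -> "TrajectoryMatrix":
        expr = self.expression
        if genes is not None:
            expr = expr.loc[genes]
        if cells is not None:
            expr = expr.loc[:, cells]
        labels = self.labels.loc[expr.index] if self.labels is not None else None
        return TrajectoryMatrix(
            expression=expr,
            pseudotime=self.pseudotime.loc[expr.columns],
            labels=labels,
        )


@dataclass
class SyntheticImage:
    """A rendered multi-channel field of view with its ground truth.

    channels maps channel name (dapi, phalloidin, rbp4, sod3, ifitm3) to
    a uint16 pixel array; nucleus_mask / cell_mask are integer label
    masks (background 0, labels 1..K matching truth.cell_id); truth is a
    per-cell measurement table with MEASUREMENT_COLUMNS.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    nucleus_mask: np.ndarray
    cell_mask: np.ndarray
    truth: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        shapes |= {self.nucleus_mask.shape, self.cell_mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel/mask shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
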