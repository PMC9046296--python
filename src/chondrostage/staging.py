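"""Reference-model construction and nearest-reference stage assignment.

A reference model is a normalized, round-sorted feature matrix of
stage-labeled samples covering P0/P2/P4/P8 together with the frozen
normalization parameters.  An unknown sample is projected with those
parameters, its rounds sorted, and its Euclidean distance to every
reference sample computed on the concatenated per-sample vector (6
indicators x 20 rounds = 120 dimensions by default).  The assigned
stage is that of the nearest reference; confidence is the two-nearest-
stage ratio d_other / (d_other + d_assigned), which is 1 for an exact
match and <= 0.5 at a tie (flagged ambiguous, tie broken toward the
earlier stage).  A query far from all references relative to the spread
of the references themselves is additionally flagged out-of-model
rather than silently force-assigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

from .datatypes import INDICATORS, REFERENCE_STAGES, SampleProfile, StageLabel
from .features import (
    FeatureMatrix,
    apply_normalization,
    assemble_matrix,
    normalize_matrix,
    sort_rounds,
)

__all__ = [
    "ReferenceModel",
    "StagingResult",
    "build_reference",
    "sample_distance_matrix",
    "pca_embed",
    "assign_stage",
]

logger = logging.getLogger(__name__)


@dataclass
class ReferenceModel:
    """Frozen staged reference: normalized, round-sorted profiles P0-P8."""

    matrix: FeatureMatrix
    panel: tuple[str, ...] = INDICATORS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.state != "normalized" or self.matrix.norm_params is None:
            raise ValueError("reference matrix must be normalized")
        stages = {self.matrix.stage_of(s) for s in self.matrix.sample_ids}
        missing = [s.value for s in REFERENCE_STAGES if s not in stages]
        if missing:
            raise ValueError(f"stage {missing[0]} absent from reference profiles")

    @property
    def norm_params(self) -> dict[str, tuple[float, float]]:
        assert self.matrix.norm_params is not None
        return self.matrix.norm_params

    @property
    def sample_stages(self) -> pd.Series:
        return pd.Series(
            {s: self.matrix.stage_of(s) for s in self.matrix.sample_ids},
            name="stage",
        )


@dataclass
class StagingResult:
    """Outcome of projecting one query against a reference model."""

    sample_id: str
    distances: pd.Series  # distance to each reference sample
    stage: StageLabel
    confidence: float
    ambiguous: bool
    out_of_model: bool
    pca_reference: pd.DataFrame  # reference coords, 2 components
    pca_query: np.ndarray  # query coords, shape (2,)
    explained_variance: np.ndarray
    n_clipped: int = 0


def build_reference(
    profiles: list[SampleProfile],
    metadata: dict | None = None,
) -> ReferenceModel:
    """Assemble, normalize, and round-sort stage-labeled profiles.

    All four stages must be represented; normalization parameters are
    fitted on the reference set and frozen in the model.
    """
    stages = {p.stage for p in profiles}
    for s in REFERENCE_STAGES:
        if s not in stages:
            raise ValueError(f"stage {s.value} absent from reference profiles")
    if StageLabel.UNKNOWN in stages:
        raise ValueError("reference profiles must not carry the UNKNOWN stage")
    matrix = sort_rounds(normalize_matrix(assemble_matrix(profiles)))
    return ReferenceModel(matrix=matrix, metadata=dict(metadata or {}))


def sample_distance_matrix(matrix: FeatureMatrix) -> pd.DataFrame:
    """Symmetric Euclidean distances between per-sample feature vectors."""
    if matrix.state != "normalized":
        raise ValueError("distance matrix requires a normalized feature matrix")
    vectors = matrix.sample_vectors()
    if len(vectors) == 1:
        warnings.warn("single sample: trivial 1x1 distance table", stacklevel=2)
        return pd.DataFrame(
            [[0.0]], index=vectors.index, columns=vectors.index
        )
    d = squareform(pdist(vectors.to_numpy(), metric="euclidean"))
    return pd.DataFrame(d, index=vectors.index, columns=vectors.index)


def _fix_signs(pca: PCA, coords: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    for k, comp in enumerate(pca.components_):
        j = int(np.argmax(np.abs(comp)))
        if comp[j] < 0:
            pca.components_[k] = -comp
            coords[:, k] = -coords[:, k]
    return coords


def pca_embed(
    matrix: FeatureMatrix,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray, PCA]:
    """Column-centered PCA of the per-sample vectors.

    Returns (coordinates, explained-variance fractions, fitted PCA).
    Components are ordered by decreasing explained variance with a fixed
    sign convention; if fewer samples than components are available the
    embedding is truncated with a warning.
    """
    vectors = matrix.sample_vectors()
    n_samples = len(vectors)
    if n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    k = min(n_components, n_samples - 1, vectors.shape[1])
    if k < n_components:
        warnings.warn(
            f"only {k} PCA component(s) available for {n_samples} samples",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(vectors.to_numpy())
    coords = _fix_signs(pca, coords)
    frame = pd.DataFrame(
        coords, index=vectors.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return frame, pca.explained_variance_ratio_.copy(), pca


def _query_vector(
    query: SampleProfile,
    model: ReferenceModel,
) -> tuple[np.ndarray, int]:
    missing = [ind for ind in model.panel if ind not in query.values.columns]
    if missing:
        raise ValueError(f"query panel is missing indicators: {missing}")
    if query.n_rounds != model.matrix.n_rounds:
        raise ValueError(
            f"query has {query.n_rounds} rounds, model expects "
            f"{model.matrix.n_rounds}"
        )
    normalized, n_clipped = apply_normalization(query, model.norm_params)
    # round-sort per indicator, then concatenate in panel order
    parts = [np.sort(normalized[ind].to_numpy()) for ind in model.panel]
    return np.concatenate(parts), n_clipped


def assign_stage(
    query: SampleProfile,
    model: ReferenceModel,
    out_of_model_factor: float = 1.5,
) -> StagingResult:
    """Assign a dedifferentiation stage to a query sample.

    The query is normalized with the model's frozen parameters (values
    outside the fitted range clipped), round-sorted, and compared with
    every reference sample by Euclidean distance.  Ties between stages
    are broken toward the earlier stage and flagged ambiguous.  A query
    whose nearest-reference distance exceeds ``out_of_model_factor``
    times the median reference-to-reference distance is flagged
    out-of-model.
    """
    qvec, n_clipped = _query_vector(query, model)
    ref_vectors = model.matrix.sample_vectors()
    diffs = ref_vectors.to_numpy() - qvec[None, :]
    dists = pd.Series(
        np.sqrt(np.sum(diffs * diffs, axis=1)), index=ref_vectors.index,
        name="distance",
    )

    stages = model.sample_stages
    stage_min = {}
    for s in REFERENCE_STAGES:
        members = stages[stages == s].index
        stage_min[s] = float(dists.loc[members].min())

    # earliest stage wins exact ties (REFERENCE_STAGES is passage-ordered)
    assigned = min(REFERENCE_STAGES, key=lambda s: (stage_min[s], s.order))
    d_assigned = stage_min[assigned]
    d_other = min(stage_min[s] for s in REFERENCE_STAGES if s is not assigned)
    if d_assigned == 0.0 and d_other == 0.0:
        confidence = 0.5
    elif d_assigned == 0.0:
        confidence = 1.0
    else:
        confidence = d_other / (d_other + d_assigned)
    ambiguous = confidence <= 0.5

    ref_dist = pdist(ref_vectors.to_numpy())
    threshold = out_of_model_factor * float(np.median(ref_dist))
    out_of_model = bool(dists.min() > threshold)

    coords, evr, pca = pca_embed(model.matrix, n_components=2)
    q_coords = pca.transform(qvec[None, :])[0]

    if ambiguous:
        logger.info("query %s: ambiguous assignment (confidence %.3f)",
                    query.sample_id, confidence)
    return StagingResult(
        sample_id=query.sample_id,
        distances=dists,
        stage=assigned,
        confidence=float(confidence),
        ambiguous=ambiguous,
        out_of_model=out_of_model,
        pca_reference=coords,
        pca_query=q_coords,
        explained_variance=evr,
        n_clipped=n_clipped,
    )
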