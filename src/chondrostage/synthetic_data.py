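"""Synthetic ground-truth generators for the biphasic dedifferentiation model.

Three generators back the rest of the package:

* per-cell marker/size measurements drawn from stage-dependent
  distributions (log-normal intensities, correlated truncated-normal
  diameters);
* renderable multi-channel fluorescence images with exact label masks
  and a ground-truth measurement table;
* gene-by-cell trajectory matrices in which each gene follows one of
  five temporal archetypes (or a flat background) along pseudotime.

Default stage parameters live in ``data/stage_defaults.yaml`` and encode
only the ordinal biology of the biphasic model: RBP4/SOD3 peak at P2,
IFITM3/F-actin and cell/nucleus size increase monotonically with
passage.  The numeric values are illustrative configuration, not
measurements.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from skimage.draw import ellipse as draw_ellipse

from .datatypes import (
    DYNAMIC_PATTERNS,
    MARKERS,
    MEASUREMENT_COLUMNS,
    PatternClass,
    StageLabel,
    SyntheticImage,
    TrajectoryMatrix,
)

__all__ = [
    "StageParams",
    "ImageConfig",
    "make_stage_params",
    "sample_cell_measurements",
    "render_image",
    "simulate_trajectory_matrix",
    "simulate_profile",
    "load_default_stage_table",
    "PATTERN_TEMPLATES",
]

# Override keys accepted by make_stage_params, matching the YAML schema.
_PARAM_KEYS = (
    [f"{m}_mean" for m in MARKERS]
    + [f"{m}_cv" for m in MARKERS]
    + [
        "cell_diameter_mean",
        "cell_diameter_sd",
        "nucleus_diameter_mean",
        "nucleus_diameter_sd",
        "size_correlation",
        "aspect_ratio_max",
    ]
)


@dataclass(frozen=True)
class StageParams:
    """Generator parameters for one passage stage.

    Intensity means/CVs are in arbitrary fluorescence units; diameters
    in micrometres (equivalent-circle diameter of the cell or nucleus
    footprint); ``size_correlation`` couples cell and nucleus diameter;
    ``aspect_ratio_max`` bounds the uniform aspect-ratio draw used when
    rendering elliptical cells.
    """

    stage: StageLabel
    rbp4_mean: float
    sod3_mean: float
    ifitm3_mean: float
    factin_mean: float
    rbp4_cv: float
    sod3_cv: float
    ifitm3_cv: float
    factin_cv: float
    cell_diameter_mean: float
    cell_diameter_sd: float
    nucleus_diameter_mean: float
    nucleus_diameter_sd: float
    size_correlation: float
    aspect_ratio_max: float

    def __post_init__(self) -> None:
        for m in MARKERS:
            mean = getattr(self, f"{m}_mean")
            cv = getattr(self, f"{m}_cv")
            if mean <= 0:
                raise ValueError(f"{m}_mean must be > 0, got {mean}")
            if not (0 <= cv <= 1):
                raise ValueError(f"{m}_cv must be in [0, 1], got {cv}")
        if self.cell_diameter_mean <= 0 or self.nucleus_diameter_mean <= 0:
            raise ValueError("diameter means must be > 0")
        if self.nucleus_diameter_mean >= self.cell_diameter_mean:
            raise ValueError("nucleus diameter mean must be < cell diameter mean")
        if self.cell_diameter_sd < 0 or self.nucleus_diameter_sd < 0:
            raise ValueError("diameter sds must be >= 0")
        if not (0 <= self.size_correlation < 1):
            raise ValueError("size_correlation must be in [0, 1)")
        if self.aspect_ratio_max < 1.0:
            raise ValueError("aspect_ratio_max must be >= 1")

    def marker_mean(self, marker: str) -> float:
        return getattr(self, f"{marker}_mean")

    def marker_cv(self, marker: str) -> float:
        return getattr(self, f"{marker}_cv")


def load_default_stage_table() -> dict[StageLabel, dict[str, float]]:
    """Load the packaged illustrative per-stage defaults."""
    text = (
        importlib.resources.files("chondrostage")
        .joinpath("data/stage_defaults.yaml")
        .read_text()
    )
    raw = yaml.safe_load(text)["stages"]
    return {StageLabel(k): {p: float(v) for p, v in d.items()} for k, d in raw.items()}


def make_stage_params(
    stage: StageLabel | str,
    overrides: Mapping[str, float] | None = None,
) -> StageParams:
    """Build stage parameters from packaged defaults plus overrides.

    Parameters
    ----------
    stage : StageLabel or str
        One of P0, P2, P4, P8 (UNKNOWN is rejected).
    overrides : mapping, optional
        Parameter-name -> value replacements; keys must be known
        parameter names (e.g. ``rbp4_mean``, ``cell_diameter_sd``).

    Raises
    ------
    KeyError
        On an unknown stage or override key, naming the offender.
    """
    stage = StageLabel(stage) if not isinstance(stage, StageLabel) else stage
    if stage is StageLabel.UNKNOWN:
        raise KeyError("stage UNKNOWN has no generator parameters")
    table = load_default_stage_table()
    values = dict(table[stage])
    for key, val in (overrides or {}).items():
        if key not in _PARAM_KEYS:
            raise KeyError(f"unknown stage parameter override: {key!r}")
        values[key] = float(val)
    return StageParams(stage=stage, **values)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _sample_diameters(
    params: StageParams, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (cell, nucleus) diameters, truncated to 0 < nucleus < cell.

    Rejection sampling on the bivariate normal; with the default
    parameters violations are vanishingly rare, so the loop is cheap.
    """
    rho = params.size_correlation
    mean = np.array([params.cell_diameter_mean, params.nucleus_diameter_mean])
    sds = np.array([params.cell_diameter_sd, params.nucleus_diameter_sd])
    cov = np.array(
        [
            [sds[0] ** 2, rho * sds[0] * sds[1]],
            [rho * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    out = np.empty((n, 2))
    filled = 0
    for _ in range(1000):
        need = n - filled
        if need == 0:
            break
        # svd handles the degenerate (zero-sd) covariance as well
        draw = rng.multivariate_normal(mean, cov, size=need, method="svd")
        ok = (draw[:, 1] > 0) & (draw[:, 0] > draw[:, 1])
        good = draw[ok]
        out[filled : filled + len(good)] = good
        filled += len(good)
    if filled < n:
        raise RuntimeError(
            "diameter rejection sampling failed; check size parameters"
        )
    return out[:, 0], out[:, 1]


def sample_cell_measurements(
    params: StageParams,
    n_cells: int,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Draw per-cell measurements for one stage.

    Marker intensities are log-normal with the configured arithmetic
    mean and CV; cell/nucleus diameters are correlated truncated
    normals; areas are the equivalent-circle areas pi * d^2 / 4 (an
    elliptical footprint of the same area is assigned at render time).

    Returns a DataFrame with MEASUREMENT_COLUMNS plus the raw diameters
    and an aspect ratio column used for rendering.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    data: dict[str, np.ndarray] = {}
    for m in MARKERS:
        mu, sigma = _lognormal_params(params.marker_mean(m), params.marker_cv(m))
        data[m] = rng.lognormal(mean=mu, sigma=sigma, size=n_cells)

    cell_d, nuc_d = _sample_diameters(params, n_cells, rng)
    aspect = rng.uniform(1.0, params.aspect_ratio_max, size=n_cells)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            **{m: data[m] for m in MARKERS},
            "cell_area_um2": np.pi * cell_d**2 / 4.0,
            "nucleus_area_um2": np.pi * nuc_d**2 / 4.0,
            "cell_diameter_um": cell_d,
            "nucleus_diameter_um": nuc_d,
            "aspect_ratio": aspect,
        }
    )
    return table


@dataclass(frozen=True)
class ImageConfig:
    """Rendering parameters for synthetic fields of view.

    16-bit canvas of ``shape`` pixels at ``pixel_size`` um/px.  Noise is
    Poisson shot noise on the expected photon count (toggled by
    ``poisson_noise``) plus zero-mean Gaussian read noise of sd
    ``read_noise_sd``; both off reproduce the noiseless quantized image.
    ``min_spacing_um`` is the extra clearance required between cell
    outlines during rejection placement.
    """

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.5
    dapi_intensity: float = 120.0
    background: float = 0.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    gaussian_blur_sigma: float = 0.0
    min_spacing_um: float = 2.0
    border_margin_um: float = 1.0
    max_retries: int = 200
    exclude_holes: bool = True


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"placed only {placed} of {requested} cells without overlap; "
            "reduce cell count/size or enlarge the canvas"
        )


def _place_centers(
    semi_major_px: np.ndarray,
    shape: tuple[int, int],
    spacing_px: float,
    margin_px: float,
    rng: np.random.Generator,
    max_retries: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping centers (conservative circle test)."""
    n = len(semi_major_px)
    centers = np.zeros((n, 2))
    order = np.argsort(-semi_major_px)  # place big cells first
    placed_idx: list[int] = []
    for i in order:
        a = semi_major_px[i]
        lo = a + margin_px
        hi_r = shape[0] - a - margin_px
        hi_c = shape[1] - a - margin_px
        if hi_r <= lo or hi_c <= lo:
            raise PlacementError(len(placed_idx), n)
        ok = False
        for _ in range(max_retries):
            cand = np.array([rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)])
            if all(
                np.hypot(*(cand - centers[j])) > a + semi_major_px[j] + spacing_px
                for j in placed_idx
            ):
                centers[i] = cand
                placed_idx.append(i)
                ok = True
                break
        if not ok:
            raise PlacementError(len(placed_idx), n)
    return centers


def render_image(
    cells: pd.DataFrame,
    config: ImageConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticImage:
    """Render a measurement table into a multi-channel image with ground truth.

    Each cell becomes an ellipse of the tabulated area and aspect ratio
    (random orientation); its nucleus is a concentric disk.  Marker
    channels are uniform at the cell's tabulated intensity inside the
    cell mask, phalloidin at the F-actin intensity, DAPI at
    ``config.dapi_intensity`` inside the nucleus.  The returned ground
    truth records what is actually in the image: quantized intensities
    and mask-pixel areas.
    """
    config = config or ImageConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px = config.pixel_size
    n = len(cells)
    if n == 0:
        raise ValueError("no cells to render")

    cell_d_px = cells["cell_diameter_um"].to_numpy() / px
    nuc_d_px = cells["nucleus_diameter_um"].to_numpy() / px
    aspect = cells["aspect_ratio"].to_numpy()
    # Ellipse of equal area: semi-axes (d/2)*sqrt(q) and (d/2)/sqrt(q).
    semi_major = cell_d_px / 2.0 * np.sqrt(aspect)
    semi_minor = cell_d_px / 2.0 / np.sqrt(aspect)

    centers = _place_centers(
        semi_major,
        config.shape,
        config.min_spacing_um / px,
        config.border_margin_um / px,
        rng,
        config.max_retries,
    )
    theta = rng.uniform(0.0, np.pi, size=n)

    cell_mask = np.zeros(config.shape, dtype=np.int32)
    nucleus_mask = np.zeros(config.shape, dtype=np.int32)
    channels = {
        name: np.full(config.shape, config.background, dtype=np.float64)
        for name in ("dapi", "phalloidin", "rbp4", "sod3", "ifitm3")
    }
    marker_to_channel = {"rbp4": "rbp4", "sod3": "sod3", "ifitm3": "ifitm3"}

    truth_rows = []
    for i in range(n):
        label = int(cells["cell_id"].iloc[i])
        rr, cc = draw_ellipse(
            centers[i, 0], centers[i, 1], semi_major[i], semi_minor[i],
            shape=config.shape, rotation=theta[i],
        )
        nrr, ncc = draw_ellipse(
            centers[i, 0], centers[i, 1], nuc_d_px[i] / 2.0, nuc_d_px[i] / 2.0,
            shape=config.shape,
        )
        cell_mask[rr, cc] = label
        nucleus_mask[nrr, ncc] = label

        quantized = {}
        for m, ch in marker_to_channel.items():
            v = float(np.round(cells[m].iloc[i]))
            channels[ch][rr, cc] = v
            quantized[m] = v
        v_act = float(np.round(cells["factin"].iloc[i]))
        channels["phalloidin"][rr, cc] = v_act
        quantized["factin"] = v_act
        channels["dapi"][nrr, ncc] = np.round(config.dapi_intensity)

        truth_rows.append(
            {
                "cell_id": label,
                **quantized,
                "cell_area_um2": len(rr) * px * px,
                "nucleus_area_um2": len(nrr) * px * px,
            }
        )

    if config.gaussian_blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for name in channels:
            channels[name] = gaussian_filter(
                channels[name], config.gaussian_blur_sigma
            )

    out_channels: dict[str, np.ndarray] = {}
    for name, img in channels.items():
        if config.poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
        if config.read_noise_sd > 0:
            img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
        out_channels[name] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame(truth_rows, columns=list(MEASUREMENT_COLUMNS))
    return SyntheticImage(
        channels=out_channels,
        pixel_size=px,
        nucleus_mask=nucleus_mask,
        cell_mask=cell_mask,
        truth=truth,
    )


def simulate_profile(
    params: StageParams,
    sample_id: str,
    batch_id: str = "batch1",
    n_rounds: int = 20,
    seed: int | np.random.Generator = 0,
    stage_label: StageLabel | None = None,
    shared_cells: bool = False,
) -> "SampleProfile":
    """Simulate one sample's round-by-indicator profile.

    By default each marker's rounds come from an independent cell draw
    (the four stains on separate coverslips, with sizes from a fifth
    draw); ``shared_cells=True`` instead measures all indicators on one
    shared set of cells.  ``stage_label`` overrides the recorded stage
    (e.g. UNKNOWN for query samples); the generating stage remains
    ``params.stage``.
    """
    from .datatypes import SampleProfile

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if shared_cells:
        table = sample_cell_measurements(params, n_rounds, rng)
        cols = {m: table[m].to_numpy() for m in MARKERS}
        cols["cell_size"] = table["cell_area_um2"].to_numpy()
        cols["nucleus_size"] = table["nucleus_area_um2"].to_numpy()
    else:
        cols = {}
        for m in MARKERS:
            cols[m] = sample_cell_measurements(params, n_rounds, rng)[m].to_numpy()
        size_table = sample_cell_measurements(params, n_rounds, rng)
        cols["cell_size"] = size_table["cell_area_um2"].to_numpy()
        cols["nucleus_size"] = size_table["nucleus_area_um2"].to_numpy()

    return SampleProfile(
        sample_id=sample_id,
        batch_id=batch_id,
        stage=stage_label if stage_label is not None else params.stage,
        values=pd.DataFrame(cols),
    )


# ---------------------------------------------------------------------------
# trajectory archetypes


def _step(t: np.ndarray, where: float, low_after: bool) -> np.ndarray:
    high = (t < where) if low_after else (t >= where)
    return high.astype(float)


#: Canonical archetype templates on pseudotime t in [0, 1], range [0, 1].
PATTERN_TEMPLATES: dict[PatternClass, "np.ufunc | object"] = {
    PatternClass.IMMEDIATE_DOWN: lambda t: _step(t, 0.15, low_after=True),
    PatternClass.GRADUAL_DOWN: lambda t: 1.0 - t,
    PatternClass.DELAYED_UP: lambda t: _step(t, 0.85, low_after=False),
    PatternClass.GRADUAL_UP: lambda t: np.asarray(t, dtype=float),
    # One full sine period: the minimal non-monotone archetype
    # (two internal extrema).
    PatternClass.TIDE_WAVE: lambda t: 0.5 + 0.5 * np.sin(2.0 * np.pi * t),
    PatternClass.FLAT: lambda t: np.full_like(np.asarray(t, dtype=float), 0.5),
}

#: Baseline and amplitude mapping the [0, 1] template to expression units.
TEMPLATE_BASELINE = 0.5
TEMPLATE_AMPLITUDE = 2.0


def simulate_trajectory_matrix(
    n_per_class: Mapping[PatternClass, int] | int,
    n_flat: int,
    n_cells: int,
    noise_sd: float,
    seed: int | np.random.Generator,
) -> TrajectoryMatrix:
    """Simulate a genes x cells matrix with archetypal pseudotime dynamics.

    Pseudotime is uniform on [0, 1].  Each dynamic gene follows its
    class template scaled to ``TEMPLATE_BASELINE + TEMPLATE_AMPLITUDE *
    template(t)`` plus Gaussian noise of sd ``noise_sd`` (clipped at 0);
    flat background genes are constant at the baseline + half amplitude
    midpoint scale-free level plus the same noise.  True labels are
    recorded on the result.
    """
    if isinstance(n_per_class, int):
        n_per_class = {cls: n_per_class for cls in DYNAMIC_PATTERNS}
    counts = {cls: int(n_per_class.get(cls, 0)) for cls in DYNAMIC_PATTERNS}
    if any(c < 0 for c in counts.values()) or n_flat < 0:
        raise ValueError("gene counts must be nonnegative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if n_cells < 20:
        raise ValueError(f"n_cells must be >= 20, got {n_cells}")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = rng.uniform(0.0, 1.0, size=n_cells)
    cells = pd.Index([f"cell_{i:05d}" for i in range(n_cells)], name="cell")

    rows, names, labels = [], [], []
    for cls in DYNAMIC_PATTERNS:
        template = PATTERN_TEMPLATES[cls](t)
        base = TEMPLATE_BASELINE + TEMPLATE_AMPLITUDE * template
        for g in range(counts[cls]):
            rows.append(base)
            names.append(f"{cls.value}_{g:04d}")
            labels.append(cls)
    flat_level = TEMPLATE_BASELINE + TEMPLATE_AMPLITUDE * 0.5
    for g in range(n_flat):
        rows.append(np.full(n_cells, flat_level))
        names.append(f"FLAT_{g:04d}")
        labels.append(PatternClass.FLAT)

    if not rows:
        raise ValueError("no genes requested")
    values = np.vstack(rows)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)

    genes = pd.Index(names, name="gene")
    return TrajectoryMatrix(
        expression=pd.DataFrame(values, index=genes, columns=cells),
        pseudotime=pd.Series(t, index=cells, name="pseudotime"),
        labels=pd.Series(labels, index=genes, name="pattern"),
    )
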