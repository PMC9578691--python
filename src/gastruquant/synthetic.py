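"""Seeded generators for gastruloid-like images and marker-structured count matrices.

Every generator returns its ground truth alongside the data, so the
downstream segmentation, profiling and classification stages can be tested
against known answers without any external data.

The image generator draws an elliptical body (semi-axes ``a >= b``, in µm)
with Gaussian-blob nuclei in a DAPI channel and, optionally, a posteriorly
polarized reporter channel whose intensity follows a logistic gradient in
relative axial position ``p``::

    reporter(p) = baseline + amplitude / (1 + exp(-steepness * (p - midpoint)))

An ellipse is used because its area (``pi*a*b``) and Feret diameters
(``2a``, ``2b``) have closed forms, giving exact oracles for the
morphometry stage.  The DAPI channel carries a uniform in-body baseline in
addition to the nucleus blobs, mimicking cytoplasmic/out-of-focus signal;
this keeps per-sample DAPI normalization of reporter profiles well behaved.

Randomness: each call creates one ``numpy.random.Generator`` from the seed
and consumes it in a fixed, documented order (nucleus positions, nucleus
radii, per-channel noise; or class by class for count matrices), so equal
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageSimParams",
    "ImageGroundTruth",
    "CellSimParams",
    "simulate_gastruloid_image",
    "simulate_cell_table",
]


# ---------------------------------------------------------------------------
# image simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of a synthetic two-channel gastruloid image.

    Lengths are in µm; intensities in arbitrary units.
    """

    body_semi_axes: tuple[float, float] = (150.0, 50.0)  # (a, b), a >= b
    pixel_size: float = 2.0  # µm / pixel
    n_nuclei: int = 150
    nucleus_radius_mean: float = 4.0  # µm
    nucleus_radius_sd: float = 0.8  # µm
    reporter_polarized: bool = True
    gradient_midpoint: float = 0.6  # relative A-P position of half-max
    gradient_steepness: float = 15.0
    noise_sd: float = 2.0
    seed: int = 0
    # intensity model (arbitrary units)
    reporter_amplitude: float = 200.0
    reporter_baseline: float = 10.0
    dapi_amplitude: float = 100.0
    dapi_baseline: float = 120.0
    margin: float = 20.0  # µm of background around the body

    def validate(self) -> None:
        a, b = self.body_semi_axes
        if not (a >= b > 0):
            raise ValueError(f"body semi-axes must satisfy a >= b > 0, got {(a, b)}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if 2 * a < self.pixel_size or 2 * b < self.pixel_size:
            raise ValueError("body smaller than one pixel")


@dataclass
class ImageGroundTruth:
    """Noise-free truth accompanying a simulated image."""

    body_mask: np.ndarray  # boolean raster
    true_area: float  # µm², analytic pi*a*b
    true_feret_max: float  # µm, 2a
    true_feret_min: float  # µm, 2b
    nucleus_centers: np.ndarray  # (n, 2) array of (row, col) pixel coords
    per_pixel_true_reporter: np.ndarray  # noise-free reporter raster


def simulate_gastruloid_image(params: ImageSimParams):
    """Render a two-channel (dapi, reporter) image plus ground truth.

    Returns ``(LabeledImage, ImageGroundTruth)``.  The body is an
    axis-aligned ellipse with the major axis along image columns; relative
    axial position 0 is the left (anterior) tip, 1 the right (posterior)
    tip, so a polarized reporter is brightest on the right.
    """
    from .morphometry import LabeledImage  # local import avoids cycle

    params.validate()
    a, b = params.body_semi_axes
    ps = params.pixel_size
    rng = np.random.default_rng(params.seed)

    ncols = int(np.ceil(2 * (a + params.margin) / ps))
    nrows = int(np.ceil(2 * (b + params.margin) / ps))
    rr, cc = np.mgrid[0:nrows, 0:ncols]
    # physical coordinates of pixel centers, origin at image center
    y = (rr - (nrows - 1) / 2.0) * ps
    x = (cc - (ncols - 1) / 2.0) * ps
    body = (x / a) ** 2 + (y / b) ** 2 <= 1.0

    # relative axial position within [0, 1] along the major axis
    p = np.clip((x + a) / (2 * a), 0.0, 1.0)

    if params.reporter_polarized:
        grad = 1.0 / (1.0 + np.exp(-params.gradient_steepness * (p - params.gradient_midpoint)))
        reporter_true = np.where(body, params.reporter_baseline + params.reporter_amplitude * grad, 0.0)
    else:
        reporter_true = np.where(body, params.reporter_baseline + 0.5 * params.reporter_amplitude, 0.0)

    # nuclei: uniform in a slightly shrunk ellipse so blobs stay inside
    n = params.n_nuclei
    u = rng.random(n)
    theta = rng.random(n) * 2 * np.pi
    rad = np.sqrt(u)
    nx = 0.92 * a * rad * np.cos(theta)
    ny = 0.92 * b * rad * np.sin(theta)
    radii = rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd, n)
    radii = np.clip(radii, 0.25 * params.nucleus_radius_mean, None)

    dapi_true = np.where(body, params.dapi_baseline, 0.0)
    for i in range(n):
        sig = radii[i] / 2.0  # blob sigma, radius ~ 2 sigma
        blob = params.dapi_amplitude * np.exp(
            -(((x - nx[i]) ** 2) + ((y - ny[i]) ** 2)) / (2 * sig**2)
        )
        dapi_true = dapi_true + blob
    dapi_true = np.where(body, dapi_true, 0.0)

    if params.noise_sd > 0:
        dapi = dapi_true + rng.normal(0.0, params.noise_sd, dapi_true.shape)
        reporter = reporter_true + rng.normal(0.0, params.noise_sd, reporter_true.shape)
    else:
        dapi = dapi_true.copy()
        reporter = reporter_true.copy()
    dapi = np.clip(dapi, 0.0, None)
    reporter = np.clip(reporter, 0.0, None)

    centers_rc = np.column_stack(
        [ny / ps + (nrows - 1) / 2.0, nx / ps + (ncols - 1) / 2.0]
    ) if n else np.empty((0, 2))

    image = LabeledImage(
        channels={"dapi": dapi, "reporter": reporter},
        pixel_size=ps,
        image_id=f"sim-{params.seed}",
    )
    truth = ImageGroundTruth(
        body_mask=body,
        true_area=np.pi * a * b,
        true_feret_max=2 * a,
        true_feret_min=2 * b,
        nucleus_centers=centers_rc,
        per_pixel_true_reporter=reporter_true,
    )
    return image, truth


# ---------------------------------------------------------------------------
# count-matrix simulation
# ---------------------------------------------------------------------------

SIM_CLASSES = (
    "hox_positive",
    "brain_like",
    "spinal_like",
    "dorsal",
    "midline",
    "ventral",
    "background",
)


@dataclass(frozen=True)
class CellSimParams:
    """Parameters of a synthetic marker-structured count matrix."""

    n_cells_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 50 for c in SIM_CLASSES}
    )
    marker_mean_expression: float = 10.0  # expected count of an "on" marker
    dropout_rate: float = 0.0  # P(an "on" marker reads 0)
    library_noise: float = 0.3  # sd of the per-cell gamma size factor
    seed: int = 0
    n_background_genes: int = 20
    background_mean: float = 1.0

    def validate(self) -> None:
        for cls, cnt in self.n_cells_per_class.items():
            if cls not in SIM_CLASSES:
                raise ValueError(f"unknown simulation class {cls!r}")
            if cnt < 0:
                raise ValueError(f"negative cell count for class {cls!r}")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.marker_mean_expression < 1.0:
            raise ValueError("marker_mean_expression must be >= 1")


def _class_markers(rules) -> dict[str, list[str]]:
    """The genes each planted class switches 'on'."""
    return {
        "hox_positive": list(rules.hox_genes),
        "brain_like": list(rules.brain_markers),
        "spinal_like": [rules.spinal_exclusion_gene],
        "dorsal": list(rules.dv_modules["dorsal"]),
        "midline": list(rules.dv_modules["midline"]),
        "ventral": list(rules.dv_modules["ventral"]),
        "background": [],
    }


def simulate_cell_table(params: CellSimParams, rules):
    """Plant marker-defined cell populations into a count matrix.

    Each cell of class *c* expresses every marker of *c* with counts
    ``1 + Poisson(size_factor * (marker_mean_expression - 1))`` — at least
    one by construction — then each "on" count is independently zeroed with
    probability ``dropout_rate``.  All other rule markers are exactly 0;
    background genes carry low Poisson counts in every cell.

    Returns ``(CellTable, true_labels)`` where ``true_labels`` is a pandas
    Series of planted class names indexed by cell id.
    """
    from .cell_rules import CellTable  # local import avoids cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    class_markers = _class_markers(rules)

    marker_union: list[str] = []
    for cls in SIM_CLASSES:
        for g in class_markers[cls]:
            if g not in marker_union:
                marker_union.append(g)
    bg_genes = [f"bg{i:03d}" for i in range(params.n_background_genes)]
    genes = marker_union + bg_genes
    gene_index = {g: j for j, g in enumerate(genes)}

    rows: list[np.ndarray] = []
    labels: list[str] = []
    cell_ids: list[str] = []
    for cls in SIM_CLASSES:  # fixed iteration order for determinism
        n = int(params.n_cells_per_class.get(cls, 0))
        on_idx = np.array([gene_index[g] for g in class_markers[cls]], dtype=int)
        for i in range(n):
            size = rng.gamma(
                shape=1.0 / params.library_noise**2,
                scale=params.library_noise**2,
            ) if params.library_noise > 0 else 1.0
            counts = np.zeros(len(genes), dtype=np.int64)
            if on_idx.size:
                lam = size * (params.marker_mean_expression - 1.0)
                counts[on_idx] = 1 + rng.poisson(lam, on_idx.size)
                if params.dropout_rate > 0:
                    drop = rng.random(on_idx.size) < params.dropout_rate
                    counts[on_idx[drop]] = 0
            if bg_genes:
                counts[len(marker_union):] = rng.poisson(
                    size * params.background_mean, len(bg_genes)
                )
            rows.append(counts)
            labels.append(cls)
            cell_ids.append(f"{cls}_{i:04d}")

    if rows:
        matrix = np.vstack(rows)
    else:
        matrix = np.zeros((0, len(genes)), dtype=np.int64)
    meta = pd.DataFrame({"condition": "sim"}, index=cell_ids) if cell_ids else None
    table = CellTable(counts=matrix, gene_names=genes, cell_ids=cell_ids, cell_meta=meta)
    true_labels = pd.Series(labels, index=cell_ids, name="true_label")
    return table, true_labels


def params_to_dict(p) -> dict:
    """Serialize a params dataclass to plain types (for manifests/YAML)."""
    d = dataclasses.asdict(p)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
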