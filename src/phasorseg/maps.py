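"""Reciprocity mapping and rendering: phasor clusters back to image space.

Because every phasor traces back to exactly one pixel, cluster labels
assigned in the phasor domain become a spatial segmentation of the
fluorescence-lifetime map.  Unclassified pixels (filtered out or invalid)
are first-class citizens with label 0 so all output maps align with the
input geometry.

Renderers produce deterministic 8-bit RGB images:

* tau-phase maps on a blue-to-red ramp over a fixed lifetime range
  (default 2.0 ns blue to 4.5 ns red, clipped at the ends),
* hard-cluster maps (cluster 1 red, cluster 2 green, unclassified grey),
* probability blends whose colour tones mix the cluster palette by the
  GMM responsibilities.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field
from itertools import permutations
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .errors import ConfigurationError, DomainError, IntegrityError
from .gmm import FitResult
from .phasor import PhasorCloud, TauPhaseMap

__all__ = [
    "SegmentationMap",
    "RenderedImage",
    "CLUSTER_PALETTE",
    "GREY",
    "map_labels_to_image",
    "render_tau_map",
    "render_cluster_map",
    "render_probability_blend",
    "segmentation_accuracy",
    "save_image",
    "export_tau_map",
]

GREY = (128, 128, 128)
# Cluster 1 red, cluster 2 green; documented extension for K > 2.
CLUSTER_PALETTE: Tuple[Tuple[int, int, int], ...] = (
    (255, 0, 0),
    (0, 255, 0),
    (0, 0, 255),
    (255, 0, 255),
    (0, 255, 255),
    (255, 255, 0),
)


@dataclass
class SegmentationMap:
    """Per-pixel integer labels: 0 unclassified, 1..K cluster ids."""

    labels: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    @property
    def k(self) -> int:
        return int(self.labels.max())


@dataclass
class RenderedImage:
    """8-bit RGB raster plus its value-to-colour legend."""

    rgb: np.ndarray  # (rows, cols, 3) uint8
    legend: Dict[str, object] = field(default_factory=dict)


def map_labels_to_image(
    cloud: PhasorCloud, labels: np.ndarray, shape: Tuple[int, int]
) -> SegmentationMap:
    """Trace phasor-domain cluster labels back to pixel space.

    Each retained pixel receives its phasor's label; everything else is 0.
    """
    labels = np.asarray(labels)
    if len(labels) != len(cloud):
        raise DomainError("labels must align with the phasor cloud")
    rows, cols = shape
    if np.any(cloud.pixels[:, 0] >= rows) or np.any(cloud.pixels[:, 1] >= cols):
        raise DomainError("pixel back-reference outside the requested shape")
    grid = np.zeros((rows, cols), dtype=np.int64)
    flat = cloud.pixels[:, 0] * cols + cloud.pixels[:, 1]
    if len(np.unique(flat)) != len(flat):
        raise IntegrityError("duplicate pixel back-references in the cloud")
    grid[cloud.pixels[:, 0], cloud.pixels[:, 1]] = labels
    return SegmentationMap(labels=grid)


def _ramp_color(fraction: float) -> Tuple[int, int, int]:
    """Blue-to-red colour: HSV hue sweep 240 deg (blue) -> 0 deg (red)."""
    hue = (1.0 - fraction) * (240.0 / 360.0)
    r, g, b = colorsys.hsv_to_rgb(hue, 1.0, 1.0)
    return int(round(r * 255)), int(round(g * 255)), int(round(b * 255))


def render_tau_map(
    tau_map: TauPhaseMap, t_min_ns: float = 2.0, t_max_ns: float = 4.5
) -> RenderedImage:
    """False-colour lifetime image: tau mapped linearly onto blue->red,
    clipped at the range ends; missing pixels neutral grey."""
    if not (t_min_ns < t_max_ns):
        raise DomainError("tau colour range must satisfy t_min < t_max")
    values = tau_map.values
    rows, cols = values.shape
    rgb = np.empty((rows, cols, 3), dtype=np.uint8)
    rgb[...] = GREY
    finite = np.isfinite(values)
    frac = np.clip((values[finite] - t_min_ns) / (t_max_ns - t_min_ns), 0.0, 1.0)
    # 256-entry lookup keeps rendering exact and fast.
    lut = np.array([_ramp_color(i / 255.0) for i in range(256)], dtype=np.uint8)
    idx = np.rint(frac * 255).astype(int)
    rgb[finite] = lut[idx]
    return RenderedImage(
        rgb=rgb,
        legend={
            "t_min_ns": t_min_ns,
            "t_max_ns": t_max_ns,
            "min_color": tuple(int(v) for v in lut[0]),
            "max_color": tuple(int(v) for v in lut[255]),
            "missing_color": GREY,
        },
    )


def render_cluster_map(seg: SegmentationMap) -> RenderedImage:
    """Hard-assignment colour map: cluster 1 red, 2 green, 0 grey."""
    k = seg.k
    if k > len(CLUSTER_PALETTE):
        raise ConfigurationError(
            f"{k} clusters exceed the {len(CLUSTER_PALETTE)}-colour palette"
        )
    rows, cols = seg.shape
    rgb = np.empty((rows, cols, 3), dtype=np.uint8)
    rgb[...] = GREY
    for cid in range(1, k + 1):
        rgb[seg.labels == cid] = CLUSTER_PALETTE[cid - 1]
    legend = {"unclassified": GREY}
    legend.update(
        {f"cluster_{cid}": CLUSTER_PALETTE[cid - 1] for cid in range(1, k + 1)}
    )
    return RenderedImage(rgb=rgb, legend=legend)


def render_probability_blend(
    cloud: PhasorCloud, result: FitResult, shape: Tuple[int, int]
) -> RenderedImage:
    """Soft segmentation: per-pixel colour is the responsibility-weighted
    channel-wise mix of the cluster palette colours.

    A pixel with responsibilities (1, 0) renders exactly the hard cluster-1
    colour; (0.5, 0.5) is the channel-wise average of red and green.
    """
    resp = result.responsibilities
    if len(resp) != len(cloud):
        raise DomainError("responsibilities must align with the phasor cloud")
    k = resp.shape[1]
    if k > len(CLUSTER_PALETTE):
        raise ConfigurationError(
            f"{k} clusters exceed the {len(CLUSTER_PALETTE)}-colour palette"
        )
    rows, cols = shape
    rgb = np.empty((rows, cols, 3), dtype=np.uint8)
    rgb[...] = GREY
    palette = np.asarray(CLUSTER_PALETTE[:k], dtype=float)
    mixed = np.rint(resp @ palette).astype(np.uint8)
    rgb[cloud.pixels[:, 0], cloud.pixels[:, 1]] = mixed
    legend = {"unclassified": GREY}
    legend.update(
        {f"cluster_{cid}": CLUSTER_PALETTE[cid - 1] for cid in range(1, k + 1)}
    )
    return RenderedImage(rgb=rgb, legend=legend)


def segmentation_accuracy(
    seg: SegmentationMap, truth_labels: np.ndarray
) -> float:
    """Fraction of retained (label > 0) pixels correctly classified under
    the best label permutation (exhaustive for K <= 3)."""
    truth = np.asarray(truth_labels)
    if truth.shape != seg.shape:
        raise DomainError("truth labels must match the segmentation shape")
    retained = seg.labels > 0
    n = int(retained.sum())
    if n == 0:
        raise DomainError("no retained pixels; accuracy undefined")
    pred = seg.labels[retained]
    true = truth[retained]
    pred_ids = sorted(int(v) for v in np.unique(pred))
    true_ids = sorted(int(v) for v in np.unique(np.concatenate([np.unique(true), pred_ids])))
    if len(true_ids) > 3:
        raise DomainError("exhaustive permutation matching supports K <= 3")
    best = 0.0
    for perm in permutations(true_ids, len(pred_ids)):
        mapping = dict(zip(pred_ids, perm))
        mapped = np.vectorize(mapping.get)(pred)
        best = max(best, float((mapped == true).mean()))
    return best


def save_image(image: RenderedImage, path: Union[str, Path]) -> None:
    """Write a rendered image as PNG or TIFF, selected by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.rgb)
    else:
        from PIL import Image

        Image.fromarray(image.rgb, mode="RGB").save(path)


def export_tau_map(
    tau_map: TauPhaseMap, path: Union[str, Path]
) -> None:
    """Export a tau-phase map: 32-bit float TIFF (NaN = missing) or CSV
    with columns row, col, tau_ns (finite pixels only)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, tau_map.values.astype(np.float32))
    else:
        import pandas as pd

        rr, cc = np.nonzero(tau_map.finite_mask)
        pd.DataFrame(
            {"row": rr, "col": cc, "tau_ns": tau_map.values[rr, cc]}
        ).to_csv(path, index=False)
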