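"""End-to-end segmentation workflow.

Chains the full analysis of one decay map: peak-count filter -> phasor
transform -> Gaussian-mixture fit on (g, s) -> canonical cluster ordering
-> hard assignment -> reciprocity mapping back to image space -> per-cluster
lifetime summaries and rendered maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

from .acquisition import AcquisitionConfig, DecayMap
from .gmm import (
    ClusterSummary,
    FitResult,
    cluster_summary,
    fit_gmm,
    hard_assign,
    order_clusters,
    save_fit_report,
    summaries_to_frame,
)
from .maps import (
    SegmentationMap,
    export_tau_map,
    map_labels_to_image,
    render_cluster_map,
    render_probability_blend,
    render_tau_map,
    save_image,
)
from .phasor import PhasorCloud, TauPhaseMap, compute_phasor_cloud

logger = logging.getLogger("phasorseg")

__all__ = ["RunConfig", "SegmentationResult", "run_segmentation"]


@dataclass
class RunConfig:
    """Aggregated defaults of one analysis run."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    peak_threshold: int = 100
    k_clusters: int = 2
    seed: int = 0
    tau_color_range: Tuple[float, float] = (2.0, 4.5)
    output_dir: Optional[Path] = None

    def __post_init__(self) -> None:
        from .errors import ConfigurationError

        if self.peak_threshold < 0:
            raise ConfigurationError("peak_threshold must be >= 0")
        if self.k_clusters < 1:
            raise ConfigurationError("k_clusters must be >= 1")


@dataclass
class SegmentationResult:
    """All artifacts of one pipeline run."""

    cloud: PhasorCloud
    tau_map: TauPhaseMap
    fit: FitResult
    labels: "object"  # (n,) cluster labels aligned with the cloud
    segmentation: SegmentationMap
    summaries: List[ClusterSummary]


def run_segmentation(
    decay_map: DecayMap, run_config: Optional[RunConfig] = None
) -> SegmentationResult:
    """Run filter -> phasor -> GMM -> order -> assign -> map -> summarize."""
    cfg = run_config or RunConfig(acquisition=decay_map.config)
    cloud, tau_map = compute_phasor_cloud(decay_map, threshold=cfg.peak_threshold)
    logger.info("retained %d / %d pixels", len(cloud), decay_map.n_pixels)
    fit = fit_gmm(cloud, k=cfg.k_clusters, seed=cfg.seed)
    fit = order_clusters(fit, cloud)
    logger.info(
        "GMM converged=%s after %d iterations, log-likelihood %.3f",
        fit.converged,
        fit.n_iter,
        fit.log_likelihood,
    )
    labels = hard_assign(fit)
    seg = map_labels_to_image(cloud, labels, decay_map.shape)
    summaries = cluster_summary(cloud, tau_map, labels)
    result = SegmentationResult(
        cloud=cloud,
        tau_map=tau_map,
        fit=fit,
        labels=labels,
        segmentation=seg,
        summaries=summaries,
    )
    if cfg.output_dir is not None:
        write_artifacts(result, cfg)
    return result


def write_artifacts(result: SegmentationResult, cfg: RunConfig) -> None:
    """Write the standard artifact set of a run into cfg.output_dir."""
    import numpy as np
    import pandas as pd

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    export_tau_map(result.tau_map, out / "tau_map.csv")
    export_tau_map(result.tau_map, out / "tau_map.tif")
    pd.DataFrame(
        {
            "row": result.cloud.pixels[:, 0],
            "col": result.cloud.pixels[:, 1],
            "g": result.cloud.g,
            "s": result.cloud.s,
            "cluster": result.labels,
        }
    ).to_csv(out / "phasors.csv", index=False)
    save_fit_report(result.fit, out / "fit_report.txt")
    summaries_to_frame(result.summaries).to_csv(out / "cluster_summary.csv", index=False)
    t_min, t_max = cfg.tau_color_range
    save_image(render_tau_map(result.tau_map, t_min, t_max), out / "tau_map.png")
    save_image(render_cluster_map(result.segmentation), out / "cluster_map.png")
    save_image(
        render_probability_blend(
            result.cloud, result.fit, result.segmentation.shape
        ),
        out / "probability_blend.png",
    )
    # Raw label mask as single-channel 8-bit PNG.
    from PIL import Image

    Image.fromarray(result.segmentation.labels.astype(np.uint8), mode="L").save(
        out / "labels.png"
    )
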