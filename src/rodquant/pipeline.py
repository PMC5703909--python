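"""Convenience pipelines tying the stages together for population studies.

A "population" here is a set of independently simulated (or acquired)
fields analyzed with shared parameters; large synthetic populations are
generated as several moderate tiles rather than one huge field so that
non-overlap placement stays cheap.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .foci import DetectionParams, compute_segregation_metrics, detect_foci, population_metrics
from .geometry import extract_geometry
from .simulate import SimConfig, simulate_field

__all__ = ["simulate_tiles", "measure_segregation", "evaluate_detection"]


def simulate_tiles(base_cfg: SimConfig, n_tiles: int):
    """Simulate ``n_tiles`` independent fields, seeded base_cfg.seed + i."""
    out = []
    for i in range(n_tiles):
        cfg = replace(base_cfg, seed=base_cfg.seed + i, channels=list(base_cfg.channels))
        out.append((cfg,) + simulate_field(cfg))
    return out


def measure_segregation(
    channels: np.ndarray,
    labels: np.ndarray,
    cfg: SimConfig,
    channel_name: str,
    params: DetectionParams | None = None,
):
    """Detect foci on one field and compute per-cell segregation metrics.

    Returns ``(geometries, foci, metrics)`` where metrics is one
    :class:`SegregationMetrics` per segmented cell.
    """
    names = [c.name for c in cfg.channels]
    img = channels[names.index(channel_name)]
    geoms = extract_geometry(labels, cfg.pixel_size)
    if params is None:
        params = DetectionParams(psf_sigma=cfg.psf_sigma)
    foci = detect_foci(img, labels, geoms, params, channel=channel_name)
    by_cell: dict[int, list] = {}
    for f in foci:
        by_cell.setdefault(f.cell_id, []).append(f)
    metrics = [compute_segregation_metrics(by_cell.get(g.cell_id, []), g) for g in geoms]
    return geoms, foci, metrics


def segregation_table(tiles, channel_name: str, params: DetectionParams | None = None):
    """Metrics table over several simulated tiles, with unique cell ids."""
    frames = []
    offset = 0
    for cfg, truths, channels, labels in tiles:
        _, _, metrics = measure_segregation(channels, labels, cfg, channel_name, params)
        df, _ = population_metrics(metrics)
        df["cell_id"] = df["cell_id"] + offset
        offset += int(labels.max())
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def evaluate_detection(truths, geoms, foci, channel_name: str, match_radius_px: float = 2.6):
    """Recall, precision, and axial RMSE of detected foci against truth.

    Detected foci are matched greedily (nearest first) to true focus
    positions of the same cell within ``match_radius_px``; each truth
    matches at most one detection.  Axial error is measured along the
    cell axis in pixels.
    """
    geo_by_id = {g.cell_id: g for g in geoms}
    det_by_cell: dict[int, list] = {}
    for f in foci:
        det_by_cell.setdefault(f.cell_id, []).append(f)
    n_true = 0
    n_det = len(foci)
    matched = 0
    sq_axial = []
    for t in truths:
        true_xy = t.focus_xy(channel_name)
        n_true += len(true_xy)
        dets = det_by_cell.get(t.cell_id, [])
        if len(true_xy) == 0 or not dets or t.cell_id not in geo_by_id:
            continue
        g = geo_by_id[t.cell_id]
        pairs = []
        for di, f in enumerate(dets):
            for ti, (r, c) in enumerate(true_xy):
                d = float(np.hypot(f.center[0] - r, f.center[1] - c))
                if d <= match_radius_px:
                    pairs.append((d, di, ti))
        used_d, used_t = set(), set()
        for d, di, ti in sorted(pairs):
            if di in used_d or ti in used_t:
                continue
            used_d.add(di)
            used_t.add(ti)
            matched += 1
            s_true = t.focus_positions[channel_name][ti]
            sq_axial.append(((dets[di].s - s_true) * g.length_px) ** 2)
    return {
        "n_true": n_true,
        "n_detected": n_det,
        "recall": matched / n_true if n_true else float("nan"),
        "precision": matched / n_det if n_det else float("nan"),
        "axial_rmse_px": float(np.sqrt(np.mean(sq_axial))) if sq_axial else float("nan"),
    }
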