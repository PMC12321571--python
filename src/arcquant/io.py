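"""Readers and writers for the pipeline's on-disk formats.

Cell maps, section series, contours, polylines and result tables travel as
tidy CSV; probe stacks and ROI label images as multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .morphometry import ContourSet, SectionSeries
from .neighborhood import AggregateDecision, InteractionResult, StreamPath

CELLMAP_COLUMNS = ["cell_id", "image_id", "x", "y", "type"]


def write_cell_map(cells: pd.DataFrame, path) -> None:
    cells[CELLMAP_COLUMNS].to_csv(path, index=False)


def read_cell_map(path) -> pd.DataFrame:
    cells = pd.read_csv(path)
    missing = set(CELLMAP_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"cell map CSV lacks columns: {sorted(missing)}")
    return cells


def write_probe_stack(stack: np.ndarray, path) -> None:
    # one grayscale page per gene channel
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def read_probe_stack(path) -> np.ndarray:
    arr = tifffile.imread(path)
    return arr[None] if arr.ndim == 2 else arr


def write_roi_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.int32))


def read_roi_labels(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int64)


def write_gene_manifest(genes: Sequence[str], path) -> None:
    pd.DataFrame({"gene": list(genes)}).to_csv(path, index=False)


def read_gene_manifest(path) -> list[str]:
    return pd.read_csv(path)["gene"].astype(str).tolist()


def write_section_series(series: SectionSeries, path) -> None:
    spacing = np.concatenate([[np.nan], series.spacing])  # gap before section k
    pd.DataFrame({
        "section_index": np.arange(1, series.n + 1),
        "area": series.areas,
        "spacing": spacing,
    }).to_csv(path, index=False)


def read_section_series(path) -> SectionSeries:
    df = pd.read_csv(path).sort_values("section_index")
    return SectionSeries(df["area"].to_numpy(),
                         df["spacing"].to_numpy()[1:])


def write_contours(contours: ContourSet, path) -> None:
    frames = []
    for name, poly in (("full", contours.full), ("outer", contours.outer)):
        if poly is None:
            continue
        frames.append(pd.DataFrame({
            "contour": name,
            "point_index": np.arange(len(poly)),
            "x": poly[:, 0], "y": poly[:, 1],
        }))
    pd.concat(frames).to_csv(path, index=False)


def read_contours(path) -> ContourSet:
    df = pd.read_csv(path)
    polys = {
        name: g.sort_values("point_index")[["x", "y"]].to_numpy()
        for name, g in df.groupby("contour")
    }
    if "full" not in polys:
        raise ValueError("contour CSV lacks a 'full' contour")
    return ContourSet(full=polys["full"], outer=polys.get("outer"))


def read_stream_path(path) -> StreamPath:
    df = pd.read_csv(path)
    return StreamPath(df[["x", "y"]].to_numpy())


def interaction_results_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["type_a"], d["type_b"] = d.pop("pair")
        rows.append(d)
    return pd.DataFrame(rows)


def aggregate_decisions_frame(decisions: Sequence[AggregateDecision]) -> pd.DataFrame:
    rows = []
    for d in decisions:
        row = asdict(d)
        row["type_a"], row["type_b"] = row.pop("pair")
        rows.append(row)
    return pd.DataFrame(rows)
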