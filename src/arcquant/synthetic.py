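"""Ground-truth generators for every stage of the pipeline.

Emulates, with planted and exactly known truth: (a) per-cell probe signal —
each cell type expresses each gene with a stated probe-pixel probability on
top of background speckle; (b) 2-D cell maps under complete spatial
randomness (CSR) or with planted spatial attraction/avoidance between
types (Neyman-Scott parent-offspring clustering); (c) analytic solids
sliced into serial sections for the volume estimator; (d) closed cortical
contours with controllable sinusoidal folding for the gyrification index.

Coordinates are 0-based pixel indices, origin top-left, y downward; all
generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .morphometry import ContourSet, SectionSeries

__all__ = [
    "SolidSpec",
    "InteractionSpec",
    "ExpressionModel",
    "ARC_GENE_PANEL",
    "arc_expression_model",
    "generate_section_profile",
    "generate_contour",
    "generate_cell_map",
    "generate_probe_images",
    "generate_region_masks",
    "generate_subtype_benchmark",
]


# ---------------------------------------------------------------------------
# Solids and contours
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolidSpec:
    """An analytic solid to be sliced into evenly spaced serial sections.

    Shapes: ``cylinder`` (radius, height), ``cone`` (base radius, height;
    sectioned apex-first), ``sphere`` (radius; sectioned pole-first), and
    ``frustum_stack`` (radii at evenly spaced knots spanning ``height``;
    sections are taken exactly at the knots, where the frustum volume
    formula is exact).  Lengths in mm.
    """

    shape: str
    n_sections: int | None = None
    spacing: float | None = None
    radius: float | None = None
    height: float | None = None
    radii: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.shape not in ("cylinder", "cone", "sphere", "frustum_stack"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.shape == "frustum_stack":
            if self.radii is None or len(self.radii) < 2:
                raise ValueError("frustum_stack needs >= 2 knot radii")
            if self.height is None or self.height <= 0:
                raise ValueError("frustum_stack needs a positive height")
            if any(r < 0 for r in self.radii):
                raise ValueError("radii must be non-negative")
            return
        if self.radius is None or self.radius <= 0:
            raise ValueError(f"{self.shape} needs a positive radius")
        if self.n_sections is None or self.n_sections < 2:
            raise ValueError("need at least 2 sections")
        if self.spacing is None or self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.shape in ("cylinder", "cone"):
            if self.height is None or self.height <= 0:
                raise ValueError(f"{self.shape} needs a positive height")


def generate_section_profile(solid: SolidSpec) -> SectionSeries:
    """Analytic cross-section areas at evenly spaced cutting planes.

    Sections start at one end of the solid (apex for a cone, pole for a
    sphere) and advance by ``spacing``; the sampled span must not exceed
    the solid's extent.  Cross-sections are exact closed forms:
    pi r^2 for cylinders, pi (r z / H)^2 for cones, pi (r^2 - (z - r)^2)
    for spheres.
    """
    if solid.shape == "frustum_stack":
        radii = np.asarray(solid.radii, dtype=float)
        spacing = solid.height / (radii.size - 1)
        return SectionSeries(np.pi * radii**2, spacing)

    n, h = solid.n_sections, solid.spacing
    span = h * (n - 1)
    z = h * np.arange(n)
    if solid.shape == "cylinder":
        if span > solid.height + 1e-12:
            raise ValueError("sections extend past the cylinder height")
        areas = np.full(n, np.pi * solid.radius**2)
    elif solid.shape == "cone":
        if span > solid.height + 1e-12:
            raise ValueError("sections extend past the cone height")
        areas = np.pi * (solid.radius * z / solid.height) ** 2
    else:  # sphere, sectioned from a pole
        if span > 2 * solid.radius + 1e-12:
            raise ValueError("sections extend past the sphere diameter")
        areas = np.pi * np.maximum(solid.radius**2 - (z - solid.radius) ** 2, 0.0)
    return SectionSeries(areas, h)


def generate_contour(
    base_radius: float,
    fold_amplitude: float,
    fold_frequency: int,
    n_points: int = 512,
) -> ContourSet:
    """Closed folded contour r(theta) = R + a sin(k theta), plus envelope.

    The outer envelope is the circle of radius R + a through the gyral
    crests.  Ground-truth lengths by adaptive quadrature of
    sqrt(r^2 + r'^2) are attached for validation.  Requires a < R (the
    radial profile then stays positive, so the curve cannot
    self-intersect) and at least 64 sample points.
    """
    R, a, k = float(base_radius), float(fold_amplitude), int(fold_frequency)
    if R <= 0:
        raise ValueError("base radius must be positive")
    if a < 0 or a >= R:
        raise ValueError("fold amplitude must satisfy 0 <= a < R "
                         "(larger amplitudes self-intersect)")
    if n_points < 64:
        raise ValueError("need at least 64 contour points")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = R + a * np.sin(k * theta)
    full = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    r_out = R + a
    outer = np.column_stack([r_out * np.cos(theta), r_out * np.sin(theta)])

    def speed(t):
        rr = R + a * np.sin(k * t)
        dr = a * k * np.cos(k * t)
        return np.sqrt(rr * rr + dr * dr)

    full_len, _ = quad(speed, 0.0, 2.0 * np.pi, limit=200 + 50 * max(k, 1))
    return ContourSet(full=full, outer=outer,
                      full_length_true=float(full_len),
                      outer_length_true=float(2.0 * np.pi * r_out))


# ---------------------------------------------------------------------------
# Cell maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionSpec:
    """Planted spatial interaction structure between cell types.

    ``modes`` maps an ordered type pair to one of ``csr`` (uniform,
    independent), ``attract`` or ``avoid``.  A homotypic pair ("A", "A")
    set to ``attract`` places that type as a Neyman-Scott cluster process
    (Poisson parents of intensity ``cluster_parent_rate`` per px^2, or
    ``n_type / mean_offspring`` parents when the rate is omitted, with
    isotropic Gaussian offspring of s.d. ``cluster_sd`` px).  A heterotypic
    ``attract`` pair scatters B around the already placed A cells; ``avoid``
    resamples B points falling within ``cluster_sd`` of any A cell.
    Unlisted pairs default to CSR.
    """

    modes: Mapping[tuple[str, str], str] = field(default_factory=dict)
    cluster_parent_rate: float | None = None
    cluster_sd: float = 2.0
    mean_offspring: float | None = 10.0

    def __post_init__(self):
        for pair, mode in self.modes.items():
            if mode not in ("csr", "attract", "avoid"):
                raise ValueError(f"unknown interaction mode {mode!r} for {pair}")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be positive")
        if self.cluster_parent_rate is not None and self.cluster_parent_rate <= 0:
            raise ValueError("cluster_parent_rate must be positive")
        if self.mean_offspring is not None and self.mean_offspring <= 0:
            raise ValueError("mean_offspring must be positive")
        clustered = any(m != "csr" for m in self.modes.values())
        if clustered and self.cluster_parent_rate is None and self.mean_offspring is None:
            raise ValueError("attract/avoid modes need cluster parameters")

    def mode_of(self, a: str, b: str) -> str:
        return self.modes.get((a, b), "csr")


def _neyman_scott(
    rng: np.random.Generator,
    n_pts: int,
    parents: np.ndarray | None,
    spec: InteractionSpec,
    size: tuple[int, int],
) -> np.ndarray:
    """Offspring positions around parents, wrapped onto the image torus."""
    h, w = size
    if parents is None:
        if spec.cluster_parent_rate is not None:
            n_par = max(1, int(rng.poisson(spec.cluster_parent_rate * h * w)))
        else:
            n_par = max(1, int(round(n_pts / spec.mean_offspring)))
        parents = np.column_stack([rng.uniform(0, w, n_par),
                                   rng.uniform(0, h, n_par)])
    assign = rng.integers(0, parents.shape[0], n_pts)
    pts = parents[assign] + rng.normal(0.0, spec.cluster_sd, (n_pts, 2))
    pts[:, 0] %= w
    pts[:, 1] %= h
    return pts


def generate_cell_map(
    n_cells: int,
    type_proportions: Mapping[str, float],
    interaction: InteractionSpec | None = None,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
    image_id: object = 0,
    border_margin: float = 0.0,
) -> pd.DataFrame:
    """Simulate a 2-D cell map with planted spatial structure.

    Returns a table with columns cell_id, image_id, x, y, type.  Type
    counts are multinomial in ``type_proportions``; under CSR every type is
    uniform and independent (the exchangeable null of the permutation
    test), while ``attract``/``avoid`` modes plant the requested structure.
    ``border_margin`` shrinks the placement window on every side (so that
    downstream ROI disks fit inside the image).  Deterministic given
    ``seed``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    names = list(type_proportions)
    p = np.array([type_proportions[t] for t in names], dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("type proportions must be non-negative and sum to 1")
    h, w = image_size
    if h <= 0 or w <= 0:
        raise ValueError("image size must be positive")
    m = float(border_margin)
    if m < 0 or 2 * m >= min(h, w):
        raise ValueError("border margin must be non-negative and leave room")
    spec = interaction or InteractionSpec()

    def uniform(rng, n):
        return np.column_stack([rng.uniform(m, w - m, n),
                                rng.uniform(m, h - m, n)])

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_cells, p)
    placed: dict[str, np.ndarray] = {}
    for t, n_t in zip(names, counts):
        if n_t == 0:
            placed[t] = np.empty((0, 2))
            continue
        if spec.mode_of(t, t) == "attract":
            placed[t] = _neyman_scott(rng, n_t, None, spec, (h, w))
            continue
        hetero = [s for s in names if s != t
                  and spec.mode_of(s, t) != "csr" and s in placed]
        if hetero and spec.mode_of(hetero[0], t) == "attract":
            placed[t] = _neyman_scott(rng, n_t, placed[hetero[0]], spec, (h, w))
        elif hetero and spec.mode_of(hetero[0], t) == "avoid":
            other = placed[hetero[0]]
            pts = uniform(rng, n_t)
            for _ in range(200):
                if other.size == 0:
                    break
                d = np.min(np.linalg.norm(
                    pts[:, None, :] - other[None, :, :], axis=2), axis=1)
                bad = d < spec.cluster_sd
                if not bad.any():
                    break
                pts[bad] = uniform(rng, int(bad.sum()))
            placed[t] = pts
        else:
            placed[t] = uniform(rng, n_t)

    xs = np.concatenate([placed[t][:, 0] for t in names])
    ys = np.concatenate([placed[t][:, 1] for t in names])
    types = np.concatenate([[t] * len(placed[t]) for t in names])
    return pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),  # positive ids double as ROI labels
        "image_id": image_id,
        "x": xs, "y": ys, "type": types,
    })


# ---------------------------------------------------------------------------
# Probe images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionModel:
    """Per-(cell type, gene) probe-pixel probabilities plus background.

    ``probabilities`` is a types x genes table of Bernoulli probabilities
    that a pixel inside a cell's ROI carries probe signal for that gene;
    ``speckle_rate`` is the per-pixel background positive rate outside any
    ROI; ROIs are disks of ``roi_radius`` pixels at the cell centroids.
    """

    probabilities: pd.DataFrame
    speckle_rate: float = 0.0
    roi_radius: float = 3.0
    signal_level: int = 255

    def __post_init__(self):
        v = self.probabilities.to_numpy(dtype=float)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("probe probabilities must lie in [0, 1]")
        if not 0 <= self.speckle_rate <= 1:
            raise ValueError("speckle rate must lie in [0, 1]")
        if self.roi_radius <= 0:
            raise ValueError("roi_radius must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.probabilities.columns)

    @property
    def cell_types(self) -> list[str]:
        return list(self.probabilities.index)


def roi_label_image(
    cells: pd.DataFrame,
    roi_radius: float,
    image_size: tuple[int, int],
) -> np.ndarray:
    """Disk ROIs at cell centroids, overlaps resolved by nearest centroid.

    Each pixel within ``roi_radius`` of at least one centroid is labelled
    with the cell_id of the nearest centroid (lowest cell_id on exact
    ties), giving an unambiguous partition for pixel-count oracles.
    """
    h, w = image_size
    r = float(roi_radius)
    labels = np.zeros((h, w), dtype=np.int32)
    bestd = np.full((h, w), np.inf)
    ri = int(np.ceil(r))
    for row in cells.sort_values("cell_id").itertuples():
        cx, cy = float(row.x), float(row.y)
        if cx - r < -0.5 or cy - r < -0.5 or cx + r > w - 0.5 or cy + r > h - 0.5:
            raise ValueError(f"ROI of cell {row.cell_id} does not fit the image")
        x0, x1 = int(np.floor(cx - ri)), int(np.ceil(cx + ri)) + 1
        y0, y1 = int(np.floor(cy - ri)), int(np.ceil(cy + ri)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, w), min(y1, h)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d = np.hypot(xx - cx, yy - cy)
        take = (d <= r) & (d < bestd[y0:y1, x0:x1])
        labels[y0:y1, x0:x1][take] = int(row.cell_id)
        bestd[y0:y1, x0:x1][take] = d[take]
    return labels


def generate_probe_images(
    cells: pd.DataFrame,
    model: ExpressionModel,
    image_size: tuple[int, int] = (256, 256),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate a probe-channel stack with exactly known expression truth.

    Returns ``(stack, roi_labels, truth)``: a (genes, h, w) uint8 stack
    (signal pixels at ``signal_level``, background 0), the ROI label image,
    and the realised ground-truth pixel-percentage table (cells x genes) —
    the value the quantification pipeline must reproduce when speckle and
    the small-object filter are off.
    """
    missing = set(cells["type"]) - set(model.cell_types)
    if missing:
        raise ValueError(f"cell types absent from the expression model: "
                         f"{sorted(missing)}")
    if cells["cell_id"].min() < 1:
        raise ValueError("cell ids must be positive (they double as ROI labels)")
    labels = roi_label_image(cells, model.roi_radius, image_size)
    flat = labels.ravel()
    order = cells.sort_values("cell_id")
    cell_ids = order["cell_id"].to_numpy()
    cell_types = order["type"].to_numpy()
    roi_idx = [np.flatnonzero(flat == cid) for cid in cell_ids]
    if any(ix.size == 0 for ix in roi_idx):
        raise ValueError("a cell lost all its ROI pixels to nearer neighbors")
    bg_idx = np.flatnonzero(flat == 0)

    rng = np.random.default_rng(seed)
    h, w = image_size
    genes = model.genes
    stack = np.zeros((len(genes), h, w), dtype=np.uint8)
    truth = np.zeros((len(cell_ids), len(genes)))
    for j, gene in enumerate(genes):
        page = stack[j].ravel()
        for i, (cid, ctype) in enumerate(zip(cell_ids, cell_types)):
            prob = float(model.probabilities.at[ctype, gene])
            hits = rng.random(roi_idx[i].size) < prob
            page[roi_idx[i][hits]] = model.signal_level
            truth[i, j] = 100.0 * hits.sum() / roi_idx[i].size
        if model.speckle_rate > 0 and bg_idx.size:
            hits = rng.random(bg_idx.size) < model.speckle_rate
            page[bg_idx[hits]] = model.signal_level
    truth_df = pd.DataFrame(truth, index=pd.Index(cell_ids, name="cell_id"),
                            columns=genes)
    return stack, labels, truth_df


# ---------------------------------------------------------------------------
# Region masks
# ---------------------------------------------------------------------------

def generate_region_masks(
    areas: Sequence[int],
    image_size: tuple[int, int],
) -> np.ndarray:
    """Non-overlapping labelled rectangles with exact pixel counts.

    Region ``i`` (label ``i + 1``) is a rectangle of exactly ``areas[i]``
    pixels; regions are stacked top to bottom, each on its own rows, with
    the widest rectangle (width a divisor of the area, at most the image
    width) chosen per region.  Requests that cannot be packed this way are
    rejected.
    """
    h, w = image_size
    areas = [int(a) for a in areas]
    if any(a <= 0 for a in areas):
        raise ValueError("areas must be positive pixel counts")
    if sum(areas) > h * w:
        raise ValueError("total requested area exceeds the image area")
    mask = np.zeros((h, w), dtype=np.int32)
    row = 0
    for i, a in enumerate(areas):
        width = next((cand for cand in range(min(a, w), 0, -1)
                      if a % cand == 0 and a // cand <= h - row), None)
        if width is None:
            raise ValueError(f"cannot pack region of {a} px as a rectangle "
                             f"within the remaining {h - row} rows")
        height = a // width
        mask[row:row + height, :width] = i + 1
        row += height
    return mask


# ---------------------------------------------------------------------------
# Planted subtype benchmark
# ---------------------------------------------------------------------------

#: 32-gene probe panel covering inhibitory identity and migration markers
#: (ganglionic-eminence transcription factors, mature interneuron markers,
#: migration receptors and pan-neuroblast genes).
ARC_GENE_PANEL: tuple[str, ...] = (
    "DCX", "GAD1", "GAD2", "DLX2", "DLX5", "SOX11",
    "NKX2.1", "MAF1", "LHX6", "SST", "MEF2C", "CRABP1",
    "COUP-TFII", "SP8", "TBR1", "CALB2", "VIP", "PROX1", "SCGN", "PAX6",
    "SATB2", "CNR1", "RELN", "CCK",
    "VLDLR", "LRP8", "CXCR4", "CXCR7",
    "FOXP2", "MEIS2", "TSHZ1", "ADARB2",
)

#: Probe-pixel probabilities above background for each planted subtype:
#: the two defining markers are strong, lineage/migration co-markers
#: moderate.  Background probability applies to every unlisted gene.
_SUBTYPE_MARKER_PROBS: dict[str, dict[str, float]] = {
    "NKX2.1+MAF1+": {"NKX2.1": 0.6, "MAF1": 0.6, "GAD1": 0.45, "GAD2": 0.35,
                     "DLX2": 0.3, "VLDLR": 0.4, "CXCR7": 0.3, "DCX": 0.7},
    "SST+LHX6+": {"SST": 0.6, "LHX6": 0.6, "GAD1": 0.45, "GAD2": 0.35,
                  "MEF2C": 0.3, "CXCR4": 0.4, "DCX": 0.7},
    "COUP-TFII+SP8+": {"COUP-TFII": 0.6, "SP8": 0.6, "GAD1": 0.45,
                       "PROX1": 0.3, "SCGN": 0.3, "VLDLR": 0.4,
                       "CXCR7": 0.3, "DCX": 0.7},
    "COUP-TFII+TBR1+": {"COUP-TFII": 0.6, "TBR1": 0.6, "GAD1": 0.45,
                        "LRP8": 0.4, "DCX": 0.7},
    "COUP-TFII+CALB2+": {"COUP-TFII": 0.6, "CALB2": 0.6, "GAD1": 0.45,
                         "PROX1": 0.3, "RELN": 0.25, "DCX": 0.7},
    "VIP+GAD1+": {"VIP": 0.6, "GAD1": 0.6, "GAD2": 0.4, "CALB2": 0.25,
                  "CXCR4": 0.4, "CCK": 0.3, "DCX": 0.7},
    "SATB2+ (EN)": {"SATB2": 0.6, "SOX11": 0.35, "DCX": 0.5},
}

#: Planted composition: the six inhibitory subtypes carry 13% of cells
#: each (78% combined), the excitatory SATB2+ population the rest.
SUBTYPE_PROPORTIONS: dict[str, float] = {
    name: 0.13 for name in _SUBTYPE_MARKER_PROBS if name != "SATB2+ (EN)"
}
SUBTYPE_PROPORTIONS["SATB2+ (EN)"] = 1.0 - sum(SUBTYPE_PROPORTIONS.values())


def arc_expression_model(
    background_p: float = 0.05,
    speckle_rate: float = 0.001,
    roi_radius: float = 3.0,
) -> ExpressionModel:
    """Expression model for the 32-gene panel over the planted subtypes.

    Marker probabilities follow ``_SUBTYPE_MARKER_PROBS``; every other
    (type, gene) combination expresses at ``background_p``.
    """
    probs = pd.DataFrame(background_p, index=list(_SUBTYPE_MARKER_PROBS),
                         columns=list(ARC_GENE_PANEL), dtype=float)
    for ctype, markers in _SUBTYPE_MARKER_PROBS.items():
        for gene, p in markers.items():
            probs.at[ctype, gene] = p
    return ExpressionModel(probs, speckle_rate=speckle_rate,
                           roi_radius=roi_radius)


def generate_subtype_benchmark(
    n_cells: int = 700,
    image_size: tuple[int, int] = (384, 384),
    seed: int = 0,
    model: ExpressionModel | None = None,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame, ExpressionModel]:
    """End-to-end fixture: planted subtypes -> probe stack -> known truth.

    Places ``n_cells`` under CSR with the planted subtype composition,
    simulates the 32-gene probe stack, and returns
    ``(cells, stack, roi_labels, truth, model)``, where each cell's planted
    subtype is the ``type`` column of ``cells``.
    """
    model = model or arc_expression_model()
    cells = generate_cell_map(
        n_cells, SUBTYPE_PROPORTIONS, image_size=image_size, seed=seed,
        border_margin=model.roi_radius + 1.0)
    stack, labels, truth = generate_probe_images(
        cells, model, image_size, seed=seed + 1)
    return cells, stack, labels, truth, model
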