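"""Per-cell quantification of multiplexed smFISH probe channels.

Pipeline: each probe channel is binarised with a Renyi-entropy automatic
threshold, small foreground specks are removed, and each cell's expression
value is the percentage of its ROI pixels covered by probe signal
("pixel-percentage expression", in [0, 100]).  Per gene, values at or below
the across-cell median are treated as background and zeroed; the resulting
matrix is log-transformed, scaled, reduced with PCA (all components kept),
clustered with the Leiden algorithm and embedded in 2-D, and clusters are
assigned to interneuron subtypes from marker-gene rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import remove_small_objects

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "SubtypeRules",
    "DEFAULT_SUBTYPE_RULES",
    "renyi_threshold",
    "renyi_bin_threshold",
    "quantify_cell",
    "build_expression_matrix",
    "median_zero",
    "normalize_cluster_embed",
    "assign_subtypes",
]

#: Renyi orders evaluated by the reference auto-threshold dialect:
#: alpha = 1/2, the Shannon limit alpha -> 1, and alpha = 2.
DEFAULT_ALPHA_SET: tuple[float, ...] = (0.5, 1.0, 2.0)


# ---------------------------------------------------------------------------
# Expression containers
# ---------------------------------------------------------------------------

_STAGES = ("raw", "median_zeroed", "normalized")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Cells x genes matrix of pixel-percentage expression values.

    ``stage`` records provenance: ``raw`` straight from quantification,
    ``median_zeroed`` after per-gene background zeroing, ``normalized``
    after log/scale transforms (at which point values leave [0, 100]).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"stage must be one of {_STAGES}")
        df = self.data
        if not isinstance(df, pd.DataFrame):
            df = pd.DataFrame(df)
            object.__setattr__(self, "data", df)
        if df.columns.duplicated().any():
            raise ValueError("duplicated gene names")
        if self.stage in ("raw", "median_zeroed"):
            v = df.to_numpy(dtype=float)
            if np.any(v < 0) or np.any(v > 100):
                raise ValueError(f"{self.stage} values must lie in [0, 100]")

    @property
    def cells(self) -> pd.Index:
        return self.data.index

    @property
    def genes(self) -> pd.Index:
        return self.data.columns

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="cell_id")

    def to_mtx(self, prefix) -> None:
        """Write sparse matrix-market plus row/column name sidecars."""
        from pathlib import Path

        from scipy import io as sio
        from scipy import sparse

        prefix = Path(prefix)
        sio.mmwrite(str(prefix.with_suffix(".mtx")),
                    sparse.csr_matrix(self.data.to_numpy(dtype=float)))
        prefix.with_suffix(".cells.txt").write_text(
            "\n".join(map(str, self.cells)) + "\n")
        prefix.with_suffix(".genes.txt").write_text(
            "\n".join(map(str, self.genes)) + "\n")


@dataclass(frozen=True)
class ClusterResult:
    """Leiden cluster labels with a 2-D embedding, reproducible by seed."""

    labels: pd.Series
    embedding: pd.DataFrame | None
    resolution: float
    seed: int


@dataclass(frozen=True)
class SubtypeRules:
    """Ordered marker-gene requirements defining each cell subtype."""

    rules: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("empty subtype rules")
        norm = tuple((name, tuple(markers)) for name, markers in self.rules)
        if any(not markers for _, markers in norm):
            raise ValueError("every subtype needs at least one marker gene")
        object.__setattr__(self, "rules", norm)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rules]

    def required_genes(self) -> set[str]:
        return {g for _, markers in self.rules for g in markers}


#: Six inhibitory subtypes of the postnatal migratory streams plus the
#: SATB2+ excitatory population.  MGE-derived: NKX2.1/MAF1 and SST/LHX6;
#: CGE-derived: the COUP-TFII (NR2F2) combinations and VIP/GAD1.
DEFAULT_SUBTYPE_RULES = SubtypeRules((
    ("NKX2.1+MAF1+", ("NKX2.1", "MAF1")),
    ("SST+LHX6+", ("SST", "LHX6")),
    ("COUP-TFII+SP8+", ("COUP-TFII", "SP8")),
    ("COUP-TFII+TBR1+", ("COUP-TFII", "TBR1")),
    ("COUP-TFII+CALB2+", ("COUP-TFII", "CALB2")),
    ("VIP+GAD1+", ("VIP", "GAD1")),
    ("SATB2+ (EN)", ("SATB2",)),
))

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# Renyi-entropy automatic thresholding
# ---------------------------------------------------------------------------

def _renyi_objective_curves(p: np.ndarray, alpha: float) -> np.ndarray:
    """Combined below/above Renyi entropy for every candidate threshold bin.

    For candidate bin t the histogram is split into [0, t] and (t, end];
    each side is renormalised and its Renyi entropy of order alpha taken
    (Shannon entropy in the alpha -> 1 limit).  Invalid candidates (one
    side empty) get -inf.
    """
    P = np.cumsum(p)
    total = P[-1]
    Pa = total - P  # mass strictly above each bin
    with np.errstate(divide="ignore", invalid="ignore"):
        if alpha == 1.0:
            plogp = np.where(p > 0, p * np.log(p), 0.0)
            S = np.cumsum(plogp)
            h_below = np.log(P) - S / P
            h_above = np.log(Pa) - (S[-1] - S) / Pa
        else:
            pa = np.cumsum(p ** alpha)
            h_below = np.log(P ** -alpha * pa) / (1.0 - alpha)
            h_above = np.log(Pa ** -alpha * (pa[-1] - pa)) / (1.0 - alpha)
    obj = h_below + h_above
    obj[(P <= 0) | (Pa <= 0)] = -np.inf
    return obj


def _single_alpha_bin(p: np.ndarray, alpha: float) -> int:
    obj = _renyi_objective_curves(p, alpha)
    if not np.any(np.isfinite(obj)):
        raise ValueError("histogram has a single occupied bin; no threshold exists")
    return int(np.argmax(obj))  # first maximiser on ties


def renyi_bin_threshold(
    hist: np.ndarray,
    alpha_set: Sequence[float] = DEFAULT_ALPHA_SET,
) -> int:
    """Renyi-entropy threshold bin index for an intensity histogram.

    Each order in ``alpha_set`` contributes its own entropic threshold (the
    bin maximising the sum of below/above Renyi entropies).  With exactly
    three orders the candidates are combined by the reference dialect's
    ordering-and-weighting rule: the three thresholds are sorted, weighted
    by how close they fall to one another, and blended with the cumulative
    histogram mass

        t* = t1 (P1 + w b1 / 4) + t2 w b2 / 4 + t3 (P3' + w b3 / 4)

    where ``w`` is the mass between the extreme candidates, ``P1`` the mass
    at or below the lowest and ``P3'`` the mass above the highest, and the
    integer weights ``b`` are (1,2,1) when the candidates agree to within 5
    bins (or all disagree), and (0,1,3) / (3,1,0) when only the upper / lower
    pair agrees.  Other alpha-set sizes use the median candidate.

    Pixels in bins strictly above the returned index are foreground.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be a 1-D array of at least 2 bins")
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    alphas = [float(a) for a in alpha_set]
    if not alphas or any(a <= 0 for a in alphas):
        raise ValueError("alpha_set must contain positive orders")
    p = hist / total
    cands = sorted(_single_alpha_bin(p, a) for a in alphas)
    if len(cands) == 1:
        return cands[0]
    if len(cands) != 3:
        return cands[len(cands) // 2]
    t1, t2, t3 = cands
    if abs(t1 - t2) <= 5:
        b = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    P = np.cumsum(p)
    omega = P[t3] - P[t1]
    t_opt = (t1 * (P[t1] + 0.25 * omega * b[0])
             + 0.25 * t2 * omega * b[1]
             + t3 * ((1.0 - P[t3]) + 0.25 * omega * b[2]))
    return int(t_opt)


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    idx = (values - lo) * (n_bins / (hi - lo))
    return np.minimum(idx.astype(np.int64), n_bins - 1)


def renyi_threshold(
    image: np.ndarray,
    alpha_set: Sequence[float] = DEFAULT_ALPHA_SET,
    n_bins: int = 256,
) -> float:
    """Automatic intensity threshold by the Renyi-entropy rule.

    Intensities are binned to ``n_bins`` equal-width levels between the
    image minimum and maximum; the threshold bin is chosen by
    :func:`renyi_bin_threshold` and mapped back to intensity units as the
    midpoint between the largest sub-threshold and the smallest
    supra-threshold pixel value, so that "strictly above the threshold"
    coincides exactly with "in a foreground bin".  The returned foreground
    rule is therefore invariant to adding a constant to the image.
    """
    vals = np.asarray(image, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("empty image")
    if float(vals.min()) == float(vals.max()):
        raise ValueError("constant image: no separable intensity classes")
    idx = _bin_indices(vals, n_bins)
    t_bin = renyi_bin_threshold(np.bincount(idx, minlength=n_bins), alpha_set)
    below = vals[idx <= t_bin]
    above = vals[idx > t_bin]
    return float(below.max() + above.min()) / 2.0


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def quantify_cell(probe_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Pixel-percentage expression: probe-positive ROI pixels / ROI pixels.

    Returns ``100 * |probe AND roi| / |roi|`` in [0, 100].
    """
    probe = np.asarray(probe_mask) > 0
    roi = np.asarray(roi_mask) > 0
    if probe.shape != roi.shape:
        raise ValueError("probe and ROI masks must share a shape")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    return 100.0 * float((probe & roi).sum()) / n_roi


def _channel_foreground(
    channel: np.ndarray,
    alpha_set: Sequence[float],
    min_object_px: int,
    n_bins: int,
) -> np.ndarray:
    vals = np.asarray(channel, dtype=float)
    if float(vals.min()) == float(vals.max()):
        # No intensity structure to separate: treat as signal-free.
        logger.info("constant probe channel treated as all-background")
        return np.zeros(vals.shape, dtype=bool)
    idx = _bin_indices(vals.ravel(), n_bins).reshape(vals.shape)
    t_bin = renyi_bin_threshold(
        np.bincount(idx.ravel(), minlength=n_bins), alpha_set)
    mask = idx > t_bin
    if min_object_px > 1:
        # drop components strictly smaller than min_object_px
        mask = remove_small_objects(mask, max_size=min_object_px - 1,
                                    connectivity=2)
    return mask


def build_expression_matrix(
    probe_stack: np.ndarray,
    roi_labels: np.ndarray,
    gene_names: Sequence[str],
    min_object_px: int = 0,
    alpha_set: Sequence[float] = DEFAULT_ALPHA_SET,
    n_bins: int = 256,
) -> ExpressionMatrix:
    """Quantify every probe channel against every cell ROI.

    Each page of ``probe_stack`` is one gene's probe channel; ``roi_labels``
    encodes cell ids as positive integer labels on the same pixel grid.
    Channels are thresholded with the Renyi rule, connected foreground
    components smaller than ``min_object_px`` pixels are discarded (the
    reproducible stand-in for manual speck removal), and the per-cell
    pixel percentage is computed for each gene.
    """
    stack = np.asarray(probe_stack)
    labels = np.asarray(roi_labels)
    if stack.ndim != 3:
        raise ValueError("probe stack must be (genes, rows, cols)")
    if labels.shape != stack.shape[1:]:
        raise ValueError("ROI label image shape must match the channels")
    gene_names = list(gene_names)
    if len(gene_names) != stack.shape[0]:
        raise ValueError("one gene name per stack page required")
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("duplicated gene names")
    if not np.issubdtype(labels.dtype, np.integer) or labels.min() < 0:
        raise ValueError("ROI labels must be non-negative integers")
    cell_ids = np.unique(labels)
    cell_ids = cell_ids[cell_ids > 0]
    if cell_ids.size == 0:
        raise ValueError("ROI label image contains no cells")
    roi_sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=cell_ids)

    values = np.empty((cell_ids.size, len(gene_names)), dtype=float)
    for j in range(stack.shape[0]):
        mask = _channel_foreground(stack[j], alpha_set, min_object_px, n_bins)
        pos = ndimage.sum_labels(mask.astype(float), labels, index=cell_ids)
        values[:, j] = 100.0 * pos / roi_sizes
    df = pd.DataFrame(values, index=pd.Index(cell_ids, name="cell_id"),
                      columns=gene_names)
    return ExpressionMatrix(df, stage="raw")


def median_zero(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Zero per-gene background: keep only values strictly above the median.

    For each gene the median is taken over all cells (zeros included,
    pooled across images); entries at or below it are set to 0, entries
    strictly greater are kept unchanged.  Cells not exceeding a gene's
    median are treated as not truly expressing that gene.
    """
    if matrix.stage != "raw":
        raise ValueError("median_zero expects a raw matrix")
    df = matrix.data
    med = df.median(axis=0)
    zeroed = df.where(df.gt(med, axis=1), 0.0)
    return ExpressionMatrix(zeroed, stage="median_zeroed")


# ---------------------------------------------------------------------------
# Clustering, embedding, subtype assignment
# ---------------------------------------------------------------------------

def normalize_cluster_embed(
    matrix: ExpressionMatrix,
    resolution: float = 1.0,
    n_neighbors: int = 20,
    seed: int = 0,
    embed: bool = True,
) -> ClusterResult:
    """Log-normalise, scale, PCA (all components), Leiden cluster, embed.

    Follows the standard single-cell workflow on the pixel-percentage
    matrix: log(1 + x) on the 0-100 scale, per-gene standardisation, PCA
    retaining every available component, a k-nearest-neighbour graph,
    Leiden community detection at ``resolution``, and (optionally) a UMAP
    embedding.  Fully deterministic given ``seed``.
    """
    n_cells, n_genes = matrix.data.shape
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_cells <= n_neighbors:
        raise ValueError(
            f"n_neighbors={n_neighbors} must be smaller than the number of "
            f"cells ({n_cells}); lower n_neighbors or supply more cells")

    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(matrix.data.to_numpy(dtype=np.float64).copy())
    adata.obs_names = matrix.cells.astype(str)
    adata.var_names = matrix.genes.astype(str)
    sc.pp.log1p(adata)
    sc.pp.scale(adata)
    # zero-variance genes scale to NaN; they carry no signal
    adata.X = np.nan_to_num(adata.X, nan=0.0)
    n_comps = min(n_cells - 1, n_genes)
    sc.tl.pca(adata, n_comps=n_comps, svd_solver="full", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.pp.neighbors(adata, n_neighbors=n_neighbors, use_rep="X_pca",
                        random_state=seed)
        sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                     flavor="leidenalg")
        embedding = None
        if embed:
            sc.tl.umap(adata, random_state=seed)
            embedding = pd.DataFrame(adata.obsm["X_umap"],
                                     index=matrix.cells,
                                     columns=["umap1", "umap2"])
    labels = pd.Series(adata.obs["leiden"].astype(int).to_numpy(),
                       index=matrix.cells, name="cluster")
    return ClusterResult(labels=labels, embedding=embedding,
                         resolution=float(resolution), seed=int(seed))


def assign_subtypes(
    clusters: ClusterResult,
    matrix: ExpressionMatrix,
    rules: SubtypeRules = DEFAULT_SUBTYPE_RULES,
    margin: float = 0.1,
) -> pd.Series:
    """Label each cluster with the best-matching marker-defined subtype.

    Per gene, expression is standardised across all cells; each cluster's
    score for a subtype is the mean standardised expression of that
    subtype's required markers over the cluster's cells.  The top-scoring
    subtype is assigned when it beats the runner-up by at least ``margin``
    (z-score units); otherwise the cluster is left ``unassigned``.  Cells
    inherit their cluster's label.
    """
    missing = rules.required_genes() - set(matrix.genes)
    if missing:
        raise ValueError(f"marker genes absent from matrix: {sorted(missing)}")
    df = matrix.data
    std = df.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (df - df.mean(axis=0)) / std

    labels = clusters.labels.reindex(df.index)
    if labels.isna().any():
        raise ValueError("cluster labels do not cover every cell")
    out = pd.Series(index=df.index, dtype=object, name="subtype")
    for cluster_id, idx in labels.groupby(labels).groups.items():
        zc = z.loc[idx]
        scores = np.array([
            zc[list(markers)].to_numpy().mean()
            for _, markers in rules.rules
        ])
        order = np.argsort(scores)[::-1]
        if len(scores) == 1 or scores[order[0]] - scores[order[1]] >= margin:
            out.loc[idx] = rules.names[order[0]]
        else:
            out.loc[idx] = UNASSIGNED
    return out
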