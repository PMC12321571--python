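"""Cell-type neighborhood interaction analysis (histoCAT-style).

Within each image, cells closer than a pixel distance threshold (default
4 px, strict) are neighbors.  For an ordered type pair (A, B) the
interaction score is the mean number of B-neighbors per A-cell.  Its
significance is assessed by a one-tailed permutation test that shuffles the
type labels over the fixed cell positions; across images, a pair is kept
when it is significant (P < alpha) in at least ``sig_frac`` of the images
and both types are present in at least ``presence_frac`` of the images.

Also provides topographic mapping of cells onto a migratory-stream
polyline (normalised arc-length position plus signed perpendicular offset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "NeighborGraph",
    "InteractionResult",
    "AggregateDecision",
    "StreamPath",
    "build_neighbor_graph",
    "interaction_statistic",
    "permutation_test",
    "aggregate_images",
    "map_to_stream",
]

DEFAULT_DISTANCE_THRESHOLD = 4.0


@dataclass(frozen=True)
class NeighborGraph:
    """Per-image undirected neighbor graph under a strict distance rule.

    ``edges`` holds index pairs (i < j) into ``cell_ids``/``xy``; an edge
    exists iff the Euclidean centroid distance is strictly below
    ``distance_threshold`` pixels.
    """

    image_id: object
    cell_ids: np.ndarray
    xy: np.ndarray
    edges: np.ndarray
    distance_threshold: float

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.size)

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def directed_edges(self) -> np.ndarray:
        """Both orientations of every undirected edge, as an (2m, 2) array."""
        if self.n_edges == 0:
            return np.empty((0, 2), dtype=np.int64)
        return np.vstack([self.edges, self.edges[:, ::-1]])


@dataclass(frozen=True)
class InteractionResult:
    """Permutation-test outcome for one ordered type pair in one image."""

    image_id: object
    pair: tuple[str, str]
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    present: bool


@dataclass(frozen=True)
class AggregateDecision:
    """Cross-image keep/drop decision for one ordered type pair."""

    pair: tuple[str, str]
    frac_significant: float
    frac_present: float
    keep: bool
    alpha: float
    sig_frac: float
    presence_frac: float


@dataclass(frozen=True)
class StreamPath:
    """Ordered polyline along a migratory stream, in pixel coordinates."""

    vertices: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ValueError("path needs at least two 2-D vertices")
        seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("degenerate path: zero-length segment")
        object.__setattr__(self, "vertices", v)

    @property
    def cumulative_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])


def _cells_arrays(cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    for col in ("cell_id", "x", "y"):
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column '{col}'")
    return (cells["cell_id"].to_numpy(),
            cells[["x", "y"]].to_numpy(dtype=float))


def build_neighbor_graph(
    cells: pd.DataFrame,
    distance_threshold: float = DEFAULT_DISTANCE_THRESHOLD,
) -> NeighborGraph:
    """Neighbor graph of one image: edges strictly below the threshold.

    ``cells`` must carry columns cell_id, x, y (and a single image_id if
    present).  A pair at exactly the threshold distance is NOT connected.
    """
    if distance_threshold <= 0:
        raise ValueError("distance threshold must be positive")
    if "image_id" in cells.columns and cells["image_id"].nunique() > 1:
        raise ValueError("cells from several images; build one graph per image")
    image_id = cells["image_id"].iloc[0] if "image_id" in cells.columns else None
    ids, xy = _cells_arrays(cells)
    pairs = cKDTree(xy).query_pairs(r=distance_threshold, output_type="ndarray")
    if pairs.size:
        d2 = np.sum((xy[pairs[:, 0]] - xy[pairs[:, 1]]) ** 2, axis=1)
        pairs = pairs[d2 < distance_threshold**2]  # strict inequality
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    return NeighborGraph(image_id=image_id, cell_ids=ids, xy=xy,
                         edges=pairs, distance_threshold=float(distance_threshold))


def _align_labels(graph: NeighborGraph, labels) -> np.ndarray:
    """Per-node type labels in graph order, from a Series keyed by cell_id
    or a positional sequence."""
    if isinstance(labels, pd.Series):
        aligned = labels.reindex(graph.cell_ids)
        if aligned.isna().any():
            raise ValueError("labels do not cover every cell in the graph")
        return aligned.to_numpy()
    arr = np.asarray(labels)
    if arr.shape[0] != graph.n_cells:
        raise ValueError("labels must cover all nodes")
    return arr


def _neighbor_count_operator(graph: NeighborGraph) -> sparse.csr_matrix:
    """Sparse (n, 2m) incidence operator: row i sums over directed edges
    leaving node i, so counts-of-type = operator @ indicator(edge targets)."""
    de = graph.directed_edges()
    n, m2 = graph.n_cells, de.shape[0]
    if m2 == 0:
        return sparse.csr_matrix((n, 0))
    return sparse.csr_matrix(
        (np.ones(m2), (de[:, 0], np.arange(m2))), shape=(n, m2))


def _pair_statistic(
    labels: np.ndarray, counts_b: np.ndarray, a: object
) -> np.ndarray:
    """Mean B-neighbor count over A-cells, for stacked label rows."""
    is_a = labels == a
    n_a = is_a.sum(axis=-1)
    with np.errstate(invalid="ignore"):
        return np.where(is_a, counts_b, 0.0).sum(axis=-1) / n_a


def interaction_statistic(
    graph: NeighborGraph,
    labels,
    pair: tuple[str, str],
    all_types: Iterable | None = None,
) -> float:
    """Observed interaction score: mean B-neighbors per A-cell.

    Homotypic pairs (A == B) count same-type contacts.  If either type has
    no cell in the image the score is undefined and ``nan`` is returned
    (the pair is "not present"); a type name outside the declared universe
    raises instead.
    """
    lab = _align_labels(graph, labels)
    a, b = pair
    universe = set(all_types) if all_types is not None else set(np.unique(lab))
    for t in (a, b):
        if t not in universe:
            raise ValueError(f"unknown type name: {t!r}")
    if not np.any(lab == a) or not np.any(lab == b):
        return float("nan")
    de = graph.directed_edges()
    counts_b = np.zeros(graph.n_cells)
    if de.shape[0]:
        np.add.at(counts_b, de[:, 0], (lab[de[:, 1]] == b).astype(float))
    return float(_pair_statistic(lab[None, :], counts_b[None, :], a)[0])


def permutation_test(
    graph: NeighborGraph,
    labels,
    pair: tuple[str, str],
    n_permutations: int = 1000,
    seed: int = 0,
    tail: str = "enrichment",
    all_types: Iterable | None = None,
) -> InteractionResult:
    """One-tailed label-permutation test of the interaction score.

    Cell positions (hence the graph) stay fixed; type labels are permuted
    over the nodes, preserving composition.  The add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_permutations)`` (``<=`` for the
    avoidance tail) is valid under exchangeability and never returns 0.
    If either type is absent the pair is reported as not present, untested.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if tail not in ("enrichment", "avoidance"):
        raise ValueError("tail must be 'enrichment' or 'avoidance'")
    lab = _align_labels(graph, labels)
    a, b = pair
    universe = set(all_types) if all_types is not None else set(np.unique(lab))
    for t in (a, b):
        if t not in universe:
            raise ValueError(f"unknown type name: {t!r}")
    if not np.any(lab == a) or not np.any(lab == b):
        return InteractionResult(graph.image_id, (a, b), float("nan"),
                                 float("nan"), float("nan"), float("nan"),
                                 n_permutations, present=False)

    op = _neighbor_count_operator(graph)  # (n, 2m)
    de = graph.directed_edges()

    def stats_for(label_rows: np.ndarray) -> np.ndarray:
        # counts of B-neighbors per node, rows = label assignments
        if de.shape[0]:
            is_b = (label_rows[:, de[:, 1]] == b).astype(float)
            counts = is_b @ op.T
        else:
            counts = np.zeros((label_rows.shape[0], graph.n_cells))
        return _pair_statistic(label_rows, counts, a)

    observed = float(stats_for(lab[None, :])[0])
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    chunk = max(1, min(n_permutations, 512))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        perms = rng.permuted(np.tile(lab, (k, 1)), axis=1)
        null[done:done + k] = stats_for(perms)
        done += k
    tol = 1e-9
    if tail == "enrichment":
        extreme = int(np.sum(null >= observed - tol))
    else:
        extreme = int(np.sum(null <= observed + tol))
    p = (1.0 + extreme) / (1.0 + n_permutations)
    return InteractionResult(graph.image_id, (a, b), observed,
                             float(null.mean()), float(null.std(ddof=0)),
                             p, n_permutations, present=True)


def aggregate_images(
    results: Sequence[InteractionResult],
    alpha: float = 0.05,
    sig_frac: float = 0.30,
    presence_frac: float = 0.90,
) -> list[AggregateDecision]:
    """Cross-image keep/drop rule for each ordered type pair.

    A pair is kept iff it is significant (P < alpha) in at least
    ``sig_frac`` of the images AND present (both types occur) in at least
    ``presence_frac`` of the images; both fractions use >= and are taken
    over all images contributing a result for the pair.
    """
    if not results:
        raise ValueError("no interaction results to aggregate")
    by_pair: dict[tuple, list[InteractionResult]] = {}
    for r in results:
        by_pair.setdefault(tuple(r.pair), []).append(r)
    decisions = []
    for pair in sorted(by_pair):
        rs = by_pair[pair]
        n = len(rs)
        f_sig = sum(1 for r in rs if r.present and r.p_value < alpha) / n
        f_pres = sum(1 for r in rs if r.present) / n
        decisions.append(AggregateDecision(
            pair=pair, frac_significant=f_sig, frac_present=f_pres,
            keep=(f_sig >= sig_frac) and (f_pres >= presence_frac),
            alpha=alpha, sig_frac=sig_frac, presence_frac=presence_frac))
    return decisions


def map_to_stream(cells: pd.DataFrame, path: StreamPath) -> pd.DataFrame:
    """Project cells onto a migratory-stream polyline.

    Each cell maps to its nearest point on the path; ``position`` is the
    cumulative arc length at that point divided by the total path length
    (0 at the stream origin near the Arc, 1 at the cortical end), and
    ``offset`` is the signed perpendicular distance in pixels (positive to
    the left of the direction of travel).
    """
    ids, xy = _cells_arrays(cells)
    v = path.vertices
    cum = path.cumulative_length
    total = path.total_length
    a = v[:-1]                      # (s, 2) segment starts
    d = np.diff(v, axis=0)          # (s, 2) segment vectors
    seg_len = np.linalg.norm(d, axis=1)
    # (n, s) projections of every point on every segment
    rel = xy[:, None, :] - a[None, :, :]
    t = np.clip(np.einsum("nsk,sk->ns", rel, d) / (seg_len**2), 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * d[None, :, :]
    diff = xy[:, None, :] - proj
    dist = np.linalg.norm(diff, axis=2)
    best = np.argmin(dist, axis=1)  # first minimum on ties
    n = np.arange(ids.size)
    tb = t[n, best]
    pos = (cum[best] + tb * seg_len[best]) / total
    cross = d[best, 0] * diff[n, best, 1] - d[best, 1] * diff[n, best, 0]
    offset = np.sign(cross) * dist[n, best]
    return pd.DataFrame({"cell_id": ids, "position": pos, "offset": offset})
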