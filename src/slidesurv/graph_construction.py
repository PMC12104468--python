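"""Spatial tile graphs for whole-slide images.

A whole-slide image (WSI) is tiled into non-overlapping squares covering
512 µm × 512 µm of tissue each (512 px at 10x / 1.0 mpp, or 1024 px at
20x / 0.5 mpp — same physical footprint either way).  Tiles with less than
20% tissue are dropped.  Each retained tile becomes a graph node carrying

* deep features (e.g. foundation-model embeddings, consumed pre-computed),
* a 16-dimensional 2-D sinusoidal positional encoding of its grid position,
* a histologic subtype label (five lung-adenocarcinoma growth patterns plus
  non-tumor).

Edges connect each node to its k = 8 spatially nearest neighbours (Euclidean
distance between tile centres, directed neighbour→node).  Each edge carries a
categorical feature — which of the 21 unordered subtype pairs it joins — and
two continuous features: cosine similarity of the endpoint deep features and
the spatial distance between the endpoints (min-max scaled per graph).

Tile-sampling strategies (random percentage, aggressive-subtypes-only,
non-aggressive-only) subset the tiles before the graph is rebuilt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TILE_FOOTPRINT_UM = 512.0
#: pixels-per-tile and microns-per-pixel for the two supported scan modes;
#: both cover the same 512 µm square of tissue.
MAGNIFICATION_MODES = {"10x": (512, 1.0), "20x": (1024, 0.5)}

#: canonical (alphabetical) subtype order; indices are the categorical codes.
SUBTYPES = ("acinar", "lepidic", "micropapillary", "non-tumor", "papillary", "solid")
SUBTYPE_INDEX = {s: i for i, s in enumerate(SUBTYPES)}
AGGRESSIVE_SUBTYPES = frozenset({"micropapillary", "solid"})
NONAGGRESSIVE_SUBTYPES = frozenset({"non-tumor", "lepidic"})

N_SUBTYPE_PAIRS = len(SUBTYPES) * (len(SUBTYPES) + 1) // 2  # 21

GRAPH_FORMAT_VERSION = 1

DEFAULT_K = 8
DEFAULT_PE_DIM = 16
DEFAULT_MIN_TISSUE = 0.20


class GraphTooSmallError(ValueError):
    """Fewer than two nodes survive; no k-NN graph can be built."""


class SamplingMode(str, Enum):
    ALL = "all"
    RANDOM_FRACTION = "random_fraction"
    AGGRESSIVE_ONLY = "aggressive_only"
    NONAGGRESSIVE_ONLY = "nonaggressive_only"


@dataclass(frozen=True)
class TileRecord:
    """One tile: grid position, physical centre (µm), tissue fraction, subtype."""

    slide_id: str
    row: int
    col: int
    center_x: float
    center_y: float
    tissue_fraction: float
    subtype: str

    def __post_init__(self):
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError(f"tissue_fraction {self.tissue_fraction} outside [0, 1]")
        if self.subtype not in SUBTYPE_INDEX:
            raise ValueError(f"unknown subtype {self.subtype!r}")


@dataclass(frozen=True)
class SamplingSpec:
    """Which tiles to keep before the graph is (re)built."""

    mode: SamplingMode = SamplingMode.ALL
    fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside (0, 1]")


@dataclass(frozen=True)
class GraphConfig:
    k: int = DEFAULT_K
    pe_dim: int = DEFAULT_PE_DIM
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    symmetrize: bool = False
    scale_distances: bool = True


@dataclass
class WSIGraph:
    """One slide as an initialized spatial graph (see module docstring)."""

    slide_id: str
    coords: np.ndarray  # (N, 2) µm
    X_deep: np.ndarray  # (N, D)
    X_pe: np.ndarray  # (N, pe_dim)
    edge_index: np.ndarray  # (2, E) rows = (source, target)
    E_cat: np.ndarray  # (E,) ints in [0, 21)
    E_cont: np.ndarray  # (E, 2) cosine similarity, scaled distance
    subtypes: np.ndarray  # (N,) ints indexing SUBTYPES
    rows: np.ndarray | None = None  # (N,) grid rows (raster order bookkeeping)
    cols: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def validate(self) -> None:
        n = self.n_nodes
        if self.edge_index.size and self.edge_index.max() >= n:
            raise ValueError("edge endpoint out of range")
        if np.any(self.E_cont[:, 0] < -1 - 1e-9) or np.any(self.E_cont[:, 0] > 1 + 1e-9):
            raise ValueError("cosine similarity outside [-1, 1]")
        if np.any(self.E_cont[:, 1] < -1e-12):
            raise ValueError("negative edge distance")
        if self.X_deep.shape[0] != n or self.X_pe.shape[0] != n:
            raise ValueError("node feature row count mismatch")


# ---------------------------------------------------------------------------
# tiling geometry


def tile_grid(
    slide_width_um: float, slide_height_um: float, magnification_mode: str = "10x"
) -> list[TileRecord]:
    """Lay a non-overlapping tile grid over a slide; geometry-only stubs.

    Partial boundary tiles are dropped. Both magnification modes produce the
    same 512 µm physical footprint, so the grid is identical across modes.
    """
    if magnification_mode not in MAGNIFICATION_MODES:
        raise ValueError(
            f"magnification_mode must be one of {sorted(MAGNIFICATION_MODES)}"
        )
    if slide_width_um <= 0 or slide_height_um <= 0:
        raise ValueError("slide dimensions must be positive")
    n_cols = int(slide_width_um // TILE_FOOTPRINT_UM)
    n_rows = int(slide_height_um // TILE_FOOTPRINT_UM)
    tiles = []
    for r in range(n_rows):
        for c in range(n_cols):
            tiles.append(
                TileRecord(
                    slide_id="",
                    row=r,
                    col=c,
                    center_x=(c + 0.5) * TILE_FOOTPRINT_UM,
                    center_y=(r + 0.5) * TILE_FOOTPRINT_UM,
                    tissue_fraction=1.0,
                    subtype="non-tumor",
                )
            )
    return tiles


def filter_tiles(
    tiles: Sequence[TileRecord], min_tissue_fraction: float = DEFAULT_MIN_TISSUE
) -> list[TileRecord]:
    """Keep tiles with tissue_fraction >= threshold (boundary retained)."""
    kept = [t for t in tiles if t.tissue_fraction >= min_tissue_fraction]
    if not kept:
        warnings.warn(
            "no tiles pass the tissue-fraction filter; graph cannot be built",
            stacklevel=2,
        )
    return kept


# ---------------------------------------------------------------------------
# connectivity and node/edge features


def knn_edges(coords: np.ndarray, k: int) -> np.ndarray:
    """Directed k-nearest-neighbour edges (source j -> target i).

    Each node receives edges from its min(k, N-1) nearest neighbours by
    Euclidean distance, self excluded; ties broken by smaller source index;
    edge list sorted by (target, source).  Returns a (2, E) int array with
    rows (source, target).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 2:
        raise GraphTooSmallError(f"need >= 2 nodes for a k-NN graph, got {n}")
    if k < 1:
        raise ValueError("k must be >= 1")
    kk = min(k, n - 1)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(n)
    sources = []
    targets = []
    for i in range(n):
        # lexsort: primary key distance, secondary key node index
        order = np.lexsort((idx, d2[i]))[:kk]
        order = np.sort(order)  # edge list per target ordered by source
        sources.append(order)
        targets.append(np.full(kk, i))
    return np.stack([np.concatenate(sources), np.concatenate(targets)])


def symmetrize_edges(edge_index: np.ndarray) -> np.ndarray:
    """Union of edges with their reverses, deduplicated, sorted by (target, source)."""
    fwd = edge_index.T
    rev = edge_index[::-1].T
    allp = np.unique(np.concatenate([fwd, rev]), axis=0)
    order = np.lexsort((allp[:, 0], allp[:, 1]))
    return allp[order].T


def positional_encoding(row: int, col: int, d_pe: int = DEFAULT_PE_DIM) -> np.ndarray:
    """2-D sinusoidal positional encoding of a tile's grid position.

    The first d_pe/2 entries encode the row index, the last d_pe/2 the column
    index; within each half, entry 2m is sin(p / 10000^(2m/(d_pe/2))) and
    entry 2m+1 the matching cosine, with p the 0-based grid index.
    """
    if d_pe % 4 != 0:
        raise ValueError("pe_dim must be divisible by 4 (sin/cos per axis)")
    if row < 0 or col < 0:
        raise ValueError("grid indices must be >= 0")
    half = d_pe // 2
    m = np.arange(half // 2)
    freq = 1.0 / (10000.0 ** (2.0 * m / half))
    out = np.empty(d_pe)
    for h, p in enumerate((row, col)):
        args = p * freq
        out[h * half : (h + 1) * half : 2] = np.sin(args)
        out[h * half + 1 : (h + 1) * half : 2] = np.cos(args)
    return out


def positional_encoding_matrix(
    rows: np.ndarray, cols: np.ndarray, d_pe: int = DEFAULT_PE_DIM
) -> np.ndarray:
    """Vectorised :func:`positional_encoding` over node arrays."""
    if d_pe % 4 != 0:
        raise ValueError("pe_dim must be divisible by 4 (sin/cos per axis)")
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    half = d_pe // 2
    m = np.arange(half // 2)
    freq = 1.0 / (10000.0 ** (2.0 * m / half))
    out = np.empty((rows.shape[0], d_pe))
    for h, p in enumerate((rows, cols)):
        args = p[:, None] * freq[None, :]
        out[:, h * half : (h + 1) * half : 2] = np.sin(args)
        out[:, h * half + 1 : (h + 1) * half : 2] = np.cos(args)
    return out


def subtype_pair_category(subtype_a: str, subtype_b: str) -> int:
    """Category id in [0, 21) of an unordered subtype pair (a = b allowed).

    The six classes are ordered alphabetically; unordered pairs (i, j), i <= j,
    are enumerated lexicographically, a bijection onto {0, ..., 20}.
    """
    try:
        i, j = SUBTYPE_INDEX[subtype_a], SUBTYPE_INDEX[subtype_b]
    except KeyError as e:
        raise ValueError(f"unknown subtype {e.args[0]!r}") from None
    if i > j:
        i, j = j, i
    s = len(SUBTYPES)
    return i * s - i * (i + 1) // 2 + j


def _pair_category_codes(code_a: np.ndarray, code_b: np.ndarray) -> np.ndarray:
    i = np.minimum(code_a, code_b)
    j = np.maximum(code_a, code_b)
    s = len(SUBTYPES)
    return i * s - i * (i + 1) // 2 + j


def edge_features(
    X_deep: np.ndarray, coords: np.ndarray, edge_index: np.ndarray
) -> np.ndarray:
    """Per-edge (cosine similarity, raw Euclidean distance) matrix, E x 2."""
    src, tgt = edge_index
    a = X_deep[src]
    b = X_deep[tgt]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = na * nb
    zero = denom == 0.0
    if np.any(zero):
        logger.warning(
            "%d edges touch zero-norm feature rows; cosine set to 0", int(zero.sum())
        )
    denom = np.where(zero, 1.0, denom)
    cos = np.where(zero, 0.0, np.einsum("ij,ij->i", a, b) / denom)
    dist = np.linalg.norm(coords[src] - coords[tgt], axis=1)
    return np.stack([cos, dist], axis=1)


def minmax_scale_distances(dist: np.ndarray) -> np.ndarray:
    """Min-max scale a distance vector to [0, 1]; constant vectors map to 0."""
    lo, hi = dist.min(), dist.max()
    if hi - lo <= 0:
        return np.zeros_like(dist)
    return (dist - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# tile sampling


def sample_tiles(tiles: Sequence[TileRecord], spec: SamplingSpec) -> list[TileRecord]:
    """Subset tiles per the sampling strategy; original order preserved."""
    tiles = list(tiles)
    if spec.mode == SamplingMode.ALL:
        return tiles
    if spec.mode == SamplingMode.AGGRESSIVE_ONLY:
        return [t for t in tiles if t.subtype in AGGRESSIVE_SUBTYPES]
    if spec.mode == SamplingMode.NONAGGRESSIVE_ONLY:
        return [t for t in tiles if t.subtype in NONAGGRESSIVE_SUBTYPES]
    # random_fraction
    n_keep = int(np.rint(spec.fraction * len(tiles)))
    rng = np.random.default_rng(spec.seed)
    keep = np.sort(rng.choice(len(tiles), size=n_keep, replace=False))
    return [tiles[i] for i in keep]


# ---------------------------------------------------------------------------
# assembly


def build_graph(
    tiles: Sequence[TileRecord],
    X_deep: np.ndarray,
    config: GraphConfig = GraphConfig(),
) -> WSIGraph:
    """Compose filtering, sampling, k-NN connectivity and feature initialization.

    ``X_deep`` must be row-aligned with ``tiles`` (pre-filter); rows of dropped
    tiles are dropped with them.  Nodes are ordered row-major by (row, col).
    """
    tiles = list(tiles)
    X_deep = np.asarray(X_deep, dtype=np.float64)
    slide_id = tiles[0].slide_id if tiles else ""
    if X_deep.shape[0] != len(tiles):
        raise ValueError(
            f"slide {slide_id!r}: feature rows ({X_deep.shape[0]}) do not match "
            f"tile count ({len(tiles)})"
        )
    keep_mask = [t.tissue_fraction >= config.min_tissue_fraction for t in tiles]
    kept = [t for t, m in zip(tiles, keep_mask) if m]
    X = X_deep[np.asarray(keep_mask, dtype=bool)]
    if not kept:
        warnings.warn("no tiles pass the tissue-fraction filter", stacklevel=2)

    if config.sampling.mode != SamplingMode.ALL:
        pos = {(t.row, t.col): i for i, t in enumerate(kept)}
        kept = sample_tiles(kept, config.sampling)
        X = X[[pos[(t.row, t.col)] for t in kept]]

    if len(kept) < 2:
        raise GraphTooSmallError(
            f"slide {slide_id!r}: {len(kept)} tiles after filtering/sampling"
        )

    # raster order: by (row, col)
    order = sorted(range(len(kept)), key=lambda i: (kept[i].row, kept[i].col))
    kept = [kept[i] for i in order]
    X = X[order]

    rows = np.array([t.row for t in kept])
    cols = np.array([t.col for t in kept])
    coords = np.array([[t.center_x, t.center_y] for t in kept])
    codes = np.array([SUBTYPE_INDEX[t.subtype] for t in kept])

    edge_index = knn_edges(coords, config.k)
    if config.symmetrize:
        edge_index = symmetrize_edges(edge_index)
    e_cont = edge_features(X, coords, edge_index)
    if config.scale_distances:
        e_cont = e_cont.copy()
        e_cont[:, 1] = minmax_scale_distances(e_cont[:, 1])
    e_cat = _pair_category_codes(codes[edge_index[0]], codes[edge_index[1]])

    g = WSIGraph(
        slide_id=slide_id,
        coords=coords,
        X_deep=X,
        X_pe=positional_encoding_matrix(rows, cols, config.pe_dim),
        edge_index=edge_index,
        E_cat=e_cat,
        E_cont=e_cont,
        subtypes=codes,
        rows=rows,
        cols=cols,
    )
    g.validate()
    return g


# ---------------------------------------------------------------------------
# I/O: tile tables, feature arrays, graph containers

TILE_TABLE_COLUMNS = [
    "slide_id",
    "row",
    "col",
    "center_x_um",
    "center_y_um",
    "tissue_fraction",
    "subtype",
]


def write_tile_table(tiles: Sequence[TileRecord], path) -> None:
    df = pd.DataFrame(
        [
            (t.slide_id, t.row, t.col, t.center_x, t.center_y, t.tissue_fraction, t.subtype)
            for t in tiles
        ],
        columns=TILE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_tile_table(path) -> dict[str, list[TileRecord]]:
    """Read a tile TSV; returns tiles grouped by slide_id, file order preserved."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TILE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tile table missing columns: {sorted(missing)}")
    out: dict[str, list[TileRecord]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(str(rec.slide_id), []).append(
            TileRecord(
                slide_id=str(rec.slide_id),
                row=int(rec.row),
                col=int(rec.col),
                center_x=float(rec.center_x_um),
                center_y=float(rec.center_y_um),
                tissue_fraction=float(rec.tissue_fraction),
                subtype=str(rec.subtype),
            )
        )
    return out


def write_features(features: dict[str, np.ndarray], path) -> None:
    """One HDF5 dataset per slide_id, rows aligned with the slide's tile table."""
    with h5py.File(path, "w") as f:
        for sid, arr in features.items():
            f.create_dataset(sid, data=np.asarray(arr, dtype=np.float64))


def read_features(path) -> dict[str, np.ndarray]:
    p = str(path)
    if p.endswith(".npz"):
        with np.load(p) as z:
            return {k: z[k] for k in z.files}
    with h5py.File(p, "r") as f:
        return {k: f[k][()] for k in f.keys()}


def save_graph(graph: WSIGraph, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = GRAPH_FORMAT_VERSION
        f.attrs["slide_id"] = graph.slide_id
        for name in ("coords", "X_deep", "X_pe", "edge_index", "E_cat", "E_cont", "subtypes"):
            f.create_dataset(name, data=getattr(graph, name))
        if graph.rows is not None:
            f.create_dataset("rows", data=graph.rows)
            f.create_dataset("cols", data=graph.cols)


def load_graph(path) -> WSIGraph:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != GRAPH_FORMAT_VERSION:
            raise ValueError(f"unsupported graph format version {version}")
        g = WSIGraph(
            slide_id=str(f.attrs["slide_id"]),
            coords=f["coords"][()],
            X_deep=f["X_deep"][()],
            X_pe=f["X_pe"][()],
            edge_index=f["edge_index"][()],
            E_cat=f["E_cat"][()],
            E_cont=f["E_cont"][()],
            subtypes=f["subtypes"][()],
            rows=f["rows"][()] if "rows" in f else None,
            cols=f["cols"][()] if "cols" in f else None,
        )
    g.validate()
    return g
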