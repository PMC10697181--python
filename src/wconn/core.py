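"""Shared data types and delimited-text IO for weighted connectome analysis.

The in-memory convention throughout the package is 0-based integer node
indices in parcellation order; files carry node identifiers instead, so the
readers and writers below translate between the two.  All matrices are dense
``numpy`` arrays (N is at most ~1,000 here, so dense CSV is simpler and
diff-able), symmetric with a zero diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MODULES",
    "UNIMODAL_MODULES",
    "TRANSMODAL_MODULES",
    "STREAMLINE_WEIGHTS",
    "TRACTOMETRY_WEIGHTS",
    "SC_WEIGHTS",
    "WEIGHT_NAMES",
    "METRICS",
    "FormatError",
    "ConsistencyError",
    "Parcellation",
    "StreamlineTable",
    "WeightedConnectome",
    "SubjectEnsemble",
    "EdgeVector",
    "read_matrix",
    "write_matrix",
    "read_parcellation",
    "write_parcellation",
    "read_streamlines",
    "write_streamlines",
    "edge_vectorize",
    "edge_devectorize",
]

#: Canonical resting-state modules plus the subcortex.
MODULES = ("SUB", "VIS", "SMN", "DAN", "SVAN", "LIMB", "CONT", "DMN")
UNIMODAL_MODULES = ("VIS", "SMN")
TRANSMODAL_MODULES = ("DMN", "CONT", "DAN", "SVAN")

STREAMLINE_WEIGHTS = ("NoS", "LoS", "SIFT2", "COMMIT")
TRACTOMETRY_WEIGHTS = ("R1", "FA", "RD", "ICVF")
SC_WEIGHTS = STREAMLINE_WEIGHTS + TRACTOMETRY_WEIGHTS
WEIGHT_NAMES = SC_WEIGHTS + ("FC", "binary")
METRICS = ("R1", "FA", "RD", "ICVF")

#: Relative tolerance below which an asymmetric input is silently symmetrized.
SYMMETRY_RTOL = 1e-10

STREAMLINE_COLUMNS = (
    "node_i",
    "node_j",
    "length_mm",
    "w_commit",
    "w_sift2",
    "med_R1",
    "med_FA",
    "med_RD",
    "med_ICVF",
)

PARCELLATION_COLUMNS = ("node_id", "label", "module", "volume_mm3", "x", "y", "z")


class FormatError(ValueError):
    """A file or table does not have the documented layout."""


class ConsistencyError(ValueError):
    """Values are syntactically valid but violate an invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Parcellation:
    """Node metadata: identifiers, module assignment, volumes, coordinates.

    Parameters
    ----------
    node_ids : list of str
        Unique node identifiers, in matrix order.
    labels : list of str
        Human-readable anatomical labels.
    module : ndarray of str
        Module assignment per node, drawn from :data:`MODULES`.
    volume : ndarray
        Node volume in mm^3, strictly positive.
    coords : ndarray, shape (N, 3)
        Node centroid coordinates in mm.
    """

    node_ids: list
    labels: list
    module: np.ndarray
    volume: np.ndarray
    coords: np.ndarray

    def __post_init__(self):
        self.node_ids = list(self.node_ids)
        self.labels = list(self.labels)
        self.module = np.asarray(self.module, dtype=object)
        self.volume = np.asarray(self.volume, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.node_ids)
        if n < 2:
            raise ConsistencyError("parcellation needs at least 2 nodes")
        if len(set(self.node_ids)) != n:
            raise ConsistencyError("node_ids must be unique")
        if len(self.labels) != n or len(self.module) != n:
            raise FormatError("labels/module length mismatch with node_ids")
        if self.volume.shape != (n,):
            raise FormatError("volume must be one scalar per node")
        if not np.all(np.isfinite(self.volume)) or np.any(self.volume <= 0):
            raise ConsistencyError("node volumes must be finite and strictly positive")
        if self.coords.shape != (n, 3):
            raise FormatError("coords must have shape (N, 3)")
        bad = sorted(set(self.module) - set(MODULES))
        if bad:
            raise FormatError(f"unknown module label(s): {bad}; allowed: {MODULES}")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distance between node centroids (mm)."""
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def index_of(self, node_id: str) -> int:
        return self.node_ids.index(node_id)


@dataclass
class StreamlineTable:
    """Per-streamline records: endpoints, length, weights, metric medians.

    ``node_i``/``node_j`` are 0-based node indices canonicalized to i < j at
    construction.  One row per streamline.
    """

    df: pd.DataFrame
    subject_id: str = "unknown"

    def __post_init__(self):
        df = self.df
        missing = [c for c in STREAMLINE_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"streamline table missing column(s): {missing}")
        df = df[list(STREAMLINE_COLUMNS)].reset_index(drop=True).copy()
        i = df["node_i"].to_numpy(dtype=np.int64)
        j = df["node_j"].to_numpy(dtype=np.int64)
        if np.any(i == j):
            raise ConsistencyError("self-pair streamlines (node_i == node_j) not allowed")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        df["node_i"], df["node_j"] = lo, hi
        lengths = df["length_mm"].to_numpy(dtype=float)
        if not np.all(np.isfinite(lengths)) or np.any(lengths <= 0):
            raise ConsistencyError("streamline lengths must be finite and positive")
        for col in ("w_commit", "w_sift2"):
            w = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(w)) or np.any(w < 0):
                raise ConsistencyError(f"{col} must be finite and nonnegative")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def validate_against(self, parc: Parcellation) -> None:
        """Check every endpoint exists in the parcellation."""
        idx = self.df[["node_i", "node_j"]].to_numpy()
        if idx.size and (idx.min() < 0 or idx.max() >= parc.n_nodes):
            raise ConsistencyError("streamline endpoints outside parcellation")


def _validate_matrix(matrix: np.ndarray, weight_name: str) -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise FormatError(f"connectivity matrix must be square, got {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise ConsistencyError("matrix contains NaN/Inf entries")
    scale = max(np.abs(matrix).max(), 1.0)
    asym = np.abs(matrix - matrix.T).max()
    if asym > SYMMETRY_RTOL * scale:
        raise ConsistencyError(
            f"matrix asymmetry {asym:.3g} exceeds relative tolerance {SYMMETRY_RTOL}"
        )
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 0.0)
    if weight_name not in ("FC",) and np.any(matrix < 0):
        raise ConsistencyError(f"{weight_name} edge weights must be nonnegative")
    return matrix


@dataclass
class WeightedConnectome:
    """Symmetric node-by-node matrix tagged with a weight name and subject."""

    weight_name: str
    subject_id: str
    matrix: np.ndarray

    def __post_init__(self):
        if self.weight_name not in WEIGHT_NAMES:
            raise FormatError(
                f"unknown weight_name {self.weight_name!r}; allowed: {WEIGHT_NAMES}"
            )
        self.matrix = _validate_matrix(self.matrix, self.weight_name)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def binary(self) -> np.ndarray:
        """Boolean adjacency map of nonzero edges."""
        return self.matrix != 0

    def density(self) -> float:
        n = self.n_nodes
        return float(np.count_nonzero(np.triu(self.matrix, 1))) / (n * (n - 1) / 2)


@dataclass
class SubjectEnsemble:
    """Per-subject connectomes sharing one parcellation and weight name."""

    parcellation: Parcellation
    weight_name: str
    subjects: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.subjects) < 1:
            raise ConsistencyError("ensemble needs at least one subject")
        n = self.parcellation.n_nodes
        for net in self.subjects:
            if net.weight_name != self.weight_name:
                raise ConsistencyError(
                    f"subject {net.subject_id}: weight {net.weight_name} != {self.weight_name}"
                )
            if net.n_nodes != n:
                raise ConsistencyError("subject matrix shape mismatch with parcellation")

    def __len__(self) -> int:
        return len(self.subjects)

    def stack(self) -> np.ndarray:
        """Stack subject matrices into an (S, N, N) array."""
        return np.stack([net.matrix for net in self.subjects])


@dataclass
class EdgeVector:
    """Upper-triangle edge values with an explicit, sorted (i, j) index."""

    idx: np.ndarray  # (m, 2) int, i < j, lexicographically sorted
    values: np.ndarray
    weight_name: str = "binary"
    subject_id: str = "unknown"

    def __post_init__(self):
        self.idx = np.asarray(self.idx, dtype=np.int64).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float)
        if self.idx.shape[0] != self.values.shape[0]:
            raise ConsistencyError("edge index and values length mismatch")
        if np.any(self.idx[:, 0] >= self.idx[:, 1]):
            raise ConsistencyError("edge index must satisfy i < j")
        order = np.lexsort((self.idx[:, 1], self.idx[:, 0]))
        if not np.array_equal(order, np.arange(len(order))):
            raise ConsistencyError("edge index must be lexicographically sorted")
        if len({(int(i), int(j)) for i, j in self.idx}) != len(self.idx):
            raise ConsistencyError("duplicate edges in index")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# matrix IO (dense CSV, node_id header row + column, '.' decimal, UTF-8)
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless round-trip contract


def read_matrix(
    path,
    expected_nodes: int | None = None,
    weight_name: str = "binary",
    subject_id: str = "unknown",
) -> WeightedConnectome:
    """Read a connectivity matrix from CSV with node_id header row/column."""
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse matrix CSV {path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"matrix in {path} is not square: {df.shape}")
    matrix = df.to_numpy(dtype=float)
    if expected_nodes is not None and matrix.shape[0] != expected_nodes:
        raise FormatError(
            f"expected {expected_nodes} nodes, found {matrix.shape[0]} in {path}"
        )
    return WeightedConnectome(weight_name=weight_name, subject_id=subject_id, matrix=matrix)


def write_matrix(net: WeightedConnectome, path, node_ids=None):
    """Write a connectome as dense CSV; returns the path written."""
    n = net.n_nodes
    ids = list(node_ids) if node_ids is not None else [f"n{k:03d}" for k in range(n)]
    if len(ids) != n:
        raise FormatError("node_ids length mismatch with matrix")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(net.matrix, index=ids, columns=ids).to_csv(path, float_format=_FLOAT_FMT)
    return path


# ---------------------------------------------------------------------------
# parcellation IO (TSV + JSON sidecar with the declared module level set)
# ---------------------------------------------------------------------------


def write_parcellation(parc: Parcellation, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "node_id": parc.node_ids,
            "label": parc.labels,
            "module": parc.module,
            "volume_mm3": parc.volume,
            "x": parc.coords[:, 0],
            "y": parc.coords[:, 1],
            "z": parc.coords[:, 2],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"module_levels": list(MODULES)}, indent=2))
    return path


def read_parcellation(path) -> Parcellation:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PARCELLATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parcellation missing column(s): {missing}")
    return Parcellation(
        node_ids=[str(v) for v in df["node_id"]],
        labels=[str(v) for v in df["label"]],
        module=df["module"].to_numpy(dtype=object),
        volume=df["volume_mm3"].to_numpy(dtype=float),
        coords=df[["x", "y", "z"]].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# streamline IO (TSV, one streamline per row; files carry node_ids)
# ---------------------------------------------------------------------------


def write_streamlines(table: StreamlineTable, parc: Parcellation, path):
    table.validate_against(parc)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = table.df.copy()
    ids = np.asarray(parc.node_ids, dtype=object)
    df["node_i"] = ids[df["node_i"].to_numpy()]
    df["node_j"] = ids[df["node_j"].to_numpy()]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    return path


def read_streamlines(path, parc: Parcellation, subject_id: str = "unknown") -> StreamlineTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in STREAMLINE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"streamline table missing column(s): {missing}")
    lookup = {nid: k for k, nid in enumerate(parc.node_ids)}
    try:
        df["node_i"] = [lookup[str(v)] for v in df["node_i"]]
        df["node_j"] = [lookup[str(v)] for v in df["node_j"]]
    except KeyError as exc:
        raise ConsistencyError(f"streamline endpoint {exc} not in parcellation") from exc
    return StreamlineTable(df=df, subject_id=subject_id)


# ---------------------------------------------------------------------------
# edge vectorization
# ---------------------------------------------------------------------------


def edge_vectorize(net: WeightedConnectome, mask: WeightedConnectome | None = None) -> EdgeVector:
    """Upper-triangle edge values in lexicographic (i, j) order.

    When ``mask`` is given, only its nonzero edges are kept.
    """
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    if mask is not None:
        if mask.n_nodes != n:
            raise ConsistencyError("mask/matrix shape mismatch")
        keep = mask.matrix[iu, ju] != 0
        iu, ju = iu[keep], ju[keep]
    return EdgeVector(
        idx=np.column_stack([iu, ju]),
        values=net.matrix[iu, ju],
        weight_name=net.weight_name,
        subject_id=net.subject_id,
    )


def edge_devectorize(ev: EdgeVector, n_nodes: int) -> WeightedConnectome:
    """Inverse of :func:`edge_vectorize` over a full mask (absent edges -> 0)."""
    matrix = np.zeros((n_nodes, n_nodes))
    matrix[ev.idx[:, 0], ev.idx[:, 1]] = ev.values
    matrix += matrix.T
    return WeightedConnectome(
        weight_name=ev.weight_name, subject_id=ev.subject_id, matrix=matrix
    )
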