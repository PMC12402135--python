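"""Domain types, file readers/writers and the packaged convergence-table fixture.

Everything downstream of this module speaks in terms of four containers:

* :class:`Parcellation` — per-ROI metadata (class, resting-state network,
  bilateral centroids in MNI mm, voxel counts).
* :class:`TimeSeriesPanel` — per (subject, session) ROI time-series matrices.
* :class:`ConnectivityResult` — subject-level regression betas plus the
  group-level t / binary / normalized-weight matrices.
* :class:`BinaryGraph` — a labelled 0/1 adjacency, directed or not.

Internal indices are 0-based throughout; every on-disk format carries explicit
ROI labels so external ordering never matters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CORTICAL_RSNS",
    "PRIMARY_NETWORKS",
    "ASSOCIATION_NETWORKS",
    "SUBCORTICAL_NETWORKS",
    "Parcellation",
    "TimeSeriesPanel",
    "ConnectivityResult",
    "BinaryGraph",
    "FixtureError",
    "read_panel",
    "write_panel",
    "read_matrix",
    "write_matrix",
    "write_report",
    "load_table1_fixture",
    "table1_printed_counts",
]

#: The eight cortical resting-state networks (cerebellum counted with cortex).
CORTICAL_RSNS = ("VIS", "SOM", "DAN", "VAN", "LIM", "CON", "DMN", "CER")
#: Early sensory / motor networks plus cerebellum.
PRIMARY_NETWORKS = frozenset({"VIS", "SOM", "CER"})
#: Higher-order networks.
ASSOCIATION_NETWORKS = frozenset({"DAN", "VAN", "LIM", "CON", "DMN"})
#: Subcortical communities: thalamic, basal-ganglia and subcortical-limbic.
SUBCORTICAL_NETWORKS = ("THA", "BGN", "SLN")

_ROI_CLASSES = ("cortical", "cerebellar", "subcortical")
_NETWORK_CLASSES = ("primary", "association", "not_applicable")


class FixtureError(RuntimeError):
    """Raised when a packaged fixture fails its integrity check."""


def _as_centroid(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(-1, 3)
    if arr.shape[0] not in (1, 2):
        raise ValueError("a ROI carries one (medial) or two (bilateral) centroids")
    return arr


@dataclass
class Parcellation:
    """ROI metadata table.

    Parameters
    ----------
    labels
        Unique ROI names.
    roi_class
        Per ROI, one of ``cortical | cerebellar | subcortical``.
    rsn
        Resting-state-network label; the eight cortical networks for
        cortical/cerebellar ROIs, a subcortical community (e.g. THA/BGN/SLN)
        or a placeholder for subcortical ROIs.
    centroids
        Per ROI an array of shape (1, 3) or (2, 3): MNI centroid(s) in mm,
        stored exactly as supplied (no axis flips). NaN marks an unknown
        centroid; distance computations refuse those ROIs.
    voxel_counts
        Region size in isotropic voxels (>= 1).
    network_class
        ``primary`` (VIS/SOM/CER), ``association`` (DAN/VAN/LIM/CON/DMN) or
        ``not_applicable``; derived from ``rsn`` when omitted.
    """

    labels: list[str]
    roi_class: list[str]
    rsn: list[str]
    centroids: list[np.ndarray]
    voxel_counts: np.ndarray
    network_class: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ValueError(f"ROI labels must be unique; duplicated: {dupes}")
        self.centroids = [_as_centroid(c) for c in self.centroids]
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        if not self.network_class:
            self.network_class = [
                "primary" if r in PRIMARY_NETWORKS
                else "association" if r in ASSOCIATION_NETWORKS
                else "not_applicable"
                for r in self.rsn
            ]
        for name, seq, allowed in (
            ("roi_class", self.roi_class, _ROI_CLASSES),
            ("network_class", self.network_class, _NETWORK_CLASSES),
        ):
            bad = sorted({x for x in seq if x not in allowed})
            if bad:
                raise ValueError(f"invalid {name} values: {bad}")
        if not all(
            len(x) == n
            for x in (self.roi_class, self.rsn, self.centroids,
                      self.voxel_counts, self.network_class)
        ):
            raise ValueError("all parcellation columns must share length")
        for lbl, cls, r in zip(self.labels, self.roi_class, self.rsn):
            if cls in ("cortical", "cerebellar") and r not in CORTICAL_RSNS:
                raise ValueError(f"{lbl}: cortical/cerebellar ROI with RSN {r!r}")
        if np.any(self.voxel_counts < 1):
            raise ValueError("voxel counts must be >= 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices_where(self, **conditions) -> np.ndarray:
        """Indices of ROIs matching all given column=value conditions."""
        mask = np.ones(self.n, dtype=bool)
        for col, value in conditions.items():
            column = getattr(self, col)
            values = set(value) if isinstance(value, (set, list, tuple, frozenset)) else {value}
            mask &= np.array([v in values for v in column])
        return np.flatnonzero(mask)

    def subset(self, indices: Sequence[int]) -> "Parcellation":
        idx = list(indices)
        return Parcellation(
            labels=[self.labels[i] for i in idx],
            roi_class=[self.roi_class[i] for i in idx],
            rsn=[self.rsn[i] for i in idx],
            centroids=[self.centroids[i] for i in idx],
            voxel_counts=self.voxel_counts[idx],
            network_class=[self.network_class[i] for i in idx],
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for i in range(self.n):
            c = self.centroids[i]
            c2 = c[1] if c.shape[0] == 2 else [np.nan] * 3
            rows.append({
                "label": self.labels[i], "class": self.roi_class[i],
                "rsn": self.rsn[i], "network_class": self.network_class[i],
                "x1": c[0, 0], "y1": c[0, 1], "z1": c[0, 2],
                "x2": c2[0], "y2": c2[1], "z2": c2[2],
                "voxel_count": int(self.voxel_counts[i]),
            })
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Parcellation":
        df = pd.read_csv(path, sep="\t")
        centroids = []
        for _, row in df.iterrows():
            c1 = [row["x1"], row["y1"], row["z1"]]
            c2 = [row["x2"], row["y2"], row["z2"]]
            centroids.append([c1] if np.isnan(c2).all() else [c1, c2])
        return cls(
            labels=df["label"].tolist(),
            roi_class=df["class"].tolist(),
            rsn=df["rsn"].tolist(),
            centroids=centroids,
            voxel_counts=df["voxel_count"].to_numpy(),
            network_class=df["network_class"].tolist(),
        )


@dataclass
class TimeSeriesPanel:
    """Per-(subject, session) ROI x time matrices with a shared ROI ordering."""

    roi_labels: list[str]
    data: dict[tuple[str, str], np.ndarray]
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        n_roi = len(self.roi_labels)
        for key, mat in self.data.items():
            mat = np.asarray(mat, dtype=float)
            if mat.ndim != 2 or mat.shape[1] != n_roi:
                raise ValueError(
                    f"{key}: expected time x {n_roi} matrix, got {mat.shape}")
            self.data[key] = mat

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s, _ in self.data:
            seen.setdefault(s, None)
        return list(seen)

    @property
    def sessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, ses in self.data:
            seen.setdefault(ses, None)
        return list(seen)

    def sessions_of(self, subject: str) -> list[tuple[str, str]]:
        keys = [k for k in self.data if k[0] == subject]
        if not keys:
            raise KeyError(f"unknown subject {subject!r}")
        return sorted(keys)


@dataclass
class ConnectivityResult:
    """Group-level partial-correlation connectivity.

    ``binary[j, i] == 1`` iff regressor j had a significant influence on
    target i at the Bonferroni-corrected level; ``weighted`` holds the mean
    significant beta, rescaled so the largest magnitude is 1.
    """

    roi_labels: list[str]
    betas: dict[str, np.ndarray]
    t_matrix: np.ndarray
    dof: int
    binary: np.ndarray
    weighted: np.ndarray
    alpha: float
    n_comparisons: int

    def __post_init__(self) -> None:
        for name in ("t_matrix", "binary", "weighted"):
            mat = getattr(self, name)
            if np.any(np.diag(mat) != 0):
                raise ValueError(f"{name} must have a zero diagonal")
        if ((self.binary != 0) != (self.weighted != 0)).any():
            raise ValueError("binary and weighted supports must coincide")


@dataclass
class BinaryGraph:
    """Labelled 0/1 adjacency; ``subsets`` maps role names to index arrays."""

    adjacency: np.ndarray
    directed: bool = False
    labels: list[str] | None = None
    subsets: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not self.directed and not np.array_equal(A, A.T):
            raise ValueError("undirected graph requires symmetric adjacency")
        self.adjacency = A.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


# ---------------------------------------------------------------------------
# Delimited-matrix IO
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, sep: str = "\t") -> tuple[np.ndarray, list[str]]:
    """Read one time x ROI matrix with a header row of ROI labels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged matrix ({exc})") from exc
    labels = [str(c) for c in df.columns]
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{path}: non-numeric cells")
    if np.isnan(values).any():
        raise ValueError(f"{path}: ragged matrix or non-numeric cells (NaN found)")
    return values.astype(float), labels


def write_matrix(path: str | Path, matrix: np.ndarray,
                 labels: Sequence[str], sep: str = "\t") -> None:
    pd.DataFrame(np.asarray(matrix), columns=list(labels)).to_csv(
        path, sep=sep, index=False, float_format="%.17g")


def read_panel(
    files: Mapping[tuple[str, str], str | Path] | Iterable[tuple[str, str, str | Path]],
    tr_seconds: float = 0.72,
    sep: str = "\t",
    roi_labels: Sequence[str] | None = None,
) -> TimeSeriesPanel:
    """Read a multi-subject, multi-session panel of delimited matrices.

    ``files`` maps (subject, session) to a path, or is an iterable of
    (subject, session, path) triples. All files must agree on the header
    labels; when ``roi_labels`` is given, each file is additionally checked
    (and re-ordered) against it.
    """
    if isinstance(files, Mapping):
        items = [(s, ses, p) for (s, ses), p in files.items()]
    else:
        items = list(files)
    if not items:
        raise ValueError("no input files")
    data: dict[tuple[str, str], np.ndarray] = {}
    ref_labels = list(roi_labels) if roi_labels is not None else None
    for subject, session, path in items:
        values, labels = read_matrix(path, sep=sep)
        if ref_labels is None:
            ref_labels = labels
        elif labels != ref_labels:
            if sorted(labels) != sorted(ref_labels):
                unknown = sorted(set(labels) ^ set(ref_labels))
                raise ValueError(f"{path}: unknown or missing ROI labels {unknown}")
            order = [labels.index(l) for l in ref_labels]
            values = values[:, order]
        data[(str(subject), str(session))] = values
    return TimeSeriesPanel(roi_labels=ref_labels, data=data, tr_seconds=tr_seconds)


def write_panel(panel: TimeSeriesPanel, directory: str | Path,
                sep: str = "\t") -> dict[tuple[str, str], Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for (subject, session), mat in panel.data.items():
        path = directory / f"{subject}_{session}.tsv"
        write_matrix(path, mat, panel.roi_labels, sep=sep)
        out[(subject, session)] = path
    return out


def write_report(path: str | Path, report: dict) -> None:
    """JSON report writer; converts numpy scalars/arrays to plain Python."""

    def conv(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (set, frozenset)):
            return sorted(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=conv))


# ---------------------------------------------------------------------------
# Packaged convergence-table fixture
# ---------------------------------------------------------------------------

_TABLE1_RESOURCE = "table1_convergence.tsv"
_TABLE1_SHA256 = "919c4b78fa0c79191bd906e384d65114de123a24ab76c4c9dbadaf4f17fc2a23"

_SUBCORTICAL_NETWORK_OF = {
    "THA": "THA", "PUT": "BGN", "CAU": "BGN", "NAC": "BGN",
    "GPL": "BGN", "HIP": "SLN", "AMY": "SLN",
}


def _table1_text() -> str:
    text = (resources.files("corticosub") / "data" / _TABLE1_RESOURCE).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE1_SHA256:
        raise FixtureError(
            f"convergence-table fixture checksum mismatch: {digest}")
    return text


def table1_printed_counts() -> pd.Series:
    """The printed per-subcortical-ROI converging-connection counts."""
    df = pd.read_csv(pd.io.common.StringIO(_table1_text()), sep="\t")
    counts = df.drop_duplicates("subcortical_roi").set_index("subcortical_roi")
    return counts["printed_count"].astype(int)


def load_table1_fixture() -> tuple[Parcellation, BinaryGraph]:
    """Load the published cortico-subcortical convergence table.

    Returns the 27 subcortical ROIs plus the 71 distinct converging cortical
    ROIs (identity keyed on the printed bilateral centroids; duplicate names
    at different centroids stay distinct), and the symmetric bipartite
    adjacency with one edge per printed (subcortical, cortical) entry.
    Subcortical ROIs carry their subcortical network (THA/BGN/SLN) as RSN and
    a NaN centroid (the table prints cortical centroids only).
    """
    df = pd.read_csv(pd.io.common.StringIO(_table1_text()), sep="\t")
    sub_labels = df["subcortical_roi"].drop_duplicates().tolist()
    if len(sub_labels) != 27:
        raise FixtureError(f"expected 27 subcortical ROIs, found {len(sub_labels)}")

    edges = df[df["cortical_id"] != "-"]
    cort = edges.drop_duplicates("cortical_id")
    cort_labels = cort["cortical_id"].tolist()

    labels = sub_labels + cort_labels
    roi_class = (["subcortical"] * len(sub_labels)
                 + ["cerebellar" if r == "CER" else "cortical"
                    for r in cort["rsn"]])
    rsn = ([_SUBCORTICAL_NETWORK_OF[l.split("-")[0]] for l in sub_labels]
           + cort["rsn"].tolist())
    centroids: list[np.ndarray] = [np.full((1, 3), np.nan)] * len(sub_labels)
    for _, row in cort.iterrows():
        c1 = [row["x1"], row["y1"], row["z1"]]
        c2 = [row["x2"], row["y2"], row["z2"]]
        cent = np.array([c1]) if np.isnan(c2).any() else np.array([c1, c2])
        if not np.isfinite(cent).all():
            raise FixtureError(f"non-finite centroid for {row['cortical_id']}")
        centroids.append(cent)
    parcellation = Parcellation(
        labels=labels, roi_class=roi_class, rsn=rsn, centroids=centroids,
        voxel_counts=np.ones(len(labels), dtype=int),
        network_class=(["not_applicable"] * len(sub_labels)
                       + ["primary" if r in PRIMARY_NETWORKS else "association"
                          for r in cort["rsn"]]),
    )

    n = len(labels)
    adjacency = np.zeros((n, n), dtype=np.int8)
    pos = {lbl: i for i, lbl in enumerate(labels)}
    for _, row in edges.iterrows():
        i, j = pos[row["subcortical_roi"]], pos[row["cortical_id"]]
        adjacency[i, j] = adjacency[j, i] = 1

    degrees = adjacency[:len(sub_labels)].sum(axis=1)
    printed = df.drop_duplicates("subcortical_roi")["printed_count"].to_numpy()
    if not np.array_equal(degrees, printed):
        raise FixtureError("fixture edge counts disagree with printed counts")

    graph = BinaryGraph(
        adjacency=adjacency, directed=False, labels=labels,
        subsets={
            "subcortical": np.arange(len(sub_labels)),
            "cortical": np.arange(len(sub_labels), n),
        },
    )
    return parcellation, graph
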