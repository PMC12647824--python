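"""Clustered data containers and delimited-text readers.

Two input shapes are supported:

* two-sample clustered data (possibly right-censored): one record per
  subject with a cluster id, an outcome ``y`` (for survival data the
  observed time ``min(T, C)``), an optional event indicator, and a binary
  treatment-arm indicator;
* clustered paired data: one record per subunit with a cluster id, a
  subunit id and either a precomputed paired difference ``d`` or the pair
  ``(y1, y2)`` from which ``d = y2 - y1`` is formed.

Clusters are the independence units: observations within a cluster may be
arbitrarily correlated, observations in different clusters are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusteredDataset",
    "PairedClusteredDataset",
    "read_clustered_csv",
    "read_paired_csv",
]


def _as_cluster_codes(cluster_id) -> tuple[np.ndarray, np.ndarray]:
    """Map arbitrary cluster labels to integer codes 0..M-1 (order of first
    appearance, so results are invariant to the label values themselves)."""
    labels, codes = np.unique(np.asarray(cluster_id), return_inverse=True)
    return codes.astype(np.intp), labels


@dataclass(frozen=True)
class ClusteredDataset:
    """Two-sample clustered outcomes, optionally right-censored.

    Parameters
    ----------
    cluster_id : array-like
        Cluster label per subject (any hashable dtype).
    y : array-like of float
        Outcome per subject; for survival data the observed time
        ``min(T, C)``.
    arm : array-like of {0, 1}
        Treatment indicator (1 = treatment A).
    event : array-like of {0, 1}, optional
        Event indicator (1 = event observed). ``None`` means uncensored
        data and is treated as all ones.
    """

    cluster_id: np.ndarray
    y: np.ndarray
    arm: np.ndarray
    event: np.ndarray | None = None
    # derived, set in __post_init__
    cluster: np.ndarray = field(init=False, repr=False)
    cluster_labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        arm = np.asarray(self.arm)
        if y.size == 0:
            raise ValueError("dataset must contain at least one record")
        bad = np.flatnonzero(~np.isfinite(y))
        if bad.size:
            raise ValueError(f"non-finite outcome y at record index {bad[0]}")
        if not np.isin(arm, (0, 1)).all():
            raise ValueError("arm indicator must be strictly binary (0/1)")
        event = self.event
        if event is not None:
            event = np.asarray(event)
            if not np.isin(event, (0, 1)).all():
                raise ValueError("event indicator must be strictly binary (0/1)")
            if event.shape != y.shape:
                raise ValueError("event and y must have equal length")
            object.__setattr__(self, "event", event.astype(np.int8))
        if arm.shape != y.shape:
            raise ValueError("arm and y must have equal length")
        codes, labels = _as_cluster_codes(self.cluster_id)
        if codes.shape != y.shape:
            raise ValueError("cluster_id and y must have equal length")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "arm", arm.astype(np.int8))
        object.__setattr__(self, "cluster", codes)
        object.__setattr__(self, "cluster_labels", labels)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.size)

    @property
    def n_subjects(self) -> int:
        return int(self.y.size)

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster, minlength=self.n_clusters)

    def events(self) -> np.ndarray:
        """Event indicators, defaulting to all observed when absent."""
        if self.event is None:
            return np.ones(self.n_subjects, dtype=np.int8)
        return self.event

    def with_y(self, y: np.ndarray) -> "ClusteredDataset":
        """Copy with replaced outcomes (used by effect-shift adjustment)."""
        return ClusteredDataset(self.cluster_id, y, self.arm, self.event)


@dataclass(frozen=True)
class PairedClusteredDataset:
    """Clustered paired differences (one record per subunit)."""

    cluster_id: np.ndarray
    d: np.ndarray
    subunit_id: np.ndarray | None = None
    cluster: np.ndarray = field(init=False, repr=False)
    cluster_labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.size == 0:
            raise ValueError("dataset must contain at least one record")
        bad = np.flatnonzero(~np.isfinite(d))
        if bad.size:
            raise ValueError(f"non-finite difference d at record index {bad[0]}")
        codes, labels = _as_cluster_codes(self.cluster_id)
        if codes.shape != d.shape:
            raise ValueError("cluster_id and d must have equal length")
        object.__setattr__(self, "d", d)
        object.__setattr__(self, "cluster", codes)
        object.__setattr__(self, "cluster_labels", labels)

    @classmethod
    def from_pairs(cls, cluster_id, y1, y2, subunit_id=None) -> "PairedClusteredDataset":
        d = np.asarray(y2, dtype=float) - np.asarray(y1, dtype=float)
        return cls(cluster_id, d, subunit_id)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_labels.size)

    @property
    def n_subunits(self) -> int:
        return int(self.d.size)

    def with_d(self, d: np.ndarray) -> "PairedClusteredDataset":
        return PairedClusteredDataset(self.cluster_id, d, self.subunit_id)


def _read_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


def read_clustered_csv(path) -> ClusteredDataset:
    """Read two-sample clustered data from CSV/TSV.

    Required columns: ``cluster``, ``y``, ``arm``; optional ``event``.
    Extra columns are ignored.
    """
    df = _read_table(path)
    _require(df, ["cluster", "y", "arm"], path)
    event = df["event"].to_numpy() if "event" in df.columns else None
    return ClusteredDataset(df["cluster"].to_numpy(), df["y"].to_numpy(),
                            df["arm"].to_numpy(), event)


def read_paired_csv(path) -> PairedClusteredDataset:
    """Read clustered paired data from CSV/TSV.

    Accepts either a ``d`` column or the pair ``y1``/``y2`` (then
    ``d = y2 - y1``). Requires ``cluster``; ``subunit`` is optional.
    """
    df = _read_table(path)
    _require(df, ["cluster"], path)
    sub = df["subunit"].to_numpy() if "subunit" in df.columns else None
    if "d" in df.columns:
        return PairedClusteredDataset(df["cluster"].to_numpy(), df["d"].to_numpy(), sub)
    _require(df, ["y1", "y2"], path)
    return PairedClusteredDataset.from_pairs(
        df["cluster"].to_numpy(), df["y1"].to_numpy(), df["y2"].to_numpy(), sub
    )
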