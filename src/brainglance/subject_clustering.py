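"""Exemplar-based subject clustering via affinity propagation.

Affinity propagation (AP) picks actual subjects as cluster exemplars by
exchanging responsibility and availability messages, and needs no
a-priori cluster count — both properties that make it suitable for
summarizing a cohort by a representative subset of its members.

The similarity between subjects is the negative squared Euclidean
distance between their region-vector columns; the shared preference
defaults to the median off-diagonal similarity, which yields a moderate
number of clusters.  Message passing is implemented here directly so
that a non-converged run still returns a usable (flagged) partition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .region_extraction import RegionMatrix
from .volumes import ScalarVolume, ValidationError


@dataclass
class APParameters:
    """Affinity-propagation hyperparameters.

    Defaults favour stability over speed: heavy damping, a long run
    budget and a 50-iteration stable window before declaring
    convergence.
    """

    damping: float = 0.9
    preference: float | str = "median"
    max_iterations: int = 1000
    convergence_window: int = 50

    def __post_init__(self):
        if not (0.5 <= self.damping < 1.0):
            raise ValidationError(f"damping must be in [0.5, 1), got {self.damping}")
        if self.max_iterations < 1 or self.convergence_window < 1:
            raise ValidationError("iteration counts must be positive")
        if isinstance(self.preference, str) and self.preference != "median":
            raise ValidationError(f"preference must be a number or 'median', got {self.preference!r}")


@dataclass
class ClusterResult:
    """Exemplar-based partition of the subjects.

    ``assignments[j]`` is the cluster id of subject j; each cluster's
    exemplar is one of its own members; ``order`` is the display order
    (descending size, ties broken by exemplar index).
    """

    assignments: np.ndarray
    exemplars: dict[int, int]
    sizes: dict[int, int]
    order: list[int]
    converged: bool
    n_iterations: int
    subject_ids: list[str] | None = None
    parameters: APParameters | None = None

    def __post_init__(self):
        a = np.asarray(self.assignments, dtype=int)
        ids = set(a.tolist())
        if ids != set(self.exemplars):
            raise ValidationError("cluster ids of assignments and exemplars differ")
        for cid, ex in self.exemplars.items():
            if a[ex] != cid:
                raise ValidationError(f"exemplar {ex} is not a member of its cluster {cid}")
        if sum(self.sizes.values()) != a.size:
            raise ValidationError("cluster sizes do not sum to the number of subjects")
        if sorted(self.order) != sorted(self.exemplars):
            raise ValidationError("order must list every cluster id exactly once")
        self.assignments = a

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster_id)

    def to_json(self, path=None) -> str:
        obj = {
            "assignments": self.assignments.tolist(),
            "exemplars": {str(k): int(v) for k, v in self.exemplars.items()},
            "sizes": {str(k): int(v) for k, v in self.sizes.items()},
            "order": self.order,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "subject_ids": self.subject_ids,
            "parameters": None
            if self.parameters is None
            else {
                "damping": self.parameters.damping,
                "preference": self.parameters.preference,
                "max_iterations": self.parameters.max_iterations,
                "convergence_window": self.parameters.convergence_window,
            },
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ClusterResult":
        s = str(source)
        text = Path(s).read_text() if "\n" not in s and Path(s).exists() else s
        obj = json.loads(text)
        params = obj.get("parameters")
        return cls(
            assignments=np.array(obj["assignments"], dtype=int),
            exemplars={int(k): v for k, v in obj["exemplars"].items()},
            sizes={int(k): v for k, v in obj["sizes"].items()},
            order=list(obj["order"]),
            converged=obj["converged"],
            n_iterations=obj["n_iterations"],
            subject_ids=obj.get("subject_ids"),
            parameters=None if params is None else APParameters(**params),
        )


def binarize_matrix(S: RegionMatrix, threshold: float) -> RegionMatrix:
    """Threshold S to {0, 1}: 1 where value > threshold. Missing stays missing."""
    if not np.isfinite(threshold):
        raise ValidationError("binarization threshold must be finite")
    vals = np.where(S.values > threshold, 1.0, 0.0)
    vals[~np.isfinite(S.values)] = np.nan
    return RegionMatrix(
        vals,
        list(S.region_labels),
        list(S.region_names),
        list(S.subject_ids),
        f"binary({S.statistic}>{threshold:g})",
        S.sizes,
    )


def _affinity_propagation(
    sim: np.ndarray, params: APParameters
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Responsibility/availability message passing on a similarity matrix.

    Returns (exemplar indices, per-sample exemplar index, converged,
    iterations run).  Ties are broken deterministically by lowest index.
    """
    n = sim.shape[0]
    lam = params.damping
    R = np.zeros((n, n))
    A = np.zeros((n, n))
    idx = np.arange(n)
    prev_exemplars: frozenset | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        # responsibilities
        AS = A + sim
        first = AS.argmax(axis=1)
        first_val = AS[idx, first]
        AS[idx, first] = -np.inf
        second_val = AS.max(axis=1)
        Rnew = sim - first_val[:, None]
        Rnew[idx, first] = sim[idx, first] - second_val
        R = lam * R + (1 - lam) * Rnew
        # availabilities
        Rp = np.maximum(R, 0.0)
        np.fill_diagonal(Rp, np.diag(R))
        colsum = Rp.sum(axis=0)
        Anew = colsum[None, :] - Rp
        diag = np.diag(Anew).copy()
        Anew = np.minimum(Anew, 0.0)
        np.fill_diagonal(Anew, diag)
        A = lam * A + (1 - lam) * Anew

        exemplars = frozenset(np.flatnonzero(np.diag(A) + np.diag(R) > 0).tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= params.convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars

    E = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
    if E.size == 0:
        # no positive evidence for any exemplar: fall back to the single
        # best candidate so a valid partition is always returned
        E = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
    labels = E[np.argmax(sim[:, E], axis=1)]
    labels[E] = E
    return E, labels, converged, it


def cluster_subjects(
    S: RegionMatrix,
    params: APParameters | None = None,
    binarize: float | None = None,
) -> ClusterResult:
    """Partition the subjects of S by affinity propagation.

    ``binarize`` optionally thresholds S first (the binary-matrix
    variant); by default the continuous values are clustered.  Missing
    entries are rejected — impute or drop the affected regions first.
    """
    params = params or APParameters()
    if binarize is not None:
        S = binarize_matrix(S, binarize)
    X = S.values.T  # subjects as samples
    if X.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 subjects")
    if not np.all(np.isfinite(X)):
        raise ValidationError(
            "region matrix has missing entries; impute them or exclude the "
            "affected regions before clustering"
        )
    sq = np.sum(X**2, axis=1)
    sim = -(sq[:, None] + sq[None, :] - 2.0 * X @ X.T)
    np.fill_diagonal(sim, 0.0)
    if np.all(sim == 0.0):
        # zero-distance degenerate case: every subject is identical, so the
        # only sensible partition is a single cluster around subject 0
        n = X.shape[0]
        return ClusterResult(
            assignments=np.zeros(n, dtype=int),
            exemplars={0: 0},
            sizes={0: n},
            order=[0],
            converged=True,
            n_iterations=0,
            subject_ids=list(S.subject_ids),
            parameters=params,
        )
    if isinstance(params.preference, str):
        off = sim[~np.eye(sim.shape[0], dtype=bool)]
        pref = float(np.median(off))
    else:
        pref = float(params.preference)
    np.fill_diagonal(sim, pref)

    E, exemplar_of, converged, n_iter = _affinity_propagation(sim, params)
    if not converged:
        warnings.warn(
            f"affinity propagation did not converge within {params.max_iterations} "
            "iterations; returning the current (unstable) partition",
            stacklevel=2,
        )
    # cluster ids 0..k-1 in exemplar-index order
    id_of = {int(ex): cid for cid, ex in enumerate(sorted(int(e) for e in E))}
    assignments = np.array([id_of[int(e)] for e in exemplar_of])
    exemplars = {cid: ex for ex, cid in id_of.items()}
    sizes = {cid: int(np.sum(assignments == cid)) for cid in exemplars}
    order = sorted(exemplars, key=lambda cid: (-sizes[cid], exemplars[cid]))
    return ClusterResult(
        assignments=assignments,
        exemplars=exemplars,
        sizes=sizes,
        order=order,
        converged=converged,
        n_iterations=n_iter,
        subject_ids=list(S.subject_ids),
        parameters=params,
    )


def summarize_clusters(
    S: RegionMatrix, clusters: ClusterResult, statistic: str = "mean"
) -> RegionMatrix:
    """Condense S to one column per cluster, in display order.

    ``statistic="mean"`` averages the (un-binarized) member columns,
    ignoring missing entries; ``"exemplar"`` takes the exemplar subject's
    column.  Cluster sizes are carried for row-height scaling.
    """
    if statistic not in ("mean", "exemplar"):
        raise ValidationError(f"unknown cluster statistic {statistic!r}")
    if clusters.assignments.size != S.N:
        raise ValidationError(
            f"cluster assignments cover {clusters.assignments.size} subjects, "
            f"matrix has {S.N}"
        )
    cols, ids, sizes = [], [], []
    for cid in clusters.order:
        members = clusters.members(cid)
        if statistic == "mean":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                cols.append(np.nanmean(S.values[:, members], axis=1))
        else:
            cols.append(S.values[:, clusters.exemplars[cid]].copy())
        ex_id = (
            S.subject_ids[clusters.exemplars[cid]]
            if S.subject_ids
            else str(clusters.exemplars[cid])
        )
        ids.append(f"{ex_id} (n={clusters.sizes[cid]})")
        sizes.append(clusters.sizes[cid])
    return RegionMatrix(
        np.column_stack(cols),
        list(S.region_labels),
        list(S.region_names),
        ids,
        f"cluster-{statistic}({S.statistic})",
        sizes,
    )


def cluster_mean_volumes(
    maps: list[ScalarVolume], clusters: ClusterResult
) -> list[ScalarVolume]:
    """Voxel-wise mean map per cluster (one input map per subject)."""
    if len(maps) != clusters.assignments.size:
        raise ValidationError("need exactly one map per clustered subject")
    shape = maps[0].grid.shape
    for m in maps[1:]:
        if m.grid.shape != shape:
            raise ValidationError(
                f"maps are not on one grid: {m.grid.shape} vs {shape}"
            )
    out = []
    for cid in clusters.order:
        members = clusters.members(cid)
        mean = np.mean(np.stack([maps[j].grid for j in members]), axis=0)
        out.append(
            ScalarVolume(mean, maps[0].voxel_size, f"cluster-{cid}", maps[0].affine)
        )
    return out
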