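"""Reduce per-subject 3D maps to one value per atlas area.

The central object is the region-by-subject matrix ``S`` (M areas ×
N subjects), where ``S[i, j]`` summarizes the map of subject ``j``
over all voxels of area ``i``.  The default summary is the voxel mean;
min, max, sample standard deviation and median are also available.
Regions with zero voxels in a subject's label volume yield an explicit
missing value (NaN), never a silent zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas_model import AtlasDefinition
from .volumes import (
    LabelVolume,
    ScalarVolume,
    ValidationError,
    load_label_volume,
    load_scalar_volume,
)

STATISTICS = ("mean", "min", "max", "sd", "median")


def _summary(values: np.ndarray, statistic: str) -> float:
    if statistic == "mean":
        return float(np.mean(values))
    if statistic == "min":
        return float(np.min(values))
    if statistic == "max":
        return float(np.max(values))
    if statistic == "sd":
        # sample sd; a single-voxel region has no spread
        return float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if statistic == "median":
        return float(np.median(values))
    raise ValidationError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")


@dataclass
class SubjectRecord:
    """One subject: a scalar map plus a coregistered label volume."""

    subject_id: str
    map_path: str | Path
    atlas_path: str | Path

    def validate(self) -> None:
        for p in (self.map_path, self.atlas_path):
            if not Path(p).exists():
                raise ValidationError(f"subject {self.subject_id}: file not found: {p}")


@dataclass
class RegionMatrix:
    """M regions × N subjects matrix of scalar summaries.

    Missing entries (region absent from a subject's label volume) are
    NaN.  ``sizes`` is set on cluster-level matrices and carries member
    counts for row-height scaling in the rendering.
    """

    values: np.ndarray
    region_labels: list[int]
    region_names: list[str]
    subject_ids: list[str]
    statistic: str = "mean"
    sizes: list[int] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError(f"region matrix must be 2D, got shape {v.shape}")
        if v.shape != (len(self.region_labels), len(self.subject_ids)):
            raise ValidationError(
                f"matrix shape {v.shape} does not match {len(self.region_labels)} "
                f"regions x {len(self.subject_ids)} subjects"
            )
        if len(self.region_names) != len(self.region_labels):
            raise ValidationError("region_names and region_labels lengths differ")
        if self.sizes is not None and len(self.sizes) != len(self.subject_ids):
            raise ValidationError("sizes must have one entry per column")
        self.values = v

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def N(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path=None) -> str:
        """TSV: comment header, then label / name / one column per subject.

        Values are written with 12 significant digits, which round-trips
        bit-exactly through :meth:`from_tsv`.
        """
        lines = [f"# statistic: {self.statistic}"]
        if self.sizes is not None:
            lines.append("# sizes: " + ",".join(map(str, self.sizes)))
        lines.append("label\tname\t" + "\t".join(self.subject_ids))
        for i in range(self.M):
            cells = [
                "nan" if not np.isfinite(x) else format(x, ".12g")
                for x in self.values[i]
            ]
            lines.append(f"{self.region_labels[i]}\t{self.region_names[i]}\t" + "\t".join(cells))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source) -> "RegionMatrix":
        s = str(source)
        text = Path(s).read_text() if "\n" not in s and Path(s).exists() else s
        statistic, sizes = "mean", None
        rows, labels, names, subject_ids = [], [], [], None
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("statistic:"):
                    statistic = body.split(":", 1)[1].strip()
                elif body.startswith("sizes:"):
                    sizes = [int(s) for s in body.split(":", 1)[1].split(",")]
                continue
            fields = line.split("\t")
            if subject_ids is None:
                subject_ids = fields[2:]
                continue
            labels.append(int(fields[0]))
            names.append(fields[1])
            rows.append([float(x) for x in fields[2:]])
        if subject_ids is None:
            raise ValidationError("region matrix TSV has no header row")
        return cls(np.array(rows, dtype=float).reshape(len(labels), len(subject_ids)),
                   labels, names, subject_ids, statistic, sizes)

    def to_json(self, path=None) -> str:
        obj = {
            "statistic": self.statistic,
            "region_labels": self.region_labels,
            "region_names": self.region_names,
            "subject_ids": self.subject_ids,
            "sizes": self.sizes,
            "values": [[None if not np.isfinite(x) else x for x in row] for row in self.values],
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def extract_region_values(
    map_vol: ScalarVolume,
    atlas: LabelVolume,
    definition: AtlasDefinition,
    statistic: str = "mean",
) -> np.ndarray:
    """Summarize one subject's map over every atlas area.

    Returns a length-M vector in definition order; zero-voxel regions are
    NaN.  Non-finite map voxels inside a region are excluded from the
    statistic and reported via a warning.
    """
    if statistic not in STATISTICS:
        raise ValidationError(f"unknown statistic {statistic!r}; choose from {STATISTICS}")
    if map_vol.grid.shape != atlas.grid.shape:
        raise ValidationError(
            f"map shape {map_vol.grid.shape} does not match atlas shape {atlas.grid.shape}"
        )
    flat_map = map_vol.grid.ravel()
    flat_lab = atlas.grid.ravel()
    out = np.full(definition.M, np.nan)
    n_dropped = 0
    for i, area in enumerate(definition.areas):
        vox = flat_map[flat_lab == area.label]
        if vox.size == 0:
            continue
        finite = np.isfinite(vox)
        if not finite.all():
            n_dropped += int((~finite).sum())
            vox = vox[finite]
            if vox.size == 0:
                continue
        out[i] = _summary(vox, statistic)
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} non-finite voxel(s) from region statistics",
            stacklevel=2,
        )
    return out


def region_matrix_from_volumes(
    maps: list[ScalarVolume],
    atlases: list[LabelVolume],
    subject_ids: list[str],
    definition: AtlasDefinition,
    statistic: str = "mean",
) -> RegionMatrix:
    """Assemble S from in-memory volumes (one map + atlas per subject)."""
    if not maps:
        raise ValidationError("need at least one subject")
    if not (len(maps) == len(atlases) == len(subject_ids)):
        raise ValidationError("maps, atlases and subject_ids must have equal length")
    cols = []
    for sid, m, a in zip(subject_ids, maps, atlases):
        try:
            cols.append(extract_region_values(m, a, definition, statistic))
        except BaseException as exc:
            raise ValidationError(f"extraction failed for subject {sid}: {exc}") from exc
    return RegionMatrix(
        np.column_stack(cols),
        list(definition.labels),
        [a.name_area for a in definition.areas],
        list(subject_ids),
        statistic,
    )


def build_region_matrix(
    records: list[SubjectRecord],
    definition: AtlasDefinition,
    statistic: str = "mean",
) -> RegionMatrix:
    """Assemble S from per-subject NIfTI files, in record order."""
    if not records:
        raise ValidationError("need at least one subject record")
    maps, atlases, ids = [], [], []
    for rec in records:
        rec.validate()
        try:
            maps.append(load_scalar_volume(rec.map_path))
            atlases.append(load_label_volume(rec.atlas_path))
        except ValidationError:
            raise
        except BaseException as exc:
            raise ValidationError(f"failed loading subject {rec.subject_id}: {exc}") from exc
        ids.append(rec.subject_id)
    return region_matrix_from_volumes(maps, atlases, ids, definition, statistic)


def average_sessions(matrices: list[RegionMatrix]) -> RegionMatrix:
    """Element-wise mean of per-session matrices, ignoring missing entries.

    All matrices must share region and subject orderings; an entry is
    missing in the result only when missing in every session.
    """
    if not matrices:
        raise ValidationError("need at least one session matrix")
    first = matrices[0]
    for m in matrices[1:]:
        if m.region_labels != first.region_labels or m.subject_ids != first.subject_ids:
            raise ValidationError("session matrices differ in region or subject ordering")
    stack = np.stack([m.values for m in matrices])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return RegionMatrix(
        mean,
        list(first.region_labels),
        list(first.region_names),
        list(first.subject_ids),
        first.statistic,
    )
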