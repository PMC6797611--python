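"""Atlas description model and the mirror-symmetric display column layout.

An atlas is described by a table mapping each integer label found in the
parcellation volume to a short area name (e.g. ``INS_6_1``), a gross
anatomical region tag used for visual grouping (e.g. ``FRO``, ``INS``,
``TEM``) and a hemisphere (``L`` or ``R``).  From this description we
derive the display ordering of the figure's columns: left-hemisphere
areas on the left half, right-hemisphere areas on the right half, with
the within-hemisphere order mirrored so that the innermost columns of
both halves show the same (gross region, area) pair.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volumes import LabelVolume, ValidationError

#: Default column indices of the description table:
#: label, area name, gross-region tag, hemisphere.
DEFAULT_COLUMN_MAP = {
    "label": 0,
    "name_area": 1,
    "name_largescale_region": 2,
    "hemisphere": 3,
}


@dataclass(frozen=True)
class AtlasArea:
    """One labeled brain area of the parcellation."""

    label: int
    name_area: str
    name_largescale_region: str
    hemisphere: str

    def __post_init__(self):
        if int(self.label) < 1:
            raise ValidationError(
                f"area label must be >= 1 (0 is background), got {self.label}"
            )
        object.__setattr__(self, "label", int(self.label))
        if not self.name_area:
            raise ValidationError("name_area must be non-empty")
        if self.hemisphere not in ("L", "R"):
            raise ValidationError(
                f"hemisphere must be 'L' or 'R', got {self.hemisphere!r} "
                f"(area {self.name_area})"
            )


class AtlasDefinition:
    """Ordered catalogue of :class:`AtlasArea` with unique labels."""

    def __init__(self, areas=()):
        self._areas: list[AtlasArea] = []
        self._by_label: dict[int, AtlasArea] = {}
        for a in areas:
            self.add_area(a)

    def add_area(self, area: AtlasArea) -> None:
        if area.label in self._by_label:
            raise ValidationError(f"duplicate atlas label {area.label}")
        self._areas.append(area)
        self._by_label[area.label] = area

    @property
    def areas(self) -> tuple[AtlasArea, ...]:
        return tuple(self._areas)

    @property
    def M(self) -> int:
        """Total number of brain areas."""
        return len(self._areas)

    @property
    def labels(self) -> list[int]:
        return [a.label for a in self._areas]

    def area(self, label: int) -> AtlasArea:
        return self._by_label[label]

    def __len__(self) -> int:
        return self.M

    def __eq__(self, other) -> bool:
        return isinstance(other, AtlasDefinition) and self.areas == other.areas

    def mirror_violations(self) -> list[str]:
        """Areas whose (gross region, name) pair is absent contralaterally.

        Reported, not fatal: the layout keeps such areas at the outer
        edge of their hemisphere's half.
        """
        by_hemi = {"L": set(), "R": set()}
        for a in self._areas:
            by_hemi[a.hemisphere].add((a.name_largescale_region, a.name_area))
        msgs = []
        for a in self._areas:
            other = "R" if a.hemisphere == "L" else "L"
            if (a.name_largescale_region, a.name_area) not in by_hemi[other]:
                msgs.append(
                    f"area {a.label} ({a.hemisphere} {a.name_largescale_region} "
                    f"{a.name_area}) has no contralateral partner"
                )
        return msgs

    def to_table(self, delimiter: str = "\t") -> str:
        """Serialize in the default column order (round-trips via parse)."""
        lines = ["# label\tname_area\tname_largescale_region\themisphere".replace("\t", delimiter)]
        for a in self._areas:
            lines.append(
                delimiter.join(
                    [str(a.label), a.name_area, a.name_largescale_region, a.hemisphere]
                )
            )
        return "\n".join(lines) + "\n"


def parse_atlas_description(
    table_text: str,
    column_map: dict[str, int] | None = None,
    delimiter: str = "\t",
    comment: str = "#",
    skip_header: bool = False,
) -> AtlasDefinition:
    """Parse a delimited atlas description table.

    Lines starting with ``comment`` and blank lines are skipped; the first
    data row is additionally skipped when ``skip_header`` is true.
    Hemisphere values are upper-cased before validation, matching the
    convention of common atlas description files.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    missing = {"label", "name_area", "name_largescale_region", "hemisphere"} - set(cmap)
    if missing:
        raise ValidationError(f"column_map lacks fields: {sorted(missing)}")
    definition = AtlasDefinition()
    n_rows = 0
    for raw in table_text.splitlines():
        line = raw.strip()
        if not line or line.startswith(comment):
            continue
        n_rows += 1
        if skip_header and n_rows == 1:
            continue
        fields = line.split(delimiter)
        try:
            label_s = fields[cmap["label"]]
            name_area = fields[cmap["name_area"]].strip()
            region = fields[cmap["name_largescale_region"]].strip().upper()
            hemi = fields[cmap["hemisphere"]].strip().upper()
        except IndexError:
            raise ValidationError(
                f"row {n_rows} has {len(fields)} columns; column_map addresses "
                f"index {max(cmap.values())}"
            ) from None
        try:
            label = int(label_s)
        except ValueError:
            raise ValidationError(f"row {n_rows}: label {label_s!r} is not an integer") from None
        definition.add_area(AtlasArea(label, name_area, region, hemi))
    if definition.M == 0:
        raise ValidationError("atlas description table contains no data rows")
    return definition


@dataclass
class ValidationReport:
    """Cross-check of a label volume against an atlas definition."""

    unknown_labels: list[int]
    empty_labels: list[int]
    voxel_counts: dict[int, int]

    @property
    def ok(self) -> bool:
        return not self.unknown_labels and not self.empty_labels

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "unknown_labels": self.unknown_labels,
                "empty_labels": self.empty_labels,
                "voxel_counts": {str(k): v for k, v in self.voxel_counts.items()},
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = []
        if self.unknown_labels:
            lines.append(
                "labels present in the volume but absent from the definition: "
                + ", ".join(map(str, self.unknown_labels))
            )
        if self.empty_labels:
            lines.append(
                "definition labels with zero voxels (will be missing downstream): "
                + ", ".join(map(str, self.empty_labels))
            )
        if not lines:
            lines.append("label volume is consistent with the atlas definition")
        lines.append(f"voxel counts: {self.voxel_counts}")
        return "\n".join(lines)


def validate_label_volume(vol: LabelVolume, definition: AtlasDefinition) -> ValidationReport:
    """Report unknown labels, empty regions and per-label voxel counts.

    A warped atlas can silently lose small regions or carry stray labels;
    this guard surfaces both before extraction.
    """
    present, counts = np.unique(vol.grid, return_counts=True)
    count_of = {int(l): int(c) for l, c in zip(present, counts) if l > 0}
    def_labels = set(definition.labels)
    unknown = sorted(l for l in count_of if l not in def_labels)
    empty = [l for l in definition.labels if l not in count_of]
    voxel_counts = {l: count_of.get(l, 0) for l in definition.labels}
    return ValidationReport(unknown, empty, voxel_counts)


@dataclass
class ColumnLayout:
    """Mirror-symmetric ordering of the display columns.

    ``columns`` holds one ``(label, name_area, name_largescale_region,
    hemisphere)`` tuple per area; the first ``hemisphere_boundary``
    entries are the left-hemisphere half.  ``group_boundaries`` are the
    column indices where a gross-region group starts (used for visual
    separators).
    """

    columns: list[tuple[int, str, str, str]]
    group_boundaries: list[int]
    hemisphere_boundary: int
    warnings: list[str] = field(default_factory=list)

    @property
    def labels(self) -> list[int]:
        return [c[0] for c in self.columns]

    def __len__(self) -> int:
        return len(self.columns)


def _group_by_region(areas: list[AtlasArea]) -> list[AtlasArea]:
    """Reorder so each gross region is contiguous, regions in order of
    first appearance, areas within a region in input order."""
    order: list[str] = []
    for a in areas:
        if a.name_largescale_region not in order:
            order.append(a.name_largescale_region)
    out = []
    for region in order:
        out.extend(a for a in areas if a.name_largescale_region == region)
    return out


def build_column_layout(definition: AtlasDefinition) -> ColumnLayout:
    """Derive the mirror-symmetric column ordering.

    Left half: all L areas grouped by gross region in definition order.
    Right half: the paired R areas with group order and within-group
    order reversed, so the innermost columns of both halves correspond
    to the same (gross region, area) pair.  Areas without a contralateral
    partner are kept at the outer edge of their half, with a warning.
    """
    if definition.M == 0:
        raise ValidationError("cannot lay out an empty atlas definition")
    left = [a for a in definition.areas if a.hemisphere == "L"]
    right = [a for a in definition.areas if a.hemisphere == "R"]

    # pair L and R areas one-to-one by (gross region, area name)
    pool: dict[tuple[str, str], list[AtlasArea]] = {}
    for a in right:
        pool.setdefault((a.name_largescale_region, a.name_area), []).append(a)
    mirrored_left, partners = [], []
    unmirrored_left = []
    for a in left:
        key = (a.name_largescale_region, a.name_area)
        if pool.get(key):
            mirrored_left.append(a)
            partners.append(pool[key].pop(0))
        else:
            unmirrored_left.append(a)
    unmirrored_right = [a for rest in pool.values() for a in rest]
    # keep unmatched R areas in definition order
    unmirrored_right.sort(key=lambda a: definition.labels.index(a.label))

    msgs = []
    for a in unmirrored_left + unmirrored_right:
        msgs.append(
            f"area {a.label} ({a.hemisphere} {a.name_largescale_region} "
            f"{a.name_area}) has no contralateral partner; placed at the "
            f"outer edge of the {a.hemisphere} half"
        )
    for m in msgs:
        warnings.warn(m, stacklevel=2)

    grouped_left = _group_by_region(mirrored_left)
    partner_of = dict(zip((id(a) for a in mirrored_left), partners))
    grouped_partners = [partner_of[id(a)] for a in grouped_left]

    left_half = _group_by_region(unmirrored_left) + grouped_left
    right_half = list(reversed(grouped_partners)) + _group_by_region(unmirrored_right)

    ordered = left_half + right_half
    columns = [
        (a.label, a.name_area, a.name_largescale_region, a.hemisphere) for a in ordered
    ]
    boundaries = [0] if columns else []
    for i in range(1, len(ordered)):
        prev, cur = ordered[i - 1], ordered[i]
        if (
            cur.name_largescale_region != prev.name_largescale_region
            or cur.hemisphere != prev.hemisphere
        ):
            boundaries.append(i)
    return ColumnLayout(
        columns=columns,
        group_boundaries=boundaries,
        hemisphere_boundary=len(left_half),
        warnings=msgs,
    )
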