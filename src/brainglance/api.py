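"""Object-style convenience front end.

Mirrors the incremental workflow of describing the atlas area by area,
adding subjects one by one, and finally drawing the fingerprint figure::

    bg = BrainGlance()
    bg.add_atlas_definition_area(1, "area1", "FRO", "L")
    bg.add_atlas_definition_area(2, "area1", "FRO", "R")
    bg.add_subject("sub01_map.nii.gz", "sub01_atlas.nii.gz", "subject-01")
    bg.draw_fingerprint("fingerprint.svg")
"""

from __future__ import annotations

from .atlas_model import AtlasArea, AtlasDefinition, build_column_layout
from .region_extraction import RegionMatrix, SubjectRecord, build_region_matrix
from .render import GridGeometry, RenderStyle, render_brainglance
from .volumes import ValidationError


class BrainGlance:
    """Incrementally assembled fingerprint: atlas areas, subjects, figure."""

    def __init__(self, statistic: str = "mean", style: RenderStyle | None = None):
        self.definition = AtlasDefinition()
        self.records: list[SubjectRecord] = []
        self.statistic = statistic
        self.style = style or RenderStyle()
        self._matrix: RegionMatrix | None = None

    def add_atlas_definition_area(
        self, label: int, name_area: str, name_largescale_region: str, hemisphere: str
    ) -> None:
        """Register one atlas area; hemisphere is upper-cased before validation."""
        self.definition.add_area(
            AtlasArea(label, name_area, name_largescale_region.upper(), hemisphere.upper())
        )
        self._matrix = None

    def add_subject(self, fp_brainmap, fp_atlas, subject_id: str | None = None) -> None:
        """Add a subject's scalar map and coregistered label volume."""
        if subject_id is None:
            subject_id = f"subject-{len(self.records) + 1:02d}"
        self.records.append(SubjectRecord(subject_id, fp_brainmap, fp_atlas))
        self._matrix = None

    def get_region_matrix(self) -> RegionMatrix:
        if self._matrix is None:
            if self.definition.M == 0:
                raise ValidationError("no atlas areas defined")
            if not self.records:
                raise ValidationError("no subjects added")
            self._matrix = build_region_matrix(
                self.records, self.definition, self.statistic
            )
        return self._matrix

    def draw_fingerprint(self, fp_figure) -> GridGeometry:
        """Extract (if needed), lay out and render the fingerprint figure."""
        matrix = self.get_region_matrix()
        layout = build_column_layout(self.definition)
        return render_brainglance(matrix, layout, self.style, fp_figure)
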