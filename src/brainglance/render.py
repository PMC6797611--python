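"""Draw the fingerprint grid: all subjects × all brain areas at one glance.

Each cell is a square whose color encodes one subject's summary value in
one brain area.  Columns follow the mirror-symmetric atlas layout (left
hemisphere on the left, right on the right, a wider separator between
the halves, thin separators between gross-region groups); rows are
subjects, or clusters whose height scales with the logarithm of the
cluster size.  Color normalization is global across the whole matrix by
default so values are comparable across subjects within a column.
Missing cells (regions without voxels in a subject's atlas) are drawn
hatched grey, never as a fake zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
from matplotlib.backends.backend_agg import FigureCanvasAgg  # noqa: F401  (registers Agg)
from matplotlib.cm import ScalarMappable
from matplotlib.colors import LinearSegmentedColormap, Normalize
from matplotlib.figure import Figure
from matplotlib.patches import Rectangle

from .atlas_model import ColumnLayout
from .region_extraction import RegionMatrix
from .volumes import ValidationError

# positive values in orange, negative in blue
_BLUE_ORANGE = LinearSegmentedColormap.from_list(
    "blue_orange", ["#2166ac", "#f7f7f7", "#e08214"]
)
try:
    matplotlib.colormaps.register(_BLUE_ORANGE)
except ValueError:  # already registered
    pass

#: salt for SVG element ids, fixed so repeated renders are byte-identical
_SVG_HASHSALT = "brainglance"


@dataclass
class RenderStyle:
    colormap: str = "blue_orange"
    color_limits: tuple[float, float] | str = "auto"
    cell_size: int = 18
    separator_width: int = 6
    label_font_size: int = 6
    missing_cell_style: dict = field(
        default_factory=lambda: {"facecolor": "0.85", "hatch": "///", "edgecolor": "0.55"}
    )


def compute_row_heights(sizes) -> np.ndarray:
    """Row units per cluster: 1 + log10(size), so size 1 stays one unit."""
    sizes = np.asarray(sizes)
    if sizes.size and sizes.min() < 1:
        raise ValidationError(f"cluster sizes must be >= 1, got {sizes.min()}")
    return 1.0 + np.log10(sizes.astype(float))


def resolve_color_limits(values: np.ndarray, style: RenderStyle) -> tuple[float, float]:
    """Resolve 'auto' limits; explicit limits must be symmetric for signed data."""
    finite = values[np.isfinite(values)]
    has_pos = finite.size > 0 and finite.max() > 0
    has_neg = finite.size > 0 and finite.min() < 0
    if isinstance(style.color_limits, str):
        if style.color_limits != "auto":
            raise ValidationError(f"unknown color_limits {style.color_limits!r}")
        if finite.size == 0:
            return (-1.0, 1.0)
        if has_pos and has_neg:
            vmax = float(np.max(np.abs(finite)))
            return (-vmax, vmax)
        if not has_neg:
            return (0.0, float(finite.max()) or 1.0)
        return (float(finite.min()), 0.0)
    lo, hi = (float(style.color_limits[0]), float(style.color_limits[1]))
    if lo >= hi:
        raise ValidationError(f"color limits must be increasing, got ({lo}, {hi})")
    if has_pos and has_neg and not np.isclose(lo, -hi):
        raise ValidationError(
            f"data spans both signs; color limits must be symmetric about 0, got ({lo}, {hi})"
        )
    return (lo, hi)


def map_colors(
    values: np.ndarray,
    style: RenderStyle,
    limits: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linear value→color mapping (clipping outside the limits).

    Missing values get the missing-cell face color.  Returns an RGBA
    array of shape ``values.shape + (4,)``.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = limits if limits is not None else resolve_color_limits(values, style)
    cmap = matplotlib.colormaps[style.colormap]
    pos = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    rgba = cmap(np.where(np.isfinite(pos), pos, 0.0))
    missing_rgba = matplotlib.colors.to_rgba(style.missing_cell_style.get("facecolor", "0.85"))
    rgba[~np.isfinite(values)] = missing_rgba
    return rgba


@dataclass
class GridGeometry:
    """Internal layout of a rendered figure, checked before writing."""

    n_columns: int
    n_rows: int
    row_heights: np.ndarray
    column_x: np.ndarray
    hemisphere_boundary: int
    group_boundaries: list[int]
    color_limits: tuple[float, float]

    @property
    def total_row_units(self) -> float:
        return float(self.row_heights.sum())

    @property
    def total_width_units(self) -> float:
        return float(self.column_x[-1] + 1.0) if self.n_columns else 0.0


def _column_positions(layout: ColumnLayout, style: RenderStyle) -> np.ndarray:
    """Column left-edge x in cell units, with group and hemisphere gaps."""
    sep = style.separator_width / style.cell_size
    xs, x = [], 0.0
    for j in range(len(layout)):
        if j > 0:
            if j == layout.hemisphere_boundary:
                x += 3.0 * sep  # wider central separator between hemispheres
            elif j in layout.group_boundaries:
                x += sep
        xs.append(x)
        x += 1.0
    return np.array(xs)


def _draw_grid(ax, display, row_heights, col_x, colors, style):
    """Rectangles for one matrix panel; rows stacked top-down."""
    y_tops = np.concatenate([[0.0], np.cumsum(row_heights)])
    for r in range(display.shape[0]):
        for c in range(display.shape[1]):
            kwargs = {"facecolor": colors[r, c], "edgecolor": "none"}
            if not np.isfinite(display[r, c]):
                kwargs = dict(style.missing_cell_style)
                kwargs.setdefault("edgecolor", "0.55")
            ax.add_patch(
                Rectangle(
                    (col_x[c], -y_tops[r + 1]),
                    1.0,
                    row_heights[r],
                    **kwargs,
                )
            )
    ax.set_xlim(0, col_x[-1] + 1.0)
    ax.set_ylim(-y_tops[-1], 0)
    ax.set_aspect("equal")
    ax.axis("off")
    return y_tops


def _group_spans(layout: ColumnLayout, col_x: np.ndarray):
    """(start_x, end_x, 'HEMI REGION') for each contiguous gross-region group."""
    spans = []
    bounds = list(layout.group_boundaries) + [len(layout)]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        _, _, region, hemi = layout.columns[b0]
        spans.append((col_x[b0], col_x[b1 - 1] + 1.0, f"{hemi} {region}"))
    return spans


def _align_to_layout(matrix: RegionMatrix, layout: ColumnLayout) -> np.ndarray:
    """Subjects × layout-columns display array; layout columns absent from
    the matrix become missing."""
    known = set(layout.labels)
    unknown = [l for l in matrix.region_labels if l not in known]
    if unknown:
        raise ValidationError(
            f"matrix contains region label(s) not in the layout: {unknown[:5]}"
        )
    row_of = {l: i for i, l in enumerate(matrix.region_labels)}
    display = np.full((matrix.N, len(layout)), np.nan)
    for j, label in enumerate(layout.labels):
        if label in row_of:
            display[:, j] = matrix.values[row_of[label], :]
    return display


def _save(fig: Figure, output_path) -> None:
    path = Path(output_path)
    suffix = path.suffix.lower()
    meta = None
    if suffix == ".svg":
        meta = {"Date": None}
    elif suffix == ".pdf":
        meta = {"CreationDate": None}
    try:
        with matplotlib.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
            fig.savefig(str(path), metadata=meta) if meta else fig.savefig(str(path))
    except OSError as exc:
        raise ValidationError(f"cannot write figure to {path}: {exc}") from exc


def render_brainglance(
    matrix: RegionMatrix,
    layout: ColumnLayout,
    style: RenderStyle | None = None,
    output_path=None,
) -> GridGeometry:
    """Render the fingerprint grid and (optionally) write it to a file.

    Rows are the matrix columns (subjects or clusters, cluster height
    from :func:`compute_row_heights`), columns follow the layout.  The
    format is chosen by the output path's extension (.svg/.png/.pdf);
    SVG output is deterministic and diffable.  Returns the grid
    geometry, validated before writing.
    """
    style = style or RenderStyle()
    display = _align_to_layout(matrix, layout)
    row_heights = (
        compute_row_heights(matrix.sizes)
        if matrix.sizes is not None
        else np.ones(matrix.N)
    )
    col_x = _column_positions(layout, style)
    limits = resolve_color_limits(display, style)
    geom = GridGeometry(
        n_columns=len(layout),
        n_rows=matrix.N,
        row_heights=row_heights,
        column_x=col_x,
        hemisphere_boundary=layout.hemisphere_boundary,
        group_boundaries=list(layout.group_boundaries),
        color_limits=limits,
    )
    assert geom.n_columns == len(layout.columns)
    assert np.isclose(geom.total_row_units, row_heights.sum())

    if output_path is None:
        return geom

    colors = map_colors(display, style, limits)
    px = style.cell_size
    fig_w = (geom.total_width_units + 8.0) * px / 100.0 + 1.2  # room for labels + colorbar
    fig_h = (geom.total_row_units + 4.0) * px / 100.0 + 0.8
    fig = Figure(figsize=(fig_w, fig_h), dpi=100)
    ax = fig.add_axes([0.10, 0.12, 0.78, 0.76])
    y_tops = _draw_grid(ax, display, row_heights, col_x, colors, style)

    fs = style.label_font_size
    for j, (label, name, region, hemi) in enumerate(layout.columns):
        ax.text(col_x[j] + 0.5, -y_tops[-1] - 0.15, name, rotation=90,
                ha="center", va="top", fontsize=fs, clip_on=False)
    for x0, x1, text in _group_spans(layout, col_x):
        ax.text((x0 + x1) / 2.0, 0.25, text, ha="center", va="bottom",
                fontsize=fs + 1, clip_on=False)
    for r, sid in enumerate(matrix.subject_ids):
        ax.text(-0.3, -(y_tops[r] + y_tops[r + 1]) / 2.0, sid, ha="right",
                va="center", fontsize=fs, clip_on=False)

    sm = ScalarMappable(norm=Normalize(*limits), cmap=matplotlib.colormaps[style.colormap])
    cax = fig.add_axes([0.91, 0.2, 0.015, 0.6])
    cb = fig.colorbar(sm, cax=cax)
    cb.ax.tick_params(labelsize=fs)
    _save(fig, output_path)
    return geom


def render_comparison(
    result,
    layout: ColumnLayout,
    style: RenderStyle | None = None,
    output_path=None,
    title: str = "",
):
    """Two-panel figure for a native-vs-template comparison.

    Upper panel: mean difference (native minus template) per region.
    Lower panel: t statistic, shown only where significant at the
    result's alpha (non-significant regions are blanked).
    """
    style = style or RenderStyle()
    mean_mat = RegionMatrix(
        result.mean_difference[:, None],
        list(result.region_labels),
        list(result.region_names),
        ["mean diff"],
    )
    t_masked = np.where(result.significant, result.t_statistic, np.nan)
    # degenerate infinite t would break the linear color scale; show at the
    # largest finite magnitude instead
    finite_t = t_masked[np.isfinite(t_masked)]
    cap = float(np.max(np.abs(finite_t))) if finite_t.size else 1.0
    t_masked = np.clip(t_masked, -cap, cap)
    col_x = _column_positions(layout, style)
    px = style.cell_size
    width_units = float(col_x[-1] + 1.0)
    fig_w = (width_units + 8.0) * px / 100.0 + 1.2
    fig = Figure(figsize=(fig_w, 3.2), dpi=100)
    fs = style.label_font_size
    panels = [
        ("mean difference (native − template)", mean_mat.values.T),
        (f"t where p < {result.alpha:g}", t_masked[None, :]),
    ]
    geoms = []
    for k, (label, row) in enumerate(panels):
        ax = fig.add_axes([0.10, 0.62 - 0.42 * k, 0.78, 0.30])
        disp_mat = RegionMatrix(
            row.T, list(result.region_labels), list(result.region_names), [label]
        )
        display = _align_to_layout(disp_mat, layout)
        limits = resolve_color_limits(display, style)
        colors = map_colors(display, style, limits)
        _draw_grid(ax, display, np.ones(1), col_x, colors, style)
        ax.text(-0.3, -0.5, label, ha="right", va="center", fontsize=fs, clip_on=False)
        geoms.append(limits)
    if title:
        fig.suptitle(title, fontsize=fs + 2)
    if output_path is not None:
        _save(fig, output_path)
    return geoms
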