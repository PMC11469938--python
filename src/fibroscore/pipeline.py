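"""End-to-end convenience: section raster -> composite Ashcroft score."""

from __future__ import annotations

from typing import Optional, Tuple

from .grading import ClassifierModel, TileGradeMap, predict_grades
from .imaging_io import (
    DEFAULT_DOWNSCALE,
    DEFAULT_MIN_TISSUE_FRACTION,
    DEFAULT_TILE_SIZE,
    SectionImage,
    TileGrid,
    downscale,
    tile_section,
)
from .scoring import CompositeScore, composite_score


def score_section(
    section: SectionImage,
    model: ClassifierModel,
    downscale_factor: float = DEFAULT_DOWNSCALE,
    tile_size: int = DEFAULT_TILE_SIZE,
    min_tissue_fraction: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> Tuple[CompositeScore, TileGradeMap, TileGrid]:
    """Run the full scoring pipeline on one section.

    Downscale (default 50%), tile (default 512x512), classify each tile,
    and average included tile grades into the whole-section composite
    score.
    """
    small = downscale(section, downscale_factor)
    grid = tile_section(small, tile_size=tile_size, min_tissue_fraction=min_tissue_fraction)
    grade_map = predict_grades(model, grid)
    return composite_score(grade_map), grade_map, grid
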