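"""Whole-section composite Ashcroft score, group distributions and heatmaps.

The composite score of a section is the tile-count-weighted mean grade

    score = (0*n0 + 1*n1 + ... + 8*n8) / (n0 + n1 + ... + n8)

where ``n_g`` counts the included tiles of grade ``g``.  Non-alveolar and
low-tissue tiles are excluded from both numerator and denominator; a
section with no included tiles has an undefined score and raises rather
than silently reporting 0 (which would read as "no fibrosis").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grading import TileGradeMap
from .imaging_io import SectionImage
from .labels import GRADES, NON_ALVEOLAR_CODE

#: Neutral gray used for excluded tiles in heatmaps.
EXCLUDED_COLOR = (128, 128, 128)


class UndefinedScoreError(ValueError):
    """Raised when a section has no included tiles to score."""


@dataclass
class GradeDistribution:
    """Tile counts per grade (n0..n8) plus the excluded-tile count."""

    counts: np.ndarray
    n_excluded: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (9,) or c.min() < 0 or self.n_excluded < 0:
            raise ValueError("counts must be 9 nonnegative integers")
        self.counts = c

    @property
    def total_included(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        tot = self.total_included
        if tot == 0:
            raise UndefinedScoreError("no included tiles")
        return self.counts / tot


@dataclass
class CompositeScore:
    """The whole-section score with its underlying grade distribution."""

    value: float
    distribution: GradeDistribution
    ident: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 8.0):
            raise ValueError("composite score must lie in [0, 8]")


def grade_distribution(grade_map: TileGradeMap) -> GradeDistribution:
    """Tally included tiles per grade; everything excluded goes to n_excluded."""
    included = ~grade_map.excluded
    codes = grade_map.codes[included]
    # a non-excluded tile can never carry the non-alveolar code
    codes = codes[codes != NON_ALVEOLAR_CODE]
    counts = np.bincount(codes, minlength=9)[:9]
    n_excluded = int(grade_map.codes.size - counts.sum())
    return GradeDistribution(counts=counts, n_excluded=n_excluded)


def composite_score(grade_map: TileGradeMap) -> CompositeScore:
    """Tile-count-weighted mean grade over included tiles."""
    dist = grade_distribution(grade_map)
    if dist.total_included == 0:
        raise UndefinedScoreError(
            f"section {grade_map.ident!r} has no included tiles; composite score undefined"
        )
    value = float(np.dot(np.arange(9), dist.counts) / dist.total_included)
    return CompositeScore(value=value, distribution=dist, ident=grade_map.ident)


def score_distribution(
    grade_maps: Sequence[TileGradeMap], group_labels: Sequence[str]
) -> pd.DataFrame:
    """Pooled per-group grade distribution (counts and proportions).

    One row per group, columns ``n0..n8``, ``p0..p8``, ``n_excluded``,
    ``n_sections``.  Proportions within a group sum to 1.
    """
    if len(grade_maps) != len(group_labels):
        raise ValueError("one group label per grade map required")
    if len(grade_maps) == 0:
        raise ValueError("no grade maps given")
    rows = {}
    for gm, grp in zip(grade_maps, group_labels):
        d = grade_distribution(gm)
        if grp not in rows:
            rows[grp] = {"counts": np.zeros(9, dtype=np.int64), "n_excluded": 0, "n_sections": 0}
        rows[grp]["counts"] += d.counts
        rows[grp]["n_excluded"] += d.n_excluded
        rows[grp]["n_sections"] += 1
    records = []
    for grp, r in rows.items():
        tot = r["counts"].sum()
        if tot == 0:
            raise UndefinedScoreError(f"group {grp!r} has no included tiles")
        rec = {"group": grp, "n_sections": r["n_sections"], "n_excluded": r["n_excluded"]}
        for g in GRADES:
            rec[f"n{g}"] = int(r["counts"][g])
        for g in GRADES:
            rec[f"p{g}"] = r["counts"][g] / tot
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("group")


def grade_color_ramp(n: int = 9) -> np.ndarray:
    """Monotone perceptually-uniform colors for grades 0..8 (viridis ramp)."""
    from matplotlib import colormaps

    cmap = colormaps["viridis"]
    cols = cmap(np.linspace(0.0, 1.0, n))[:, :3]
    return np.rint(cols * 255).astype(np.uint8)


@dataclass
class HeatmapRaster:
    """Rendered grade heatmap (one block per tile) plus legend metadata."""

    pixels: np.ndarray
    block_size: int
    legend: dict


def render_heatmap(
    grade_map: TileGradeMap,
    block_size: int = 16,
    section: Optional[SectionImage] = None,
    alpha: float = 0.5,
) -> HeatmapRaster:
    """Render one colored block per tile; excluded tiles in neutral gray.

    Colors follow a monotone 0-to-8 ramp.  When ``section`` is given, the
    heatmap is alpha-blended onto it (the section must be the tile-grid
    mosaic the map was computed from; block_size is then the tile size).
    """
    ramp = grade_color_ramp()
    n_rows, n_cols = grade_map.shape
    small = np.empty((n_rows, n_cols, 3), dtype=np.uint8)
    for r in range(n_rows):
        for c in range(n_cols):
            if grade_map.excluded[r, c] or grade_map.codes[r, c] == NON_ALVEOLAR_CODE:
                small[r, c] = EXCLUDED_COLOR
            else:
                small[r, c] = ramp[grade_map.codes[r, c]]
    if section is not None:
        block_size_eff = section.height // n_rows
        if block_size_eff * n_rows != section.height or section.width // n_cols * n_cols != section.width:
            raise ValueError("grade map is not aligned to the section's tile grid")
        big = np.repeat(np.repeat(small, block_size_eff, axis=0), block_size_eff, axis=1)
        blended = np.clip(
            np.rint((1 - alpha) * section.pixels.astype(np.float64) + alpha * big), 0, 255
        ).astype(np.uint8)
        pixels, bs = blended, block_size_eff
    else:
        pixels = np.repeat(np.repeat(small, block_size, axis=0), block_size, axis=1)
        bs = block_size
    legend = {
        "ramp": {str(g): ramp[g].tolist() for g in GRADES},
        "excluded": list(EXCLUDED_COLOR),
        "scale": "Ashcroft grade 0 (normal) to 8 (total fibrous obliteration)",
    }
    return HeatmapRaster(pixels=pixels, block_size=bs, legend=legend)


def write_scores_tsv(scores: Sequence[CompositeScore], path) -> None:
    """Scores TSV: ident, score, n0..n8, n_excluded, n_total."""
    records = []
    for s in scores:
        rec = {"ident": s.ident, "score": s.value}
        for g in GRADES:
            rec[f"n{g}"] = int(s.distribution.counts[g])
        rec["n_excluded"] = s.distribution.n_excluded
        rec["n_total"] = s.distribution.total_included + s.distribution.n_excluded
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)
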