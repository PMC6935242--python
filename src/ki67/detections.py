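"""Detection records produced by the staged nuclei-separation procedures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Detection", "detection_from_pixels"]


@dataclass
class Detection:
    """One detected nucleus: its pixels, centroid, polarity and provenance.

    ``stage`` records which procedure accepted the region: 'isolated'
    (shape-tree pass on the raw mask), 'log' (multiscale LoG voting),
    'stress' (masked-STRESS separation) or 'leftover' (final admission).
    Coordinates are 0-based (row, col) in the frame of the full field.
    """

    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple
    polarity: str
    stage: str
    tile_id: int = 0
    tumor_region_id: int = 0

    @property
    def area(self) -> int:
        return int(self.rows.size)

    def shifted(self, dr: int, dc: int) -> "Detection":
        return Detection(
            rows=self.rows + dr,
            cols=self.cols + dc,
            centroid=(self.centroid[0] + dr, self.centroid[1] + dc),
            polarity=self.polarity,
            stage=self.stage,
            tile_id=self.tile_id,
            tumor_region_id=self.tumor_region_id,
        )


def detection_from_pixels(
    rows: np.ndarray, cols: np.ndarray, polarity: str, stage: str, tile_id: int = 0
) -> Detection:
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    if rows.size == 0:
        raise ValueError("detection must have at least one pixel")
    return Detection(
        rows=rows,
        cols=cols,
        centroid=(float(rows.mean()), float(cols.mean())),
        polarity=polarity,
        stage=stage,
        tile_id=tile_id,
    )
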