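"""Normalization of raw cell measurements into the three relative coordinates.

Each labeled soma is reduced to three dimensionless positions: laminar
height (position within the epithelial layer, 0 basal to 1 apical), relative
radius (position along the lamella, 0 innermost at the median raphe to 1
outermost), and organ height (section index along the organ axis, 0 top to
1 bottom).  The radial coordinate is undefined on the topmost sections,
where the lamella is too short to carry a meaningful radial scale; such
cells keep their laminar and organ-height values and are merely flagged as
radially excluded.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .simulate import DEFAULT_RADIAL_MIN_LENGTH_UM

__all__ = [
    "InvalidRecordError",
    "RADIAL_EXCLUDED",
    "laminar_height",
    "radial_position",
    "organ_height",
    "normalize_table",
    "NORMALIZED_COLUMNS",
]

#: sentinel for a cell excluded from the radial analysis
RADIAL_EXCLUDED = float("nan")

NORMALIZED_COLUMNS = ["organ_id", "gene", "section_index", "h_rel", "r_rel", "z_rel"]


class InvalidRecordError(ValueError):
    """A raw measurement violates its physical invariants."""


def laminar_height(soma_height: float, layer_thickness: float) -> float:
    """Soma height over local layer thickness: 0 = basal border, 1 = apical."""
    if layer_thickness <= 0:
        raise InvalidRecordError(f"layer thickness must be positive, got {layer_thickness}")
    if not 0 <= soma_height <= layer_thickness:
        raise InvalidRecordError(
            f"soma height {soma_height} outside [0, {layer_thickness}]"
        )
    return soma_height / layer_thickness


def radial_position(
    radial_distance: float,
    lamella_length: float,
    min_length: float = DEFAULT_RADIAL_MIN_LENGTH_UM,
) -> float:
    """Radial distance from the lamellar apex over lamella length.

    0 = innermost (at the median raphe), 1 = outermost.  Returns the
    excluded sentinel (NaN) when the lamella is shorter than ``min_length``,
    which removes the very first sections where the sensory surface does not
    yet extend toward the median raphe.
    """
    if radial_distance < 0:
        raise InvalidRecordError(f"negative radial distance {radial_distance}")
    if lamella_length < min_length:
        return RADIAL_EXCLUDED
    if radial_distance > lamella_length:
        raise InvalidRecordError(
            f"radial distance {radial_distance} exceeds lamella length {lamella_length}"
        )
    return radial_distance / lamella_length


def organ_height(section_index: int, total_sections: int) -> float:
    """Section index normalized so that 0 is the top section (organ opening)
    and 1 the bottommost; a single-section organ maps to 0."""
    if total_sections < 1:
        raise InvalidRecordError(f"total_sections must be >= 1, got {total_sections}")
    if not 0 <= section_index < total_sections:
        raise InvalidRecordError(
            f"section index {section_index} outside [0, {total_sections})"
        )
    if total_sections == 1:
        return 0.0
    return section_index / (total_sections - 1)


def normalize_table(
    raw: pd.DataFrame,
    min_length: float = DEFAULT_RADIAL_MIN_LENGTH_UM,
    lenient: bool = False,
) -> pd.DataFrame:
    """Normalize a raw measurement table row by row.

    Left and right sides are pooled (no side difference is expected), the
    organ id is retained for per-organ curves, and counts are conserved:
    every valid raw record yields exactly one normalized record.  By default
    a malformed row aborts the run with its row number; under ``lenient``
    such rows are skipped and reported in ``result.attrs['skipped_rows']``.
    """
    records = []
    skipped: list[tuple[int, str]] = []
    for row in raw.itertuples(index=True):
        try:
            h = laminar_height(row.soma_height_um, row.layer_thickness_um)
            r = radial_position(
                row.radial_distance_um, row.lamella_length_um, min_length
            )
            z = organ_height(int(row.section_index), int(row.total_sections))
        except InvalidRecordError as err:
            if lenient:
                skipped.append((row.Index, str(err)))
                continue
            raise InvalidRecordError(f"row {row.Index}: {err}") from err
        records.append((row.organ_id, row.gene, int(row.section_index), h, r, z))
    out = pd.DataFrame(records, columns=NORMALIZED_COLUMNS)
    out.attrs["skipped_rows"] = skipped
    return out


def coordinate_samples(
    normalized: pd.DataFrame, gene: str, coordinate: str
) -> np.ndarray:
    """Pooled sample of one coordinate for one gene, exclusions dropped."""
    col = {"laminar": "h_rel", "radial": "r_rel", "z": "z_rel"}[coordinate]
    values = normalized.loc[normalized["gene"] == gene, col].to_numpy(float)
    return values[~np.isnan(values)]
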