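"""Golgi/centrosome polarity classification (Classes I-IV).

Rule order, applied to a cell with known elongation, nuclear geometry and
organelle positions:

* Class IV — Golgi dispersed into at least ``dispersal_min_foci`` foci
  (typical of dividing cells).
* Class III — geometrically round cell (elongation below
  ``ei_round_threshold``) with an eccentric Golgi.
* Class I — elongated cell whose principal Golgi centroid projects beyond
  a nuclear extreme (minus ``pole_margin``) along the long axis.
* Class II — elongated cell with the Golgi adjacent to or above the
  nucleus.

Cells lacking organelle data are reported as unclassifiable, distinct from
the four classes.  The centrosome is used only as a consistency check: the
record is flagged when it sits more than ``CENTROSOME_GOLGI_MAX_UM`` from
the Golgi, since the two are expected to colocalize.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "PolarityClass", "PolarityRecord", "classify_polarity",
    "class_distribution", "CENTROSOME_GOLGI_MAX_UM",
]

CENTROSOME_GOLGI_MAX_UM = 3.0


class PolarityClass(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNCLASSIFIABLE = "unclassifiable"


@dataclass
class PolarityRecord:
    """Per-cell geometry in a common coordinate frame (um)."""

    cell_id: int
    ei: float
    long_axis_dir: np.ndarray            # unit vector
    nucleus_centroid: np.ndarray
    nucleus_extent_along_axis: tuple[float, float]  # [min, max] projections
    golgi_foci: list[np.ndarray] = field(default_factory=list)
    centrosome_centroid: np.ndarray | None = None
    assigned_class: PolarityClass | None = None
    centrosome_discrepant: bool = False


def _project(point: np.ndarray, origin: np.ndarray, axis: np.ndarray) -> float:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return float(np.dot(np.asarray(point, dtype=float) - origin, axis))


def classify_polarity(record: PolarityRecord,
                      ei_round_threshold: float = 0.10,
                      pole_margin: float = 0.5,
                      dispersal_min_foci: int = 3) -> PolarityClass:
    """Assign one of Classes I-IV (or unclassifiable) to a cell.

    The rule order is total and deterministic; the result is stored on the
    record and returned.
    """
    if not record.golgi_foci:
        record.assigned_class = PolarityClass.UNCLASSIFIABLE
        return record.assigned_class

    golgi = np.mean(np.asarray(record.golgi_foci, dtype=float), axis=0)
    if record.centrosome_centroid is not None:
        d = float(np.linalg.norm(golgi - np.asarray(record.centrosome_centroid)))
        record.centrosome_discrepant = d > CENTROSOME_GOLGI_MAX_UM

    if len(record.golgi_foci) >= dispersal_min_foci:
        record.assigned_class = PolarityClass.IV
    elif record.ei < ei_round_threshold:
        record.assigned_class = PolarityClass.III
    else:
        s = _project(golgi, record.nucleus_centroid, record.long_axis_dir)
        smin, smax = record.nucleus_extent_along_axis
        if s > smax - pole_margin or s < smin + pole_margin:
            record.assigned_class = PolarityClass.I
        else:
            record.assigned_class = PolarityClass.II
    return record.assigned_class


def class_distribution(records: Sequence[PolarityRecord]) -> dict:
    """Tally classified records into counts and percentages per class.

    Also reports the combined Class I + III frequency (cells with an
    asymmetric Golgi under the alternative grouping) and the number of
    unclassifiable records, which are excluded from percentages.
    """
    counts = Counter(
        r.assigned_class for r in records if r.assigned_class is not None
    )
    n_unclassifiable = counts.pop(PolarityClass.UNCLASSIFIABLE, 0)
    by_class = {c.value: counts.get(c, 0)
                for c in (PolarityClass.I, PolarityClass.II,
                          PolarityClass.III, PolarityClass.IV)}
    n = sum(by_class.values())
    pct = {c: (100.0 * k / n if n else 0.0) for c, k in by_class.items()}
    asym = by_class["I"] + by_class["III"]
    return {
        "counts": by_class,
        "percentages": pct,
        "n_classified": n,
        "n_unclassifiable": n_unclassifiable,
        "asymmetric_golgi": {
            "count": asym,
            "percentage": 100.0 * asym / n if n else 0.0,
        },
    }
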