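"""Marker-positive subset selection and co-label frequencies.

An object is marker-positive when its mean intensity in the marker channel
exceeds the channel-wide ``mean + k_marker * SD`` threshold AND at least
``min_overlap_fraction`` of its voxels individually exceed that threshold.
Both knobs are exposed because the original protocol names intensity and
colocalization criteria without formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .errors import ConfigurationError
from .segmentation import SegmentedObject
from .stack import IntensityStack

__all__ = ["ColabelCriteria", "ColabelResult", "colabel_fraction"]


@dataclass
class ColabelCriteria:
    marker_channel: str
    k_marker: float = 3.5
    min_overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.k_marker <= 0:
            raise ConfigurationError(
                f"k_marker must be > 0, got {self.k_marker}"
            )
        if not 0 < self.min_overlap_fraction <= 1:
            raise ConfigurationError(
                "min_overlap_fraction must be in (0, 1], got "
                f"{self.min_overlap_fraction}"
            )


@dataclass
class ColabelResult:
    positive_labels: list[int]
    n_total: int
    percentage: float | None            # 100 * positives / total; None if empty
    ci95: tuple[float, float] | None    # exact binomial CI on the percentage
    table: pd.DataFrame                 # per-object marker stats

    @property
    def n_positive(self) -> int:
        return len(self.positive_labels)


def colabel_fraction(objects: Sequence[SegmentedObject],
                     stack: IntensityStack,
                     criteria: ColabelCriteria) -> ColabelResult:
    """Select marker-positive objects and report their frequency.

    Returns labels of positive objects, the percentage of positives among
    all objects (with an exact Clopper-Pearson 95% CI), and a per-object
    table.  An empty object list yields an undefined percentage and a
    warning.
    """
    data = stack.channel(criteria.marker_channel)
    mu = float(data.mean())
    sd = float(data.std())
    threshold = mu + criteria.k_marker * sd

    rows = []
    positives = []
    for obj in objects:
        vals = data[tuple(obj.coords.T)]
        mean_marker = float(vals.mean())
        overlap = float(np.mean(vals > threshold))
        positive = (mean_marker > threshold
                    and overlap >= criteria.min_overlap_fraction)
        if positive:
            positives.append(obj.label)
        rows.append({
            "label": obj.label,
            "marker_mean": mean_marker,
            "overlap_fraction": overlap,
            "positive": positive,
        })
    table = pd.DataFrame(
        rows, columns=["label", "marker_mean", "overlap_fraction", "positive"]
    )

    if not objects:
        warnings.warn(
            "co-label percentage undefined for an empty object list",
            stacklevel=2,
        )
        return ColabelResult(positive_labels=[], n_total=0,
                             percentage=None, ci95=None, table=table)

    n = len(objects)
    k = len(positives)
    ci = binomtest(k, n).proportion_ci(0.95)
    return ColabelResult(
        positive_labels=positives,
        n_total=n,
        percentage=100.0 * k / n,
        ci95=(100.0 * ci.low, 100.0 * ci.high),
        table=table,
    )
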