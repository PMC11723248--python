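"""Condition-grid scanning and case-study classification.

Given a fitted featurizer + model, ``scan_conditions`` sweeps two assay
conditions (typically extrusion pressure and speed) over value grids
while holding the remaining conditions at a base setting, and predicts
the probability of a good print for each cell and each requested
property.  The measured-property condition ``c0`` is set to the property
being scanned, which is how a single multi-property model yields one
heatmap per property.

``classify_case`` discretizes actually measured case-study values
against the registered acceptance ranges, for observed-vs-predicted
comparison tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assaydb import AssayConditions, AssayRecord, DescriptorTable, Ink
from .featurize import PTFeaturizer, assemble_assay_frame
from .fusion import CutoffRange, classify_outcome

__all__ = ["HeatmapGrid", "scan_conditions", "classify_case",
           "DEFAULT_BANDS"]

#: probability bands for the low/medium/high colour code
DEFAULT_BANDS = (0.33, 0.66)


@dataclass
class HeatmapGrid:
    """Probability-of-good-print matrix over a 2-condition sweep."""

    property: str
    axis1: tuple[int, Sequence]          # (condition index, values)
    axis2: tuple[int, Sequence]
    base: AssayConditions
    cells: np.ndarray                    # shape |axis1| x |axis2|

    def band(self, value: float,
             thresholds: tuple[float, float] = DEFAULT_BANDS) -> str:
        """Colour band for one probability: low / medium / high."""
        lo, hi = thresholds
        if value < lo:
            return "low"
        return "medium" if value < hi else "high"

    def to_frame(self) -> pd.DataFrame:
        j1, vals1 = self.axis1
        j2, vals2 = self.axis2
        return pd.DataFrame(
            self.cells,
            index=pd.Index(vals1, name=f"c{j1}"),
            columns=pd.Index(vals2, name=f"c{j2}"),
        )


def _set_condition(base: AssayConditions, j: int, value) -> dict:
    kwargs = {name: getattr(base, name) for name in AssayConditions._FIELDS}
    kwargs[AssayConditions._FIELDS[j]] = value
    return kwargs


def scan_conditions(
    model,
    featurizer: PTFeaturizer,
    ink: Ink,
    descriptors: DescriptorTable,
    base: AssayConditions,
    axis1: tuple[int, Sequence],
    axis2: tuple[int, Sequence],
    properties: Sequence[str],
) -> list[HeatmapGrid]:
    """One probability grid per property over the two condition axes.

    Every cell is a plain ``predict_proba`` call on the synthesized assay
    row (no interpolation).
    """
    j1, vals1 = axis1
    j2, vals2 = axis2
    grids = []
    for prop in properties:
        rows = []
        for v1 in vals1:
            for v2 in vals2:
                kwargs = _set_condition(base, j1, v1)
                kwargs[AssayConditions._FIELDS[j2]] = v2
                kwargs["c0_property"] = prop
                rows.append(
                    AssayRecord(
                        assay_id=f"scan_{prop}_{v1}_{v2}",
                        ink=ink,
                        conditions=AssayConditions(**kwargs),
                        value=0.0,
                        source_ref="grid-scan",
                    )
                )
        frame = assemble_assay_frame(rows, descriptors)
        proba = model.predict_proba(featurizer.transform(frame))[:, 1]
        grids.append(
            HeatmapGrid(
                property=prop,
                axis1=(j1, list(vals1)),
                axis2=(j2, list(vals2)),
                base=base,
                cells=proba.reshape(len(vals1), len(vals2)),
            )
        )
    return grids


def classify_case(
    measurements: Mapping[str, float],
    cutoffs: Mapping[str, CutoffRange],
) -> dict[str, int]:
    """Observed printability class per measured property of one scaffold."""
    unknown = sorted(set(measurements) - set(cutoffs))
    if unknown:
        raise KeyError(f"no acceptance range for properties: {unknown}")
    return {
        prop: classify_outcome(value, cutoffs[prop])
        for prop, value in measurements.items()
    }
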