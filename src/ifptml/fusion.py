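"""Information fusion: per-property acceptance ranges and discretization.

The database merges sixteen heterogeneous printability endpoints
(uniformity factor, expansion ratio, porosity, moduli, viscosity, ...).
To train one multi-property classifier, every continuous measurement
``v_ij`` is discretized into a binary printability outcome: a print is
*good* (1) when its measured value falls inside the property's acceptance
interval ``[lim_inf, lim_sup]`` (inclusive on both sides) and *poor* (0)
when it falls outside on either side.

Acceptance intervals are either taken from curated cut-off tables or
derived from the data by a balance search: starting from the desired (or
mean) value, symmetric half-widths are scanned and the interval whose
good/poor class counts are most nearly balanced is retained.

One unit quirk is handled here and nowhere else: porosity is tabulated in
percent, but case-study measurements are sometimes reported as fractions;
porosity values below 1 are multiplied by 100 before comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assaydb import AssayRecord

__all__ = [
    "CutoffRange",
    "FusedRecord",
    "classify_outcome",
    "derive_cutoff_range",
    "fuse_dataset",
    "read_cutoff_table",
    "write_cutoff_table",
]

#: properties tabulated in percent whose raw measurements may arrive as
#: fractions in [0, 1)
_PERCENT_PROPERTIES = ("porosity",)


@dataclass(frozen=True)
class CutoffRange:
    """Per-property acceptance interval with its class tally.

    ``n1`` counts measurements inside ``[lim_inf, lim_sup]`` (good prints),
    ``n0`` those outside (poor prints).  ``avg`` is the centre used by the
    balance search, stored verbatim when ranges come from a curated table.
    """

    property: str
    lim_inf: float
    avg: float
    lim_sup: float
    n0: int = 0
    n1: int = 0

    def __post_init__(self) -> None:
        if self.lim_inf > self.lim_sup:
            raise ValueError(
                f"{self.property}: lim_inf {self.lim_inf} > lim_sup "
                f"{self.lim_sup}"
            )
        if self.n0 < 0 or self.n1 < 0:
            raise ValueError("class counts must be non-negative")


@dataclass(frozen=True)
class FusedRecord:
    """An assay together with its binary printability outcome."""

    assay: AssayRecord
    outcome: int

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise ValueError(f"outcome must be 0 or 1, got {self.outcome}")


def _normalize_value(value: float, property_name: str) -> float:
    name = property_name.strip().lower()
    if any(name.startswith(p) for p in _PERCENT_PROPERTIES) and value < 1:
        return value * 100.0
    return value


def classify_outcome(value: float, cutoff: CutoffRange) -> int:
    """Discretize one measurement against its property's acceptance range.

    Returns 1 iff ``lim_inf <= value <= lim_sup`` (two-sided, inclusive),
    0 otherwise.  Porosity fractions (< 1) are converted to percent first.
    """
    if not math.isfinite(value):
        raise ValueError(f"measured value must be finite, got {value!r}")
    v = _normalize_value(value, cutoff.property)
    return int(cutoff.lim_inf <= v <= cutoff.lim_sup)


def derive_cutoff_range(
    values: Sequence[float],
    property_name: str = "",
    target: float | None = None,
    *,
    delta_grid: Sequence[float] | None = None,
    n_deltas: int = 50,
) -> CutoffRange:
    """Search symmetric half-widths around a centre for the most balanced
    good/poor split.

    Parameters
    ----------
    values
        At least two finite measurements of one property.
    target
        Desired value used as interval centre; defaults to the mean.
    delta_grid
        Candidate half-widths.  Defaults to ``n_deltas`` evenly spaced
        widths spanning (0, half the data range].
    n_deltas
        Size of the default grid.

    The returned range minimizes ``|n1 - n0|`` subject to both classes
    being non-empty; ties break toward the smaller half-width.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two values to derive a range")
    if not np.all(np.isfinite(vals)):
        raise ValueError("values must be finite")
    if np.ptp(vals) == 0:
        raise ValueError(
            f"{property_name or 'property'}: all values identical, "
            "acceptance range is degenerate"
        )
    center = float(np.mean(vals)) if target is None else float(target)
    if delta_grid is None:
        half_range = np.ptp(vals) / 2.0
        delta_grid = np.linspace(half_range / n_deltas, half_range, n_deltas)

    best: CutoffRange | None = None
    best_key: tuple[int, float] | None = None
    for delta in sorted(float(d) for d in delta_grid):
        lo, hi = center - delta, center + delta
        n1 = int(np.sum((vals >= lo) & (vals <= hi)))
        n0 = vals.size - n1
        if n1 == 0 or n0 == 0:
            continue
        key = (abs(n1 - n0), delta)
        if best_key is None or key < best_key:
            best_key = key
            best = CutoffRange(
                property=property_name,
                lim_inf=lo,
                avg=center,
                lim_sup=hi,
                n0=n0,
                n1=n1,
            )
    if best is None:
        raise ValueError(
            f"{property_name or 'property'}: no half-width in the grid "
            "yields two non-empty classes"
        )
    return best


def fuse_dataset(
    records: Sequence[AssayRecord],
    cutoffs: Mapping[str, CutoffRange],
) -> tuple[list[FusedRecord], pd.DataFrame]:
    """Discretize every assay and tally class balance per property.

    Returns the fused records and a summary table with one row per
    property plus a ``Total`` row, columns ``n0``/``n1``.
    """
    missing = sorted(
        {
            r.conditions.c0_property
            for r in records
            if r.conditions.c0_property not in cutoffs
        }
    )
    if missing:
        raise KeyError(
            f"no acceptance range registered for properties: {missing}"
        )

    fused = [
        FusedRecord(
            assay=r,
            outcome=classify_outcome(r.value, cutoffs[r.conditions.c0_property]),
        )
        for r in records
    ]

    tally: dict[str, list[int]] = {}
    for f in fused:
        prop = f.assay.conditions.c0_property
        counts = tally.setdefault(prop, [0, 0])
        counts[f.outcome] += 1
    rows = {p: {"n0": c[0], "n1": c[1]} for p, c in sorted(tally.items())}
    rows["Total"] = {
        "n0": sum(c[0] for c in tally.values()),
        "n1": sum(c[1] for c in tally.values()),
    }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "property"
    return fused, summary


# ---------------------------------------------------------------------------
# cut-off table I/O (property, lim_inf, avg, lim_sup, n0, n1)


def read_cutoff_table(path) -> dict[str, CutoffRange]:
    df = pd.read_csv(path)
    required = {"property", "lim_inf", "avg", "lim_sup"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"cut-off table must have columns {sorted(required)}"
        )
    out: dict[str, CutoffRange] = {}
    for _, row in df.iterrows():
        out[str(row["property"])] = CutoffRange(
            property=str(row["property"]),
            lim_inf=float(row["lim_inf"]),
            avg=float(row["avg"]),
            lim_sup=float(row["lim_sup"]),
            n0=int(row.get("n0", 0) or 0),
            n1=int(row.get("n1", 0) or 0),
        )
    return out


def write_cutoff_table(cutoffs: Mapping[str, CutoffRange] | Iterable[CutoffRange], path) -> None:
    if isinstance(cutoffs, Mapping):
        cutoffs = cutoffs.values()
    pd.DataFrame(
        [
            {
                "property": c.property,
                "lim_inf": c.lim_inf,
                "avg": c.avg,
                "lim_sup": c.lim_sup,
                "n0": c.n0,
                "n1": c.n1,
            }
            for c in cutoffs
        ]
    ).to_csv(path, index=False)
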