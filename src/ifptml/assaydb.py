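"""Data model and I/O for multi-study bioprinting assay databases.

The assay database merges extrusion-bioprinting experiments from
heterogeneous literature sources.  Each row is one printing test of a
hydrogel ink (one or two monomer components) under a set of assay
conditions, with a single measured endpoint value ``v_ij``.  Because the
source studies use inconsistent column headers, the CSV column layout is
declared in a schema config rather than hard-coded.

Conditions follow the standard extrusion-bioprinting vocabulary:

========  =========================================
index     condition
========  =========================================
c0        measured property name (uniformity, ...)
c1        extrusion pressure (kPa)
c2        extrusion speed (mm/s)
c3        nozzle (gauge label)
c4        nozzle inner diameter (um)
c5        layers printed
c6        mixture temperature (degC)
c7        syringe temperature (degC)
c8        platform temperature (degC)
c9        ethanol content (yes/no)
========  =========================================

Missing condition cells are first-class: they are stored as ``None`` and
downstream grouping treats "missing" as its own group, never silently
imputing or zero-filling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CONDITION_INDICES",
    "NUMERIC_CONDITIONS",
    "HydrogelComponent",
    "Ink",
    "AssayConditions",
    "AssayRecord",
    "DescriptorTable",
    "SchemaError",
    "read_assay_table",
    "write_assay_table",
    "read_descriptor_table",
    "write_descriptor_table",
    "check_join_completeness",
    "DEFAULT_SCHEMA",
]

#: condition indices c1..c9 (c0, the measured property, is handled apart)
CONDITION_INDICES = tuple(range(1, 10))
#: conditions holding numeric values (c3 is a gauge label, c9 a flag)
NUMERIC_CONDITIONS = (1, 2, 4, 5, 6, 7, 8)


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


@dataclass(frozen=True)
class HydrogelComponent:
    """One monomer component of an ink, with its concentration.

    The concentration unit (weight fraction, w/v %, ...) is recorded as a
    string but never converted; only relative proportions matter for
    descriptor mixing.
    """

    monomer_id: str
    smiles: str
    concentration: float
    unit: str = "w/v%"

    def __post_init__(self) -> None:
        if not self.monomer_id:
            raise ValueError("monomer_id must be non-empty")
        if not self.smiles:
            raise ValueError("smiles must be non-empty")
        if not (self.concentration >= 0):
            raise ValueError(
                f"concentration must be >= 0, got {self.concentration!r}"
            )


@dataclass(frozen=True)
class Ink:
    """A printable formulation of one or two hydrogel components."""

    components: tuple[HydrogelComponent, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 2:
            raise ValueError(
                f"an ink has 1 or 2 components, got {len(self.components)}"
            )

    @property
    def monomer_ids(self) -> tuple[str, ...]:
        return tuple(c.monomer_id for c in self.components)


@dataclass(frozen=True)
class AssayConditions:
    """The condition vector c0..c9 of one bioprinting test.

    ``None`` marks an explicitly missing value.
    """

    c0_property: str
    c1_pressure: float | None = None
    c2_speed: float | None = None
    c3_nozzle: str | None = None
    c4_inner_diameter: float | None = None
    c5_layers: int | None = None
    c6_mixture_temp: float | None = None
    c7_syringe_temp: float | None = None
    c8_platform_temp: float | None = None
    c9_ethanol: bool | None = None

    _FIELDS = (
        "c0_property",
        "c1_pressure",
        "c2_speed",
        "c3_nozzle",
        "c4_inner_diameter",
        "c5_layers",
        "c6_mixture_temp",
        "c7_syringe_temp",
        "c8_platform_temp",
        "c9_ethanol",
    )

    def __post_init__(self) -> None:
        if not self.c0_property:
            raise ValueError("c0_property must be non-empty")
        for j in NUMERIC_CONDITIONS:
            v = self.value(j)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"condition c{j} must be finite or missing")

    def value(self, j: int):
        """Return the value of condition ``c_j`` (``None`` if missing)."""
        return getattr(self, self._FIELDS[j])


@dataclass(frozen=True)
class AssayRecord:
    """One bioprinting test: ink, conditions, measured value ``v_ij``."""

    assay_id: str
    ink: Ink
    conditions: AssayConditions
    value: float
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"assay {self.assay_id}: value must be finite")


class DescriptorTable:
    """Mapping monomer_id -> named vector of molecular descriptor values.

    Descriptors (Wiener-type, Harary-type indices, autocorrelations, ...)
    are computed externally from the monomer repeat-unit SMILES and
    consumed here as a plain numeric table.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.name is None:
            frame = frame.copy()
            frame.index.name = "monomer_id"
        numeric = frame.apply(pd.to_numeric, errors="coerce")
        finite = numeric.map(lambda v: v is not None and math.isfinite(v))
        if not finite.all().all():
            bad = ~finite
            monomer = bad.any(axis=1).idxmax()
            descriptor = bad.loc[monomer].idxmax()
            raise SchemaError(
                f"non-finite descriptor value for monomer {monomer!r}, "
                f"descriptor {descriptor!r}"
            )
        self._frame = numeric.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def descriptor_names(self) -> list[str]:
        return list(self._frame.columns)

    @property
    def monomer_ids(self) -> list[str]:
        return list(self._frame.index)

    def row(self, monomer_id: str) -> pd.Series:
        try:
            return self._frame.loc[monomer_id]
        except KeyError:
            raise KeyError(
                f"monomer {monomer_id!r} not present in descriptor table"
            ) from None

    def __contains__(self, monomer_id: str) -> bool:
        return monomer_id in self._frame.index

    def __len__(self) -> int:
        return len(self._frame)


# ---------------------------------------------------------------------------
# CSV schema-driven I/O

#: canonical column names used when the package writes its own tables
DEFAULT_SCHEMA: dict[str, str] = {
    "assay_id": "assay_id",
    "monomer_id_1": "monomer_id_1",
    "smiles_1": "smiles_1",
    "concentration_1": "concentration_1",
    "monomer_id_2": "monomer_id_2",
    "smiles_2": "smiles_2",
    "concentration_2": "concentration_2",
    "property": "property",
    "c1_pressure": "c1_pressure",
    "c2_speed": "c2_speed",
    "c3_nozzle": "c3_nozzle",
    "c4_inner_diameter": "c4_inner_diameter",
    "c5_layers": "c5_layers",
    "c6_mixture_temp": "c6_mixture_temp",
    "c7_syringe_temp": "c7_syringe_temp",
    "c8_platform_temp": "c8_platform_temp",
    "c9_ethanol": "c9_ethanol",
    "value": "value",
    "source_ref": "source_ref",
}

_MANDATORY = ("assay_id", "monomer_id_1", "property", "value")
_TRUE_TOKENS = {"y", "yes", "true", "1"}
_FALSE_TOKENS = {"n", "no", "false", "0"}


def _cell(row: pd.Series, column: str | None):
    if column is None or column not in row.index:
        return None
    v = row[column]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return v


def _parse_float(raw, *, assay_id: str, column: str) -> float | None:
    if raw is None:
        return None
    try:
        return float(raw)
    except (TypeError, ValueError):
        raise SchemaError(
            f"assay {assay_id!r}: cannot parse column {column!r} value "
            f"{raw!r} as a number"
        ) from None


def _parse_bool(raw, *, assay_id: str, column: str) -> bool | None:
    if raw is None:
        return None
    token = str(raw).strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise SchemaError(
        f"assay {assay_id!r}: cannot parse column {column!r} value {raw!r} "
        "as yes/no"
    )


def read_assay_table(
    path, schema_config: Mapping[str, str] | str | None = None
) -> list[AssayRecord]:
    """Read an assay CSV into :class:`AssayRecord` objects.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema_config
        Mapping from canonical field names (keys of ``DEFAULT_SCHEMA``) to
        the actual column headers of this file, or a path to a JSON file
        holding that mapping.  Omitted fields fall back to the canonical
        names; missing optional columns become missing values.
    """
    if isinstance(schema_config, (str,)) or hasattr(schema_config, "read_text"):
        with open(schema_config, encoding="utf-8") as fh:
            schema_config = json.load(fh)
    schema = dict(DEFAULT_SCHEMA)
    if schema_config:
        schema.update(schema_config)

    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for key in _MANDATORY:
        if schema[key] not in df.columns:
            raise SchemaError(
                f"mandatory column {schema[key]!r} (field {key!r}) missing "
                f"from {path}"
            )

    records: list[AssayRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        assay_id = str(_cell(row, schema["assay_id"]))
        if assay_id in seen:
            raise SchemaError(f"duplicate assay_id {assay_id!r}")
        seen.add(assay_id)

        components = []
        for slot in ("1", "2"):
            mid = _cell(row, schema[f"monomer_id_{slot}"])
            if mid is None:
                continue
            conc = _parse_float(
                _cell(row, schema[f"concentration_{slot}"]),
                assay_id=assay_id,
                column=schema[f"concentration_{slot}"],
            )
            components.append(
                HydrogelComponent(
                    monomer_id=str(mid),
                    smiles=str(_cell(row, schema[f"smiles_{slot}"]) or mid),
                    concentration=1.0 if conc is None else conc,
                )
            )
        if not components:
            raise SchemaError(f"assay {assay_id!r}: no monomer component")

        def num(key: str) -> float | None:
            return _parse_float(
                _cell(row, schema[key]), assay_id=assay_id, column=schema[key]
            )

        layers = num("c5_layers")
        conditions = AssayConditions(
            c0_property=str(_cell(row, schema["property"])),
            c1_pressure=num("c1_pressure"),
            c2_speed=num("c2_speed"),
            c3_nozzle=(
                None
                if _cell(row, schema["c3_nozzle"]) is None
                else str(_cell(row, schema["c3_nozzle"]))
            ),
            c4_inner_diameter=num("c4_inner_diameter"),
            c5_layers=None if layers is None else int(layers),
            c6_mixture_temp=num("c6_mixture_temp"),
            c7_syringe_temp=num("c7_syringe_temp"),
            c8_platform_temp=num("c8_platform_temp"),
            c9_ethanol=_parse_bool(
                _cell(row, schema["c9_ethanol"]),
                assay_id=assay_id,
                column=schema["c9_ethanol"],
            ),
        )
        value = _parse_float(
            _cell(row, schema["value"]), assay_id=assay_id, column=schema["value"]
        )
        if value is None:
            raise SchemaError(f"assay {assay_id!r}: measured value missing")
        records.append(
            AssayRecord(
                assay_id=assay_id,
                ink=Ink(components=tuple(components)),
                conditions=conditions,
                value=value,
                source_ref=str(_cell(row, schema["source_ref"]) or ""),
            )
        )
    return records


def write_assay_table(records: Sequence[AssayRecord], path) -> None:
    """Write records to CSV in the canonical (``DEFAULT_SCHEMA``) layout."""
    rows = []
    for r in records:
        comps = r.ink.components
        row: dict[str, object] = {
            "assay_id": r.assay_id,
            "monomer_id_1": comps[0].monomer_id,
            "smiles_1": comps[0].smiles,
            "concentration_1": comps[0].concentration,
            "monomer_id_2": comps[1].monomer_id if len(comps) > 1 else None,
            "smiles_2": comps[1].smiles if len(comps) > 1 else None,
            "concentration_2": comps[1].concentration if len(comps) > 1 else None,
            "property": r.conditions.c0_property,
        }
        for j in CONDITION_INDICES:
            name = AssayConditions._FIELDS[j]
            v = r.conditions.value(j)
            if j == 9 and v is not None:
                v = "Y" if v else "N"
            row[name] = v
        row["value"] = repr(r.value)
        row["source_ref"] = r.source_ref
        rows.append(row)
    pd.DataFrame(rows, columns=list(DEFAULT_SCHEMA.values())).to_csv(
        path, index=False
    )


def read_descriptor_table(path) -> DescriptorTable:
    """Read a wide descriptor CSV (first column: monomer_id)."""
    df = pd.read_csv(path, index_col=0)
    return DescriptorTable(df)


def write_descriptor_table(table: DescriptorTable, path) -> None:
    frame = table.frame.copy()
    # repr-round-trip floats so read-back is bit-exact
    frame.to_csv(path, float_format=None)


def check_join_completeness(
    records: Iterable[AssayRecord], table: DescriptorTable
) -> None:
    """Raise one aggregated error listing every unresolvable monomer."""
    missing = sorted(
        {
            mid
            for r in records
            for mid in r.ink.monomer_ids
            if mid not in table
        }
    )
    if missing:
        raise KeyError(
            "monomers referenced by assays but absent from descriptor "
            f"table: {missing}"
        )
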