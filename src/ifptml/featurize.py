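"""Perturbation-theory featurization of fused bioprinting assays.

The model input for one assay is built in four steps:

1. **Mixing** — the ink's monomer descriptor vectors are combined into one
   ink-level vector by concentration-weighted averaging,
   ``D_k(ink) = sum_c w_c * D_k(monomer_c)`` with weights normalized to 1.
2. **Scaling** — each descriptor is min-max scaled to [0, 1] using ranges
   fitted on the training rows (unseen values extrapolate; no clipping).
3. **PT operators** — for every descriptor ``k`` and condition index ``j``
   the moving-average-style perturbation feature is the deviation from the
   conditional mean, ``dD_k(c_j) = D_ki - <D_k(c_j)>``, where
   ``<D_k(c_j)>`` is the mean of the scaled descriptor over all *training*
   assays sharing the same value of condition ``c_j``.  A condition value
   never seen in training falls back to the global descriptor mean.
4. **Reference function** — the expected-value prior
   ``f_ref = p(f = 1 | c_j)``, the fraction of good outcomes among
   training assays sharing the conditioning value (by default ``c_0``,
   the measured property).

The resulting design matrix has columns ``[f_ref, {descriptor}__c{j}...]``
in a deterministic order.  Conditional means and the reference table are
fitted on training rows only; transforming validation rows reuses the
fitted statistics, so no outcome information leaks across the split.
"""

from __future__ import annotations

import json
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .assaydb import AssayConditions, AssayRecord, DescriptorTable, Ink
from .fusion import FusedRecord

__all__ = [
    "MISSING_TOKEN",
    "mix_descriptors",
    "scale_descriptors",
    "reference_function",
    "fit_group_means",
    "pt_operator",
    "assemble_assay_frame",
    "PTFeaturizer",
    "build_design_matrix",
]

#: sentinel group for an explicitly missing condition value
MISSING_TOKEN = "__missing__"

_CONDITION_COLUMNS = tuple(f"c{j}" for j in range(10))


def mix_descriptors(ink: Ink, table: DescriptorTable) -> pd.Series:
    """Concentration-weighted mix of the components' descriptor vectors.

    Weights are the components' concentrations normalized to sum to 1, so
    the result is invariant to rescaling all concentrations by a common
    factor; a single-component ink returns that monomer's row unchanged.
    """
    total = sum(c.concentration for c in ink.components)
    if total <= 0:
        raise ValueError("ink has no positive concentration")
    mixed = None
    for comp in ink.components:
        row = table.row(comp.monomer_id) * (comp.concentration / total)
        mixed = row if mixed is None else mixed + row
    return mixed


def scale_descriptors(
    frame: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, list[str]]:
    """Fit min-max scaling on ``frame`` and apply it.

    Returns ``(scaled, minima, ranges, constant_columns)``.  Constant
    descriptors scale to 0 everywhere and are flagged.
    """
    if len(frame) < 2:
        raise ValueError("need at least two rows to fit descriptor scaling")
    minima = frame.min(axis=0)
    ranges = frame.max(axis=0) - minima
    constant = list(ranges.index[ranges == 0])
    safe = ranges.replace(0, 1.0)
    scaled = (frame - minima) / safe
    scaled[constant] = 0.0
    return scaled, minima, safe, constant


def reference_function(
    fused: Sequence[FusedRecord], condition_index: int = 0
) -> dict[object, float]:
    """Empirical good-print prior per value of condition ``c_j``.

    For each distinct value of ``c_j`` the prior is
    ``p = n(f = 1) / n_j``, the positive fraction among assays sharing
    that value.  Missing condition values form their own group.
    """
    if not fused:
        raise ValueError("cannot estimate a reference function from no data")
    groups: dict[object, list[int]] = {}
    for f in fused:
        key = f.assay.conditions.value(condition_index)
        key = MISSING_TOKEN if key is None else key
        groups.setdefault(key, []).append(f.outcome)
    return {k: float(np.mean(v)) for k, v in groups.items()}


def pt_operator(value: float, mean: float) -> float:
    """Perturbation operator: deviation of a descriptor from its
    conditional mean, ``dD_k(c_j) = D_ki - <D_k(c_j)>``."""
    return value - mean


def fit_group_means(
    scaled: pd.DataFrame,
    conditions: Sequence[AssayConditions],
    j_set: Iterable[int],
) -> tuple[dict[int, dict[object, pd.Series]], pd.Series]:
    """Arithmetic mean of every scaled descriptor within each
    (condition index, condition value) group, plus the global fallback."""
    if len(scaled) == 0:
        raise ValueError("empty training set")
    if len(scaled) != len(conditions):
        raise ValueError("descriptor rows and condition rows differ in length")
    global_means = scaled.mean(axis=0)
    means: dict[int, dict[object, pd.Series]] = {}
    for j in j_set:
        keys = pd.Series(
            [
                MISSING_TOKEN if c.value(j) is None else c.value(j)
                for c in conditions
            ],
            index=scaled.index,
        )
        means[j] = {
            key: sub.mean(axis=0)
            for key, sub in scaled.groupby(keys, sort=False)
        }
    return means, global_means


def assemble_assay_frame(
    records: Sequence[AssayRecord] | Sequence[FusedRecord],
    table: DescriptorTable,
) -> pd.DataFrame:
    """Flatten assays into a frame of condition columns ``c0..c9`` plus
    mixed (unscaled) descriptor columns, indexed by assay_id.

    Accepts raw or fused records; fused records contribute an ``outcome``
    column as well.
    """
    rows, outcomes = [], []
    index = []
    for item in records:
        rec = item.assay if isinstance(item, FusedRecord) else item
        if isinstance(item, FusedRecord):
            outcomes.append(item.outcome)
        cond = {f"c{j}": rec.conditions.value(j) for j in range(10)}
        cond["c0"] = rec.conditions.c0_property
        mixed = mix_descriptors(rec.ink, table)
        rows.append({**cond, **mixed.to_dict()})
        index.append(rec.assay_id)
    frame = pd.DataFrame(rows, index=pd.Index(index, name="assay_id"))
    if outcomes:
        frame["outcome"] = outcomes
    return frame


def _condition_key(value) -> object:
    return MISSING_TOKEN if value is None or (
        isinstance(value, float) and np.isnan(value)
    ) else value


class PTFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer producing the PT design matrix ``[f_ref, dD_k(c_j)...]``.

    Parameters
    ----------
    j_set : sequence of int, default ``range(10)``
        Condition indices for which perturbation columns are emitted.
    reference_condition : int, default 0
        Condition index conditioning the reference (expected-value)
        function; 0 means the measured property.
    descriptor_names : sequence of str, optional
        Restrict featurization to these descriptors (default: every
        non-condition column of the input frame).
    binning : float, optional
        Width for binning continuous condition values before grouping;
        ``None`` groups by exact value.

    Attributes
    ----------
    scale_min_, scale_range_ : pd.Series
        Fitted min-max parameters per descriptor.
    constant_descriptors_ : list of str
        Descriptors constant on the training rows (scaled to 0).
    group_means_ : dict j -> {condition value -> pd.Series}
        Conditional means of scaled descriptors, training rows only.
    global_means_ : pd.Series
        Fallback means for unseen condition values.
    reference_table_ : dict condition value -> float
        Positive-outcome prior per conditioning value.
    reference_global_ : float
        Overall training positive rate (fallback prior).
    feature_names_out_ : list of str
        Deterministic design-matrix column order.
    """

    def __init__(
        self,
        j_set: Sequence[int] = tuple(range(10)),
        reference_condition: int = 0,
        descriptor_names: Sequence[str] | None = None,
        binning: float | None = None,
    ):
        self.j_set = j_set
        self.reference_condition = reference_condition
        self.descriptor_names = descriptor_names
        self.binning = binning

    # -- internals ---------------------------------------------------------

    def _descriptor_columns(self, X: pd.DataFrame) -> list[str]:
        if self.descriptor_names is not None:
            missing = [d for d in self.descriptor_names if d not in X.columns]
            if missing:
                raise KeyError(f"descriptors absent from input: {missing}")
            return list(self.descriptor_names)
        return [
            c
            for c in X.columns
            if c not in _CONDITION_COLUMNS and c != "outcome"
        ]

    def _group_key(self, j: int, value) -> object:
        key = _condition_key(value)
        if (
            self.binning
            and key is not MISSING_TOKEN
            and isinstance(key, (int, float))
            and not isinstance(key, bool)
        ):
            key = round(float(key) / self.binning) * self.binning
        return key

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None) -> "PTFeaturizer":
        """Fit scaling, conditional means and the reference table.

        ``X`` is an assay frame from :func:`assemble_assay_frame`; ``y``
        is the binary outcome vector (may also be given as an ``outcome``
        column of ``X``).
        """
        if y is None:
            if "outcome" not in X.columns:
                raise ValueError("y (or an 'outcome' column) is required")
            y = X["outcome"]
        y = np.asarray(y, dtype=int)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")

        desc_cols = self._descriptor_columns(X)
        scaled, self.scale_min_, self.scale_range_, self.constant_descriptors_ = (
            scale_descriptors(X[desc_cols].astype(float))
        )
        self.descriptor_names_ = desc_cols

        self.group_means_ = {}
        for j in self.j_set:
            keys = X[f"c{j}"].map(lambda v, j=j: self._group_key(j, v))
            self.group_means_[int(j)] = {
                key: sub.mean(axis=0)
                for key, sub in scaled.groupby(keys, sort=False)
            }
        self.global_means_ = scaled.mean(axis=0)

        ref_keys = X[f"c{self.reference_condition}"].map(
            lambda v: self._group_key(self.reference_condition, v)
        )
        self.reference_table_ = {
            key: float(np.mean(y[np.asarray(ref_keys == key)]))
            for key in pd.unique(ref_keys)
        }
        self.reference_global_ = float(np.mean(y))

        self.feature_names_out_ = ["f_ref"] + [
            f"{k}__c{j}" for k in desc_cols for j in self.j_set
        ]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "feature_names_out_")
        missing = [d for d in self.descriptor_names_ if d not in X.columns]
        if missing:
            raise KeyError(
                f"descriptor columns missing at transform time: {missing}"
            )
        scaled = (
            X[self.descriptor_names_].astype(float) - self.scale_min_
        ) / self.scale_range_
        scaled[self.constant_descriptors_] = 0.0

        out = pd.DataFrame(
            index=X.index, columns=self.feature_names_out_, dtype=float
        )
        ref_keys = X[f"c{self.reference_condition}"].map(
            lambda v: self._group_key(self.reference_condition, v)
        )
        out["f_ref"] = [
            self.reference_table_.get(k, self.reference_global_)
            for k in ref_keys
        ]
        for j in self.j_set:
            j = int(j)
            keys = X[f"c{j}"].map(lambda v, j=j: self._group_key(j, v))
            means = pd.DataFrame(
                [
                    self.group_means_[j].get(k, self.global_means_)
                    for k in keys
                ],
                index=X.index,
            )
            delta = scaled - means[self.descriptor_names_]
            for k in self.descriptor_names_:
                out[f"{k}__c{j}"] = delta[k]
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_out_")
        return np.asarray(self.feature_names_out_, dtype=object)

    # -- persistence -------------------------------------------------------

    def to_json(self) -> str:
        """Serialize fitted state (scaling, means, reference, columns)."""
        check_is_fitted(self, "feature_names_out_")

        def enc_key(k):
            return json.dumps(k) if not isinstance(k, str) else "s:" + k

        state = {
            "params": {
                "j_set": list(int(j) for j in self.j_set),
                "reference_condition": int(self.reference_condition),
                "descriptor_names": (
                    None
                    if self.descriptor_names is None
                    else list(self.descriptor_names)
                ),
                "binning": self.binning,
            },
            "descriptor_names_": self.descriptor_names_,
            "scale_min_": self.scale_min_.to_dict(),
            "scale_range_": self.scale_range_.to_dict(),
            "constant_descriptors_": self.constant_descriptors_,
            "global_means_": self.global_means_.to_dict(),
            "group_means_": {
                str(j): {enc_key(k): v.to_dict() for k, v in groups.items()}
                for j, groups in self.group_means_.items()
            },
            "reference_table_": {
                enc_key(k): v for k, v in self.reference_table_.items()
            },
            "reference_global_": self.reference_global_,
            "feature_names_out_": self.feature_names_out_,
        }
        return json.dumps(state, sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "PTFeaturizer":
        state = json.loads(payload)

        def dec_key(k: str):
            return k[2:] if k.startswith("s:") else json.loads(k)

        obj = cls(**{
            **state["params"],
            "j_set": tuple(state["params"]["j_set"]),
        })
        obj.descriptor_names_ = state["descriptor_names_"]
        obj.scale_min_ = pd.Series(state["scale_min_"])
        obj.scale_range_ = pd.Series(state["scale_range_"])
        obj.constant_descriptors_ = state["constant_descriptors_"]
        obj.global_means_ = pd.Series(state["global_means_"])
        obj.group_means_ = {
            int(j): {dec_key(k): pd.Series(v) for k, v in groups.items()}
            for j, groups in state["group_means_"].items()
        }
        obj.reference_table_ = {
            dec_key(k): v for k, v in state["reference_table_"].items()
        }
        obj.reference_global_ = state["reference_global_"]
        obj.feature_names_out_ = state["feature_names_out_"]
        return obj


def build_design_matrix(
    fused: Sequence[FusedRecord],
    table: DescriptorTable,
    j_set: Sequence[int] = tuple(range(10)),
    featurizer: PTFeaturizer | None = None,
) -> tuple[pd.DataFrame, np.ndarray, PTFeaturizer]:
    """One-call featurization: assemble, (fit and) transform.

    When ``featurizer`` is given it must already be fitted (on training
    data) and is only applied; otherwise a new one is fitted on ``fused``.
    Returns ``(X_design, y, featurizer)``.
    """
    frame = assemble_assay_frame(fused, table)
    y = frame.pop("outcome").to_numpy()
    if featurizer is None:
        featurizer = PTFeaturizer(j_set=j_set).fit(frame, y)
    return featurizer.transform(frame), y, featurizer
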