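"""End-to-end orchestration: fuse, split, featurize, train, evaluate.

This is the engine behind the command-line interface and the acceptance
harness.  A run is fully determined by (database, options, seed); every
artifact a run writes is hashed into its manifest so replays can be
verified byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assaydb import AssayRecord, DescriptorTable
from .evaluate import EvalReport, confusion_metrics, split_dataset
from .featurize import PTFeaturizer, assemble_assay_frame
from .fusion import CutoffRange, fuse_dataset
from .models import ModelSpec, TreeClassifier, make_model

__all__ = ["PipelineResult", "run_pipeline", "hash_file", "write_manifest"]


@dataclass
class PipelineResult:
    """Everything a single train/evaluate run produces."""

    featurizer: PTFeaturizer
    model: object
    train_report: EvalReport
    val_report: EvalReport
    train_idx: list[int]
    val_idx: list[int]
    X_train: pd.DataFrame
    X_val: pd.DataFrame
    y_train: np.ndarray
    y_val: np.ndarray
    fusion_summary: pd.DataFrame


def run_pipeline(
    records: Sequence[AssayRecord],
    descriptors: DescriptorTable,
    cutoffs: dict[str, CutoffRange],
    model_spec: ModelSpec | None = None,
    ratio: float = 0.70,
    j_set: Sequence[int] = tuple(range(10)),
    seed: int = 0,
) -> PipelineResult:
    """Fuse, split 70/30 stratified, featurize (fit on train only),
    train the requested family and evaluate both splits."""
    if model_spec is None:
        model_spec = ModelSpec(family="DTC", seed=seed)

    fused, summary = fuse_dataset(records, cutoffs)
    outcomes = [f.outcome for f in fused]
    train_idx, val_idx = split_dataset(fused, outcomes, ratio=ratio,
                                       seed=seed)

    frame = assemble_assay_frame(fused, descriptors)
    y = frame.pop("outcome").to_numpy()
    featurizer = PTFeaturizer(j_set=tuple(j_set)).fit(
        frame.iloc[train_idx], y[train_idx]
    )
    X_train = featurizer.transform(frame.iloc[train_idx])
    X_val = featurizer.transform(frame.iloc[val_idx])
    y_train, y_val = y[train_idx], y[val_idx]

    model = make_model(model_spec)
    if isinstance(model, TreeClassifier):
        model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
    else:
        model.fit(X_train, y_train)

    train_report = confusion_metrics(
        y_train, model.predict(X_train), split="training",
        scores=model.predict_proba(X_train)[:, 1],
    )
    val_report = confusion_metrics(
        y_val, model.predict(X_val), split="validation",
        scores=model.predict_proba(X_val)[:, 1],
    )
    return PipelineResult(
        featurizer=featurizer, model=model,
        train_report=train_report, val_report=val_report,
        train_idx=train_idx, val_idx=val_idx,
        X_train=X_train, X_val=X_val, y_train=y_train, y_val=y_val,
        fusion_summary=summary,
    )


def hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, config: dict, artifacts: Sequence[Path]) -> Path:
    """Write a run manifest with the config and sha256 of each artifact."""
    out_dir = Path(out_dir)
    manifest = {
        "config": config,
        "artifacts": {
            str(Path(a).relative_to(out_dir)): hash_file(a)
            for a in artifacts
        },
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
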