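"""Delimited-text dataset files and structured-text model files.

A dataset is two CSV files: a bag manifest (``bag_id,label,prior_weight``)
and an instance table (``bag_id,instance_id[,truth_positive,truth_subtype],
f_0..f_{D-1}``).  Instances keep their file order within a bag; bags keep
manifest order.  Models are versioned JSON; a round trip reproduces
bit-identical predictions.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .boosting import MILModel, StrongClassifier
from .core import Bag
from .synthetic import GroundTruth
from .weak import Stump

__all__ = ["read_dataset", "write_dataset", "read_model", "write_model", "MODEL_FORMAT_VERSION"]

MODEL_FORMAT_VERSION = 1


def write_dataset(bags, manifest_path, instances_path, truth: GroundTruth | None = None) -> None:
    """Write the bag manifest and instance table (CSV with header)."""
    pd.DataFrame({
        "bag_id": [b.bag_id for b in bags],
        "label": [b.label for b in bags],
        "prior_weight": [b.prior_weight for b in bags],
    }).to_csv(manifest_path, index=False)

    frames = []
    for bag in bags:
        d = bag.n_features
        frame = {"bag_id": bag.bag_id,
                 "instance_id": [f"{bag.bag_id}:{j}" for j in range(bag.n_instances)]}
        if truth is not None:
            frame["truth_positive"] = truth.positive[bag.bag_id].astype(int)
            frame["truth_subtype"] = truth.subtype[bag.bag_id]
        for j in range(d):
            frame[f"f_{j}"] = bag.instances[:, j]
        frames.append(pd.DataFrame(frame))
    pd.concat(frames, ignore_index=True).to_csv(instances_path, index=False)


def read_dataset(manifest_path, instances_path):
    """Read (bags, ground_truth-or-None); validates labels and referential integrity.

    Errors name the offending data line (header is line 1).
    """
    try:
        manifest = pd.read_csv(manifest_path, float_precision="round_trip")
        inst = pd.read_csv(instances_path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"malformed dataset file: {exc}") from exc

    for col in ("bag_id", "label"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")
    bad = ~manifest["label"].isin([-1, 1])
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(f"manifest line {line}: label must be -1 or +1")
    if manifest["bag_id"].duplicated().any():
        dup = manifest["bag_id"][manifest["bag_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate bag_id {dup!r} in manifest")
    if "prior_weight" not in manifest.columns:
        manifest["prior_weight"] = 1.0

    feature_cols = [c for c in inst.columns if c.startswith("f_")]
    if not feature_cols:
        raise ValueError("instance table has no feature columns f_0..f_{D-1}")
    feature_cols = sorted(feature_cols, key=lambda c: int(c[2:]))

    known = set(manifest["bag_id"].astype(str))
    unknown = ~inst["bag_id"].astype(str).isin(known)
    if unknown.any():
        line = int(np.flatnonzero(unknown)[0]) + 2
        bad_id = inst["bag_id"].iloc[int(np.flatnonzero(unknown)[0])]
        raise ValueError(f"instance table line {line}: unknown bag_id {bad_id!r}")

    feats = inst[feature_cols]
    try:
        features = feats.to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature value: {exc}") from exc
    if not np.all(np.isfinite(features)):
        line = int(np.flatnonzero(~np.isfinite(features).all(axis=1))[0]) + 2
        raise ValueError(f"instance table line {line}: non-finite or missing feature")

    has_truth = "truth_positive" in inst.columns and "truth_subtype" in inst.columns
    bags, positive, subtype = [], {}, {}
    groups = {str(b): g for b, g in inst.groupby("bag_id", sort=False)}
    for row in manifest.itertuples(index=False):
        bag_id = str(row.bag_id)
        if bag_id not in groups:
            raise ValueError(f"bag {bag_id!r} has no instances")
        g = groups[bag_id]
        x = features[g.index.to_numpy()]
        bags.append(Bag(bag_id, int(row.label), x, float(row.prior_weight)))
        if has_truth:
            positive[bag_id] = g["truth_positive"].to_numpy().astype(bool)
            subtype[bag_id] = g["truth_subtype"].to_numpy().astype(np.int64)
    truth = GroundTruth(positive, subtype) if has_truth else None
    return bags, truth


def write_model(model: MILModel, path) -> None:
    """Serialize a trained model (versioned JSON; exact float round trip)."""
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "mode": model.mode,
        "K": model.K,
        "r": model.r,
        "D": model.D,
        "clusters": [
            {
                "cluster_index": c.cluster_index,
                "terms": [
                    {"feature_index": s.feature_index, "threshold": s.threshold,
                     "polarity": s.polarity, "weighted_error": s.weighted_error,
                     "alpha": alpha}
                    for alpha, s in c.terms
                ],
            }
            for c in model.classifiers
        ],
        "training_log": model.training_log,
        "config": model.config,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_model(path) -> MILModel:
    """Read a model file; rejects truncated files and unknown format versions."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"model file {path} is truncated or corrupt: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r} "
                         f"(expected {MODEL_FORMAT_VERSION})")
    classifiers = []
    for c in doc["clusters"]:
        terms = [(term["alpha"],
                  Stump(term["feature_index"], term["threshold"],
                        term["polarity"], term["weighted_error"]))
                 for term in c["terms"]]
        classifiers.append(StrongClassifier(c["cluster_index"], terms))
    return MILModel(mode=doc["mode"], K=doc["K"], r=doc["r"], D=doc["D"],
                    classifiers=classifiers, training_log=doc.get("training_log", []),
                    config=doc.get("config", {}))
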