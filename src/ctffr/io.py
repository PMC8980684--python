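"""File formats: vessel-tree JSON, boundary-parameter JSON, cohort CSV, YAML config.

All round-trips preserve numbers to full precision (floats are serialized
via ``repr``-faithful JSON).  Validation errors carry JSON-pointer-style
paths to the offending field.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import COHORT_COLUMNS
from .errors import SchemaError
from .geometry import Lesion, Segment, VesselTree
from .hemodynamics import BoundaryParams

_LESION_FIELDS = {
    "segment_id": str,
    "start": (int, float),
    "length": (int, float),
    "degree": (int, float),
}


def tree_to_dict(tree: VesselTree) -> dict:
    return {
        "vessel_label": tree.vessel_label,
        "segments": [
            {
                "id": seg.id,
                "parent_id": seg.parent_id,
                "samples": [
                    [float(s), float(rl), float(rr)]
                    for s, rl, rr in zip(seg.arc, seg.lumen_radius, seg.reference_radius)
                ],
                "is_outlet": seg.is_outlet,
            }
            for seg in tree.segments.values()
        ],
        "lesions": [dataclasses.asdict(l) for l in tree.lesions],
    }


def tree_from_dict(data: Mapping, path: str = "") -> VesselTree:
    if not isinstance(data, Mapping):
        raise SchemaError("expected an object", path or "/")
    for key in ("vessel_label", "segments"):
        if key not in data:
            raise SchemaError(f"missing required key {key!r}", f"{path}/{key}")
    if not isinstance(data["segments"], list) or not data["segments"]:
        raise SchemaError("must be a non-empty array", f"{path}/segments")
    segments = []
    for i, sd in enumerate(data["segments"]):
        sp = f"{path}/segments/{i}"
        if not isinstance(sd, Mapping):
            raise SchemaError("expected an object", sp)
        for key in ("id", "samples"):
            if key not in sd:
                raise SchemaError(f"missing required key {key!r}", f"{sp}/{key}")
        samples = sd["samples"]
        if not isinstance(samples, list) or len(samples) < 2:
            raise SchemaError("needs >= 2 [arc, lumen_r, ref_r] samples", f"{sp}/samples")
        for j, row in enumerate(samples):
            if not isinstance(row, (list, tuple)) or len(row) != 3:
                raise SchemaError("sample must be [arc_mm, r_lumen_mm, r_ref_mm]",
                                  f"{sp}/samples/{j}")
        arr = np.asarray(samples, dtype=float)
        try:
            segments.append(
                Segment(
                    id=str(sd["id"]),
                    parent_id=sd.get("parent_id"),
                    arc=arr[:, 0],
                    lumen_radius=arr[:, 1],
                    reference_radius=arr[:, 2],
                    is_outlet=bool(sd.get("is_outlet", False)),
                )
            )
        except ValueError as exc:
            raise SchemaError(str(exc), sp) from exc
    lesions = []
    for i, ld in enumerate(data.get("lesions", [])):
        lp = f"{path}/lesions/{i}"
        if not isinstance(ld, Mapping):
            raise SchemaError("expected an object", lp)
        for key, typ in _LESION_FIELDS.items():
            if key not in ld:
                raise SchemaError(f"missing required key {key!r}", f"{lp}/{key}")
            if not isinstance(ld[key], typ):
                raise SchemaError(f"wrong type for {key!r}", f"{lp}/{key}")
        try:
            lesions.append(Lesion(**ld))
        except ValueError as exc:
            raise SchemaError(str(exc), lp) from exc
    try:
        return VesselTree.from_segments(segments, str(data["vessel_label"]), lesions)
    except ValueError as exc:
        raise SchemaError(str(exc), path or "/") from exc


def save_tree(tree: VesselTree, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tree_to_dict(tree), indent=1))


def load_tree(path: str | Path) -> VesselTree:
    return tree_from_dict(json.loads(Path(path).read_text()))


def save_trees(trees: Mapping[str, tuple[VesselTree, Lesion]], path: str | Path) -> None:
    payload = {vid: tree_to_dict(tree) for vid, (tree, _lesion) in trees.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_trees(path: str | Path) -> dict[str, tuple[VesselTree, Lesion]]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for vid, td in payload.items():
        tree = tree_from_dict(td, path=f"/{vid}")
        if not tree.lesions:
            raise SchemaError("tree carries no lesion", f"/{vid}/lesions")
        out[vid] = (tree, tree.lesions[0])
    return out


# -- boundary parameters ----------------------------------------------------

def theta_to_dict(theta: BoundaryParams) -> dict:
    return dataclasses.asdict(theta)


def save_theta(theta: BoundaryParams, path: str | Path, meta: Mapping | None = None) -> None:
    payload = {"boundary_params": theta_to_dict(theta)}
    if meta:
        payload["meta"] = dict(meta)
    Path(path).write_text(json.dumps(payload, indent=1))


def load_theta(path: str | Path) -> BoundaryParams:
    data = json.loads(Path(path).read_text())
    block = data.get("boundary_params", data)
    known = {f.name for f in dataclasses.fields(BoundaryParams)}
    unknown = set(block) - known
    if unknown:
        raise SchemaError(f"unknown parameter(s) {sorted(unknown)}", "/boundary_params")
    try:
        return BoundaryParams(**block)
    except ValueError as exc:
        raise SchemaError(str(exc), "/boundary_params") from exc


# -- cohort CSV -------------------------------------------------------------

def save_cohort(
    cohort: pd.DataFrame, path: str | Path, *, seed: int | None = None,
    config_hash: str | None = None,
) -> None:
    """UTF-8 comma CSV with '#'-prefixed provenance header lines."""
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config_hash is not None:
        lines.append(f"# config_hash={config_hash}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in lines:
            fh.write(line + "\n")
        cohort.to_csv(fh, index=False)


def load_cohort(path: str | Path, required: tuple[str, ...] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = required or ("vessel_id", "ct_ffr", "measured_ffr", "cta_percent_stenosis")
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}", f"/columns/{col}")
    return df


# -- flow solutions ---------------------------------------------------------

def solution_to_frames(solution) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate a FlowSolution: per-node (segment, arc, pressure, FFR) and
    per-segment flow."""
    p_a = solution.aortic_pressure
    node_rows = [{"node_id": "ostium", "segment_id": "", "arc_mm": 0.0,
                  "pressure_mmHg": p_a, "ffr": 1.0}]
    for sid, prof in solution.sample_pressures.items():
        arc = solution.tree.segments[sid].arc
        for i, (s, p) in enumerate(zip(arc, prof)):
            node_rows.append(
                {"node_id": f"{sid}:{i}", "segment_id": sid, "arc_mm": float(s),
                 "pressure_mmHg": float(p), "ffr": float(p) / p_a}
            )
    flow_rows = [{"segment_id": sid, "flow_mL_s": q}
                 for sid, q in solution.segment_flows.items()]
    return pd.DataFrame(node_rows), pd.DataFrame(flow_rows)


def save_solution(solution, nodes_path: str | Path, flows_path: str | Path) -> None:
    nodes, flows = solution_to_frames(solution)
    nodes.to_csv(nodes_path, index=False)
    flows.to_csv(flows_path, index=False)


# -- misc -------------------------------------------------------------------

def config_hash(obj) -> str:
    """Stable SHA-256 of a (nested) configuration object."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"unhashable config element {type(o)}")

    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
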