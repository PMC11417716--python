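"""File formats and model serialization.

FASTA in and out goes through Biopython; descriptor tables are plain CSV
with an ``id`` first column and numeric descriptor columns. Trained
models serialize to a structured JSON document (``format_version`` 1)
with full-precision floats, so a loaded model reproduces every score
bit for bit; provenance records the seed and a hash of the model
payload, never wall-clock time, keeping seeded runs byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .conservation import MsaMatrix
from .encoding import ALPHABET, GAP, DescriptorBinSpec, EncodingScheme, SequenceRecord
from .models import SensorModel
from .nucleation import HelixBattery
from .sensors import VirtualSensor

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_descriptor_csv",
    "read_labels",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]

MODEL_FORMAT_VERSION = 1


def read_fasta(path, labels_from_header: bool = False):
    """Read a multi-record FASTA into SequenceRecords.

    Gaps are rejected (use :func:`read_aligned_fasta` for alignments) and
    duplicate ids are an error. With ``labels_from_header`` the token
    after the first ``|`` in each header id becomes the record's label;
    returns ``(records, labels)`` in that case, else just records.
    """
    path = Path(path)
    records, labels, seen = [], {}, set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        label = None
        if labels_from_header and "|" in name:
            name, label = name.split("|", 1)
        if name in seen:
            raise ValueError(f"{path}: duplicate record id {name!r}")
        seen.add(name)
        residues = str(rec.seq).upper()
        if GAP in residues:
            raise ValueError(
                f"{path}: record {name!r} contains gaps; "
                f"plain FASTA must be ungapped"
            )
        try:
            records.append(SequenceRecord(name, residues))
        except ValueError as e:
            raise ValueError(f"{path}: record {name!r}: {e}") from None
        if label is not None:
            labels[name] = label
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if labels_from_header:
        return records, labels
    return records


def write_fasta(records, path, labels: dict | None = None) -> None:
    """Write records as 60-column wrapped FASTA; labels go after '|'."""
    bio = []
    for rec in records:
        name = rec.id
        if labels and rec.id in labels:
            name = f"{rec.id}|{labels[rec.id]}"
        bio.append(BioSeqRecord(Seq(rec.residues), id=name, description=""))
    SeqIO.write(bio, str(path), "fasta")


def read_aligned_fasta(path) -> MsaMatrix:
    """Read an aligned FASTA (gaps allowed) into an MsaMatrix."""
    path = Path(path)
    rows, ids, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        row = str(rec.seq).upper()
        for c, ch in enumerate(row):
            if ch not in ALPHABET:
                raise ValueError(
                    f"{path}: record {rec.id!r}, column {c}: invalid symbol {ch!r}"
                )
        rows.append(row)
        ids.append(rec.id)
    if not rows:
        raise ValueError(f"{path}: no FASTA records found")
    try:
        return MsaMatrix(tuple(rows), tuple(ids))
    except ValueError as e:
        raise ValueError(f"{path}: {e}") from None


def write_aligned_fasta(msa: MsaMatrix, path) -> None:
    ids = msa.ids or tuple(f"seq_{i:03d}" for i in range(msa.k))
    bio = [
        BioSeqRecord(Seq(row), id=name, description="")
        for name, row in zip(ids, msa.rows)
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_descriptor_csv(path) -> pd.DataFrame:
    """Read a descriptor table: first column ``id``, rest numeric."""
    path = Path(path)
    table = pd.read_csv(path)
    if table.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {table.columns[0]!r}")
    if table["id"].duplicated().any():
        dup = table["id"][table["id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate id {dup!r}")
    table = table.set_index("id")
    for col in table.columns:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"{path}: non-numeric descriptor at row {row!r}, column {col!r}"
            )
        table[col] = numeric
    return table


def read_labels(path, positive: str | None = None):
    """Read an ``id,label`` CSV; with ``positive`` given, return booleans."""
    path = Path(path)
    table = pd.read_csv(path)
    if list(table.columns[:2]) != ["id", "label"]:
        raise ValueError(f"{path}: expected columns 'id,label'")
    series = table.set_index("id")["label"]
    if positive is not None:
        return series.astype(str) == positive
    return series


# --- model serialization -------------------------------------------------


def _sensor_to_dict(s: VirtualSensor) -> dict:
    return {
        "id": s.id,
        "pattern": "".join(str(int(b)) for b in s.pattern),
        "weights": [float(w) for w in s.weights],
        "placement": s.placement,
        "start": s.start,
        "stride": s.stride,
        "class_tag": s.class_tag,
    }


def _sensor_from_dict(d: dict) -> VirtualSensor:
    return VirtualSensor(
        id=d["id"],
        pattern=np.array([int(c) for c in d["pattern"]], dtype=np.uint8),
        weights=np.array(d["weights"], dtype=float),
        placement=d["placement"],
        start=int(d["start"]),
        stride=int(d["stride"]),
        class_tag=d.get("class_tag", ""),
    )


def _scheme_to_dict(scheme: EncodingScheme) -> dict:
    d = {"mode": scheme.mode}
    if scheme.mode == "sequence":
        d["max_length"] = scheme.max_length
    else:
        d["bins"] = [
            {
                "descriptor_name": b.descriptor_name,
                "edges": [float(e) for e in b.edges],
                "degenerate": b.degenerate,
            }
            for b in scheme.bins
        ]
    return d


def _scheme_from_dict(d: dict) -> EncodingScheme:
    if d["mode"] == "sequence":
        return EncodingScheme("sequence", max_length=int(d["max_length"]))
    bins = tuple(
        DescriptorBinSpec(
            b["descriptor_name"], tuple(b["edges"]), degenerate=b["degenerate"]
        )
        for b in d["bins"]
    )
    return EncodingScheme("descriptor", bins=bins)


def _model_to_dict(model: SensorModel) -> dict:
    d = {
        "scheme": _scheme_to_dict(model.scheme),
        "sensor_weights": [float(w) for w in np.atleast_1d(model.sensor_weights)],
        "threshold": float(model.threshold),
        "index_scale": list(model.index_scale) if model.index_scale else None,
        "label_positive": model.label_positive,
    }
    if model.battery is not None:
        d["battery"] = {
            "sensors": [_sensor_to_dict(s) for s in model.battery.sensors],
            "sensor_weights": [float(w) for w in model.battery.sensor_weights],
            "min_gap": model.battery.min_gap,
            "order_penalty": model.battery.order_penalty,
            "converged": list(model.battery.converged),
        }
    else:
        d["sensors"] = [_sensor_to_dict(s) for s in model.sensors]
    return d


def _model_from_dict(d: dict) -> SensorModel:
    scheme = _scheme_from_dict(d["scheme"])
    battery = None
    sensors = ()
    if "battery" in d:
        b = d["battery"]
        battery = HelixBattery(
            sensors=tuple(_sensor_from_dict(s) for s in b["sensors"]),
            sensor_weights=np.array(b["sensor_weights"], dtype=float),
            min_gap=int(b["min_gap"]),
            order_penalty=float(b["order_penalty"]),
            converged=tuple(b.get("converged", ())),
        )
        weights = np.ones(1)
    else:
        sensors = tuple(_sensor_from_dict(s) for s in d["sensors"])
        weights = np.array(d["sensor_weights"], dtype=float)
    return SensorModel(
        scheme=scheme,
        sensors=sensors,
        battery=battery,
        sensor_weights=weights,
        threshold=float(d["threshold"]),
        index_scale=tuple(d["index_scale"]) if d["index_scale"] else None,
        label_positive=d["label_positive"],
    )


def save_model(model, path, seed: int | None = None) -> None:
    """Serialize a SensorModel (or a {label: model} dict) to JSON.

    Floats are written with full repr precision, so load -> score is
    bit-exact. Provenance carries the seed and a sha256 of the payload.
    """
    if isinstance(model, dict):
        payload = {
            "kind": "multiclass",
            "models": {str(k): _model_to_dict(m) for k, m in sorted(model.items())},
        }
    else:
        payload = {"kind": "binary", "model": _model_to_dict(model)}
    body = json.dumps(payload, sort_keys=True)
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "provenance": {
            "seed": seed,
            "config_hash": hashlib.sha256(body.encode()).hexdigest(),
        },
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def load_model(path):
    """Load a model file; returns a SensorModel or a {label: model} dict."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format_version {version!r} "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    if doc["kind"] == "multiclass":
        return {k: _model_from_dict(m) for k, m in doc["models"].items()}
    return _model_from_dict(doc["model"])
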