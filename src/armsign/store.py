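"""Persistence: dictionaries, datasets, ARFF export, model files.

Dataset directory layout (a plain-text replacement for the original
embedded database):

    dictionary.json   ordered word list
    recordings.jsonl  one recording per line: metadata + channel arrays
    features.csv      1044 feature columns + final ``label`` column

All writers are deterministic: stable key order and fixed numeric
formatting (``repr`` round-trips doubles exactly).
"""

from __future__ import annotations

import csv
import io
import json
import pickle
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .classify import ClassifierSpec, Model
from .dataset import Dictionary, FeatureTable, SignDataset
from .features import feature_names
from .synth import ArmbandStream, TwoArmRecording

__all__ = [
    "import_dictionary_txt",
    "load_dictionary_txt",
    "save_dataset",
    "load_dataset",
    "export_arff",
    "read_arff",
    "save_model",
    "load_model",
    "DatasetLoadError",
]

PathLike = Union[str, Path]


class DatasetLoadError(RuntimeError):
    """A dataset directory is corrupt or incomplete; names the offending file."""


def load_dictionary_txt(path: PathLike) -> Dictionary:
    """Read a UTF-8 one-word-per-line dictionary file.

    Blank lines are skipped; duplicates are rejected with their line numbers;
    an effectively empty file is an error.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    words: list[str] = []
    seen: dict[str, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        word = raw.strip()
        if not word:
            continue
        if word in seen:
            raise ValueError(
                f"{path}: duplicate word {word!r} on line {lineno} (first on line {seen[word]})"
            )
        seen[word] = lineno
        words.append(word)
    if not words:
        raise ValueError(f"{path}: dictionary file contains no words")
    return Dictionary(words)


def import_dictionary_txt(
    path: PathLike,
    dataset: Optional[SignDataset] = None,
    confirm_replace: bool = False,
) -> SignDataset:
    """Load a txt dictionary, replacing the active one.

    Importing over a dataset that already holds records deletes them, so it
    requires ``confirm_replace=True``; without the flag the existing data are
    left untouched and an error is raised.
    """
    new_dict = load_dictionary_txt(path)  # fails before touching anything
    if dataset is not None and len(dataset.recordings) > 0 and not confirm_replace:
        raise PermissionError(
            "importing a dictionary deletes all existing records; pass confirm_replace=True"
        )
    return SignDataset(dictionary=new_dict)


# ---------------------------------------------------------------------------
# dataset directory


def _stream_to_json(arm: ArmbandStream) -> dict:
    return {
        "device_id": arm.device_id,
        "emg_t": arm.emg_t.tolist(),
        "emg": arm.emg.astype(int).tolist(),
        "imu_t": arm.imu_t.tolist(),
        "accel": arm.accel.tolist(),
        "gyro": arm.gyro.tolist(),
        "quat": arm.quat.tolist(),
    }


def _stream_from_json(d: dict) -> ArmbandStream:
    return ArmbandStream(
        device_id=d["device_id"],
        emg_t=np.array(d["emg_t"], dtype=float),
        emg=np.array(d["emg"], dtype=np.int16).reshape(len(d["emg_t"]), -1),
        imu_t=np.array(d["imu_t"], dtype=float),
        accel=np.array(d["accel"], dtype=float).reshape(len(d["imu_t"]), -1),
        gyro=np.array(d["gyro"], dtype=float).reshape(len(d["imu_t"]), -1),
        quat=np.array(d["quat"], dtype=float).reshape(len(d["imu_t"]), -1),
    )


def recording_to_json(rec: TwoArmRecording) -> str:
    payload = {
        "label": rec.label,
        "repetition": rec.repetition,
        "left": _stream_to_json(rec.left),
        "right": _stream_to_json(rec.right),
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def recording_from_json(line: str) -> TwoArmRecording:
    d = json.loads(line)
    return TwoArmRecording(
        left=_stream_from_json(d["left"]),
        right=_stream_from_json(d["right"]),
        label=d["label"],
        repetition=d["repetition"],
    )


def _write_features_csv(table: FeatureTable, path: Path) -> None:
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(table.names + ["label"])
        for row, label in zip(table.X, table.labels):
            writer.writerow([repr(float(v)) for v in row] + [label])


def _read_features_csv(path: Path) -> FeatureTable:
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        names = header[:-1]
        rows, labels = [], []
        for rec in reader:
            rows.append([float(v) for v in rec[:-1]])
            labels.append(rec[-1])
    X = np.array(rows, dtype=float) if rows else np.zeros((0, len(names)))
    return FeatureTable(names, X, labels)


def save_dataset(dataset: SignDataset, directory: PathLike) -> None:
    """Write dictionary.json, recordings.jsonl and (if present) features.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "dictionary.json").write_text(
        json.dumps({"words": dataset.dictionary.words}, ensure_ascii=False, indent=0) + "\n",
        encoding="utf-8",
    )
    with (directory / "recordings.jsonl").open("w", encoding="utf-8") as fh:
        for rec in dataset.recordings:
            fh.write(recording_to_json(rec) + "\n")
    if dataset.features is not None:
        _write_features_csv(dataset.features, directory / "features.csv")


def load_dataset(directory: PathLike) -> SignDataset:
    """Inverse of :func:`save_dataset`; errors name the corrupt file."""
    directory = Path(directory)
    dict_path = directory / "dictionary.json"
    rec_path = directory / "recordings.jsonl"
    if not dict_path.exists():
        raise DatasetLoadError(f"missing {dict_path}")
    try:
        words = json.loads(dict_path.read_text(encoding="utf-8"))["words"]
        dictionary = Dictionary(words)
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise DatasetLoadError(f"corrupt {dict_path}: {exc}") from exc
    recordings: list[TwoArmRecording] = []
    if rec_path.exists():
        with rec_path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    recordings.append(recording_from_json(line))
                except (json.JSONDecodeError, KeyError, ValueError) as exc:
                    raise DatasetLoadError(f"corrupt {rec_path} line {lineno}: {exc}") from exc
    features = None
    feat_path = directory / "features.csv"
    if feat_path.exists():
        try:
            features = _read_features_csv(feat_path)
        except (ValueError, IndexError, StopIteration) as exc:
            raise DatasetLoadError(f"corrupt {feat_path}: {exc}") from exc
    return SignDataset(dictionary=dictionary, recordings=recordings, features=features)


# ---------------------------------------------------------------------------
# continuous sessions (for the record/recognize CLI loops)


def save_session(session, path: PathLike) -> None:
    """Write a continuous two-armband session (plus annotations) as JSON."""
    payload = {
        "left": _stream_to_json(session.left),
        "right": _stream_to_json(session.right),
        "annotations": [
            {"start_t": a.start_t, "end_t": a.end_t, "word": a.word}
            for a in session.annotations
        ],
    }
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, separators=(",", ":")) + "\n", encoding="utf-8"
    )


def load_session(path: PathLike):
    from .synth import SegmentAnnotation, Session

    d = json.loads(Path(path).read_text(encoding="utf-8"))
    return Session(
        left=_stream_from_json(d["left"]),
        right=_stream_from_json(d["right"]),
        annotations=[
            SegmentAnnotation(a["start_t"], a["end_t"], a["word"]) for a in d["annotations"]
        ],
    )


# ---------------------------------------------------------------------------
# ARFF


def _arff_quote(value: str) -> str:
    if any(ch in value for ch in " ,'\"{}%\t") or value == "":
        return "'" + value.replace("\\", "\\\\").replace("'", "\\'") + "'"
    return value


def export_arff(
    dataset: SignDataset,
    path: PathLike,
    relation: str = "armsign_features",
) -> None:
    """Write the feature table as an ARFF file: 1044 numeric attributes plus
    one nominal class attribute enumerating the dictionary."""
    if dataset.features is None or len(dataset.features) == 0:
        raise ValueError("dataset has no feature table to export")
    table = dataset.features
    path = Path(path)
    lines = [f"@RELATION {_arff_quote(relation)}", ""]
    for name in table.names:
        lines.append(f"@ATTRIBUTE {_arff_quote(name)} NUMERIC")
    class_values = ",".join(_arff_quote(w) for w in dataset.dictionary.words)
    lines.append(f"@ATTRIBUTE class {{{class_values}}}")
    lines.append("")
    lines.append("@DATA")
    for row, label in zip(table.X, table.labels):
        lines.append(",".join(repr(float(v)) for v in row) + "," + _arff_quote(label))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _arff_unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == tok[-1] and tok[0] in "'\"":
        return tok[1:-1].replace("\\'", "'").replace("\\\\", "\\")
    return tok


def _split_quoted(text: str, sep: str = ",") -> list[str]:
    out, buf, quote = [], [], None
    i = 0
    while i < len(text):
        ch = text[i]
        if quote:
            if ch == "\\" and i + 1 < len(text):
                buf.append(ch)
                buf.append(text[i + 1])
                i += 2
                continue
            if ch == quote:
                quote = None
            buf.append(ch)
        elif ch in "'\"":
            quote = ch
            buf.append(ch)
        elif ch == sep:
            out.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
        i += 1
    out.append("".join(buf))
    return out


def read_arff(path: PathLike) -> tuple[str, list[tuple[str, object]], list[list]]:
    """Strict ARFF reader: (relation, [(attr_name, 'numeric'|values)], data rows).

    Serves as the parse-back check for :func:`export_arff` (no external ARFF
    library is assumed to be installed).
    """
    relation = ""
    attributes: list[tuple[str, object]] = []
    data: list[list] = []
    in_data = False
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        upper = line.upper()
        if in_data:
            toks = _split_quoted(line)
            if len(toks) != len(attributes):
                raise ValueError(f"line {lineno}: {len(toks)} values for {len(attributes)} attributes")
            row: list = []
            for tok, (_, kind) in zip(toks, attributes):
                val = _arff_unquote(tok)
                if kind == "numeric":
                    row.append(float(val))
                else:
                    if val not in kind:
                        raise ValueError(f"line {lineno}: {val!r} not a declared nominal value")
                    row.append(val)
            data.append(row)
        elif upper.startswith("@RELATION"):
            relation = _arff_unquote(line[len("@RELATION") :].strip())
        elif upper.startswith("@ATTRIBUTE"):
            rest = line[len("@ATTRIBUTE") :].strip()
            if rest.startswith(("'", '"')):
                q = rest[0]
                end = 1
                while end < len(rest):
                    if rest[end] == "\\":
                        end += 2
                        continue
                    if rest[end] == q:
                        break
                    end += 1
                name = _arff_unquote(rest[: end + 1])
                typepart = rest[end + 1 :].strip()
            else:
                name, _, typepart = rest.partition(" ")
                typepart = typepart.strip()
            if typepart.upper() in ("NUMERIC", "REAL", "INTEGER"):
                attributes.append((name, "numeric"))
            elif typepart.startswith("{") and typepart.endswith("}"):
                values = [_arff_unquote(v) for v in _split_quoted(typepart[1:-1])]
                attributes.append((name, values))
            else:
                raise ValueError(f"line {lineno}: unsupported attribute type {typepart!r}")
        elif upper.startswith("@DATA"):
            if not attributes:
                raise ValueError("@DATA before any @ATTRIBUTE")
            in_data = True
        else:
            raise ValueError(f"line {lineno}: unrecognized ARFF construct {line!r}")
    return relation, attributes, data


# ---------------------------------------------------------------------------
# model files

_MODEL_FORMAT_VERSION = 1


def save_model(model: Model, path: PathLike) -> None:
    """Persist a fitted model with algorithm name, parameters, seed,
    standardization statistics and the feature-registry hash."""
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "algorithm": model.spec.algorithm,
        "params": model.spec.resolved_params(),
        "seed": model.seed,
        "feature_names_hash": model.feature_names_hash,
        "scaler_mean": model.scaler.mean_.tolist(),
        "scaler_scale": model.scaler.scale_.tolist(),
        "classes": [str(c) for c in model.classes],
        "model": model,
    }
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: PathLike, expected_names_hash: Optional[str] = None) -> Model:
    """Reload a model file; refuses a feature-registry hash mismatch."""
    with Path(path).open("rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {payload.get('format_version')!r}")
    model: Model = payload["model"]
    if model.feature_names_hash != payload["feature_names_hash"]:
        raise ValueError("model file is inconsistent: embedded feature-registry hash mismatch")
    if expected_names_hash is not None and model.feature_names_hash != expected_names_hash:
        raise ValueError(
            "feature-registry hash mismatch: model was trained against a different feature layout"
        )
    return model
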