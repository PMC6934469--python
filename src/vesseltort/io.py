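"""File formats: vessel-graph JSON, ratings CSV, score/result CSV writers.

The vessel-graph schema (version "1.0") is a JSON object::

    {
      "schema_version": "1.0",
      "meta": {"seed": ..., "config_hash": ...},        # optional
      "retinas": [
        {
          "retina_id": "r000",
          "landmarks": {"od_center": [x, y], "od_radius": r,
                        "fovea_center": [x, y],
                        "image_width": W, "image_height": H},
          "vessels": [
            {"vessel_id": "r000-v00", "av_class": "artery",
             "points": [[x, y], ...], "calibers": [c, ...]}
          ]
        }, ...
      ]
    }

Coordinates are continuous [x, y] pairs in pixel units, 0-based, origin at
the top-left with y increasing downward (raster convention). Ratings are a
CSV with columns retina_id, E1..E5 and binary cells; lines starting with
``#`` are metadata comments (config hash and seed of the producing run).
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .anatomy import LandmarkSet
from .errors import RatingsFormatError, VesselGraphError, VesseltortError
from .evaluate import N_RATERS, RatingSet
from .sample import RetinaSample, Vessel

SCHEMA_VERSION = "1.0"
_RATER_COLS = [f"E{i + 1}" for i in range(N_RATERS)]


def write_vessel_graph(samples, path, meta: dict | None = None) -> None:
    """Serialize a cohort to the vessel-graph JSON schema."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "meta": meta or {},
        "retinas": [
            {
                "retina_id": s.retina_id,
                "landmarks": {
                    "od_center": list(map(float, s.landmarks.od_center)),
                    "od_radius": float(s.landmarks.od_radius),
                    "fovea_center": list(map(float, s.landmarks.fovea_center)),
                    "image_width": int(s.landmarks.image_width),
                    "image_height": int(s.landmarks.image_height),
                },
                "vessels": [
                    {
                        "vessel_id": v.vessel_id,
                        "av_class": v.av_class,
                        "points": v.points.tolist(),
                        "calibers": v.calibers.tolist(),
                    }
                    for v in s.vessels
                ],
            }
            for s in samples
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_vessel_graph(path) -> list[RetinaSample]:
    """Read and validate a vessel-graph JSON file into retina samples.

    Schema violations raise :class:`VesselGraphError` naming the offending
    retina/vessel.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise VesselGraphError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "retinas" not in doc:
        raise VesselGraphError(f"{path}: missing 'retinas' array")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise VesselGraphError(
            f"{path}: unknown schema version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    samples = []
    for r in doc["retinas"]:
        rid = r.get("retina_id", "<missing id>")
        try:
            lm = r["landmarks"]
            landmarks = LandmarkSet(
                od_center=tuple(lm["od_center"]),
                od_radius=float(lm["od_radius"]),
                fovea_center=tuple(lm["fovea_center"]),
                image_width=int(lm["image_width"]),
                image_height=int(lm["image_height"]),
            )
            vessels = []
            for v in r["vessels"]:
                vid = v.get("vessel_id", "<missing id>")
                try:
                    vessels.append(Vessel(
                        vessel_id=vid,
                        points=np.asarray(v["points"], dtype=float),
                        av_class=v["av_class"],
                        calibers=np.asarray(v["calibers"], dtype=float),
                    ))
                except (VesseltortError, KeyError, ValueError) as exc:
                    raise VesselGraphError(
                        f"{path}: retina {rid!r}, vessel {vid!r}: {exc}"
                    ) from exc
            samples.append(RetinaSample(retina_id=rid, landmarks=landmarks,
                                        vessels=tuple(vessels)))
        except VesselGraphError:
            raise
        except (VesseltortError, KeyError, TypeError, ValueError) as exc:
            raise VesselGraphError(f"{path}: retina {rid!r}: {exc}") from exc
    ids = [s.retina_id for s in samples]
    if len(set(ids)) != len(ids):
        raise VesselGraphError(f"{path}: duplicate retina_id")
    return samples


def _meta_header(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
    return f"# {parts}\n"


def write_ratings(ratings: RatingSet, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(ratings.ratings, columns=_RATER_COLS)
    df.insert(0, "retina_id", list(ratings.retina_ids))
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, index=False)


def read_ratings(path) -> RatingSet:
    """Read a ratings CSV (retina_id, E1..E5 with binary cells)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise RatingsFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in ["retina_id", *_RATER_COLS] if c not in df.columns]
    if missing:
        raise RatingsFormatError(f"{path}: missing columns {missing}")
    cells = df[_RATER_COLS].to_numpy()
    if not np.isin(cells, (0, 1)).all():
        raise RatingsFormatError(f"{path}: rating cells must be binary 0/1")
    ids = df["retina_id"].astype(str).tolist()
    if len(set(ids)) != len(ids):
        raise RatingsFormatError(f"{path}: duplicate retina_id")
    return RatingSet(retina_ids=tuple(ids), ratings=cells.astype(int))


def write_scores(rows: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Deterministic column-ordered CSV writer with a metadata comment header."""
    with open(path, "w") as fh:
        fh.write(_meta_header(meta))
        rows.to_csv(fh, index=False, float_format="%.12g")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
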