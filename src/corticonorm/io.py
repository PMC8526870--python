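"""File-format contracts shared by all pipeline stages.

All tables are tidy UTF-8 TSV with '.' decimal separator and LF endings:

- ``subjects.tsv``: subject_id, group, ga_birth, pma_scan, sex,
  bsid_motor, bsid_language, bsid_cognitive
- ``features.tsv`` (long): subject_id, parcel_id, metric, value
- ``parcels.tsv``: parcel_id, hemisphere, region, x, y, z
- ``ground_truth.tsv`` (long, nonzero entries): subject_id, parcel_id,
  metric, sign
- ``z_scores.tsv`` / ``extreme_mask.tsv`` / ``overlap_map.tsv`` /
  ``atypicality.tsv`` / ``stat_map.tsv``: see the writers below

Readers validate the schema strictly (unknown metric names, duplicate keys
and non-numeric values are rejected with the offending row named).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import METRICS, FeatureTable, GroundTruth, ParcelSet
from .deviations import AtypicalityIndex, ExtremeMask, OverlapMap, ZScoreTable
from .permutation import PermutationResult

_SUBJECT_COLUMNS = ["subject_id", "group", "ga_birth", "pma_scan", "sex"]


def _to_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_subjects(subjects: pd.DataFrame, path) -> None:
    _to_tsv(subjects, path)


def read_subjects(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _SUBJECT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"subjects file missing columns: {missing}")
    if frame["subject_id"].duplicated().any():
        dup = frame.loc[frame["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")
    return frame


def write_parcels(parcels: ParcelSet, path) -> None:
    _to_tsv(parcels.table, path)


def read_parcels(path) -> ParcelSet:
    frame = pd.read_csv(path, sep="\t")
    needed = ["parcel_id", "hemisphere", "region", "x", "y", "z"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"parcels file missing columns: {missing}")
    return ParcelSet(frame)


def write_feature_table(table: FeatureTable, path) -> None:
    _to_tsv(table.to_long(), path)


def read_feature_table(
    path, subjects: pd.DataFrame | None = None, parcels: ParcelSet | None = None
) -> FeatureTable:
    """Read a long-format feature TSV into a FeatureTable.

    When subject/parcel metadata files are not supplied, minimal frames are
    reconstructed from the ids present (group and covariates then missing).
    """
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    needed = ["subject_id", "parcel_id", "metric", "value"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise ValueError(f"feature file missing columns: {missing}")
    unknown = set(frame["metric"].unique()) - set(METRICS)
    if unknown:
        row = int(frame.index[frame["metric"].isin(unknown)][0]) + 2  # 1-based + header
        raise ValueError(f"unknown metric names {sorted(unknown)} (first at row {row})")
    values_col = pd.to_numeric(frame["value"], errors="coerce")
    if values_col.isna().any():
        row = int(frame.index[values_col.isna()][0]) + 2
        raise ValueError(f"non-numeric value at row {row}")
    dup = frame.duplicated(subset=["subject_id", "parcel_id", "metric"])
    if dup.any():
        key = frame.loc[dup, ["subject_id", "parcel_id", "metric"]].iloc[0]
        raise ValueError(
            f"duplicate row for subject {key['subject_id']!r}, "
            f"parcel {key['parcel_id']}, metric {key['metric']!r}"
        )

    subject_ids = (
        subjects["subject_id"].tolist()
        if subjects is not None
        else sorted(frame["subject_id"].unique())
    )
    parcel_ids = (
        parcels.parcel_ids.tolist()
        if parcels is not None
        else sorted(frame["parcel_id"].unique())
    )
    wide = frame.pivot_table(
        index="subject_id", columns=["parcel_id", "metric"], values="value",
        aggfunc="first", observed=True,
    )
    values = np.empty((len(subject_ids), len(parcel_ids), len(METRICS)))
    for p_i, pid in enumerate(parcel_ids):
        for m_i, metric in enumerate(METRICS):
            col = wide[(pid, metric)].reindex(subject_ids)
            if col.isna().any():
                bad = col.index[col.isna()][0]
                raise ValueError(
                    f"missing value for subject {bad!r}, parcel {pid}, "
                    f"metric {metric!r}"
                )
            values[:, p_i, m_i] = col.to_numpy(float)

    if subjects is None:
        subjects = pd.DataFrame({"subject_id": subject_ids})
    if parcels is None:
        parcels = ParcelSet(
            pd.DataFrame(
                {
                    "parcel_id": parcel_ids,
                    "hemisphere": "unknown",
                    "region": "unknown",
                    "x": 0.0, "y": 0.0, "z": 0.0,
                }
            )
        )
    return FeatureTable(values=values, subjects=subjects.reset_index(drop=True),
                        parcels=parcels)


def write_ground_truth(truth: GroundTruth, table: FeatureTable, path) -> None:
    idx = np.argwhere(truth.extreme_mask_true != 0)
    frame = pd.DataFrame(
        {
            "subject_id": table.subject_ids[idx[:, 0]],
            "parcel_id": table.parcels.parcel_ids[idx[:, 1]],
            "metric": [table.metrics[j] for j in idx[:, 2]],
            "sign": truth.extreme_mask_true[idx[:, 0], idx[:, 1], idx[:, 2]],
        }
    )
    _to_tsv(frame, path)


def write_z_scores(z: ZScoreTable, path) -> None:
    n_s, n_p, n_m = z.z.shape
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(z.subject_ids, n_p * n_m),
            "parcel_id": np.tile(np.repeat(z.parcel_ids, n_m), n_s),
            "metric": np.tile(list(z.metrics), n_s * n_p),
            "z": z.z.ravel(),
        }
    )
    _to_tsv(frame, path)


def write_extreme_mask(mask: ExtremeMask, path) -> None:
    n_s, n_p, n_m = mask.label.shape
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(mask.subject_ids, n_p * n_m),
            "parcel_id": np.tile(np.repeat(mask.parcel_ids, n_m), n_s),
            "metric": np.tile(list(mask.metrics), n_s * n_p),
            "label": mask.label.ravel(),
        }
    )
    _to_tsv(frame, path)


def write_overlap_map(overlap: OverlapMap, path, group: str = "") -> None:
    n_p, n_m = overlap.percent_pos.shape
    frame = pd.DataFrame(
        {
            "parcel_id": np.repeat(overlap.parcel_ids, n_m),
            "metric": np.tile(list(overlap.metrics), n_p),
            "percent_pos": overlap.percent_pos.ravel(),
            "percent_neg": overlap.percent_neg.ravel(),
            "group": group,
        }
    )
    _to_tsv(frame, path)


def write_atypicality(indices: AtypicalityIndex, path) -> None:
    n_s, n_m = indices.pos_index.shape
    frame = pd.DataFrame(
        {
            "subject_id": np.repeat(indices.subject_ids, n_m),
            "metric": np.tile(list(indices.metrics), n_s),
            "pos_index": indices.pos_index.ravel(),
            "neg_index": indices.neg_index.ravel(),
            "pos_index_rounded": indices.pos_rounded.ravel(),
            "neg_index_rounded": indices.neg_rounded.ravel(),
        }
    )
    _to_tsv(frame, path)


def read_atypicality(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_stat_map(
    result: PermutationResult, parcel_ids, metrics, path, contrast_name: str = ""
) -> None:
    n_p, n_m = result.t.shape
    rows = []
    for contrast, p_map in (("positive", result.p_pos), ("negative", result.p_neg)):
        rows.append(
            pd.DataFrame(
                {
                    "parcel_id": np.repeat(parcel_ids, n_m),
                    "metric": np.tile(list(metrics), n_p),
                    "contrast": contrast,
                    "t": result.t.ravel(),
                    "r": result.r.ravel(),
                    "p_mcfwe": p_map.ravel(),
                    "significant": (p_map < result.alpha).ravel(),
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True)
    if contrast_name:
        frame.insert(2, "design", contrast_name)
    _to_tsv(frame, path)


def file_hash(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def hash_directory_outputs(out_dir) -> dict[str, str]:
    out_dir = Path(out_dir)
    return {
        p.name: file_hash(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.suffix in (".tsv", ".json")
        and p.name != "manifest.json"
    }
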