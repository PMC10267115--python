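"""Plain-text study I/O: TSV time series with JSON sidecars, a JSON study
manifest, CSV covariate and behaviour tables.

A study on disk looks like::

    study/
      manifest.json              # sessions, covariate/behaviour paths, tr
      sessions/sub-01_placebo.tsv / .json
      covariates.csv             # subject_id, heart_rate, dbp, sbp, temperature
      behaviour.csv              # subject_id, behaviour

Volumetric images are out of scope: extracting region time series from
NIfTI volumes is a documented pre-step outside this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONDITIONS, RoiTimeSeries
from .simulate import SyntheticStudy


@dataclass
class StudyManifest:
    """Index of a study directory; every subject appears with both conditions."""

    sessions: list[tuple[str, str, str]]  # (subject_id, condition, timeseries_path)
    covariates_path: str
    behaviour_path: str
    tr: float
    atlas_labels_path: str | None = None

    def validate(self, root: Path) -> None:
        by_subject: dict[str, set[str]] = {}
        for subject, condition, path in self.sessions:
            by_subject.setdefault(subject, set()).add(condition)
            if not (root / path).exists():
                raise FileNotFoundError(f"missing time series file: {path}")
        for subject, conds in by_subject.items():
            if conds != set(CONDITIONS):
                raise ValueError(
                    f"subject {subject} has conditions {sorted(conds)}; "
                    f"expected both of {list(CONDITIONS)}"
                )
        for p in (self.covariates_path, self.behaviour_path):
            if not (root / p).exists():
                raise FileNotFoundError(f"missing table: {p}")


def write_session(ts: RoiTimeSeries, path: Path) -> None:
    """TSV (T rows, R named columns) plus a JSON sidecar with the metadata."""
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(path, sep="\t", index=False)
    sidecar = {
        "tr": ts.tr, "subject": ts.subject_id, "condition": ts.condition,
        "labels": ts.region_labels,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_session(path: Path) -> RoiTimeSeries:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != list(sidecar["labels"]):
        raise ValueError(f"column/label mismatch in {path}")
    return RoiTimeSeries(
        data=df.to_numpy(float), tr=float(sidecar["tr"]),
        region_labels=list(sidecar["labels"]), subject_id=sidecar["subject"],
        condition=sidecar["condition"],
    )


def write_study(study: SyntheticStudy, out_dir: Path) -> Path:
    """Serialize a synthetic study; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "sessions").mkdir(parents=True, exist_ok=True)
    entries = []
    for ts in study.sessions:
        rel = f"sessions/{ts.subject_id}_{ts.condition}.tsv"
        write_session(ts, out_dir / rel)
        entries.append([ts.subject_id, ts.condition, rel])
    study.covariates.to_csv(out_dir / "covariates.csv")
    study.behaviour.to_frame().to_csv(out_dir / "behaviour.csv")
    manifest = {
        "sessions": entries,
        "covariates_path": "covariates.csv",
        "behaviour_path": "behaviour.csv",
        "tr": study.sessions[0].tr,
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return mpath


def read_study(manifest_path: Path) -> tuple[list[RoiTimeSeries], pd.DataFrame, pd.Series]:
    """Load sessions, covariates and behaviour from a manifest, validating
    the pairing and shape invariants."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    raw = json.loads(manifest_path.read_text())
    manifest = StudyManifest(
        sessions=[tuple(e) for e in raw["sessions"]],
        covariates_path=raw["covariates_path"],
        behaviour_path=raw["behaviour_path"],
        tr=float(raw["tr"]),
        atlas_labels_path=raw.get("atlas_labels_path"),
    )
    manifest.validate(root)
    sessions = [read_session(root / p) for _, _, p in manifest.sessions]
    shapes = {ts.data.shape for ts in sessions}
    if len(shapes) != 1:
        raise ValueError(f"sessions disagree in (T, R): {sorted(shapes)}")
    covariates = pd.read_csv(root / manifest.covariates_path,
                             index_col="subject_id", float_precision="round_trip")
    behaviour = pd.read_csv(root / manifest.behaviour_path, index_col="subject_id",
                            float_precision="round_trip")["behaviour"]
    subjects = {ts.subject_id for ts in sessions}
    if not subjects <= set(covariates.index):
        raise ValueError("covariates missing for some subjects")
    return sessions, covariates, behaviour


def write_matrix_tsv(matrix: np.ndarray, labels: list[str], path: Path) -> None:
    """Square connectivity matrix as TSV (row = target, column = source)."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )
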