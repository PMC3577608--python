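"""Readers, writers and configuration for the pipeline's text formats.

All artifacts are plain text: per-subject time series as TSV (header row
of region labels, one row per volume), motion regressors as TSV, labels
as a two-column TSV, ground truth and results as JSON. Outputs carry the
configuration and seed so every run is auditable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .connectivity import edge_to_pair, n_edges
from .model import CVResult, PermutationResult
from .signatures import EdgeWeightMap, SignatureSet, label_edges
from .synthetic import (
    CLASS_ORDER,
    CohortConfig,
    GroundTruth,
    PlantedEdgeSet,
    SyntheticCohort,
)
from .timeseries import RegionalTimeSeries, default_region_labels

__all__ = [
    "PipelineConfig",
    "read_timeseries_table",
    "write_timeseries_table",
    "read_labels",
    "write_labels",
    "read_region_labels",
    "write_cohort",
    "read_cohort",
    "write_ground_truth",
    "read_ground_truth",
    "cohort_config_to_dict",
    "cohort_config_from_dict",
    "write_results",
    "read_edge_weight_maps",
]

VALID_CLASSES = set(CLASS_ORDER)


@dataclass
class PipelineConfig:
    """Every tunable parameter of the classification pipeline."""

    discard: int = 0
    low_hz: float = 0.01
    high_hz: float = 0.08
    filter_order: int = 4
    ripple_db: float = 0.5
    regress_global: bool = True
    n_components: int | None = None  # None -> per-fold maximum
    cost_c: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    selection_fraction: float = 0.05
    top_k: int | None = None
    use_fisher_z: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------- time series


def write_timeseries_table(ts: RegionalTimeSeries, path: str | Path) -> None:
    """TSV with one column per region (header = labels), one row per volume."""
    df = pd.DataFrame(ts.data.T, columns=list(ts.region_labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_timeseries_table(
    path: str | Path, tr_seconds: float = 2.0, subject_id: str = ""
) -> RegionalTimeSeries:
    """Parse a delimited time-series table into a RegionalTimeSeries.

    Regions may be columns (header row of region labels) or rows (a
    leading ``region`` column holding the labels); the orientation is
    auto-detected. Missing or malformed cells are rejected with their
    location.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate region labels in {path.name}: {dupes}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0].strip().lower() == "region":
        labels = [str(v) for v in df.iloc[:, 0]]
        body = df.iloc[:, 1:].T
        body.columns = labels
        df = body.reset_index(drop=True)
    labels = [str(c) for c in df.columns]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate region labels in {path.name}: {dupes}")
    values = np.empty(df.shape, dtype=float)
    for cidx, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(converted.to_numpy(dtype=float)))[0]
        if bad.size:
            row = int(bad[0])
            raise ValueError(
                f"non-numeric or missing value at row {row + 2}, "
                f"column {col!r} of {path.name}"
            )
        values[:, cidx] = converted.to_numpy(dtype=float)
    return RegionalTimeSeries(
        data=values.T,
        tr_seconds=tr_seconds,
        region_labels=tuple(labels),
        subject_id=subject_id or path.stem.replace("_timeseries", ""),
    )


def write_motion_table(motion: np.ndarray, path: str | Path) -> None:
    cols = [f"motion{k + 1}" for k in range(motion.shape[1])]
    pd.DataFrame(motion, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_motion_table(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", float_precision="round_trip").to_numpy(
        dtype=float
    )


# --------------------------------------------------------------------- labels


def write_labels(
    subject_ids: list[str], labels: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"subject": subject_ids, "class": labels}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column subject -> class table; class names are validated."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["subject", "class"]:
        raise ValueError("label file must have 'subject' and 'class' columns")
    unknown = sorted(set(df["class"]) - VALID_CLASSES)
    if unknown:
        raise ValueError(
            f"unknown class name(s) {unknown}; expected one of "
            f"{sorted(VALID_CLASSES)}"
        )
    return dict(zip(df["subject"].astype(str), df["class"]))


def read_region_labels(path: str | Path) -> tuple[str, ...]:
    lines = Path(path).read_text().splitlines()
    labels = tuple(line.strip() for line in lines if line.strip())
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate region labels")
    return labels


def write_region_labels(labels: tuple[str, ...], path: str | Path) -> None:
    Path(path).write_text("\n".join(labels) + "\n")


# ------------------------------------------------------------- cohort on disk


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    for key in ("state", "trait", "compensatory"):
        d[key] = {
            "edges": [list(e) for e in d[key]["edges"]],
            "delta_r": d[key]["delta_r"],
        }
    d["n_per_group"] = list(d["n_per_group"])
    return d


def cohort_config_from_dict(d: Mapping) -> CohortConfig:
    d = dict(d)
    for key in ("state", "trait", "compensatory"):
        if key in d:
            spec = d[key]
            d[key] = PlantedEdgeSet(
                edges=tuple(tuple(e) for e in spec.get("edges", ())),
                delta_r=float(spec.get("delta_r", 0.0)),
            )
    if "n_per_group" in d:
        d["n_per_group"] = tuple(int(n) for n in d["n_per_group"])
    return CohortConfig(**d)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "n_regions": truth.group_covariances[CLASS_ORDER[0]].shape[0],
        "state_edges": sorted(truth.state_edges),
        "trait_edges": sorted(truth.trait_edges),
        "compensatory_edges": sorted(truth.compensatory_edges),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write a cohort as per-subject TSVs plus labels, truth and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = []
    for ts, motion in zip(cohort.subjects, cohort.motion):
        ids.append(ts.subject_id)
        write_timeseries_table(ts, out / f"{ts.subject_id}_timeseries.tsv")
        if motion.size:
            write_motion_table(motion, out / f"{ts.subject_id}_motion.tsv")
    write_labels(ids, cohort.labels, out / "labels.tsv")
    write_region_labels(
        cohort.subjects[0].region_labels, out / "region_labels.txt"
    )
    write_ground_truth(cohort.ground_truth, out / "ground_truth.json")
    (out / "cohort_config.yaml").write_text(
        yaml.safe_dump(cohort_config_to_dict(cohort.config), sort_keys=True)
    )


def read_cohort(
    in_dir: str | Path, tr_seconds: float | None = None
) -> tuple[list[RegionalTimeSeries], list[np.ndarray | None], np.ndarray]:
    """Load a cohort directory: subjects, motion tables (or None), labels.

    Subjects appear in label-file order; a missing time-series file for a
    listed subject is an error.
    """
    in_dir = Path(in_dir)
    label_map = read_labels(in_dir / "labels.tsv")
    if tr_seconds is None:
        cfg_path = in_dir / "cohort_config.yaml"
        if cfg_path.exists():
            tr_seconds = float(yaml.safe_load(cfg_path.read_text())["tr_seconds"])
        else:
            tr_seconds = 2.0
    subjects, motions, labels = [], [], []
    for sid, cls in label_map.items():
        ts_path = in_dir / f"{sid}_timeseries.tsv"
        if not ts_path.exists():
            raise FileNotFoundError(
                f"subject {sid!r} listed in labels.tsv has no time-series file"
            )
        subjects.append(read_timeseries_table(ts_path, tr_seconds, sid))
        motion_path = in_dir / f"{sid}_motion.tsv"
        motions.append(read_motion_table(motion_path) if motion_path.exists() else None)
        labels.append(cls)
    return subjects, motions, np.array(labels)


# -------------------------------------------------------------------- results


def _confusion_payload(cv: CVResult) -> dict:
    return {
        "class_order": list(cv.class_order),
        "rows_true_columns_predicted_percent": [
            [round(float(v), 10) for v in row] for row in cv.confusion_percent
        ],
    }


def write_results(
    out_dir: str | Path,
    cv: CVResult,
    perm: PermutationResult | None,
    maps: Mapping[str, EdgeWeightMap],
    region_labels: tuple[str, ...],
    config: PipelineConfig,
) -> None:
    """Write results.json, the edge-weight table and region labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "accuracy_percent": round(cv.accuracy * 100.0, 10),
        "per_class_accuracy_percent": {
            k: round(v, 10) for k, v in cv.per_class_accuracy().items()
        },
        "confusion_matrix": _confusion_payload(cv),
        "n_subjects": int(cv.n_folds),
        "config": config.to_dict(),
    }
    if perm is not None:
        payload["permutation"] = {
            "n_perm": perm.n_perm,
            "p_value": perm.p_value,
            "null_accuracy_mean_percent": round(
                float(perm.null_accuracies.mean() * 100.0), 10
            ),
        }
    (out / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))

    first = next(iter(maps.values()))
    e = first.weights.size
    pairs = [edge_to_pair(i, first.n_regions) for i in range(e)]
    table = {
        "edge_index": np.arange(e),
        "region_i": [i + 1 for i, _ in pairs],
        "region_j": [j + 1 for _, j in pairs],
    }
    for cls in CLASS_ORDER:
        table[f"weight_{cls}"] = maps[cls].weights
    pd.DataFrame(table).to_csv(out / "edge_weights.tsv", sep="\t", index=False)
    write_region_labels(region_labels, out / "region_labels.txt")


def read_edge_weight_maps(in_dir: str | Path) -> dict[str, EdgeWeightMap]:
    """Rebuild classifier edge maps from an edge_weights.tsv table."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "edge_weights.tsv", sep="\t")
    e = len(df)
    # invert E = R(R-1)/2
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if n_edges(r) != e:
        raise ValueError(f"edge count {e} is not R(R-1)/2 for any integer R")
    return {
        cls: EdgeWeightMap(
            classifier_id=cls,
            weights=df[f"weight_{cls}"].to_numpy(dtype=float),
            n_regions=r,
        )
        for cls in CLASS_ORDER
    }


def write_signatures(
    out_dir: str | Path,
    signatures: SignatureSet,
    maps: Mapping[str, EdgeWeightMap],
    region_labels: tuple[str, ...],
    recovery: dict | None = None,
) -> None:
    """Per-signature edge tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inverse = {"state": "patient", "trait": "control", "compensatory": "sibling"}
    for name in ("state", "trait", "compensatory"):
        table = label_edges(
            signatures.edges_for(name), region_labels, maps[inverse[name]]
        )
        table.to_csv(out / f"{name}_edges.tsv", sep="\t", index=False)
    summary = {
        "selection_fraction": signatures.selection_fraction,
        "top_k": signatures.top_k,
        "n_regions": signatures.n_regions,
        "overlaps": signatures.overlaps(),
    }
    if recovery is not None:
        summary["recovery"] = recovery
    (out / "signatures.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
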