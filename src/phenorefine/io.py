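"""TSV/JSON file interfaces.

Expression matrices are tab-separated with samples in rows (first column the
sample id, remaining columns numeric attributes); a ``transpose`` flag
accommodates genes-in-rows exports.  Survival tables carry sample_id, time,
event columns; labels carry sample_id, label (1/2), provenance.  Refinement
traces round-trip through JSON; trained ensembles through pickle archives.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import EnsembleClassifier
from .ira import IterationRecord, RefinementTrace
from .survival import LabelAssignment, SurvivalTable
from .synthgen import Dataset

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_survival_tsv",
    "write_survival_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_association_tsv",
    "write_histogram_tsv",
    "write_trace",
    "read_trace",
    "save_ensemble",
    "load_ensemble",
    "write_rnk",
]

TRACE_SCHEMA_VERSION = 1


def read_expression_tsv(path, transpose: bool = False) -> Dataset:
    """Read a samples-by-attributes numeric matrix.

    Duplicate sample ids and missing or non-numeric cells are rejected with
    the offending row/column named.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing value at sample {df.index[r]!r}, "
            f"attribute {df.columns[c]!r} in {path}"
        )
    return Dataset(
        sample_ids=df.index.to_numpy(dtype=object),
        attribute_ids=df.columns.to_numpy(dtype=object),
        values=numeric.to_numpy(dtype=float),
    )


def write_expression_tsv(data: Dataset, path) -> None:
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.attribute_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_survival_tsv(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table {path} lacks column {col!r}")
    time = pd.to_numeric(df["time"], errors="coerce")
    event = pd.to_numeric(df["event"], errors="coerce")
    for i, (t, e) in enumerate(zip(time, event)):
        if not np.isfinite(t) or t <= 0:
            raise ValueError(f"invalid time {df['time'][i]!r} at row {i + 2} of {path}")
        if e not in (0, 1):
            raise ValueError(f"invalid event {df['event'][i]!r} at row {i + 2} of {path}")
    return SurvivalTable(
        df["sample_id"].to_numpy(dtype=object),
        time.to_numpy(dtype=float),
        event.to_numpy(dtype=int),
    )


def write_survival_tsv(surv: SurvivalTable, path) -> None:
    pd.DataFrame(
        {"sample_id": surv.sample_ids, "time": surv.time, "event": surv.event}
    ).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> LabelAssignment:
    df = pd.read_csv(path, sep="\t")
    prov = str(df["provenance"].iloc[0]) if "provenance" in df.columns and len(df) else ""
    return LabelAssignment(
        df["sample_id"].to_numpy(dtype=object),
        df["label"].to_numpy(dtype=int),
        prov,
    )


def write_labels_tsv(labels: LabelAssignment, path) -> None:
    pd.DataFrame(
        {
            "sample_id": labels.sample_ids,
            "label": labels.labels,
            "provenance": labels.provenance,
        }
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "phenotype"):
        if col not in df.columns:
            raise ValueError(f"truth table {path} lacks column {col!r}")
    return df


def write_truth_tsv(sample_ids, phenotype, path) -> None:
    pd.DataFrame({"sample_id": sample_ids, "phenotype": phenotype}).to_csv(
        path, sep="\t", index=False
    )


def _record_to_json(rec: IterationRecord) -> dict:
    return {
        "iteration": rec.iteration,
        "sample_ids": rec.labels.sample_ids.tolist(),
        "labels": rec.labels.labels.tolist(),
        "provenance": rec.labels.provenance,
        "n_label_changes": rec.n_label_changes,
        "dev_hr": None if not np.isfinite(rec.dev_hr) else rec.dev_hr,
        "concordance_with_truth": rec.concordance_with_truth,
    }


def write_trace(trace: RefinementTrace, path, config: dict | None = None) -> None:
    """Serialize a refinement trace to JSON (classifier state excluded; use
    ``save_ensemble`` for that)."""
    payload = {
        "schema_version": TRACE_SCHEMA_VERSION,
        "status": trace.status,
        "cycle_length": trace.cycle_length,
        "config": config or {},
        "iterations": [_record_to_json(r) for r in trace.iterations],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_trace(path) -> RefinementTrace:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != TRACE_SCHEMA_VERSION:
        raise ValueError(f"unsupported trace schema in {path}")
    records = []
    for r in payload["iterations"]:
        lab = LabelAssignment(
            np.array(r["sample_ids"], dtype=object),
            np.array(r["labels"], dtype=int),
            r.get("provenance", ""),
        )
        hr = r["dev_hr"]
        records.append(
            IterationRecord(
                r["iteration"], lab, r["n_label_changes"],
                float("nan") if hr is None else hr,
                r.get("concordance_with_truth"),
            )
        )
    return RefinementTrace(records, payload["status"], payload.get("cycle_length"))


def save_ensemble(clf: EnsembleClassifier, path) -> None:
    with open(path, "wb") as fh:
        pickle.dump(clf, fh)


def load_ensemble(path) -> EnsembleClassifier:
    with open(path, "rb") as fh:
        clf = pickle.load(fh)
    if not isinstance(clf, EnsembleClassifier):
        raise ValueError(f"{path} does not contain an ensemble classifier")
    return clf


def write_association_tsv(assoc, path) -> None:
    """Per-attribute association table (t statistic, p value, Bonferroni call)."""
    pd.DataFrame(
        {
            "attribute_id": assoc.attribute_ids,
            "t_stat": assoc.t_stat,
            "p_value": assoc.p_value,
            "significant_bonferroni": assoc.significant_bonferroni.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_histogram_tsv(hist, path, value_range=(-20.0, 20.0)) -> None:
    """Dense count matrix with bin-edge metadata in a header comment."""
    lo, hi = value_range
    n = hist.shape[0]
    with open(path, "w") as fh:
        fh.write(f"# bins={n} range=[{lo},{hi}] rows=dev cols=val\n")
        pd.DataFrame(hist).to_csv(fh, sep="\t", index=False, header=False)


def write_rnk(attribute_ids, scores, path) -> None:
    """Two-column ranked gene list (id, score) for set enrichment tools."""
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    pd.DataFrame(
        {"id": np.asarray(attribute_ids, dtype=object)[order],
         "score": np.asarray(scores, dtype=float)[order]}
    ).to_csv(path, sep="\t", index=False, header=False)
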