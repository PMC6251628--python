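"""Readers and writers for the pipeline's plain-text table formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import SyntheticTruth


def read_bed(path, names=("chrom", "start", "end", "name", "score",
                          "strand")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = list(names)[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_patterns(path) -> pd.DataFrame:
    """Read-pattern TSV: read_id <tab> M/U pattern string."""
    return pd.read_csv(path, sep="\t", header=None,
                       names=["read_id", "pattern"], dtype=str)


def write_patterns(reads: pd.DataFrame, path) -> None:
    reads[["read_id", "pattern"]].to_csv(path, sep="\t", header=False,
                                         index=False)


def read_window_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_window_counts(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_truth(truth: SyntheticTruth, path) -> None:
    """JSON sidecar with the generating parameters and planted labels."""
    payload = {"config": json.loads(truth.config.to_json())}
    if truth.region_truth is not None:
        payload["region_truth"] = truth.region_truth.to_dict(orient="list")
    if truth.window_is_enriched is not None:
        payload["window_is_enriched"] = [
            bool(x) for x in truth.window_is_enriched]
    if truth.per_site_probability is not None:
        payload["per_site_probability"] = [
            float(x) for x in truth.per_site_probability]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> dict:
    return json.loads(Path(path).read_text())
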