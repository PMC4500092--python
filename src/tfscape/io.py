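"""Delimited-text formats for measurements, landscapes, features and graphs.

All tabular formats are comma-separated UTF-8 with a mandatory header
row and "." decimals; floats are written with 17 significant digits so
every round trip is lossless.  Genotype labels are validated strictly
against the canonical sequence space and malformed rows are reported
with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .binding import BindingEstimate, TitrationCurve
from .genotype_space import (
    ProteinGenotype,
    REGenotype,
    UnknownGenotypeError,
    enumerate_re_genotypes,
    probe_sequence,
)

__all__ = [
    "DataError",
    "read_measurements",
    "write_measurements",
    "read_landscape",
    "write_landscape",
    "read_features",
    "write_features",
    "read_titrations",
    "write_estimates",
    "write_probe_fasta",
    "write_graphml",
    "write_edge_list",
    "write_json_report",
]

FLOAT_FORMAT = "%.17g"


class DataError(ValueError):
    """A data file is malformed or inconsistent with the sequence space."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise DataError(f"{path}: no data rows")
    return df


def _validate_labels(df: pd.DataFrame, path) -> None:
    # header is line 1; first data row is line 2
    for idx, (p, r) in enumerate(zip(df["protein"], df["re"])):
        try:
            ProteinGenotype.from_label(str(p))
            REGenotype.from_label(str(r))
        except UnknownGenotypeError as exc:
            raise DataError(f"{path}, line {idx + 2}: {exc}") from None


def read_measurements(path) -> pd.DataFrame:
    """Replicate-level table: protein, re, replicate, dG_kcal_mol."""
    df = _read_csv(path, ("protein", "re", "replicate", "dG_kcal_mol"))
    _validate_labels(df, path)
    return df


def write_measurements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_landscape(path) -> pd.DataFrame:
    """Cell-mean table: protein, re, mean_dG."""
    df = _read_csv(path, ("protein", "re", "mean_dG"))
    _validate_labels(df, path)
    return df


def write_landscape(landscape: pd.DataFrame, path) -> None:
    landscape.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_features(path) -> pd.DataFrame:
    """Structural feature table: protein, re, feature, mean[, sem, n]."""
    df = _read_csv(path, ("protein", "re", "feature", "mean"))
    _validate_labels(df, path)
    return df


def write_features(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_titrations(path) -> list[TitrationCurve]:
    """Raw titrations: protein, re, replicate, concentration_M, anisotropy."""
    df = _read_csv(
        path, ("protein", "re", "replicate", "concentration_M", "anisotropy")
    )
    _validate_labels(df, path)
    curves = []
    for (p, r, rep), block in df.groupby(
        ["protein", "re", "replicate"], sort=True
    ):
        block = block.sort_values("concentration_M")
        curves.append(
            TitrationCurve(
                protein=ProteinGenotype.from_label(str(p)),
                probe=REGenotype.from_label(str(r)),
                replicate=int(rep),
                concentrations_M=tuple(block["concentration_M"].astype(float)),
                anisotropy=tuple(block["anisotropy"].astype(float)),
            )
        )
    return curves


def write_estimates(
    estimates: list[tuple[TitrationCurve, BindingEstimate]], path
) -> None:
    rows = [
        {
            "protein": c.protein.label,
            "re": c.probe.label,
            "replicate": c.replicate,
            "Kd_M": e.Kd_M,
            "dG_kcal_mol": e.dG_kcal_mol,
            "converged": e.converged,
            "in_range": e.in_range,
        }
        for c, e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_probe_fasta(path) -> None:
    """All 16 forward-strand probe 8-mers, record IDs = RE labels."""
    records = [
        SeqRecord(Seq(probe_sequence(re)), id=re.label, description="")
        for re in enumerate_re_genotypes()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"node1": u, "node2": v, "move_type": d.get("move_type", "")}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node1", "node2", "move_type"]).to_csv(
        path, index=False
    )


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
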