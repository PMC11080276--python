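"""File formats: cohort CSV tables, BayesNet JSON, Graphviz DOT export.

All formats are plain text.  Cohort CSVs are comma-delimited UTF-8 with a
mandatory header row; BayesNet JSON stores nodes, state vocabularies,
parent lists and CPT rows and round-trips bit-identically.
"""

from __future__ import annotations

import csv
import json

import numpy as np
import pandas as pd

from .bayesnet import CPT, DAG, BayesNet, InvalidNetError


class CohortFileError(ValueError):
    """Raised for malformed cohort CSV files."""


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table; raises on ragged rows or a missing header."""
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFileError(f"{path}: empty file, missing header") from None
        if len(header) != len(set(header)) or any(not c for c in header):
            raise CohortFileError(f"{path}: malformed header {header}")
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise CohortFileError(
                    f"{path}: line {lineno} has {len(row)} fields, "
                    f"expected {len(header)}"
                )
            rows.append(row)
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        try:
            converted = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            converted = df[col]
        if converted.dtype != object:
            # integers stay integers so codes round-trip exactly
            as_float = converted.astype(float)
            if np.all(as_float == np.round(as_float)):
                converted = as_float.astype(int)
        df[col] = converted
    return df


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, encoding="utf-8")


def write_bn_json(net: BayesNet, path) -> None:
    """Serialize a BayesNet (structure, states and CPTs) to JSON."""
    doc = {"nodes": []}
    for node in net.dag.nodes:
        entry = {
            "name": node,
            "states": list(net.states[node]),
            "parents": list(net.dag.parents(node)),
        }
        if node in net.cpts:
            cpt = net.cpts[node]
            entry["cpt"] = cpt.table.tolist()
            entry["counts"] = cpt.counts.tolist()
        doc["nodes"].append(entry)
    if hasattr(path, "write"):
        json.dump(doc, path, indent=1)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


def read_bn_json(path) -> BayesNet:
    if hasattr(path, "read"):
        doc = json.load(path)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    if not isinstance(doc, dict) or "nodes" not in doc:
        raise InvalidNetError("malformed network document: no 'nodes'")
    names, states, edges = [], {}, []
    for entry in doc["nodes"]:
        name = entry["name"]
        names.append(name)
        states[name] = tuple(entry["states"])
        for p in entry.get("parents", []):
            edges.append((p, name))
    dag = DAG(names, edges)
    cpts = {}
    for entry in doc["nodes"]:
        if "cpt" not in entry:
            continue
        name = entry["name"]
        cpts[name] = CPT(
            node=name,
            parents=dag.parents(name),
            table=np.asarray(entry["cpt"], dtype=float),
            counts=np.asarray(entry.get("counts", []), dtype=float)
            if entry.get("counts")
            else None,
        )
    return BayesNet(dag=dag, states=states, cpts=cpts)


def export_dot(net_or_dag) -> str:
    """Render the network structure as Graphviz DOT text."""
    dag = net_or_dag.dag if isinstance(net_or_dag, BayesNet) else net_or_dag
    lines = ["digraph bayesnet {"]
    for node in dag.nodes:
        lines.append(f'  "{node}";')
    for u, v in sorted(dag.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines)
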