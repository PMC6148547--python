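"""Plain-text readers/writers for the pipeline's input and output formats.

Expression matrices are genes x samples TSV with a two-column group file;
interaction networks are STRING-style edge TSVs (``node_a  node_b
score``) where integer scores above 1 are interpreted as the STRING
0-1000 dialect and divided by 1000; pathway collections are GMT; UTR and
miRNA sequences are FASTA (via Biopython); ground truth travels in a JSON
sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionStudy

__all__ = [
    "read_expression_study",
    "write_expression_study",
    "read_votes",
    "write_votes",
    "read_edges",
    "write_edges",
    "read_fasta",
    "write_fasta",
    "read_clinical",
    "write_clinical",
]


def read_expression_study(
    expr_path, groups_path, study_id: str | None = None,
    log2: bool = False, subgroup: str | None = None,
) -> ExpressionStudy:
    expr_path = Path(expr_path)
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
    return ExpressionStudy(
        study_id or expr_path.stem, values, groups, log2=log2, subgroup=subgroup
    )


def write_expression_study(study: ExpressionStudy, expr_path, groups_path) -> None:
    study.values.rename_axis("gene").to_csv(expr_path, sep="\t")
    study.groups.rename("group").rename_axis("sample").to_csv(groups_path, sep="\t")


def read_votes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(bool)


def write_votes(votes: pd.DataFrame, path) -> None:
    votes.astype(int).rename_axis("gene").to_csv(path, sep="\t")


def read_edges(path) -> nx.Graph:
    """STRING-style weighted edge list; scores > 1 are divided by 1000."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"edge file {path} needs node_a, node_b, score columns")
    a, b, s = df.columns[:3]
    g = nx.Graph()
    scores = df[s].astype(float)
    if (scores > 1.0).any():
        scores = scores / 1000.0
    for u, v, score in zip(df[a], df[b], scores):
        if u == v:
            continue
        g.add_edge(str(u), str(v), score=float(score))
    return g


def write_edges(g: nx.Graph, path) -> None:
    rows = [
        {"node_a": u, "node_b": v, "score": round(d.get("score", 1.0), 6)}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path) -> dict[str, str]:
    with open(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_clinical(path) -> tuple[pd.Series, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "marker_expr" not in df.columns:
        raise ValueError(f"clinical table {path} lacks a marker_expr column")
    expr = df["marker_expr"].astype(float)
    return expr, df.drop(columns=["marker_expr"])


def write_clinical(expr: pd.Series, table: pd.DataFrame, path) -> None:
    out = table.copy()
    out.insert(0, "marker_expr", expr)
    out.rename_axis("sample").to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
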