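"""Readers and writers for the flat-text formats the pipeline exchanges.

Everything is plain TSV/FASTA/GMT/line-oriented text so outputs diff
cleanly and round-trip through their readers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import ExpressionMatrix
from .mining import Corpus
from .motifs import PWM, PromoterWindow
from .perturbation import PerturbationMatrix

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_corpus", "write_corpus",
    "read_tf_table", "write_tf_table",
    "read_pwms", "write_pwms",
    "read_promoters", "write_promoters",
    "read_gmt", "write_gmt",
    "read_perturbation_matrix", "write_perturbation_matrix",
    "write_edge_list", "read_edge_list",
]


# --- expression ------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, expr_path, groups_path, detection_path=None) -> None:
    """Write (probe_id, symbol, samples...) TSV plus a two-column sample ->
    group map; detection p-values go to a third file when present."""
    df = matrix.values.copy()
    df.insert(0, "symbol", matrix.symbols)
    df.to_csv(expr_path, sep="\t", index_label="probe_id")
    pd.Series(matrix.sample_groups, name="group").rename_axis("sample").to_csv(groups_path, sep="\t")
    if detection_path is not None and matrix.detection_pvals is not None:
        matrix.detection_pvals.to_csv(detection_path, sep="\t", index_label="probe_id")


def read_expression_tsv(expr_path, groups_path, detection_path=None, log_scale=False) -> ExpressionMatrix:
    df = pd.read_csv(expr_path, sep="\t", index_col="probe_id")
    symbols = df.pop("symbol")
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"].to_dict()
    det = None
    if detection_path is not None and Path(detection_path).exists():
        det = pd.read_csv(detection_path, sep="\t", index_col="probe_id")
    return ExpressionMatrix(
        values=df, symbols=symbols, sample_groups=groups, detection_pvals=det, log_scale=log_scale
    )


# --- corpus / TF table -----------------------------------------------------

def write_corpus(corpus: Corpus, path) -> None:
    """One abstract per line, whitespace-delimited lower-case tokens."""
    with open(path, "w") as fh:
        for ab in corpus.abstracts:
            fh.write(" ".join(ab) + "\n")


def read_corpus(path) -> Corpus:
    with open(path) as fh:
        abstracts = [line.split() for line in fh if line.strip()]
    return Corpus(abstracts=abstracts)


def write_tf_table(tf_table: dict[str, list[str]], path) -> None:
    """TSV of (symbol, pipe-delimited synonyms)."""
    with open(path, "w") as fh:
        fh.write("symbol\tsynonyms\n")
        for sym, syns in tf_table.items():
            fh.write(f"{sym}\t{'|'.join(syns)}\n")


def read_tf_table(path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row["symbol"]: [s for s in row["synonyms"].split("|") if s]
        for _, row in df.iterrows()
    }


# --- PWMs / promoters ------------------------------------------------------

def write_pwms(pwms: list[PWM], path) -> None:
    """Whitespace-delimited count blocks headed by ">NAME" lines."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for row in pwm.counts:
                fh.write("\t".join(f"{v:g}" for v in row) + "\n")


def read_pwms(path, pseudocount: float = 0.5) -> list[PWM]:
    pwms: list[PWM] = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    pwms.append(PWM(name=name, counts=np.array(rows), pseudocount=pseudocount))
                name, rows = line[1:].split()[0], []
            else:
                rows.append([float(v) for v in line.split()])
    if name is not None:
        pwms.append(PWM(name=name, counts=np.array(rows), pseudocount=pseudocount))
    return pwms


def write_promoters(windows: list[PromoterWindow], path) -> None:
    records = [
        SeqRecord(Seq(w.sequence), id=w.probe_id, description="") for w in windows
    ]
    SeqIO.write(records, path, "fasta")


def read_promoters(path) -> list[PromoterWindow]:
    return [
        PromoterWindow(probe_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


# --- gene sets -------------------------------------------------------------

def write_gmt(annotation: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotation.items():
            fh.write("\t".join([term, term] + list(genes)) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    annotation: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                annotation[parts[0]] = [g for g in parts[2:] if g]
    return annotation


# --- perturbation matrix / graph ------------------------------------------

def write_perturbation_matrix(matrix: PerturbationMatrix, path, mock_path=None) -> None:
    matrix.relative_expression.to_csv(path, sep="\t")
    if mock_path is not None and matrix.mock is not None:
        matrix.mock.rename("mock").rename_axis("measured").to_csv(mock_path, sep="\t")


def read_perturbation_matrix(path, mock_path=None) -> PerturbationMatrix:
    rel = pd.read_csv(path, sep="\t", index_col=0)
    rel.index.name = "measured"
    rel.columns.name = "transduced"
    mock = None
    if mock_path is not None and Path(mock_path).exists():
        mock = pd.read_csv(mock_path, sep="\t", index_col="measured")["mock"]
    return PerturbationMatrix(relative_expression=rel, mock=mock)


def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\trelative_expression\n")
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('relative_expression', float('nan')):.6g}\n")


def read_edge_list(path) -> list[tuple[str, str, float]]:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    return [tuple(r) for r in df.itertuples(index=False, name=None)]
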