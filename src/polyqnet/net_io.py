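"""Readers and writers for every external format the pipeline touches.

Supported inputs: confidence-scored interaction edge tables (the raw HIPPIE
tab-separated dialect), GMT gene-set collections, FASTA transcript files and
CIS-BP-style position weight matrices.  Pipeline outputs (coordinates,
sectors, enrichment) are plain TSV with headers; numerics are serialized with
Python's shortest round-trip float representation, so a write/read round
trip reproduces them bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .geometry import HyperbolicPoint

__all__ = [
    "GeneSet",
    "PWM",
    "read_interaction_table",
    "extract_lcc",
    "read_gene_sets",
    "write_gene_sets",
    "read_fasta",
    "write_fasta",
    "read_pwm",
    "write_pwm",
    "read_edge_list",
    "write_edge_list",
    "read_coordinates",
    "write_coordinates",
    "read_sectors",
    "write_sectors",
    "write_enrichment",
    "read_enrichment",
]

RNA_ALPHABET = "ACGU"

#: format string for PWM probability output (12 significant digits)
PWM_FMT = "%.12g"


@dataclass
class GeneSet:
    """One GMT entry: a named set of member genes."""

    term_id: str
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise ValueError(f"gene set {self.term_id!r} has no members")


@dataclass
class PWM:
    """RNA position weight matrix over {A, C, G, U}.

    probs      (width, 4) row-stochastic matrix, columns ordered A, C, G, U
    background scalar background probability per base (uniform 0.25)
    threshold  log-odds score cutoff in bits (standard value 6)
    """

    probs: np.ndarray
    background: float = 0.25
    threshold: float = 6.0
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be a (width, 4) matrix over A,C,G,U")
        if not 1 <= self.width <= 30:
            raise ValueError(f"PWM width must lie in [1, 30], got {self.width}")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM rows must each sum to 1 within 1e-6")

    @property
    def width(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# interaction tables and networks


def read_interaction_table(
    path,
    score_threshold: float = 0.71,
    discard_self: bool = True,
    use_symbols: bool = True,
) -> nx.Graph:
    """Parse a raw HIPPIE-dialect edge table into an undirected simple graph.

    Columns (tab-separated, no header, '#' header tolerated): gene symbol A,
    numeric id A, gene symbol B, numeric id B, confidence score, evidence.
    Node identity is the gene symbol, falling back to the numeric id when the
    symbol is '-' or empty (set ``use_symbols=False`` to key on numeric ids).
    Duplicate pairs keep their maximum score before thresholding; only
    interactions with score >= ``score_threshold`` are retained and self
    pairs are dropped when ``discard_self`` is set.
    """
    if not 0 <= score_threshold <= 1:
        raise ValueError(f"score threshold must lie in [0, 1], got {score_threshold}")
    best: dict[tuple, float] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            sym_a, id_a, sym_b, id_b, score_txt = fields[:5]
            a = _node_identity(sym_a, id_a, use_symbols)
            b = _node_identity(sym_b, id_b, use_symbols)
            if not a or not b:
                raise ValueError(f"{path}: line {lineno}: empty node identifier")
            try:
                score = float(score_txt)
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: unparseable score {score_txt!r}"
                ) from None
            if not math.isfinite(score):
                raise ValueError(f"{path}: line {lineno}: non-finite score")
            n_rows += 1
            if discard_self and a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if score > best.get(key, -math.inf):
                best[key] = score
    if n_rows == 0:
        raise ValueError(f"{path}: no interaction rows found")
    g = nx.Graph()
    for (a, b), score in best.items():
        if score >= score_threshold:
            g.add_edge(a, b, score=score)
    return g


def _node_identity(symbol: str, numeric_id: str, use_symbols: bool) -> str:
    symbol = symbol.strip()
    numeric_id = numeric_id.strip()
    if use_symbols:
        return symbol if symbol and symbol != "-" else numeric_id
    return numeric_id if numeric_id and numeric_id != "-" else symbol


def extract_lcc(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the smallest lexicographic node id contained, so
    the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot extract the LCC of an empty network")
    components = [sorted(c, key=str) for c in nx.connected_components(graph)]
    size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == size]
    best = min(tied, key=lambda c: str(c[0]))
    return graph.subgraph(best).copy()


def read_edge_list(path) -> nx.Graph:
    """Read a 2/3-column TSV edge list (node_a, node_b[, score]) with header."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, float_precision="round_trip")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        attrs = {"score": float(row[2])} if len(row) > 2 else {}
        g.add_edge(str(row[0]), str(row[1]), **attrs)
    return g


def write_edge_list(path, graph: nx.Graph) -> None:
    rows = [
        (str(u), str(v), data.get("score", 1.0))
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path) -> dict[str, GeneSet]:
    """Read a GMT file: term id, description, then member genes, tab-separated.

    Duplicate member genes within a line are collapsed; term ids must be
    unique across the file.
    """
    collection: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT lines need >= 3 fields "
                    f"(term, description, members), got {len(fields)}"
                )
            term, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValueError(f"{path}: line {lineno}: gene set {term!r} is empty")
            if term in collection:
                raise ValueError(f"{path}: line {lineno}: duplicate term id {term!r}")
            collection[term] = GeneSet(term, name, genes)
    if not collection:
        raise ValueError(f"{path}: no gene sets found")
    return collection


def write_gene_sets(path, collection: dict[str, GeneSet]) -> None:
    with open(path, "w") as fh:
        for term in collection:
            gs = collection[term]
            members = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.term_id}\t{gs.name}\t{members}\n")


# ---------------------------------------------------------------------------
# sequences (FASTA)


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) in file order.

    Sequences are upper-cased and DNA T is normalized to RNA U.  A record
    with an empty sequence is an error.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=str(name), description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# position weight matrices (CIS-BP text dialect)


def read_pwm(path, background: float = 0.25, threshold: float = 6.0) -> PWM:
    """Read a CIS-BP-style PWM: header 'Pos A C G U', one row per position.

    A DNA header (T instead of U) is accepted and treated as RNA.  Rows whose
    probabilities deviate from sum 1 by more than 1e-3 are an error; smaller
    deviations are renormalized.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty PWM file")
    header = lines[0].split("\t")
    if len(header) == 1:  # tolerate whitespace-separated files
        header = lines[0].split()
    letters = [h.upper().replace("T", "U") for h in header[1:]]
    if letters != list(RNA_ALPHABET):
        raise ValueError(
            f"{path}: line 1: expected header 'Pos A C G U' (or T), got {lines[0]!r}"
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 5:
            raise ValueError(f"{path}: line {lineno}: expected 5 fields, got {len(fields)}")
        try:
            probs = [float(x) for x in fields[1:]]
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: unparseable probability") from None
        total = sum(probs)
        if abs(total - 1.0) > 1e-3:
            raise ValueError(
                f"{path}: line {lineno}: probabilities sum to {total:.6g}, "
                "deviating from 1 by more than 1e-3"
            )
        rows.append([p / total for p in probs])
    if not 1 <= len(rows) <= 30:
        raise ValueError(f"{path}: PWM width {len(rows)} outside [1, 30]")
    return PWM(np.array(rows), background=background, threshold=threshold,
               name=Path(str(path)).stem)


def write_pwm(path, pwm: PWM) -> None:
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tU\n")
        for i, row in enumerate(pwm.probs, start=1):
            fh.write(str(i) + "\t" + "\t".join(PWM_FMT % p for p in row) + "\n")


# ---------------------------------------------------------------------------
# pipeline outputs


def write_coordinates(path, coords: dict) -> None:
    """Write a node -> HyperbolicPoint map as TSV (node, r, theta)."""
    rows = [(str(n), coords[n].r, coords[n].theta) for n in sorted(coords, key=str)]
    df = pd.DataFrame(rows, columns=["node", "r", "theta"])
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype={"node": str}, float_precision="round_trip")
    for col in ("node", "r", "theta"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return {
        str(row.node): HyperbolicPoint(float(row.r), float(row.theta))
        for row in df.itertuples(index=False)
    }


def write_sectors(path, partition) -> None:
    """Write a SectorPartition as TSV (node, sector_id, theta)."""
    rows = []
    for sector in partition.sectors:
        for node, theta in zip(sector.members, sector.thetas):
            rows.append((str(node), sector.sector_id, theta))
    df = pd.DataFrame(rows, columns=["node", "sector_id", "theta"])
    df.to_csv(path, sep="\t", index=False)


def read_sectors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"node": str}, float_precision="round_trip")
    for col in ("node", "sector_id", "theta"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df


ENRICHMENT_COLUMNS = ["sector_id", "term", "k", "K", "n", "N", "p", "q"]


def write_enrichment(path, results: pd.DataFrame) -> None:
    """Write enrichment results; tolerates an empty frame (header-only file)."""
    df = results.loc[:, [c for c in ENRICHMENT_COLUMNS if c in results.columns]]
    if df.empty:
        df = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_enrichment(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
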