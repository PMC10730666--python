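"""End-to-end orchestration of the network-geometry analysis.

Stages, in order: enriched-gene selection from a differential-enrichment
table -> confidence filtering + LCC of the interaction network -> LaBNE+HM
embedding (reusing a cached coordinates file when supplied, since the
embedding is the slow stage) -> seed-neighborhood subnetwork -> angular-gap
sectors -> per-sector hypergeometric enrichment.  Every run writes TSV
outputs plus a JSON manifest recording parameters, stage row counts and
sha256 checksums, so reruns with an identical configuration are bit-
identical and verifiable.

A synthetic demo bundle (PS network with known coordinates, planted gene
sets, planted DE table) exercises the full pipeline without any external
download.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import net_io
from .embedding import embed_labne_hm
from .enrichment import enrich_sectors
from .geometry import TWO_PI
from .quant import filter_enriched
from .sectors import GapParams, angular_gap_clusters, tune_gap_threshold
from .subnetwork import restrict_coordinates, seed_neighborhood
from .synthetic_data import (
    generate_de_table,
    generate_ps_network,
    generate_sector_gene_sets,
)

__all__ = ["PipelineConfig", "run_pipeline", "make_synthetic_bundle", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    ``gap`` is either a threshold in radians or the string "tune" to recover
    the threshold maximizing the sector count at the given minimum size.
    ``edges_format`` selects the edge-table dialect: "hippie" (raw 6-column)
    or "tsv" (node_a/node_b/score with header).
    """

    edges: str
    de_table: str
    gene_sets: str
    outdir: str
    coordinates: str | None = None  # optional cache of a previous embedding
    edges_format: str = "hippie"
    score_threshold: float = 0.71
    gamma: float = 2.97
    temp: float = 0.83
    window: float = TWO_PI
    gap: float | str = 0.0346
    min_size: int = 5
    p_max: float = 0.05
    use_adjusted: bool = True
    alpha: float = 0.05
    n_sweeps: int = 1
    n_candidates: int = 360
    seed: int = 0

    def validate(self) -> None:
        for name in ("edges", "de_table", "gene_sets"):
            path = getattr(self, name)
            if not Path(path).is_file():
                raise FileNotFoundError(f"config {name}: no such file: {path}")
        if self.coordinates is not None and not Path(self.coordinates).is_file():
            raise FileNotFoundError(f"config coordinates: no such file: {self.coordinates}")
        if self.gap != "tune" and float(self.gap) <= 0:
            raise ValueError(f"gap must be positive or 'tune', got {self.gap}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_de_table(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


def _stage(name: str, inputs: str, fn, *args, **kwargs):
    logger.info("stage %s (%s)", name, inputs)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed on {inputs}: {exc}") from exc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the output manifest (also written as JSON)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("polyqnet")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        manifest = _run_stages(config, outdir)
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)
        handler.close()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _run_stages(config: PipelineConfig, outdir: Path) -> dict:
    params = {k: v for k, v in asdict(config).items()}
    logger.info("parameters: %s", json.dumps(params, sort_keys=True, default=str))

    de = _stage("filter_enriched", config.de_table, _read_de_table, config.de_table)
    seeds = _stage(
        "filter_enriched", config.de_table, filter_enriched,
        de, p_max=config.p_max, lfc_min=0.0, use_adjusted=config.use_adjusted,
    )
    logger.info("%d enriched seed genes", len(seeds))

    if config.edges_format == "hippie":
        graph = _stage(
            "read_interaction_table", config.edges, net_io.read_interaction_table,
            config.edges, score_threshold=config.score_threshold,
        )
    elif config.edges_format == "tsv":
        graph = _stage("read_edge_list", config.edges, net_io.read_edge_list, config.edges)
    else:
        raise ValueError(f"unknown edges_format {config.edges_format!r}")
    graph = _stage("extract_lcc", config.edges, net_io.extract_lcc, graph)
    logger.info("network LCC: %d nodes, %d edges",
                graph.number_of_nodes(), graph.number_of_edges())

    coords_path = outdir / "coordinates.tsv"
    if config.coordinates is not None:
        coords = _stage("read_coordinates", config.coordinates,
                        net_io.read_coordinates, config.coordinates)
        missing = set(graph.nodes) - set(coords)
        if missing:
            raise StageError(
                f"stage 'read_coordinates' failed on {config.coordinates}: "
                f"{len(missing)} network nodes lack cached coordinates"
            )
        net_io.write_coordinates(coords_path, {v: coords[v] for v in graph.nodes})
    else:
        embedded = _stage(
            "embed_labne_hm", config.edges, embed_labne_hm,
            graph, gamma=config.gamma, temp=config.temp, window=config.window,
            n_candidates=config.n_candidates, n_sweeps=config.n_sweeps,
        )
        coords = embedded.coords
        net_io.write_coordinates(coords_path, coords)
        logger.info("embedding log-likelihood trace: %s", embedded.loglik_trace)

    subnet = _stage("seed_neighborhood", config.de_table, seed_neighborhood, graph, seeds)
    subnet_path = outdir / "subnetwork.tsv"
    net_io.write_edge_list(subnet_path, subnet)
    logger.info("seed subnetwork: %d nodes, %d edges",
                subnet.number_of_nodes(), subnet.number_of_edges())

    sub_coords = _stage("restrict_coordinates", str(coords_path),
                        restrict_coordinates, coords, subnet.nodes)
    if config.gap == "tune":
        gap_value = _stage("tune_gap_threshold", str(coords_path),
                           tune_gap_threshold, sub_coords, config.min_size)
        logger.info("tuned gap threshold g = %.6g", gap_value)
    else:
        gap_value = float(config.gap)
    partition = _stage(
        "angular_gap_clusters", str(coords_path), angular_gap_clusters,
        sub_coords, GapParams(g=gap_value, min_size=config.min_size),
    )
    sectors_path = outdir / "sectors.tsv"
    net_io.write_sectors(sectors_path, partition)
    logger.info("%d sectors", partition.n_sectors)

    gene_sets = _stage("read_gene_sets", config.gene_sets,
                       net_io.read_gene_sets, config.gene_sets)
    results = _stage(
        "enrich_sectors", config.gene_sets, enrich_sectors,
        partition, gene_sets, universe=set(graph.nodes), alpha=config.alpha,
    )
    enrichment_path = outdir / "enrichment.tsv"
    net_io.write_enrichment(enrichment_path, results)

    top_terms = {}
    for sid, block in results.groupby("sector_id"):
        top_terms[str(int(sid))] = str(block.iloc[0]["term"])

    manifest = {
        "parameters": {**params, "gap_used": gap_value},
        "counts": {
            "seeds": len(seeds),
            "network_nodes": graph.number_of_nodes(),
            "network_edges": graph.number_of_edges(),
            "subnetwork_nodes": subnet.number_of_nodes(),
            "subnetwork_edges": subnet.number_of_edges(),
            "sectors": partition.n_sectors,
            "enrichment_rows": int(len(results)),
        },
        "top_term_per_sector": top_terms,
        "outputs": {
            "coordinates": str(coords_path),
            "subnetwork": str(subnet_path),
            "sectors": str(sectors_path),
            "enrichment": str(enrichment_path),
        },
        "checksums": {
            p.name: _sha256(p)
            for p in (coords_path, subnet_path, sectors_path, enrichment_path)
        },
    }
    return manifest


# ---------------------------------------------------------------------------
# synthetic demo bundle


@dataclass
class SyntheticBundle:
    """Paths and ground truth of a generated synthetic input bundle."""

    edges: str
    de_table: str
    gene_sets: str
    true_coordinates: str
    ground_truth: str
    planted_terms: dict = field(default_factory=dict)
    planted_genes: list = field(default_factory=list)


def make_synthetic_bundle(
    outdir,
    n_nodes: int = 500,
    m: int = 4,
    gamma: float = 2.5,
    temp: float = 0.1,
    n_terms: int = 30,
    enriched_term_fraction: float = 0.1,
    de_enriched_fraction: float = 0.1,
    de_effect_size: float = 6.0,
    seed: int = 42,
) -> SyntheticBundle:
    """Write a complete synthetic input bundle for the pipeline.

    Generates a PS network with known coordinates, a gene-set collection
    with terms planted on angular blocks, and a DE table whose gene ids are
    the network's nodes with a planted enriched fraction.  A JSON sidecar
    records all ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graph, truth = generate_ps_network(n_nodes, m, gamma, temp, seed)
    collection, planted = generate_sector_gene_sets(
        truth, n_terms=n_terms, enriched_fraction=enriched_term_fraction,
        seed=seed + 1,
    )
    de = generate_de_table(
        n_nodes, de_enriched_fraction, de_effect_size, seed=seed + 2
    )
    nodes = sorted(graph.nodes, key=str)
    de = de.assign(gene=nodes)  # DE genes are the network's nodes

    edges_path = outdir / "edges.tsv"
    net_io.write_edge_list(edges_path, graph)
    coords_path = outdir / "true_coordinates.tsv"
    net_io.write_coordinates(coords_path, truth.coords)
    gmt_path = outdir / "gene_sets.gmt"
    net_io.write_gene_sets(gmt_path, collection)
    de_path = outdir / "de_table.csv"
    de.to_csv(de_path, index=False)

    truth_path = outdir / "ground_truth.json"
    sidecar = {
        "ps_params": {"n": n_nodes, "m": m, "gamma": gamma, "temp": temp, "seed": seed},
        "planted_terms": {t: sorted(genes) for t, genes in planted.items()},
        "planted_genes": de.loc[de["planted"], "gene"].tolist(),
    }
    with open(truth_path, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)

    return SyntheticBundle(
        edges=str(edges_path),
        de_table=str(de_path),
        gene_sets=str(gmt_path),
        true_coordinates=str(coords_path),
        ground_truth=str(truth_path),
        planted_terms={t: set(g) for t, g in planted.items()},
        planted_genes=sidecar["planted_genes"],
    )


def synthetic_demo_config(bundle: SyntheticBundle, outdir, seed: int = 42) -> PipelineConfig:
    """Pipeline configuration matched to the synthetic bundle's generator."""
    return PipelineConfig(
        edges=bundle.edges,
        de_table=bundle.de_table,
        gene_sets=bundle.gene_sets,
        outdir=str(outdir),
        edges_format="tsv",
        gamma=2.5,
        temp=0.1,
        gap="tune",
        use_adjusted=False,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# flat key = value config files


_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def load_config(path) -> PipelineConfig:
    """Parse a flat ``key = value`` text file into a PipelineConfig."""
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected key = value")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            values[key] = _coerce(key, raw)
    try:
        return PipelineConfig(**values)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def _coerce(key: str, raw: str):
    if key == "gap" and raw == "tune":
        return "tune"
    if raw.lower() in _BOOL:
        return _BOOL[raw.lower()]
    for cast in (int, float):
        try:
            value = cast(raw)
            if cast is float and not math.isfinite(value):
                break
            return value
        except ValueError:
            continue
    return raw
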