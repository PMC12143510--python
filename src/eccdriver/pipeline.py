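"""End-to-end run orchestration: EDG calling → driver ranking → extras.

A :class:`RunConfig` gathers every effective parameter (defaults match the
method's stated constants: 35 bp promoter pad, depth-2 local network,
|log2FC| > 1 and q < 0.01 DEG filters, top 100 candidates). Each run writes
its outputs plus ``manifest.json`` recording the parameters, a config hash
and every file produced, so reruns with the same config and inputs are
byte-identical and auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import io as eio
from .benchmark import confusion_metrics
from .identify import DEFAULT_PAD_BP, call_edgs
from .rank import (
    DEFAULT_LFC_THRESHOLD,
    DEFAULT_Q_THRESHOLD,
    DEFAULT_TOP_M,
    LOCAL_NETWORK_DEPTH,
    rank_drivers,
    top_candidates,
)
from .signature import load_model, score_expression

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONFIDENCE = 700.0  # STRING-style 0-1000 scale


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with the method's defaults."""

    ecc: str = ""
    transcripts: str = ""
    enhancers: str = ""
    ppi: str = ""
    deg: str = ""
    benchmark: str = ""      # optional driver truth list
    expression: str = ""     # optional matrix for signature scoring
    out_dir: str = "eccdriver_run"
    dataset: str = "default"
    mode: str = "full"
    pad_bp: int = DEFAULT_PAD_BP
    min_confidence: float = DEFAULT_MIN_CONFIDENCE
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD
    q_threshold: float = DEFAULT_Q_THRESHOLD
    top_m: int = DEFAULT_TOP_M
    min_fraction: float = 0.5
    depth: int = LOCAL_NETWORK_DEPTH
    signature_model: str = "builtin:cedg17"
    seed: int = 0

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load a flat key-value YAML file; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute EDG calling and driver ranking (plus optional benchmark and
    signature stages) and write all artifacts under ``config.out_dir``.

    Returns the manifest dictionary. Any missing input is reported before
    computation starts; a stage failure aborts with the stage name.
    """
    required = {"ecc": config.ecc, "transcripts": config.transcripts,
                "enhancers": config.enhancers, "ppi": config.ppi, "deg": config.deg}
    for name, path in required.items():
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input {name!r} missing or not found: {path!r}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "outputs": {},
    }

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        eccdnas = eio.read_bed(config.ecc, dataset=config.dataset)
        transcripts = eio.read_transcripts(config.transcripts)
        enhancers = eio.read_enhancers(config.enhancers)
        biotypes = eio.biotype_map(transcripts)
        edges = eio.read_ppi(config.ppi, min_confidence=config.min_confidence)
        ppi = eio.ppi_graph(edges)
        deg_table = eio.read_deg_table(config.deg)
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc

    try:
        _stage("edg_call")
        catalog = call_edgs(
            eccdnas, transcripts, enhancers, biotypes,
            pad_bp=config.pad_bp, mode=config.mode, dataset=config.dataset,
        )
        catalog_path = out / "edg_catalog.tsv"
        eio.write_edg_catalog(catalog, catalog_path)
        manifest["outputs"]["edg_catalog"] = str(catalog_path)
        manifest["n_edgs"] = len(catalog.calls)
        manifest["n_coding_edgs"] = len(catalog.coding)
    except Exception as exc:
        raise RuntimeError(f"stage 'edg_call' failed: {exc}") from exc

    try:
        _stage("driver_rank")
        records = rank_drivers(
            catalog.coding, ppi, deg_table,
            top_m=config.top_m,
            lfc_threshold=config.lfc_threshold,
            q_threshold=config.q_threshold,
        )
        full_path = out / "centrality.tsv"
        top_path = out / "centrality.top.tsv"
        eio.write_centrality_table(records, full_path)
        top = top_candidates(records, config.top_m)
        eio.write_centrality_table(top, top_path)
        manifest["outputs"]["centrality"] = str(full_path)
        manifest["outputs"]["candidates"] = str(top_path)
        manifest["n_candidates"] = len(top)
    except Exception as exc:
        raise RuntimeError(f"stage 'driver_rank' failed: {exc}") from exc

    if config.benchmark:
        try:
            _stage("benchmark")
            truth = eio.read_gene_list(config.benchmark)
            universe = set(ppi.nodes) | set(biotypes)
            metrics = confusion_metrics({r.gene_id for r in top}, truth, universe)
            bench_path = out / "benchmark.json"
            with open(bench_path, "w") as fh:
                json.dump(dataclasses.asdict(metrics), fh, indent=2, sort_keys=True)
            manifest["outputs"]["benchmark"] = str(bench_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'benchmark' failed: {exc}") from exc

    if config.expression:
        try:
            _stage("signature")
            expr = eio.read_expression(config.expression)
            model = load_model(config.signature_model)
            risk = score_expression(expr, model)
            risk_path = out / "risk_table.tsv"
            risk.to_csv(risk_path, sep="\t", index_label="sample_id")
            manifest["outputs"]["risk_table"] = str(risk_path)
        except Exception as exc:
            raise RuntimeError(f"stage 'signature' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
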