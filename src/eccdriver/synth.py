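"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its arguments (including the seed) and
plants known structure — fully contained elements, partially overlapping
decoys, a DEG-enriched driver gene, signature genes with known shifts — so
identification, ranking and scoring can be tested end to end without any
external downloads. Ground truth is returned (and written as ``truth.json``
by the presets) alongside the data.

Coordinates are laid out collision-free by slab allocation: the chromosome
is divided into equal slabs, one element per slab, and every planted eccDNA
stays inside its element's slab. Overlap therefore occurs only where
planted. The generators emulate the *logic* of real inputs, not their
marginal distributions (eccDNA length spectra, PPI degree laws, expression
dispersion are all simplified).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as eio
from .identify import pad_transcript
from .signature import CEDG17
from .types import (
    EccDNARecord,
    EnhancerRecord,
    GenomicInterval,
    TranscriptRecord,
)

_MIN_SLAB = 400  # bp; room for an element, its promoter pad and ecc margins


@dataclass(frozen=True)
class PlantSpec:
    """What to plant in a synthetic dataset.

    ``n_planted_eeg``/``n_planted_erg`` genes are made callable through full
    containment; ``n_decoy_partial`` enhancers overlap an eccDNA by >= 1 bp
    without being contained. For the network side, the two-hop neighborhood
    of ``driver_gene`` is DEG-labeled at rate ``p_near`` against a
    ``p_background`` elsewhere.
    """

    n_planted_eeg: int = 3
    n_planted_erg: int = 3
    n_decoy_partial: int = 2
    n_background: int = 5
    driver_gene: str | None = None
    p_near: float = 0.9
    p_background: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_background < self.p_near <= 1:
            raise ValueError(
                f"need 0 <= p_background < p_near <= 1, got "
                f"{self.p_background} / {self.p_near}"
            )
        for name in ("n_planted_eeg", "n_planted_erg", "n_decoy_partial", "n_background"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Annotation:
    """A synthetic annotation bundle with its slab layout."""

    chrom: str
    chrom_length: int
    transcripts: list = field(default_factory=list)
    enhancers: list = field(default_factory=list)
    biotypes: dict = field(default_factory=dict)
    # element_id -> (slab_start, slab_end); used to keep planted circles local
    slabs: dict = field(default_factory=dict)

    @property
    def genes(self) -> list:
        return sorted({tx.gene_id for tx in self.transcripts})

    @property
    def coding_genes(self) -> list:
        return [g for g in self.genes if self.biotypes.get(g) == "protein_coding"]


def make_annotation(
    n_genes: int,
    chrom_length: int,
    seed: int,
    n_enhancers: int | None = None,
    coding_fraction: float = 0.8,
    chrom: str = "chrS",
) -> Annotation:
    """Generate non-overlapping transcripts and enhancers on one chromosome.

    Each gene gets one transcript on a random strand; about
    ``coding_fraction`` of genes are protein_coding, the rest lncRNA. Each
    enhancer targets 1-3 genes with distinct S_GE scores. The last ~15% of
    the chromosome is left element-free for background circles.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_enhancers is None:
        n_enhancers = max(1, n_genes // 2)
    rng = np.random.default_rng(seed)

    n_units = n_genes + n_enhancers
    usable = int(chrom_length * 0.85)
    slab = usable // n_units
    if slab < _MIN_SLAB:
        raise ValueError(
            f"chromosome of {chrom_length} bp too short for {n_units} elements "
            f"(need >= {_MIN_SLAB} bp per element)"
        )

    ann = Annotation(chrom=chrom, chrom_length=chrom_length)
    # interleave genes and enhancers along the chromosome
    kinds = ["gene"] * n_genes + ["enh"] * n_enhancers
    rng.shuffle(kinds)
    gene_no = enh_no = 0
    margin = 120  # keeps element + pad + ecc margins inside the slab
    for unit, kind in enumerate(kinds):
        s0, s1 = unit * slab, (unit + 1) * slab
        if kind == "gene":
            gene_id = f"G{gene_no:04d}"
            length = int(rng.integers(80, max(81, slab - 2 * margin)))
            start = s0 + margin
            strand = "+" if rng.random() < 0.5 else "-"
            tx = TranscriptRecord(
                GenomicInterval(chrom, start, start + length, strand),
                transcript_id=f"T{gene_no:04d}",
                gene_id=gene_id,
                biotype="protein_coding"
                if rng.random() < coding_fraction
                else "lncRNA",
            )
            ann.transcripts.append(tx)
            ann.biotypes[gene_id] = tx.biotype
            ann.slabs[tx.transcript_id] = (s0, s1)
            gene_no += 1
        else:
            enh_id = f"E{enh_no:04d}"
            length = int(rng.integers(50, max(51, min(500, slab - 2 * margin))))
            start = s0 + margin
            # targets drawn later once all genes exist
            ann.slabs[enh_id] = (s0, s1)
            ann.enhancers.append((enh_id, GenomicInterval(chrom, start, start + length)))
            enh_no += 1

    genes = [tx.gene_id for tx in ann.transcripts]
    enhancers = []
    for enh_id, iv in ann.enhancers:
        n_targets = int(rng.integers(1, min(4, len(genes) + 1)))
        targets = rng.choice(genes, size=n_targets, replace=False)
        scores = rng.choice(np.arange(10, 2000), size=n_targets, replace=False) / 10.0
        pairs = sorted(zip(targets.tolist(), scores.tolist()), key=lambda t: (-t[1], t[0]))
        enhancers.append(EnhancerRecord(iv, enh_id, tuple(pairs)))
    ann.enhancers = enhancers
    return ann


def make_eccdna(annotation: Annotation, spec: PlantSpec):
    """Generate eccDNA circles realizing a :class:`PlantSpec`.

    Returns ``(records, truth)`` where ``truth`` holds the exact EEG/ERG
    gene sets recoverable in full mode, the decoy enhancers' top targets
    (recoverable only in partial mode) and the supporting circle ids.
    """
    rng = np.random.default_rng(spec.seed)
    coding_tx = [
        tx for tx in annotation.transcripts
        if annotation.biotypes[tx.gene_id] == "protein_coding"
    ]
    if spec.n_planted_eeg > len(coding_tx):
        raise ValueError("not enough coding transcripts to plant EEGs")
    if spec.n_planted_erg + spec.n_decoy_partial > len(annotation.enhancers):
        raise ValueError("not enough enhancers to plant ERGs and decoys")

    tx_pick = rng.choice(len(coding_tx), size=spec.n_planted_eeg, replace=False)
    enh_pick = rng.choice(
        len(annotation.enhancers),
        size=spec.n_planted_erg + spec.n_decoy_partial,
        replace=False,
    )
    erg_enh = [annotation.enhancers[i] for i in enh_pick[: spec.n_planted_erg]]
    decoy_enh = [annotation.enhancers[i] for i in enh_pick[spec.n_planted_erg :]]

    records: list[EccDNARecord] = []
    chrom = annotation.chrom

    def _add(start: int, end: int) -> str:
        ecc_id = f"ecc_{len(records)}"
        records.append(EccDNARecord(GenomicInterval(chrom, start, end), ecc_id, "synthetic"))
        return ecc_id

    truth = {
        "eeg_genes": [],
        "erg_genes": [],
        "decoy_top_targets": [],
        "ecc_for": {},
    }

    for i in tx_pick:
        tx = coding_tx[i]
        padded = pad_transcript(tx)
        s0, s1 = annotation.slabs[tx.transcript_id]
        lo = int(rng.integers(max(s0, padded.start - 60), padded.start + 1))
        hi = int(rng.integers(padded.end, min(s1, padded.end + 60) + 1))
        ecc_id = _add(lo, max(hi, padded.end))
        truth["eeg_genes"].append(tx.gene_id)
        truth["ecc_for"][tx.gene_id] = ecc_id

    for enh in erg_enh:
        iv = enh.interval
        s0, s1 = annotation.slabs[enh.enh_id]
        lo = int(rng.integers(max(s0, iv.start - 60), iv.start + 1))
        hi = int(rng.integers(iv.end, min(s1, iv.end + 60) + 1))
        ecc_id = _add(lo, max(hi, iv.end))
        truth["erg_genes"].append(enh.top_target)
        truth["ecc_for"][enh.top_target] = ecc_id

    for enh in decoy_enh:
        iv = enh.interval
        s0, s1 = annotation.slabs[enh.enh_id]
        # starts strictly inside the enhancer: overlap without containment
        lo = int(rng.integers(iv.start + 1, iv.end))
        hi = min(s1, iv.end + 50)
        _add(lo, max(hi, lo + 1))
        truth["decoy_top_targets"].append(enh.top_target)

    # background circles in the element-free chromosome tail
    tail_start = int(annotation.chrom_length * 0.85) + 10
    for _ in range(spec.n_background):
        span = int(rng.integers(200, 2000))
        lo = int(rng.integers(tail_start, annotation.chrom_length - span))
        _add(lo, lo + span)

    truth["eeg_genes"] = sorted(set(truth["eeg_genes"]))
    truth["erg_genes"] = sorted(set(truth["erg_genes"]))
    truth["decoy_top_targets"] = sorted(set(truth["decoy_top_targets"]))
    return records, truth


def make_ppi_and_degs(
    n_nodes: int,
    mean_degree: float,
    spec: PlantSpec,
    model: str = "er",
    n_edg: int = 10,
    extra_driver_edges: int = 10,
):
    """Random PPI with a planted DEG-enriched driver, plus a DEG table.

    The graph is Erdős–Rényi (``model="er"``) or preferential attachment
    (``model="ba"``). The driver gains ``extra_driver_edges`` additional
    random neighbors, then every node within two hops of the driver is
    DEG-labeled with probability ``p_near`` against ``p_background``
    elsewhere. log2FC and q-values are synthesized consistent with the
    labels under the strict thresholds (|log2FC| > 1, q < 0.01).

    Returns ``(edges_df, deg_table_df, truth)`` with
    ``truth = {"driver": ..., "edg_genes": [...], "deg_genes": [...]}``.
    """
    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if mean_degree >= n_nodes:
        raise ValueError("mean_degree must be < n_nodes")
    rng = np.random.default_rng(spec.seed)
    nodes = [f"G{i:04d}" for i in range(n_nodes)]

    gseed = int(rng.integers(0, 2**31 - 1))
    if model == "er":
        g = nx.gnp_random_graph(n_nodes, mean_degree / (n_nodes - 1), seed=gseed)
    elif model == "ba":
        g = nx.barabasi_albert_graph(n_nodes, max(1, int(mean_degree // 2)), seed=gseed)
    else:
        raise ValueError(f"unknown graph model {model!r}")
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))

    driver = spec.driver_gene or nodes[0]
    if driver not in g:
        g.add_node(driver)
    non_neighbors = [v for v in nodes if v != driver and not g.has_edge(driver, v)]
    extra = rng.choice(
        len(non_neighbors), size=min(extra_driver_edges, len(non_neighbors)), replace=False
    )
    for i in extra:
        g.add_edge(driver, non_neighbors[i])

    near = set(nx.single_source_shortest_path_length(g, driver, cutoff=2)) - {driver}
    deg_genes = []
    rows = []
    for v in nodes:
        p = spec.p_near if v in near else spec.p_background
        is_deg = v != driver and rng.random() < p
        if is_deg:
            lfc = float(rng.uniform(1.2, 4.0)) * (1 if rng.random() < 0.5 else -1)
            q = float(rng.uniform(1e-8, 0.009))
            deg_genes.append(v)
        else:
            lfc = float(rng.uniform(-0.9, 0.9))
            q = float(rng.uniform(0.02, 1.0))
        rows.append((v, lfc, q))
    deg_table = pd.DataFrame(rows, columns=["gene_id", "log2fc", "q_value"])

    others = [v for v in nodes if v != driver]
    edg_pick = rng.choice(len(others), size=min(n_edg - 1, len(others)), replace=False)
    edg_genes = sorted([driver] + [others[i] for i in edg_pick])

    edges = pd.DataFrame(
        [
            (min(a, b), max(a, b), float(rng.integers(700, 1000)))
            for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges()))
        ],
        columns=["gene_a", "gene_b", "confidence"],
    )
    truth = {"driver": driver, "edg_genes": edg_genes, "deg_genes": sorted(deg_genes)}
    return edges, deg_table, truth


def make_expression(
    genes,
    n_samples: int,
    effect_vector=None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian genes x samples matrix with per-gene mean shifts."""
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    genes = list(genes)
    rng = np.random.default_rng(seed)
    effects = np.zeros(len(genes)) if effect_vector is None else np.asarray(effect_vector, float)
    if effects.shape != (len(genes),):
        raise ValueError("effect_vector length must match genes")
    values = effects[:, None] + noise_sd * rng.standard_normal((len(genes), n_samples))
    return pd.DataFrame(
        values, index=pd.Index(genes, name="gene_id"),
        columns=[f"S{i:03d}" for i in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESETS = ("small", "driver-recovery", "signature")


def generate_preset(preset: str, seed: int = 0) -> dict:
    """Build one of the named study fixtures fully in memory."""
    if preset == "small":
        ann = make_annotation(n_genes=30, chrom_length=600_000, seed=seed)
        spec = PlantSpec(
            n_planted_eeg=3, n_planted_erg=3, n_decoy_partial=2,
            n_background=5, seed=seed,
        )
        ecc, truth = make_eccdna(ann, spec)
        return {"annotation": ann, "eccdna": ecc, "truth": truth, "spec": spec}
    if preset == "driver-recovery":
        spec = PlantSpec(p_near=0.9, p_background=0.05, seed=seed)
        edges, deg_table, truth = make_ppi_and_degs(
            n_nodes=200, mean_degree=6, spec=spec
        )
        return {"ppi": edges, "deg_table": deg_table, "truth": truth, "spec": spec}
    if preset == "signature":
        rng = np.random.default_rng(seed)
        extra = [f"X{i:03d}" for i in range(33)]
        genes = list(CEDG17.genes) + extra
        effects = rng.uniform(-2, 2, size=len(genes))
        expr = make_expression(genes, n_samples=60, effect_vector=effects, seed=seed)
        return {
            "expression": expr,
            "truth": {"signature_genes": list(CEDG17.genes), "n_samples": 60},
        }
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


def write_preset(preset: str, out_dir, seed: int = 0) -> dict:
    """Generate a preset and write its files plus ``truth.json``.

    Returns a mapping of logical names to the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_preset(preset, seed)
    written = {}
    if "annotation" in bundle:
        ann: Annotation = bundle["annotation"]
        eio.write_bed(bundle["eccdna"], out / "ecc.bed")
        eio.write_transcripts(ann.transcripts, out / "transcripts.tsv")
        eio.write_enhancers(ann.enhancers, out / "enhancers.tsv")
        pd.DataFrame(
            sorted(ann.biotypes.items()), columns=["gene_id", "biotype"]
        ).to_csv(out / "biotypes.tsv", sep="\t", index=False)
        written.update(
            ecc=out / "ecc.bed", transcripts=out / "transcripts.tsv",
            enhancers=out / "enhancers.tsv", biotypes=out / "biotypes.tsv",
        )
    if "ppi" in bundle:
        eio.write_ppi(bundle["ppi"], out / "ppi.tsv")
        bundle["deg_table"].to_csv(out / "deg.tsv", sep="\t", index=False)
        eio.write_gene_list(bundle["truth"]["edg_genes"], out / "edg.txt")
        written.update(ppi=out / "ppi.tsv", deg=out / "deg.tsv", edg=out / "edg.txt")
    if "expression" in bundle:
        eio.write_expression(bundle["expression"], out / "expression.tsv")
        written["expression"] = out / "expression.tsv"
    truth = dict(bundle["truth"])
    if "spec" in bundle:
        truth["plant_spec"] = asdict(bundle["spec"])
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    written["truth"] = out / "truth.json"
    return {k: str(v) for k, v in written.items()}
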