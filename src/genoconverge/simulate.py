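"""Seeded synthetic inputs for every pipeline stage.

The generators emulate the statistical shape of the real inputs the
pipeline is designed for — GWAS summary statistics with LD-clustered
association peaks, multi-dataset probe-level expression matrices with
signed group effects, cis-eQTL Z/p tables consistent with a
standard-normal tail, and two-group qPCR Ct tables — without modelling
genotypes, haplotypes or array chemistry.  Everything is a pure
function of a :class:`SimConfig`; a fixed seed reproduces identical
tables.

LD is emulated positionally: a planted association peak contributes a
cluster of co-located, co-significant SNPs whose -log10 p values
scatter around the configured peak height.  Defaults place background
SNPs at roughly one per 4 kb, the density of a dense genotyping array
over a fine-mapped locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eqtl import z_to_p
from .expression import ExpressionDataset

# stream tags keep the per-stage RNGs independent under one config seed
_TAG_GWAS, _TAG_EXPR, _TAG_EQTL, _TAG_CT, _TAG_EDGES = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class PlantedLocus:
    """An association peak to plant: cluster center and -log10 p height."""

    center_bp: int
    peak: float
    span_bp: int = 20_000


@dataclass(frozen=True)
class DeGene:
    """A differentially expressed gene: signed effect in SD units and
    the indices of the expression datasets it affects."""

    gene: str
    effect_d: float
    datasets: tuple[int, ...] = (0, 1)


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    # GWAS summary statistics
    n_snps: int = 10_000
    chrom: str = "12"
    chrom_length_bp: int = 40_000_000
    ld_cluster_size: int = 10
    planted_loci: tuple[PlantedLocus, ...] = ()
    # expression matrices
    n_genes: int = 100
    probes_per_gene: int = 3
    de_genes: tuple[DeGene, ...] = ()
    n_case: int = 20
    n_control: int = 20
    # qPCR
    ct_shift: float = 1.0
    ct_sigma: float = 0.25
    ct_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        for locus in self.planted_loci:
            half = locus.span_bp // 2
            if locus.center_bp - half < 1 or locus.center_bp + half > self.chrom_length_bp:
                raise ValueError(
                    f"planted locus at {locus.center_bp} does not fit in "
                    f"chromosome of length {self.chrom_length_bp}"
                )
        spans = sorted(
            (l.center_bp - l.span_bp // 2, l.center_bp + l.span_bp // 2, l)
            for l in self.planted_loci
        )
        for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(
                    f"planted loci overlap: centers {l1.center_bp} and {l2.center_bp}"
                )

    def _rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([tag, self.seed])


def gene_names(cfg: SimConfig) -> list[str]:
    return [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]


def sim_annotation(cfg: SimConfig, gene_span_bp: int = 20_000) -> pd.DataFrame:
    """Gene intervals tiled evenly along the simulated chromosome.

    Gene i is centered at i * L / (n_genes + 1); spans are clipped to
    the chromosome and to the inter-gene spacing so genes never
    overlap.  Deterministic given the config (no randomness needed).
    """
    spacing = cfg.chrom_length_bp // (cfg.n_genes + 1)
    span = min(gene_span_bp, spacing - 1)
    rows = []
    for i, symbol in enumerate(gene_names(cfg), start=1):
        center = i * spacing
        rows.append(
            {
                "symbol": symbol,
                "chrom": cfg.chrom,
                "start": max(1, center - span // 2),
                "end": min(cfg.chrom_length_bp, center + span // 2),
                "strand": "+" if i % 2 else "-",
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"])


def gene_at(cfg: SimConfig, pos: int, gene_span_bp: int = 20_000) -> str | None:
    """Symbol of the simulated gene covering ``pos``, if any."""
    ann = sim_annotation(cfg, gene_span_bp)
    hit = ann[(ann["start"] <= pos) & (ann["end"] >= pos)]
    return None if hit.empty else str(hit["symbol"].iloc[0])


def sim_gwas(cfg: SimConfig) -> pd.DataFrame:
    """GWAS summary-statistic table with optional planted peaks.

    Background SNPs get positions uniform on the chromosome and
    p-values uniform on (0, 1].  Each planted locus adds
    ``ld_cluster_size`` SNPs inside its span whose -log10 p values are
    Normal(peak, 0.5), floored at 1.3 (p = 0.05) so every cluster
    member stays nominally significant — a positional stand-in for an
    LD block around a causal variant.
    """
    rng = cfg._rng(_TAG_GWAS)
    pos = rng.integers(1, cfg.chrom_length_bp + 1, size=cfg.n_snps)
    pvals = 1.0 - rng.random(cfg.n_snps)  # (0, 1]

    extra_pos, extra_p = [], []
    for locus in cfg.planted_loci:
        half = locus.span_bp // 2
        cluster_pos = rng.integers(
            locus.center_bp - half, locus.center_bp + half + 1,
            size=cfg.ld_cluster_size,
        )
        neglog = np.maximum(rng.normal(locus.peak, 0.5, cfg.ld_cluster_size), 1.3)
        extra_pos.append(cluster_pos)
        extra_p.append(np.power(10.0, -neglog))
    if extra_pos:
        pos = np.concatenate([pos, *extra_pos])
        pvals = np.concatenate([pvals, *extra_p])

    order = np.argsort(pos, kind="stable")
    df = pd.DataFrame(
        {
            "snp_id": [f"rs{i + 1:06d}" for i in range(len(pos))],
            "chrom": cfg.chrom,
            "pos": pos[order].astype(np.int64),
            "p": pvals[order],
        }
    )
    return df


def sim_expression(cfg: SimConfig, n_datasets: int = 3) -> list[ExpressionDataset]:
    """Probe-level expression matrices for ``n_datasets`` datasets.

    Null probes are Normal(0, 1) per sample.  For each DE gene, every
    probe of the gene in each affected dataset has its case-group mean
    shifted by ``effect_d`` — the same sign across probes and datasets,
    which is exactly the directional-alignment structure convergence
    looks for.
    """
    if cfg.probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    universe = set(gene_names(cfg))
    for de in cfg.de_genes:
        if de.gene not in universe:
            raise ValueError(f"DE gene {de.gene!r} not in simulated gene universe")
        if any(d >= n_datasets or d < 0 for d in de.datasets):
            raise ValueError(f"DE gene {de.gene!r} affects a dataset out of range")

    rng = cfg._rng(_TAG_EXPR)
    probes = [
        f"{g}_p{j}" for g in gene_names(cfg) for j in range(1, cfg.probes_per_gene + 1)
    ]
    probe_gene = pd.Series(
        {p: p.rsplit("_p", 1)[0] for p in probes}, name="gene"
    )
    samples = [f"case{i:02d}" for i in range(1, cfg.n_case + 1)] + [
        f"control{i:02d}" for i in range(1, cfg.n_control + 1)
    ]
    groups = pd.Series(
        ["case"] * cfg.n_case + ["control"] * cfg.n_control, index=samples, name="group"
    )

    datasets = []
    for d in range(n_datasets):
        values = rng.normal(0.0, 1.0, size=(len(probes), len(samples)))
        mat = pd.DataFrame(values, index=probes, columns=samples)
        for de in cfg.de_genes:
            if d in de.datasets:
                rows = [p for p in probes if probe_gene[p] == de.gene]
                mat.loc[rows, groups == "case"] += de.effect_d
        datasets.append(
            ExpressionDataset(
                dataset_id=f"ds{d + 1}",
                values=mat,
                groups=groups.copy(),
                probe_gene=probe_gene.copy(),
            )
        )
    return datasets


def sim_eqtl(
    snps: pd.DataFrame,
    genes,
    cfg: SimConfig,
    planted=(),
    n_background: int = 200,
) -> pd.DataFrame:
    """cis-eQTL table over given SNPs and genes.

    Background rows pair random SNPs with random genes and draw Z from
    Normal(0, 2) — a mix of null and modest regulatory effects.
    ``planted`` rows (snp_id, gene, z) are appended verbatim.  Every
    row's p is the two-sided normal tail of its Z by construction, the
    consistency the overlap stage assumes of browser exports.
    """
    if len(snps) == 0 or len(list(genes)) == 0:
        raise ValueError("need non-empty SNP and gene lists")
    rng = cfg._rng(_TAG_EQTL)
    genes = list(genes)
    snp_ids = snps["snp_id"].astype(str).to_numpy()
    rows = []
    for _ in range(n_background):
        snp = snp_ids[rng.integers(len(snp_ids))]
        gene = genes[rng.integers(len(genes))]
        z = float(rng.normal(0.0, 2.0))
        rows.append((snp, gene, z))
    for snp, gene, z in planted:
        rows.append((str(snp), str(gene), float(z)))
    df = pd.DataFrame(rows, columns=["snp_id", "gene", "z"])
    df["p"] = [z_to_p(z) for z in df["z"]]
    df["cis"] = True
    return df


def sim_edges(cfg: SimConfig, n_edges: int = 300) -> pd.DataFrame:
    """Interaction-score table over the simulated gene universe.

    Random gene pairs get channel scores drawn Beta(1, 6) — mostly weak
    evidence, as in genome-scale interaction databases.  Pairs of
    DE genes additionally get coexpression scores Uniform(0.3, 0.9), so
    planted candidates form a connected, clusterable neighborhood.
    """
    rng = cfg._rng(_TAG_EDGES)
    names = gene_names(cfg)
    seen: set[tuple[str, str]] = set()
    rows = []

    def add(a: str, b: str, co: float, ex: float) -> None:
        key = (a, b) if a < b else (b, a)
        if a == b or key in seen:
            return
        seen.add(key)
        rows.append(
            {
                "gene_a": key[0],
                "gene_b": key[1],
                "coexpression": round(co, 3),
                "experimental": round(ex, 3),
                "combined": round(min(1.0, 1 - (1 - co) * (1 - ex)), 3),
            }
        )

    de = [d.gene for d in cfg.de_genes]
    for i, a in enumerate(de):
        for b in de[i + 1 :]:
            add(a, b, float(rng.uniform(0.3, 0.9)), float(rng.beta(1, 6)))
    for _ in range(n_edges):
        a = names[rng.integers(len(names))]
        b = names[rng.integers(len(names))]
        add(a, b, float(rng.beta(1, 6)), float(rng.beta(1, 6)))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "coexpression", "experimental", "combined"]
    )


def sim_ct(
    cfg: SimConfig,
    targets,
    housekeeping=("GAPDH", "ACT"),
) -> pd.DataFrame:
    """Two-group qPCR Ct table with replicate-level technical noise.

    Housekeeping genes share one mean Ct across groups; each target
    gene's case-group Ct is lowered by ``ct_shift`` cycles (lower Ct =
    higher expression, so a shift of 1 doubles relative expression).
    Replicate noise is Normal(0, ct_sigma), the scale of routine qPCR
    technical variation.
    """
    housekeeping = list(housekeeping)
    if not housekeeping:
        raise ValueError("housekeeping gene list is empty")
    targets = list(targets)
    rng = cfg._rng(_TAG_CT)

    base_ct = {}
    for i, hk in enumerate(housekeeping):
        base_ct[hk] = 19.0 + i  # abundant housekeeping transcripts
    for i, tg in enumerate(targets):
        base_ct[tg] = 25.0 + i

    samples = [("case", f"case{i:02d}") for i in range(1, cfg.n_case + 1)] + [
        ("control", f"control{i:02d}") for i in range(1, cfg.n_control + 1)
    ]
    rows = []
    for group, sample in samples:
        for gene in housekeeping + targets:
            mean = base_ct[gene]
            if gene in targets and group == "case":
                mean -= cfg.ct_shift
            for rep in range(1, cfg.ct_replicates + 1):
                ct = mean + rng.normal(0.0, cfg.ct_sigma)
                rows.append((sample, group, gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
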