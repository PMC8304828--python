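"""End-to-end orchestration: association scan to ranked candidate report.

The pipeline chains the stages in the order the analysis is designed:

1. window scan + locus merge over GWAS summary statistics,
2. locus-to-gene mapping against the annotation (the reference list),
3. per-dataset probe tests and cross-dataset convergence with
   directional alignment, FDR and Bonferroni gates,
4. cis-eQTL overlap for nominally significant SNPs inside called loci,
5. interaction-network filtering and spectral k-means clustering,

and emits a candidate report ranking genes lexicographically by
(called, fdr_pass, has_eqtl, ascending gene_p).  Every stage's table is
written to the output directory; the run log records parameters and the
seed so a report can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, eqtl, expression, genes, gwas, io, network, simulate


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass(frozen=True)
class StageParams:
    window_bp: int = 20_000
    alpha: float = 0.05
    score_weight: float = 1.0
    score_threshold: float | None = None
    merge_gap_bp: int | None = None
    min_datasets: int = 2
    gwas_alpha: float = 0.05
    min_score: float = 0.15
    channels: tuple[str, ...] = ("coexpression", "experimental")
    k: int = 3


@dataclass
class PipelineConfig:
    seed: int
    output_dir: Path
    params: StageParams = field(default_factory=StageParams)
    sim: simulate.SimConfig | None = None
    n_datasets: int = 3
    # file inputs, used when no simulate block is given
    gwas_path: Path | None = None
    annotation_path: Path | None = None
    expression_specs: tuple[dict, ...] = ()
    eqtl_path: Path | None = None
    edges_path: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = StageParams(**{
            k: tuple(v) if k == "channels" else v
            for k, v in raw.get("params", {}).items()
        })
        sim_cfg = None
        if "simulate" in raw:
            sim_raw = dict(raw["simulate"])
            sim_raw["planted_loci"] = tuple(
                simulate.PlantedLocus(**d) for d in sim_raw.get("planted_loci", [])
            )
            sim_raw["de_genes"] = tuple(
                simulate.DeGene(
                    gene=d["gene"], effect_d=d["effect_d"],
                    datasets=tuple(d.get("datasets", (0, 1))),
                )
                for d in sim_raw.get("de_genes", [])
            )
            sim_raw.setdefault("seed", raw["seed"])
            sim_cfg = simulate.SimConfig(**sim_raw)
        inputs = raw.get("inputs", {})
        return cls(
            seed=int(raw["seed"]),
            output_dir=Path(raw["output_dir"]),
            params=params,
            sim=sim_cfg,
            n_datasets=int(raw.get("n_datasets", 3)),
            gwas_path=inputs.get("gwas"),
            annotation_path=inputs.get("annotation"),
            expression_specs=tuple(inputs.get("expression", ())),
            eqtl_path=inputs.get("eqtl"),
            edges_path=inputs.get("edges"),
        )


def _demo_planted_eqtls(sim_cfg, gwas_df):
    """Pair each planted locus's best SNP with the gene at its center.

    The planted Z carries the sign of the gene's expression effect (a
    repressed gene gets a negative Z) at magnitude 6 — a clearly
    significant cis-eQTL on the blood-eQTL scale.
    """
    effects = {d.gene: d.effect_d for d in sim_cfg.de_genes}
    planted = []
    for locus in sim_cfg.planted_loci:
        half = locus.span_bp // 2
        inside = gwas_df[
            (gwas_df["pos"] >= locus.center_bp - half)
            & (gwas_df["pos"] <= locus.center_bp + half)
        ]
        if inside.empty:
            continue
        top = inside.sort_values(["p", "pos", "snp_id"]).iloc[0]
        gene = simulate.gene_at(sim_cfg, locus.center_bp)
        if gene is None:
            continue
        sign = 1.0 if effects.get(gene, 1.0) >= 0 else -1.0
        planted.append((str(top["snp_id"]), gene, 6.0 * sign))
    return planted


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """Run every stage, write all outputs, return the candidate report."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.params
    if params.score_threshold is None:
        raise PipelineError("config", "params.score_threshold is required")

    # ------------------------------------------------------------------ inputs
    if cfg.sim is not None:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        gwas_df = simulate.sim_gwas(sim_cfg)
        annotation = simulate.sim_annotation(sim_cfg)
        datasets = simulate.sim_expression(sim_cfg, n_datasets=cfg.n_datasets)
        eqtl_df = simulate.sim_eqtl(
            gwas_df, simulate.gene_names(sim_cfg), sim_cfg,
            planted=_demo_planted_eqtls(sim_cfg, gwas_df),
        )
        edges_df = simulate.sim_edges(sim_cfg)
        inputs_dir = out / "inputs"
        io.write_gwas(gwas_df, inputs_dir / "gwas.tsv")
        io.write_annotation(annotation, inputs_dir / "annotation.tsv")
        for ds in datasets:
            io.write_expression_dataset(ds, inputs_dir)
        io.write_eqtl(eqtl_df, inputs_dir / "eqtl.tsv")
        io.write_edges(edges_df, inputs_dir / "edges.tsv")
    else:
        if cfg.gwas_path is None:
            raise PipelineError("gwas_scan", "no GWAS input and no simulate block")
        if cfg.annotation_path is None:
            raise PipelineError("locus_genes", "no annotation input")
        if not cfg.expression_specs:
            raise PipelineError("expression_convergence", "no expression inputs")
        gwas_df = io.read_gwas(cfg.gwas_path)
        annotation = io.read_annotation(cfg.annotation_path)
        datasets = [
            io.read_expression_dataset(
                s["matrix"], s["samples"], s["probes"], s["id"]
            )
            for s in cfg.expression_specs
        ]
        eqtl_df = io.read_eqtl(cfg.eqtl_path) if cfg.eqtl_path else None
        edges_df = io.read_edges(cfg.edges_path) if cfg.edges_path else None

    # --------------------------------------------------------------- gwas scan
    try:
        windows = gwas.scan_windows(
            gwas_df, window_bp=params.window_bp, alpha=params.alpha,
            weight=params.score_weight,
        )
        loci = gwas.merge_loci(
            windows, score_threshold=params.score_threshold,
            max_gap_bp=params.merge_gap_bp,
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("gwas_scan", str(exc)) from exc
    io.write_gwas(gwas.export_top_snps(windows), out / "top_snps.tsv")
    gwas.windows_frame(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    gwas.loci_frame(loci).to_csv(out / "loci.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- locus genes
    try:
        locus_genes = genes.genes_for_loci(annotation, loci)
    except Exception as exc:
        raise PipelineError("locus_genes", str(exc)) from exc
    gene_locus: dict[str, str] = {}
    for key, frame in locus_genes.items():
        for sym in frame["symbol"]:
            gene_locus.setdefault(str(sym), key)
    reference_genes = sorted(gene_locus)
    pd.DataFrame(
        [(g, l) for g, l in sorted(gene_locus.items())], columns=["gene", "locus"]
    ).to_csv(out / "locus_genes.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- convergence
    try:
        results = {
            ds.dataset_id: expression.probe_tests(ds, alpha=params.alpha)
            for ds in datasets
        }
        if reference_genes:
            calls = expression.converge(
                results, reference_genes,
                min_datasets=params.min_datasets, alpha=params.alpha,
            )
            calls = expression.adjust(calls, alpha=params.alpha)
        else:
            calls = []
    except Exception as exc:
        raise PipelineError("expression_convergence", str(exc)) from exc
    all_probe_results = [r for rs in results.values() for r in rs]
    expression.probe_results_frame(all_probe_results).to_csv(
        out / "probe_tests.tsv", sep="\t", index=False
    )
    expression.calls_frame(calls).to_csv(
        out / "convergence.tsv", sep="\t", index=False
    )

    # ------------------------------------------------------------ eQTL overlap
    hits: list[eqtl.EqtlHit] = []
    if eqtl_df is not None and loci:
        try:
            in_locus = pd.concat(
                [
                    gwas_df[
                        (gwas_df["chrom"].astype(str) == l.chrom)
                        & (gwas_df["pos"] >= l.start)
                        & (gwas_df["pos"] < l.end)
                    ]
                    for l in loci
                ]
            )
            sig = in_locus[in_locus["p"] < params.gwas_alpha]
            hits = eqtl.rank_hits(eqtl.overlap(sig, eqtl_df, reference_genes))
        except Exception as exc:
            raise PipelineError("eqtl_overlap", str(exc)) from exc
    eqtl.hits_frame(hits).to_csv(out / "eqtl_hits.tsv", sep="\t", index=False)

    # ----------------------------------------------------------------- network
    clusters: dict[str, int] = {}
    if edges_df is not None and len(edges_df):
        try:
            called_genes = [c.gene for c in calls if c.called]
            graph = network.filter_edges(
                edges_df, min_score=params.min_score,
                channels=params.channels, seed_genes=called_genes,
            )
            if graph.number_of_nodes() >= params.k:
                clusters = network.cluster_kmeans(graph, k=params.k, seed=cfg.seed)
        except Exception as exc:
            raise PipelineError("network_analysis", str(exc)) from exc
    network.clusters_frame(clusters).to_csv(
        out / "clusters.tsv", sep="\t", index=False
    )

    # ------------------------------------------------------------------ report
    best_hit: dict[str, eqtl.EqtlHit] = {}
    for h in hits:  # hits already ranked; keep the first per gene
        best_hit.setdefault(h.gene, h)
    call_by_gene = {c.gene: c for c in calls}
    rows = []
    for gene in reference_genes:
        c = call_by_gene.get(gene)
        h = best_hit.get(gene)
        rows.append(
            {
                "gene": gene,
                "locus": gene_locus[gene],
                "called": bool(c.called) if c else False,
                "n_datasets_significant": c.n_datasets_significant if c else 0,
                "aligned": bool(c.aligned) if c else False,
                "gene_p": c.gene_p if c else float("nan"),
                "fdr_pass": bool(c.fdr_pass) if c else False,
                "bonferroni_pass": bool(c.bonferroni_pass) if c else False,
                "best_eqtl_snp": h.snp_id if h else "",
                "eqtl_z": h.z if h else float("nan"),
                "eqtl_direction": h.direction if h else "",
                "network_cluster": clusters.get(gene, -1),
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        report = report.sort_values(
            by=["called", "fdr_pass", "best_eqtl_snp", "gene_p", "gene"],
            ascending=[False, False, True, True, True],
            key=lambda col: (
                col.eq("") if col.name == "best_eqtl_snp" else col
            ),
            kind="mergesort",
        ).reset_index(drop=True)
        report.insert(0, "rank", range(1, len(report) + 1))
    else:
        report.insert(0, "rank", [])

    report.to_csv(out / "report.tsv", sep="\t", index=False)
    meta = {
        "genoconverge_version": __version__,
        "seed": cfg.seed,
        "params": dataclasses.asdict(params),
        "n_datasets": len(datasets),
        "n_loci": len(loci),
        "n_reference_genes": len(reference_genes),
        "n_called": int(sum(c.called for c in calls)),
        "ranking": "lexicographic on (called, fdr_pass, has_eqtl, gene_p ascending)",
    }
    (out / "report.json").write_text(
        json.dumps(
            {"meta": meta, "report": report.to_dict(orient="records")},
            indent=2, default=str,
        )
        + "\n"
    )
    return report
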