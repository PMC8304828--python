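"""TSV readers and writers for every table the pipeline exchanges.

All formats are plain tab-separated text with a header row:

========================  =====================================================
GWAS summary statistics   ``snp_id  chrom  pos  p``
gene annotation           ``symbol  chrom  start  end  strand`` (1-based incl.)
expression matrix         probes as rows, samples as columns (index column
                          ``probe``), plus a sample table ``sample  group``
                          and a probe map ``probe  gene``
cis-eQTL table            ``snp_id  gene  z  p  cis``
qPCR Ct table             ``sample  group  gene  replicate  ct``
interaction edges         ``gene_a  gene_b  coexpression  experimental
                          combined``
========================  =====================================================
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .expression import ExpressionDataset


def _read(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def _write(df: pd.DataFrame, path, **kw) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", **kw)


def read_gwas(path) -> pd.DataFrame:
    df = _read(path, dtype={"snp_id": str, "chrom": str})
    df["pos"] = df["pos"].astype("int64")
    df["p"] = df["p"].astype(float)
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    _write(df, path)


def read_annotation(path, bed: bool = False) -> pd.DataFrame:
    if bed:
        from .genes import read_bed4

        return read_bed4(path)
    df = _read(path, dtype={"symbol": str, "chrom": str, "strand": str})
    df["start"] = df["start"].astype("int64")
    df["end"] = df["end"].astype("int64")
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    _write(df, path)


def read_expression_dataset(
    matrix_path, samples_path, probe_map_path, dataset_id: str
) -> ExpressionDataset:
    values = _read(matrix_path, index_col=0)
    values.index = values.index.astype(str)
    samples = _read(samples_path, dtype=str).set_index("sample")["group"]
    probe_map = _read(probe_map_path, dtype=str).set_index("probe")["gene"]
    return ExpressionDataset(
        dataset_id=dataset_id,
        values=values,
        groups=samples.loc[values.columns],
        probe_gene=probe_map,
    )


def write_expression_dataset(ds: ExpressionDataset, directory) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / f"{ds.dataset_id}_matrix.tsv",
        "samples": directory / f"{ds.dataset_id}_samples.tsv",
        "probe_map": directory / f"{ds.dataset_id}_probes.tsv",
    }
    ds.values.rename_axis("probe").to_csv(
        paths["matrix"], sep="\t", lineterminator="\n"
    )
    ds.groups.rename_axis("sample").reset_index().to_csv(
        paths["samples"], sep="\t", index=False, lineterminator="\n"
    )
    ds.probe_gene.rename_axis("probe").reset_index().to_csv(
        paths["probe_map"], sep="\t", index=False, lineterminator="\n"
    )
    return paths


def read_eqtl(path) -> pd.DataFrame:
    df = _read(path, dtype={"snp_id": str, "gene": str})
    df["z"] = df["z"].astype(float)
    df["p"] = df["p"].astype(float)
    return df


def write_eqtl(df: pd.DataFrame, path) -> None:
    _write(df, path)


def read_ct(path) -> pd.DataFrame:
    df = _read(path, dtype={"sample": str, "group": str, "gene": str})
    df["replicate"] = df["replicate"].astype(int)
    df["ct"] = df["ct"].astype(float)
    return df


def write_ct(df: pd.DataFrame, path) -> None:
    _write(df, path)


def read_edges(path) -> pd.DataFrame:
    return _read(path, dtype={"gene_a": str, "gene_b": str})


def write_edges(df: pd.DataFrame, path) -> None:
    _write(df, path)
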