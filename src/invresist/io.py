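"""Readers and writers for the pipeline's plain-text formats.

Plates are CSV triples (A570, A600, layout), expression data TSV
(counts + samples metadata), interaction edges 3-column TSV, gene sets
GMT, and networks GraphML (via networkx) plus a nodes TSV.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .cytotox import ViabilityCurve
from .de import CountData
from .simulate import Plate

__all__ = [
    "write_plate",
    "read_plate",
    "write_counts",
    "read_counts",
    "write_curve",
    "read_curves",
    "write_edges",
    "read_edges",
    "write_gmt",
    "read_gmt",
    "write_network",
]


def _slug(line: str, drug: str, rep: int) -> str:
    return f"{line}_{drug}_p{rep}".replace("/", "-")


def write_plate(plate: Plate, outdir) -> list[Path]:
    """Write one plate as <line>_<drug>_p<rep>_{A570,A600,layout}.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = _slug(plate.cell_line, plate.drug, plate.replicate)
    paths = []
    for name, grid in (("A570", plate.a570), ("A600", plate.a600)):
        p = outdir / f"{base}_{name}.csv"
        grid.to_csv(p, index_label="row")
        paths.append(p)
    layout = plate.layout.copy()
    layout.insert(0, "cell_line", plate.cell_line)
    layout.insert(1, "drug", plate.drug)
    layout.insert(2, "unit", plate.unit)
    layout.insert(3, "replicate", plate.replicate)
    p = outdir / f"{base}_layout.csv"
    layout.to_csv(p, index=False)
    paths.append(p)
    return paths


def read_plate(outdir, line: str, drug: str, replicate: int = 1) -> Plate:
    outdir = Path(outdir)
    base = _slug(line, drug, replicate)
    a570 = pd.read_csv(outdir / f"{base}_A570.csv", index_col="row")
    a600 = pd.read_csv(outdir / f"{base}_A600.csv", index_col="row")
    a570.columns = a570.columns.astype(int)
    a600.columns = a600.columns.astype(int)
    a570.index.name = a600.index.name = None
    layout = pd.read_csv(outdir / f"{base}_layout.csv")
    unit = str(layout["unit"].iloc[0])
    layout = layout[["row", "col", "role", "conc"]]
    return Plate(cell_line=line, drug=drug, unit=unit, a570=a570, a600=a600,
                 layout=layout, replicate=replicate)


def list_plates(outdir) -> list[tuple[str, str, int]]:
    """(line, drug, replicate) triples available in a plate directory."""
    outdir = Path(outdir)
    triples = []
    for p in sorted(outdir.glob("*_layout.csv")):
        base = p.name[: -len("_layout.csv")]
        line, drug, rep = base.rsplit("_", 2)
        triples.append((line, drug, int(rep[1:])))
    return triples


def write_counts(data: CountData, outdir, truth: pd.DataFrame | None = None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene")
    data.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene")


def read_counts(counts_path, samples_path) -> CountData:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    counts.index.name = None
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    samples.index.name = None
    order = [c for c in samples["cell_line"].drop_duplicates()]
    samples["cell_line"] = pd.Categorical(
        samples["cell_line"], categories=order, ordered=True
    )
    return CountData(counts, samples)


def write_curve(curve: ViabilityCurve, path, append: bool = False):
    """Tidy TSV: cell_line, drug, unit, conc, mean_viab, sd, n."""
    t = curve.points.copy()
    t.insert(0, "cell_line", curve.cell_line)
    t.insert(1, "drug", curve.drug)
    t.insert(2, "unit", curve.unit)
    mode = "a" if append else "w"
    t.to_csv(path, sep="\t", index=False, mode=mode,
             header=not (append and Path(path).exists()))


def read_curves(path) -> list[ViabilityCurve]:
    t = pd.read_csv(path, sep="\t")
    curves = []
    for (line, drug, unit), grp in t.groupby(["cell_line", "drug", "unit"]):
        curves.append(
            ViabilityCurve(line, drug, unit,
                           grp[["conc", "mean_viab", "sd", "n"]].reset_index(drop=True))
        )
    return curves


def write_edges(edges: pd.DataFrame, path):
    edges.to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gmt(gene_sets: dict, path):
    """GMT: term <tab> description <tab> gene1 <tab> gene2 ..."""
    with open(path, "w") as fh:
        for term, genes in gene_sets.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_gmt(path) -> dict:
    sets = {}
    with open(path) as fh:
        for raw in fh:
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_network(net, outdir, hub_degree: int = 7):
    """GraphML + nodes TSV (gene, direction, degree, is_hub)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.graph, outdir / "network.graphml")
    net.nodes_table(hub_degree=hub_degree).to_csv(outdir / "nodes.tsv", sep="\t")
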