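"""Pearson co-expression networks with Cytoscape-compatible export.

Edges connect gene pairs whose expression profiles correlate significantly:
two-sided p from the t transform t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom, thresholded with the boundary semantics p <= 0.05 (inclusive) and
r strictly > 0.5 (positive), > 0.8 (strong positive) or < -0.5 (negative).
p-values are raw (no multiple-testing correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("positive", "strong_positive", "negative")


@dataclass(frozen=True)
class Edge:
    gene_i: str          # canonical order: gene_i < gene_j
    gene_j: str
    r: float
    n: int
    p: float
    edge_class: str

    def __post_init__(self) -> None:
        if self.gene_i >= self.gene_j:
            raise ValueError("edges must be in canonical (i < j) order")
        if self.edge_class not in CLASSES:
            raise ValueError(f"unknown edge class {self.edge_class!r}")


def _p_from_r(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def pcc_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles differ in length")
    n = x.size
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant profile")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(_p_from_r(np.array(r), n))


def correlation_matrices(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """r and p matrices over all gene pairs (genes x samples input).

    Constant genes give NaN rows/columns (pairs later skipped with a log).
    """
    arr = profiles.to_numpy(dtype=float)
    n = arr.shape[1]
    if n < 3:
        raise ValueError("need at least three samples")
    sd = arr.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    p = _p_from_r(r, n)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    idx = profiles.index
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))


def build_network(r: pd.DataFrame, p: pd.DataFrame,
                  positive: float = 0.5, strong: float = 0.8,
                  negative: float = -0.5, alpha: float = 0.05,
                  n_samples: int = 0) -> list[Edge]:
    """Classified edge list from aligned symmetric r and p matrices."""
    if list(r.index) != list(r.columns) or list(r.index) != list(p.index):
        raise ValueError("r and p matrices must share an aligned gene order")
    genes = sorted(r.index)
    edges: list[Edge] = []
    for a_pos, gi in enumerate(genes):
        for gj in genes[a_pos + 1:]:
            rv, pv = float(r.loc[gi, gj]), float(p.loc[gi, gj])
            if np.isnan(rv) or np.isnan(pv):
                continue
            if pv > alpha:
                continue
            if rv > strong:
                cls = "strong_positive"
            elif rv > positive:
                cls = "positive"
            elif rv < negative:
                cls = "negative"
            else:
                continue
            edges.append(Edge(gi, gj, rv, n_samples, pv, cls))
    return edges


def network_stats(edges: Iterable[Edge]) -> dict[str, int]:
    edges = list(edges)
    nodes = {g for e in edges for g in (e.gene_i, e.gene_j)}
    out = {"nodes": len(nodes), "edges": len(edges)}
    for cls in CLASSES:
        out[cls] = sum(e.edge_class == cls for e in edges)
    # strong positives are also positive correlations
    out["positive_total"] = out["positive"] + out["strong_positive"]
    return out


def export_network(edges: Sequence[Edge], outdir: str | Path,
                   basename: str = "network",
                   formats: Sequence[str] = ("sif", "attributes", "json")) -> list[Path]:
    """Write SIF / edge-attribute TSV / GraphML / summary JSON files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    known = {"sif", "attributes", "graphml", "json"}
    bad = set(formats) - known
    if bad:
        raise ValueError(f"unsupported export format(s): {sorted(bad)}")
    if "sif" in formats:
        path = outdir / f"{basename}.sif"
        path.write_text("".join(
            f"{e.gene_i}\t{e.edge_class}\t{e.gene_j}\n" for e in edges))
        written.append(path)
    if "attributes" in formats:
        path = outdir / f"{basename}_edges.tsv"
        pd.DataFrame([{
            "source": e.gene_i, "target": e.gene_j, "class": e.edge_class,
            "r": e.r, "p": e.p,
        } for e in edges], columns=["source", "target", "class", "r", "p"]
        ).to_csv(path, sep="\t", index=False)
        written.append(path)
    if "graphml" in formats:
        g = nx.Graph()
        for e in edges:
            g.add_edge(e.gene_i, e.gene_j, r=e.r, p=e.p,
                       edge_class=e.edge_class)
        path = outdir / f"{basename}.graphml"
        nx.write_graphml(g, path)
        written.append(path)
    if "json" in formats:
        path = outdir / f"{basename}_summary.json"
        path.write_text(json.dumps(network_stats(edges), indent=2))
        written.append(path)
    return written


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    """Round-trip helper: (source, class, target) triples from a SIF file."""
    out = set()
    for line in Path(path).read_text().splitlines():
        if line.strip():
            src, cls, dst = line.split("\t")
            out.add((src, cls, dst))
    return out
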