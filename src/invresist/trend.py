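"""Kinetic trend classification across the ordered contrast series.

Genes are classified by the sign trajectory of their log2 fold changes
over the subline-vs-parent contrasts into five classes: consistently up,
consistently down, rising (down then up, one reversal), descending (up
then down, one reversal) and variable (two or more reversals). The module
also selects the "scaffold" gene set (significant with a large fold change
in every contrast), builds shared-DEG matrices with an early/late
partition, and provides PCA and hierarchical clustering of samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .de import DEComparison, DEGSet

__all__ = [
    "TrendAssignment",
    "ScaffoldSet",
    "SharedDEGMatrix",
    "PCAResult",
    "ClusterResult",
    "TREND_CLASSES",
    "classify_trend",
    "select_scaffold",
    "shared_deg_matrix",
    "embed_pca",
    "cluster_samples",
]

TREND_CLASSES = (
    "consistently_up",
    "consistently_down",
    "rising",
    "descending",
    "variable",
)

#: Dead zone: |log2FC| below this counts as sign 0 (inherits neighbours).
SIGN_EPSILON = 0.1


@dataclass
class TrendAssignment:
    gene: str | None
    sign_pattern: tuple          # raw per-contrast signs, '+', '-' or '0'
    klass: str
    switch_index: int | None     # 1-based contrast of the single reversal
    zero_pattern: bool = False   # all contrasts inside the dead zone


@dataclass
class ScaffoldSet:
    """Genes passing q and |log2FC| thresholds in every contrast."""

    q_threshold: float
    fc_threshold: float
    contrasts: list
    table: pd.DataFrame  # per-gene log2FC columns + klass + direction

    @property
    def genes(self) -> list:
        return self.table.index.tolist()

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class SharedDEGMatrix:
    """Pairwise shared-DEG counts over contrasts.

    Upper triangle: shared upregulated genes; lower triangle: shared
    downregulated genes; diagonal: total DEGs of the contrast. Partition
    totals aggregate over unordered pairs that involve an early contrast
    versus pairs entirely within the late contrasts.
    """

    matrix: pd.DataFrame
    up_sizes: pd.Series
    down_sizes: pd.Series
    partition_totals: dict = field(default_factory=dict)


def classify_trend(log2fc, epsilon: float = SIGN_EPSILON,
                   gene: str | None = None) -> TrendAssignment:
    """Classify one gene's log2FC trajectory over the ordered contrasts.

    Signs inside the dead zone (|log2FC| < epsilon) inherit the previous
    nonzero sign; leading zeros inherit the first nonzero sign. An
    all-zero trajectory is labelled variable with ``zero_pattern=True``.
    """
    v = np.asarray(log2fc, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need a 1-D log2FC vector of length >= 2")
    if np.isnan(v).any():
        raise ValueError("log2FC vector contains NaN")
    raw = np.where(np.abs(v) < epsilon, "0", np.where(v > 0, "+", "-"))
    pattern = tuple(raw.tolist())

    nz = [s for s in raw if s != "0"]
    if not nz:
        return TrendAssignment(gene, pattern, "variable", None, zero_pattern=True)
    # inherit: leading zeros take the first nonzero sign, later zeros the
    # previous nonzero sign
    eff = []
    prev = nz[0]
    for s in raw:
        if s == "0":
            eff.append(prev)
        else:
            eff.append(s)
            prev = s
    switches = [i for i in range(1, len(eff)) if eff[i] != eff[i - 1]]
    if not switches:
        klass = "consistently_up" if eff[0] == "+" else "consistently_down"
        return TrendAssignment(gene, pattern, klass, None)
    if len(switches) == 1:
        idx = switches[0] + 1  # 1-based contrast where the new sign starts
        if eff[0] == "-":
            return TrendAssignment(gene, pattern, "rising", idx)
        return TrendAssignment(gene, pattern, "descending", idx)
    return TrendAssignment(gene, pattern, "variable", None)


def select_scaffold(de_list: list[DEComparison], q_threshold: float = 0.001,
                    fc_threshold: float = 2.0,
                    epsilon: float = SIGN_EPSILON) -> ScaffoldSet:
    """Intersection of per-contrast DEG sets at (q, |log2FC|) thresholds.

    A gene belongs to the scaffold iff it satisfies q < ``q_threshold`` and
    |log2FC| > ``fc_threshold`` in *every* contrast; members are annotated
    with their kinetic trend class and a direction summary (up / down /
    nonconsistent). The result is invariant to contrast order.
    """
    if not de_list:
        raise ValueError("empty contrast list")
    universe = de_list[0].genes
    for de in de_list[1:]:
        if not universe.equals(de.genes):
            if set(universe) != set(de.genes):
                raise ValueError("contrasts have mismatched gene universes")
    keep = pd.Series(True, index=universe)
    lfc_cols = {}
    for de in de_list:
        t = de.table.reindex(universe)
        keep &= (t["q"] < q_threshold) & (t["log2fc"].abs() > fc_threshold)
        lfc_cols[f"lfc_{de.contrast[1]}"] = t["log2fc"]
    lfc = pd.DataFrame(lfc_cols).loc[keep[keep].index]
    klasses, switches, directions = [], [], []
    for g in lfc.index:
        ta = classify_trend(lfc.loc[g].to_numpy(), epsilon=epsilon, gene=g)
        klasses.append(ta.klass)
        switches.append(ta.switch_index if ta.switch_index is not None else -1)
        directions.append(
            {"consistently_up": "up", "consistently_down": "down"}.get(
                ta.klass, "nonconsistent"
            )
        )
    table = lfc.copy()
    table["klass"] = klasses
    table["switch_index"] = switches
    table["direction"] = directions
    return ScaffoldSet(
        q_threshold=q_threshold,
        fc_threshold=fc_threshold,
        contrasts=[de.contrast for de in de_list],
        table=table,
    )


def shared_deg_matrix(deg_sets: list[DEGSet], labels: list[str] | None = None,
                      early: list[str] | None = None,
                      late: list[str] | None = None) -> SharedDEGMatrix:
    """Pairwise shared up-/downregulated DEG counts over contrasts.

    ``early``/``late`` partition the contrast labels; totals aggregate
    shared counts over unordered pairs involving an early contrast versus
    pairs entirely within the late group.
    """
    if len(deg_sets) < 2:
        raise ValueError("need at least 2 contrasts")
    if labels is None:
        labels = [ds.contrast[1] for ds in deg_sets]
    if len(labels) != len(deg_sets):
        raise ValueError("labels must match deg_sets")
    k = len(labels)
    ups = [set(ds.up) for ds in deg_sets]
    downs = [set(ds.down) for ds in deg_sets]
    mat = np.zeros((k, k), dtype=int)
    for i in range(k):
        mat[i, i] = len(ups[i] | downs[i])
        for j in range(i + 1, k):
            mat[i, j] = len(ups[i] & ups[j])
            mat[j, i] = len(downs[i] & downs[j])
    matrix = pd.DataFrame(mat, index=labels, columns=labels)
    up_sizes = pd.Series([len(u) for u in ups], index=labels)
    down_sizes = pd.Series([len(d) for d in downs], index=labels)

    totals = {}
    if early is not None or late is not None:
        early = list(early or [])
        late = list(late or [])
        unknown = (set(early) | set(late)) - set(labels)
        if unknown:
            raise ValueError(f"unknown partition labels: {sorted(unknown)}")
        e = set(early)
        lt = set(late)
        for key in ("early_up", "early_down", "late_up", "late_down"):
            totals[key] = 0
        for i in range(k):
            for j in range(i + 1, k):
                li, lj = labels[i], labels[j]
                if li in e or lj in e:
                    totals["early_up"] += int(matrix.iloc[i, j])
                    totals["early_down"] += int(matrix.iloc[j, i])
                elif li in lt and lj in lt:
                    totals["late_up"] += int(matrix.iloc[i, j])
                    totals["late_down"] += int(matrix.iloc[j, i])
    return SharedDEGMatrix(matrix, up_sizes, down_sizes, totals)


# ---------------------------------------------------------------------------
# Ordination and clustering
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    coordinates: pd.DataFrame        # samples x components
    explained_variance_ratio: np.ndarray

    def summary(self) -> str:
        parts = ", ".join(
            f"PC{i + 1} {100 * f:.2f}%" for i, f in
            enumerate(self.explained_variance_ratio[:4])
        )
        return f"PCA of {len(self.coordinates)} samples: {parts}"


def embed_pca(mat: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal components of samples from a genes x samples matrix.

    Genes are centred (no unit-variance scaling); components come from the
    SVD of the centred sample matrix. Explained-variance fractions sum
    to 1 over the retained rank.
    """
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = mat.to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if n_components is None:
        n_components = rank
    n_components = min(n_components, rank)
    coords = u[:, :n_components] * s[:n_components]
    var = s**2
    ratio = var[:n_components] / var.sum() if var.sum() > 0 else var[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        pd.DataFrame(coords, index=mat.columns, columns=cols), ratio
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    labels: list
    method: str
    metric: str

    @property
    def leaf_order(self) -> list:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def to_newick(self) -> str:
        tree = sch.to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});"


def cluster_samples(mat: pd.DataFrame, method: str = "average",
                    metric: str = "euclidean") -> ClusterResult:
    """Agglomerative clustering of samples (columns of genes x samples)."""
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = mat.to_numpy(dtype=float).T
    if np.isnan(X).any():
        raise ValueError("NaN values in expression matrix")
    Z = sch.linkage(X, method=method, metric=metric)
    return ClusterResult(Z, list(mat.columns), method, metric)
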