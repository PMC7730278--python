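"""Differential expression over the ordered cell-line series.

Counts are filtered on a counts-per-million threshold, log-CPM transformed,
and each subline-vs-parent contrast is tested with a moderated t-statistic:
per-gene residual variances are shrunk toward a pooled prior whose degrees
of freedom and scale are estimated by matching the moments of the
log-variances (the standard empirical-Bayes construction for small
replicate numbers). FDR control is Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountData",
    "DEComparison",
    "DEGSet",
    "filter_low_expression",
    "effective_library_sizes",
    "normalize_log",
    "fit_de",
    "adjust_fdr",
    "call_degs",
    "correlate_deg_counts",
    "series_contrasts",
]


@dataclass
class CountData:
    """Gene x sample integer counts plus sample metadata.

    ``samples`` is indexed by sample name with columns ``cell_line``
    (ordered categorical over the derivation series) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not self.counts.columns.equals(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("counts columns and sample metadata disagree")
            self.samples = self.samples.loc[self.counts.columns]
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        reps = self.samples.groupby("cell_line", observed=True).size()
        if (reps < 2).any():
            raise ValueError("every cell line needs >= 2 replicates")

    @property
    def lines(self) -> list[str]:
        cl = self.samples["cell_line"]
        if isinstance(cl.dtype, pd.CategoricalDtype):
            return [c for c in cl.cat.categories if c in set(cl)]
        return list(pd.unique(cl))


@dataclass
class DEComparison:
    """Per-gene differential-expression result for one contrast.

    ``table`` columns: log2fc (treatment minus baseline), stat (moderated
    t), p, q. ``prior_df``/``prior_var`` record the fitted empirical-Bayes
    prior.
    """

    contrast: tuple
    table: pd.DataFrame
    prior_df: float
    prior_var: float
    residual_df: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def summary(self) -> str:
        n = len(self.table)
        n05 = int((self.table["q"] < 0.05).sum())
        n01 = int((self.table["q"] < 0.01).sum())
        a, b = self.contrast
        return (
            f"Contrast {b} vs {a}: {n} genes tested; "
            f"{n05} DEGs at q<0.05, {n01} at q<0.01; "
            f"prior df {self.prior_df:.3g}, prior var {self.prior_var:.3g}"
        )


@dataclass
class DEGSet:
    """Differentially expressed genes for one contrast and threshold."""

    contrast: tuple
    q_threshold: float
    fc_threshold: float | None
    up: list = field(default_factory=list)
    down: list = field(default_factory=list)

    @property
    def genes(self) -> list:
        return sorted(set(self.up) | set(self.down))

    def __len__(self) -> int:
        return len(set(self.up) | set(self.down))


# ---------------------------------------------------------------------------
# Filtering and normalisation
# ---------------------------------------------------------------------------


def filter_low_expression(data: CountData, min_cpm: float = 5.0,
                          min_samples: int = 2) -> CountData:
    """Keep genes with CPM-normalised counts > ``min_cpm`` in at least
    ``min_samples`` samples (a single global filter across all samples)."""
    if data.counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if data.counts.empty:
        raise ValueError("empty count matrix")
    lib = data.counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    cpm = data.counts / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return CountData(data.counts.loc[keep], data.samples)


def effective_library_sizes(data: CountData,
                            method: str = "median_ratio") -> pd.Series:
    """Composition-robust library sizes.

    ``median_ratio`` computes DESeq-style size factors (median per-sample
    ratio to the per-gene geometric mean over genes detected everywhere)
    and rescales them to the magnitude of the raw column totals, so the
    log-CPM scale is preserved. ``total`` returns plain column sums, which
    are confounded when a large planted (or biological) effect mass sits
    on one side: every null gene then appears shifted.
    """
    totals = data.counts.sum(axis=0).astype(float)
    if (totals == 0).any():
        raise ValueError("sample with zero library size")
    if method == "total":
        return totals
    if method != "median_ratio":
        raise ValueError(f"unknown library-size method {method!r}")
    counts = data.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 10:
        return totals
    logc = np.log(counts[positive])
    ref = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - ref, axis=0))
    lib = factors * np.exp(np.mean(np.log(totals.to_numpy() / factors)))
    return pd.Series(lib, index=data.counts.columns)


def normalize_log(data: CountData, lib_sizes: pd.Series | None = None):
    """log2 CPM with small offsets: log2((count + 0.5)/(libsize + 1) * 1e6).

    Returns ``(logmat, lib_sizes)``; the library size defaults to the
    column sum, or pass :func:`effective_library_sizes` output for
    composition-robust scaling.
    """
    lib = data.counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    logmat = np.log2((data.counts + 0.5) / (lib + 1.0) * 1e6)
    return logmat, lib


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = scipy.special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / scipy.special.polygamma(2, x)
        x += dif
        if abs(dif / x) < 1e-10:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to observed gene
    variances: returns (prior_df, prior_var)."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - scipy.special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(scipy.special.polygamma(1, df / 2.0))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0 = float(
        np.exp(emean + scipy.special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    return d0, s0


def fit_de(logmat: pd.DataFrame, samples: pd.DataFrame,
           contrast: tuple[str, str], *, prior_df: float | None = None,
           prior_var: float | None = None) -> DEComparison:
    """Moderated-t differential expression for one two-line contrast.

    ``contrast = (baseline, treatment)``: positive log2FC means higher
    expression in the treatment line. ``prior_df``/``prior_var`` override
    the empirical-Bayes estimates (``prior_df=0`` recovers the ordinary
    two-sample t, ``prior_df=np.inf`` with a fixed ``prior_var`` the pooled
    z-test).
    """
    base, treat = contrast
    cols_a = samples.index[samples["cell_line"] == base]
    cols_b = samples.index[samples["cell_line"] == treat]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each line of the contrast needs >= 2 replicates")
    xa = logmat[cols_a].to_numpy(dtype=float)
    xb = logmat[cols_b].to_numpy(dtype=float)
    n1, n2 = xa.shape[1], xb.shape[1]
    df_resid = n1 + n2 - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    lfc = xb.mean(axis=1) - xa.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / df_resid

    d0, s0 = _fit_variance_prior(s2, df_resid)
    if prior_df is not None:
        d0 = float(prior_df)
    if prior_var is not None:
        s0 = float(prior_var)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = lfc / se
    degenerate = se == 0
    if degenerate.any():
        # no residual variability at all: treat a zero difference as null
        stat = np.where(degenerate & (lfc == 0), 0.0, stat)
    if np.isinf(df_total):
        p = 2.0 * scipy.stats.norm.sf(np.abs(stat))
    else:
        p = 2.0 * scipy.stats.t.sf(np.abs(stat), df_total)
    p = np.where(np.isnan(stat), np.nan, p)
    p = np.where(np.isinf(stat), 0.0, p)

    table = pd.DataFrame(
        {"log2fc": lfc, "stat": stat, "p": p}, index=logmat.index
    )
    table["q"] = adjust_fdr(table["p"].to_numpy())
    return DEComparison(
        contrast=(base, treat), table=table, prior_df=float(d0),
        prior_var=float(s0), residual_df=float(df_resid),
    )


def series_contrasts(data_or_lines, reference: str | None = None) -> list[tuple]:
    """(parent, subline) contrast list for every non-reference line, in
    series order."""
    lines = data_or_lines.lines if hasattr(data_or_lines, "lines") else list(data_or_lines)
    ref = reference if reference is not None else lines[0]
    if ref not in lines:
        raise ValueError(f"reference {ref!r} not among lines")
    return [(ref, ln) for ln in lines if ln != ref]


# ---------------------------------------------------------------------------
# FDR and DEG calling
# ---------------------------------------------------------------------------


def adjust_fdr(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clipped to 1).

    NaN p-values propagate to NaN q-values with a warning and do not count
    toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    nan = np.isnan(p)
    q = np.full_like(p, np.nan)
    if nan.any():
        warnings.warn(f"{int(nan.sum())} NaN p-values propagated", stacklevel=2)
    if (~nan).any():
        if method == "bh":
            q[~nan] = multipletests(p[~nan], method="fdr_bh")[1]
        elif method == "storey":
            q[~nan] = _storey_q(p[~nan])
        else:
            raise ValueError(f"unknown FDR method {method!r}")
    return q


def _storey_q(p: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate."""
    m = p.size
    pi0 = min(1.0, np.mean(p > lam) / (1.0 - lam)) if m else 1.0
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        val = min(prev, pi0 * p[i] * m / (rank + 1))
        q[i] = val
        prev = val
    return q


def call_degs(de: DEComparison, q_threshold: float = 0.05,
              fc_threshold: float | None = None) -> DEGSet:
    """Genes with q below threshold (and |log2FC| above ``fc_threshold``
    if given), split by fold-change sign."""
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must lie in (0, 1)")
    t = de.table
    sel = t["q"] < q_threshold
    if fc_threshold is not None:
        sel &= t["log2fc"].abs() > fc_threshold
    up = t.index[sel & (t["log2fc"] > 0)].tolist()
    down = t.index[sel & (t["log2fc"] < 0)].tolist()
    return DEGSet(de.contrast, q_threshold, fc_threshold, up=up, down=down)


def correlate_deg_counts(deg_counts, deltas) -> tuple[float, float]:
    """Spearman rank correlation between per-pair DEG totals and the
    corresponding |delta RI| or |delta SI| values."""
    x = np.asarray(deg_counts, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if x.size != y.size:
        raise ValueError("input vectors must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)
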