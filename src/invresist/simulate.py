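"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (viability curves, differential
expression over the ordered subline series, trend classification, hub
detection) is exercised against data produced here, so each generator
returns both the simulated observables and a truth table describing what
was planted.

The defaults describe the study system: a parental ovarian-carcinoma line
(A2780) and six paclitaxel-selected sublines, assayed for paclitaxel (PTX,
nM) and cisplatin (CDDP, uM) cytotoxicity on 96-well plates, and profiled
by bulk mRNA-seq in two biological replicates per line.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Plate",
    "DEFAULT_LINES",
    "DEFAULT_TRUE_IC50",
    "DRUG_UNITS",
    "PATTERN_CLASSES",
    "logistic_viability",
    "simulate_plate",
    "simulate_assay",
    "simulate_counts",
    "simulate_network",
]

#: Ordered derivation series: parent first, then sublines by selection dose.
DEFAULT_LINES = ("A2780", "A4PTX", "A8PTX", "A16PTX", "A32PTX", "A64PTX", "A128PTX")

#: Native concentration unit per drug (PTX in nanomolar, CDDP in micromolar).
DRUG_UNITS = {"PTX": "nM", "CDDP": "uM"}

#: Reported 120-h IC50 values for the series, used as simulator truth.
DEFAULT_TRUE_IC50 = {
    ("A2780", "PTX"): 4.62,
    ("A4PTX", "PTX"): 11.47,
    ("A8PTX", "PTX"): 18.71,
    ("A16PTX", "PTX"): 77.54,
    ("A32PTX", "PTX"): 148.47,
    ("A64PTX", "PTX"): 173.86,
    ("A128PTX", "PTX"): 272.47,
    ("A2780", "CDDP"): 4.58,
    ("A4PTX", "CDDP"): 4.27,
    ("A8PTX", "CDDP"): 2.12,
    ("A16PTX", "CDDP"): 0.65,
    ("A32PTX", "CDDP"): 0.44,
    ("A64PTX", "CDDP"): 0.40,
    ("A128PTX", "CDDP"): 0.83,
}

PATTERN_CLASSES = (
    "consistently_up",
    "rising",
    "variable",
    "descending",
    "consistently_down",
    "null",
)


def _default_pattern_props() -> dict[str, float]:
    # Trend-class mix of the expressed transcriptome: the 997-gene
    # significant set split 190:295:138:174:200 over the five kinetic
    # classes, embedded in 11,588 expressed genes (remainder null).
    total = 11588.0
    counts = {
        "consistently_up": 190,
        "rising": 295,
        "variable": 138,
        "descending": 174,
        "consistently_down": 200,
    }
    props = {k: v / total for k, v in counts.items()}
    props["null"] = 1.0 - sum(props.values())
    return props


def _default_conc_grid(true_ic50: dict) -> dict:
    # Per-line, per-drug eight-point doubling series centred on the true
    # IC50, mimicking the individually tailored dilution ranges of the
    # assay; spans ~8% to ~92% viability at Hill slope 1.
    grid = {}
    for (line, drug), ic50 in true_ic50.items():
        grid[(line, drug)] = ic50 * 2.0 ** np.arange(-3.5, 4.0, 1.0)
    return grid


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    seed : int
        Root seed; every generator derives its stream from it.
    n_lines, n_reps : int
        Cell lines in the ordered series (parent first) and mRNA-seq
        replicates per line.
    n_genes : int
        Genes in the simulated count matrix.
    pattern_props : dict
        Fraction of genes planted in each kinetic class (must sum to 1).
    effect_log2fc : float
        Planted |log2 fold change| at full effect.
    dispersion : float
        Negative-binomial dispersion (var = mu + dispersion * mu**2).
    lib_size_mean : int
        Mean library size per sample.
    true_ic50 : dict
        (line, drug) -> true IC50 in the drug's native unit.
    hill_slope : float
        Hill coefficient of the four-parameter-logistic viability curve.
    plate_noise_sd : float
        SD of additive Gaussian noise on per-well % viability, truncated
        to [-5, 120].
    conc_grid : dict
        (line, drug) -> eight ascending assay concentrations.
    """

    seed: int = 0
    n_lines: int = 7
    n_reps: int = 2
    n_genes: int = 11588
    pattern_props: dict = field(default_factory=_default_pattern_props)
    effect_log2fc: float = 3.0
    dispersion: float = 0.05
    lib_size_mean: int = 25_000_000
    true_ic50: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_IC50))
    hill_slope: float = 1.0
    plate_noise_sd: float = 3.0
    conc_grid: dict = None
    lines: tuple = None

    def __post_init__(self):
        if self.lines is None:
            if self.n_lines == len(DEFAULT_LINES):
                self.lines = DEFAULT_LINES
            else:
                self.lines = tuple(
                    ["A2780"] + [f"S{i}" for i in range(1, self.n_lines)]
                )
        self.lines = tuple(self.lines)
        if len(self.lines) != self.n_lines:
            raise ValueError("lines must have length n_lines")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        total = sum(self.pattern_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_props must sum to 1, got {total}")
        unknown = set(self.pattern_props) - set(PATTERN_CLASSES)
        if unknown:
            raise ValueError(f"unknown pattern classes: {sorted(unknown)}")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.plate_noise_sd < 0:
            raise ValueError("plate_noise_sd must be nonnegative")
        if self.conc_grid is None:
            self.conc_grid = _default_conc_grid(self.true_ic50)
        for key, grid in self.conc_grid.items():
            grid = np.asarray(grid, dtype=float)
            if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
                raise ValueError(
                    f"concentration grid for {key} must be positive and "
                    "strictly increasing"
                )
            self.conc_grid[key] = grid

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Cytotoxicity plates
# ---------------------------------------------------------------------------

#: Molar extinction coefficients of the resazurin redox indicator
#: (oxidized/reduced forms at the two read wavelengths).
EXTINCTION = {"ox570": 80586.0, "ox600": 117216.0, "red570": 155677.0, "red600": 14652.0}

#: Dye concentration x path length used to scale simulated absorbances.
_DYE_SCALE = 5e-6
#: Fraction of dye reduced by untreated control wells at readout.
_CONTROL_REDUCTION = 0.85

ROWS = tuple("ABCDEFGH")


def _stable_hash(key) -> int:
    """Process-independent 31-bit hash used to split RNG streams."""
    return zlib.crc32(repr(key).encode()) % (2**31)


@dataclass
class Plate:
    """One 96-well cytotoxicity plate: paired absorbance reads + layout.

    ``a570``/``a600`` are 8x12 DataFrames (rows A-H, columns 1-12);
    ``layout`` is a long table (row, col, role, conc) where role is one of
    blank / control / drug / unused.
    """

    cell_line: str
    drug: str
    unit: str
    a570: pd.DataFrame
    a600: pd.DataFrame
    layout: pd.DataFrame
    replicate: int = 1


def logistic_viability(conc, ic50: float, hill: float) -> np.ndarray:
    """Four-parameter logistic with asymptotes 100 and 0; v(IC50) = 50."""
    conc = np.asarray(conc, dtype=float)
    return 100.0 / (1.0 + (conc / ic50) ** hill)


def _plate_layout(concs: np.ndarray) -> pd.DataFrame:
    records = []
    for r in ROWS:
        for c in range(1, 13):
            if c in (1, 12):
                role, conc = "blank", np.nan
            elif c in (2, 11):
                role, conc = "control", np.nan
            elif r in ("A", "B", "C", "D"):
                role, conc = "drug", concs[c - 3]
            else:
                role, conc = "unused", np.nan
            records.append((r, c, role, conc))
    return pd.DataFrame(records, columns=["row", "col", "role", "conc"])


def _absorbance_from_reduction(frac: np.ndarray):
    """Map per-well reduced-dye fractions to (A570, A600) absorbances."""
    e = EXTINCTION
    a570 = _DYE_SCALE * ((1.0 - frac) * e["ox570"] + frac * e["red570"])
    a600 = _DYE_SCALE * ((1.0 - frac) * e["ox600"] + frac * e["red600"])
    return a570, a600


def simulate_plate(cfg: SimConfig, line: str, drug: str, *, replicate: int = 1,
                   rng: np.random.Generator | None = None) -> Plate:
    """Simulate one 96-well plate for (line, drug).

    Columns 1 and 12 are medium blanks, 2 and 11 drug-free growth controls,
    and 3-10 carry the line's eight assay concentrations in four wells each
    (rows A-D). True viability follows the four-parameter logistic at the
    configured IC50; per-well noise is additive Gaussian on the viability
    scale, truncated to [-5, 120].
    """
    key = (line, drug)
    if key not in cfg.true_ic50:
        raise KeyError(f"no true IC50 configured for {key}")
    if key not in cfg.conc_grid:
        raise KeyError(f"no concentration grid configured for {key}")
    concs = np.asarray(cfg.conc_grid[key], dtype=float)
    if concs.shape[0] != 8:
        raise ValueError("conc_grid must provide exactly 8 concentrations")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, _stable_hash(key), replicate])
    layout = _plate_layout(concs)

    viab = np.empty(len(layout))
    for i, rec in enumerate(layout.itertuples(index=False)):
        if rec.role == "drug":
            viab[i] = logistic_viability(rec.conc, cfg.true_ic50[key], cfg.hill_slope)
        elif rec.role == "control":
            viab[i] = 100.0
        else:  # blank / unused: no cells
            viab[i] = 0.0
    noisy = viab.copy()
    live = layout["role"].isin(["drug", "control"]).to_numpy()
    if cfg.plate_noise_sd > 0:
        noise = rng.normal(0.0, cfg.plate_noise_sd, size=live.sum())
        noisy[live] = np.clip(viab[live] + noise, -5.0, 120.0)

    frac = _CONTROL_REDUCTION * noisy / 100.0
    a570, a600 = _absorbance_from_reduction(frac)

    def grid(vals):
        g = pd.DataFrame(
            vals.reshape(len(ROWS), 12), index=list(ROWS), columns=range(1, 13)
        )
        return g

    return Plate(
        cell_line=line,
        drug=drug,
        unit=DRUG_UNITS.get(drug, "nM"),
        a570=grid(a570),
        a600=grid(a600),
        layout=layout,
        replicate=replicate,
    )


def simulate_assay(cfg: SimConfig, line: str, drug: str, n_plates: int = 3) -> list[Plate]:
    """Simulate the full assay for one line/drug: ``n_plates`` replicate plates."""
    rng = np.random.default_rng([cfg.seed, _stable_hash((line, drug))])
    return [
        simulate_plate(cfg, line, drug, replicate=i + 1, rng=rng)
        for i in range(n_plates)
    ]


# ---------------------------------------------------------------------------
# Count matrices with planted trend structure
# ---------------------------------------------------------------------------


def _planted_lfc(klass: str, k: int, effect: float, rng: np.random.Generator) -> tuple[np.ndarray, int | None]:
    """Per-contrast true log2FC vector for one gene, plus its switch index."""
    if klass == "null":
        return np.zeros(k), None
    if klass == "consistently_up":
        return np.full(k, effect), None
    if klass == "consistently_down":
        return np.full(k, -effect), None
    if klass in ("rising", "descending"):
        # single sign switch; position drawn from contrasts 2..k-1 so the
        # rule is tested away from the fixed stage the study observed
        lo, hi = 2, max(2, k - 1)
        s = int(rng.integers(lo, hi + 1))
        lfc = np.full(k, -effect)
        lfc[s - 1:] = effect
        if klass == "descending":
            lfc = -lfc
        return lfc, s
    if klass == "variable":
        if k < 3:
            raise ValueError("variable patterns require >= 3 contrasts")
        while True:
            signs = rng.choice([-1.0, 1.0], size=k)
            if (np.diff(np.sign(signs)) != 0).sum() >= 2:
                return signs * effect, None
    raise ValueError(f"unknown pattern class {klass!r}")


def simulate_counts(cfg: SimConfig):
    """Simulate the ordered-series count matrix with planted trends.

    Returns ``(counts, samples, truth)``:

    * ``counts`` — genes x samples integer DataFrame, negative-binomial
      around library-size-scaled expected expression;
    * ``samples`` — per-sample metadata (cell_line as ordered categorical,
      replicate);
    * ``truth`` — per-gene planted class, switch index and true log2FC for
      each of the ``n_lines - 1`` contrasts against the parental line.
    """
    if cfg.n_lines < 3:
        raise ValueError("need at least 3 lines (parent + 2 sublines)")
    rng = np.random.default_rng([cfg.seed, 2])
    k = cfg.n_lines - 1
    classes = list(cfg.pattern_props)
    probs = np.array([cfg.pattern_props[c] for c in classes])
    gene_class = rng.choice(len(classes), size=cfg.n_genes, p=probs)

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    base_log2cpm = rng.uniform(3.0, 9.0, size=cfg.n_genes)

    lfc = np.zeros((cfg.n_genes, k))
    switch = np.full(cfg.n_genes, -1)
    klasses = []
    for g in range(cfg.n_genes):
        klass = classes[gene_class[g]]
        klasses.append(klass)
        vec, s = _planted_lfc(klass, k, cfg.effect_log2fc, rng)
        lfc[g] = vec
        if s is not None:
            switch[g] = s

    sample_names, sample_line, sample_rep = [], [], []
    for line in cfg.lines:
        for r in range(1, cfg.n_reps + 1):
            sample_names.append(f"{line}_r{r}")
            sample_line.append(line)
            sample_rep.append(r)
    n_samples = len(sample_names)
    lib_sizes = np.round(
        cfg.lib_size_mean * rng.uniform(0.9, 1.1, size=n_samples)
    ).astype(np.int64)

    # expected log2 CPM per gene x line: parent baseline + planted contrast
    line_lfc = np.zeros((cfg.n_genes, cfg.n_lines))
    line_lfc[:, 1:] = lfc
    counts = np.empty((cfg.n_genes, n_samples), dtype=np.int64)
    for j, line in enumerate(sample_line):
        li = cfg.lines.index(line)
        mu = 2.0 ** (base_log2cpm + line_lfc[:, li]) * lib_sizes[j] / 1e6
        if cfg.dispersion > 0:
            n_param = 1.0 / cfg.dispersion
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, j] = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=sample_names)
    samples = pd.DataFrame(
        {
            "cell_line": pd.Categorical(
                sample_line, categories=list(cfg.lines), ordered=True
            ),
            "replicate": sample_rep,
        },
        index=sample_names,
    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "klass": klasses,
            "switch_index": switch,
        }
    ).set_index("gene")
    for i in range(k):
        truth[f"lfc_{cfg.lines[i + 1]}"] = lfc[:, i]
    return counts_df, samples, truth


# ---------------------------------------------------------------------------
# Planted-hub interaction networks
# ---------------------------------------------------------------------------


def simulate_network(cfg: SimConfig, genes: list[str], n_hubs: int, *,
                     hub_degree: int = 9, n_background: int | None = None):
    """Simulate a scored edge list with planted hubs.

    Each of ``n_hubs`` planted hubs receives exactly ``hub_degree``
    partners among the non-hub genes; non-hub degrees are kept strictly
    below ``hub_degree``. Edge scores are uniform on [0, 1].

    Returns ``(edges, hubs)`` where edges is a (gene_a, gene_b, score)
    DataFrame and hubs the planted hub list.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must not be empty")
    if n_hubs > len(genes):
        raise ValueError("n_hubs exceeds number of genes")
    rng = np.random.default_rng([cfg.seed, 3])
    hubs = sorted(rng.choice(genes, size=n_hubs, replace=False).tolist())
    nonhubs = [g for g in genes if g not in set(hubs)]
    if n_hubs and len(nonhubs) < hub_degree:
        raise ValueError("not enough non-hub genes to realise hub degree")

    degree = {g: 0 for g in genes}
    cap = hub_degree - 1  # non-hub degrees stay below the hub threshold
    edge_set = set()

    def add_edge(a, b):
        key = (a, b) if a < b else (b, a)
        if a == b or key in edge_set:
            return False
        edge_set.add(key)
        degree[a] += 1
        degree[b] += 1
        return True

    for h in hubs:
        eligible = [g for g in nonhubs if degree[g] < cap]
        if len(eligible) < hub_degree:
            raise ValueError("cannot plant hubs without exceeding non-hub cap")
        partners = rng.choice(eligible, size=hub_degree, replace=False)
        for p in partners:
            add_edge(h, p)

    if n_background is None:
        n_background = len(nonhubs)
    attempts = 0
    added = 0
    while added < n_background and attempts < 20 * n_background:
        attempts += 1
        if len(nonhubs) < 2:
            break
        a, b = rng.choice(nonhubs, size=2, replace=False)
        if degree[a] >= cap or degree[b] >= cap:
            continue
        if add_edge(a, b):
            added += 1

    records = [
        (a, b, float(s))
        for (a, b), s in zip(sorted(edge_set), rng.uniform(0, 1, size=len(edge_set)))
    ]
    edges = pd.DataFrame(records, columns=["gene_a", "gene_b", "score"])
    return edges, hubs
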