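"""Cytotoxicity dose-response analysis.

From paired 570/600 nm plate absorbances to percent-viability curves, the
eight-level concentration grid obtained by linear interpolation, IC50 and
pIC50, resistance/sensitivity indices and consecutive fold changes, and two
statistical comparisons of dose-response between cell lines: a random-slope
linear mixed model on well-level viabilities and a pooled-variance t-test
on replicate pIC50 values.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .simulate import EXTINCTION, Plate

__all__ = [
    "ViabilityCurve",
    "ViabilityGrid",
    "ResistanceProfile",
    "CurveComparison",
    "DegeneratePlateError",
    "BracketError",
    "MultiCrossingWarning",
    "GRID_LEVELS",
    "percent_viability",
    "plate_viability_long",
    "combine_curves",
    "viability_grid",
    "ic50",
    "pic50",
    "resistance_index",
    "sensitivity_index",
    "resistance_profiles",
    "fold_change_consecutive",
    "round_half_away",
    "compare_lmm",
    "compare_ttest_pic50",
]

#: The eight viability levels of the interpolation grid, in percent.
GRID_LEVELS = (90.0, 80.0, 70.0, 60.0, 50.0, 40.0, 30.0, 20.0)

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}


class DegeneratePlateError(ValueError):
    """Control wells do not exceed blank signal; the plate is unusable."""


class BracketError(ValueError):
    """A requested viability level is never bracketed by the curve."""


class MultiCrossingWarning(UserWarning):
    """A non-monotone curve crosses a level more than once."""


@dataclass
class ViabilityCurve:
    """Per-concentration viability summary for one cell line and drug."""

    cell_line: str
    drug: str
    unit: str
    points: pd.DataFrame  # columns: conc, mean_viab, sd, n (conc ascending)

    def __post_init__(self):
        pts = self.points.sort_values("conc").reset_index(drop=True)
        if pts["conc"].duplicated().any():
            raise ValueError("duplicate concentrations in viability curve")
        if (pts["n"] < 1).any():
            raise ValueError("each curve point needs n >= 1 wells")
        self.points = pts


@dataclass
class ViabilityGrid:
    """Concentrations reaching each requested viability level (or NaN)."""

    cell_line: str
    drug: str
    unit: str
    levels: tuple
    conc_at_level: dict  # level -> concentration or nan


@dataclass
class ResistanceProfile:
    cell_line: str
    drug: str
    unit: str
    ic50: float
    pic50: float
    index: float          # RI or SI vs the reference line, unrounded
    index_kind: str       # "RI" or "SI"
    reference: str

    @property
    def index_rounded(self) -> float:
        return round_half_away(self.index, 2)


@dataclass
class CurveComparison:
    """Result of comparing two dose-response datasets.

    Either side may be absent: ``lmm_p`` from the random-slope mixed model
    on well-level viabilities, ``ttest_p`` from the pooled t-test on
    replicate pIC50 values.
    """

    line_pair: tuple
    drug: str | None = None
    lmm_p: float | None = None
    ttest_p: float | None = None
    slope_estimates: dict = field(default_factory=dict)
    intercept_estimates: dict = field(default_factory=dict)
    slope_diff: float | None = None
    slope_diff_se: float | None = None
    ci95: tuple | None = None
    tstat: float | None = None
    df: float | None = None
    mean_diff: float | None = None
    flagged: bool = False

    def summary(self) -> str:
        a, b = self.line_pair
        lines = [f"Dose-response comparison: {a} vs {b}"]
        if self.drug:
            lines.append(f"  drug: {self.drug}")
        if self.lmm_p is not None:
            lo, hi = self.ci95
            lines.append(
                f"  LMM slope difference: {self.slope_diff:.4g} "
                f"(95% CI {lo:.4g} to {hi:.4g}), p = {self.lmm_p:.3g}"
            )
            if self.flagged:
                lines.append("  [flagged: mixed-model fit did not fully converge]")
        if self.ttest_p is not None:
            lines.append(
                f"  pIC50 t-test: mean diff {self.mean_diff:.4g}, "
                f"t = {self.tstat:.3f} (df {self.df:g}), p = {self.ttest_p:.3g}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Plate -> curve
# ---------------------------------------------------------------------------


def _well_reductions(plate: Plate) -> pd.DataFrame:
    """Percent dye reduction per well via the two-wavelength formula.

    %reduction = (eps_ox600*A570 - eps_ox570*A600)_well /
                 (eps_red570*A600 - eps_red600*A570)_blank * 100
    """
    e = EXTINCTION
    lay = plate.layout.copy()
    a570 = np.array([plate.a570.at[r, c] for r, c in zip(lay["row"], lay["col"])])
    a600 = np.array([plate.a600.at[r, c] for r, c in zip(lay["row"], lay["col"])])
    num = e["ox600"] * a570 - e["ox570"] * a600
    blank = lay["role"] == "blank"
    denom = float(np.mean(e["red570"] * a600[blank] - e["red600"] * a570[blank]))
    if denom <= 0:
        raise DegeneratePlateError("blank wells give nonpositive normalisation")
    lay["reduction"] = num / denom * 100.0
    return lay


def plate_viability_long(plate: Plate) -> pd.DataFrame:
    """Well-level % viability for drug wells (for mixed-model comparison)."""
    lay = _well_reductions(plate)
    ctrl = lay.loc[lay["role"] == "control", "reduction"].mean()
    if ctrl <= 0:
        raise DegeneratePlateError("control signal does not exceed blank signal")
    drug = lay[lay["role"] == "drug"].copy()
    drug["viability"] = 100.0 * drug["reduction"] / ctrl
    drug["cell_line"] = plate.cell_line
    drug["drug"] = plate.drug
    drug["plate"] = plate.replicate
    return drug[["cell_line", "drug", "plate", "conc", "viability"]].reset_index(drop=True)


def percent_viability(plate: Plate) -> ViabilityCurve:
    """Summarise a plate into one viability point per concentration.

    Drug-free control wells define 100%; per concentration the mean, SD and
    well count over its (four) wells are reported.
    """
    long = plate_viability_long(plate)
    if long.empty:
        raise ValueError("plate has no drug wells")
    pts = (
        long.groupby("conc")["viability"]
        .agg(mean_viab="mean", sd="std", n="count")
        .reset_index()
    )
    pts["sd"] = pts["sd"].fillna(0.0)
    return ViabilityCurve(plate.cell_line, plate.drug, plate.unit, pts)


def combine_curves(curves: list[ViabilityCurve]) -> ViabilityCurve:
    """Average replicate-plate curves: mean of per-plate means at each
    concentration, SD across plate means, n = total wells."""
    if not curves:
        raise ValueError("no curves to combine")
    first = curves[0]
    for c in curves[1:]:
        if (c.cell_line, c.drug, c.unit) != (first.cell_line, first.drug, first.unit):
            raise ValueError("curves to combine must share line, drug and unit")
    stacked = pd.concat([c.points.assign(_rep=i) for i, c in enumerate(curves)])
    pts = (
        stacked.groupby("conc")
        .agg(mean_viab=("mean_viab", "mean"), sd=("mean_viab", "std"), n=("n", "sum"))
        .reset_index()
    )
    pts["sd"] = pts["sd"].fillna(0.0)
    return ViabilityCurve(first.cell_line, first.drug, first.unit, pts)


# ---------------------------------------------------------------------------
# Interpolation grid / IC50
# ---------------------------------------------------------------------------


def _interp(x1, x2, y1, y2, y):
    return x1 + (x2 - x1) * (y - y1) / (y2 - y1)


def viability_grid(curve: ViabilityCurve, levels=GRID_LEVELS, *,
                   extrapolate: bool = False) -> ViabilityGrid:
    """Concentration reaching each viability level by linear interpolation.

    Brackets are scanned from the lowest concentration; the first crossing
    is used and additional crossings raise :class:`MultiCrossingWarning`.
    Levels never bracketed are NaN unless ``extrapolate`` extends the
    terminal segment.
    """
    pts = curve.points
    if len(pts) < 2:
        raise ValueError("viability grid needs at least 2 curve points")
    conc = pts["conc"].to_numpy(dtype=float)
    viab = pts["mean_viab"].to_numpy(dtype=float)
    out = {}
    for level in levels:
        y = float(level)
        found = None
        crossings = 0
        exact = np.nonzero(viab == y)[0]
        if exact.size:
            found = conc[exact[0]]
            crossings = len(exact)
        for i in range(len(conc) - 1):
            y1, y2 = viab[i], viab[i + 1]
            if (y1 - y) * (y2 - y) < 0:
                crossings += 1
                if found is None:
                    found = _interp(conc[i], conc[i + 1], y1, y2, y)
        if crossings > 1:
            warnings.warn(
                f"{curve.cell_line}/{curve.drug}: level {y}% crossed "
                f"{crossings} times; using first crossing",
                MultiCrossingWarning,
                stacklevel=2,
            )
        if found is None and extrapolate:
            if y < viab.min():
                i = len(conc) - 2
            else:
                i = 0
            y1, y2 = viab[i], viab[i + 1]
            if y1 != y2:
                found = _interp(conc[i], conc[i + 1], y1, y2, y)
        out[y] = float(found) if found is not None else float("nan")
    return ViabilityGrid(curve.cell_line, curve.drug, curve.unit, tuple(levels), out)


def ic50(curve: ViabilityCurve, *, extrapolate: bool = False) -> float:
    """IC50 as the 50% entry of the interpolation grid."""
    grid = viability_grid(curve, levels=(50.0,), extrapolate=extrapolate)
    val = grid.conc_at_level[50.0]
    if np.isnan(val):
        raise BracketError(
            f"{curve.cell_line}/{curve.drug}: 50% viability never bracketed"
        )
    return val


def pic50(ic50_value: float, unit: str) -> float:
    """Negative log10 of the IC50 expressed in molar."""
    if ic50_value <= 0:
        raise ValueError("IC50 must be positive")
    try:
        factor = _UNIT_TO_MOLAR[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
    return -np.log10(ic50_value * factor)


# ---------------------------------------------------------------------------
# Indices and fold changes
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    d = decimal.Decimal(repr(float(x))).quantize(
        decimal.Decimal(f"1e-{ndigits}"), rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def _check_units(unit_a, unit_b):
    if unit_a is not None and unit_b is not None and unit_a != unit_b:
        raise ValueError(f"unit mismatch: {unit_a!r} vs {unit_b!r}")


def resistance_index(ic50_sub: float, ic50_ref: float, *,
                     unit_sub: str | None = None, unit_ref: str | None = None) -> float:
    """RI = subline IC50 / reference IC50 (selecting drug)."""
    _check_units(unit_sub, unit_ref)
    if ic50_sub <= 0 or ic50_ref <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_sub / ic50_ref


def sensitivity_index(ic50_ref: float, ic50_sub: float, *,
                      unit_sub: str | None = None, unit_ref: str | None = None) -> float:
    """SI = reference IC50 / subline IC50 (bystander drug)."""
    _check_units(unit_sub, unit_ref)
    if ic50_sub <= 0 or ic50_ref <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_ref / ic50_sub


def resistance_profiles(ic50s: dict[str, float], drug: str, unit: str,
                        reference: str, index_kind: str) -> list[ResistanceProfile]:
    """Build per-line profiles (IC50, pIC50, RI or SI vs the reference)."""
    if reference not in ic50s:
        raise KeyError(f"reference line {reference!r} missing from IC50 table")
    if index_kind not in ("RI", "SI"):
        raise ValueError("index_kind must be 'RI' or 'SI'")
    ref = ic50s[reference]
    out = []
    for line, val in ic50s.items():
        idx = (
            resistance_index(val, ref) if index_kind == "RI"
            else sensitivity_index(ref, val)
        )
        out.append(
            ResistanceProfile(line, drug, unit, val, pic50(val, unit), idx,
                              index_kind, reference)
        )
    return out


def fold_change_consecutive(profiles: list[ResistanceProfile]) -> pd.DataFrame:
    """Fold change between consecutive lines of the derivation series.

    For the selecting drug (RI kind) the fold is child/parent IC50; for the
    bystander drug (SI kind) it is parent/child. The product of the
    unrounded folds equals the end-to-end index.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    kinds = {p.index_kind for p in profiles}
    units = {p.unit for p in profiles}
    drugs = {p.drug for p in profiles}
    if len(kinds) != 1 or len(units) != 1 or len(drugs) != 1:
        raise ValueError("profiles must share drug, unit and index kind")
    kind = kinds.pop()
    rows = []
    for parent, child in zip(profiles[:-1], profiles[1:]):
        fold = (
            child.ic50 / parent.ic50 if kind == "RI" else parent.ic50 / child.ic50
        )
        rows.append(
            {
                "pair": f"{parent.cell_line}-{child.cell_line}",
                "parent": parent.cell_line,
                "child": child.cell_line,
                "fold": fold,
                "fold_rounded": round_half_away(fold, 2),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------


def _plate_slopes(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(line, plate) OLS slope and intercept of viability on dose."""
    rows = []
    for (line, plate), grp in df.groupby(["cell_line", "plate"], sort=False):
        x = grp["x"].to_numpy(dtype=float)
        y = grp["viability"].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            raise ValueError(
                f"line {line!r} plate {plate!r} needs >= 2 concentrations"
            )
        slope, intercept = np.polyfit(x, y, 1)
        rows.append({"cell_line": line, "plate": plate,
                     "slope": slope, "intercept": intercept})
    return pd.DataFrame(rows)


def compare_lmm(data: pd.DataFrame, line_pair: tuple[str, str] | None = None,
                *, log_conc: bool = False, fit_model: bool = True) -> CurveComparison:
    """Random-slope comparison of two dose-response datasets.

    ``data`` holds well-level observations with columns ``cell_line``,
    ``plate``, ``conc`` and ``viability``. Each line's viability is
    modelled as a line-specific linear function of dose whose slope varies
    from plate to plate (the plate is the random-effect grouping). For
    this balanced design the fixed-effect slope contrast of the mixed
    model coincides with the classical two-stage estimate — the mean of
    per-plate OLS slopes — and the two-stage pooled t-test on per-plate
    slopes is the exact small-sample inference for the slope difference
    regardless of the true plate-slope variance, so the reported p-value
    and CI come from it. When ``fit_model`` is true a REML mixed model
    (fixed line intercepts and slopes, random slope per line x plate) is
    also fitted and its estimates reported. Concentration enters on the
    linear scale by default (``log_conc`` switches to log10).
    """
    df = data.copy()
    required = {"cell_line", "plate", "conc", "viability"}
    if missing := required - set(df.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    lines = list(pd.unique(df["cell_line"]))
    if line_pair is None:
        if len(lines) != 2:
            raise ValueError("data must contain exactly two cell lines")
        line_pair = (lines[0], lines[1])
    else:
        df = df[df["cell_line"].isin(line_pair)].copy()
        if df["cell_line"].nunique() != 2:
            raise ValueError("both lines of line_pair must be present")
    a, b = line_pair
    for line in line_pair:
        if df.loc[df["cell_line"] == line, "conc"].nunique() < 2:
            raise ValueError(f"line {line!r} needs >= 2 concentrations")
    df["x"] = np.log10(df["conc"]) if log_conc else df["conc"]

    # exact two-stage inference on per-plate slopes
    slopes = _plate_slopes(df)
    sa = slopes.loc[slopes["cell_line"] == a, "slope"].to_numpy()
    sb = slopes.loc[slopes["cell_line"] == b, "slope"].to_numpy()
    est = float(sb.mean() - sa.mean())
    dof = sa.size + sb.size - 2
    if dof <= 0 or sa.size < 2 or sb.size < 2:
        raise ValueError("need >= 2 plates per line for slope inference")
    pooled = ((sa.size - 1) * sa.var(ddof=1) + (sb.size - 1) * sb.var(ddof=1)) / dof
    se = float(np.sqrt(pooled * (1.0 / sa.size + 1.0 / sb.size)))
    if se == 0:
        p = 1.0 if est == 0 else 0.0
        tstat = 0.0 if est == 0 else np.inf * np.sign(est)
    else:
        tstat = est / se
        p = float(2 * scipy.stats.t.sf(abs(tstat), dof))
    tcrit = float(scipy.stats.t.ppf(0.975, dof))
    ci = (est - tcrit * se, est + tcrit * se)

    slope_estimates = {a: float(sa.mean()), b: float(sb.mean())}
    intercepts = (
        slopes.groupby("cell_line")["intercept"].mean().to_dict()
    )
    flagged = False
    if fit_model:
        # REML mixed model for reporting; regressor rescaled so optimiser
        # tolerances act uniformly across per-line concentration ranges
        scale = df["x"].abs().max()
        if scale == 0:
            raise ValueError("concentrations are all zero")
        df["xs"] = df["x"] / scale
        df["line"] = pd.Categorical(df["cell_line"], categories=[a, b])
        df["group"] = df["cell_line"].astype(str) + ":" + df["plate"].astype(str)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            model = smf.mixedlm(
                "viability ~ line + xs + xs:line",
                df,
                groups=df["group"],
                re_formula="0 + xs",
            )
            try:
                fit = model.fit(method="lbfgs", reml=True)
                if not fit.converged:
                    flagged = True
            except Exception:
                try:
                    fit = model.fit(method="powell", reml=True)
                except Exception:
                    fit = None
                flagged = True
        if fit is not None:
            slope_a = fit.params["xs"] / scale
            slope_b = slope_a + fit.params[f"xs:line[T.{b}]"] / scale
            slope_estimates = {a: float(slope_a), b: float(slope_b)}
            intercepts = {
                a: float(fit.params["Intercept"]),
                b: float(fit.params["Intercept"] + fit.params[f"line[T.{b}]"]),
            }
    drug = df["drug"].iloc[0] if "drug" in df.columns else None
    return CurveComparison(
        line_pair=(a, b),
        drug=drug,
        lmm_p=p,
        slope_estimates=slope_estimates,
        intercept_estimates=intercepts,
        slope_diff=est,
        slope_diff_se=se,
        ci95=ci,
        tstat=float(tstat),
        df=float(dof),
        flagged=flagged,
    )


def compare_ttest_pic50(pic50_reps_a, pic50_reps_b,
                        line_pair: tuple[str, str] = ("a", "b"),
                        drug: str | None = None) -> CurveComparison:
    """Pooled-variance two-sided t-test on replicate pIC50 values.

    If both groups have zero variance and equal means the comparison is
    exactly null and p = 1 by convention.
    """
    a = np.asarray(pic50_reps_a, dtype=float)
    b = np.asarray(pic50_reps_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 replicates per line")
    df_total = a.size + b.size - 2
    mean_diff = a.mean() - b.mean()
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if mean_diff == 0:
            return CurveComparison(line_pair=line_pair, drug=drug, ttest_p=1.0,
                                   tstat=0.0, df=df_total, mean_diff=0.0)
        t, p = np.inf * np.sign(mean_diff), 0.0
    else:
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return CurveComparison(
        line_pair=line_pair, drug=drug, ttest_p=float(p), tstat=float(t),
        df=float(df_total), mean_diff=float(mean_diff),
    )
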