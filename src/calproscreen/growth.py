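"""Nutritional-immunity growth-curve analysis.

The pipeline quantifies dose-dependent growth inhibition by a metal-
sequestering protein: OD600 series are background-subtracted against matched
no-bacteria blanks, integrated over 0–13 h by the composite trapezoid rule,
and each treated culture's AUC is compared with the same replicate's 0 µM
control (ΔAUC = AUC_treated − AUC_control; negative means inhibition).
Replicate ΔAUC values at one dose feed a two-way ANOVA (protein + strain)
with Tukey-Kramer post-hoc comparisons on the protein factor.

Technical replicate wells are averaged within a biological replicate before
any statistics; means ± SEM are across biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

from .tables import BLANK, GROWTH_SERIES_KEY, TableError

CURVE_KEY = ["strain", "protein", "concentration", "replicate_bio"]


class GrowthError(ValueError):
    pass


@dataclass(frozen=True)
class GrowthCurve:
    strain: str
    protein: str
    concentration: float
    replicate_bio: int
    times: np.ndarray
    od: np.ndarray
    subtracted: bool = True

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise GrowthError("times and od must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise GrowthError("times must be strictly increasing")

    @property
    def key(self) -> tuple:
        return (self.strain, self.protein, self.concentration, self.replicate_bio)


@dataclass(frozen=True)
class AUCResult:
    strain: str
    protein: str
    concentration: float
    replicate_bio: int
    auc: float  # OD·h
    window: tuple[float, float]


def _interpolate_gaps(t: np.ndarray, y: np.ndarray, label) -> np.ndarray:
    nan = np.isnan(y)
    if not nan.any():
        return y
    # two consecutive missing points cannot be filled defensibly
    if np.any(nan[:-1] & nan[1:]) or nan[0] or nan[-1]:
        raise GrowthError(
            f"series {label}: consecutive or terminal missing OD values"
        )
    y = y.copy()
    y[nan] = np.interp(t[nan], t[~nan], y[~nan])
    return y


def subtract_background(table: pd.DataFrame) -> list[GrowthCurve]:
    """Blank-subtract every bacterial series and average technical wells.

    Each (protein, concentration) condition is subtracted pointwise by the
    mean of its matching no-bacteria blank wells (strain == BLANK). Blanks
    recorded under the same biological replicate are preferred (each
    replicate is typically its own plate); otherwise all blanks of that
    (protein, concentration) are pooled. Isolated missing timepoints are
    linearly interpolated; consecutive ones raise. Negative subtracted
    values are retained.
    """
    blanks = table[table["strain"] == BLANK]
    cond = table[table["strain"] != BLANK]
    if cond.empty:
        raise GrowthError("growth table contains only blank wells")
    blank_mean_rep = (
        blanks.groupby(["protein", "concentration", "replicate_bio", "time"])["od600"]
        .mean()
        .rename("blank")
    )
    blank_mean = (
        blanks.groupby(["protein", "concentration", "time"])["od600"]
        .mean()
        .rename("blank")
    )
    curves: list[GrowthCurve] = []
    for (strain, protein, conc, rep), sub in cond.groupby(
        CURVE_KEY, sort=False
    ):
        try:
            bl = blank_mean_rep.loc[(protein, conc, rep)]
        except KeyError:
            try:
                bl = blank_mean.loc[(protein, conc)]
            except KeyError:
                raise GrowthError(
                    f"no matching blank wells for (protein={protein!r}, "
                    f"concentration={conc})"
                ) from None
        # average technical wells on the shared grid, then subtract
        mean_od = sub.groupby("time")["od600"].mean()
        t = mean_od.index.to_numpy()
        y = _interpolate_gaps(t, mean_od.to_numpy(), (strain, protein, conc, rep))
        bl_y = bl.reindex(mean_od.index).to_numpy()
        if np.isnan(bl_y).any():
            raise GrowthError(
                f"blank grid for (protein={protein!r}, concentration={conc}) "
                f"does not cover the condition grid"
            )
        curves.append(
            GrowthCurve(
                strain=strain,
                protein=protein,
                concentration=float(conc),
                replicate_bio=int(rep),
                times=t,
                od=y - bl_y,
            )
        )
    return curves


def auc_trapezoid(
    curve: GrowthCurve, window: tuple[float, float] = (0.0, 13.0)
) -> AUCResult:
    """Composite trapezoid AUC of a curve restricted to ``window`` (hours).

    Window endpoints must lie on the observed grid; no extrapolation or
    smoothing is applied.
    """
    t0, t1 = window
    t = curve.times
    if not (np.any(np.isclose(t, t0)) and np.any(np.isclose(t, t1))):
        raise GrowthError(
            f"window [{t0}, {t1}] h not on the observed grid "
            f"[{t[0]}, {t[-1]}]"
        )
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    auc = float(np.trapezoid(curve.od[mask], t[mask]))
    return AUCResult(
        strain=curve.strain,
        protein=curve.protein,
        concentration=curve.concentration,
        replicate_bio=curve.replicate_bio,
        auc=auc,
        window=(t0, t1),
    )


def delta_auc(treated: AUCResult, control: AUCResult) -> float:
    """AUC(treated) − AUC(control); negative values mean growth inhibition."""
    if treated.strain != control.strain:
        raise GrowthError(
            f"strain mismatch: {treated.strain!r} vs {control.strain!r}"
        )
    return treated.auc - control.auc


def dose_response(
    curves: list[GrowthCurve], window: tuple[float, float] = (0.0, 13.0)
) -> pd.DataFrame:
    """Replicate-matched ΔAUC dose-response summary.

    Each biological replicate's ΔAUC at a dose uses that same replicate's
    0 µM curve as control. Returns one row per (strain, protein,
    concentration) with mean ΔAUC, SEM (sd/√n, ddof=1; 0 when n == 1) and n,
    plus a ``per_replicate`` attribute table in ``DataFrame.attrs``.
    """
    aucs = {c.key: auc_trapezoid(c, window) for c in curves}
    rows = []
    for (strain, protein, conc, rep), res in aucs.items():
        if conc == 0:
            continue
        control = aucs.get((strain, protein, 0.0, rep))
        if control is None:
            raise GrowthError(
                f"replicate {rep} of (strain={strain!r}, protein={protein!r}) "
                f"lacks a 0 µM control curve"
            )
        rows.append(
            {
                "strain": strain,
                "protein": protein,
                "concentration": conc,
                "replicate_bio": rep,
                "delta_auc": delta_auc(res, control),
            }
        )
    if not rows:
        raise GrowthError("no non-zero concentrations found")
    per_rep = pd.DataFrame(rows)
    grouped = per_rep.groupby(["strain", "protein", "concentration"], sort=True)
    summary = grouped["delta_auc"].agg(
        mean_delta_auc="mean",
        sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
        n="count",
    ).reset_index()
    summary.attrs["per_replicate"] = per_rep
    return summary


@dataclass
class AnovaTukeyResult:
    anova_table: pd.DataFrame          # F and p per factor
    comparisons: pd.DataFrame          # all protein pairs, Tukey-adjusted
    residual_ms: float
    residual_df: float
    design: str

    def summary(self) -> str:
        lines = ["ANOVA (" + self.design + ")", self.anova_table.to_string()]
        lines += ["", "Tukey HSD on protein", self.comparisons.to_string(index=False)]
        return "\n".join(lines)


def _tukey_from_fit(
    per_rep: pd.DataFrame, mse: float, df_resid: float
) -> pd.DataFrame:
    groups = per_rep.groupby("protein")["delta_auc"]
    means = groups.mean()
    ns = groups.count()
    k = len(means)
    rows = []
    for p1, p2 in combinations(sorted(means.index), 2):
        diff = means[p1] - means[p2]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[p1] + 1.0 / ns[p2]))
        q = abs(diff) / se
        p_adj = float(studentized_range.sf(q, k, df_resid))
        rows.append(
            {
                "group1": p1,
                "group2": p2,
                "mean_diff": diff,
                "q": q,
                "p_adj": min(max(p_adj, 0.0), 1.0),
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(points: pd.DataFrame, design: str = "two-way") -> AnovaTukeyResult:
    """ANOVA on per-replicate ΔAUC with Tukey post-hoc on the protein factor.

    ``points`` needs columns strain, protein, delta_auc (one row per
    biological replicate, typically at a single dose). The default two-way
    additive design models protein + strain; ``design="one-way"`` drops the
    strain term. Tukey-Kramer comparisons use the fitted model's residual
    mean square and degrees of freedom.
    """
    for col in ("strain", "protein", "delta_auc"):
        if col not in points.columns:
            raise GrowthError(f"points table missing column {col!r}")
    if points["protein"].nunique() < 2:
        raise GrowthError("need at least 2 proteins for ANOVA")
    counts = points.groupby("protein")["delta_auc"].count()
    single = counts[counts < 2]
    if not single.empty:
        raise GrowthError(
            f"protein(s) with a single observation: {', '.join(single.index)}"
        )
    if design == "two-way":
        formula = "delta_auc ~ C(protein) + C(strain)"
    elif design == "one-way":
        formula = "delta_auc ~ C(protein)"
    else:
        raise GrowthError(f"unknown design {design!r}")
    fit = smf.ols(formula, data=points).fit()
    scale = max(1.0, float(np.mean(points["delta_auc"] ** 2)))
    if (
        fit.df_resid <= 0
        or not np.isfinite(fit.mse_resid)
        or fit.mse_resid <= 1e-12 * scale
    ):
        raise GrowthError("zero residual variance; ANOVA undefined")
    table = sm.stats.anova_lm(fit, typ=2)
    comparisons = _tukey_from_fit(points, fit.mse_resid, fit.df_resid)
    return AnovaTukeyResult(
        anova_table=table,
        comparisons=comparisons,
        residual_ms=float(fit.mse_resid),
        residual_df=float(fit.df_resid),
        design=design,
    )
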