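"""Dual-luciferase TLR4 activation analysis.

Each well carries an NF-κB-driven firefly luciferase signal (the readout) and
a constitutively expressed Renilla luciferase signal (the transfection
control). The analysis:

1. subtracts from each well's firefly signal the mean firefly signal of
   vehicle-treated wells transfected with the same receptor complex;
2. subtracts from each well's Renilla signal the mean Renilla signal of
   empty-vector wells under the same treatment;
3. takes the per-well firefly/Renilla ratio;
4. normalizes every ratio to the mean ratio of a reference condition
   (human TLR4 + endotoxin by default), so the reference group averages
   exactly 1;
5. compares groups by two-sided Welch t-tests (unequal variances,
   Welch–Satterthwaite degrees of freedom), unadjusted by default.

Wells whose background-subtracted Renilla is non-positive indicate failed
transfection and are excluded with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import VECTOR, VEHICLE

logger = logging.getLogger("calproscreen")


class ReporterError(ValueError):
    pass


def subtract_reporter_background(
    table: pd.DataFrame,
    vehicle_label: str = VEHICLE,
    vector_label: str = VECTOR,
) -> pd.DataFrame:
    """Add ``ff_bs`` and ``rn_bs`` columns (complex- and treatment-matched).

    Requires vehicle-treated wells for every complex and vector-only wells
    for every treatment.
    """
    df = table.copy()
    ff_bg = (
        df[df["treatment"] == vehicle_label]
        .groupby("complex")["firefly"]
        .mean()
    )
    rn_bg = (
        df[df["complex"] == vector_label]
        .groupby("treatment")["renilla"]
        .mean()
    )
    missing_ff = set(df["complex"]) - set(ff_bg.index)
    if missing_ff:
        raise ReporterError(
            f"no vehicle wells for complex(es): {', '.join(sorted(missing_ff))}"
        )
    missing_rn = set(df["treatment"]) - set(rn_bg.index)
    if missing_rn:
        raise ReporterError(
            f"no vector-only wells for treatment(s): {', '.join(sorted(missing_rn))}"
        )
    df["ff_bs"] = df["firefly"] - df["complex"].map(ff_bg)
    df["rn_bs"] = df["renilla"] - df["treatment"].map(rn_bg)
    return df


def normalize_activation(
    table: pd.DataFrame,
    reference_complex: str = "hTLR4",
    reference_treatment: str = "ENDOTOXIN",
    vehicle_label: str = VEHICLE,
    vector_label: str = VECTOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well normalized activation and per-group summary.

    Returns ``(wells, summary)``: wells carries ratio and normalized columns
    (vector wells and failed-Renilla wells excluded); summary has mean, SEM
    and n per (complex, treatment). The reference group's mean normalized
    value is exactly 1 by construction.
    """
    if "ff_bs" not in table.columns:
        table = subtract_reporter_background(
            table, vehicle_label=vehicle_label, vector_label=vector_label
        )
    wells = table[table["complex"] != vector_label].copy()
    bad = wells["rn_bs"] <= 0
    if bad.any():
        for _, row in wells[bad].iterrows():
            logger.warning(
                "well (%s, %s, rep %s): non-positive background-subtracted "
                "Renilla (%.3g); excluded",
                row["complex"], row["treatment"], row["replicate"], row["rn_bs"],
            )
        wells = wells[~bad]
    wells["ratio"] = wells["ff_bs"] / wells["rn_bs"]
    ref = wells[
        (wells["complex"] == reference_complex)
        & (wells["treatment"] == reference_treatment)
    ]
    if ref.empty:
        raise ReporterError(
            f"no usable reference wells for ({reference_complex}, "
            f"{reference_treatment})"
        )
    ref_mean = ref["ratio"].mean()
    if ref_mean <= 0:
        raise ReporterError(
            f"reference group mean ratio is non-positive ({ref_mean:.3g})"
        )
    wells["normalized"] = wells["ratio"] / ref_mean
    summary = (
        wells.groupby(["complex", "treatment"], sort=True)["normalized"]
        .agg(
            mean="mean",
            sem=lambda v: (v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return wells, summary


def replicate_mean_groups(wells: pd.DataFrame) -> dict[str, np.ndarray]:
    """Normalized values averaged within biological replicate, per group.

    Technical wells share a ``replicate`` label; averaging them first gives
    one value per biological replicate, the unit the Welch tests compare.
    Group keys are ``"complex|treatment"``.
    """
    means = (
        wells.groupby(["complex", "treatment", "replicate"])["normalized"]
        .mean()
        .reset_index()
    )
    return {
        f"{c}|{t}": sub["normalized"].to_numpy()
        for (c, t), sub in means.groupby(["complex", "treatment"])
    }


@dataclass(frozen=True)
class WelchResult:
    group1: str
    group2: str
    t: float
    df: float
    p: float
    p_adj: float | None = None


def welch_tests(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    holm: bool = False,
) -> list[WelchResult]:
    """Two-sided Welch t-tests for the requested group pairs.

    No multiplicity adjustment by default; ``holm=True`` adds Holm-adjusted
    p-values. Each group needs n ≥ 2 and at least one group of a pair must
    have nonzero variance.
    """
    results = []
    for g1, g2 in comparisons:
        for g in (g1, g2):
            if g not in groups:
                raise ReporterError(f"unknown group {g!r}")
            if len(groups[g]) < 2:
                raise ReporterError(f"group {g!r} has n < 2")
        x, y = np.asarray(groups[g1], float), np.asarray(groups[g2], float)
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            raise ReporterError(f"both groups {g1!r}, {g2!r} have zero variance")
        res = stats.ttest_ind(x, y, equal_var=False)
        results.append(
            WelchResult(g1, g2, float(res.statistic), float(res.df), float(res.pvalue))
        )
    if holm:
        from statsmodels.stats.multitest import multipletests

        p = [r.p for r in results]
        _, p_adj, _, _ = multipletests(p, method="holm")
        results = [
            WelchResult(r.group1, r.group2, r.t, r.df, r.p, float(pa))
            for r, pa in zip(results, p_adj)
        ]
    return results


def welch_results_frame(results: list[WelchResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
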