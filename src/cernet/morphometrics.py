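"""Two-group phenotype statistics on animal-level means.

Technical replicates (individual myofibrils, fibers, or assay repeats)
are first averaged per animal so that the biological replicate — the
animal — is the unit of analysis; the t-test n is the number of animals,
never the number of replicates. Normality (Shapiro–Wilk, per group) and
homogeneity of variances (Levene, mean-centred) are reported alongside
the pooled-variance Student t (Welch available as a variant) but no
automatic nonparametric fallback is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MeasurementTable, ValidationError

ALPHA = 0.05


@dataclass
class GroupComparison:
    """One trait's LE-vs-HE comparison with assumption checks."""

    trait: str
    n_LE: int
    n_HE: int
    mean_LE: float
    mean_HE: float
    sd_LE: float
    sd_HE: float
    shapiro_p_LE: float
    shapiro_p_HE: float
    levene_p: float
    t_stat: float
    df: float
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.n_LE < 2 or self.n_HE < 2:
            raise ValidationError(f"{self.trait}: need >= 2 animals per group")
        if self.sd_LE < 0 or self.sd_HE < 0:
            raise ValidationError(f"{self.trait}: negative standard deviation")


def animal_means(table: MeasurementTable) -> pd.DataFrame:
    """Arithmetic mean of replicate values per (animal, trait).

    Returns a DataFrame with columns (animal_id, group, trait, mean_value);
    downstream sample sizes count animals, not replicates.
    """
    agg = (
        table.data.groupby(["animal_id", "group", "trait"], sort=False)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_value"})
    )
    return agg


def levene_pvalue(values_le, values_he) -> tuple[float, float]:
    """Mean-centred Levene statistic and p-value for two groups.

    When every absolute deviation is identical in both groups the F ratio
    is 0/0; there is then no evidence of unequal spread, reported as
    (W = 0, p = 1).
    """
    le = np.asarray(values_le, dtype=float)
    he = np.asarray(values_he, dtype=float)
    with np.errstate(invalid="ignore"):
        lev = stats.levene(le, he, center="mean")
    if np.isnan(lev.statistic):
        return 0.0, 1.0
    return float(lev.statistic), float(lev.pvalue)


def assumption_checks(values_le, values_he) -> tuple[float, float, float]:
    """Shapiro–Wilk p per group and the mean-centred Levene p.

    Shapiro–Wilk needs n >= 3 per group. A constant group contributes zero
    deviations to Levene (handled by :func:`levene_pvalue`).
    """
    le = np.asarray(values_le, dtype=float)
    he = np.asarray(values_he, dtype=float)
    if len(le) < 3 or len(he) < 3:
        raise ValidationError("Shapiro–Wilk requires n >= 3 per group")
    sw_le = float(stats.shapiro(le).pvalue)
    sw_he = float(stats.shapiro(he).pvalue)
    _, lev_p = levene_pvalue(le, he)
    return sw_le, sw_he, lev_p


def two_group_t(values_le, values_he, variant: str = "student") -> tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``variant="student"`` uses the pooled variance (the default, matching a
    classical independent-samples design); ``"welch"`` drops the equal-
    variance assumption. Zero pooled variance with equal means gives
    t = 0, p = 1; with unequal means it is an error.
    """
    le = np.asarray(values_le, dtype=float)
    he = np.asarray(values_he, dtype=float)
    if len(le) < 2 or len(he) < 2:
        raise ValidationError("t-test requires n >= 2 per group")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    if le.var(ddof=1) == 0 and he.var(ddof=1) == 0:
        if le.mean() == he.mean():
            n1, n2 = len(le), len(he)
            df = n1 + n2 - 2 if variant == "student" else float(n1 + n2 - 2)
            return 0.0, float(df), 1.0
        raise ValidationError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind(le, he, equal_var=(variant == "student"))
    df = float(res.df)
    return float(res.statistic), df, float(res.pvalue)


def compare_groups(table: MeasurementTable, variant: str = "student",
                   alpha: float = ALPHA) -> list[GroupComparison]:
    """Full per-trait analysis: animal means → checks → t-test."""
    means = animal_means(table)
    out = []
    for trait in table.traits:
        sub = means[means["trait"] == trait]
        le = sub.loc[sub["group"] == "LE", "mean_value"].to_numpy()
        he = sub.loc[sub["group"] == "HE", "mean_value"].to_numpy()
        sw_le, sw_he, lev_p = assumption_checks(le, he)
        t, df, p = two_group_t(le, he, variant)
        out.append(
            GroupComparison(
                trait=trait, n_LE=len(le), n_HE=len(he),
                mean_LE=float(le.mean()), mean_HE=float(he.mean()),
                sd_LE=float(le.std(ddof=1)), sd_HE=float(he.std(ddof=1)),
                shapiro_p_LE=sw_le, shapiro_p_HE=sw_he, levene_p=lev_p,
                t_stat=t, df=df, p_value=p, significant=bool(p < alpha),
            )
        )
    return out


def comparisons_to_frame(comparisons) -> pd.DataFrame:
    cols = ["trait", "n_LE", "n_HE", "mean_LE", "mean_HE", "sd_LE", "sd_HE",
            "shapiro_p_LE", "shapiro_p_HE", "levene_p", "t_stat", "df",
            "p_value", "significant"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in comparisons], columns=cols)
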