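"""Expression filtering, fold change, FDR and threshold DE classification.

The classification step reproduces the study's two published threshold
regimes, both with strict inequalities:

* mRNA mode     — |FC| > 2 and FDR < 0.05
* lncRNA mode   — |FC| > 1.5 and raw p < 0.05

Fold changes are oriented HE over LE (high-exercise as "treatment").
The built-in per-feature test (``simple_de_test``) is a deliberately plain
Welch t on log2(TPM + c); production analyses computed with a count-based
GLM (e.g. DESeq2) can be supplied instead via ``external_stats`` tables —
the classifier only needs (log2fc, p, fdr) per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, ValidationError

#: TPM floor for calling a transcript expressed (strict: mean TPM must exceed it)
EXPRESSED_TPM_THRESHOLD = 0.01

#: pseudo-count added to TPM before ratios/logs
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class DEThresholds:
    """Fold-change and significance gates for DE classification."""

    fc_min: float
    use_fdr: bool
    alpha: float

    def __post_init__(self) -> None:
        if not self.fc_min > 1:
            raise ValidationError("fc_min must be > 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")


MRNA_THRESHOLDS = DEThresholds(fc_min=2.0, use_fdr=True, alpha=0.05)
LNCRNA_THRESHOLDS = DEThresholds(fc_min=1.5, use_fdr=False, alpha=0.05)


@dataclass
class DERecord:
    """Per-transcript DE statistics and threshold status."""

    feature_id: str
    biotype: str
    mean_tpm_LE: float
    mean_tpm_HE: float
    log2fc: float
    p_value: float
    fdr: float
    status: str  # up | down | ns

    def __post_init__(self) -> None:
        for name in ("p_value", "fdr"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{self.feature_id}: {name} outside [0, 1]")
        if self.status not in ("up", "down", "ns"):
            raise ValidationError(f"{self.feature_id}: unknown status {self.status!r}")


def counts_to_tpm(counts: ExpressionMatrix, lengths: Mapping[str, float]) -> ExpressionMatrix:
    """Convert raw counts to TPM using per-feature lengths (bp).

    TPM_i = (count_i / length_kb_i) / sum_j(count_j / length_kb_j) * 1e6,
    per sample; every column sums to 1e6.
    """
    if counts.unit_kind != "count":
        raise ValidationError("counts_to_tpm expects a count matrix")
    lens = np.array([lengths.get(f, 0.0) for f in counts.feature_ids], dtype=float)
    missing = [f for f, l in zip(counts.feature_ids, lens) if l <= 0]
    if missing:
        raise ValidationError(f"missing or non-positive length for feature(s): {missing[:5]}")
    rate = counts.values.to_numpy(dtype=float) / (lens[:, None] / 1000.0)
    totals = rate.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValidationError(f"zero total count in sample {counts.sample_ids[zero[0]]!r}")
    tpm = rate / totals * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.feature_ids, columns=counts.sample_ids),
        "tpm", dict(counts.groups),
    )


def expressed_filter(
    tpm: ExpressionMatrix,
    threshold: float = EXPRESSED_TPM_THRESHOLD,
    scope: str = "per_group",
) -> tuple[dict[str, set[str]], set[str]]:
    """Identify expressed transcripts (mean TPM strictly above the floor).

    Returns (per-group expressed sets, their intersection) — the quantities
    behind the two-group Venn counts. ``scope="overall"`` uses the pooled
    mean instead and labels both groups with the same set.
    """
    if tpm.unit_kind != "tpm":
        raise ValidationError("expressed_filter expects a TPM matrix")
    per_group: dict[str, set[str]] = {}
    if scope == "overall":
        mean = tpm.values.mean(axis=1)
        s = set(mean.index[mean > threshold])
        per_group = {"LE": set(s), "HE": set(s)}
    elif scope == "per_group":
        for g in ("LE", "HE"):
            mean = tpm.group_values(g).mean(axis=1)
            per_group[g] = set(mean.index[mean > threshold])
    else:
        raise ValidationError(f"unknown scope {scope!r}")
    return per_group, per_group["LE"] & per_group["HE"]


def simple_de_test(
    tpm: ExpressionMatrix,
    feature_subset: Optional[Sequence[str]] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Plain per-feature two-group test on TPM (a pipeline stand-in).

    log2fc = log2((mean_HE + c) / (mean_LE + c)); p from a two-sided Welch
    t-test on log2(TPM + c). Features with zero variance in both groups and
    equal means get p = 1. Returns a DataFrame indexed by feature with
    columns (mean_tpm_LE, mean_tpm_HE, log2fc, p_value).
    """
    tpm.require_replicates(2)
    feats = list(feature_subset) if feature_subset is not None else tpm.feature_ids
    sub = tpm.values.loc[feats]
    le = sub[tpm.samples_in("LE")].to_numpy(dtype=float)
    he = sub[tpm.samples_in("HE")].to_numpy(dtype=float)
    mean_le, mean_he = le.mean(axis=1), he.mean(axis=1)
    log2fc = np.log2((mean_he + pseudocount) / (mean_le + pseudocount))
    log_le = np.log2(le + pseudocount)
    log_he = np.log2(he + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(log_he, log_le, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = (log_le.std(axis=1) == 0) & (log_he.std(axis=1) == 0)
    p[degenerate & (log_le.mean(axis=1) == log_he.mean(axis=1))] = 1.0
    if np.isnan(p).any():
        raise ValidationError("degenerate feature with zero variance but unequal means")
    return pd.DataFrame(
        {"mean_tpm_LE": mean_le, "mean_tpm_HE": mean_he, "log2fc": log2fc, "p_value": p},
        index=pd.Index(feats, name="feature_id"),
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def classify_de(
    stats_table: pd.DataFrame,
    thresholds: DEThresholds,
    biotype: str = "mRNA",
) -> list[DERecord]:
    """Apply the threshold gates to per-feature statistics.

    ``stats_table`` is indexed by feature id with columns log2fc, p_value
    and (if absent) fdr computed here by BH across the table. Status:
    up if log2fc > log2(fc_min) and the gated significance < alpha;
    down for the mirrored fold change; ns otherwise. All strict.
    """
    tab = stats_table.copy()
    if "fdr" not in tab.columns:
        tab["fdr"] = bh_fdr(tab["p_value"].to_numpy())
    lfc_min = np.log2(thresholds.fc_min)
    records = []
    for fid, row in tab.iterrows():
        sig = (row["fdr"] if thresholds.use_fdr else row["p_value"]) < thresholds.alpha
        if sig and row["log2fc"] > lfc_min:
            status = "up"
        elif sig and row["log2fc"] < -lfc_min:
            status = "down"
        else:
            status = "ns"
        records.append(
            DERecord(
                feature_id=str(fid), biotype=biotype,
                mean_tpm_LE=float(row.get("mean_tpm_LE", np.nan)),
                mean_tpm_HE=float(row.get("mean_tpm_HE", np.nan)),
                log2fc=float(row["log2fc"]), p_value=float(row["p_value"]),
                fdr=float(row["fdr"]), status=status,
            )
        )
    return records


def de_counts(records: Sequence[DERecord]) -> dict[str, int]:
    return {
        "n_up": sum(r.status == "up" for r in records),
        "n_down": sum(r.status == "down" for r in records),
        "n_ns": sum(r.status == "ns" for r in records),
    }


def audit_de(records: Sequence[DERecord], thresholds: DEThresholds) -> None:
    """Recompute every record's status from its own statistics; raise on mismatch."""
    lfc_min = np.log2(thresholds.fc_min)
    for r in records:
        sig = (r.fdr if thresholds.use_fdr else r.p_value) < thresholds.alpha
        expect = "up" if (sig and r.log2fc > lfc_min) else (
            "down" if (sig and r.log2fc < -lfc_min) else "ns")
        if r.status != expect:
            raise ValidationError(
                f"{r.feature_id}: status {r.status!r} inconsistent with thresholds "
                f"(expected {expect!r})"
            )


def de_records_to_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    cols = ["feature_id", "biotype", "mean_tpm_LE", "mean_tpm_HE",
            "log2fc", "p_value", "fdr", "status"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def read_external_stats(path) -> pd.DataFrame:
    """Read an externally computed (feature_id, log2fc, p_value[, fdr]) TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str}).set_index("feature_id")
    required = {"log2fc", "p_value"}
    if not required.issubset(df.columns):
        raise ValidationError(f"external stats table needs columns {sorted(required)}")
    return df
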