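"""The ceRNA screen as a model/results pair.

``CeRNAScreen`` holds the three expression matrices, the candidate pair
lists and the screening thresholds; ``fit()`` runs the two negative
Spearman screens, derives the (lncRNA, mRNA) closure candidates, runs the
positive Pearson screen on them, and assembles triplets. The returned
``CeRNAScreenResults`` carries every computed edge (passed or not), the
triplet list, summary statistics, exporters and a ground-truth scorer.

Correlations pool the LE and HE samples. When ``log_transform`` is on
(default), Pearson is computed on log2(x + 1) — rank-based Spearman is
unaffected, and log-scale co-expression avoids the instability of raw
abundance correlations under heavy-tailed expression at small n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import correlation as corr
from .correlation import CorrelationEdge, EDGE_ALPHA, R_MIN, RHO_MAX, passed_edges
from .io import ExpressionMatrix, ValidationError, write_network
from .network import (
    CeRNATriplet,
    assemble_triplets,
    audit_triplets,
    cerna_pairs,
    network_summary,
    triplets_to_frame,
    write_triplets,
)
from .simulate import PlantedTruth, truth_confusion


def _log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(np.log2(m.values + 1.0), m.unit_kind, dict(m.groups))


@dataclass
class CeRNAScreen:
    """Sign-constrained correlation screen over three expression layers.

    Parameters
    ----------
    lnc, mir, mrna : ExpressionMatrix
        Abundance tables (typically TPM of the differentially expressed
        transcripts) over an identical ordered sample set.
    lnc_mir_candidates, mir_mrna_candidates : optional pair sets
        Predicted targeting pairs to restrict the negative screens
        (all-vs-all when omitted).
    rho_max, alpha : float
        Spearman gates for the repressive layers (strict).
    r_min : float
        Pearson gate for the lncRNA-mRNA layer (strict; no p gate).
    log_transform : bool
        Compute Pearson on log2(x + 1).
    """

    lnc: ExpressionMatrix
    mir: ExpressionMatrix
    mrna: ExpressionMatrix
    lnc_mir_candidates: Optional[Iterable[tuple[str, str]]] = None
    mir_mrna_candidates: Optional[Iterable[tuple[str, str]]] = None
    rho_max: float = RHO_MAX
    alpha: float = EDGE_ALPHA
    r_min: float = R_MIN
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.lnc.sample_ids != self.mir.sample_ids or self.mir.sample_ids != self.mrna.sample_ids:
            raise ValidationError("the three matrices must share one ordered sample set")
        overlap = (set(self.lnc.feature_ids) & set(self.mir.feature_ids)) | \
                  (set(self.mir.feature_ids) & set(self.mrna.feature_ids)) | \
                  (set(self.lnc.feature_ids) & set(self.mrna.feature_ids))
        if overlap:
            raise ValidationError(f"feature id(s) present in more than one layer: {sorted(overlap)[:5]}")

    def fit(self) -> "CeRNAScreenResults":
        lnc_mir = corr.screen_negative_pairs(
            self.lnc, self.mir, self.lnc_mir_candidates,
            self.rho_max, self.alpha, layer_pair="lnc_mir")
        mir_mrna = corr.screen_negative_pairs(
            self.mir, self.mrna, self.mir_mrna_candidates,
            self.rho_max, self.alpha, layer_pair="mir_mrna")

        # closure candidates: (L, G) sharing at least one passing miRNA
        by_mir_l: dict[str, set[str]] = {}
        for e in passed_edges(lnc_mir):
            by_mir_l.setdefault(e.id_b, set()).add(e.id_a)
        closure: set[tuple[str, str]] = set()
        for e in passed_edges(mir_mrna):
            for L in by_mir_l.get(e.id_a, ()):
                closure.add((L, e.id_b))

        pos_lnc = _log2p1(self.lnc) if self.log_transform else self.lnc
        pos_mrna = _log2p1(self.mrna) if self.log_transform else self.mrna
        lnc_mrna = corr.screen_positive_pairs(pos_lnc, pos_mrna, closure, self.r_min)

        triplets = assemble_triplets(
            passed_edges(lnc_mir), passed_edges(mir_mrna), passed_edges(lnc_mrna))
        audit_triplets(triplets, self.rho_max, self.alpha, self.r_min)
        return CeRNAScreenResults(
            model=self, lnc_mir_edges=lnc_mir, mir_mrna_edges=mir_mrna,
            lnc_mrna_edges=lnc_mrna, triplets=triplets)


@dataclass
class CeRNAScreenResults:
    """Fitted screen: every computed edge, the triplet network, summaries."""

    model: CeRNAScreen = field(repr=False)
    lnc_mir_edges: list[CorrelationEdge]
    mir_mrna_edges: list[CorrelationEdge]
    lnc_mrna_edges: list[CorrelationEdge]
    triplets: list[CeRNATriplet]

    # -- summaries --------------------------------------------------------
    def counts(self) -> dict[str, int]:
        return {
            "lnc_mir_pairs": len(passed_edges(self.lnc_mir_edges)),
            "mir_mrna_pairs": len(passed_edges(self.mir_mrna_edges)),
            "lnc_mrna_pairs": len(passed_edges(self.lnc_mrna_edges)),
            "triplets": len(self.triplets),
            "cerna_pairs": len(cerna_pairs(self.triplets)),
        }

    def network_summary(self) -> dict:
        return network_summary(self.triplets)

    def summary(self) -> str:
        c = self.counts()
        m = self.model
        lines = [
            "ceRNA screen results",
            "====================",
            f"samples (pooled LE+HE):      {len(m.lnc.sample_ids)}",
            f"features (lnc/mir/mrna):     {len(m.lnc.feature_ids)}/"
            f"{len(m.mir.feature_ids)}/{len(m.mrna.feature_ids)}",
            f"gates: SCC < {m.rho_max}, p < {m.alpha}; PCC > {m.r_min}",
            f"lncRNA-miRNA pairs passing:  {c['lnc_mir_pairs']} of {len(self.lnc_mir_edges)} screened",
            f"miRNA-mRNA pairs passing:    {c['mir_mrna_pairs']} of {len(self.mir_mrna_edges)} screened",
            f"lncRNA-mRNA pairs passing:   {c['lnc_mrna_pairs']} of {len(self.lnc_mrna_edges)} screened",
            f"ceRNA triplets:              {c['triplets']}",
            f"distinct ceRNA (L, G) pairs: {c['cerna_pairs']}",
        ]
        return "\n".join(lines)

    # -- scoring & export -------------------------------------------------
    def score(self, truth: PlantedTruth) -> tuple[float, int]:
        """(recall of planted triplets, count of non-planted triplets)."""
        return truth_confusion(self.triplets, truth)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"id_a": e.id_a, "id_b": e.id_b, "layer_pair": e.layer_pair,
             "method": e.method, "coefficient": e.coefficient,
             "p_value": e.p_value, "passed": e.passed}
            for e in (*self.lnc_mir_edges, *self.mir_mrna_edges, *self.lnc_mrna_edges)
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "layer_pair", "method",
                                           "coefficient", "p_value", "passed"])

    def triplets_frame(self) -> pd.DataFrame:
        return triplets_to_frame(self.triplets)

    def export(self, edge_path, sankey_path, triplet_path=None) -> None:
        write_network(self.triplets, edge_path, sankey_path)
        if triplet_path is not None:
            write_triplets(self.triplets, triplet_path)


def screen_bundle(bundle, **kwargs) -> CeRNAScreenResults:
    """Screen a synthetic bundle's abundances with its candidate whitelists.

    The generated count matrices are screened directly: the simulator
    draws every sample at the same depth, so the counts already are
    depth-normalized abundances. Re-normalizing to TPM over a universe of
    only a few hundred synthetic features would let the planted features'
    swings dominate the per-sample normalizer and leak spurious
    correlated variation into every decoy — an artifact a
    transcriptome-wide TPM normalization (where the planted features are
    a vanishing fraction of the library) does not have.
    """
    screen = CeRNAScreen(
        bundle.lnc, bundle.mir, bundle.mrna,
        lnc_mir_candidates=bundle.lnc_mir_candidates,
        mir_mrna_candidates=bundle.mir_mrna_candidates,
        **kwargs,
    )
    return screen.fit()
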