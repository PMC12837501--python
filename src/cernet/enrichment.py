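"""Over-representation analysis via the one-sided Fisher exact test.

For each term with K annotated genes in a universe of N, and a DE set of
n genes of which k are annotated, the p-value is the hypergeometric upper
tail P(X >= k). BH-adjusted values are reported alongside, but the
significance flag follows the raw p < 0.05 gate. The enrichment universe
is supplied by the caller (by default the expressed-transcript set of the
relevant biotype, TPM > 0.01 in both groups).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io import TermAnnotation, ValidationError


@dataclass
class EnrichmentResult:
    """One term's 2×2 contingency summary and test outcome."""

    term_id: str
    term_name: str
    k: int  # DE ∩ term
    K: int  # term size within universe
    n: int  # DE size within universe
    N: int  # universe size
    p_value: float
    fdr: float
    fold_enrichment: float
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValidationError(
                f"term {self.term_id}: inconsistent counts k={self.k} K={self.K} "
                f"n={self.n} N={self.N}"
            )


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    de_set: Iterable[str],
    annotations: Sequence[TermAnnotation],
    universe: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided Fisher enrichment of ``de_set`` against each term.

    ``de_set`` must be contained in ``universe``; term member sets are
    clipped to the universe. Results are sorted by ascending p (ties by
    term id), with BH fdr computed across the tested terms.
    """
    de = set(de_set)
    uni = set(universe)
    outside = de - uni
    if outside:
        raise ValidationError(f"DE feature(s) outside the universe: {sorted(outside)[:5]}")
    n, N = len(de), len(uni)
    rows = []
    for term in annotations:
        members = term.member_ids & uni
        if not members:
            continue
        K = len(members)
        k = len(de & members)
        p = hypergeom_upper_tail(k, N, K, n)
        fe = (k / n) / (K / N) if n > 0 else float("nan")
        rows.append((term, k, K, p, fe))
    fdrs = bh_fdr([r[3] for r in rows]) if rows else []
    results = [
        EnrichmentResult(
            term_id=term.term_id, term_name=term.term_name,
            k=k, K=K, n=n, N=N, p_value=p, fdr=float(q),
            fold_enrichment=fe, significant=bool(p < alpha),
        )
        for (term, k, K, p, fe), q in zip(rows, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "fdr",
            "fold_enrichment", "significant"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
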