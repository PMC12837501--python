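"""Triplet assembly and network summaries.

A ceRNA triplet (L, m, G) is emitted when three screened edges close:
L-m negative, m-G negative, and L-G positive. The assembly is an index
join — hash on the shared miRNA, then look up the (L, G) positive edge —
which scales to the edge counts a transcriptome-wide screen produces. A
brute-force enumeration over all L × m × G combinations is kept in the
test suite as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import pandas as pd

from .correlation import CorrelationEdge, EDGE_ALPHA, R_MIN, RHO_MAX
from .io import ValidationError


@dataclass
class CeRNATriplet:
    """One (lncRNA, miRNA, mRNA) axis with its three supporting statistics."""

    lnc_id: str
    mir_id: str
    mrna_id: str
    scc_lnc_mir: float
    p_lnc_mir: float
    scc_mir_mrna: float
    p_mir_mrna: float
    pcc_lnc_mrna: float

    def ids(self) -> tuple[str, str, str]:
        return (self.lnc_id, self.mir_id, self.mrna_id)

    def satisfies_thresholds(self, rho_max: float = RHO_MAX, alpha: float = EDGE_ALPHA,
                             r_min: float = R_MIN) -> bool:
        """All five stored statistics clear the (strict) screening gates."""
        return (
            self.scc_lnc_mir < rho_max
            and self.p_lnc_mir < alpha
            and self.scc_mir_mrna < rho_max
            and self.p_mir_mrna < alpha
            and self.pcc_lnc_mrna > r_min
        )


def audit_triplets(triplets: Sequence[CeRNATriplet], rho_max: float = RHO_MAX,
                   alpha: float = EDGE_ALPHA, r_min: float = R_MIN) -> None:
    """Raise if any stored triplet fails its own screening thresholds."""
    for t in triplets:
        if not t.satisfies_thresholds(rho_max, alpha, r_min):
            raise ValidationError(f"triplet {t.ids()} violates its screening thresholds")


def assemble_triplets(
    lnc_mir_edges: Sequence[CorrelationEdge],
    mir_mrna_edges: Sequence[CorrelationEdge],
    lnc_mrna_edges: Sequence[CorrelationEdge],
) -> list[CeRNATriplet]:
    """Join passed edges from the three layers into ceRNA triplets.

    Inputs must contain only passed edges (an unpassed edge is an audit
    failure and raises). Output is in lexicographic (lnc, mir, mrna) order.
    """
    for edges, name in ((lnc_mir_edges, "lnc_mir"), (mir_mrna_edges, "mir_mrna"),
                        (lnc_mrna_edges, "lnc_mrna")):
        for e in edges:
            if not e.passed:
                raise ValidationError(f"unpassed edge ({e.id_a}, {e.id_b}) in {name} input")

    by_mir_lnc: dict[str, list[CorrelationEdge]] = {}
    for e in lnc_mir_edges:
        by_mir_lnc.setdefault(e.id_b, []).append(e)
    by_mir_mrna: dict[str, list[CorrelationEdge]] = {}
    for e in mir_mrna_edges:
        by_mir_mrna.setdefault(e.id_a, []).append(e)
    pos = {(e.id_a, e.id_b): e for e in lnc_mrna_edges}

    out: list[CeRNATriplet] = []
    for mir, lnc_edges in by_mir_lnc.items():
        for le in lnc_edges:
            for ge in by_mir_mrna.get(mir, ()):  # edges m -> G
                pe = pos.get((le.id_a, ge.id_b))
                if pe is not None:
                    out.append(
                        CeRNATriplet(
                            lnc_id=le.id_a, mir_id=mir, mrna_id=ge.id_b,
                            scc_lnc_mir=le.coefficient, p_lnc_mir=le.p_value,
                            scc_mir_mrna=ge.coefficient, p_mir_mrna=ge.p_value,
                            pcc_lnc_mrna=pe.coefficient,
                        )
                    )
    out.sort(key=lambda t: t.ids())
    return out


def cerna_pairs(triplets: Sequence[CeRNATriplet]) -> set[tuple[str, str]]:
    """Distinct (lncRNA, mRNA) pairs supported by at least one triplet."""
    return {(t.lnc_id, t.mrna_id) for t in triplets}


def network_summary(triplets: Sequence[CeRNATriplet]) -> dict:
    """Node degrees, layer counts, ceRNA-pair count and component count.

    Degree of a node = number of triplets containing it. Components are
    counted on the union graph of all triplet edges.
    """
    degree: dict[str, int] = {}
    g = nx.Graph()
    lncs, mirs, mrnas = set(), set(), set()
    for t in triplets:
        lncs.add(t.lnc_id)
        mirs.add(t.mir_id)
        mrnas.add(t.mrna_id)
        for node in t.ids():
            degree[node] = degree.get(node, 0) + 1
        g.add_edge(t.lnc_id, t.mir_id)
        g.add_edge(t.mir_id, t.mrna_id)
        g.add_edge(t.lnc_id, t.mrna_id)
    return {
        "n_triplets": len(triplets),
        "n_lncRNA": len(lncs),
        "n_miRNA": len(mirs),
        "n_mRNA": len(mrnas),
        "n_cerna_pairs": len(cerna_pairs(triplets)),
        "n_components": nx.number_connected_components(g),
        "degree": dict(sorted(degree.items())),
    }


def triplets_to_frame(triplets: Sequence[CeRNATriplet]) -> pd.DataFrame:
    cols = ["lnc_id", "mir_id", "mrna_id", "scc_lnc_mir", "p_lnc_mir",
            "scc_mir_mrna", "p_mir_mrna", "pcc_lnc_mrna"]
    return pd.DataFrame([{c: getattr(t, c) for c in cols} for t in triplets], columns=cols)


def write_triplets(triplets: Sequence[CeRNATriplet], path) -> None:
    triplets_to_frame(triplets).to_csv(path, sep="\t", index=False, float_format="%.6g")
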