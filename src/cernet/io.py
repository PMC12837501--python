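"""Tabular readers/writers and the shared domain types.

Everything downstream operates on a small set of validated containers:

* :class:`ExpressionMatrix` — a transcripts × samples abundance table
  (raw counts or TPM) with an LE/HE group label per sample.
* :class:`TranscriptRecord` — identity, biotype, structure and per-tool
  coding-potential verdicts for one transcript.
* :class:`MeasurementTable` — long-form morphometric replicate measurements
  (animal, group, trait, value).
* :class:`TermAnnotation` — one annotation term (GO/KEGG-style) with its
  member gene set.

All files are plain TSV, UTF-8, "." decimal mark, no quoting dialects;
malformed input fails loudly rather than being coerced.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cernet")

GROUPS = ("LE", "HE")
BIOTYPES = ("mRNA", "lncRNA", "miRNA", "novel")
VERDICTS = ("coding", "noncoding", "unknown")

#: layer label of each edge type in the exported network
EDGE_TYPE_LABELS = {
    "lnc_mir": "lncRNA-miRNA",
    "mir_mrna": "miRNA-mRNA",
    "lnc_mrna": "lncRNA-mRNA",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Transcripts × samples abundance table with group labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Features in rows (index = feature ids), samples in columns.
        All entries must be finite and >= 0.
    unit_kind : {"count", "tpm"}
    groups : mapping of sample id -> {"LE", "HE"}
        Must cover every sample column.
    """

    values: pd.DataFrame
    unit_kind: str
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.unit_kind not in ("count", "tpm"):
            raise ValidationError(f"unit_kind must be 'count' or 'tpm', got {self.unit_kind!r}")
        _check_unique(list(self.values.index), "feature")
        _check_unique(list(self.values.columns), "sample")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if arr.size and (not np.all(np.isfinite(arr)) or (arr < 0).any()):
            bad = np.argwhere(~np.isfinite(arr) | (arr < 0))[0]
            raise ValidationError(
                f"negative or non-finite value at feature {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        for s in self.values.columns:
            if s not in self.groups:
                raise ValidationError(f"sample {s!r} has no group label")
            if self.groups[s] not in GROUPS:
                raise ValidationError(f"sample {s!r}: unknown group {self.groups[s]!r}")

    # -- convenience ------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [f for f in self.feature_ids if f in set(feature_ids)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.unit_kind, dict(self.groups))

    def require_replicates(self, n_min: int = 2) -> None:
        """Statistical stages need at least ``n_min`` samples per group."""
        for g in GROUPS:
            if len(self.samples_in(g)) < n_min:
                raise ValidationError(f"group {g} has fewer than {n_min} samples")


def read_expression_matrix(path: str | Path, unit_kind: str, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column = feature ids).

    Row/column order is preserved from the file. Duplicate ids, negative or
    non-numeric cells, and samples missing from ``groups`` are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(list(df.index), "feature")
    _check_unique(list(df.columns), "sample")
    try:
        num = df.astype(float)
    except ValueError as exc:
        # locate the offending cell for the error message
        for i, fid in enumerate(df.index):
            for j, sid in enumerate(df.columns):
                try:
                    float(df.iat[i, j])
                except ValueError:
                    raise ValidationError(
                        f"non-numeric cell at feature {fid!r}, sample {sid!r} in {path}"
                    ) from exc
        raise
    return ExpressionMatrix(num, unit_kind, {s: groups[s] for s in num.columns} if all(
        s in groups for s in num.columns
    ) else _missing_group(num.columns, groups))


def _missing_group(samples: Iterable[str], groups: Mapping[str, str]) -> dict[str, str]:
    missing = [s for s in samples if s not in groups]
    raise ValidationError(f"samples missing from group map: {missing}")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) TSV into a group map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["group"]))


def write_group_table(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript records
# ---------------------------------------------------------------------------

@dataclass
class TranscriptRecord:
    """One transcript: identity, structure, and coding-potential verdicts.

    ``coding_verdicts`` maps a tool name (e.g. "CPC2") to one of
    "coding"/"noncoding"/"unknown"; it may be empty only for transcripts
    that are not novel.
    """

    id: str
    biotype: str
    length_bp: int
    exon_count: int
    coding_verdicts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.length_bp < 1:
            raise ValidationError(f"{self.id}: length_bp must be >= 1")
        if self.exon_count < 1:
            raise ValidationError(f"{self.id}: exon_count must be >= 1")
        for tool, v in self.coding_verdicts.items():
            if v not in VERDICTS:
                raise ValidationError(f"{self.id}: tool {tool!r} has unknown verdict {v!r}")
        if not self.coding_verdicts and self.biotype == "novel":
            raise ValidationError(f"{self.id}: novel transcript lacks coding-potential verdicts")


def _verdicts_to_str(verdicts: Mapping[str, str]) -> str:
    return ";".join(f"{t}={verdicts[t]}" for t in sorted(verdicts))


def _verdicts_from_str(s: str) -> dict[str, str]:
    if not s or s == ".":
        return {}
    out = {}
    for part in s.split(";"):
        tool, _, verdict = part.partition("=")
        out[tool] = verdict
    return out


def write_transcript_records(records: Sequence[TranscriptRecord], path: str | Path) -> None:
    rows = [
        {
            "id": r.id,
            "biotype": r.biotype,
            "length_bp": r.length_bp,
            "exon_count": r.exon_count,
            "coding_verdicts": _verdicts_to_str(r.coding_verdicts) or ".",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["id", "biotype", "length_bp", "exon_count", "coding_verdicts"]).to_csv(
        path, sep="\t", index=False
    )


def read_transcript_records(path: str | Path) -> list[TranscriptRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "coding_verdicts": str})
    records = [
        TranscriptRecord(
            id=row.id,
            biotype=row.biotype,
            length_bp=int(row.length_bp),
            exon_count=int(row.exon_count),
            coding_verdicts=_verdicts_from_str(row.coding_verdicts if isinstance(row.coding_verdicts, str) else ""),
        )
        for row in df.itertuples()
    ]
    _check_unique([r.id for r in records], "transcript")
    return records


# ---------------------------------------------------------------------------
# morphometric measurements
# ---------------------------------------------------------------------------

@dataclass
class MeasurementTable:
    """Long-form morphometric replicate table.

    One row per technical replicate: (animal_id, group, trait, value).
    Each animal belongs to exactly one group, and each (animal, trait)
    combination must have at least one replicate.
    """

    data: pd.DataFrame  # columns: animal_id, group, trait, value

    def __post_init__(self) -> None:
        required = {"animal_id", "group", "trait", "value"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"measurement table needs columns {sorted(required)}")
        bad = set(self.data["group"]) - set(GROUPS)
        if bad:
            raise ValidationError(f"unknown groups in measurement table: {sorted(bad)}")
        grp = self.data.groupby("animal_id")["group"].nunique()
        multi = grp[grp > 1]
        if len(multi):
            raise ValidationError(f"animal(s) assigned to multiple groups: {list(multi.index)}")
        if not np.isfinite(self.data["value"].to_numpy(dtype=float)).all():
            raise ValidationError("non-finite measurement value")

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data["trait"]))

    def group_of_animal(self) -> dict[str, str]:
        return dict(self.data.drop_duplicates("animal_id")[["animal_id", "group"]].values)


def read_measurement_table(path: str | Path) -> MeasurementTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "group": str, "trait": str})
    df["value"] = df["value"].astype(float)
    return MeasurementTable(df)


def write_measurement_table(table: MeasurementTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# term annotations
# ---------------------------------------------------------------------------

@dataclass
class TermAnnotation:
    """A single annotation term and its member feature ids."""

    term_id: str
    term_name: str
    member_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValidationError(f"term {self.term_id}: empty member set")


def read_term_annotations(path: str | Path) -> list[TermAnnotation]:
    """Read a (term_id, term_name, member_id) long-form TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for (tid, tname), sub in df.groupby(["term_id", "term_name"], sort=False):
        out.append(TermAnnotation(tid, tname, frozenset(sub["member_id"])))
    return out


def write_term_annotations(terms: Sequence[TermAnnotation], path: str | Path) -> None:
    rows = [
        {"term_id": t.term_id, "term_name": t.term_name, "member_id": m}
        for t in terms
        for m in sorted(t.member_ids)
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "member_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(triplets: Sequence, edge_path: str | Path, sankey_path: str | Path) -> None:
    """Export a triplet list as a deduplicated edge TSV plus a Sankey JSON.

    The edge list has one row per distinct edge, ordered lexicographically by
    (edge_type, source, target). The Sankey document has layered nodes
    (lncRNA / miRNA / mRNA) and links whose ``value`` is the number of
    triplets supporting that link. An empty triplet list still produces both
    files (header only / empty arrays) with a logged warning.
    """
    if not triplets:
        logger.warning("write_network called with an empty triplet list")

    # deduplicate edges; keep the supporting statistic of the first occurrence
    # (identical by construction: one statistic per screened pair)
    edges: dict[tuple[str, str, str], tuple[float, float | None]] = {}
    support: dict[tuple[str, str, str], int] = {}
    nodes: dict[str, str] = {}
    for t in triplets:
        nodes[t.lnc_id] = "lncRNA"
        nodes[t.mir_id] = "miRNA"
        nodes[t.mrna_id] = "mRNA"
        for key, stat, p in (
            (("lncRNA-miRNA", t.lnc_id, t.mir_id), t.scc_lnc_mir, t.p_lnc_mir),
            (("miRNA-mRNA", t.mir_id, t.mrna_id), t.scc_mir_mrna, t.p_mir_mrna),
            (("lncRNA-mRNA", t.lnc_id, t.mrna_id), t.pcc_lnc_mrna, None),
        ):
            edges.setdefault(key, (stat, p))
        for link in ((t.lnc_id, t.mir_id), (t.mir_id, t.mrna_id)):
            support[("link",) + link] = support.get(("link",) + link, 0) + 1

    edge_rows = [
        {
            "source": src,
            "target": tgt,
            "edge_type": etype,
            "statistic": f"{stat:.6g}",
            "p": "NA" if p is None else f"{p:.6g}",
        }
        for (etype, src, tgt), (stat, p) in sorted(edges.items())
    ]
    pd.DataFrame(edge_rows, columns=["source", "target", "edge_type", "statistic", "p"]).to_csv(
        edge_path, sep="\t", index=False
    )

    layer_order = {"lncRNA": 0, "miRNA": 1, "mRNA": 2}
    sankey = {
        "nodes": [
            {"id": nid, "layer": layer}
            for nid, layer in sorted(nodes.items(), key=lambda kv: (layer_order[kv[1]], kv[0]))
        ],
        "links": [
            {"source": src, "target": tgt, "value": n}
            for (_, src, tgt), n in sorted(support.items())
        ],
    }
    Path(sankey_path).write_text(json.dumps(sankey, indent=2) + "\n", encoding="utf-8")


def read_pair_whitelist(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column (id_a, id_b) candidate-pair TSV (e.g. predicted targets)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return set(map(tuple, df[cols].itertuples(index=False, name=None)))


def write_pair_whitelist(pairs: Iterable[tuple[str, str]], path: str | Path,
                         columns: tuple[str, str] = ("id_a", "id_b")) -> None:
    pd.DataFrame(sorted(pairs), columns=list(columns)).to_csv(path, sep="\t", index=False)
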