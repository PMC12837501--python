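"""Structural and coding-potential consensus filters for novel lncRNAs.

A candidate survives when it is at least 200 bp long with two or more
exons, and when every required coding-potential tool (CPC2 / CNCI / FEELnc
by default — the names are arbitrary, the tools themselves run upstream)
called it noncoding. An "unknown" verdict does not count as noncoding:
the consensus demands a positive noncoding call from every tool.
Both filters are row-wise predicates, so their composition is
order-independent and adding tools can only shrink the output.
"""

from __future__ import annotations

from typing import Sequence

from .io import TranscriptRecord, ValidationError

DEFAULT_REQUIRED_TOOLS = frozenset({"CPC2", "CNCI", "FEELnc"})

MIN_LNC_LENGTH_BP = 200
MIN_LNC_EXONS = 2


def structural_filter(
    records: Sequence[TranscriptRecord],
    min_len: int = MIN_LNC_LENGTH_BP,
    min_exons: int = MIN_LNC_EXONS,
) -> list[TranscriptRecord]:
    """Keep transcripts with length >= min_len and exon count >= min_exons.

    Both bounds are inclusive; input order is preserved.
    """
    if not records:
        raise ValidationError("structural_filter: empty record list")
    return [r for r in records if r.length_bp >= min_len and r.exon_count >= min_exons]


def coding_consensus(
    records: Sequence[TranscriptRecord],
    required_tools: frozenset[str] | set[str] = DEFAULT_REQUIRED_TOOLS,
) -> list[TranscriptRecord]:
    """Keep transcripts called noncoding by ALL required tools.

    A missing verdict for a required tool is a hard error (the record
    cannot be adjudicated); order is preserved.
    """
    if not records:
        raise ValidationError("coding_consensus: empty record list")
    out = []
    for r in records:
        for tool in sorted(required_tools):
            if tool not in r.coding_verdicts:
                raise ValidationError(f"transcript {r.id!r}: missing verdict for tool {tool!r}")
        if all(r.coding_verdicts[t] == "noncoding" for t in required_tools):
            out.append(r)
    return out


def identify_lncrnas(
    records: Sequence[TranscriptRecord],
    min_len: int = MIN_LNC_LENGTH_BP,
    min_exons: int = MIN_LNC_EXONS,
    required_tools: frozenset[str] | set[str] = DEFAULT_REQUIRED_TOOLS,
) -> list[TranscriptRecord]:
    """Structural filter followed by the coding-potential consensus."""
    kept = structural_filter(records, min_len, min_exons)
    if not kept:
        return []
    return coding_consensus(kept, required_tools)
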