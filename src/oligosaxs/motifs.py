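"""Sequence-motif scanning for the SMN YG-domain signatures.

Two overlapping C-terminal elements govern SMN self-association: the
glycine-zipper YG-box, YxxGYxxGYxxG, whose glycines allow tight
helix–helix packing, and the serine-motif, SxxxSWxxSxxxT, which lines
the anti-parallel stacking interface.  Species variants replace
individual anchor residues (S. pombe carries K at the first and A at
the third serine position; D. melanogaster A at the second), so the
scanner supports a canonical pattern, per-species relaxations, and
their union.  All matches, including overlapping ones, are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

__all__ = [
    "MotifHit",
    "SequenceError",
    "scan_yg_box",
    "scan_serine_motif",
    "scan_fasta",
    "YG_BOX_LENGTH",
    "SERINE_MOTIF_LENGTH",
]

YG_BOX_LENGTH = 12
SERINE_MOTIF_LENGTH = 13

#: residues accepted in input sequences ('X' = unknown is tolerated)
_ALLOWED = set("ACDEFGHIKLMNPQRSTVWYXBZ")
_GAP_CHARS = "-."


class SequenceError(ValueError):
    """A sequence contains characters outside the amino-acid alphabet."""


@dataclass(frozen=True)
class MotifHit:
    """One motif match.

    ``start`` is 1-based in the ungapped sequence; ``aln_start`` maps
    back to the 1-based alignment column when the input carried gaps.
    """

    motif_name: str  # "yg_box" | "serine_motif"
    start: int
    matched_span: str
    variant: str  # "canonical" | "degenerate"
    aln_start: int | None = None


def _prepare(seq: str) -> tuple[str, list[int]]:
    """Uppercase, strip gaps, validate; return (sequence, column map)."""
    raw = seq.upper()
    stripped = []
    columns = []
    bad = set()
    for col, ch in enumerate(raw, start=1):
        if ch in _GAP_CHARS or ch.isspace():
            continue
        if ch not in _ALLOWED:
            bad.add(ch)
        stripped.append(ch)
        columns.append(col)
    if bad:
        raise SequenceError(
            f"non-standard residue character(s): {', '.join(sorted(bad))}"
        )
    return "".join(stripped), columns


def _scan(
    seq: str,
    pattern: str,
    canonical_pattern: str,
    motif_name: str,
) -> list[MotifHit]:
    clean, columns = _prepare(seq)
    gapped = len(columns) and columns[-1] != len(columns)
    canon = re.compile(canonical_pattern)
    hits = []
    for m in re.finditer(f"(?=({pattern}))", clean):
        span = m.group(1)
        hits.append(
            MotifHit(
                motif_name=motif_name,
                start=m.start() + 1,
                matched_span=span,
                variant="canonical" if canon.fullmatch(span) else "degenerate",
                aln_start=columns[m.start()] if gapped else None,
            )
        )
    return hits


def scan_yg_box(seq: str, degenerate: bool = False) -> list[MotifHit]:
    """Find YxxGYxxGYxxG matches (all, including overlapping).

    ``degenerate`` additionally allows F/L at the tyrosine positions
    and A/S at the glycine positions — a documented relaxation for
    divergent orthologs, not part of the canonical definition.
    """
    canonical = "Y..G" * 3
    pattern = "[YFL]..[GAS]" * 3 if degenerate else canonical
    return _scan(seq, pattern, canonical, "yg_box")


_SERINE_PATTERNS = {
    # anchor positions: 1, 5, 9, 13 of SxxxSWxxSxxxT
    "canonical": "S...SW..S...T",
    "pombe": "[SK]...SW..[SA]...T",  # K at position 1, A at position 9
    "fly": "S...[SA]W..S...T",  # A at position 5
    "all": "[SK]...[SA]W..[SA]...T",
}


def scan_serine_motif(seq: str, variant_set: str = "all") -> list[MotifHit]:
    """Find serine-motif (SxxxSWxxSxxxT) matches.

    ``variant_set`` selects the allowed anchor substitutions:
    ``canonical`` (strict S/S/S), ``pombe`` (KxxxSWxxAxxxT),
    ``fly`` (A at the second serine), or ``all`` (their union).
    Hits matching the strict pattern are labelled canonical, the rest
    degenerate.
    """
    if variant_set not in _SERINE_PATTERNS:
        raise ValueError(
            f"variant_set must be one of {sorted(_SERINE_PATTERNS)}"
        )
    return _scan(
        seq,
        _SERINE_PATTERNS[variant_set],
        _SERINE_PATTERNS["canonical"],
        "serine_motif",
    )


def scan_fasta(
    path: str | Path,
    degenerate_yg: bool = False,
    serine_variant_set: str = "all",
) -> dict[str, list[MotifHit]]:
    """Scan every record of a (plain or aligned) FASTA file for both
    motifs; returns {record id: hits}."""
    from Bio import SeqIO

    out: dict[str, list[MotifHit]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        out[record.id] = scan_yg_box(seq, degenerate=degenerate_yg) + (
            scan_serine_motif(seq, variant_set=serine_variant_set)
        )
    return out
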