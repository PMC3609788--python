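"""Seed-site scanning of 3'UTR sequences.

miR-195/miR-497 family targeting is screened here by presence of a short
heptamer (default ACGACGA) on the sense strand of the 3'UTR. Matching is
case-insensitive, U is equivalent to T, overlapping occurrences all count,
and the ambiguity code N never matches. Only the sense strand is searched:
presence/absence of at least one site is what the downstream gene-universe
restriction consumes.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

logger = logging.getLogger(__name__)

DEFAULT_MOTIF = "ACGACGA"

_SEQ_ALPHABET = set("ACGTN")
_MOTIF_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class UtrRecord:
    """A gene's 3'UTR, normalized to uppercase DNA (U -> T)."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    start: int  # 1-based position on the sense strand
    motif: str


def normalize_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTUN characters: {sorted(bad)}")
    return s


def normalize_motif(motif: str) -> str:
    if not motif:
        raise ValueError("motif must be non-empty")
    m = motif.upper().replace("U", "T")
    bad = set(m) - _MOTIF_ALPHABET
    if bad:
        raise ValueError(f"motif contains non-ACGTU characters: {sorted(bad)}")
    return m


def scan_motif(utr: UtrRecord | str, motif: str = DEFAULT_MOTIF,
               gene_id: str = "") -> list[MotifHit]:
    """All (possibly overlapping) motif occurrences, 1-based start positions."""
    if isinstance(utr, UtrRecord):
        gene_id, seq = utr.gene_id, utr.sequence
    else:
        seq = normalize_sequence(utr)
    m = normalize_motif(motif)
    hits: list[MotifHit] = []
    pos = seq.find(m)
    while pos != -1:
        hits.append(MotifHit(gene_id=gene_id, start=pos + 1, motif=m))
        pos = seq.find(m, pos + 1)
    return hits


def count_hits(sequence: str, motif: str = DEFAULT_MOTIF) -> int:
    return len(scan_motif(sequence, motif))


def filter_by_motif(genes: Iterable[str], utrs: Mapping[str, str],
                    motif: str = DEFAULT_MOTIF) -> set[str]:
    """Genes with at least one motif hit in their UTR.

    Genes without a UTR record are excluded and counted in a log summary.
    """
    keep: set[str] = set()
    missing = 0
    for g in genes:
        seq = utrs.get(g)
        if seq is None:
            missing += 1
            continue
        if scan_motif(seq, motif, gene_id=g):
            keep.add(g)
    if missing:
        logger.info("filter_by_motif: %d genes had no UTR record and were excluded", missing)
    return keep
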