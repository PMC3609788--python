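"""RPKM quantification and Ago2-IP fold-enrichment scoring.

Per gene and fraction, RPKM = 1e9 * C / (N * L) with C the gene's read
count, N the fraction's total mapped reads and L the gene length in bp.
The abundant-Ago2 fraction is the per-gene ratio of Ago2-IP RPKM to
total-RNA RPKM within a condition; gene length and library size cancel, so
this is a relative RISC-occupancy measure. The fold-enrichment score is the
ratio of abundant-Ago2 fractions between the miRNA-transfected and
non-transfected conditions: genes recruited into Ago2 complexes by the
transfected miRNA score above 1. Genes below an RPKM floor in a required
total-RNA fraction are non-evaluable and excluded from the ranking rather
than smoothed with pseudocounts.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default total-RNA RPKM floor below which a gene is non-evaluable
DEFAULT_RPKM_FLOOR = 0.5


def rpkm(counts: pd.DataFrame, lengths: pd.Series, totals: Mapping[str, float]) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, per gene x fraction.

    ``counts`` is genes x fractions; ``lengths`` gives bp per gene;
    ``totals`` the total mapped reads per fraction (column).
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    out = {}
    for col in counts.columns:
        total = float(totals[col])
        if total <= 0:
            raise ValueError(f"total mapped reads must be > 0 (fraction {col!r})")
        out[col] = 1e9 * counts[col] / (total * lengths)
    return pd.DataFrame(out, index=counts.index)


def abundant_fraction(rpkm_ip: pd.Series, rpkm_total: pd.Series,
                      floor: float = DEFAULT_RPKM_FLOOR) -> pd.Series:
    """Per-gene Ago2-IP / total-RNA RPKM ratio within one condition.

    Genes whose total-RNA RPKM is below ``floor`` are returned as NaN
    (non-evaluable) — raw ratios are unstable near zero.
    """
    rpkm_ip, rpkm_total = rpkm_ip.align(rpkm_total, join="inner")
    if (rpkm_ip < 0).any() or (rpkm_total < 0).any():
        raise ValueError("RPKM values must be >= 0")
    ok = rpkm_total >= floor
    out = pd.Series(np.nan, index=rpkm_ip.index, dtype=float)
    out[ok] = rpkm_ip[ok] / rpkm_total[ok]
    return out


def fold_enrichment(fraction_transfected: pd.Series, fraction_nt: pd.Series) -> pd.DataFrame:
    """Rank genes by transfected / non-transfected abundant-Ago2 fraction.

    Returns a table (gene_id index) with columns ``fraction_tx``,
    ``fraction_nt``, ``score`` and ``rank`` (1 = highest score), sorted
    descending by score with ties broken by gene id. Genes evaluable in
    only one condition, or with a zero non-transfected fraction, are
    excluded and logged.
    """
    tx, nt = fraction_transfected.align(fraction_nt, join="outer")
    evaluable = tx.notna() & nt.notna() & (nt > 0)
    n_drop = int((~evaluable).sum())
    if n_drop:
        logger.info("fold_enrichment: excluding %d non-evaluable genes", n_drop)
    tx, nt = tx[evaluable], nt[evaluable]
    score = tx / nt
    tab = pd.DataFrame({"fraction_tx": tx, "fraction_nt": nt, "score": score})
    # stable sort on id first, then on score, yields (score desc, id asc)
    tab = tab.sort_index(kind="mergesort").sort_values("score", ascending=False,
                                                       kind="mergesort")
    tab["rank"] = np.arange(1, len(tab) + 1)
    return tab


def enrichment_from_counts(counts: pd.DataFrame, lengths: pd.Series,
                           totals: Mapping[str, float],
                           floor: float = DEFAULT_RPKM_FLOOR) -> pd.DataFrame:
    """Counts -> RPKM -> abundant fractions -> ranked fold-enrichment table.

    Expects the four fraction columns ``total_nt``, ``total_tx``, ``ip_nt``,
    ``ip_tx``.
    """
    rp = rpkm(counts, lengths, totals)
    frac_tx = abundant_fraction(rp["ip_tx"], rp["total_tx"], floor)
    frac_nt = abundant_fraction(rp["ip_nt"], rp["total_nt"], floor)
    return fold_enrichment(frac_tx, frac_nt)
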