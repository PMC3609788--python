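"""Weighted Kolmogorov-Smirnov gene set enrichment analysis, from scratch.

Given a gene list ranked by an expression-response metric (log2 ratio of
transfected over control, descending), the running enrichment statistic
walks the list adding |metric|^p / sum(|metric|^p over hits) at each gene in
the set and subtracting 1/(N - Nh) at each gene outside it; the enrichment
score ES is the signed maximum deviation of this running sum. A strongly
negative ES means the set concentrates among the most repressed genes.

Because the underlying design has a single (duplicate-averaged) array per
condition, the null is generated by resampling random gene sets of equal
size from the ranked universe, not by phenotype permutation. NES divides ES
by the mean |ES| of same-sign null samples; the permutation p-value is the
fraction of same-sign nulls at least as extreme; the FDR q compares the
observed NES against the pooled sign-normalized null.

The cut-off scan takes the genes ranked by Ago2-IP fold enrichment
(restricted to the seed-motif universe), forms the top-r% set for each rate
r on a grid, and reports the rate whose set attains the most negative NES
against the expression ranking — the data-driven choice of how deep into
the IP ranking true targets extend.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_WEIGHT_EXPONENT = 1.0
DEFAULT_N_PERM = 1000


@dataclass
class RankedGeneList:
    """Gene ids with their ranking metric, sorted (metric desc, id asc)."""

    gene_ids: np.ndarray
    metric: np.ndarray

    @classmethod
    def from_scores(cls, gene_ids: Iterable[str], metric: Iterable[float]) -> "RankedGeneList":
        ids = np.asarray(list(gene_ids), dtype=object)
        met = np.asarray(list(metric), dtype=float)
        if len(ids) != len(met):
            raise ValueError("gene_ids and metric lengths differ")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene ids in ranked list")
        order = np.lexsort((ids, -met))
        return cls(gene_ids=ids[order], metric=met[order])

    def __len__(self) -> int:
        return len(self.gene_ids)


def ranking_metric(expr_transfected: pd.Series, expr_control: pd.Series) -> RankedGeneList:
    """log2(transfected / control) per gene, ranked descending.

    Duplicate measurements per gene (repeated index entries) are averaged
    before the ratio is taken. Non-positive expression is an error.
    """
    tx = expr_transfected.groupby(level=0).mean()
    ctrl = expr_control.groupby(level=0).mean()
    tx, ctrl = tx.align(ctrl, join="inner")
    bad = tx.index[(tx <= 0) | (ctrl <= 0)]
    if len(bad):
        raise ValueError(f"non-positive expression for genes: {sorted(map(str, bad))[:10]}")
    metric = np.log2(tx / ctrl)
    return RankedGeneList.from_scores(metric.index.to_numpy(dtype=object), metric.to_numpy())


def _hit_mask(ranked: RankedGeneList, gene_set: Iterable[str]) -> np.ndarray:
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.gene_ids), dtype=bool,
                      count=len(ranked))
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set has no members in the ranked list")
    if nh == len(ranked):
        raise ValueError("gene set equals the ranked universe (degenerate normalization)")
    return hit


def _running_sum(metric: np.ndarray, hit: np.ndarray, weight_exponent: float) -> np.ndarray:
    n = len(metric)
    nh = int(hit.sum())
    w = np.abs(metric[hit]) ** weight_exponent
    total = w.sum()
    steps = np.full(n, -1.0 / (n - nh))
    if total > 0:
        steps[hit] = w / total
    else:  # all-zero metric: fall back to equal hit weights
        steps[hit] = 1.0 / nh
    return np.cumsum(steps)


def enrichment_score(ranked: RankedGeneList, gene_set: Iterable[str],
                     weight_exponent: float = DEFAULT_WEIGHT_EXPONENT,
                     ) -> tuple[float, np.ndarray]:
    """ES (signed maximum deviation) and the full running-sum profile."""
    hit = _hit_mask(ranked, gene_set)
    rs = _running_sum(ranked.metric, hit, weight_exponent)
    es = float(rs[np.argmax(np.abs(rs))])
    return es, rs


def _null_es(metric: np.ndarray, k: int, n_perm: int, rng: np.random.Generator,
             weight_exponent: float, chunk: int = 256) -> np.ndarray:
    """ES of ``n_perm`` random k-gene sets drawn from the ranked universe."""
    n = len(metric)
    absw = np.abs(metric) ** weight_exponent
    miss = -1.0 / (n - k)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        # random k-subsets: k smallest of iid uniforms per row
        idx = np.argpartition(rng.random((b, n)), k - 1, axis=1)[:, :k]
        w = absw[idx]
        tot = w.sum(axis=1, keepdims=True)
        steps = np.full((b, n), miss)
        rows = np.repeat(np.arange(b), k)
        # equal hit weights for the (rare) all-zero-metric rows
        wn = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 1.0 / k)
        steps[rows, idx.ravel()] = wn.ravel()
        rs = np.cumsum(steps, axis=1)
        amax = np.argmax(np.abs(rs), axis=1)
        out[done:done + b] = rs[np.arange(b), amax]
        done += b
    return out


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray
    nes: float
    p_value: float
    fdr_q: float
    n_perm: int
    seed: int
    n_hits: int

    def to_dict(self) -> dict:
        return {"es": self.es, "nes": self.nes, "p_value": self.p_value,
                "fdr_q": self.fdr_q, "n_perm": self.n_perm, "seed": self.seed,
                "n_hits": self.n_hits}


def gsea_test(ranked: RankedGeneList, gene_set: Iterable[str],
              n_perm: int = DEFAULT_N_PERM, seed: int = 0,
              weight_exponent: float = DEFAULT_WEIGHT_EXPONENT) -> GseaResult:
    """Permutation GSEA with a gene-set-resampling null. Deterministic per seed."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    hit = _hit_mask(ranked, gene_set)
    k = int(hit.sum())
    rs = _running_sum(ranked.metric, hit, weight_exponent)
    es = float(rs[np.argmax(np.abs(rs))])
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.metric, k, n_perm, rng, weight_exponent)

    if es == 0.0:
        return GseaResult(es=0.0, running_sum=rs, nes=0.0, p_value=1.0, fdr_q=1.0,
                          n_perm=n_perm, seed=seed, n_hits=k)
    same = null[np.sign(null) == np.sign(es)]
    if len(same) == 0:
        logger.warning("gsea_test: no same-sign null samples; NES undefined")
        nes, p = float("nan"), 1.0 / n_perm
    else:
        nes = es / float(np.mean(np.abs(same)))
        p = float(np.mean(np.abs(same) >= abs(es)))

    # pooled sign-normalized null for the FDR q (single observed set)
    pos, neg = null[null > 0], null[null < 0]
    parts = []
    if len(pos):
        parts.append(pos / pos.mean())
    if len(neg):
        parts.append(neg / np.abs(neg).mean())
    pooled = np.concatenate(parts) if parts else np.array([])
    if np.isnan(nes) or len(pooled) == 0:
        q = 1.0
    elif es < 0:
        q = float(np.mean(pooled <= nes))
    else:
        q = float(np.mean(pooled >= nes))
    return GseaResult(es=es, running_sum=rs, nes=nes, p_value=p, fdr_q=min(q, 1.0),
                      n_perm=n_perm, seed=seed, n_hits=k)


@dataclass
class CutoffScanResult:
    rates: np.ndarray
    nes_per_rate: np.ndarray
    set_sizes: np.ndarray
    optimum_rate: float
    optimum_set: set[str] = field(default_factory=set)
    results: dict[float, GseaResult] = field(default_factory=dict)

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame({"rate_percent": self.rates, "set_size": self.set_sizes,
                             "nes": self.nes_per_rate})


def cutoff_scan(enrichment: pd.DataFrame, ranked: RankedGeneList,
                motif_universe: Iterable[str] | None = None,
                grid: Sequence[float] = tuple(range(1, 101)),
                n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                weight_exponent: float = DEFAULT_WEIGHT_EXPONENT) -> CutoffScanResult:
    """NES of the top-r% fold-enrichment set for every rate r on the grid.

    ``enrichment`` is the ranked fold-enrichment table (gene_id index,
    ``score``/``rank`` columns); if ``motif_universe`` is given the table is
    restricted to those genes before percentages are taken. The optimum is
    the rate with the most negative NES, ties broken toward the smaller
    rate. Rates whose top set is empty, or spans the whole ranked universe,
    are skipped (NES = NaN in the profile).

    The permutation seed for each rate is derived from (seed, set size), so
    adjacent rates with identical top sets get identical NES.
    """
    tab = enrichment
    if motif_universe is not None:
        tab = tab.loc[tab.index.isin(set(motif_universe))]
    tab = tab.sort_values("rank") if "rank" in tab.columns else tab
    ordered = tab.index.to_numpy(dtype=object)
    n_u = len(ordered)
    if n_u == 0:
        raise ValueError("enrichment table is empty after motif restriction")

    grid = np.asarray(sorted(grid), dtype=float)
    nes = np.full(len(grid), np.nan)
    sizes = np.zeros(len(grid), dtype=int)
    by_size: dict[int, GseaResult] = {}
    results: dict[float, GseaResult] = {}
    for i, r in enumerate(grid):
        k = int(round(n_u * r / 100.0))
        sizes[i] = k
        if k == 0:
            logger.info("cutoff_scan: rate %.3g%% gives an empty set; skipped", r)
            continue
        top = ordered[:k]
        if k not in by_size:
            sub_seed = (int(seed) * 1_000_003 + k) % (2 ** 31)
            try:
                by_size[k] = gsea_test(ranked, top, n_perm=n_perm, seed=sub_seed,
                                       weight_exponent=weight_exponent)
            except ValueError as exc:
                logger.info("cutoff_scan: rate %.3g%% skipped (%s)", r, exc)
                continue
        res = by_size[k]
        results[float(r)] = res
        nes[i] = res.nes
    if np.all(np.isnan(nes)):
        raise ValueError("no rate on the grid produced a defined NES")
    best = int(np.nanargmin(nes))
    opt_rate = float(grid[best])
    opt_set = set(ordered[:sizes[best]])
    return CutoffScanResult(rates=grid, nes_per_rate=nes, set_sizes=sizes,
                            optimum_rate=opt_rate, optimum_set=opt_set, results=results)
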