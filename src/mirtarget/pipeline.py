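"""Final candidate selection, pathway over-representation and clinical summaries.

Direct-target candidates are the intersection of the Ago2-IP top set (from
the cut-off scan) with genes repressed more than ``fold_threshold``-fold on
the expression array (linear transfected/control ratio strictly below
1/fold). Pathway over-representation of the candidates is a one-sided
hypergeometric tail against a GMT gene-set collection with Benjamini-
Hochberg correction across sets, evaluated on the universe of genes that
were evaluable in both the enrichment and expression stages.
``run_pipeline`` orchestrates the whole flow on synthetic data with known
ground truth and reports recovery metrics.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import enrichment as enr
from . import gsea as gsea_mod
from . import motif as motif_mod
from . import screening as screening_mod
from . import synthetic as synth_mod

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """Genes passing both the Ago2-IP cut-off and the repression filter."""

    gene_ids: list[str]
    annotations: pd.DataFrame  # fold_enrichment, log2_expression_ratio, motif_hits

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_candidates(top_set: Iterable[str], expression_ratios: Mapping[str, float],
                      fold_threshold: float = 2.0) -> list[str]:
    """Members of the top set with linear expression ratio < 1/fold (strict).

    Genes missing an expression value are excluded and logged.
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    cut = 1.0 / fold_threshold
    keep, missing = [], 0
    for g in sorted(set(top_set)):
        r = expression_ratios.get(g)
        if r is None or (isinstance(r, float) and np.isnan(r)):
            missing += 1
            continue
        if r < cut:
            keep.append(g)
    if missing:
        logger.info("select_candidates: %d top-set genes lacked expression values", missing)
    return keep


def over_representation(candidates: Iterable[str], gene_sets: Mapping[str, Iterable[str]],
                        universe: Iterable[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Gene sets and candidates are intersected with the universe first.
    Returns one row per set: overlap, set_size, candidate_size,
    universe_size, p_value, q_value, sorted by p then name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    cand = set(candidates) & uni
    stray = set(candidates) - uni
    if stray:
        logger.info("over_representation: %d candidates outside the universe dropped",
                    len(stray))
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        overlap = len(members & cand)
        # P(X >= overlap), X ~ Hypergeom(N=|uni|, K=|set|, n=|cand|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(members), len(cand)))
        rows.append((name, overlap, len(members), len(cand), len(uni), min(p, 1.0)))
    tab = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "candidate_size", "universe_size", "p_value"])
    if len(tab):
        tab["q_value"] = multipletests(tab["p_value"], method="fdr_bh")[1]
    else:
        tab["q_value"] = pd.Series(dtype=float)
    return tab.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)


def expression_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment r with its two-sided t-distribution p-value.

    Returns (nan, nan) with a warning when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("expression_correlation: zero variance; correlation undefined")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tumor_upregulation_frequency(tumor: pd.DataFrame, nontumor: pd.DataFrame,
                                 fold: float = 2.0) -> pd.Series:
    """Per-gene fraction of evaluable pairs with tumor/non-tumor strictly > fold.

    ``tumor`` and ``nontumor`` are genes x cases with matching columns
    (paired by position and name). Missing values drop the pair from that
    gene's denominator; a gene with no evaluable pair is an error.
    """
    if list(tumor.columns) != list(nontumor.columns) or not tumor.index.equals(nontumor.index):
        raise ValueError("tumor and nontumor tables must share index and paired columns")
    t = tumor.to_numpy(dtype=float)
    n = nontumor.to_numpy(dtype=float)
    evaluable = ~(np.isnan(t) | np.isnan(n))
    n_eval = evaluable.sum(axis=1)
    if (n_eval == 0).any():
        bad = list(tumor.index[n_eval == 0])
        raise ValueError(f"no evaluable tumor/non-tumor pairs for genes: {bad[:10]}")
    up = (t > fold * n) & evaluable
    return pd.Series(up.sum(axis=1) / n_eval, index=tumor.index, name="upregulation_frequency")


@dataclass
class PipelineConfig:
    """End-to-end run configuration (synthetic inputs + analysis settings)."""

    sim: synth_mod.SimulationConfig = field(default_factory=synth_mod.SimulationConfig)
    rpkm_floor: float = enr.DEFAULT_RPKM_FLOOR
    fold_threshold: float = 2.0
    weight_exponent: float = gsea_mod.DEFAULT_WEIGHT_EXPONENT
    grid: tuple[float, ...] = tuple(range(1, 101))
    n_perm: int = gsea_mod.DEFAULT_N_PERM
    cutoff_rate: float | None = None  # fixed top-X% instead of the NES scan
    seed: int = 0


@dataclass
class PipelineReport:
    config: PipelineConfig
    enrichment: pd.DataFrame
    ranked: gsea_mod.RankedGeneList
    motif_universe: set[str]
    scan: gsea_mod.CutoffScanResult | None
    top_set: set[str]
    candidates: CandidateSet
    ora: pd.DataFrame
    recovery: dict

    def summary(self) -> dict:
        """JSON-serializable stage-by-stage summary with provenance."""
        out = {
            "seed": self.config.seed,
            "n_genes": int(self.config.sim.n_genes),
            "n_evaluable": int(len(self.enrichment)),
            "n_motif_universe": int(len(self.motif_universe)),
            "cutoff_rate_percent": (float(self.scan.optimum_rate) if self.scan is not None
                                    else float(self.config.cutoff_rate)),
            "top_set_size": int(len(self.top_set)),
            "n_candidates": int(len(self.candidates)),
            "ora_top_set": self.ora.iloc[0]["set_name"] if len(self.ora) else None,
            "ora_top_q": float(self.ora.iloc[0]["q_value"]) if len(self.ora) else None,
            "recovery": self.recovery,
        }
        if self.scan is not None:
            opt = self.scan.results.get(self.scan.optimum_rate)
            if opt is not None:
                out["optimum_nes"] = float(opt.nes)
                out["optimum_p"] = float(opt.p_value)
                out["optimum_fdr_q"] = float(opt.fdr_q)
        return out


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Synthetic data -> enrichment -> motif filter -> GSEA cut-off -> candidates -> ORA.

    Deterministic given the config (simulation seed + analysis seed).
    """
    tr = synth_mod.simulate_transcriptome(config.sim)
    lengths = tr.genes.set_index("gene_id")["length_bp"]
    table = enr.enrichment_from_counts(tr.counts, lengths, tr.totals,
                                       floor=config.rpkm_floor)
    motif_universe = motif_mod.filter_by_motif(table.index, tr.utrs,
                                               config.sim.normalized_motif)
    ranked = gsea_mod.ranking_metric(tr.expression["transfected"], tr.expression["control"])

    sub = table.loc[table.index.isin(motif_universe)]
    if config.cutoff_rate is not None:
        scan = None
        k = int(round(len(sub) * config.cutoff_rate / 100.0))
        top_set = set(sub.index[:max(k, 0)])
        rate = float(config.cutoff_rate)
    else:
        scan = gsea_mod.cutoff_scan(table, ranked, motif_universe, grid=config.grid,
                                    n_perm=config.n_perm, seed=config.seed,
                                    weight_exponent=config.weight_exponent)
        top_set = scan.optimum_set
        rate = scan.optimum_rate

    ratios = (tr.expression["transfected"] / tr.expression["control"])
    cand_ids = select_candidates(top_set, ratios.to_dict(), config.fold_threshold)
    ann = pd.DataFrame(index=pd.Index(cand_ids, name="gene_id"))
    ann["fold_enrichment"] = table["score"].reindex(cand_ids)
    ann["log2_expression_ratio"] = np.log2(ratios.reindex(cand_ids))
    ann["motif_hits"] = [len(motif_mod.scan_motif(tr.utrs[g], config.sim.normalized_motif,
                                                  gene_id=g)) for g in cand_ids]
    candidates = CandidateSet(gene_ids=cand_ids, annotations=ann)

    universe = set(table.index) & set(ratios.index)
    ora = over_representation(cand_ids, tr.gene_sets, universe)

    truth = tr.truth.true_target_ids
    n_cand = len(cand_ids)
    tp = len(set(cand_ids) & truth)
    recovery = {
        "n_true_targets": len(truth),
        "true_positives": tp,
        "precision": tp / n_cand if n_cand else float("nan"),
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "top_set_rate_percent": rate,
    }
    logger.info("pipeline: rate %.3g%%, %d top-set genes, %d candidates "
                "(precision %.3g, sensitivity %.3g)", rate, len(top_set), n_cand,
                recovery["precision"], recovery["sensitivity"])
    return PipelineReport(config=config, enrichment=table, ranked=ranked,
                          motif_universe=motif_universe, scan=scan, top_set=top_set,
                          candidates=candidates, ora=ora, recovery=recovery)


def run_screen_pipeline(config: synth_mod.SimulationConfig,
                        thresholds: screening_mod.ScreenThresholds | None = None) -> dict:
    """Simulate the miRNA screen and run the triage; report recovery vs truth."""
    thresholds = thresholds or screening_mod.ScreenThresholds()
    sim = synth_mod.simulate_screen(config)
    res = screening_mod.run_screen(sim.growth, sim.panel, thresholds)
    recovered = set(res["candidates"])
    planted = sim.truth.true_ts_mirna_ids
    res["recovery"] = {
        "n_planted": len(planted),
        "n_recovered": len(recovered & planted),
        "false_positives": len(recovered - planted),
    }
    return res
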