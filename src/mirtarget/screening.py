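"""Two-arm screening triage for tumor-suppressive miRNA candidates.

The function-based arm calls a miRNA a hit when its control-normalized
growth ratio falls strictly below a cut-off (default 0.8) in at least
``min_hit_lines`` cell lines (default 4 of 6). The expression-based arm
calls a miRNA commonly downregulated when its signal is strictly more than
``downregulation_fold``-fold (default 2) below the reference summary in
every cell line, where the reference summary is the minimum over the
normal-liver reference samples (the miRNA must be below threshold against
both references). Candidate TS-miRNAs are the intersection of the two arms,
optionally narrowed by panel downregulation frequencies (cell-line panel and
paired tumor/non-tumor panel, both at a strict >50% frequency cut by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ScreenMatrix:
    """miRNA x sample matrix with per-sample roles.

    ``values`` is indexed by miRNA id with one column per sample. ``roles``
    maps each sample to one of ``cell_line``, ``normal_reference``,
    ``tumor:<pair>`` or ``nontumor:<pair>``; tumor/non-tumor samples sharing
    a pair token are matched.
    """

    values: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.values.columns if c not in self.roles]
        if missing:
            raise ValueError(f"samples without a declared role: {missing}")
        if (self.values.to_numpy(dtype=float, na_value=np.nan) < 0).any():
            raise ValueError("screen values must be >= 0")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.values.columns if self.roles.get(s) == role]

    @property
    def cell_lines(self) -> list[str]:
        return self.samples_with_role("cell_line")

    @property
    def references(self) -> list[str]:
        return self.samples_with_role("normal_reference")

    @property
    def tumor_pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, nontumor_sample) for every declared pair.

        A tumor sample whose pair token has no non-tumor partner is an
        error: tumor-specific frequencies are defined on pairs only.
        """
        tumors: dict[str, str] = {}
        nontumors: dict[str, str] = {}
        for s in self.values.columns:
            role = self.roles.get(s, "")
            if role.startswith("tumor:"):
                tumors[role.split(":", 1)[1]] = s
            elif role.startswith("nontumor:"):
                nontumors[role.split(":", 1)[1]] = s
        unpaired = sorted(set(tumors) ^ set(nontumors))
        if unpaired:
            raise ValueError(f"unpaired tumor/non-tumor samples for pairs: {unpaired}")
        return [(tumors[p], nontumors[p]) for p in sorted(tumors)]


@dataclass(frozen=True)
class ScreenThresholds:
    growth_ratio_cut: float = 0.8
    min_hit_lines: int = 4
    downregulation_fold: float = 2.0
    panel_frequency_cut: float = 0.5

    def __post_init__(self) -> None:
        if self.growth_ratio_cut <= 0 or self.downregulation_fold <= 0:
            raise ValueError("cut-offs must be positive")
        if self.min_hit_lines < 1:
            raise ValueError("min_hit_lines must be >= 1")


def functional_hits(growth: ScreenMatrix,
                    thresholds: ScreenThresholds = ScreenThresholds()) -> set[str]:
    """miRNAs with growth ratio strictly below the cut in >= min_hit_lines lines."""
    lines = growth.cell_lines
    if thresholds.min_hit_lines > len(lines):
        raise ValueError("min_hit_lines exceeds the number of cell lines")
    vals = growth.values[lines]
    bad = vals.index[vals.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"missing growth ratios for miRNAs: {sorted(bad)}")
    n_hit_lines = (vals < thresholds.growth_ratio_cut).sum(axis=1)
    return set(vals.index[n_hit_lines >= thresholds.min_hit_lines])


def _reference_summary(panel: ScreenMatrix) -> pd.Series:
    refs = panel.references
    if not refs:
        raise ValueError("panel has no normal_reference samples")
    # a miRNA must be downregulated against BOTH references -> compare to the min
    return panel.values[refs].min(axis=1)


def commonly_downregulated(panel: ScreenMatrix,
                           thresholds: ScreenThresholds = ScreenThresholds()) -> set[str]:
    """miRNAs strictly > fold-fold below the reference summary in ALL cell lines.

    Values missing in a cell line count as not-downregulated there, so a
    miRNA unquantified in any line never qualifies.
    """
    lines = panel.cell_lines
    if not lines:
        raise ValueError("panel has no cell_line samples")
    ref = _reference_summary(panel)
    cut = ref / thresholds.downregulation_fold
    below = panel.values[lines].lt(cut, axis=0).fillna(False)
    return set(below.index[below.all(axis=1)])


def candidate_ts_mirnas(functional: set[str], downregulated: set[str]) -> set[str]:
    """Intersection of the two screening arms."""
    return set(functional) & set(downregulated)


def panel_frequency(panel: ScreenMatrix,
                    thresholds: ScreenThresholds = ScreenThresholds()) -> pd.DataFrame:
    """Downregulation frequencies across the cell-line and tumor panels.

    Returns a per-miRNA table with ``line_frequency`` (fraction of cell
    lines with <0.5-fold expression vs the reference summary),
    ``tumor_frequency`` (fraction of evaluable tumor/non-tumor pairs with
    tumor <0.5-fold of its partner) and ``passes`` (both frequencies
    strictly above ``panel_frequency_cut``).
    """
    lines = panel.cell_lines
    pairs = panel.tumor_pairs
    if not lines or not pairs:
        raise ValueError("panel needs cell_line samples and tumor/non-tumor pairs")
    ref = _reference_summary(panel)
    line_down = panel.values[lines].lt(ref * 0.5, axis=0)
    line_freq = line_down.sum(axis=1) / line_down.notna().sum(axis=1).clip(lower=1)

    t_cols = [t for t, _ in pairs]
    n_cols = [n for _, n in pairs]
    tumor = panel.values[t_cols].to_numpy(dtype=float)
    nontumor = panel.values[n_cols].to_numpy(dtype=float)
    evaluable = ~(np.isnan(tumor) | np.isnan(nontumor))
    down = (tumor < 0.5 * nontumor) & evaluable
    n_eval = evaluable.sum(axis=1)
    with np.errstate(invalid="ignore"):
        tumor_freq = np.where(n_eval > 0, down.sum(axis=1) / np.maximum(n_eval, 1), np.nan)

    out = pd.DataFrame(
        {"line_frequency": line_freq.to_numpy(dtype=float), "tumor_frequency": tumor_freq},
        index=panel.values.index,
    )
    cut = thresholds.panel_frequency_cut
    out["passes"] = (out["line_frequency"] > cut) & (out["tumor_frequency"] > cut)
    return out


def run_screen(growth: ScreenMatrix, panel: ScreenMatrix,
               thresholds: ScreenThresholds = ScreenThresholds()) -> dict:
    """Full triage: both arms, intersection, and panel frequencies."""
    fn = functional_hits(growth, thresholds)
    dn = commonly_downregulated(panel, thresholds)
    cand = candidate_ts_mirnas(fn, dn)
    freq = panel_frequency(panel, thresholds)
    passing = set(freq.index[freq["passes"]]) & cand
    logger.info("screen: %d functional, %d downregulated, %d candidates, %d pass panels",
                len(fn), len(dn), len(cand), len(passing))
    return {
        "functional_hits": sorted(fn),
        "commonly_downregulated": sorted(dn),
        "candidates": sorted(cand),
        "panel_passing": sorted(passing),
        "panel_frequency": freq,
    }
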