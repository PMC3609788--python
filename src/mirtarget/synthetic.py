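"""Synthetic data generator for the miRNA target-discovery pipeline.

Emulates the statistical structure of an Ago2-IP-seq target-identification
experiment with a single library per fraction (total-RNA / Ago2-IP, each in
miRNA-transfected and non-transfected conditions), an expression-array
readout of the transfection response, 3'UTR sequences carrying planted seed
heptamers, and a miRNA mimic growth screen across a panel of cell lines.
Every dataset comes with a :class:`SyntheticTruth` sidecar recording which
genes are true targets and which miRNAs are planted growth suppressors, so
downstream recovery can be scored exactly.

Counts are negative binomial with a shared dispersion around means
proportional to expression x gene length, scaled to a fixed library size.
Ago2-IP means are expression x a per-gene IP affinity (constant across
genes), so the fold-enrichment score of a non-target is centred at 1 by
construction, while true targets carry ``ip_enrichment_factor`` in the
transfected IP fraction and ``1/repression_factor`` in the transfected
total/expression data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: library fractions, in column order: total-RNA / Ago2-IP x non-transfected / transfected
FRACTIONS = ("total_nt", "total_tx", "ip_nt", "ip_tx")

_DNA = np.array(list("ACGT"))
_GENE_LENGTH_RANGE = (500, 5000)  # bp, transcript length used for RPKM
_N_NORMAL_REFS = 2      # normal liver reference samples in the expression panel
_N_TUMOR_PAIRS = 18     # paired tumor / non-tumorous cases in the clinical panel
_TS_LINE_FACTOR = 0.2   # expression of a planted TS-miRNA in cell lines vs reference
_TS_TUMOR_FACTOR = 0.3  # expression of a planted TS-miRNA in tumor vs paired non-tumor


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig fails validation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults are the study conditions exercised throughout the test-suite:
    4,000 genes of which 5% are true targets, 4x Ago2-IP enrichment and
    2.5x mRNA repression for true targets, NB dispersion 0.1 at a library
    size of 2x10^6 reads, and a 470-miRNA x 6-cell-line growth screen with
    10 planted growth-suppressive miRNAs.
    """

    n_genes: int = 4000
    target_fraction: float = 0.05
    utr_length_range: tuple[int, int] = (200, 2000)
    motif: str = "ACGACGA"
    planted_sites_per_target: int = 2
    baseline_log_expression: tuple[float, float] = (0.0, 1.0)
    nb_dispersion: float = 0.1
    ip_enrichment_factor: float = 4.0
    repression_factor: float = 2.5
    library_size: int = 2_000_000
    array_noise_sd: float = 0.25
    n_mirnas: int = 470
    n_cell_lines: int = 6
    ts_mirna_fraction: float = 10 / 470
    growth_effect: float = 0.6
    growth_noise_sd: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1:
            raise ConfigurationError("n_genes and n_mirnas must be positive")
        if self.n_cell_lines < 1:
            raise ConfigurationError("n_cell_lines must be >= 1")
        for name in ("target_fraction", "ts_mirna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("nb_dispersion", "ip_enrichment_factor", "repression_factor",
                     "library_size", "growth_effect"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.array_noise_sd < 0 or self.growth_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        motif = self.motif.upper().replace("U", "T")
        if not motif or set(motif) - set("ACGT"):
            raise ConfigurationError(f"motif must be a non-empty ACGTU string, got {self.motif!r}")
        lo, hi = self.utr_length_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("utr_length_range must satisfy 1 <= min <= max")
        if self.planted_sites_per_target < 1:
            raise ConfigurationError("planted_sites_per_target must be >= 1")
        if lo < self.planted_sites_per_target * len(motif):
            raise ConfigurationError(
                "minimum UTR length cannot accommodate planted_sites_per_target motif copies")

    @property
    def normalized_motif(self) -> str:
        return self.motif.upper().replace("U", "T")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset."""

    true_target_ids: set[str] = field(default_factory=set)
    true_ts_mirna_ids: set[str] = field(default_factory=set)
    per_gene_true_fold_change: dict[str, float] = field(default_factory=dict)
    per_gene_true_ip_enrichment: dict[str, float] = field(default_factory=dict)


@dataclass
class TranscriptomeSim:
    """Bundle returned by :func:`simulate_transcriptome`.

    genes: per-gene annotation (gene_id, length_bp, utr_length).
    utrs: gene_id -> 3'UTR sequence (DNA alphabet, U already normalized to T).
    counts: genes x fractions read-count table.
    totals: fraction -> total mapped reads (column sums of ``counts``).
    expression: genes x (control, transfected) array-style expression values.
    gene_sets: pathway collection emitted alongside the data; the
        "CELL_CYCLE" set is enriched for planted true targets so that
        over-representation of recovered candidates is testable.
    truth: planted ground truth.
    """

    config: SimulationConfig
    genes: pd.DataFrame
    utrs: dict[str, str]
    counts: pd.DataFrame
    totals: dict[str, int]
    expression: pd.DataFrame
    gene_sets: dict[str, set[str]]
    truth: SyntheticTruth


@dataclass
class ScreenSim:
    """Bundle returned by :func:`simulate_screen` (growth + expression panel)."""

    config: SimulationConfig
    growth: "ScreenMatrix"
    panel: "ScreenMatrix"
    truth: SyntheticTruth


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    # var = mu + dispersion * mu^2
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p)


def _random_utr(rng: np.random.Generator, length: int) -> np.ndarray:
    return _DNA[rng.integers(0, 4, size=length)]


def _plant_motif(rng: np.random.Generator, seq: np.ndarray, motif: str, copies: int) -> np.ndarray:
    """Overwrite `copies` non-overlapping windows with the motif.

    The sequence is cut into `copies` equal segments and one site is placed
    at a random offset inside each, which guarantees non-overlap.
    """
    m = len(motif)
    motif_arr = np.array(list(motif))
    seg = len(seq) // copies
    for c in range(copies):
        lo = c * seg
        hi = lo + seg if c < copies - 1 else len(seq)
        start = int(rng.integers(lo, hi - m + 1))
        seq[start:start + m] = motif_arr
    return seq


def simulate_transcriptome(config: SimulationConfig) -> TranscriptomeSim:
    """Simulate the four sequencing libraries, expression arrays and UTRs.

    Deterministic: identical config (including ``rng_seed``) yields
    byte-identical outputs.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    n_targets = round(n * config.target_fraction)
    target_idx = rng.choice(n, size=n_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    lengths = rng.integers(_GENE_LENGTH_RANGE[0], _GENE_LENGTH_RANGE[1] + 1, size=n)
    mu_log, sd_log = config.baseline_log_expression
    base = np.exp(rng.normal(mu_log, sd_log, size=n))

    repression = np.where(is_target, config.repression_factor, 1.0)
    ip_gain = np.where(is_target, config.ip_enrichment_factor, 1.0)
    expr = {
        "total_nt": base,
        "total_tx": base / repression,
        "ip_nt": base,
        "ip_tx": base / repression * ip_gain,
    }

    counts = {}
    for frac in FRACTIONS:
        w = expr[frac] * lengths
        mu = config.library_size * w / w.sum()
        counts[frac] = _nb_counts(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"))
    totals = {frac: int(counts_df[frac].sum()) for frac in FRACTIONS}

    noise = lambda: 2.0 ** rng.normal(0.0, config.array_noise_sd, size=n)
    expression = pd.DataFrame(
        {"control": base * noise(), "transfected": expr["total_tx"] * noise()},
        index=pd.Index(gene_ids, name="gene_id"),
    )

    lo, hi = config.utr_length_range
    utr_lengths = rng.integers(lo, hi + 1, size=n)
    motif = config.normalized_motif
    utrs: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        seq = _random_utr(rng, int(utr_lengths[i]))
        if is_target[i]:
            seq = _plant_motif(rng, seq, motif, config.planted_sites_per_target)
        utrs[gid] = "".join(seq)

    genes = pd.DataFrame(
        {"gene_id": gene_ids, "length_bp": lengths, "utr_length": utr_lengths}
    )
    truth = SyntheticTruth(
        true_target_ids=set(gene_ids[is_target]),
        true_ts_mirna_ids=set(),
        per_gene_true_fold_change={g: float(1.0 / r) for g, r in zip(gene_ids, repression)},
        per_gene_true_ip_enrichment={g: float(f) for g, f in zip(gene_ids, ip_gain)},
    )
    gene_sets = _make_gene_sets(rng, gene_ids, is_target)
    return TranscriptomeSim(
        config=config, genes=genes, utrs=utrs, counts=counts_df, totals=totals,
        expression=expression, gene_sets=gene_sets, truth=truth,
    )


def _make_gene_sets(rng: np.random.Generator, gene_ids: np.ndarray,
                    is_target: np.ndarray, n_random_sets: int = 19) -> dict[str, set[str]]:
    """Pathway collection: one "CELL_CYCLE" set holding half the true targets
    (diluted 1:1 with non-targets) plus size-matched random sets."""
    targets = gene_ids[is_target]
    others = gene_ids[~is_target]
    k = max(1, len(targets) // 2)
    cc = set(rng.choice(targets, size=k, replace=False)) | set(
        rng.choice(others, size=min(k, len(others)), replace=False))
    sets = {"CELL_CYCLE": cc}
    for j in range(n_random_sets):
        size = int(rng.integers(max(2, k), max(3, 2 * k)))
        size = min(size, len(gene_ids))
        sets[f"RANDOM_SET_{j + 1:02d}"] = set(rng.choice(gene_ids, size=size, replace=False))
    return sets


def simulate_screen(config: SimulationConfig) -> ScreenSim:
    """Simulate the miRNA mimic growth screen and the expression panel.

    The growth matrix holds control-normalized viability ratios per miRNA x
    cell line; planted TS-miRNAs are centred at ``growth_effect`` in every
    line, others at 1.0, with Gaussian noise ``growth_noise_sd`` (truncated
    at 0). The expression panel covers the cell lines, two normal-liver
    reference samples, and 18 paired tumor / non-tumorous cases; planted
    TS-miRNAs are expressed at 0.2x the reference in cell lines and 0.3x the
    paired non-tumor in tumors (log2-normal measurement noise
    ``array_noise_sd``).
    """
    from .screening import ScreenMatrix  # local import to avoid a cycle

    rng = np.random.default_rng([config.rng_seed, 1])
    m = config.n_mirnas
    mirna_ids = np.array([f"mir{i + 1:04d}" for i in range(m)])
    n_ts = round(m * config.ts_mirna_fraction)
    ts_idx = rng.choice(m, size=n_ts, replace=False)
    is_ts = np.zeros(m, dtype=bool)
    is_ts[ts_idx] = True

    lines = [f"LINE{j + 1}" for j in range(config.n_cell_lines)]
    growth_mean = np.where(is_ts, config.growth_effect, 1.0)
    growth = growth_mean[:, None] + rng.normal(
        0.0, config.growth_noise_sd, size=(m, len(lines)))
    growth = np.clip(growth, 0.0, None)
    growth_df = pd.DataFrame(growth, index=pd.Index(mirna_ids, name="mirna_id"),
                             columns=lines)
    growth_sm = ScreenMatrix(values=growth_df,
                             roles={c: "cell_line" for c in lines})

    refs = [f"NORMAL{j + 1}" for j in range(_N_NORMAL_REFS)]
    tumors = [f"T{j + 1:02d}" for j in range(_N_TUMOR_PAIRS)]
    nontumors = [f"N{j + 1:02d}" for j in range(_N_TUMOR_PAIRS)]
    base = 100.0 * 2.0 ** rng.normal(0.0, 1.0, size=m)
    line_factor = np.where(is_ts, _TS_LINE_FACTOR, 1.0)
    tumor_factor = np.where(is_ts, _TS_TUMOR_FACTOR, 1.0)

    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    noise = lambda: 2.0 ** rng.normal(0.0, config.array_noise_sd, size=m)
    for r in refs:
        cols[r] = base * noise()
        roles[r] = "normal_reference"
    for c in lines:
        cols[c] = base * line_factor * noise()
        roles[c] = "cell_line"
    for j, (t, nt) in enumerate(zip(tumors, nontumors)):
        pair = f"P{j + 1:02d}"
        nontumor_val = base * noise()
        cols[nt] = nontumor_val
        cols[t] = nontumor_val * tumor_factor * noise()
        roles[nt] = f"nontumor:{pair}"
        roles[t] = f"tumor:{pair}"
    panel_df = pd.DataFrame(cols, index=pd.Index(mirna_ids, name="mirna_id"))
    panel_sm = ScreenMatrix(values=panel_df, roles=roles)

    truth = SyntheticTruth(true_ts_mirna_ids=set(mirna_ids[is_ts]))
    return ScreenSim(config=config, growth=growth_sm, panel=panel_sm, truth=truth)
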