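import numpy as np
import pandas as pd
import pytest

from mirtarget import ScreenMatrix, SimulationConfig


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale simulation used across tests."""
    return SimulationConfig(n_genes=600, rng_seed=11)


@pytest.fixture
def toy_growth() -> ScreenMatrix:
    """3 miRNAs x 6 cell lines of control-normalized growth ratios."""
    lines = [f"L{i}" for i in range(1, 7)]
    values = pd.DataFrame(
        [
            [0.5] * 6,                                  # suppressed everywhere
            [0.79, 0.79, 0.79, 0.79, 1.0, 1.0],         # exactly 4 hit lines
            [0.79, 0.79, 0.79, 1.0, 1.0, 1.0],          # only 3 hit lines
        ],
        index=["miR-A", "miR-B", "miR-C"],
        columns=lines,
    )
    return ScreenMatrix(values=values, roles={c: "cell_line" for c in lines})


def make_panel(line_values: dict[str, list[float]], ref: float = 100.0,
               tn_ratios: dict[str, list[tuple[float, float]]] | None = None) -> ScreenMatrix:
    """Build a screen panel with one reference, 6 lines, optional T/N pairs."""
    mirnas = list(line_values)
    lines = [f"L{i}" for i in range(1, 7)]
    cols = {"REF": [ref] * len(mirnas)}
    roles = {"REF": "normal_reference"}
    for j, c in enumerate(lines):
        cols[c] = [line_values[m][j] for m in mirnas]
        roles[c] = "cell_line"
    if tn_ratios:
        n_pairs = len(next(iter(tn_ratios.values())))
        for p in range(n_pairs):
            t, n = f"T{p}", f"N{p}"
            cols[t] = [tn_ratios[m][p][0] for m in mirnas]
            cols[n] = [tn_ratios[m][p][1] for m in mirnas]
            roles[t] = f"tumor:P{p}"
            roles[n] = f"nontumor:P{p}"
    values = pd.DataFrame(cols, index=mirnas)
    return ScreenMatrix(values=values, roles=roles)


def brute_force_running_sum(metrics: np.ndarray, hit: np.ndarray,
                            exponent: float = 1.0) -> np.ndarray:
    """Independent position-by-position recomputation of the weighted-KS walk."""
    n = len(metrics)
    nh = int(hit.sum())
    denom = sum(abs(metrics[i]) ** exponent for i in range(n) if hit[i])
    rs, acc = [], 0.0
    for i in range(n):
        if hit[i]:
            acc += (abs(metrics[i]) ** exponent) / denom if denom > 0 else 1.0 / nh
        else:
            acc -= 1.0 / (n - nh)
        rs.append(acc)
    return np.asarray(rs)


def brute_force_es(metrics: np.ndarray, hit: np.ndarray, exponent: float = 1.0) -> float:
    rs = brute_force_running_sum(metrics, hit, exponent)
    return float(rs[int(np.argmax(np.abs(rs)))])
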