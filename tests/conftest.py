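import numpy as np
import pandas as pd
import pytest

from lpsmono import qc, simulate
from lpsmono.gpr import ArrayScan


@pytest.fixture(scope="session")
def small_config():
    """A fast-but-realistic design: 300 genes, full array complement."""
    return simulate.SimulationConfig(n_genes=300, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    arrays, metadata, truth = simulate.generate_experiment(small_config)
    annotation = simulate.make_annotation(small_config)
    return {"arrays": arrays, "metadata": metadata, "truth": truth,
            "annotation": annotation, "config": small_config}


def clean_spot(**overrides):
    """A spot that passes every QC criterion with margin."""
    spot = {
        "block": 1, "row": 1, "column": 1, "spot_id": "SP1", "gene_id": "G1",
        "flag": 0,
    }
    for k in (1, 2):
        spot.update({
            f"f{k}_median": 1000.0, f"f{k}_mean": 1010.0, f"f{k}_sd": 100.0,
            f"b{k}_median": 50.0, f"b{k}_sd": 5.0,
            f"f{k}_pct_sat": 1.0, f"f{k}_pct_gt_b1sd": 98.0,
            f"f{k}_pct_gt_b2sd": 95.0,
        })
    spot.update(overrides)
    return spot


def random_spot_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Spots with values straddling every QC decision boundary."""
    cols = {
        "block": np.ones(n, dtype=int), "row": np.arange(n) + 1,
        "column": np.ones(n, dtype=int),
        "spot_id": [f"SP{i}" for i in range(n)],
        "gene_id": [f"G{i}" for i in range(n)],
        "flag": rng.choice([0, 0, 0, -100, 50], size=n),
    }
    for k in (1, 2):
        median = rng.uniform(0, 2000, n)
        cols[f"f{k}_median"] = median
        cols[f"f{k}_mean"] = median * rng.uniform(0.8, 1.2, n)
        cols[f"f{k}_sd"] = cols[f"f{k}_mean"] * rng.uniform(0.1, 1.0, n)
        cols[f"b{k}_median"] = rng.uniform(0, 200, n)
        cols[f"b{k}_sd"] = rng.uniform(0, 20, n)
        cols[f"f{k}_pct_sat"] = rng.uniform(0, 40, n)
        cols[f"f{k}_pct_gt_b1sd"] = rng.uniform(80, 100, n)
        cols[f"f{k}_pct_gt_b2sd"] = rng.uniform(70, 100, n)
    return pd.DataFrame(cols)


def scan_from_spots(spots: pd.DataFrame, array_id="A1", subject_id="S01",
                    contrast="T0_vs_T4", arm="LPS",
                    dye_of_post_sample="ch2") -> ArrayScan:
    return ArrayScan(array_id=array_id, subject_id=subject_id,
                     contrast=contrast, arm=arm,
                     dye_of_post_sample=dye_of_post_sample, spots=spots)


def brute_force_spot_qc(spot: dict, t: qc.QCThresholds) -> set:
    """Independent scalar re-evaluation of the five inclusion criteria."""
    failed = set()
    if spot["flag"] != 0:
        failed.add("flagged")
    for k in (1, 2):
        med, mean = spot[f"f{k}_median"], spot[f"f{k}_mean"]
        if med == 0 or abs(med - mean) / med >= t.max_median_mean_dev:
            failed.add("median_mean_dev")
        if spot[f"f{k}_pct_sat"] >= t.max_saturation:
            failed.add("saturation")
        sd = spot[f"f{k}_sd"]
        if sd == 0:
            if not mean > 0:
                failed.add("snr")
        elif mean / sd <= t.min_snr:
            failed.add("snr")
        if (spot[f"f{k}_pct_gt_b1sd"] <= t.min_pct_bg1sd
                or spot[f"f{k}_pct_gt_b2sd"] <= t.min_pct_bg2sd):
            failed.add("bg_exceedance")
    return failed


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH by direct evaluation of the defining minimum:
    q_i = min over {j : p_j >= p_i} of m * p_j / rank_j, clipped to 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    ranks = np.empty(m, dtype=int)
    ranks[np.argsort(p, kind="mergesort")] = np.arange(1, m + 1)
    adjusted = m * p / ranks
    q = np.array([adjusted[p >= pi].min() for pi in p])
    return np.minimum(q, 1.0)
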