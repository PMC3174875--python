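"""Synthetic paired two-color hybridization experiments with known truth.

The generator emulates the study design this pipeline targets: for each
subject, RNA drawn before and after an endotoxin (or saline) infusion is
labelled with two dyes and co-hybridized, so each array measures one
paired post/pre contrast.  A configurable fraction of genes is spiked
with true fold changes; control (saline) arrays carry no true signal.

Per-spot intensities follow an MA-style construction: the average log2
intensity A of a gene is drawn once, the true log2 ratio M of gene g on
array a is  true_log2_fc(g) + u_a + dye_bias_a + eps  with a
between-array random effect u_a and spot-level noise eps, and the two
channel foreground medians are background + 2^(A +/- M/2).  Pixel-level
summary statistics (mean, SD, saturation, background-exceedance
percentages) are generated so that clean spots pass every QC criterion
with margin, while independently drawn fractions of spots violate each
criterion individually.

All randomness derives from a single integer seed through named
substreams; identical config + seed reproduces every table bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .gpr import ArrayScan, write_gpr

_STREAMS = ("truth", "intensity", "lps_arrays", "control_arrays", "metadata", "qpcr")


@dataclass(frozen=True)
class SimulationConfig:
    """Design parameters of one synthetic experiment.

    Defaults reproduce the study conditions: 10 LPS arrays (5 subjects,
    duplicate hybridizations) vs 4 control arrays for the 4-hour
    contrast, duplicate spots per gene, and spiked fold changes spanning
    the published range 2.0-5.9.
    """

    n_genes: int = 2000
    n_spots_per_gene: int = 2
    n_arrays_lps: int = 10
    n_arrays_control: int = 4
    frac_de: float = 0.05
    fc_range: tuple[float, float] = (2.0, 5.9)
    frac_down: float = 0.1
    dye_bias_sd: float = 0.1       # log2 units, per array
    array_effect_sd: float = 0.2   # log2 units (tau)
    spot_noise_sd: float = 0.3     # log2 units (sigma)
    frac_flagged: float = 0.05
    frac_saturated: float = 0.02
    frac_bad_snr: float = 0.02
    frac_bad_median_mean: float = 0.02
    frac_bad_bg: float = 0.02
    background_level: float = 100.0
    a_range: tuple[float, float] = (8.0, 14.0)  # log2 intensity of spots
    purity_range: tuple[float, float] = (85.0, 99.0)
    contrast: str = "T0_vs_T4"
    dye_swap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_spots_per_gene", "n_arrays_lps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(name, "must be >= 1")
        if self.n_arrays_control < 0:
            raise ConfigurationError("n_arrays_control", "must be >= 0")
        for name in ("frac_de", "frac_down", "frac_flagged", "frac_saturated",
                     "frac_bad_snr", "frac_bad_median_mean", "frac_bad_bg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(name, f"{v} outside [0, 1]")
        lo, hi = self.fc_range
        if lo <= 1:
            raise ConfigurationError("fc_range", "lower bound must be > 1")
        if hi < lo:
            raise ConfigurationError("fc_range", "upper bound below lower")
        for name in ("dye_bias_sd", "array_effect_sd", "spot_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(name, "must be >= 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level", "must be >= 0")
        plo, phi = self.purity_range
        if not (0 <= plo <= phi <= 100):
            raise ConfigurationError("purity_range", "must satisfy 0 <= lo <= hi <= 100")
        if self.contrast not in ("T0_vs_T1", "T0_vs_T4"):
            raise ConfigurationError("contrast", f"unknown contrast '{self.contrast}'")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def gene_ids_for(config: SimulationConfig) -> np.ndarray:
    return np.array([f"GENE{i + 1:05d}" for i in range(config.n_genes)])


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic spot -> gene annotation for the simulated layout."""
    genes = gene_ids_for(config)
    rows = [{"spot_id": f"SP{i + 1:05d}.{r + 1}", "gene_id": genes[i]}
            for i in range(config.n_genes)
            for r in range(config.n_spots_per_gene)]
    return pd.DataFrame(rows)


def make_truth(config: SimulationConfig,
               rng: np.random.Generator) -> pd.DataFrame:
    genes = gene_ids_for(config)
    n_de = round(config.n_genes * config.frac_de)
    fc = np.zeros(config.n_genes)
    is_de = np.zeros(config.n_genes, dtype=bool)
    if n_de:
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
        lo, hi = np.log2(config.fc_range[0]), np.log2(config.fc_range[1])
        mag = rng.uniform(lo, hi, size=n_de)
        n_down = round(n_de * config.frac_down)
        sign = np.ones(n_de)
        if n_down:
            sign[rng.choice(n_de, size=n_down, replace=False)] = -1.0
        fc[de_idx] = sign * mag
        is_de[de_idx] = True
    return pd.DataFrame({"gene_id": genes, "true_log2_fc": fc, "is_de": is_de})


def _simulate_array(config: SimulationConfig, true_fc: np.ndarray,
                    a_gene: np.ndarray, rng: np.random.Generator,
                    array_id: str, subject_id: str, arm: str,
                    dye_of_post: str) -> ArrayScan:
    n_spots = config.n_genes * config.n_spots_per_gene
    fc_spot = np.repeat(true_fc, config.n_spots_per_gene)
    a_spot = np.repeat(a_gene, config.n_spots_per_gene) + rng.normal(0, 0.1, n_spots)

    u = rng.normal(0, config.array_effect_sd)
    dye = rng.normal(0, config.dye_bias_sd)
    m_spot = fc_spot + u + dye + rng.normal(0, config.spot_noise_sd, n_spots)

    net_post = 2.0 ** (a_spot + m_spot / 2)
    net_pre = 2.0 ** (a_spot - m_spot / 2)
    bg = {ch: config.background_level * rng.uniform(0.8, 1.2, n_spots)
          for ch in ("ch1", "ch2")}
    net = {dye_of_post: net_post,
           ("ch1" if dye_of_post == "ch2" else "ch2"): net_pre}

    cols: dict[str, np.ndarray] = {}
    # independent per-criterion violations, injected on channel 1 (the
    # either-channel rule makes the whole spot fail)
    bad_mm = rng.random(n_spots) < config.frac_bad_median_mean
    bad_snr = rng.random(n_spots) < config.frac_bad_snr
    bad_sat = rng.random(n_spots) < config.frac_saturated
    bad_bg = rng.random(n_spots) < config.frac_bad_bg
    flagged = rng.random(n_spots) < config.frac_flagged

    for k, ch in enumerate(("ch1", "ch2"), start=1):
        fg_median = net[ch] + bg[ch]
        delta = rng.uniform(-0.05, 0.05, n_spots)
        if ch == "ch1":
            delta = np.where(
                bad_mm,
                np.sign(rng.standard_normal(n_spots)) * rng.uniform(0.12, 0.4, n_spots),
                delta)
        fg_mean = fg_median * (1 + delta)
        snr = rng.uniform(4.0, 12.0, n_spots)
        if ch == "ch1":
            snr = np.where(bad_snr, rng.uniform(0.5, 1.8, n_spots), snr)
        fg_sd = fg_mean / snr
        pct_sat = rng.uniform(0.0, 10.0, n_spots)
        if ch == "ch1":
            pct_sat = np.where(bad_sat, rng.uniform(25.0, 95.0, n_spots), pct_sat)
        p1 = rng.uniform(92.0, 100.0, n_spots)
        p2 = rng.uniform(82.0, 100.0, n_spots)
        if ch == "ch1":
            p1 = np.where(bad_bg, rng.uniform(50.0, 88.0, n_spots), p1)
        cols[f"f{k}_median"] = fg_median
        cols[f"f{k}_mean"] = fg_mean
        cols[f"f{k}_sd"] = fg_sd
        cols[f"b{k}_median"] = bg[ch]
        cols[f"b{k}_sd"] = 0.1 * bg[ch]
        cols[f"f{k}_pct_sat"] = pct_sat
        cols[f"f{k}_pct_gt_b1sd"] = p1
        cols[f"f{k}_pct_gt_b2sd"] = p2

    idx = np.arange(n_spots)
    spots = pd.DataFrame({
        "block": idx // 10000 + 1,
        "row": (idx % 10000) // 100 + 1,
        "column": idx % 100 + 1,
        "spot_id": [f"SP{i // config.n_spots_per_gene + 1:05d}."
                    f"{i % config.n_spots_per_gene + 1}" for i in idx],
        "gene_id": np.repeat(gene_ids_for(config), config.n_spots_per_gene),
        **cols,
        "flag": np.where(flagged, -100, 0),
    })
    return ArrayScan(array_id=array_id, subject_id=subject_id,
                     contrast=config.contrast, arm=arm,
                     dye_of_post_sample=dye_of_post, spots=spots)


def generate_experiment(config: SimulationConfig
                        ) -> tuple[list[ArrayScan], pd.DataFrame, pd.DataFrame]:
    """Simulate one experiment: (arrays, sample metadata, truth table).

    LPS arrays carry the spiked fold changes of the truth table; control
    (saline) arrays are generated with all true log2 fold changes at 0.
    Subjects contribute duplicate hybridizations (two arrays each).
    """
    streams = _streams(config.seed)
    truth = make_truth(config, streams["truth"])
    a_gene = streams["intensity"].uniform(*config.a_range, size=config.n_genes)

    post_hour = 1 if config.contrast == "T0_vs_T1" else 4

    def build_arm(n_arrays: int, arm: str, prefix: str,
                  rng: np.random.Generator, fc: np.ndarray) -> list[ArrayScan]:
        arrays = []
        for j in range(n_arrays):
            subject = f"{prefix}{j // 2 + 1:02d}"
            dye = "ch2"
            if config.dye_swap and j % 2 == 1:
                dye = "ch1"
            arrays.append(_simulate_array(
                config, fc, a_gene, rng,
                array_id=f"{arm}_{config.contrast}_{subject}_r{j % 2 + 1}",
                subject_id=subject, arm=arm, dye_of_post=dye))
        return arrays

    arrays = build_arm(config.n_arrays_lps, "LPS", "S", streams["lps_arrays"],
                       truth["true_log2_fc"].to_numpy())
    arrays += build_arm(config.n_arrays_control, "saline", "C",
                        streams["control_arrays"], np.zeros(config.n_genes))

    rng_meta = streams["metadata"]
    meta_rows = []
    for scan in arrays:
        for tp in (0, post_hour):
            meta_rows.append({"subject_id": scan.subject_id, "timepoint": tp,
                              "facs_purity": rng_meta.uniform(*config.purity_range),
                              "arm": scan.arm})
    metadata = (pd.DataFrame(meta_rows)
                .drop_duplicates(subset=["subject_id", "timepoint"])
                .reset_index(drop=True))
    return arrays, metadata, truth


def generate_qpcr(truth: pd.DataFrame, n_subjects: int, ct_noise_sd: float,
                  seed: int, gene_ids: list[str] | None = None) -> pd.DataFrame:
    """Synthetic qPCR Ct table whose expected ddCt equals -true_log2_fc.

    Reference-gene wells are exact; Gaussian noise with the stated SD is
    added to the target-gene wells only, so the per-subject ddCt noise SD
    is ct_noise_sd * sqrt(2).
    """
    if truth.empty:
        raise ConfigurationError("truth", "truth table is empty")
    if n_subjects < 1:
        raise ConfigurationError("n_subjects", "must be >= 1")
    if ct_noise_sd < 0:
        raise ConfigurationError("ct_noise_sd", "must be >= 0")
    rng = _streams(seed)["qpcr"]
    sub = truth if gene_ids is None else truth[truth["gene_id"].isin(gene_ids)]
    rows = []
    for rec in sub.itertuples():
        dct0 = rng.uniform(2.0, 8.0)
        for s in range(n_subjects):
            shift = rng.uniform(-1.0, 1.0)  # per-subject plate shift
            ref = 20.0 + shift
            rows.append({"gene_id": rec.gene_id, "subject_id": f"Q{s + 1:02d}",
                         "timepoint": "pre", "ct_target":
                         ref + dct0 + rng.normal(0, ct_noise_sd),
                         "ct_reference": ref})
            rows.append({"gene_id": rec.gene_id, "subject_id": f"Q{s + 1:02d}",
                         "timepoint": "post", "ct_target":
                         ref + dct0 - rec.true_log2_fc + rng.normal(0, ct_noise_sd),
                         "ct_reference": ref})
    return pd.DataFrame(rows)


def write_experiment(arrays: list[ArrayScan], metadata: pd.DataFrame,
                     truth: pd.DataFrame, annotation: pd.DataFrame,
                     out_dir: str | Path, config: SimulationConfig) -> None:
    """Write GPR files, metadata/truth/annotation TSVs and a provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scan in arrays:
        write_gpr(scan, out / f"{scan.array_id}.gpr")
    metadata.to_csv(out / "sample_metadata.tsv", sep="\t", index=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    provenance = {"seed": config.seed, "config": dataclasses.asdict(config)}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
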