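"""Sample gating and spot/feature quality control.

Implements the study's stringent inclusion rules: a FACS-purity gate on
samples, five per-spot criteria evaluated on both channels (a spot needs
two trustworthy channels to yield a ratio), and a per-gene inclusion
filter on the ratio matrix (enough valid arrays, consistent direction of
regulation).  All printed thresholds are strict inequalities: a spot
exactly at a boundary fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .gpr import ArrayScan

log = logging.getLogger(__name__)

#: QC criterion labels, in the order they are reported.
CRITERIA = ("flagged", "median_mean_dev", "saturation", "snr", "bg_exceedance")


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds for the sample gate and the five spot criteria.

    Defaults are the study's values.  ``min_direction_fraction`` and
    ``min_valid_fraction`` govern the gene-level inclusion filter.
    """

    min_purity: float = 80.0            # %
    max_median_mean_dev: float = 0.1    # |median - mean| / median
    max_saturation: float = 20.0        # % saturated pixels
    min_snr: float = 2.0                # mean / SD
    min_pct_bg1sd: float = 90.0         # % pixels > background + 1 SD
    min_pct_bg2sd: float = 80.0         # % pixels > background + 2 SD
    min_direction_fraction: float = 0.5
    min_valid_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("min_purity", "max_saturation", "min_pct_bg1sd", "min_pct_bg2sd"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(name, f"{v} outside [0, 100]")
        for name in ("min_direction_fraction", "min_valid_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(name, f"{v} outside [0, 1]")
        if self.max_median_mean_dev < 0:
            raise ConfigurationError("max_median_mean_dev", "must be >= 0")
        if self.min_snr < 0:
            raise ConfigurationError("min_snr", "must be >= 0")


@dataclass
class SpotQCResult:
    """QC outcome for one spot."""

    spot_id: str
    passed: bool
    failed_criteria: set = field(default_factory=set)

    def __post_init__(self) -> None:
        assert self.passed == (not self.failed_criteria)


def gate_samples(metadata: pd.DataFrame, thresholds: QCThresholds) -> set[tuple]:
    """Retain samples with FACS purity strictly above the gate.

    Returns the set of included ``(subject_id, timepoint)`` pairs.
    Raises :class:`DataError` listing any samples with missing purity.
    """
    missing = metadata[metadata["facs_purity"].isna()]
    if len(missing):
        samples = [f"{r.subject_id}@T{r.timepoint}" for r in missing.itertuples()]
        raise DataError(f"missing FACS purity for samples: {samples}")
    kept = metadata[metadata["facs_purity"] > thresholds.min_purity]
    if kept.empty:
        log.warning("sample gate at purity > %s excluded all %d samples",
                    thresholds.min_purity, len(metadata))
    return {(r.subject_id, r.timepoint) for r in kept.itertuples()}


def select_top_samples(metadata: pd.DataFrame, k: int,
                       thresholds: QCThresholds | None = None) -> set[str]:
    """The ``k`` gated subjects with the highest FACS purity.

    A subject's purity is the minimum over its gated samples (a paired
    hybridization needs both timepoints to be clean).  Ties at the cut
    are broken by lexicographic subject_id.
    """
    thresholds = thresholds or QCThresholds()
    gated = gate_samples(metadata, thresholds)
    rows = metadata[[(r.subject_id, r.timepoint) in gated
                     for r in metadata.itertuples()]]
    per_subject = rows.groupby("subject_id")["facs_purity"].min()
    if k > len(per_subject):
        raise DataError(f"k={k} exceeds the {len(per_subject)} gated subjects")
    order = sorted(per_subject.items(), key=lambda kv: (-kv[1], kv[0]))
    return {subject for subject, _ in order[:k]}


def spot_qc_table(spots: pd.DataFrame, thresholds: QCThresholds) -> pd.DataFrame:
    """Vectorized evaluation of the five criteria on a spot table.

    Returns a frame indexed like ``spots`` with one boolean ``fail_*``
    column per criterion plus ``passed``.  Criteria (ii)-(v) are applied
    to both channels; the spot fails if either channel fails.
    """
    t = thresholds
    out = pd.DataFrame(index=spots.index)
    out["fail_flagged"] = spots["flag"].to_numpy() != 0

    def per_channel(fn) -> np.ndarray:
        return fn("f1", "b1") | fn("f2", "b2")

    def median_mean(f: str, b: str) -> np.ndarray:
        med = spots[f"{f}_median"].to_numpy(dtype=float)
        mean = spots[f"{f}_mean"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs(med - mean) / med
        dev = np.where(med == 0, np.inf, dev)  # divide-by-zero sentinel
        return dev >= t.max_median_mean_dev

    def saturation(f: str, b: str) -> np.ndarray:
        return spots[f"{f}_pct_sat"].to_numpy(dtype=float) >= t.max_saturation

    def snr(f: str, b: str) -> np.ndarray:
        mean = spots[f"{f}_mean"].to_numpy(dtype=float)
        sd = spots[f"{f}_sd"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mean / sd
        ratio = np.where(sd == 0, np.where(mean > 0, np.inf, 0.0), ratio)
        return ratio <= t.min_snr

    def bg(f: str, b: str) -> np.ndarray:
        p1 = spots[f"{f}_pct_gt_b1sd"].to_numpy(dtype=float)
        p2 = spots[f"{f}_pct_gt_b2sd"].to_numpy(dtype=float)
        return (p1 <= t.min_pct_bg1sd) | (p2 <= t.min_pct_bg2sd)

    out["fail_median_mean_dev"] = per_channel(median_mean)
    out["fail_saturation"] = per_channel(saturation)
    out["fail_snr"] = per_channel(snr)
    out["fail_bg_exceedance"] = per_channel(bg)
    out["passed"] = ~out[[f"fail_{c}" for c in CRITERIA]].any(axis=1)
    return out


def spot_qc(spot: Mapping | pd.Series, thresholds: QCThresholds) -> SpotQCResult:
    """Evaluate the five criteria on a single spot."""
    frame = pd.DataFrame([dict(spot)])
    row = spot_qc_table(frame, thresholds).iloc[0]
    failed = {c for c in CRITERIA if row[f"fail_{c}"]}
    return SpotQCResult(spot_id=str(spot.get("spot_id", "?")),
                        passed=not failed, failed_criteria=failed)


def feature_inclusion(ratios, thresholds: QCThresholds) -> tuple[np.ndarray, pd.DataFrame]:
    """Gene-level inclusion filter on a :class:`~lpsmono.model.RatioMatrix`.

    A gene is retained iff it has valid measurements on at least
    ``min_valid_fraction`` of the arrays, and among valid arrays the
    larger of the up/down fractions reaches ``min_direction_fraction``
    (M = 0 counts in neither direction).  Returns ``(mask, audit)``.
    """
    M, valid = ratios.M, ratios.valid_mask
    n_arrays = M.shape[1]
    n_valid = valid.sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac_up = np.where(n_valid > 0,
                           ((M > 0) & valid).sum(axis=1) / np.maximum(n_valid, 1), 0.0)
        frac_down = np.where(n_valid > 0,
                             ((M < 0) & valid).sum(axis=1) / np.maximum(n_valid, 1), 0.0)
    enough_valid = n_valid >= thresholds.min_valid_fraction * n_arrays
    directional = np.maximum(frac_up, frac_down) >= thresholds.min_direction_fraction
    mask = enough_valid & directional & (n_valid > 0)

    reason = np.full(len(mask), "", dtype=object)
    reason[~directional] = "direction_fraction"
    reason[~enough_valid] = "insufficient_valid_arrays"
    reason[n_valid == 0] = "no_valid_measurements"
    reason[mask] = ""
    audit = pd.DataFrame({
        "gene_id": ratios.gene_ids,
        "n_valid": n_valid,
        "frac_up": frac_up,
        "frac_down": frac_down,
        "included": mask,
        "reason": reason,
    })
    return mask, audit


def qc_summary(qc_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-array spot pass fractions plus the cross-array mean row.

    ``qc_tables`` maps array_id -> output of :func:`spot_qc_table`.
    """
    rows = []
    for array_id, table in qc_tables.items():
        n = len(table)
        n_pass = int(table["passed"].sum())
        rows.append({"array_id": array_id, "n_spots": n, "n_pass": n_pass,
                     "pass_fraction": n_pass / n if n else float("nan")})
    summary = pd.DataFrame(rows)
    mean_row = {"array_id": "MEAN", "n_spots": summary["n_spots"].sum(),
                "n_pass": summary["n_pass"].sum(),
                "pass_fraction": summary["pass_fraction"].mean()}
    summary = pd.concat([summary, pd.DataFrame([mean_row])], ignore_index=True)
    for row in rows:
        log.info("array %s: %.1f%% of spots passed QC",
                 row["array_id"], 100 * row["pass_fraction"])
    return summary


def run_spot_qc(arrays: Iterable[ArrayScan],
                thresholds: QCThresholds) -> dict[str, pd.DataFrame]:
    """Apply :func:`spot_qc_table` to every array; keyed by array_id."""
    return {scan.array_id: spot_qc_table(scan.spots, thresholds) for scan in arrays}
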