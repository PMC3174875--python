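"""Differential-expression calls, direction classification, and overlaps.

A gene is called DE when it clears all four gates simultaneously:
FDR q-value, posterior probability, fold change (applied symmetrically:
FC > threshold or FC < 1/threshold), and the fraction of arrays showing
the fold change in the called direction.  Down-regulation is represented
on the ratio scale as FC < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, NamespaceError
from .fixtures import PaperGeneRecord


@dataclass(frozen=True)
class CallThresholds:
    """The study's call gates (defaults are its published values)."""

    max_fdr: float = 0.005
    min_posterior: float = 0.95
    min_fold: float = 2.0
    min_consistency: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.max_fdr <= 1:
            raise ConfigurationError("max_fdr", "must be in (0, 1]")
        if not 0 <= self.min_posterior < 1:
            raise ConfigurationError("min_posterior", "must be in [0, 1)")
        if self.min_fold <= 1:
            raise ConfigurationError("min_fold", "must be > 1")
        if not 0 <= self.min_consistency <= 1:
            raise ConfigurationError("min_consistency", "must be in [0, 1]")


@dataclass
class DEList:
    """Called genes for one contrast."""

    contrast: str
    records: pd.DataFrame  # gene_id, fold_change, direction, q_value, posterior_prob

    def __len__(self) -> int:
        return len(self.records)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.records["gene_id"])


def fold_gate(fold_change, min_fold: float = 2.0):
    """Symmetric fold-change gate: FC > min_fold or FC < 1/min_fold."""
    fc = np.asarray(fold_change, dtype=float)
    return (fc > min_fold) | (fc < 1.0 / min_fold)


def call_de(results: pd.DataFrame, thresholds: CallThresholds,
            contrast: str = "T0_vs_T4") -> DEList:
    """Apply the four gates to a GeneResult frame (see :mod:`lpsmono.model`)."""
    r = results
    called = (
        (r["q_value"] < thresholds.max_fdr)
        & (r["posterior_prob"] > thresholds.min_posterior)
        & fold_gate(r["fold_change"], thresholds.min_fold)
        & (r["consistency_fraction"] >= thresholds.min_consistency)
    ).fillna(False)
    cols = ["gene_id", "fold_change", "direction", "q_value",
            "posterior_prob", "consistency_fraction", "mu_hat"]
    cols = [c for c in cols if c in r.columns]
    records = r.loc[called, cols].sort_values(
        "fold_change", ascending=False).reset_index(drop=True)
    return DEList(contrast=contrast, records=records)


def classify_directions(de_list: DEList) -> tuple[int, int]:
    """(n_up, n_down) by fold-change direction; the two partition the list."""
    if de_list.records.empty:
        return 0, 0
    up = (de_list.records["fold_change"] > 1).sum()
    return int(up), int(len(de_list.records) - up)


def delist_from_paper_records(records: Sequence[PaperGeneRecord],
                              contrast: str,
                              min_fold: float = 2.0) -> DEList:
    """Published table rows -> DEList, applying only the fold gate.

    The published rows already passed the statistical gates; the fold
    gate is re-applied so the direction classification is reproducible.
    """
    frame = pd.DataFrame({
        "gene_id": [r.ensembl_id for r in records],
        "hugo_id": [r.hugo_id for r in records],
        "fold_change": [r.fold_change for r in records],
        "p_value": [r.p_value for r in records],
    })
    frame = frame[fold_gate(frame["fold_change"], min_fold)]
    frame["direction"] = np.where(frame["fold_change"] > 1, "up", "down")
    return DEList(contrast=contrast, records=frame.reset_index(drop=True))


def _check_namespace(ids: Iterable[str]) -> None:
    ids = list(ids)
    n_ensg = sum(1 for i in ids if str(i).startswith("ENSG"))
    if 0 < n_ensg < len(ids):
        raise NamespaceError(
            "gene-id set mixes Ensembl (ENSG...) and other identifiers")


def overlap(list_a: Iterable[str], list_b: Iterable[str]) -> set[str]:
    """Exact intersection of two gene-ID sets from one namespace."""
    set_a, set_b = set(list_a), set(list_b)
    _check_namespace(set_a | set_b)
    return set_a & set_b


def candidate_report(in_vivo: Sequence[DEList],
                     in_vitro: set[str]) -> tuple[pd.DataFrame, str]:
    """Genes DE both in vivo (any contrast) and in vitro.

    Returns ``(report, note)``: one row per candidate with the
    contrast(s) of the in-vivo call and its fold change(s), sorted by
    largest fold change descending.
    """
    columns = ["gene_id", "hugo_id", "contrasts", "fold_changes", "max_fold_change"]
    if not in_vitro:
        return (pd.DataFrame(columns=columns),
                "in vitro gene list is empty; no candidates can be selected")
    rows: dict[str, dict] = {}
    for de_list in in_vivo:
        for rec in de_list.records.itertuples():
            entry = rows.setdefault(rec.gene_id, {
                "gene_id": rec.gene_id,
                "hugo_id": getattr(rec, "hugo_id", ""),
                "contrasts": [], "fold_changes": []})
            entry["contrasts"].append(de_list.contrast)
            entry["fold_changes"].append(rec.fold_change)
    union = set(rows)
    candidates = overlap(union, in_vitro)
    out = []
    for gene in candidates:
        entry = rows[gene]
        out.append({
            "gene_id": gene, "hugo_id": entry["hugo_id"],
            "contrasts": ",".join(entry["contrasts"]),
            "fold_changes": ",".join(f"{fc:.2f}" for fc in entry["fold_changes"]),
            "max_fold_change": max(entry["fold_changes"]),
        })
    report = pd.DataFrame(out, columns=columns)
    if len(report):
        report = report.sort_values(
            "max_fold_change", ascending=False).reset_index(drop=True)
    note = f"{len(report)} candidate gene(s) differentially expressed in vivo and in vitro"
    return report, note
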