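"""Relative quantification by the comparative-Ct (delta-delta-Ct) method.

Threshold cycles of the target transcript are normalized to a reference
gene within each sample (dCt = Ct_target - Ct_reference), differenced
between post- and pre-infusion samples of the same subject
(ddCt = dCt_post - dCt_pre), and converted to a fold change as
2^(-mean ddCt), i.e. the geometric mean of per-subject fold changes.
Amplification efficiency is assumed to be exactly 2 per cycle.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)

QPCR_COLUMNS = ["gene_id", "subject_id", "timepoint", "ct_target", "ct_reference"]


def validate_qpcr_table(table: pd.DataFrame) -> None:
    missing = [c for c in QPCR_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"qPCR table missing columns: {missing}")
    bad_tp = set(table["timepoint"]) - {"pre", "post"}
    if bad_tp:
        raise DataError(f"qPCR timepoint must be pre/post, got {sorted(bad_tp)}")
    for col in ("ct_target", "ct_reference"):
        vals = table[col].to_numpy(dtype=float)
        if np.any(~((vals > 0) & (vals < 45))):
            raise DataError(f"{col} outside the valid Ct range (0, 45)")


def ddct_fold_change(table: pd.DataFrame, gene_id: str) -> tuple[float, pd.DataFrame]:
    """Fold change for one gene and the per-subject ddCt values behind it.

    Subjects lacking either the pre or the post row are excluded with a
    warning; an error is raised if none remain.
    """
    validate_qpcr_table(table)
    rows = table[table["gene_id"] == gene_id]
    if rows.empty:
        raise DataError(f"no qPCR rows for gene {gene_id}")
    ddcts = []
    for subject, grp in rows.groupby("subject_id"):
        pre = grp[grp["timepoint"] == "pre"]
        post = grp[grp["timepoint"] == "post"]
        if len(pre) != 1 or len(post) != 1:
            log.warning("gene %s subject %s: unpaired qPCR rows excluded",
                        gene_id, subject)
            continue
        dct_pre = float(pre["ct_target"].iloc[0] - pre["ct_reference"].iloc[0])
        dct_post = float(post["ct_target"].iloc[0] - post["ct_reference"].iloc[0])
        ddcts.append({"subject_id": subject, "ddct": dct_post - dct_pre})
    if not ddcts:
        raise DataError(f"gene {gene_id}: no complete pre/post subject pairs")
    per_subject = pd.DataFrame(ddcts)
    fold = float(2.0 ** (-per_subject["ddct"].mean()))
    return fold, per_subject


def all_fold_changes(table: pd.DataFrame) -> dict[str, float]:
    """ddCt fold change for every gene present in the table."""
    return {g: ddct_fold_change(table, g)[0]
            for g in pd.unique(table["gene_id"])}


def concordance(microarray, qpcr_folds: Mapping[str, float]) -> tuple[pd.DataFrame, str]:
    """Direction agreement between microarray calls and qPCR fold changes.

    ``microarray`` is a :class:`~lpsmono.calls.DEList` or a frame with
    ``gene_id`` and ``direction``.  Genes present on only one side are
    listed as untested and not counted in the summary denominator.
    Returns ``(table, summary)`` with summary like ``"7 of 8"``.
    """
    records = getattr(microarray, "records", microarray)
    rows = []
    for rec in records.itertuples():
        fold = qpcr_folds.get(rec.gene_id)
        if fold is None:
            rows.append({"gene_id": rec.gene_id, "microarray_direction": rec.direction,
                         "qpcr_fold_change": np.nan, "qpcr_direction": "untested",
                         "agree": pd.NA})
            continue
        q_dir = "up" if fold > 1 else "down"
        rows.append({"gene_id": rec.gene_id, "microarray_direction": rec.direction,
                     "qpcr_fold_change": fold, "qpcr_direction": q_dir,
                     "agree": q_dir == rec.direction})
    array_genes = {r.gene_id for r in records.itertuples()}
    for gene in sorted(set(qpcr_folds) - array_genes):
        rows.append({"gene_id": gene, "microarray_direction": "untested",
                     "qpcr_fold_change": qpcr_folds[gene],
                     "qpcr_direction": "up" if qpcr_folds[gene] > 1 else "down",
                     "agree": pd.NA})
    table = pd.DataFrame(rows, columns=["gene_id", "microarray_direction",
                                        "qpcr_fold_change", "qpcr_direction", "agree"])
    tested = table["agree"].notna()
    n = int(tested.sum())
    k = int(table.loc[tested, "agree"].sum()) if n else 0
    return table, f"{k} of {n}"
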