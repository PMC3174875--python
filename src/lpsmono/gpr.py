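"""Reader/writer for the simplified GenePix-results (GPR) dialect.

One file holds one two-color hybridization: a tab-delimited table with a
fixed header of per-spot, per-channel pixel statistics, preceded by
``# key=value`` comment lines carrying the array's design metadata
(subject, contrast, arm, dye orientation).  Real GenePix exports can be
down-converted to this dialect by a simple column mapping; the full ATF
preamble is not supported.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError

#: Header of the dialect, in order.  F/B = foreground/background,
#: 1/2 = channel, %Sat = percent saturated pixels, %>B+nSD = percent of
#: feature pixels above background plus n background SDs.
GPR_COLUMNS = [
    "Block", "Row", "Column", "ID", "Name",
    "F1 Median", "F1 Mean", "F1 SD", "B1 Median", "B1 SD",
    "F1 %Sat", "F1 %>B1+1SD", "F1 %>B1+2SD",
    "F2 Median", "F2 Mean", "F2 SD", "B2 Median", "B2 SD",
    "F2 %Sat", "F2 %>B2+1SD", "F2 %>B2+2SD",
    "Flags",
]

#: GPR header name -> internal spot-table column name.
_COLUMN_MAP = {
    "Block": "block", "Row": "row", "Column": "column",
    "ID": "spot_id", "Name": "gene_id",
    "F1 Median": "f1_median", "F1 Mean": "f1_mean", "F1 SD": "f1_sd",
    "B1 Median": "b1_median", "B1 SD": "b1_sd",
    "F1 %Sat": "f1_pct_sat",
    "F1 %>B1+1SD": "f1_pct_gt_b1sd", "F1 %>B1+2SD": "f1_pct_gt_b2sd",
    "F2 Median": "f2_median", "F2 Mean": "f2_mean", "F2 SD": "f2_sd",
    "B2 Median": "b2_median", "B2 SD": "b2_sd",
    "F2 %Sat": "f2_pct_sat",
    "F2 %>B2+1SD": "f2_pct_gt_b1sd", "F2 %>B2+2SD": "f2_pct_gt_b2sd",
    "Flags": "flag",
}

SPOT_COLUMNS = list(_COLUMN_MAP.values())

_INT_COLUMNS = ["block", "row", "column", "flag"]
_STR_COLUMNS = ["spot_id", "gene_id"]
_FLOAT_COLUMNS = [c for c in SPOT_COLUMNS if c not in _INT_COLUMNS + _STR_COLUMNS]

_PCT_COLUMNS = [c for c in _FLOAT_COLUMNS if "pct" in c]
_SD_COLUMNS = ["f1_sd", "b1_sd", "f2_sd", "b2_sd"]
_INTENSITY_COLUMNS = ["f1_median", "f1_mean", "b1_median",
                      "f2_median", "f2_mean", "b2_median"]

CONTRASTS = ("T0_vs_T1", "T0_vs_T4")
ARMS = ("LPS", "saline")
CHANNELS = ("ch1", "ch2")


@dataclass
class ArrayScan:
    """All spots of one two-color hybridization plus its design metadata.

    ``spots`` is a DataFrame with the columns in :data:`SPOT_COLUMNS`.
    ``dye_of_post_sample`` states which channel carries the post-infusion
    sample; ratio orientation downstream is defined by this field, never
    by column order.
    """

    array_id: str
    subject_id: str
    contrast: str
    arm: str
    dye_of_post_sample: str
    spots: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise FormatError(f"unknown contrast '{self.contrast}'")
        if self.arm not in ARMS:
            raise FormatError(f"unknown arm '{self.arm}'")
        if self.dye_of_post_sample not in CHANNELS:
            raise FormatError(
                f"dye_of_post_sample must be ch1/ch2, got '{self.dye_of_post_sample}'")
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise FormatError(f"spot table missing columns: {missing}")
        validate_spots(self.spots)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def with_dye_swapped(self) -> "ArrayScan":
        """Same physical scan with the complementary dye orientation label."""
        other = "ch1" if self.dye_of_post_sample == "ch2" else "ch2"
        return replace(self, dye_of_post_sample=other)


def validate_spots(spots: pd.DataFrame) -> None:
    """Enforce the per-spot invariants; raise :class:`FormatError` on violation."""
    if spots.empty:
        return
    for c in _PCT_COLUMNS:
        vals = spots[c].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise FormatError(f"column '{c}' outside [0, 100]")
    for c in _INTENSITY_COLUMNS:
        if np.any(spots[c].to_numpy(dtype=float) < 0):
            raise FormatError(f"negative intensity in column '{c}'")
    for c in _SD_COLUMNS:
        if np.any(spots[c].to_numpy(dtype=float) < 0):
            raise FormatError(f"negative SD in column '{c}'")
    grid = spots[["block", "row", "column"]]
    if grid.duplicated().any():
        raise FormatError("duplicate (block, row, column) grid coordinates")


def _parse_preamble(lines: Iterable[str]) -> dict:
    meta = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def read_gpr(path: str | Path) -> ArrayScan:
    """Read one array's feature table.

    Raises :class:`FormatError` on a missing mandatory column (naming it)
    or a non-numeric cell (naming the 1-based line number).
    """
    path = Path(path)
    text = path.read_text()
    preamble: list[str] = []
    data_lines: list[str] = []
    for line in text.splitlines():
        (preamble if line.startswith("#") else data_lines).append(line)
    if not data_lines:
        raise FormatError(f"{path}: no header row")
    meta = _parse_preamble(preamble)

    header = data_lines[0].split("\t")
    missing = [c for c in GPR_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing mandatory column '{missing[0]}'")

    frame = pd.read_csv(
        io.StringIO("\n".join(data_lines)), sep="\t", dtype=str,
        keep_default_na=False,
    )
    frame = frame[GPR_COLUMNS].rename(columns=_COLUMN_MAP)
    n_preamble = len(preamble)
    for col in _INT_COLUMNS + _FLOAT_COLUMNS:
        raw = frame[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & (raw.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line plus 1-based numbering
            raise FormatError(
                f"{path}: non-numeric value '{raw.iloc[row]}' in column "
                f"'{col}' at line {row + n_preamble + 2}")
        if converted.isna().any():
            raise FormatError(f"{path}: empty numeric cell in column '{col}'")
        frame[col] = converted
    for col in _INT_COLUMNS:
        frame[col] = frame[col].astype(int)
    frame["gene_id"] = frame["gene_id"].replace("", pd.NA)

    return ArrayScan(
        array_id=meta.get("array_id", path.stem),
        subject_id=meta.get("subject_id", "unknown"),
        contrast=meta.get("contrast", "T0_vs_T4"),
        arm=meta.get("arm", "LPS"),
        dye_of_post_sample=meta.get("dye_of_post_sample", "ch2"),
        spots=frame.reset_index(drop=True),
    )


def write_gpr(scan: ArrayScan, path: str | Path) -> None:
    """Write the scan in the dialect; numeric values round-trip losslessly."""
    path = Path(path)
    out = scan.spots.copy()
    out = out.rename(columns={v: k for k, v in _COLUMN_MAP.items()})
    out = out[GPR_COLUMNS]
    out["Name"] = out["Name"].fillna("")
    with path.open("w") as fh:
        for key in ("array_id", "subject_id", "contrast", "arm", "dye_of_post_sample"):
            fh.write(f"# {key}={getattr(scan, key)}\n")
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample-metadata TSV: subject_id, timepoint, facs_purity, arm [, rna_yield]."""
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "timepoint", "facs_purity", "arm"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    bad = ~frame["facs_purity"].isna() & (
        (frame["facs_purity"] < 0) | (frame["facs_purity"] > 100))
    if bad.any():
        raise FormatError("facs_purity outside [0, 100]")
    return frame


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV: spot_id -> gene_id (Ensembl) [-> hugo_id]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"spot_id", "gene_id"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"annotation missing columns: {sorted(missing)}")
    return frame
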