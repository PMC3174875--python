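"""Packaged reference tables.

Two fixtures transcribe the published DE gene tables of the in-vivo LPS
study verbatim (including their European decimal commas, which the
parser normalizes); a third is a synthetic stand-in for the in-vitro DE
gene list, shipped as a one-column Ensembl-ID file so a real list can be
plugged in identically.  Checksums guard against accidental edits.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import FormatError, IntegrityError

_CHECKSUMS = {
    "table1.tsv": "c03897efe2698658c3300161af743d534d83d3f95fa6de59023716a49afe390b",
    "table2.tsv": "91368fc7b39bc025bb6381a3d1d87164941c056d7ff5121047d77b072ef59623",
    "invitro_de_genes_synthetic.tsv":
        "485f9dc7c38de42efd3956622c88178c510a28ca38a8dd0def61c359a5af7eb8",
}


@dataclass(frozen=True)
class PaperGeneRecord:
    """One row of a published DE table."""

    ensembl_id: str
    hugo_id: str
    full_name: str
    fold_change: float  # ratio scale; < 1 means down-regulated
    p_value: float

    def __post_init__(self) -> None:
        if not self.fold_change > 0:
            raise FormatError(f"{self.ensembl_id}: fold_change must be > 0")
        if not (0 < self.p_value <= 1):
            raise FormatError(f"{self.ensembl_id}: p_value outside (0, 1]")


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("lpsmono.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise IntegrityError(
            f"fixture {name} checksum mismatch: {digest} != {_CHECKSUMS[name]}")
    return data


def parse_decimal(text: str) -> float:
    """Parse a printed number: decimal comma, optional spaced exponent ('6,0 E-04')."""
    return float(text.strip().replace(" ", "").replace(",", "."))


def _parse_table(name: str) -> list[PaperGeneRecord]:
    lines = _fixture_bytes(name).decode().strip().splitlines()
    records = []
    for line in lines[1:]:
        ensembl, hugo, full_name, fold, p = line.split("\t")
        records.append(PaperGeneRecord(
            ensembl_id=ensembl, hugo_id=hugo, full_name=full_name,
            fold_change=parse_decimal(fold), p_value=parse_decimal(p)))
    return records


def load_paper_tables() -> tuple[list[PaperGeneRecord], list[PaperGeneRecord]]:
    """Published DE gene tables for the 1 h and 4 h post-infusion contrasts.

    Returns ``(t1_records, t4_records)`` — 11 and 28 records respectively.
    """
    return _parse_table("table1.tsv"), _parse_table("table2.tsv")


def load_invitro_genes(path: str | Path | None = None) -> set[str]:
    """In-vitro DE gene-ID set.

    By default the packaged synthetic stub (six established candidates
    plus decoys); pass ``path`` to use a real one-column gene-ID file.
    """
    if path is None:
        lines = _fixture_bytes("invitro_de_genes_synthetic.tsv").decode().strip().splitlines()
    else:
        lines = Path(path).read_text().strip().splitlines()
    header = lines[0].strip().lower()
    body = lines[1:] if header in {"gene_id", "ensembl_id"} else lines
    return {line.strip() for line in body if line.strip()}
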