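"""Repertoire input/output: FASTA, AIRR-style rearrangement TSV, filters.

AIRR region columns use 1-based closed coordinates by convention; everything
internal is 0-based half-open, converted on read and write.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .annotate import annotate_regions
from .errors import ConsistencyError, ParseError, SchemaError, ValidationError
from .records import REGIONS, RegionAnnotation, VhhRecord

logger = logging.getLogger(__name__)

_AIRR_REGION_COLS = {
    "FR1": "fwr1", "CDR1": "cdr1", "FR2": "fwr2", "CDR2": "cdr2",
    "FR3": "fwr3", "CDR3": "cdr3", "FR4": "fwr4",
}
_META_COLS = ("count", "animal_id", "age_group", "hinge_suffix")


def read_fasta(
    path: str | Path, metadata: Optional[pd.DataFrame] = None
) -> list[VhhRecord]:
    """Read amino-acid sequences from FASTA into records.

    ``metadata`` is an optional table indexed by (or with a column)
    ``sequence_id`` carrying count, animal_id, age_group and hinge_suffix;
    the count defaults to 1 when absent.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1 does not start a FASTA entry")
    meta = None
    if metadata is not None:
        meta = metadata.set_index("sequence_id") if "sequence_id" in metadata.columns else metadata
    records: list[VhhRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate FASTA header {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper()
        if "*" in seq or "-" in seq or "." in seq:
            raise ValidationError(
                f"record {entry.id!r}: stop ('*') or gap characters are not allowed"
            )
        kwargs = {}
        if meta is not None and entry.id in meta.index:
            row = meta.loc[entry.id]
            if "count" in row and pd.notna(row["count"]):
                kwargs["count"] = int(row["count"])
            for col in ("animal_id", "age_group", "hinge_suffix"):
                if col in row and pd.notna(row[col]):
                    kwargs[col] = str(row[col])
        records.append(VhhRecord(id=entry.id, aa_seq=seq, **kwargs))
    return records


def read_airr_table(path: str | Path) -> list[tuple[VhhRecord, RegionAnnotation]]:
    """Read an AIRR-style rearrangement TSV with region annotations.

    Regions may be given as strings (``fwr1`` .. ``fwr4``, ``cdr1`` ..
    ``cdr3``) or as 1-based closed amino-acid coordinates (``fwr1_start`` /
    ``fwr1_end`` ...).  Rows whose annotation violates the region invariants
    are logged and skipped.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("sequence_id", "sequence_aa"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    has_strings = all(c in df.columns for c in _AIRR_REGION_COLS.values())
    has_coords = all(
        f"{c}_start" in df.columns and f"{c}_end" in df.columns
        for c in _AIRR_REGION_COLS.values()
    )
    if not (has_strings or has_coords):
        raise SchemaError(f"{path}: need region string columns or start/end columns")

    out: list[tuple[VhhRecord, RegionAnnotation]] = []
    for _, row in df.iterrows():
        aa = row["sequence_aa"].upper()
        boundaries: dict[str, tuple[int, int]] = {}
        if has_strings:
            cursor = 0
            ok = True
            for region in REGIONS:
                part = row[_AIRR_REGION_COLS[region]].upper()
                if aa[cursor : cursor + len(part)] != part:
                    raise ConsistencyError(
                        f"{path}: row {row['sequence_id']!r}: {region} string does not "
                        f"match sequence_aa at position {cursor}"
                    )
                boundaries[region] = (cursor, cursor + len(part))
                cursor += len(part)
            if cursor != len(aa):
                ok = False
        else:
            ok = True
            for region in REGIONS:
                start = int(row[f"{_AIRR_REGION_COLS[region]}_start"]) - 1
                end = int(row[f"{_AIRR_REGION_COLS[region]}_end"])  # closed -> half-open
                boundaries[region] = (start, end)
        imgt_map = _imgt_map_from_boundaries(aa, boundaries)
        try:
            ann = RegionAnnotation(boundaries, imgt_map)
            ann.validate_against(aa)
            if not ok:
                raise ValidationError("regions do not cover sequence_aa")
        except ValidationError as exc:
            logger.warning("skipping %s: %s", row["sequence_id"], exc)
            continue
        kwargs = {}
        if "duplicate_count" in df.columns and row["duplicate_count"] != "":
            kwargs["count"] = int(row["duplicate_count"])
        if "sequence" in df.columns and row["sequence"] != "":
            kwargs["nt_seq"] = row["sequence"].upper()
        for col in ("animal_id", "age_group", "hinge_suffix"):
            if col in df.columns and row[col] != "":
                kwargs[col] = row[col]
        out.append((VhhRecord(id=row["sequence_id"], aa_seq=aa, **kwargs), ann))
    return out


def _imgt_map_from_boundaries(
    aa: str, boundaries: Mapping[str, tuple[int, int]]
) -> dict[int, int]:
    """Recover the named IMGT positions from region boundaries.

    FR2 is assumed to span IMGT 39-55 without gaps; the conserved cysteines
    are the ones closest to the expected offsets within FR1/FR3.
    """
    imgt: dict[int, int] = {}
    fr2s, fr2e = boundaries["FR2"]
    if fr2e - fr2s == 17:
        for pos, off in ((39, 0), (40, 1), (41, 2), (42, 3), (49, 10),
                         (50, 11), (52, 13), (53, 14), (55, 16)):
            imgt[pos] = fr2s + off
    fr1s, fr1e = boundaries["FR1"]
    c1 = aa.rfind("C", fr1s, fr1e)
    if c1 >= 0:
        imgt[23] = c1
    fr3s, fr3e = boundaries["FR3"]
    c2 = aa.rfind("C", fr3s, fr3e)
    if c2 >= 0:
        imgt[104] = c2
    imgt[118] = boundaries["FR4"][0]
    return imgt


def write_airr_table(
    items: Iterable[tuple[VhhRecord, RegionAnnotation]], path: str | Path
) -> None:
    """Write records + annotations as an AIRR-style TSV (region strings)."""
    rows = []
    for record, ann in items:
        row = {"sequence_id": record.id, "sequence_aa": record.aa_seq}
        for region in REGIONS:
            row[_AIRR_REGION_COLS[region]] = ann.region_seq(record.aa_seq, region)
        row["duplicate_count"] = record.count
        if record.nt_seq:
            row["sequence"] = record.nt_seq
        row["animal_id"] = record.animal_id
        row["age_group"] = record.age_group or ""
        row["hinge_suffix"] = record.hinge_suffix or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def apply_count_filter(records: list[VhhRecord], min_count: int = 5) -> list[VhhRecord]:
    """Keep records observed at least ``min_count`` times (default 5 reads)."""
    return [r for r in records if r.count >= min_count]


def deduplicate_aa(records: list[VhhRecord]) -> list[VhhRecord]:
    """One record per distinct amino-acid sequence.

    The representative is the highest-count record (first seen wins ties);
    counts are not summed -- duplicates are removed, not collapsed.
    """
    best: dict[str, VhhRecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.aa_seq)
        if cur is None:
            best[r.aa_seq] = r
            order.append(r.aa_seq)
        elif r.count > cur.count:
            best[r.aa_seq] = r
    return [best[seq] for seq in order]


def annotate_repertoire(
    records: Iterable[VhhRecord],
) -> list[tuple[VhhRecord, RegionAnnotation]]:
    """Annotate every record, dropping (and logging) annotation failures."""
    out = []
    for record in records:
        try:
            out.append((record, annotate_regions(record)))
        except Exception as exc:  # noqa: BLE001 - QC drop, reason logged
            logger.warning("dropping %s: %s", record.id, exc)
    return out
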