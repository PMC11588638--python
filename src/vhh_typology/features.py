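"""Per-region physicochemical features of VHH sequences.

Three feature families are computed per record:

* net charge at pH 7.4 using a fixed integer scheme -- D and E count -1,
  R and K count +1, H counts +0.1, every other residue 0 (termini ignored);
* hydropathy as the arithmetic mean of Kyte-Doolittle values over a region;
* isoelectric point (pI) as the root of a Henderson-Hasselbalch net-charge
  model, solved by bisection on pH 0..14 to 1e-4.

The fixed charge scheme and the Henderson-Hasselbalch model coexist on
purpose: the former is the repertoire-level region charge, the latter is
only used inside the pI root-finder.  Regions containing 'X' yield missing
values and are excluded from downstream statistics.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional

import pandas as pd

from .errors import ValidationError
from .records import RegionAnnotation, VhhRecord

#: fixed per-residue charges at pH 7.4
CHARGE_SCHEME = {"D": -1.0, "E": -1.0, "R": 1.0, "K": 1.0, "H": 0.1}

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: named pKa sets for the pI model; keys: N-/C-terminus and ionizable side chains
PKA_SETS = {
    # IPC "protein" set (Kozlowski 2016)
    "IPC_protein": {
        "Nterm": 9.094, "Cterm": 2.869,
        "C": 7.555, "D": 3.872, "E": 4.412, "H": 5.637,
        "K": 9.052, "R": 11.84, "Y": 10.85,
    },
    "EMBOSS": {
        "Nterm": 8.6, "Cterm": 3.6,
        "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5,
        "K": 10.8, "R": 12.5, "Y": 10.1,
    },
}

FEATURE_REGIONS = ("CDR1", "CDR2", "CDR3", "CDRs", "VHH")


def net_charge(region_seq: str) -> float:
    """Net charge of a region at pH 7.4 under the fixed integer scheme."""
    if not region_seq:
        raise ValidationError("empty region")
    if "X" in region_seq:
        return math.nan  # feature undefined; excluded from statistics
    return sum(CHARGE_SCHEME.get(aa, 0.0) for aa in region_seq)


def hydropathy_index(region_seq: str) -> float:
    """Mean Kyte-Doolittle hydropathy of a region (range -4.5 .. 4.5)."""
    if not region_seq:
        raise ValidationError("empty region")
    if "X" in region_seq:
        return math.nan
    return sum(KYTE_DOOLITTLE[aa] for aa in region_seq) / len(region_seq)


def _hh_charge(aa_seq: str, ph: float, pka: dict[str, float]) -> float:
    """Henderson-Hasselbalch net charge of the whole peptide at a given pH."""
    pos = [pka["Nterm"]] + [pka[a] for a in aa_seq if a in "KRH" and a in pka]
    neg = [pka["Cterm"]] + [pka[a] for a in aa_seq if a in "DECY" and a in pka]
    charge = sum(1.0 / (1.0 + 10 ** (ph - p)) for p in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (p - ph)) for p in neg)
    return charge


def isoelectric_point(aa_seq: str, pka_set: str = "IPC_protein", tol: float = 1e-4) -> float:
    """pH at which the modeled net charge of the peptide is zero.

    The charge function is strictly decreasing in pH (every term is), so the
    root on [0, 14] is unique; it is found by bisection to ``tol`` pH units.
    """
    if not aa_seq:
        raise ValidationError("empty sequence")
    pka = PKA_SETS[pka_set]
    lo, hi = 0.0, 14.0
    if _hh_charge(aa_seq, lo, pka) < 0:
        return math.nan  # no ionizable balance within range
    if _hh_charge(aa_seq, hi, pka) > 0:
        return math.nan
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _hh_charge(aa_seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_feature_table(
    items: Iterable[tuple[VhhRecord, RegionAnnotation]],
    pka_set: str = "IPC_protein",
) -> pd.DataFrame:
    """Feature table: CDR3 length, per-region charge/hydropathy, pI.

    One row per record; the aggregate region ``CDRs`` is the concatenation
    CDR1+CDR2+CDR3 and ``VHH`` is the full V region.  Cells for regions
    containing 'X' are NaN.
    """
    rows = []
    for record, ann in items:
        seqs = {r: ann.region_seq(record.aa_seq, r) for r in ("CDR1", "CDR2", "CDR3")}
        seqs["CDRs"] = seqs["CDR1"] + seqs["CDR2"] + seqs["CDR3"]
        seqs["VHH"] = record.aa_seq
        row: dict[str, object] = {
            "sequence_id": record.id,
            "cdr3_length": len(seqs["CDR3"]),
        }
        for region, seq in seqs.items():
            row[f"net_charge_{region}"] = net_charge(seq) if seq else math.nan
            row[f"hydropathy_{region}"] = hydropathy_index(seq) if seq else math.nan
        row["pI"] = (
            isoelectric_point(record.aa_seq, pka_set)
            if "X" not in record.aa_seq
            else math.nan
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["pka_set"] = pka_set
    return df
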