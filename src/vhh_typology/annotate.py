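"""IMGT-anchored region annotation for well-formed VHH domains.

The annotator is deliberately simple and pluggable: production users with
arbitrary antibodies should supply external numbering through AIRR input
(see :mod:`vhh_typology.io`).  The built-in heuristic targets well-formed
V domains and locates three sequence anchors:

* the first conserved cysteine (IMGT 23) inside the FR1 window,
* the invariant FR2 tryptophan (IMGT 41), two residues after the CDR1/FR2
  junction, preferring the canonical ``W[x]RQ`` context,
* the FR4 start motif ``[WR]G.G`` (IMGT 118-121) near the C terminus, and
* the second conserved cysteine (IMGT 104) as the last ``YYC`` context
  preceding FR4 (falling back to the last cysteine before FR4).

Fixed IMGT offsets then place FR2 positions 39-55 relative to the FR2 start
and FR3 as the 39 positions ending at IMGT 104 (no IMGT gaps assumed).
Alternatively a reference annotation can be transferred through a pairwise
alignment (used for germline-guided annotation).
"""

from __future__ import annotations

import re
from typing import Optional

from Bio import Align

from .errors import AnnotationError, ValidationError
from .records import RegionAnnotation, VhhRecord

FR2_LENGTH = 17  # IMGT 39..55
FR3_LENGTH = 39  # IMGT 66..104
FR1_TAIL_AFTER_CYS = 3  # IMGT 24..26 follow the conserved Cys 23

# zero-width lookahead so overlapping candidate sites are all seen
_FR4_MOTIF = re.compile(r"(?=[WR]G.G)")

#: offsets of named FR2 IMGT positions from the index of IMGT 39
_FR2_OFFSETS = {39: 0, 40: 1, 41: 2, 42: 3, 49: 10, 50: 11, 52: 13, 53: 14, 55: 16}


def _find_fr4_start(aa: str) -> int:
    tail_from = max(0, len(aa) - 25)
    matches = list(_FR4_MOTIF.finditer(aa, tail_from))
    if not matches:
        raise AnnotationError("FR4 motif [WR]G.G not found near C terminus", anchor="118")
    return matches[-1].start()


def annotate_regions(
    record: VhhRecord,
    reference: Optional[tuple[str, RegionAnnotation]] = None,
) -> RegionAnnotation:
    """Annotate the seven regions of ``record.aa_seq``.

    Parameters
    ----------
    record:
        The repertoire entry to annotate (``aa_seq`` length >= 90).
    reference:
        Optional ``(reference_aa, reference_annotation)`` pair; when given,
        FR1..FR3 boundaries are transferred through a global pairwise
        alignment instead of the anchor heuristic.  FR4 is always located by
        its start motif and CDR3 is whatever lies between IMGT 104 and FR4.

    Raises
    ------
    AnnotationError
        When an anchor cannot be located; ``.anchor`` names the failing one.
    """
    aa = record.aa_seq
    if len(aa) < 90:
        raise AnnotationError(
            f"record {record.id!r}: sequence too short to annotate ({len(aa)} aa)"
        )
    if reference is not None:
        return _annotate_by_transfer(aa, *reference)

    c1 = aa.find("C", 0, 30)
    if c1 < 0:
        raise AnnotationError(
            f"record {record.id!r}: no cysteine in FR1 window", anchor="23"
        )
    fr1_end = c1 + FR1_TAIL_AFTER_CYS + 1

    # CDR1 lengths 4..12 put the FR2 tryptophan (IMGT 41) 6..14 past FR1
    lo, hi = fr1_end + 6, min(fr1_end + 15, len(aa))
    candidates = [i for i in range(lo, hi) if aa[i] == "W"]
    if not candidates:
        raise AnnotationError(
            f"record {record.id!r}: FR2 tryptophan not found", anchor="41"
        )
    w = next((i for i in candidates if aa[i + 2 : i + 4] == "RQ"), candidates[0])
    fr2_start = w - 2
    fr2_end = fr2_start + FR2_LENGTH

    f4 = _find_fr4_start(aa)

    yyc = aa.rfind("YYC", 0, f4)
    c2 = yyc + 2 if yyc >= 0 else aa.rfind("C", fr2_end, f4)
    if c2 < fr2_end:
        raise AnnotationError(
            f"record {record.id!r}: conserved cysteine 104 not found", anchor="104"
        )
    fr3_start = c2 + 1 - FR3_LENGTH
    if not (fr2_end + 2 <= fr3_start <= c2):
        raise AnnotationError(
            f"record {record.id!r}: CDR2 span inconsistent with FR3 anchor", anchor="104"
        )
    if c2 + 1 >= f4:
        raise AnnotationError(f"record {record.id!r}: empty CDR3", anchor="104")

    boundaries = {
        "FR1": (0, fr1_end),
        "CDR1": (fr1_end, fr2_start),
        "FR2": (fr2_start, fr2_end),
        "CDR2": (fr2_end, fr3_start),
        "FR3": (fr3_start, c2 + 1),
        "CDR3": (c2 + 1, f4),
        "FR4": (f4, len(aa)),
    }
    imgt_map = {pos: fr2_start + off for pos, off in _FR2_OFFSETS.items()}
    imgt_map[23] = c1
    imgt_map[104] = c2
    imgt_map[118] = f4
    try:
        ann = RegionAnnotation(boundaries, imgt_map)
        ann.validate_against(aa)
    except ValidationError as exc:
        raise AnnotationError(f"record {record.id!r}: {exc}") from exc
    return ann


def _aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.end_deletion_score = 0.0  # reference may stop before CDR3/FR4
    return aligner


def _annotate_by_transfer(aa: str, ref_aa: str, ref_ann: RegionAnnotation) -> RegionAnnotation:
    alignment = _aa_aligner().align(aa, ref_aa)[0]
    query_blocks, ref_blocks = alignment.aligned

    def map_pos(ref_idx: int) -> int:
        for (qs, qe), (rs, re_) in zip(query_blocks, ref_blocks):
            if rs <= ref_idx < re_:
                return qs + (ref_idx - rs)
        raise AnnotationError(f"reference position {ref_idx} not alignable", anchor="transfer")

    f4 = _find_fr4_start(aa)
    b = ref_ann.boundaries
    fr1_end = map_pos(b["FR1"][1] - 1) + 1
    fr2_start = map_pos(b["FR2"][0])
    fr2_end = map_pos(b["FR2"][1] - 1) + 1
    fr3_start = map_pos(b["FR3"][0])
    c2 = map_pos(b["FR3"][1] - 1)
    boundaries = {
        "FR1": (0, fr1_end),
        "CDR1": (fr1_end, fr2_start),
        "FR2": (fr2_start, fr2_end),
        "CDR2": (fr2_end, fr3_start),
        "FR3": (fr3_start, c2 + 1),
        "CDR3": (c2 + 1, f4),
        "FR4": (f4, len(aa)),
    }
    imgt_map = {pos: map_pos(idx) for pos, idx in ref_ann.imgt_map.items() if pos != 118}
    imgt_map[118] = f4
    try:
        ann = RegionAnnotation(boundaries, imgt_map)
        ann.validate_against(aa)
    except ValidationError as exc:
        raise AnnotationError(f"transferred annotation invalid: {exc}") from exc
    return ann
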