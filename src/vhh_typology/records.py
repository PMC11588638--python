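"""Core repertoire records and region annotations.

A :class:`VhhRecord` is one unique repertoire entry: the amino-acid V region
(FR1 through FR4, hinge excluded), an optional in-frame nucleotide sequence,
a read count and animal metadata.  A :class:`RegionAnnotation` addresses the
seven canonical regions of the V domain plus a handful of IMGT positions used
by the typing rules (hallmark positions 42/49/50/52 in FR2, the two conserved
cysteines 23 and 104, and 118 at the start of FR4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .errors import ValidationError

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

AGE_GROUPS = ("0-1", "1-2", "3-4")

#: IMGT positions the typing and structure analyses address by name.
IMGT_POSITIONS = (23, 39, 40, 41, 42, 49, 50, 52, 53, 55, 104, 118)


@dataclass
class VhhRecord:
    id: str
    aa_seq: str
    nt_seq: Optional[str] = None
    count: int = 1
    animal_id: str = ""
    age_group: Optional[str] = None
    hinge_suffix: Optional[str] = None

    def __post_init__(self):
        if not self.aa_seq:
            raise ValidationError(f"record {self.id!r}: empty amino-acid sequence")
        bad = set(self.aa_seq) - AA_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: non-amino-acid symbol(s) {sorted(bad)}"
            )
        if self.count < 0:
            raise ValidationError(f"record {self.id!r}: negative count")
        if self.age_group is not None and self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"record {self.id!r}: age_group {self.age_group!r} not one of {AGE_GROUPS}"
            )
        if self.nt_seq is not None:
            if len(self.nt_seq) != 3 * len(self.aa_seq):
                raise ValidationError(
                    f"record {self.id!r}: nt length {len(self.nt_seq)} != 3 x aa length"
                )
            translated = str(Seq(self.nt_seq).translate())
            for got, want in zip(translated, self.aa_seq):
                if want != "X" and got != "X" and got != want:
                    raise ValidationError(
                        f"record {self.id!r}: nt_seq does not translate to aa_seq"
                    )


@dataclass
class RegionAnnotation:
    """Half-open 0-based region boundaries plus an IMGT position map.

    ``boundaries`` maps each region name to ``(start, end)`` indices into the
    amino-acid sequence; ``imgt_map`` maps an IMGT position number to a
    sequence index (positions absent from the sequence are simply missing).
    """

    boundaries: dict[str, tuple[int, int]]
    imgt_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        missing = [r for r in REGIONS if r not in self.boundaries]
        if missing:
            raise ValidationError(f"annotation missing regions {missing}")
        prev_end = 0
        for r in REGIONS:
            s, e = self.boundaries[r]
            if s != prev_end or e < s:
                raise ValidationError(
                    f"regions must be contiguous and ordered; {r} has ({s},{e}), "
                    f"expected start {prev_end}"
                )
            prev_end = e
        fr2 = self.boundaries["FR2"]
        for pos in (42, 49, 50, 52):
            idx = self.imgt_map.get(pos)
            if idx is not None and not (fr2[0] <= idx < fr2[1]):
                raise ValidationError(f"IMGT {pos} maps outside FR2")
        idx118 = self.imgt_map.get(118)
        if idx118 is not None and idx118 != self.boundaries["FR4"][0]:
            raise ValidationError("IMGT 118 must index the first FR4 residue")

    @property
    def length(self) -> int:
        return self.boundaries["FR4"][1]

    def region_of(self, index: int) -> str:
        for r in REGIONS:
            s, e = self.boundaries[r]
            if s <= index < e:
                return r
        raise ValidationError(f"index {index} outside annotated sequence")

    def region_seq(self, aa_seq: str, region: str) -> str:
        s, e = self.boundaries[region]
        return aa_seq[s:e]

    def residue_at(self, aa_seq: str, imgt_pos: int) -> Optional[str]:
        idx = self.imgt_map.get(imgt_pos)
        return aa_seq[idx] if idx is not None else None

    def validate_against(self, aa_seq: str) -> None:
        if self.length != len(aa_seq):
            raise ValidationError(
                f"annotation spans {self.length} residues, sequence has {len(aa_seq)}"
            )
        for pos in (23, 104):
            idx = self.imgt_map.get(pos)
            if idx is not None and aa_seq[idx] != "C":
                raise ValidationError(f"IMGT {pos} does not index a cysteine")
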