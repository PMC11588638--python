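"""Germline assignment, somatic-hypermutation scoring and VHH typing.

A VHH is *classical* when it carries the framework-2 hallmark residues
(F/Y at IMGT 42, E/Q at 49, R at 50) or when its best-matching germline is on
a whitelist of known VHH germlines.  Position 52, the fourth hallmark, is
deliberately not tested: it is too variable, and at least one VHH germline
carries W there.  Classical VHHs split into three types by the residue at 42
and the total cysteine count (Y_C2, F_C2, F_C4); non-classical VHHs split by
best-germline family (N_V3, N_V4).  Everything else is UNASSIGNED.

Somatic hypermutation is scored as mismatches per 100 bp of germline
alignment; gap columns are not counted as mismatches, so the score is a
per-100-bp substitution rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import Align, SeqIO

from .errors import ConfigurationError, ConsistencyError, ValidationError, VhhError
from .records import RegionAnnotation, VhhRecord

VHH_TYPES = ("Y_C2", "F_C2", "F_C4", "N_V3", "N_V4", "UNASSIGNED")

CLASSICAL_R42 = frozenset("FY")
CLASSICAL_R49 = frozenset("EQ")
CLASSICAL_R50 = "R"


@dataclass(frozen=True)
class GermlineEntry:
    gene_name: str
    nt_seq: str
    aa_seq: Optional[str] = None
    region_annotation: Optional[RegionAnnotation] = None

    @property
    def family(self) -> str:
        for fam in ("IGHV1", "IGHV3", "IGHV4"):
            if self.gene_name.startswith(fam) and not self.gene_name[5:6].isdigit():
                return fam
        raise ValidationError(f"cannot parse family from gene name {self.gene_name!r}")


@dataclass
class GermlineDb:
    entries: list[GermlineEntry]
    vhh_whitelist: set[str] = field(default_factory=set)

    def __post_init__(self):
        names = [e.gene_name for e in self.entries]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate gene names in germline db")
        missing = self.vhh_whitelist - set(names)
        if missing:
            raise ConfigurationError(f"whitelisted genes absent from db: {sorted(missing)}")

    def __getitem__(self, gene_name: str) -> GermlineEntry:
        for e in self.entries:
            if e.gene_name == gene_name:
                return e
        raise KeyError(gene_name)


@dataclass(frozen=True)
class GermlineHit:
    gene_name: str
    family: str
    alignment_length: int
    mismatches: int
    score: float
    aa_based: bool = False

    def __post_init__(self):
        if not (0 <= self.mismatches <= self.alignment_length):
            raise ValidationError("mismatches outside [0, alignment_length]")

    @property
    def mismatch_score(self) -> float:
        return mismatch_score(self.mismatches, self.alignment_length)


@dataclass(frozen=True)
class TypeAssignment:
    classical: bool
    vhh_type: str
    rule: str  # hallmark | germline_whitelist | nonclassical
    residue42: str
    n_cys: int

    def __post_init__(self):
        if self.vhh_type not in VHH_TYPES:
            raise ValidationError(f"unknown type {self.vhh_type!r}")
        if self.vhh_type in ("Y_C2", "F_C2", "F_C4") and not self.classical:
            raise ValidationError(f"{self.vhh_type} must be classical")
        if self.vhh_type in ("N_V3", "N_V4") and self.classical:
            raise ValidationError(f"{self.vhh_type} must be non-classical")


def mismatch_score(mismatches: int, alignment_length: int) -> float:
    """Somatic-hypermutation score: mismatches per 100 bp of alignment."""
    if alignment_length <= 0:
        raise ValidationError("alignment_length must be positive")
    return 100.0 * mismatches / alignment_length


def _nt_aligner() -> Align.PairwiseAligner:
    # Scoring in the spirit of short-read nucleotide aligners: the germline
    # (query side) may end before the CDR3/FR4 tail of the expressed sequence,
    # so end gaps on the germline side are free.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    aligner.end_deletion_score = 0.0
    return aligner


_ALIGNER = _nt_aligner()


def align_to_germlines(seq: str, db: GermlineDb, aa_based: bool = False) -> GermlineHit:
    """Best glocal alignment of ``seq`` against every germline.

    Ties on score are broken by fewer mismatches, then lexicographic gene
    name.  ``aa_based=True`` runs the same scoring on amino acids (used when
    no nucleotide sequence is available); the resulting mismatch score is per
    100 residues and is not comparable to the nucleotide-based score.
    """
    if not db.entries:
        raise ConfigurationError("empty germline db")
    if len(seq) < (20 if aa_based else 60):
        raise ValidationError("query too short for germline alignment")
    best: Optional[tuple] = None
    for entry in sorted(db.entries, key=lambda e: e.gene_name):
        ref = entry.aa_seq if aa_based else entry.nt_seq
        if ref is None:
            continue
        alignment = _ALIGNER.align(seq, ref)[0]
        mism = 0
        length = 0
        for (qs, qe), (rs, _) in zip(*alignment.aligned):
            length += qe - qs
            mism += sum(1 for a, b in zip(seq[qs:qe], ref[rs : rs + qe - qs]) if a != b)
        key = (-alignment.score, mism, entry.gene_name)
        if best is None or key < best[0]:
            best = (key, entry, alignment.score, mism, length)
    if best is None or best[2] <= 0:
        raise VhhError("no alignment above score 0")
    _, entry, score, mism, length = best
    return GermlineHit(
        gene_name=entry.gene_name,
        family=entry.family,
        alignment_length=length,
        mismatches=mism,
        score=score,
        aa_based=aa_based,
    )


def is_classical(
    annotation: RegionAnnotation,
    aa_seq: str,
    hit: Optional[GermlineHit],
    db: GermlineDb,
) -> tuple[bool, str]:
    """Classical/non-classical decision with rule provenance.

    Classical iff the FR2 hallmark residues are present (F/Y at 42, E/Q at
    49, R at 50) or the best-matched germline is whitelisted.
    """
    r42 = annotation.residue_at(aa_seq, 42)
    r49 = annotation.residue_at(aa_seq, 49)
    r50 = annotation.residue_at(aa_seq, 50)
    if r42 is None or r49 is None or r50 is None:
        raise ValidationError("IMGT positions 42/49/50 not mapped")
    if r42 in CLASSICAL_R42 and r49 in CLASSICAL_R49 and r50 == CLASSICAL_R50:
        return True, "hallmark"
    if hit is not None and hit.gene_name in db.vhh_whitelist:
        return True, "germline_whitelist"
    return False, "nonclassical"


def count_cysteines(aa_seq: str) -> int:
    """Cysteines in the full V region (hinge excluded)."""
    return aa_seq.count("C")


def assign_type(
    classical: bool,
    residue42: str,
    n_cys: int,
    hit: Optional[GermlineHit],
    rule: str = "hallmark",
) -> TypeAssignment:
    """Five-type assignment from hallmark residue 42, cysteine count and germline family."""
    if classical:
        vhh_type = {
            ("Y", 2): "Y_C2",
            ("F", 2): "F_C2",
            ("F", 4): "F_C4",
        }.get((residue42, n_cys), "UNASSIGNED")
    else:
        rule = "nonclassical"
        if hit is not None and hit.family == "IGHV3":
            vhh_type = "N_V3"
        elif hit is not None and hit.family == "IGHV4":
            vhh_type = "N_V4"
        else:
            vhh_type = "UNASSIGNED"  # IGHV1 or no hit; a rare minority
    return TypeAssignment(classical, vhh_type, rule, residue42, n_cys)


def detect_fr4_arginine(
    annotation: RegionAnnotation, aa_seq: str, nt_seq: Optional[str] = None
) -> tuple[bool, Optional[str], Optional[bool]]:
    """Tryptophan-to-arginine replacement at the first FR4 residue (IMGT 118).

    Returns ``(has_R_at_118, codon, single_substitution_from_TGG)``; the last
    two are None without a nucleotide sequence.  A single substitution away
    from TGG (the unique W codon) marks the likely mutational origin.
    """
    idx = annotation.imgt_map.get(118)
    if idx is None:
        raise ValidationError("IMGT 118 not mapped")
    has_r = aa_seq[idx] == "R"
    if nt_seq is None:
        return has_r, None, None
    if len(nt_seq) != 3 * len(aa_seq):
        raise ConsistencyError("nt_seq out of frame with aa_seq")
    codon = nt_seq[3 * idx : 3 * idx + 3]
    single_sub = sum(1 for a, b in zip(codon, "TGG") if a != b) == 1
    return has_r, codon, single_sub


def detect_hinge(hinge_suffix: str, hinge_db: Mapping[str, str]) -> str:
    """Name of the hinge whose motif prefixes ``hinge_suffix`` (longest wins)."""
    if not hinge_db:
        raise ConfigurationError("empty hinge motif db")
    best = "none"
    best_len = -1
    for name, motif in hinge_db.items():
        if hinge_suffix.startswith(motif) and len(motif) > best_len:
            best, best_len = name, len(motif)
    return best


def load_germline_fasta(path: str | Path, whitelist: Optional[Iterable[str]] = None) -> GermlineDb:
    """Load nucleotide germlines from FASTA (headers are IMGT gene names)."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        nt = str(rec.seq).upper()
        aa = str(rec.seq.translate()).rstrip("*")
        entries.append(GermlineEntry(gene_name=rec.id, nt_seq=nt, aa_seq=aa))
    return GermlineDb(entries, set(whitelist or ()))


def load_whitelist(path: str | Path) -> set[str]:
    """One gene name per line; '#' starts a comment."""
    names = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.add(line)
    return names


def placeholder_whitelist() -> set[str]:
    """The shipped PARTIAL whitelist of well-known alpaca VHH germline genes.

    Under-calls classical VHHs on real data; substitute a curated list.
    """
    import importlib.resources as resources

    path = resources.files("vhh_typology") / "data" / "alpaca_vhh_whitelist.txt"
    return load_whitelist(Path(str(path)))


@dataclass
class TypedRecord:
    record: VhhRecord
    annotation: RegionAnnotation
    assignment: TypeAssignment
    hit: Optional[GermlineHit]
    hinge: str = "none"
    fr4_arg: bool = False
    fr4_codon: Optional[str] = None


def type_repertoire(
    items: Iterable[tuple[VhhRecord, RegionAnnotation]],
    db: GermlineDb,
    hinge_db: Optional[Mapping[str, str]] = None,
    align_all: bool = True,
) -> list[TypedRecord]:
    """Full typing pass over an annotated repertoire.

    With ``align_all=False`` germline alignment is skipped for records that
    already pass the hallmark test (faster; no mismatch scores for those).
    """
    out = []
    for record, ann in items:
        aa = record.aa_seq
        r42 = ann.residue_at(aa, 42)
        r49 = ann.residue_at(aa, 49)
        r50 = ann.residue_at(aa, 50)
        hallmark = r42 in CLASSICAL_R42 and r49 in CLASSICAL_R49 and r50 == CLASSICAL_R50
        hit: Optional[GermlineHit] = None
        if align_all or not hallmark:
            seq = record.nt_seq if record.nt_seq else aa
            try:
                hit = align_to_germlines(seq, db, aa_based=record.nt_seq is None)
            except VhhError:
                hit = None
        classical, rule = is_classical(ann, aa, hit, db)
        assignment = assign_type(classical, r42, count_cysteines(aa), hit, rule)
        fr4_arg, codon, _ = detect_fr4_arginine(ann, aa, record.nt_seq)
        hinge = "none"
        if hinge_db and record.hinge_suffix:
            hinge = detect_hinge(record.hinge_suffix, hinge_db)
        out.append(TypedRecord(record, ann, assignment, hit, hinge, fr4_arg, codon))
    return out
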