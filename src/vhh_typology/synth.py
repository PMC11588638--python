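"""Seeded synthetic repertoires and toy complexes with ground-truth labels.

The repertoire generator emulates the statistical structure the typing
pipeline assumes: five VHH types in configurable proportions built on
synthetic scaffold "germlines" (names mimic IMGT nomenclature but the
sequences are invented -- they are NOT real alpaca germlines), type-specific
CDR3 length and composition laws, uniform per-base somatic hypermutation,
two hinge isotypes and a positive-integer read-count law.

Ground-truth labels must stay well defined under mutation, so hypermutation
never touches the label-defining and anchor codons (hallmark positions
42/49/50/52, the conserved tryptophan 41, the conserved cysteines and their
YY context, FR4 start) and never creates a cysteine, tryptophan, stop codon,
or a tyrosine directly before a cysteine.  Mutations are drawn as a binomial
over the full germline-covered span, so the expected mismatch score of a
cohort equals 100 x the per-base rate.

Toy complexes are two-chain structures with one pseudo-atom per residue,
placed so that planted antibody-antigen pairs sit at requested distances,
every other cross-chain pair exceeds 6 A, and the CDR3 pseudo-loop realizes
a requested extended/bent minimum distance to the residue at IMGT 42.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, GenerationError
from .germline import GermlineDb, GermlineEntry
from .records import RegionAnnotation, VhhRecord
from .structure import (
    Atom,
    ComplexStructure,
    Residue,
    imgt_cdr3_positions,
    write_pdb,
)

# --------------------------------------------------------------------------
# scaffolds

_FR1 = "QVQLVESGGGLVQPGGSLRLSCAAS"  # 25 aa, conserved Cys at index 21 (IMGT 23)
_FR3 = "NAYADSVKGRFTISRDNAKNTLYLQMNSLKPEDTAVYYC"  # 39 aa, IMGT 66-104
_FR3_C4 = "C" + _FR3[1:]  # extra cysteine adjacent to CDR2 (IMGT 66)
_FR3_V4 = "NAYPDSVKGRFTISADNSKNTAYLQMNSLKPEDTAVYYC"
_FR4 = "WGQGTQVTVSS"  # 11 aa, IMGT 118-128

_FR2_CLASSICAL_Y = "MAWYRQAPGKERELVAA"  # hallmarks Y42 E49 R50, L52
_FR2_CLASSICAL_F = "MAWFRQAPGKERELVAA"
_FR2_VHLIKE = "MAWVRQAPGKGLEWVSA"  # conventional V42 G49 L50 W52


@dataclass(frozen=True)
class Scaffold:
    gene_name: str
    fr1: str
    cdr1: str
    fr2: str
    cdr2: str
    fr3: str
    classical: bool

    @property
    def v_aa(self) -> str:
        return self.fr1 + self.cdr1 + self.fr2 + self.cdr2 + self.fr3


SCAFFOLDS = {
    "Y_C2": Scaffold("IGHV3S53*01", _FR1, "GSIFSINA", _FR2_CLASSICAL_Y, "ITSGGSTN", _FR3, True),
    "F_C2": Scaffold("IGHV3-3*01", _FR1, "GRTFSSYA", _FR2_CLASSICAL_F, "ISSSGGST", _FR3, True),
    "F_C4": Scaffold("IGHV3S65*01", _FR1, "GDTFSSYA", _FR2_CLASSICAL_F, "IDSDGSTS", _FR3_C4, True),
    "N_V3": Scaffold("IGHV3S39*01", _FR1, "GFTFSSYA", _FR2_VHLIKE, "ISSGGSYT", _FR3, False),
    "N_V4": Scaffold("IGHV4S5*01", _FR1, "GYSITSGY", _FR2_VHLIKE, "ITYSGSTY", _FR3_V4, False),
}

_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

#: synthetic stand-in hinge motifs (the real IgG2b/IgG2c hinges are isotype
#: specific; users supply their own motif map for real data)
SYNTHETIC_HINGE_MOTIFS = {"2B": "EPKTPKPQPQPQPN", "2C": "AHHSEDPSSKAPKA"}

_BASE_CDR3_WEIGHTS = {
    "G": 0.10, "S": 0.08, "Y": 0.10, "D": 0.08, "R": 0.07, "A": 0.07,
    "T": 0.06, "L": 0.05, "V": 0.05, "N": 0.05, "P": 0.04, "E": 0.04,
    "I": 0.03, "F": 0.03, "K": 0.03, "H": 0.02, "Q": 0.03, "M": 0.01,
}


def _adjust(weights: dict[str, float], **delta: float) -> dict[str, float]:
    w = dict(weights)
    for aa, d in delta.items():
        w[aa] = max(w[aa] + d, 0.001)
    total = sum(w.values())
    return {aa: v / total for aa, v in w.items()}


DEFAULT_CDR3_WEIGHTS = {
    "Y_C2": _adjust(_BASE_CDR3_WEIGHTS),
    "F_C2": _adjust(_BASE_CDR3_WEIGHTS),
    "F_C4": _adjust(_BASE_CDR3_WEIGHTS, D=0.05, E=0.03, R=-0.04, K=-0.02),
    "N_V3": _adjust(_BASE_CDR3_WEIGHTS, R=0.04, K=0.03, D=-0.04),
    "N_V4": _adjust(_BASE_CDR3_WEIGHTS, R=0.04, K=0.03, D=-0.04),
    "UNASSIGNED": _adjust(_BASE_CDR3_WEIGHTS),
}

#: from-the-repertoire ordering of mean CDR3 lengths:
#: Y_C2 < N_V3 ~ N_V4 < F_C2 < F_C4
DEFAULT_CDR3_MEANS = {
    "Y_C2": 12.3, "N_V3": 14.0, "N_V4": 14.0,
    "F_C2": 16.0, "F_C4": 18.8, "UNASSIGNED": 15.0,
}

DEFAULT_TYPE_PROPORTIONS = {
    "Y_C2": 0.331, "F_C2": 0.227, "F_C4": 0.240,
    "N_V3": 0.055, "N_V4": 0.034, "UNASSIGNED": 0.113,
}


@dataclass
class RepertoireConfig:
    n_sequences: int = 1000
    type_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_PROPORTIONS)
    )
    cdr3_length_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CDR3_MEANS)
    )
    cdr3_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CDR3_WEIGHTS.items()}
    )
    shm_rate: float = 0.03
    hinge_mix: dict[str, float] = field(default_factory=lambda: {"2B": 0.56, "2C": 0.44})
    count_geometric_p: float = 0.15
    fr4_arg_rate_classical: float = 0.027
    fr4_arg_rate_nonclassical: float = 0.112
    fr4_arg_codon_weights: dict[str, float] = field(
        default_factory=lambda: {"CGG": 0.689, "AGG": 0.255, "CGT": 0.056}
    )
    n_animals: int = 22
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences <= 0:
            raise ConfigurationError("n_sequences must be positive")
        if abs(sum(self.type_proportions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("type proportions must sum to 1")
        if not 0.0 <= self.shm_rate <= 0.2:
            raise ConfigurationError("shm_rate outside [0, 0.2]")
        for p in self.hinge_mix.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("hinge probabilities outside [0, 1]")

    def expected_cdr3_charge(self, vhh_type: str) -> float:
        """Expected CDR3 net charge under the type's composition and length law."""
        from .features import CHARGE_SCHEME

        w = self.cdr3_weights[vhh_type]
        per_residue = sum(w[aa] * CHARGE_SCHEME.get(aa, 0.0) for aa in w)
        return self.cdr3_length_means[vhh_type] * per_residue


def generate_germline_db(seed: int = 0) -> GermlineDb:
    """Scaffold germline database; whitelist = the classical scaffolds."""
    entries = []
    for scaffold in SCAFFOLDS.values():
        aa = scaffold.v_aa
        nt = "".join(_CODON[a] for a in aa)
        entries.append(GermlineEntry(gene_name=scaffold.gene_name, nt_seq=nt, aa_seq=aa))
    whitelist = {s.gene_name for s in SCAFFOLDS.values() if s.classical}
    return GermlineDb(entries, whitelist)


def _scaffold_annotation(scaffold: Scaffold, cdr3_len: int) -> RegionAnnotation:
    f1 = len(scaffold.fr1)
    c1e = f1 + len(scaffold.cdr1)
    f2e = c1e + len(scaffold.fr2)
    c2e = f2e + len(scaffold.cdr2)
    f3e = c2e + len(scaffold.fr3)
    boundaries = {
        "FR1": (0, f1), "CDR1": (f1, c1e), "FR2": (c1e, f2e),
        "CDR2": (f2e, c2e), "FR3": (c2e, f3e),
        "CDR3": (f3e, f3e + cdr3_len), "FR4": (f3e + cdr3_len, f3e + cdr3_len + len(_FR4)),
    }
    imgt = {pos: c1e + off for pos, off in
            ((39, 0), (40, 1), (41, 2), (42, 3), (49, 10), (50, 11), (52, 13), (53, 14), (55, 16))}
    imgt[23] = scaffold.fr1.rfind("C")
    imgt[104] = f3e - 1
    imgt[118] = f3e + cdr3_len
    return RegionAnnotation(boundaries, imgt)


def _draw_cdr3(rng: np.random.Generator, vhh_type: str, config: RepertoireConfig) -> str:
    mean = config.cdr3_length_means[vhh_type]
    length = max(5, 5 + int(rng.poisson(max(mean - 5.0, 0.1))))
    weights = config.cdr3_weights[vhh_type]
    alphabet = list(weights)
    probs = np.array([weights[a] for a in alphabet])
    probs = probs / probs.sum()
    n_extra_cys = {"F_C4": 1, "UNASSIGNED": 1}.get(vhh_type, 0)
    for _ in range(100):
        seq = list(rng.choice(alphabet, size=length, p=probs))
        if n_extra_cys:
            mid = length // 2
            seq[mid] = "C"
            if mid >= 1 and seq[mid - 1] == "Y":
                seq[mid - 1] = "G"
        s = "".join(seq)
        if "YYC" not in s and not s.endswith("YY"):
            return s
    raise GenerationError("could not draw a CDR3 without a spurious YYC anchor")


def _protected_aa_positions(scaffold: Scaffold) -> set[int]:
    f1 = len(scaffold.fr1)
    c1e = f1 + len(scaffold.cdr1)
    c2 = c1e + len(scaffold.fr2) + len(scaffold.cdr2) + len(scaffold.fr3) - 1
    protected = {scaffold.fr1.rfind("C")}
    protected |= {c1e + off for off in (2, 3, 10, 11, 13)}  # IMGT 41, 42, 49, 50, 52
    protected |= {c2 - 2, c2 - 1, c2}  # YY context + conserved Cys 104
    if "C" in scaffold.fr3:
        protected.add(c1e + len(scaffold.fr2) + len(scaffold.cdr2) + scaffold.fr3.find("C"))
    return protected


def _apply_shm(
    rng: np.random.Generator,
    nt: list[str],
    aa: list[str],
    n_mut: int,
    eligible_nt: np.ndarray,
) -> int:
    """Place exactly ``n_mut`` single-base substitutions at distinct positions.

    A substitution is rejected (and redrawn) when the new codon would encode
    a stop, create a cysteine or tryptophan, or create a tyrosine within two
    residues upstream of a cysteine (which could forge a spurious anchor).
    """
    chosen = rng.choice(eligible_nt, size=n_mut, replace=False)
    placed = 0
    pool = list(chosen)
    retried = set()
    while pool:
        pos = pool.pop()
        codon_i = pos // 3
        old_aa = aa[codon_i]
        bases = [b for b in "ACGT" if b != nt[pos]]
        rng.shuffle(bases)
        done = False
        for base in bases:
            codon = nt[3 * codon_i : 3 * codon_i + 3]
            codon[pos % 3] = base
            new_aa = _CODON_TABLE["".join(codon)]
            if new_aa == "*" or (new_aa in "CW" and new_aa != old_aa):
                continue
            if new_aa == "Y" and new_aa != old_aa:
                nxt = aa[codon_i + 1 : codon_i + 3]
                if "C" in nxt:
                    continue
            nt[pos] = base
            aa[codon_i] = new_aa
            placed += 1
            done = True
            break
        if not done and pos not in retried:
            # no admissible base here; move the mutation to a fresh position
            retried.add(pos)
            remaining = np.setdiff1d(eligible_nt, np.array(list(chosen) + list(retried)))
            if remaining.size:
                pool.append(int(rng.choice(remaining)))
    return placed


def generate_repertoire(
    config: RepertoireConfig,
) -> tuple[list[VhhRecord], list[RegionAnnotation], "pd.DataFrame"]:
    """Generate a labeled repertoire; pure function of the config (incl. seed).

    Returns parallel lists of records and true annotations plus a truth table
    with one row per record (type, germline, mutation count, hinge, ...).
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    types = list(config.type_proportions)
    probs = np.array([config.type_proportions[t] for t in types])
    drawn = rng.choice(types, size=config.n_sequences, p=probs)

    n_old = max(config.n_animals - 2 * (config.n_animals // 4), 1)
    ages = ["3-4"] * n_old + ["1-2"] * (config.n_animals // 4) + ["0-1"] * (config.n_animals // 4)
    animals = [f"A{i + 1:02d}" for i in range(config.n_animals)]

    hinges = list(config.hinge_mix)
    hinge_p = np.array([config.hinge_mix[h] for h in hinges], dtype=float)
    hinge_p = hinge_p / hinge_p.sum()

    records: list[VhhRecord] = []
    annotations: list[RegionAnnotation] = []
    truth_rows = []
    for i, vhh_type in enumerate(drawn):
        scaffold = (
            SCAFFOLDS[vhh_type]
            if vhh_type != "UNASSIGNED"
            else SCAFFOLDS[rng.choice(["Y_C2", "F_C2"])]
        )
        cdr3 = _draw_cdr3(rng, vhh_type, config)
        fr4 = _FR4
        fr4_codon0 = _CODON["W"]
        fr4_arg_rate = (
            config.fr4_arg_rate_classical
            if scaffold.classical
            else config.fr4_arg_rate_nonclassical
        )
        fr4_arg = bool(rng.random() < fr4_arg_rate)
        if fr4_arg:
            fr4 = "R" + fr4[1:]
            codons = list(config.fr4_arg_codon_weights)
            w = np.array([config.fr4_arg_codon_weights[c] for c in codons])
            fr4_codon0 = str(rng.choice(codons, p=w / w.sum()))

        v_aa = scaffold.v_aa
        aa = list(v_aa + cdr3 + fr4)
        nt = list("".join(_CODON[a] for a in v_aa + cdr3) + fr4_codon0
                  + "".join(_CODON[a] for a in fr4[1:]))

        germline_nt_len = 3 * len(v_aa)
        n_mut = int(rng.binomial(germline_nt_len, config.shm_rate))
        protected = _protected_aa_positions(scaffold)
        eligible = np.array(
            [p for p in range(germline_nt_len) if (p // 3) not in protected], dtype=int
        )
        placed = _apply_shm(rng, nt, aa, n_mut, eligible) if n_mut else 0

        hinge = str(rng.choice(hinges, p=hinge_p))
        animal_idx = int(rng.integers(config.n_animals))
        count = int(rng.geometric(config.count_geometric_p))
        record = VhhRecord(
            id=f"seq{i:06d}",
            aa_seq="".join(aa),
            nt_seq="".join(nt),
            count=count,
            animal_id=animals[animal_idx],
            age_group=ages[animal_idx],
            hinge_suffix=SYNTHETIC_HINGE_MOTIFS[hinge] + "GS",
        )
        records.append(record)
        annotations.append(_scaffold_annotation(scaffold, len(cdr3)))
        truth_rows.append({
            "sequence_id": record.id,
            "vhh_type": vhh_type,
            "classical": scaffold.classical,
            "germline": scaffold.gene_name,
            "n_mut": placed,
            "germline_nt_length": germline_nt_len,
            "hinge": hinge,
            "fr4_arg": fr4_arg,
            "fr4_codon": fr4_codon0,
            "cdr3_length": len(cdr3),
            "count": count,
            "animal_id": record.animal_id,
            "age_group": record.age_group,
        })
    return records, annotations, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# toy complexes

_AXIS_LAYOUT = (("FR1", 2), ("CDR1", 3), ("FR2", 5), ("CDR2", 3), ("FR3", 2))
FR2_IMGT = ("39", "40", "42", "50", "55")
_SPACING = 8.0  # A between scaffold pseudo-residues
_RAY_STEP = 6.0  # A between CDR3 pseudo-residues on the ray below IMGT 42


@dataclass
class ToyComplexConfig:
    complex_id: str = "toy"
    n_antigen_residues: int = 10
    #: (antibody (region, index-within-region), antigen residue index, distance A)
    planted_contacts: Sequence[tuple[tuple[str, int], int, float]] = ()
    cdr3_geometry: str = "extended"  # extended | bent
    cdr3_target_distance: Optional[float] = None  # default 14 (extended) / 6 (bent)
    cdr3_length: int = 9
    closest_terminal: bool = False  # adversarial: nearest CDR3 residue is a trimmed terminus
    #: (FR2 IMGT position, CDR3 residue index, distance A) intra-antibody contacts
    fr2_cdr3_contacts: Sequence[tuple[int, int, float]] = ()
    seed: int = 0

    def __post_init__(self):
        if self.cdr3_geometry not in ("extended", "bent"):
            raise ConfigurationError("cdr3_geometry must be 'extended' or 'bent'")
        if self.cdr3_length < 1:
            raise ConfigurationError("cdr3_length must be positive")
        for _, ag_idx, dist in self.planted_contacts:
            if dist <= 0:
                raise ConfigurationError("planted distances must be positive")
            if not 0 <= ag_idx < self.n_antigen_residues:
                raise ConfigurationError("planted antigen residue index out of range")

    @property
    def target_distance(self) -> float:
        if self.cdr3_target_distance is not None:
            return self.cdr3_target_distance
        return 14.0 if self.cdr3_geometry == "extended" else 6.0


@dataclass
class ToyComplexTruth:
    structure: ComplexStructure
    manifest: dict
    contacts: set[tuple[str, str]]  # (antibody resnum, antigen resnum)
    min_dist_42_cdr3: Optional[float]
    bsa_positive: bool


def generate_toy_complex(
    config: ToyComplexConfig, pdb_path: Optional[str | Path] = None
) -> ToyComplexTruth:
    """Build a toy antibody-antigen complex with planted geometry.

    Antibody scaffold residues sit on a line (8 A spacing, one pseudo-atom
    each); the CDR3 pseudo-loop hangs below the IMGT 42 residue so that the
    closest untrimmed CDR3 residue is at the configured target distance.
    Planted antigen residues are offset perpendicular to the antibody plane;
    all other cross-chain distances exceed 6 A by construction (verified, a
    violation raises :class:`GenerationError`).
    """
    L = config.cdr3_length
    coords: dict[str, np.ndarray] = {}
    region_map: dict[str, tuple[str, Optional[str]]] = {}
    order: list[str] = []

    slot = 0
    resnum = 0
    for region, n in _AXIS_LAYOUT:
        for j in range(n):
            resnum += 1
            key = str(resnum)
            coords[key] = np.array([_SPACING * slot, 0.0, 0.0])
            imgt = FR2_IMGT[j] if region == "FR2" else None
            region_map[key] = (region, imgt)
            order.append(key)
            if imgt == "42":
                p42_key = key
            slot += 1
    p42 = coords[p42_key]

    target = config.target_distance
    interior = list(range(2, L - 2))
    rank = {}
    for r, j in enumerate(interior):
        rank[j] = r
    for r, j in enumerate([j for j in range(L) if j not in rank]):
        rank[j] = len(interior) + r
    cdr3_labels = imgt_cdr3_positions(L)
    cdr3_keys = []
    for j in range(L):
        resnum += 1
        key = str(resnum)
        d = target + _RAY_STEP * rank[j]
        if config.closest_terminal and j == 0:
            d = max(2.0, target - 4.0)
        coords[key] = p42 + np.array([0.0, 0.0, -d])
        region_map[key] = ("CDR3", cdr3_labels[j])
        order.append(key)
        cdr3_keys.append(key)
    overridden: set[int] = set()
    for imgt_pos, j, dist in config.fr2_cdr3_contacts:
        if j in overridden:
            raise GenerationError(
                f"CDR3 residue {j} planted on two FR2 positions: distances conflict"
            )
        overridden.add(j)
        fr2_key = next(k for k, (r, im) in region_map.items() if im == str(imgt_pos))
        coords[cdr3_keys[j]] = coords[fr2_key] + np.array([0.0, 0.0, -dist])
    for j in range(2):
        resnum += 1
        key = str(resnum)
        coords[key] = np.array([_SPACING * slot, 0.0, 0.0])
        region_map[key] = ("FR4", "118" if j == 0 else None)
        order.append(key)
        slot += 1

    # antigen chain
    ag_coords: dict[int, np.ndarray] = {
        i: np.array([_SPACING * i, 60.0, 0.0]) for i in range(config.n_antigen_residues)
    }
    contacts: set[tuple[str, str]] = set()
    planted_ag = {}
    region_index: dict[str, list[str]] = {}
    for key in order:
        region_index.setdefault(region_map[key][0], []).append(key)
    for (region, idx), ag_idx, dist in config.planted_contacts:
        try:
            ab_key = region_index[region][idx]
        except (KeyError, IndexError) as exc:
            raise ConfigurationError(f"no antibody residue ({region}, {idx})") from exc
        if ag_idx in planted_ag:
            raise ConfigurationError(f"antigen residue {ag_idx} planted twice")
        ag_coords[ag_idx] = coords[ab_key] + np.array([0.0, dist, 0.0])
        planted_ag[ag_idx] = (ab_key, dist)
        contacts.add((ab_key, str(ag_idx + 1)))

    # verify: planted pairs at their distance, all other cross-chain pairs > 6 A
    for ag_idx, pos in ag_coords.items():
        for key in order:
            d = float(np.linalg.norm(coords[key] - pos))
            if ag_idx in planted_ag and planted_ag[ag_idx][0] == key:
                continue
            if d <= 6.0:
                raise GenerationError(
                    f"unplanted pair antibody {key} / antigen {ag_idx} at {d:.2f} A"
                )

    # truth for the CDR3 conformation metric (trim 2 both sides)
    trimmed = cdr3_keys[2 : L - 2]
    min_dist = (
        min(float(np.linalg.norm(coords[k] - p42)) for k in trimmed) if trimmed else None
    )
    # the regime is asserted over residues not explicitly re-planted onto FR2
    free_interior = [k for j, k in enumerate(cdr3_keys) if 2 <= j < L - 2 and j not in overridden]
    if free_interior:
        regime_min = min(float(np.linalg.norm(coords[k] - p42)) for k in free_interior)
        if abs(regime_min - target) > 0.5:
            raise GenerationError(
                f"requested CDR3 geometry unrealizable: min distance {regime_min:.2f} "
                f"vs target {target:.2f}"
            )

    residues = [
        Residue("A", key, "GLY", [Atom("C", *coords[key])]) for key in order
    ] + [
        Residue("B", str(i + 1), "GLY", [Atom("C", *ag_coords[i])])
        for i in range(config.n_antigen_residues)
    ]
    cs = ComplexStructure(
        complex_id=config.complex_id,
        residues=residues,
        antibody_chain="A",
        antigen_chains={"B"},
        antibody_region_map=region_map,
    )
    manifest = {
        "complex_id": config.complex_id,
        "pdb_path": str(pdb_path) if pdb_path else "",
        "antibody_chain": "A",
        "antigen_chains": "B",
    }
    if pdb_path is not None:
        write_pdb(cs, pdb_path)
    bsa_positive = any(dist < 6.2 for _, dist in planted_ag.values())
    return ToyComplexTruth(cs, manifest, contacts, min_dist, bsa_positive)


#: structure-dataset defaults: share of each type (no N_V4 -- it is absent
#: from structural datasets), chance of an FR2-involving paratope, and the
#: CDR3 conformation regime per type
DEFAULT_STRUCTURE_TYPE_MIX = {"Y_C2": 0.35, "F_C2": 0.30, "F_C4": 0.20, "N_V3": 0.15}
FR2_INVOLVING_PROB = {"Y_C2": 0.70, "N_V3": 0.65, "F_C2": 0.25, "F_C4": 0.25}
CDR3_REGIME = {"Y_C2": 14.0, "N_V3": 10.0, "F_C2": 6.0, "F_C4": 6.0}
_STRUCT_CDR3_LEN = {"Y_C2": 8, "N_V3": 9, "F_C2": 10, "F_C4": 12}
_FAVORED_FR2 = {"Y_C2": 2, "N_V3": 3, "F_C2": 4, "F_C4": 4}  # index into FR2_IMGT


def generate_toy_complex_set(
    n_complexes: int,
    seed: int = 0,
    type_mix: Optional[dict[str, float]] = None,
    outdir: Optional[str | Path] = None,
) -> list[tuple[str, ToyComplexTruth]]:
    """A labeled set of toy complexes mirroring the per-type interface trends.

    Each complex draws a VHH type, an FR2-involving or CDR-only paratope
    (type-dependent odds), planted contact counts per region and a CDR3
    conformation regime (extended for Y_C2, bent for F_C2/F_C4, intermediate
    for N_V3).  PDB files are written under ``outdir`` when given.
    """
    rng = np.random.default_rng(seed)
    mix = type_mix or DEFAULT_STRUCTURE_TYPE_MIX
    types = list(mix)
    probs = np.array([mix[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    out = []
    for i in range(n_complexes):
        vhh_type = str(rng.choice(types, p=probs))
        L = int(_STRUCT_CDR3_LEN[vhh_type] + rng.integers(-1, 2))
        L = max(L, 7)
        fr2_involving = bool(rng.random() < FR2_INVOLVING_PROB[vhh_type])
        n_fr2 = int(rng.integers(1, 4)) if fr2_involving else 0
        # short-CDR3 types compensate with more CDR1/FR2 contacts
        n_cdr3 = int(np.clip(rng.integers(3, 7) + (L - 9) // 3, 2, L))
        n_cdr1 = int(rng.integers(1, 4)) if vhh_type == "Y_C2" else int(rng.integers(0, 3))
        n_cdr2 = int(rng.integers(0, 3))
        # ensure the epitope survives the >= 8 residue filter
        n_cdr3 = min(max(n_cdr3, 8 - n_cdr1 - n_cdr2 - n_fr2), L)
        n_cdr1 = min(max(n_cdr1, 8 - n_cdr2 - n_cdr3 - n_fr2), 3)
        n_cdr2 = min(max(n_cdr2, 8 - n_cdr1 - n_cdr3 - n_fr2), 3)
        planted: list[tuple[tuple[str, int], int, float]] = []
        ag_idx = 0

        def _plant(region: str, indices: Sequence[int]):
            nonlocal ag_idx
            for j in indices:
                planted.append(
                    ((region, int(j)), ag_idx, float(rng.uniform(3.2, 3.9)))
                )
                ag_idx += 1

        _plant("CDR1", rng.choice(3, size=n_cdr1, replace=False))
        _plant("CDR2", rng.choice(3, size=n_cdr2, replace=False))
        _plant("CDR3", rng.choice(L, size=n_cdr3, replace=False))
        if n_fr2:
            favored = _FAVORED_FR2[vhh_type]
            others = [k for k in range(5) if k != favored]
            fr2_idx = [favored] + list(rng.choice(others, size=n_fr2 - 1, replace=False))
            _plant("FR2", fr2_idx)
        config = ToyComplexConfig(
            complex_id=f"toy{i:03d}",
            n_antigen_residues=ag_idx + 3,
            planted_contacts=planted,
            cdr3_geometry="extended" if CDR3_REGIME[vhh_type] >= 12 else "bent",
            cdr3_target_distance=CDR3_REGIME[vhh_type],
            cdr3_length=L,
            seed=seed + i,
        )
        pdb_path = Path(outdir) / f"toy{i:03d}.pdb" if outdir else None
        out.append((vhh_type, generate_toy_complex(config, pdb_path)))
    return out
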