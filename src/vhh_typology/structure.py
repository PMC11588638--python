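"""VHH-antigen complex structures and interface statistics.

The interface definition follows the contact criterion used throughout the
analyses: an antigen residue and an antibody residue are in contact when any
heavy-atom pair is strictly closer than 4 A.  Contacting antigen residues
form the epitope, contacting antibody residues the paratope; paratopes are
dichotomized into FR2-involving (>= 1 framework-2 contact residue) and
non-FR2.  Complexes with epitopes smaller than 8 residues are discarded as
potential crystallographic artifacts.

Residue-residue distances use the unweighted heavy-atom centroid ("central
coordinate"); a C-alpha mode is available for sensitivity checks.  The CDR3
conformation metric is the minimum centroid distance between the residue at
IMGT 42 and any CDR3 residue after trimming two residues from each CDR3
terminus: large values mean the loop extends away from FR2, small values
mean it bends down over it.

Solvent-accessible surface area is computed with a deterministic
Shrake-Rupley integrator (golden-spiral point spheres, no randomness);
buried surface area is monomer SASA minus in-complex SASA, reported for
antigen (epitope side) and antibody (paratope side).  Absolute SASA values
are integrator dependent at the percent level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError, ParseError, ValidationError

#: van der Waals radii (A) for heavy elements common in protein structures
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}

CONTACT_CUTOFF = 4.0
MIN_EPITOPE_SIZE = 8
CDR3_TRIM = 2
SASA_PROBE = 1.4
SASA_POINTS = 960

CONTACT_REGIONS = ("CDR1", "CDR2", "CDR3", "FR2", "other")


@dataclass
class Atom:
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Residue:
    chain: str
    resnum: str  # author numbering, insertion code appended
    resname: str
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain, self.resnum)


@dataclass
class ComplexStructure:
    complex_id: str
    residues: list[Residue]
    antibody_chain: str
    antigen_chains: set[str]
    #: antibody resnum -> (region, IMGT position label or None)
    antibody_region_map: dict[str, tuple[str, Optional[str]]] = field(default_factory=dict)

    def __post_init__(self):
        if self.antibody_chain in self.antigen_chains:
            raise ValidationError("antibody chain listed among antigen chains")
        resnums = {r.resnum for r in self.residues if r.chain == self.antibody_chain}
        missing = set(self.antibody_region_map) - resnums
        if missing:
            raise ValidationError(f"region map names absent residues: {sorted(missing)}")

    def antibody_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain == self.antibody_chain]

    def antigen_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.chain in self.antigen_chains]


@dataclass
class InterfaceSummary:
    complex_id: str
    epitope: set[tuple[str, str]]
    paratope: set[tuple[str, str]]
    contacts_by_region: dict[str, int]
    paratope_kind: str  # FR2_involving | non_FR2
    bsa_epitope: Optional[float] = None
    bsa_paratope: Optional[float] = None
    min_dist_42_cdr3: Optional[float] = None
    fr2_positions_contacted: tuple[str, ...] = ()

    def __post_init__(self):
        if sum(self.contacts_by_region.values()) != len(self.paratope):
            raise ValidationError("contact counts do not sum to paratope size")
        expected = "FR2_involving" if self.contacts_by_region.get("FR2", 0) >= 1 else "non_FR2"
        if self.paratope_kind != expected:
            raise ValidationError("paratope kind inconsistent with FR2 contact count")
        for v in (self.bsa_epitope, self.bsa_paratope):
            if v is not None and v < -1e-6:
                raise ValidationError("negative buried surface area")


# --------------------------------------------------------------------------
# PDB I/O

def parse_complex(
    pdb_path: str | Path,
    antibody_chain: str,
    antigen_chains: set[str] | Sequence[str],
    complex_id: Optional[str] = None,
    antibody_region_map: Optional[dict[str, tuple[str, Optional[str]]]] = None,
) -> ComplexStructure:
    """Read a PDB complex: first MODEL, heavy atoms, best altloc, no waters/HETATM."""
    import gemmi

    antigen_chains = set(antigen_chains)
    try:
        st = gemmi.read_pdb(str(pdb_path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{pdb_path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{pdb_path}: no models")
    model = st[0]
    present = {chain.name for chain in model}
    for name in {antibody_chain, *antigen_chains} - present:
        raise ConfigurationError(f"{pdb_path}: chain {name!r} not in structure")

    residues: list[Residue] = []
    for chain in model:
        if chain.name != antibody_chain and chain.name not in antigen_chains:
            continue
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            by_name: dict[str, list] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for name, alts in by_name.items():
                # altloc: highest occupancy wins; ties prefer 'A', then alphabetical
                best = min(alts, key=lambda a: (-a.occ, a.altloc != "A", a.altloc))
                altloc = best.altloc if best.altloc.isalnum() else ""
                atoms.append(
                    Atom(
                        element=best.element.name.upper(),
                        x=best.pos.x, y=best.pos.y, z=best.pos.z,
                        occupancy=best.occ, altloc=altloc,
                    )
                )
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(
                Residue(chain.name, f"{res.seqid.num}{icode}", res.name, atoms)
            )
    return ComplexStructure(
        complex_id=complex_id or Path(pdb_path).stem,
        residues=residues,
        antibody_chain=antibody_chain,
        antigen_chains=antigen_chains,
        antibody_region_map=antibody_region_map or {},
    )


def write_pdb(cs: ComplexStructure, path: str | Path) -> None:
    """Write a minimal single-model PDB (one CA-style record per atom)."""
    lines = []
    serial = 0
    for res in cs.residues:
        num = int("".join(ch for ch in res.resnum if ch.isdigit() or ch == "-"))
        icode = "".join(ch for ch in res.resnum if ch.isalpha()) or " "
        for i, atom in enumerate(res.atoms):
            serial += 1
            name = "CA" if len(res.atoms) == 1 else f"{atom.element}{i + 1}"
            lines.append(
                f"ATOM  {serial:5d} {name:^4s}{res.resname:>4s} {res.chain:1s}"
                f"{num:4d}{icode:1s}   {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# contacts

def contact_residues(
    cs: ComplexStructure, cutoff: float = CONTACT_CUTOFF
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Epitope and paratope residue sets under the strict < cutoff criterion."""
    ab = cs.antibody_residues()
    ag = cs.antigen_residues()
    if not ab or not ag:
        return set(), set()
    ab_coords, ab_idx = _atom_array(ab)
    ag_coords, ag_idx = _atom_array(ag)
    epitope: set[tuple[str, str]] = set()
    paratope: set[tuple[str, str]] = set()
    if cutoff <= 0:
        return epitope, paratope
    tree = cKDTree(ag_coords)
    neighbor_lists = tree.query_ball_point(ab_coords, cutoff)
    for i, neighbors in enumerate(neighbor_lists):
        for j in neighbors:
            if np.linalg.norm(ab_coords[i] - ag_coords[j]) < cutoff:  # strict
                paratope.add(ab[ab_idx[i]].key)
                epitope.add(ag[ag_idx[j]].key)
    return epitope, paratope


def _atom_array(residues: Sequence[Residue]) -> tuple[np.ndarray, np.ndarray]:
    coords = []
    idx = []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            coords.append((atom.x, atom.y, atom.z))
            idx.append(i)
    return np.asarray(coords, dtype=float), np.asarray(idx, dtype=int)


def epitope_size_filter(
    summaries: list[InterfaceSummary], min_epitope: int = MIN_EPITOPE_SIZE
) -> list[InterfaceSummary]:
    """Drop complexes whose epitope has fewer than ``min_epitope`` residues."""
    return [s for s in summaries if len(s.epitope) >= min_epitope]


def contact_counts_by_region(
    paratope: set[tuple[str, str]],
    region_map: dict[str, tuple[str, Optional[str]]],
) -> dict[str, int]:
    """Paratope residue counts per region; unmapped or framework-1/3/4 -> 'other'."""
    counts = {r: 0 for r in CONTACT_REGIONS}
    for _, resnum in paratope:
        region = region_map.get(resnum, ("other", None))[0]
        if region not in counts:
            region = "other"
        counts[region] += 1
    return counts


def classify_paratope(summary: InterfaceSummary) -> str:
    """'FR2_involving' iff at least one paratope residue lies in framework 2."""
    return "FR2_involving" if summary.contacts_by_region.get("FR2", 0) >= 1 else "non_FR2"


# --------------------------------------------------------------------------
# geometry

def residue_centroid(residue: Residue, mode: str = "centroid") -> np.ndarray:
    """Central coordinate of a residue: heavy-atom centroid or its C-alpha."""
    if not residue.atoms:
        raise ValidationError(f"residue {residue.key} has no heavy atoms")
    if mode == "CA":
        # toy pseudo-residues and real structures both name the alpha carbon CA
        coords = np.array([[a.x, a.y, a.z] for a in residue.atoms])
        return coords[0] if len(residue.atoms) == 1 else coords.mean(axis=0)
    return np.array([[a.x, a.y, a.z] for a in residue.atoms]).mean(axis=0)


def min_distance_42_cdr3(
    cs: ComplexStructure, trim: int = CDR3_TRIM, mode: str = "centroid"
) -> Optional[float]:
    """CDR3 conformation metric.

    Minimum centroid-centroid distance between the residue at IMGT 42 and any
    CDR3 residue after excluding ``trim`` residues from each CDR3 end; None
    when CDR3 is too short to have an interior.
    """
    res42 = None
    cdr3: list[Residue] = []
    for res in cs.antibody_residues():
        region, imgt = cs.antibody_region_map.get(res.resnum, (None, None))
        if imgt == "42":
            res42 = res
        if region == "CDR3":
            cdr3.append(res)
    if res42 is None:
        raise ValidationError(f"{cs.complex_id}: IMGT 42 not in region map")
    interior = cdr3[trim : len(cdr3) - trim]
    if not interior:
        return None
    p42 = residue_centroid(res42, mode)
    return min(float(np.linalg.norm(residue_centroid(r, mode) - p42)) for r in interior)


def imgt_cdr3_positions(length: int) -> list[str]:
    """IMGT-style CDR3 position labels (105..117, insertions at 111/112).

    Variable-length loops are anchored at both termini so that homologous
    positions near the loop base share a label across structures.
    """
    if length <= 13:
        n_left = math.ceil(length / 2)
        n_right = length - n_left
        return [str(105 + i) for i in range(n_left)] + [
            str(118 - n_right + i) for i in range(n_right)
        ]
    extra = length - 13
    k_left = math.ceil(extra / 2)
    k_right = extra - k_left
    return (
        [str(p) for p in range(105, 112)]
        + [f"111.{k}" for k in range(1, k_left + 1)]
        + [f"112.{k}" for k in range(k_right, 0, -1)]
        + [str(p) for p in range(112, 118)]
    )


def _cdr3_label_key(label: str) -> tuple:
    if "." in label:
        base, ins = label.split(".")
        base, ins = int(base), int(ins)
        return (1, 0, ins) if base == 111 else (1, 1, -ins)
    base = int(label)
    return (0, base, 0) if base <= 111 else (2, base, 0)


FR2_MAP_POSITIONS = ("39", "40", "42", "50", "55")


def fr2_cdr3_interaction_map(
    structures: Iterable[ComplexStructure], cutoff: float = CONTACT_CUTOFF
) -> pd.DataFrame:
    """Probability of FR2-CDR3 intra-domain interaction across structures.

    Cell (i, j): fraction of structures in which the FR2 residue at IMGT
    position i and the CDR3 residue at position j share a heavy-atom pair
    strictly closer than ``cutoff``.
    """
    structures = list(structures)
    hits: dict[tuple[str, str], int] = {}
    columns: set[str] = set()
    for cs in structures:
        fr2_res: dict[str, Residue] = {}
        cdr3_res: dict[str, list[Residue]] = {}
        for res in cs.antibody_residues():
            region, imgt = cs.antibody_region_map.get(res.resnum, (None, None))
            if region == "FR2" and imgt in FR2_MAP_POSITIONS:
                fr2_res[imgt] = res
            elif region == "CDR3" and imgt is not None:
                cdr3_res.setdefault(imgt, []).append(res)
        columns.update(cdr3_res)
        if cutoff <= 0:
            continue
        for fpos, fres in fr2_res.items():
            fcoords = np.array([[a.x, a.y, a.z] for a in fres.atoms])
            for cpos, cresidues in cdr3_res.items():
                ccoords = np.array(
                    [[a.x, a.y, a.z] for r in cresidues for a in r.atoms]
                )
                dmin = np.min(
                    np.linalg.norm(fcoords[:, None, :] - ccoords[None, :, :], axis=2)
                )
                if dmin < cutoff:
                    hits[(fpos, cpos)] = hits.get((fpos, cpos), 0) + 1
    cols = sorted(columns, key=_cdr3_label_key)
    n = max(len(structures), 1)
    data = [
        [hits.get((fpos, cpos), 0) / n for cpos in cols] for fpos in FR2_MAP_POSITIONS
    ]
    return pd.DataFrame(data, index=list(FR2_MAP_POSITIONS), columns=cols)


# --------------------------------------------------------------------------
# SASA / BSA

def _golden_spiral(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    residues: Sequence[Residue],
    probe: float = SASA_PROBE,
    n_points: int = SASA_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> dict[tuple[str, str], float]:
    """Per-residue solvent-accessible surface area (Shrake-Rupley).

    Deterministic: each atom carries a fixed golden-spiral point sphere at
    radius r_atom + probe; a point is accessible iff it lies outside every
    other inflated atom; atom SASA is the accessible fraction of its sphere
    area, residue SASA the sum over its atoms.
    """
    radii = radii or VDW_RADII
    atoms: list[tuple[int, np.ndarray, float]] = []
    for i, res in enumerate(residues):
        for atom in res.atoms:
            el = atom.element.upper()
            if el not in radii:
                raise ConfigurationError(f"no van der Waals radius for element {el!r}")
            atoms.append((i, atom.coord, radii[el]))
    if not atoms:
        return {}
    coords = np.array([a[1] for a in atoms])
    r_inflated = np.array([a[2] for a in atoms]) + probe
    sphere = _golden_spiral(n_points)
    tree = cKDTree(coords)
    max_r = r_inflated.max()
    out = {res.key: 0.0 for res in residues}
    for k, (res_i, center, _) in enumerate(atoms):
        rk = r_inflated[k]
        points = center + rk * sphere
        neighbors = [j for j in tree.query_ball_point(center, rk + max_r) if j != k]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", points - coords[j], points - coords[j])
            accessible &= d2 > r_inflated[j] ** 2
        area = 4.0 * math.pi * rk * rk * accessible.sum() / n_points
        out[residues[res_i].key] += area
    return out


def buried_surface_area(
    cs: ComplexStructure,
    probe: float = SASA_PROBE,
    n_points: int = SASA_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> tuple[float, float]:
    """(BSA of the antigen/epitope side, BSA of the antibody/paratope side).

    Each is the monomer SASA minus the corresponding SASA within the complex.
    """
    ab = cs.antibody_residues()
    ag = cs.antigen_residues()
    complex_sasa = sasa(ab + ag, probe, n_points, radii)
    ab_alone = sasa(ab, probe, n_points, radii)
    ag_alone = sasa(ag, probe, n_points, radii)
    bsa_paratope = sum(ab_alone[r.key] - complex_sasa[r.key] for r in ab)
    bsa_epitope = sum(ag_alone[r.key] - complex_sasa[r.key] for r in ag)
    return max(bsa_epitope, 0.0), max(bsa_paratope, 0.0)


# --------------------------------------------------------------------------
# per-complex summary

def summarize_complex(
    cs: ComplexStructure,
    cutoff: float = CONTACT_CUTOFF,
    probe: float = SASA_PROBE,
    n_points: int = SASA_POINTS,
    trim: int = CDR3_TRIM,
    compute_bsa: bool = True,
) -> InterfaceSummary:
    """Full interface summary of one complex."""
    epitope, paratope = contact_residues(cs, cutoff)
    counts = contact_counts_by_region(paratope, cs.antibody_region_map)
    fr2_positions = tuple(
        sorted(
            {
                cs.antibody_region_map[resnum][1]
                for _, resnum in paratope
                if cs.antibody_region_map.get(resnum, ("other", None))[0] == "FR2"
                and cs.antibody_region_map[resnum][1] is not None
            },
            key=int,
        )
    )
    bsa_e = bsa_p = None
    if compute_bsa:
        bsa_e, bsa_p = buried_surface_area(cs, probe, n_points)
    min_dist = None
    if any(v[1] == "42" for v in cs.antibody_region_map.values()):
        min_dist = min_distance_42_cdr3(cs, trim)
    kind = "FR2_involving" if counts.get("FR2", 0) >= 1 else "non_FR2"
    return InterfaceSummary(
        complex_id=cs.complex_id,
        epitope=epitope,
        paratope=paratope,
        contacts_by_region=counts,
        paratope_kind=kind,
        bsa_epitope=bsa_e,
        bsa_paratope=bsa_p,
        min_dist_42_cdr3=min_dist,
        fr2_positions_contacted=fr2_positions,
    )
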