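"""Complex parsing, contacts, geometry, SASA/BSA and paratope classification."""

import math

import numpy as np
import pytest

from vhh_typology import (
    Atom,
    ComplexStructure,
    GenerationError,
    InterfaceSummary,
    Residue,
    ToyComplexConfig,
    buried_surface_area,
    classify_paratope,
    contact_counts_by_region,
    contact_residues,
    epitope_size_filter,
    fr2_cdr3_interaction_map,
    generate_toy_complex,
    imgt_cdr3_positions,
    min_distance_42_cdr3,
    parse_complex,
    residue_centroid,
    sasa,
    write_pdb,
)
from vhh_typology.errors import ConfigurationError, ValidationError


def _two_chain(pairs, extra_ag=()):
    """Minimal complex: antibody residues at given coords, antigen at given coords."""
    ab, ag = [], []
    for i, coord in enumerate(pairs["A"]):
        ab.append(Residue("A", str(i + 1), "GLY", [Atom("C", *coord)]))
    for i, coord in enumerate(pairs["B"]):
        ag.append(Residue("B", str(i + 1), "GLY", [Atom("C", *coord)]))
    return ComplexStructure("mini", ab + ag, "A", {"B"})


def brute_force_contacts(cs, cutoff=4.0):
    epitope, paratope = set(), set()
    for ra in cs.antibody_residues():
        for rg in cs.antigen_residues():
            dmin = min(
                np.linalg.norm(a.coord - b.coord) for a in ra.atoms for b in rg.atoms
            )
            if dmin < cutoff:
                paratope.add(ra.key)
                epitope.add(rg.key)
    return epitope, paratope


class TestContacts:
    def test_strictly_inside_cutoff(self):
        cs = _two_chain({"A": [(0, 0, 0)], "B": [(0, 0, 3.9)]})
        epitope, paratope = contact_residues(cs)
        assert epitope and paratope

    def test_exactly_at_cutoff_excluded(self):
        cs = _two_chain({"A": [(0, 0, 0)], "B": [(0, 0, 4.0)]})
        epitope, paratope = contact_residues(cs)
        assert not epitope and not paratope

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_on_random_clouds(self, seed):
        rng = np.random.default_rng(seed)
        cs = _two_chain({
            "A": rng.uniform(0, 15, size=(20, 3)),
            "B": rng.uniform(0, 15, size=(20, 3)),
        })
        assert contact_residues(cs) == brute_force_contacts(cs)

    def test_sets_shrink_with_cutoff(self):
        rng = np.random.default_rng(3)
        cs = _two_chain({
            "A": rng.uniform(0, 12, size=(15, 3)),
            "B": rng.uniform(0, 12, size=(15, 3)),
        })
        prev_e, prev_p = contact_residues(cs, 6.0)
        for cutoff in (5.0, 4.0, 3.0, 2.0):
            e, p = contact_residues(cs, cutoff)
            assert e <= prev_e and p <= prev_p
            prev_e, prev_p = e, p


class TestParsing:
    def test_round_trip_toy_complex(self, tmp_path):
        truth = generate_toy_complex(
            ToyComplexConfig(planted_contacts=[(("CDR3", 2), 0, 3.5)]),
            tmp_path / "toy.pdb",
        )
        cs = parse_complex(tmp_path / "toy.pdb", "A", {"B"})
        assert len(cs.residues) == len(truth.structure.residues)
        for got, want in zip(cs.residues, truth.structure.residues):
            assert got.key == want.key
            np.testing.assert_allclose(
                got.atoms[0].coord, want.atoms[0].coord, atol=1e-3
            )

    def test_only_first_model_kept(self, tmp_path):
        pdb = tmp_path / "two.pdb"
        atom = "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C"
        atom2 = atom.replace("A   1", "B   1")
        pdb.write_text(
            "MODEL     1\n" + atom + "\n" + atom2 + "\nENDMDL\n"
            "MODEL     2\n" + atom + "\n" + atom2 + "\n"
            + atom2.replace("  1 ", " 2  ").replace("B   1", "B   2") + "\nENDMDL\nEND\n"
        )
        cs = parse_complex(pdb, "A", {"B"})
        assert len(cs.residues) == 2

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        pdb = tmp_path / "alt.pdb"
        pdb.write_text(
            "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BGLY A   1       9.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      3  CA  GLY B   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cs = parse_complex(pdb, "A", {"B"})
        (res,) = cs.antibody_residues()
        assert res.atoms[0].x == pytest.approx(9.0)
        assert res.atoms[0].altloc == "B"

    def test_waters_and_hetatm_dropped(self, tmp_path):
        pdb = tmp_path / "het.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "HETATM    2 ZN    ZN A 101       1.000   0.000   0.000  1.00  0.00          ZN\n"
            "HETATM    3  O   HOH B 201       2.000   0.000   0.000  1.00  0.00           O\n"
            "ATOM      4  CA  GLY B   1       8.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        cs = parse_complex(pdb, "A", {"B"})
        assert len(cs.residues) == 2

    def test_missing_chain_is_configuration_error(self, tmp_path):
        truth = generate_toy_complex(ToyComplexConfig(), tmp_path / "toy.pdb")
        with pytest.raises(ConfigurationError):
            parse_complex(tmp_path / "toy.pdb", "Z", {"B"})
        assert truth is not None


class TestGeometry:
    def test_centroid_single_atom_identity(self):
        res = Residue("A", "1", "GLY", [Atom("C", 1.0, 2.0, 3.0)])
        np.testing.assert_allclose(residue_centroid(res), [1.0, 2.0, 3.0])

    def test_centroid_midpoint(self):
        res = Residue("A", "1", "GLY", [Atom("C", 0, 0, 0), Atom("N", 2, 0, 0)])
        np.testing.assert_allclose(residue_centroid(res), [1.0, 0.0, 0.0])

    def test_centroid_four_atoms(self):
        coords = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 4)]
        res = Residue("A", "1", "GLY", [Atom("C", *c) for c in coords])
        np.testing.assert_allclose(residue_centroid(res), np.mean(coords, axis=0))

    def test_empty_residue_rejected(self):
        with pytest.raises(ValidationError):
            residue_centroid(Residue("A", "1", "GLY", []))


class TestConformationMetric:
    def test_recovers_extended_and_bent_regimes(self):
        for geometry, target in (("extended", 14.0), ("bent", 6.0)):
            truth = generate_toy_complex(ToyComplexConfig(cdr3_geometry=geometry))
            got = min_distance_42_cdr3(truth.structure)
            assert got == pytest.approx(target, abs=0.5)

    def test_trimmed_terminal_is_ignored(self):
        """A terminal CDR3 residue closer than every interior one must not count."""
        truth = generate_toy_complex(
            ToyComplexConfig(cdr3_geometry="bent", closest_terminal=True)
        )
        got = min_distance_42_cdr3(truth.structure)
        assert got == pytest.approx(6.0, abs=0.5)  # not the 2.0 of the terminal

    def test_short_cdr3_undefined(self):
        truth = generate_toy_complex(ToyComplexConfig(cdr3_length=4))
        assert min_distance_42_cdr3(truth.structure) is None


class TestInteractionMap:
    def test_planted_fraction(self):
        structures = []
        for i in range(4):
            contacts = [(42, 4, 3.0)] if i < 3 else []
            truth = generate_toy_complex(
                ToyComplexConfig(cdr3_geometry="bent", fr2_cdr3_contacts=contacts,
                                 cdr3_length=9, seed=i)
            )
            structures.append(truth.structure)
        m = fr2_cdr3_interaction_map(structures)
        label = imgt_cdr3_positions(9)[4]
        assert m.loc["42", label] == pytest.approx(0.75)

    def test_zero_cutoff_all_zero(self):
        truth = generate_toy_complex(ToyComplexConfig(cdr3_geometry="bent"))
        m = fr2_cdr3_interaction_map([truth.structure], cutoff=0.0)
        assert (m.values == 0).all()

    def test_single_structure_binary(self):
        truth = generate_toy_complex(
            ToyComplexConfig(cdr3_geometry="bent", fr2_cdr3_contacts=[(50, 3, 3.2)])
        )
        m = fr2_cdr3_interaction_map([truth.structure])
        assert set(np.unique(m.values)) <= {0.0, 1.0}

    def test_cdr3_labels_anchor_both_ends(self):
        assert imgt_cdr3_positions(4) == ["105", "106", "116", "117"]
        assert imgt_cdr3_positions(13)[0] == "105"
        assert imgt_cdr3_positions(13)[-1] == "117"
        labels15 = imgt_cdr3_positions(15)
        assert "111.1" in labels15 and labels15[-1] == "117"


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        res = Residue("A", "1", "GLY", [Atom("N", 0, 0, 0)])
        area = sasa([res])[("A", "1")]
        exact = 4 * math.pi * (1.55 + 1.4) ** 2
        assert abs(area - exact) / exact < 0.005

    def test_distant_pair_unoccluded(self):
        r1 = Residue("A", "1", "GLY", [Atom("C", 0, 0, 0)])
        r2 = Residue("A", "2", "GLY", [Atom("C", 10, 0, 0)])
        areas = sasa([r1, r2])
        exact = 4 * math.pi * (1.7 + 1.4) ** 2
        for v in areas.values():
            assert v == pytest.approx(exact, rel=1e-9)

    def test_two_sphere_overlap_matches_monte_carlo(self):
        """Deterministic integrator vs an independent MC point-sampling oracle."""
        r1 = Residue("A", "1", "GLY", [Atom("C", 0, 0, 0)])
        r2 = Residue("A", "2", "GLY", [Atom("C", 3.0, 0, 0)])
        areas = sasa([r1, r2], n_points=960)
        rng = np.random.default_rng(42)
        r = 1.7 + 1.4
        n = 100_000
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        pts *= r
        other = np.array([3.0, 0, 0])
        frac = np.mean(np.linalg.norm(pts - other, axis=1) ** 2 > r * r)
        mc_area = 4 * math.pi * r * r * frac
        assert abs(areas[("A", "1")] - mc_area) / mc_area < 0.02

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 6, size=(8, 3))
        residues = [
            Residue("A", str(i + 1), "GLY", [Atom("C", *c)]) for i, c in enumerate(coords)
        ]
        base = sasa(residues)
        theta = 0.7
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = [
            Residue("A", str(i + 1), "GLY", [Atom("C", *(rot @ c + np.array([5, -3, 2])))])
            for i, c in enumerate(coords)
        ]
        after = sasa(moved)
        # discretization of the point sphere bounds the residual variance
        assert sum(after.values()) == pytest.approx(sum(base.values()), rel=5e-3)
        for key, area in after.items():
            assert area == pytest.approx(base[key], abs=1.0)

    def test_monotone_under_added_occluders(self):
        target = Residue("A", "1", "GLY", [Atom("C", 0, 0, 0)])
        occluders = [
            Residue("A", str(i + 2), "GLY", [Atom("C", *c)])
            for i, c in enumerate([(3, 0, 0), (0, 3, 0), (0, 0, 3)])
        ]
        prev = math.inf
        for k in range(len(occluders) + 1):
            area = sasa([target] + occluders[:k])[("A", "1")]
            assert area <= prev + 1e-9
            prev = area

    def test_unknown_element_rejected(self):
        res = Residue("A", "1", "UNK", [Atom("Q", 0, 0, 0)])
        with pytest.raises(ConfigurationError, match="Q"):
            sasa([res])


class TestBsa:
    def test_disjoint_chains_zero(self):
        cs = _two_chain({"A": [(0, 0, 0)], "B": [(50, 0, 0)]})
        bsa_e, bsa_p = buried_surface_area(cs)
        assert bsa_e == 0.0 and bsa_p == 0.0

    def test_touching_spheres_positive_and_symmetric(self):
        cs = _two_chain({"A": [(0, 0, 0)], "B": [(3.0, 0, 0)]})
        bsa_e, bsa_p = buried_surface_area(cs)
        assert bsa_e > 0
        assert bsa_e == pytest.approx(bsa_p, rel=0.02)

    def test_matches_monte_carlo_oracle(self):
        cs = _two_chain({"A": [(0, 0, 0), (2, 0, 0)], "B": [(4.5, 0, 0)]})
        bsa_e, bsa_p = buried_surface_area(cs, n_points=960)
        rng = np.random.default_rng(7)

        def mc_sasa(centers, all_centers, n=60_000):
            r = 1.7 + 1.4
            total = 0.0
            for c in centers:
                pts = rng.normal(size=(n, 3))
                pts /= np.linalg.norm(pts, axis=1)[:, None]
                pts = c + r * pts
                ok = np.ones(n, dtype=bool)
                for other in all_centers:
                    if np.allclose(other, c):
                        continue
                    ok &= np.sum((pts - other) ** 2, axis=1) > r * r
                total += 4 * math.pi * r * r * ok.mean()
            return total

        a = [np.array([0.0, 0, 0]), np.array([2.0, 0, 0])]
        b = [np.array([4.5, 0, 0])]
        mc_bsa_p = mc_sasa(a, a) - mc_sasa(a, a + b)
        mc_bsa_e = mc_sasa(b, b) - mc_sasa(b, a + b)
        assert bsa_p == pytest.approx(mc_bsa_p, rel=0.05, abs=1.0)
        assert bsa_e == pytest.approx(mc_bsa_e, rel=0.05, abs=1.0)


class TestParatopeClassification:
    def _summary(self, counts):
        paratope = {("A", str(i)) for i in range(sum(counts.values()))}
        kind = "FR2_involving" if counts.get("FR2", 0) else "non_FR2"
        return InterfaceSummary("x", set(), paratope, counts, kind)

    def test_fr2_involving(self):
        s = self._summary({"CDR1": 0, "CDR2": 0, "CDR3": 3, "FR2": 1, "other": 0})
        assert classify_paratope(s) == "FR2_involving"

    def test_all_cdr(self):
        s = self._summary({"CDR1": 1, "CDR2": 1, "CDR3": 3, "FR2": 0, "other": 0})
        assert classify_paratope(s) == "non_FR2"

    def test_empty_paratope(self):
        s = self._summary({"CDR1": 0, "CDR2": 0, "CDR3": 0, "FR2": 0, "other": 0})
        assert classify_paratope(s) == "non_FR2"

    def test_counts_by_region_and_other(self):
        region_map = {"1": ("CDR1", None), "2": ("CDR1", None), "3": ("FR3", None)}
        paratope = {("A", "1"), ("A", "2"), ("A", "3"), ("A", "99")}
        counts = contact_counts_by_region(paratope, region_map)
        assert counts == {"CDR1": 2, "CDR2": 0, "CDR3": 0, "FR2": 0, "other": 2}
        assert sum(counts.values()) == len(paratope)

    def test_epitope_size_filter(self):
        sizes = [3, 7, 8, 12]
        summaries = []
        for i, n in enumerate(sizes):
            epitope = {("B", str(j)) for j in range(n)}
            summaries.append(
                InterfaceSummary(str(i), epitope, set(),
                                 {r: 0 for r in ("CDR1", "CDR2", "CDR3", "FR2", "other")},
                                 "non_FR2")
            )
        assert len(epitope_size_filter(summaries)) == 2
        assert epitope_size_filter(summaries, min_epitope=0) == summaries
        assert epitope_size_filter([]) == []


def test_generation_error_on_conflicting_geometry():
    # the same CDR3 residue cannot sit at two planted distances at once
    with pytest.raises(GenerationError):
        generate_toy_complex(
            ToyComplexConfig(
                cdr3_geometry="bent",
                fr2_cdr3_contacts=[(42, 3, 3.0), (50, 3, 3.2)],
            )
        )
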