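"""Descriptor correctness: HSE counts, SASA burial, B averaging, pKa plumbing."""

import numpy as np
import pytest

from redoxpair import (
    TablePkaProvider,
    extract_cysteine_sites,
    half_sphere_exposure,
    min_pka,
    pair_descriptors,
    pct_buried,
    scan_pairs,
    sg_distance,
)
from redoxpair.structure_io import Atom, Residue, Structure
from redoxpair.fixtures import (
    ChainSpec,
    FixtureSpec,
    make_cys_pair_structure,
    make_random_cys_structure,
)
from helpers import brute_force_hse


def _cys_residue(chain, seq, ca, cb_dir=(0.0, 0.0, 1.0), b=20.0):
    ca = np.asarray(ca, dtype=float)
    cb = ca + 1.54 * np.asarray(cb_dir, dtype=float)
    return Residue(
        chain, seq, "", "CYS",
        atoms=[
            Atom("N", "N", ca + [-1.2, 0.8, 0.3], b_factor=b),
            Atom("CA", "C", ca, b_factor=b),
            Atom("C", "C", ca + [1.2, 0.8, -0.3], b_factor=b),
            Atom("CB", "C", cb, b_factor=b),
            Atom("SG", "S", cb + [0.0, 0.0, 1.8], b_factor=b),
        ],
    )


def _ca_only_residue(chain, seq, ca):
    return Residue(chain, seq, "", "ALA", atoms=[Atom("CA", "C", np.asarray(ca, float))])


class TestSgDistance:
    def test_axis_aligned(self):
        assert sg_distance((0, 0, 0), (0, 0, 3)) == pytest.approx(3.0)

    def test_identical_points(self):
        assert sg_distance((1, 1, 1), (1, 1, 1)) == 0.0

    def test_three_four_five(self):
        assert sg_distance((1, 2, 3), (4, 6, 3)) == pytest.approx(5.0)

    def test_symmetric(self):
        a, b = np.array([0.3, -1.2, 9.0]), np.array([4.4, 2.0, -3.0])
        assert sg_distance(a, b) == sg_distance(b, a)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            sg_distance((np.nan, 0, 0), (0, 0, 0))


class TestHalfSphereExposure:
    def test_no_neighbours(self):
        s = Structure("t", {"A": [_cys_residue("A", 1, (0, 0, 0))]})
        h = half_sphere_exposure(s.chains["A"][0] and extract_cysteine_sites(s)[0], s)
        assert (h.hse_up, h.hse_down) == (0, 0)

    def test_constructed_three_up_two_down(self):
        # site CB points +z; 3 neighbour CAs above the plane, 2 below, all 6 A out
        residues = [_cys_residue("A", 1, (0, 0, 0), cb_dir=(0, 0, 1))]
        up_pos = [(6, 0, 2), (0, 6, 3), (-4, 0, 4)]
        down_pos = [(6, 0, -2), (0, -6, -1)]
        for i, p in enumerate(up_pos + down_pos, start=2):
            residues.append(_ca_only_residue("A", i, p))
        s = Structure("t", {"A": residues})
        site = extract_cysteine_sites(s)[0]
        h = half_sphere_exposure(site, s, radius=12.0)
        assert (h.hse_up, h.hse_down) == (3, 2)
        assert h == half_sphere_exposure(site, s, radius=12.0)  # deterministic
        assert (h.hse_up, h.hse_down) == brute_force_hse(site, s, 12.0)

    def test_neighbour_at_radius_excluded(self):
        residues = [
            _cys_residue("A", 1, (0, 0, 0)),
            _ca_only_residue("A", 2, (12.0, 0, 0)),
            _ca_only_residue("A", 3, (11.9, 0, 0)),
        ]
        s = Structure("t", {"A": residues})
        h = half_sphere_exposure(extract_cysteine_sites(s)[0], s, radius=12.0)
        assert h.total == 1

    def test_in_plane_neighbour_counts_down(self):
        residues = [
            _cys_residue("A", 1, (0, 0, 0), cb_dir=(0, 0, 1)),
            _ca_only_residue("A", 2, (5.0, 0.0, 0.0)),  # dot product exactly 0
        ]
        s = Structure("t", {"A": residues})
        h = half_sphere_exposure(extract_cysteine_sites(s)[0], s)
        assert (h.hse_up, h.hse_down) == (0, 1)

    def test_pseudo_cb_used_for_glycine(self):
        res = _cys_residue("A", 1, (0, 0, 0))
        res.res_name = "CYS"
        res.atoms = [a for a in res.atoms if a.name != "CB"]
        s = Structure("t", {"A": [res, _ca_only_residue("A", 2, (4, 0, 0))]})
        site = extract_cysteine_sites(s)[0]
        h = half_sphere_exposure(site, s)
        assert h.basis == "pseudo_cb" and h.total == 1

    def test_missing_backbone_gives_missing(self):
        res = Residue("A", 1, "", "CYS", atoms=[Atom("SG", "S", np.zeros(3))])
        s = Structure("t", {"A": [res]})
        assert half_sphere_exposure(extract_cysteine_sites(s)[0], s) is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_recount(self, seed):
        s = make_random_cys_structure(30, seed=seed, box=25.0)
        sites = extract_cysteine_sites(s)
        for site in sites[:10]:
            h = half_sphere_exposure(site, s, radius=12.0)
            assert (h.hse_up, h.hse_down) == brute_force_hse(site, s, 12.0)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        s = make_random_cys_structure(25, seed=11, box=25.0)
        before = [
            (h.hse_up, h.hse_down)
            for h in (
                half_sphere_exposure(x, s) for x in extract_cysteine_sites(s)
            )
        ]
        rot = Rotation.from_euler("xyz", [31, -57, 101], degrees=True).as_matrix()
        shift = np.array([13.0, -7.0, 4.5])
        for r in s.residues():
            for a in r.atoms:
                a.coords = rot @ a.coords + shift
        after = [
            (h.hse_up, h.hse_down)
            for h in (
                half_sphere_exposure(x, s) for x in extract_cysteine_sites(s)
            )
        ]
        assert before == after


class TestPctBuried:
    def test_enclosed_site_fully_buried(self):
        s = make_cys_pair_structure(
            FixtureSpec(
                chains=[ChainSpec("A", "ACA")],
                burial_shells=[(("A", 2), 6.0, 200)],
            )
        )
        site = extract_cysteine_sites(s)[0]
        assert pct_buried(site, s) >= 99.0

    def test_extended_tripeptide_mostly_exposed(self):
        s = make_cys_pair_structure(FixtureSpec(chains=[ChainSpec("A", "GCG")]))
        site = extract_cysteine_sites(s)[0]
        assert pct_buried(site, s) <= 15.0

    def test_isolated_residue_clamps_to_zero(self):
        s = Structure("t", {"A": [_cys_residue("A", 1, (0, 0, 0))]})
        site = extract_cysteine_sites(s)[0]
        assert pct_buried(site, s) == 0.0

    def test_monotone_under_added_occlusion(self):
        bare = make_cys_pair_structure(FixtureSpec(chains=[ChainSpec("A", "ACA")]))
        shelled = make_cys_pair_structure(
            FixtureSpec(
                chains=[ChainSpec("A", "ACA")],
                burial_shells=[(("A", 2), 7.0, 80)],
            )
        )
        b0 = pct_buried(extract_cysteine_sites(bare)[0], bare)
        b1 = pct_buried(extract_cysteine_sites(shelled)[0], shelled)
        assert b1 > b0


class TestMinPka:
    def test_minimum_of_two_sites(self, disulphide_structure):
        (pair,) = scan_pairs(disulphide_structure)
        provider = TablePkaProvider({("A", 58): 5.1, ("B", 158): 8.3})
        assert min_pka(pair, disulphide_structure, provider) == pytest.approx(5.1)

    def test_equal_values(self, disulphide_structure):
        (pair,) = scan_pairs(disulphide_structure)
        provider = TablePkaProvider({("A", 58): 7.0, ("B", 158): 7.0})
        assert min_pka(pair, disulphide_structure, provider) == pytest.approx(7.0)

    def test_provider_crash_becomes_missing(self, disulphide_structure):
        class Broken:
            def predict(self, s):
                raise RuntimeError("engine exploded")

        (pair,) = scan_pairs(disulphide_structure)
        assert min_pka(pair, disulphide_structure, Broken()) is None

    def test_absent_prediction_is_missing(self, disulphide_structure):
        (pair,) = scan_pairs(disulphide_structure)
        assert min_pka(pair, disulphide_structure, TablePkaProvider({})) is None

    def test_tsv_backed_provider(self, disulphide_structure, tmp_path):
        table = tmp_path / "pka.tsv"
        table.write_text(
            "structure_id\tchain\tresidue\tpka\nssfix\tA\t58\t5.0\nssfix\tB\t158\t9.1\n"
        )
        (pair,) = scan_pairs(disulphide_structure)
        provider = TablePkaProvider(table)
        assert min_pka(pair, disulphide_structure, provider) == pytest.approx(5.0)


class TestPairDescriptors:
    def test_hse_additivity_and_b_average(self):
        spec = FixtureSpec(
            chains=[ChainSpec("A", "ACAAC")],
            sg_constraints=[(("A", 2), ("A", 5), 4.0)],
            b_factor_plan={("A", 2): 20.0, ("A", 5): 40.0},
        )
        s = make_cys_pair_structure(spec)
        (pair,) = scan_pairs(s)
        vec = pair_descriptors(pair, s)
        ha = half_sphere_exposure(pair.site_a, s)
        hb = half_sphere_exposure(pair.site_b, s)
        assert vec.hse_up_pair == ha.hse_up + hb.hse_up
        assert vec.hse_down_pair == ha.hse_down + hb.hse_down
        assert vec.hse_total == vec.hse_up_pair + vec.hse_down_pair
        # both CYS residues have the same atom count -> pooled mean is midpoint
        assert vec.avg_b == pytest.approx(30.0)
        assert vec.sg_distance == pytest.approx(4.0)

    def test_burial_is_mean_of_sites(self):
        s = make_cys_pair_structure(
            FixtureSpec(
                chains=[ChainSpec("A", "ACAAC")],
                sg_constraints=[(("A", 2), ("A", 5), 4.0)],
            )
        )
        (pair,) = scan_pairs(s)
        vec = pair_descriptors(pair, s)
        expected = 0.5 * (pct_buried(pair.site_a, s) + pct_buried(pair.site_b, s))
        assert vec.pct_buried == pytest.approx(expected)

    def test_missing_pka_flagged_not_zeroed(self, disulphide_structure):
        (pair,) = scan_pairs(disulphide_structure)
        vec = pair_descriptors(pair, disulphide_structure, pka_provider=None)
        assert vec.min_pka is None
        assert vec.missing["min_pka"]
        assert not vec.missing["sg_distance"]

    def test_avg_b_invariant_to_atom_order(self, disulphide_structure):
        (pair,) = scan_pairs(disulphide_structure)
        v1 = pair_descriptors(pair, disulphide_structure)
        for res in disulphide_structure.residues():
            res.atoms = list(reversed(res.atoms))
        v2 = pair_descriptors(pair, disulphide_structure)
        assert v1.avg_b == v2.avg_b
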