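"""Cross-section tables, interpolation, materials, and the HDF5 container."""

import hashlib

import h5py
import numpy as np
import pytest

from voxdose.nuclear_data import (
    AVOGADRO,
    EnergyGrid,
    Library,
    LibraryFormatError,
    Material,
    NuclideData,
    VACUUM,
    build_material,
    interpolate_xs,
    macro_xs,
    make_synthetic_library,
    read_library,
    toy_tissue_spec,
    write_library,
)


def _single_nuclide_lib(reactions, name="X", particle="neutron", **kw):
    return make_synthetic_library([{
        "name": name, "particle": particle, "mass_ratio_A": 10.0,
        "reactions": reactions, **kw,
    }])


class TestSyntheticLibrary:
    def test_one_over_v_scales_as_inverse_sqrt_energy(self):
        lib = _single_nuclide_lib({"capture": {"form": "one_over_v", "sigma_ref": 100.0}})
        nuc = lib.get("neutron", "X")
        # a factor 100 in energy is a factor 10 in cross section
        s1 = interpolate_xs(nuc, "capture", 0.0253)
        s2 = interpolate_xs(nuc, "capture", 2.53)
        assert s1 == pytest.approx(100.0, rel=1e-4)
        assert s2 == pytest.approx(10.0, rel=1e-4)

    def test_constant_elastic_satisfies_sum_rule_at_every_node(self):
        lib = _single_nuclide_lib({
            "elastic": {"form": "constant", "value": 4.0},
            "capture": {"form": "one_over_v", "sigma_ref": 1.0},
        })
        nuc = lib.get("neutron", "X")
        np.testing.assert_allclose(nuc.sigma_total - nuc.partials["capture"], 4.0, rtol=1e-12)

    def test_toy_tissue_set_passes_invariant_suite(self, toy_library):
        names = {(n.particle, n.name) for n in toy_library}
        for nuclide in ("H1", "C12", "N14", "O16", "B10"):
            assert ("neutron", nuclide) in names and ("photon", nuclide) in names
        for nuc in toy_library:
            total = sum(nuc.partials.values())
            np.testing.assert_allclose(nuc.sigma_total, total, rtol=1e-9)
            assert np.all(nuc.heating_H >= 0)
            assert np.all(np.diff(nuc.grid.nodes) > 0)
            # re-validation from raw arrays must succeed
            NuclideData(nuc.name, nuc.particle, nuc.mass_ratio_A, nuc.grid,
                        nuc.sigma_total, nuc.partials, nuc.heating_H,
                        nuc.capture_gamma_energy)

    def test_negative_parameter_rejected_with_nuclide_and_field(self):
        with pytest.raises(ValueError, match=r"B10.capture.*sigma_ref"):
            _single_nuclide_lib({"capture": {"form": "one_over_v", "sigma_ref": -1.0}},
                                name="B10")

    def test_pair_partial_vanishes_below_threshold(self, toy_library):
        nuc = toy_library.get("photon", "O16")
        below = nuc.grid.nodes < 1.022e6
        assert np.all(nuc.partials["pair"][below] == 0)
        assert nuc.partials["pair"][-1] > 0

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError, match="no nuclides"):
            make_synthetic_library([])


class TestEnergyGridValidation:
    @pytest.mark.parametrize("nodes", [
        [1.0], [1.0, 1.0], [2.0, 1.0], [0.0, 1.0], [-1.0, 1.0], [1.0, np.inf],
    ])
    def test_invalid_grids_rejected(self, nodes):
        with pytest.raises(ValueError):
            EnergyGrid(np.array(nodes))


class TestInterpolation:
    def test_node_hit_returns_tabulated_value(self, toy_library):
        nuc = toy_library.get("neutron", "O16")
        j = 700
        e = float(nuc.grid.nodes[j])
        assert interpolate_xs(nuc, "total", e) == pytest.approx(nuc.sigma_total[j], rel=1e-14)

    def test_linlin_midpoint(self):
        grid = EnergyGrid(np.array([1.0, 3.0]))
        nuc = NuclideData("M", "neutron", 1.0, grid,
                          sigma_total=np.array([2.0, 6.0]),
                          partials={"capture": np.array([2.0, 6.0])},
                          heating_H=np.zeros(2))
        assert interpolate_xs(nuc, "total", 2.0) == pytest.approx(4.0)

    def test_matches_scan_all_intervals_oracle(self, toy_library):
        nuc = toy_library.get("neutron", "N14")
        nodes, table = nuc.grid.nodes, nuc.sigma_total
        rng = np.random.default_rng(42)
        energies = rng.uniform(nodes[0], nodes[-1], 1000)
        for e in energies:
            # brute force: scan every interval for the bracket
            j = next(i for i in range(len(nodes) - 1)
                     if nodes[i] <= e and (e < nodes[i + 1] or i == len(nodes) - 2))
            expected = table[j] + (e - nodes[j]) / (nodes[j + 1] - nodes[j]) * (table[j + 1] - table[j])
            assert interpolate_xs(nuc, "total", e) == pytest.approx(expected, rel=1e-12)

    def test_out_of_range_energy_rejected(self, toy_library):
        nuc = toy_library.get("neutron", "H1")
        with pytest.raises(ValueError, match="outside grid range"):
            interpolate_xs(nuc, "total", 1e-7)


class TestMacroXs:
    def _flat_lib(self, entries):
        """Nuclides with constant totals, split between elastic and capture."""
        spec = []
        for name, sigma in entries:
            spec.append({"name": name, "particle": "neutron", "mass_ratio_A": 10.0,
                         "reactions": {"elastic": {"form": "constant", "value": sigma}}})
        return make_synthetic_library(spec)

    def test_unit_product(self):
        lib = self._flat_lib([("A", 2.0)])
        mat = Material(1, "m", (("A", 1.0),), 1.0)
        assert macro_xs(mat, lib, "neutron", 100.0).sigma_t == pytest.approx(2.0, rel=1e-12)

    def test_additive_over_components(self):
        lib = self._flat_lib([("A", 2.0), ("B", 4.0)])
        mat = Material(1, "m", (("A", 0.5), ("B", 0.25)), 1.0)
        assert macro_xs(mat, lib, "neutron", 100.0).sigma_t == pytest.approx(2.0, rel=1e-12)

    def test_linear_in_number_density(self):
        lib = self._flat_lib([("A", 3.0)])
        m1 = Material(1, "m1", (("A", 0.2),), 1.0)
        m2 = Material(2, "m2", (("A", 0.6),), 1.0)
        b1 = macro_xs(m1, lib, "neutron", 50.0)
        b2 = macro_xs(m2, lib, "neutron", 50.0)
        assert b2.sigma_t == pytest.approx(3 * b1.sigma_t, rel=1e-12)

    def test_toy_tissue_matches_brute_force_sum(self, toy_library):
        mat = build_material(1, "blood", {"H1": 0.101, "C12": 0.111, "N14": 0.026,
                                          "O16": 0.762}, 1.0, boron10_ppm=25.0)
        e = 0.0253
        bundle = macro_xs(mat, toy_library, "neutron", e)
        expected = sum(rho * interpolate_xs(toy_library.get("neutron", n), "total", e)
                       for n, rho in mat.components)
        assert bundle.sigma_t == pytest.approx(expected, rel=1e-12)
        # the B-10-only response is retained for boron-dose separation
        b10_rho = dict(mat.components)["B10"]
        nuc = toy_library.get("neutron", "B10")
        exp_boron = (b10_rho * interpolate_xs(nuc, "total", e)
                     * interpolate_xs(nuc, "heating", e))
        assert bundle.boron_response == pytest.approx(exp_boron, rel=1e-12)

    def test_vacuum_has_zero_sigma(self, toy_library):
        assert macro_xs(VACUUM, toy_library, "neutron", 1.0).sigma_t == 0.0

    def test_unknown_nuclide_is_a_lookup_error(self, toy_library):
        mat = Material(1, "m", (("XX", 1.0),), 1.0)
        with pytest.raises(KeyError, match="XX"):
            macro_xs(mat, toy_library, "neutron", 1.0)


class TestBuildMaterial:
    def test_zero_ppm_has_no_boron_component(self):
        mat = build_material(1, "t", {"H1": 1.0}, 1.0, boron10_ppm=0.0)
        assert "B10" not in dict(mat.components)

    def test_tumor_to_blood_boron_ratio_is_exactly_three(self):
        base = {"H1": 0.101, "C12": 0.111, "N14": 0.026, "O16": 0.762}
        blood = build_material(1, "blood", base, 1.0, boron10_ppm=25.0)
        tumor = build_material(2, "tumor", base, 1.0, boron10_ppm=75.0)
        ratio = dict(tumor.components)["B10"] / dict(blood.components)["B10"]
        assert ratio == pytest.approx(3.0, rel=1e-14)
        # trace addition leaves the host densities untouched
        for nuc in base:
            assert dict(tumor.components)[nuc] == dict(blood.components)[nuc]

    def test_water_hydrogen_number_density(self):
        mat = build_material(1, "water", {"H1": 2 * 1.008 / 18.015, "O16": 15.999 / 18.015},
                             1.0, molar_masses={"O16": 15.999})
        expected = 2 * AVOGADRO / 18.015 * 1e-24  # atoms/(barn cm)
        assert dict(mat.components)["H1"] == pytest.approx(expected, rel=1e-3)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            build_material(1, "m", {"H1": 0.5}, 1.0)
        with pytest.raises(ValueError, match="negative"):
            build_material(1, "m", {"H1": 1.5, "O16": -0.5}, 1.0)

    def test_vacuum_is_reserved_and_empty(self):
        assert VACUUM.is_vacuum and VACUUM.components == ()


class TestLibraryContainer:
    def test_round_trip_is_bit_exact(self, toy_library, tmp_path):
        path = tmp_path / "lib.h5"
        write_library(toy_library, path)
        lib2 = read_library(path)
        assert len(lib2) == len(toy_library)
        for nuc in toy_library:
            other = lib2.get(nuc.particle, nuc.name)
            np.testing.assert_array_equal(nuc.grid.nodes, other.grid.nodes)
            np.testing.assert_array_equal(nuc.sigma_total, other.sigma_total)
            np.testing.assert_array_equal(nuc.heating_H, other.heating_H)
            for r, s in nuc.partials.items():
                np.testing.assert_array_equal(s, other.partials[r])
            assert nuc.mass_ratio_A == other.mass_ratio_A
            assert nuc.capture_gamma_energy == other.capture_gamma_energy

    def test_double_write_is_byte_identical(self, toy_library, tmp_path):
        p1, p2 = tmp_path / "a.h5", tmp_path / "b.h5"
        write_library(toy_library, p1)
        write_library(toy_library, p2)
        assert hashlib.sha256(p1.read_bytes()).digest() == hashlib.sha256(p2.read_bytes()).digest()

    def test_missing_sigma_total_names_the_nuclide(self, toy_library, tmp_path):
        path = tmp_path / "broken.h5"
        write_library(toy_library, path)
        with h5py.File(path, "a") as f:
            del f["library/neutron/C12/sigma_total"]
        with pytest.raises(LibraryFormatError, match="C12"):
            read_library(path)

    def test_missing_version_tag_rejected(self, toy_library, tmp_path):
        path = tmp_path / "untagged.h5"
        write_library(toy_library, path)
        with h5py.File(path, "a") as f:
            del f["library"].attrs["version"]
        with pytest.raises(LibraryFormatError, match="version"):
            read_library(path)
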