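"""Radius of gyration, RDF, Flory exponent, secondary-structure fractions."""

import numpy as np
import pytest

from fibrilmod.errors import ParameterError
from fibrilmod.metrics import (
    fit_flory_exponent,
    flory_fit,
    radial_distribution,
    radius_of_gyration,
    ss_fractions,
)
from fibrilmod.synthetic import (
    generate_gaussian_chain_ensemble,
    generate_ideal_gas_ensemble,
)

from conftest import make_ensemble


def _rod(n_frames, n_res, spacing):
    coords = np.zeros((n_frames, n_res, 3))
    coords[:, :, 0] = np.arange(n_res) * spacing
    return coords


class TestRadiusOfGyration:
    def test_coincident_atoms_give_zero(self):
        rg = radius_of_gyration(make_ensemble(np.zeros((3, 4, 3)), [1] * 4),
                                weighting="uniform")
        assert rg.mean == 0.0

    def test_two_point_closed_form(self):
        # two equal-mass atoms 2 nm apart: R_g = d/2 = 1 nm
        coords = np.zeros((5, 2, 3))
        coords[:, 1, 0] = 2.0
        rg = radius_of_gyration(make_ensemble(coords, [1, 1]), weighting="uniform")
        assert rg.mean == pytest.approx(1.0, abs=1e-12)

    def test_linear_rod_closed_form(self):
        # n beads spacing d: R_g = d * sqrt((n^2 - 1) / 12); n=7, d=0.4 -> 0.8
        rg = radius_of_gyration(make_ensemble(_rod(2, 7, 0.4), [1] * 7),
                                weighting="uniform")
        assert rg.mean == pytest.approx(0.4 * np.sqrt(48 / 12), abs=1e-12)
        assert rg.mean == pytest.approx(0.8, abs=1e-12)

    def test_four_block_sem_frozen_value(self):
        # per-frame R_g = d/2 with d = [2,4,2,4,6,8,6,8] nm
        ds = [2, 4, 2, 4, 6, 8, 6, 8]
        coords = np.zeros((8, 2, 3))
        for f, d in enumerate(ds):
            coords[f, 1, 0] = d
        rg = radius_of_gyration(make_ensemble(coords, [1, 1]),
                                weighting="uniform", n_blocks=4)
        # blocks of 2 frames: means [1.5, 1.5, 3.5, 3.5]; SEM = std(ddof=1)/2
        assert rg.block_error == pytest.approx(0.5773502691896258, abs=1e-12)

    def test_block_error_unavailable_below_block_count(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 1.0
        rg = radius_of_gyration(make_ensemble(coords, [1, 1]),
                                weighting="uniform", n_blocks=4)
        assert rg.block_error is None and rg.mean == pytest.approx(0.5)

    def test_rigid_motion_invariance(self, rng):
        coords = rng.random((6, 10, 3))
        base = radius_of_gyration(make_ensemble(coords, [1] * 10),
                                  weighting="uniform").mean
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1]])
        moved = coords @ rot.T + np.array([3.0, -1.0, 2.0])
        assert radius_of_gyration(make_ensemble(moved, [1] * 10),
                                  weighting="uniform").mean == pytest.approx(base)

    def test_histogram_integrates_to_one(self, rng):
        coords = rng.random((50, 5, 3))
        rg = radius_of_gyration(make_ensemble(coords, [1] * 5), weighting="uniform")
        widths = np.diff(rg.hist_edges)
        assert (rg.hist_density * widths).sum() == pytest.approx(1.0)


class TestRadialDistribution:
    def test_uniform_system_is_flat_at_one(self):
        ens = generate_ideal_gas_ensemble(n_protein=100, n_ligand=100,
                                          box_len=10.0, n_frames=100, seed=2)
        rdf = radial_distribution(ens, bin_width=0.1, r_max=5.0)
        window = (rdf.r >= 1.0)
        assert np.all(np.abs(rdf.g[window] - 1.0) < 0.05)

    def test_distant_ligands_give_zero(self):
        n_res = 5
        coords = np.zeros((4, n_res + 1, 3)) + 1.0
        coords[:, -1, :] = 9.0  # ligand ~ 13.8 nm away before wrapping
        ens = make_ensemble(coords, [1] * n_res, ligand_atoms=[1], box_len=20.0)
        rdf = radial_distribution(ens, bin_width=0.2, r_max=5.0)
        assert np.all(rdf.g == 0.0)

    def test_matches_brute_force_binning(self, rng):
        box = 4.0
        coords = rng.random((6, 8, 3)) * box
        ens = make_ensemble(coords, [1] * 5, ligand_atoms=[1, 1, 1], box_len=box)
        bw, rmax = 0.25, 2.0
        rdf = radial_distribution(ens, bin_width=bw, r_max=rmax)
        edges = np.arange(0.0, rmax + bw, bw)
        counts = np.zeros(len(edges) - 1)
        for f in range(6):
            for i in range(5):
                for j in range(5, 8):
                    d = coords[f, i] - coords[f, j]
                    d -= box * np.round(d / box)
                    r = np.linalg.norm(d)
                    if r < edges[-1]:
                        counts[min(int(r // bw), len(counts) - 1)] += 1
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        expected = counts / (6 * 15 * shell / box ** 3)
        np.testing.assert_allclose(rdf.g, expected, atol=1e-9)

    def test_r_max_beyond_half_box_rejected(self):
        ens = generate_ideal_gas_ensemble(5, 2, box_len=4.0, n_frames=2, seed=0)
        with pytest.raises(ParameterError):
            radial_distribution(ens, bin_width=0.1, r_max=3.0)


class TestFloryFit:
    def test_exact_power_law_inverted(self):
        s = np.arange(1, 60)
        for nu in (0.33, 0.5, 0.59, 1.0):
            fit = fit_flory_exponent(s, 0.55 * s ** nu, prefactor=0.55)
            assert fit.nu == pytest.approx(nu, abs=1e-10)

    def test_straight_rod_gives_nu_one(self):
        ens = make_ensemble(_rod(3, 30, 0.55), [1] * 30)
        assert flory_fit(ens).nu == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_chains_give_half(self):
        ens = generate_gaussian_chain_ensemble(n_residues=64, n_chains=10_000,
                                               seed=8, bond_rms=0.55)
        fit = flory_fit(ens)
        assert fit.nu == pytest.approx(0.5, abs=0.02)

    def test_too_short_fit_range_rejected(self):
        with pytest.raises(ParameterError):
            fit_flory_exponent(np.array([1, 2]), np.array([0.5, 0.7]),
                               fit_range=(5, 10))


class TestSSFractions:
    def test_all_sheet(self):
        ss = ss_fractions(["EEEE", "EEEE", "EEEE"])
        np.testing.assert_allclose(ss.f_E, 1.0)
        np.testing.assert_allclose(ss.f_H, 0.0)

    def test_half_helix_half_coil(self):
        ss = ss_fractions(["H", "C", "H", "C"])
        assert ss.f_H[0] == 0.5 and ss.f_C[0] == 0.5

    def test_grouping_collapses_dssp_codes(self):
        ss = ss_fractions(["GHI", "TSB"])
        np.testing.assert_allclose(ss.f_H, [0.5, 0.5, 0.5])
        np.testing.assert_allclose(ss.f_E, [0.0, 0.0, 0.5])

    def test_random_matrix_matches_counting_oracle(self, rng):
        codes = np.array(list("HGIEBTSC~"))
        mat = codes[rng.integers(0, len(codes), size=(40, 12))]
        ss = ss_fractions(["".join(r) for r in mat])
        helix = np.isin(mat, list("HGI")).mean(axis=0)
        sheet = np.isin(mat, list("EB")).mean(axis=0)
        np.testing.assert_allclose(ss.f_H, helix)
        np.testing.assert_allclose(ss.f_E, sheet)
        np.testing.assert_allclose(ss.f_H + ss.f_E + ss.f_C, 1.0)

    def test_unknown_code_rejected(self):
        with pytest.raises(KeyError):
            ss_fractions(["HX"], grouping={"H": "H"})
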