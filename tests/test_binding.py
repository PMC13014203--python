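"""Ligand-residue binding profiles, mediated contacts, residence times."""

import numpy as np
import pytest

from fibrilmod.binding import (
    ligand_count_profile,
    mediated_contact_map,
    residence_analysis,
)
from fibrilmod.errors import EmptyEnsembleError, ParameterError
from fibrilmod.synthetic import BindingSite, GeneratorSpec, generate_ensemble

from conftest import brute_force_ligand_counts, make_ensemble


def _spread_chain(n_frames, n_res, spacing=5.0):
    """Residue beads far apart so only intended contacts occur."""
    coords = np.zeros((n_frames, n_res, 3))
    for i in range(n_res):
        coords[:, i, 0] = i * spacing
    return coords


class TestLigandCountProfile:
    def test_single_fixed_ligand_counts_one(self):
        n_res = 10
        chain = _spread_chain(4, n_res)
        lig = chain[:, 6:7, :].copy()
        lig[:, 0, 1] = 0.40  # 0.40 nm from residue 7 only
        ens = make_ensemble(np.concatenate([chain, lig], axis=1),
                            [1] * n_res, ligand_atoms=[1])
        profile = ligand_count_profile(ens, cutoff=0.45)
        expected = np.zeros(n_res)
        expected[6] = 1.0
        np.testing.assert_allclose(profile.n_ligand, expected)

    def test_two_half_time_ligands_average_to_one(self):
        n_res, n_frames = 10, 8
        chain = _spread_chain(n_frames, n_res)
        ligs = np.zeros((n_frames, 2, 3))
        for k in range(2):
            ligs[:, k, 0] = chain[0, 6, 0]
            ligs[:, k, 1] = 0.40
            ligs[n_frames // 2:, k, 1] = 50.0  # far in second half
        ens = make_ensemble(np.concatenate([chain, ligs], axis=1),
                            [1] * n_res, ligand_atoms=[1, 1])
        profile = ligand_count_profile(ens, cutoff=0.45)
        assert profile.n_ligand[6] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_multiatom_ensemble

        ens = random_multiatom_ensemble(rng, n_res=8, n_frames=20,
                                        ligand_atoms=[2, 3, 1])
        profile = ligand_count_profile(ens, cutoff=0.45)
        np.testing.assert_allclose(profile.n_ligand,
                                   brute_force_ligand_counts(ens, 0.45))

    def test_no_ligands_raises(self):
        ens = make_ensemble(np.zeros((2, 3, 3)), [1, 1, 1])
        with pytest.raises(EmptyEnsembleError):
            ligand_count_profile(ens)


class TestMediatedContactMap:
    def test_bridging_ligand_gives_probability_one(self):
        n_res = 12
        chain = _spread_chain(5, n_res, spacing=1.0)
        lig = np.zeros((5, 1, 3))
        # ligand midway between residues 3 and 9 vertically offset:
        # place it 0.5 nm from each by construction
        lig[:, 0, 0] = chain[0, 2, 0]
        lig[:, 0, 1] = 0.5
        chain[:, 8, 0] = chain[0, 2, 0]
        chain[:, 8, 1] = 1.0
        ens = make_ensemble(np.concatenate([chain, lig], axis=1),
                            [1] * n_res, ligand_atoms=[1])
        med = mediated_contact_map(ens, cutoff=0.6, min_separation=4)
        assert med.pairs[(3, 9)] == 1.0

    def test_different_ligands_do_not_bridge(self):
        n_res = 12
        chain = _spread_chain(3, n_res, spacing=5.0)
        ligs = np.zeros((3, 2, 3))
        ligs[:, 0, 0] = chain[0, 2, 0]
        ligs[:, 0, 1] = 0.5
        ligs[:, 1, 0] = chain[0, 8, 0]
        ligs[:, 1, 1] = 0.5
        ens = make_ensemble(np.concatenate([chain, ligs], axis=1),
                            [1] * n_res, ligand_atoms=[1, 1])
        med = mediated_contact_map(ens, cutoff=0.6)
        assert med.pairs == {}

    def test_matches_triple_loop_oracle(self, rng):
        from conftest import random_multiatom_ensemble

        ens = random_multiatom_ensemble(rng, n_res=8, n_frames=15,
                                        ligand_atoms=[1, 2], spread=2.0)
        med = mediated_contact_map(ens, cutoff=0.6, min_separation=4)
        # oracle: explicit (i, ligand, j) triples
        top = ens.topology
        rows = {aid: k for k, aid in enumerate(top.atom_ids)}
        expected = {}
        for ri in range(top.n_residues):
            for rj in range(ri + 4, top.n_residues):
                hits = 0
                for f in range(ens.n_frames):
                    bridged = False
                    for lig in top.ligands:
                        def near(res):
                            return any(
                                np.linalg.norm(ens.coords[f, rows[ai]]
                                               - ens.coords[f, rows[aj]]) < 0.6
                                for ai in res.heavy_atom_ids
                                for aj in lig.heavy_atom_ids
                            )
                        if near(top.residues[ri]) and near(top.residues[rj]):
                            bridged = True
                            break
                    hits += bridged
                if hits:
                    expected[(ri + 1, rj + 1)] = hits / ens.n_frames
        assert med.pairs == pytest.approx(expected)


class TestResidenceAnalysis:
    def test_single_event_duration(self):
        n_res, n_frames = 8, 150
        dt = 2.5e-4  # ns (0.25 ps cadence)
        chain = _spread_chain(n_frames, n_res)
        lig = np.zeros((n_frames, 1, 3))
        lig[:, 0, 0] = chain[0, 4, 0]
        lig[:100, 0, 1] = 0.40
        lig[100:, 0, 1] = 5.0
        ens = make_ensemble(np.concatenate([chain, lig], axis=1),
                            [1] * n_res, ligand_atoms=[1], dt=dt)
        stats = residence_analysis(ens)
        row = stats.table[stats.table.residue == 5].iloc[0]
        assert row.n_events == 1
        assert row.mean_tau_residue == pytest.approx(100 * dt)  # 25 ps
        assert row.mean_tau_protein == pytest.approx(100 * dt)

    def test_fully_bound_ligand_is_censored(self):
        n_res, n_frames = 8, 50
        chain = _spread_chain(n_frames, n_res)
        lig = np.zeros((n_frames, 1, 3))
        lig[:, 0, 0] = chain[0, 4, 0]
        lig[:, 0, 1] = 0.40
        ens = make_ensemble(np.concatenate([chain, lig], axis=1),
                            [1] * n_res, ligand_atoms=[1], dt=0.1)
        stats = residence_analysis(ens)
        row = stats.table[stats.table.residue == 5].iloc[0]
        assert row.n_events == 0 and row.n_censored == 1
        assert np.isnan(row.mean_tau_residue)

    def test_exponential_dwell_time_recovery(self):
        spec = GeneratorSpec(seed=21, chain_length=5, n_frames=120_000,
                             frame_dt=0.25,
                             binding_spec=[BindingSite(3, k_on=0.2, k_off=0.05)])
        stats = residence_analysis(generate_ensemble(spec))
        row = stats.table[stats.table.residue == 3].iloc[0]
        assert row.n_events >= 1000
        assert row.mean_tau_residue == pytest.approx(20.0, rel=0.10)

    def test_tau_protein_dominates_tau_residue(self):
        spec = GeneratorSpec(seed=5, chain_length=6, n_frames=5000, frame_dt=0.1,
                             binding_spec=[BindingSite(2, 0.5, 0.5)])
        stats = residence_analysis(generate_ensemble(spec))
        for e in stats.events:
            if e.tau_residue is not None and e.tau_protein is not None:
                assert e.tau_protein >= e.tau_residue - 1e-12

    def test_exchange_rate_times_time_is_integer(self):
        spec = GeneratorSpec(seed=9, chain_length=5, n_frames=3000, frame_dt=0.1,
                             binding_spec=[BindingSite(3, 0.5, 0.5)])
        stats = residence_analysis(generate_ensemble(spec))
        for _, row in stats.table.iterrows():
            n = row.exchange_rate * stats.analyzed_time
            assert n == pytest.approx(round(n), abs=1e-9)
            assert round(n) == row.n_events

    def test_invalid_hysteresis_rejected(self):
        ens = generate_ensemble(GeneratorSpec(seed=1, chain_length=5, n_frames=10,
                                              binding_spec=[BindingSite(2, 1, 1)]))
        with pytest.raises(ParameterError):
            residence_analysis(ens, r_on=0.6, r_off=0.45)
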