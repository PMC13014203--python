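"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use naive nested loops, independent of the
vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from fibrilmod.trajectory import Ensemble, Ligand, LigandCondition, Residue, Topology


def make_topology(atoms_per_residue: list[int], ligand_atoms: list[int] | None = None,
                  sequence_offset: int = 0) -> Topology:
    """Topology with the given heavy-atom counts per residue and per ligand."""
    residues = []
    next_id = 1
    for i, n in enumerate(atoms_per_residue):
        ids = tuple(range(next_id, next_id + n))
        residues.append(Residue(index=i + 1, name="GLY", chain_id="A",
                                heavy_atom_ids=ids, calpha_atom_id=ids[0]))
        next_id += n
    ligands = []
    for k, n in enumerate(ligand_atoms or []):
        ids = tuple(range(next_id, next_id + n))
        ligands.append(Ligand(index=k + 1, heavy_atom_ids=ids))
        next_id += n
    return Topology(residues=tuple(residues), ligands=tuple(ligands),
                    sequence_offset=sequence_offset)


def make_ensemble(coords: np.ndarray, atoms_per_residue: list[int],
                  ligand_atoms: list[int] | None = None,
                  box_len: float | None = None, dt: float = 1.0,
                  ratio: float = 0.0) -> Ensemble:
    coords = np.asarray(coords, dtype=float)
    top = make_topology(atoms_per_residue, ligand_atoms)
    n = coords.shape[0]
    boxes = None
    if box_len is not None:
        boxes = np.broadcast_to(np.eye(3) * box_len, (n, 3, 3)).copy()
    return Ensemble(topology=top, coords=coords, times=np.arange(n) * dt,
                    boxes=boxes, condition=LigandCondition(ratio))


def random_multiatom_ensemble(rng: np.random.Generator, n_res: int, n_frames: int,
                              max_atoms: int = 5, spread: float = 1.5,
                              ligand_atoms: list[int] | None = None,
                              box_len: float | None = None) -> Ensemble:
    """Residues with 1..max_atoms heavy atoms at random positions."""
    atoms_per_residue = list(rng.integers(1, max_atoms + 1, size=n_res))
    n_lig_atoms = sum(ligand_atoms or [])
    n_atoms = sum(atoms_per_residue) + n_lig_atoms
    coords = rng.random((n_frames, n_atoms, 3)) * spread
    if box_len is not None:
        coords = coords % box_len
    return make_ensemble(coords, atoms_per_residue, ligand_atoms, box_len)


# --------------------------------------------------------------------------
# Brute-force oracles
# --------------------------------------------------------------------------

def _mi_dist(a: np.ndarray, b: np.ndarray, box_len: float | None) -> float:
    d = a - b
    if box_len is not None:
        d = d - box_len * np.round(d / box_len)
    return float(np.sqrt((d ** 2).sum()))


def brute_force_contact_map(ensemble: Ensemble, cutoff: float,
                            min_separation: int) -> dict[tuple[int, int], float]:
    """Naive all-atom-pairs contact probabilities (cubic boxes only)."""
    top = ensemble.topology
    box_len = None
    if ensemble.boxes is not None:
        box_len = float(ensemble.boxes[0][0, 0])
    rows = {aid: k for k, aid in enumerate(top.atom_ids)}
    out: dict[tuple[int, int], float] = {}
    for ri in range(top.n_residues):
        for rj in range(ri + 1, top.n_residues):
            if (rj - ri) < min_separation:
                continue
            hits = 0
            for f in range(ensemble.n_frames):
                found = False
                for ai in top.residues[ri].heavy_atom_ids:
                    for aj in top.residues[rj].heavy_atom_ids:
                        if _mi_dist(ensemble.coords[f, rows[ai]],
                                    ensemble.coords[f, rows[aj]], box_len) < cutoff:
                            found = True
                            break
                    if found:
                        break
                hits += found
            if hits:
                out[(ri + 1, rj + 1)] = hits / ensemble.n_frames
    return out


def brute_force_ligand_counts(ensemble: Ensemble, cutoff: float) -> np.ndarray:
    """Naive per-residue mean number of ligand molecules in contact."""
    top = ensemble.topology
    rows = {aid: k for k, aid in enumerate(top.atom_ids)}
    box_len = None
    if ensemble.boxes is not None:
        box_len = float(ensemble.boxes[0][0, 0])
    total = np.zeros(top.n_residues)
    for f in range(ensemble.n_frames):
        for ri, res in enumerate(top.residues):
            for lig in top.ligands:
                close = False
                for ai in res.heavy_atom_ids:
                    for aj in lig.heavy_atom_ids:
                        if _mi_dist(ensemble.coords[f, rows[ai]],
                                    ensemble.coords[f, rows[aj]], box_len) < cutoff:
                            close = True
                            break
                    if close:
                        break
                total[ri] += close
    return total / ensemble.n_frames


def brute_force_image_violation(ensemble: Ensemble, threshold: float) -> np.ndarray:
    """Per-frame periodic-image violation flags by explicit pairwise loops."""
    n_prot = ensemble.topology.n_protein_atoms()
    flags = np.zeros(ensemble.n_frames, dtype=bool)
    shifts = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
              if (i, j, k) != (0, 0, 0)]
    for f in range(ensemble.n_frames):
        box = ensemble.boxes[f]
        pts = ensemble.coords[f, :n_prot]
        done = False
        for (si, sj, sk) in shifts:
            shift = si * box[0] + sj * box[1] + sk * box[2]
            for a in pts:
                for b in pts:
                    if np.linalg.norm(a - (b + shift)) < threshold:
                        flags[f] = True
                        done = True
                        break
                if done:
                    break
            if done:
                break
    return flags


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
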