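"""Synthetic-data generators with known ground truth.

Every pipeline stage can be exercised without any external download: bead
chains with programmed per-pair contact occupancies that vary linearly with
ligand ratio, two-state (telegraph) ligand-residue binding processes with
known on/off rates, fibril-like structure sets with a designed
shared-contact cluster layout, and logistic ThT curves with known
parameters and Gaussian noise.

The generators target the *statistical* structure the analyses assume, not
force-field thermodynamics: chains are one bead (standing for one heavy
atom, the Calpha) per residue, built as random walks; programmed contact
pairs are realised geometrically by placing the partner bead inside
(0.40 nm) or outside (0.80 nm) the contact cutoff.  Each generator is a
pure function of its spec (and ratio): a fixed seed reproduces identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError, SpecError
from .fibrils import FibrilStructure
from .kinetics import KineticsDataset, logistic
from .trajectory import Ensemble, Ligand, LigandCondition, Residue, Topology

_BOND = 0.38        # nm, Calpha-Calpha virtual bond
_CONTACT_D = 0.40   # nm, realised distance of a formed contact
_BROKEN_D = 0.80    # nm, realised distance of a broken programmed contact
_LIG_BOUND_D = 0.40     # nm, bound ligand-residue distance
_LIG_FAR_MIN = 0.70     # nm, minimum unbound ligand-protein distance


@dataclass
class ProgrammedContact:
    """Pair (i, j) whose occupancy is intercept + slope * ratio."""

    i: int
    j: int
    intercept: float
    slope: float = 0.0

    def occupancy(self, ratio: float) -> float:
        return self.intercept + self.slope * ratio


@dataclass
class BindingSite:
    """A residue with a telegraph-bound ligand: on/off rates in /ns."""

    residue: int
    k_on: float
    k_off: float


@dataclass
class FibrilDesign:
    """One synthetic fibril structure defined by its intended contact set."""

    structure_id: str
    contacts: list[tuple[int, int]]
    n_residues: int | None = None
    renumber_offset: int = 0


@dataclass
class ThTDesign:
    F0: float = 0.1
    Fmax: float = 1.0
    k: float = 0.05          # per minute
    t_half: float = 300.0    # minutes
    noise_sd: float = 0.0
    n_replicates: int = 3
    t_max: float = 700.0     # minutes
    dt: float = 7.0          # minutes between reads (plate-reader cadence)
    condition: str = ""
    ratio: float | None = None


@dataclass
class GeneratorSpec:
    seed: int = 0
    chain_length: int = 30
    n_frames: int = 1000
    frame_dt: float = 0.1           # ns
    box: float | None = None        # nm, cubic; None = auto-size from chain
    ligand_count: int = 0
    programmed_contacts: list[ProgrammedContact] = field(default_factory=list)
    binding_spec: list[BindingSite] = field(default_factory=list)
    fibril_spec: list[FibrilDesign] = field(default_factory=list)
    tht_spec: list[ThTDesign] = field(default_factory=list)
    sequence_offset: int = 0


# --------------------------------------------------------------------------
# Telegraph processes
# --------------------------------------------------------------------------

def telegraph_states(
    k_on: float, k_off: float, dt: float, n_steps: int,
    rng: np.random.Generator, start: bool | None = None,
) -> np.ndarray:
    """Sampled two-state continuous-time telegraph process.

    Dwell times are exponential (rate ``k_off`` while on, ``k_on`` while
    off); the process is sampled every ``dt``.  The autocorrelation of the
    resulting series decays as exp(-(k_on + k_off) t).  ``start=None``
    draws the initial state from the stationary distribution.
    """
    if k_on <= 0 or k_off <= 0:
        raise SpecError("telegraph rates must be positive")
    total = n_steps * dt
    if start is None:
        state = bool(rng.random() < k_on / (k_on + k_off))
    else:
        state = bool(start)
    # draw alternating dwell times until the trajectory is covered
    switch_times: list[np.ndarray] = []
    t, s = 0.0, state
    while t < total:
        n_draw = max(64, int(1.5 * (total - t) * (k_on * k_off) / (k_on + k_off)))
        rates = np.empty(n_draw)
        rates[0::2] = k_off if s else k_on
        rates[1::2] = k_on if s else k_off
        dwells = rng.exponential(1.0 / rates)
        times = t + np.cumsum(dwells)
        switch_times.append(times)
        t = times[-1]
        s = s if n_draw % 2 == 0 else not s
    switches = np.concatenate(switch_times)
    sample_t = np.arange(n_steps) * dt
    n_switches = np.searchsorted(switches, sample_t, side="right")
    return np.where(n_switches % 2 == 0, state, ~np.array(state, dtype=bool))


def _unit_vectors(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    v = rng.normal(size=(*shape, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


# --------------------------------------------------------------------------
# Bead-chain ensembles
# --------------------------------------------------------------------------

def _bead_topology(n_res: int, n_lig: int, sequence_offset: int = 0) -> Topology:
    residues = tuple(
        Residue(index=i + 1, name="GLY", chain_id="A",
                heavy_atom_ids=(i + 1,), calpha_atom_id=i + 1)
        for i in range(n_res)
    )
    ligands = tuple(
        Ligand(index=k + 1, heavy_atom_ids=(n_res + k + 1,)) for k in range(n_lig)
    )
    return Topology(residues=residues, ligands=ligands, sequence_offset=sequence_offset)


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def _stable_tag(text: str) -> int:
    # process-independent (unlike hash()) so fixed seeds reproduce bytes
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


def generate_ensemble(spec: GeneratorSpec, ratio: float = 0.0) -> Ensemble:
    """A bead-per-residue ensemble realising the programmed statistics.

    The chain is a fresh random walk each frame (virtual bond 0.38 nm).
    Each programmed pair's contact state is drawn independently per frame
    with probability intercept + slope * ratio and realised by placing bead
    j at 0.40 nm (formed) or 0.80 nm (broken) from bead i.  Ligand beads
    follow telegraph binding processes: bound frames put them 0.40 nm from
    their site residue, unbound frames place them uniformly in the box but
    at least 0.70 nm away from every protein bead.
    """
    n = spec.chain_length
    occ = {}
    used_residues: set[int] = set()
    for pc in spec.programmed_contacts:
        p = pc.occupancy(ratio)
        if not 0.0 <= p <= 1.0:
            raise SpecError(
                f"programmed occupancy {p:.3f} for pair ({pc.i},{pc.j}) "
                f"at ratio {ratio} is outside [0, 1]"
            )
        if pc.j in used_residues or pc.i in used_residues:
            raise SpecError("programmed contacts must use disjoint residues")
        used_residues.update((pc.i, pc.j))
        occ[(pc.i, pc.j)] = p

    ratio_tag = int(round(ratio * 1000))
    rng_chain = _substream(spec.seed, 1, ratio_tag)
    rng_contacts = _substream(spec.seed, 2, ratio_tag)
    rng_lig = _substream(spec.seed, 3, ratio_tag)

    steps = _unit_vectors(rng_chain, (spec.n_frames, n - 1)) * _BOND
    coords = np.concatenate(
        [np.zeros((spec.n_frames, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )

    for (i, j), p in occ.items():
        formed = rng_contacts.random(spec.n_frames) < p
        u = _unit_vectors(rng_contacts, (spec.n_frames,))
        dist = np.where(formed, _CONTACT_D, _BROKEN_D)
        coords[:, j - 1, :] = coords[:, i - 1, :] + u * dist[:, None]

    # box sized so the chain can never approach its own periodic image
    extent = float(np.ptp(coords, axis=(0, 1)).max()) if n > 1 else 1.0
    box_len = spec.box if spec.box is not None else 2.0 * extent + 2.0
    center = coords.mean(axis=(0, 1))
    coords += (box_len / 2.0 - center)[None, None, :]

    n_lig = max(spec.ligand_count, len(spec.binding_spec))
    lig_coords = np.empty((spec.n_frames, n_lig, 3)) if n_lig else None
    for li in range(n_lig):
        if li < len(spec.binding_spec):
            site = spec.binding_spec[li]
            bound = telegraph_states(site.k_on, site.k_off, spec.frame_dt,
                                     spec.n_frames, rng_lig)
            target = coords[:, site.residue - 1, :]
        else:
            bound = np.zeros(spec.n_frames, dtype=bool)
            target = coords[:, 0, :]
        u = _unit_vectors(rng_lig, (spec.n_frames,))
        pos = target + u * _LIG_BOUND_D
        far = _far_positions(rng_lig, coords, box_len, (~bound).sum())
        pos[~bound] = far
        lig_coords[:, li, :] = pos

    top = _bead_topology(n, n_lig, spec.sequence_offset)
    all_coords = coords if lig_coords is None else np.concatenate(
        [coords, lig_coords], axis=1
    )
    boxes = np.broadcast_to(np.eye(3) * box_len, (spec.n_frames, 3, 3)).copy()
    return Ensemble(
        topology=top,
        coords=all_coords,
        times=np.arange(spec.n_frames) * spec.frame_dt,
        boxes=boxes,
        condition=LigandCondition(ratio=ratio, label=f"ratio_{ratio:g}"),
    )


def _far_positions(rng: np.random.Generator, chain: np.ndarray,
                   box_len: float, count: int) -> np.ndarray:
    """Uniform positions in the box at least _LIG_FAR_MIN from every bead.

    Rejection sampling against the frame-wise maximum chain envelope is
    avoided by testing against all frames' bead cloud bounding sphere; with
    the auto-sized box most draws are accepted immediately.
    """
    if count == 0:
        return np.empty((0, 3))
    center = chain.mean(axis=(0, 1))
    radius = np.linalg.norm(chain - center, axis=-1).max() + _LIG_FAR_MIN
    out = np.empty((count, 3))
    filled = 0
    while filled < count:
        cand = rng.random((2 * (count - filled) + 8, 3)) * box_len
        good = np.linalg.norm(cand - center, axis=1) > radius
        take = cand[good][: count - filled]
        out[filled: filled + len(take)] = take
        filled += len(take)
    return out


def generate_gaussian_chain_ensemble(
    n_residues: int, n_chains: int, seed: int, bond_rms: float = 0.55
) -> Ensemble:
    """Ideal (Gaussian) chains: R(s) = bond_rms * sqrt(s) in expectation.

    Each frame is an independent chain; useful for checking that the Flory
    fit recovers nu = 0.5 at the theta point.
    """
    rng = np.random.default_rng(seed)
    sigma = bond_rms / np.sqrt(3.0)
    steps = rng.normal(scale=sigma, size=(n_chains, n_residues - 1, 3))
    coords = np.concatenate(
        [np.zeros((n_chains, 1, 3)), np.cumsum(steps, axis=1)], axis=1
    )
    top = _bead_topology(n_residues, 0)
    return Ensemble(topology=top, coords=coords,
                    times=np.arange(n_chains, dtype=float))


def generate_ideal_gas_ensemble(
    n_protein: int, n_ligand: int, box_len: float, n_frames: int, seed: int
) -> Ensemble:
    """Uncorrelated uniform 'protein' beads and ligand beads in a cubic box.

    The protein-ligand radial distribution function of this system is 1 at
    every distance, which anchors the RDF normalisation.
    """
    rng = np.random.default_rng(seed)
    coords = rng.random((n_frames, n_protein + n_ligand, 3)) * box_len
    top = _bead_topology(n_protein, n_ligand)
    boxes = np.broadcast_to(np.eye(3) * box_len, (n_frames, 3, 3)).copy()
    return Ensemble(topology=top, coords=coords,
                    times=np.arange(n_frames, dtype=float), boxes=boxes)


# --------------------------------------------------------------------------
# Fibril-like structure sets
# --------------------------------------------------------------------------

def _fold_chain(n_res: int, contacts: list[tuple[int, int]],
                rng: np.random.Generator, n_iter: int = 4000) -> np.ndarray | None:
    """Fold a bead chain so exactly the designed pairs are within 0.45 nm.

    Starts from an extended conformation (every long-range pair far apart)
    and relaxes a soft potential by gradient descent: bonds at 0.38 nm,
    designed pairs pulled to 0.40 nm, all other pairs with |i-j| >= 4
    repelled below a 0.60 nm buffer (margin above the 0.45 nm cutoff, so
    residual penalty violations stay on the correct side).  Returns
    coordinates (nm) or None when the design was not realised.
    """
    pos = np.zeros((n_res, 3))
    pos[:, 0] = np.arange(n_res) * _BOND
    pos += rng.normal(scale=0.02, size=pos.shape)
    contact_idx = np.array([(i - 1, j - 1) for i, j in contacts], dtype=int) \
        if contacts else np.empty((0, 2), dtype=int)
    others = np.array(
        [(i, j) for i in range(n_res) for j in range(i + 4, n_res)
         if (i + 1, j + 1) not in set(contacts)],
        dtype=int,
    )
    buffer_d, w_rep, w_con = 0.60, 4.0, 10.0
    for it in range(n_iter):
        lr = 0.05 if it < n_iter // 2 else 0.01
        grad = np.zeros_like(pos)
        # bonds
        dv = pos[1:] - pos[:-1]
        dn = np.linalg.norm(dv, axis=1, keepdims=True)
        f = 2.0 * (dn - _BOND) * dv / np.maximum(dn, 1e-9)
        grad[1:] += f
        grad[:-1] -= f
        # designed contacts
        if len(contact_idx):
            a, b = contact_idx[:, 0], contact_idx[:, 1]
            dv = pos[b] - pos[a]
            dn = np.linalg.norm(dv, axis=1, keepdims=True)
            f = 2.0 * w_con * (dn - _CONTACT_D) * dv / np.maximum(dn, 1e-9)
            np.add.at(grad, b, f)
            np.add.at(grad, a, -f)
        # repulsion for non-designed long-range pairs
        if len(others):
            a, b = others[:, 0], others[:, 1]
            dv = pos[b] - pos[a]
            dn = np.linalg.norm(dv, axis=1, keepdims=True)
            f = np.where(dn < buffer_d, 2.0 * w_rep * (dn - buffer_d), 0.0) \
                * dv / np.maximum(dn, 1e-9)
            np.add.at(grad, b, f)
            np.add.at(grad, a, -f)
        pos -= lr * grad
    # verify realisation
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    want = {(i - 1, j - 1) for i, j in contacts}
    for i in range(n_res):
        for j in range(i + 4, n_res):
            is_contact = d[i, j] < 0.45
            if is_contact != ((i, j) in want):
                return None
    return pos


def generate_fibril_structure(design: FibrilDesign, seed: int,
                              max_retries: int = 8) -> FibrilStructure:
    """Build one synthetic fibril-like monomer realising a designed contact set."""
    for i, j in design.contacts:
        if j - i < 4:
            raise SpecError(f"designed pair ({i},{j}) violates |i-j| >= 4")
    n_res = design.n_residues or (max(j for _, j in design.contacts) + 2
                                  if design.contacts else 12)
    for attempt in range(max_retries):
        rng = _substream(seed, 4, attempt, _stable_tag(design.structure_id))
        pos = _fold_chain(n_res, design.contacts, rng)
        if pos is not None:
            nums = np.arange(1, n_res + 1) + design.renumber_offset
            return FibrilStructure(
                structure_id=design.structure_id,
                residue_numbers=nums,
                residue_names=["GLY"] * n_res,
                coords=pos,
                atom_starts=np.arange(n_res, dtype=np.intp),
                source_chain="A",
                resolved_range=(int(nums[0]), int(nums[-1])),
            )
    # identify which designed pair failed on the last attempt for the message
    raise GenerationError(
        f"could not realise contact design for {design.structure_id}: "
        f"{design.contacts}"
    )


def write_fibril_pdb(structure: FibrilStructure, path: str | Path) -> None:
    """Write a Calpha-trace PDB (nm -> Angstrom) for the synthetic monomer."""
    lines = []
    for k, (num, xyz) in enumerate(zip(structure.residue_numbers, structure.coords), 1):
        x, y, z = xyz * 10.0
        lines.append(
            f"ATOM  {k:5d}  CA  GLY A{int(num):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_fibril_set(spec: GeneratorSpec, out_dir: str | Path) -> list[Path]:
    """Write one PDB per designed structure; returns the file paths.

    The designed contact overlaps between structures define a ground-truth
    clustering that the shared-contact clustering must recover.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for design in spec.fibril_spec:
        st = generate_fibril_structure(design, spec.seed)
        p = out_dir / f"{design.structure_id}.pdb"
        write_fibril_pdb(st, p)
        paths.append(p)
    return paths


# --------------------------------------------------------------------------
# ThT curves
# --------------------------------------------------------------------------

def generate_tht_curve(design: ThTDesign, seed: int) -> KineticsDataset:
    """Logistic fluorescence curves plus seeded Gaussian noise."""
    if design.noise_sd < 0:
        raise SpecError("noise_sd must be >= 0")
    rng = _substream(seed, 5, _stable_tag(design.condition))
    t = np.arange(0.0, design.t_max + design.dt / 2, design.dt)
    clean = logistic(t, design.F0, design.Fmax, design.k, design.t_half)
    reps = clean[None, :] + rng.normal(
        scale=design.noise_sd, size=(design.n_replicates, t.size)
    )
    return KineticsDataset(t, reps, condition=design.condition, ratio=design.ratio)


def generate_tht_curves(spec: GeneratorSpec) -> list[KineticsDataset]:
    return [generate_tht_curve(d, spec.seed) for d in spec.tht_spec]


def write_kinetics_csv(datasets: list[KineticsDataset], path: str | Path) -> None:
    """Long-format plate CSV: time_min, value, replicate, condition, ratio."""
    with open(path, "w") as fh:
        fh.write("time_min,value,replicate,condition,ratio\n")
        for ds in datasets:
            for rep in range(ds.replicates.shape[0]):
                for t, v in zip(ds.time, ds.replicates[rep]):
                    ratio = "" if ds.ratio is None else f"{ds.ratio:g}"
                    fh.write(f"{t:g},{v:.6f},{rep + 1},{ds.condition},{ratio}\n")
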