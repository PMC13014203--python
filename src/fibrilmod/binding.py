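"""Ligand-protein association analytics.

Three views of how a polyvalent ligand (e.g. spermine) engages a disordered
chain: the mean number of ligand molecules in contact with each residue,
the probability that a single ligand molecule simultaneously bridges two
residues (ligand-mediated contacts), and the kinetics of binding events —
per-residue residence times, protein-level residence times, and exchange
rates.

Binding events use the same enter/exit hysteresis pair as the contact
analysis: an event begins when a ligand comes within ``r_on`` (0.45 nm) of
a residue and ends at the first frame its distance exceeds ``r_off``
(0.6 nm); re-entering the dead zone in between does not end the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import block_min_reduce, min_image_displacements
from .errors import EmptyEnsembleError, ParameterError
from .trajectory import Ensemble


@dataclass
class BindingProfile:
    """Mean number of distinct ligand molecules in contact per residue."""

    n_ligand: np.ndarray          # (n_residues,)
    residue_numbers: np.ndarray   # full-length numbering
    cutoff: float


@dataclass
class MediatedContactMap:
    """P_isj: probability residues i and j contact the *same* ligand molecule."""

    pairs: dict[tuple[int, int], float]
    cutoff: float
    min_separation: int
    n_frames: int
    n_residues: int
    sequence_offset: int = 0


@dataclass
class BindingEvent:
    ligand: int
    residue: int              # local index
    start_frame: int
    tau_residue: float | None     # ns; None if censored
    tau_protein: float | None     # ns; None if censored at protein level


@dataclass
class ResidenceStats:
    """Per-residue residence-time and exchange-rate summary.

    ``table`` columns: residue (full numbering), mean_tau_residue,
    mean_tau_protein, exchange_rate (completed dissociation events per ns of
    analyzed time), n_events, n_censored.  Means exclude censored events.
    """

    table: pd.DataFrame
    events: list[BindingEvent] = field(default_factory=list)
    r_on: float = 0.45
    r_off: float = 0.6
    analyzed_time: float = 0.0  # ns


# --------------------------------------------------------------------------

def _residue_ligand_distances(ensemble: Ensemble) -> np.ndarray:
    """Min heavy-atom distance matrix (n_frames, n_residues, n_ligands)."""
    top = ensemble.topology
    if top.n_ligands == 0:
        raise EmptyEnsembleError("ensemble declares no ligand molecules")
    n_prot = top.n_protein_atoms()
    res_starts = top.residue_atom_starts()
    lig_starts = top.ligand_atom_starts()
    out = np.empty((ensemble.n_frames, top.n_residues, top.n_ligands))
    prot = ensemble.coords[:, :n_prot, :]
    lig = ensemble.coords[:, n_prot:, :]
    for f in range(ensemble.n_frames):
        d = prot[f][:, None, :] - lig[f][None, :, :]
        d = min_image_displacements(d, ensemble.box(f))
        mat = np.linalg.norm(d, axis=-1)
        out[f] = block_min_reduce(mat, res_starts, lig_starts)
    return out


def ligand_count_profile(ensemble: Ensemble, cutoff: float = 0.45) -> BindingProfile:
    """Mean over frames of the number of distinct ligand molecules whose any
    heavy atom lies within ``cutoff`` of any heavy atom of each residue."""
    d = _residue_ligand_distances(ensemble)
    counts = (d < cutoff).sum(axis=2)          # (n_frames, n_residues)
    return BindingProfile(
        n_ligand=counts.mean(axis=0),
        residue_numbers=ensemble.topology.full_residue_numbers(),
        cutoff=cutoff,
    )


def mediated_contact_map(
    ensemble: Ensemble, cutoff: float = 0.6, min_separation: int = 4
) -> MediatedContactMap:
    """P_isj = fraction of frames in which residues i and j are both within
    ``cutoff`` of the same ligand molecule, for |i-j| >= min_separation.

    Pairs in direct contact are not excluded; attributing a pair to direct
    versus ligand-mediated interaction is done downstream by comparing this
    map against the plain contact map.
    """
    d = _residue_ligand_distances(ensemble)
    near = d < cutoff                          # (F, R, L)
    n_res = ensemble.topology.n_residues
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f in range(ensemble.n_frames):
        bridged = near[f] @ near[f].T          # (R, R) int: shared-ligand count
        counts += bridged > 0
    iu = np.triu_indices(n_res, k=min_separation)
    pairs = {
        (int(i) + 1, int(j) + 1): float(c) / ensemble.n_frames
        for i, j, c in zip(*iu, counts[iu])
        if c
    }
    return MediatedContactMap(
        pairs=pairs,
        cutoff=cutoff,
        min_separation=min_separation,
        n_frames=ensemble.n_frames,
        n_residues=n_res,
        sequence_offset=ensemble.topology.sequence_offset,
    )


# --------------------------------------------------------------------------
# Residence times and exchange rates
# --------------------------------------------------------------------------

def residence_analysis(
    ensemble: Ensemble, r_on: float = 0.45, r_off: float = 0.6
) -> ResidenceStats:
    """Binding-event kinetics per (ligand, residue) pair.

    tau_residue: time for a ligand initially within ``r_on`` of a residue to
    move beyond ``r_off`` of that residue.  tau_protein: time for the same
    ligand, from the same event start, to move beyond ``r_off`` of *all*
    residues.  Events still bound at the end of the trajectory are counted
    as censored and excluded from means.  exchange_rate is completed
    tau_residue dissociation events per ns of analyzed time (n_frames * dt).
    """
    if r_on >= r_off:
        raise ParameterError(f"r_on ({r_on}) must be < r_off ({r_off})")
    dt = ensemble.frame_spacing()
    d = _residue_ligand_distances(ensemble)    # (F, R, L)
    n_frames, n_res, n_lig = d.shape
    analyzed_time = n_frames * dt
    dmin_protein = d.min(axis=1)               # (F, L)

    events: list[BindingEvent] = []
    for lig in range(n_lig):
        protein_free = dmin_protein[:, lig] > r_off
        for res in range(n_res):
            series = d[:, res, lig]
            bound = _hysteretic_bound(series, r_on, r_off)
            starts, ends = _bound_runs(bound)
            for s, e in zip(starts, ends):
                tau_r = (e - s) * dt if e < n_frames else None
                free_after = np.flatnonzero(protein_free[s:])
                tau_p = float(free_after[0]) * dt if free_after.size else None
                events.append(BindingEvent(lig + 1, res + 1, int(s), tau_r, tau_p))

    full_numbers = ensemble.topology.full_residue_numbers()
    rows = []
    for res in range(n_res):
        ev = [e for e in events if e.residue == res + 1]
        taus_r = [e.tau_residue for e in ev if e.tau_residue is not None]
        taus_p = [e.tau_protein for e in ev if e.tau_protein is not None]
        n_censored = sum(1 for e in ev if e.tau_residue is None)
        rows.append({
            "residue": int(full_numbers[res]),
            "mean_tau_residue": float(np.mean(taus_r)) if taus_r else np.nan,
            "mean_tau_protein": float(np.mean(taus_p)) if taus_p else np.nan,
            "exchange_rate": len(taus_r) / analyzed_time,
            "n_events": len(taus_r),
            "n_censored": n_censored,
        })
    return ResidenceStats(
        table=pd.DataFrame(rows),
        events=events,
        r_on=r_on,
        r_off=r_off,
        analyzed_time=analyzed_time,
    )


def _hysteretic_bound(series: np.ndarray, r_on: float, r_off: float) -> np.ndarray:
    """Bound-state series: enters below r_on, leaves above r_off.

    An ambiguous prefix (starting in the dead zone) is treated as unbound:
    an event must begin with an observed entry.
    """
    codes = np.zeros(series.size, dtype=np.int8)
    codes[series < r_on] = 1
    codes[series > r_off] = -1
    idx = np.where(codes != 0, np.arange(series.size), -1)
    idx = np.maximum.accumulate(idx)
    bound = np.zeros(series.size, dtype=bool)
    valid = idx >= 0
    bound[valid] = codes[idx[valid]] == 1
    return bound


def _bound_runs(bound: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and exclusive end indices of contiguous bound runs."""
    padded = np.concatenate([[False], bound, [False]]).astype(np.int8)
    diff = np.diff(padded)
    return np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)


def write_residence_tsv(stats: ResidenceStats, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# r_on_nm={stats.r_on}\n# r_off_nm={stats.r_off}\n")
        fh.write(f"# analyzed_time_ns={stats.analyzed_time}\n")
        stats.table.to_csv(fh, sep="\t", index=False)


def write_binding_profile_tsv(profile: BindingProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cutoff_nm={profile.cutoff}\n")
        fh.write("residue\tn_ligand\n")
        for r, n in zip(profile.residue_numbers, profile.n_ligand):
            fh.write(f"{int(r)}\t{n:.6f}\n")
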