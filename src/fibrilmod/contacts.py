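"""Intrachain contact maps, contact deltas, twin-cutoff state series and
contact relaxation times.

A residue pair (i, j) is "in contact" in a frame when any heavy atom of i
lies within the cutoff (default 0.45 nm) of any heavy atom of j.  Pairs
separated by fewer than three intervening residues are excluded, i.e. the
map keeps only |i - j| >= 4.  Maps store only pairs with nonzero
probability together with the pair-universe size, so downstream
zero-handling is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import block_min_reduce, min_image_displacements
from .errors import (
    EmptyEnsembleError,
    IncompatibleMapsError,
    NonFluctuatingError,
    ParameterError,
)
from .trajectory import Ensemble, LigandCondition

DEFAULT_CONTACT_CUTOFF = 0.45  # nm, heavy-atom minimum distance
DEFAULT_MIN_SEPARATION = 4    # |i-j| >= 4: at least three residues in between


@dataclass
class ContactMap:
    """Per-pair contact probabilities at one ligand condition.

    ``pairs`` maps local residue pairs (i, j), i < j, to P_ij; pairs absent
    from the dict but inside the universe (|i-j| >= min_separation within the
    chain) have probability exactly zero.
    """

    pairs: dict[tuple[int, int], float]
    cutoff: float
    min_separation: int
    n_frames: int
    n_residues: int
    condition: LigandCondition = field(default_factory=lambda: LigandCondition(0.0))
    sequence_offset: int = 0

    def probability(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        return self.pairs.get((i, j), 0.0)

    def universe(self) -> set[tuple[int, int]]:
        n, s = self.n_residues, self.min_separation
        return {(i, j) for i in range(1, n + 1) for j in range(i + s, n + 1)}

    def compatible_with(self, other: "ContactMap") -> bool:
        return (
            np.isclose(self.cutoff, other.cutoff)
            and self.min_separation == other.min_separation
        )


@dataclass
class ContactDelta:
    """ΔP_ij between a ligand-bound and a ligand-free condition."""

    pairs: dict[tuple[int, int], float]
    condition_with: LigandCondition
    condition_without: LigandCondition
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION


@dataclass
class ContactStateTrajectory:
    """Binary formed/broken series from the twin-cutoff (hysteresis) scheme."""

    pair: tuple[int, int]
    states: np.ndarray  # bool, True = formed
    r_on: float
    r_off: float
    dt: float  # ns
    first_frame: int = 0  # > 0 when the ambiguous prefix was dropped


@dataclass
class RelaxationResult:
    pair: tuple[int, int]
    tau: float            # ns; nan when the fit was rejected
    fit_window: float     # ns, span of lags used
    fit_quality: float    # RMS residual of the log-linear fit (inf if rejected)

    @property
    def ok(self) -> bool:
        return np.isfinite(self.tau) and self.tau > 0


# --------------------------------------------------------------------------

def residue_min_distances(ensemble: Ensemble, frame: int) -> np.ndarray:
    """Residue-residue heavy-atom minimum-distance matrix for one frame."""
    top = ensemble.topology
    n_prot = top.n_protein_atoms()
    pts = ensemble.coords[frame, :n_prot, :]
    box = ensemble.box(frame)
    d = pts[:, None, :] - pts[None, :, :]
    d = min_image_displacements(d, box)
    mat = np.linalg.norm(d, axis=-1)
    starts = top.residue_atom_starts()
    return block_min_reduce(mat, starts, starts)


def compute_contact_map(
    ensemble: Ensemble,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> ContactMap:
    """P_ij = fraction of frames with residues i, j within ``cutoff``.

    Residue-residue distance is the minimum over heavy-atom pairs (with the
    minimum-image convention when the frame carries a box).
    """
    if ensemble.n_frames == 0:
        raise EmptyEnsembleError("contact map of an empty ensemble")
    n_res = ensemble.topology.n_residues
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    for f in range(ensemble.n_frames):
        dmat = residue_min_distances(ensemble, f)
        counts += dmat < cutoff
    iu = np.triu_indices(n_res, k=min_separation)
    pairs: dict[tuple[int, int], float] = {}
    for i, j, c in zip(*iu, counts[iu]):
        if c:
            pairs[(int(i) + 1, int(j) + 1)] = float(c) / ensemble.n_frames
    return ContactMap(
        pairs=pairs,
        cutoff=cutoff,
        min_separation=min_separation,
        n_frames=ensemble.n_frames,
        n_residues=n_res,
        condition=ensemble.condition,
        sequence_offset=ensemble.topology.sequence_offset,
    )


def contact_delta(map_with: ContactMap, map_without: ContactMap) -> ContactDelta:
    """ΔP_ij = P_ij(with ligand) - P_ij(without), over the shared pair universe.

    A pair stored in one map but absent from the other contributes zero for
    the sparse side (absence means no frames in contact).
    """
    if not map_with.compatible_with(map_without):
        raise IncompatibleMapsError(
            "contact maps differ in cutoff or min_separation"
        )
    keys = set(map_with.pairs) | set(map_without.pairs)
    n = min(map_with.n_residues, map_without.n_residues)
    pairs = {
        k: map_with.probability(*k) - map_without.probability(*k)
        for k in keys
        if k[1] <= n
    }
    return ContactDelta(
        pairs=pairs,
        condition_with=map_with.condition,
        condition_without=map_without.condition,
        cutoff=map_with.cutoff,
        min_separation=map_with.min_separation,
    )


# --------------------------------------------------------------------------
# Twin-cutoff state series and relaxation times
# --------------------------------------------------------------------------

def hysteresis_states(
    distances: np.ndarray, r_on: float, r_off: float, initial: str = "backfill"
) -> tuple[np.ndarray, int]:
    """Binary states from a distance series under the twin-cutoff rule.

    Formed below ``r_on``, broken above ``r_off``; distances in between keep
    the previous state.  An ambiguous prefix is back-filled from the first
    unambiguous state (default) or dropped (``initial="drop"``).
    Returns (states, first_frame).
    """
    if r_on >= r_off:
        raise ParameterError(f"r_on ({r_on}) must be < r_off ({r_off})")
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ParameterError("empty distance series")
    codes = np.zeros(d.size, dtype=np.int8)
    codes[d < r_on] = 1
    codes[d > r_off] = -1
    nz = np.flatnonzero(codes)
    if nz.size == 0:
        raise ParameterError("distance series never leaves the dead zone")
    idx = np.where(codes != 0, np.arange(d.size), -1)
    idx = np.maximum.accumulate(idx)
    states = np.empty(d.size, dtype=bool)
    valid = idx >= 0
    states[valid] = codes[idx[valid]] == 1
    first = 0
    if not valid.all():
        if initial == "drop":
            first = int(nz[0])
            states = states[first:]
        else:
            states[~valid] = codes[nz[0]] == 1
    return states, first


def contact_state_trajectory(
    distance_series: np.ndarray,
    r_on: float = 0.45,
    r_off: float = 0.6,
    dt: float = 1.0,
    pair: tuple[int, int] = (0, 0),
    initial: str = "backfill",
) -> ContactStateTrajectory:
    states, first = hysteresis_states(distance_series, r_on, r_off, initial)
    return ContactStateTrajectory(pair=pair, states=states, r_on=r_on,
                                  r_off=r_off, dt=dt, first_frame=first)


def _autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Normalised fluctuation autocorrelation C(0..max_lag) via FFT."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conj(f))[: max_lag + 1]
    if acf[0] <= 0:
        raise NonFluctuatingError("zero variance in state series")
    return acf / acf[0]


def contact_relaxation_time(traj: ContactStateTrajectory,
                            c_floor: float = 0.05) -> RelaxationResult:
    """Relaxation time from a single-exponential fit of the contact
    autocorrelation.

    C(t) = exp(-t/tau) is fitted over lags 1 .. L-1, where L is the first
    lag at which C drops below ``c_floor`` or 10% of the series length,
    whichever is smaller.  The one-parameter fit is done in linear space
    (initialised from a log-linear slope): near the window floor the noise
    on C is comparable to C itself, so least squares on log C would be
    dominated by the tail; the linear-space fit weights the well-determined
    early decay properly.  A window too short for a fit (or a non-decaying
    C) yields a rejected result (tau = nan, fit_quality = inf).
    """
    states = traj.states.astype(float)
    if states.min() == states.max():
        raise NonFluctuatingError(f"pair {traj.pair} never changes state")
    max_lag = max(2, states.size // 10)
    c = _autocorrelation(states, max_lag)
    below = np.flatnonzero(c < c_floor)
    stop = int(below[0]) if below.size else max_lag + 1
    lags = np.arange(1, min(stop, max_lag + 1))
    lags = lags[c[lags] > 0]
    if lags.size < 2:
        return RelaxationResult(traj.pair, np.nan, 0.0, np.inf)
    t = lags * traj.dt
    cw = c[lags]
    slope = np.polyfit(t, np.log(cw), 1)[0]
    if slope >= 0:
        return RelaxationResult(traj.pair, np.nan, float(t[-1] - t[0]), np.inf)
    from scipy.optimize import curve_fit

    try:
        popt, _ = curve_fit(lambda tt, tau: np.exp(-tt / tau), t, cw,
                            p0=[-1.0 / slope], maxfev=1000)
    except RuntimeError:
        return RelaxationResult(traj.pair, np.nan, float(t[-1] - t[0]), np.inf)
    tau = float(popt[0])
    if tau <= 0:
        return RelaxationResult(traj.pair, np.nan, float(t[-1] - t[0]), np.inf)
    quality = float(np.sqrt(np.mean((cw - np.exp(-t / tau)) ** 2)))
    return RelaxationResult(traj.pair, tau, float(t[-1] - t[0]), quality)


# --------------------------------------------------------------------------
# TSV export
# --------------------------------------------------------------------------

def write_contact_map_tsv(cmap: ContactMap, path) -> None:
    """Sparse TSV with a header block recording the contact definition."""
    off = cmap.sequence_offset
    with open(path, "w") as fh:
        fh.write(f"# cutoff_nm={cmap.cutoff}\n# min_separation={cmap.min_separation}\n")
        fh.write(f"# n_frames={cmap.n_frames}\n# n_residues={cmap.n_residues}\n")
        fh.write(f"# ratio={cmap.condition.ratio}\tlabel={cmap.condition.label}\n")
        fh.write("i\tj\ti_full\tj_full\tP\n")
        for (i, j), p in sorted(cmap.pairs.items()):
            fh.write(f"{i}\t{j}\t{i + off}\t{j + off}\t{p:.6f}\n")


def contact_map_matrix(cmap: ContactMap) -> np.ndarray:
    """Dense symmetric matrix (n_residues x n_residues) for plotting."""
    m = np.zeros((cmap.n_residues, cmap.n_residues))
    for (i, j), p in cmap.pairs.items():
        m[i - 1, j - 1] = m[j - 1, i - 1] = p
    return m
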