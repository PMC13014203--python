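"""Ensemble I/O and periodic-image quality control.

Internal units are nm and ns everywhere.  Angstrom-based formats (PDB, XTC
and DCD as exposed by their readers) are converted on load.  Hydrogens, if
declared in a topology file, are dropped at load: all contact analyses in
this package operate on heavy (non-hydrogen) atoms only.

A :class:`Topology` orders protein residues first and ligand molecules
after them; coordinates are stored as one dense ``(n_frames, n_atoms, 3)``
array whose atom axis follows that order, with residues (and ligands)
occupying contiguous runs.  That layout is what lets the contact code reduce
atom-atom distance matrices to residue-residue minima in one pass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FormatError, QCUnavailableError, TopologyError

_HYDROGEN_NAMES = ("H", "D")


@dataclass(frozen=True)
class LigandCondition:
    """A ligand:protein molar ratio, e.g. 0, 1, 5, 10 or 50 spermine per chain."""

    ratio: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError(f"ligand ratio must be >= 0, got {self.ratio}")


@dataclass(frozen=True)
class Residue:
    index: int  # local, 1-based, contiguous
    name: str
    chain_id: str
    heavy_atom_ids: tuple[int, ...]
    calpha_atom_id: int | None = None


@dataclass(frozen=True)
class Ligand:
    index: int
    heavy_atom_ids: tuple[int, ...]


@dataclass(frozen=True)
class Topology:
    """Residue/ligand declarations plus the local -> isoform numbering offset.

    ``sequence_offset`` maps local residue index to full-length isoform
    numbering, e.g. offset 243 maps K18 local residue 1 to Tau residue 244.
    """

    residues: tuple[Residue, ...]
    ligands: tuple[Ligand, ...] = ()
    sequence_offset: int = 0

    def __post_init__(self) -> None:
        if not self.residues:
            raise TopologyError("topology declares no residues")
        seen: set[int] = set()
        prev = None
        for res in self.residues:
            if not res.heavy_atom_ids:
                raise TopologyError(f"residue {res.index} has no heavy atoms")
            if prev is not None and res.index <= prev:
                raise TopologyError("residue indices must be strictly increasing")
            prev = res.index
            for aid in res.heavy_atom_ids:
                if aid in seen:
                    raise TopologyError(f"duplicate atom id {aid}")
                seen.add(aid)
        for lig in self.ligands:
            for aid in lig.heavy_atom_ids:
                if aid in seen:
                    raise TopologyError(f"duplicate atom id {aid}")
                seen.add(aid)

    # ---- derived layout ------------------------------------------------
    @property
    def atom_ids(self) -> tuple[int, ...]:
        """All heavy-atom ids, residues first then ligands, each contiguous."""
        ids: list[int] = []
        for res in self.residues:
            ids.extend(res.heavy_atom_ids)
        for lig in self.ligands:
            ids.extend(lig.heavy_atom_ids)
        return tuple(ids)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    def residue_atom_starts(self) -> np.ndarray:
        """Start offsets of each residue's atoms within the atom axis."""
        sizes = [len(r.heavy_atom_ids) for r in self.residues]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)

    def n_protein_atoms(self) -> int:
        return sum(len(r.heavy_atom_ids) for r in self.residues)

    def ligand_atom_starts(self) -> np.ndarray:
        """Start offsets of each ligand's atoms within the *ligand block*."""
        sizes = [len(l.heavy_atom_ids) for l in self.ligands]
        return np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)

    def calpha_rows(self) -> np.ndarray:
        """Atom-axis rows of the Calpha atoms (falls back to first heavy atom)."""
        id_to_row = {aid: i for i, aid in enumerate(self.atom_ids)}
        rows = []
        for res in self.residues:
            aid = res.calpha_atom_id if res.calpha_atom_id is not None else res.heavy_atom_ids[0]
            rows.append(id_to_row[aid])
        return np.asarray(rows, dtype=np.intp)

    def full_residue_numbers(self) -> np.ndarray:
        return np.asarray([r.index + self.sequence_offset for r in self.residues])


@dataclass
class Ensemble:
    """A topology plus frames (coordinates in nm, times in ns).

    ``coords`` has shape (n_frames, n_atoms, 3) following ``topology.atom_ids``;
    ``boxes`` is (n_frames, 3, 3) row-vector boxes or ``None`` for open
    boundaries; ``times`` is (n_frames,) in ns, non-decreasing.
    """

    topology: Topology
    coords: np.ndarray
    times: np.ndarray
    boxes: np.ndarray | None = None
    condition: LigandCondition = field(default_factory=lambda: LigandCondition(0.0))

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TopologyError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.coords.shape[1]} atoms but topology "
                f"declares {self.topology.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise TopologyError("times and coords disagree on frame count")
        if np.any(np.diff(self.times) < 0):
            raise TopologyError("frame times must be non-decreasing")
        if self.boxes is not None:
            self.boxes = np.asarray(self.boxes, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def box(self, frame: int) -> np.ndarray | None:
        return None if self.boxes is None else self.boxes[frame]

    def protein_coords(self) -> np.ndarray:
        return self.coords[:, : self.topology.n_protein_atoms(), :]

    def ligand_coords(self) -> np.ndarray:
        return self.coords[:, self.topology.n_protein_atoms():, :]

    def calpha_coords(self) -> np.ndarray:
        return self.coords[:, self.topology.calpha_rows(), :]

    def frame_spacing(self) -> float:
        """Uniform frame spacing in ns (raises if spacing is non-uniform)."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 frames to determine frame spacing")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("frame spacing is non-uniform")
        return float(dts[0])

    def subset(self, frame_mask: np.ndarray) -> "Ensemble":
        """Ensemble restricted to frames where ``frame_mask`` is True."""
        return replace(
            self,
            coords=self.coords[frame_mask],
            times=self.times[frame_mask],
            boxes=None if self.boxes is None else self.boxes[frame_mask],
        )


# --------------------------------------------------------------------------
# Topology I/O
# --------------------------------------------------------------------------

def load_topology(path: str | Path) -> Topology:
    """Read a topology from a JSON sidecar or a PDB/mmCIF file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _topology_from_json(path)
    if path.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent"):
        return _topology_from_structure(path)
    raise FormatError(f"unrecognised topology format: {path.name}")


def _topology_from_json(path: Path) -> Topology:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid topology JSON {path}: {exc}") from exc
    residues = tuple(
        Residue(
            index=int(r["index"]),
            name=str(r.get("name", "UNK")),
            chain_id=str(r.get("chain", "A")),
            heavy_atom_ids=tuple(int(a) for a in r["heavy_atoms"]),
            calpha_atom_id=(int(r["calpha"]) if r.get("calpha") is not None else None),
        )
        for r in doc["residues"]
    )
    ligands = tuple(
        Ligand(index=int(l["index"]), heavy_atom_ids=tuple(int(a) for a in l["heavy_atoms"]))
        for l in doc.get("ligands", [])
    )
    return Topology(residues=residues, ligands=ligands,
                    sequence_offset=int(doc.get("sequence_offset", 0)))


def _topology_from_structure(path: Path) -> Topology:
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse structure {path}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    model = st[0]
    residues: list[Residue] = []
    ligands: list[Ligand] = []
    local = 0
    for chain in model:
        for res in chain:
            heavy = [a for a in res if a.element.name not in _HYDROGEN_NAMES]
            if not heavy:
                continue
            ids = tuple(a.serial for a in heavy)
            info = gemmi.find_tabulated_residue(res.name)
            if info.is_amino_acid():
                local += 1
                ca = next((a.serial for a in heavy if a.name == "CA"), None)
                residues.append(Residue(local, res.name, chain.name, ids, ca))
            elif not info.is_water():
                ligands.append(Ligand(len(ligands) + 1, ids))
    if not residues:
        raise FormatError(f"no protein residues found in {path}")
    return Topology(residues=tuple(residues), ligands=tuple(ligands))


# --------------------------------------------------------------------------
# Trajectory readers (coordinates returned in nm)
# --------------------------------------------------------------------------

def _read_pdb_frames(path: Path) -> tuple[dict[int, np.ndarray], np.ndarray | None, list]:
    """Multi-model PDB -> ({atom serial: (n_models, 3) nm}, box or None, serials)."""
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse trajectory {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    box = None
    cell = st.cell
    if cell.a > 1.0 and not (cell.a == cell.b == cell.c == 1.0):
        # gemmi stores Angstrom cell parameters; orthogonalisation matrix rows
        frac = np.array(cell.orth.mat.tolist()) / 10.0
        box = frac.T  # rows = box vectors in nm
    serials: list[int] = []
    per_model: list[dict[int, np.ndarray]] = []
    for model in st:
        coords: dict[int, np.ndarray] = {}
        for chain in model:
            for res in chain:
                for atom in res:
                    coords[atom.serial] = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) / 10.0
        per_model.append(coords)
    serials = sorted(per_model[0])
    stacked = {s: np.stack([m[s] for m in per_model]) for s in serials}
    return stacked, box, serials


def _read_tsv_frames(path: Path) -> tuple[dict[int, np.ndarray], None, list]:
    """Plain-text fallback: columns frame, atom_id, x, y, z (nm, tab/space separated)."""
    import pandas as pd

    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#",
                         names=["frame", "atom_id", "x", "y", "z"], header=None, skiprows=_tsv_skip(path))
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"cannot parse coordinate table {path}: {exc}") from exc
    frames = np.sort(df["frame"].unique())
    stacked: dict[int, np.ndarray] = {}
    for aid, grp in df.groupby("atom_id"):
        grp = grp.sort_values("frame")
        if len(grp) != len(frames):
            raise FormatError(f"atom {aid} missing from some frames in {path}")
        stacked[int(aid)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return stacked, None, sorted(stacked)


def _tsv_skip(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    return 1 if first.lower().lstrip().startswith("frame") else 0


def _read_mda_frames(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    """XTC/DCD via the MDAnalysis coordinate readers (Angstrom -> nm)."""
    import MDAnalysis.coordinates as mdac

    reader_cls = {".xtc": mdac.XTC.XTCReader, ".dcd": mdac.DCD.DCDReader}[path.suffix.lower()]
    coords = []
    boxes = []
    with reader_cls(str(path)) as reader:
        for ts in reader:
            coords.append(ts.positions / 10.0)
            if ts.dimensions is not None and ts.dimensions[:3].min() > 0:
                boxes.append(ts.triclinic_dimensions / 10.0)
    coords_arr = np.asarray(coords)
    boxes_arr = np.asarray(boxes) if len(boxes) == len(coords) else None
    return coords_arr, boxes_arr


def load_ensemble(
    topology_file: str | Path,
    trajectory_file: str | Path,
    condition: LigandCondition = LigandCondition(0.0),
    skip_frames: int = 0,
    frame_dt: float | None = None,
) -> Ensemble:
    """Load an ensemble, dropping the first ``skip_frames`` equilibration frames.

    ``skip_frames`` is a count, not a time; callers discarding e.g. the first
    500 ns convert using their output cadence.  ``frame_dt`` (ns) supplies
    frame times for formats that do not carry them.
    """
    topology_file, trajectory_file = Path(topology_file), Path(trajectory_file)
    for p in (topology_file, trajectory_file):
        if not p.exists():
            raise FileNotFoundError(p)
    topology = load_topology(topology_file)
    suffix = trajectory_file.suffix.lower()

    if suffix in (".xtc", ".dcd"):
        coords, boxes = _read_mda_frames(trajectory_file)
        if coords.shape[1] != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {coords.shape[1]} atoms, topology declares {topology.n_atoms}"
            )
        # atom order in XTC/DCD is positional: sorted topology atom ids
        coords = coords[:, _positional_rows(topology), :]
    else:
        if suffix in (".pdb", ".ent"):
            stacked, box, serials = _read_pdb_frames(trajectory_file)
        elif suffix in (".tsv", ".txt", ".dat"):
            stacked, box, serials = _read_tsv_frames(trajectory_file)
        else:
            raise FormatError(f"unrecognised trajectory format: {trajectory_file.name}")
        missing = [a for a in topology.atom_ids if a not in stacked]
        if missing:
            raise TopologyError(
                f"trajectory atoms do not cover topology (missing ids {missing[:5]})"
            )
        if len(serials) != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {len(serials)} atoms, topology declares "
                f"{topology.n_atoms}"
            )
        coords = np.stack([stacked[a] for a in topology.atom_ids], axis=1)
        n = coords.shape[0]
        boxes = None if box is None else np.broadcast_to(box, (n, 3, 3)).copy()

    n = coords.shape[0]
    dt = 1.0 if frame_dt is None else float(frame_dt)
    times = np.arange(n) * dt
    ens = Ensemble(topology=topology, coords=coords, times=times, boxes=boxes,
                   condition=condition)
    if skip_frames:
        if skip_frames >= n:
            raise ValueError(f"skip_frames={skip_frames} >= n_frames={n}")
        mask = np.zeros(n, dtype=bool)
        mask[skip_frames:] = True
        ens = ens.subset(mask)
        ens.times = ens.times - ens.times[0]
    return ens


def _positional_rows(topology: Topology) -> np.ndarray:
    """Map positional (sorted-id) trajectory rows onto the topology atom order."""
    sorted_ids = sorted(topology.atom_ids)
    pos = {aid: i for i, aid in enumerate(sorted_ids)}
    return np.asarray([pos[a] for a in topology.atom_ids], dtype=np.intp)


# --------------------------------------------------------------------------
# Writers (multi-model PDB + JSON topology sidecar)
# --------------------------------------------------------------------------

def write_topology_json(topology: Topology, path: str | Path) -> None:
    doc = {
        "sequence_offset": topology.sequence_offset,
        "residues": [
            {
                "index": r.index,
                "name": r.name,
                "chain": r.chain_id,
                "heavy_atoms": list(r.heavy_atom_ids),
                "calpha": r.calpha_atom_id,
            }
            for r in topology.residues
        ],
        "ligands": [
            {"index": l.index, "heavy_atoms": list(l.heavy_atom_ids)}
            for l in topology.ligands
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_ensemble_pdb(ensemble: Ensemble, path: str | Path) -> None:
    """Write a multi-model PDB (nm -> Angstrom) readable by :func:`load_ensemble`."""
    top = ensemble.topology
    lines: list[str] = []
    if ensemble.boxes is not None:
        a, b, c = (np.linalg.norm(ensemble.boxes[0][k]) * 10.0 for k in range(3))
        lines.append(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1")
    records: list[tuple[int, str, str, str, int]] = []  # serial, name, resname, chain, resseq
    for res in top.residues:
        for k, aid in enumerate(res.heavy_atom_ids):
            name = "CA" if aid == res.calpha_atom_id else f"C{k}"
            records.append((aid, name, res.name[:3], res.chain_id[:1] or "A", res.index))
    for lig in top.ligands:
        for k, aid in enumerate(lig.heavy_atom_ids):
            records.append((aid, f"N{k}", "LIG", "X", lig.index))
    rows = {aid: i for i, aid in enumerate(top.atom_ids)}
    for f in range(ensemble.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for serial, name, resname, chain, resseq in records:
            x, y, z = ensemble.coords[f, rows[serial]] * 10.0
            lines.append(
                f"ATOM  {serial:5d} {name:<4s}{resname:>3s} {chain}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble_tsv(ensemble: Ensemble, path: str | Path) -> None:
    """Plain-text coordinate table: frame, atom_id, x, y, z in nm."""
    top = ensemble.topology
    with open(path, "w") as fh:
        fh.write("frame\tatom_id\tx\ty\tz\n")
        for f in range(ensemble.n_frames):
            for i, aid in enumerate(top.atom_ids):
                x, y, z = ensemble.coords[f, i]
                fh.write(f"{f}\t{aid}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


# --------------------------------------------------------------------------
# Periodic-image QC
# --------------------------------------------------------------------------

_NEIGHBOR_SHIFTS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
     if (i, j, k) != (0, 0, 0)],
    dtype=float,
)


def periodic_image_violation_fraction(
    ensemble: Ensemble, threshold: float = 0.3
) -> tuple[float, np.ndarray]:
    """Fraction of frames with a protein atom within ``threshold`` nm of its own
    periodic image, plus per-frame violation flags.

    The check enumerates all 26 neighbour cells explicitly; frames flagged
    here are meant to be excluded before any downstream analysis.
    """
    if ensemble.boxes is None:
        raise QCUnavailableError("periodic-image QC needs box vectors")
    flags = np.zeros(ensemble.n_frames, dtype=bool)
    prot = ensemble.protein_coords()
    for f in range(ensemble.n_frames):
        box = ensemble.boxes[f]
        pts = prot[f]
        shifts = _NEIGHBOR_SHIFTS @ box
        for s in shifts:
            d = pts[:, None, :] - (pts[None, :, :] + s)
            if np.min(np.linalg.norm(d, axis=-1)) < threshold:
                flags[f] = True
                break
    return float(flags.mean()), flags


def apply_qc_filter(ensemble: Ensemble, threshold: float = 0.3) -> tuple[Ensemble, dict]:
    """Drop frames failing the periodic-image check; return ensemble + report."""
    frac, flags = periodic_image_violation_fraction(ensemble, threshold)
    report = {
        "n_frames": int(ensemble.n_frames),
        "n_violations": int(flags.sum()),
        "fraction": frac,
        "threshold_nm": threshold,
    }
    return ensemble.subset(~flags), report
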