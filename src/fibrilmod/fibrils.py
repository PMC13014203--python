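"""Fibril reference structures: monomer extraction, native contacts,
and polymorph clustering by shared intrachain contacts.

Patient-derived amyloid filaments of the same protein adopt distinct folds
(polymorphs).  To organise them, each deposited structure is reduced to the
set of intrachain residue pairs in close contact within one monomer layer
("fibril-native contacts"), and structures are clustered by contact
sharing: structures sharing at least one contact (by default) are joined,
and clusters are the connected components of that graph.  Structures
sharing no contact with any other remain singletons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from ._geometry import pair_distance_matrix
from .contacts import DEFAULT_CONTACT_CUTOFF, DEFAULT_MIN_SEPARATION
from .errors import EmptyStructureError, FormatError

_HYDROGEN = ("H", "D")


def _is_amino_acid(res) -> bool:
    import gemmi

    return gemmi.find_tabulated_residue(res.name).is_amino_acid()


@dataclass
class FibrilStructure:
    """One monomer of a fibril assembly, heavy atoms only, nm coordinates.

    ``residue_numbers`` are in full-length isoform numbering (after applying
    ``renumber_offset``); atoms of each residue are contiguous in ``coords``.
    """

    structure_id: str
    residue_numbers: np.ndarray          # strictly increasing
    residue_names: list[str]
    coords: np.ndarray                   # (n_atoms, 3) nm
    atom_starts: np.ndarray              # first atom row of each residue
    source_chain: str
    resolved_range: tuple[int, int]

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)


@dataclass
class NativeContactSet:
    """Intrachain contacts of one fibril monomer, full-length numbering."""

    structure_id: str
    contacts: frozenset[tuple[int, int]]
    cutoff: float = DEFAULT_CONTACT_CUTOFF
    min_separation: int = DEFAULT_MIN_SEPARATION
    resolved_range: tuple[int, int] | None = None

    def shared(self, other: "NativeContactSet") -> int:
        return len(self.contacts & other.contacts)

    def jaccard(self, other: "NativeContactSet") -> float:
        union = self.contacts | other.contacts
        if not union:
            return 0.0
        return len(self.contacts & other.contacts) / len(union)


@dataclass
class FibrilClustering:
    clusters: list[list[str]]                       # partition of structure ids
    similarity: dict[tuple[str, str], tuple[int, float]]  # (shared, jaccard)
    edge_rule: str

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, structure_id: str) -> int:
        for k, members in enumerate(self.clusters):
            if structure_id in members:
                return k
        raise KeyError(structure_id)


# --------------------------------------------------------------------------

def load_fibril_structure(
    file: str | Path,
    chain_policy: str = "central",
    renumber_offset: int = 0,
    structure_id: str | None = None,
) -> FibrilStructure:
    """Extract one monomer from a fibril PDB/mmCIF file.

    ``chain_policy`` is ``"central"`` (the chain whose centroid lies nearest
    the assembly centroid — an interior protofilament layer, avoiding
    stack-edge effects), ``"first"``, or an explicit chain id.
    """
    import gemmi

    file = Path(file)
    try:
        st = gemmi.read_structure(str(file))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {file}: {exc}") from exc
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    model = st[0]
    protein_chains = [
        ch for ch in model
        if any(_is_amino_acid(res) for res in ch)
    ]
    if not protein_chains:
        raise EmptyStructureError(f"no protein chain in {file}")

    if chain_policy == "first":
        chain = protein_chains[0]
    elif chain_policy == "central":
        centroids = []
        for ch in protein_chains:
            pos = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for res in ch if _is_amino_acid(res)
                 for a in res]
            )
            centroids.append(pos.mean(axis=0))
        centroids = np.asarray(centroids)
        assembly = centroids.mean(axis=0)
        chain = protein_chains[int(np.argmin(np.linalg.norm(centroids - assembly, axis=1)))]
    else:
        match = [ch for ch in protein_chains if ch.name == chain_policy]
        if not match:
            raise EmptyStructureError(
                f"chain {chain_policy!r} not found in {file} "
                f"(available: {[c.name for c in protein_chains]})"
            )
        chain = match[0]

    numbers: list[int] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    starts: list[int] = []
    for res in chain:
        if not _is_amino_acid(res):
            continue
        heavy = [a for a in res if a.element.name not in _HYDROGEN]
        if not heavy:
            continue  # fully unresolved residue: excluded from the universe
        starts.append(len(coords))
        numbers.append(res.seqid.num + renumber_offset)
        names.append(res.name)
        coords.extend(np.array([a.pos.x, a.pos.y, a.pos.z]) / 10.0 for a in heavy)
    if not numbers:
        raise EmptyStructureError(f"chain {chain.name} of {file} has no heavy atoms")
    numbers_arr = np.asarray(numbers)
    if np.any(np.diff(numbers_arr) <= 0):
        raise FormatError(f"residue numbers not strictly increasing in {file}")
    return FibrilStructure(
        structure_id=structure_id or file.stem,
        residue_numbers=numbers_arr,
        residue_names=names,
        coords=np.asarray(coords),
        atom_starts=np.asarray(starts, dtype=np.intp),
        source_chain=chain.name,
        resolved_range=(int(numbers_arr[0]), int(numbers_arr[-1])),
    )


def extract_native_contacts(
    structure: FibrilStructure,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> NativeContactSet:
    """Residue pairs of the monomer within ``cutoff`` (heavy-atom minimum
    distance), at sequence separation >= ``min_separation`` in full-length
    numbering — the same contact definition used for simulation ensembles."""
    dmat = pair_distance_matrix(structure.coords, structure.coords, box=None)
    res_min = np.minimum.reduceat(
        np.minimum.reduceat(dmat, structure.atom_starts, axis=0),
        structure.atom_starts, axis=1,
    )
    nums = structure.residue_numbers
    contacts = {
        (int(nums[i]), int(nums[j]))
        for i in range(len(nums))
        for j in range(i + 1, len(nums))
        if nums[j] - nums[i] >= min_separation and res_min[i, j] < cutoff
    }
    return NativeContactSet(
        structure_id=structure.structure_id,
        contacts=frozenset(contacts),
        cutoff=cutoff,
        min_separation=min_separation,
        resolved_range=structure.resolved_range,
    )


def cluster_fibrils(
    sets: list[NativeContactSet],
    min_shared: int = 1,
    min_jaccard: float | None = None,
) -> FibrilClustering:
    """Cluster fibril structures by shared intrachain contacts.

    An edge joins two structures when they share at least ``min_shared``
    contacts (or, if ``min_jaccard`` is given, when their contact-set Jaccard
    index reaches it); clusters are the connected components.  With the
    default rule, a structure sharing no contact with any other is a
    singleton cluster.
    """
    if not sets:
        raise ValueError("need at least one contact set")
    g = nx.Graph()
    similarity: dict[tuple[str, str], tuple[int, float]] = {}
    for s in sets:
        g.add_node(s.structure_id)
    any_shared = False
    for a_idx in range(len(sets)):
        for b_idx in range(a_idx + 1, len(sets)):
            a, b = sets[a_idx], sets[b_idx]
            sh, jc = a.shared(b), a.jaccard(b)
            key = tuple(sorted((a.structure_id, b.structure_id)))
            similarity[key] = (sh, jc)
            any_shared = any_shared or sh > 0
            if min_jaccard is not None:
                if jc >= min_jaccard and sh > 0:
                    g.add_edge(a.structure_id, b.structure_id)
            elif sh >= min_shared:
                g.add_edge(a.structure_id, b.structure_id)
    if len(sets) > 1 and not any_shared:
        warnings.warn(
            "no contacts shared between any pair of structures; "
            "all clusters will be singletons (check residue numbering)",
            stacklevel=2,
        )
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    rule = (f"jaccard >= {min_jaccard}" if min_jaccard is not None
            else f"shared contacts >= {min_shared}")
    return FibrilClustering(clusters=comps, similarity=similarity, edge_rule=rule)


def consensus_contacts(sets: list[NativeContactSet], members: list[str],
                       min_fraction: float = 0.5) -> frozenset[tuple[int, int]]:
    """Contacts present in at least ``min_fraction`` of a cluster's members."""
    chosen = [s for s in sets if s.structure_id in members]
    if not chosen:
        return frozenset()
    counts: dict[tuple[int, int], int] = {}
    for s in chosen:
        for c in s.contacts:
            counts[c] = counts.get(c, 0) + 1
    need = min_fraction * len(chosen)
    return frozenset(c for c, n in counts.items() if n >= need)


def write_contacts_tsv(ncs: NativeContactSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# structure_id={ncs.structure_id}\n")
        fh.write(f"# cutoff_nm={ncs.cutoff}\n# min_separation={ncs.min_separation}\n")
        fh.write("i_full\tj_full\n")
        for i, j in sorted(ncs.contacts):
            fh.write(f"{i}\t{j}\n")


def read_contacts_tsv(path, structure_id: str | None = None) -> NativeContactSet:
    cutoff, min_sep, sid = DEFAULT_CONTACT_CUTOFF, DEFAULT_MIN_SEPARATION, None
    contacts = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "cutoff_nm=" in line:
                    cutoff = float(line.split("=", 1)[1])
                elif "min_separation=" in line:
                    min_sep = int(line.split("=", 1)[1])
                elif "structure_id=" in line:
                    sid = line.split("=", 1)[1]
                continue
            if line.startswith("i_full"):
                continue
            i, j = line.split("\t")[:2]
            contacts.add((int(i), int(j)))
    return NativeContactSet(
        structure_id=structure_id or sid or str(path),
        contacts=frozenset(contacts),
        cutoff=cutoff,
        min_separation=min_sep,
    )
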