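"""Topology and multi-replica trajectory data model.

The package represents one simulation condition (receptor bound to its
ligand, or free) as a :class:`TrajectoryEnsemble`: a shared atom topology
plus an ordered list of replicas, each replica an ordered list of frames,
each frame one 3D coordinate per atom.  Coordinates are stored in Ångström
throughout.

Trajectories are read from and written to multi-model PDB files (one file
per replica, MODEL/ENDMDL records delimit frames) via MDAnalysis.  Which
chain belongs to which molecular component (receptor α/β chain, ligand
MHC/peptide) comes from the user's config, never from the code.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigError,
    EmptyInputError,
    EmptyRegionError,
    TopologyError,
)

__all__ = [
    "Component",
    "AtomRecord",
    "Topology",
    "TrajectoryEnsemble",
    "RegionDefinition",
    "RegionSet",
    "load_ensemble",
    "write_ensemble",
    "select_region",
    "strip_component",
    "STANDARD_MASSES",
    "STANDARD_VDW_RADII",
]


class Component(str, enum.Enum):
    """Molecular component a chain belongs to."""

    RECEPTOR_ALPHA = "receptor_alpha"
    RECEPTOR_BETA = "receptor_beta"
    LIGAND_MHC = "ligand_mhc"
    LIGAND_PEPTIDE = "ligand_peptide"

    @property
    def is_receptor(self) -> bool:
        return self in (Component.RECEPTOR_ALPHA, Component.RECEPTOR_BETA)


RECEPTOR_COMPONENTS = frozenset(
    {Component.RECEPTOR_ALPHA, Component.RECEPTOR_BETA}
)

# Standard atomic masses (amu) for the elements that occur in proteins.
STANDARD_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

# van der Waals radii (Å), Bondi values; used for rolling-probe SASA.
STANDARD_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}

# A polar hydrogen is covalently attached to one of these elements.
_POLAR_HEAVY = {"N", "O", "S"}
# Generous covalent-bond cutoff for X–H attachment (Å).
_XH_BOND_CUTOFF = 1.25


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the shared topology.

    ``residue_seq`` uses author (PDB) numbering, 1-based; ``insertion_code``
    is part of residue identity.  ``donor_flag``/``acceptor_flag``/
    ``polar_hydrogen_flag`` drive the geometric hydrogen-bond detector.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_seq: int
    residue_name: str
    chain_id: str
    component: Component
    mass: float
    vdw_radius: float
    donor_flag: bool = False
    acceptor_flag: bool = False
    polar_hydrogen_flag: bool = False
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise TopologyError(f"atom {self.atom_id}: mass must be > 0")
        if not self.vdw_radius > 0:
            raise TopologyError(f"atom {self.atom_id}: vdW radius must be > 0")


class Topology:
    """Ordered atom records with cached numeric arrays."""

    def __init__(self, atoms: Sequence[AtomRecord]):
        atoms = list(atoms)
        if not atoms:
            raise EmptyInputError("topology has no atoms")
        ids = [a.atom_id for a in atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_id values must be unique")
        self._atoms = atoms
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.vdw_radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        self.chain_ids = np.array([a.chain_id for a in atoms])
        self.residue_seqs = np.array([a.residue_seq for a in atoms], dtype=int)
        self.elements = np.array([a.element for a in atoms])
        self.atom_names = np.array([a.atom_name for a in atoms])
        self.components = np.array([a.component.value for a in atoms])
        self.donor_mask = np.array([a.donor_flag for a in atoms], dtype=bool)
        self.acceptor_mask = np.array(
            [a.acceptor_flag for a in atoms], dtype=bool
        )
        self.polar_h_mask = np.array(
            [a.polar_hydrogen_flag for a in atoms], dtype=bool
        )

    def __len__(self) -> int:
        return len(self._atoms)

    def __getitem__(self, i: int) -> AtomRecord:
        return self._atoms[i]

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._atoms)

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self._atoms)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """(chain, residue_seq, insertion_code) per atom, topology order."""
        return [
            (a.chain_id, a.residue_seq, a.insertion_code) for a in self._atoms
        ]

    def subset(self, indices: np.ndarray) -> "Topology":
        return Topology([self._atoms[int(i)] for i in indices])

    def identity_tuples(self) -> list[tuple]:
        """Per-atom identity used to check cross-file consistency."""
        return [
            (a.chain_id, a.residue_seq, a.insertion_code, a.residue_name,
             a.atom_name)
            for a in self._atoms
        ]


@dataclass
class TrajectoryEnsemble:
    """One condition's set of replicas over a shared topology.

    ``coordinates`` holds one ``(n_frames, n_atoms, 3)`` float array per
    replica (Å).  Frame counts may differ between replicas.
    """

    condition_label: str
    topology: Topology
    coordinates: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition_label not in ("bound", "unbound"):
            raise ConfigError(
                f"condition_label must be 'bound' or 'unbound', "
                f"got {self.condition_label!r}"
            )
        if not self.coordinates:
            raise EmptyInputError("ensemble has no replicas")
        n_atoms = len(self.topology)
        clean = []
        for r, xyz in enumerate(self.coordinates):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 3 or xyz.shape[1] != n_atoms or xyz.shape[2] != 3:
                raise TopologyError(
                    f"replica {r}: coordinate array shape {xyz.shape} does "
                    f"not match topology ({n_atoms} atoms)"
                )
            if xyz.shape[0] == 0:
                raise EmptyInputError(f"replica {r} has no frames")
            if not np.all(np.isfinite(xyz)):
                raise TopologyError(f"replica {r}: non-finite coordinates")
            clean.append(xyz)
        self.coordinates = clean

    @property
    def n_replicas(self) -> int:
        return len(self.coordinates)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    @property
    def frames_per_replica(self) -> list[int]:
        return [xyz.shape[0] for xyz in self.coordinates]

    @property
    def total_frames(self) -> int:
        return sum(self.frames_per_replica)

    def iter_frames(self) -> Iterator[np.ndarray]:
        """All frames, replicas in order."""
        for xyz in self.coordinates:
            yield from xyz

    def mean_coordinates(self) -> np.ndarray:
        """Time-average position per atom over all frames and replicas."""
        total = np.zeros((self.n_atoms, 3))
        n = 0
        for xyz in self.coordinates:
            total += xyz.sum(axis=0)
            n += xyz.shape[0]
        return total / n

    def subset_atoms(self, indices: np.ndarray) -> "TrajectoryEnsemble":
        indices = np.asarray(indices, dtype=int)
        if indices.size == 0:
            raise EmptyInputError("atom subset is empty")
        return TrajectoryEnsemble(
            condition_label=self.condition_label,
            topology=self.topology.subset(indices),
            coordinates=[xyz[:, indices, :] for xyz in self.coordinates],
        )

    def subset_frames(self, frame_slice: slice) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            condition_label=self.condition_label,
            topology=self.topology,
            coordinates=[xyz[frame_slice] for xyz in self.coordinates],
        )


@dataclass(frozen=True)
class RegionDefinition:
    """Named residue range on one chain, inclusive, author numbering."""

    name: str
    chain_id: str
    start_residue: int
    end_residue: int

    def __post_init__(self) -> None:
        if self.start_residue > self.end_residue:
            raise ConfigError(
                f"region {self.name}: start_residue > end_residue"
            )


class RegionSet(dict):
    """Mapping region name -> RegionDefinition with unique names."""

    def __init__(self, regions: Iterable[RegionDefinition] = ()):
        super().__init__()
        for r in regions:
            self.add(r)

    def add(self, region: RegionDefinition) -> None:
        if region.name in self:
            raise ConfigError(f"duplicate region name {region.name!r}")
        self[region.name] = region

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Mapping]) -> "RegionSet":
        """Build from a config dict: name -> {chain, start, end}."""
        rs = cls()
        for name, spec in mapping.items():
            rs.add(
                RegionDefinition(
                    name=name,
                    chain_id=str(spec["chain"]),
                    start_residue=int(spec["start"]),
                    end_residue=int(spec["end"]),
                )
            )
        return rs


def select_region(
    topology: Topology, region: RegionDefinition
) -> np.ndarray:
    """Atom indices of a region, in topology order.

    Raises :class:`EmptyRegionError` when nothing matches — this almost
    always means the region config and the loaded structure disagree.
    """
    mask = (topology.chain_ids == region.chain_id) & (
        (topology.residue_seqs >= region.start_residue)
        & (topology.residue_seqs <= region.end_residue)
    )
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptyRegionError(
            f"region {region.name!r} (chain {region.chain_id}, residues "
            f"{region.start_residue}-{region.end_residue}) selects no atoms"
        )
    return idx


def strip_component(
    ensemble: TrajectoryEnsemble, keep: Iterable[Component | str]
) -> TrajectoryEnsemble:
    """Restrict an ensemble to the given components (e.g. receptor only).

    Used for the "as if no ligand were present" SASA mode: the same frames
    of the bound ensemble, with the ligand atoms removed.
    """
    keep_vals = {Component(c).value for c in keep}
    if not keep_vals:
        raise EmptyInputError("keep set is empty")
    mask = np.isin(ensemble.topology.components, list(keep_vals))
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise EmptyInputError(
            f"stripping to components {sorted(keep_vals)} removes all atoms"
        )
    return ensemble.subset_atoms(idx)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (MDAnalysis backend)
# ---------------------------------------------------------------------------


def _guess_element(name: str, given: str | None) -> str:
    if given:
        el = given.strip().upper()
        if el:
            return el
    name = name.strip()
    # PDB convention: leading digits belong to hydrogens (e.g. 1HB2)
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot infer element for atom name {name!r}")
    if stripped[0] == "H":
        return "H"
    for two in ("SE",):
        if stripped[:2].upper() == two:
            return two
    return stripped[0].upper()


def _annotate_hbond_flags(
    elements: np.ndarray,
    first_frame: np.ndarray,
    residue_keys: list[tuple],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign donor/acceptor/polar-H flags from elements and geometry.

    Acceptors: N/O (and S).  Polar hydrogens: H within covalent range of an
    N/O/S heavy atom *of the same residue* in the first frame.  Donors:
    heavy atoms carrying at least one polar hydrogen.
    """
    n = len(elements)
    acceptor = np.isin(elements, ("N", "O", "S"))
    polar_h = np.zeros(n, dtype=bool)
    donor = np.zeros(n, dtype=bool)
    h_idx = np.nonzero(elements == "H")[0]
    heavy_idx = np.nonzero(np.isin(elements, tuple(_POLAR_HEAVY)))[0]
    if h_idx.size and heavy_idx.size:
        d = np.linalg.norm(
            first_frame[h_idx, None, :] - first_frame[None, heavy_idx, :],
            axis=-1,
        )
        same_res = np.array(
            [
                [residue_keys[h] == residue_keys[x] for x in heavy_idx]
                for h in h_idx
            ]
        )
        attached = (d <= _XH_BOND_CUTOFF) & same_res
        polar_h[h_idx] = attached.any(axis=1)
        donor_cols = attached.any(axis=0)
        donor[heavy_idx[donor_cols]] = True
    return donor, acceptor, polar_h


def _dedupe_altlocs(u) -> np.ndarray:
    """Indices keeping the highest-occupancy conformer per atom identity."""
    atoms = u.atoms
    try:
        altlocs = atoms.altLocs
    except Exception:
        return np.arange(len(atoms))
    try:
        occ = atoms.occupancies
    except Exception:
        occ = np.ones(len(atoms))
    best: dict[tuple, int] = {}
    chains = _chain_ids(u)
    icodes = _icodes(u)
    for i in range(len(atoms)):
        if not altlocs[i].strip():
            key = (chains[i], atoms.resids[i], icodes[i], atoms.names[i])
            best[key] = i
            continue
        key = (chains[i], atoms.resids[i], icodes[i], atoms.names[i])
        if key not in best or occ[i] > occ[best[key]]:
            best[key] = i
    return np.array(sorted(best.values()), dtype=int)


def _chain_ids(u) -> np.ndarray:
    try:
        c = u.atoms.chainIDs
        if any(str(x).strip() for x in c):
            return np.array([str(x).strip() for x in c])
    except Exception:
        pass
    return np.array([str(s).strip() for s in u.atoms.segids])


def _icodes(u) -> np.ndarray:
    try:
        return np.array([str(x).strip() for x in u.atoms.icodes])
    except Exception:
        return np.array([""] * len(u.atoms))


def load_ensemble(
    paths: Sequence[str | Path],
    condition_label: str,
    chain_components: Mapping[str, Component | str],
    masses: Mapping[str, float] | None = None,
    vdw_radii: Mapping[str, float] | None = None,
) -> TrajectoryEnsemble:
    """Read one replica per multi-model PDB file into an ensemble.

    All files must share the atom ordering (same topology); frames are the
    MODEL records in file order.  ``chain_components`` maps chain IDs to
    components; every chain present must be mapped.
    """
    import MDAnalysis as mda

    if not paths:
        raise EmptyInputError("no trajectory files given")
    masses = dict(STANDARD_MASSES, **(masses or {}))
    vdw_radii = dict(STANDARD_VDW_RADII, **(vdw_radii or {}))

    topology: Topology | None = None
    identity_ref: list[tuple] | None = None
    coords: list[np.ndarray] = []
    for path in paths:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                u = mda.Universe(str(path))
            except IndexError as exc:
                raise EmptyInputError(
                    f"{path}: file contains no atoms/models"
                ) from exc
            except (ValueError, EOFError) as exc:
                raise TopologyError(
                    f"{path}: inconsistent or malformed MODEL records ({exc})"
                ) from exc
        keep = _dedupe_altlocs(u)
        sel = u.atoms[keep]
        chains = _chain_ids(u)[keep]
        icodes = _icodes(u)[keep]
        try:
            given_elements = [str(e) for e in sel.elements]
        except Exception:
            given_elements = [None] * len(sel)
        elements = np.array(
            [
                _guess_element(n, e)
                for n, e in zip(sel.names, given_elements)
            ]
        )
        try:
            frames = []
            for _ in u.trajectory:
                frames.append(sel.positions.astype(float).copy())
        except (ValueError, EOFError) as exc:
            raise TopologyError(
                f"{path}: a MODEL record has a different atom count ({exc})"
            ) from exc
        if not frames:
            raise EmptyInputError(f"{path}: file contains no MODEL frames")
        xyz = np.stack(frames)

        if topology is None:
            res_keys = [
                (chains[i], int(sel.resids[i]), icodes[i])
                for i in range(len(sel))
            ]
            donor, acceptor, polar_h = _annotate_hbond_flags(
                elements, xyz[0], res_keys
            )
            records = []
            for i in range(len(sel)):
                chain = chains[i]
                if chain not in chain_components:
                    raise ConfigError(
                        f"{path}: chain {chain!r} has no component mapping"
                    )
                el = elements[i]
                records.append(
                    AtomRecord(
                        atom_id=i,
                        atom_name=str(sel.names[i]),
                        element=el,
                        residue_seq=int(sel.resids[i]),
                        residue_name=str(sel.resnames[i]),
                        chain_id=chain,
                        component=Component(chain_components[chain]),
                        mass=masses.get(el, 12.011),
                        vdw_radius=vdw_radii.get(el, 1.70),
                        donor_flag=bool(donor[i]),
                        acceptor_flag=bool(acceptor[i]),
                        polar_hydrogen_flag=bool(polar_h[i]),
                        insertion_code=str(icodes[i]),
                    )
                )
            topology = Topology(records)
            identity_ref = topology.identity_tuples()
        else:
            identity = [
                (chains[i], int(sel.resids[i]), icodes[i],
                 str(sel.resnames[i]), str(sel.names[i]))
                for i in range(len(sel))
            ]
            if identity != identity_ref:
                raise TopologyError(
                    f"{path}: atom records do not match the first file"
                )
        coords.append(xyz)

    assert topology is not None
    return TrajectoryEnsemble(
        condition_label=condition_label,
        topology=topology,
        coordinates=coords,
    )


def write_ensemble(
    ensemble: TrajectoryEnsemble, directory: str | Path, prefix: str = "rep"
) -> list[Path]:
    """Write one multi-model PDB per replica; returns the file paths."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    top = ensemble.topology
    n = len(top)

    resindex = np.zeros(n, dtype=int)
    seen: dict[tuple, int] = {}
    for i, key in enumerate(top.residue_keys()):
        if key not in seen:
            seen[key] = len(seen)
        resindex[i] = seen[key]
    n_res = len(seen)
    res_first_atom = np.zeros(n_res, dtype=int)
    for i in range(n - 1, -1, -1):
        res_first_atom[resindex[i]] = i

    chain_per_res = [top.chain_ids[res_first_atom[r]] for r in range(n_res)]
    seg_labels = sorted(set(chain_per_res))
    segindex = np.array([seg_labels.index(c) for c in chain_per_res])

    paths = []
    for r, xyz in enumerate(ensemble.coordinates):
        u = mda.Universe.empty(
            n,
            n_residues=n_res,
            n_segments=len(seg_labels),
            atom_resindex=resindex,
            residue_segindex=segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", list(top.atom_names))
        u.add_TopologyAttr("elements", list(top.elements))
        u.add_TopologyAttr(
            "resnames",
            [top[res_first_atom[i]].residue_name for i in range(n_res)],
        )
        u.add_TopologyAttr(
            "resids",
            [int(top.residue_seqs[res_first_atom[i]]) for i in range(n_res)],
        )
        u.add_TopologyAttr(
            "icodes",
            [top[res_first_atom[i]].insertion_code for i in range(n_res)],
        )
        u.add_TopologyAttr("chainIDs", list(top.chain_ids))
        u.add_TopologyAttr("segids", seg_labels)
        u.load_new(xyz.astype(np.float32), format=MemoryReader)
        path = directory / f"{prefix}{r:03d}.pdb"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), multiframe=True) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        paths.append(path)
    return paths
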