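"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators cover the two levels of the pipeline:

* :func:`generate_descriptor_series` draws descriptor values directly — a
  hierarchical model with replica-level means (between-replica spread),
  AR(1)-correlated frames within each replica (MD frames are
  time-correlated), and an optional condition shift Δ added to the bound
  condition's replica means.  This is the distribution-level stand-in used
  to study the statistics themselves.

* :func:`generate_toy_ensemble` builds a geometric two-chain "receptor"
  with backbone-only residues (N, H, Cα, C, O), central interface loops
  that bulge toward the partner chain, an optional rigid ligand block
  contacting the loops in the bound condition, per-region Gaussian jitter
  and centroid shifts, and a designated inter-chain hydrogen bond whose
  per-frame presence is Bernoulli with a per-condition probability.  Every
  descriptor and the full pipeline run on it unchanged.

Defaults mirror the study design the package targets: 10 replicas per
condition, interface loops less mobile and shifted by ~0.9 Å in the bound
condition, and a lower inter-chain H-bond occupancy when bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .descriptors import DescriptorSeries
from .ensemble import (
    AtomRecord,
    Component,
    RegionDefinition,
    RegionSet,
    STANDARD_MASSES,
    STANDARD_VDW_RADII,
    Topology,
    TrajectoryEnsemble,
    write_ensemble,
)

__all__ = [
    "SeriesSpec",
    "ToyEnsembleSpec",
    "generate_descriptor_series",
    "generate_toy_ensemble",
    "write_synthetic_system",
]


@dataclass(frozen=True)
class SeriesSpec:
    """Hierarchical model of one descriptor under two conditions.

    Replica means are Normal(grand_mean [+ condition_shift for bound],
    between_replica_sd²); frames follow an AR(1) process around the replica
    mean with stationary sd ``within_replica_sd`` and lag-one correlation
    ``ar1_coefficient``.
    """

    n_replicas: int = 10
    n_frames: int = 1000
    grand_mean: float = 0.0
    within_replica_sd: float = 1.0
    between_replica_sd: float = 0.5
    ar1_coefficient: float = 0.8
    condition_shift: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicas < 1 or self.n_frames < 1:
            raise ValueError("n_replicas and n_frames must be ≥ 1")
        if self.within_replica_sd < 0 or self.between_replica_sd < 0:
            raise ValueError("standard deviations must be ≥ 0")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")


def _ar1_replica(
    rng: np.random.Generator, mu: float, sd: float, phi: float, n: int
) -> np.ndarray:
    z = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = mu + sd * z[0]
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + innov_sd * z[t]
    return x


def generate_descriptor_series(
    spec: SeriesSpec,
    descriptor_name: str = "synthetic",
    units: str = "Å",
) -> tuple[DescriptorSeries, DescriptorSeries]:
    """Draw (bound, unbound) series from the hierarchical model.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out = {}
    for condition in ("bound", "unbound"):
        shift = spec.condition_shift if condition == "bound" else 0.0
        values = []
        for _ in range(spec.n_replicas):
            mu = (
                spec.grand_mean
                + shift
                + spec.between_replica_sd * rng.standard_normal()
            )
            values.append(
                _ar1_replica(
                    rng, mu, spec.within_replica_sd,
                    spec.ar1_coefficient, spec.n_frames,
                )
            )
        out[condition] = DescriptorSeries(
            descriptor_name=descriptor_name,
            region_names=("synthetic",),
            condition_label=condition,
            values=values,
            units=units,
        )
    return out["bound"], out["unbound"]


# ---------------------------------------------------------------------------
# Geometry-level toy ensemble
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyEnsembleSpec:
    """Two-chain backbone-only receptor with switchable interface contacts.

    ``loop_jitter`` / ``stem_jitter`` are per-coordinate Gaussian amplitudes
    (Å).  ``loop_shift`` translates the chain-A interface loop toward the
    partner chain in the bound condition (Å; 0.9 by default, a typical
    significant interface displacement).  ``hbond_p_*`` set the per-frame
    probability that the designated inter-chain H-bond satisfies the
    geometric criteria.
    """

    residues_per_chain: int = 16
    n_replicas: int = 10
    n_frames: int = 50
    loop_jitter_bound: float = 0.5
    loop_jitter_unbound: float = 1.0
    stem_jitter: float = 0.3
    loop_shift: float = 0.9
    between_replica_sd: float = 0.15
    ligand_attached: bool = True
    hbond_p_bound: float = 0.3
    hbond_p_unbound: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.residues_per_chain < 12:
            raise ValueError("need ≥12 residues per chain")
        if self.n_replicas < 1 or self.n_frames < 1:
            raise ValueError("n_replicas and n_frames must be ≥ 1")
        for a in (
            self.loop_jitter_bound,
            self.loop_jitter_unbound,
            self.stem_jitter,
            self.between_replica_sd,
        ):
            if a < 0:
                raise ValueError("jitter amplitudes must be ≥ 0")
        for p in (self.hbond_p_bound, self.hbond_p_unbound):
            if not 0.0 <= p <= 1.0:
                raise ValueError("H-bond probabilities must be in [0, 1]")


_BACKBONE = (
    # name, element, local offset from the residue anchor (Å)
    ("N", "N", (-1.2, 0.0, 0.4)),
    ("H", "H", (-1.2, 1.0, 0.4)),  # amide H points at the partner chain
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.2, 0.0, 0.4)),
    ("O", "O", (1.2, -0.6, 1.4)),
)
_CA_SPACING = 3.5  # Å between consecutive residue anchors
_CHAIN_GAP = 10.0  # Å between the two chain axes
_LOOP_BULGE = 2.5  # Å loops protrude toward the partner chain
_HBOND_ON_DISTANCE = 2.9  # Å donor–acceptor when the contact is formed
_HBOND_OFF_DISTANCE = 5.0  # Å when broken


def _loop_bounds(n_res: int) -> tuple[int, int]:
    """1-based inclusive residue range of the central interface loop."""
    mid = n_res // 2
    return mid - 2, mid + 2


def _build_reference(
    spec: ToyEnsembleSpec, with_ligand: bool
) -> tuple[Topology, np.ndarray, dict]:
    """Reference coordinates, topology and bookkeeping indices."""
    n_res = spec.residues_per_chain
    lo, hi = _loop_bounds(n_res)
    records: list[AtomRecord] = []
    coords: list[tuple[float, float, float]] = []
    region_atoms: dict[str, list[int]] = {}
    meta: dict = {}

    def add_atom(name, element, xyz, resseq, resname, chain, component):
        i = len(records)
        records.append(
            AtomRecord(
                atom_id=i,
                atom_name=name,
                element=element,
                residue_seq=resseq,
                residue_name=resname,
                chain_id=chain,
                component=component,
                mass=STANDARD_MASSES[element],
                vdw_radius=STANDARD_VDW_RADII[element],
                donor_flag=(name == "N"),
                acceptor_flag=(element in ("N", "O")),
                polar_hydrogen_flag=(element == "H"),
            )
        )
        coords.append(tuple(xyz))
        return i

    for chain, component, y_axis, toward in (
        ("A", Component.RECEPTOR_ALPHA, 0.0, +1.0),
        ("B", Component.RECEPTOR_BETA, _CHAIN_GAP, -1.0),
    ):
        for res in range(1, n_res + 1):
            in_loop = lo <= res <= hi
            y = y_axis + (toward * _LOOP_BULGE if in_loop else 0.0)
            anchor = np.array([(res - 1) * _CA_SPACING, y, 0.0])
            for name, element, off in _BACKBONE:
                off = np.array(off)
                # amide H of chain B must point back toward chain A
                if name == "H":
                    off = off * np.array([1.0, toward, 1.0])
                idx = add_atom(
                    name, element, anchor + off, res, "GLY", chain, component
                )
                region_atoms.setdefault(f"atoms_{chain}", []).append(idx)
                if in_loop:
                    region_atoms.setdefault(f"loop_{chain}", []).append(idx)
                if name == "N" and res == (lo + hi) // 2 and chain == "A":
                    meta["hb_donor"] = idx
                if name == "H" and res == (lo + hi) // 2 and chain == "A":
                    meta["hb_hydrogen"] = idx
                if name == "O" and res == (lo + hi) // 2 and chain == "B":
                    meta["hb_acceptor"] = idx

    if with_ligand:
        # rigid slab of carbons under the interface loops
        xs = np.arange(lo - 2, hi + 3) * _CA_SPACING
        ys = np.array([_CHAIN_GAP / 2 - 2.0, _CHAIN_GAP / 2 + 2.0])
        res = 1
        for x in xs:
            for y in ys:
                add_atom(
                    "C1", "C", (x, y, -4.0), res, "LIG", "M",
                    Component.LIGAND_MHC,
                )
                res += 1

    meta["loop_lo"], meta["loop_hi"] = lo, hi
    topology = Topology(records)
    return topology, np.array(coords, dtype=float), meta


def _toy_regions(spec: ToyEnsembleSpec) -> RegionSet:
    n_res = spec.residues_per_chain
    lo, hi = _loop_bounds(n_res)
    return RegionSet(
        [
            RegionDefinition("loopA", "A", lo, hi),
            RegionDefinition("loopB", "B", lo, hi),
            RegionDefinition("stemA", "A", 1, lo - 1),
            RegionDefinition("stemB", "B", 1, lo - 1),
            RegionDefinition("tailA", "A", hi + 1, n_res),
            RegionDefinition("tailB", "B", hi + 1, n_res),
        ]
    )


def generate_toy_ensemble(
    spec: ToyEnsembleSpec,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble, RegionSet]:
    """Build (bound, unbound, regions).

    The bound receptor carries the ligand block (when ``ligand_attached``),
    lower loop jitter, the loop centroid shift, and its own H-bond
    occupancy probability.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    regions = _toy_regions(spec)
    ensembles = {}
    for condition in ("bound", "unbound"):
        with_ligand = spec.ligand_attached and condition == "bound"
        topology, ref, meta = _build_reference(spec, with_ligand)
        n_atoms = len(topology)
        loop_jitter = (
            spec.loop_jitter_bound
            if condition == "bound"
            else spec.loop_jitter_unbound
        )
        # rigid per-residue jitter keeps covalent geometry (N–H bonds)
        # intact across frames; loops move more than stems, the ligand is
        # nearly rigid
        res_keys = topology.residue_keys()
        uniq: dict[tuple, int] = {}
        for k in res_keys:
            uniq.setdefault(k, len(uniq))
        res_index = np.array([uniq[k] for k in res_keys])
        n_res = len(uniq)
        amp = np.full(n_atoms, spec.stem_jitter)
        loop_idx = np.array(
            sorted(
                set(meta_idx for key in ("loop_A", "loop_B")
                    for meta_idx in _region_indices(topology, key, meta))
            )
        )
        amp[loop_idx] = loop_jitter
        amp[topology.components == Component.LIGAND_MHC.value] = 0.05
        res_amp = np.zeros(n_res)
        res_amp[res_index] = amp  # uniform within a residue
        acceptor = meta["hb_acceptor"]

        base = ref.copy()
        if condition == "bound" and spec.loop_shift != 0.0:
            # chain-A loop moves toward chain B
            a_loop = _region_indices(topology, "loop_A", meta)
            base[a_loop, 1] += spec.loop_shift

        p_on = (
            spec.hbond_p_bound
            if condition == "bound"
            else spec.hbond_p_unbound
        )
        donor_pos = base[meta["hb_donor"]]
        h_dir = base[meta["hb_hydrogen"]] - donor_pos
        h_dir = h_dir / np.linalg.norm(h_dir)

        replicas = []
        for _ in range(spec.n_replicas):
            # replica-level offset per region keeps replicas exchangeable
            # but distinct, which the resampling tests rely on
            rep_base = base.copy()
            for key in ("loop_A", "loop_B"):
                idx = _region_indices(topology, key, meta)
                rep_base[idx] += spec.between_replica_sd * rng.standard_normal(3)
            frames = np.repeat(rep_base[None, :, :], spec.n_frames, axis=0)
            res_noise = (
                rng.standard_normal((spec.n_frames, n_res, 3))
                * res_amp[None, :, None]
            )
            frames = frames + res_noise[:, res_index, :]
            on = rng.random(spec.n_frames) < p_on
            dist = np.where(on, _HBOND_ON_DISTANCE, _HBOND_OFF_DISTANCE)
            frames[:, meta["hb_donor"], :] = donor_pos
            frames[:, meta["hb_hydrogen"], :] = donor_pos + h_dir
            frames[:, acceptor, :] = donor_pos + h_dir * dist[:, None]
            replicas.append(frames)
        ensembles[condition] = TrajectoryEnsemble(
            condition_label=condition,
            topology=topology,
            coordinates=replicas,
        )
    return ensembles["bound"], ensembles["unbound"], regions


def _region_indices(topology: Topology, key: str, meta: dict) -> np.ndarray:
    chain = key.split("_")[1]
    lo, hi = meta["loop_lo"], meta["loop_hi"]
    mask = (topology.chain_ids == chain) & (
        (topology.residue_seqs >= lo) & (topology.residue_seqs <= hi)
    ) & (topology.components != Component.LIGAND_MHC.value)
    return np.nonzero(mask)[0]


def write_synthetic_system(
    bound: TrajectoryEnsemble,
    unbound: TrajectoryEnsemble,
    regions: RegionSet,
    directory: str | Path,
) -> dict:
    """Write PDB replicas plus a pipeline-ready YAML config; returns the
    config dict."""
    import yaml

    directory = Path(directory)
    bound_paths = write_ensemble(bound, directory / "bound", prefix="bound")
    unbound_paths = write_ensemble(
        unbound, directory / "unbound", prefix="unbound"
    )
    chain_components = {}
    for ens in (bound, unbound):
        for a in ens.topology:
            chain_components[a.chain_id] = a.component.value
    config = {
        "bound": [str(p) for p in bound_paths],
        "unbound": [str(p) for p in unbound_paths],
        "chain_components": chain_components,
        "regions": {
            name: {
                "chain": r.chain_id,
                "start": r.start_residue,
                "end": r.end_residue,
            }
            for name, r in regions.items()
        },
    }
    with open(directory / "system.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return config
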