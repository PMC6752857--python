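"""Per-region trajectory descriptors.

Five descriptors summarise each ensemble: inter-region centroid distance
(DIST, Å), mass-weighted radius of gyration (RG, Å), solvent accessible
surface area (SASA, Å², rolling-probe), per-residue root mean square
fluctuation (RMSF, Å, after least-squares superposition), and geometric
hydrogen-bond counts between two selections.  Each produces a
:class:`DescriptorSeries`: per-replica, per-frame scalar values for one
condition, which the comparison layer consumes.

Conventions follow common MD practice: centroids and RG are mass-weighted,
H-bonds use a 3.5 Å donor–acceptor distance and 30° hydrogen–donor–acceptor
angle cutoff, SASA uses a 1.4 Å probe.  All cutoffs are overridable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import (
    Component,
    RECEPTOR_COMPONENTS,
    RegionDefinition,
    Topology,
    TrajectoryEnsemble,
    select_region,
)
from .errors import (
    AnnotationError,
    EmptyInputError,
    EmptyRegionError,
    FitError,
    InsufficientDataError,
)

__all__ = [
    "DescriptorSeries",
    "HBondFrequencyTable",
    "region_distance",
    "radius_of_gyration",
    "rmsf",
    "rmsf_series",
    "sasa",
    "hbond_count",
    "hbond_frequency_table",
    "HBOND_DISTANCE_CUTOFF",
    "HBOND_ANGLE_CUTOFF",
    "SASA_PROBE_RADIUS",
    "SASA_POINT_NUMBER",
]

HBOND_DISTANCE_CUTOFF = 3.5  # Å, donor–acceptor
HBOND_ANGLE_CUTOFF = 30.0  # degrees, hydrogen–donor–acceptor
SASA_PROBE_RADIUS = 1.4  # Å
SASA_POINT_NUMBER = 960  # sphere sample points per atom


@dataclass
class DescriptorSeries:
    """Per-replica, per-frame scalar values of one descriptor."""

    descriptor_name: str
    region_names: tuple[str, ...]
    condition_label: str
    values: list[np.ndarray]
    units: str

    def __post_init__(self) -> None:
        if not self.values:
            raise EmptyInputError(
                f"{self.descriptor_name}: series has no replicas"
            )
        clean = []
        for r, v in enumerate(self.values):
            v = np.asarray(v, dtype=float).ravel()
            if v.size == 0:
                raise EmptyInputError(
                    f"{self.descriptor_name}: replica {r} has no frames"
                )
            if not np.all(np.isfinite(v)):
                raise ValueError(
                    f"{self.descriptor_name}: replica {r} has non-finite "
                    f"values"
                )
            clean.append(v)
        self.values = clean

    @property
    def n_replicas(self) -> int:
        return len(self.values)

    @property
    def total_frames(self) -> int:
        return sum(v.size for v in self.values)

    def pooled(self) -> np.ndarray:
        """All values over all frames and replicas, replicas in order."""
        return np.concatenate(self.values)

    def replica_means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.values])

    def replica_frame_counts(self) -> np.ndarray:
        return np.array([v.size for v in self.values])

    def to_records(self):
        """Tidy rows: (condition, replica, frame, descriptor, region, value,
        units)."""
        region = "+".join(self.region_names)
        for r, v in enumerate(self.values):
            for f, x in enumerate(v):
                yield (
                    self.condition_label,
                    r,
                    f,
                    self.descriptor_name,
                    region,
                    float(x),
                    self.units,
                )


@dataclass
class HBondFrequencyTable:
    """Occupancy fraction per donor–acceptor pair, pooled over all frames
    and replicas of one condition.  Pairs never observed are absent."""

    frequencies: dict[tuple[int, int], float]
    total_frames: int
    topology: Topology = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for pair, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"pair {pair}: occupancy {f} outside [0,1]")


def _weighted_centroid(
    coords: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Mass-weighted centroid per frame; coords (F, A, 3), masses (A,)."""
    return np.einsum("fad,a->fd", coords, masses) / masses.sum()


def region_distance(
    ensemble: TrajectoryEnsemble,
    region_a: RegionDefinition,
    region_b: RegionDefinition,
) -> DescriptorSeries:
    """Per-frame distance between the mass-weighted centroids of two
    regions (Å)."""
    idx_a = select_region(ensemble.topology, region_a)
    idx_b = select_region(ensemble.topology, region_b)
    m_a = ensemble.topology.masses[idx_a]
    m_b = ensemble.topology.masses[idx_b]
    values = []
    for xyz in ensemble.coordinates:
        ca = _weighted_centroid(xyz[:, idx_a, :], m_a)
        cb = _weighted_centroid(xyz[:, idx_b, :], m_b)
        values.append(np.linalg.norm(ca - cb, axis=1))
    return DescriptorSeries(
        descriptor_name=f"DIST {region_a.name}-{region_b.name}",
        region_names=(region_a.name, region_b.name),
        condition_label=ensemble.condition_label,
        values=values,
        units="Å",
    )


def radius_of_gyration(
    ensemble: TrajectoryEnsemble, region: RegionDefinition
) -> DescriptorSeries:
    """Per-frame mass-weighted radius of gyration of a region (Å):
    sqrt(Σ mᵢ|rᵢ−r̄|² / Σ mᵢ) with r̄ the mass-weighted centroid."""
    idx = select_region(ensemble.topology, region)
    m = ensemble.topology.masses[idx]
    values = []
    for xyz in ensemble.coordinates:
        sub = xyz[:, idx, :]
        com = _weighted_centroid(sub, m)
        d2 = ((sub - com[:, None, :]) ** 2).sum(axis=2)
        values.append(np.sqrt((d2 * m).sum(axis=1) / m.sum()))
    return DescriptorSeries(
        descriptor_name=f"RG {region.name}",
        region_names=(region.name,),
        condition_label=ensemble.condition_label,
        values=values,
        units="Å",
    )


def _kabsch_transform(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray
):
    """Optimal rotation+translation of ``mobile`` onto ``reference``.

    Returns (rotation_matrix, mobile_centroid, reference_centroid) so that
    aligned = (x - mobile_centroid) @ R.T + reference_centroid.
    """
    w = weights / weights.sum()
    cm = (mobile * w[:, None]).sum(axis=0)
    cr = (reference * w[:, None]).sum(axis=0)
    a = mobile - cm
    b = reference - cr
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            rot, _ = Rotation.align_vectors(b, a, weights=weights)
        except (UserWarning, ValueError) as exc:
            raise FitError(f"superposition failed: {exc}") from exc
    return rot.as_matrix(), cm, cr


def _superpose_replica(
    xyz: np.ndarray, fit_idx: np.ndarray, masses: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto the replica's first frame using the fit
    atoms (mass-weighted least squares)."""
    ref = xyz[0, fit_idx, :]
    w = masses[fit_idx]
    out = np.empty_like(xyz)
    out[0] = xyz[0]
    for f in range(1, xyz.shape[0]):
        rmat, cm, cr = _kabsch_transform(xyz[f, fit_idx, :], ref, w)
        out[f] = (xyz[f] - cm) @ rmat.T + cr
    return out


def _check_fit_region(xyz0: np.ndarray, fit_idx: np.ndarray) -> None:
    if fit_idx.size < 3:
        raise FitError("fit region needs at least 3 atoms")
    pts = xyz0[fit_idx]
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise FitError("fit region atoms are collinear")


def rmsf(
    ensemble: TrajectoryEnsemble,
    fit_region: RegionDefinition | Sequence[RegionDefinition],
    target_region: RegionDefinition | None = None,
    representative_atom: str = "CA",
) -> tuple[dict[tuple[str, int, str], float], float]:
    """Per-residue RMSF (Å) and the mean over the target region.

    Every frame of a replica is superposed onto that replica's first frame
    using the fit-region atoms; the RMSF of a residue is the root of the
    time-averaged squared deviation of its representative atom (Cα by
    default) from its time-average position.  The returned values are means
    over replicas.
    """
    top = ensemble.topology
    regions = (
        [fit_region]
        if isinstance(fit_region, RegionDefinition)
        else list(fit_region)
    )
    fit_idx = np.unique(
        np.concatenate([select_region(top, r) for r in regions])
    )
    if min(ensemble.frames_per_replica) < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames per replica")
    _check_fit_region(ensemble.coordinates[0][0], fit_idx)

    if target_region is None:
        target_idx = np.arange(len(top))
    else:
        target_idx = select_region(top, target_region)
    rep_mask = top.atom_names[target_idx] == representative_atom
    rep_idx = target_idx[rep_mask]
    if rep_idx.size == 0:
        raise EmptyRegionError(
            f"no {representative_atom!r} atoms in target region"
        )
    keys = [top.residue_keys()[int(i)] for i in rep_idx]

    per_replica = []
    for xyz in ensemble.coordinates:
        aligned = _superpose_replica(xyz, fit_idx, top.masses)
        sub = aligned[:, rep_idx, :]
        mean_pos = sub.mean(axis=0)
        msd = ((sub - mean_pos) ** 2).sum(axis=2).mean(axis=0)
        per_replica.append(np.sqrt(msd))
    mean_rmsf = np.mean(per_replica, axis=0)
    mapping = {k: float(v) for k, v in zip(keys, mean_rmsf)}
    return mapping, float(mean_rmsf.mean())


def rmsf_series(
    ensemble: TrajectoryEnsemble,
    fit_region: RegionDefinition | Sequence[RegionDefinition],
    target_region: RegionDefinition,
    representative_atom: str = "CA",
) -> DescriptorSeries:
    """Region-mean RMSF as a one-value-per-replica series.

    RMSF is a per-replica summary (it already averages over time), so for
    condition comparison each replica contributes a single value: the mean
    RMSF over the target region's residues in that replica.
    """
    top = ensemble.topology
    regions = (
        [fit_region]
        if isinstance(fit_region, RegionDefinition)
        else list(fit_region)
    )
    fit_idx = np.unique(
        np.concatenate([select_region(top, r) for r in regions])
    )
    if min(ensemble.frames_per_replica) < 2:
        raise InsufficientDataError("RMSF needs at least 2 frames per replica")
    _check_fit_region(ensemble.coordinates[0][0], fit_idx)
    target_idx = select_region(top, target_region)
    rep_mask = top.atom_names[target_idx] == representative_atom
    rep_idx = target_idx[rep_mask]
    if rep_idx.size == 0:
        raise EmptyRegionError(
            f"no {representative_atom!r} atoms in target region"
        )
    values = []
    for xyz in ensemble.coordinates:
        aligned = _superpose_replica(xyz, fit_idx, top.masses)
        sub = aligned[:, rep_idx, :]
        msd = ((sub - sub.mean(axis=0)) ** 2).sum(axis=2).mean(axis=0)
        values.append(np.array([float(np.sqrt(msd).mean())]))
    return DescriptorSeries(
        descriptor_name=f"RMSF {target_region.name}",
        region_names=(target_region.name,),
        condition_label=ensemble.condition_label,
        values=values,
        units="Å",
    )


def sasa(
    ensemble: TrajectoryEnsemble,
    region: RegionDefinition,
    context: Sequence[Component | str] | None = None,
    probe_radius: float = SASA_PROBE_RADIUS,
    point_number: int = SASA_POINT_NUMBER,
) -> DescriptorSeries:
    """Per-frame summed SASA (Å²) of a region's atoms.

    Occlusion is computed over all atoms whose component is in ``context``
    (default: every component present).  Passing the receptor components
    only, on a bound ensemble, yields the "ligand removed" mode: the same
    frames scored as if the ligand were absent.
    """
    import biotite.structure as struc

    top = ensemble.topology
    region_idx = select_region(top, region)
    region_components = set(top.components[region_idx])
    if not region_components <= {c.value for c in RECEPTOR_COMPONENTS}:
        raise EmptyRegionError(
            f"SASA region {region.name!r} must lie within the receptor"
        )
    if context is None:
        context_vals = set(top.components)
    else:
        context_vals = {Component(c).value for c in context}
    if not region_components <= context_vals:
        raise EmptyInputError(
            "SASA context must contain the region's components"
        )
    ctx_idx = np.nonzero(np.isin(top.components, list(context_vals)))[0]
    if ctx_idx.size == 0:
        raise EmptyInputError("SASA context selects no atoms")

    # region positions within the context subset
    pos_in_ctx = {int(a): j for j, a in enumerate(ctx_idx)}
    region_in_ctx = np.array([pos_in_ctx[int(i)] for i in region_idx])

    arr = struc.AtomArray(ctx_idx.size)
    arr.chain_id = top.chain_ids[ctx_idx]
    arr.res_id = top.residue_seqs[ctx_idx]
    arr.res_name = np.array([top[int(i)].residue_name for i in ctx_idx])
    arr.atom_name = top.atom_names[ctx_idx]
    arr.element = top.elements[ctx_idx]
    radii = top.vdw_radii[ctx_idx]
    atom_filter = np.zeros(ctx_idx.size, dtype=bool)
    atom_filter[region_in_ctx] = True

    values = []
    for xyz in ensemble.coordinates:
        frame_vals = np.empty(xyz.shape[0])
        for f in range(xyz.shape[0]):
            arr.coord = xyz[f, ctx_idx, :].astype(np.float32)
            per_atom = struc.sasa(
                arr,
                probe_radius=probe_radius,
                atom_filter=atom_filter,
                ignore_ions=False,
                point_number=point_number,
                vdw_radii=radii,
            )
            frame_vals[f] = np.nansum(per_atom[region_in_ctx])
        values.append(frame_vals)
    suffix = "" if context is None else " ctx=" + "+".join(
        sorted(context_vals)
    )
    return DescriptorSeries(
        descriptor_name=f"SASA {region.name}{suffix}",
        region_names=(region.name,),
        condition_label=ensemble.condition_label,
        values=values,
        units="Å²",
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


def _donor_hydrogen_map(
    top: Topology, first_frame: np.ndarray
) -> dict[int, np.ndarray]:
    """Map donor atom index -> indices of its attached polar hydrogens,
    from covalent distances in the reference frame (same residue only)."""
    donors = np.nonzero(top.donor_mask)[0]
    hydrogens = np.nonzero(top.polar_h_mask)[0]
    out: dict[int, np.ndarray] = {}
    if donors.size == 0 or hydrogens.size == 0:
        return out
    d = np.linalg.norm(
        first_frame[donors, None, :] - first_frame[None, hydrogens, :],
        axis=-1,
    )
    keys = top.residue_keys()
    same_res = np.array(
        [[keys[don] == keys[h] for h in hydrogens] for don in donors]
    )
    attached = (d <= 1.25) & same_res
    for row, don in enumerate(donors):
        hs = hydrogens[attached[row]]
        if hs.size:
            out[int(don)] = hs
    return out


def _frame_hbond_pairs(
    frame: np.ndarray,
    donors: np.ndarray,
    acceptors: np.ndarray,
    dh_map: dict[int, np.ndarray],
    distance_cutoff: float,
    angle_cutoff: float,
) -> list[tuple[int, int]]:
    """Donor–acceptor pairs H-bonded in one frame."""
    if donors.size == 0 or acceptors.size == 0:
        return []
    dv = frame[acceptors][None, :, :] - frame[donors][:, None, :]
    dist = np.linalg.norm(dv, axis=-1)
    cand = np.argwhere(dist <= distance_cutoff)
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    pairs = []
    for i, j in cand:
        don = int(donors[i])
        acc = int(acceptors[j])
        if don == acc:
            continue
        hs = dh_map.get(don)
        if hs is None:
            continue
        d_pos = frame[don]
        a_vec = frame[acc] - d_pos
        a_norm = np.linalg.norm(a_vec)
        if a_norm == 0:
            continue
        h_vec = frame[hs] - d_pos
        h_norm = np.linalg.norm(h_vec, axis=1)
        ok = h_norm > 0
        if not ok.any():
            continue
        cosang = (h_vec[ok] @ a_vec) / (h_norm[ok] * a_norm)
        if np.any(cosang >= cos_cut):
            pairs.append((don, acc))
    return pairs


def _hbond_prepare(
    ensemble: TrajectoryEnsemble,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
):
    top = ensemble.topology
    sel_a = np.asarray(selection_a, dtype=int)
    sel_b = np.asarray(selection_b, dtype=int)
    if np.intersect1d(sel_a, sel_b).size:
        raise ValueError("H-bond selections must be disjoint")
    if sel_a.size == 0 or sel_b.size == 0:
        return None
    union = np.concatenate([sel_a, sel_b])
    if not (
        top.donor_mask[union].any()
        or top.acceptor_mask[union].any()
        or top.polar_h_mask[union].any()
    ):
        raise AnnotationError(
            "selections carry no donor/acceptor/polar-hydrogen annotations"
        )
    dh_map = _donor_hydrogen_map(top, ensemble.coordinates[0][0])
    d_a = sel_a[top.donor_mask[sel_a]]
    a_a = sel_a[top.acceptor_mask[sel_a]]
    d_b = sel_b[top.donor_mask[sel_b]]
    a_b = sel_b[top.acceptor_mask[sel_b]]
    return (d_a, a_b), (d_b, a_a), dh_map


def hbond_count(
    ensemble: TrajectoryEnsemble,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
    name: str = "n of H-bonds",
) -> DescriptorSeries:
    """Per-frame count of hydrogen bonds between two disjoint selections.

    A bond requires donor–acceptor distance ≤ ``distance_cutoff`` and a
    hydrogen–donor–acceptor angle ≤ ``angle_cutoff`` for some hydrogen
    attached to the donor; both directions (donor in A or in B) count.
    """
    prep = _hbond_prepare(ensemble, selection_a, selection_b)
    if prep is None:
        values = [np.zeros(f) for f in ensemble.frames_per_replica]
    else:
        (d_a, a_b), (d_b, a_a), dh_map = prep
        values = []
        for xyz in ensemble.coordinates:
            counts = np.zeros(xyz.shape[0])
            for f in range(xyz.shape[0]):
                n = len(
                    _frame_hbond_pairs(
                        xyz[f], d_a, a_b, dh_map, distance_cutoff,
                        angle_cutoff,
                    )
                ) + len(
                    _frame_hbond_pairs(
                        xyz[f], d_b, a_a, dh_map, distance_cutoff,
                        angle_cutoff,
                    )
                )
                counts[f] = n
            values.append(counts)
    return DescriptorSeries(
        descriptor_name=name,
        region_names=("selectionA", "selectionB"),
        condition_label=ensemble.condition_label,
        values=values,
        units="count",
    )


def hbond_frequency_table(
    ensemble: TrajectoryEnsemble,
    selection_a: np.ndarray,
    selection_b: np.ndarray,
    distance_cutoff: float = HBOND_DISTANCE_CUTOFF,
    angle_cutoff: float = HBOND_ANGLE_CUTOFF,
) -> HBondFrequencyTable:
    """Occupancy fraction per donor–acceptor pair, pooled over all frames
    and replicas.  Pairs that never form are absent from the table."""
    prep = _hbond_prepare(ensemble, selection_a, selection_b)
    total = ensemble.total_frames
    counts: dict[tuple[int, int], int] = {}
    if prep is not None:
        (d_a, a_b), (d_b, a_a), dh_map = prep
        for xyz in ensemble.coordinates:
            for f in range(xyz.shape[0]):
                for pair in _frame_hbond_pairs(
                    xyz[f], d_a, a_b, dh_map, distance_cutoff, angle_cutoff
                ):
                    counts[pair] = counts.get(pair, 0) + 1
                for pair in _frame_hbond_pairs(
                    xyz[f], d_b, a_a, dh_map, distance_cutoff, angle_cutoff
                ):
                    counts[pair] = counts.get(pair, 0) + 1
    return HBondFrequencyTable(
        frequencies={p: c / total for p, c in counts.items()},
        total_frames=total,
        topology=ensemble.topology,
    )


def write_series_tsv(
    series: Sequence[DescriptorSeries], path
) -> None:
    """Write descriptor series as tidy TSV rows."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            ["condition", "replica", "frame", "descriptor", "region",
             "value", "units"]
        )
        for s in series:
            for row in s.to_records():
                w.writerow(row)
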