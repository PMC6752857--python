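"""Hydrogen-bond network difference maps between two conditions.

Each donor–acceptor pair observed in either condition becomes an
:class:`HBondRecord` carrying its occupancy in both conditions and the
difference ``delta = freq_bound − freq_unbound``.  Records passing a
minimum |delta| (6% by default — smaller occupancy changes are within
replica-to-replica chance, as the replica-variance bootstrap shows) can be
exported as 3D cylinders: endpoints at the time-averaged donor and acceptor
positions, radius proportional to |delta|, coloured red where the bond is
more occupied in the bound condition and blue where it is more occupied in
the free condition.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .descriptors import HBondFrequencyTable
from .ensemble import TrajectoryEnsemble
from .errors import TopologyError

__all__ = [
    "HBondRecord",
    "bond_difference_map",
    "filter_threshold",
    "export_cylinders",
    "DEFAULT_DELTA_THRESHOLD",
]

DEFAULT_DELTA_THRESHOLD = 0.06


@dataclass(frozen=True)
class HBondRecord:
    """One donor–acceptor pair with per-condition occupancy."""

    donor_id: int
    acceptor_id: int
    freq_bound: float
    freq_unbound: float
    chain_pair: tuple[str, str] = ("", "")

    @property
    def delta(self) -> float:
        return self.freq_bound - self.freq_unbound

    @property
    def is_interchain(self) -> bool:
        return self.chain_pair[0] != self.chain_pair[1]


def bond_difference_map(
    table_bound: HBondFrequencyTable,
    table_unbound: HBondFrequencyTable,
) -> list[HBondRecord]:
    """Per-pair occupancy differences over the union of both tables.

    A pair absent from one condition contributes frequency 0 there.  Both
    tables must come from the same topology (atom ids must mean the same
    atoms).
    """
    top_b = table_bound.topology
    top_u = table_unbound.topology
    if top_b is not None and top_u is not None:
        ids = sorted(
            {p for pair in table_bound.frequencies for p in pair}
            | {p for pair in table_unbound.frequencies for p in pair}
        )
        for i in ids:
            if i >= len(top_b) or i >= len(top_u):
                raise TopologyError(f"atom id {i} outside a table's topology")
            a, b = top_b[i], top_u[i]
            if (a.chain_id, a.residue_seq, a.atom_name) != (
                b.chain_id, b.residue_seq, b.atom_name,
            ):
                raise TopologyError(
                    f"atom id {i} differs between the two tables' topologies"
                )
    keys = set(table_bound.frequencies) | set(table_unbound.frequencies)
    records = []
    for don, acc in sorted(keys):
        fb = table_bound.frequencies.get((don, acc), 0.0)
        fu = table_unbound.frequencies.get((don, acc), 0.0)
        top = top_b if top_b is not None else top_u
        pair = (
            (top[don].chain_id, top[acc].chain_id)
            if top is not None
            else ("", "")
        )
        records.append(
            HBondRecord(
                donor_id=don,
                acceptor_id=acc,
                freq_bound=fb,
                freq_unbound=fu,
                chain_pair=pair,
            )
        )
    return records


def filter_threshold(
    records: Sequence[HBondRecord],
    threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> list[HBondRecord]:
    """Records with |delta| strictly above the threshold, largest first."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [r for r in records if abs(r.delta) > threshold]
    return sorted(kept, key=lambda r: abs(r.delta), reverse=True)


def export_cylinders(
    records: Sequence[HBondRecord],
    reference_ensemble: TrajectoryEnsemble,
    path: str | Path,
    radius_scale: float = 1.0,
    viewer_script: str | Path | None = None,
) -> Path:
    """Write a viewer-agnostic cylinder TSV for the difference map.

    Endpoints are the time-averaged donor/acceptor positions over the
    reference ensemble (the bound condition by convention); the radius is
    ``radius_scale * |delta|``.  ``sign_color`` is red for delta > 0 (more
    occupied when bound) and blue for delta < 0.  Optionally also writes a
    PyMOL script drawing the cylinders as CGO objects.
    """
    path = Path(path)
    n_atoms = reference_ensemble.n_atoms
    for r in records:
        if r.donor_id >= n_atoms or r.acceptor_id >= n_atoms:
            raise TopologyError(
                f"record ({r.donor_id},{r.acceptor_id}) references atoms "
                f"missing from the reference ensemble"
            )
    mean_xyz = reference_ensemble.mean_coordinates()
    rows = []
    for r in records:
        p1 = mean_xyz[r.donor_id]
        p2 = mean_xyz[r.acceptor_id]
        rows.append(
            [
                r.donor_id,
                r.acceptor_id,
                *(f"{v:.4f}" for v in p1),
                *(f"{v:.4f}" for v in p2),
                f"{radius_scale * abs(r.delta):.4f}",
                "red" if r.delta > 0 else "blue",
                f"{r.delta:.4f}",
                f"{r.chain_pair[0]}-{r.chain_pair[1]}",
                "inter" if r.is_interchain else "intra",
            ]
        )
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(
            [
                "donor_id", "acceptor_id",
                "x1", "y1", "z1", "x2", "y2", "z2",
                "radius", "sign_color", "delta", "chain_pair", "bond_kind",
            ]
        )
        w.writerows(rows)
    if viewer_script is not None:
        _write_pymol_script(rows, Path(viewer_script))
    return path


def _write_pymol_script(rows, path: Path) -> None:
    lines = ["from pymol.cgo import CYLINDER", "obj = []"]
    for row in rows:
        x1, y1, z1, x2, y2, z2 = row[2:8]
        radius = row[8]
        rgb = "1.0, 0.2, 0.2" if row[9] == "red" else "0.2, 0.2, 1.0"
        lines.append(
            f"obj += [CYLINDER, {x1}, {y1}, {z1}, {x2}, {y2}, {z2}, "
            f"{radius}, {rgb}, {rgb}]"
        )
    lines.append('cmd.load_cgo(obj, "hbond_difference")')
    path.write_text("\n".join(lines) + "\n")
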