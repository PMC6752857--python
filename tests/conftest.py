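import numpy as np
import pytest

from ensdiff.ensemble import (
    AtomRecord,
    Component,
    Topology,
    TrajectoryEnsemble,
)


def make_atom(
    i,
    name="CA",
    element="C",
    resseq=1,
    chain="A",
    component=Component.RECEPTOR_ALPHA,
    mass=12.011,
    vdw=1.70,
    donor=False,
    acceptor=False,
    polar_h=False,
    resname="GLY",
):
    return AtomRecord(
        atom_id=i,
        atom_name=name,
        element=element,
        residue_seq=resseq,
        residue_name=resname,
        chain_id=chain,
        component=component,
        mass=mass,
        vdw_radius=vdw,
        donor_flag=donor,
        acceptor_flag=acceptor,
        polar_hydrogen_flag=polar_h,
    )


def make_ensemble(topology, replicas, condition="bound"):
    """replicas: list of (n_frames, n_atoms, 3) arrays or lists of frames."""
    coords = [np.asarray(r, dtype=float) for r in replicas]
    return TrajectoryEnsemble(
        condition_label=condition, topology=topology, coordinates=coords
    )


def grid_topology(n_residues, atoms_per_residue=4, chain="A",
                  component=Component.RECEPTOR_ALPHA):
    """Simple topology: ``atoms_per_residue`` carbons per residue."""
    atoms = []
    i = 0
    for res in range(1, n_residues + 1):
        for a in range(atoms_per_residue):
            atoms.append(
                make_atom(i, name=f"C{a}", resseq=res, chain=chain,
                          component=component)
            )
            i += 1
    return Topology(atoms)


def grid_coords(topology, spacing=4.0):
    """One frame with atoms spread on a line, well separated."""
    n = len(topology)
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * spacing
    return xyz


@pytest.fixture(scope="session")
def toy_system():
    """Small bound/unbound toy system shared by slower tests."""
    from ensdiff.synthetic import ToyEnsembleSpec, generate_toy_ensemble

    spec = ToyEnsembleSpec(seed=11, n_replicas=4, n_frames=15)
    bound, unbound, regions = generate_toy_ensemble(spec)
    return bound, unbound, regions
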