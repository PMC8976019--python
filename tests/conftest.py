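import numpy as np
import pandas as pd
import pytest

from kvcoupling import (
    SegmentDefinition,
    SyntheticTrajectoryConfig,
    TrajectoryEnsemble,
    generate_reference_geometry,
)


def make_atoms(n, chain="A", atom_name="CA", start_res=1):
    """Minimal atom table: one Cα per residue on one chain."""
    return pd.DataFrame(
        {
            "chain_id": [chain] * n,
            "residue_number": np.arange(start_res, start_res + n),
            "residue_name": ["ALA"] * n,
            "atom_name": [atom_name] * n,
            "element": ["C"] * n,
            "hetero": [False] * n,
        }
    )


def make_trajectory(coords, dt=0.25, **kwargs):
    """Ensemble from raw (n_frames, n_atoms, 3) coordinates."""
    coords = np.asarray(coords, dtype=float)
    atoms = make_atoms(coords.shape[1])
    timestamps = np.arange(1, coords.shape[0] + 1) * dt
    return TrajectoryEnsemble(atoms=atoms, coords=coords, timestamps=timestamps, **kwargs)


@pytest.fixture(scope="session")
def ref_geometry():
    """Four-subunit toy channel, 20 residues per chain (80 Cα atoms)."""
    return generate_reference_geometry(n_subunits=4, residues_per_subunit=20)


@pytest.fixture(scope="session")
def seg_pair():
    """Two disjoint 7-residue segments on different chains of the toy geometry."""
    return (
        SegmentDefinition("segA", "B", 1, 7),
        SegmentDefinition("segB", "A", 1, 7),
    )


def block_config(seg_a, seg_b, rho, n_frames=2000, seed=0, **kwargs):
    from kvcoupling import CorrelationBlock

    return SyntheticTrajectoryConfig(
        n_frames=n_frames,
        seed=seed,
        correlation_blocks=[CorrelationBlock(seg_a, seg_b, rho)],
        **kwargs,
    )
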