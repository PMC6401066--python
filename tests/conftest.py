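import numpy as np
import pandas as pd
import pytest

from sas6flex import DimerModelParams, Trajectory
from sas6flex.synthetic import TitrationDesign


@pytest.fixture
def wt_params() -> DimerModelParams:
    """Wild-type-like NN dimerisation ground truth (K_d 100 μM)."""
    return DimerModelParams(kd=100.0, p_base=80.0, dp_max=60.0)


@pytest.fixture
def standard_design() -> TitrationDesign:
    """Three replicates, 12 log-spaced concentrations 1-1000 μM, σ = 2 mP."""
    return TitrationDesign.log_spaced(seed=1)


def random_toy_trajectory(
    n_frames: int = 20,
    n_residues_per_chain: int = 15,
    atoms_per_residue: int = 3,
    box: float = 12.0,
    seed: int = 0,
) -> Trajectory:
    """Random two-chain trajectory for brute-force contact oracles."""
    rng = np.random.default_rng(seed)
    rows = []
    for chain in "AB":
        for resid in range(1, n_residues_per_chain + 1):
            for a in range(atoms_per_residue):
                rows.append((chain, resid, "ALA", f"X{a}", "H" if a == atoms_per_residue - 1 else "C"))
    atoms = pd.DataFrame(rows, columns=["chain", "resid", "resname", "name", "element"])
    coords = rng.uniform(0.0, box, size=(n_frames, len(atoms), 3))
    return Trajectory(coords=coords, atoms=atoms)
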