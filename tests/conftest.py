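"""Shared fixtures: substrates, printed reference masses, peak lists."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from acecleave import SpectrumParams, get_substrate
from acecleave.traj import Trajectory

# Calculated [M+H]+ values of the four substrates and seven products,
# keyed by (sequence, n_mod, c_mod). These are the printed calculated
# masses the package must reproduce from first principles.
CALCULATED_MH = {
    ("DAEFRHDSGYEVHHQK", "free", "free"): 1954.87906,
    ("DAEFRHDSGYEVHHQK", "free", "amide"): 1953.89505,
    ("DAEFRHDSGYEVHHQK", "acetyl", "amide"): 1995.90561,
    ("DAEFGHDSGFEVRHQK", "acetyl", "amide"): 1899.87325,
    ("DAEFRHDSGYEVHH", "free", "free"): 1698.72552,
    ("DAEFRHDSGYEVH", "free", "free"): 1561.66661,
    ("HDSGYEVHHQK", "free", "amide"): 1335.61887,
    ("DAEFR", "acetyl", "free"): 679.30458,
    ("DAEFGHDSGFEVRHQ", "acetyl", "free"): 1772.76230,
    ("DAEFGHDSGFEVRH", "acetyl", "free"): 1644.70372,
    ("DAEFGHDSGFEVR", "acetyl", "free"): 1507.64481,
}

# Mean observed m/z per substrate/enzyme (parent peak first), as printed.
OBSERVED_PEAKS = {
    ("Abeta1-16", "N-ACE"): [1954.8, 1698.6],
    ("Abeta1-16", "C-ACE"): [1954.8, 1561.5, 1698.6],
    ("Abeta1-16-amide", "N-ACE"): [1953.9, 1335.6],
    ("Abeta1-16-amide", "C-ACE"): [1953.9],
    ("Ac-Abeta1-16-amide", "N-ACE"): [1995.8, 1335.6, 679.3],
    ("Ac-Abeta1-16-amide", "C-ACE"): [1995.8],
    ("Ac-ratAbeta1-16-amide", "N-ACE"): [1899.9, 1507.5],
    ("Ac-ratAbeta1-16-amide", "C-ACE"): [1899.9, 1507.5, 1644.9, 1772.9],
}

# Ground truth per substrate/enzyme: observed product intervals, cleaved
# bonds (parent coordinates), and the enzyme's mode of action.
EXPECTED_MAPS = {
    ("Abeta1-16", "N-ACE"): (
        {(1, 14)}, {14}, "dipeptidyl_carboxypeptidase"),
    ("Abeta1-16", "C-ACE"): (
        {(1, 13), (1, 14)}, {13, 14}, "processive_carboxypeptidase"),
    ("Abeta1-16-amide", "N-ACE"): ({(6, 16)}, {5}, "endopeptidase"),
    ("Abeta1-16-amide", "C-ACE"): (set(), set(), "none"),
    ("Ac-Abeta1-16-amide", "N-ACE"): (
        {(1, 5), (6, 16)}, {5}, "endopeptidase"),
    ("Ac-Abeta1-16-amide", "C-ACE"): (set(), set(), "none"),
    ("Ac-ratAbeta1-16-amide", "N-ACE"): ({(1, 13)}, {13}, "endopeptidase"),
    ("Ac-ratAbeta1-16-amide", "C-ACE"): (
        {(1, 13), (1, 14), (1, 15)}, {13, 14, 15},
        "processive_carboxypeptidase"),
}

SUBSTRATE_NAMES = list(OBSERVED_PEAKS)


@pytest.fixture
def noiseless_params() -> SpectrumParams:
    return SpectrumParams(noise_cv=0.0, calibration_offset=0.0, seed=7)


@pytest.fixture
def acetyl_amide_substrate():
    return get_substrate("Ac-Abeta1-16-amide")


def peak_list_spectrum(mzs):
    """Spectrum object from a bare list of printed m/z values."""
    from acecleave import Spectrum

    mz = np.sort(np.asarray(mzs, dtype=float))
    return Spectrum(mz, np.ones_like(mz))


def make_test_trajectory(n_frames: int = 1, n_atoms: int = 12, seed: int = 0):
    """A labeled single- or multi-frame trajectory of random coordinates."""
    rng = np.random.default_rng(seed)
    atoms = pd.DataFrame(
        {
            "name": [f"X{i}" for i in range(n_atoms)],
            "resname": ["GLY"] * n_atoms,
            "resid": list(range(1, n_atoms + 1)),
            "chain": ["A"] * n_atoms,
        }
    )
    coords = rng.normal(0.0, 3.0, size=(n_frames, n_atoms, 3))
    return Trajectory(atoms, coords)


def write_multimodel_pdb(path, traj: Trajectory) -> None:
    """Minimal multi-model PDB writer for reader round-trip tests."""
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, row in traj.atoms.iterrows():
                x, y, z = traj.coords[f, i]
                name = str(row["name"])[:4]
                fh.write(
                    f"ATOM  {i + 1:5d} {name:<4s}{str(row['resname'])[:3]:>3s} "
                    f"{str(row['chain'])[:1]}{int(row['resid']):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")
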