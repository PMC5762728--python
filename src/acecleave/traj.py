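"""Trajectory statistics for Michaelis-complex stability analyses.

Implements the analyses used to rationalize protease specificity from
molecular-dynamics trajectories of enzyme-peptide complexes: RMSD of a
selection versus the initial structure (Kabsch superposition), hydrogen
bond contact populations under a geometric criterion, backbone phi/psi
dihedral series with circular statistics, and a tetrahedral-zinc
coordination check. Also provides a synthetic-trajectory generator so
every statistic can be validated by construction, since production MD
trajectories are large and rarely deposited.

Coordinates are Angstrom internally; frames share one atom table.
Atom selection uses a "chain:resid:atom" mini-language where each field
may be ``*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "HBondSpec",
    "ContactPopulation",
    "select_atoms",
    "superpose_kabsch",
    "rmsd_series",
    "hbond_populations",
    "dihedral_series",
    "circular_mean_deg",
    "circular_variance_deg",
    "zinc_geometry_check",
    "synth_trajectory",
    "read_pdb_trajectory",
    "read_xyz_trajectory",
]

TETRAHEDRAL_ANGLE = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.471... deg


@dataclass
class Trajectory:
    """Multi-frame coordinates over a fixed, labeled atom list.

    atoms: DataFrame with columns name, resname, resid, chain.
    coords: array (n_frames, n_atoms, 3), Angstrom.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    timestep_ps: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("frame atom count does not match atom table")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for col in ("name", "resname", "resid", "chain"):
            if col not in self.atoms.columns:
                raise ValueError(f"atom table missing column {col!r}")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def concat(self, other: "Trajectory") -> "Trajectory":
        if not self.atoms[["name", "resid", "chain"]].equals(
            other.atoms[["name", "resid", "chain"]]
        ):
            raise ValueError("cannot concatenate trajectories over different atoms")
        return Trajectory(
            self.atoms, np.concatenate([self.coords, other.coords]), self.timestep_ps
        )


class SelectorError(ValueError):
    """A selection expression resolved to no atom (or the wrong count)."""


def select_atoms(traj: Trajectory, expr: str) -> np.ndarray:
    """Indices matching a ``chain:resid:atom`` expression (``*`` wildcards).

    ``all`` selects every atom. Examples: ``P:6:N`` (backbone N of
    residue 6 in chain P), ``P:*:*`` (all atoms of chain P).
    """
    if expr == "all":
        return np.arange(traj.n_atoms)
    parts = expr.split(":")
    if len(parts) != 3:
        raise SelectorError(f"selector {expr!r} is not chain:resid:atom")
    chain, resid, name = (p.strip() for p in parts)
    mask = np.ones(traj.n_atoms, dtype=bool)
    if chain != "*":
        mask &= (traj.atoms["chain"].astype(str) == chain).to_numpy()
    if resid != "*":
        mask &= (traj.atoms["resid"].astype(int) == int(resid)).to_numpy()
    if name != "*":
        mask &= (traj.atoms["name"].astype(str) == name).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise SelectorError(f"selector {expr!r} matches no atom")
    return idx


def _select_one(traj: Trajectory, expr: str) -> int:
    idx = select_atoms(traj, expr)
    if idx.size != 1:
        raise SelectorError(f"selector {expr!r} must match exactly one atom")
    return int(idx[0])


@dataclass(frozen=True)
class HBondSpec:
    """Geometric hydrogen-bond criterion between three named atoms.

    A frame satisfies the contact iff the donor-acceptor distance is
    <= distance_cutoff AND the hydrogen-donor-acceptor angle is
    <= angle_cutoff. Boundary values count as satisfied.
    """

    donor: str
    hydrogen: str
    acceptor: str
    distance_cutoff: float = 3.5  # Angstrom
    angle_cutoff: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @property
    def label(self) -> str:
        return f"{self.donor}...{self.acceptor}"


@dataclass(frozen=True)
class ContactPopulation:
    spec: HBondSpec
    population: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.population <= 1.0:
            raise ValueError("population must be in [0, 1]")


def superpose_kabsch(
    ref_frame: np.ndarray,
    mobile_frame: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition (proper rotation) of mobile onto ref.

    Returns (rotation, translation, rmsd) where
    ``mobile @ rotation.T + translation`` best fits ref over the
    selection in the least-squares sense.
    """
    ref = np.asarray(ref_frame, dtype=float)
    mob = np.asarray(mobile_frame, dtype=float)
    if selection is not None:
        ref, mob = ref[selection], mob[selection]
    if ref.shape != mob.shape or ref.shape[0] < 3:
        raise ValueError("need >= 3 atoms present in both frames")
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    correction = np.diag([1.0, 1.0, d])
    rotation = vt.T @ correction @ u.T
    translation = ref.mean(axis=0) - rotation @ mob.mean(axis=0)
    fitted = mob_c @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref_c) ** 2, axis=1))))
    return rotation, translation, rmsd


def rmsd_series(traj: Trajectory, selection: str | np.ndarray = "all") -> np.ndarray:
    """Per-frame RMSD vs frame 0 after superposition on the selection."""
    if traj.n_frames == 0:
        return np.array([])
    idx = select_atoms(traj, selection) if isinstance(selection, str) else selection
    ref = traj.coords[0]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = superpose_kabsch(ref, traj.coords[f], idx)
    return out


def _hbond_satisfied(frame: np.ndarray, d: int, h: int, a: int, spec: HBondSpec) -> bool:
    da = frame[a] - frame[d]
    dist = float(np.linalg.norm(da))
    if dist > spec.distance_cutoff:
        return False
    dh = frame[h] - frame[d]
    denom = np.linalg.norm(dh) * dist
    if denom == 0:
        return False
    cosang = float(np.clip(dh @ da / denom, -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return angle <= spec.angle_cutoff


def hbond_populations(
    traj: Trajectory, specs: list[HBondSpec]
) -> list[ContactPopulation]:
    """Fraction of frames satisfying each hydrogen-bond criterion."""
    out = []
    for spec in specs:
        d = _select_one(traj, spec.donor)
        h = _select_one(traj, spec.hydrogen)
        a = _select_one(traj, spec.acceptor)
        hits = sum(
            _hbond_satisfied(traj.coords[f], d, h, a, spec)
            for f in range(traj.n_frames)
        )
        out.append(ContactPopulation(spec, hits / traj.n_frames))
    return out


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180] (IUPAC sign)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    x = v @ w
    y = np.cross(b1n, v) @ w
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang == -180.0 else ang


def dihedral_series(
    traj: Trajectory,
    resid: int,
    angle: str,
    chain: str = "*",
) -> np.ndarray:
    """Backbone phi or psi of one residue, per frame, in degrees.

    phi(i): C(i-1)-N(i)-CA(i)-C(i); psi(i): N(i)-CA(i)-C(i)-N(i+1).
    """
    if angle not in ("phi", "psi"):
        raise ValueError("angle must be 'phi' or 'psi'")
    if angle == "phi":
        sel = [
            f"{chain}:{resid - 1}:C",
            f"{chain}:{resid}:N",
            f"{chain}:{resid}:CA",
            f"{chain}:{resid}:C",
        ]
    else:
        sel = [
            f"{chain}:{resid}:N",
            f"{chain}:{resid}:CA",
            f"{chain}:{resid}:C",
            f"{chain}:{resid + 1}:N",
        ]
    idx = [_select_one(traj, s) for s in sel]
    return np.array(
        [
            dihedral(*[traj.coords[f, i] for i in idx])
            for f in range(traj.n_frames)
        ]
    )


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))))


def circular_variance_deg(angles_deg: np.ndarray) -> float:
    rad = np.radians(np.asarray(angles_deg, dtype=float))
    r = float(np.hypot(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    return 1.0 - r


def zinc_geometry_check(
    traj: Trajectory,
    zinc: str,
    ligands: list[str],
    dist_range: tuple[float, float] = (1.8, 2.6),
    angle_tol: float = 15.0,
) -> pd.DataFrame:
    """Per-frame tetrahedral-coordination diagnostics for a zinc site.

    A frame "retains" tetrahedral coordination iff all four Zn-ligand
    distances lie in ``dist_range`` and the mean absolute deviation of
    the six ligand-Zn-ligand angles from 109.47 deg is <= angle_tol.
    """
    if len(ligands) != 4:
        raise ValueError(f"need exactly 4 ligand selectors, got {len(ligands)}")
    zi = _select_one(traj, zinc)
    li = [_select_one(traj, s) for s in ligands]
    records = []
    for f in range(traj.n_frames):
        frame = traj.coords[f]
        vecs = [frame[i] - frame[zi] for i in li]
        dists = [float(np.linalg.norm(v)) for v in vecs]
        angles = []
        for a in range(4):
            for b in range(a + 1, 4):
                cosang = np.clip(
                    vecs[a] @ vecs[b] / (dists[a] * dists[b]), -1.0, 1.0
                )
                angles.append(float(np.degrees(np.arccos(cosang))))
        dev = float(np.mean([abs(x - TETRAHEDRAL_ANGLE) for x in angles]))
        retained = (
            all(dist_range[0] <= d <= dist_range[1] for d in dists)
            and dev <= angle_tol
        )
        records.append(
            {
                "frame": f,
                **{f"d{k + 1}": dists[k] for k in range(4)},
                "angle_deviation": dev,
                "retained": retained,
            }
        )
    return pd.DataFrame.from_records(records).set_index("frame")


def synth_trajectory(
    template: Trajectory,
    schedules: dict[HBondSpec, np.ndarray] | None = None,
    jitter_sigma: float = 0.0,
    n_frames: int | None = None,
    seed: int = 0,
    on_distance: float = 2.9,
    off_distance: float = 5.5,
) -> Trajectory:
    """Build a trajectory with prescribed per-frame contact states.

    Frames are copies of the template's first frame with isotropic
    Gaussian jitter; for each contact spec whose schedule is True
    (False) in a frame, the acceptor atom is placed on the donor-
    hydrogen axis at ``on_distance`` (``off_distance``) from the donor,
    overriding the jitter on that atom, so the geometric criterion is
    satisfied (violated) by construction. Deterministic per seed.
    """
    schedules = schedules or {}
    lengths = {len(s) for s in schedules.values()}
    if n_frames is None:
        if len(lengths) != 1:
            raise ValueError("n_frames required when schedules are absent/unequal")
        n_frames = lengths.pop()
    elif lengths and lengths != {n_frames}:
        raise ValueError("schedule lengths must equal n_frames")
    rng = np.random.default_rng(seed)
    base = template.coords[0]
    resolved = {
        spec: (
            _select_one(template, spec.donor),
            _select_one(template, spec.hydrogen),
            _select_one(template, spec.acceptor),
        )
        for spec in schedules
    }
    frames = np.empty((n_frames, template.n_atoms, 3))
    for f in range(n_frames):
        frame = base + rng.normal(0.0, jitter_sigma, size=base.shape)
        for spec, on in schedules.items():
            d, h, a = resolved[spec]
            axis = frame[h] - frame[d]
            norm = np.linalg.norm(axis)
            axis = axis / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
            dist = on_distance if on[f] else off_distance
            frame[a] = frame[d] + dist * axis
        frames[f] = frame
    return Trajectory(template.atoms, frames, template.timestep_ps)


def _universe_to_trajectory(universe) -> Trajectory:
    atoms = universe.atoms
    try:
        resnames = atoms.resnames
    except Exception:
        resnames = np.array(["UNK"] * len(atoms))
    try:
        resids = atoms.resids
    except Exception:
        resids = np.ones(len(atoms), dtype=int)
    try:
        chains = atoms.chainIDs
    except Exception:
        try:
            chains = atoms.segids
        except Exception:
            chains = np.array(["A"] * len(atoms))
    chains = np.where(
        np.char.strip(np.asarray(chains, dtype=str)) == "", "A", chains
    )
    table = pd.DataFrame(
        {
            "name": atoms.names,
            "resname": resnames,
            "resid": resids,
            "chain": chains,
        }
    )
    coords = np.stack([universe.atoms.positions.copy() for _ in universe.trajectory])
    dt = getattr(universe.trajectory, "dt", None)
    return Trajectory(table, coords.astype(float), dt)


def read_pdb_trajectory(path) -> Trajectory:
    """Read a multi-model PDB file (one MODEL per frame)."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _universe_to_trajectory(mda.Universe(str(path)))


def read_xyz_trajectory(path) -> Trajectory:
    """Read a multi-frame XYZ trajectory (element names only)."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return _universe_to_trajectory(mda.Universe(str(path), format="XYZ"))


def populations_table(populations: list[ContactPopulation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contact": [p.spec.label for p in populations],
            "population": [p.population for p in populations],
        }
    )
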