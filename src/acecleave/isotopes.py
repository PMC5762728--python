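"""Isotope-envelope prediction by elemental convolution.

An envelope is computed by convolving per-element isotope distributions
(each element's n-atom distribution obtained by repeated self-convolution,
exponentiation-by-squaring). Peaks are then aggregated on a 0.2 Da grid
(abundance-weighted centroids), mirroring what a MALDI-TOF reflector
resolves: isotopomer spacing, but not fine structure.

The 18O-labeling model describes internal standards made by enzymatic
hydrolysis in heavy water: up to two exchangeable C-terminal carboxyl
oxygens, each independently 18O with probability ``p_inc`` (the heavy
water is 95-98% 18O, so incorporation is incomplete and the labeled
envelope overlaps the analyte envelope at +2 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import ElementalComposition
from .constants import ISOTOPES, MERGE_TOLERANCE, O18_SHIFT

__all__ = [
    "IsotopePattern",
    "LabelingModel",
    "isotope_pattern",
    "labeled_pattern",
    "write_pattern",
    "read_pattern",
]

_O16_MASS = ISOTOPES["O"][0][0]
_O18_MASS = ISOTOPES["O"][2][0]

#: abundances below this are pruned mid-convolution (well under any
#: reported abundance; keeps array sizes bounded)
_PRUNE = 1e-15


@dataclass(frozen=True)
class IsotopePattern:
    """Ordered (mass Da, abundance fraction) peak list.

    Before truncation, abundances sum to 1; after truncation the peaks
    retain their original fractions (no renormalization), so the sum
    reports how much of the envelope survived.
    """

    masses: np.ndarray
    abundances: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.masses, dtype=float)
        a = np.asarray(self.abundances, dtype=float)
        if m.shape != a.shape or m.ndim != 1:
            raise ValueError("masses and abundances must be 1-D and equal length")
        if m.size > 1 and not np.all(np.diff(m) > 0):
            raise ValueError("masses must be strictly increasing")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "abundances", a)

    def __len__(self) -> int:
        return int(self.masses.size)

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.masses.tolist(), self.abundances.tolist()))

    @property
    def monoisotopic_mass(self) -> float:
        return float(self.masses[0])

    def shifted(self, delta: float) -> "IsotopePattern":
        return IsotopePattern(self.masses + delta, self.abundances.copy())

    def scaled(self, factor: float) -> "IsotopePattern":
        return IsotopePattern(self.masses.copy(), self.abundances * factor)


@dataclass(frozen=True)
class LabelingModel:
    """Binomial 18O incorporation at the C-terminal carboxyl.

    n_sites: exchangeable oxygens (0, 1 or 2); an amidated C-terminus
    or an unlabeled standard uses fewer than 2.
    p_inc: per-site probability of carrying 18O.
    """

    n_sites: int = 2
    p_inc: float = 0.95

    def __post_init__(self) -> None:
        if self.n_sites not in (0, 1, 2):
            raise ValueError(f"n_sites must be 0, 1 or 2, got {self.n_sites}")
        if not 0.0 <= self.p_inc <= 1.0:
            raise ValueError(f"p_inc must be in [0, 1], got {self.p_inc}")

    def site_state_weights(self) -> list[tuple[float, float]]:
        """(mass shift, weight) for k = 0..n_sites heavy oxygens."""
        from math import comb

        p, n = self.p_inc, self.n_sites
        return [
            (k * O18_SHIFT, comb(n, k) * p**k * (1 - p) ** (n - k))
            for k in range(n + 1)
        ]


def _convolve(a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]):
    ma, aa = a
    mb, ab = b
    masses = (ma[:, None] + mb[None, :]).ravel()
    abund = (aa[:, None] * ab[None, :]).ravel()
    return _compact(masses, abund, tol=1e-6)


def _compact(masses: np.ndarray, abund: np.ndarray, tol: float):
    """Sort, merge peaks closer than tol (weighted centroid), prune."""
    order = np.argsort(masses, kind="stable")
    masses, abund = masses[order], abund[order]
    keep = abund > _PRUNE
    masses, abund = masses[keep], abund[keep]
    if masses.size == 0:
        return masses, abund
    # group indices: new group wherever the gap exceeds tol
    group = np.concatenate([[0], np.cumsum(np.diff(masses) > tol)])
    n_groups = int(group[-1]) + 1
    g_ab = np.bincount(group, weights=abund, minlength=n_groups)
    g_ma = np.bincount(group, weights=abund * masses, minlength=n_groups)
    nz = g_ab > 0
    return g_ma[nz] / g_ab[nz], g_ab[nz]


def _element_distribution(element: str, n: int):
    """Isotope distribution of n atoms of one element (binary powering)."""
    table = ISOTOPES[element]
    base = (
        np.array([m for m, _ in table]),
        np.array([a for _, a in table]),
    )
    result = (np.array([0.0]), np.array([1.0]))
    power = base
    while n:
        if n & 1:
            result = _convolve(result, power)
        n >>= 1
        if n:
            power = _convolve(power, power)
    return result


def _raw_pattern(c: ElementalComposition):
    c.validate()
    masses, abund = np.array([0.0]), np.array([1.0])
    for element, n in c.items():
        if n:
            masses, abund = _convolve((masses, abund), _element_distribution(element, n))
    return masses, abund


def isotope_pattern(
    c: ElementalComposition,
    truncate: float = 1e-4,
    merge_tol: float = MERGE_TOLERANCE,
) -> IsotopePattern:
    """Predicted isotope envelope of a neutral composition.

    truncate: relative-abundance threshold below which peaks are dropped
    (after the full normalized envelope is computed, so the retained
    abundances are true fractions of the whole).
    """
    if not 0.0 < truncate < 1.0:
        raise ValueError(f"truncate must be in (0, 1), got {truncate}")
    masses, abund = _raw_pattern(c)
    masses, abund = _compact(masses, abund, tol=merge_tol)
    keep = abund >= truncate
    return IsotopePattern(masses[keep], abund[keep])


def labeled_pattern(
    c: ElementalComposition,
    lm: LabelingModel,
    truncate: float = 1e-4,
    merge_tol: float = MERGE_TOLERANCE,
) -> IsotopePattern:
    """Envelope of a peptide carrying binomial 18O labels.

    The natural envelope of (composition minus n_sites oxygens) is
    convolved with the n_sites label-site distribution, each site being
    16O with probability 1-p_inc or 18O with probability p_inc.
    """
    if not 0.0 < truncate < 1.0:
        raise ValueError(f"truncate must be in (0, 1), got {truncate}")
    if c["O"] < lm.n_sites:
        raise ValueError(
            f"composition has {c['O']} oxygens, fewer than n_sites={lm.n_sites}"
        )
    reduced = c - ElementalComposition({"O": lm.n_sites})
    masses, abund = _raw_pattern(reduced.validate())
    if lm.n_sites:
        site = (
            np.array([_O16_MASS, _O18_MASS]),
            np.array([1.0 - lm.p_inc, lm.p_inc]),
        )
        sites = (np.array([0.0]), np.array([1.0]))
        for _ in range(lm.n_sites):
            sites = _convolve(sites, site)
        masses, abund = _convolve((masses, abund), sites)
    masses, abund = _compact(masses, abund, tol=merge_tol)
    keep = abund >= truncate
    return IsotopePattern(masses[keep], abund[keep])


def write_pattern(pattern: IsotopePattern, path, metadata: dict | None = None) -> None:
    """Two-column TSV (mass, abundance) with '#' metadata header lines."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# mass\tabundance\n")
        for m, a in pattern.peaks:
            fh.write(f"{m:.6f}\t{a:.8g}\n")


def read_pattern(path) -> tuple[IsotopePattern, dict]:
    metadata: dict[str, str] = {}
    masses, abund = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            m, a = line.split("\t")
            masses.append(float(m))
            abund.append(float(a))
    return IsotopePattern(np.array(masses), np.array(abund)), metadata
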