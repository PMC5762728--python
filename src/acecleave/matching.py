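"""MALDI peak assignment and cleavage-map inference.

Given a centroid spectrum of a limited-digestion mixture and the
candidate fragment space of a substrate, assign peaks to fragments by
monoisotopic [M+H]+ mass within a tolerance, infer which peptide bonds
were cleaved, classify the enzyme's mode of action from the product
geometry, and validate the map against an inhibitor-control spectrum.

Bond support bookkeeping distinguishes three evidence levels: a bond
corroborated by both complementary fragments; a bond seen from one side
whose missing complement falls below the matrix-suppression cutoff
(accepted - the complement is unobservable on this instrument); and a
bond seen from one side whose complement should have been visible
(kept, but flagged tentative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import Peptide, fragment, mz_of
from .digest import enumerate_candidate_fragments
from .synth import Spectrum

__all__ = [
    "PeakMatch",
    "BondSupport",
    "CleavageMap",
    "match_peaks",
    "infer_cleavage_map",
    "classify_mode",
    "validate_with_inhibitor",
    "bond_label",
]

DEFAULT_TOLERANCE = 0.3  # Da; covers reflector centroid error with margin
DEFAULT_SUPPRESSION_CUTOFF = 500.0

_THREE_LETTER = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


class SubstrateMismatchError(ValueError):
    """A match references a candidate not derived from the substrate."""


@dataclass(frozen=True)
class PeakMatch:
    """One peak assigned to one candidate fragment."""

    mz: float
    intensity: float
    candidate: Peptide
    mass_error: float  # observed - calculated, Da
    is_parent: bool = False


@dataclass(frozen=True)
class BondSupport:
    """Evidence for one cleaved bond (parent-coordinate index)."""

    bond: int
    n_side: bool  # fragment ending at the bond matched
    c_side: bool  # fragment starting after the bond matched
    complement_suppressed: bool
    status: str  # corroborated | suppressed_complement | tentative

    @property
    def accepted(self) -> bool:
        return self.status in ("corroborated", "suppressed_complement")


@dataclass
class CleavageMap:
    """Inferred cleavage sites, products and enzyme-mode call."""

    substrate: Peptide
    bonds: dict[int, BondSupport] = field(default_factory=dict)
    products: list[Peptide] = field(default_factory=list)
    matches: list[PeakMatch] = field(default_factory=list)
    mode_call: str = "none"
    control_validated: bool | None = None

    def bond_indices(self) -> set[int]:
        return set(self.bonds)

    def product_intervals(self) -> set[tuple[int, int]]:
        return {p.interval for p in self.products}


def bond_label(substrate: Peptide, bond: int) -> str:
    """Human-readable bond name, e.g. ``Arg5-His6``."""
    left = substrate.sequence[bond - substrate.start]
    right = substrate.sequence[bond - substrate.start + 1]
    return f"{_THREE_LETTER[left]}{bond}-{_THREE_LETTER[right]}{bond + 1}"


#: 13C isotopomer spacing used to recognize envelope tail peaks
_ISOTOPOMER_SPACING = 1.00335


def _is_envelope_tail(
    s: Spectrum, i: int, window: float = 0.25, min_frac: float = 0.05
) -> bool:
    """True when peak i sits one isotopomer above a comparable peak.

    Matching is monoisotopic: only the first peak of each envelope is
    assigned, so higher isotopomers of one fragment cannot be
    mis-assigned to another candidate.
    """
    target = s.mz[i] - _ISOTOPOMER_SPACING
    sel = np.abs(s.mz - target) <= window
    return bool(np.any(s.intensity[sel] >= min_frac * s.intensity[i]))


def match_peaks(
    s: Spectrum,
    candidates: list[Peptide],
    tol: float = DEFAULT_TOLERANCE,
    substrate: Peptide | None = None,
    heads_only: bool = True,
) -> list[PeakMatch]:
    """Assign envelope-leading peaks to all candidates within ``tol`` of [M+H]+.

    All candidates inside the tolerance are reported, nearest first
    (never silently picking one of several); peaks matching the
    substrate itself are flagged as parent. With ``heads_only`` (the
    default) peaks recognized as higher isotopomers of a lower peak are
    not assigned; a bare centroid list without envelopes is unaffected.
    """
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    calc = [(c, mz_of(c)) for c in candidates]
    out: list[PeakMatch] = []
    for i, (mz, intensity) in enumerate(s.peaks):
        if heads_only and _is_envelope_tail(s, i):
            continue
        hits = [
            (c, mz - value)
            for c, value in calc
            if abs(mz - value) <= tol
        ]
        hits.sort(key=lambda h: abs(h[1]))
        for candidate, error in hits:
            is_parent = substrate is not None and candidate.same_interval(substrate)
            out.append(PeakMatch(mz, intensity, candidate, error, is_parent))
    return out


def _check_provenance(match: PeakMatch, substrate: Peptide) -> None:
    c = match.candidate
    if not (substrate.start <= c.start <= c.end <= substrate.end):
        raise SubstrateMismatchError(
            f"candidate {c.name} is outside substrate {substrate.name}"
        )
    expected = fragment(substrate, c.start, c.end)
    if expected.sequence != c.sequence:
        raise SubstrateMismatchError(
            f"candidate {c.name} sequence disagrees with substrate {substrate.name}"
        )


def infer_cleavage_map(
    matches: list[PeakMatch],
    substrate: Peptide,
    suppression_cutoff: float = DEFAULT_SUPPRESSION_CUTOFF,
) -> CleavageMap:
    """Infer the cleaved-bond set from assigned fragment peaks.

    Each non-parent fragment implies its boundary bond(s); complementary
    fragments corroborate a bond; a one-sided bond is accepted when the
    missing complement's [M+H]+ lies below the suppression cutoff and
    flagged tentative otherwise.
    """
    for m in matches:
        _check_provenance(m, substrate)
    product_matches = [
        m for m in matches if not (m.is_parent or m.candidate.same_interval(substrate))
    ]
    intervals = sorted({m.candidate.interval for m in product_matches})
    n_side: set[int] = set()
    c_side: set[int] = set()
    for a, b in intervals:
        if a > substrate.start:
            c_side.add(a - 1)
        if b < substrate.end:
            n_side.add(b)
    bonds: dict[int, BondSupport] = {}
    for bond in sorted(n_side | c_side):
        has_n, has_c = bond in n_side, bond in c_side
        if has_n and has_c:
            bonds[bond] = BondSupport(bond, True, True, False, "corroborated")
            continue
        # the unobserved complement of the observed one-sided fragment
        if has_n:
            complement = fragment(substrate, bond + 1, substrate.end)
        else:
            complement = fragment(substrate, substrate.start, bond)
        suppressed = mz_of(complement) < suppression_cutoff
        status = "suppressed_complement" if suppressed else "tentative"
        bonds[bond] = BondSupport(bond, has_n, has_c, suppressed, status)
    products = [fragment(substrate, a, b) for a, b in intervals]
    cmap = CleavageMap(
        substrate=substrate,
        bonds=bonds,
        products=products,
        matches=list(matches),
    )
    cmap.mode_call = classify_mode(cmap)
    return cmap


def classify_mode(cmap: CleavageMap) -> str:
    """Classify the enzyme's mode of action from product geometry.

    * a single cut exactly two residues from the C-terminus ->
      dipeptidyl_carboxypeptidase (ACE's canonical action);
    * cuts at several depths within the last three residues ->
      processive_carboxypeptidase;
    * cuts at internal bonds (more than two residues from the
      C-terminus) evidenced by an N-terminally truncated product, a
      complementary pair, or an N-side product whose complement is
      matrix-suppressed -> endopeptidase;
    * anything else -> ambiguous.
    """
    if not cmap.bonds:
        return "none"
    s = cmap.substrate
    depths = {s.end - bond for bond in cmap.bonds}
    if depths == {2}:
        return "dipeptidyl_carboxypeptidase"
    if depths <= {1, 2, 3} and len(depths) >= 2:
        return "processive_carboxypeptidase"
    internal = all(depth >= 3 for depth in depths)
    evidenced = all(
        sup.c_side or sup.complement_suppressed for sup in cmap.bonds.values()
    )
    if internal and evidenced:
        return "endopeptidase"
    return "ambiguous"


def validate_with_inhibitor(
    cmap: CleavageMap,
    control: Spectrum,
    tol: float = DEFAULT_TOLERANCE,
    intensity_floor: float | None = None,
) -> CleavageMap:
    """Check an inhibitor-control spectrum against the inferred map.

    The map validates iff none of its product peaks appears in the
    control above the intensity floor (default: 3x the control's median
    intensity); the parent peak is allowed. Bonds are retained either
    way; failure only clears the validation flag.
    """
    if len(control) == 0:
        cmap.control_validated = True
        return cmap
    floor = (
        intensity_floor
        if intensity_floor is not None
        else 3.0 * float(np.median(control.intensity))
    )
    offending = False
    for product in cmap.products:
        target = mz_of(product)
        for mz, intensity in control.peaks:
            if abs(mz - target) <= tol and intensity > floor:
                offending = True
    cmap.control_validated = not offending
    return cmap


def candidates_for(substrate: Peptide, min_length: int = 1) -> list[Peptide]:
    """Convenience: the full candidate fragment space of a substrate."""
    return enumerate_candidate_fragments(substrate, min_length=min_length)
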