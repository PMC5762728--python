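"""Peptide representation and exact-mass arithmetic.

Peptides are intervals of a (possibly anonymous) parent chain with
independent N- and C-terminal modification states. Two terminal
modifications are supported, matching the synthetic substrates used to
probe ACE specificity on the amyloid-beta metal-binding domain (MBD,
residues 1-16): N-terminal acetylation (+C2H2O) and C-terminal
amidation (+NH, -O; net -0.98402 Da vs the free acid), the latter
mimicking continuation of the chain in full-length amyloid-beta.

Masses are monoisotopic throughout; ``mz_of`` returns [M+zH]z+ values
for singly or multiply protonated species (MALDI work uses z=1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .constants import ATOMIC_MASS, PROTON_MASS

__all__ = [
    "ElementalComposition",
    "TerminalMod",
    "Peptide",
    "Residue",
    "RESIDUES",
    "SUBSTRATE_REGISTRY",
    "parse_peptide",
    "format_peptide",
    "composition_of",
    "monoisotopic_mass",
    "mz_of",
    "fragment",
    "read_parent_fasta",
]


class PeptideParseError(ValueError):
    """Raised when a peptide notation string cannot be interpreted."""


@dataclass(frozen=True)
class ElementalComposition:
    """Signed element -> count map over C, H, N, O, S.

    Intermediate arithmetic (terminal-mod deltas) may be negative;
    a composition describing a real molecule must be non-negative,
    which callers assert via :meth:`validate`.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {e: int(n) for e, n in self.counts.items() if n != 0}
        unknown = set(clean) - set(ATOMIC_MASS)
        if unknown:
            raise ValueError(f"unknown element(s): {sorted(unknown)}")
        object.__setattr__(self, "counts", clean)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, n in other.counts.items():
            merged[e] = merged.get(e, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, n in other.counts.items():
            merged[e] = merged.get(e, 0) - n
        return ElementalComposition(merged)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def validate(self) -> "ElementalComposition":
        negative = {e: n for e, n in self.counts.items() if n < 0}
        if negative:
            raise ValueError(f"negative element counts: {negative}")
        return self

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(sorted(self.counts.items()))

    def hill_formula(self) -> str:
        parts = []
        for e in ("C", "H", "N", "O", "S"):
            n = self[e]
            if n == 1:
                parts.append(e)
            elif n != 0:
                parts.append(f"{e}{n}")
        return "".join(parts)


def _comp(**counts: int) -> ElementalComposition:
    return ElementalComposition(counts)


@dataclass(frozen=True)
class Residue:
    """A standard amino-acid residue (dehydrated, in-chain) composition."""

    code: str
    formula: ElementalComposition

    @property
    def mono_mass(self) -> float:
        return monoisotopic_mass(self.formula)


RESIDUES: dict[str, Residue] = {
    code: Residue(code, _comp(C=c, H=h, N=n, O=o, S=s))
    for code, (c, h, n, o, s) in {
        "G": (2, 3, 1, 1, 0),
        "A": (3, 5, 1, 1, 0),
        "S": (3, 5, 1, 2, 0),
        "P": (5, 7, 1, 1, 0),
        "V": (5, 9, 1, 1, 0),
        "T": (4, 7, 1, 2, 0),
        "C": (3, 5, 1, 1, 1),
        "L": (6, 11, 1, 1, 0),
        "I": (6, 11, 1, 1, 0),
        "N": (4, 6, 2, 2, 0),
        "D": (4, 5, 1, 3, 0),
        "Q": (5, 8, 2, 2, 0),
        "K": (6, 12, 2, 1, 0),
        "E": (5, 7, 1, 3, 0),
        "M": (5, 9, 1, 1, 1),
        "H": (6, 7, 3, 1, 0),
        "F": (9, 9, 1, 1, 0),
        "R": (6, 12, 4, 1, 0),
        "Y": (9, 9, 1, 2, 0),
        "W": (11, 10, 2, 1, 0),
    }.items()
}


@dataclass(frozen=True)
class TerminalMod:
    """A terminal modification: a named, signed composition delta."""

    name: str
    delta_formula: ElementalComposition
    applies_to: str  # "N" or "C"


FREE_N = TerminalMod("free", _comp(), "N")
FREE_C = TerminalMod("free", _comp(), "C")
ACETYL = TerminalMod("acetyl", _comp(C=2, H=2, O=1), "N")
AMIDE = TerminalMod("amide", _comp(N=1, H=1, O=-1), "C")

_N_MODS = {"free": FREE_N, "acetyl": ACETYL}
_C_MODS = {"free": FREE_C, "amide": AMIDE}


@dataclass(frozen=True)
class Peptide:
    """A residue interval of a parent chain plus terminal states.

    ``start``/``end`` are 1-based inclusive positions in the parent;
    anonymous peptides use parent=None with start=1.
    """

    sequence: str
    n_mod: TerminalMod = FREE_N
    c_mod: TerminalMod = FREE_C
    parent: str | None = None
    start: int = 1
    end: int = field(default=0)

    def __post_init__(self) -> None:
        if self.end == 0:
            object.__setattr__(self, "end", self.start + len(self.sequence) - 1)
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end}")
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("interval length does not match sequence length")
        bad = [c for c in self.sequence if c not in RESIDUES]
        if bad:
            raise PeptideParseError(f"unknown residue letter(s): {bad}")
        if self.n_mod.applies_to != "N" or self.c_mod.applies_to != "C":
            raise ValueError("terminal mods applied to the wrong terminus")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def name(self) -> str:
        """Human-readable fragment name, e.g. ``[Acetyl]-Abeta(1-5)``."""
        core = (
            f"{self.parent}({self.start}-{self.end})"
            if self.parent
            else self.sequence
        )
        if self.n_mod.name == "acetyl":
            core = f"[Acetyl]-{core}"
        if self.c_mod.name == "amide":
            core = f"{core}-[Amide]"
        return core

    def same_interval(self, other: "Peptide") -> bool:
        return self.interval == other.interval and self.sequence == other.sequence


_PEPTIDE_RE = re.compile(
    r"^\s*(?:\[\s*acetyl\s*\]\s*-?\s*)?([A-Za-z\s]+?)\s*(?:-?\s*\[?\s*amide\s*\]\s*)?$",
    re.IGNORECASE,
)


def parse_peptide(text: str) -> Peptide:
    """Parse annotated notation like ``[Acetyl]-DAEFR`` or ``HDSGYEVHHQK-[Amide]``.

    Whitespace-tolerant; round-trips through :func:`format_peptide`.
    """
    m = _PEPTIDE_RE.match(text)
    if not m:
        raise PeptideParseError(f"cannot parse peptide notation: {text!r}")
    n_mod = ACETYL if re.match(r"\s*\[\s*acetyl", text, re.IGNORECASE) else FREE_N
    c_mod = AMIDE if re.search(r"amide\s*\]\s*$", text, re.IGNORECASE) else FREE_C
    seq = "".join(m.group(1).split()).upper()
    if not seq:
        raise PeptideParseError(f"empty sequence in {text!r}")
    bad = sorted({c for c in seq if c not in RESIDUES})
    if bad:
        raise PeptideParseError(f"unknown residue letter(s) {bad} in {text!r}")
    return Peptide(seq, n_mod=n_mod, c_mod=c_mod)


def format_peptide(p: Peptide) -> str:
    out = p.sequence
    if p.n_mod.name == "acetyl":
        out = f"[Acetyl]-{out}"
    if p.c_mod.name == "amide":
        out = f"{out}-[Amide]"
    return out


def composition_of(p: Peptide) -> ElementalComposition:
    """Elemental composition: residue formulas + one water + terminal deltas."""
    total = _comp(H=2, O=1)
    for code in p.sequence:
        total = total + RESIDUES[code].formula
    total = total + p.n_mod.delta_formula + p.c_mod.delta_formula
    return total.validate()


def monoisotopic_mass(c: ElementalComposition) -> float:
    """Monoisotopic mass in Da from the pinned atomic-mass table."""
    return sum(n * ATOMIC_MASS[e] for e, n in c.counts.items())


def peptide_mass(p: Peptide) -> float:
    return monoisotopic_mass(composition_of(p))


def mz_of(p: Peptide, charge: int = 1) -> float:
    """m/z of the [M+zH]z+ ion; MALDI spectra here are all z=1."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (peptide_mass(p) + charge * PROTON_MASS) / charge


def fragment(p: Peptide, start: int, end: int) -> Peptide:
    """Sub-peptide at parent positions [start, end] with mod inheritance.

    An N-terminal fragment keeps the substrate's N-mod and gains a free
    carboxyl; a C-terminal fragment gains a free amine and keeps the
    substrate's C-mod; internal fragments are free/free.
    """
    if not (p.start <= start <= end <= p.end):
        raise ValueError(f"fragment {start}..{end} outside {p.start}..{p.end}")
    seq = p.sequence[start - p.start : end - p.start + 1]
    n_mod = p.n_mod if start == p.start else FREE_N
    c_mod = p.c_mod if end == p.end else FREE_C
    return Peptide(seq, n_mod=n_mod, c_mod=c_mod, parent=p.parent, start=start, end=end)


# The four synthetic MBD substrates, addressable by name. Human MBD is
# DAEFRHDSGYEVHHQK; the rat chain differs by R5G, Y10F, H13R.
HUMAN_MBD = "DAEFRHDSGYEVHHQK"
RAT_MBD = "DAEFGHDSGFEVRHQK"

SUBSTRATE_REGISTRY: dict[str, Peptide] = {
    "Abeta1-16": Peptide(HUMAN_MBD, parent="Abeta"),
    "Abeta1-16-amide": Peptide(HUMAN_MBD, c_mod=AMIDE, parent="Abeta"),
    "Ac-Abeta1-16-amide": Peptide(
        HUMAN_MBD, n_mod=ACETYL, c_mod=AMIDE, parent="Abeta"
    ),
    "Ac-ratAbeta1-16-amide": Peptide(
        RAT_MBD, n_mod=ACETYL, c_mod=AMIDE, parent="ratAbeta"
    ),
}


def get_substrate(name: str) -> Peptide:
    """Look up a registered substrate by name, or parse notation directly."""
    if name in SUBSTRATE_REGISTRY:
        return SUBSTRATE_REGISTRY[name]
    return parse_peptide(name)


def read_parent_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader for parent chains (id -> sequence)."""
    chains: dict[str, str] = {}
    current: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                chains[current] = ""
            elif current is not None:
                chains[current] += line.upper()
    return chains
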