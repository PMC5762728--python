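"""Rule-based limited-proteolysis engine.

Encodes protease specificity as declarative cleavage rules and applies
them to annotated peptide substrates. The shipped ``ace_observed``
preset captures the observed behaviour of the two catalytic domains of
somatic angiotensin-converting enzyme (ACE) on amyloid-beta
metal-binding-domain (MBD) substrates:

* N-ACE acts as an arginine-specific endopeptidase (Arg|His) on
  C-amidated MBDs, and as a dipeptidyl carboxypeptidase on the free
  acid;
* C-ACE acts as a (di/tri-peptide-removing) carboxypeptidase on free
  substrates, is blocked entirely by C-amidation of the human MBD, but
  trims the amidated rat MBD processively at its C-terminus;
* lisinopril abolishes all ACE products (specificity control);
* trypsin (used to make 18O-labeled standards) cleaves after Lys/Arg
  except before Pro, to completion.

Bond ``i-(i+1)`` denotes the peptide bond between parent positions i
and i+1; cleaving it yields fragments (start..i) and (i+1..end) with
terminal-mod inheritance from :func:`acecleave.chem.fragment`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .chem import Peptide, fragment

__all__ = [
    "CleavageRule",
    "DigestResult",
    "digest_with_rules",
    "enumerate_candidate_fragments",
    "trypsin_digest",
    "load_rules",
    "default_rules",
    "ACE_PRESET",
]

MODES = {
    "endopeptidase",
    "dipeptidyl_carboxypeptidase",
    "processive_carboxypeptidase",
}


@dataclass(frozen=True)
class CleavageRule:
    """One specificity rule for a named enzyme.

    For endopeptidase mode, ``p1``/``p1prime`` are the allowed residues
    flanking the scissile bond ("*" in p1prime means any). For the
    carboxypeptidase modes, ``min_trim``/``max_trim`` bound how many
    residues are removed from the C-terminus (dipeptidyl mode is fixed
    at exactly 2 and ignores them). ``requires_c_mod``/``forbids_c_mod``
    and ``requires_sequence`` condition the rule on the substrate.
    """

    enzyme: str
    mode: str
    p1: frozenset[str] = frozenset()
    p1prime: frozenset[str] = frozenset("*")
    requires_c_mod: str | None = None
    forbids_c_mod: str | None = None
    requires_sequence: str | None = None
    min_trim: int = 1
    max_trim: int = 2
    inhibitable_by: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "endopeptidase" and not self.p1:
            raise ValueError("endopeptidase rule needs a non-empty p1 set")
        if self.mode == "processive_carboxypeptidase" and not (
            1 <= self.min_trim <= self.max_trim
        ):
            raise ValueError("need 1 <= min_trim <= max_trim")

    def applies_to(self, substrate: Peptide) -> bool:
        if self.requires_c_mod and substrate.c_mod.name != self.requires_c_mod:
            return False
        if self.forbids_c_mod and substrate.c_mod.name == self.forbids_c_mod:
            return False
        if self.requires_sequence and substrate.sequence != self.requires_sequence:
            return False
        return True


@dataclass
class DigestResult:
    """Products and provenance of one limited-digestion pass.

    ``bonds_cleaved`` holds parent-coordinate bond indices i (bond
    between residues i and i+1); ``rules_fired`` maps each bond to the
    rule that produced it. Endopeptidase bonds contribute both
    complementary fragments to ``products``.
    """

    substrate: Peptide
    products: list[Peptide] = field(default_factory=list)
    bonds_cleaved: set[int] = field(default_factory=set)
    rules_fired: dict[int, CleavageRule] = field(default_factory=dict)
    inhibited: bool = False
    warning: str | None = None

    def product_intervals(self) -> set[tuple[int, int]]:
        return {p.interval for p in self.products}


def _add_product(result: DigestResult, p: Peptide) -> None:
    if not any(p.same_interval(q) for q in result.products):
        result.products.append(p)


def _cleave_bond(result: DigestResult, bond: int, rule: CleavageRule) -> None:
    s = result.substrate
    _add_product(result, fragment(s, s.start, bond))
    _add_product(result, fragment(s, bond + 1, s.end))
    result.bonds_cleaved.add(bond)
    result.rules_fired.setdefault(bond, rule)


def digest_with_rules(
    substrate: Peptide,
    enzyme: str,
    rules: list[CleavageRule] | None = None,
    inhibitor: str | None = None,
) -> DigestResult:
    """Apply every matching rule of ``enzyme`` to the substrate once.

    Products are single-cleavage only (limited hydrolysis); feed
    products back in for iterative digestion. An inhibitor named in a
    matching rule's ``inhibitable_by`` abolishes the whole product set.
    """
    if rules is None:
        rules = default_rules()
    enzyme_rules = [r for r in rules if r.enzyme == enzyme]
    if not enzyme_rules:
        raise ValueError(f"no rules registered for enzyme {enzyme!r}")
    result = DigestResult(substrate=substrate)
    applicable = [r for r in enzyme_rules if r.applies_to(substrate)]
    if inhibitor is not None and any(
        inhibitor in r.inhibitable_by for r in applicable
    ):
        result.inhibited = True
        return result
    n = len(substrate)
    for rule in applicable:
        if rule.mode == "endopeptidase":
            for i in range(n - 1):  # local bond i .. i+1 (0-based local)
                if substrate.sequence[i] in rule.p1 and (
                    "*" in rule.p1prime or substrate.sequence[i + 1] in rule.p1prime
                ):
                    _cleave_bond(result, substrate.start + i, rule)
        elif rule.mode == "dipeptidyl_carboxypeptidase":
            if n < 3:
                result.warning = "substrate too short for carboxypeptidase mode"
                continue
            _cleave_bond(result, substrate.end - 2, rule)
        else:  # processive_carboxypeptidase
            if n < 3:
                result.warning = "substrate too short for carboxypeptidase mode"
                continue
            for k in range(rule.min_trim, min(rule.max_trim, n - 1) + 1):
                _cleave_bond(result, substrate.end - k, rule)
    result.products.sort(key=lambda p: p.interval)
    return result


def enumerate_candidate_fragments(
    substrate: Peptide,
    min_length: int = 1,
    include_parent: bool = True,
) -> list[Peptide]:
    """All contiguous sub-peptides with terminal-mod inheritance.

    The candidate space for peak matching: n(n+1)/2 intervals for a
    length-n substrate (at min_length=1), deduplicated by interval.
    """
    out: list[Peptide] = []
    for i in range(substrate.start, substrate.end + 1):
        for j in range(i + min_length - 1, substrate.end + 1):
            if j < i:
                continue
            if not include_parent and (i, j) == substrate.interval:
                continue
            out.append(fragment(substrate, i, j))
    return out


def trypsin_digest(substrate: Peptide) -> DigestResult:
    """Complete tryptic digestion: cleave after K/R except before P.

    All eligible bonds are cut simultaneously (48 h hydrolysis to
    completion, as used when preparing 18O-labeled standards), so the
    products partition the substrate.
    """
    seq = substrate.sequence
    n = len(seq)
    cut_after_local = [
        i for i in range(n - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    result = DigestResult(substrate=substrate)
    rule = CleavageRule(
        enzyme="trypsin",
        mode="endopeptidase",
        p1=frozenset("KR"),
        p1prime=frozenset(set("ACDEFGHIKLMNQRSTVWY")),
    )
    if not cut_after_local:
        result.products = [substrate]
        return result
    bounds = [substrate.start - 1] + [substrate.start + i for i in cut_after_local]
    bounds.append(substrate.end)
    for a, b in zip(bounds[:-1], bounds[1:]):
        _add_product(result, fragment(substrate, a + 1, b))
    for i in cut_after_local:
        bond = substrate.start + i
        result.bonds_cleaved.add(bond)
        result.rules_fired[bond] = rule
    result.products.sort(key=lambda p: p.interval)
    return result


def _rule_from_dict(d: dict) -> CleavageRule:
    return CleavageRule(
        enzyme=d["enzyme"],
        mode=d["mode"],
        p1=frozenset(d.get("p1", [])),
        p1prime=frozenset(d.get("p1prime", ["*"])),
        requires_c_mod=d.get("requires_c_mod"),
        forbids_c_mod=d.get("forbids_c_mod"),
        requires_sequence=d.get("requires_sequence"),
        min_trim=int(d.get("min_trim", 1)),
        max_trim=int(d.get("max_trim", 2)),
        inhibitable_by=frozenset(d.get("inhibitable_by", [])),
    )


def load_rules(path) -> list[CleavageRule]:
    """Load a rule set from a YAML config (list under key ``rules``)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [_rule_from_dict(d) for d in doc["rules"]]


ACE_PRESET = "ace_observed"
_cached_default: list[CleavageRule] | None = None


def default_rules() -> list[CleavageRule]:
    """The shipped ACE rule preset (observed MBD behaviour)."""
    global _cached_default
    if _cached_default is None:
        ref = resources.files("acecleave").joinpath("data/ace_rules.yaml")
        with resources.as_file(ref) as path:
            _cached_default = load_rules(path)
    return _cached_default
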