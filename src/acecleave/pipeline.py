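"""Scenario configuration and end-to-end pipeline orchestration.

A scenario bundles everything needed to emulate and analyze one
digestion experiment: substrate, enzyme and rule set, optional
inhibitor, per-bond kinetics, spectrum-render parameters, matching
tolerance, and an optional quantitation block (analyte, labeling and
internal-standard concentration). ``run_pipeline`` executes
simulate -> match -> infer (-> quant) and writes per-stage artifacts
plus a structured summary report. All randomness flows from the
scenario's spectrum seed, so re-running a scenario reproduces its
numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chem import Peptide, fragment, get_substrate
from .digest import (
    CleavageRule,
    default_rules,
    digest_with_rules,
    enumerate_candidate_fragments,
    load_rules,
)
from .isotopes import LabelingModel
from .matching import (
    DEFAULT_TOLERANCE,
    bond_label,
    infer_cleavage_map,
    match_peaks,
)
from .synth import (
    KineticScheme,
    SpectrumParams,
    render_spectrum,
    simulate_timecourse,
    timecourse_mixture,
    write_spectrum,
)
from .quant import quantify_analyte

log = logging.getLogger("acecleave.pipeline")

__all__ = ["Scenario", "ScenarioError", "run_pipeline"]


class ScenarioError(ValueError):
    """A scenario failed validation before any stage ran."""


@dataclass
class QuantBlock:
    analyte: str  # "start-end" interval of the substrate, or notation/name
    standard_conc: float = 10.0  # uM
    p_inc: float = 0.95
    n_sites: int = 2


@dataclass
class Scenario:
    substrate: str
    enzyme: str
    rules_path: str | None = None
    inhibitor: str | None = None
    rates: dict[int, float] = field(default_factory=dict)
    times: tuple[float, ...] = (10.0, 20.0, 40.0)
    c0: float = 40.0
    spectrum: SpectrumParams = field(default_factory=SpectrumParams)
    tolerance: float = DEFAULT_TOLERANCE
    quant: QuantBlock | None = None
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        try:
            spectrum_kwargs = dict(doc.get("spectrum", {}))
            if "mz_window" in spectrum_kwargs:
                spectrum_kwargs["mz_window"] = tuple(spectrum_kwargs["mz_window"])
            kinetics = doc.get("kinetics", {})
            quant_doc = doc.get("quant")
            return cls(
                substrate=doc["substrate"],
                enzyme=doc["enzyme"],
                rules_path=doc.get("rules"),
                inhibitor=doc.get("inhibitor"),
                rates={int(k): float(v) for k, v in kinetics.get("rates", {}).items()},
                times=tuple(kinetics.get("times", (10.0, 20.0, 40.0))),
                c0=float(kinetics.get("c0", 40.0)),
                spectrum=SpectrumParams(**spectrum_kwargs),
                tolerance=float(doc.get("matching", {}).get("tolerance", DEFAULT_TOLERANCE)),
                quant=QuantBlock(**quant_doc) if quant_doc else None,
                output_dir=doc.get("output_dir"),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ScenarioError(f"malformed scenario config: {exc}") from exc

    def resolve(self) -> tuple[Peptide, list[CleavageRule]]:
        """Validate references and return (substrate, rules)."""
        try:
            substrate = get_substrate(self.substrate)
        except Exception as exc:
            raise ScenarioError(f"unresolvable substrate {self.substrate!r}: {exc}")
        rules = load_rules(self.rules_path) if self.rules_path else default_rules()
        if not any(r.enzyme == self.enzyme for r in rules):
            raise ScenarioError(f"no rules for enzyme {self.enzyme!r}")
        for bond in self.rates:
            if not substrate.start <= bond < substrate.end:
                raise ScenarioError(f"kinetic rate for bond {bond} outside substrate")
        return substrate, rules


DEFAULT_RATE = 0.05  # 1/min per cleavable bond when the scenario sets none


def _resolve_analyte(substrate: Peptide, spec: str) -> Peptide:
    if "-" in spec and spec.replace("-", "").isdigit():
        a, b = (int(x) for x in spec.split("-"))
        return fragment(substrate, a, b)
    return get_substrate(spec)


def run_pipeline(scenario: Scenario, output_dir=None) -> dict:
    """Execute digest -> simulate -> match -> infer (-> quant).

    Returns the summary report (also written as report.yaml when an
    output directory is given): cleavage bonds with labels and support
    status, mode call, inhibitor flag, and the per-time concentration
    estimates when a quant block is present.
    """
    substrate, rules = scenario.resolve()
    outdir = Path(output_dir or scenario.output_dir) if (output_dir or scenario.output_dir) else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    digest = digest_with_rules(substrate, scenario.enzyme, rules, scenario.inhibitor)
    for bond, rule in sorted(digest.rules_fired.items()):
        log.info("rule fired: %s %s at %s", rule.enzyme, rule.mode, bond_label(substrate, bond))
    rates = dict(scenario.rates) or {
        bond: DEFAULT_RATE for bond in sorted(digest.bonds_cleaved)
    }
    if rates and not digest.inhibited:
        scheme = KineticScheme(substrate, rates, scenario.times, scenario.c0)
        timecourse = simulate_timecourse(scheme)
        mixture = timecourse_mixture(scheme, len(scenario.times) - 1)
    else:
        scheme = None
        timecourse = None
        mixture = {substrate: scenario.c0}

    spectrum = render_spectrum(mixture, scenario.spectrum)
    candidates = enumerate_candidate_fragments(substrate, min_length=1)
    matches = match_peaks(spectrum, candidates, scenario.tolerance, substrate=substrate)
    for m in matches:
        log.info(
            "match: peak %.3f -> %s (error %+.4f Da)%s",
            m.mz, m.candidate.name, m.mass_error, " [parent]" if m.is_parent else "",
        )
    cmap = infer_cleavage_map(matches, substrate, scenario.spectrum.suppression_cutoff)

    report: dict = {
        "substrate": substrate.name,
        "enzyme": scenario.enzyme,
        "inhibitor": scenario.inhibitor,
        "inhibited": digest.inhibited,
        "bonds": {
            bond_label(substrate, b): sup.status for b, sup in cmap.bonds.items()
        },
        "products": sorted(p.name for p in cmap.products),
        "mode": cmap.mode_call,
    }

    if scenario.quant and scheme is not None:
        analyte = _resolve_analyte(substrate, scenario.quant.analyte)
        lm = LabelingModel(scenario.quant.n_sites, scenario.quant.p_inc)
        series = {}
        for i, t in enumerate(scenario.times):
            mix_t = timecourse_mixture(scheme, i)
            species = [(p, c, None) for p, c in mix_t.items()]
            species.append((analyte, scenario.quant.standard_conc, lm))
            sp_t = dataclasses.replace(scenario.spectrum, seed=scenario.spectrum.seed + i)
            spec_t = render_spectrum(species, sp_t)
            est = quantify_analyte(spec_t, analyte, lm, scenario.quant.standard_conc)
            series[float(t)] = est.analyte_conc
        report["quant"] = {
            "analyte": analyte.name,
            "standard_conc_uM": scenario.quant.standard_conc,
            "concentration_uM_by_time_min": series,
        }

    if outdir:
        write_spectrum(spectrum, outdir / "spectrum.csv")
        if timecourse is not None:
            timecourse.to_csv(outdir / "timecourse.tsv", sep="\t")
        with open(outdir / "report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    return report
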