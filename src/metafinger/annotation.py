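"""Putative metabolite annotation by accurate mass and isotope pattern.

An observed fingerprint ion carries no structure, only an m/z.  Annotation
proceeds by computing, for every metabolite in a reference table and every
adduct form eligible in the spectrum's polarity, the theoretical m/z from the
molecular formula's monoisotopic mass plus an electron-corrected adduct mass
delta, and retaining candidates within a relative ppm tolerance (default
5 ppm).  A first-order isotope-abundance check on the M+1/M0 ratio can then
demote formulas whose predicted carbon/nitrogen content is inconsistent with
the observed isotope envelope.

Identification here is putative: accurate mass plus isotope ratio, no MS/MS
fragment matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ELEMENT_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ADDUCTS",
    "AdductRule",
    "MetaboliteRecord",
    "AnnotationCandidate",
    "parse_formula",
    "monoisotopic_mass",
    "theoretical_mz",
    "annotate_ion",
    "isotope_check",
    "load_metabolite_db",
]

# CODATA/AME monoisotopic masses of the most abundant isotope (Da)
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = ELEMENT_MASS["H"] - ELECTRON_MASS  # 1.007276...

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class AdductRule:
    """A singly charged adduct form with its exact mass delta.

    ``delta`` is the mass added to the neutral monoisotopic mass to obtain
    the ion m/z, already including the gain or loss of one electron mass.
    """

    label: str
    polarity: str
    delta: float
    charge: int = 1


def _delta(gain: dict[str, int] | None = None, loss: dict[str, int] | None = None,
           charge_sign: int = +1) -> float:
    """Adduct mass delta from gained/lost atoms plus electron correction."""
    d = 0.0
    for el, n in (gain or {}).items():
        d += n * ELEMENT_MASS[el]
    for el, n in (loss or {}).items():
        d -= n * ELEMENT_MASS[el]
    # a cation is one electron light, an anion one electron heavy
    return d - charge_sign * ELECTRON_MASS


#: Adduct forms considered, in priority order within each polarity.
ADDUCTS: dict[str, AdductRule] = {
    "[M+H]+": AdductRule("[M+H]+", "positive", _delta({"H": 1})),
    "[M+Na]+": AdductRule("[M+Na]+", "positive", _delta({"Na": 1})),
    "[M+K]+": AdductRule("[M+K]+", "positive", _delta({"K": 1})),
    "[M-H2O+H]+": AdductRule("[M-H2O+H]+", "positive", _delta({"H": 1}, {"H": 2, "O": 1})),
    "[M+2Na-H]+": AdductRule("[M+2Na-H]+", "positive", _delta({"Na": 2}, {"H": 1})),
    "[M+2K-H]+": AdductRule("[M+2K-H]+", "positive", _delta({"K": 2}, {"H": 1})),
    "[M+NH4]+": AdductRule("[M+NH4]+", "positive", _delta({"N": 1, "H": 4})),
    "[M-H]-": AdductRule("[M-H]-", "negative", _delta(None, {"H": 1}, charge_sign=-1)),
    "[M+Na-2H]-": AdductRule("[M+Na-2H]-", "negative", _delta({"Na": 1}, {"H": 2}, charge_sign=-1)),
    "[M+K-2H]-": AdductRule("[M+K-2H]-", "negative", _delta({"K": 1}, {"H": 2}, charge_sign=-1)),
    "[M+Cl]-": AdductRule("[M+Cl]-", "negative", _delta({"Cl": 1}, None, charge_sign=-1)),
}

_ADDUCT_PRIORITY = {label: rank for rank, label in enumerate(ADDUCTS)}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C6H14N4O2`` into element counts.

    Raises
    ------
    ValueError
        On unknown element symbols or unparseable text.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        if not match.group(0):
            break
        el = match.group(1)
        if el not in ELEMENT_MASS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        n = int(match.group(2)) if match.group(2) else 1
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (most abundant isotope) mass of a neutral formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(ELEMENT_MASS[el] * n for el, n in counts.items())


def theoretical_mz(formula: str | dict[str, int], adduct: str | AdductRule) -> float:
    """Theoretical m/z of a formula under a given singly charged adduct.

    >>> round(theoretical_mz("C6H14N4O2", "[M+H]+"), 4)   # arginine
    175.119
    """
    rule = ADDUCTS[adduct] if isinstance(adduct, str) else adduct
    return monoisotopic_mass(formula) + rule.delta


@dataclass(frozen=True)
class MetaboliteRecord:
    """One reference metabolite: name, formula, and human-presence flag."""

    name: str
    formula: str
    human: bool = True

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass
class AnnotationCandidate:
    """One (metabolite, adduct) explanation of an observed ion."""

    metabolite: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float
    isotope_ok: bool | None = None


def annotate_ion(
    observed_mz: float,
    polarity: str,
    db: list[MetaboliteRecord],
    tolerance_ppm: float = 5.0,
) -> list[AnnotationCandidate]:
    """All database explanations of an observed ion within a ppm tolerance.

    Every polarity-eligible adduct of every human-flagged metabolite is
    tried; candidates with ``|ppm error| <= tolerance_ppm`` are returned
    sorted by absolute ppm error, ties broken by the adduct priority order.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    hits: list[AnnotationCandidate] = []
    for rec in db:
        if not rec.human:
            continue
        mass = rec.mass
        for rule in ADDUCTS.values():
            if rule.polarity != polarity:
                continue
            theo = mass + rule.delta
            ppm = (observed_mz - theo) / theo * 1e6
            if abs(ppm) <= tolerance_ppm:
                hits.append(AnnotationCandidate(rec.name, rec.formula, rule.label, theo, ppm))
    hits.sort(key=lambda c: (abs(c.ppm_error), _ADDUCT_PRIORITY[c.adduct]))
    return hits


# Natural isotope abundance ratios entering the first-order M+1 estimate:
# 13C/12C, 2H/1H, 15N/14N.
_C13_RATIO = 0.0107 / 0.9893
_H2_RATIO = 0.000115
_N15_RATIO = 0.00364


def expected_m1_ratio(formula: str | dict[str, int]) -> float:
    """First-order expected (M+1)/M0 intensity ratio for a neutral formula."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return (counts.get("C", 0) * _C13_RATIO
            + counts.get("H", 0) * _H2_RATIO
            + counts.get("N", 0) * _N15_RATIO)


def isotope_check(
    candidate: AnnotationCandidate,
    observed_m1_over_m0: float,
    rel_tolerance: float = 0.3,
) -> tuple[bool, float]:
    """Compare an observed M+1/M0 ratio against the formula's expectation.

    Returns ``(passed, expected_ratio)``; the candidate's ``isotope_ok`` flag
    is updated in place.  Passing requires
    ``|observed - expected| <= rel_tolerance * expected`` (a zero-C/N formula
    with expected ratio ~0 passes only a near-zero observation).
    """
    if observed_m1_over_m0 < 0:
        raise ValueError("observed isotope ratio must be >= 0")
    if not candidate.formula:
        raise ValueError("candidate has no formula for an isotope check")
    expected = expected_m1_ratio(candidate.formula)
    passed = abs(observed_m1_over_m0 - expected) <= rel_tolerance * expected
    candidate.isotope_ok = bool(passed)
    return bool(passed), expected


def load_metabolite_db(path: str | Path | None = None) -> list[MetaboliteRecord]:
    """Load a metabolite reference table from TSV (name, formula, human).

    With no path, the small curated table shipped with the package is used.
    """
    if path is None:
        source = resources.files("metafinger").joinpath("data/metabolites.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    if "human" not in table.columns:
        table["human"] = True
    return [
        MetaboliteRecord(str(name), str(formula), bool(human))
        for name, formula, human in zip(table["name"], table["formula"], table["human"])
    ]
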