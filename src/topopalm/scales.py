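"""Amino-acid property scales and window-level numeric primitives.

Every numeric descriptor used elsewhere in the package — hydropathy means,
average peptide mass, formal net charge, aliphatic index, polarity and
transmembrane tendency — is computed from the tables in this module.  The
tables are shipped as plain tab-separated data files (``topopalm/data``)
so that users can swap in alternative scales without touching code.

Conventions
-----------
* Hydropathy is the Kyte–Doolittle scale (positive = hydrophobic).
* Polarity is the Zimmerman polarity scale; transmembrane tendency is the
  Zhao–London scale.
* Masses are AVERAGE residue masses in daltons; a peptide mass is the sum
  of its residue masses plus one water (18.01528 Da).  Average rather than
  monoisotopic masses are used because the detectability window they feed
  is a coarse heuristic, for which average masses are conventional.
* Formal side-chain charge at physiological pH: K/R = +1, D/E = −1,
  histidine = 0 (configurable by editing the charge table).

Sequences containing non-standard letters (X, B, Z, U, ...) yield
``math.nan`` from the mean-type functions rather than a fabricated value;
callers treat NaN as a missing-value flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Mapping

__all__ = [
    "STANDARD_RESIDUES",
    "WATER_MASS",
    "ScaleTable",
    "load_scale",
    "kyte_doolittle",
    "polarity_scale",
    "tm_tendency_scale",
    "residue_masses",
    "charge_scale",
    "mean_scale",
    "peptide_mass",
    "net_charge",
    "aliphatic_index",
    "kd_mean",
    "polarity_mean",
    "tm_tendency_mean",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average mass of one water molecule in daltons, added once per peptide.
WATER_MASS = 18.01528


@dataclass(frozen=True)
class ScaleTable:
    """A named residue → value lookup covering the 20 standard residues."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        covered = set(self.values)
        if covered != STANDARD_RESIDUES:
            missing = sorted(STANDARD_RESIDUES - covered)
            extra = sorted(covered - STANDARD_RESIDUES)
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing {missing}, unexpected {extra})"
            )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def _read_table(filename: str, name: str) -> ScaleTable:
    values: Dict[str, float] = {}
    text = resources.files("topopalm.data").joinpath(filename).read_text()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        residue, value = line.split("\t")
        values[residue] = float(value)
    return ScaleTable(name=name, values=values)


_SCALE_FILES = {
    "kyte_doolittle": "kyte_doolittle.tsv",
    "polarity": "zimmerman_polarity.tsv",
    "tm_tendency": "tm_tendency.tsv",
    "residue_mass": "residue_mass_avg.tsv",
    "charge": "side_chain_charge.tsv",
}

_CACHE: Dict[str, ScaleTable] = {}


def load_scale(name: str) -> ScaleTable:
    """Load one of the packaged scale tables by short name."""
    if name not in _SCALE_FILES:
        raise KeyError(f"unknown scale {name!r}; choose from {sorted(_SCALE_FILES)}")
    if name not in _CACHE:
        _CACHE[name] = _read_table(_SCALE_FILES[name], name)
    return _CACHE[name]


def kyte_doolittle() -> ScaleTable:
    return load_scale("kyte_doolittle")


def polarity_scale() -> ScaleTable:
    return load_scale("polarity")


def tm_tendency_scale() -> ScaleTable:
    return load_scale("tm_tendency")


def residue_masses() -> ScaleTable:
    return load_scale("residue_mass")


def charge_scale() -> ScaleTable:
    return load_scale("charge")


def mean_scale(seq: str, scale: ScaleTable) -> float:
    """Arithmetic mean of per-residue scale values over ``seq``.

    Returns NaN (missing-value flag) when the sequence contains a letter
    outside the 20-residue alphabet.  Raises on an empty sequence: a mean
    over nothing is undefined and always indicates a caller bug here.
    """
    if not seq:
        raise ValueError("mean_scale: empty sequence")
    total = 0.0
    for residue in seq:
        value = scale.values.get(residue)
        if value is None:
            return math.nan
        total += value
    return total / len(seq)


def peptide_mass(seq: str) -> float:
    """Average molecular mass of a peptide in daltons (residues + water)."""
    if not seq:
        raise ValueError("peptide_mass: empty sequence")
    masses = residue_masses()
    total = WATER_MASS
    for residue in seq:
        value = masses.values.get(residue)
        if value is None:
            raise ValueError(f"peptide_mass: non-standard residue {residue!r}")
        total += value
    return total


def net_charge(seq: str) -> float:
    """Formal net side-chain charge: +1 per K/R, −1 per D/E, 0 otherwise.

    An empty sequence carries zero charge (a truncated window at a protein
    terminus is a legitimate input).  Returns NaN for non-standard letters.
    """
    table = charge_scale()
    total = 0.0
    for residue in seq:
        value = table.values.get(residue)
        if value is None:
            return math.nan
        total += value
    return total


def aliphatic_index(seq: str) -> float:
    """Ikai aliphatic index from mole-percent composition.

    AI = X(Ala) + 2.9·X(Val) + 3.9·(X(Ile) + X(Leu)) where X is the
    mole percentage of the residue in ``seq``.
    """
    if not seq:
        raise ValueError("aliphatic_index: empty sequence")
    if any(residue not in STANDARD_RESIDUES for residue in seq):
        return math.nan
    n = len(seq)
    x_ala = 100.0 * seq.count("A") / n
    x_val = 100.0 * seq.count("V") / n
    x_il = 100.0 * (seq.count("I") + seq.count("L")) / n
    return x_ala + 2.9 * x_val + 3.9 * x_il


def kd_mean(seq: str) -> float:
    """Mean Kyte–Doolittle hydropathy of ``seq``."""
    return mean_scale(seq, kyte_doolittle())


def polarity_mean(seq: str) -> float:
    """Mean Zimmerman polarity of ``seq``."""
    return mean_scale(seq, polarity_scale())


def tm_tendency_mean(seq: str) -> float:
    """Mean Zhao–London transmembrane tendency of ``seq``."""
    return mean_scale(seq, tm_tendency_scale())
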