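"""In-silico trypsinization and peptide-level detectability analysis.

Bottom-up proteomics sees a protein only through its tryptic peptides, and
a peptide is only identifiable by LC-MS when its mass and hydrophobicity
fall in a fairly narrow range.  This module quantifies that bias for
cysteine-containing peptides of transmembrane proteins: digest every
protein, compute each Cys peptide's average mass and mean Kyte–Doolittle
hydropathy, classify it against a "detectability box" (700–3000 Da and
mean hydropathy −2 to +1, bounds inclusive), and tabulate the detectable
fraction by group — e.g. peptides carrying a reported S-palmitoyl site
versus peptides whose Cys lies within 20 residues of a transmembrane
segment (membrane-proximal, the presumed S-palmitoyl hot spots).

Digestion is complete (no missed cleavages by default): cleavage occurs
on the C-terminal side of every Lys or Arg except when the next residue
is Pro.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .scales import kd_mean, peptide_mass
from .topology import ProteinRecord, SegmentKind, TopologySegment

__all__ = [
    "Peptide",
    "PeptideRecord",
    "digest_trypsin",
    "detectable",
    "membrane_proximal",
    "digest_proteome",
    "summarize_detectability",
    "MASS_RANGE",
    "KD_RANGE",
]

#: Inclusive detectability box for bottom-up proteomics.
MASS_RANGE = (700.0, 3000.0)
KD_RANGE = (-2.0, 1.0)


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide in protein coordinates (1-based inclusive)."""

    sequence: str
    start: int
    end: int


@dataclass
class PeptideRecord:
    """A Cys-containing tryptic peptide with its biophysical annotations."""

    accession: str
    start: int
    end: int
    sequence: str
    mass: float
    mean_kd: float
    cys_positions: List[int] = field(default_factory=list)
    detectable: bool = False
    membrane_proximal: bool = False
    reported_palmitoyl: bool = False


def digest_trypsin(sequence: str, missed_cleavages: int = 0) -> List[Peptide]:
    """Cleave after every K/R not followed by P; return ordered peptides.

    Peptide coordinates are kept in protein coordinates so that site
    tables keyed by (accession, position) join without conversion.
    ``missed_cleavages`` > 0 additionally returns peptides spanning up to
    that many internal cleavage sites (appended after the complete
    digest, ordered by start then length).
    """
    if not sequence:
        raise ValueError("digest_trypsin: empty sequence")
    cut_after = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + [i + 1 for i in cut_after] + [len(sequence)]
    core = [
        Peptide(sequence[a:b], a + 1, b)
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    if missed_cleavages <= 0:
        return core
    extra: List[Peptide] = []
    for k in range(1, missed_cleavages + 1):
        for i in range(len(core) - k):
            a = core[i].start
            b = core[i + k].end
            extra.append(Peptide(sequence[a - 1 : b], a, b))
    return core + sorted(extra, key=lambda p: (p.start, p.end))


def detectable(mass: float, mean_kd: float) -> bool:
    """True iff (mass, mean hydropathy) falls inside the detectability box."""
    if math.isnan(mass) or math.isnan(mean_kd):
        return False
    return (
        MASS_RANGE[0] <= mass <= MASS_RANGE[1]
        and KD_RANGE[0] <= mean_kd <= KD_RANGE[1]
    )


def membrane_proximal(
    cys_position: int,
    segments: Sequence[TopologySegment],
    cutoff: int = 20,
) -> bool:
    """True iff the Cys lies within ``cutoff`` residues of a TM segment.

    Distance is counted in residues from the nearest TM boundary: a Cys
    inside a TM has distance 0 and a Cys at boundary+1 has distance 1.
    A protein without any TM segment yields False with a warning.
    """
    tms = [s for s in segments if s.kind is SegmentKind.TRANSMEMBRANE]
    if not tms:
        warnings.warn(
            "membrane_proximal called on a protein with no TM segment",
            stacklevel=2,
        )
        return False
    for seg in tms:
        if seg.contains(cys_position):
            return True
        dist = (
            seg.start - cys_position
            if cys_position < seg.start
            else cys_position - seg.end
        )
        if dist <= cutoff:
            return True
    return False


def digest_proteome(
    proteins: Iterable[ProteinRecord],
    known_sites: Set[Tuple[str, int]] | None = None,
    cutoff: int = 20,
    missed_cleavages: int = 0,
) -> pd.DataFrame:
    """Digest every protein and annotate its Cys-containing peptides.

    ``known_sites`` is an optional set of (accession, position) pairs of
    reported S-palmitoyl sites; a peptide is flagged ``reported_palmitoyl``
    when any of its Cys positions matches.  Peptides containing residues
    outside the standard alphabet get NaN mass/hydropathy and are never
    detectable.  Returns one row per Cys-containing peptide.
    """
    known_sites = known_sites or set()
    rows = []
    for protein in proteins:
        for pep in digest_trypsin(protein.sequence, missed_cleavages):
            cys = [
                pep.start + i for i, c in enumerate(pep.sequence) if c == "C"
            ]
            if not cys:
                continue
            try:
                mass = peptide_mass(pep.sequence)
            except ValueError:
                mass = math.nan
            mkd = kd_mean(pep.sequence)
            rec = PeptideRecord(
                accession=protein.accession,
                start=pep.start,
                end=pep.end,
                sequence=pep.sequence,
                mass=mass,
                mean_kd=mkd,
                cys_positions=cys,
                detectable=detectable(mass, mkd),
                membrane_proximal=any(
                    membrane_proximal(p, protein.segments, cutoff)
                    for p in cys
                )
                if protein.tm_segments
                else False,
                reported_palmitoyl=any(
                    (protein.accession, p) in known_sites for p in cys
                ),
            )
            rows.append(vars(rec).copy())
    frame = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "start",
            "end",
            "sequence",
            "mass",
            "mean_kd",
            "cys_positions",
            "detectable",
            "membrane_proximal",
            "reported_palmitoyl",
        ],
    )
    return frame.sort_values(["accession", "start"]).reset_index(drop=True)


def summarize_detectability(
    peptides: pd.DataFrame, grouping: str
) -> pd.DataFrame:
    """Per-group detectable counts and fractions.

    ``grouping`` is the name of a boolean peptide column, normally
    ``reported_palmitoyl`` or ``membrane_proximal``.  Returns one row per
    group value (False before True) with columns n, n_detectable and
    fraction_detectable; empty input yields an empty table.
    """
    if grouping not in ("reported_palmitoyl", "membrane_proximal"):
        raise ValueError(f"unsupported grouping {grouping!r}")
    if peptides.empty:
        return pd.DataFrame(
            columns=[grouping, "n", "n_detectable", "fraction_detectable"]
        )
    grouped = (
        peptides.groupby(grouping, sort=True)["detectable"]
        .agg(n="size", n_detectable="sum")
        .reset_index()
    )
    grouped["fraction_detectable"] = grouped["n_detectable"] / grouped["n"]
    return grouped
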