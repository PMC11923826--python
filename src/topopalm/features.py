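"""Per-cysteine topology and window features for transmembrane proteins.

Every inference-eligible cysteine of an annotated transmembrane protein
is described by 28 features drawn from three families:

* where the Cys sits in the protein's topology — containing segment kind,
  TM orientation, segment length, absolute and relative position within
  the segment and the protein, and the distance to the
  cytoplasmic–membrane interface (the single most informative quantity:
  experimentally characterized S-palmitoyl sites cluster within a few
  residues of that interface);
* what flanks it — two 5-residue windows on the N- and C-terminal sides
  (the central Cys in neither), scored for hydropathy, formal charge,
  polarity, aliphatic index and transmembrane tendency per side, plus
  sum/gradient combinations (a positive hydropathy gradient means
  hydrophobicity increasing toward the C-terminus);
* local cysteine clustering — a window Cys score awarding
  distance-decaying points for neighbouring cysteines, plus basic-residue
  and asparagine counts across both windows.

Featurization is a pure function of the :class:`~topopalm.topology.ProteinRecord`:
no randomness anywhere, identical inputs give bit-identical rows.

Eligibility.  A Cys yields a feature row only when its protein has at
least one TM segment, the Cys is covered by an annotated segment that is
neither a signal peptide nor an intramembrane stretch, its TM (when it
sits in one) has a known orientation, and its windows contain only
standard residues.  Everything else is excluded with a logged reason —
exclusions are data, not failures.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from . import scales
from .topology import (
    ProteinRecord,
    SegmentKind,
    TMOrientation,
    TopologySegment,
    segment_covering,
)

__all__ = [
    "FEATURE_NAMES",
    "TOPOLOGY_KIND_CODES",
    "ORIENTATION_CODES",
    "WINDOW_SIZE",
    "CYS_SCORE_WEIGHTS",
    "feature_registry_hash",
    "locate_topology",
    "interface_distance",
    "extract_windows",
    "window_cys_score",
    "hydropathy_block",
    "property_block",
    "featurize_site",
    "featurize_proteome",
    "FeaturizeResult",
]

WINDOW_SIZE = 5

#: Points for a window Cys at offset d = 1..5 from the central residue.
#: Linear decay: adjacent Cys are worth the most, per the cooperativity
#: rationale; the vector is configuration, not hard-coded arithmetic.
CYS_SCORE_WEIGHTS = tuple((6 - d) / 5 for d in range(1, WINDOW_SIZE + 1))

#: Fixed category → integer registries so models serialize portably.
TOPOLOGY_KIND_CODES = {
    SegmentKind.CYTOPLASMIC: 0,
    SegmentKind.EXTRACELLULAR: 1,
    SegmentKind.TRANSMEMBRANE: 2,
}
ORIENTATION_CODES = {
    None: 0,  # site not inside a TM segment
    TMOrientation.INWARD: 1,
    TMOrientation.OUTWARD: 2,
}

FEATURE_NAMES: Tuple[str, ...] = (
    "topology_kind",
    "tm_orientation",
    "segment_length",
    "dist_segment_start",
    "dist_segment_end",
    "rel_position_in_segment",
    "interface_distance",
    "protein_length",
    "dist_N_term",
    "dist_C_term",
    "rel_position_in_protein",
    "window_cys_score",
    "kd_mean_N",
    "kd_mean_C",
    "kd_sum",
    "kd_gradient",
    "charge_N",
    "charge_C",
    "charge_gradient",
    "polarity_N",
    "polarity_C",
    "aliphatic_N",
    "aliphatic_C",
    "tmtend_N",
    "tmtend_C",
    "window_basic_count",
    "window_asn_count",
    "tm_segment_count",
)

assert len(FEATURE_NAMES) == 28


def feature_registry_hash(names: Sequence[str] = FEATURE_NAMES) -> str:
    """Stable hash of the ordered feature roster; models refuse mismatches."""
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


class SiteIneligible(Exception):
    """Raised by featurize_site when the Cys cannot receive an inference."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def locate_topology(
    position: int, segments: Sequence[TopologySegment]
) -> Tuple[TopologySegment, int, int, float]:
    """Containing segment plus (dist_start, dist_end, relative position).

    Relative position is 0 at the segment's N-terminal end and 1 at its
    C-terminal end; a degenerate length-1 segment maps to 0.
    """
    seg = segment_covering(segments, position)
    if seg is None:
        raise SiteIneligible("position falls in an annotation gap")
    dist_start = position - seg.start
    dist_end = seg.end - position
    rel = 0.0 if seg.length == 1 else dist_start / (seg.length - 1)
    return seg, dist_start, dist_end, rel


def interface_distance(
    position: int,
    segment: TopologySegment,
    protein: ProteinRecord,
) -> int:
    """Residue distance from the Cys to the cytoplasmic–membrane interface.

    Inside a TM the relevant interface is the cytoplasmic end of the
    helix: ``end − position`` for inward TMs (C-terminal side faces the
    cytoplasm) and ``position − start`` for outward ones.  In a soluble
    segment the distance runs to the nearest segment edge that abuts a TM
    — ``position − start`` for a tail (TM precedes), ``end − position``
    for a head (TM follows), and the minimum of the two for an internal
    loop.  A Cys in the first residue after a TM therefore scores 0.
    """
    segs = protein.segments
    if segment.kind is SegmentKind.TRANSMEMBRANE:
        if segment.orientation is TMOrientation.INWARD:
            return segment.end - position
        if segment.orientation is TMOrientation.OUTWARD:
            return position - segment.start
        raise SiteIneligible("transmembrane orientation unknown")
    tm_spans = [
        (s.start, s.end) for s in segs if s.kind is SegmentKind.TRANSMEMBRANE
    ]
    if not tm_spans:
        raise SiteIneligible("protein has no transmembrane segment")
    candidates: List[int] = []
    n_adjacent = any(end == segment.start - 1 for _, end in tm_spans)
    c_adjacent = any(start == segment.end + 1 for start, _ in tm_spans)
    if n_adjacent:
        candidates.append(position - segment.start)
    if c_adjacent:
        candidates.append(segment.end - position)
    if candidates:
        return min(candidates)
    # Annotation gap between this segment and the nearest TM: fall back to
    # the residue-gap count to the nearest TM boundary.
    return min(
        (start - position - 1) if position < start else (position - end - 1)
        for start, end in tm_spans
    )


def extract_windows(
    sequence: str, position: int, k: int = WINDOW_SIZE
) -> Tuple[str, str]:
    """Up to ``k`` residues flanking ``position`` on each side.

    Windows are truncated at the protein termini and never include the
    central residue.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence")
    n_window = sequence[max(0, position - 1 - k) : position - 1]
    c_window = sequence[position : position + k]
    return n_window, c_window


def window_cys_score(
    n_window: str,
    c_window: str,
    weights: Sequence[float] = CYS_SCORE_WEIGHTS,
) -> float:
    """Distance-weighted tally of cysteines in the flanking windows.

    A Cys at offset d (1 = adjacent) from the central residue contributes
    ``weights[d-1]``; contributions from both windows add.  Captures the
    cooperative clustering of S-palmitoyl sites.
    """
    score = 0.0
    for d, residue in enumerate(reversed(n_window), start=1):
        if residue == "C":
            score += weights[d - 1]
    for d, residue in enumerate(c_window, start=1):
        if residue == "C":
            score += weights[d - 1]
    return score


def hydropathy_block(
    n_window: str, c_window: str
) -> Tuple[float, float, float, float]:
    """(kd_mean_N, kd_mean_C, kd_sum, kd_gradient) for the two windows.

    gradient = mean_C − mean_N, so positive values mean hydrophobicity
    rising toward the C-terminus; sum = mean_C + mean_N.  An empty window
    (site at a terminus) contributes NaN, which propagates.
    """
    mean_n = scales.kd_mean(n_window) if n_window else math.nan
    mean_c = scales.kd_mean(c_window) if c_window else math.nan
    return mean_n, mean_c, mean_c + mean_n, mean_c - mean_n


def property_block(n_window: str, c_window: str) -> dict:
    """Charge, polarity, aliphatic index, TM tendency and residue counts."""
    charge_n = scales.net_charge(n_window)
    charge_c = scales.net_charge(c_window)
    both = n_window + c_window
    return {
        "charge_N": charge_n,
        "charge_C": charge_c,
        "charge_gradient": charge_c - charge_n,
        "polarity_N": scales.polarity_mean(n_window) if n_window else math.nan,
        "polarity_C": scales.polarity_mean(c_window) if c_window else math.nan,
        "aliphatic_N": scales.aliphatic_index(n_window) if n_window else math.nan,
        "aliphatic_C": scales.aliphatic_index(c_window) if c_window else math.nan,
        "tmtend_N": scales.tm_tendency_mean(n_window) if n_window else math.nan,
        "tmtend_C": scales.tm_tendency_mean(c_window) if c_window else math.nan,
        "window_basic_count": both.count("K") + both.count("R"),
        "window_asn_count": both.count("N"),
    }


def featurize_site(protein: ProteinRecord, position: int) -> dict:
    """Compute the 28-feature row for one residue position.

    Raises :class:`SiteIneligible` with a reason when no inference can be
    offered for this position (signal peptide, intramembrane stretch,
    annotation gap, unknown TM orientation, non-standard window residue,
    missing TM annotation).
    """
    if not protein.tm_segments:
        raise SiteIneligible("protein has no transmembrane segment")
    seg, dist_start, dist_end, rel_seg = locate_topology(
        position, protein.segments
    )
    if seg.kind is SegmentKind.SIGNAL:
        raise SiteIneligible("site on a signal peptide")
    if seg.kind is SegmentKind.INTRAMEMBRANE:
        raise SiteIneligible("site in an intramembrane segment")
    iface = interface_distance(position, seg, protein)
    n_window, c_window = extract_windows(protein.sequence, position)
    if not n_window and not c_window:
        raise SiteIneligible("no flanking residues")
    if any(
        residue not in scales.STANDARD_RESIDUES
        for residue in n_window + c_window + protein.sequence[position - 1]
    ):
        raise SiteIneligible("non-standard residue in site window")
    length = len(protein.sequence)
    kd_n, kd_c, kd_sum, kd_gradient = hydropathy_block(n_window, c_window)
    orientation = (
        seg.orientation if seg.kind is SegmentKind.TRANSMEMBRANE else None
    )
    row = {
        "topology_kind": TOPOLOGY_KIND_CODES[seg.kind],
        "tm_orientation": ORIENTATION_CODES[orientation],
        "segment_length": seg.length,
        "dist_segment_start": dist_start,
        "dist_segment_end": dist_end,
        "rel_position_in_segment": rel_seg,
        "interface_distance": iface,
        "protein_length": length,
        "dist_N_term": position - 1,
        "dist_C_term": length - position,
        "rel_position_in_protein": 0.0
        if length == 1
        else (position - 1) / (length - 1),
        "window_cys_score": window_cys_score(n_window, c_window),
        "kd_mean_N": kd_n,
        "kd_mean_C": kd_c,
        "kd_sum": kd_sum,
        "kd_gradient": kd_gradient,
        **property_block(n_window, c_window),
        "tm_segment_count": len(protein.tm_segments),
    }
    return {name: row[name] for name in FEATURE_NAMES}


@dataclass
class FeaturizeResult:
    features: pd.DataFrame  # accession, position + FEATURE_NAMES
    excluded: pd.DataFrame  # accession, position, reason


def featurize_proteome(proteins: Iterable[ProteinRecord]) -> FeaturizeResult:
    """One feature row per inference-eligible Cys, in (accession, position)
    order; ineligible cysteines land in ``excluded`` with their reason."""
    rows: List[dict] = []
    excluded: List[dict] = []
    for protein in sorted(proteins, key=lambda p: p.accession):
        for position in protein.cys_positions():
            try:
                feats = featurize_site(protein, position)
            except SiteIneligible as err:
                excluded.append(
                    {
                        "accession": protein.accession,
                        "position": position,
                        "reason": err.reason,
                    }
                )
                continue
            rows.append(
                {"accession": protein.accession, "position": position, **feats}
            )
    features = pd.DataFrame(
        rows, columns=["accession", "position", *FEATURE_NAMES]
    )
    if not features.empty:
        features = features.sort_values(["accession", "position"]).reset_index(
            drop=True
        )
    excluded_frame = pd.DataFrame(
        excluded, columns=["accession", "position", "reason"]
    )
    return FeaturizeResult(features=features, excluded=excluded_frame)
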