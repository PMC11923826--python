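"""Protein topology records and UniProt-style annotation I/O.

A transmembrane protein is represented as a :class:`ProteinRecord`: an
accession, the amino-acid sequence and an ordered, non-overlapping list of
:class:`TopologySegment` spans.  Coordinates are 1-based inclusive
throughout the package (the UniProt convention); this is the only place
that convention is documented — all downstream arithmetic assumes it.

Annotations are consumed in the UniProt tab-separated export dialect,
where each feature column holds a flat string such as::

    TRANSMEM 51..71; /note="Helical"; TRANSMEM 95..115; /note="Helical"
    TOPO_DOM 1..50; /note="Extracellular"; TOPO_DOM 72..94; /note="Cytoplasmic"

Segment classes are canonicalized to five kinds: raw labels "Lumenal",
"Stromal" and "Extracellular" all become ``EXTRACELLULAR`` so that
categorical variables align across annotation dialects; unrecognized
labels raise rather than being silently coerced.

Transmembrane orientation follows segment adjacency: a TM whose
immediately preceding domain (the segment ending at TM start − 1) is
extracellular runs inward (C-terminal side cytoplasmic); a cytoplasmic
predecessor means outward.  A TM with no predecessor, or a predecessor
of any other kind, is left ``UNKNOWN`` — the convention deliberately
refuses to guess for N-terminal TMs.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SegmentKind",
    "TMOrientation",
    "TopologySegment",
    "ProteinRecord",
    "TopologyError",
    "parse_uniprot_feature_string",
    "canonicalize_kind",
    "assign_tm_orientation",
    "read_proteome",
    "write_proteome",
    "segment_covering",
]


class SegmentKind(enum.Enum):
    CYTOPLASMIC = "Cytoplasmic"
    EXTRACELLULAR = "Extracellular"
    TRANSMEMBRANE = "Transmembrane"
    INTRAMEMBRANE = "Intramembrane"
    SIGNAL = "Signal"


class TMOrientation(enum.Enum):
    INWARD = "inward"
    OUTWARD = "outward"
    UNKNOWN = "unknown"


class TopologyError(ValueError):
    """Malformed topology annotation (bad span, unknown label, overlap...)."""


@dataclass(frozen=True)
class TopologySegment:
    """One annotated span; ``start``/``end`` are 1-based inclusive."""

    kind: SegmentKind
    start: int
    end: int
    orientation: TMOrientation = TMOrientation.UNKNOWN
    raw_label: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise TopologyError(
                f"invalid span {self.start}..{self.end} for {self.kind.value}"
            )
        if (
            self.orientation is not TMOrientation.UNKNOWN
            and self.kind is not SegmentKind.TRANSMEMBRANE
        ):
            raise TopologyError(
                "orientation is meaningful only for transmembrane segments"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    segments: Tuple[TopologySegment, ...]
    species: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        n = len(self.sequence)
        prev_end = 0
        for seg in self.segments:
            if seg.start <= prev_end:
                raise TopologyError(
                    f"{self.accession}: segments must be sorted and "
                    f"non-overlapping (span {seg.start}..{seg.end})"
                )
            if seg.end > n:
                raise TopologyError(
                    f"{self.accession}: segment {seg.start}..{seg.end} exceeds "
                    f"sequence length {n}"
                )
            prev_end = seg.end

    @property
    def tm_segments(self) -> Tuple[TopologySegment, ...]:
        return tuple(
            s for s in self.segments if s.kind is SegmentKind.TRANSMEMBRANE
        )

    @property
    def has_nonstandard_residues(self) -> bool:
        from .scales import STANDARD_RESIDUES

        return any(c not in STANDARD_RESIDUES for c in self.sequence)

    def cys_positions(self) -> List[int]:
        """1-based positions of every cysteine in the sequence."""
        return [i + 1 for i, c in enumerate(self.sequence) if c == "C"]


# Raw annotation labels → canonical segment kind.  "Lumenal" and "Stromal"
# are folded into Extracellular so categorical levels align.
_KIND_ALIASES = {
    "cytoplasmic": SegmentKind.CYTOPLASMIC,
    "extracellular": SegmentKind.EXTRACELLULAR,
    "lumenal": SegmentKind.EXTRACELLULAR,
    "stromal": SegmentKind.EXTRACELLULAR,
    "helical": SegmentKind.TRANSMEMBRANE,
    "transmem": SegmentKind.TRANSMEMBRANE,
    "transmembrane": SegmentKind.TRANSMEMBRANE,
    "intramem": SegmentKind.INTRAMEMBRANE,
    "intramembrane": SegmentKind.INTRAMEMBRANE,
    "signal": SegmentKind.SIGNAL,
    "signal peptide": SegmentKind.SIGNAL,
}


def canonicalize_kind(raw_label: str) -> SegmentKind:
    """Map a raw annotation label onto a canonical segment kind.

    Unknown labels raise :class:`TopologyError` — silent coercion of an
    unrecognized topological class would corrupt every downstream
    categorical feature.
    """
    key = raw_label.strip().strip('"').lower()
    try:
        return _KIND_ALIASES[key]
    except KeyError:
        raise TopologyError(f"unrecognized topology label {raw_label!r}") from None


_FEATURE_RE = re.compile(
    r"(?P<key>TRANSMEM|TOPO_DOM|INTRAMEM|SIGNAL)\s+"
    r"(?P<start>\?|[<>]?\d+)\.{2,3}(?P<end>\?|[<>]?\d+)"
    r"(?P<rest>(?:;\s*/[a-z_]+=\"[^\"]*\")*)"
)
_NOTE_RE = re.compile(r'/note="([^"]*)"')

_KEY_DEFAULT_LABEL = {
    "TRANSMEM": "Helical",
    "INTRAMEM": "Intramembrane",
    "SIGNAL": "Signal",
}


def parse_uniprot_feature_string(
    text: str, accession: str = "?"
) -> List[TopologySegment]:
    """Parse a UniProt flat feature field into topology segments.

    Accepts both ``51..71`` and ``51...71`` span dialects.  TOPO_DOM
    entries take their kind from the ``/note`` label; TRANSMEM, INTRAMEM
    and SIGNAL entries are mapped directly.  Segments are returned in
    ascending start order with the raw note label preserved.
    """
    if text is None or not str(text).strip() or str(text).strip().lower() == "nan":
        return []
    text = str(text)
    segments: List[TopologySegment] = []
    matched_spans: List[Tuple[int, int]] = []
    for m in _FEATURE_RE.finditer(text):
        key = m.group("key")
        raw_start, raw_end = m.group("start"), m.group("end")
        if "?" in (raw_start, raw_end):
            # Unknown endpoint: the span is unusable for positional features.
            raise TopologyError(
                f"{accession}: unresolved endpoint in span "
                f"{raw_start}..{raw_end} ({key})"
            )
        start = int(raw_start.lstrip("<>"))
        end = int(raw_end.lstrip("<>"))
        if end < start:
            raise TopologyError(
                f"{accession}: inverted span {start}..{end} ({key})"
            )
        note = _NOTE_RE.search(m.group("rest") or "")
        if key == "TOPO_DOM":
            if note is None:
                raise TopologyError(
                    f"{accession}: TOPO_DOM {start}..{end} lacks a /note label"
                )
            label = note.group(1)
            kind = canonicalize_kind(label)
        else:
            label = note.group(1) if note else _KEY_DEFAULT_LABEL[key]
            kind = canonicalize_kind(_KEY_DEFAULT_LABEL[key])
        segments.append(
            TopologySegment(kind=kind, start=start, end=end, raw_label=label)
        )
        matched_spans.append(m.span())
    # Anything between matches that still looks like a feature token means the
    # field is malformed rather than merely empty.
    leftover = text
    for a, b in sorted(matched_spans, reverse=True):
        leftover = leftover[:a] + leftover[b:]
    stray = re.search(r"(TRANSMEM|TOPO_DOM|INTRAMEM|SIGNAL)\s+\S+", leftover)
    if stray:
        raise TopologyError(
            f"{accession}: malformed feature token {stray.group(0)!r}"
        )
    segments.sort(key=lambda s: s.start)
    return segments


def assign_tm_orientation(
    segments: Sequence[TopologySegment],
) -> List[TopologySegment]:
    """Set inward/outward orientation on each transmembrane segment.

    The predecessor of a TM is the segment whose ``end`` equals the TM's
    ``start`` − 1.  Extracellular predecessor → inward; cytoplasmic →
    outward; no predecessor or any other kind → unknown.  Orientation is
    a pure function of segment adjacency.
    """
    ordered = sorted(segments, key=lambda s: s.start)
    by_end = {s.end: s for s in ordered}
    out: List[TopologySegment] = []
    for seg in ordered:
        if seg.kind is not SegmentKind.TRANSMEMBRANE:
            out.append(seg)
            continue
        pred = by_end.get(seg.start - 1)
        if pred is None:
            orientation = TMOrientation.UNKNOWN
        elif pred.kind is SegmentKind.EXTRACELLULAR:
            orientation = TMOrientation.INWARD
        elif pred.kind is SegmentKind.CYTOPLASMIC:
            orientation = TMOrientation.OUTWARD
        else:
            orientation = TMOrientation.UNKNOWN
        out.append(replace(seg, orientation=orientation))
    return out


def segment_covering(
    segments: Sequence[TopologySegment], position: int
) -> Optional[TopologySegment]:
    """Return the segment containing ``position`` or None (annotation gap)."""
    for seg in segments:
        if seg.contains(position):
            return seg
    return None


# ---------------------------------------------------------------------------
# Proteome I/O: FASTA + UniProt-style tab-separated annotation table
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "Entry",
    "Transmembrane",
    "Topological domain",
    "Intramembrane",
    "Signal peptide",
)


@dataclass
class ProteomeReadResult:
    records: List[ProteinRecord]
    excluded: List[Tuple[str, str]] = field(default_factory=list)  # (acc, reason)


def read_proteome(
    fasta_path: str | Path, annotation_path: str | Path
) -> ProteomeReadResult:
    """Join a FASTA file with a UniProt-style annotation table on accession.

    Proteins lacking a sequence, lacking any annotation row, or whose
    annotation is malformed/out-of-range are collected in ``excluded``
    with a reason; they are data, not failures.  A duplicated accession
    in either input is an error.
    """
    sequences: dict[str, str] = {}
    species: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        acc = _fasta_accession(rec)
        if acc in sequences:
            raise TopologyError(f"duplicate accession {acc!r} in FASTA")
        sequences[acc] = str(rec.seq).upper()
        m = re.search(r"OS=([^=]+?)(?:\s+\w\w=|$)", rec.description)
        species[acc] = m.group(1).strip() if m else ""

    table = pd.read_csv(annotation_path, sep="\t", dtype=str).fillna("")
    if "Entry" not in table.columns:
        raise TopologyError("annotation table lacks an 'Entry' column")
    if table["Entry"].duplicated().any():
        dup = table.loc[table["Entry"].duplicated(), "Entry"].iloc[0]
        raise TopologyError(f"duplicate accession {dup!r} in annotation table")

    annotated = set(table["Entry"])
    result = ProteomeReadResult(records=[])
    for acc in sequences:
        if acc not in annotated:
            result.excluded.append((acc, "no annotation row"))
    for _, row in table.iterrows():
        acc = row["Entry"]
        seq = sequences.get(acc) or str(row.get("Sequence", "")).strip()
        if not seq:
            result.excluded.append((acc, "no sequence"))
            continue
        try:
            segments: List[TopologySegment] = []
            for col in ("Transmembrane", "Topological domain", "Intramembrane",
                        "Signal peptide"):
                if col in row.index:
                    segments.extend(
                        parse_uniprot_feature_string(row[col], accession=acc)
                    )
            segments = assign_tm_orientation(segments)
            record = ProteinRecord(
                accession=acc,
                sequence=seq,
                segments=tuple(segments),
                species=str(row.get("Species", species.get(acc, ""))),
            )
        except TopologyError as err:
            result.excluded.append((acc, str(err)))
            continue
        result.records.append(record)
    return result


def _fasta_accession(rec: SeqRecord) -> str:
    # sp|P12345|NAME_MOUSE → P12345; otherwise the first id token.
    parts = rec.id.split("|")
    return parts[1] if len(parts) >= 3 else parts[0]


def write_proteome(
    records: Iterable[ProteinRecord],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    """Serialize records back to FASTA + annotation table (round-trippable)."""
    records = list(records)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.accession)
        for r in records
    ]
    SeqIO.write(seq_records, str(fasta_path), "fasta")

    rows = []
    for r in records:
        cols = {c: [] for c in ("Transmembrane", "Topological domain",
                                "Intramembrane", "Signal peptide")}
        for seg in r.segments:
            if seg.kind is SegmentKind.TRANSMEMBRANE:
                cols["Transmembrane"].append(
                    f'TRANSMEM {seg.start}..{seg.end}; /note="Helical"'
                )
            elif seg.kind is SegmentKind.INTRAMEMBRANE:
                cols["Intramembrane"].append(
                    f'INTRAMEM {seg.start}..{seg.end}; /note="Intramembrane"'
                )
            elif seg.kind is SegmentKind.SIGNAL:
                cols["Signal peptide"].append(f"SIGNAL {seg.start}..{seg.end}")
            else:
                label = seg.raw_label or seg.kind.value
                cols["Topological domain"].append(
                    f'TOPO_DOM {seg.start}..{seg.end}; /note="{label}"'
                )
        rows.append(
            {
                "Entry": r.accession,
                "Species": r.species,
                **{k: "; ".join(v) for k, v in cols.items()},
            }
        )
    pd.DataFrame(rows).to_csv(annotation_path, sep="\t", index=False)
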