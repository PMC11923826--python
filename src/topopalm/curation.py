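"""Curate a labeled S-palmitoyl training set from a site-table export.

The positive class comes from a SwissPalm-style "Sites" table filtered to
high-confidence experimental evidence — technique text containing
"Point mutation" (site-directed mutagenesis) or "palmitate" (radiolabel
incorporation) — restricted to an allowed species list, optionally merged
with supplemental positive lists (e.g. database cross-references or
quantitative LC-MS studies thresholded at palmitoyl fraction > 0.25).

The negative class is inferred, never asserted: every inference-eligible
cysteine on a protein that carries at least one positive and is not
itself positive becomes a negative.  Proteins without any positive
contribute no labels at all, so unstudied proteins cannot contaminate
the negative class.

The class imbalance is reported as (positives + negatives) / positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .features import FeaturizeResult, featurize_proteome
from .topology import ProteinRecord

__all__ = [
    "DEFAULT_TECHNIQUE_TERMS",
    "DEFAULT_SPECIES_ALLOWLIST",
    "LabeledDataset",
    "read_sites_table",
    "filter_sites",
    "merge_supplements",
    "filter_palmitoyl_fraction",
    "infer_negatives",
    "class_imbalance",
    "CurationReport",
]

DEFAULT_TECHNIQUE_TERMS: Tuple[str, ...] = ("Point mutation", "palmitate")

#: The seven-species allowlist used for training-set curation; this is
#: configuration, not code — pass your own list for other corpora.
DEFAULT_SPECIES_ALLOWLIST: Tuple[str, ...] = (
    "Homo sapiens",
    "Mus musculus",
    "Rattus norvegicus",
    "Arabidopsis thaliana",
    "Saccharomyces cerevisiae",
    "Bos taurus",
    "synthetic",
)

REQUIRED_SITE_COLUMNS = ("accession", "position", "site_techniques", "species")


@dataclass
class LabeledDataset:
    """Feature rows joined with class labels and per-row provenance.

    ``table`` carries accession, position, the feature columns, ``label``
    (1 = S-palmitoyl, 0 = negative) and ``source`` (provenance of each
    positive; negatives are tagged "inferred").
    """

    table: pd.DataFrame
    feature_names: Tuple[str, ...]

    @property
    def n_positive(self) -> int:
        return int((self.table["label"] == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.table["label"] == 0).sum())

    def X(self) -> pd.DataFrame:
        return self.table[list(self.feature_names)]

    def y(self) -> pd.Series:
        return self.table["label"]


def read_sites_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    table = pd.read_csv(path, sep=sep, dtype={"accession": str})
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"sites table lacks required columns {missing}")
    return table


def filter_sites(
    site_table: pd.DataFrame,
    technique_terms: Sequence[str] = DEFAULT_TECHNIQUE_TERMS,
    species_allowlist: Sequence[str] = DEFAULT_SPECIES_ALLOWLIST,
    case_insensitive: bool = False,
) -> pd.DataFrame:
    """High-confidence positives from a SwissPalm-style sites table.

    Keeps rows whose technique text contains any of ``technique_terms``
    as a plain substring (case-sensitive by default — the filter terms
    are literal strings from the source dialect), then applies the
    species allowlist, then deduplicates on (accession, position).
    Output columns: accession, position, site_techniques, species,
    source="sites_table".
    """
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in site_table.columns]
    if missing:
        raise ValueError(f"sites table lacks required columns {missing}")
    tech = site_table["site_techniques"].astype(str)
    if case_insensitive:
        mask = tech.str.lower().apply(
            lambda t: any(term.lower() in t for term in technique_terms)
        )
    else:
        mask = tech.apply(lambda t: any(term in t for term in technique_terms))
    kept = site_table.loc[mask]
    if species_allowlist is not None:
        kept = kept.loc[kept["species"].isin(set(species_allowlist))]
    kept = (
        kept.drop_duplicates(subset=["accession", "position"])
        .assign(source="sites_table")
        .sort_values(["accession", "position"])
        .reset_index(drop=True)
    )
    kept["position"] = kept["position"].astype(int)
    return kept[["accession", "position", "site_techniques", "species", "source"]]


def _as_positive_frame(
    rows: Iterable[Tuple[str, int]], source: str
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "accession": acc,
                "position": int(pos),
                "site_techniques": "",
                "species": "",
                "source": source,
            }
            for acc, pos in rows
        ],
        columns=["accession", "position", "site_techniques", "species", "source"],
    )


def merge_supplements(
    positives: pd.DataFrame,
    uniprot_supplement: Iterable[Tuple[str, int]] = (),
    literature_supplement: Iterable[Tuple[str, int]] = (),
    proteome: Sequence[ProteinRecord] | None = None,
) -> pd.DataFrame:
    """Union curated positives with supplemental positive lists.

    Supplements can only add positives, never remove; a supplement row
    duplicating an existing positive leaves the count unchanged.  When
    ``proteome`` is given, a supplement position beyond the protein's
    length is an error naming the offending row.
    """
    frames = [
        positives,
        _as_positive_frame(uniprot_supplement, "uniprot_supplement"),
        _as_positive_frame(literature_supplement, "literature_supplement"),
    ]
    merged = pd.concat(frames, ignore_index=True)
    if proteome is not None:
        lengths = {p.accession: len(p.sequence) for p in proteome}
        for _, row in merged.iterrows():
            n = lengths.get(row["accession"])
            if n is not None and row["position"] > n:
                raise ValueError(
                    f"supplement site {row['accession']} position "
                    f"{row['position']} beyond protein length {n}"
                )
    merged = (
        merged.drop_duplicates(subset=["accession", "position"], keep="first")
        .sort_values(["accession", "position"])
        .reset_index(drop=True)
    )
    return merged


def filter_palmitoyl_fraction(
    table: pd.DataFrame, threshold: float = 0.25
) -> List[Tuple[str, int]]:
    """Sites from a quantitative (accession, position, fraction) table
    whose palmitoyl fraction strictly exceeds ``threshold``."""
    required = {"accession", "position", "fraction"}
    if not required.issubset(table.columns):
        raise ValueError(f"fraction table needs columns {sorted(required)}")
    kept = table.loc[table["fraction"] > threshold]
    return [
        (str(row["accession"]), int(row["position"]))
        for _, row in kept.iterrows()
    ]


def infer_negatives(
    positives: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    featurized: FeaturizeResult | None = None,
) -> LabeledDataset:
    """Label every eligible Cys on positive-bearing proteins.

    Eligible cysteines that match a positive row get label 1 with that
    row's provenance; the remainder become the inferred negative class.
    A positive pointing at a residue that is not a cysteine raises — in
    real data this almost always means an isoform or coordinate-version
    mismatch that must not be papered over.
    """
    from .features import FEATURE_NAMES

    if featurized is None:
        featurized = featurize_proteome(proteome)
    by_accession = {p.accession: p for p in proteome}
    positive_keys: Set[Tuple[str, int]] = set()
    source_by_key = {}
    for _, row in positives.iterrows():
        key = (row["accession"], int(row["position"]))
        protein = by_accession.get(key[0])
        if protein is not None:
            residue = protein.sequence[key[1] - 1]
            if residue != "C":
                raise ValueError(
                    f"positive site {key[0]}:{key[1]} is {residue!r}, not Cys "
                    "(isoform or coordinate mismatch?)"
                )
        positive_keys.add(key)
        source_by_key[key] = row["source"]

    feats = featurized.features
    positive_accessions = {acc for acc, _ in positive_keys}
    feats = feats.loc[feats["accession"].isin(positive_accessions)].copy()
    keys = list(zip(feats["accession"], feats["position"]))
    feats["label"] = [1 if k in positive_keys else 0 for k in keys]
    feats["source"] = [source_by_key.get(k, "inferred") for k in keys]
    feats = feats.sort_values(["accession", "position"]).reset_index(drop=True)
    return LabeledDataset(table=feats, feature_names=FEATURE_NAMES)


def class_imbalance(n_positive: int, n_negative: int) -> float:
    """Total-to-positive ratio, (positives + negatives) / positives."""
    if n_positive <= 0:
        raise ValueError("class imbalance undefined without positives")
    return (n_positive + n_negative) / n_positive


@dataclass
class CurationReport:
    """Per-stage attrition counts so users can reconcile curation runs."""

    n_input_rows: int = 0
    n_after_technique_filter: int = 0
    n_after_species_filter: int = 0
    n_after_dedup: int = 0
    n_supplemented: int = 0
    n_positive_final: int = 0
    n_negative_inferred: int = 0
    imbalance: float = float("nan")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def curate(
    site_table: pd.DataFrame,
    proteome: Sequence[ProteinRecord],
    technique_terms: Sequence[str] = DEFAULT_TECHNIQUE_TERMS,
    species_allowlist: Sequence[str] | None = DEFAULT_SPECIES_ALLOWLIST,
    uniprot_supplement: Iterable[Tuple[str, int]] = (),
    literature_supplement: Iterable[Tuple[str, int]] = (),
) -> Tuple[LabeledDataset, CurationReport]:
    """End-to-end curation: filter → supplement → infer negatives."""
    report = CurationReport(n_input_rows=len(site_table))
    tech_only = filter_sites(
        site_table, technique_terms, species_allowlist=None
    )
    report.n_after_technique_filter = len(tech_only)
    positives = filter_sites(site_table, technique_terms, species_allowlist)
    report.n_after_species_filter = report.n_after_dedup = len(positives)
    merged = merge_supplements(
        positives, uniprot_supplement, literature_supplement, proteome
    )
    report.n_supplemented = len(merged) - len(positives)
    dataset = infer_negatives(merged, proteome)
    report.n_positive_final = dataset.n_positive
    report.n_negative_inferred = dataset.n_negative
    if dataset.n_positive:
        report.imbalance = class_imbalance(
            dataset.n_positive, dataset.n_negative
        )
    return dataset, report
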