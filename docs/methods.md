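# Methods

## Scope and data model

`topopalm` operates on three inputs: protein sequences (FASTA), per-protein
topology annotations in the UniProt tab-separated export dialect
(`TRANSMEM 51..71; /note="Helical"`, `TOPO_DOM 1..50; /note="Cytoplasmic"`,
plus `INTRAMEM` and `SIGNAL` spans), and a delimited *S*-palmitoyl site
table (accession, position, `site_techniques` free text, species). All
coordinates are 1-based inclusive, the UniProt convention; this is asserted
once in `topology.py` and assumed everywhere else. Both `..` and `...`
span dialects are accepted; anything else is a parse error naming the
accession — silent coercion of malformed topology would poison every
downstream categorical feature.

Segment classes canonicalize to five kinds. "Lumenal" and "Stromal" fold
into Extracellular so categorical levels align across organelles; unknown
labels raise. TM orientation is a pure function of adjacency: the segment
ending at `start − 1` of a TM decides it (extracellular predecessor →
inward, cytoplasmic → outward). A TM with no predecessor — an N-terminal
helix — is left `unknown` rather than guessed, and cysteines inside such a
helix are excluded from inference with a logged reason, because the
interface distance is undefined without an orientation.

## Detectability analysis

Trypsinization is modelled as complete digestion: cleavage after every
Lys/Arg not followed by Pro (`missed_cleavages` exists but defaults to 0).
Peptides keep protein coordinates so site tables join without conversion.
Each Cys-containing peptide gets an average molecular mass (residue-mass
table + one water, 18.01528 Da) and a mean Kyte–Doolittle hydropathy; the
detectability box is 700–3000 Da × hydropathy [−2, +1], bounds inclusive
(the underlying heuristic does not distinguish open from closed bounds, so
the inclusive reading is the conservative one). Average rather than
monoisotopic masses are used because the box is a coarse instrument-domain
heuristic for which average masses are conventional. Membrane proximity of
a Cys is distance ≤ 20 residues from the nearest TM boundary, with a
residue immediately adjacent to the membrane at distance 1 and an in-TM
residue at 0; the flag is monotone in the cutoff by construction.

## Feature engineering

The 28-feature roster is frozen in `features.FEATURE_NAMES` and hashed;
a fitted model refuses tables whose registry hash differs. The roster is
one concrete instantiation of the three feature families (topology
placement, flanking-window physicochemistry, Cys clustering) — the exact
membership is a design choice of this package, kept in a single auditable
registry precisely so it can be swapped.

Interface distance: inside an inward TM, `end − position` (the C-terminal
side faces the cytoplasm); inside an outward TM, `position − start`; in a
soluble segment, the offset to the nearest segment edge that abuts a TM
(tails count from their TM-adjacent start, heads to their TM-adjacent end,
internal loops take the minimum). A Cys in the first residue after a TM
scores 0. Where annotation gaps leave a soluble segment without an abutting
TM, the fallback is the residue-gap count to the nearest TM boundary. The
implementation is verified against an independent scan-outward oracle in
the tests.

Windows are up to 5 residues per side, truncated at termini, never
containing the central residue. Truncated windows are averaged over the
available residues (no padding); an empty window contributes NaN, which the
booster treats natively as missingness. Count features (basic residues,
asparagines) are raw counts. The window Cys score awards `(6 − d)/5` points
for a neighbouring Cys at offset `d` — a linear distance decay satisfying
"nearer contributes more", with the weight vector exposed as configuration
since alternative decays are equally defensible.

Eligibility: a Cys row requires ≥1 TM segment in the protein, coverage by
an annotated segment that is neither signal peptide nor intramembrane, a
known orientation when inside a TM, and standard residues throughout the
site window. Non-standard letters (X, B, Z, U) never receive fabricated
scale values — the site is excluded with a reason. Exclusions are data, not
failures, and featurization is pure: identical records give bit-identical
rows.

## Curation

Positives are site-table rows whose technique text contains "Point
mutation" or "palmitate" as literal substrings (case-sensitive by default,
because the terms are dialect-specific literals; a flag enables
case-insensitive matching), filtered by a configurable species allowlist
and deduplicated on (accession, position). Supplements — database
cross-references or quantitative LC-MS lists thresholded at palmitoyl
fraction strictly > 0.25 — can only add positives. Negatives are inferred,
never asserted: every eligible, non-positive Cys **on a protein that
carries at least one positive** becomes a negative, so unstudied proteins
cannot contaminate the negative class. A positive at a non-Cys residue
raises, since it almost always indicates an isoform or coordinate-version
mismatch. Class imbalance is reported as (positives + negatives)/positives.

## Model

The classifier is a gradient-boosted tree (xgboost backend, single thread,
exact split method, fixed seed — bit-reproducible). The classical knobs
map directly: interaction depth → max tree depth, shrinkage → learning
rate, minimum observations per node → minimum child weight. Shipped
defaults are depth 18, 2000 trees, shrinkage 0.08, min 5 per node, 10-fold
stratified CV. Two shrinkage conventions (0.08 and 0.008) circulate for
this configuration; 0.08 is the default here and the value is ordinary
configuration. No class-imbalance reweighting is applied by default. CV
folds are stratified by site, not grouped by protein; protein-level
grouping would be stricter against sibling-site leakage and can be imposed
by the caller via a custom split. `fit()` raises if any fold would be
single-class.

Evaluation definitions (shared with the brute-force test oracle): positive
call at score ≥ t; PR curve swept over unique scores with ties grouped;
PR-AUC by trapezoid over (recall, precision) with a (0, 1) anchor;
F1 = 2PR/(P+R); MCC by the standard confusion-matrix formula; 0/0 ratios
defined as 0 so degenerate predictors score 0 rather than NaN. Threshold
counts ("sites above high confidence") use strict `>`. Ranks are ordinal
(1 = best), ties broken by accession then position, always a permutation of
1..N. External score tables are joined on (accession, position) and pushed
through the identical report so cross-tool comparisons are
apples-to-apples; unmatched rows are returned, not silently dropped.

Cys scanning substitutes Cys at every position outside signal/intramembrane
segments (native cysteines scored as-is), re-featurizes the mutated
sequence at that one site and scores the batch. Ineligible positions appear
in the landscape with a reason and a NaN score.

## Synthetic data

The generator emulates the statistical structure the features assume, not
real biology: alternating soluble/TM topology (1–4 TMs, TM length 18–25,
loops 15–90, termini 20–120 residues), per-kind residue composition
(TM enriched in I/L/V/F/A, soluble in charged/polar residues; tables
shipped as data), explicit per-kind Cys rates (3.5% soluble, 2%
membrane/signal), signal peptides at 10% and intramembrane stretches at 5%
to exercise the exclusion paths. Labels follow one latent rule: Cys with
interface distance ≤ d_near = 10 are positive with p_near = 0.8, others
with p_far = 0.02 — strong but noisy juxtamembrane enrichment of the size
reported in the experimental literature (characterized sites sit a median
of ~1–10 residues from the interface). The plant deliberately uses *only*
interface distance so feature-importance recovery has a unique expected
answer. Defaults are 500 proteins.

What the generator does **not** emulate: evolutionary sequence structure,
motif context, real topology-annotation error modes, inter-protein
homology. Passing the recovery tests therefore demonstrates that the
pipeline is correct and that the model class can learn a juxtamembrane
rule from these features — not that any particular real-data AUC will be
achieved.

## Numerical and sizing choices

Scale tables (Kyte–Doolittle hydropathy, Zimmerman polarity, Zhao–London
TM tendency, average residue masses, formal side-chain charge with His = 0
at physiological pH) ship as TSV data files guarded by checksum tests, so
users can substitute alternatives deliberately but not accidentally.
Peptide-mass additivity holds to ≤1e-6 Da; metric implementations agree
with brute-force confusion enumeration to ≤1e-9.

Recovery runs (tests and the acceptance script) use the 500-protein plant
with a scaled booster — depth 4, 300 trees, shrinkage 0.1 — because the
planted rule is a single threshold on one feature and shallow trees
saturate it; the full-depth default remains the shipped configuration for
real corpora. Held-out evaluation splits 20% of proteins (not sites) into
the holdout. The smoke-scale fixtures in the unit tests use 120 proteins.

## Known limitations

* Restricted to TMPs with usable topology annotation; no topology
  prediction is attempted for unannotated proteins, and incompletely
  annotated regions simply yield no inference.
* Signal-peptide and intramembrane cysteines are excluded from inference
  (unrepresented in any plausible training corpus), as are N-terminal TMs
  of unknown orientation.
* No pH-dependent charge model, no isotopic envelopes, no missed-cleavage
  enrichment modelling beyond the optional flag.
* Orthologue mapping is out of scope: site positives are taken at face
  value on their accession.
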