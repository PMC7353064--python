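# Methods

## Scope and model

`secretalk` implements an in-silico workflow that turns tissue proteome
lists plus per-protein predictor evidence into (i) predicted secretomes,
(ii) predicted surfaceomes, (iii) GO-term enrichment summaries, and (iv) a
directed bipartite "crosstalk" network linking proteins secreted by one
tissue to cell-surface proteins of another. The canonical application is
the adipose-muscle pair, where secreted proteins are relabeled as
adipokines (adipose only), myokines (muscle only) or adipomyokines (both).

All classification is deterministic rule evaluation over precomputed
predictor features; nothing is estimated from data. The features emulate
the outputs of standard subcellular-prediction tools: a signal-peptide
discrimination score (D-score) in [0, 1], a transmembrane-topology and
GPI-anchor call, a targeting class (secretory pathway / mitochondrial /
other) with a 1–5 reliability class (RC, 1 = most reliable), and GO
cellular-component annotations.

### Secretome rules

* **Classical route** (ER/Golgi export via an N-terminal signal peptide):
  no transmembrane segment, D-score strictly greater than
  `signalp_threshold` (default 0.5), and RC ≤ `targetp_rc_max` (default 2).
  The upstream predictor's cleavage-site sensitivity setting (D-cutoff
  0.34) is carried as parser metadata only; it is never a classification
  threshold here.
* **Non-classical route** (exosomes, membrane flip-flop, transporters):
  evaluated only on classical-route negatives, so the two routes partition
  the secretome. Requires targeting class "other", RC ≤ `targetp_rc_max`,
  and at least one GO term whose reflexive `is_a` closure reaches an
  extracellular root (defaults: extracellular region GO:0005576,
  extracellular space GO:0005615, extracellular exosome GO:0070062).
  "TargetP score ≤ 2" is interpreted as the RC bound; the tool's 1–5
  reliability scale is the only integer-valued "score" it reports.
  UniProt subcellular-location strings, when supplied, are recorded as
  corroborating evidence but are not required — the rule set above is the
  binding criterion.

Proteins missing a required feature are reported in a dedicated
`unevaluated` list rather than silently counted negative; proteins absent
from the feature table entirely are `uncovered`.

### Surfaceome rules

Two complementary strategies, unioned per tissue with per-call basis
bookkeeping:

* **Predicted**: at least one α-helical or β-barrel transmembrane segment
  or a GPI anchor, *and* plasma-membrane GO annotation (GO:0005886 or an
  `is_a` descendant; a strict exact-term mode exists because annotation
  practice varies).
* **Atlas**: membership in a reference compendium of published
  cell-surface protein lists, intersected with the tissue proteome. The
  contributing lists are inputs, not bundled data.

### Ontology handling

The GO DAG is stored with `is_a` parent links only; `part_of` and other
relations are not traversed (a known limitation — a protein annotated only
to a `part_of` child of an extracellular term will be missed).
Ancestor closure is reflexive and memoized; construction rejects cyclic
inputs naming an offending edge. Enrichment annotation maps propagate each
GAF annotation to all `is_a` ancestors by default, the standard
GO-enrichment convention.

### Enrichment

One-sided hypergeometric over-representation (Fisher exact, greater tail)
per GO term, Benjamini–Hochberg step-up adjustment across all terms tested
in one run (one family per dataset, not per namespace), reported subset
filtered to adjusted p < `bh_alpha` (default 0.01) and at least
`min_annotated` (default 2) study proteins. The background defaults to the
annotated universe of the supplied GAF and is overridable. Enrichments are
also emitted as −log10(adjusted p) for plotting. The upper tail is
computed via `scipy.stats.hypergeom.sf` (log-space stable); BH via
`statsmodels.stats.multitest.multipletests`; both are cross-checked in the
test suite against independent brute-force oracles (exhaustive draw
enumeration for all urns with N ≤ 12; a literal step-up implementation).

### Crosstalk network

An interaction record (PSI-MITAB 2.5; unordered duplicate rows aggregated
with merged provenance) is retained iff, in order:

1. it is not a self-interaction;
2. its evidence class is experimental (when `require_experimental_ppi`);
   the mapping from detection-method text to evidence class is
   table-driven and config-editable, since interaction databases vary in
   vocabulary;
3. one interactor is in the secretome of tissue A and the other in the
   surfaceome of tissue B (a pair orientable both ways yields one edge per
   satisfiable orientation); otherwise the record is tallied
   `wrong_compartment` when both endpoints are known to the role sets and
   `non_member` when not;
4. both endpoints are expressed in their respective tissues (when
   `require_expression_check`). Unknown expression status passes with a
   warning by default (`unknown_expression_action: pass`), because
   expression tables supplied as files are rarely complete; a `reject`
   mode exists.

Edges are oriented secreted → surface (the ligand → receptor reading).
Rejection reasons are tallied so that retained records plus rejections
always reconcile with the input record count.

## Configuration

Every numeric criterion lives in `CriteriaConfig` (YAML-serializable; CLI
flags override file values): `signalp_threshold` (0.5), `targetp_rc_max`
(2), `bh_alpha` (0.01), `min_annotated` (2), the extracellular root set,
the plasma-membrane root, the two PPI policy switches, and the detection-
method marker vocabularies. No module hard-codes a criterion constant.

## Synthetic data generator

`GeneratorSpec`/`generate_bundle` emit a complete input bundle (two
proteome TSVs, signal-peptide, targeting and topology tables, GAF, a ~30-
term mini cellular-component DAG, atlas TSV, MITAB, expression TSV,
ortholog map) with planted class structure and a ground-truth manifest.
Defaults mirror the study conditions: 750 adipose and 531 muscle proteins,
classical/non-classical fractions of 9% and 2.7% (the adipose secretome
proportions), predicted-surface fractions of 0.6%/0.3% (TM/GPI), an atlas
intersecting 2.8% of each proteome, ~30% cross-tissue sharing, two planted
crosstalk interactions with ten decoys, and 94% ortholog-map coverage.

Planted members draw feature values uniformly from the interior of their
class's criterion region (e.g. D-score ~ U(0.51, 0.99) for classical
members); every non-member fails at least one criterion by construction.
Decoy interaction records each violate exactly one crosstalk filter
(non-experimental evidence, wrong compartment, or a non-member endpoint);
when a small bundle exhausts the available orientable pairs, the remaining
decoys fall back to the always-constructible non-member kind, and the
manifest records what was actually planted. Atlas membership is planted as
every other surface member (exercising the dual-basis path) plus
atlas-only members drawn from the negatives plus out-of-proteome extras.
Generated symbols use a reserved `SYN`/`DECOY` namespace and can never
collide with real gene symbols.

Because the rules are deterministic, the pipeline must recover the
manifest exactly for any seed — the test suite asserts this for 20 seeds
at 60/50 proteins per tissue, a size chosen to exercise all code paths
while keeping the default test run fast. What passing these tests shows is
that the rule calculus, parsers and graph filters are internally
consistent; it does not validate the upstream predictors themselves, nor
realistic feature noise (real D-scores cluster near the threshold; real GO
annotation is incomplete and biased), nor real PPI false-positive rates.

## Study fixtures

The packaged fixtures encode the study's printed gene lists verbatim after
symbol normalization: the 77 signal-peptide-route proteins (39 adipose-
only / 9 muscle-only / 29 shared) and 22 non-classical proteins (12/2/8),
the crosstalk interactors of both directions, and membership lists
realizing the published surfaceome cardinalities (7/4 predicted, 21/11
atlas, unions 26/13). One printed table entry ("SPET5") differs from the
running-text spelling of the same protein; the fixture keeps the table
spelling. Three quantities the source does not print are constructed and
flagged as such: the predicted-vs-atlas overlap of 2 per tissue (forced by
inclusion–exclusion on the printed counts), the pairing of the 11
muscle→adipose interactions (only the 16 endpoint names and the
hemopexin–CDC42 link are printed), and the APOA1–KRT1 assignment in the
adipose→muscle direction (PLG–ENO1 is confirmed; the remaining pairing is
the only consistent completion under distinct endpoints).

Identified-proteome headline counts that depend on external database
versions (ortholog assignment totals, the enriched-term lists of the
study's figures, the atlas contributor lists of 2882/3702/4016 genes) are
deliberately not fixture targets; those paths are validated by the
property-based tests instead.

## Numerical and design choices

* Canonical key everywhere is the uppercased, whitespace-trimmed gene
  symbol; accessions are provenance only. Duplicate accessions collapsing
  to one symbol collapse to one record.
* The classical D-score comparison is strictly greater-than; a protein at
  exactly the threshold is negative.
* Hypergeometric p of an empty draw (k = 0) is returned as exactly 1.0,
  covering the degenerate empty-urn case.
* Enrichment results sort by adjusted p with term-id tie-breaks, so output
  order is total and reproducible.
* Ortholog mapping is first-listed-wins when a table maps one bovine id to
  several human symbols; alternatives are logged. Symbol lookup precedes
  accession lookup.
* One-to-one re-application of an identity ortholog map is a no-op at the
  symbol level (idempotence is tested).
* Tissue labels are open strings with two canonical values ("adipose",
  "muscle"); kine labeling is defined only for the canonical pair.

## Known limitations

* `part_of` edges are not traversed in GO closures.
* Evidence-code filtering of GO annotations is not applied (all accepted).
* The crosstalk step is binary retain/reject; no interaction scoring.
* The generator does not simulate mass spectra, abundances, or the
  identification error of upstream proteomics.
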