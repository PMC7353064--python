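# secretalk

Secretome and surfaceome prediction, GO enrichment, and tissue-crosstalk
network inference from proteome lists.

## The problem

Tissues talk to each other through proteins: one tissue secretes a ligand,
the other displays a receptor at the cell surface. Given only lists of
proteins identified in two tissues (for example by 2-DE / nano-LC-MS/MS),
which secreted–surface pairs could carry that conversation? `secretalk`
answers this in silico for the adipose–muscle pair (and any other
two-tissue setting), for physiologists and proteomicists who have proteome
lists plus standard predictor outputs and want reproducible, rule-based
calls instead of a black box.

## The method

For each protein the package consumes precomputed predictor features — a
signal-peptide D-score, transmembrane/GPI topology, a targeting class with
reliability class RC ∈ 1..5 (1 best), and GO cellular-component terms —
and applies:

* **Classical secretion**: noTM ∧ D > 0.5 ∧ RC ≤ 2.
* **Non-classical secretion** (evaluated on classical negatives):
  targeting class "other" ∧ RC ≤ 2 ∧ ∃ GO term with an extracellular
  ancestor (GO:0005576 / GO:0005615 / GO:0070062 by `is_a` closure).
* **Surfaceome**: (≥1 α-helical or β-barrel TM segment ∨ GPI anchor) ∧
  plasma-membrane annotation (GO:0005886 or descendant), unioned with the
  intersection of the proteome against a reference surface-protein atlas.
* **Enrichment**: per-term hypergeometric upper tail
  P(X ≥ k | N, K, n), Benjamini–Hochberg adjusted; reported when
  p_BH < 0.01 and the term annotates ≥ 2 study proteins.
* **Crosstalk**: a PPI record (PSI-MITAB) becomes a directed edge
  secreted(A) → surface(B) iff it is experimentally evidenced, one
  interactor is in the secretome of A and the other in the surfaceome of
  B, and both endpoints are expressed in their tissues.

Secreted proteins of the adipose/muscle pair are relabeled by Venn
position: adipokine (adipose only), myokine (muscle only), adipomyokine
(both). Every threshold lives in a single `CriteriaConfig`
(YAML-overridable); see `docs/methods.md` for the full rule semantics and
design rationale.

## Worked example

The package ships desk-scale fixtures encoding the published gene lists of
a fetal bovine adipose/muscle proteome study. Materialize them and run the
secretome classifier for muscle:

```bash
secretalk fixtures --out-dir demo/fixtures
f=demo/fixtures/tables_1_2
secretalk secretome --proteome $f/muscle_proteome.tsv --tissue muscle \
    --signalp $f/signalp.tsv --targetp $f/targetp.tsv \
    --topology $f/topology.tsv --gaf $f/annotations.gaf \
    --obo $f/ontology.obo --out demo/muscle_calls.tsv
```

prints

```
{"total": 48, "classical": 38, "non_classical": 10, "unevaluated": 0, "uncovered": 0}
```

i.e. 48 muscle proteins are called secreted — 38 through the classical
signal-peptide route and 10 through signal-peptide-independent routes —
and `demo/muscle_calls.tsv` records each call with its firing evidence:

```
symbol	route	evidence
ADIPOQ	classical	{"d_score": 0.9, "no_tm": true, "rc": 1}
AFP	classical	{"d_score": 0.9, "no_tm": true, "rc": 1}
```

The muscle-secreted → adipose-surface crosstalk network on the
corresponding fixture:

```bash
c=demo/fixtures/crosstalk_muscle_to_at
secretalk crosstalk --secretome $c/secretome_muscle.tsv \
    --surfaceome $c/surfaceome_adipose.tsv --tissue-a muscle \
    --tissue-b adipose --mitab $c/ppi.mitab \
    --expression $c/expression.tsv --out demo/edges.tsv
```

prints

```
{"tissue_a": "muscle", "tissue_b": "adipose", "edges": 11, "nodes": 16,
 "sources": 9, "targets": 7, "retained_records": 11,
 "rejections": {"wrong_compartment": 3, "non_experimental": 4, "non_member": 3},
 "warnings": 0}
```

— 11 retained interactions among 16 distinct proteins (9 secreted, 7
surface), with every decoy record rejected under a tallied reason. The
edge list starts:

```
secreted	surface	evidence_class	source_dbs
AHSG	KRT1	experimental	IntAct
ANXA2	ARRB1	experimental	IntAct
```

Other entry points: `secretalk run` (full pipeline with `report.json`),
`surfaceome`, `enrich`, `atlas-build`, and `simulate` (synthetic bundles
with a ground-truth manifest for end-to-end validation).

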