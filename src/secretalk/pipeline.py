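"""End-to-end workflow: compendium -> secretome -> surfaceome -> enrichment
-> crosstalk -> kine labeling, with a machine-readable run report.

Stage order mirrors the study workflow: per-tissue proteome lists are
merged into compendia, optionally translated to human symbols through an
ortholog map, classified into secretomes and surfaceomes, GO-enriched, and
finally crossed into the two directed crosstalk networks. Optional stages
(orthology, enrichment, crosstalk) degrade gracefully with warnings when
their inputs are absent; every count in the report is recomputable from
the emitted stage outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .core import ADIPOSE, MUSCLE, CriteriaConfig
from .crosstalk import build_crosstalk, network_summary
from .enrichment import enrich
from .io_formats import (
    annotation_map,
    assemble_features,
    read_atlas_table,
    read_expression_table,
    read_gaf,
    read_mitab,
    read_obo,
    read_proteome_table,
    read_signalp_table,
    read_targetp_table,
    read_topology_table,
)
from .core import merge_proteomes
from .orthology import map_to_human, read_ortholog_map
from .secretome import label_kines, predict_secretome
from .surfaceome import SurfaceomeAtlas, build_atlas, predict_surfaceome

__all__ = ["PipelineInputs", "RunReport", "run_pipeline"]

log = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    """A mandatory input is missing or unreadable."""


@dataclass
class PipelineInputs:
    """File paths for one run; tissue -> list of proteome TSVs."""

    proteomes: dict[str, list[str]]
    signalp: str | None = None
    targetp: str | None = None
    topology: str | None = None
    gaf: str | None = None
    obo: str | None = None
    atlas: list[str] = field(default_factory=list)
    mitab: str | None = None
    expression: str | None = None
    ortholog_map: str | None = None

    def validate(self) -> None:
        if not self.proteomes:
            raise ConfigurationError("no proteome inputs configured (field: proteomes)")
        for name in ("signalp", "targetp", "gaf", "obo"):
            if getattr(self, name) is None:
                raise ConfigurationError(f"missing mandatory input (field: {name})")


@dataclass
class RunReport:
    """Per-stage counts, warnings and the config echo for one run."""

    config: dict
    strict: bool
    stages: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)

    def warn(self, category: str, n: int = 1) -> None:
        self.warnings[category] = self.warnings.get(category, 0) + n

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "strict": self.strict,
                    "stages": self.stages,
                    "warnings": self.warnings,
                },
                fh,
                indent=1,
                sort_keys=True,
                default=sorted,
            )


def run_pipeline(
    inputs: PipelineInputs,
    config: CriteriaConfig | None = None,
    out_dir=None,
    strict: bool = True,
) -> RunReport:
    """Run every stage over the configured inputs.

    Returns the :class:`RunReport`; when ``out_dir`` is given, also writes
    per-stage TSVs, GraphML networks and ``report.json`` there.
    """
    config = config or CriteriaConfig()
    inputs.validate()
    report = RunReport(config=config.to_dict(), strict=strict)
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)

    # --- compendium ---
    proteomes = {}
    for tissue, paths in inputs.proteomes.items():
        parts = []
        for path in paths:
            proteome, plog = read_proteome_table(path, tissue, strict=strict)
            report.warn("proteome_rows_skipped", plog.skipped) if plog.skipped else None
            parts.append(proteome)
        proteomes[tissue] = merge_proteomes(parts)
    report.stages["compendium"] = {t: len(p) for t, p in proteomes.items()}

    # --- orthology (optional) ---
    if inputs.ortholog_map:
        omap, plog = read_ortholog_map(inputs.ortholog_map, strict=strict)
        unmapped_report = {}
        for tissue in list(proteomes):
            mapped, unmapped = map_to_human(proteomes[tissue], omap)
            proteomes[tissue] = mapped
            unmapped_report[tissue] = len(unmapped)
            if out is not None and unmapped:
                with open(out / f"unmapped_{tissue}.tsv", "w") as fh:
                    fh.write("symbol\n")
                    fh.writelines(s + "\n" for s in unmapped)
        report.stages["orthology"] = {
            "mapped": {t: len(p) for t, p in proteomes.items()},
            "unmapped": unmapped_report,
        }

    # --- features ---
    signalp, sp_log = read_signalp_table(inputs.signalp, strict=strict)
    targetp, tp_log = read_targetp_table(inputs.targetp, strict=strict)
    topology = {}
    if inputs.topology:
        topology, _ = read_topology_table(inputs.topology, strict=strict)
    gaf_records, gaf_log = read_gaf(inputs.gaf, strict=strict)
    dag = read_obo(inputs.obo)
    for plog, cat in ((sp_log, "signalp_rows_skipped"), (tp_log, "targetp_rows_skipped"),
                      (gaf_log, "gaf_rows_skipped")):
        if plog.skipped:
            report.warn(cat, plog.skipped)
    features = assemble_features(
        signalp=signalp, targetp=targetp, gaf_records=gaf_records, topology=topology
    )

    # --- secretome ---
    secretomes = {}
    for tissue, proteome in proteomes.items():
        result = predict_secretome(proteome, features, dag, config)
        secretomes[tissue] = result
        report.stages.setdefault("secretome", {})[tissue] = result.counts()
        if out is not None:
            with open(out / f"secretome_{tissue}.tsv", "w") as fh:
                fh.write("symbol\troute\tevidence\n")
                for sym in sorted(result.calls):
                    call = result.calls[sym]
                    fh.write(f"{sym}\t{call.route}\t{json.dumps(call.evidence_dict)}\n")

    # --- surfaceome ---
    atlas = SurfaceomeAtlas()
    if inputs.atlas:
        lists, names = [], []
        for path in inputs.atlas:
            members, _ = read_atlas_table(path, strict=strict)
            lists.append(set(members))
            names.append(Path(path).stem)
        atlas = build_atlas(lists, names)
    surfaceomes = {}
    for tissue, proteome in proteomes.items():
        result = predict_surfaceome(proteome, features, dag, atlas, config)
        surfaceomes[tissue] = result
        report.stages.setdefault("surfaceome", {})[tissue] = result.counts()
        if out is not None:
            with open(out / f"surfaceome_{tissue}.tsv", "w") as fh:
                fh.write("symbol\tbasis\n")
                for sym in sorted(result.calls):
                    fh.write(f"{sym}\t{','.join(result.calls[sym].basis_sorted)}\n")

    # --- enrichment (per tissue, background = annotated universe) ---
    annotations = annotation_map(gaf_records, dag=dag, propagate=True)
    background = {r.db_object_symbol for r in gaf_records}
    enrichment_counts = {}
    for tissue, proteome in proteomes.items():
        study = proteome.symbols & background
        dropped = len(proteome) - len(study)
        if dropped:
            report.warn("unannotated_study_symbols", dropped)
        if not background:
            report.warn("enrichment_skipped_empty_background")
            continue
        results = enrich(study, background, annotations, config,
                         term_names={t: dag.name(t) for t in dag.terms})
        significant = [r for r in results if r.significant]
        enrichment_counts[tissue] = {"tested": len(results), "significant": len(significant)}
        if out is not None:
            with open(out / f"enrichment_{tissue}.tsv", "w") as fh:
                fh.write("go_id\tname\tk\tn\tK\tN\tp_raw\tp_bh\tneg_log10_bh\tsignificant\n")
                for r in results:
                    fh.write(
                        f"{r.go_id}\t{r.name}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                        f"{r.p_raw:.4g}\t{r.p_bh:.4g}\t{r.neg_log10_bh:.3f}\t{int(r.significant)}\n"
                    )
    report.stages["enrichment"] = enrichment_counts

    # --- crosstalk (both directions) ---
    if inputs.mitab:
        ppi, ppi_log = read_mitab(inputs.mitab, strict=strict, config=config)
        if ppi_log.skipped:
            report.warn("mitab_rows_skipped", ppi_log.skipped)
        expression = None
        if inputs.expression:
            expression, _ = read_expression_table(inputs.expression, strict=strict)
        tissues = sorted(proteomes)
        for tissue_a in tissues:
            for tissue_b in tissues:
                if tissue_a == tissue_b:
                    continue
                net = build_crosstalk(
                    secretomes[tissue_a].symbols,
                    surfaceomes[tissue_b].symbols,
                    ppi,
                    expression,
                    tissue_a,
                    tissue_b,
                    config,
                )
                summary = network_summary(net)
                report.stages.setdefault("crosstalk", {})[f"{tissue_a}->{tissue_b}"] = summary
                if net.warnings:
                    report.warn("expression_unknown", len(net.warnings))
                if out is not None:
                    stem = f"crosstalk_{tissue_a}_to_{tissue_b}"
                    with open(out / f"{stem}.tsv", "w") as fh:
                        fh.write("secreted\tsurface\tevidence_class\tsource_dbs\n")
                        for u, v, data in sorted(net.graph.edges(data=True)):
                            fh.write(
                                f"{u}\t{v}\t{data['evidence_class']}\t{';'.join(data['source_dbs'])}\n"
                            )
                    net.to_graphml(out / f"{stem}.graphml")

    # --- kine labeling (canonical two-tissue runs only) ---
    if set(proteomes) == {ADIPOSE, MUSCLE}:
        labels = label_kines({t: secretomes[t] for t in (ADIPOSE, MUSCLE)})
        counts = {}
        for lab in labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        report.stages["kines"] = counts
        if out is not None:
            with open(out / "kines.tsv", "w") as fh:
                fh.write("symbol\tlabel\n")
                for sym in sorted(labels):
                    fh.write(f"{sym}\t{labels[sym]}\n")
    else:
        report.warn("kine_labeling_skipped_nonstandard_tissues")

    if out is not None:
        report.to_json(out / "report.json")
    return report
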