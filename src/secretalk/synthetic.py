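"""Synthetic input bundles with planted class structure.

The generator emits a complete, internally consistent set of pipeline
inputs -- two tissue proteomes, predictor tables, GO annotations, a mini
GO DAG, a surface atlas, interaction records, an expression table and an
ortholog map -- together with a ground-truth manifest of every planted
membership. Planted members receive features sampled from the interior of
their class's criterion region; every non-member fails at least one
criterion, so the deterministic rule classifiers must recover the manifest
exactly for any seed.

Generated symbols live in a reserved ``SYN``/``DECOY`` namespace so they can
never collide with real gene symbols used by the packaged study fixtures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import ADIPOSE, MUSCLE, TissueProteome
from .io_formats import (
    ExpressionTable,
    MitabRecord,
    GafRecord,
    assemble_features,
    write_atlas_table,
    write_expression_table,
    write_gaf,
    write_mitab,
    write_obo,
    write_proteome_table,
    write_signalp_table,
    write_targetp_table,
    write_topology_table,
)
from .ontology import GODag
from .orthology import OrthologMap, write_ortholog_map

__all__ = ["GeneratorSpec", "Bundle", "mini_ontology", "generate_bundle"]

# Mini cellular-component ontology (~30 real GO terms, is_a edges only).
# Contains the extracellular and plasma-membrane branches the predicates
# need, each with at least one descendant, plus decoy branches
# (mitochondrion, nucleus, cytosol, ER, Golgi).
_MINI_TERMS: dict[str, tuple[str, tuple[str, ...]]] = {
    "GO:0005575": ("cellular_component", ()),
    "GO:0110165": ("cellular anatomical entity", ("GO:0005575",)),
    "GO:0005576": ("extracellular region", ("GO:0110165",)),
    "GO:0005615": ("extracellular space", ("GO:0005576",)),
    "GO:0031012": ("extracellular matrix", ("GO:0110165",)),
    "GO:0062023": ("collagen-containing extracellular matrix", ("GO:0031012", "GO:0005576")),
    "GO:0031982": ("vesicle", ("GO:0110165",)),
    "GO:0043230": ("extracellular organelle", ("GO:0110165",)),
    "GO:1903561": ("extracellular vesicle", ("GO:0031982", "GO:0043230")),
    "GO:0070062": ("extracellular exosome", ("GO:1903561",)),
    "GO:0016020": ("membrane", ("GO:0110165",)),
    "GO:0071944": ("cell periphery", ("GO:0110165",)),
    "GO:0005886": ("plasma membrane", ("GO:0016020", "GO:0071944")),
    "GO:0098552": ("side of membrane", ("GO:0016020",)),
    "GO:0009897": ("external side of plasma membrane", ("GO:0005886", "GO:0098552")),
    "GO:0009986": ("cell surface", ("GO:0071944",)),
    "GO:0043226": ("organelle", ("GO:0110165",)),
    "GO:0043227": ("membrane-bounded organelle", ("GO:0043226",)),
    "GO:0005737": ("cytoplasm", ("GO:0110165",)),
    "GO:0005829": ("cytosol", ("GO:0005737",)),
    "GO:0005739": ("mitochondrion", ("GO:0043227", "GO:0005737")),
    "GO:0005759": ("mitochondrial matrix", ("GO:0005739",)),
    "GO:0005634": ("nucleus", ("GO:0043227",)),
    "GO:0005654": ("nucleoplasm", ("GO:0005634",)),
    "GO:0005783": ("endoplasmic reticulum", ("GO:0043227", "GO:0005737")),
    "GO:0005788": ("endoplasmic reticulum lumen", ("GO:0005783",)),
    "GO:0005794": ("Golgi apparatus", ("GO:0043227", "GO:0005737")),
    "GO:0005856": ("cytoskeleton", ("GO:0005737",)),
    "GO:0005764": ("lysosome", ("GO:0043227",)),
    "GO:0005773": ("vacuole", ("GO:0043227",)),
}

EXTRACELLULAR_LEAVES = ("GO:0005615", "GO:0070062", "GO:0062023")
PLASMA_MEMBRANE_LEAVES = ("GO:0009897", "GO:0005886")
DECOY_LEAVES = ("GO:0005829", "GO:0005654", "GO:0005759", "GO:0005788", "GO:0005856")


def mini_ontology() -> GODag:
    """The packaged ~30-term cellular-component DAG used for testing."""
    terms = {t: (name, "cellular_component") for t, (name, _) in _MINI_TERMS.items()}
    edges = [(t, p) for t, (_, parents) in _MINI_TERMS.items() for p in parents]
    return GODag.from_edges(terms, edges)


CLASS_CLASSICAL = "classical"
CLASS_NON_CLASSICAL = "non_classical"
CLASS_SURFACE_TM = "surface_tm"
CLASS_SURFACE_GPI = "surface_gpi"
CLASS_NEGATIVE = "negative"

_PLANTED_CLASSES = (CLASS_CLASSICAL, CLASS_NON_CLASSICAL, CLASS_SURFACE_TM, CLASS_SURFACE_GPI)


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic bundle.

    Defaults emulate the fetal bovine study: 750 adipose and 531 muscle
    proteins; a classical-route fraction of ~9% and non-classical ~2.7%
    (the adipose secretome proportions); small predicted-surface fractions
    and an atlas intersecting ~2.8% of the proteome; two planted crosstalk
    interactions plus ten decoys; 94% ortholog-map coverage.
    """

    seed: int = 0
    n_proteins: dict = field(default_factory=lambda: {ADIPOSE: 750, MUSCLE: 531})
    fraction_classical: float = 0.09
    fraction_nonclassical: float = 0.027
    fraction_surface_tm: float = 0.006
    fraction_surface_gpi: float = 0.003
    fraction_atlas_extra: float = 0.028
    cross_tissue_overlap: float = 0.3
    n_planted_crosstalk: int = 2
    n_decoy_ppi: int = 10
    decoy_weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    map_coverage: float = 0.94

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_classical,
            self.fraction_nonclassical,
            self.fraction_surface_tm,
            self.fraction_surface_gpi,
            self.fraction_atlas_extra,
            self.cross_tissue_overlap,
            self.map_coverage,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        route_sum = (
            self.fraction_classical
            + self.fraction_nonclassical
            + self.fraction_surface_tm
            + self.fraction_surface_gpi
        )
        if route_sum > 1.0:
            raise ValueError(f"planted class fractions sum to {route_sum} > 1")
        if self.n_planted_crosstalk < 0 or self.n_decoy_ppi < 0:
            raise ValueError("interaction counts must be non-negative")
        if len(self.decoy_weights) != 3 or any(w < 0 for w in self.decoy_weights):
            raise ValueError("decoy_weights must be three non-negative numbers")


@dataclass
class Bundle:
    """In-memory synthetic input bundle plus its ground-truth manifest."""

    proteomes: dict[str, TissueProteome]
    features: dict
    dag: GODag
    signalp: dict
    targetp: dict
    topology: dict
    gaf_records: set
    atlas_members: dict[str, set[str]]
    mitab_records: set
    expression: ExpressionTable
    ortholog_entries: dict[str, tuple[str, str]]
    manifest: dict

    def write(self, outdir) -> None:
        """Materialize the bundle as the pipeline's file formats."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for tissue, proteome in self.proteomes.items():
            write_proteome_table(out / f"{tissue}_proteome.tsv", proteome)
        write_signalp_table(out / "signalp.tsv", self.signalp)
        write_targetp_table(out / "targetp.tsv", self.targetp)
        write_topology_table(out / "topology.tsv", self.topology)
        write_gaf(out / "annotations.gaf", self.gaf_records)
        write_obo(out / "ontology.obo", self.dag)
        write_atlas_table(out / "atlas.tsv", self.atlas_members)
        write_mitab(out / "ppi.mitab", self.mitab_records)
        write_expression_table(out / "expression.tsv", self.expression)
        write_ortholog_map(out / "orthologs.tsv", OrthologMap(entries=dict(self.ortholog_entries)))
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True, default=sorted)


def _plant_counts(n: int, spec: GeneratorSpec) -> dict[str, int]:
    counts = {
        CLASS_CLASSICAL: round(spec.fraction_classical * n),
        CLASS_NON_CLASSICAL: round(spec.fraction_nonclassical * n),
        CLASS_SURFACE_TM: round(spec.fraction_surface_tm * n),
        CLASS_SURFACE_GPI: round(spec.fraction_surface_gpi * n),
    }
    if sum(counts.values()) > n:
        raise ValueError("planted class counts exceed group size")
    return counts


def generate_bundle(spec: GeneratorSpec) -> Bundle:
    """Generate a deterministic bundle with planted class structure.

    Symbols are partitioned into a shared group (present in both tissue
    proteomes) and per-tissue groups; within each group the planted class
    counts are ``round(fraction * group size)``, so planted counts are a
    deterministic function of the spec. Feature values are drawn uniformly
    from the interior of each class's criterion region.
    """
    rng = np.random.default_rng(spec.seed)
    dag = mini_ontology()
    n_a = spec.n_proteins.get(ADIPOSE, 0)
    n_m = spec.n_proteins.get(MUSCLE, 0)
    n_shared = round(spec.cross_tissue_overlap * min(n_a, n_m))
    groups = {
        "shared": [f"SYNS{i:05d}" for i in range(n_shared)],
        ADIPOSE: [f"SYNA{i:05d}" for i in range(n_a - n_shared)],
        MUSCLE: [f"SYNM{i:05d}" for i in range(n_m - n_shared)],
    }
    class_of: dict[str, str] = {}
    for name, symbols in groups.items():
        counts = _plant_counts(len(symbols), spec)
        order = list(rng.permutation(len(symbols)))
        pos = 0
        for cls in _PLANTED_CLASSES:
            for idx in order[pos : pos + counts[cls]]:
                class_of[symbols[idx]] = cls
            pos += counts[cls]
        for idx in order[pos:]:
            class_of[symbols[idx]] = CLASS_NEGATIVE

    tissue_symbols = {
        ADIPOSE: sorted(groups["shared"] + groups[ADIPOSE]),
        MUSCLE: sorted(groups["shared"] + groups[MUSCLE]),
    }
    all_symbols = sorted(class_of)

    signalp: dict[str, tuple[float, bool, bool]] = {}
    targetp: dict[str, tuple[str, int]] = {}
    topology: dict[str, tuple[int, int, bool]] = {}
    go_of: dict[str, set[str]] = {}
    for sym in all_symbols:
        cls = class_of[sym]
        lo_d = float(rng.uniform(0.05, 0.45))
        rc_good = int(rng.integers(1, 3))       # {1, 2}
        rc_any = int(rng.integers(1, 6))        # {1..5}
        if cls == CLASS_CLASSICAL:
            d = float(rng.uniform(0.51, 0.99))
            signalp[sym] = (d, True, True)
            topology[sym] = (0, 0, False)
            targetp[sym] = ("secretory_pathway", rc_good)
            go_of[sym] = {str(rng.choice(DECOY_LEAVES))}
        elif cls == CLASS_NON_CLASSICAL:
            signalp[sym] = (lo_d, False, True)
            topology[sym] = (0, 0, False)
            targetp[sym] = ("other", rc_good)
            go_of[sym] = {str(rng.choice(EXTRACELLULAR_LEAVES)), str(rng.choice(DECOY_LEAVES))}
        elif cls == CLASS_SURFACE_TM:
            signalp[sym] = (lo_d, False, False)
            barrel = int(rng.integers(0, 2))
            topology[sym] = (int(rng.integers(1, 4)) if not barrel else 0, barrel, False)
            targetp[sym] = ("other", rc_any)
            go_of[sym] = {str(rng.choice(PLASMA_MEMBRANE_LEAVES))}
        elif cls == CLASS_SURFACE_GPI:
            signalp[sym] = (lo_d, False, True)
            topology[sym] = (0, 0, True)
            targetp[sym] = ("other", rc_any)
            go_of[sym] = {str(rng.choice(PLASMA_MEMBRANE_LEAVES))}
        else:  # negative: fails every route
            signalp[sym] = (lo_d, False, True)
            topology[sym] = (0, 0, False)
            tp_cls = "mitochondrial" if rng.random() < 0.5 else "other"
            targetp[sym] = (tp_cls, rc_any)
            go_of[sym] = {str(rng.choice(DECOY_LEAVES))}

    gaf_records = {
        GafRecord(
            db="SYN",
            db_object_id=f"ACC:{sym}",
            db_object_symbol=sym,
            qualifier="",
            go_id=go,
            evidence_code="IDA",
            aspect="C",
            taxon="taxon:9606",
        )
        for sym in all_symbols
        for go in sorted(go_of[sym])
    }

    # atlas: every other planted surface member (exercises the both-bases
    # path) + atlas-only members drawn from the negatives + out-of-proteome
    # extras, spread over three synthetic source lists
    surface_members = sorted(s for s, c in class_of.items() if c in (CLASS_SURFACE_TM, CLASS_SURFACE_GPI))
    atlas_syms = set(surface_members[::2])
    negatives = [s for s in all_symbols if class_of[s] == CLASS_NEGATIVE]
    atlas_only: set[str] = set()
    for tissue in (ADIPOSE, MUSCLE):
        want = round(spec.fraction_atlas_extra * len(tissue_symbols[tissue]))
        pool = [s for s in tissue_symbols[tissue] if class_of[s] == CLASS_NEGATIVE and s not in atlas_only]
        atlas_only |= {pool[i] for i in rng.choice(len(pool), size=min(want, len(pool)), replace=False)}
    atlas_syms |= atlas_only
    n_extra = round(spec.fraction_atlas_extra * len(all_symbols))
    atlas_syms |= {f"SYNX{i:05d}" for i in range(n_extra)}
    sources = ("atlas_srcA", "atlas_srcB", "atlas_srcC")
    atlas_members = {s: {sources[i % 3]} for i, s in enumerate(sorted(atlas_syms))}

    # ground-truth memberships
    manifest: dict = {"seed": spec.seed, "tissues": {}}
    secretome_of: dict[str, set[str]] = {}
    surfaceome_of: dict[str, set[str]] = {}
    for tissue in (ADIPOSE, MUSCLE):
        syms = set(tissue_symbols[tissue])
        classical = {s for s in syms if class_of[s] == CLASS_CLASSICAL}
        non_classical = {s for s in syms if class_of[s] == CLASS_NON_CLASSICAL}
        surf_tm = {s for s in syms if class_of[s] == CLASS_SURFACE_TM}
        surf_gpi = {s for s in syms if class_of[s] == CLASS_SURFACE_GPI}
        atlas_hits = syms & atlas_syms
        secretome_of[tissue] = classical | non_classical
        surfaceome_of[tissue] = surf_tm | surf_gpi | atlas_hits
        manifest["tissues"][tissue] = {
            "n_proteins": len(syms),
            "classical": sorted(classical),
            "non_classical": sorted(non_classical),
            "surface_tm": sorted(surf_tm),
            "surface_gpi": sorted(surf_gpi),
            "atlas_hits": sorted(atlas_hits),
            "secretome": sorted(secretome_of[tissue]),
            "surfaceome": sorted(surfaceome_of[tissue]),
        }

    expression = ExpressionTable()
    for tissue in (ADIPOSE, MUSCLE):
        for sym in tissue_symbols[tissue]:
            expression.set(sym, tissue, True)

    mitab_records, planted_edges, decoy_plan = _plant_ppi(
        rng, spec, secretome_of[ADIPOSE], surfaceome_of[MUSCLE], sorted(negatives)
    )
    manifest["crosstalk"] = {
        "tissue_a": ADIPOSE,
        "tissue_b": MUSCLE,
        "planted_edges": sorted(planted_edges),
        "decoys": decoy_plan,
    }

    n_union = len(all_symbols)
    n_mapped = round(spec.map_coverage * n_union)
    mapped_syms = sorted(
        np.array(all_symbols)[rng.choice(n_union, size=n_mapped, replace=False)].tolist()
    )
    ortholog_entries = {s: (f"H{s}", "ortholog") for s in mapped_syms}
    manifest["orthology"] = {"n_input": n_union, "n_mapped": n_mapped}

    proteomes = {
        tissue: TissueProteome.from_symbols(tissue, tissue_symbols[tissue])
        for tissue in (ADIPOSE, MUSCLE)
    }
    features = assemble_features(
        signalp=signalp, targetp=targetp, gaf_records=gaf_records, topology=topology
    )
    return Bundle(
        proteomes=proteomes,
        features=features,
        dag=dag,
        signalp=signalp,
        targetp=targetp,
        topology=topology,
        gaf_records=gaf_records,
        atlas_members=atlas_members,
        mitab_records=mitab_records,
        expression=expression,
        ortholog_entries=ortholog_entries,
        manifest=manifest,
    )


_EXPERIMENTAL_METHODS = ("two hybrid", "anti bait coimmunoprecipitation", "pull down")
_PREDICTED_METHOD = "in silico prediction"


def _plant_ppi(rng, spec, sec_a, surf_b, negatives):
    """Plant true crosstalk edges and reason-tagged decoy records."""
    sec = sorted(sec_a)
    surf = sorted(surf_b)
    records: set[MitabRecord] = set()
    used_pairs: set[frozenset] = set()

    def _mk(a, b, method, sources=("IntAct",)):
        return MitabRecord(
            interactor_a=min(a, b),
            interactor_b=max(a, b),
            detection_methods=frozenset({method}),
            interaction_types=frozenset({"association"}),
            evidence_class="predicted" if method == _PREDICTED_METHOD else "experimental",
            source_dbs=frozenset(sources),
            publications=frozenset({f"pubmed:{int(rng.integers(10**6, 10**7))}"}),
        )

    def _fresh_pair(pool_a, pool_b):
        """A not-yet-used unordered pair, or None when the pool is exhausted."""
        if not pool_a or not pool_b:
            return None
        for _ in range(200):
            x = pool_a[int(rng.integers(len(pool_a)))]
            y = pool_b[int(rng.integers(len(pool_b)))]
            if x != y and frozenset((x, y)) not in used_pairs:
                used_pairs.add(frozenset((x, y)))
                return x, y
        exhaustive = [
            (x, y) for x in pool_a for y in pool_b
            if x != y and frozenset((x, y)) not in used_pairs
        ]
        if not exhaustive:
            return None
        x, y = exhaustive[int(rng.integers(len(exhaustive)))]
        used_pairs.add(frozenset((x, y)))
        return x, y

    planted = []
    n_true = min(spec.n_planted_crosstalk, len(sec) * len(surf))
    for _ in range(n_true):
        pair = _fresh_pair(sec, surf)
        if pair is None:
            break
        a, b = pair
        method = str(rng.choice(_EXPERIMENTAL_METHODS))
        records.add(_mk(a, b, method))
        planted.append((a, b) if a in sec_a else (b, a))
    # normalize orientation secreted -> surface
    planted = [(x, y) if x in sec_a and y in surf_b else (y, x) for x, y in planted]

    weights = np.asarray(spec.decoy_weights, dtype=float)
    decoy_plan: dict[str, int] = {"non_experimental": 0, "wrong_compartment": 0, "non_member": 0}
    decoy_counter = 0
    if spec.n_decoy_ppi and weights.sum() > 0:
        probs = weights / weights.sum()
        kinds = rng.choice(3, size=spec.n_decoy_ppi, p=probs)
        for kind in kinds:
            pair = None
            if kind == 0:
                pair = _fresh_pair(sec, surf)
            elif kind == 1:
                pair = _fresh_pair(sec, sec)
            if kind == 0 and pair is not None:
                records.add(_mk(*pair, _PREDICTED_METHOD))
                decoy_plan["non_experimental"] += 1
            elif kind == 1 and pair is not None:
                records.add(_mk(*pair, str(rng.choice(_EXPERIMENTAL_METHODS))))
                decoy_plan["wrong_compartment"] += 1
            else:
                # pool exhausted (or kind 2): fall back to a non-member decoy,
                # always constructible from the reserved DECOY namespace
                a = sec[int(rng.integers(len(sec)))] if sec else negatives[0] if negatives else "SYNNONE0"
                b = f"DECOY{decoy_counter:04d}"
                decoy_counter += 1
                used_pairs.add(frozenset((a, b)))
                records.add(_mk(a, b, str(rng.choice(_EXPERIMENTAL_METHODS))))
                decoy_plan["non_member"] += 1
    return records, planted, decoy_plan
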