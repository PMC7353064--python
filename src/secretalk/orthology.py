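"""Cross-species identifier translation through a user-supplied mapping table.

Bovine proteome lists are translated to human gene symbols so that
annotation-rich human resources (GO, interaction databases) can be applied.
The mapping is file-driven (TSV: ``bovine_id  human_symbol  relation``);
every input protein is accounted for as exactly one of mapped or unmapped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from .core import InvalidSymbolError, ProteinRecord, TissueProteome, normalize_symbol
from .io_formats import FormatError, ParseLog, _data_lines

__all__ = ["OrthologMap", "read_ortholog_map", "write_ortholog_map", "map_to_human"]

log = logging.getLogger(__name__)

RELATIONS = ("ortholog", "homolog")


@dataclass
class OrthologMap:
    """bovine id/symbol -> (human symbol, relation) lookups.

    One bovine identifier maps to one human symbol (first-listed wins when a
    table lists several, with the alternatives logged); many bovine ids may
    map to the same human symbol.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    alternatives: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, bovine_id: str, human_symbol: str, relation: str = "ortholog") -> None:
        if relation not in RELATIONS:
            raise ValueError(f"relation must be one of {RELATIONS}, got {relation!r}")
        key = normalize_symbol(bovine_id)
        human = normalize_symbol(human_symbol)
        if key in self.entries:
            if self.entries[key][0] != human:
                self.alternatives.setdefault(key, []).append(human)
                log.warning(
                    "bovine id %s maps to multiple human symbols; keeping first (%s), also saw %s",
                    key, self.entries[key][0], human,
                )
            return
        self.entries[key] = (human, relation)

    def lookup(self, identifier: str) -> tuple[str, str] | None:
        """Mapped-or-unmapped lookup; never raises for unknown ids."""
        try:
            return self.entries.get(normalize_symbol(identifier))
        except InvalidSymbolError:
            return None


def read_ortholog_map(path, strict: bool = True) -> tuple[OrthologMap, ParseLog]:
    """Read a headered mapping TSV (bovine_id, human_symbol, relation)."""
    plog = ParseLog()
    omap = OrthologMap()
    lines = list(_data_lines(path, "#"))
    for lineno, line in lines[1:] if lines else []:
        parts = line.split("\t")
        if len(parts) < 2:
            plog.skip(f"{path}:{lineno}: expected >= 2 columns", strict)
            continue
        relation = parts[2].strip() if len(parts) > 2 and parts[2].strip() else "ortholog"
        try:
            omap.add(parts[0], parts[1], relation)
        except (InvalidSymbolError, ValueError) as exc:
            plog.skip(f"{path}:{lineno}: {exc}", strict)
    return omap, plog


def write_ortholog_map(path, omap: OrthologMap) -> None:
    with open(path, "w") as fh:
        fh.write("bovine_id\thuman_symbol\trelation\n")
        for key in sorted(omap.entries):
            human, relation = omap.entries[key]
            fh.write(f"{key}\t{human}\t{relation}\n")


def map_to_human(
    proteome: TissueProteome, omap: OrthologMap
) -> tuple[TissueProteome, list[str]]:
    """Translate a proteome to human symbols, returning (mapped, unmapped).

    Lookups try the canonical symbol first, then each accession. Records
    mapping to the same human symbol collapse into one with unioned
    provenance; the original bovine symbol joins the accession set. Every
    input record appears exactly once across the two outputs.
    """
    if len(omap) == 0:
        raise ValueError("empty ortholog map")
    mapped: list[ProteinRecord] = []
    unmapped: list[str] = []
    for rec in proteome:
        hit = omap.lookup(rec.canonical_symbol)
        if hit is None:
            for acc in sorted(rec.accessions):
                hit = omap.lookup(acc)
                if hit is not None:
                    break
        if hit is None:
            unmapped.append(rec.canonical_symbol)
            continue
        human_symbol, relation = hit
        mapped.append(
            ProteinRecord(
                canonical_symbol=human_symbol,
                accessions=rec.accessions | {rec.canonical_symbol},
                species="human",
                source_tags=rec.source_tags | {f"relation:{relation}"},
            )
        )
    return TissueProteome.from_records(proteome.tissue, mapped), sorted(unmapped)
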