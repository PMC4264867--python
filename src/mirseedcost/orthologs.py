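"""Cross-species target-set comparison through an ortholog map.

Conserved miRNAs carry sequentially identical seeds across species, yet the
genes they target can diverge because seed-complementary sites in
orthologous 3'UTRs are gained and lost over evolutionary time (target-site
turnover). This module maps per-species target sets through a two-species
ortholog table and contrasts intra-specific overlap (two miRNAs compared
within one species) with inter-specific overlap (the same miRNA's targets
compared across species after ortholog restriction and mapping).

Ortholog maps are consumed from two-column TSV files (a BioMart-export
layout); live ortholog queries are out of scope. One-to-many orthologs
expand into all partners — the only policy that cannot silently drop true
overlap — and are flagged in the report; many-to-one relations merge under
set semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .overlap import cosine_similarity
from .targets import TargetSet

logger = logging.getLogger(__name__)

__all__ = [
    "OrthologMap",
    "read_ortholog_map",
    "restrict_to_orthologs",
    "map_target_set",
    "species_overlap_report",
]


@dataclass
class OrthologMap:
    """Directed gene-id correspondence between species A and species B.

    Lookup works both ways; many-to-many relations are allowed but flagged
    via ``has_multi_mappings``.
    """

    forward: dict[str, set[str]] = field(default_factory=dict)  # A gene -> B genes
    reverse: dict[str, set[str]] = field(default_factory=dict)  # B gene -> A genes

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        m = cls()
        for a, b in pairs:
            m.forward.setdefault(a, set()).add(b)
            m.reverse.setdefault(b, set()).add(a)
        return m

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.forward.values())

    @property
    def has_multi_mappings(self) -> bool:
        return any(len(v) > 1 for v in self.forward.values()) or any(
            len(v) > 1 for v in self.reverse.values()
        )

    def lookup(self, side: str) -> dict[str, set[str]]:
        if side == "a":
            return self.forward
        if side == "b":
            return self.reverse
        raise ValueError(f"side must be 'a' or 'b', got {side!r}")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Load a two-column TSV (header required) into an OrthologMap.

    Duplicate identical rows collapse to one pair; a row with an empty cell
    is an error reported with its line number.
    """
    pairs: list[tuple[str, str]] = []
    with open(path) as handle:
        header = handle.readline()
        if not header.strip():
            logger.warning("%s: empty ortholog file; map is empty", path)
            return OrthologMap()
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: row with missing gene id")
            pairs.append((fields[0].strip(), fields[1].strip()))
    if not pairs:
        logger.warning("%s: no ortholog pairs found", path)
    return OrthologMap.from_pairs(pairs)


def restrict_to_orthologs(target_set: TargetSet, omap: OrthologMap, side: str) -> TargetSet:
    """Drop genes that have no ortholog in the other species.

    ``side`` names the species the set belongs to ("a" or "b").
    """
    lookup = omap.lookup(side)
    return TargetSet(
        mirna_id=target_set.mirna_id,
        genes={g for g in target_set.genes if g in lookup},
        provenance=target_set.provenance,
    )


def map_target_set(target_set: TargetSet, omap: OrthologMap, side: str) -> TargetSet:
    """Translate a target set into the other species' gene namespace.

    Every gene is replaced by all of its orthologs (one-to-many expands;
    many-to-one merges under set semantics). The set must already be
    restricted to orthologs — an unmapped gene is an error.
    """
    lookup = omap.lookup(side)
    mapped: set[str] = set()
    for gene in target_set.genes:
        if gene not in lookup:
            raise KeyError(
                f"gene {gene!r} has no ortholog; call restrict_to_orthologs first"
            )
        mapped |= lookup[gene]
    return TargetSet(
        mirna_id=target_set.mirna_id, genes=mapped, provenance=target_set.provenance
    )


def species_overlap_report(
    sets_species_a: Mapping[str, TargetSet],
    sets_species_b: Mapping[str, TargetSet],
    omap: OrthologMap,
    direction: str = "b_to_a",
) -> pd.DataFrame:
    """Intra- and inter-specific cosine overlaps for two species' target sets.

    Intra-specific rows compare every miRNA pair within one species.
    Inter-specific rows compare, for each miRNA id present in both panels,
    its species-A set with its species-B set after both are restricted to
    orthologs and the B side is mapped into A's namespace (``direction``
    "b_to_a"; "a_to_b" mirrors this, and "symmetric" averages the two).
    Pairs with an empty post-restriction set are skipped with a warning.

    Returns a DataFrame with columns: comparison (intra_a / intra_b /
    inter), id_a, id_b, n_a, n_b, n_shared, cosine, multi_mapping_flag.
    """
    if direction not in ("b_to_a", "a_to_b", "symmetric"):
        raise ValueError(f"unknown direction {direction!r}")
    rows: list[dict] = []

    def _intra(sets: Mapping[str, TargetSet], label: str) -> None:
        ids = sorted(sets)
        for i, ida in enumerate(ids):
            for idb in ids[i + 1 :]:
                a, b = sets[ida].genes, sets[idb].genes
                if not a or not b:
                    logger.warning("skipping intra pair (%s, %s): empty set", ida, idb)
                    continue
                rows.append(
                    dict(
                        comparison=label, id_a=ida, id_b=idb,
                        n_a=len(a), n_b=len(b), n_shared=len(a & b),
                        cosine=cosine_similarity(a, b),
                        multi_mapping_flag=omap.has_multi_mappings,
                    )
                )

    _intra(sets_species_a, "intra_a")
    _intra(sets_species_b, "intra_b")

    def _inter_cosine(ts_a: TargetSet, ts_b: TargetSet, d: str) -> tuple[set, set] | None:
        if d == "b_to_a":
            ra = restrict_to_orthologs(ts_a, omap, "a").genes
            rb = map_target_set(restrict_to_orthologs(ts_b, omap, "b"), omap, "b").genes
        else:  # a_to_b
            ra = map_target_set(restrict_to_orthologs(ts_a, omap, "a"), omap, "a").genes
            rb = restrict_to_orthologs(ts_b, omap, "b").genes
        if not ra or not rb:
            return None
        return ra, rb

    for mid in sorted(set(sets_species_a) & set(sets_species_b)):
        ts_a, ts_b = sets_species_a[mid], sets_species_b[mid]
        dirs = ["b_to_a", "a_to_b"] if direction == "symmetric" else [direction]
        cosines, na, nb, nsh = [], 0, 0, 0
        skipped = False
        for d in dirs:
            pair = _inter_cosine(ts_a, ts_b, d)
            if pair is None:
                skipped = True
                break
            ra, rb = pair
            cosines.append(cosine_similarity(ra, rb))
            na, nb, nsh = len(ra), len(rb), len(ra & rb)
        if skipped or not cosines:
            logger.warning("skipping inter comparison for %s: empty post-restriction set", mid)
            continue
        rows.append(
            dict(
                comparison="inter", id_a=mid, id_b=mid,
                n_a=na, n_b=nb, n_shared=nsh,
                cosine=float(sum(cosines) / len(cosines)),
                multi_mapping_flag=omap.has_multi_mappings,
            )
        )

    return pd.DataFrame(
        rows,
        columns=[
            "comparison", "id_a", "id_b", "n_a", "n_b",
            "n_shared", "cosine", "multi_mapping_flag",
        ],
    )
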