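"""Mature miRNA parsing, seed extraction, and pairwise seed distances.

The target specificity of an animal miRNA is encoded almost entirely in its
*seed region*: the 7 nucleotides at mature positions 2-8 (1-based, inclusive,
counted from the 5' end). This module loads mature miRNA panels from FASTA,
extracts seeds, and computes pairwise Hamming distances between seeds — the
number of nucleotide changes needed to transform one seed into another —
which downstream analyses use to group miRNA pairs into mismatch classes 0-7.

Coordinates are 1-based inclusive throughout, so "positions 2-8" means the
second through eighth nucleotide of the mature sequence.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")

__all__ = [
    "MatureMiRNA",
    "SeedRegion",
    "MismatchClassTable",
    "canonicalize_rna",
    "read_mature_fasta",
    "extract_seed",
    "hamming_distance",
    "mismatch_positions",
    "build_mismatch_table",
    "group_identical_seeds",
    "write_mismatch_table",
]


def canonicalize_rna(sequence: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T->U; reject anything outside {A,C,G,U}.

    DNA-alphabet input (miRBase and UTR files differ on this) is silently
    converted to RNA. Ambiguity codes are a hard error: a 7-mer seed
    containing N has no defined match set.
    """
    canonical = sequence.upper().replace("T", "U")
    bad = set(canonical) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{context} contains non-ACGU characters after canonicalization: "
            f"{sorted(bad)}"
        )
    return canonical


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3', canonical RNA alphabet.

    ``species_prefix`` is the leading token of a miRBase-style id
    ("hsa-miR-429" -> "hsa"); empty when the id has no dash-separated prefix.
    """

    id: str
    sequence: str
    species_prefix: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", canonicalize_rna(self.sequence, context=f"miRNA {self.id!r}")
        )
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.id!r}: mature sequence must be >= 8 nt, got {len(self.sequence)}"
            )
        if not self.species_prefix:
            head, dash, _ = self.id.partition("-")
            object.__setattr__(self, "species_prefix", head if dash else "")


@dataclass(frozen=True)
class SeedRegion:
    """The seed of one miRNA: mature positions ``start_pos``-``end_pos`` (1-based inclusive)."""

    mirna_id: str
    seed: str
    start_pos: int = 2
    end_pos: int = 8

    def __post_init__(self) -> None:
        expected = self.end_pos - self.start_pos + 1
        if len(self.seed) != expected:
            raise ValueError(
                f"seed of {self.mirna_id!r} has length {len(self.seed)}, "
                f"expected {expected} for positions {self.start_pos}-{self.end_pos}"
            )


@dataclass
class MismatchClassTable:
    """All unordered miRNA pairs with their seed Hamming distances.

    ``pairs`` holds one entry per unordered pair as
    (mirna_id_a, mirna_id_b, distance), with a < b lexicographically so the
    table is byte-for-byte reproducible.
    """

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    seeds: dict[str, str] = field(default_factory=dict)

    def distance(self, a: str, b: str) -> int:
        a, b = sorted((a, b))
        for pa, pb, d in self.pairs:
            if pa == a and pb == b:
                return d
        raise KeyError(f"pair ({a!r}, {b!r}) not in table")

    def by_class(self) -> dict[int, list[tuple[str, str]]]:
        out: dict[int, list[tuple[str, str]]] = {}
        for a, b, d in self.pairs:
            out.setdefault(d, []).append((a, b))
        return out


def read_mature_fasta(path: str | Path) -> list[MatureMiRNA]:
    """Read a mature-miRNA FASTA (plain or gzip) into a panel.

    The header token before the first whitespace becomes the id. Ids must be
    unique within the file; T is canonicalized to U.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    panel: list[MatureMiRNA] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise ValueError(f"{path}: FASTA record with empty header")
            if record.id in seen:
                raise ValueError(f"{path}: duplicate miRNA id {record.id!r}")
            seq = str(record.seq)
            if not seq:
                raise ValueError(f"{path}: record {record.id!r} has an empty sequence")
            panel.append(MatureMiRNA(id=record.id, sequence=seq))
            seen.add(record.id)
    return panel


def extract_seed(mirna: MatureMiRNA, start: int = 2, end: int = 8) -> SeedRegion:
    """Extract the seed: mature positions ``start``..``end``, 1-based inclusive.

    Defaults give the canonical 7-nt seed at positions 2-8.
    """
    if start < 1 or end < start:
        raise ValueError(f"invalid seed window {start}-{end}")
    if len(mirna.sequence) < end:
        raise ValueError(
            f"miRNA {mirna.id!r}: sequence length {len(mirna.sequence)} "
            f"shorter than seed window end {end}"
        )
    return SeedRegion(
        mirna_id=mirna.id,
        seed=mirna.sequence[start - 1 : end],
        start_pos=start,
        end_pos=end,
    )


def _check_equal_length(a: SeedRegion, b: SeedRegion) -> None:
    if len(a.seed) != len(b.seed):
        raise ValueError(
            f"seed length mismatch: {a.mirna_id!r} has {len(a.seed)} nt, "
            f"{b.mirna_id!r} has {len(b.seed)} nt"
        )


def hamming_distance(a: SeedRegion, b: SeedRegion) -> int:
    """Number of positions at which two equal-length seeds differ."""
    _check_equal_length(a, b)
    return sum(x != y for x, y in zip(a.seed, b.seed))


def mismatch_positions(a: SeedRegion, b: SeedRegion, coordinate_offset: int = 2) -> list[int]:
    """Mature-coordinate positions (1-based) where two seeds differ.

    Seed index i (0-based) maps to mature position ``i + coordinate_offset``;
    the default offset 2 places the first seed nucleotide at mature position 2.
    """
    _check_equal_length(a, b)
    return [i + coordinate_offset for i, (x, y) in enumerate(zip(a.seed, b.seed)) if x != y]


def build_mismatch_table(panel: Iterable[MatureMiRNA]) -> MismatchClassTable:
    """Hamming distance for every unordered pair in the panel (canonical order a < b)."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel is empty")
    seeds = {m.id: extract_seed(m) for m in panel}
    table = MismatchClassTable(seeds={mid: s.seed for mid, s in seeds.items()})
    for a, b in combinations(sorted(seeds), 2):
        table.pairs.append((a, b, hamming_distance(seeds[a], seeds[b])))
    return table


def group_identical_seeds(panel: Iterable[MatureMiRNA]) -> dict[str, list[str]]:
    """Partition the panel into identical-seed families: seed string -> sorted miRNA ids.

    A family of size k contributes k(k-1)/2 identical-seed (class 0) pairs.
    """
    families: dict[str, list[str]] = {}
    for mirna in panel:
        families.setdefault(extract_seed(mirna).seed, []).append(mirna.id)
    return {seed: sorted(ids) for seed, ids in families.items()}


def write_mismatch_table(table: MismatchClassTable, path: str | Path) -> None:
    """Write the pair table as TSV: mirna_a, mirna_b, seed_a, seed_b, distance."""
    with open(path, "w") as out:
        out.write("mirna_a\tmirna_b\tseed_a\tseed_b\tdistance\n")
        for a, b, d in table.pairs:
            out.write(f"{a}\t{b}\t{table.seeds[a]}\t{table.seeds[b]}\t{d}\n")
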