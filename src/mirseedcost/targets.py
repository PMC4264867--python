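"""Target prediction: seed-complementary site scanning and prediction-table readers.

A miRNA recognizes a target through Watson-Crick pairing between its seed and
a complementary window in the mRNA 3'UTR. We scan supplied UTR sequences
(mRNA sense strand, 5'->3') for the canonical site classes of the
TargetScan literature, built from the reverse complement of the seed:

* ``7mer-m8`` — exact match to revcomp of the full 7-nt seed (mature 2-8);
* ``7mer-A1`` — match to revcomp of seed nucleotides 1-6 (mature 2-7)
  followed by an A in the UTR (the position opposite mature position 1);
* ``8mer``    — both: revcomp of the full seed followed by an A;
* ``6mer``    — the 6-nt core match alone.

Every core occurrence is classified into its strongest class (8mer beats the
two 7mers, which beat 6mer) and reported once. Gene-level set semantics:
a gene enters a miRNA's target set once, however many sites it carries —
the analyses downstream count overlapping *genes*.

Precomputed prediction tables are supported in two TSV dialects: the
miRanda-mirSVR layout (mirna_id, gene_symbol, mirsvr_score; records kept when
the score is strictly below a threshold, default -0.2, more negative =
stronger predicted down-regulation) and a generic two-column layout
(mirna_id, gene_symbol; TargetScan/PicTar-style lists, kept as-is).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .seed import MatureMiRNA, SeedRegion, canonicalize_rna, extract_seed

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
DEFAULT_SITE_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

__all__ = [
    "UTRSequence",
    "TargetSite",
    "TargetSet",
    "SITE_TYPES",
    "DEFAULT_SITE_TYPES",
    "reverse_complement",
    "read_utr_fasta",
    "seed_match_sites",
    "predict_targets",
    "load_prediction_table",
    "write_target_sets",
]


@dataclass(frozen=True)
class UTRSequence:
    """One gene's 3'UTR, mRNA sense strand, canonical RNA alphabet."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"UTR of {self.gene_id!r} is empty")
        object.__setattr__(
            self, "sequence", canonicalize_rna(self.sequence, context=f"UTR {self.gene_id!r}")
        )


@dataclass(frozen=True)
class TargetSite:
    """A seed-complementary match window in one UTR; start/end 1-based inclusive."""

    gene_id: str
    site_type: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.end < self.start:
            raise ValueError(f"site end {self.end} < start {self.start}")


@dataclass
class TargetSet:
    """The genes predicted as targets of one miRNA (set semantics)."""

    mirna_id: str
    genes: set[str] = field(default_factory=set)
    provenance: str = "scanned"


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string."""
    return canonicalize_rna(seq, context="sequence")[::-1].translate(_COMPLEMENT)


def read_utr_fasta(path: str | Path) -> list[UTRSequence]:
    """Read a 3'UTR FASTA (plain or gzip); header token before whitespace = gene id."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    utrs: list[UTRSequence] = []
    seen: set[str] = set()
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"{path}: duplicate gene id {record.id!r}")
            utrs.append(UTRSequence(gene_id=record.id, sequence=str(record.seq)))
            seen.add(record.id)
    return utrs


def _classify_core_hit(utr_seq: str, pos: int, m8_char: str) -> tuple[str, int, int]:
    """Classify the core-6 occurrence at 0-based ``pos`` into its strongest class.

    Returns (site_type, start0, end0_exclusive) of the full match window.
    """
    has_m8 = pos > 0 and utr_seq[pos - 1] == m8_char
    has_a1 = pos + 6 < len(utr_seq) and utr_seq[pos + 6] == "A"
    if has_m8 and has_a1:
        return "8mer", pos - 1, pos + 7
    if has_m8:
        return "7mer-m8", pos - 1, pos + 6
    if has_a1:
        return "7mer-A1", pos, pos + 7
    return "6mer", pos, pos + 6


def seed_match_sites(
    seed: SeedRegion,
    utr: UTRSequence,
    site_types: Iterable[str] = DEFAULT_SITE_TYPES,
) -> list[TargetSite]:
    """All seed-complementary sites of the requested classes in one UTR.

    Scanning anchors on the 6-nt core (revcomp of seed nucleotides 1-6) and
    extends: a preceding match to the complement of seed nucleotide 7 gives
    the m8 pairing, a following A gives the A1 anchor. Each occurrence is
    reported once under its strongest class; an 8mer is never additionally
    reported as its constituent 7mers. Sites are returned 5'->3' by start,
    coordinates 1-based inclusive.
    """
    requested = set(site_types)
    if not requested:
        raise ValueError("site_types must be non-empty")
    unknown = requested - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site types: {sorted(unknown)}")
    if len(seed.seed) != 7:
        raise ValueError(f"seed of {seed.mirna_id!r} must be 7 nt, got {len(seed.seed)}")

    core = reverse_complement(seed.seed[:6])          # matches mature positions 2-7
    m8_char = seed.seed[6].translate(_COMPLEMENT)     # complement of mature position 8
    seq = utr.sequence
    sites: list[TargetSite] = []
    pos = seq.find(core)
    while pos != -1:
        site_type, s0, e0 = _classify_core_hit(seq, pos, m8_char)
        if site_type in requested:
            sites.append(TargetSite(utr.gene_id, site_type, start=s0 + 1, end=e0))
        pos = seq.find(core, pos + 1)
    return sites


def predict_targets(
    panel: Sequence[MatureMiRNA],
    utrs: Sequence[UTRSequence],
    site_types: Iterable[str] = DEFAULT_SITE_TYPES,
    min_sites: int = 1,
) -> dict[str, TargetSet]:
    """Scan every UTR with every panel miRNA's seed; gene-level target sets.

    A gene enters a miRNA's set iff it carries at least ``min_sites``
    qualifying sites. miRNAs with identical seeds necessarily receive
    identical sets.
    """
    if not panel or not utrs:
        raise ValueError("panel and UTR pool must be non-empty")
    site_types = frozenset(site_types)
    result: dict[str, TargetSet] = {}
    # scan once per distinct seed, then fan out to the miRNAs sharing it
    by_seed: dict[str, list[str]] = {}
    for mirna in panel:
        by_seed.setdefault(extract_seed(mirna).seed, []).append(mirna.id)
    for seed_str, mirna_ids in by_seed.items():
        seed = SeedRegion(mirna_id=mirna_ids[0], seed=seed_str)
        genes = {
            utr.gene_id
            for utr in utrs
            if len(seed_match_sites(seed, utr, site_types)) >= min_sites
        }
        for mid in mirna_ids:
            result[mid] = TargetSet(mirna_id=mid, genes=set(genes), provenance="scanned")
    return result


def load_prediction_table(
    path: str | Path,
    dialect: str = "mirsvr",
    score_threshold: float = -0.2,
) -> dict[str, TargetSet]:
    """Read a precomputed prediction TSV into per-miRNA target sets.

    ``mirsvr`` dialect (header mirna_id, gene_symbol, mirsvr_score) keeps a
    record iff its score is strictly less than ``score_threshold`` — the
    default -0.2 cut minimizes false positives. ``two_column`` (header
    mirna_id, gene_symbol) keeps every record. Duplicate rows collapse under
    set semantics.
    """
    if dialect not in ("mirsvr", "two_column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    expected_cols = 3 if dialect == "mirsvr" else 2
    sets: dict[str, TargetSet] = {}
    with open(path) as handle:
        header = handle.readline()
        if not header.strip():
            raise ValueError(f"{path}: missing header row")
        for lineno, line in enumerate(handle, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < expected_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected_cols} columns, got {len(fields)}"
                )
            mirna_id, gene = fields[0], fields[1]
            if not mirna_id or not gene:
                raise ValueError(f"{path}:{lineno}: empty miRNA or gene field")
            if dialect == "mirsvr":
                try:
                    score = float(fields[2])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad score {fields[2]!r}") from exc
                if not score < score_threshold:  # strict "less than"
                    continue
            ts = sets.setdefault(
                mirna_id, TargetSet(mirna_id=mirna_id, genes=set(), provenance=f"table:{dialect}")
            )
            ts.genes.add(gene)
    return sets


def write_target_sets(sets: dict[str, TargetSet], path: str | Path) -> None:
    """Export target sets as TSV (mirna_id, gene_id), sorted for reproducibility."""
    with open(path, "w") as out:
        out.write("mirna_id\tgene_id\n")
        for mid in sorted(sets):
            for gene in sorted(sets[mid].genes):
                out.write(f"{mid}\t{gene}\n")
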