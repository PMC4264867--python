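"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study design end to end without any downloads:

* miRNA panels whose pairwise seed mismatch counts (and, optionally, the
  exact mismatch positions) are controlled, with identical non-seed
  regions within a constrained group — mirroring synthetic miRNA
  constructs that isolate the effect of seed variation;
* 3'UTR pools with seed-complementary sites planted at recorded offsets,
  over a rejection-sampled background guaranteed to contain no unplanned
  site of any panel seed — intentionally cleaner than biology, so
  planted-site recovery is exact rather than statistical;
* Gaussian log2-scale expression matrices with a planted fraction of
  differentially expressed genes at a stated effect size (in units of the
  noise standard deviation), emulating triplicate transfection contrasts;
* two-species ortholog scenarios in which species B's UTRs start as copies
  of species A's and each planted site is independently destroyed with a
  tunable turnover probability, plus the bijective ortholog map.

Every generator is driven by an explicit seed (no hidden global state), so
identical seeds give byte-identical outputs, and each returns its truth
object alongside the data; downstream recovery tests consume only
(data, truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .orthologs import OrthologMap
from .seed import MatureMiRNA, SeedRegion, extract_seed, hamming_distance, mismatch_positions
from .targets import TargetSite, UTRSequence, reverse_complement, seed_match_sites

RNA = "ACGU"

__all__ = [
    "SimulationTruth",
    "gen_mirna_panel",
    "gen_utr_pool",
    "independent_site_plan",
    "gen_expression",
    "gen_ortholog_scenario",
    "write_panel_fasta",
    "write_utr_fasta",
    "make_fixtures",
]


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside generated data.

    Only the fields relevant to the emitting generator are populated:
    ``sites`` maps (mirna_id, gene_id) to the planted/recovered TargetSites,
    ``pair_mismatches`` maps canonical miRNA pairs to intended Hamming
    distance, ``de_direction`` maps planted DE genes to +1/-1,
    ``absent_features`` lists features planted as absent,
    ``site_retained`` maps (gene_id, site_start) to the species-B retention
    flag of an ortholog scenario.
    """

    rng_seed: int = 0
    sites: dict[tuple[str, str], list[TargetSite]] = field(default_factory=dict)
    pair_mismatches: dict[tuple[str, str], int] = field(default_factory=dict)
    de_direction: dict[str, int] = field(default_factory=dict)
    effect_size: float = 0.0
    absent_features: list[str] = field(default_factory=list)
    site_retained: dict[tuple[str, int], bool] = field(default_factory=dict)

    def target_genes(self, mirna_id: str) -> set[str]:
        """True target-gene set of one miRNA (genes with >= 1 planted site)."""
        return {g for (m, g), s in self.sites.items() if m == mirna_id and s}


# ---------------------------------------------------------------------------
# miRNA panels with controlled seed mismatches


def _random_rna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(RNA), size=length))


def _mutate_seed(
    mature: str,
    k: int,
    positions: Sequence[int] | None,
    rng: np.random.Generator,
    start: int = 2,
    end: int = 8,
) -> str:
    """Mutate exactly k seed positions (1-based mature coordinates) of ``mature``."""
    window = list(range(start, end + 1))
    if positions is None:
        positions = sorted(rng.choice(window, size=k, replace=False))
    else:
        positions = sorted(positions)
        if len(positions) != k or any(p not in window for p in positions):
            raise ValueError(
                f"mismatch positions {positions} inconsistent with k={k} and "
                f"seed window {start}-{end}"
            )
    seq = list(mature)
    for pos in positions:
        current = seq[pos - 1]
        seq[pos - 1] = rng.choice([b for b in RNA if b != current])
    return "".join(seq)


def _normalize_spec(
    mismatch_spec: Iterable[tuple], ids: Sequence[str]
) -> list[tuple[str, str, int, tuple[int, ...] | None]]:
    norm = []
    for entry in mismatch_spec:
        if len(entry) == 3:
            a, b, k = entry
            positions = None
        elif len(entry) == 4:
            a, b, k, positions = entry
            positions = tuple(positions)
        else:
            raise ValueError(f"mismatch spec entry must be (a, b, k[, positions]): {entry}")
        a = ids[a] if isinstance(a, int) else a
        b = ids[b] if isinstance(b, int) else b
        if a == b:
            raise ValueError(f"self-pair in mismatch spec: {a}")
        if not 0 <= k <= 7:
            raise ValueError(f"mismatch count must be in [0, 7], got {k}")
        norm.append((a, b, int(k), positions))
    return norm


def _shifted_core_collision(seeds: dict[str, str]) -> bool:
    """True if one seed's maximal complement pattern embeds another's core.

    The widest site window for a seed is m8 + core + A (8 nt); if a
    *different* core occurs anywhere inside it, any planted site for the
    first miRNA is an unavoidable off-target site for the second, and a
    clean background cannot exist.
    """
    patterns = {s: _site_pattern(s, "8mer") for s in set(seeds.values())}
    cores = {s: reverse_complement(s[:6]) for s in set(seeds.values())}
    for sx, pattern in patterns.items():
        for sy, core_y in cores.items():
            if cores[sx] != core_y and core_y in pattern:
                return True
    return False


def gen_mirna_panel(
    n: int,
    mismatch_spec: Iterable[tuple] = (),
    rng_seed: int = 0,
    mature_length: int = 22,
    ids: Sequence[str] | None = None,
    max_attempts: int = 200,
    exclusive_cores: bool = True,
) -> tuple[list[MatureMiRNA], SimulationTruth]:
    """Generate ``n`` mature miRNAs with controlled pairwise seed mismatches.

    ``mismatch_spec`` entries are (id_or_index_a, id_or_index_b, k) or
    (..., k, positions) with positions in 1-based mature coordinates within
    the seed window 2-8. Constrained miRNAs share identical non-seed
    regions within each connected constraint group; unconstrained miRNAs
    are fully random. With ``exclusive_cores`` (the default) panels where
    one seed's complement pattern embeds a different seed's 6-nt core are
    resampled, so planted sites stay specific to their intended seed. An
    unsatisfiable (cyclic, contradictory) spec raises after bounded retries.
    """
    if ids is None:
        ids = [f"syn-miR-{i + 1}" for i in range(n)]
    if len(ids) != n or len(set(ids)) != n:
        raise ValueError("ids must be unique and match n")
    spec = _normalize_spec(mismatch_spec, ids)

    adjacency: dict[str, list[tuple[str, int, tuple[int, ...] | None]]] = {i: [] for i in ids}
    for a, b, k, positions in spec:
        adjacency[a].append((b, k, positions))
        adjacency[b].append((a, k, positions))

    rng = np.random.default_rng(rng_seed)
    for _ in range(max_attempts):
        sequences: dict[str, str] = {}
        # BFS over constraint components; roots get random sequences
        for root in ids:
            if root in sequences:
                continue
            sequences[root] = _random_rna(mature_length, rng)
            queue = [root]
            while queue:
                node = queue.pop(0)
                for other, k, positions in adjacency[node]:
                    if other in sequences:
                        continue
                    sequences[other] = _mutate_seed(sequences[node], k, positions, rng)
                    queue.append(other)
        panel = [MatureMiRNA(id=i, sequence=sequences[i]) for i in ids]
        seeds = {m.id: extract_seed(m) for m in panel}
        ok = all(
            hamming_distance(seeds[a], seeds[b]) == k
            and (positions is None or tuple(mismatch_positions(seeds[a], seeds[b])) == positions)
            for a, b, k, positions in spec
        )
        if ok and exclusive_cores:
            ok = not _shifted_core_collision({i: s.seed for i, s in seeds.items()})
        if ok:
            truth = SimulationTruth(rng_seed=rng_seed)
            for a, b, k, _ in spec:
                truth.pair_mismatches[tuple(sorted((a, b)))] = k
            return panel, truth
    raise ValueError(
        "mismatch spec could not be satisfied (contradictory or cyclic constraints)"
    )


# ---------------------------------------------------------------------------
# UTR pools with planted sites over a clean background


def _site_pattern(seed: str, site_type: str) -> str:
    """The exact UTR window that constitutes a site of ``site_type`` for ``seed``."""
    core = reverse_complement(seed[:6])
    m8 = reverse_complement(seed[6])
    if site_type == "7mer-m8":
        return m8 + core
    if site_type == "7mer-A1":
        return core + "A"
    if site_type == "8mer":
        return m8 + core + "A"
    if site_type == "6mer":
        return core
    raise ValueError(f"unknown site type {site_type!r}")


def _core_occurrences(seq: str, core: str) -> list[int]:
    out, pos = [], seq.find(core)
    while pos != -1:
        out.append(pos)
        pos = seq.find(core, pos + 1)
    return out


def _assemble_gene(
    windows: list[tuple[str, str, int]],
    utr_length: int,
    cores: set[str],
    rng: np.random.Generator,
    max_attempts: int = 100,
) -> tuple[str, list[int]]:
    """One UTR of ``utr_length`` containing the windows and no stray core match.

    Each window is (pattern, core, core_offset): the planted string, the
    6-nt core it realizes, and the core's 0-based offset within the
    pattern. Windows are placed in random order at random non-overlapping
    offsets; the whole gene is resampled until, for every panel core, the
    occurrence positions in the assembled sequence are exactly the designed
    ones — no background hit, no junction-spanning hit, no shifted hit
    inside a window. Returns (sequence, 0-based window starts in input
    order).
    """
    total_win = sum(len(w[0]) for w in windows)
    if total_win > utr_length:
        raise ValueError(
            f"planted windows ({total_win} nt) do not fit in UTR length {utr_length}"
        )
    for _ in range(max_attempts):
        order = list(rng.permutation(len(windows))) if windows else []
        bg_total = utr_length - total_win
        # split the background into len(windows)+1 random-size gaps
        cuts = np.sort(rng.integers(0, bg_total + 1, size=len(windows))) if windows else []
        gaps = np.diff(np.concatenate(([0], cuts, [bg_total]))) if windows else [bg_total]
        parts: list[str] = []
        starts = [0] * len(windows)
        cursor = 0
        for slot, gap in zip(order + [None], gaps):
            parts.append(_random_rna(int(gap), rng))
            cursor += int(gap)
            if slot is not None:
                starts[slot] = cursor
                parts.append(windows[slot][0])
                cursor += len(windows[slot][0])
        seq = "".join(parts)
        designed: dict[str, set[int]] = {c: set() for c in cores}
        for i, (_, core, core_offset) in enumerate(windows):
            designed.setdefault(core, set()).add(starts[i] + core_offset)
        if all(set(_core_occurrences(seq, c)) == designed.get(c, set()) for c in cores):
            return seq, starts
    raise RuntimeError(
        "background rejection failed repeatedly; the panel's seed density is too "
        "high for this UTR length — use longer UTRs or fewer planted sites"
    )


def independent_site_plan(
    mirna_ids: Sequence[str],
    gene_ids: Sequence[str],
    site_prob: float,
    rng: np.random.Generator,
) -> dict[tuple[str, str], int]:
    """Independent random site placement: each (miRNA, gene) gets one site
    with probability ``site_prob``, independently — no engineered sharing."""
    plan: dict[tuple[str, str], int] = {}
    for mid in mirna_ids:
        hits = rng.random(len(gene_ids)) < site_prob
        for gid, hit in zip(gene_ids, hits):
            if hit:
                plan[(mid, gid)] = 1
    return plan


def gen_utr_pool(
    panel: Sequence[MatureMiRNA],
    n_genes: int,
    utr_length: int,
    site_plan: Mapping[tuple[str, str], int],
    rng_seed: int = 0,
    site_type: str = "7mer-m8",
    gene_prefix: str = "G",
) -> tuple[list[UTRSequence], SimulationTruth]:
    """A pool of ``n_genes`` UTRs with sites planted per ``site_plan``.

    ``site_plan`` maps (mirna_id, gene_id) to a planted site count; gene ids
    are ``{gene_prefix}0001`` .. and may also appear only implicitly (genes
    absent from the plan get pure background). The background is
    rejection-sampled so that no unplanned window matches ANY panel seed's
    complement in any site class (every 7mer/8mer class contains the 6-nt
    core, so excluding the cores excludes them all).

    Truth records, per (miRNA, gene), the sites actually recoverable by
    scanning — which includes sites planted for an identical-core seed of a
    different miRNA, so the truth is exact for every panel member.
    """
    gene_ids = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    known = set(gene_ids)
    for (mid, gid) in site_plan:
        if gid not in known:
            raise ValueError(f"site plan references unknown gene {gid!r}")
        if mid not in {m.id for m in panel}:
            raise ValueError(f"site plan references unknown miRNA {mid!r}")

    seeds = {m.id: extract_seed(m) for m in panel}
    if _shifted_core_collision({mid: s.seed for mid, s in seeds.items()}):
        raise ValueError(
            "panel seeds collide: one seed's complement pattern embeds another's "
            "core, so a clean background is impossible — regenerate the panel "
            "(gen_mirna_panel with exclusive_cores=True avoids this)"
        )
    cores = {reverse_complement(s.seed[:6]) for s in seeds.values()}
    core_offset = 1 if site_type in ("7mer-m8", "8mer") else 0
    rng = np.random.default_rng(rng_seed)

    utrs: list[UTRSequence] = []
    truth = SimulationTruth(rng_seed=rng_seed)
    for gid in gene_ids:
        windows: list[tuple[str, str, int]] = []
        for mid in sorted(seeds):
            count = site_plan.get((mid, gid), 0)
            pattern = _site_pattern(seeds[mid].seed, site_type)
            core = reverse_complement(seeds[mid].seed[:6])
            windows.extend([(pattern, core, core_offset)] * count)
        seq, _ = _assemble_gene(windows, utr_length, cores, rng)
        utr = UTRSequence(gene_id=gid, sequence=seq)
        utrs.append(utr)
        for mid, seed in seeds.items():
            found = seed_match_sites(seed, utr, site_types=("8mer", "7mer-m8", "7mer-A1", "6mer"))
            if found:
                truth.sites[(mid, gid)] = found
    return utrs, truth


# ---------------------------------------------------------------------------
# expression matrices with planted DE genes


def gen_expression(
    n_genes: int,
    n_per_group: int = 3,
    de_fraction: float = 0.1,
    effect_size: float = 3.0,
    noise_sd: float = 0.25,
    rng_seed: int = 0,
    absent_fraction: float = 0.0,
    baseline_range: tuple[float, float] = (6.0, 12.0),
    de_genes: Sequence[str] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, SimulationTruth]:
    """Gaussian log2-scale matrix with a planted fraction of DE genes.

    Each gene gets a baseline drawn uniformly from ``baseline_range`` and
    i.i.d. Gaussian noise with ``noise_sd``. Exactly
    round(de_fraction * n_genes) genes are shifted in the treated group by
    ±(effect_size * noise_sd), direction random, recorded in the truth;
    ``de_genes`` pins the planted set explicitly (overriding
    ``de_fraction``), which lets two contrasts share planted truth.
    Presence calls are all-present except for a planted ``absent_fraction``
    of genes called absent in every sample (these should fall to the
    presence filter). Returns (matrix, calls, truth).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    samples = [f"treated_{i + 1}" for i in range(n_per_group)] + [
        f"control_{i + 1}" for i in range(n_per_group)
    ]
    baseline = rng.uniform(*baseline_range, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, 2 * n_per_group))

    truth = SimulationTruth(rng_seed=rng_seed, effect_size=effect_size)
    if de_genes is not None:
        index = {g: i for i, g in enumerate(genes)}
        unknown = [g for g in de_genes if g not in index]
        if unknown:
            raise ValueError(f"unknown de_genes: {unknown[:3]}")
        de_idx = np.array([index[g] for g in de_genes], dtype=int)
        n_de = len(de_idx)
    else:
        n_de = round(de_fraction * n_genes)
        de_idx = rng.choice(n_genes, size=n_de, replace=False)
    directions = rng.choice([-1, 1], size=n_de)
    for idx, direction in zip(de_idx, directions):
        values[idx, :n_per_group] += direction * effect_size * noise_sd
        truth.de_direction[genes[idx]] = int(direction)

    calls = pd.DataFrame(True, index=genes, columns=samples)
    n_absent = round(absent_fraction * n_genes)
    if n_absent:
        absent_idx = rng.choice(
            np.setdiff1d(np.arange(n_genes), de_idx), size=n_absent, replace=False
        )
        for idx in absent_idx:
            calls.iloc[idx, :] = False
            truth.absent_features.append(genes[idx])

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        groups=pd.Series(
            ["treated"] * n_per_group + ["control"] * n_per_group, index=samples
        ),
    )
    return matrix, calls, truth


# ---------------------------------------------------------------------------
# two-species ortholog scenarios with target-site turnover


def gen_ortholog_scenario(
    panel: Sequence[MatureMiRNA],
    n_genes: int,
    turnover_rate: float,
    rng_seed: int = 0,
    utr_length: int = 200,
    site_prob: float = 0.4,
    site_type: str = "7mer-m8",
    site_plan: Mapping[tuple[str, str], int] | None = None,
    max_attempts: int = 100,
) -> tuple[list[UTRSequence], list[UTRSequence], OrthologMap, SimulationTruth]:
    """Two species' UTR pools related by site turnover, plus the ortholog map.

    Species A's pool is generated like :func:`gen_utr_pool` (with an
    independent random site plan at ``site_prob`` unless ``site_plan`` is
    given). Species B starts as a base-identical copy with its own gene
    namespace, and each planted site window is independently destroyed —
    overwritten with rejection-sampled background that creates no new site
    — with probability ``turnover_rate``. The emitted ortholog map is
    bijective (GA... <-> GB...). Truth carries species A's sites, per-site
    retention flags, and species B's recoverable sites.
    """
    if not 0.0 <= turnover_rate <= 1.0:
        raise ValueError("turnover_rate must be in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    gene_ids_a = [f"GA{i + 1:04d}" for i in range(n_genes)]
    if site_plan is None:
        site_plan = independent_site_plan(
            sorted({m.id for m in panel}), gene_ids_a, site_prob, rng
        )
    pool_a, truth = gen_utr_pool(
        panel,
        n_genes,
        utr_length,
        site_plan,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        site_type=site_type,
        gene_prefix="GA",
    )

    seeds = {m.id: extract_seed(m) for m in panel}
    cores = {reverse_complement(s.seed[:6]) for s in seeds.values()}
    a_to_b = {ga: "GB" + ga[2:] for ga in gene_ids_a}
    omap = OrthologMap.from_pairs(sorted(a_to_b.items()))

    # distinct site windows per gene (identical-seed miRNAs share windows);
    # each entry: (span_start_1based, span_end_1based, core_pos_0based, core)
    windows_by_gene: dict[str, list[tuple[int, int, int, str]]] = {}
    seq_by_gene = {u.gene_id: u.sequence for u in pool_a}
    for (mid, gid), sites in truth.sites.items():
        for s in sites:
            core0 = s.start if s.site_type in ("8mer", "7mer-m8") else s.start - 1
            entry = (s.start, s.end, core0, seq_by_gene[gid][core0 : core0 + 6])
            lst = windows_by_gene.setdefault(gid, [])
            if entry not in lst:
                lst.append(entry)

    pool_b: list[UTRSequence] = []
    for utr in pool_a:
        gb = a_to_b[utr.gene_id]
        spans = sorted(windows_by_gene.get(utr.gene_id, []))
        destroy = [bool(rng.random() < turnover_rate) for _ in spans]
        for span, lost in zip(spans, destroy):
            truth.site_retained[(gb, span[0])] = not lost
        seq = utr.sequence
        for _ in range(max_attempts):
            chars = list(seq)
            for (start, end, _, _), lost in zip(spans, destroy):
                if lost:
                    chars[start - 1 : end] = list(_random_rna(end - start + 1, rng))
            candidate = "".join(chars)
            kept: dict[str, set[int]] = {c: set() for c in cores}
            for (_, _, core0, core), lost in zip(spans, destroy):
                if not lost:
                    kept.setdefault(core, set()).add(core0)
            if all(
                set(_core_occurrences(candidate, c)) == kept.get(c, set()) for c in cores
            ):
                break
        else:
            raise RuntimeError(
                "could not destroy sites without creating new ones; use longer UTRs"
            )
        utr_b = UTRSequence(gene_id=gb, sequence=candidate)
        pool_b.append(utr_b)
        for mid, seed in seeds.items():
            found = seed_match_sites(
                seed, utr_b, site_types=("8mer", "7mer-m8", "7mer-A1", "6mer")
            )
            if found:
                truth.sites[(mid, gb)] = found
    return pool_a, pool_b, omap, truth


# ---------------------------------------------------------------------------
# file materialization


def write_panel_fasta(panel: Sequence[MatureMiRNA], path: str | Path) -> None:
    with open(path, "w") as out:
        for m in panel:
            out.write(f">{m.id}\n{m.sequence}\n")


def write_utr_fasta(utrs: Sequence[UTRSequence], path: str | Path) -> None:
    with open(path, "w") as out:
        for u in utrs:
            out.write(f">{u.gene_id}\n{u.sequence}\n")


def make_fixtures(
    outdir: str | Path,
    rng_seed: int = 0,
    n_genes: int = 300,
    utr_length: int = 200,
    site_prob: float = 0.15,
    n_expr_genes: int = 1000,
    turnover_rate: float = 0.5,
) -> dict[str, Path]:
    """Materialize a complete demo dataset (FASTA/TSV) in ``outdir``.

    Emits a mismatch-controlled 8-miRNA panel, a UTR pool with independent
    site placement, a 3 vs 3 expression matrix with 10% planted DE genes, a
    probe->gene map, and a two-species ortholog scenario. Returns a name ->
    path map of everything written. Deterministic given ``rng_seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)

    panel, _ = gen_mirna_panel(
        8, mismatch_spec=default_panel_spec(), rng_seed=int(seeds[0])
    )
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    plan = independent_site_plan(
        [m.id for m in panel], gene_ids, site_prob, np.random.default_rng(int(seeds[1]))
    )
    utrs, _ = gen_utr_pool(panel, n_genes, utr_length, plan, rng_seed=int(seeds[1]))
    matrix, calls, _ = gen_expression(
        n_expr_genes, n_per_group=3, de_fraction=0.1, effect_size=3.0, rng_seed=int(seeds[2])
    )
    pool_a, pool_b, omap, _ = gen_ortholog_scenario(
        panel[:2], n_genes=max(100, n_genes // 2), turnover_rate=turnover_rate,
        rng_seed=int(seeds[3]), utr_length=utr_length,
    )

    paths = {
        "panel_fasta": outdir / "panel.fa",
        "utr_fasta": outdir / "utrs.fa",
        "expression_tsv": outdir / "expression.tsv",
        "groups_tsv": outdir / "groups.tsv",
        "calls_tsv": outdir / "presence_calls.tsv",
        "probe_map_tsv": outdir / "probe_to_gene.tsv",
        "utr_fasta_species_a": outdir / "species_a_utrs.fa",
        "utr_fasta_species_b": outdir / "species_b_utrs.fa",
        "ortholog_map_tsv": outdir / "orthologs.tsv",
    }
    write_panel_fasta(panel, paths["panel_fasta"])
    write_utr_fasta(utrs, paths["utr_fasta"])
    matrix.values.to_csv(paths["expression_tsv"], sep="\t")
    with open(paths["groups_tsv"], "w") as out:
        out.write("sample_id\tgroup\n")
        for sample, group in matrix.groups.items():
            out.write(f"{sample}\t{group}\n")
    calls.astype(int).to_csv(paths["calls_tsv"], sep="\t")
    with open(paths["probe_map_tsv"], "w") as out:
        out.write("probe_id\tgene_symbol\n")
        for feature in matrix.values.index:
            out.write(f"{feature}\tSYM_{feature}\n")
    write_utr_fasta(pool_a, paths["utr_fasta_species_a"])
    write_utr_fasta(pool_b, paths["utr_fasta_species_b"])
    with open(paths["ortholog_map_tsv"], "w") as out:
        out.write("gene_a\tgene_b\n")
        for ga in sorted(omap.forward):
            for gb in sorted(omap.forward[ga]):
                out.write(f"{ga}\t{gb}\n")
    return paths


def default_panel_spec() -> list[tuple]:
    """Mismatch spec for an 8-miRNA panel whose pairs span classes 0-7.

    syn-miR-1/2 are an identical-seed pair (class 0); syn-miR-3..8 differ
    from syn-miR-1 by 1..6 seed nucleotides. Mismatch positions stay inside
    mature positions 2-7 (the 6-nt core) so every non-identical pair also
    differs in its core and planted sites remain miRNA-exclusive; the pair
    (syn-miR-3, syn-miR-8) realizes class 7.
    """
    return [
        ("syn-miR-1", "syn-miR-2", 0),
        ("syn-miR-1", "syn-miR-3", 1, (2,)),
        ("syn-miR-1", "syn-miR-4", 2, (3, 4)),
        ("syn-miR-1", "syn-miR-5", 3, (3, 5, 6)),
        ("syn-miR-1", "syn-miR-6", 4, (2, 4, 5, 7)),
        ("syn-miR-1", "syn-miR-7", 5, (2, 3, 5, 6, 7)),
        ("syn-miR-1", "syn-miR-8", 6, (3, 4, 5, 6, 7, 8)),
    ]
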