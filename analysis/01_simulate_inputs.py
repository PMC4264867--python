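"""Materialize the synthetic inputs every later analysis step consumes.

Writes a mismatch-controlled 8-miRNA panel, a 3'UTR pool with planted
seed-complementary sites, a 3 vs 3 expression matrix with 10% planted DE
genes, and a two-species ortholog scenario, all under results/fixtures/.
Everything downstream (02-05) can also regenerate data in memory; these
files exist so the full pipeline is inspectable as plain FASTA/TSV.
"""

import argparse
from pathlib import Path

from mirseedcost.simulate import make_fixtures


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    paths = make_fixtures(args.outdir / "fixtures", rng_seed=args.seed)
    print(f"wrote {len(paths)} fixture files under {args.outdir / 'fixtures'}:")
    for name, path in sorted(paths.items()):
        print(f"  {name:24s} {path}")


if __name__ == "__main__":
    main()
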