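"""Cross-species target overlap under increasing target-site turnover.

Generates two-species UTR scenarios for an identical-seed miRNA pair
(emulating miR-429/miR-200b, whose seeds are identical in human and
mouse) at turnover rates 0 to 0.75. Within each species the two miRNAs
overlap completely (identical seeds, same UTRs); across species the
overlap decays as planted sites are lost, approximately as
sqrt(retained fraction). Writes the full intra/inter report per rate
under results/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mirseedcost import predict_targets, species_overlap_report
from mirseedcost.simulate import gen_mirna_panel, gen_ortholog_scenario

RATES = (0.0, 0.25, 0.5, 0.75)
N_GENES = 500


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    panel, _ = gen_mirna_panel(
        2, [("syn-miR-1", "syn-miR-2", 0)], rng_seed=int(rng.integers(0, 2**31 - 1))
    )
    frames = []
    print("turnover  intra-species%  inter-species%  sqrt(retained)%")
    for rate in RATES:
        pa, pb, omap, _ = gen_ortholog_scenario(
            panel, N_GENES, rate, rng_seed=int(rng.integers(0, 2**31 - 1)), site_prob=0.4
        )
        rep = species_overlap_report(
            predict_targets(panel, pa), predict_targets(panel, pb), omap
        )
        rep.insert(0, "turnover", rate)
        frames.append(rep)
        intra = rep[rep.comparison.isin(["intra_a", "intra_b"])].cosine.mean() * 100
        inter = rep[rep.comparison == "inter"].cosine.mean() * 100
        print(f"{rate:8.2f}  {intra:14.1f}  {inter:14.1f}  {np.sqrt(1 - rate) * 100:15.1f}")

    pd.concat(frames).to_csv(
        args.outdir / "species_overlap_by_turnover.tsv", sep="\t", index=False,
        float_format="%.6f",
    )
    print(
        f"\nidentical seeds keep intra-species overlap at 100% while site "
        f"turnover divorces the cross-species target sets; full report in "
        f"{args.outdir / 'species_overlap_by_turnover.tsv'}"
    )


if __name__ == "__main__":
    main()
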