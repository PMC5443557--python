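#!/usr/bin/env python
"""Per-study gene scores: normalize, gate, collapse probes, standardize.

Turns each study's probe statistics into one standardized score per gene:
the normalized median-ratio effect weighted by |logFC_m|/(|logFC_m|+MAD)
and gated on adjusted p <= 0.05 and B > 0, with multi-probe genes collapsed
to their most variable probe. Tables land under results/gene_scores/.
"""

import argparse
from pathlib import Path

from nfmeta import io, scoring

STUDIES = ["HS1", "HS2", "HS3", "HS4", "MS1"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic_inputs"))
    ap.add_argument("--stats", type=Path, default=Path("results/de_stats"))
    ap.add_argument("--out", type=Path, default=Path("results/gene_scores"))
    args = ap.parse_args()

    for sid in STUDIES:
        stats = io.read_table(args.stats / f"{sid}_stats.tsv")
        probe_map = io.read_probe_map(args.inputs / f"{sid}_probe_map.tsv")
        genes = scoring.score_study(stats, probe_map)
        io.write_table(genes, args.out / f"{sid}_gene_scores.tsv")
        nonnull = (genes["s_std"] != 0).sum()
        print(f"{sid}: {genes.shape[0]} genes after collapse, "
              f"{nonnull} with non-null score")
    print(f"gene scores written to {args.out}")


if __name__ == "__main__":
    main()
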