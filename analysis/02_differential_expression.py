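#!/usr/bin/env python
"""Per-study differential statistics between the two phenotypes.

Reads the cohort written by 01_simulate_cohort.py, applies the ANOVA/FDR
prefilter, and computes per-probe effect sizes (logFC, median-ratio
logFC_m), the MAD reproducibility penalty, and moderated t / B statistics.
One stats table per study lands under results/de_stats/.
"""

import argparse
from pathlib import Path

from nfmeta import destats, io

STUDIES = [("HS1", "human"), ("HS2", "human"), ("HS3", "human"),
           ("HS4", "human"), ("MS1", "mouse")]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--inputs", type=Path, default=Path("results/synthetic_inputs"))
    ap.add_argument("--out", type=Path, default=Path("results/de_stats"))
    args = ap.parse_args()

    for sid, species in STUDIES:
        study = io.read_expression_study(
            args.inputs / f"{sid}_matrix.tsv",
            args.inputs / f"{sid}_samples.tsv",
            args.inputs / f"{sid}_probe_map.tsv",
            species=species,
            study_id=sid,
            comparison=("MPNST", "NF"),
        )
        filtered = destats.anova_prefilter(study)
        stats = destats.probe_stats(filtered)
        io.write_table(stats, args.out / f"{sid}_stats.tsv")
        n_sig = (stats["adj_p"] <= 0.05).sum()
        print(f"{sid}: {study.n_probes} probes -> {filtered.n_probes} after "
              f"prefilter; {n_sig} with adjusted p <= 0.05")
    print(f"stats written to {args.out}")


if __name__ == "__main__":
    main()
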