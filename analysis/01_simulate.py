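#!/usr/bin/env python
"""Generate the synthetic study: feature table, sample metadata, truth.

Emulates the culture-experiment design — 470 metabolites (372 abundant),
7 isolates in two supplemented media with n=3 replicates, a producer
cell-extract / spent-minimal-medium block, and an n=8-per-timepoint
soil-water wetting time course. Writes everything under
results/synthetic/.
"""

import argparse
from pathlib import Path

from exoniche.io import write_adduct_rules, write_feature_table, write_sample_metadata, default_adduct_rules
from exoniche.simulate import GeneratorConfig, generate_experiment, generate_timecourse


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    cfg = GeneratorConfig(seed=args.seed)
    table, meta, truth = generate_experiment(cfg)
    abundance, sw_meta, truth = generate_timecourse(cfg, truth)

    write_feature_table(table, out / "features.tsv")
    write_sample_metadata(meta, out / "samples.tsv")
    write_adduct_rules(default_adduct_rules(), out / "adduct_rules.yaml")
    abundance.to_csv(out / "soil_water.tsv", sep="\t")
    write_sample_metadata(sw_meta, out / "soil_water_samples.tsv")
    (out / "truth.json").write_text(truth.to_json())

    print(f"metabolites: {len(truth.metabolites)} "
          f"(abundant: {int(truth.metabolites['abundant'].sum())})")
    print(f"features: {len(table.features)}  samples: {len(table.sample_ids)}")
    print(f"soil-water metabolites: {len(abundance)} over "
          f"{sw_meta['timepoint_min'].nunique()} timepoints")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
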