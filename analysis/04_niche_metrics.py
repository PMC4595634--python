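#!/usr/bin/env python
"""Niche-partitioning statistics and the bipartite network.

Builds the isolate x metabolite utilization matrix over the available
set, then reports per-isolate used fractions, the shared-use
distribution, competition and cross-feeding candidate sets, and pairwise
niche overlap. Writes summary JSON, TSVs and GraphML under results/.
"""

import argparse
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from exoniche.io import read_feature_table, read_sample_metadata
from exoniche.niche import pairwise_overlap, percent, shared_use_distribution
from exoniche.pipeline import PipelineConfig, analyze_experiment
from exoniche.simulate import RELEASE_MEDIUM


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_feature_table(args.indir / "features.tsv")
    meta = read_sample_metadata(args.indir / "samples.tsv")
    cfg = PipelineConfig(release_medium=RELEASE_MEDIUM, assign_formulas=False)
    res = analyze_experiment(table, meta, cfg)
    s = res.summary

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    res.matrix.calls.to_csv(out / "utilization_matrix.tsv", sep="\t")
    hist, cum = shared_use_distribution(res.matrix)
    pd.DataFrame({"n_isolates": list(hist), "n_metabolites": list(hist.values()),
                  "n_metabolites_at_least": list(cum.values())}
                 ).to_csv(out / "shared_use.tsv", sep="\t", index=False)
    pairwise_overlap(res.matrix, "jaccard").to_csv(out / "overlap_jaccard.tsv", sep="\t")
    res.edges.to_csv(out / "bipartite_edges.tsv", sep="\t", index=False)
    nx.write_graphml(res.graph, out / "bipartite.graphml")
    with open(out / "niche_summary.json", "w") as fh:
        json.dump(s, fh, indent=2, sort_keys=True)

    d = s["denominator"]
    lo = min(s["per_isolate_used_fraction"].values())
    hi = max(s["per_isolate_used_fraction"].values())
    print(f"available metabolites: {d}; isolates: {s['n_isolates']}")
    print(f"per-isolate used fraction: {percent(lo)}-{percent(hi)}% "
          f"(unused by all: {s['unused_percent']}%)")
    print(f"used by every isolate: {s['n_used_by_all']}")
    print(f"competition candidates (>=2 uptake, 0 release): {s['n_competition_candidates']}")
    print(f"cross-feeding candidates (release + uptake by another): "
          f"{s['n_crossfeeding_candidates']}")
    print(f"mean pairwise Jaccard overlap of uptake sets: "
          f"{s['mean_pairwise_jaccard']:.3f}")
    print(f"wrote niche tables and {out}/bipartite.graphml")


if __name__ == "__main__":
    main()
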