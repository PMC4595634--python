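"""End-to-end orchestration: ion resolution -> classification -> niche stats.

``analyze_experiment`` runs the whole culture-experiment analysis in memory;
``run_pipeline`` wraps it with file I/O, persisting every stage intermediate
as TSV/JSON so stages are independently inspectable and re-runnable.  All
outputs are deterministic for fixed inputs (sorted keys, no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import classify as _classify
from . import ion_grouping as _ig
from . import niche as _niche
from . import release as _release
from . import wetting as _wetting
from .formulas import assign_formula
from .io import (
    FeatureTable,
    default_adduct_rules,
    read_adduct_rules,
    read_feature_table,
    read_sample_metadata,
)

log = logging.getLogger("exoniche")


@dataclass
class PipelineConfig:
    """All stage parameters, with assay-derived defaults."""

    feature_table: str | None = None
    sample_metadata: str | None = None
    adduct_rules: str | None = None
    outdir: str = "results"
    seed: int = 0
    # ion grouping
    rt_tol: float = 0.3
    corr_min: float = 0.9
    mz_tol: float = 0.02
    mass_tol: float = 0.005
    # formula assignment
    assign_formulas: bool = True
    formula_ppm: float = 5.0
    # classification
    alpha: float = 0.05
    min_area: float = 5000.0
    detect_area: float = 1000.0
    abundance_mode: str = "any_sample"
    fdr: bool = False
    log10_areas: bool = False
    media: list[str] | None = None  # utilization media; None = all spent media
    conflict_policy: str = "as_resolved"
    # release profile
    release_medium: str | None = None  # medium holding the producer's spent minimal samples
    # wetting time course
    dilution_factor: float = 1.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def classify_params(self) -> _classify.ClassifyParams:
        return _classify.ClassifyParams(
            alpha=self.alpha,
            min_area=self.min_area,
            detect_area=self.detect_area,
            abundance_mode=self.abundance_mode,
            fdr=self.fdr,
            log10_areas=self.log10_areas,
        )


@dataclass
class ExperimentResult:
    groups: list
    records: list
    records_table: pd.DataFrame
    abundance: pd.DataFrame
    abundant_ids: pd.Index
    calls: pd.DataFrame
    consensus: pd.DataFrame
    matrix: _niche.UtilizationMatrix
    summary: dict
    edges: pd.DataFrame
    graph: nx.Graph
    release_profile: _release.ReleaseProfile | None = None
    release_table: pd.DataFrame | None = None


def analyze_experiment(
    table: FeatureTable,
    meta: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> ExperimentResult:
    """Run ion resolution, classification and niche statistics in memory."""
    cfg = config or PipelineConfig()
    rules = read_adduct_rules(cfg.adduct_rules) if cfg.adduct_rules else default_adduct_rules()

    log.info("grouping %d features across %d samples", len(table.features), len(table.sample_ids))
    # correlate across the comparative media runs only: cell extracts (and a
    # dedicated release-assay medium) live on a different intensity scale
    # and would leverage unrelated co-eluting metabolites together
    corr_samples = meta.index[
        meta["role"].isin(("control", "spent"))
        & (meta["medium_id"] != cfg.release_medium if cfg.release_medium else True)
    ]
    corr_samples = [s for s in corr_samples if s in table.sample_ids]
    groups, records = _ig.resolve_metabolites(
        table,
        rules,
        rt_tol=cfg.rt_tol,
        corr_min=cfg.corr_min,
        mz_tol=cfg.mz_tol,
        mass_tol=cfg.mass_tol,
        sample_subset=corr_samples or None,
    )
    log.info("resolved %d ion groups into %d putative metabolites", len(groups), len(records))

    if cfg.assign_formulas:
        group_by_id = {g.group_id: g for g in groups}
        for rec in records:
            if rec.neutral_mass is None:
                continue
            m1 = None
            for gid in rec.source_groups:
                m1 = _ig.estimate_m1_ratio(group_by_id[gid], table, cfg.mz_tol)
                if m1 is not None:
                    break
            cands = assign_formula(rec.neutral_mass, m1_ratio=m1, mass_tol_ppm=cfg.formula_ppm)
            if cands:
                rec.formula = cands[0].formula

    abundance = _ig.abundance_table(records, table)
    abundant_ids = _classify.filter_abundant(
        abundance, meta, min_area=cfg.min_area, mode=cfg.abundance_mode
    )
    log.info("%d of %d metabolites abundant (>= %g counts in a control sample)",
             len(abundant_ids), len(records), cfg.min_area)

    media = cfg.media
    if media is None and cfg.release_medium is not None:
        spent_media = sorted(set(meta.loc[meta["role"] == "spent", "medium_id"].dropna()))
        media = [m for m in spent_media if m != cfg.release_medium]
    calls = _classify.classify_experiment(abundance, meta, cfg.classify_params(), media=media)
    consensus = _classify.combine_across_media(calls)
    isolates = sorted(calls["isolate_id"].unique())
    matrix = _niche.build_utilization_matrix(
        consensus, abundant_ids, isolates, conflict_policy=cfg.conflict_policy
    )
    summary = _niche.niche_summary(matrix)
    graph, edges = _niche.export_bipartite(matrix)

    result = ExperimentResult(
        groups=groups,
        records=records,
        records_table=_ig.records_frame(records),
        abundance=abundance,
        abundant_ids=abundant_ids,
        calls=calls,
        consensus=consensus,
        matrix=matrix,
        summary=summary,
        edges=edges,
        graph=graph,
    )

    if cfg.release_medium is not None:
        result.release_profile, result.release_table = _release_stage(
            abundance, meta, cfg
        )
    return result


def _release_stage(abundance: pd.DataFrame, meta: pd.DataFrame, cfg: PipelineConfig):
    ext_ids = list(meta.index[meta["role"] == "cell_extract"])
    ctl_ids = list(
        meta.index[(meta["role"] == "control") & (meta["medium_id"] == cfg.release_medium)]
    )
    spent_ids = list(
        meta.index[(meta["role"] == "spent") & (meta["medium_id"] == cfg.release_medium)]
    )
    if not ext_ids or not ctl_ids or not spent_ids:
        raise ValueError(
            f"release stage needs cell_extract samples plus control and spent samples "
            f"in medium {cfg.release_medium!r}"
        )
    profile = _release.classify_release(
        abundance[ext_ids], abundance[spent_ids], abundance[ctl_ids], cfg.detect_area
    )
    return profile, _release.rank_abundance_table(profile)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-level orchestration; returns the report dict written to disk."""
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    if cfg.feature_table is None or cfg.sample_metadata is None:
        raise ValueError("feature_table and sample_metadata paths are required")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = read_feature_table(cfg.feature_table)
    meta = read_sample_metadata(cfg.sample_metadata)
    res = analyze_experiment(table, meta, cfg)

    res.records_table.to_csv(outdir / "metabolites.tsv", sep="\t")
    res.abundance.to_csv(outdir / "abundance.tsv", sep="\t")
    res.calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    res.consensus.to_csv(outdir / "consensus.tsv", sep="\t", index=False)
    res.matrix.calls.to_csv(outdir / "utilization_matrix.tsv", sep="\t")
    hist, cum = _niche.shared_use_distribution(res.matrix)
    pd.DataFrame(
        {"n_isolates": list(hist), "n_metabolites": list(hist.values()),
         "n_metabolites_at_least": list(cum.values())}
    ).to_csv(outdir / "shared_use.tsv", sep="\t", index=False)
    _niche.pairwise_overlap(res.matrix, "jaccard").to_csv(outdir / "overlap_jaccard.tsv", sep="\t")
    res.edges.to_csv(outdir / "bipartite_edges.tsv", sep="\t", index=False)
    nx.write_graphml(res.graph, outdir / "bipartite.graphml")
    with open(outdir / "niche_summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=2, sort_keys=True)

    report = {
        "n_features": int(len(table.features)),
        "n_samples": int(len(table.sample_ids)),
        "n_ion_groups": int(len(res.groups)),
        "n_metabolites": int(len(res.records)),
        "n_abundant": int(len(res.abundant_ids)),
        "n_released_novel": len(res.matrix.released_novel),
        "niche": res.summary,
    }
    if res.release_table is not None:
        res.release_table.to_csv(outdir / "release_rank_abundance.tsv", sep="\t")
        rel_summary = {
            "release_breadth": res.release_profile.release_breadth,
            "class_counts": res.release_profile.classes.value_counts().to_dict(),
            "detect_area": res.release_profile.detect_area,
        }
        with open(outdir / "release_summary.json", "w") as fh:
            json.dump(rel_summary, fh, indent=2, sort_keys=True)
        report["release"] = rel_summary
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_timecourse(
    abundance_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    alpha: float = 0.05,
    dilution_factor: float = 1.0,
) -> dict:
    """Soil-water trend analysis from a metabolite x sample abundance TSV."""
    abundance = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = read_sample_metadata(metadata_path)
    res = _wetting.timepoint_trend(abundance, meta, alpha=alpha, dilution_factor=dilution_factor)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(outdir / "timecourse_trends.tsv", sep="\t")
    report = {
        "t_first_min": res.t_first,
        "t_last_min": res.t_last,
        "n_metabolites": int(len(res.table)),
        "n_depleted": int(len(res.depleted)),
        "n_accumulated": int(len(res.accumulated)),
        "alpha": alpha,
        "dilution_factor": dilution_factor,
    }
    with open(outdir / "timecourse_summary.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
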