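"""End-to-end orchestration: from a study bundle to pooled meta-analytic effects.

Stages, in the order they run:

1. rarefaction of the count table to a common depth;
2. per-sample variables: alpha diversity (+ Faith PD) and community-weighted
   traits/functions;
3. beta diversity: Bray-Curtis, PCoA, PERMANOVA (permutations within study);
4. compositional differential abundance (CLR Dirichlet Monte-Carlo);
5. per-compartment co-occurrence networks with the full topology suite;
6. per-study effect records per variable and random-effects pooling with
   bootstrap CIs, subgroup partition, and publication-bias diagnostics.

Every stage is callable on its own; `run_pipeline` wires them together and
returns a plain dict of DataFrames/dataclasses that the CLI writes as TSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffabund as da
from . import diversity as dv
from . import meta as ma
from . import network as nw
from . import traits as tr
from .synth import StudySet

logger = logging.getLogger("rhizometa")


@dataclass(frozen=True)
class PipelineConfig:
    rarefaction_depth: int = 10000
    n_boot: int = 999
    n_mc: int = 128
    fdr_threshold: float = 0.05
    min_relabund: float = 0.0002
    nsti_cutoff: float = 2.0
    min_subgroup_k: int = 10
    n_permutations: int = 999
    subgroup_column: str | None = "ecosystem"
    run_networks: bool = True
    run_diffabund: bool = True


def per_sample_variables(counts: pd.DataFrame, bundle: StudySet,
                         cfg: PipelineConfig) -> pd.DataFrame:
    """Alpha diversity plus community-weighted trait/function variables."""
    alpha = dv.alpha_diversity(counts, bundle.tree)
    ctt = tr.community_trait_table(counts, bundle.traits, bundle.taxonomy,
                                   bundle.function_map, cfg.nsti_cutoff)
    return alpha.join(ctt)


def study_effect_records(values: pd.DataFrame, metadata: pd.DataFrame
                         ) -> dict[str, list[ma.EffectRecord]]:
    """One EffectRecord per (study, variable) from per-sample values."""
    meta_aligned = metadata.loc[values.index]
    records: dict[str, list[ma.EffectRecord]] = {var: [] for var in values.columns}
    for study, sub in meta_aligned.groupby("study_id", sort=True):
        rhizo_ids = sub.index[sub["compartment"] == "rhizosphere"]
        bulk_ids = sub.index[sub["compartment"] == "bulk"]
        if len(rhizo_ids) == 0 or len(bulk_ids) == 0:
            logger.info("study %s lacks one compartment after filtering; skipped", study)
            continue
        for var in values.columns:
            rec = ma.effect_from_groups(values.loc[rhizo_ids, var],
                                        values.loc[bulk_ids, var],
                                        study_id=str(study), variable=var)
            if rec is not None:
                records[var].append(rec)
    return records


def compartment_network(counts: pd.DataFrame, taxonomy: pd.DataFrame,
                        cfg: PipelineConfig) -> dict:
    """Correlation network and topology metrics for one compartment's samples."""
    rho, p, q = nw.filter_and_correlate(counts, cfg.min_relabund)
    rmt = nw.rmt_threshold(rho)
    graph = nw.build_network(rho, q, rmt["threshold"], taxonomy=taxonomy,
                             rel_abundance=counts.div(counts.sum(axis=1), axis=0).mean())
    modules = nw.greedy_modules(graph)
    roles = nw.node_roles(graph, modules["assignment"])
    robustness = (nw.robustness_curve(graph)
                  if graph.number_of_nodes() >= 5 else None)
    return {
        "rho_star": rmt["threshold"],
        "rmt_converged": rmt["converged"],
        "graph": graph,
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "modularity": modules["modularity"],
        "n_modules": modules["n_modules"],
        "roles": roles,
        "natural_connectivity": nw.natural_connectivity(graph),
        "robustness": robustness,
    }


def run_pipeline(bundle: StudySet, cfg: PipelineConfig | None = None,
                 seed: int = 0) -> dict:
    """Run every stage on a study bundle; see the module docstring for order."""
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    results: dict = {"config": cfg}

    rarefied = dv.rarefy(bundle.counts, cfg.rarefaction_depth, rng)
    rarefied = rarefied.loc[:, rarefied.sum(axis=0) > 0]
    results["rarefied_samples"] = int(rarefied.shape[0])

    values = per_sample_variables(rarefied, bundle, cfg)
    results["per_sample_variables"] = values
    metadata = bundle.metadata.loc[values.index]

    # beta diversity with study-restricted permutations
    bc = dv.bray_curtis(rarefied)
    results["pcoa"] = dv.pcoa(bc, k=2)
    results["permanova"] = dv.permanova(
        bc, metadata["compartment"], n_perm=cfg.n_permutations,
        seed=rng, strata=metadata["study_id"])

    if cfg.run_diffabund:
        instances = da.dirichlet_instances(rarefied, cfg.n_mc, rng)
        results["diffabund"] = da.test_differential(
            instances, metadata["compartment"].to_numpy(),
            sample_ids=rarefied.index.to_numpy(),
            fdr_threshold=cfg.fdr_threshold,
            seed=seed, taxa=rarefied.columns)

    if cfg.run_networks:
        networks = {}
        for comp in ("rhizosphere", "bulk"):
            ids = metadata.index[metadata["compartment"] == comp]
            try:
                networks[comp] = compartment_network(
                    rarefied.loc[ids], bundle.taxonomy, cfg)
            except ValueError as exc:
                logger.warning("network for %s skipped: %s", comp, exc)
        results["networks"] = networks

    records = study_effect_records(values, metadata)
    results["effect_records"] = records
    summaries, diagnostics = [], {}
    for var, recs in records.items():
        if len(recs) < 2:
            logger.info("variable %s has fewer than 2 studies; not pooled", var)
            continue
        summaries.append(ma.random_effects_pool(recs, cfg.n_boot, rng))
        if len(recs) >= 3:
            diagnostics[var] = {
                "egger": ma.egger_test(recs),
                "trim_and_fill": ma.trim_and_fill(recs),
            }
    results["meta_summaries"] = summaries
    results["bias_diagnostics"] = diagnostics

    if cfg.subgroup_column and cfg.subgroup_column in metadata.columns:
        study_labels = (metadata.groupby("study_id")[cfg.subgroup_column]
                        .agg(lambda s: s.iloc[0]))
        feasible = (study_labels.value_counts() >= cfg.min_subgroup_k).sum() >= 2
        if feasible:
            subgroups = {}
            for var, recs in records.items():
                if len(recs) >= 2:
                    subgroups[var] = ma.subgroup_analysis(
                        recs, study_labels, min_k=cfg.min_subgroup_k,
                        n_boot=cfg.n_boot, seed=rng)
            results["subgroups"] = subgroups
        else:
            logger.info("subgroup analysis skipped: no category level reaches "
                        "min_k=%d studies", cfg.min_subgroup_k)
    return results


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def summaries_to_frame(summaries: list[ma.MetaSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries])


def write_results(results: dict, outdir: str | Path) -> None:
    """Write the pipeline outputs as plain TSV/text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results["per_sample_variables"].to_csv(out / "per_sample_variables.tsv",
                                           sep="\t", index_label="sample_id")
    if results.get("meta_summaries"):
        summaries_to_frame(results["meta_summaries"]).to_csv(
            out / "meta_summary.tsv", sep="\t", index=False)
    if "diffabund" in results:
        results["diffabund"].to_csv(out / "diffabund.tsv", sep="\t")
    perma = results.get("permanova")
    if perma:
        pd.DataFrame([perma]).to_csv(out / "permanova.tsv", sep="\t", index=False)
    for comp, net in results.get("networks", {}).items():
        net["roles"].to_csv(out / f"network_{comp}_nodes.tsv", sep="\t")
        if net["robustness"] is not None:
            net["robustness"].to_csv(out / f"network_{comp}_robustness.tsv",
                                     sep="\t", index=False)
        edges = [
            {"u": u, "v": v, "rho": d["rho"], "q": d["q"]}
            for u, v, d in net["graph"].edges(data=True)
        ]
        pd.DataFrame(edges).to_csv(out / f"network_{comp}_edges.tsv",
                                   sep="\t", index=False)
    rows = []
    for var, diag in results.get("bias_diagnostics", {}).items():
        rows.append({
            "variable": var,
            "egger_intercept": diag["egger"]["intercept"],
            "egger_p": diag["egger"]["p_value"],
            "trimfill_k0": diag["trim_and_fill"].k0,
            "trimfill_adjusted_mean": diag["trim_and_fill"].adjusted_mean,
        })
    if rows:
        pd.DataFrame(rows).to_csv(out / "bias_diagnostics.tsv", sep="\t", index=False)
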