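"""End-to-end orchestration: network -> DE -> MRA -> GSEA2 -> survival -> CMap.

Every stage writes its tables under the configured output directory; a run
log records parameters and seeds (no timestamps, so reruns with the same
config are byte-identical).  Stage failures abort with the stage name;
outputs written before the failure are retained.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import cmap as cmap_mod
from . import diffexp, enrichment, mra, network, survival
from .config import PipelineConfig
from .io import (ExpressionMatrix, read_clinical, read_expression,
                 read_gene_sets, write_gene_sets)

log = logging.getLogger("regmaster")

__all__ = ["run_pipeline", "PipelineError"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _read_labeled(spec) -> ExpressionMatrix:
    expr = read_expression(spec.expression)
    if spec.labels:
        lab = pd.read_csv(spec.labels, sep="\t").set_index("sample_id")
        expr.sample_groups = [str(lab.loc[s, "group"]) for s in expr.sample_ids]
    return expr


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns a report dict of key outputs."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    report: dict = {"networks": {}, "outdir": str(out)}
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    net_seed, gsea_seed, cmap_seed = seeds[0], seeds[1], seeds[2]

    with open(config.tfs) as fh:
        tfs = [line.strip() for line in fh if line.strip()]

    # --- reference networks -------------------------------------------------
    regulons_by_net: dict[str, list[network.Regulon]] = {}
    universe_by_net: dict[str, set[str]] = {}
    try:
        for i, ref in enumerate(config.reference_cohorts):
            expr = read_expression(ref.expression)
            seed = int(net_seed.spawn(i + 1)[-1].generate_state(1)[0] % 2**31)
            net = network.infer_edges(
                expr, [t for t in tfs if t in expr.gene_ids],
                n_perm=p.n_perm, p_cut=p.p_cut, n_boot=p.n_boot,
                support_min=p.support_min, seed=seed,
                null_pairs_per_perm=p.null_pairs_per_perm)
            net = network.apply_dpi(net, tolerance=p.dpi_tolerance)
            regs = network.assign_modes(net, expr)
            regulons_by_net[ref.id] = regs
            universe_by_net[ref.id] = set(expr.gene_ids)
            _write_network(net, regs, out, ref.id)
            report["networks"][ref.id] = {
                "n_edges": len(net.edges), "n_regulons": len(regs)}
    except Exception as exc:
        raise PipelineError("network_inference", exc) from exc

    # --- differential expression -------------------------------------------
    deg_tables: dict[str, pd.DataFrame] = {}
    study_genes: dict[str, set[str]] = {}
    try:
        for spec in config.case_control:
            expr = _read_labeled(spec)
            table = diffexp.fit_differential(expr, study_id=spec.id)
            deg_tables[spec.id] = table
            study_genes[spec.id] = set(expr.gene_ids)
            _write(table.drop(columns="zero_variance"),
                   out / f"deg_{spec.id}.tsv")
    except Exception as exc:
        raise PipelineError("differential_expression", exc) from exc

    # --- MRA + consensus ----------------------------------------------------
    common_by_net: dict[str, list[str]] = {}
    try:
        for net_id, regs in regulons_by_net.items():
            frames = []
            for study_id, table in deg_tables.items():
                universe = universe_by_net[net_id] & study_genes[study_id]
                degs = set(diffexp.select_degs(
                    table, fdr_max=p.deg_fdr, lfc_min=p.deg_lfc).index) & universe
                frames.append(mra.mra_study(regs, degs, universe,
                                            study_id=study_id,
                                            fdr_max=p.mra_fdr))
            all_mra = pd.concat(frames, ignore_index=True)
            _write(all_mra, out / f"mra_{net_id}.tsv", index=False)
            cons = mra.study_consensus(all_mra, min_frac=p.consensus_frac,
                                       min_size=p.min_regulon_size,
                                       fdr_max=p.mra_fdr)
            _write(cons, out / f"common_mr_{net_id}.tsv")
            common_by_net[net_id] = sorted(cons.index[cons["common_MR"]])
        report["common_mrs"] = common_by_net
        net_ids = list(regulons_by_net)
        if len(net_ids) >= 2:
            consensus = mra.network_consensus(common_by_net[net_ids[0]],
                                              common_by_net[net_ids[1]])
        else:
            consensus = common_by_net[net_ids[0]]
        report["consensus_mrs"] = consensus
        pd.Series(consensus, name="regulon").to_csv(
            out / "consensus_mr.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("master_regulators", exc) from exc

    # --- two-tailed GSEA ----------------------------------------------------
    try:
        for net_id, regs in regulons_by_net.items():
            keep = [r for r in regs if r.tf_id in set(common_by_net[net_id])]
            if not keep:
                continue
            frames = []
            for j, (study_id, table) in enumerate(deg_tables.items()):
                seed = gsea_seed.spawn(j + 1)[-1]
                res = enrichment.gsea2_study(
                    keep, table, n_perm=p.gsea_n_perm, rank_by=p.gsea_rank_by,
                    fdr_max=p.gsea_fdr, seed=seed)
                res.insert(0, "study", study_id)
                frames.append(res)
            _write(pd.concat(frames, ignore_index=True),
                   out / f"gsea2_{net_id}.tsv", index=False)
    except Exception as exc:
        raise PipelineError("regulon_enrichment", exc) from exc

    # --- survival (optional) ------------------------------------------------
    survival_mrs_by_net: dict[str, list[str]] = {}
    if config.survival:
        try:
            surv_expr = {s.id: read_expression(s.expression)
                         for s in config.survival}
            surv_clin = {s.id: read_clinical(s.clinical)
                         for s in config.survival}
            covariates = [c for c in ("stage", "age")
                          if all(c in cl.columns for cl in surv_clin.values())]
            for net_id, regs in regulons_by_net.items():
                keep = [r for r in regs if r.tf_id in set(common_by_net[net_id])]
                if not keep:
                    survival_mrs_by_net[net_id] = []
                    continue
                fits: list[survival.CoxResult] = []
                scores_by_reg: dict[str, dict[str, pd.Series]] = {
                    r.tf_id: {} for r in keep}
                for study_id, expr in surv_expr.items():
                    activity = enrichment.gsva_scores(
                        expr, keep, mode_handling=p.gsva_mode_handling)
                    _write(activity, out / f"activity_{net_id}_{study_id}.tsv")
                    for tf_id in activity.index:
                        s = activity.loc[tf_id]
                        scores_by_reg[tf_id][study_id] = s
                        fits.append(survival.fit_cox_regulon(
                            s, surv_clin[study_id], covariates,
                            study=study_id, unit=tf_id))
                fit_df = pd.DataFrame([{
                    "study": f.study, "regulon": f.unit, "coef": f.coef,
                    "HR": f.hr, "p": f.p, "converged": f.converged,
                    "strata": ",".join(f.strata)} for f in fits])
                _write(fit_df, out / f"cox_{net_id}.tsv", index=False)
                cons = survival.survival_consensus(
                    fits, min_frac=p.survival_frac, p_max=p.survival_p)
                _write(cons, out / f"survival_consensus_{net_id}.tsv")
                surv_mrs = sorted(cons.index[cons["consensus"]])
                survival_mrs_by_net[net_id] = surv_mrs
                for tf_id in surv_mrs:
                    groups = survival.merge_and_discretize(scores_by_reg[tf_id])
                    merged_clin = pd.concat(surv_clin.values(),
                                            ignore_index=True)
                    curves, chi2, logrank_p = survival.km_logrank(
                        groups, merged_clin)
                    km = pd.concat(
                        [c.assign(group=g) for g, c in curves.items()])
                    km.attrs["logrank_p"] = logrank_p
                    _write(km, out / f"km_{net_id}_{tf_id}.tsv")
            report["survival_mrs"] = survival_mrs_by_net
        except Exception as exc:
            raise PipelineError("survival_analysis", exc) from exc

    # --- connectivity map (optional) ----------------------------------------
    if config.drug_reference:
        try:
            ref = pd.read_csv(config.drug_reference, sep="\t", index_col=0)
            frames = []
            for net_id, regs in regulons_by_net.items():
                by_id = {r.tf_id: r for r in regs}
                presets = {"common": common_by_net[net_id],
                           "consensus": report["consensus_mrs"]}
                if survival_mrs_by_net.get(net_id):
                    presets["survival"] = survival_mrs_by_net[net_id]
                for q, (query_name, tf_list) in enumerate(presets.items()):
                    chosen = [by_id[t] for t in tf_list if t in by_id]
                    if not chosen:
                        continue
                    for j, (study_id, table) in enumerate(deg_tables.items()):
                        up, down = cmap_mod.build_query(chosen, table,
                                                        min_tags=p.min_tags)
                        seed = cmap_seed.spawn(100 * q + j + 1)[-1]
                        res = cmap_mod.score_reference(
                            up, down, ref, n_perm=p.cmap_n_perm, seed=seed,
                            study=study_id, query=query_name,
                            min_tags=p.min_tags)
                        res.insert(0, "network", net_id)
                        frames.append(res)
            all_scores = pd.concat(frames, ignore_index=True)
            _write(all_scores, out / "cmap_scores.tsv", index=False)
            combos, final = cmap_mod.repositioning_consensus(all_scores)
            combos["reverters"] = combos["reverters"].map(",".join)
            _write(combos, out / "cmap_reverters.tsv", index=False)
            pd.Series(final, name="drug").to_csv(
                out / "cmap_final_candidates.tsv", sep="\t", index=False)
            report["final_drugs"] = final
        except Exception as exc:
            raise PipelineError("connectivity_map", exc) from exc

    _write_run_log(config, out)
    with open(out / "report.json", "w") as fh:
        payload = {k: v for k, v in report.items() if k != "outdir"}
        json.dump(payload, fh, indent=2, sort_keys=True)
    return report


def _write_network(net: network.TranscriptionalNetwork,
                   regulons: list[network.Regulon],
                   out: Path, net_id: str) -> None:
    rows = [{"tf": e.tf, "target": e.target, "mi": e.mi,
             "mode": 0, "support": e.support} for e in net.edges]
    df = pd.DataFrame(rows)
    if not df.empty:
        modes = {(r.tf_id, g): m for r in regulons for g, m in r.members.items()}
        df["mode"] = [modes.get((t, g), 0) for t, g in zip(df["tf"], df["target"])]
    _write(df, out / f"network_{net_id}.tsv", index=False)
    write_gene_sets([r.to_gene_set() for r in regulons],
                    out / f"regulons_{net_id}.gmt")
    g = nx.DiGraph()
    for e in net.edges:
        g.add_edge(e.tf, e.target, mi=e.mi, support=e.support)
    nx.write_graphml(g, out / f"network_{net_id}.graphml")


def _write_run_log(config: PipelineConfig, out: Path) -> None:
    import dataclasses
    payload = {
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "reference_cohorts": [c.id for c in config.reference_cohorts],
        "case_control": [c.id for c in config.case_control],
        "survival": [c.id for c in config.survival],
        "drug_reference": bool(config.drug_reference),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def load_regulons_gmt(path: str | Path) -> list[network.Regulon]:
    """Read a signed GMT back into Regulon objects."""
    return [network.Regulon(s.name, dict(s.members))
            for s in read_gene_sets(path)]
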