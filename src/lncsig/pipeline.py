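"""End-to-end orchestration of the discovery, replication and target stages.

``run_discovery`` reproduces the selection funnel on a stimulated time
course: lncRNA filter → LRT (padj < 0.05) → kinetic classes → up-regulated
expressed PCGs (mean FPKM > 2 in ≥ 1 condition) → IFN/antiviral term
enrichment → lncRNA–PCG correlation → ±150 kb cis filter → candidate table.

``run_cohort`` tests candidates for replication (up-regulation versus HC in
≥ 2 case groups) and correlates each with the six-gene IFN score.

``run_targets`` builds one signed co-expression network per dataset,
extracts the query lncRNA's module from each, intersects them and nominates
the common protein-coding genes as putative targets.

Every run can write its intermediate tables plus a manifest recording the
configuration, seed, input digests and output paths.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .candidates import (
    PipelineConfig,
    cis_pairs,
    cohort_replication_filter,
    correlate_lnc_pcg,
    ifn_score,
    score_correlation,
    select_ifn_viral_lncrnas,
)
from .coexpression import SignedCoexpressionNetwork, intersect_modules, nominate_targets
from .data import CountMatrix
from .diffexpr import classify_lncrna, fpkm, nb_lrt_test, nb_wald_test, size_factors, vst
from .enrichment import genes_of_terms, hypergeom_enrich, select_response_terms
from .kinetics import KineticProfiler
from .simulate import SimulationConfig

log = logging.getLogger("lncsig")


def load_config(path) -> tuple[SimulationConfig, PipelineConfig]:
    """Read a YAML config with optional ``simulation`` and ``pipeline`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.get("simulation", {})
    if "groups" in sim:
        sim["groups"] = dict(sim["groups"])
    for key in ("kinetic_class_probs", "cis_gap_range", "lib_size_range"):
        if key in sim:
            sim[key] = tuple(sim[key])
    pipe = raw.get("pipeline", {})
    if "ifn_genes" in pipe:
        pipe["ifn_genes"] = tuple(pipe["ifn_genes"])
    return SimulationConfig(**sim), PipelineConfig(**pipe)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(outdir: Path, config: dict, seed: int, inputs: dict, outputs: dict) -> Path:
    manifest = {
        "tool": "lncsig",
        "version": __version__,
        "seed": seed,
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": _digest(v)} for k, v in inputs.items()
                   if v is not None and Path(v).exists()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


def run_discovery(counts: CountMatrix, annotation: pd.DataFrame, termmap,
                  cfg: PipelineConfig | None = None, seed: int = 0,
                  outdir=None) -> dict:
    """Time-course discovery: from counts to the candidate lncRNA table.

    Returns a dict with every intermediate (DE table, kinetic assignments,
    enrichment, correlation and cis pairs, candidates) plus the funnel of
    gene counts surviving each filter.  An empty candidate set is a valid,
    logged outcome.
    """
    cfg = cfg or PipelineConfig()
    timepoints = counts.sample_meta["timepoint"]
    required = {"t0", "t1.5", "t4"}
    if not required <= set(timepoints):
        raise ValueError(f"missing timepoints: {sorted(required - set(timepoints))}")

    ann = annotation.loc[annotation.index.intersection(counts.gene_ids)]
    lnc_ids = classify_lncrna(ann)
    pcg_ids = set(ann.index[ann["biotype"] == "protein_coding"])

    factors = size_factors(counts)
    v = vst(counts, factors)
    de = nb_lrt_test(counts, full=timepoints, full_col="timepoint", factors=factors)

    modulated = set(de.index[de["padj"] < cfg.padj_max])
    modulated_lnc = sorted(modulated & lnc_ids)
    log.info("funnel: %d lncRNAs, %d modulated (padj < %g)",
             len(lnc_ids), len(modulated_lnc), cfg.padj_max)

    kin = pd.DataFrame()
    if modulated_lnc:
        profiler = KineticProfiler(seed=seed)
        direction = np.sign(de.loc[modulated_lnc, "log2fc"]).replace(0, 1)
        profiler.fit(v.loc[modulated_lnc], timepoints, direction=direction)
        kin = profiler.assignments_

    fpkm_mat = fpkm(counts, ann)
    cond_means = fpkm_mat.T.groupby(timepoints).mean().T
    expressed = set(cond_means.index[(cond_means > cfg.fpkm_min).any(axis=1)])
    up_pcgs = {g for g in pcg_ids & modulated & expressed if de.loc[g, "log2fc"] > 0}
    log.info("funnel: %d up-regulated expressed PCGs (FPKM > %g)", len(up_pcgs), cfg.fpkm_min)

    universe = expressed
    enrich = pd.DataFrame()
    sel_terms: list[str] = []
    isg_pcgs: set[str] = set()
    if up_pcgs:
        enrich = hypergeom_enrich(up_pcgs, universe, termmap)
        sel_terms = select_response_terms(enrich, fdr_max=cfg.enrich_fdr_max)
        isg_pcgs = genes_of_terms(sel_terms, termmap, restrict=up_pcgs)
    log.info("funnel: %d IFN/antiviral terms, %d associated PCGs", len(sel_terms), len(isg_pcgs))

    corr = correlate_lnc_pcg(v.loc[modulated_lnc], v.loc[sorted(isg_pcgs)], cfg)
    cis = cis_pairs(ann.loc[modulated_lnc], ann.loc[sorted(isg_pcgs)], cfg.cis_window)
    candidates = select_ifn_viral_lncrnas(corr, cis)
    log.info("funnel: %d correlated pairs, %d cis pairs, %d candidate lncRNAs",
             len(corr), len(cis), len(candidates))
    if len(candidates) == 0:
        log.info("empty candidate set")

    result = {
        "de": de,
        "modulated_lnc": modulated_lnc,
        "kinetics": kin,
        "up_pcgs": up_pcgs,
        "enrichment": enrich,
        "selected_terms": sel_terms,
        "isg_pcgs": isg_pcgs,
        "correlations": corr,
        "cis": cis,
        "candidates": candidates,
        "vst": v,
        "funnel": {
            "lncRNAs": len(lnc_ids),
            "modulated_lncRNAs": len(modulated_lnc),
            "up_pcgs": len(up_pcgs),
            "response_terms": len(sel_terms),
            "isg_pcgs": len(isg_pcgs),
            "correlated_pairs": len(corr),
            "cis_pairs": len(cis),
            "candidates": len(candidates),
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        outputs = {}
        for name in ("de", "kinetics", "enrichment", "correlations", "cis", "candidates"):
            path = outdir / f"{name}.tsv"
            obj = result[name]
            (obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)).to_csv(path, sep="\t")
            outputs[name] = path
        funnel_path = outdir / "funnel.json"
        funnel_path.write_text(json.dumps(result["funnel"], indent=1))
        outputs["funnel"] = funnel_path
        write_manifest(outdir, {"pipeline": asdict(cfg)}, seed, {}, outputs)
    return result


def run_cohort(counts: CountMatrix, cfg: PipelineConfig | None = None,
               candidates=(), outdir=None, seed: int = 0) -> dict:
    """Cohort replication and IFN-score correlation for candidate lncRNAs."""
    cfg = cfg or PipelineConfig()
    groups = counts.sample_meta["group"]
    if "HC" not in set(groups):
        raise ValueError("cohort needs an HC control group")
    case_groups = [g for g in dict.fromkeys(groups) if g != "HC"]
    if len(case_groups) < cfg.min_groups:
        raise ValueError(
            f"replication needs >= {cfg.min_groups} case groups, found {len(case_groups)}"
        )

    de_by_group = {}
    for grp in case_groups:
        sub = counts.subset_samples(groups.index[groups.isin(["HC", grp])])
        de_by_group[grp] = nb_wald_test(sub, ("HC", grp), groups=groups.loc[sub.sample_ids])
    replicated = cohort_replication_filter(list(de_by_group.values()), cfg)

    v = vst(counts)
    hc_samples = list(groups.index[groups == "HC"])
    scores = ifn_score(v, cfg, hc_samples)

    candidates = [c for c in candidates if c in v.index]
    rows = []
    for lnc in candidates:
        n_up = sum(
            (res.loc[lnc, "log2fc"] >= cfg.log2fc_min) and (res.loc[lnc, "p"] <= cfg.p_max)
            for res in de_by_group.values() if lnc in res.index
        )
        rho, p = score_correlation(v.loc[lnc], scores)
        rows.append((lnc, n_up, lnc in replicated, rho, p))
    report = pd.DataFrame(
        rows, columns=["lnc_id", "n_groups_up", "replicated", "score_rho", "score_p"]
    ).set_index("lnc_id")
    log.info("cohort: %d/%d candidates replicated in >= %d groups",
             int(report["replicated"].sum()), len(report), cfg.min_groups)

    result = {"de_by_group": de_by_group, "replicated": replicated,
              "scores": scores, "report": report, "vst": v}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "replication_report.tsv", sep="\t")
        scores.rename_axis("sample").to_csv(outdir / "ifn_scores.tsv", sep="\t")
        for grp, res in de_by_group.items():
            res.to_csv(outdir / f"de_{grp}_vs_HC.tsv", sep="\t")
        write_manifest(outdir, {"pipeline": asdict(cfg)}, seed,
                       {}, {"report": outdir / "replication_report.tsv"})
    return result


def run_targets(timecourse_expr: pd.DataFrame, cohort_expr: pd.DataFrame,
                cfg: PipelineConfig | None = None, query: str = "NRIR",
                annotation: pd.DataFrame | None = None,
                de_flags: dict | None = None, outdir=None, seed: int = 0) -> dict:
    """Cross-dataset module intersection and putative target nomination."""
    cfg = cfg or PipelineConfig()
    for name, expr in (("timecourse", timecourse_expr), ("cohort", cohort_expr)):
        if query not in expr.index:
            raise KeyError(f"query gene {query!r} absent from the {name} dataset")

    nets = {}
    modules = {}
    for name, expr in (("timecourse", timecourse_expr), ("cohort", cohort_expr)):
        net = SignedCoexpressionNetwork(
            beta=cfg.betas[name],
            min_module_size=cfg.min_module_size[name],
            cut_height=cfg.cut_height,
        ).fit(expr)
        nets[name] = net
        modules[name] = net.module_of(query)
        if modules[name] is None:
            log.info("query %s unassigned in the %s network", query, name)
            return {"status": "no_module", "dataset": name, "networks": nets}

    inter = intersect_modules(modules["timecourse"], modules["cohort"], annotation)
    targets = nominate_targets(inter, de_flags)
    log.info("modules: %d (timecourse) ∩ %d (cohort) = %d common (%d PCG, %d ncRNA)",
             len(inter.module_a), len(inter.module_b), len(inter.common),
             len(inter.common_pcg), len(inter.common_ncrna))

    result = {"status": "ok", "networks": nets, "modules": modules,
              "intersection": inter, "targets": targets}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        targets.to_csv(outdir / "targets.tsv", sep="\t")
        for name, net in nets.items():
            net.module_labels_.rename_axis("gene_id").to_csv(
                outdir / f"modules_{name}.tsv", sep="\t")
        write_manifest(
            outdir, {"pipeline": asdict(cfg)}, seed, {},
            {"targets": outdir / "targets.tsv",
             "n_common_pcg": len(inter.common_pcg),
             "n_common_ncrna": len(inter.common_ncrna)},
        )
    return result
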