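"""End-to-end orchestration: clinical battery -> marker meta-analysis ->
candidate screen -> enrichment -> PPI hubs -> pathway crosstalk ->
key genes -> seed sites, from one config, with a reproducibility
manifest.

Every stage consumes and emits plain in-memory objects (DataFrames,
graphs, gene sets), so any stage can be run standalone, and the file
front-end (``make_fixtures`` / ``run_all``) round-trips everything
through the same TSV/GMT/FASTA formats real downloaded data would use.
Identical seed and config yield a byte-identical summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as mio
from . import meta as mmeta
from .containers import ExpressionStudy
from .crosstalk import build_crosstalk, map_gene_pathway, mcode, select_core
from .enrich import GeneSetCollection, hypergeom_enrich
from .keygenes import crucial_pathways, keygene_influence
from .network import (centralities, consensus_hubs, degree_betweenness_core,
                      filter_edges, main_component)
from .screen import clinical_assoc, de_test, intersect_candidates, vote_filter
from .seedscan import classify_are, seed_sites
from .synthetic import (SyntheticConfig, gen_clinical, gen_expression_studies,
                        gen_gene_studies, gen_pathways, gen_ppi, gen_sequences,
                        gen_target_votes, gen_tumor_normal_matrix)

__all__ = [
    "PipelineError",
    "PipelineParams",
    "PipelineConfig",
    "PipelineInputs",
    "RunReport",
    "make_fixtures",
    "synthetic_inputs",
    "run_stages",
    "run_all",
]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    """All stage parameters, with the workflow's standard defaults."""

    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    min_db: int = 5
    enrich_mode: str = "ease"
    go_threshold: float = 0.01
    pathway_threshold: float = 0.05
    min_score: float = 0.7
    top_k: int = 20
    min_count: int = 2
    min_genes: int = 3
    min_shared: int = 2
    mcode_score: float = 4.0
    alpha: float = 0.05
    n_perm: int = 10000
    epc_samples: int = 1000


@dataclass
class PipelineConfig:
    """File paths plus parameters for a file-based run."""

    meta_studies: list[str]
    meta_groups: list[str]
    expression: str
    groups: str
    votes: str
    edges: str
    pathways: str
    mirna_fasta: str
    utr_fasta: str
    clinical: str
    gene_studies: list[str]
    gene_groups: list[str]
    outdir: str = "mirkey_out"
    seed: int = 0
    subgroups: list[str] | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pnames = {f.name for f in dataclasses.fields(PipelineParams)}
        cnames = {f.name for f in dataclasses.fields(cls)} - {"params"}
        unknown = set(d) - pnames - cnames
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = PipelineParams(**{k: d.pop(k) for k in list(d) if k in pnames})
        return cls(params=params, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(d.pop("params"))
        return d


@dataclass
class PipelineInputs:
    """In-memory input bundle for one run."""

    meta_studies: list[ExpressionStudy]
    matrix: ExpressionStudy
    votes: pd.DataFrame
    ppi: nx.Graph
    pathways: GeneSetCollection
    mirna: str
    utrs: dict[str, str]
    marker_expr: pd.Series
    clinical: pd.DataFrame
    gene_studies: list[ExpressionStudy]


@dataclass
class RunReport:
    clinical: pd.DataFrame
    study_effects: list
    meta_fixed: mmeta.MetaResult
    meta_random: mmeta.MetaResult
    meta_selected: str
    egger: mmeta.EggerResult | None
    influence: list
    subgroups: dict
    deg_table: pd.DataFrame
    candidates: set
    venn: object
    enrichment: pd.DataFrame
    network_sizes: dict
    centrality_table: pd.DataFrame
    hub_counts: object
    hub_genes: list
    clusters: list
    cluster_pathways: list
    main_genes: list
    core_pathways: list
    gene_records: list
    key_genes: list
    crucial_pathways: list
    seed_matches: list
    are_reports: list
    summary: dict
    manifest: dict


def synthetic_inputs(config: SyntheticConfig) -> tuple[PipelineInputs, "object"]:
    """Generate a full in-memory input bundle plus its planted truth."""
    matrix, truth = gen_tumor_normal_matrix(config)
    votes, _ = gen_target_votes(config)
    ppi, _ = gen_ppi(config)
    pathways, _ = gen_pathways(config)
    mirna, utr_records, truth = gen_sequences(config)
    marker_expr, clinical = gen_clinical(config)
    gene_studies, _ = gen_gene_studies(config)
    return (
        PipelineInputs(
            gen_expression_studies(config),
            matrix,
            votes,
            ppi,
            pathways,
            mirna,
            {r.utr_id: r.sequence for r in utr_records},
            marker_expr,
            clinical,
            gene_studies,
        ),
        truth,
    )


def make_fixtures(config: SyntheticConfig, outdir) -> dict[str, str]:
    """Write the full synthetic input bundle plus a ground-truth JSON
    sidecar; returns the path map (also usable as a PipelineConfig base)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    inputs, truth = synthetic_inputs(config)
    paths: dict[str, object] = {
        "meta_studies": [], "meta_groups": [],
        "gene_studies": [], "gene_groups": [],
    }
    for st in inputs.meta_studies:
        e, g = out / f"{st.study_id}_expr.tsv", out / f"{st.study_id}_groups.tsv"
        mio.write_expression_study(st, e, g)
        paths["meta_studies"].append(str(e))
        paths["meta_groups"].append(str(g))
    for st in inputs.gene_studies:
        e, g = out / f"{st.study_id}_expr.tsv", out / f"{st.study_id}_groups.tsv"
        mio.write_expression_study(st, e, g)
        paths["gene_studies"].append(str(e))
        paths["gene_groups"].append(str(g))
    mio.write_expression_study(inputs.matrix, out / "expression.tsv", out / "groups.tsv")
    mio.write_votes(inputs.votes, out / "votes.tsv")
    mio.write_edges(inputs.ppi, out / "ppi_edges.tsv")
    inputs.pathways.to_gmt(out / "pathways.gmt")
    mio.write_fasta({"mirna": inputs.mirna}, out / "mirna.fa")
    mio.write_fasta(inputs.utrs, out / "utrs.fa")
    mio.write_clinical(inputs.marker_expr, inputs.clinical, out / "clinical.tsv")
    mio.write_json(truth.to_json_dict(), out / "truth.json")
    paths.update(
        expression=str(out / "expression.tsv"), groups=str(out / "groups.tsv"),
        votes=str(out / "votes.tsv"), edges=str(out / "ppi_edges.tsv"),
        pathways=str(out / "pathways.gmt"), mirna_fasta=str(out / "mirna.fa"),
        utr_fasta=str(out / "utrs.fa"), clinical=str(out / "clinical.tsv"),
    )
    paths["subgroups"] = [st.subgroup for st in inputs.meta_studies]
    return paths


def load_inputs(config: PipelineConfig) -> PipelineInputs:
    subs = config.subgroups or [None] * len(config.meta_studies)
    meta_studies = [
        mio.read_expression_study(e, g, subgroup=s)
        for e, g, s in zip(config.meta_studies, config.meta_groups, subs)
    ]
    gene_studies = [
        mio.read_expression_study(e, g)
        for e, g in zip(config.gene_studies, config.gene_groups)
    ]
    matrix = mio.read_expression_study(config.expression, config.groups)
    mirna_map = mio.read_fasta(config.mirna_fasta)
    if len(mirna_map) != 1:
        raise PipelineError("load", f"{config.mirna_fasta} must hold one miRNA")
    marker_expr, clinical = mio.read_clinical(config.clinical)
    return PipelineInputs(
        meta_studies, matrix, mio.read_votes(config.votes),
        mio.read_edges(config.edges),
        GeneSetCollection.from_gmt(config.pathways),
        next(iter(mirna_map.values())), mio.read_fasta(config.utr_fasta),
        marker_expr, clinical, gene_studies,
    )


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # halt with the stage name and cause
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


def run_stages(
    inputs: PipelineInputs,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> RunReport:
    """Execute the whole cascade on an in-memory input bundle."""
    params = params or PipelineParams()
    rng = np.random.default_rng([seed, 99])

    # clinical association battery
    clin = _stage("clinical")(clinical_assoc)(inputs.marker_expr, inputs.clinical)

    # marker meta-analysis
    @_stage("meta")
    def _meta():
        effects = []
        for st in inputs.meta_studies:
            st = st.to_log2()
            t, n = st.group_values(st.values.index[0])
            effects.append(mmeta.compute_smd(t, n, st.study_id, st.subgroup))
        fixed = mmeta.pool_fixed(effects)
        random_ = mmeta.pool_random(effects) if len(effects) > 1 else fixed
        _, _, p_Q, I2 = (
            mmeta.heterogeneity(effects) if len(effects) > 1 else (0.0, 0, 1.0, 0.0)
        )
        model = mmeta.select_model(p_Q, I2)
        egger = mmeta.egger_test(effects) if len(effects) >= 3 else None
        infl = mmeta.influence_loo(effects) if len(effects) >= 3 else []
        subs = (
            mmeta.subgroup_pool(effects)
            if all(e.subgroup for e in effects) and len(effects) > 1
            else {}
        )
        return effects, fixed, random_, model, egger, infl, subs

    effects, fixed, random_, model, egger, infl, subs = _meta()

    # candidate screen
    @_stage("screen")
    def _screen():
        degs = de_test(inputs.matrix, params.lfc_threshold, params.fdr_threshold)
        predicted = vote_filter(inputs.votes, params.min_db)
        cand, venn = intersect_candidates(degs, predicted)
        if not cand:
            raise ValueError("empty candidate set; downstream stages need candidates")
        return degs, predicted, cand, venn

    degs, predicted, candidates, venn = _screen()

    # enrichment
    @_stage("enrich")
    def _enrich():
        universe = set(inputs.matrix.values.index) & inputs.pathways.genes()
        res = hypergeom_enrich(
            candidates & universe, inputs.pathways, universe,
            params.enrich_mode, params.go_threshold, params.pathway_threshold,
        )
        sig = res[res["significant"] & (res["category"] == "pathway")]
        return res, list(sig["term_id"])

    enr, sig_pathways = _enrich()

    # PPI hubs
    @_stage("network")
    def _network():
        sub = inputs.ppi.subgraph(
            [v for v in inputs.ppi if v in candidates]
        ).copy()
        filtered = filter_edges(sub, params.min_score)
        main = main_component(filtered)
        core, mean_deg, mean_btw = degree_betweenness_core(main)
        core_main = main_component(core)
        table = centralities(core_main, seed=rng, epc_samples=params.epc_samples)
        hubs = consensus_hubs(table, params.top_k, params.min_count)
        sizes = {
            "input": (sub.number_of_nodes(), sub.number_of_edges()),
            "filtered": (filtered.number_of_nodes(), filtered.number_of_edges()),
            "main": (main.number_of_nodes(), main.number_of_edges()),
            "core": (core_main.number_of_nodes(), core_main.number_of_edges()),
            "mean_degree": mean_deg,
            "mean_betweenness": mean_btw,
        }
        return sizes, table, hubs

    sizes, table, hubs = _network()
    hub_genes = hubs.hubs

    # pathway crosstalk
    @_stage("crosstalk")
    def _crosstalk():
        sig_coll = GeneSetCollection(
            {p: inputs.pathways[p] for p in sig_pathways},
            {p: "pathway" for p in sig_pathways},
        )
        net = build_crosstalk(sig_coll, params.min_genes, params.min_shared)
        clusters = mcode(net, min_score=params.mcode_score)
        retained = [c for c in clusters if c.retained]
        cluster_pws = sorted({p for c in retained for p in c.members})
        gp = map_gene_pathway(hub_genes, cluster_pws, inputs.pathways)
        main_genes, core_pws = select_core(gp)
        return clusters, cluster_pws, main_genes, core_pws

    clusters, cluster_pws, main_genes, core_pws = _crosstalk()

    # key genes
    @_stage("keygenes")
    def _keygenes():
        records = keygene_influence(
            inputs.gene_studies, inputs.gene_studies[0].values.index,
            params.alpha, params.n_perm, rng,
        )
        by_gene = {r.gene: r for r in records}
        main_records = [by_gene[g] for g in main_genes if g in by_gene]
        keys = [r.gene for r in main_records if r.key]
        sig_coll = GeneSetCollection(
            {p: inputs.pathways[p] for p in sig_pathways},
            {p: "pathway" for p in sig_pathways},
        )
        crucial = sorted(crucial_pathways(keys, sig_coll)) if keys else []
        return main_records, keys, crucial

    gene_records, key_genes, crucial = _keygenes()

    # seed sites
    @_stage("seeds")
    def _seeds():
        matches, ares = [], []
        for uid, seq in inputs.utrs.items():
            matches.extend(seed_sites(inputs.mirna, seq, uid))
            ares.append(classify_are(seq, uid))
        return matches, ares

    matches, ares = _seeds()

    summary = {
        "pooled_smd": round(random_.pooled if model == "random" else fixed.pooled, 4),
        "meta_model": model,
        "I2": round(random_.I2, 2),
        "n_degs": int(degs["selected"].sum()),
        "n_predicted": len(predicted),
        "n_candidates": len(candidates),
        "n_significant_pathways": len(sig_pathways),
        "hub_genes": hub_genes,
        "main_genes": main_genes,
        "key_genes": key_genes,
        "crucial_pathways": crucial,
        "seed_sites": {
            uid: sorted(m.start for m in matches if m.utr_id == uid)
            for uid in inputs.utrs
        },
    }
    manifest = _manifest(seed, params, summary, sizes)
    return RunReport(
        clin, effects, fixed, random_, model, egger, infl, subs, degs,
        candidates, venn, enr, sizes, table, hubs, hub_genes, clusters,
        cluster_pws, main_genes, core_pws, gene_records, key_genes, crucial,
        matches, ares, summary, manifest,
    )


def _manifest(seed, params, summary, sizes) -> dict:
    import networkx
    import scipy

    from . import __version__

    cfg = dataclasses.asdict(params)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return {
        "versions": {
            "mirkey": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "networkx": networkx.__version__,
        },
        "seed": seed,
        "params": cfg,
        "config_hash": cfg_hash,
        "stage_counts": {
            "network": {k: v for k, v in sizes.items() if k in
                        ("input", "filtered", "main", "core")},
            "n_hub_genes": len(summary["hub_genes"]),
            "n_key_genes": len(summary["key_genes"]),
            "n_crucial_pathways": len(summary["crucial_pathways"]),
        },
    }


def run_all(config: PipelineConfig) -> RunReport:
    """File-based end-to-end run: parse inputs, execute all stages, write
    per-stage TSVs plus summary.json and manifest.json to the outdir."""
    inputs = _stage("load")(load_inputs)(config)
    report = run_stages(inputs, config.params, config.seed)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.clinical.to_csv(out / "clinical_assoc.tsv", sep="\t", index=False)
    _forest_table(report).to_csv(out / "meta_forest.tsv", sep="\t", index=False)
    report.deg_table.rename_axis("gene").to_csv(out / "deg_table.tsv", sep="\t")
    (out / "candidates.txt").write_text(
        "\n".join(sorted(report.candidates)) + "\n"
    )
    report.enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    report.centrality_table.rename_axis("gene").to_csv(
        out / "centralities.tsv", sep="\t"
    )
    report.hub_counts.table().to_csv(out / "hub_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"members": ";".join(map(str, c.members)), "n_nodes": c.n_nodes,
          "n_edges": c.n_edges, "score": round(c.score, 4),
          "retained": c.retained} for c in report.clusters]
    ).to_csv(out / "mcode_clusters.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"gene": r.gene, "combined_p": r.combined_p,
          "loo_p": ";".join(f"{p:.6g}" for p in r.loo_p),
          "stable": r.stable, "key": r.key} for r in report.gene_records]
    ).to_csv(out / "key_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"utr_id": m.utr_id, "start": m.start, "end": m.end,
          "site_seq": m.site_seq, "au_fraction": round(m.au_fraction, 4)}
         for m in report.seed_matches]
    ).to_csv(out / "seed_sites.tsv", sep="\t", index=False)
    mio.write_json(report.summary, out / "summary.json")
    mio.write_json(report.manifest, out / "manifest.json")
    return report


def _forest_table(report: RunReport) -> pd.DataFrame:
    rows = []
    w_total = sum(1.0 / e.var_g for e in report.study_effects)
    for e in report.study_effects:
        rows.append(
            {"study": e.study_id, "g": round(e.g, 4),
             "ci_low": round(e.g - 1.96 * e.se, 4),
             "ci_high": round(e.g + 1.96 * e.se, 4),
             "weight_pct": round(100.0 / e.var_g / w_total, 2),
             "subgroup": e.subgroup}
        )
    for label, res in (("pooled_fixed", report.meta_fixed),
                       ("pooled_random", report.meta_random)):
        rows.append(
            {"study": label, "g": round(res.pooled, 4),
             "ci_low": round(res.ci_low, 4), "ci_high": round(res.ci_high, 4),
             "weight_pct": 100.0, "subgroup": None}
        )
    return pd.DataFrame(rows)
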