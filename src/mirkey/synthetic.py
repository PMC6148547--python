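"""Synthetic pipeline inputs with planted, recoverable ground truth.

Every generator is deterministic under the config seed and returns its
ground truth (planted labels, module membership, site offsets) alongside
the data, so each downstream stage has a parameter-recovery test without
any external download. The generators emulate, at desk scale:

* multi-study two-group marker expression with a planted standardized
  mean difference (meta-analysis input),
* a tumour/normal expression matrix with a planted DE gene fraction
  (DEG-screen input),
* per-database target-vote matrices with set sensitivity/specificity
  around a planted true-target set,
* a preferential-attachment interaction graph with a planted near-clique
  hub module whose edges survive the 0.7 confidence filter,
* overlapping pathway gene sets, three of which are designated to contain
  all anchor genes (and are the only ones containing all three together),
* 3'UTR sequences with planted 7-mer seed sites embedded in AU-rich
  windows, and
* a clinical covariate table with one expression-dependent ordinal item.

Expression noise is Gaussian on the log2 scale and emitted on the raw
scale (2^x) so the pipeline's own log2 step is exercised.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionStudy
from .enrich import GeneSetCollection
from .seedscan import seed_sequence, _clean_rna

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "ground_truth",
    "gen_expression_studies",
    "gen_tumor_normal_matrix",
    "gen_target_votes",
    "gen_ppi",
    "gen_pathways",
    "gen_sequences",
    "gen_clinical",
    "gen_gene_studies",
    "UTRRecord",
]

MIR_106B_5P = "UAAAGUGCUGACAGUGCAGAU"

# per-generator RNG stream tags (default_rng([seed, tag]))
_TAG = {
    "truth": 0, "studies": 1, "matrix": 2, "votes": 3, "ppi": 4,
    "pathways": 5, "sequences": 6, "clinical": 7, "gene_studies": 8,
}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic bundle (all seeded)."""

    seed: int = 0
    # marker meta-analysis studies
    n_studies: int = 4
    planted_smd: float = 2.85
    n_tumor: int = 20
    n_normal: int = 20
    mu_normal: float = 6.0  # log2 units
    sigma: float = 1.0
    marker_id: str = "miR-106b-5p"
    # tumour/normal screening matrix
    n_genes: int = 800
    de_fraction: float = 0.25
    lfc_effect: float = 3.0
    matrix_n_tumor: int = 30
    matrix_n_normal: int = 30
    gene_sigma: float = 1.0
    target_fraction: float = 0.5
    # target-vote matrix
    n_databases: int = 12
    db_sensitivity: float = 0.7
    db_specificity: float = 0.9
    # interaction graph
    graph_nodes: int = 120
    attach_edges: int = 2
    hub_module_size: int = 15
    module_edge_prob: float = 0.9
    module_attach: int = 4
    # pathway collection
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (12, 28)
    overlap_rate: float = 0.2
    cluster_pathways: int = 8
    n_anchors: int = 3
    # sequences
    utr_length: int = 300
    n_planted_sites: int = 2
    n_negative_utrs: int = 3
    # clinical table
    n_clinical: int = 300
    clinical_effect: float = 0.8
    # external gene-level validation studies
    n_gene_studies: int = 9
    gene_study_n: int = 20
    anchor_shift: float = 2.0  # in units of gene_sigma, log2 scale

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.gene_sigma <= 0:
            raise ValueError("noise SD must be positive")
        if self.n_studies < 1:
            raise ValueError("need at least one study")
        if min(self.n_tumor, self.n_normal, self.matrix_n_tumor,
               self.matrix_n_normal, self.gene_study_n) < 2:
            raise ValueError("group sizes must be >= 2 per arm")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.target_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if not 0 <= self.db_sensitivity <= 1 or not 0 <= self.db_specificity <= 1:
            raise ValueError("sensitivity/specificity must lie in [0, 1]")
        if self.hub_module_size >= self.graph_nodes:
            raise ValueError("hub module must be smaller than the graph")
        lo, hi = self.pathway_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid pathway size range")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _TAG[stream]])


@dataclass
class SyntheticTruth:
    """Planted ground truth shared by all generators of one config."""

    genes: list[str]
    de_genes: list[str]
    de_signs: dict[str, int]
    true_targets: list[str]
    module_nodes: list[str]
    anchor_genes: list[str]
    designated_pathways: list[str]
    cluster_pathway_ids: list[str]
    planted_sites: dict[str, list[int]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return asdict(self)


def ground_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Deterministic planted labels: DE genes, true targets, hub module and
    anchors (module genes are always upregulated DE true-targets)."""
    rng = config.rng("truth")
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    n_de = int(config.de_fraction * config.n_genes)
    de = [str(g) for g in rng.choice(genes, size=n_de, replace=False)] if n_de else []
    n_tg = int(round(config.target_fraction * config.n_genes))
    # targets sampled so that enough DE genes are targets to host the module
    de_targets = [str(g) for g in rng.choice(
        de, size=min(len(de), max(config.hub_module_size * 3,
                                  int(n_tg * config.de_fraction))),
        replace=False)] if de else []
    others = [g for g in genes if g not in set(de_targets)]
    rest = [str(g) for g in rng.choice(
        others, size=max(0, n_tg - len(de_targets)), replace=False)]
    targets = sorted(set(de_targets) | set(rest))
    pool = de_targets
    if len(pool) < config.hub_module_size:
        raise ValueError("not enough DE target genes to plant the hub module")
    module = [str(g) for g in rng.choice(pool, size=config.hub_module_size,
                                         replace=False)]
    anchors = sorted(module[: config.n_anchors])
    signs = {g: int(s) for g, s in zip(de, rng.choice([-1, 1], size=len(de)))}
    for g in module:
        signs[g] = 1  # module genes planted upregulated
    n_cluster = config.cluster_pathways
    cluster_ids = [f"PW{i + 1:02d}" for i in range(n_cluster)]
    return SyntheticTruth(
        genes, sorted(de), signs, targets, sorted(module), anchors,
        cluster_ids[: config.n_anchors], cluster_ids,
    )


# ---------------------------------------------------------------------------
# expression


def gen_expression_studies(
    config: SyntheticConfig,
) -> list[ExpressionStudy]:
    """Marker expression studies: tumour mean shifted by planted_smd x sigma
    on the log2 scale, emitted on the raw scale; subgroups alternate
    squamous/adeno labels."""
    rng = config.rng("studies")
    studies = []
    subtypes = itertools.cycle(["SCC", "ADC"])
    for i in range(config.n_studies):
        t = rng.normal(config.mu_normal + config.planted_smd * config.sigma,
                       config.sigma, config.n_tumor)
        n = rng.normal(config.mu_normal, config.sigma, config.n_normal)
        sid = f"study{i + 1}"
        cols = [f"{sid}_T{j}" for j in range(config.n_tumor)] + [
            f"{sid}_N{j}" for j in range(config.n_normal)
        ]
        vals = pd.DataFrame(
            [np.concatenate([t, n])], index=[config.marker_id], columns=cols
        )
        groups = pd.Series(
            ["tumor"] * config.n_tumor + ["normal"] * config.n_normal, index=cols
        )
        studies.append(
            ExpressionStudy(sid, np.power(2.0, vals), groups, log2=False,
                            subgroup=next(subtypes))
        )
    return studies


def _matrix(
    rng: np.random.Generator,
    config: SyntheticConfig,
    truth: SyntheticTruth,
    n_tumor: int,
    n_normal: int,
    shifted: dict[str, float],
    study_id: str,
) -> ExpressionStudy:
    genes = truth.genes
    base = rng.uniform(5.0, 10.0, size=len(genes))
    vals = rng.normal(
        base[:, None], config.gene_sigma, size=(len(genes), n_tumor + n_normal)
    )
    shift_vec = np.array([shifted.get(g, 0.0) for g in genes])
    vals[:, :n_tumor] += shift_vec[:, None]
    cols = [f"{study_id}_T{j}" for j in range(n_tumor)] + [
        f"{study_id}_N{j}" for j in range(n_normal)
    ]
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=cols)
    df = pd.DataFrame(np.power(2.0, vals), index=genes, columns=cols)
    return ExpressionStudy(study_id, df, groups, log2=False)


def gen_tumor_normal_matrix(
    config: SyntheticConfig,
) -> tuple[ExpressionStudy, SyntheticTruth]:
    """Tumour/normal screening matrix: planted DE genes shifted by
    sign x lfc_effect on the log2 scale (raw-scale output)."""
    if int(config.de_fraction * config.n_genes) < 1:
        raise ValueError("de_fraction * n_genes must be >= 1")
    truth = ground_truth(config)
    shifts = {g: truth.de_signs[g] * config.lfc_effect for g in truth.de_genes}
    study = _matrix(
        config.rng("matrix"), config, truth,
        config.matrix_n_tumor, config.matrix_n_normal, shifts, "cesc",
    )
    return study, truth


def gen_gene_studies(
    config: SyntheticConfig,
) -> tuple[list[ExpressionStudy], SyntheticTruth]:
    """External validation compendium for the key-gene meta-analysis:
    independent tumour/normal studies over the same gene universe where
    only the anchor genes carry a planted (upregulated) shift."""
    truth = ground_truth(config)
    rng = config.rng("gene_studies")
    shift = {g: config.anchor_shift * config.gene_sigma for g in truth.anchor_genes}
    studies = [
        _matrix(rng, config, truth, config.gene_study_n, config.gene_study_n,
                shift, f"onc{i + 1}")
        for i in range(config.n_gene_studies)
    ]
    return studies, truth


# ---------------------------------------------------------------------------
# target votes


def gen_target_votes(
    config: SyntheticConfig, true_targets=None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Boolean gene x database vote matrix: Bernoulli(sensitivity) on true
    targets, Bernoulli(1 - specificity) elsewhere, independent databases."""
    truth = ground_truth(config)
    targets = set(true_targets) if true_targets is not None else set(truth.true_targets)
    rng = config.rng("votes")
    is_target = np.array([g in targets for g in truth.genes])
    p = np.where(is_target, config.db_sensitivity, 1.0 - config.db_specificity)
    votes = rng.random((config.n_genes, config.n_databases)) < p[:, None]
    df = pd.DataFrame(
        votes, index=truth.genes,
        columns=[f"DB{i + 1:02d}" for i in range(config.n_databases)],
    )
    return df, truth


# ---------------------------------------------------------------------------
# interaction graph


def gen_ppi(config: SyntheticConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free backbone plus a planted near-clique hub module.

    The backbone is preferential attachment over candidate-like genes
    (planted DE targets first) with confidence scores U(0.5, 1); module
    edges appear with probability ``module_edge_prob`` and module and
    attachment edges score U(0.75, 1), so the module survives the 0.7
    filter intact. Each module node attaches to ``module_attach`` backbone
    nodes.
    """
    truth = ground_truth(config)
    rng = config.rng("ppi")
    module = truth.module_nodes
    de_t = [g for g in truth.de_genes
            if g in set(truth.true_targets) and g not in set(module)]
    other = [g for g in truth.genes if g not in set(de_t) and g not in set(module)]
    n_backbone = config.graph_nodes - config.hub_module_size
    backbone_pool = de_t + [str(g) for g in rng.permutation(other)]
    backbone_nodes = backbone_pool[:n_backbone]

    seed_int = int(rng.integers(0, 2**31 - 1))
    bb = nx.barabasi_albert_graph(n_backbone, config.attach_edges, seed=seed_int)
    g = nx.Graph()
    g.add_nodes_from(backbone_nodes)
    g.add_nodes_from(module)
    for u, v in bb.edges():
        g.add_edge(backbone_nodes[u], backbone_nodes[v],
                   score=float(rng.uniform(0.5, 1.0)))
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            if rng.random() < config.module_edge_prob:
                g.add_edge(a, b, score=float(rng.uniform(0.75, 1.0)))
        attach = rng.choice(n_backbone, size=config.module_attach, replace=False)
        for j in attach:
            g.add_edge(a, backbone_nodes[j], score=float(rng.uniform(0.75, 1.0)))
    return g, truth


# ---------------------------------------------------------------------------
# pathways


def gen_pathways(
    config: SyntheticConfig, anchor_genes=None
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Pathway gene sets with a dense crosstalk cluster and three
    designated anchor pathways.

    The first ``cluster_pathways`` sets draw most genes from a shared
    candidate-gene pool (hub module plus other planted DE targets), so
    they overlap heavily and are strongly enriched in the screened
    candidates. The three designated sets contain all anchor genes; every
    other cluster set contains exactly two of the three, and background
    sets never contain all three, so the designated pathways are the only
    ones shared by every anchor. Background set pairs (2i, 2i+1) share
    ``overlap_rate`` of their genes.
    """
    truth = ground_truth(config)
    anchors = list(anchor_genes) if anchor_genes is not None else truth.anchor_genes
    rng = config.rng("pathways")
    lo, hi = config.pathway_size_range
    module = truth.module_nodes
    de_t = [g for g in truth.de_genes
            if g in set(truth.true_targets) and g not in set(module)]
    pool = module + de_t[: max(0, 4 * config.hub_module_size - len(module))]
    pool_wo_anchors = [g for g in pool if g not in set(anchors)]
    anchor_pairs = itertools.cycle(itertools.combinations(anchors, len(anchors) - 1))

    sets: dict[str, set[str]] = {}
    ids = [f"PW{i + 1:02d}" for i in range(config.n_pathways)]
    for i, pid in enumerate(ids[: config.cluster_pathways]):
        size = int(rng.integers(lo, hi + 1))
        if i < len(truth.designated_pathways):
            fixed = list(anchors)
        else:
            fixed = list(next(anchor_pairs))
        n_extra = max(1, size - len(fixed))
        extra = rng.choice(pool_wo_anchors, size=min(n_extra, len(pool_wo_anchors)),
                           replace=False)
        sets[pid] = set(fixed) | {str(g) for g in extra}
    # background pathways in consecutive pairs with controlled overlap
    bg_ids = ids[config.cluster_pathways:]
    universe = truth.genes
    i = 0
    while i < len(bg_ids):
        size_a = int(rng.integers(lo, hi + 1))
        a = {str(g) for g in rng.choice(universe, size=size_a, replace=False)}
        sets[bg_ids[i]] = a
        if i + 1 < len(bg_ids):
            size_b = int(rng.integers(lo, hi + 1))
            n_shared = min(int(round(config.overlap_rate * size_b)), len(a), size_b)
            shared = rng.choice(sorted(a), size=n_shared, replace=False)
            remaining = [g for g in universe if g not in a]
            fresh = rng.choice(remaining, size=size_b - n_shared, replace=False)
            sets[bg_ids[i + 1]] = {str(g) for g in shared} | {str(g) for g in fresh}
        i += 2
    # never let a non-designated set contain every anchor
    for pid, s in sets.items():
        if pid not in truth.designated_pathways and set(anchors) <= s:
            s.discard(anchors[int(rng.integers(len(anchors)))])
    coll = GeneSetCollection(
        sets, categories={pid: "pathway" for pid in sets},
        descriptions={pid: "category:pathway" for pid in sets},
    )
    return coll, truth


# ---------------------------------------------------------------------------
# sequences


@dataclass(frozen=True)
class UTRRecord:
    utr_id: str
    sequence: str
    planted_offsets: tuple[int, ...]


def _background(rng: np.random.Generator, length: int, forbid: str) -> str:
    letters = np.array(list("ACGU"))
    seq = list(rng.choice(letters, size=length))
    s = "".join(seq)
    # mutate the centre of any accidental site until the sequence is clean
    guard = 0
    while forbid in s:
        pos = s.find(forbid)
        mid = pos + len(forbid) // 2
        alternatives = [c for c in "ACGU" if c != s[mid]]
        s = s[:mid] + str(rng.choice(alternatives)) + s[mid + 1:]
        guard += 1
        if guard > 10 * length:
            raise RuntimeError("could not scrub seed sites from background")
    return s


def gen_sequences(
    config: SyntheticConfig, mirna: str = MIR_106B_5P
) -> tuple[str, list[UTRRecord], SyntheticTruth]:
    """miRNA plus positive (anchor-gene) and negative UTRs.

    Each positive UTR carries exactly ``n_planted_sites`` copies of the
    reverse complement of miRNA positions 2-8, embedded in 15-nt windows
    with A/U flanks (window AU fraction >= 0.6); negative UTRs carry none.
    """
    mirna = _clean_rna(mirna, "miRNA")
    site = seed_sequence(mirna)
    truth = ground_truth(config)
    rng = config.rng("sequences")
    flank_len = 4
    win = len(site) + 2 * flank_len
    if config.n_planted_sites * (win + 10) > config.utr_length:
        raise ValueError("UTR too short for the requested number of sites")
    records = []
    for gene in truth.anchor_genes:
        for _ in range(200):  # rejection loop: embedding must not add sites
            bg = _background(rng, config.utr_length, site)
            span = config.utr_length // config.n_planted_sites
            offsets = []
            seq = bg
            for j in range(config.n_planted_sites):
                start = j * span + int(rng.integers(0, span - win + 1))
                flanks = rng.choice(list("AU"), size=2 * flank_len)
                window = "".join(flanks[:flank_len]) + site + "".join(flanks[flank_len:])
                seq = seq[:start] + window + seq[start + win:]
                offsets.append(start + flank_len)
            found = [i for i in range(len(seq) - len(site) + 1)
                     if seq[i: i + len(site)] == site]
            if found == sorted(offsets):
                break
        else:
            raise RuntimeError("failed to plant the requested seed sites")
        records.append(UTRRecord(gene, seq, tuple(sorted(offsets))))
        truth.planted_sites[gene] = sorted(offsets)
    for j in range(config.n_negative_utrs):
        uid = f"NEG{j + 1}"
        records.append(UTRRecord(uid, _background(rng, config.utr_length, site), ()))
        truth.planted_sites[uid] = []
    return mirna, records, truth


# ---------------------------------------------------------------------------
# clinical covariates


def gen_clinical(
    config: SyntheticConfig, marker_expression: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Clinical table with one expression-dependent ordinal covariate
    (lymph-node class) and otherwise independent items, plus censored
    survival independent of expression."""
    rng = config.rng("clinical")
    if marker_expression is None:
        idx = [f"S{i + 1:04d}" for i in range(config.n_clinical)]
        marker_expression = pd.Series(
            rng.normal(config.mu_normal + config.planted_smd * config.sigma,
                       config.sigma, config.n_clinical),
            index=idx, name="marker_expr",
        )
    n = len(marker_expression)
    z = (marker_expression - marker_expression.mean()) / marker_expression.std()
    latent = config.clinical_effect * z.to_numpy() + rng.normal(0, 1, n)
    lymph = np.digitize(latent, np.quantile(latent, [0.25, 0.5, 0.75]))
    df = pd.DataFrame(
        {
            "lymph_nodes": lymph.astype(int),
            "tumor_purity": rng.beta(5, 2, n),
            "race": rng.choice(["white", "black", "asian"], size=n),
            "path_m_stage": rng.choice(["M0", "M1"], size=n),
            "years_to_birth": rng.normal(50, 12, n),
            "histology": rng.choice(["squamous", "adeno", "adenosquamous"], size=n),
            "ethnicity": rng.choice(["hispanic", "non-hispanic"], size=n),
            "radiation": rng.choice(["yes", "no"], size=n),
            "path_n_stage": rng.choice(["N0", "N1"], size=n),
            "path_t_stage": rng.choice(["T1", "T2", "T3", "T4"], size=n),
            "os_time": rng.exponential(50.0, n),
            "os_event": rng.random(n) < 0.4,
        },
        index=marker_expression.index,
    )
    return marker_expression, df
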