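"""Over-representation analysis of candidate genes against gene-set
collections (GO-style categories and pathways).

Two hypergeometric variants are provided: the exact one-sided tail
P(X >= k) and the EASE-score variant P(X >= k - 1), the deliberately
conservative default of the DAVID service it emulates. BH adjustment is
applied within each category; GO categories use the P < 0.01 call
threshold and pathways P < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "hypergeom_enrich", "top_terms"]

GO_CATEGORIES = ("CC", "BP", "MF")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set category and descriptions."""

    sets: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def category(self, name: str) -> str:
        return self.categories.get(name, "pathway")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out

    def restricted(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: s & universe for n, s in self.sets.items()},
            dict(self.categories),
            dict(self.descriptions),
        )

    def sets_of(self, gene: str) -> set[str]:
        return {n for n, s in self.sets.items() if gene in s}

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        """Read a GMT file (term <TAB> description <TAB> genes...).

        A description of the form ``category:XX`` assigns the set to
        category XX; anything else defaults to 'pathway'.
        """
        sets, cats, descs = {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
                name, desc, genes = parts[0], parts[1], parts[2:]
                sets[name] = {g for g in genes if g}
                descs[name] = desc
                if desc.startswith("category:"):
                    cats[name] = desc.split(":", 1)[1]
        return cls(sets, cats, descs)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, s in self.sets.items():
                desc = self.descriptions.get(name) or (
                    f"category:{self.categories[name]}" if name in self.categories else "na"
                )
                fh.write("\t".join([name, desc, *sorted(s)]) + "\n")


def hypergeom_enrich(
    candidates,
    sets: GeneSetCollection,
    universe,
    mode: str = "ease",
    go_threshold: float = 0.01,
    pathway_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per gene set.

    Exact mode tests P(X >= k); EASE mode tests P(X >= k - 1) given k > 0.
    Sets are intersected with the universe first; terms with zero overlap
    are dropped. BH FDR is computed within each category. Returns a
    DataFrame sorted by p with columns term_id, term_name, category, k, n,
    K, N, p, fdr, neg_log10_p, significant.
    """
    if mode not in ("exact", "ease"):
        raise ValueError(f"mode must be 'exact' or 'ease', got {mode!r}")
    universe = set(universe)
    cand = set(candidates)
    stray = cand - universe
    if stray:
        raise ValueError(f"{len(stray)} candidate genes outside the universe")
    N, n = len(universe), len(cand)
    rows = []
    for term, genes in sets.restricted(universe).sets.items():
        K = len(genes)
        k = len(genes & cand)
        if k == 0 or K == 0:
            continue
        shift = 1 if mode == "exact" else 2  # sf(k-1) = P(X>=k); sf(k-2) = P(X>=k-1)
        p = float(min(1.0, stats.hypergeom.sf(k - shift, N, K, n)))
        rows.append(
            {
                "term_id": term,
                "term_name": sets.descriptions.get(term, term),
                "category": sets.category(term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "term_name", "category", "k", "n", "K", "N",
                     "p", "fdr", "neg_log10_p", "significant"]
        )
    df = pd.DataFrame(rows)
    df["fdr"] = 1.0
    for cat, idx in df.groupby("category").groups.items():
        df.loc[idx, "fdr"] = multipletests(df.loc[idx, "p"], method="fdr_bh")[1]
    df["neg_log10_p"] = -df["p"].map(math.log10)
    thr = df["category"].map(
        lambda c: go_threshold if c in GO_CATEGORIES else pathway_threshold
    )
    df["significant"] = df["p"] < thr
    return df.sort_values(
        ["p", "k", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)


def top_terms(results: pd.DataFrame, per_category: int = 20) -> pd.DataFrame:
    """Top terms per category by ascending p; ties broken by larger overlap
    k, then lexical term id."""
    if results.empty:
        raise ValueError("no enrichment results to rank")
    ordered = results.sort_values(
        ["category", "p", "k", "term_id"], ascending=[True, True, False, True]
    )
    return ordered.groupby("category", group_keys=False).head(per_category).reset_index(
        drop=True
    )
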