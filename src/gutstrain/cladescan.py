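"""Phylogenetic clade disease-enrichment scan.

Every internal node of a strain tree is tested for case/control enrichment
of its leaves against an expected case fraction (chi-square goodness of
fit, 1 df, no continuity correction); clades consisting of a single
infant's samples are flagged as infant-oriented. Significant clades can be
characterised by their clade-unique genes (present in nearly all clade
genomes, nearly absent outside) and a generic term over-representation
test against a user-supplied gene -> term map.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .differential import bh_adjust
from .trees import StrainTree


@dataclass
class CladeResult:
    node_id: str
    n_leaves: int
    n_case: int
    n_control: int
    expected_case_fraction: float
    chi2: float          # NaN when the node is below min_leaves
    p: float
    infant_oriented: bool
    infants: frozenset
    leaves: tuple

    def to_row(self) -> dict:
        return {"node_id": self.node_id, "n_leaves": self.n_leaves,
                "n_case": self.n_case, "n_control": self.n_control,
                "expected_case_fraction": self.expected_case_fraction,
                "chi2": self.chi2, "p": self.p,
                "infant_oriented": self.infant_oriented,
                "n_infants": len(self.infants)}


def chi_square_node(n_case: int, n_control: int,
                    expected_case_fraction: float) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of an observed (case, control) leaf
    split against the expected fraction; no continuity correction."""
    n = n_case + n_control
    e_case = n * expected_case_fraction
    e_ctrl = n - e_case
    stat = (n_case - e_case) ** 2 / e_case + (n_control - e_ctrl) ** 2 / e_ctrl
    return float(stat), float(chi2.sf(stat, df=1))


def infant_oriented(leaf_infants) -> bool:
    """True iff all leaves below the node map to a single infant
    (single-leaf nodes are infant-oriented by definition)."""
    return len(set(leaf_infants)) == 1


def scan_tree(tree: StrainTree, labels: pd.DataFrame | None = None,
              expected_case_fraction: float | None = None,
              min_leaves: int = 6,
              adjust: bool = False, maximal_only: bool = False) -> list[CladeResult]:
    """Chi-square enrichment scan over all internal nodes.

    ``labels``: DataFrame indexed by leaf name with columns ``infant_id``
    and ``group`` (defaults to the tree's annotations). The expected case
    fraction defaults to the observed fraction over all leaves; pass 0.5
    to force the even-split null of a balanced case-control selection.
    Nodes with fewer than ``min_leaves`` leaves get chi2/p = NaN but are
    still reported with their infant-oriented flag. Results are sorted by
    p then node id. ``adjust`` adds BH q across tested nodes;
    ``maximal_only`` keeps significant nodes whose parent is not
    significant (p < 0.05).
    """
    if min_leaves < 2:
        raise ValueError("min_leaves must be >= 2")
    if labels is None:
        labels = tree.annotations
    if labels is None:
        raise ValueError("leaf labels required")
    missing = set(tree.leaf_names) - set(labels.index)
    if missing:
        raise ValueError(f"unlabelled leaves: {sorted(missing)[:5]}")
    group = labels["group"]
    infant = labels["infant_id"]
    if expected_case_fraction is None:
        expected_case_fraction = float(
            (group.loc[tree.leaf_names] == "case").mean())
    if not 0 < expected_case_fraction < 1:
        raise ValueError("expected case fraction must lie in (0, 1)")

    results: list[CladeResult] = []
    node_p: dict[int, float] = {}
    counter = 0
    for node in tree.tree.preorder():
        if node.is_tip():
            continue
        node_id = f"N{counter:04d}"
        counter += 1
        leaves = tuple(t.name for t in node.tips())
        n_case = int((group.loc[list(leaves)] == "case").sum())
        n_control = len(leaves) - n_case
        if len(leaves) >= min_leaves:
            stat, p = chi_square_node(n_case, n_control, expected_case_fraction)
        else:
            stat, p = np.nan, np.nan
        node_p[id(node)] = p
        results.append(CladeResult(
            node_id, len(leaves), n_case, n_control, expected_case_fraction,
            stat, p, infant_oriented(infant.loc[list(leaves)]),
            frozenset(infant.loc[list(leaves)]), leaves))

    if maximal_only:
        keep = []
        by_id = {id(n): r for n, r in zip(
            (n for n in tree.tree.preorder() if not n.is_tip()), results)}
        for node in tree.tree.preorder():
            if node.is_tip():
                continue
            r = by_id[id(node)]
            sig = not np.isnan(r.p) and r.p < 0.05
            parent_p = node_p.get(id(node.parent), np.nan)
            parent_sig = not np.isnan(parent_p) and parent_p < 0.05
            if sig and not parent_sig:
                keep.append(r)
        results = keep

    results.sort(key=lambda r: (np.isnan(r.p), r.p if not np.isnan(r.p) else 0.0,
                                r.node_id))
    if adjust:
        tested = [r for r in results if not np.isnan(r.p)]
        qs = bh_adjust([r.p for r in tested])
        for r, q in zip(tested, qs):
            r.q = float(q)  # dynamic attribute; reported by scan_table
    return results


def scan_table(results: list[CladeResult]) -> pd.DataFrame:
    rows = [r.to_row() for r in results]
    df = pd.DataFrame(rows)
    qs = [getattr(r, "q", np.nan) for r in results]
    if not all(np.isnan(q) for q in qs):
        df["q"] = qs
    return df


@dataclass
class UniqueGeneSet:
    node_id: str
    genes: list
    in_fraction: pd.Series
    out_fraction: pd.Series

    def __len__(self) -> int:
        return len(self.genes)


def clade_unique_genes(gpm: pd.DataFrame, clade_genomes,
                       in_min: float = 0.95, out_max: float = 0.05,
                       node_id: str = "") -> UniqueGeneSet:
    """Genes present in >= ``in_min`` of clade genomes and <= ``out_max``
    of the complement. ``gpm``: binary genes x genomes matrix."""
    clade = [g for g in clade_genomes]
    missing = set(clade) - set(gpm.columns)
    if missing:
        raise KeyError(f"clade genomes not in matrix: {sorted(missing)[:5]}")
    out_genomes = [g for g in gpm.columns if g not in set(clade)]
    if not clade or not out_genomes:
        raise ValueError("clade and complement must both be non-empty")
    x = (gpm > 0).astype(float)
    in_frac = x[clade].mean(axis=1)
    out_frac = x[out_genomes].mean(axis=1)
    keep = in_frac.index[(in_frac >= in_min) & (out_frac <= out_max)]
    return UniqueGeneSet(node_id, list(keep), in_frac.loc[keep], out_frac.loc[keep])


def term_enrichment(genes, annotation: dict[str, list], background) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    ``genes``: query gene ids (or a UniqueGeneSet); ``annotation``: gene ->
    list of terms; ``background``: the gene universe. BH-adjusted across
    terms, ranked by p.
    """
    query = set(getattr(genes, "genes", genes))
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query &= background
    covered = query & set(annotation)
    if not covered:
        raise ValueError("annotation covers no query gene")
    term_genes: dict[str, set] = {}
    for gene in background:
        for term in annotation.get(gene, []):
            term_genes.setdefault(term, set()).add(gene)
    n_bg, n_q = len(background), len(query)
    rows = []
    for term, members in sorted(term_genes.items()):
        k = len(members & query)
        m = len(members)
        # P(X >= k) for X ~ Hypergeom(N=n_bg, K=m, n=n_q); zero overlap -> p=1
        p = float(hypergeom.sf(k - 1, n_bg, m, n_q)) if k > 0 else 1.0
        rows.append({"term": term, "n_term": m, "n_overlap": k, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].values)
    return df.sort_values(["p", "term"]).reset_index(drop=True)
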