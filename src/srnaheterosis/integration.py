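"""Joining the expression and methylation layers.

Builds (expression superclass, context, methylation pattern) groups of siRNA
clusters — the six focal ones are HPE-{CG,CHG,CHH}-TCM and
LPE-{CG,CHG,CHH}-TCdM — collects their associated protein-coding genes via
the cluster annotations, and tests associations with Fisher's exact test.
Also detects opposing miRNA-target pairs (miRNA and target on opposite
HPE/LPE sides) and provides generic hypergeometric term enrichment for
user-supplied gene-set annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_patterns import SUPERCLASS
from .genomic_context import GENE_CATEGORIES, ClusterAnnotation
from .io_formats import CONTEXTS

FOCAL_COMBOS = tuple([("HPE", ctx, "TCM") for ctx in CONTEXTS]
                     + [("LPE", ctx, "TCdM") for ctx in CONTEXTS])


@dataclass
class PatternGroup:
    """Clusters sharing an expression superclass and a per-context
    methylation pattern, with the genes they sit in or flank."""

    expression_superclass: str
    context: str
    methylation_pattern: str
    member_cluster_ids: list[str] = field(default_factory=list)
    associated_gene_ids: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return f"{self.expression_superclass}-{self.context}-{self.methylation_pattern}"


@dataclass(frozen=True)
class AssociationTest:
    label: str
    table: tuple  # ((a, b), (c, d))
    odds_ratio: float
    p: float


@dataclass(frozen=True)
class PairRecord:
    mirna_id: str
    mirna_pattern: str
    mirna_da: float
    target_gene_id: str
    gene_pattern: str
    gene_da: float
    source: str = "predicted"


def build_pattern_groups(expr_calls: pd.DataFrame,
                         meth_calls_by_context: dict[str, pd.DataFrame],
                         annotations: list[ClusterAnnotation],
                         focal_only: bool = False
                         ) -> tuple[list[PatternGroup], dict]:
    """Cross expression superclasses with per-context methylation patterns.

    ``expr_calls`` is a classified-call table for clusters (index cluster
    id, column ``pattern``); ``meth_calls_by_context`` maps context ->
    Met_d/a call table (index region/cluster id, column ``pattern``).
    Contexts are handled independently, so one cluster can belong to one
    group per context.  Associated genes are the deduplicated linked genes
    of members annotated as gene body / up2kb / down2kb.

    Clusters with an expression call but no methylation call in a context
    are excluded there and tallied in the returned report.
    """
    gene_of = {a.cluster_id: a.linked_gene_id for a in annotations
               if a.category in GENE_CATEGORIES}
    superclass = {cid: SUPERCLASS[p]
                  for cid, p in expr_calls["pattern"].items()}
    groups: dict[tuple, PatternGroup] = {}
    missing = {ctx: 0 for ctx in meth_calls_by_context}
    for ctx, meth in meth_calls_by_context.items():
        meth_pattern = meth["pattern"].to_dict()
        for cid, sc in superclass.items():
            mp = meth_pattern.get(cid)
            if mp is None:
                missing[ctx] += 1
                continue
            key = (sc, ctx, mp)
            if focal_only and key not in FOCAL_COMBOS:
                continue
            grp = groups.setdefault(key, PatternGroup(*key))
            grp.member_cluster_ids.append(cid)
            g = gene_of.get(cid)
            if g and g not in grp.associated_gene_ids:
                grp.associated_gene_ids.append(g)
    # stable order: focal combos first, then the rest alphabetically
    ordered = [groups[k] for k in FOCAL_COMBOS if k in groups]
    ordered += [groups[k] for k in sorted(groups)
                if k not in FOCAL_COMBOS]
    report = {"missing_methylation_call": missing}
    return ordered, report


def fisher_association(set_a: np.ndarray, set_b: np.ndarray,
                       label: str = "") -> AssociationTest:
    """Two-sided Fisher's exact test of two membership vectors.

    The p-value sums hypergeometric probabilities of tables at most as
    probable as the observed one.  The odds ratio is the unconditional
    ad/bc; a 0.5 Haldane correction is applied only when a margin cell is
    zero, and only for reporting the OR (never for p).
    """
    a = np.asarray(set_a, dtype=bool)
    b = np.asarray(set_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("membership vectors must have equal length")
    if a.size == 0:
        raise ValueError("empty universe")
    t11 = int(np.sum(a & b))
    t10 = int(np.sum(a & ~b))
    t01 = int(np.sum(~a & b))
    t00 = int(np.sum(~a & ~b))
    return fisher_from_table(t11, t10, t01, t00, label)


def fisher_from_table(t11: int, t10: int, t01: int, t00: int,
                      label: str = "") -> AssociationTest:
    p = float(stats.fisher_exact([[t11, t10], [t01, t00]],
                                 alternative="two-sided")[1])
    if min(t11, t10, t01, t00) == 0:
        num = (t11 + 0.5) * (t00 + 0.5)
        den = (t10 + 0.5) * (t01 + 0.5)
        orat = num / den
    else:
        orat = (t11 * t00) / (t10 * t01)
    return AssociationTest(label, ((t11, t10), (t01, t00)), float(orat),
                           min(p, 1.0))


def opposing_pairs(pair_table: pd.DataFrame, mirna_calls: pd.DataFrame,
                   gene_calls: pd.DataFrame) -> tuple[list[PairRecord], dict]:
    """miRNA-target pairs whose two ends fall on opposite HPE/LPE sides.

    ``pair_table`` needs columns ``mirna_id`` and ``target_gene_id``
    (optional ``source``).  Pairs whose miRNA or gene lacks a pattern call
    are skipped and tallied in the returned report.
    """
    mir_pat = mirna_calls["pattern"].to_dict()
    mir_da = mirna_calls["da_ratio"].to_dict()
    gene_pat = gene_calls["pattern"].to_dict()
    gene_da = gene_calls["da_ratio"].to_dict()
    kept: list[PairRecord] = []
    skipped = 0
    for row in pair_table.itertuples(index=False):
        mp = mir_pat.get(row.mirna_id)
        gp = gene_pat.get(row.target_gene_id)
        if mp is None or gp is None:
            skipped += 1
            continue
        sides = {SUPERCLASS[mp], SUPERCLASS[gp]}
        if sides == {"HPE", "LPE"}:
            kept.append(PairRecord(
                row.mirna_id, mp, float(mir_da[row.mirna_id]),
                row.target_gene_id, gp, float(gene_da[row.target_gene_id]),
                getattr(row, "source", "predicted")))
    return kept, {"skipped_unmatched": skipped}


def gene_pattern_enrichment_in_groups(groups: list[PatternGroup],
                                      gene_calls: pd.DataFrame
                                      ) -> list[AssociationTest]:
    """Fisher tests of gene superclasses within each pattern group.

    Background = all pattern-called genes associated with any of the given
    groups' clusters.  For each (group, gene superclass) pair the 2x2 table
    crosses group membership with superclass membership over that
    background.  Empty groups are skipped.
    """
    gene_sc = {g: SUPERCLASS[p] for g, p in gene_calls["pattern"].items()}
    universe = sorted({g for grp in groups for g in grp.associated_gene_ids
                       if g in gene_sc})
    tests: list[AssociationTest] = []
    if not universe:
        return tests
    uni = np.array(universe)
    for grp in groups:
        members = {g for g in grp.associated_gene_ids if g in gene_sc}
        if not members:
            continue
        in_group = np.array([g in members for g in uni])
        for sc in ("HPE", "LPE", "AE"):
            in_sc = np.array([gene_sc[g] == sc for g in uni])
            tests.append(fisher_association(in_group, in_sc,
                                            label=f"{grp.name}|{sc}"))
    return tests


def term_enrichment(gene_set, annotation: dict, universe) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of terms in a gene set.

    ``annotation`` maps gene -> iterable of terms.  For each term with K
    annotated genes in the universe of size N, and k of the n query genes,
    p = P(X >= k) with X ~ Hypergeom(N, K, n); BH-FDR across terms.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    n, N = len(gene_set), len(universe)
    term_genes: dict[str, set] = {}
    for g in universe:
        for t in annotation.get(g, ()):
            term_genes.setdefault(t, set()).add(g)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        K = len(members)
        k = len(members & gene_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"]
                       ).set_index("term")
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) \
        else np.array([])
    return out


def expression_by_methylation_pattern(expr_levels: pd.Series,
                                      meth_calls: pd.DataFrame
                                      ) -> list[tuple[str, str, float, float]]:
    """Welch t-tests of hybrid expression between methylation patterns.

    ``expr_levels`` holds per-cluster hybrid RPM (indexed by cluster id);
    comparison is on log2(RPM + 1).  Returns (pattern_a, pattern_b, t, p)
    for every unordered pair of TCM/TCdM/NIM.  A pattern with < 2 clusters
    is an error.
    """
    pattern = meth_calls["pattern"]
    by_pat = {}
    for pat in ("TCM", "TCdM", "NIM"):
        ids = pattern.index[pattern == pat]
        vals = np.log2(expr_levels.reindex(ids).dropna().to_numpy() + 1)
        by_pat[pat] = vals
    out = []
    for i, pa in enumerate(("TCM", "TCdM", "NIM")):
        for pb in ("TCM", "TCdM", "NIM")[i + 1:]:
            x, y = by_pat[pa], by_pat[pb]
            if len(x) < 2 or len(y) < 2:
                raise ValueError(f"pattern {pa if len(x) < 2 else pb} has "
                                 "fewer than 2 clusters")
            if np.array_equal(np.sort(x), np.sort(y)):
                out.append((pa, pb, 0.0, 1.0))
                continue
            t, p = stats.ttest_ind(x, y, equal_var=False)
            out.append((pa, pb, float(t), float(p)))
    return out
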