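from math import comb

import numpy as np
import pandas as pd
import pytest

from srnaheterosis import integration as it
from srnaheterosis.genomic_context import ClusterAnnotation


# ---------------------------------------------------------------------------
# Fisher's exact test vs full enumeration
# ---------------------------------------------------------------------------

def enumeration_fisher(t11, t10, t01, t00):
    """Two-sided Fisher p by summing hypergeometric probabilities of all
    tables with the observed margins that are at most as probable."""
    r1, r2 = t11 + t10, t01 + t00
    c1 = t11 + t01
    n = r1 + r2
    def prob(a):
        b, c, d = r1 - a, c1 - a, r2 - (c1 - a)
        if min(b, c, d) < 0:
            return 0.0
        return comb(r1, a) * comb(r2, c) / comb(n, c1)
    p_obs = prob(t11)
    total = 0.0
    for a in range(0, min(r1, c1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


@pytest.mark.parametrize("table,expected", [
    ((5, 5, 5, 5), 1.0),
    ((10, 0, 0, 10), 2 / comb(20, 10)),
    ((3, 1, 1, 3), 34 / 70),
])
def test_fisher_known_tables(table, expected):
    res = it.fisher_from_table(*table)
    assert res.p == pytest.approx(expected, rel=1e-9)


def test_fisher_balanced_table_or_one():
    res = it.fisher_from_table(5, 5, 5, 5)
    assert res.odds_ratio == pytest.approx(1.0)


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(2)
    for _ in range(200):
        n = int(rng.integers(4, 41))
        cells = rng.multinomial(n, [0.25] * 4)
        res = it.fisher_from_table(*cells)
        assert res.p == pytest.approx(enumeration_fisher(*cells), rel=1e-9)


def test_fisher_membership_vectors_and_errors():
    a = np.array([True] * 10 + [False] * 10)
    res = it.fisher_association(a, a)
    assert res.table == ((10, 0), (0, 10))
    with pytest.raises(ValueError):
        it.fisher_association([], [])
    with pytest.raises(ValueError):
        it.fisher_association([True], [True, False])


def test_fisher_haldane_only_for_odds_ratio():
    res = it.fisher_from_table(10, 0, 0, 10)
    # p untouched by the correction; OR finite via Haldane
    assert res.p == pytest.approx(2 / comb(20, 10), rel=1e-9)
    assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1


# ---------------------------------------------------------------------------
# pattern groups
# ---------------------------------------------------------------------------

def _expr_calls(d):
    return pd.DataFrame({"pattern": pd.Series(d), "da_ratio": 1.0})


def _meth_calls(d):
    return pd.DataFrame({"pattern": pd.Series(d)})


def test_build_pattern_groups_construction():
    expr = _expr_calls({"c1": "THPE", "c2": "DLPE", "c3": "AE"})
    meth = {"CG": _meth_calls({"c1": "TCM", "c2": "TCdM", "c3": "TCM"})}
    anns = [ClusterAnnotation("c1", "gene_body", "G1"),
            ClusterAnnotation("c2", "up2kb", "G2"),
            ClusterAnnotation("c3", "intergenic")]
    groups, report = it.build_pattern_groups(expr, meth, anns)
    by_name = {g.name: g for g in groups}
    assert by_name["HPE-CG-TCM"].member_cluster_ids == ["c1"]
    assert by_name["HPE-CG-TCM"].associated_gene_ids == ["G1"]
    assert by_name["LPE-CG-TCdM"].member_cluster_ids == ["c2"]
    # AE clusters never enter the six focal groups
    focal_members = {c for name, g in by_name.items()
                     if (g.expression_superclass, g.context,
                         g.methylation_pattern) in it.FOCAL_COMBOS
                     for c in g.member_cluster_ids}
    assert "c3" not in focal_members
    assert report["missing_methylation_call"]["CG"] == 0


def test_build_pattern_groups_counts_missing_methylation():
    expr = _expr_calls({"c1": "THPE", "c2": "THPE"})
    meth = {"CHH": _meth_calls({"c1": "TCM"})}
    groups, report = it.build_pattern_groups(expr, meth, [])
    assert report["missing_methylation_call"]["CHH"] == 1


def test_pattern_groups_partition_per_context():
    """Each (cluster, context) pair lands in exactly one group."""
    rng = np.random.default_rng(3)
    ids = [f"c{i}" for i in range(60)]
    expr = _expr_calls({i: rng.choice(["THPE", "DHPE", "AE", "DLPE", "TLPE"])
                        for i in ids})
    meth = {ctx: _meth_calls({i: rng.choice(["TCM", "TCdM", "NIM"])
                              for i in ids}) for ctx in ("CG", "CHG")}
    groups, _ = it.build_pattern_groups(expr, meth, [])
    for ctx in ("CG", "CHG"):
        members = [c for g in groups if g.context == ctx
                   for c in g.member_cluster_ids]
        assert sorted(members) == sorted(ids)


def test_gene_deduplicated_within_group():
    expr = _expr_calls({"c1": "THPE", "c2": "DHPE"})
    meth = {"CG": _meth_calls({"c1": "TCM", "c2": "TCM"})}
    anns = [ClusterAnnotation("c1", "gene_body", "G"),
            ClusterAnnotation("c2", "down2kb", "G")]
    groups, _ = it.build_pattern_groups(expr, meth, anns)
    grp = {g.name: g for g in groups}["HPE-CG-TCM"]
    assert grp.associated_gene_ids == ["G"]


# ---------------------------------------------------------------------------
# opposing pairs
# ---------------------------------------------------------------------------

def test_opposing_pairs_rules():
    mirna = pd.DataFrame({"pattern": ["THPE", "AE", "DHPE"],
                          "da_ratio": [5.23, 0.1, 1.0]},
                         index=["mir160", "mirAE", "mirH"])
    genes = pd.DataFrame({"pattern": ["TLPE", "THPE", "THPE"],
                          "da_ratio": [-15.86, 3.0, 2.5]},
                         index=["ARF17", "gH", "gH2"])
    table = pd.DataFrame({
        "mirna_id": ["mir160", "mirAE", "mirH", "ghost"],
        "target_gene_id": ["ARF17", "gH", "gH2", "gH"],
        "source": ["degradome", "predicted", "predicted", "predicted"]})
    pairs, report = it.opposing_pairs(table, mirna, genes)
    assert len(pairs) == 1
    p = pairs[0]
    assert (p.mirna_id, p.target_gene_id) == ("mir160", "ARF17")
    assert p.mirna_da == pytest.approx(5.23)
    assert p.source == "degradome"
    assert report["skipped_unmatched"] == 1


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def test_term_enrichment_hypergeometric_oracle():
    universe = [f"g{i}" for i in range(20)]
    gene_set = universe[:5]
    annotation = {g: ["hit"] for g in gene_set}
    annotation.update({g: ["bg"] for g in universe})
    for g in gene_set:
        annotation[g] = ["hit", "bg"]
    res = it.term_enrichment(gene_set, annotation, universe)
    assert res.loc["hit", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-12)
    assert res.loc["bg", "p"] == pytest.approx(1.0)


def test_term_enrichment_full_set_and_absent_term():
    universe = [f"g{i}" for i in range(10)]
    annotation = {g: ["t1"] for g in universe}
    annotation["g0"] = ["t1", "t2"]
    res = it.term_enrichment(universe, annotation, universe)
    assert np.allclose(res["p"], 1.0)
    # k = 0: never significant
    res2 = it.term_enrichment(universe[5:], {"g0": ["only0"]}, universe)
    assert res2.loc["only0", "p"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        it.term_enrichment(["zz"], annotation, universe)


def test_group_gene_enrichment_detects_planted_skew():
    genes = {f"L{i}": "DLPE" for i in range(10)}
    genes.update({f"H{i}": "DHPE" for i in range(10)})
    calls = pd.DataFrame({"pattern": pd.Series(genes)})
    grp = it.PatternGroup("HPE", "CG", "TCM",
                          member_cluster_ids=["c"],
                          associated_gene_ids=[f"L{i}" for i in range(10)])
    bg = it.PatternGroup("LPE", "CG", "TCdM",
                         member_cluster_ids=["d"],
                         associated_gene_ids=list(genes))
    tests = it.gene_pattern_enrichment_in_groups([grp, bg], calls)
    by_label = {t.label: t for t in tests}
    hit = by_label["HPE-CG-TCM|LPE"]
    assert hit.odds_ratio > 1
    # all-LPE group against a balanced background: enumeration gives
    # p = 2 / C(20,10) for the 10/10 split
    assert hit.p == pytest.approx(2 / comb(20, 10), rel=1e-9)


# ---------------------------------------------------------------------------
# expression by methylation pattern
# ---------------------------------------------------------------------------

def test_expression_by_methylation_pattern_planted_shift():
    rng = np.random.default_rng(4)
    ids_tcm = [f"t{i}" for i in range(200)]
    ids_nim = [f"n{i}" for i in range(200)]
    ids_tcdm = [f"d{i}" for i in range(200)]
    meth = pd.DataFrame({"pattern": ["TCM"] * 200 + ["NIM"] * 200
                         + ["TCdM"] * 200},
                        index=ids_tcm + ids_nim + ids_tcdm)
    base = pd.Series(rng.uniform(50, 60, 600), index=meth.index)
    base.loc[ids_tcm] *= 4.0  # +2 log2 units
    res = it.expression_by_methylation_pattern(base, meth)
    res = {(a, b): (t, p) for a, b, t, p in res}
    t, p = res[("TCM", "NIM")]
    assert t > 0 and p < 1e-10


def test_expression_by_methylation_pattern_errors_on_tiny_group():
    meth = pd.DataFrame({"pattern": ["TCM", "NIM", "NIM", "TCdM", "TCdM"]},
                        index=list("abcde"))
    expr = pd.Series(1.0, index=meth.index)
    with pytest.raises(ValueError, match="fewer than 2"):
        it.expression_by_methylation_pattern(expr, meth)
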