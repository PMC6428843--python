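"""Glycosite tables, co-occurrence, networks, subcellular profiles, domains."""

import itertools

import numpy as np
import pandas as pd
import pytest

from glycoscape.heterogeneity import (
    GlycositeTable,
    build_site_table,
    cluster_domains,
    collapse_cc_terms,
    collapse_domain_label,
    cooccurrence_matrix,
    domain_stats,
    export_network,
    glycan_type_labels,
    profile_distance_matrix,
    subcellular_profiles,
)

HM = "HexNAc(2)Hex(9)"      # high mannose
SIA = "HexNAc(4)Hex(4)Fuc(1)NeuAc(1)"  # sialylated + fucosylated
PAU = "HexNAc(2)Hex(3)"     # paucimannose
CH = "HexNAc(4)Hex(5)"      # complex/hybrid


def _table(rows):
    """rows: (protein, site, glycan[, psm_count])"""
    recs = [
        {"protein_accession": r[0], "site": r[1], "glycan": r[2],
         "psm_count": r[3] if len(r) > 3 else 1}
        for r in rows
    ]
    return GlycositeTable(pd.DataFrame(recs))


def test_build_site_table_dedups_and_counts(psm_factory):
    rows = [{"protein_site": 10}] * 3 + [
        {"protein_site": 10, "glycan": SIA},
        {"protein_site": 44, "glycan": SIA},
        {"protein_site": np.nan},
        {"is_decoy": True, "protein_site": 99},
    ]
    with pytest.warns(UserWarning, match="lack a protein site"):
        table = build_site_table(psm_factory(rows))
    assert len(table) == 3
    row = table.data[(table.data["site"] == 10) & (table.data["glycan"] == HM)]
    assert row["psm_count"].iloc[0] == 3
    assert table.n_sites == 2
    assert table.n_proteins == 1
    assert dict(table.glycans_per_site()) == {1: 1, 2: 1}


def test_cooccurrence_examples():
    one_site = _table([("P1", 5, "A" if False else HM), ("P1", 5, SIA), ("P1", 5, PAU)])
    mat = cooccurrence_matrix(one_site)
    for a, b in itertools.combinations([HM, SIA, PAU], 2):
        assert mat.loc[a, b] == 1
    assert (np.diag(mat.to_numpy()) == 0).all()

    two_sites = _table([("P1", 5, HM), ("P1", 5, SIA), ("P2", 9, HM), ("P2", 9, SIA)])
    assert cooccurrence_matrix(two_sites).loc[HM, SIA] == 2


def test_cooccurrence_total_identity_random_tables():
    """Upper-triangle total equals sum over sites of C(k, 2)."""
    rng = np.random.default_rng(23)
    glycans = [HM, SIA, PAU, CH, "HexNAc(2)Hex(5)", "HexNAc(3)Hex(4)NeuAc(1)"]
    for _ in range(25):
        rows = []
        for s in range(rng.integers(3, 12)):
            k = int(rng.integers(1, len(glycans) + 1))
            chosen = rng.choice(len(glycans), size=k, replace=False)
            rows += [("P%d" % rng.integers(3), s, glycans[int(g)]) for g in chosen]
        table = _table(rows)
        mat = cooccurrence_matrix(table).to_numpy()
        upper = np.triu(mat).sum()
        expected = sum(
            len(g) * (len(g) - 1) // 2 for g in table.site_glycan_sets().values()
        )
        assert upper == expected
        assert (mat == mat.T).all()


def test_bipartite_network_dedups_edges():
    table = _table([("P1", 5, HM), ("P1", 9, HM), ("P1", 9, SIA)])
    g, edges = export_network(table, "bipartite")
    assert len(edges) == 2
    assert g.nodes["P1"]["n_glycosites"] == 2
    assert g.nodes[HM]["kind"] == "glycan"


def test_source_glycan_star_equals_matrix_row():
    rng = np.random.default_rng(7)
    glycans = [HM, SIA, PAU, CH]
    rows = []
    for s in range(10):
        chosen = rng.choice(4, size=int(rng.integers(1, 5)), replace=False)
        rows += [("P1", s, glycans[int(g)]) for g in chosen]
    table = _table(rows)
    mat = cooccurrence_matrix(table)
    _, star = export_network(table, "source_glycan", source=SIA)
    weights = dict(zip(star["target"], star["weight"]))
    for other in mat.columns:
        if other != SIA and mat.loc[SIA, other] > 0:
            assert weights[other] == mat.loc[SIA, other]
    with pytest.raises(ValueError, match="not observed"):
        export_network(table, "source_glycan", source="HexNAc(2)Hex(12)")


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        cooccurrence_matrix(_table([]))


@pytest.mark.parametrize(
    "term,group",
    [
        ("plasma membrane", "plasma_membrane"),
        ("integral component of membrane", "other_membrane"),
        ("synaptic vesicle membrane", "other_membrane"),  # membrane rule first
        ("axon terminal", "neural"),
        ("myelin sheath", "neural"),
        ("Golgi apparatus", "Golgi"),
        ("Golgi-associated endoplasmic reticulum", "ER"),
        ("endoplasmic reticulum lumen", "ER"),
        ("cell surface", "cell_surface"),
        ("synapse", "synapse"),
        ("transport vesicle", "vesicle"),
        ("lysosome", "lysosome"),
        ("extracellular space", "secreted"),
        ("cytoplasm", "other_cellular_component"),
    ],
)
def test_collapse_cc_terms(term, group):
    assert collapse_cc_terms([term]) == {group}


def test_collapse_cc_no_terms_and_multiple_groups():
    assert collapse_cc_terms([]) == {"none_listed"}
    got = collapse_cc_terms(["plasma membrane", "lysosome"])
    assert got == {"plasma_membrane", "lysosome"}


def test_subcellular_profiles_and_conservation():
    table = _table([("P1", 5, HM), ("P1", 9, SIA), ("P2", 3, HM)])
    order = [HM, SIA, PAU]
    single = {"P1": {"lysosome"}, "P2": {"ER"}}
    prof = subcellular_profiles(table, single, order)
    assert prof.loc["lysosome", HM] == 1
    assert prof.loc["lysosome", SIA] == 1
    assert prof.loc["ER", HM] == 1
    assert prof.to_numpy().sum() == 3  # single-group proteins conserve totals
    multi = {"P1": {"lysosome", "ER"}, "P2": {"ER"}}
    prof2 = subcellular_profiles(table, multi, order)
    assert prof2.to_numpy().sum() == 5  # multi-membership inflates


def test_profile_distances_metric_properties():
    rng = np.random.default_rng(31)
    prof = pd.DataFrame(rng.integers(0, 20, size=(6, 10)).astype(float),
                        index=[f"g{i}" for i in range(6)])
    d = profile_distance_matrix(prof)
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)
    for i, j, k in itertools.permutations(range(6), 3):
        assert d.iloc[i, j] <= d.iloc[i, k] + d.iloc[k, j] + 1e-9
    # hand values
    two = pd.DataFrame([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], index=["a", "b"])
    assert profile_distance_matrix(two).loc["a", "b"] == pytest.approx(np.sqrt(2))


def test_glycan_type_labels_multilabel_rule():
    assert glycan_type_labels(SIA) == {"sialylated", "fucosylated"}
    assert glycan_type_labels(SIA, multilabel=False) == {"sialylated"}
    assert glycan_type_labels("HexNAc(2)Hex(3)Fuc(1)") == {"fucosylated"}
    assert glycan_type_labels(HM) == {"high_mannose"}


@pytest.mark.parametrize(
    "label,collapsed",
    [
        ("Ig-like C2-type", "Ig-like"),
        ("Ig-like V-type", "Ig-like"),
        ("Ig-like", "Ig-like"),
        ("EGF-like 3", "EGF-like"),
        ("Fibronectin type-III 7", "Fibronectin type-III"),
        ("Sushi", "Sushi"),
    ],
)
def test_collapse_domain_label(label, collapsed):
    assert collapse_domain_label(label) == collapsed


def _domain_setup():
    # P1 sites 5, 20, 30 inside an Ig-like domain 1..40; site 50 outside
    table = _table(
        [
            ("P1", 5, HM),
            ("P1", 20, HM), ("P1", 20, SIA),
            ("P1", 30, HM), ("P1", 30, SIA), ("P1", 30, PAU),
            ("P1", 50, CH),
        ]
    )
    ann = pd.DataFrame(
        [{"protein_accession": "P1", "domain": "Ig-like C2-type",
          "start": 1, "end": 40}]
    )
    return table, ann


def test_domain_heterogeneity_ratio():
    """Sites with 1, 2, 3 glycan types give ratio (1+2+3)/3 = 2."""
    table, ann = _domain_setup()
    stats = domain_stats(table, ann, {"Ig-like": 10}, min_sites=1)
    ig = next(s for s in stats if s.domain == "Ig-like")
    assert ig.n_glycosites == 3
    # type sets: {hm}, {hm, sia, fuc}... careful: SIA is sialylated+fucosylated
    # site 5 -> {high_mannose}=1; site 20 -> {hm, sial, fuc}=3;
    # site 30 -> {hm, sial, fuc, pauci}=4; ratio = 8/3
    assert ig.heterogeneity_ratio == pytest.approx(8 / 3)
    assert ig.pct_domains_with_glycosite == pytest.approx(10.0)


def test_domain_composition_difference_sums_to_zero():
    table, ann = _domain_setup()
    stats = domain_stats(table, ann, min_sites=1)
    for s in stats:
        assert sum(s.composition_difference.values()) == pytest.approx(0.0, abs=1e-9)


def test_domain_pooling_below_min_sites():
    table, ann = _domain_setup()
    stats = domain_stats(table, ann, min_sites=7)
    names = {s.domain for s in stats}
    assert "Ig-like" not in names
    assert "other domains" in names


def test_pooled_other_domains_matches_global_mix():
    """A pooled domain whose sites are all the sites has a ~zero difference."""
    table, _ = _domain_setup()
    ann = pd.DataFrame(
        [{"protein_accession": "P1", "domain": "TinyDom", "start": 1, "end": 60}]
    )
    stats = domain_stats(table, ann, min_sites=7)
    other = next(s for s in stats if s.domain == "other domains")
    assert other.n_glycosites == 4
    for v in other.composition_difference.values():
        assert v == pytest.approx(0.0, abs=1e-9)


def test_domain_zero_proteome_count_flagged():
    table, ann = _domain_setup()
    with pytest.warns(UserWarning, match="zero or missing"):
        stats = domain_stats(table, ann, {"SomethingElse": 5}, min_sites=1)
    ig = next(s for s in stats if s.domain == "Ig-like")
    assert ig.pct_domains_with_glycosite is None


def test_heterogeneity_ratio_at_least_one_random_tables():
    rng = np.random.default_rng(41)
    glycans = [HM, SIA, PAU, CH]
    for _ in range(20):
        rows = []
        for s in range(int(rng.integers(2, 8))):
            chosen = rng.choice(4, size=int(rng.integers(1, 5)), replace=False)
            rows += [("P1", s + 1, glycans[int(g)]) for g in chosen]
        table = _table(rows)
        ann = pd.DataFrame(
            [{"protein_accession": "P1", "domain": "D", "start": 1, "end": 100}]
        )
        stats = domain_stats(table, ann, min_sites=1)
        for s in stats:
            if s.n_glycosites:
                assert s.heterogeneity_ratio >= 1.0


def _stats_from_vectors(vectors):
    from glycoscape.heterogeneity import DomainStats
    from glycoscape.glycans import GLYCAN_TYPES

    return [
        DomainStats(f"d{i}", 1, 1.0, None, dict(zip(GLYCAN_TYPES, v)))
        for i, v in enumerate(vectors)
    ]


def test_cluster_domains_outlier_last():
    close_a = [0, 0, 0, 0, 0, 0]
    close_b = [1, 0, 0, 0, 0, -1]
    outlier = [50, -10, -10, -10, -10, -10]
    order = cluster_domains(_stats_from_vectors([outlier, close_a, close_b]))
    assert order.index("d0") in (0, 2)  # outlier at one end of the leaf order
    assert {order[0], order[1], order[2]} == {"d0", "d1", "d2"}
    # identical vectors merge first: put two equal, they stay adjacent
    order2 = cluster_domains(_stats_from_vectors([close_a, outlier, close_a]))
    assert abs(order2.index("d0") - order2.index("d2")) == 1


def test_cluster_domains_permutation_invariant():
    """Shuffling the input list leaves the (label-sorted, deterministic)
    leaf ordering unchanged."""
    vecs = [[0, 1, 0, 0, -1, 0], [5, 0, -5, 0, 0, 0], [0, 0, 0, 2, -2, 0]]
    stats = _stats_from_vectors(vecs)
    a = cluster_domains(stats)
    b = cluster_domains(stats[::-1])
    assert a == b


def test_cluster_single_domain_identity():
    assert cluster_domains(_stats_from_vectors([[1, 0, 0, 0, 0, -1]])) == ["d0"]
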