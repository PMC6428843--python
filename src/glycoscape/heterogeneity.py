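"""Systems-level analytics over filtered glycopeptide identifications.

Filtered identifications are aggregated to (protein, site, glycan) triples —
the glycosite table — from which everything else derives: glycans-per-site and
sites-per-protein distributions, glycan co-occurrence counts and networks,
subcellular glycosylation profiles with Euclidean distances, and per-domain
glyco-type statistics with hierarchical clustering.

Glycan-type accounting uses six categories (paucimannose, high mannose,
complex/hybrid, fucosylated, sialylated, M6P).  Two typings are exposed: the
exclusive class (one bucket per glycan, used for network node coloring) and a
multi-label typing in which a fucosylated paucimannose or sialylated glycan
also counts as fucosylated (used for composition-difference statistics).
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .glycans import GLYCAN_TYPES, GlycanComposition, classify_glycan, parse_composition

__all__ = [
    "GlycositeTable",
    "build_site_table",
    "cooccurrence_matrix",
    "export_network",
    "collapse_cc_terms",
    "subcellular_profiles",
    "profile_distance_matrix",
    "DomainStats",
    "domain_stats",
    "cluster_domains",
    "DEFAULT_CC_RULES",
    "SUBCELLULAR_GROUPS",
    "glycan_type_labels",
    "collapse_domain_label",
]


@dataclass
class GlycositeTable:
    """Deduplicated (protein, site, glycan) triples with PSM tallies.

    ``data`` has columns protein_accession, site (1-based protein coordinate),
    glycan (canonical composition string), psm_count.
    """

    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_sites(self) -> int:
        return self.data[["protein_accession", "site"]].drop_duplicates().shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data["protein_accession"].nunique()

    @property
    def n_glycans(self) -> int:
        return self.data["glycan"].nunique()

    def glycans_per_site(self) -> pd.Series:
        """Histogram: number of sites (value) with k distinct glycans (index)."""
        k = self.data.groupby(["protein_accession", "site"])["glycan"].nunique()
        return k.value_counts().sort_index()

    def sites_per_protein(self) -> pd.Series:
        k = self.data.groupby("protein_accession")["site"].nunique()
        return k.value_counts().sort_index()

    def site_glycan_sets(self) -> dict[tuple[str, int], set[str]]:
        out: dict[tuple[str, int], set[str]] = {}
        for (acc, site), grp in self.data.groupby(["protein_accession", "site"]):
            out[(acc, int(site))] = set(grp["glycan"])
        return out

    def summary(self) -> dict:
        return {
            "n_site_glycan_pairs": len(self),
            "n_glycosites": self.n_sites,
            "n_glycoproteins": self.n_proteins,
            "n_glycans": self.n_glycans,
        }


def build_site_table(filtered_psms: pd.DataFrame) -> GlycositeTable:
    """Aggregate filtered PSMs to unique (protein, site, glycan) rows.

    Expects columns ``protein_accession``, ``protein_site`` (1-based protein
    coordinate of the glycosite) and ``glycan``; rows with a missing site
    position are rejected with a warning.  Decoy rows, if present, are
    dropped.
    """
    df = filtered_psms
    if "is_decoy" in df.columns:
        df = df[~df["is_decoy"].astype(bool)]
    df = df[df["glycan"].notna() & (df["glycan"].astype(str) != "")]
    missing = df["protein_site"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} rows lack a protein site position; rejected",
            stacklevel=2,
        )
        df = df[~missing]
    grouped = (
        df.assign(site=df["protein_site"].astype(int))
        .groupby(["protein_accession", "site", "glycan"])
        .size()
        .rename("psm_count")
        .reset_index()
        .sort_values(["protein_accession", "site", "glycan"])
        .reset_index(drop=True)
    )
    return GlycositeTable(grouped)


def cooccurrence_matrix(
    table: GlycositeTable, glycan_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric glycan pair co-occurrence counts.

    Cell (a, b) is the number of glycosites where both glycans were observed;
    the diagonal is zero and the upper-triangle total equals
    sum over sites of C(k_site, 2).
    """
    if len(table) == 0:
        raise ValueError("empty glycosite table")
    if glycan_order is None:
        glycan_order = sorted(table.data["glycan"].unique())
    idx = {g: i for i, g in enumerate(glycan_order)}
    mat = np.zeros((len(glycan_order), len(glycan_order)), dtype=int)
    for glycans in table.site_glycan_sets().values():
        for a, b in itertools.combinations(sorted(glycans), 2):
            if a in idx and b in idx:
                mat[idx[a], idx[b]] += 1
                mat[idx[b], idx[a]] += 1
    return pd.DataFrame(mat, index=list(glycan_order), columns=list(glycan_order))


def export_network(
    table: GlycositeTable,
    mode: str = "bipartite",
    source: str | GlycanComposition | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Build a network and its edge list from a glycosite table.

    Modes: ``bipartite`` (glycan-protein edges, protein nodes annotated with
    their glycosite count), ``cooccurrence`` (weighted glycan-glycan edges)
    and ``source_glycan`` (the star of co-occurrence edges around *source*).
    Returns the graph and a deterministic edge-list DataFrame.
    """
    if mode == "bipartite":
        g = nx.Graph()
        counts = table.data.groupby("protein_accession")["site"].nunique()
        edges = set()
        for _, row in table.data.iterrows():
            edges.add((row["glycan"], row["protein_accession"]))
        for glycan in sorted({e[0] for e in edges}):
            g.add_node(glycan, kind="glycan",
                       glycan_class=classify_glycan(parse_composition(glycan)).exclusive_class)
        for acc in sorted({e[1] for e in edges}):
            g.add_node(acc, kind="protein", n_glycosites=int(counts[acc]))
        g.add_edges_from(edges)
        df = pd.DataFrame(
            sorted(edges), columns=["glycan", "protein_accession"]
        )
        return g, df

    mat = cooccurrence_matrix(table)
    if mode == "cooccurrence":
        g = nx.Graph()
        rows = []
        for a, b in itertools.combinations(mat.index, 2):
            w = int(mat.loc[a, b])
            if w > 0:
                g.add_edge(a, b, weight=w)
                rows.append((a, b, w))
        df = pd.DataFrame(rows, columns=["glycan_a", "glycan_b", "weight"])
        return g, df

    if mode == "source_glycan":
        if source is None:
            raise ValueError("source glycan required for source_glycan mode")
        key = str(source if isinstance(source, GlycanComposition)
                  else parse_composition(str(source)))
        if key not in mat.index:
            raise ValueError(f"source glycan {key} not observed in the table")
        g = nx.Graph()
        rows = []
        for other in mat.columns:
            w = int(mat.loc[key, other])
            if w > 0:
                g.add_edge(key, other, weight=w)
                rows.append((key, other, w))
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        return g, df

    raise ValueError(f"unknown network mode {mode!r}")


#: The twelve subcellular groups.
SUBCELLULAR_GROUPS = (
    "plasma_membrane",
    "other_membrane",
    "synapse",
    "vesicle",
    "cell_surface",
    "neural",
    "lysosome",
    "secreted",
    "Golgi",
    "ER",
    "other_cellular_component",
    "none_listed",
)

#: Ordered collapsing rules: (kind, pattern(s), group).  ``exact`` matches the
#: whole term; ``contains`` matches substrings; ``contains_without`` requires
#: the first substring and forbids the second.  The first matching rule wins.
DEFAULT_CC_RULES: tuple = (
    ("exact", ("plasma membrane",), "plasma_membrane"),
    ("contains", ("membrane",), "other_membrane"),
    ("contains", ("axon", "neuro", "myelin"), "neural"),
    ("contains_without", ("golgi", "endoplasmic"), "Golgi"),
    ("contains", ("endoplasmic",), "ER"),
    ("contains", ("surface",), "cell_surface"),
    ("contains", ("synap",), "synapse"),
    ("contains", ("vesicle",), "vesicle"),
    ("contains", ("lysosom",), "lysosome"),
    ("contains", ("secret", "extracellular"), "secreted"),
)


def collapse_cc_terms(
    terms: Iterable[str], rules: Sequence[tuple] = DEFAULT_CC_RULES
) -> set[str]:
    """Collapse GO cellular-component terms to subcellular groups.

    Each term maps to the first matching rule's group (e.g. exact "plasma
    membrane" -> plasma_membrane, any other term containing "membrane" ->
    other_membrane, terms containing axon/neuro/myelin -> neural); terms that
    match no rule fall into ``other_cellular_component``, and a protein with
    no terms at all maps to ``none_listed``.  A protein may belong to several
    groups.
    """
    terms = [t for t in terms if t and str(t).strip()]
    if not terms:
        return {"none_listed"}
    groups: set[str] = set()
    for term in terms:
        t = str(term).strip().lower()
        matched = None
        for kind, patterns, group in rules:
            if kind == "exact" and t in patterns:
                matched = group
            elif kind == "contains" and any(p in t for p in patterns):
                matched = group
            elif kind == "contains_without" and patterns[0] in t and patterns[1] not in t:
                matched = group
            if matched:
                break
        groups.add(matched or "other_cellular_component")
    return groups


def subcellular_profiles(
    table: GlycositeTable,
    protein_groups: Mapping[str, Iterable[str]],
    glycan_order: Sequence[str],
    count_psms: bool = False,
) -> pd.DataFrame:
    """Per-group glycan occurrence vectors.

    Rows are subcellular groups, columns the glycan database order; cell
    values count unique site-glycan observations (default) or PSMs within the
    group.  A protein mapped to k groups contributes to all k, so group totals
    can exceed the overall observation count.
    """
    profiles = pd.DataFrame(
        0, index=list(SUBCELLULAR_GROUPS), columns=list(glycan_order), dtype=int
    )
    for _, row in table.data.iterrows():
        acc = row["protein_accession"]
        glycan = row["glycan"]
        if glycan not in profiles.columns:
            continue
        weight = int(row["psm_count"]) if count_psms else 1
        for group in protein_groups.get(acc, {"none_listed"}):
            profiles.loc[group, glycan] += weight
    return profiles


def profile_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between group profile vectors."""
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def glycan_type_labels(glycan: str | GlycanComposition, multilabel: bool = True) -> set[str]:
    """Glycan-type label set over the six categories.

    With ``multilabel`` (default) a fucose-bearing glycan of any exclusive
    class also counts as fucosylated; otherwise only the exclusive class is
    returned.
    """
    comp = glycan if isinstance(glycan, GlycanComposition) else parse_composition(str(glycan))
    cls = classify_glycan(comp)
    labels = {cls.exclusive_class}
    if multilabel and comp["Fuc"] >= 1:
        labels.add("fucosylated")
    return labels


_SUBTYPE_SUFFIX = re.compile(r"\s+(?:C\d+-type|V-type|\d+)$")


def collapse_domain_label(label: str) -> str:
    """Collapse a domain label to its broadest common term.

    Strips subtype and repeat qualifiers, e.g. "Ig-like C2-type" -> "Ig-like"
    and "EGF-like 3" -> "EGF-like".
    """
    label = str(label).strip()
    prev = None
    while prev != label:
        prev = label
        label = _SUBTYPE_SUFFIX.sub("", label)
    return label


@dataclass
class DomainStats:
    """Glyco-type statistics for one (collapsed) domain type.

    ``heterogeneity_ratio`` is the number of glycan-type-glycosite
    combinations divided by the number of glycosites in the domain;
    ``composition_difference`` gives, per glycan type, the domain's percentage
    of type combinations minus the overall percentage (entries sum to zero).
    """

    domain: str
    n_glycosites: int
    heterogeneity_ratio: float
    pct_domains_with_glycosite: float | None
    composition_difference: dict = field(default_factory=dict)

    def vector(self) -> np.ndarray:
        return np.array([self.composition_difference[t] for t in GLYCAN_TYPES])


def _type_combinations(site_types: Mapping[tuple, set[str]]) -> dict[str, int]:
    counts = {t: 0 for t in GLYCAN_TYPES}
    for types in site_types.values():
        for t in types:
            counts[t] += 1
    return counts


def domain_stats(
    table: GlycositeTable,
    domain_annotations: pd.DataFrame,
    proteome_domain_counts: Mapping[str, int] | pd.Series | None = None,
    min_sites: int = 7,
    multilabel: bool = True,
) -> list[DomainStats]:
    """Per-domain glycan heterogeneity and composition-difference statistics.

    *domain_annotations* needs columns ``protein_accession``, ``domain``,
    ``start``, ``end`` (1-based closed spans); labels are collapsed to their
    broadest common term, and a glycosite maps to a domain instance when
    start <= site <= end.  Domains with fewer than *min_sites* glycosites are
    pooled into ``other domains``.  ``pct_domains_with_glycosite`` is the
    number of glycosylated domain instances over the proteome-wide instance
    count (None/flagged when that count is missing or zero).

    The overall heterogeneity ratio and composition percentages are computed
    over all glycosites (domain-mapped or not) and the returned list ends with
    an ``all glycosites`` entry carrying them.
    """
    site_types: dict[tuple, set[str]] = {}
    for (acc, site), glycans in table.site_glycan_sets().items():
        types: set[str] = set()
        for g in glycans:
            types |= glycan_type_labels(g, multilabel=multilabel)
        site_types[(acc, site)] = types

    overall_counts = _type_combinations(site_types)
    overall_total = sum(overall_counts.values())
    overall_pct = {
        t: (100.0 * overall_counts[t] / overall_total if overall_total else 0.0)
        for t in GLYCAN_TYPES
    }
    overall_ratio = overall_total / len(site_types) if site_types else 0.0

    ann = domain_annotations.copy()
    ann["domain"] = ann["domain"].map(collapse_domain_label)

    domain_sites: dict[str, set[tuple]] = {}
    domain_instances: dict[str, set[tuple]] = {}
    for _, row in ann.iterrows():
        dom = row["domain"]
        acc = row["protein_accession"]
        start, end = int(row["start"]), int(row["end"])
        hit = False
        for (s_acc, site) in site_types:
            if s_acc == acc and start <= site <= end:
                domain_sites.setdefault(dom, set()).add((s_acc, site))
                hit = True
        if hit:
            domain_instances.setdefault(dom, set()).add((acc, start, end))

    if proteome_domain_counts is not None and not isinstance(
        proteome_domain_counts, Mapping
    ):
        proteome_domain_counts = dict(proteome_domain_counts)

    named = {d: s for d, s in domain_sites.items() if len(s) >= min_sites}
    pooled_sites: set[tuple] = set()
    for d, s in domain_sites.items():
        if d not in named:
            pooled_sites |= s

    def _make(dom: str, sites: set[tuple], pct) -> DomainStats:
        counts = _type_combinations({k: site_types[k] for k in sites})
        total = sum(counts.values())
        pcts = {t: (100.0 * counts[t] / total if total else 0.0) for t in GLYCAN_TYPES}
        diff = {t: pcts[t] - overall_pct[t] for t in GLYCAN_TYPES}
        ratio = total / len(sites) if sites else 0.0
        return DomainStats(dom, len(sites), ratio, pct, diff)

    stats: list[DomainStats] = []
    for dom in sorted(named):
        pct = None
        if proteome_domain_counts is not None:
            n_total = int(proteome_domain_counts.get(dom, 0))
            if n_total > 0:
                pct = 100.0 * len(domain_instances.get(dom, ())) / n_total
            else:
                warnings.warn(
                    f"proteome count for domain {dom!r} is zero or missing",
                    stacklevel=2,
                )
        stats.append(_make(dom, named[dom], pct))
    if pooled_sites:
        stats.append(_make("other domains", pooled_sites, None))

    overall = DomainStats(
        "all glycosites",
        len(site_types),
        overall_ratio,
        None,
        {t: 0.0 for t in GLYCAN_TYPES},
    )
    stats.append(overall)
    return stats


def cluster_domains(
    stats: Sequence[DomainStats], method: str = "average"
) -> list[str]:
    """Leaf order from hierarchical clustering of composition-difference vectors.

    Euclidean metric with the given linkage (average by default); input is
    sorted label-lexicographically first so the ordering is deterministic
    under ties.  The ``all glycosites`` reference entry is excluded.  A single
    domain returns the identity ordering.
    """
    pool = [s for s in stats if s.domain != "all glycosites"]
    pool.sort(key=lambda s: s.domain)
    if len(pool) == 0:
        return []
    if len(pool) == 1:
        return [pool[0].domain]
    vectors = np.array([s.vector() for s in pool])
    z = linkage(vectors, method=method, metric="euclidean")
    return [pool[i].domain for i in leaves_list(z)]
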