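"""Genus/species delimitation under monophyly-and-threshold rules, plus
nomenclature-priority name resolution.

Species clusters require every internal pair to pass dDDH >= 70 AND
ANI >= 95 AND |deltaGC| < 1 (complete linkage: no threshold chaining), and
the cluster to be a clade of the rooted genome phylogeny.  Genus clusters
require all-pairs AAI >= 71 and monophyly.  Both delimitations walk the
rooted tree top-down and accept the most inclusive clades whose members
satisfy the index thresholds, so clusters are clades by construction and
the species partition refines the genus partition.  POCP is computed and
reported but deliberately not used for delimitation (a fixed 50% POCP
boundary conflicts with monophyly in practice).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from skbio import TreeNode

from .indexes import PairwiseResults
from .io import StrainMetadata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DelimitationThresholds:
    aai_genus_min: float = 71.0
    pocp_genus_min: float = 50.0  # diagnostic only, never used to delimit
    dddh_species_min: float = 70.0
    ani_species_min: float = 95.0
    gc_diff_species_max: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "aai_genus_min",
            "pocp_genus_min",
            "dddh_species_min",
            "ani_species_min",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")


@dataclass
class TaxonCluster:
    rank: str  # "genus" | "species"
    members: frozenset[str]
    monophyletic: bool = True
    resolved_name: str | None = None
    name_basis: str | None = None  # type_species_priority | publication_date |
    # page_order | placeholder_mag | unchanged
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    unresolved: bool = False
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster members must be non-empty")


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


def _clade_sets(tree: TreeNode) -> list[frozenset[str]]:
    """Tip sets of every node of a rooted tree (preorder: root first)."""
    out = []
    for node in tree.traverse(include_self=True):
        tips = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        out.append(tips)
    return out


def is_monophyletic(tree: TreeNode, taxa: Iterable[str]) -> bool:
    """True iff ``taxa`` is exactly the tip set of some node of the rooted
    tree (singletons are trivially monophyletic)."""
    taxa = frozenset(taxa)
    leaves = frozenset(t.name for t in tree.tips())
    unknown = taxa - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if len(taxa) <= 1:
        return True
    return taxa in set(_clade_sets(tree))


# ---------------------------------------------------------------------------
# Threshold-constrained clade clustering
# ---------------------------------------------------------------------------


def _max_valid_clades(
    tree: TreeNode,
    members: Iterable[str],
    pair_ok: Callable[[str, str], bool],
) -> list[frozenset[str]]:
    """Partition ``members`` into the most inclusive clades of the rooted
    tree in which every leaf pair passes ``pair_ok`` (complete linkage).

    Preorder traversal accepts a clade and skips its descendants, so the
    result is a laminar (conflict-free) partition; every remaining leaf
    becomes a singleton.  Deterministic.
    """
    members = frozenset(members)
    assigned: set[str] = set()
    clusters: list[frozenset[str]] = []

    def visit(node: TreeNode) -> None:
        tips = frozenset(t.name for t in node.tips()) or frozenset({node.name})
        tips = tips & members
        if not tips or tips <= assigned:
            return
        if tips - assigned == tips:
            ok = all(
                pair_ok(a, b)
                for i, a in enumerate(sorted(tips))
                for b in sorted(tips)[i + 1 :]
            )
            if ok:
                clusters.append(tips)
                assigned.update(tips)
                return
        for child in node.children:
            visit(child)

    visit(tree)
    for leaf in sorted(members - assigned):
        clusters.append(frozenset({leaf}))
        assigned.add(leaf)
    return clusters


def _species_pair_ok(results: PairwiseResults, thresholds: DelimitationThresholds):
    def ok(a: str, b: str) -> bool:
        c = results.get(a, b)
        if c.dddh is None or c.ani is None or c.gc_diff is None:
            return False
        return (
            c.dddh >= thresholds.dddh_species_min
            and c.ani >= thresholds.ani_species_min
            and c.gc_diff < thresholds.gc_diff_species_max
        )

    return ok


def _genus_pair_ok(results: PairwiseResults, thresholds: DelimitationThresholds):
    def ok(a: str, b: str) -> bool:
        c = results.get(a, b)
        return c.aai is not None and c.aai >= thresholds.aai_genus_min

    return ok


def infer_genus_clusters(
    tree: TreeNode,
    results: PairwiseResults,
    thresholds: DelimitationThresholds = DelimitationThresholds(),
    ingroup: Sequence[str] | None = None,
) -> list[TaxonCluster]:
    """Maximal monophyletic clades with all-pairs AAI >= the genus bound.

    Genomes lacking a proteome (absent AAI) can never satisfy the pairwise
    test and therefore end up as flagged singletons.
    """
    members = list(ingroup) if ingroup is not None else [
        t.name for t in tree.tips()
    ]
    clades = _max_valid_clades(tree, members, _genus_pair_ok(results, thresholds))
    clusters = []
    for clade in clades:
        cl = TaxonCluster(rank="genus", members=clade, monophyletic=True)
        if len(clade) == 1:
            g = next(iter(clade))
            has_aai = any(
                results.get(g, other).aai is not None
                for other in members
                if other != g
            )
            if not has_aai:
                cl.flags.append("no_proteome")
        clusters.append(cl)
    return sorted(clusters, key=lambda c: sorted(c.members)[0])


def infer_species_clusters(
    tree: TreeNode,
    results: PairwiseResults,
    thresholds: DelimitationThresholds = DelimitationThresholds(),
    genus_clusters: Sequence[TaxonCluster] | None = None,
) -> list[TaxonCluster]:
    """Monophyletic complete-linkage species clusters.

    A pair is conspecific-compatible iff dDDH >= 70 AND ANI >= 95 AND
    deltaGC < 1 (absent values fail); the conjunction already encodes the
    precedence of dDDH over borderline ANI (94-96%).  When genus clusters
    are supplied, each species clade is additionally confined to a single
    genus cluster, so the species partition refines the genus partition.
    """
    pair_ok = _species_pair_ok(results, thresholds)
    clusters: list[TaxonCluster] = []
    if genus_clusters is None:
        members = [t.name for t in tree.tips()]
        groups = [frozenset(members)]
    else:
        groups = [g.members for g in genus_clusters]
    for group in groups:
        for clade in _max_valid_clades(tree, group, pair_ok):
            clusters.append(TaxonCluster(rank="species", members=clade))
    return sorted(clusters, key=lambda c: sorted(c.members)[0])


def delimit_taxa(
    tree: TreeNode,
    results: PairwiseResults,
    thresholds: DelimitationThresholds = DelimitationThresholds(),
    outgroup: Sequence[str] = (),
) -> tuple[list[TaxonCluster], list[TaxonCluster]]:
    """Genus clusters first, then species clusters nested inside them.

    The tree is rooted on the outgroup when one is given, else at its
    midpoint — clade membership (and hence monophyly) is only meaningful on
    a rooted tree.  Outgroup leaves are excluded from both partitions.
    """
    from .phylo import root_with_outgroup  # local import: avoid cycle

    if outgroup:
        tree = root_with_outgroup(tree, list(outgroup))
    else:
        tree = tree.root_at_midpoint()
    ingroup = [t.name for t in tree.tips() if t.name not in set(outgroup)]
    genus = infer_genus_clusters(tree, results, thresholds, ingroup=ingroup)
    species = infer_species_clusters(tree, results, thresholds, genus_clusters=genus)
    return genus, species


# ---------------------------------------------------------------------------
# Nomenclature priority
# ---------------------------------------------------------------------------


def resolve_names(
    clusters: Sequence[TaxonCluster],
    metadata: dict[str, StrainMetadata],
    placeholder: str = "sp.",
) -> list[TaxonCluster]:
    """Resolve each cluster's name by nomenclatural priority.

    Within a cluster holding two or more distinct validly named taxa the
    retained (senior) name is chosen by (1) type-species status, then
    (2) earlier publication year, then (3) lower page rank within the same
    publication; the losing names are recorded as later heterotypic
    synonyms.  Clusters with only unnamed or MAG members receive a
    placeholder name and can never anchor a synonymy.  Missing years on
    both contenders leave the cluster unresolved (flagged, never guessed).
    """
    out: list[TaxonCluster] = []
    for cluster in clusters:
        cl = TaxonCluster(
            rank=cluster.rank,
            members=cluster.members,
            monophyletic=cluster.monophyletic,
            flags=list(cluster.flags),
        )
        named: dict[str, StrainMetadata] = {}
        for g in sorted(cluster.members):
            md = metadata.get(g)
            if md and md.name and not md.is_mag:
                # one entry per distinct taxon name; keep the strongest claim
                prev = named.get(md.name)
                if prev is None or (md.is_type_species and not prev.is_type_species):
                    named[md.name] = md
        if not named:
            cl.resolved_name = placeholder
            cl.name_basis = "placeholder_mag"
            out.append(cl)
            continue
        if len(named) == 1:
            cl.resolved_name = next(iter(named))
            cl.name_basis = "unchanged"
            out.append(cl)
            continue
        contenders = sorted(named.items())
        type_species = [n for n, md in contenders if md.is_type_species]
        senior: str | None = None
        basis = None
        if len(type_species) == 1:
            senior = type_species[0]
            basis = "type_species_priority"
        else:
            dated = [(n, md) for n, md in contenders if md.publication_year is not None]
            if len(dated) < len(contenders):
                cl.unresolved = True
                cl.flags.append("missing_publication_year")
                logger.warning(
                    "cluster %s unresolved: missing publication year",
                    sorted(cluster.members),
                )
                out.append(cl)
                continue
            years = sorted({md.publication_year for _, md in dated})
            earliest = [
                (n, md) for n, md in dated if md.publication_year == years[0]
            ]
            if len(earliest) == 1:
                senior = earliest[0][0]
                basis = "publication_date"
            else:
                ranked = [
                    (n, md) for n, md in earliest if md.page_rank is not None
                ]
                if len(ranked) < len(earliest):
                    cl.unresolved = True
                    cl.flags.append("missing_page_rank")
                    out.append(cl)
                    continue
                ranked.sort(key=lambda nm: (nm[1].page_rank, nm[0]))
                senior = ranked[0][0]
                basis = "page_order"
        cl.resolved_name = senior
        cl.name_basis = basis
        cl.synonyms = [(n, senior) for n, _ in contenders if n != senior]
        out.append(cl)
    return out


def reclassification_actions(
    clusters: Sequence[TaxonCluster], metadata: dict[str, StrainMetadata]
) -> dict[str, str]:
    """Per-genome action: unchanged | reclassified | synonymized | placeholder."""
    actions: dict[str, str] = {}
    for cluster in clusters:
        junior_names = {j for j, _ in cluster.synonyms}
        for g in sorted(cluster.members):
            md = metadata.get(g)
            input_name = md.name if md else ""
            if cluster.name_basis == "placeholder_mag" or cluster.resolved_name is None:
                actions[g] = "placeholder"
            elif input_name == cluster.resolved_name:
                actions[g] = "unchanged"
            elif input_name in junior_names:
                actions[g] = "synonymized"
            else:
                actions[g] = "reclassified"
    return actions


# ---------------------------------------------------------------------------
# Phyly diagnosis of input labels
# ---------------------------------------------------------------------------


def detect_phyly_problems(
    tree: TreeNode, labels: dict[str, str]
) -> dict[str, str]:
    """Classify every input label (e.g. genus name) on the rooted tree as
    monophyletic, paraphyletic or polyphyletic.

    A label is monophyletic when its leaves form a clade.  Otherwise the
    smallest clade containing them is examined: when the label's leaves
    fall into two or more maximal same-label clades and other *named*
    labels occur inside, the label is polyphyletic (independent origins);
    when every foreign leaf inside is unlabeled, the label is merely
    paraphyletic (a grade diluted by unnamed material).
    """
    leaf_names = [t.name for t in tree.tips()]
    by_label: dict[str, set[str]] = {}
    for leaf, lab in labels.items():
        if lab:
            by_label.setdefault(lab, set()).add(leaf)
    clades = set(_clade_sets(tree))
    verdict: dict[str, str] = {}
    for lab, members in sorted(by_label.items()):
        members = frozenset(members)
        if len(members) == 1 or members in clades:
            verdict[lab] = "monophyletic"
            continue
        lca = tree.lca([tree.find(m) for m in sorted(members)])
        inside = {t.name for t in lca.tips()}
        foreign = inside - members
        foreign_named = {f for f in foreign if labels.get(f)}
        if foreign_named:
            verdict[lab] = "polyphyletic"
        else:
            verdict[lab] = "paraphyletic"
    return verdict


# ---------------------------------------------------------------------------
# Classifying a new genome against an existing run
# ---------------------------------------------------------------------------


def classify_new_genome(
    query_id: str,
    query_indexes: dict[str, dict[str, float | None]],
    species_clusters: Sequence[TaxonCluster],
    genus_clusters: Sequence[TaxonCluster],
    thresholds: DelimitationThresholds = DelimitationThresholds(),
) -> dict:
    """Assign a query genome to existing clusters by its indexes against
    cluster representatives.

    ``query_indexes`` maps reference genome id -> {'ani', 'dddh', 'aai',
    'gc_diff'} (values may be None).  The query joins the best species
    cluster whose representative passes all species thresholds; failing
    that, the best genus cluster by AAI; failing that it is reported as a
    novel genus within the dataset.  The report carries every index used.
    """
    def rep(cluster: TaxonCluster) -> str:
        return sorted(cluster.members)[0]

    best_species = None
    for cl in species_clusters:
        r = rep(cl)
        idx = query_indexes.get(r, {})
        ani, dddh, gc = idx.get("ani"), idx.get("dddh"), idx.get("gc_diff")
        if (
            ani is not None
            and dddh is not None
            and gc is not None
            and ani >= thresholds.ani_species_min
            and dddh >= thresholds.dddh_species_min
            and gc < thresholds.gc_diff_species_max
        ):
            if best_species is None or dddh > best_species[0]:
                best_species = (dddh, cl, r)
    if best_species is not None:
        _, cl, r = best_species
        return {
            "query": query_id,
            "verdict": "species",
            "cluster": sorted(cl.members),
            "representative": r,
            "indexes": query_indexes.get(r, {}),
        }
    best_genus = None
    for cl in genus_clusters:
        r = rep(cl)
        aai = query_indexes.get(r, {}).get("aai")
        if aai is not None and aai >= thresholds.aai_genus_min:
            if best_genus is None or aai > best_genus[0]:
                best_genus = (aai, cl, r)
    if best_genus is not None:
        _, cl, r = best_genus
        return {
            "query": query_id,
            "verdict": "novel species",
            "genus_cluster": sorted(cl.members),
            "representative": r,
            "indexes": query_indexes.get(r, {}),
        }
    return {
        "query": query_id,
        "verdict": "novel genus (within dataset)",
        "indexes": query_indexes,
    }
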