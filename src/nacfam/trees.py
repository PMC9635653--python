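"""Support-tree handling, subfamily assignment and responsive-subclade search.

Trees are newick files with ultrafast-bootstrap style integer supports stored
as internal node labels.  Supports are attached to *edges* (bipartitions), so
rerooting never detaches a support from the split it measures.

Subfamily assignment follows a smallest-supported-clade rule: a query leaf is
given label ``L`` when the smallest clade that (i) contains the query and at
least one reference leaf and (ii) is defined by a node whose support meets
the threshold (default 70) contains reference leaves of subfamily ``L`` only.
Queries whose smallest such clade mixes subfamilies, or that never meet a
supported reference-bearing clade, stay ``unclassified``.  Unlabeled supports
count as 0, which is the conservative reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy

from .errors import ConfigurationError, InputError, ParseError

UNCLASSIFIED = "unclassified"


@dataclass
class SupportTree:
    tree: dendropy.Tree
    rooted: bool = True
    root_label: str | None = None

    @property
    def leaves(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions as frozensets of the smaller side's leaves."""
        all_leaves = frozenset(self.leaves)
        out: set[frozenset[str]] = set()
        for node in self.tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            other = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out


@dataclass
class SubfamilyAssignment:
    labels: dict[str, str]
    provenance: dict[str, str]
    support_used: dict[str, float | None] = field(default_factory=dict)

    def query_labels(self) -> dict[str, str]:
        return {
            k: v for k, v in self.labels.items() if self.provenance[k] != "reference"
        }


@dataclass
class EnrichedSubclade:
    node_id: int
    members: list[str]
    responsive_fraction: float
    subfamily_context: str
    label: str


def _attach_supports(tree: dendropy.Tree) -> None:
    missing = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is None:
            missing += 1
        node.edge.support = support
    if missing:
        warnings.warn(
            f"{missing} internal node(s) lack a support value; treated as 0",
            stacklevel=3,
        )


def edge_support(node: dendropy.Node) -> float:
    """Support of the edge subtending ``node``; unlabeled edges count as 0."""
    s = getattr(node.edge, "support", None)
    return 0.0 if s is None else s


def tree_from_string(newick: str) -> SupportTree:
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ParseError(f"unparsable newick: {exc}") from exc
    _attach_supports(tree)
    return SupportTree(tree=tree)


def read_tree(path) -> SupportTree:
    with open(path) as fh:
        return tree_from_string(fh.read())


def write_tree(st: SupportTree, path=None) -> str:
    for node in st.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        s = getattr(node.edge, "support", None)
        node.label = None if s is None else str(int(s)) if float(s).is_integer() else str(s)
    text = st.tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _clade_node(st: SupportTree, clade_leaves: set[str]) -> dendropy.Node:
    """Node subtending ``clade_leaves``; errors if they are not a clade."""
    all_leaves = set(st.leaves)
    unknown = clade_leaves - all_leaves
    if unknown:
        raise InputError(f"leaves not in tree: {sorted(unknown)}")
    taxa = [t for t in st.tree.taxon_namespace if t.label in clade_leaves]
    mrca = st.tree.mrca(taxa=taxa)
    got = {lf.taxon.label for lf in mrca.leaf_iter()}
    if got == clade_leaves:
        return mrca
    # the complement may form the clade in the unrooted sense
    comp = all_leaves - clade_leaves
    ctaxa = [t for t in st.tree.taxon_namespace if t.label in comp]
    cmrca = st.tree.mrca(taxa=ctaxa)
    cgot = {lf.taxon.label for lf in cmrca.leaf_iter()}
    if cgot == comp:
        return cmrca
    raise InputError(
        f"leaves are not monophyletic; offending extras: {sorted(got - clade_leaves)}"
    )


def reroot(st: SupportTree, clade_leaves: set[str], label: str | None = None) -> SupportTree:
    """Root the tree on the branch subtending ``clade_leaves``.

    The bipartition set is unchanged; supports ride along on their edges.
    Rerooting twice on the same clade is a no-op on the bipartition set.
    """
    node = _clade_node(st, set(clade_leaves))
    tree = st.tree
    if node.parent_node is not None:
        tree.reroot_at_edge(node.edge, update_bipartitions=False)
        tree.suppress_unifurcations()
        # the split edge halves subtend the same bipartition: share support
        kids = tree.seed_node.child_nodes()
        if len(kids) == 2:
            sups = [getattr(k.edge, "support", None) for k in kids]
            known = [s for s in sups if s is not None]
            if known:
                for k in kids:
                    if getattr(k.edge, "support", None) is None:
                        k.edge.support = known[0]
    return SupportTree(tree=tree, rooted=True, root_label=label)


def assign_subfamilies(
    st: SupportTree,
    reference_labels: dict[str, str],
    support_threshold: float = 70.0,
) -> SubfamilyAssignment:
    """Label each query leaf with the subfamily of the reference leaves in the
    smallest supported clade containing it, or ``unclassified``."""
    if not reference_labels:
        raise ConfigurationError("no reference leaves supplied")
    leaves = set(st.leaves)
    missing_refs = set(reference_labels) - leaves
    if missing_refs:
        raise ConfigurationError(f"reference leaves absent from tree: {sorted(missing_refs)}")

    ref_sets: dict[dendropy.Node, set[str]] = {}
    for node in st.tree.postorder_node_iter():
        if node.is_leaf():
            lbl = node.taxon.label
            ref_sets[node] = {reference_labels[lbl]} if lbl in reference_labels else set()
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= ref_sets[ch]
            ref_sets[node] = acc

    labels: dict[str, str] = {}
    provenance: dict[str, str] = {}
    support_used: dict[str, float | None] = {}
    for leaf in st.tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference_labels:
            labels[name] = reference_labels[name]
            provenance[name] = "reference"
            support_used[name] = None
            continue
        assigned = UNCLASSIFIED
        used: float | None = None
        node = leaf.parent_node
        while node is not None:
            has_support = node.parent_node is None or edge_support(node) >= support_threshold
            if node.parent_node is None:
                has_support = False  # whole-tree "clade" carries no bootstrap
            if has_support and ref_sets[node]:
                if len(ref_sets[node]) == 1:
                    assigned = next(iter(ref_sets[node]))
                    used = edge_support(node)
                break
            node = node.parent_node
        labels[name] = assigned
        provenance[name] = "joined-tree"
        support_used[name] = used
    return SubfamilyAssignment(labels=labels, provenance=provenance, support_used=support_used)


def assign_with_fallback(
    primary: SupportTree,
    primary_refs: dict[str, str],
    fallback: SupportTree | None = None,
    fallback_refs: dict[str, str] | None = None,
    support_threshold: float = 70.0,
) -> SubfamilyAssignment:
    """Joined-tree assignment first; leaves it cannot place retry on the
    species-specific tree (provenance ``species-tree-fallback``)."""
    main = assign_subfamilies(primary, primary_refs, support_threshold)
    if fallback is None:
        return main
    fb = assign_subfamilies(fallback, fallback_refs or primary_refs, support_threshold)
    for leaf, lbl in main.query_labels().items():
        if lbl == UNCLASSIFIED and fb.labels.get(leaf, UNCLASSIFIED) != UNCLASSIFIED:
            main.labels[leaf] = fb.labels[leaf]
            main.provenance[leaf] = "species-tree-fallback"
            main.support_used[leaf] = fb.support_used.get(leaf)
    return main


def find_enriched_subclades(
    st: SupportTree,
    responsive: set[str],
    min_fraction: float = 0.6,
    min_size: int = 5,
    assignment: SubfamilyAssignment | None = None,
) -> list[EnrichedSubclade]:
    """Maximal clades of >= min_size leaves whose responsive fraction meets
    ``min_fraction`` (boundary included); reported clades never nest."""
    leaves = set(st.leaves)
    stray = set(responsive) - leaves
    if stray:
        raise InputError(f"responsive ids absent from tree: {sorted(stray)}")

    out: list[EnrichedSubclade] = []
    ctx_counts: dict[str, int] = {}
    node_ids = {node: i for i, node in enumerate(st.tree.preorder_node_iter())}

    def visit(node: dendropy.Node) -> None:
        if node.is_leaf():
            return
        members = [lf.taxon.label for lf in node.leaf_iter()]
        n_resp = sum(1 for m in members if m in responsive)
        frac = n_resp / len(members)
        if len(members) >= min_size and frac >= min_fraction:
            ctx = "clade"
            if assignment is not None:
                subs = [assignment.labels.get(m, UNCLASSIFIED) for m in members]
                known = [s for s in subs if s != UNCLASSIFIED]
                if known:
                    ctx = max(sorted(set(known)), key=known.count)
            ctx_counts[ctx] = ctx_counts.get(ctx, 0) + 1
            out.append(
                EnrichedSubclade(
                    node_id=node_ids[node],
                    members=members,
                    responsive_fraction=frac,
                    subfamily_context=ctx,
                    label=f"{ctx}{ctx_counts[ctx]}",
                )
            )
            return  # maximality: do not descend into a reported clade
        for ch in node.child_nodes():
            visit(ch)

    visit(st.tree.seed_node)
    return out


def ladderized_leaf_order(st: SupportTree) -> list[str]:
    """Depth-first leaf order with children visited smaller-clade first.

    Ties on clade size break on the smallest leaf label, making the order a
    pure function of the topology.
    """
    sizes: dict[dendropy.Node, int] = {}
    mins: dict[dendropy.Node, str] = {}
    for node in st.tree.postorder_node_iter():
        if node.is_leaf():
            sizes[node] = 1
            mins[node] = node.taxon.label
        else:
            kids = node.child_nodes()
            sizes[node] = sum(sizes[k] for k in kids)
            mins[node] = min(mins[k] for k in kids)
    order: list[str] = []

    def visit(node: dendropy.Node) -> None:
        if node.is_leaf():
            order.append(node.taxon.label)
            return
        for ch in sorted(node.child_nodes(), key=lambda k: (sizes[k], mins[k])):
            visit(ch)

    visit(st.tree.seed_node)
    return order
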