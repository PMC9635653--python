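"""Homoeolog-group resolution and systematic gene naming.

Names follow the wheat convention ``TaNACXXX-[ABDU]<group>(-<paralog>)``:

* the base number comes from the closest rice ortholog anchor (``ONAC048``
  -> ``TaNAC048``); genes without a rice ortholog receive consecutive new
  base numbers starting at 153, ordered by their position in the tree with
  subfamily ``b`` first;
* the subgenome letter is the gene's wheat subgenome (``U`` = unknown
  chromosome);
* the group digit numbers the homoeologous groups (singletons or triads)
  that share an anchor, in ladderized tree order;
* the trailing paralog digit appears only for tandem inparalogs - genes on
  the same chromosome with at least 80% protein identity, which are treated
  as duplicates inside one homoeologous group and numbered by chromosome
  position.

Grouping is tree-primary: a homoeolog group is the largest supported clade
(bootstrap >= 70 by default) whose query leaves are exactly a set of
candidate units with pairwise-distinct subgenomes; a chromosome-``U`` unit
may join a group holding at least two located homoeologs.  Units that no
supported clade resolves fall back to the ortholog-anchor table: anchored
leftovers are packed greedily by chromosome position, anchorless leftovers
stay as singleton groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio import Align

from . import trees
from .errors import ConfigurationError, InputError
from .trees import SubfamilyAssignment, SupportTree, edge_support


@dataclass(frozen=True)
class ChromLocation:
    gene_id: str
    subgenome: str  # A, B, D or U
    chromosome: int  # 0 for unknown
    position_rank: int


@dataclass
class HomoeologGroup:
    anchor: str | None
    subfamily: str
    members: dict[str, tuple[str, int | None]]  # gene -> (subgenome, paralog idx)
    group_index: int = 0
    provenance: str = "tree"


@dataclass(frozen=True)
class GeneName:
    prefix: str
    base: int
    subgenome: str
    group: int
    paralog: int | None = None

    def render(self) -> str:
        s = f"{self.prefix}{self.base:03d}-{self.subgenome}{self.group}"
        if self.paralog is not None:
            s += f"-{self.paralog}"
        return s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    # fixed documented scheme: global alignment, match +1, mismatch -1,
    # gap open -5, gap extend -0.5
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.match_score = 1.0
        a.mismatch_score = -1.0
        a.open_gap_score = -5.0
        a.extend_gap_score = -0.5
        _ALIGNER = a
    return _ALIGNER


def pairwise_identity(seq1: str, seq2: str) -> float:
    """Percent identity under global alignment.

    Identity = matching columns / aligned columns, where terminal overhangs
    (columns before the first and after the last position at which both
    sequences hold a residue) are excluded.  Symmetric by construction.
    """
    if not seq1 or not seq2:
        raise InputError("pairwise_identity: empty sequence")
    aln = _aligner().align(seq1.upper(), seq2.upper())[0]
    r1, r2 = str(aln[0]), str(aln[1])
    both = [i for i in range(len(r1)) if r1[i] != "-" and r2[i] != "-"]
    if not both:
        return 0.0
    lo, hi = both[0], both[-1]
    cols = hi - lo + 1
    matches = sum(1 for i in range(lo, hi + 1) if r1[i] == r2[i] and r1[i] != "-")
    return 100.0 * matches / cols


def chrom_map_from_frame(df: pd.DataFrame) -> dict[str, ChromLocation]:
    return {
        r.gene_id: ChromLocation(r.gene_id, str(r.subgenome), int(r.chromosome),
                                 int(r.position_rank))
        for r in df.itertuples()
    }


def anchors_from_frame(df: pd.DataFrame) -> dict[str, str]:
    return {r.gene_id: str(r.anchor_name) for r in df.itertuples()}


@dataclass
class _Unit:
    genes: list[str]  # ordered by position rank
    subgenome: str
    chromosome: int
    min_rank: int
    anchor: str | None


def _merge_inparalogs(
    genes: list[str],
    chrom: dict[str, ChromLocation],
    sequences: dict[str, str],
    identity_threshold: float,
    anchor: str | None,
) -> list[_Unit]:
    """Union-find merge of same-chromosome genes at >= identity_threshold."""
    parent = {g: g for g in genes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_chrom: dict[tuple[str, int], list[str]] = {}
    for g in genes:
        loc = chrom[g]
        by_chrom.setdefault((loc.subgenome, loc.chromosome), []).append(g)
    for (_, _), gs in by_chrom.items():
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                a, b = gs[i], gs[j]
                if find(a) == find(b):
                    continue
                if pairwise_identity(sequences[a], sequences[b]) >= identity_threshold:
                    parent[find(b)] = find(a)
    clusters: dict[str, list[str]] = {}
    for g in genes:
        clusters.setdefault(find(g), []).append(g)
    units = []
    for members in clusters.values():
        members.sort(key=lambda g: (chrom[g].position_rank, g))
        loc = chrom[members[0]]
        units.append(
            _Unit(genes=members, subgenome=loc.subgenome, chromosome=loc.chromosome,
                  min_rank=loc.position_rank, anchor=anchor)
        )
    units.sort(key=lambda u: (u.subgenome, u.chromosome, u.min_rank))
    return units


def _valid_combination(units: list[_Unit]) -> bool:
    subs = [u.subgenome for u in units]
    non_u = [s for s in subs if s != "U"]
    if len(non_u) != len(set(non_u)):
        return False
    n_u = len(subs) - len(non_u)
    if n_u > 1:
        return False
    if n_u == 1 and len(non_u) < 2:
        return False  # a U gene joins only when it clusters with 2 located homoeologs
    return True


def _pack_greedy(units: list[_Unit]) -> list[list[_Unit]]:
    """Fallback grouping by chromosome order when the tree cannot resolve."""
    groups: list[list[_Unit]] = []
    for u in sorted(units, key=lambda u: (u.chromosome, u.min_rank, u.genes[0])):
        placed = False
        for grp in groups:
            if _valid_combination(grp + [u]):
                grp.append(u)
                placed = True
                break
        if not placed:
            groups.append([u])
    return groups


def group_homoeologs(
    tree: SupportTree,
    assignment: SubfamilyAssignment,
    chrom_map: pd.DataFrame | dict[str, ChromLocation],
    ortholog_table: pd.DataFrame | dict[str, str],
    sequences: dict[str, str],
    support_threshold: float = 70.0,
    identity_threshold: float = 80.0,
) -> list[HomoeologGroup]:
    """Partition the gene universe into homoeologous groups.

    The gene universe is every non-reference leaf of the tree; each gene
    must appear in ``chrom_map``.  See the module docstring for the rules.
    """
    chrom = chrom_map if isinstance(chrom_map, dict) else chrom_map_from_frame(chrom_map)
    anchors = (
        ortholog_table if isinstance(ortholog_table, dict)
        else anchors_from_frame(ortholog_table)
    )
    genes = [l for l in tree.leaves if assignment.provenance.get(l) != "reference"]
    missing = [g for g in genes if g not in chrom]
    if missing:
        raise InputError(f"genes missing from chrom_map: {sorted(missing)}")
    missing_seq = [g for g in genes if g not in sequences]
    if missing_seq:
        raise InputError(f"genes missing sequences: {sorted(missing_seq)}")

    # pools: one per anchor, one per subfamily for anchorless genes
    pools: dict[tuple, list[str]] = {}
    for g in genes:
        a = anchors.get(g)
        key = ("anchor", a) if a else ("orphan", assignment.labels.get(g, trees.UNCLASSIFIED))
        pools.setdefault(key, []).append(g)

    # per-node query-leaf sets, smallest clades first
    node_sets: list[tuple[frozenset[str], float]] = []
    gene_set = set(genes)
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        qset = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in gene_set
        )
        if qset:
            node_sets.append((qset, edge_support(node)))
    # widest clades first: a homoeolog group is the *largest* supported clade
    # consisting exactly of candidate units with compatible subgenomes, so a
    # full triad is not split into a pair plus a singleton
    node_sets.sort(key=lambda t: (-len(t[0]), sorted(t[0])))

    groups: list[HomoeologGroup] = []

    def emit(units: list[_Unit], anchor, subfamily, provenance) -> None:
        members: dict[str, tuple[str, int | None]] = {}
        for u in units:
            multi = len(u.genes) > 1
            for k, g in enumerate(u.genes, start=1):
                members[g] = (u.subgenome, k if multi else None)
        groups.append(
            HomoeologGroup(anchor=anchor, subfamily=subfamily, members=members,
                           provenance=provenance)
        )

    for key, pool_genes in sorted(pools.items(), key=lambda kv: str(kv[0])):
        kind, label = key
        anchor = label if kind == "anchor" else None
        units = _merge_inparalogs(
            pool_genes, chrom, sequences, identity_threshold, anchor
        )
        subfam_votes = [assignment.labels.get(g, trees.UNCLASSIFIED) for g in pool_genes]
        subfamily = max(sorted(set(subfam_votes)), key=subfam_votes.count)
        if len(units) == 1:
            emit(units, anchor, subfamily, "tree")
            continue
        ungrouped = list(units)
        unit_of_gene = {g: u for u in units for g in u.genes}
        for qset, support in node_sets:
            if support < support_threshold or len(ungrouped) < 2:
                continue
            inside = [u for u in ungrouped if all(g in qset for g in u.genes)]
            if len(inside) < 2:
                continue
            covered = {g for u in inside for g in u.genes}
            if covered != set(qset):
                continue  # clade must consist exactly of the candidate units
            if not _valid_combination(inside):
                continue
            emit(inside, anchor, subfamily, "tree")
            for u in inside:
                ungrouped.remove(u)
        if ungrouped:
            if kind == "anchor" and len(ungrouped) > 1:
                for bundle in _pack_greedy(ungrouped):
                    emit(bundle, anchor, subfamily, "ortholog-table-fallback")
            else:
                for u in ungrouped:
                    emit([u], anchor, subfamily, "tree")
        del unit_of_gene
    return groups


_ANCHOR_NUM = re.compile(r"(\d+)\s*$")


def _anchor_base(anchor: str, catalog: pd.DataFrame | None) -> int:
    """Numeric base for an anchor; multi-anchor strings (comma-separated
    paralogs on one rice chromosome) resolve to the first ortholog identified
    on the chromosome (lowest position rank in the catalogue)."""
    cands = sorted(a.strip() for a in anchor.split(",") if a.strip())
    if len(cands) > 1 and catalog is not None:
        cat = catalog.set_index("anchor_name")
        known = [a for a in cands if a in cat.index]
        if known:
            cands = sorted(
                known,
                key=lambda a: (int(cat.loc[a, "chromosome"]), int(cat.loc[a, "position_rank"])),
            )
    chosen = cands[0]
    m = _ANCHOR_NUM.search(chosen)
    if not m:
        raise InputError(f"cannot parse ortholog number from anchor '{anchor}'")
    return int(m.group(1))


def assign_names(
    groups: list[HomoeologGroup],
    tree: SupportTree,
    assignment: SubfamilyAssignment,
    ortholog_catalog: pd.DataFrame | None = None,
    start_number: int = 153,
    prefix: str = "TaNAC",
) -> dict[str, GeneName]:
    """Emit a unique :class:`GeneName` for every grouped gene.

    Groups sharing a resolved base number are numbered 1..k by ladderized
    tree order; anchorless groups receive consecutive new bases starting at
    ``start_number``, subfamily ``b`` first and then ladderized tree order.
    """
    ladder = trees.ladderized_leaf_order(tree)
    pos = {leaf: i for i, leaf in enumerate(ladder)}
    missing = [g for grp in groups for g in grp.members if g not in pos]
    if missing:
        raise ConfigurationError(f"grouped genes absent from tree: {sorted(missing)}")

    def group_pos(grp: HomoeologGroup) -> int:
        return min(pos[g] for g in grp.members)

    base_of: dict[int, int] = {}
    index_of: dict[int, int] = {}
    by_base: dict[int, list[HomoeologGroup]] = {}
    orphans: list[HomoeologGroup] = []
    for grp in groups:
        if grp.anchor:
            by_base.setdefault(_anchor_base(grp.anchor, ortholog_catalog), []).append(grp)
        else:
            orphans.append(grp)
    for base, glist in by_base.items():
        glist.sort(key=group_pos)
        for k, grp in enumerate(glist, start=1):
            base_of[id(grp)] = base
            index_of[id(grp)] = k
    orphans.sort(key=lambda grp: (grp.subfamily != "b", group_pos(grp)))
    for j, grp in enumerate(orphans):
        base_of[id(grp)] = start_number + j
        index_of[id(grp)] = 1

    names: dict[str, GeneName] = {}
    for grp in groups:
        grp.group_index = index_of[id(grp)]
        for g, (sub, paridx) in grp.members.items():
            names[g] = GeneName(
                prefix=prefix, base=base_of[id(grp)], subgenome=sub,
                group=grp.group_index, paralog=paridx,
            )
    rendered = [n.render() for n in names.values()]
    if len(set(rendered)) != len(rendered):
        dupes = sorted({r for r in rendered if rendered.count(r) > 1})
        raise RuntimeError(f"internal error: duplicate names generated: {dupes}")
    return names


def names_table(
    names: dict[str, GeneName], groups: list[HomoeologGroup]
) -> pd.DataFrame:
    """Flat TSV-ready table of the naming result."""
    by_gene: dict[str, HomoeologGroup] = {
        g: grp for grp in groups for g in grp.members
    }
    rows = []
    for g in sorted(names):
        nm, grp = names[g], by_gene[g]
        rows.append(
            (g, nm.render(), grp.anchor or "", nm.group, nm.subgenome,
             nm.paralog if nm.paralog is not None else "", grp.provenance)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "assigned_name", "anchor", "group", "subgenome",
                 "paralog_index", "provenance"],
    )
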