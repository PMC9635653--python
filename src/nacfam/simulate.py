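"""Synthetic hexaploid NAC families with recorded ground truth.

The generator emulates the structure of a wheat-like transcription-factor
family so that every downstream stage (domain scan, alignment QC, tree
classification, nomenclature, expression profiling, motif analysis) can be
tested against planted truth without any external downloads:

* 8 subfamilies labeled ``a``..``h``;
* ortholog-anchored homoeolog groups on subgenomes A/B/D, a fraction of them
  full triads, plus tandem inparalogs (same chromosome, pairwise identity
  above 80%) and anchorless (orphan) groups;
* occasional chromosome-``U`` members standing in for genes mapped to an
  unknown chromosome;
* per-pathogen differential-expression calls with planted responsive genes
  and 5-organ baseline tpm profiles including a grain-specific group;
* subfamily-, responsiveness- and grain-linked C-terminal motifs plus the
  invariant NAM subdomain anchor motifs A-E;
* non-NAC decoys obtained by shuffling real family sequences, preserving
  composition.

Sequences are generated without indels by mutating a fixed NAM-bearing
template at free (non-anchor) sites, with per-step substitution counts
calibrated so that pairwise identities land on the configured targets:
identity is the only sequence property the downstream rules consume.
A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import trees
from .errors import ConfigurationError

AA = "ACDEFGHIKLMNPQRSTVWY"

# Fixed NAM subdomain anchor motifs; protected from mutation in every family
# member, so exact-string matching recovers subdomain coordinates.
SUBDOMAIN_ANCHORS = {
    "A": "LPPGFRFH",
    "B": "NEVIPQID",
    "C": "WKATGTDK",  # the DNA-recognition motif of subdomain C
    "D": "TNWIMHEY",
    "E": "LDDWVLCR",
}

# Template layout (1-based, no indels anywhere):
#   1-10 pad | A 11-18 | 19-30 | B 31-38 | 39-52 | C 53-60 | 61-76 |
#   D 77-84 | 85-96 | E 97-104 | 105-112 | CT 113-212
_SEGMENTS = [
    ("pad", 10), ("A", 8), ("s1", 12), ("B", 8), ("s2", 14), ("C", 8),
    ("s3", 16), ("D", 8), ("s4", 12), ("E", 8), ("s5", 8), ("CT", 100),
]
SEQ_LENGTH = sum(n for _, n in _SEGMENTS)

ORGANS = ("grain", "leaf", "root", "spike", "stem")
PATHOGEN_LIFESTYLES = {
    "Fg": "hemibiotroph",  # Fusarium graminearum
    "Fp": "hemibiotroph",  # Fusarium pseudograminearum
    "Zt": "hemibiotroph",  # Zymoseptoria tritici
    "Ps": "biotroph",      # Puccinia striiformis
    "Bg": "biotroph",      # Blumeria graminis
    "Xt": "hemibiotroph",  # Xanthomonas translucens (bacterial)
}
DEFAULT_PANEL = ("Fg", "Fp", "Zt", "Ps", "Bg")

# Fraction of each subfamily planted as pathogen-responsive; a/e/f enriched,
# c/h depleted, mirroring the kind of contrast the enrichment test must see.
DEFAULT_RESPONSIVE_RATES = {
    "a": 0.80, "b": 0.25, "c": 0.11, "d": 0.25,
    "e": 0.45, "f": 0.67, "g": 0.25, "h": 0.08,
}

# CT motif slots (offsets within the 100-residue CT segment, width 10)
_CT_SLOTS = {"subfamily": 5, "responsive": 40, "grain": 70}
MOTIF_WIDTH = 10


def _subdomain_positions() -> dict[str, tuple[int, int]]:
    pos = {}
    start = 1
    for name, n in _SEGMENTS:
        if name in SUBDOMAIN_ANCHORS:
            pos[name] = (start, start + n - 1)
        start += n
    return pos


SUBDOMAIN_COORDS = _subdomain_positions()
NAM_REGION = (SUBDOMAIN_COORDS["A"][0], SUBDOMAIN_COORDS["D"][1])  # subdomains A-D
_CT_START = SEQ_LENGTH - 100 + 1  # first residue of the CT segment


def _anchor_sites() -> set[int]:
    sites = {0}  # initial Met
    for s, e in SUBDOMAIN_COORDS.values():
        sites.update(range(s - 1, e))
    return sites


_PROTECTED = _anchor_sites()
_FREE_SITES = np.array(sorted(set(range(SEQ_LENGTH)) - _PROTECTED))


def _template() -> str:
    rng = np.random.default_rng(1905)  # fixed: the template is a constant
    out = []
    for name, n in _SEGMENTS:
        if name in SUBDOMAIN_ANCHORS:
            out.append(SUBDOMAIN_ANCHORS[name])
        else:
            out.append("".join(rng.choice(list(AA), size=n)))
    seq = "".join(out)
    return "M" + seq[1:]


TEMPLATE = _template()


def planted_motif_strings(n_subfamilies: int = 8) -> dict[str, tuple[str, str, int]]:
    """Planted motif catalogue: motif id -> (region, string, offset in region).

    NT motifs are the five subdomain anchors (carried by every family
    member); CT motifs are one signature per subfamily plus a
    responsiveness-linked (``CT-R``) and a grain-linked (``CT-G``) motif.
    """
    rng = np.random.default_rng(424242)
    out: dict[str, tuple[str, str, int]] = {}
    for label, motif in SUBDOMAIN_ANCHORS.items():
        if label == "E":
            continue  # subdomain E lies beyond the NT/NAM boundary
        # NT region starts at residue 1, so the in-region offset is absolute
        out[f"NT-{label}"] = ("NT", motif, SUBDOMAIN_COORDS[label][0])
    subfams = "abcdefgh"[:n_subfamilies]
    for sf in subfams:
        s = "".join(rng.choice(list(AA), size=MOTIF_WIDTH))
        out[f"CT-{sf}"] = ("CT", s, _CT_SLOTS["subfamily"])
    out["CT-R"] = ("CT", "".join(rng.choice(list(AA), size=MOTIF_WIDTH)), _CT_SLOTS["responsive"])
    out["CT-G"] = ("CT", "".join(rng.choice(list(AA), size=MOTIF_WIDTH)), _CT_SLOTS["grain"])
    return out


@dataclass
class FamilyConfig:
    n_subfamilies: int = 8
    n_anchor_orthologs: int = 64
    triad_rate: float = 0.7
    inparalog_rate: float = 0.15
    orphan_rate: float = 0.2
    identity_inparalog: float = 90.0
    identity_cross_group: float = 65.0
    decoy_count: int = 40
    seed: int = 0
    # structure refinements beyond the core knobs
    shared_anchor_rate: float = 0.1   # anchor carries a second homoeologous group
    u_rate: float = 0.04              # triad member relocated to chromosome U
    responsive_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSIVE_RATES)
    )
    pathogen_panel: tuple[str, ...] = DEFAULT_PANEL
    motif_presence: float = 0.95      # subfamily CT motif carrier probability

    def validate(self) -> None:
        for name in ("triad_rate", "inparalog_rate", "orphan_rate",
                     "shared_anchor_rate", "u_rate", "motif_presence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if not self.identity_inparalog > 80.0:
            raise ConfigurationError("identity_inparalog must exceed 80%")
        if not self.identity_cross_group < 80.0:
            raise ConfigurationError("identity_cross_group must be below 80%")
        if not 1 <= self.n_subfamilies <= 8:
            raise ConfigurationError("n_subfamilies must be in 1..8")
        if self.n_anchor_orthologs < 1 or self.n_anchor_orthologs > 144:
            raise ConfigurationError("n_anchor_orthologs must be in 1..144")
        for p in self.pathogen_panel:
            if p not in PATHOGEN_LIFESTYLES:
                raise ConfigurationError(f"unknown pathogen '{p}'")


@dataclass
class TruthRecord:
    true_subfamily: str
    true_group_id: str
    true_subgenome: str
    true_paralog_index: int | None
    true_name: str
    responsive_pathogens: frozenset[str]
    planted_motifs: frozenset[str]
    grain_specific: bool = False


@dataclass
class SyntheticFamily:
    config: FamilyConfig
    sequences: dict[str, str]          # gene id -> protein sequence (family + decoys)
    chrom_map: pd.DataFrame            # gene_id, subgenome, chromosome, position_rank
    ortholog_table: pd.DataFrame       # gene_id, anchor_name
    truth: dict[str, TruthRecord]
    decoy_ids: list[str]

    @property
    def family_ids(self) -> list[str]:
        return list(self.truth)

    def nam_alignment(self, n: int = 24) -> list[str]:
        """Equal-length NAM-region (subdomains A-D) slices for profile training."""
        s, e = NAM_REGION
        ids = self.family_ids[:n]
        return [self.sequences[g][s - 1 : e] for g in ids]

    def reference_labels(self) -> dict[str, str]:
        subfams = sorted({t.true_subfamily for t in self.truth.values()})
        return {f"REF_{sf}_{i}": sf for sf in subfams for i in (1, 2)}

    def responsive_truth(self) -> dict[str, frozenset[str]]:
        return {g: t.responsive_pathogens for g, t in self.truth.items()}


def _mutate(rng, seq: str, n_subs: int, sites: np.ndarray | None = None) -> str:
    """Substitute exactly n_subs positions (drawn from free sites) with a
    different residue; anchors and the initial Met are never touched."""
    pool = _FREE_SITES if sites is None else sites
    n_subs = min(n_subs, len(pool))
    pos = rng.choice(pool, size=n_subs, replace=False)
    chars = list(seq)
    for p in pos:
        old = chars[p]
        choices = [c for c in AA if c != old]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


@dataclass
class _Gene:
    gene_id: str
    subfamily: str
    group_id: str
    subgenome: str
    chromosome: int
    paralog_index: int | None
    sequence: str


@dataclass
class _Group:
    group_id: str
    subfamily: str
    anchor: str | None
    genes: list[_Gene] = field(default_factory=list)


def _plant_ct_motifs(gene_seq: str, carried: set[str],
                     motifs: dict[str, tuple[str, str, int]]) -> str:
    """Write carried CT motifs verbatim into their slots.

    Slots without a carried motif keep the inherited background; a chance
    exact match of a 10-mer against random background is negligible, so
    presence/absence stays exactly the planted truth."""
    chars = list(gene_seq)
    for mid, (region, s, offset) in motifs.items():
        if region != "CT" or mid not in carried:
            continue
        start = _CT_START - 1 + offset
        chars[start : start + len(s)] = list(s)
    return "".join(chars)


def generate_family(config: FamilyConfig) -> SyntheticFamily:
    """Generate one synthetic family; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    subfams = "abcdefgh"[: config.n_subfamilies]
    motifs = planted_motif_strings(config.n_subfamilies)

    # subfamily ancestors: strong divergence, anchors protected
    sf_div = round(0.25 * SEQ_LENGTH)
    ancestors = {sf: _mutate(rng, TEMPLATE, sf_div) for sf in subfams}

    anchor_numbers = rng.choice(
        np.arange(1, 145), size=config.n_anchor_orthologs, replace=False
    )

    m_group = round((1 - config.identity_cross_group / 100) / 2 * SEQ_LENGTH)
    m_homoeo = max(2, round(0.03 * SEQ_LENGTH))
    m_inpar = round((1 - config.identity_inparalog / 100) * SEQ_LENGTH)

    groups: list[_Group] = []
    serial = 0

    def new_group(subfamily: str, anchor: str | None) -> _Group:
        nonlocal serial
        serial += 1
        g = _Group(group_id=f"g{serial:03d}", subfamily=subfamily, anchor=anchor)
        groups.append(g)
        return g

    # anchor slots round-robin over subfamilies; some slots carry two groups
    slot_specs: list[tuple[str, str | None, int]] = []
    for i, num in enumerate(anchor_numbers):
        sf = subfams[i % len(subfams)]
        anchor = None if rng.random() < config.orphan_rate else f"ONAC{num:03d}"
        n_groups = 2 if (anchor and rng.random() < config.shared_anchor_rate) else 1
        slot_specs.append((sf, anchor, n_groups))

    chrom_rank: dict[tuple[str, int], int] = {}

    def next_rank(subgenome: str, chrom: int) -> int:
        key = (subgenome, chrom)
        chrom_rank[key] = chrom_rank.get(key, 0) + 1
        return chrom_rank[key]

    gene_serial = 0

    def make_gene(grp: _Group, subgenome: str, chrom: int, seq: str,
                  paralog_index: int | None) -> _Gene:
        nonlocal gene_serial
        gene_serial += 1
        g = _Gene(
            gene_id=f"TaSYNG{gene_serial:04d}", subfamily=grp.subfamily,
            group_id=grp.group_id, subgenome=subgenome, chromosome=chrom,
            paralog_index=paralog_index, sequence=seq,
        )
        grp.genes.append(g)
        return g

    for sf, anchor, n_groups in slot_specs:
        for _ in range(n_groups):
            grp = new_group(sf, anchor)
            group_anc = _mutate(rng, ancestors[sf], m_group)
            chrom = int(rng.integers(1, 8))
            if rng.random() < config.triad_rate:
                subgenomes = ["A", "B", "D"]
            else:
                k = int(rng.integers(1, 3))
                subgenomes = sorted(rng.choice(["A", "B", "D"], size=k, replace=False))
            if len(subgenomes) == 3 and rng.random() < config.u_rate:
                subgenomes[0] = "U"  # one triad member sits on an unknown chromosome
            inpar_sub = None
            if rng.random() < config.inparalog_rate:
                non_u = [s for s in subgenomes if s != "U"]
                if non_u:
                    inpar_sub = non_u[int(rng.integers(len(non_u)))]
            for sub in subgenomes:
                base = _mutate(rng, group_anc, m_homoeo)
                sub_chrom = 0 if sub == "U" else chrom
                if sub == inpar_sub:
                    n_par = int(rng.integers(2, 4))
                    pool = rng.choice(
                        _FREE_SITES, size=min(len(_FREE_SITES), round(1.5 * m_inpar)),
                        replace=False,
                    )
                    copies = [base] + [
                        _mutate(rng, base, m_inpar, sites=pool) for _ in range(n_par - 1)
                    ]
                    for k, seq in enumerate(copies, start=1):
                        make_gene(grp, sub, sub_chrom, seq, k)
                        next_rank(sub, sub_chrom)
                else:
                    make_gene(grp, sub, sub_chrom, base, None)
                    next_rank(sub, sub_chrom)

    # position ranks follow creation order per chromosome; recompute cleanly
    rank_counter: dict[tuple[str, int], int] = {}
    gene_rank: dict[str, int] = {}
    for grp in groups:
        for g in grp.genes:
            key = (g.subgenome, g.chromosome)
            rank_counter[key] = rank_counter.get(key, 0) + 1
            gene_rank[g.gene_id] = rank_counter[key]

    # responsiveness is a per-gene property
    responsive: dict[str, frozenset[str]] = {}
    grain_groups = [g for g in groups if g.subfamily == "d"]
    grain_group_id = grain_groups[0].group_id if grain_groups else None
    for grp in groups:
        rate = config.responsive_rates.get(grp.subfamily, 0.25)
        for g in grp.genes:
            resp: set[str] = set()
            if rng.random() < rate:
                resp = {p for p in config.pathogen_panel if rng.random() < 0.45}
                if not resp:
                    resp = {config.pathogen_panel[int(rng.integers(len(config.pathogen_panel)))]}
            responsive[g.gene_id] = frozenset(resp)

    # motif carriage is decided per homoeolog unit (inparalog copies share
    # their CT slots verbatim), so planting never erodes the calibrated
    # inparalog identities
    carried: dict[str, set[str]] = {}
    for grp in groups:
        units: dict[str, list[_Gene]] = {}
        for g in grp.genes:
            units.setdefault(g.subgenome, []).append(g)
        for unit_genes in units.values():
            c = {f"NT-{x}" for x in "ABCD"}
            if rng.random() < config.motif_presence:
                c.add(f"CT-{grp.subfamily}")
            unit_resp = any(responsive[g.gene_id] for g in unit_genes)
            if rng.random() < (0.9 if unit_resp else 0.05):
                c.add("CT-R")
            if grp.group_id == grain_group_id or rng.random() < 0.02:
                c.add("CT-G")
            for g in unit_genes:
                carried[g.gene_id] = set(c)
                g.sequence = _plant_ct_motifs(g.sequence, c, motifs)

    # decoys: shuffled family sequences (same composition, no planted core)
    family_seqs = [g.sequence for grp in groups for g in grp.genes]
    decoy_ids = []
    decoys: dict[str, str] = {}
    for i in range(config.decoy_count):
        src = family_seqs[int(rng.integers(len(family_seqs)))]
        decoy = "".join(rng.permutation(list(src)))
        did = f"DECOY{i + 1:03d}"
        decoy_ids.append(did)
        decoys[did] = decoy

    # --- true names: identical ordering rules as the nomenclature stage ---
    st = _build_topology(groups, include_references=True)
    ladder = trees.ladderized_leaf_order(st)
    ladder_pos = {leaf: i for i, leaf in enumerate(ladder)}

    def group_pos(grp: _Group) -> int:
        return min(ladder_pos[g.gene_id] for g in grp.genes)

    base_number: dict[str, int] = {}
    group_index: dict[str, int] = {}
    by_anchor: dict[str, list[_Group]] = {}
    for grp in groups:
        if grp.anchor:
            by_anchor.setdefault(grp.anchor, []).append(grp)
    for anchor, glist in by_anchor.items():
        glist.sort(key=group_pos)
        num = int(anchor[-3:])
        for k, grp in enumerate(glist, start=1):
            base_number[grp.group_id] = num
            group_index[grp.group_id] = k
    orphans = [g for g in groups if g.anchor is None]
    orphans.sort(key=lambda grp: (grp.subfamily != "b", group_pos(grp)))
    for j, grp in enumerate(orphans):
        base_number[grp.group_id] = 153 + j
        group_index[grp.group_id] = 1

    truth: dict[str, TruthRecord] = {}
    sequences: dict[str, str] = {}
    chrom_rows = []
    orth_rows = []
    for grp in groups:
        for g in grp.genes:
            name = f"TaNAC{base_number[grp.group_id]:03d}-{g.subgenome}{group_index[grp.group_id]}"
            if g.paralog_index is not None:
                name += f"-{g.paralog_index}"
            truth[g.gene_id] = TruthRecord(
                true_subfamily=g.subfamily,
                true_group_id=g.group_id,
                true_subgenome=g.subgenome,
                true_paralog_index=g.paralog_index,
                true_name=name,
                responsive_pathogens=responsive[g.gene_id],
                planted_motifs=frozenset(carried[g.gene_id]),
                grain_specific=(grp.group_id == grain_group_id),
            )
            sequences[g.gene_id] = g.sequence
            chrom_rows.append(
                (g.gene_id, g.subgenome, g.chromosome, gene_rank[g.gene_id])
            )
            if grp.anchor:
                orth_rows.append((g.gene_id, grp.anchor))
    sequences.update(decoys)

    chrom_map = pd.DataFrame(
        chrom_rows, columns=["gene_id", "subgenome", "chromosome", "position_rank"]
    )
    ortholog_table = pd.DataFrame(orth_rows, columns=["gene_id", "anchor_name"])
    return SyntheticFamily(
        config=config, sequences=sequences, chrom_map=chrom_map,
        ortholog_table=ortholog_table, truth=truth, decoy_ids=decoy_ids,
    )


def _comb(taxa_or_subtrees: list) -> tuple:
    """Right-leaning comb: [c1, c2, c3] -> (c1, (c2, c3))."""
    t = taxa_or_subtrees[-1]
    for c in taxa_or_subtrees[-2::-1]:
        t = (c, t)
    return t


def _newick_of(node) -> str:
    if isinstance(node, str):
        return node
    return "(" + ",".join(_newick_of(c) for c in node) + ")"


def _groups_from_truth(truth: dict[str, TruthRecord]) -> list[_Group]:
    by_group: dict[str, _Group] = {}
    for gid, t in truth.items():
        grp = by_group.setdefault(
            t.true_group_id,
            _Group(group_id=t.true_group_id, subfamily=t.true_subfamily, anchor=None),
        )
        grp.genes.append(
            _Gene(
                gene_id=gid, subfamily=t.true_subfamily, group_id=t.true_group_id,
                subgenome=t.true_subgenome, chromosome=0,
                paralog_index=t.true_paralog_index, sequence="",
            )
        )
    for grp in by_group.values():
        grp.genes.sort(key=lambda g: (g.subgenome, g.paralog_index or 0, g.gene_id))
    return [by_group[k] for k in sorted(by_group)]


def _build_topology(groups: list[_Group], include_references: bool = True) -> trees.SupportTree:
    """Deterministic topology: groups monophyletic, units as combs, subfamily
    clades combed together with subfamily ``b`` subtending the root branch."""
    subfams = sorted({g.subfamily for g in groups})
    sf_order = [s for s in subfams if s == "b"] + [s for s in subfams if s != "b"]
    sf_clades = []
    for sf in sf_order:
        sf_groups = sorted((g for g in groups if g.subfamily == sf),
                           key=lambda g: g.group_id)
        parts = []
        for grp in sf_groups:
            units: dict[str, list[_Gene]] = {}
            for g in grp.genes:
                units.setdefault(g.subgenome, []).append(g)
            unit_trees = []
            for sub in sorted(units, key=lambda s: "ABDU".index(s)):
                genes = sorted(units[sub], key=lambda g: g.paralog_index or 0)
                unit_trees.append(_comb([g.gene_id for g in genes])
                                  if len(genes) > 1 else genes[0].gene_id)
            parts.append(_comb(unit_trees) if len(unit_trees) > 1 else unit_trees[0])
        if include_references:
            parts.append((f"REF_{sf}_1", f"REF_{sf}_2"))
        sf_clades.append(_comb(parts) if len(parts) > 1 else parts[0])
    top = _comb(sf_clades) if len(sf_clades) > 1 else (sf_clades[0],)
    newick = _newick_of(top) + ";"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # supports are attached right below
        st = trees.tree_from_string(newick)
    for node in st.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        node.edge.support = 100.0
    for edge in st.tree.preorder_edge_iter():
        edge.length = 1.0
    return st


def generate_tree(
    truth: dict[str, TruthRecord],
    noise: float = 0.0,
    seed: int = 0,
    include_references: bool = True,
) -> trees.SupportTree:
    """Rebuild the family topology from truth and degrade supports.

    Each internal edge is independently degraded with probability ``noise``
    to a support drawn uniformly below 70; the set of degraded edges is
    nested across noise levels at a fixed seed, so recovery degrades
    monotonically.  ``noise=0`` leaves every support at 100.
    """
    if not truth:
        raise ConfigurationError("empty truth: nothing to build a tree from")
    if not 0.0 <= noise <= 1.0:
        raise ConfigurationError(f"noise={noise} outside [0, 1]")
    st = _build_topology(_groups_from_truth(truth), include_references)
    rng = np.random.default_rng(seed)
    for node in st.tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        u = rng.random()
        v = rng.random()
        node.edge.support = float(int(v * 70)) if u < noise else 100.0
    return st


def generate_expression(
    truth: dict[str, TruthRecord],
    pathogens: tuple[str, ...] | None = None,
    timepoints: tuple[str, ...] = ("T1", "T2", "T3"),
    genotypes: tuple[str, ...] = ("R", "S"),
    effect: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression and baseline tables matching the planted truth.

    A planted responder gets exactly one condition per responsive pathogen
    with ``|log2fc| = effect`` and adjusted p = 0.001; every other row stays
    below both thresholds (|log2fc| < 1 or padj >= 0.05), so the classifier
    recovers exactly the planted sets whenever ``effect > 1``.
    """
    if pathogens is None:
        pathogens = DEFAULT_PANEL
    rng = np.random.default_rng(seed)
    de_rows = []
    conditions = [(g, t) for g in genotypes for t in timepoints]
    for gene, t in truth.items():
        for p in pathogens:
            hit_idx = int(rng.integers(len(conditions))) if p in t.responsive_pathogens else -1
            for ci, (gt, tp) in enumerate(conditions):
                if ci == hit_idx:
                    lfc = float(effect * (1 if rng.random() < 0.6 else -1))
                    padj = 0.001
                else:
                    lfc = float(rng.uniform(-0.9, 0.9))
                    padj = float(rng.uniform(0.05, 1.0))
                de_rows.append((gene, p, gt, tp, round(lfc, 4), round(padj, 6)))
    de = pd.DataFrame(
        de_rows, columns=["gene_id", "pathogen", "genotype", "timepoint", "log2fc", "padj"]
    )

    base_rows = []
    for gene, t in truth.items():
        for organ in ORGANS:
            if t.grain_specific:
                tpm = float(rng.uniform(0.5, 8.0)) if organ == "grain" else float(
                    rng.uniform(0.0, 0.09)
                )
            elif t.responsive_pathogens:
                tpm = float(10 ** rng.normal(0.7, 0.5))
            else:
                tpm = float(10 ** rng.normal(0.0, 0.6))
            base_rows.append((gene, organ, round(tpm, 4)))
    baseline = pd.DataFrame(base_rows, columns=["gene_id", "organ", "tpm"])
    return de, baseline


def scaled_config(seed: int, n_anchor_orthologs: int = 64, **overrides) -> FamilyConfig:
    """Convenience constructor for a study-sized family (~200 genes)."""
    return replace(FamilyConfig(seed=seed, n_anchor_orthologs=n_anchor_orthologs), **overrides)
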