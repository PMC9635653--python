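"""End-to-end orchestration of the synthetic curation pipeline.

``run_pipeline`` drives every stage in dependency order on one output
directory, writing each stage's tables before the next begins and a
machine-readable ``summary.json`` at the end.  All randomness flows through
the single configured seed, so identical configurations give byte-identical
output trees.

Stages (also exposed individually, file-driven, for the CLI subcommands):

simulate -> scan -> qc -> tree -> classify -> name -> express -> motifs -> report
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import domains, expression, motifs, msa, naming, simulate, trees
from .errors import NacfamError, PipelineError

log = logging.getLogger("nacfam.pipeline")

STAGES = ("simulate", "scan", "qc", "tree", "classify", "name",
          "express", "motifs", "report")


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 42
    noise: float = 0.0
    n_anchor_orthologs: int = 64
    decoy_count: int = 40
    evalue_cutoff: float = 0.01
    support_threshold: float = 70.0
    identity_threshold: float = 80.0
    lfc_cutoff: float = 1.0
    p_cutoff: float = 0.05
    expressed_cutoff: float = 0.1
    bin_edges: str | list[float] = field(default_factory=lambda: [0.3, 3.7])
    subclade_fraction: float = 0.6
    subclade_min_size: int = 5
    motif_signature: float = 0.9
    motif_absent: float = 0.1
    motif_conserved: float = 0.5
    scan_threshold_fraction: float = 0.5  # of the profile's maximum score

    def validate(self) -> None:
        checks = [
            ("evalue_cutoff", 0.0, 1.0), ("support_threshold", 0.0, 100.0),
            ("identity_threshold", 0.0, 100.0), ("p_cutoff", 0.0, 1.0),
            ("subclade_fraction", 0.0, 1.0), ("motif_signature", 0.0, 1.0),
            ("motif_absent", 0.0, 1.0), ("motif_conserved", 0.0, 1.0),
            ("noise", 0.0, 1.0), ("scan_threshold_fraction", 0.0, 1.0),
        ]
        for name, lo, hi in checks:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise NacfamError(f"config {name}={v} outside [{lo}, {hi}]")

    def to_json(self, path=None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


def _out(config: PipelineConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _need(config: PipelineConfig, stage: str, *files: str) -> None:
    for f in files:
        if not (_out(config) / f).exists():
            raise PipelineError(stage, f"missing required input '{f}' "
                                       f"(run the earlier stages first)")


def _write_fasta(seqs: dict[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for k in seqs:
            fh.write(f">{k}\n{seqs[k]}\n")


def _read_fasta(path: Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    for line in path.read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return seqs


def _truth_to_frame(truth: dict[str, simulate.TruthRecord]) -> pd.DataFrame:
    rows = [
        (g, t.true_subfamily, t.true_group_id, t.true_subgenome,
         t.true_paralog_index if t.true_paralog_index is not None else "",
         t.true_name, ",".join(sorted(t.responsive_pathogens)),
         ";".join(sorted(t.planted_motifs)), int(t.grain_specific))
        for g, t in truth.items()
    ]
    return pd.DataFrame(rows, columns=[
        "gene_id", "true_subfamily", "true_group_id", "true_subgenome",
        "true_paralog_index", "true_name", "responsive_pathogens",
        "planted_motifs", "grain_specific",
    ])


def _truth_from_frame(df: pd.DataFrame) -> dict[str, simulate.TruthRecord]:
    out = {}
    for r in df.itertuples():
        par = r.true_paralog_index
        par = None if (pd.isna(par) or str(par) == "") else int(par)
        resp = frozenset(str(r.responsive_pathogens).split(",")) \
            if isinstance(r.responsive_pathogens, str) and r.responsive_pathogens else frozenset()
        planted = frozenset(str(r.planted_motifs).split(";")) \
            if isinstance(r.planted_motifs, str) and r.planted_motifs else frozenset()
        out[r.gene_id] = simulate.TruthRecord(
            true_subfamily=r.true_subfamily, true_group_id=r.true_group_id,
            true_subgenome=r.true_subgenome, true_paralog_index=par,
            true_name=r.true_name, responsive_pathogens=resp,
            planted_motifs=planted, grain_specific=bool(r.grain_specific),
        )
    return out


def stage_simulate(config: PipelineConfig) -> None:
    out = _out(config)
    fam = simulate.generate_family(
        simulate.FamilyConfig(
            seed=config.seed,
            n_anchor_orthologs=config.n_anchor_orthologs,
            decoy_count=config.decoy_count,
        )
    )
    _write_fasta(fam.sequences, out / "family.fasta")
    fam.chrom_map.to_csv(out / "chrom_map.tsv", sep="\t", index=False)
    fam.ortholog_table.to_csv(out / "ortholog_table.tsv", sep="\t", index=False)
    _truth_to_frame(fam.truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "nam_training.fasta", "w") as fh:
        for i, row in enumerate(fam.nam_alignment()):
            fh.write(f">train{i + 1}\n{row}\n")
    de, baseline = simulate.generate_expression(fam.truth, seed=config.seed + 1)
    de.to_csv(out / "de_table.tsv", sep="\t", index=False)
    baseline.to_csv(out / "baseline_tpm.tsv", sep="\t", index=False)


def stage_scan(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "scan", "family.fasta", "nam_training.fasta")
    seqs = _read_fasta(out / "family.fasta")
    training = list(_read_fasta(out / "nam_training.fasta").values())
    profile = domains.build_profile(training, pseudocount=1.0, name="NAM")
    threshold = config.scan_threshold_fraction * profile.max_score
    all_hits: list[domains.DomainHit] = []
    for pid in seqs:
        rec = domains.ProteinRecord(id=pid, sequence=seqs[pid])
        all_hits.extend(domains.scan_sequence(profile, rec, threshold))
    domains.write_domtbl(all_hits, out / "domain_hits.domtbl")
    retained = domains.filter_hits(all_hits, evalue_cutoff=config.evalue_cutoff)
    by_protein: dict[str, list[domains.DomainHit]] = {}
    for h in all_hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    rows = []
    for pid in sorted(retained):
        nac = domains.split_nt_ct(
            domains.ProteinRecord(id=pid, sequence=seqs[pid]), by_protein[pid],
            subdomain_anchors=simulate.SUBDOMAIN_ANCHORS,
        )
        best = min(by_protein[pid], key=lambda h: h.full_seq_evalue)
        rows.append(
            (pid, best.full_seq_evalue, best.bit_score,
             nac.nt_region[0], nac.nt_region[1], nac.ct_region[0], nac.ct_region[1])
        )
    pd.DataFrame(
        rows, columns=["protein_id", "evalue", "bit_score",
                       "nt_start", "nt_end", "ct_start", "ct_end"],
    ).to_csv(out / "nac_regions.tsv", sep="\t", index=False)


def stage_qc(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "qc", "family.fasta", "nac_regions.tsv", "truth.tsv")
    seqs = _read_fasta(out / "family.fasta")
    regions = pd.read_csv(out / "nac_regions.tsv", sep="\t")
    truth_ids = set(pd.read_csv(out / "truth.tsv", sep="\t")["gene_id"])
    ids = [p for p in regions["protein_id"] if p in truth_ids]
    aln = msa.AlignmentMatrix(ids, [seqs[i] for i in ids])
    report = msa.completeness(aln)
    kept, removed = msa.filter_sequences(aln, report)
    report2 = msa.completeness(kept)
    masked = msa.mask_columns(kept, report2)
    unique, surplus = msa.dedup(masked)
    msa.write_fasta_alignment(unique, out / "masked.fasta")
    qc_rows = [
        (aln.ids[i], round(float(report.Cr[i]), 4),
         round(float(max(report.Cij[i, j] for j in range(aln.n_rows) if j != i)
                     if aln.n_rows > 1 else 1.0), 4),
         int(aln.ids[i] in removed))
        for i in range(aln.n_rows)
    ]
    pd.DataFrame(qc_rows, columns=["id", "Cr", "max_Cij", "removed"]).to_csv(
        out / "qc_report.tsv", sep="\t", index=False
    )
    with open(out / "surplus.json", "w") as fh:
        json.dump(surplus, fh, indent=2, sort_keys=True)
    with open(out / "qc_summary.json", "w") as fh:
        json.dump({"Ca": report.Ca, "n_removed": len(removed),
                   "n_unique": unique.n_rows}, fh, indent=2, sort_keys=True)


def stage_tree(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "tree", "truth.tsv")
    truth = _truth_from_frame(pd.read_csv(out / "truth.tsv", sep="\t"))
    st = simulate.generate_tree(truth, noise=config.noise, seed=config.seed + 2)
    trees.write_tree(st, out / "tree.nwk")


def stage_classify(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "classify", "tree.nwk")
    st = trees.read_tree(out / "tree.nwk")
    refs = {l: l.split("_")[1] for l in st.leaves if l.startswith("REF_")}
    assignment = trees.assign_subfamilies(st, refs, config.support_threshold)
    rows = [
        (leaf, assignment.labels[leaf], assignment.provenance[leaf],
         assignment.support_used.get(leaf) if assignment.support_used.get(leaf) is not None else "")
        for leaf in sorted(assignment.labels)
    ]
    pd.DataFrame(rows, columns=["leaf", "subfamily", "provenance", "support_used"]).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )


def _load_assignment(out: Path) -> trees.SubfamilyAssignment:
    df = pd.read_csv(out / "assignments.tsv", sep="\t")
    return trees.SubfamilyAssignment(
        labels={r.leaf: r.subfamily for r in df.itertuples()},
        provenance={r.leaf: r.provenance for r in df.itertuples()},
        support_used={},
    )


def stage_name(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "name", "tree.nwk", "assignments.tsv", "chrom_map.tsv",
          "ortholog_table.tsv", "family.fasta")
    st = trees.read_tree(out / "tree.nwk")
    assignment = _load_assignment(out)
    chrom_map = pd.read_csv(out / "chrom_map.tsv", sep="\t")
    orth = pd.read_csv(out / "ortholog_table.tsv", sep="\t")
    seqs = _read_fasta(out / "family.fasta")
    groups = naming.group_homoeologs(
        st, assignment, chrom_map, orth, seqs,
        support_threshold=config.support_threshold,
        identity_threshold=config.identity_threshold,
    )
    names = naming.assign_names(groups, st, assignment)
    naming.names_table(names, groups).to_csv(out / "names.tsv", sep="\t", index=False)


def stage_express(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "express", "de_table.tsv", "baseline_tpm.tsv", "assignments.tsv")
    de = pd.read_csv(out / "de_table.tsv", sep="\t")
    baseline = pd.read_csv(out / "baseline_tpm.tsv", sep="\t")
    profiles = expression.classify_responsiveness(
        de, lfc_cutoff=config.lfc_cutoff, p_cutoff=config.p_cutoff
    )
    rows = [
        (g, ",".join(sorted(p.responsive_pathogens)), p.lifestyle_category,
         int(p.universal))
        for g, p in sorted(profiles.items())
    ]
    pd.DataFrame(rows, columns=["gene_id", "responsive_pathogens",
                                "lifestyle_category", "universal"]).to_csv(
        out / "response_profiles.tsv", sep="\t", index=False
    )
    expression.lifestyle_summary(profiles).to_csv(
        out / "lifestyle_summary.tsv", sep="\t", index=False
    )
    edges = config.bin_edges if config.bin_edges == "auto" else tuple(config.bin_edges)
    bins = expression.baseline_bins(baseline, config.expressed_cutoff, edges)
    bins.table.to_csv(out / "baseline_bins.tsv", sep="\t", index=False)
    assignment = _load_assignment(out)
    queries = {l: s for l, s in assignment.labels.items()
               if assignment.provenance[l] != "reference" and l in profiles}
    responsive = {g for g, p in profiles.items() if p.responsive_pathogens}
    expression.subfamily_enrichment(queries, responsive & set(queries)).to_csv(
        out / "subfamily_enrichment.tsv", sep="\t", index=False
    )
    resp_genes = sorted(responsive)
    if resp_genes:
        mat = (
            de[de["gene_id"].isin(resp_genes)]
            .assign(cond=lambda d: d["pathogen"] + "." + d["genotype"] + "." + d["timepoint"])
            .pivot_table(index="gene_id", columns="cond", values="log2fc", aggfunc="mean")
        )
        order = expression.hclust_order(mat)
        mat.loc[order].to_csv(out / "heatmap_matrix.tsv", sep="\t")


def stage_motifs(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "motifs", "family.fasta", "nac_regions.tsv",
          "assignments.tsv", "response_profiles.tsv", "baseline_bins.tsv", "truth.tsv")
    seqs = _read_fasta(out / "family.fasta")
    regions = pd.read_csv(out / "nac_regions.tsv", sep="\t")
    truth_ids = set(pd.read_csv(out / "truth.tsv", sep="\t")["gene_id"])
    nacs: dict[str, domains.NACProtein] = {}
    for r in regions.itertuples():
        if r.protein_id not in truth_ids:
            continue
        rec = domains.ProteinRecord(id=r.protein_id, sequence=seqs[r.protein_id])
        hit = domains.DomainHit(
            protein_id=r.protein_id, profile_name="NAM",
            full_seq_evalue=float(r.evalue), bit_score=float(r.bit_score),
            domain_index=1, domain_cond_evalue=float(r.evalue),
            env_start=int(r.nt_start), env_end=int(r.nt_end),
        )
        nacs[r.protein_id] = domains.split_nt_ct(
            rec, [hit], subdomain_anchors=simulate.SUBDOMAIN_ANCHORS
        )
    catalog = simulate.planted_motif_strings()
    occs = motifs.scan_planted_motifs(nacs, catalog)
    for region in ("NT", "CT"):
        sub = [o for o in occs if o.region == region]
        widths = {m: len(catalog[m][1]) for m in catalog if catalog[m][0] == region}
        motifs.write_meme_text(sub, widths, out / f"motifs_{region.lower()}.meme.txt")
    occs = []
    for region in ("NT", "CT"):
        occs.extend(motifs.read_meme(out / f"motifs_{region.lower()}.meme.txt", region=region))
    proteins = sorted(nacs)
    mat = motifs.presence_matrix(occs, proteins, motifs=sorted(catalog))
    assignment = _load_assignment(out)
    labels = {p: assignment.labels.get(p, trees.UNCLASSIFIED) for p in proteins}
    summary = motifs.classify_motifs(
        mat, labels, config.motif_signature, config.motif_absent, config.motif_conserved
    )
    sub_labels, _ = motifs.map_to_subdomains(occs, nacs)
    prof = pd.read_csv(out / "response_profiles.tsv", sep="\t").fillna("")
    responsive = {r.gene_id: bool(r.responsive_pathogens) for r in prof.itertuples()}
    trait = {p: responsive.get(p, False) for p in proteins}
    assoc = motifs.associate_motif(mat, trait)
    assoc["subdomain"] = [sub_labels.get(m, "") for m in assoc["motif"]]
    assoc["conserved"] = [int(summary.conserved.get(m, False)) for m in assoc["motif"]]
    assoc["specific_to"] = [summary.specific_to.get(m) or "" for m in assoc["motif"]]
    assoc.to_csv(out / "motif_association.tsv", sep="\t", index=False)
    long = summary.fractions.reset_index(names="motif").melt(
        id_vars="motif", var_name="subfamily", value_name="fraction"
    )
    long["class"] = [
        summary.classes.loc[m, sf] for m, sf in zip(long["motif"], long["subfamily"])
    ]
    long.sort_values(["motif", "subfamily"]).to_csv(
        out / "motif_summary.tsv", sep="\t", index=False
    )
    mat.to_csv(out / "motif_presence.tsv", sep="\t")


def stage_report(config: PipelineConfig) -> None:
    out = _out(config)
    _need(config, "report", "truth.tsv", "names.tsv", "assignments.tsv",
          "response_profiles.tsv", "subfamily_enrichment.tsv", "tree.nwk",
          "baseline_bins.tsv")
    truth = _truth_from_frame(pd.read_csv(out / "truth.tsv", sep="\t"))
    names = pd.read_csv(out / "names.tsv", sep="\t")
    assignment = _load_assignment(out)
    prof = pd.read_csv(out / "response_profiles.tsv", sep="\t").fillna("")
    enr = pd.read_csv(out / "subfamily_enrichment.tsv", sep="\t")
    regions = pd.read_csv(out / "nac_regions.tsv", sep="\t")

    name_of = dict(zip(names["gene_id"], names["assigned_name"]))
    n_correct_names = sum(1 for g, t in truth.items() if name_of.get(g) == t.true_name)
    q = assignment.query_labels()
    n_correct_sf = sum(1 for g, t in truth.items() if q.get(g) == t.true_subfamily)
    resp_of = {
        r.gene_id: frozenset(r.responsive_pathogens.split(",")) if r.responsive_pathogens else frozenset()
        for r in prof.itertuples()
    }
    n_correct_resp = sum(
        1 for g, t in truth.items() if resp_of.get(g, frozenset()) == t.responsive_pathogens
    )
    responsive = {g for g, r in resp_of.items() if r}
    per_pathogen = {}
    for g in responsive:
        for p in resp_of[g]:
            per_pathogen[p] = per_pathogen.get(p, 0) + 1

    st = trees.read_tree(out / "tree.nwk")
    subclades = trees.find_enriched_subclades(
        st, responsive & set(st.leaves), config.subclade_fraction,
        config.subclade_min_size, assignment,
    )
    n_genes = len(truth)
    summary = {
        "n_family_genes": n_genes,
        "n_decoys": int(config.decoy_count),
        "n_retained_by_scan": int(sum(regions["protein_id"].isin(truth))),
        "n_decoys_retained": int(sum(~regions["protein_id"].isin(truth))),
        "n_named": int(len(names)),
        "naming_accuracy": n_correct_names / n_genes,
        "subfamily_accuracy": n_correct_sf / n_genes,
        "responsiveness_accuracy": n_correct_resp / n_genes,
        "n_responsive": len(responsive),
        "responsive_per_pathogen": dict(sorted(per_pathogen.items())),
        "n_enriched_subfamilies": int((enr["p_bh"] < 0.05).sum()),
        "n_enriched_subclades": len(subclades),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    bins = pd.read_csv(out / "baseline_bins.tsv", sep="\t")
    profiles = {r.gene_id: r.responsive_pathogens for r in prof.itertuples()}
    export_itol_annotations(assignment, profiles, bins, set(st.leaves), out)


def export_itol_annotations(
    assignment: trees.SubfamilyAssignment,
    profiles: dict[str, str],
    bins: pd.DataFrame,
    tree_leaves: set[str],
    outdir,
) -> list[str]:
    """Plain-text iTOL annotation files keyed by leaf id.

    Writes a subfamily color strip, per-pathogen binary symbols and an
    organ-tpm heatmap; genes absent from the tree are excluded and returned.
    """
    out = Path(outdir)
    palette = ["#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00",
               "#ffff33", "#a65628", "#f781bf", "#999999"]
    queries = assignment.query_labels()
    missing = sorted(set(queries) - tree_leaves)
    present = [g for g in sorted(queries) if g in tree_leaves]

    subfams = sorted({v for v in queries.values()})
    color = {sf: palette[i % len(palette)] for i, sf in enumerate(subfams)}
    with open(out / "itol_subfamily.txt", "w") as fh:
        fh.write("DATASET_COLORSTRIP\nSEPARATOR TAB\nDATASET_LABEL\tsubfamily\nCOLOR\t#000000\nDATA\n")
        for g in present:
            fh.write(f"{g}\t{color[queries[g]]}\t{queries[g]}\n")

    pathogens = sorted({p for v in profiles.values() if isinstance(v, str) and v
                        for p in v.split(",")})
    with open(out / "itol_pathogens.txt", "w") as fh:
        fh.write("DATASET_BINARY\nSEPARATOR TAB\nDATASET_LABEL\tpathogen response\nCOLOR\t#000000\n")
        fh.write("FIELD_SHAPES\t" + "\t".join(["2"] * len(pathogens)) + "\n")
        fh.write("FIELD_LABELS\t" + "\t".join(pathogens) + "\nDATA\n")
        for g in present:
            resp = set(str(profiles.get(g, "")).split(",")) if profiles.get(g) else set()
            fh.write(g + "\t" + "\t".join("1" if p in resp else "0" for p in pathogens) + "\n")

    organs = sorted(bins["organ"].unique())
    wide = bins.pivot_table(index="gene_id", columns="organ", values="mean_tpm")
    with open(out / "itol_baseline.txt", "w") as fh:
        fh.write("DATASET_HEATMAP\nSEPARATOR TAB\nDATASET_LABEL\tbaseline tpm\nCOLOR\t#000000\n")
        fh.write("FIELD_LABELS\t" + "\t".join(organs) + "\nDATA\n")
        for g in present:
            if g in wide.index:
                vals = [f"{wide.loc[g, o]:.4f}" for o in organs]
                fh.write(g + "\t" + "\t".join(vals) + "\n")
    return missing


_STAGE_FUNCS = {
    "simulate": stage_simulate, "scan": stage_scan, "qc": stage_qc,
    "tree": stage_tree, "classify": stage_classify, "name": stage_name,
    "express": stage_express, "motifs": stage_motifs, "report": stage_report,
}


def run_stage(config: PipelineConfig, stage: str) -> None:
    config.validate()
    if stage not in _STAGE_FUNCS:
        raise NacfamError(f"unknown stage '{stage}'")
    t0 = time.monotonic()
    try:
        _STAGE_FUNCS[stage](config)
    except PipelineError:
        raise
    except NacfamError as exc:
        raise PipelineError(stage, str(exc)) from exc
    log.info("stage %s finished in %.2fs", stage, time.monotonic() - t0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the summary dict."""
    config.validate()
    out = _out(config)
    config.to_json(out / "config.json")
    for stage in STAGES:
        run_stage(config, stage)
    with open(out / "summary.json") as fh:
        return json.load(fh)
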