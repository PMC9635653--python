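"""Pathogen-responsiveness classification, expression binning and statistics.

A gene is pathogen responsive when at least one condition (any genotype and
timepoint) shows ``|log2 fold change| > 1`` with adjusted ``p < 0.05`` (both
strict).  Responsive genes are partitioned by the lifestyle of the
activating pathogens (hemibiotroph-only / biotroph-only / both), and a gene
responsive to at least two pathogens shows the *universal* response.

Baseline expression uses per-organ mean tpm with a 0.1 tpm expressed cutoff
and low / moderate / high bins at the 1st and 3rd quartiles of the expressed
distribution (the study-scale values of those quartiles are 0.3 and 3.7 tpm,
available as fixed edges).

The statistical toolbox mirrors the comparisons used for this kind of family
survey: per-subfamily Fisher exact enrichment with Benjamini-Hochberg
correction, a family-versus-genome Pearson chi-square, a Kruskal-Wallis test
with a greedy step-down homogeneous-subset labelling of bit-score
distributions, and the Moses test of extreme reactions for mock versus
treated tpm samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InputError
from .simulate import PATHOGEN_LIFESTYLES

LIFESTYLE_CATEGORIES = ("hemibiotroph-only", "biotroph-only", "both", "none")


@dataclass
class ResponseProfile:
    gene: str
    responsive_pathogens: frozenset[str]
    directions: dict[tuple[str, str, str], str] = field(default_factory=dict)
    lifestyle_category: str = "none"

    @property
    def universal(self) -> bool:
        return len(self.responsive_pathogens) >= 2


def classify_responsiveness(
    de: pd.DataFrame,
    lifestyles: dict[str, str] | None = None,
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
) -> dict[str, ResponseProfile]:
    """Per-gene response profiles from a differential-expression table.

    Expects columns gene_id, pathogen, genotype, timepoint, log2fc, padj.
    Both thresholds are strict: ``|log2fc| > lfc_cutoff`` and
    ``padj < p_cutoff``.
    """
    if lifestyles is None:
        lifestyles = PATHOGEN_LIFESTYLES
    unknown = set(de["pathogen"].unique()) - set(lifestyles)
    if unknown:
        raise ConfigurationError(f"pathogens without a lifestyle: {sorted(unknown)}")
    profiles: dict[str, ResponseProfile] = {}
    passing = de[(de["log2fc"].abs() > lfc_cutoff) & (de["padj"] < p_cutoff)]
    for gene in de["gene_id"].unique():
        profiles[gene] = ResponseProfile(gene=gene, responsive_pathogens=frozenset())
    for gene, sub in passing.groupby("gene_id"):
        dirs = {
            (r.pathogen, r.genotype, r.timepoint): ("up" if r.log2fc > 0 else "down")
            for r in sub.itertuples()
        }
        resp = frozenset(sub["pathogen"].unique())
        styles = {lifestyles[p] for p in resp}
        if styles == {"hemibiotroph"}:
            cat = "hemibiotroph-only"
        elif styles == {"biotroph"}:
            cat = "biotroph-only"
        else:
            cat = "both"
        profiles[gene] = ResponseProfile(
            gene=gene, responsive_pathogens=resp, directions=dirs, lifestyle_category=cat
        )
    return profiles


def lifestyle_summary(profiles: dict[str, ResponseProfile]) -> pd.DataFrame:
    """Counts and fractions per lifestyle category plus per-pathogen totals."""
    responsive = [p for p in profiles.values() if p.responsive_pathogens]
    n_resp = len(responsive)
    rows = []
    for cat in LIFESTYLE_CATEGORIES[:3]:
        n = sum(1 for p in responsive if p.lifestyle_category == cat)
        rows.append(("category", cat, n, n / n_resp if n_resp else 0.0))
    rows.append(("category", "none", len(profiles) - n_resp,
                 0.0 if not profiles else (len(profiles) - n_resp) / len(profiles)))
    pathogens = sorted({pt for p in responsive for pt in p.responsive_pathogens})
    for pt in pathogens:
        n = sum(1 for p in responsive if pt in p.responsive_pathogens)
        rows.append(("pathogen", pt, n, n / n_resp if n_resp else 0.0))
    n_universal = sum(1 for p in responsive if p.universal)
    rows.append(("universal", ">=2 pathogens", n_universal,
                 n_universal / n_resp if n_resp else 0.0))
    return pd.DataFrame(rows, columns=["kind", "label", "count", "fraction"])


@dataclass
class BaselineProfile:
    table: pd.DataFrame       # gene_id, organ, mean_tpm, expressed, bin
    edges: tuple[float, float]
    expressed_cutoff: float

    def organs_expressed(self) -> pd.Series:
        return self.table.groupby("gene_id")["expressed"].sum()

    def grain_specific(self) -> set[str]:
        """Genes expressed (>= cutoff) in grain and in no other organ."""
        out = set()
        for gene, sub in self.table.groupby("gene_id"):
            exp = set(sub.loc[sub["expressed"], "organ"])
            if exp == {"grain"}:
                out.add(gene)
        return out


def baseline_bins(
    tpm: pd.DataFrame,
    expressed_cutoff: float = 0.1,
    bin_edges: str | tuple[float, float] = "auto",
) -> BaselineProfile:
    """Organ-level mean tpm with expressed flags and low/moderate/high bins.

    ``bin_edges='auto'`` places the edges at the 1st and 3rd quartiles of the
    expressed (>= cutoff) values; a fixed pair such as ``(0.3, 3.7)`` mirrors
    the published desk values.  Bins: low < lo <= moderate <= hi < high.
    """
    if (tpm["tpm"] < 0).any():
        raise InputError("negative tpm values")
    means = (
        tpm.groupby(["gene_id", "organ"], sort=True)["tpm"].mean().reset_index()
        .rename(columns={"tpm": "mean_tpm"})
    )
    means["expressed"] = means["mean_tpm"] >= expressed_cutoff
    expressed_vals = means.loc[means["expressed"], "mean_tpm"]
    if bin_edges == "auto":
        if len(expressed_vals) == 0:
            edges = (expressed_cutoff, expressed_cutoff)
        else:
            edges = (
                float(np.quantile(expressed_vals, 0.25)),
                float(np.quantile(expressed_vals, 0.75)),
            )
    else:
        edges = (float(bin_edges[0]), float(bin_edges[1]))
    lo, hi = edges

    def _bin(row):
        if not row["expressed"]:
            return "not-expressed"
        v = row["mean_tpm"]
        if v < lo:
            return "low"
        if v > hi:
            return "high"
        return "moderate"

    means["bin"] = means.apply(_bin, axis=1)
    return BaselineProfile(table=means, edges=edges, expressed_cutoff=expressed_cutoff)


def subfamily_enrichment(
    assignment: dict[str, str], responsive: set[str]
) -> pd.DataFrame:
    """Per-subfamily 2x2 Fisher exact tests of responsive-gene proportion.

    Rows: subfamily, counts (responsive/total inside and outside), odds
    ratio, two-sided exact p and Benjamini-Hochberg adjusted p.
    """
    stray = responsive - set(assignment)
    if stray:
        raise InputError(f"responsive genes without assignment: {sorted(stray)}")
    genes = list(assignment)
    total_resp = sum(1 for g in genes if g in responsive)
    rows = []
    for sf in sorted(set(assignment.values())):
        members = [g for g in genes if assignment[g] == sf]
        if not members:
            warnings.warn(f"subfamily '{sf}' has no members; skipped")
            continue
        a = sum(1 for g in members if g in responsive)          # responsive in
        b = len(members) - a                                    # nonresponsive in
        c = total_resp - a                                      # responsive out
        d = (len(genes) - len(members)) - c                     # nonresponsive out
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((sf, a, b, c, d, float(odds), float(p)))
    df = pd.DataFrame(
        rows,
        columns=["subfamily", "responsive_in", "nonresponsive_in",
                 "responsive_out", "nonresponsive_out", "odds_ratio", "p"],
    )
    if len(df):
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_bh"] = []
    return df


def family_vs_genome_chisq(
    family_responsive: int, family_total: int,
    genome_responsive: int, genome_total: int,
    continuity: bool = False,
) -> tuple[float, int, float]:
    """Pearson 2x2 chi-square comparing the family's responsive proportion
    with the genome-wide one (no continuity correction by default)."""
    for name, val in (("family_responsive", family_responsive),
                      ("family_total", family_total),
                      ("genome_responsive", genome_responsive),
                      ("genome_total", genome_total)):
        if val < 0:
            raise InputError(f"{name} < 0")
    if family_responsive > family_total or genome_responsive > genome_total:
        raise InputError("responsive count exceeds total")
    table = np.array([
        [family_responsive, family_total - family_responsive],
        [genome_responsive, genome_total - genome_responsive],
    ])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("zero expected cell; use an exact test instead")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=continuity)
    return float(stat), int(dof), float(p)


def _kw_pvalue(samples: list[np.ndarray]) -> float:
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 1.0
    try:
        return float(stats.kruskal(*samples).pvalue)
    except ValueError:
        return 1.0


def kruskal_wallis_stepdown(
    groups: dict[str, list[float]], alpha: float = 0.05
) -> tuple[float, float, dict[str, list[int]]]:
    """Kruskal-Wallis H (tie-corrected) plus homogeneous subsets.

    Subsets are built greedily: groups are ordered by mean rank and a subset
    is extended while the Kruskal-Wallis test inside it stays non-significant
    at ``alpha``; each group belongs to at least one numbered subset.  The
    step-down labelling matches the boxplot annotation style where groups
    not sharing a number differ significantly.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    for k, v in groups.items():
        if len(v) < 1:
            raise InputError(f"group '{k}' is empty")
    labels = list(groups)
    samples = {k: np.asarray(groups[k], dtype=float) for k in labels}
    pooled = np.concatenate([samples[k] for k in labels])
    ranks = stats.rankdata(pooled)
    mean_rank = {}
    offset = 0
    for k in labels:
        n = len(samples[k])
        mean_rank[k] = float(ranks[offset : offset + n].mean())
        offset += n
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*[samples[k] for k in labels])
        h, p = float(h), float(p)

    order = sorted(labels, key=lambda k: (mean_rank[k], k))
    subsets: list[list[str]] = []
    start = 0
    while start < len(order):
        end = start + 1
        while end < len(order) and _kw_pvalue(
            [samples[k] for k in order[start : end + 1]]
        ) >= alpha:
            end += 1
        subsets.append(order[start:end])
        start = end
    membership: dict[str, list[int]] = {k: [] for k in labels}
    for i, subset in enumerate(subsets, start=1):
        for k in subset:
            membership[k].append(i)
    return h, p, membership


def moses_test(
    control: list[float], experimental: list[float], trim_h: int = 1
) -> tuple[int, float]:
    """Moses test of extreme reactions.

    Pools and ranks both samples (ties broken by input order), trims the
    ``trim_h`` most extreme control ranks from each tail and measures the
    span (range + 1) of the remaining control ranks.  The exact p-value is
    ``P(span <= observed)`` under random assignment of ranks, computed from
    the combinatorial distribution of the span.  Small p indicates that the
    experimental sample pushed the control ranks into a narrow central band,
    i.e. extreme reactions in the experimental group.
    """
    nc, ne = len(control), len(experimental)
    if trim_h < 0:
        raise InputError("trim_h must be >= 0")
    if nc < 2 + 2 * trim_h or ne < 2 + 2 * trim_h:
        raise InputError(
            f"need at least {2 + 2 * trim_h} observations per sample for trim_h={trim_h}"
        )
    pooled = list(control) + list(experimental)
    ranks = stats.rankdata(pooled, method="ordinal")
    c_ranks = sorted(ranks[:nc])
    trimmed = c_ranks[trim_h : nc - trim_h]
    span = int(trimmed[-1] - trimmed[0] + 1)

    n = nc + ne
    nh = nc - 2 * trim_h
    total = comb(n, nc)
    acc = 0
    # a = rank of the (h+1)-th control value, b = rank of the (nc-h)-th
    for a in range(1, n + 1):
        for b in range(a + nh - 1, min(n, a + span - 1) + 1):
            acc += (
                comb(a - 1, trim_h)
                * comb(b - a - 1, nh - 2)
                * comb(n - b, trim_h)
            )
    return span, acc / total


def hclust_order(matrix: pd.DataFrame) -> list[str]:
    """Gene order after agglomerative clustering (Euclidean, average linkage).

    Missing cells (conditions not tested for a gene) are imputed as 0.
    Deterministic: scipy's linkage on the observation order given, ties
    resolved by row index.
    """
    if matrix.empty:
        raise InputError("empty expression matrix")
    values = matrix.fillna(0.0).to_numpy(dtype=float)
    if len(matrix) == 1:
        return list(matrix.index)
    link = hierarchy.linkage(values, method="average", metric="euclidean")
    order = hierarchy.leaves_list(link)
    return [matrix.index[i] for i in order]
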