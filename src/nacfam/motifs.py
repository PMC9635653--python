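"""Motif-occurrence parsing, presence matrices and specificity analysis.

Motif discovery itself (the MEME expectation-maximisation search) is out of
scope; this module consumes discovery *output* - MEME XML or a minimal
MEME-style text listing of sites - or occurrences produced by the
deterministic planted-motif scanner used with synthetic families.

Classification follows the subfamily-fraction scheme: a motif is a
*signature* of a subfamily when present in more than 90% of its members,
*absent* below 10%, and *present* in between (both boundaries fall in the
middle class); it is *conserved* when carried by more than half of all
proteins, and *specific to* a subfamily when it reaches the 10% presence
floor there and stays below it everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from lxml import etree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .domains import NACProtein
from .errors import InputError, ParseError

REGIONS = ("NT", "CT")


@dataclass(frozen=True)
class MotifOccurrence:
    motif_id: str
    protein_id: str
    region: str  # NT or CT
    start: int   # 1-based within the region
    end: int
    score: float = 0.0

    def __post_init__(self):
        if self.region not in REGIONS:
            raise InputError(f"unknown region '{self.region}'")
        if not 1 <= self.start <= self.end:
            raise InputError(f"bad motif coordinates {self.start}..{self.end}")


@dataclass
class MotifSummary:
    fractions: pd.DataFrame            # motif x subfamily presence fraction
    classes: pd.DataFrame              # motif x subfamily in {signature, present, absent}
    overall_fraction: pd.Series
    conserved: dict[str, bool]
    specific_to: dict[str, str | None]


# --- MEME output parsing -----------------------------------------------------

def _read_meme_xml(path, region: str) -> list[MotifOccurrence]:
    tree = etree.parse(str(path))
    root = tree.getroot()
    seq_names = {
        s.get("id"): s.get("name")
        for s in root.iter("sequence")
    }
    occs: list[MotifOccurrence] = []
    for motif in root.iter("motif"):
        mid = motif.get("name") or motif.get("id")
        width = int(motif.get("width"))
        for site in motif.iter("contributing_site"):
            sid = site.get("sequence_id")
            pos = int(site.get("position")) + 1  # MEME XML positions are 0-based
            pv = float(site.get("pvalue", "0") or 0)
            occs.append(
                MotifOccurrence(
                    motif_id=mid, protein_id=seq_names.get(sid, sid),
                    region=region, start=pos, end=pos + width - 1, score=pv,
                )
            )
    return occs


def _read_meme_text(path, region: str) -> list[MotifOccurrence]:
    """Minimal MEME-style text: ``MOTIF <id> width=<w>`` headers followed by
    one ``site`` line per occurrence: ``site <seq> <start> <score>``."""
    occs: list[MotifOccurrence] = []
    current: str | None = None
    width = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "MOTIF":
                if len(parts) < 3 or not parts[2].startswith("width="):
                    raise ParseError(f"{path}: line {lineno}: malformed MOTIF header")
                current = parts[1]
                width = int(parts[2].split("=", 1)[1])
            elif parts[0] == "site":
                if current is None:
                    raise ParseError(f"{path}: line {lineno}: site before MOTIF header")
                if len(parts) < 3:
                    raise ParseError(f"{path}: line {lineno}: malformed site line")
                start = int(parts[2])
                score = float(parts[3]) if len(parts) > 3 else 0.0
                occs.append(
                    MotifOccurrence(
                        motif_id=current, protein_id=parts[1], region=region,
                        start=start, end=start + width - 1, score=score,
                    )
                )
            elif parts[0] in {"MEME", "ALPHABET=", "ALPHABET"}:
                continue
    return occs


def read_meme(path, region: str = "NT", strict: bool = False) -> list[MotifOccurrence]:
    """Read motif occurrences from MEME XML or minimal MEME-style text.

    ``region`` declares which run the file belongs to (NT motifs allow any
    number of sites per sequence; CT motifs expect zero or one).  A CT file
    violating the zero-or-one contract warns, or raises when ``strict``.
    """
    with open(path) as fh:
        head = fh.read(64).lstrip()
    if head.startswith("<"):
        occs = _read_meme_xml(path, region)
    else:
        occs = _read_meme_text(path, region)
    if region == "CT":
        seen: dict[tuple[str, str], int] = {}
        for o in occs:
            seen[(o.motif_id, o.protein_id)] = seen.get((o.motif_id, o.protein_id), 0) + 1
        dupes = sorted(k for k, v in seen.items() if v > 1)
        if dupes:
            msg = f"CT motifs with >1 site per sequence: {dupes[:5]}"
            if strict:
                raise ParseError(msg)
            warnings.warn(msg)
    return occs


def write_meme_text(occurrences: list[MotifOccurrence], widths: dict[str, int], path) -> None:
    """Writer for the minimal MEME-style text dialect (round-trips read_meme)."""
    by_motif: dict[str, list[MotifOccurrence]] = {}
    for o in occurrences:
        by_motif.setdefault(o.motif_id, []).append(o)
    with open(path, "w") as fh:
        fh.write("MEME version 5 (minimal site listing)\n\n")
        for mid in sorted(set(widths) | set(by_motif)):
            w = widths.get(mid) or (by_motif[mid][0].end - by_motif[mid][0].start + 1)
            fh.write(f"MOTIF {mid} width={w}\n")
            for o in sorted(by_motif.get(mid, []), key=lambda o: (o.protein_id, o.start)):
                fh.write(f"site {o.protein_id} {o.start} {o.score:g}\n")


def scan_planted_motifs(
    nac_proteins: dict[str, NACProtein],
    motif_strings: dict[str, tuple[str, str, int]],
) -> list[MotifOccurrence]:
    """Deterministic exact-string scanner for planted motifs.

    ``motif_strings`` maps motif id -> (region, string, nominal offset); the
    offset is informational - every exact occurrence inside the declared
    region is reported, with coordinates 1-based within that region.
    """
    occs: list[MotifOccurrence] = []
    for pid in sorted(nac_proteins):
        nac = nac_proteins[pid]
        for mid in sorted(motif_strings):
            region, s, _ = motif_strings[mid]
            hay = nac.nt_sequence if region == "NT" else nac.ct_sequence
            start = 0
            while True:
                idx = hay.find(s, start)
                if idx < 0:
                    break
                occs.append(
                    MotifOccurrence(
                        motif_id=mid, protein_id=pid, region=region,
                        start=idx + 1, end=idx + len(s), score=1.0,
                    )
                )
                start = idx + 1
    return occs


def presence_matrix(
    occurrences: list[MotifOccurrence],
    proteins: list[str],
    motifs: list[str] | None = None,
) -> pd.DataFrame:
    """Binary motif x protein matrix; a cell is 1 iff >= 1 occurrence.

    Passing ``motifs`` keeps all-zero rows for motifs without any site.
    """
    known = set(proteins)
    stray = sorted({o.protein_id for o in occurrences} - known)
    if stray:
        raise InputError(f"occurrences reference unknown proteins: {stray[:5]}")
    motif_ids = sorted(motifs if motifs is not None else {o.motif_id for o in occurrences})
    mat = pd.DataFrame(0, index=motif_ids, columns=list(proteins), dtype=int)
    for o in occurrences:
        if o.motif_id in mat.index:
            mat.loc[o.motif_id, o.protein_id] = 1
    return mat


def classify_motifs(
    matrix: pd.DataFrame,
    assignment: dict[str, str],
    signature_threshold: float = 0.9,
    absent_threshold: float = 0.1,
    conserved_threshold: float = 0.5,
) -> MotifSummary:
    """Per-subfamily presence fractions and specificity classes.

    Boundary semantics: a fraction strictly above ``signature_threshold`` is
    a signature, strictly below ``absent_threshold`` absent, anything else
    (both boundaries included) present.
    """
    missing = sorted(set(matrix.columns) - set(assignment))
    if missing:
        raise InputError(f"proteins without subfamily assignment: {missing[:5]}")
    subfams = sorted(set(assignment.values()))
    frac = pd.DataFrame(index=matrix.index, columns=subfams, dtype=float)
    for sf in subfams:
        cols = [c for c in matrix.columns if assignment[c] == sf]
        frac[sf] = matrix[cols].mean(axis=1) if cols else 0.0

    def classify(v: float) -> str:
        if v > signature_threshold:
            return "signature"
        if v < absent_threshold:
            return "absent"
        return "present"

    classes = frac.map(classify)
    overall = matrix.mean(axis=1)
    conserved = {m: bool(overall[m] > conserved_threshold) for m in matrix.index}
    specific: dict[str, str | None] = {}
    for m in matrix.index:
        hits = [sf for sf in subfams if frac.loc[m, sf] >= absent_threshold]
        specific[m] = hits[0] if len(hits) == 1 else None
    return MotifSummary(
        fractions=frac, classes=classes, overall_fraction=overall,
        conserved=conserved, specific_to=specific,
    )


def map_to_subdomains(
    occurrences: list[MotifOccurrence],
    nac_proteins: dict[str, NACProtein],
    min_overlap: float = 0.5,
) -> tuple[dict[str, str], list[tuple[MotifOccurrence, str]]]:
    """Label motifs with the NAC subdomain (A-E) they cover.

    An occurrence overlapping a subdomain over at least ``min_overlap`` of
    its length takes that subdomain's label (largest overlap wins);
    otherwise it is ``between-subdomain``.  The motif-level label is the
    majority over its occurrences, ties to the alphabetically first label.
    """
    per_occ: list[tuple[MotifOccurrence, str]] = []
    skipped = 0
    for o in occurrences:
        nac = nac_proteins.get(o.protein_id)
        if nac is None or not nac.subdomain_coords:
            skipped += 1
            continue
        region_start = (nac.nt_region if o.region == "NT" else nac.ct_region)[0]
        abs_s = region_start + o.start - 1
        abs_e = region_start + o.end - 1
        best_label, best_ov = "between-subdomain", 0
        for label in sorted(nac.subdomain_coords):
            ds, de = nac.subdomain_coords[label]
            ov = min(abs_e, de) - max(abs_s, ds) + 1
            if ov > best_ov and ov >= min_overlap * (o.end - o.start + 1):
                best_label, best_ov = label, ov
        per_occ.append((o, best_label))
    if skipped:
        warnings.warn(f"{skipped} occurrence(s) skipped: no subdomain coordinates")
    motif_labels: dict[str, str] = {}
    by_motif: dict[str, list[str]] = {}
    for o, lbl in per_occ:
        by_motif.setdefault(o.motif_id, []).append(lbl)
    for m, lbls in by_motif.items():
        motif_labels[m] = max(sorted(set(lbls)), key=lbls.count)
    return motif_labels, per_occ


def associate_motif(
    matrix: pd.DataFrame, trait: dict[str, bool]
) -> pd.DataFrame:
    """Per-motif Fisher exact association between presence and a boolean
    trait (pathogen responsiveness, grain specificity, ...), BH-corrected."""
    missing = sorted(set(matrix.columns) - set(trait))
    if missing:
        raise InputError(f"trait undefined for proteins: {missing[:5]}")
    rows = []
    for m in matrix.index:
        present = matrix.loc[m] == 1
        a = int(sum(1 for c in matrix.columns if present[c] and trait[c]))
        b = int(sum(1 for c in matrix.columns if present[c] and not trait[c]))
        c_ = int(sum(1 for c in matrix.columns if not present[c] and trait[c]))
        d = int(sum(1 for c in matrix.columns if not present[c] and not trait[c]))
        odds, p = stats.fisher_exact([[a, b], [c_, d]], alternative="two-sided")
        rows.append((m, a, b, c_, d, float(odds), float(p)))
    df = pd.DataFrame(
        rows,
        columns=["motif", "present_trait", "present_other",
                 "absent_trait", "absent_other", "odds_ratio", "p"],
    )
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["q"] = []
    return df
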