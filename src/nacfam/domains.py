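"""NAM-domain identification and N-/C-terminal partitioning.

Two routes produce :class:`DomainHit` lists:

* :func:`read_domtbl` parses HMMER3 ``--domtblout`` tables, the format a
  production ``hmmsearch`` run against a proteome emits;
* :func:`build_profile` / :func:`scan_sequence` provide an internal,
  ungapped position-specific log-odds scanner so that the downstream rules
  can be exercised on synthetic proteomes without external binaries.  The
  internal scanner is not a profile HMM: it has no insert/delete states and
  is only meant for desk-scale, indel-free sequence sets.

Proteins retained by :func:`filter_hits` (full-sequence E-value strictly
below 0.01 by default) are partitioned by :func:`split_nt_ct`: the NAM
subdomains A-D define the N-terminal (NT) part and the remainder is the
C-terminal transcriptional activation region (TAR).  All coordinates are
1-based inclusive, following the HMMER convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParseError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    species: str = ""
    confidence: str = "high"

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"protein {self.id}: empty sequence")


@dataclass
class DomainHit:
    protein_id: str
    profile_name: str
    full_seq_evalue: float
    bit_score: float
    domain_index: int
    domain_cond_evalue: float
    env_start: int  # 1-based inclusive
    env_end: int

    def __post_init__(self):
        if not (1 <= self.env_start <= self.env_end):
            raise InputError(
                f"hit on {self.protein_id}: bad envelope {self.env_start}..{self.env_end}"
            )
        if not math.isfinite(self.bit_score):
            raise InputError(f"hit on {self.protein_id}: non-finite bit score")


@dataclass
class NACProtein:
    record: ProteinRecord
    hits: list[DomainHit]
    nt_region: tuple[int, int]
    ct_region: tuple[int, int]  # (start, end); start == end + 1 means empty
    subdomain_coords: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def nt_sequence(self) -> str:
        s, e = self.nt_region
        return self.record.sequence[s - 1 : e]

    @property
    def ct_sequence(self) -> str:
        s, e = self.ct_region
        return self.record.sequence[s - 1 : e]


@dataclass
class Profile:
    """Ungapped position-specific log-odds profile over the 20-letter alphabet."""

    name: str
    scores: np.ndarray  # (width, 20)
    background: np.ndarray  # (20,)
    consensus: str

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    def window_score(self, window: str) -> float:
        """Score one width-length window; unknown letters contribute 0."""
        total = 0.0
        for j, c in enumerate(window):
            i = AA_INDEX.get(c)
            if i is not None:
                total += self.scores[j, i]
        return total


def build_profile(
    aligned_seqs: list[str], pseudocount: float = 1.0, name: str = "NAM"
) -> Profile:
    """Build a log-odds profile from an alignment of domain sequences.

    Columns with >=50% gaps are discarded.  Each retained cell scores
    ``log2(((count + pc) / (n + 20*pc)) / background)`` where ``n`` is the
    number of residues observed in that column and the background is the
    pseudocounted residue frequency over the whole training set.
    """
    if len(aligned_seqs) < 2:
        raise InputError("profile needs at least 2 aligned sequences")
    width0 = len(aligned_seqs[0])
    for s in aligned_seqs:
        if len(s) != width0:
            raise InputError("aligned sequences differ in length")
    seqs = [s.upper() for s in aligned_seqs]

    bg_counts = np.zeros(20)
    for s in seqs:
        for c in s:
            i = AA_INDEX.get(c)
            if i is not None:
                bg_counts[i] += 1
    background = (bg_counts + pseudocount) / (bg_counts.sum() + 20 * pseudocount)

    cols = []
    for j in range(width0):
        column = [s[j] for s in seqs]
        gaps = sum(1 for c in column if c in "-.")
        if gaps / len(column) >= 0.5:
            continue
        counts = np.zeros(20)
        for c in column:
            i = AA_INDEX.get(c)
            if i is not None:
                counts[i] += 1
        n = counts.sum()
        probs = (counts + pseudocount) / (n + 20 * pseudocount)
        cols.append(np.log2(probs / background))
    if not cols:
        raise InputError("no columns survive the gap filter")
    scores = np.vstack(cols)
    consensus = "".join(AMINO_ACIDS[int(i)] for i in scores.argmax(axis=1))
    return Profile(name=name, scores=scores, background=background, consensus=consensus)


def scan_sequence(
    profile: Profile, protein: ProteinRecord, score_threshold: float
) -> list[DomainHit]:
    """Return maximal non-overlapping windows scoring >= threshold.

    Candidate windows are ranked by score (ties to the left-most window) and
    accepted greedily if they do not overlap an already accepted window; the
    result is sorted by position and numbered 1..k.  The reported E-value is
    the desk-scale conversion ``n_windows * 2**-bit_score``.
    """
    seq = protein.sequence.upper()
    w = profile.width
    n_windows = len(seq) - w + 1
    if n_windows < 1:
        return []
    cands = []
    for s in range(n_windows):
        sc = profile.window_score(seq[s : s + w])
        if sc >= score_threshold:
            cands.append((s, sc))
    cands.sort(key=lambda t: (-t[1], t[0]))
    chosen: list[tuple[int, float]] = []
    for s, sc in cands:
        if all(s + w <= cs or s >= cs + w for cs, _ in chosen):
            chosen.append((s, sc))
    chosen.sort()
    hits = []
    for k, (s, sc) in enumerate(chosen, start=1):
        ev = n_windows * 2.0**-sc
        hits.append(
            DomainHit(
                protein_id=protein.id,
                profile_name=profile.name,
                full_seq_evalue=ev,
                bit_score=sc,
                domain_index=k,
                domain_cond_evalue=ev,
                env_start=s + 1,
                env_end=s + w,
            )
        )
    return hits


# HMMER3 --domtblout layout: 22 whitespace-separated columns followed by a
# free-text description; envelope coordinates are columns 20 and 21 (1-based).
_DOMTBL_COLS = 22


def read_domtbl(path) -> list[DomainHit]:
    """Parse a HMMER3 per-domain table (``--domtblout``)."""
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < _DOMTBL_COLS:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= {_DOMTBL_COLS} columns, "
                    f"got {len(parts)}"
                )
            try:
                hits.append(
                    DomainHit(
                        protein_id=parts[0],
                        profile_name=parts[3],
                        full_seq_evalue=float(parts[6]),
                        bit_score=float(parts[13]),
                        domain_index=int(parts[9]),
                        domain_cond_evalue=float(parts[11]),
                        env_start=int(parts[19]),
                        env_end=int(parts[20]),
                    )
                )
            except (ValueError, InputError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_domtbl(hits: list[DomainHit], path, query_name: str = "NAM") -> None:
    """Write hits in the HMMER3 per-domain tabular layout (round-trips read_domtbl)."""
    with open(path, "w") as fh:
        fh.write("# target name Domain table written by nacfam\n")
        for h in hits:
            fields = [
                h.protein_id, "-", "0", h.profile_name, "-", "0",
                f"{h.full_seq_evalue:.3g}", f"{h.bit_score:.1f}", "0.0",
                str(h.domain_index), "1", f"{h.domain_cond_evalue:.3g}",
                f"{h.full_seq_evalue:.3g}", f"{h.bit_score:.1f}", "0.0",
                "1", "0", str(h.env_start), str(h.env_end),
                str(h.env_start), str(h.env_end), "0.90", "-",
            ]
            fh.write(" ".join(fields) + "\n")


def filter_hits(
    hits: list[DomainHit], evalue_cutoff: float = 0.01, per_domain: bool = False
) -> set[str]:
    """Nonredundant protein ids with at least one hit at E strictly below cutoff.

    By default the full-sequence E-value is used; ``per_domain=True`` switches
    to the conditional per-domain E-value.
    """
    retained = set()
    for h in hits:
        e = h.domain_cond_evalue if per_domain else h.full_seq_evalue
        if e < evalue_cutoff:
            retained.add(h.protein_id)
    return retained


def split_nt_ct(
    protein: ProteinRecord,
    hits: list[DomainHit],
    boundary: str = "last",
    subdomain_anchors: dict[str, str] | None = None,
) -> NACProtein:
    """Partition a protein into NT (NAM subdomains A-D) and CT (TAR) regions.

    The NT region runs from residue 1 to the envelope end of the last
    (default) or first qualifying domain; the CT region is the remainder and
    may be empty.  If ``subdomain_anchors`` maps subdomain labels to anchor
    motif strings, their exact occurrences locate the subdomain coordinates.
    """
    if not hits:
        raise InputError(f"protein {protein.id}: no domain hits to split on")
    length = len(protein.sequence)
    shits = sorted(hits, key=lambda h: h.env_start)
    for h in shits:
        if h.env_end > length:
            raise InputError(
                f"protein {protein.id}: envelope {h.env_start}..{h.env_end} "
                f"exceeds sequence length {length}"
            )
    if boundary not in {"last", "first"}:
        raise InputError(f"unknown NT/CT boundary rule '{boundary}'")
    ref = shits[-1] if boundary == "last" else shits[0]
    nt = (1, ref.env_end)
    ct = (ref.env_end + 1, length)  # empty when env_end == length
    coords: dict[str, tuple[int, int]] = {}
    if subdomain_anchors:
        for label, motif in subdomain_anchors.items():
            pos = protein.sequence.find(motif)
            if pos >= 0:
                coords[label] = (pos + 1, pos + len(motif))
    return NACProtein(
        record=protein, hits=shits, nt_region=nt, ct_region=ct,
        subdomain_coords=coords,
    )


def read_subdomain_coords(path) -> dict[str, dict[str, tuple[int, int]]]:
    """Read an annotation TSV (protein_id, subdomain, start, end) -> nested map."""
    out: dict[str, dict[str, tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#") or (
                lineno == 1 and line.lower().startswith("protein")
            ):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            pid, label, s, e = parts[:4]
            out.setdefault(pid, {})[label] = (int(s), int(e))
    return out
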