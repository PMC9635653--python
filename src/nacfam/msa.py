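"""Alignment completeness scoring and pre-tree filtering.

Completeness follows the AliStat conventions: a site is *missing* in a row
if it is a gap (``-``) or an ambiguous residue (``X``).  The report carries

* ``Ca`` - overall completeness (non-missing cells / all cells),
* ``Cr`` - per-row completeness,
* ``Cc`` - per-column completeness,
* ``Cij`` - for every pair of rows, the fraction of alignment sites at which
  both rows are non-missing (denominator = total alignment length).

Filtering removes rows whose best ``Cij`` against any partner falls below a
cutoff (default 0.5); masking drops columns with ``Cc`` below a cutoff
(default 0.6); deduplication collapses byte-identical rows, keeping the
lexicographically smallest identifier as representative so that surplus
identifiers can be re-attached after tree inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError

MISSING = {"-", "X", "x", "."}


@dataclass
class AlignmentMatrix:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise InputError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("duplicate sequence ids in alignment")
        if self.rows:
            n = len(self.rows[0])
            for i, r in enumerate(self.rows):
                if len(r) != n:
                    raise InputError(
                        f"ragged alignment: row '{self.ids[i]}' has length "
                        f"{len(r)}, expected {n}"
                    )

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def presence(self) -> np.ndarray:
        """Boolean matrix, True where a cell holds an unambiguous residue."""
        return np.array(
            [[c not in MISSING for c in row] for row in self.rows], dtype=bool
        )


@dataclass
class CompletenessReport:
    Ca: float
    Cr: np.ndarray
    Cc: np.ndarray
    Cij: np.ndarray
    ids: list[str] = field(default_factory=list)


def read_fasta_alignment(path) -> AlignmentMatrix:
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise InputError(f"no sequences in {path}")
    return AlignmentMatrix([r.id for r in recs], [str(r.seq).upper() for r in recs])


def write_fasta_alignment(msa: AlignmentMatrix, path) -> None:
    recs = [SeqRecord(Seq(row), id=i, description="") for i, row in zip(msa.ids, msa.rows)]
    SeqIO.write(recs, str(path), "fasta")


def completeness(msa: AlignmentMatrix) -> CompletenessReport:
    """Compute Ca / Cr / Cc and the pairwise shared-site matrix Cij."""
    if msa.n_rows == 0 or msa.n_sites == 0:
        raise InputError("empty alignment")
    p = msa.presence()
    n_sites = msa.n_sites
    cr = p.mean(axis=1)
    cc = p.mean(axis=0)
    ca = float(p.mean())
    pf = p.astype(float)
    cij = (pf @ pf.T) / n_sites
    return CompletenessReport(Ca=ca, Cr=cr, Cc=cc, Cij=cij, ids=list(msa.ids))


def filter_sequences(
    msa: AlignmentMatrix, report: CompletenessReport, cij_cutoff: float = 0.5
) -> tuple[AlignmentMatrix, list[str]]:
    """Drop rows that share fewer than ``cij_cutoff`` of sites with every partner."""
    n = msa.n_rows
    removed: list[str] = []
    keep_idx: list[int] = []
    for i in range(n):
        partners = [report.Cij[i, j] for j in range(n) if j != i]
        best = max(partners) if partners else 1.0
        if best < cij_cutoff:
            removed.append(msa.ids[i])
        else:
            keep_idx.append(i)
    kept = AlignmentMatrix(
        [msa.ids[i] for i in keep_idx], [msa.rows[i] for i in keep_idx]
    )
    return kept, removed


def mask_columns(
    msa: AlignmentMatrix, report: CompletenessReport, cc_cutoff: float = 0.6
) -> AlignmentMatrix:
    """Remove columns with completeness below ``cc_cutoff``, preserving order."""
    keep = [j for j in range(msa.n_sites) if report.Cc[j] >= cc_cutoff]
    rows = ["".join(row[j] for j in keep) for row in msa.rows]
    return AlignmentMatrix(list(msa.ids), rows)


def dedup(msa: AlignmentMatrix) -> tuple[AlignmentMatrix, dict[str, list[str]]]:
    """Collapse identical rows; representative is the smallest id.

    Returns the reduced alignment and a surplus map
    ``representative id -> identical ids`` that allows re-attachment of the
    removed identifiers next to their twin after tree inference.
    """
    by_seq: dict[str, list[str]] = {}
    for i, row in zip(msa.ids, msa.rows):
        by_seq.setdefault(row, []).append(i)
    ids, rows = [], []
    surplus: dict[str, list[str]] = {}
    originals = {i: r for i, r in zip(msa.ids, msa.rows)}
    for row, members in by_seq.items():
        rep = min(members)
        ids.append(rep)
        rows.append(row)
        if len(members) > 1:
            surplus[rep] = sorted(m for m in members if m != rep)
    order = sorted(range(len(ids)), key=lambda k: msa.ids.index(ids[k]))
    out = AlignmentMatrix([ids[k] for k in order], [rows[k] for k in order])
    # sanity: re-attachment must restore the original id set
    restored = set(out.ids) | {m for v in surplus.values() for m in v}
    assert restored == set(originals)
    return out, surplus


def reattach(ids: list[str], surplus: dict[str, list[str]]) -> list[str]:
    """Expand a deduplicated id list back to the full id set, twins adjacent."""
    out: list[str] = []
    for i in ids:
        out.append(i)
        out.extend(surplus.get(i, []))
    return out
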