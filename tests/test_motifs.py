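"""Motif IO, presence matrices, specificity classes, subdomain mapping."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from nacfam.domains import DomainHit, NACProtein, ProteinRecord
from nacfam.errors import InputError, ParseError
from nacfam.motifs import (
    MotifOccurrence,
    associate_motif,
    classify_motifs,
    map_to_subdomains,
    presence_matrix,
    read_meme,
    scan_planted_motifs,
    write_meme_text,
)

MEME_XML = """<?xml version="1.0"?>
<MEME version="5.0.5">
 <training_set>
  <sequence id="sequence_0" name="p1" length="200"/>
  <sequence id="sequence_1" name="p2" length="200"/>
 </training_set>
 <motifs>
  <motif id="motif_1" name="NT-1" width="8">
   <contributing_sites>
    <contributing_site sequence_id="sequence_0" position="10" pvalue="1e-9"/>
    <contributing_site sequence_id="sequence_1" position="12" pvalue="2e-8"/>
   </contributing_sites>
  </motif>
  <motif id="motif_2" name="NT-2" width="6">
   <contributing_sites>
    <contributing_site sequence_id="sequence_0" position="40" pvalue="1e-5"/>
   </contributing_sites>
  </motif>
 </motifs>
</MEME>
"""


class TestReadMeme:
    def test_xml_sites_parsed_with_one_based_coordinates(self, tmp_path):
        path = tmp_path / "meme.xml"
        path.write_text(MEME_XML)
        occs = read_meme(path, region="NT")
        assert len(occs) == 3
        first = next(o for o in occs if o.protein_id == "p1" and o.motif_id == "NT-1")
        assert (first.start, first.end) == (11, 18)  # XML position 10 is 0-based

    def test_text_round_trip(self, tmp_path):
        occs = [
            MotifOccurrence("CT-1", "p1", "CT", 5, 14, 1.0),
            MotifOccurrence("CT-1", "p2", "CT", 9, 18, 1.0),
            MotifOccurrence("CT-2", "p1", "CT", 30, 39, 1.0),
        ]
        path = tmp_path / "motifs.txt"
        write_meme_text(occs, {"CT-1": 10, "CT-2": 10}, path)
        got = read_meme(path, region="CT")
        assert sorted(got, key=lambda o: (o.motif_id, o.protein_id)) == sorted(
            occs, key=lambda o: (o.motif_id, o.protein_id)
        )

    def test_ct_zero_or_one_contract(self, tmp_path):
        occs = [MotifOccurrence("CT-1", "p1", "CT", 5, 14, 1.0),
                MotifOccurrence("CT-1", "p1", "CT", 30, 39, 1.0)]
        path = tmp_path / "motifs.txt"
        write_meme_text(occs, {"CT-1": 10}, path)
        with pytest.warns(UserWarning, match=">1 site"):
            read_meme(path, region="CT")
        with pytest.raises(ParseError):
            read_meme(path, region="CT", strict=True)

    def test_malformed_header_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("MOTIF broken\n")
        with pytest.raises(ParseError, match="line 1"):
            read_meme(path, region="NT")


class TestPresenceMatrix:
    def test_repeated_sites_collapse_to_one(self):
        occs = [MotifOccurrence("m1", "p1", "NT", i, i + 4) for i in (1, 10, 20)]
        mat = presence_matrix(occs, ["p1", "p2"])
        assert mat.loc["m1", "p1"] == 1
        assert mat.loc["m1", "p2"] == 0

    def test_motif_without_sites_keeps_zero_row(self):
        mat = presence_matrix([], ["p1"], motifs=["m1"])
        assert list(mat.loc["m1"]) == [0]

    def test_row_sums_equal_distinct_protein_counts(self):
        rng = np.random.default_rng(3)
        proteins = [f"p{i}" for i in range(10)]
        occs = []
        for m in ("m1", "m2", "m3"):
            for p in rng.choice(proteins, size=rng.integers(1, 8), replace=False):
                for _ in range(int(rng.integers(1, 3))):
                    s = int(rng.integers(1, 50))
                    occs.append(MotifOccurrence(m, str(p), "NT", s, s + 5))
        mat = presence_matrix(occs, proteins)
        for m in ("m1", "m2", "m3"):
            distinct = len({o.protein_id for o in occs if o.motif_id == m})
            assert mat.loc[m].sum() == distinct

    def test_unknown_protein_rejected(self):
        with pytest.raises(InputError):
            presence_matrix([MotifOccurrence("m1", "px", "NT", 1, 5)], ["p1"])


class TestClassify:
    def _matrix(self, fractions, n=100):
        """One subfamily per key with n members at the given presence."""
        cols, data = [], {}
        assignment = {}
        for sf, frac in fractions.items():
            for i in range(n):
                c = f"{sf}{i}"
                cols.append(c)
                assignment[c] = sf
                data[c] = 1 if i < round(frac * n) else 0
        mat = pd.DataFrame([data], index=["m"])[cols]
        return mat, assignment

    def test_signature_above_90(self):
        mat, assignment = self._matrix({"h": 0.98, "a": 0.5})
        s = classify_motifs(mat, assignment)
        assert s.classes.loc["m", "h"] == "signature"
        assert s.classes.loc["m", "a"] == "present"

    def test_boundaries_fall_in_present_class(self):
        mat, assignment = self._matrix({"x": 0.9, "y": 0.1, "z": 0.05})
        s = classify_motifs(mat, assignment)
        assert s.classes.loc["m", "x"] == "present"
        assert s.classes.loc["m", "y"] == "present"
        assert s.classes.loc["m", "z"] == "absent"

    def test_conserved_above_half_overall(self):
        mat, assignment = self._matrix({"a": 0.55, "b": 0.56})
        s = classify_motifs(mat, assignment)
        assert s.conserved["m"]
        mat2, assignment2 = self._matrix({"a": 0.4, "b": 0.4})
        assert not classify_motifs(mat2, assignment2).conserved["m"]

    def test_specific_to_single_subfamily(self):
        mat, assignment = self._matrix({"d": 0.3, "a": 0.05, "b": 0.0})
        s = classify_motifs(mat, assignment)
        assert s.specific_to["m"] == "d"
        mat2, assignment2 = self._matrix({"d": 0.3, "a": 0.15})
        assert classify_motifs(mat2, assignment2).specific_to["m"] is None


def _nac(pid, seq, coords):
    rec = ProteinRecord(id=pid, sequence=seq)
    hit = DomainHit(pid, "NAM", 1e-9, 100.0, 1, 1e-9, 1, 60)
    return NACProtein(record=rec, hits=[hit], nt_region=(1, 60),
                      ct_region=(61, len(seq)), subdomain_coords=coords)


class TestSubdomains:
    def test_motif_spanning_subdomain_takes_its_label(self):
        nac = _nac("p1", "A" * 100, {"B": (20, 29), "C": (40, 49)})
        occs = [MotifOccurrence("m1", "p1", "NT", 20, 29)]
        labels, _ = map_to_subdomains(occs, {"p1": nac})
        assert labels["m1"] == "B"

    def test_motif_between_subdomains(self):
        nac = _nac("p1", "A" * 100, {"B": (10, 19), "C": (40, 49)})
        occs = [MotifOccurrence("m1", "p1", "NT", 25, 34)]
        labels, _ = map_to_subdomains(occs, {"p1": nac})
        assert labels["m1"] == "between-subdomain"

    def test_majority_vote_matches_recount(self):
        coords = {"B": (20, 29)}
        nacs = {f"p{i}": _nac(f"p{i}", "A" * 100, coords) for i in range(10)}
        occs = [MotifOccurrence("m1", f"p{i}", "NT", 20, 29) for i in range(6)]
        occs += [MotifOccurrence("m1", f"p{i}", "NT", 31, 38) for i in range(6, 10)]
        labels, per_occ = map_to_subdomains(occs, nacs)
        votes = [lbl for _, lbl in per_occ]
        assert labels["m1"] == max(sorted(set(votes)), key=votes.count) == "B"

    def test_missing_coordinates_skipped_with_warning(self):
        nac = _nac("p1", "A" * 100, {})
        with pytest.warns(UserWarning, match="skipped"):
            labels, per = map_to_subdomains(
                [MotifOccurrence("m1", "p1", "NT", 5, 9)], {"p1": nac}
            )
        assert labels == {} and per == []


class TestAssociation:
    def test_perfect_association_matches_hypergeometric(self):
        proteins = [f"p{i}" for i in range(20)]
        trait = {p: i < 10 for i, p in enumerate(proteins)}
        occs = [MotifOccurrence("m1", p, "CT", 1, 5) for p in proteins[:10]]
        mat = presence_matrix(occs, proteins)
        df = associate_motif(mat, trait).set_index("motif")
        # P(all 10 present proteins are exactly the 10 trait-positives)
        expected = 2 / comb(20, 10)  # two-sided doubles the single extreme table
        assert df.loc["m1", "p"] == pytest.approx(expected)

    def test_ubiquitous_motif_gives_p_one(self):
        proteins = [f"p{i}" for i in range(10)]
        trait = {p: i < 5 for i, p in enumerate(proteins)}
        occs = [MotifOccurrence("m1", p, "CT", 1, 5) for p in proteins]
        df = associate_motif(presence_matrix(occs, proteins), trait).set_index("motif")
        assert df.loc["m1", "p"] == 1.0

    def test_planted_association_recovered_across_seeds(self):
        recovered = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            proteins = [f"p{i}" for i in range(120)]
            trait = {p: bool(rng.random() < 0.4) for p in proteins}
            occs = []
            for p in proteins:
                pr = 0.9 if trait[p] else 0.05
                if rng.random() < pr:
                    occs.append(MotifOccurrence("linked", p, "CT", 1, 10))
                if rng.random() < 0.5:
                    occs.append(MotifOccurrence("null", p, "CT", 20, 29))
            mat = presence_matrix(occs, proteins, motifs=["linked", "null"])
            df = associate_motif(mat, trait).set_index("motif")
            recovered += int(df.loc["linked", "q"] < 0.05)
        assert recovered / 20 >= 0.95


def test_planted_scanner_matches_generator_truth(small_family):
    from nacfam.domains import split_nt_ct
    from nacfam.simulate import NAM_REGION, SUBDOMAIN_ANCHORS, planted_motif_strings

    nacs = {}
    for g in small_family.family_ids:
        seq = small_family.sequences[g]
        rec = ProteinRecord(id=g, sequence=seq)
        hit = DomainHit(g, "NAM", 1e-9, 100.0, 1, 1e-9, NAM_REGION[0], NAM_REGION[1])
        nacs[g] = split_nt_ct(rec, [hit], subdomain_anchors=SUBDOMAIN_ANCHORS)
    occs = scan_planted_motifs(nacs, planted_motif_strings())
    carried = {}
    for o in occs:
        carried.setdefault(o.protein_id, set()).add(o.motif_id)
    for g, t in small_family.truth.items():
        planted_ct = {m for m in t.planted_motifs if m.startswith("CT")}
        assert {m for m in carried.get(g, set()) if m.startswith("CT")} == planted_ct
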