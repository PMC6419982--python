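import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pairtax as pt
from pairtax.iupac import PRIMER_515F, PRIMER_806R, expand, reverse_complement
from pairtax.otu import OTURecord
from pairtax.taxonomy import (
    DEFAULT_LEVELS,
    Assignment,
    HitProfile,
    ReferenceEntry,
    combined_identity,
    consensus_label,
    identity,
    load_references,
    search_hits,
    specificity,
    trim_database,
    trim_reference,
)

from conftest import levenshtein, random_dna


def lineage(genus="GenusX", family="FamilyX"):
    return ("Bacteria", "P", "C", "O", family, genus)


class TestTrimReference:
    def test_synthetic_construction(self):
        rng = random.Random(1)
        insert = random_dna(rng, 253)
        seq = (
            random_dna(rng, 50)
            + expand(PRIMER_515F)
            + insert
            + reverse_complement(expand(PRIMER_806R))
            + random_dna(rng, 50)
        )
        entry = ReferenceEntry("X", seq, lineage())
        t = trim_reference(entry, PRIMER_515F, PRIMER_806R, read_len=70)
        assert t is not None
        assert t.fwd_frag == insert[:70]
        assert t.rev_frag == insert[-70:]

    def test_missing_reverse_primer_site_rejected(self):
        rng = random.Random(2)
        seq = random_dna(rng, 50) + expand(PRIMER_515F) + random_dna(rng, 253)
        assert trim_reference(ReferenceEntry("X", seq, lineage()), PRIMER_515F,
                              PRIMER_806R) is None

    def test_short_interprimer_region_rejected(self):
        rng = random.Random(3)
        seq = (
            expand(PRIMER_515F)
            + random_dna(rng, 40)
            + reverse_complement(expand(PRIMER_806R))
        )
        assert trim_reference(ReferenceEntry("X", seq, lineage()), PRIMER_515F,
                              PRIMER_806R, read_len=70) is None

    def test_one_primer_mismatch_tolerated(self):
        rng = random.Random(4)
        insert = random_dna(rng, 200)
        fwd = expand(PRIMER_515F)
        fwd = ("C" if fwd[0] != "C" else "A") + fwd[1:]
        seq = fwd + insert + reverse_complement(expand(PRIMER_806R))
        t = trim_reference(ReferenceEntry("X", seq, lineage()), PRIMER_515F, PRIMER_806R)
        assert t is not None and t.fwd_frag == insert[:70]

    def test_simulator_templates_all_trim_to_truth(self, refs17, mc1_sim):
        _, _, truth = mc1_sim
        for ref in refs17:
            t = trim_reference(ref, PRIMER_515F, PRIMER_806R, 70)
            assert t is not None
            assert t.fwd_frag == truth.templates[ref.accession].fwd_frag
            assert t.rev_frag == truth.templates[ref.accession].rev_frag


class TestIdentity:
    def test_identical_sequences(self):
        assert identity("A" * 70, "A" * 70) == 1.0

    def test_single_substitution_70mer(self):
        a = "A" * 70
        b = "A" * 35 + "G" + "A" * 34
        assert identity(a, b) == pytest.approx(69 / 70)

    def test_symmetry_and_dp_oracle(self):
        rng = random.Random(99)
        for _ in range(200):
            a = random_dna(rng, rng.randint(1, 30))
            b = random_dna(rng, rng.randint(1, 30))
            expected = 1 - levenshtein(a, b) / max(len(a), len(b))
            assert identity(a, b) == pytest.approx(expected)
            assert identity(a, b) == pytest.approx(identity(b, a))


def make_db(n=6, seed=5, read_len=30):
    rng = random.Random(seed)
    db = []
    for i in range(n):
        db.append(
            pt.TrimmedReference(
                accession=f"R{i}",
                fwd_frag=random_dna(rng, read_len),
                rev_frag=random_dna(rng, read_len),
                lineage=lineage(genus=f"G{i}", family=f"F{i % 3}"),
            )
        )
    return db


class TestSearchHits:
    def test_exact_match_hits_at_full_identity(self, refs17):
        db, _ = trim_database(refs17, PRIMER_515F, PRIMER_806R, 70)
        ref = db[0]
        otu = OTURecord("o", ref.fwd_frag, reverse_complement(ref.rev_frag), 10)
        profile = search_hits(otu, db)
        assert [h[0] for h in profile.hits[1.00]] == [ref.accession]

    def test_two_substitutions_drop_below_full_identity(self, refs17):
        db, _ = trim_database(refs17, PRIMER_515F, PRIMER_806R, 70)
        ref = db[0]
        fwd = "G" + ref.fwd_frag[1:] if ref.fwd_frag[0] != "G" else "T" + ref.fwd_frag[1:]
        rev = reverse_complement(ref.rev_frag)
        rev = ("G" if rev[0] != "G" else "T") + rev[1:]
        otu = OTURecord("o", fwd, rev, 10)
        profile = search_hits(otu, db)
        accs_100 = [h[0] for h in profile.hits[1.00]]
        accs_98 = [h[0] for h in profile.hits[0.98]]
        assert ref.accession not in accs_100
        assert ref.accession in accs_98  # 138/140 ≈ 0.986

    def test_nesting_invariant_and_brute_force(self):
        rng = random.Random(11)
        db = make_db(20, seed=11)
        otu = OTURecord("o", random_dna(rng, 30), random_dna(rng, 30), 5)
        # lenient levels so random sequences produce hits
        levels = (0.9, 0.7, 0.5, 0.3)
        profile = search_hits(otu, db, levels=levels)
        for hi, lo in zip(levels, levels[1:]):
            assert {h[0] for h in profile.hits[hi]} <= {h[0] for h in profile.hits[lo]}
        for t in levels:
            expected = {
                r.accession for r in db if combined_identity(otu, r) >= t
            }
            assert {h[0] for h in profile.hits[t]} == expected


class TestSpecificity:
    def hit(self, genus, family="F"):
        return ("acc", 1.0, ("B", "P", "C", "O", family, genus))

    def test_unanimous(self):
        modal, pct, n = specificity([self.hit("G")] * 10, "genus")
        assert (modal, pct, n) == ("G", 100.0, 10)

    def test_majority(self):
        hits = [self.hit("G")] * 8 + [self.hit("H")] * 2
        assert specificity(hits, "genus") == ("G", 80.0, 10)

    def test_empty_labels_excluded_from_both_sides(self):
        hits = [self.hit("G")] * 3 + [self.hit("")] * 2
        modal, pct, n = specificity(hits, "genus")
        assert (modal, pct, n) == ("G", 100.0, 3)

    def test_no_labels(self):
        assert specificity([self.hit("")], "genus") == ("", 0.0, 0)

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_counting_oracle(self, seed):
        rng = random.Random(seed)
        labels = [rng.choice(["G1", "G2", "G3", ""]) for _ in range(rng.randint(1, 40))]
        hits = [self.hit(lab) for lab in labels]
        modal, pct, n = specificity(hits, "genus")
        present = [l for l in labels if l]
        if not present:
            assert (modal, pct, n) == ("", 0.0, 0)
        else:
            counts = {l: present.count(l) for l in set(present)}
            best = min(counts, key=lambda k: (-counts[k], k))
            assert modal == best
            assert n == len(present)
            assert pct == pytest.approx(100 * counts[best] / len(present))


def profile_from(levels_hits):
    """Build a HitProfile from {level: [(genus, family), ...]}."""
    levels = tuple(sorted(levels_hits, reverse=True))
    hits = {
        t: [
            (f"a{t}{i}", t, ("B", "P", "C", "O", fam, gen))
            for i, (gen, fam) in enumerate(levels_hits[t])
        ]
        for t in levels_hits
    }
    return HitProfile(levels=levels, hits=hits)


class TestConsensusLabel:
    def test_unanimous_genus(self):
        p = profile_from({
            1.00: [("G", "F")],
            0.98: [("G", "F"), ("G", "F")],
            0.90: [("G", "F")] * 5,
        })
        a = consensus_label(p, "o1")
        assert a.assigned_rank == "genus"
        assert a.lineage[5] == "G" and a.specificity == 100.0

    def test_discordant_genus_falls_back_to_family(self):
        p = profile_from({
            1.00: [("G", "F")],
            0.90: [("H", "F"), ("H", "F"), ("G", "F")],
        })
        a = consensus_label(p, "o1")
        assert a.assigned_rank == "family"
        assert a.lineage[4] == "F" and a.lineage[5] == ""

    def test_two_families_fall_back_to_shared_prefix(self):
        p = profile_from({
            1.00: [("G1", "F1"), ("G2", "F2")],
            0.90: [("G1", "F1"), ("G2", "F2"), ("G2", "F2")],
        })
        a = consensus_label(p, "o1")
        assert a.assigned_rank == "order"
        assert a.lineage == ("B", "P", "C", "O", "", "")

    def test_low_specificity_genus_rejected(self):
        p = profile_from({1.00: [("G", "F"), ("H", "F"), ("I", "F")]})
        a = consensus_label(p, "o1", min_spec=50.0)
        assert a.assigned_rank == "family"

    def test_empty_profile_unassigned(self):
        p = profile_from({1.00: [], 0.90: []})
        a = consensus_label(p, "o1")
        assert a.assigned_rank == "unassigned"
        assert a.lineage == ("", "", "", "", "", "")


class TestSelfClassification:
    def test_every_reference_recovers_its_own_genus(self, refs17):
        db, rejected = trim_database(refs17, PRIMER_515F, PRIMER_806R, 70)
        assert rejected == 0
        for ref in db:
            otu = OTURecord("o", ref.fwd_frag, reverse_complement(ref.rev_frag), 10)
            a = consensus_label(search_hits(otu, db), "o")
            assert a.assigned_rank == "genus"
            assert a.lineage[5] == ref.lineage[5]
            assert a.specificity == 100.0

    def test_db_order_does_not_change_assignment(self, refs17):
        db, _ = trim_database(refs17, PRIMER_515F, PRIMER_806R, 70)
        ref = db[3]
        otu = OTURecord("o", ref.fwd_frag, reverse_complement(ref.rev_frag), 10)
        a1 = consensus_label(search_hits(otu, db), "o")
        a2 = consensus_label(search_hits(otu, db[::-1]), "o")
        assert (a1.lineage, a1.assigned_rank) == (a2.lineage, a2.assigned_rank)

    def test_two_substitutions_never_change_family(self, refs17):
        rng = random.Random(17)
        db, _ = trim_database(refs17, PRIMER_515F, PRIMER_806R, 70)
        for ref in db[:5]:
            fwd = list(ref.fwd_frag)
            rev = list(reverse_complement(ref.rev_frag))
            for target in (fwd, rev):
                i = rng.randrange(70)
                target[i] = rng.choice([b for b in "ACGT" if b != target[i]])
            otu = OTURecord("o", "".join(fwd), "".join(rev), 10)
            a = consensus_label(search_hits(otu, db), "o")
            assert a.lineage[4] == ref.lineage[4]


def test_load_references_roundtrip(tmp_path, refs17):
    fasta = tmp_path / "refs.fasta"
    tsv = tmp_path / "lineage.tsv"
    with open(fasta, "w") as fh:
        for r in refs17:
            fh.write(f">{r.accession}\n{r.seq}\n")
    with open(tsv, "w") as fh:
        for r in refs17:
            fh.write(f"{r.accession}\t{';'.join(r.lineage)}\n")
    loaded = load_references(fasta, tsv)
    assert loaded == list(refs17)


def test_load_references_header_lineage_and_u_to_t(tmp_path):
    fasta = tmp_path / "refs.fasta"
    fasta.write_text(">acc1 Bacteria;P;C;O;F;G\nACGU-ACGU\n")
    (entry,) = load_references(fasta)
    assert entry.seq == "ACGTACGT"
    assert entry.lineage == ("Bacteria", "P", "C", "O", "F", "G")
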