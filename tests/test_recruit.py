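"""Read recruitment: complexity screen, exact alignment, filters, miTags."""

import numpy as np
import pytest

from helpers_oracle import best_strand_oracle, kmer_census_oracle, sw_oracle
from phytomark import (
    Read,
    RecruitmentParams,
    ValidationError,
    align_read,
    classify_ribotag,
    complexity_pass,
    recruit,
)
from phytomark.markers import MarkerRecord, ReferenceDatabase
from phytomark.recruit import read_reads
from phytomark._sw import revcomp
from phytomark.taxonomy import TaxonomyPath


def _rec(rid, seq, gene="psbO", group="diatoms", ranks=("Eukaryota", "Bacillariophyta")):
    return MarkerRecord(rid, gene, TaxonomyPath(tuple(ranks), group), seq)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestComplexity:
    params = RecruitmentParams()

    def test_homopolymer_fails(self):
        ok, reason = complexity_pass(Read("r", "A" * 100), self.params)
        assert not ok and reason == "low_complexity"

    def test_short_repeat_fails(self):
        ok, _ = complexity_pass(Read("r", "ACGT" * 25), self.params)
        assert not ok  # only 4 distinct 3-mers < 30

    def test_random_read_passes_and_census_matches_enumeration(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(rng, 100)
        ok, _ = complexity_pass(Read("r", seq), self.params)
        census = kmer_census_oracle(seq, 3)
        assert len(census) >= 30
        assert max(census.values()) * 100 < 75 * sum(census.values())
        assert ok

    def test_too_short_for_kmers(self):
        ok, reason = complexity_pass(Read("r", "AC"), self.params)
        assert not ok and reason == "too_short_for_complexity"


class TestAlignRead:
    def test_exact_substring(self, rng):
        ref = _rec("ref1", _random_seq(rng, 400))
        read = Read("r", ref.sequence[137:237])
        hit = align_read(read, ref)
        assert hit.identity == 100.0
        assert hit.aligned_read_fraction == 100.0
        assert (hit.ref_start, hit.ref_end) == (137, 237)
        assert hit.strand == "+"
        assert hit.score == 100

    def test_reverse_complement_symmetry(self, rng):
        ref = _rec("ref1", _random_seq(rng, 400))
        fwd = Read("r", ref.sequence[50:150])
        rev = Read("r", revcomp(ref.sequence[50:150]))
        h_f, h_r = align_read(fwd, ref), align_read(rev, ref)
        assert h_r.strand == "-"
        assert (h_r.identity, h_r.aligned_read_fraction) == (h_f.identity, h_f.aligned_read_fraction)
        assert (h_r.ref_start, h_r.ref_end) == (h_f.ref_start, h_f.ref_end)

    def test_point_mutations_match_brute_force(self, rng):
        ref = _rec("ref1", _random_seq(rng, 300))
        frag = list(ref.sequence[100:200])
        for p in rng.choice(100, size=25, replace=False):
            frag[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[p]]
        read = Read("r", "".join(frag))
        hit = align_read(read, ref)
        (score, i0, i1, j0, j1, matches, cols), strand = best_strand_oracle(
            read.sequence, ref.sequence
        )
        assert hit.score == score
        assert hit.identity == pytest.approx(100.0 * matches / cols)
        assert (hit.ref_start, hit.ref_end, hit.strand) == (j0, j1, strand)

    @pytest.mark.parametrize("trial", range(30))
    def test_oracle_equivalence_random_pairs(self, trial):
        """Exact agreement with an independent Smith-Waterman DP."""
        rng = np.random.default_rng(1000 + trial)
        read = Read("r", _random_seq(rng, int(rng.integers(60, 140))))
        ref = _rec("ref1", _random_seq(rng, int(rng.integers(150, 500))))
        hit = align_read(read, ref)
        (score, i0, i1, j0, j1, matches, cols), strand = best_strand_oracle(
            read.sequence, ref.sequence
        )
        if score == 0:
            assert hit is None
        else:
            assert (hit.score, hit.ref_start, hit.ref_end, hit.strand) == (
                score, j0, j1, strand,
            )
            assert hit.identity == pytest.approx(100.0 * matches / cols)
            assert hit.aligned_read_fraction == pytest.approx(
                100.0 * (i1 - i0) / read.length_bp
            )


class TestRecruit:
    def _db_of(self, rng, n_refs=5, length=400):
        return ReferenceDatabase(
            gene="psbO",
            records=[_rec(f"ref{i}", _random_seq(rng, length)) for i in range(n_refs)],
        )

    def test_too_short_read_rejected(self, rng):
        db = self._db_of(rng)
        read = Read("r", db.records[0].sequence[:69])  # perfect but 69 nt
        result = recruit([read], db)
        assert result.rejected == {"r": "too_short"}
        assert result.hits == []

    def test_provenance_recovery_error_free(self):
        """Error-free reads recruit to their source reference (nearest-
        reference brute force is trivial at zero errors)."""
        rng = np.random.default_rng(7)
        db = self._db_of(rng, n_refs=5)
        reads, sources = [], []
        for i in range(200):
            src = db.records[int(rng.integers(5))]
            start = int(rng.integers(0, 300))
            seq = src.sequence[start : start + 100]
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(Read(f"r{i}", seq))
            sources.append(src.record_id)
        result = recruit(reads, db)
        assert len(result.hits) == 200
        assigned = {h.read_id: h.reference_id for h in result.hits}
        assert all(assigned[f"r{i}"] == sources[i] for i in range(200))

    def test_prescreen_equals_exhaustive_best_hit(self):
        """The q-gram prescreen must not change any best hit (soundness of
        the skip bound), including for off-target and noisy reads."""
        from phytomark.recruit import _best_hit, _kmer_codes
        from phytomark._sw import encode_nt

        rng = np.random.default_rng(42)
        db = self._db_of(rng, n_refs=4, length=300)
        params = RecruitmentParams()
        entries = []
        for rec in db.records:
            codes = encode_nt(rec.sequence)
            entries.append((rec, codes, np.unique(_kmer_codes(codes))))
        for i in range(60):
            kind = i % 3
            if kind == 0:  # on-target with errors
                src = db.records[int(rng.integers(4))]
                s = list(src.sequence[int(rng.integers(0, 200)) :][:100])
                for p in rng.choice(100, size=int(rng.integers(0, 15)), replace=False):
                    s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
                seq = "".join(s)
            elif kind == 1:  # random (off-target)
                seq = _random_seq(rng, 100)
            else:  # chimeric half-match
                src = db.records[int(rng.integers(4))]
                seq = src.sequence[:50] + _random_seq(rng, 50)
            read = Read(f"r{i}", seq)
            fast = _best_hit(read, entries, params)
            # exhaustive: no prescreen, every (reference, strand) pair via
            # the DP oracle, ranked by the documented pooled tie-break
            # (score, identity, reference span, reference id, strand)
            from helpers_oracle import revcomp_oracle

            best = None
            for rec in db.records:
                for strand, seq in (("+", read.sequence), ("-", revcomp_oracle(read.sequence))):
                    score, i0, i1, j0, j1, matches, cols = sw_oracle(seq, rec.sequence)
                    if score <= 0:
                        continue
                    key = (-score, -matches / cols, -(j1 - j0), rec.record_id, strand)
                    if best is None or key < best[0]:
                        best = (key, rec.record_id, score)
            if best is None:
                assert fast is None
            else:
                assert (fast.reference_id, fast.score) == (best[1], best[2])

    def test_identity_threshold_boundary(self, rng):
        """79.9% identity is rejected, exactly 80.0% is recruited."""
        ref = _rec("ref1", _random_seq(rng, 1500))
        base = ref.sequence[100:1100]  # 1000 nt read

        def with_mismatches(n):
            s = list(base)
            step = len(s) / n
            for k in range(n):
                p = int(k * step + step / 2)
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s)

        db = ReferenceDatabase(gene="psbO", records=[ref])
        res_pass = recruit([Read("r80", with_mismatches(200))], db)
        assert [h.read_id for h in res_pass.hits] == ["r80"]
        assert res_pass.hits[0].identity == pytest.approx(80.0)
        res_fail = recruit([Read("r799", with_mismatches(201))], db)
        assert res_fail.rejected == {"r799": "low_identity"}

    def test_filter_monotonicity(self, rng):
        db = self._db_of(rng, n_refs=3)
        reads = []
        for i in range(40):
            src = db.records[int(rng.integers(3))]
            s = list(src.sequence[int(rng.integers(0, 300)) :][:100])
            for p in rng.choice(100, size=int(rng.integers(0, 30)), replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            reads.append(Read(f"r{i}", "".join(s)))
        loose = {h.read_id for h in recruit(reads, db, RecruitmentParams(min_identity=75)).hits}
        tight = {h.read_id for h in recruit(reads, db, RecruitmentParams(min_identity=85)).hits}
        assert tight <= loose
        loose_f = {h.read_id for h in recruit(reads, db, RecruitmentParams(min_aligned_fraction=70)).hits}
        tight_f = {h.read_id for h in recruit(reads, db, RecruitmentParams(min_aligned_fraction=90)).hits}
        assert tight_f <= loose_f

    def test_strand_symmetric_recruitment(self, rng):
        db = self._db_of(rng, n_refs=3)
        src = db.records[1]
        fwd = Read("r", src.sequence[40:140])
        rev = Read("r", revcomp(src.sequence[40:140]))
        h1 = recruit([fwd], db).hits[0]
        h2 = recruit([rev], db).hits[0]
        assert (h1.reference_id, h1.identity, h1.aligned_read_fraction) == (
            h2.reference_id, h2.identity, h2.aligned_read_fraction,
        )

    def test_deterministic_result(self, rng):
        db = self._db_of(rng, n_refs=3)
        reads = [Read(f"r{i}", db.records[i % 3].sequence[i : i + 100]) for i in range(10)]
        r1, r2 = recruit(reads, db), recruit(reads, db)
        assert r1.hits == r2.hits and r1.rejected == r2.rejected

    def test_empty_reads(self, rng):
        result = recruit([], self._db_of(rng))
        assert result.total_input_reads == 0 and result.hits == []


class TestRibotag:
    def _ribo_db(self, rng):
        base = _random_seq(rng, 600)

        def variant(nmut, ranks):
            s = list(base)
            for p in rng.choice(600, size=nmut, replace=False):
                s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
            return "".join(s), ranks

        specs = [
            ("u1", 0, ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Naviculales")),
            ("u2", 40, ("Eukaryota", "Stramenopiles", "Bacillariophyta", "Bacillariales")),
            ("u3", 120, ("Eukaryota", "Stramenopiles", "Pelagophyceae", "Pelagomonadales")),
        ]
        records = []
        for rid, nmut, ranks in specs:
            seq, _ = variant(nmut, ranks)
            records.append(
                MarkerRecord(rid, "rRNA_18S", TaxonomyPath(ranks, "diatoms" if "Bacillario" in ranks[2] else "pelagophytes"), seq)
            )
        return ReferenceDatabase(gene="rRNA_18S", records=records)

    def test_read_with_n_rejected(self, rng):
        db = self._ribo_db(rng)
        seq = db.records[0].sequence[:150]
        assert classify_ribotag(Read("r", seq[:75] + "N" + seq[76:]), db) == "has_N"

    def test_short_read_rejected(self, rng):
        db = self._ribo_db(rng)
        assert classify_ribotag(Read("r", db.records[0].sequence[:99]), db) == "too_short"

    def test_unique_best_hit_full_taxonomy(self, rng):
        db = self._ribo_db(rng)
        read = Read("r", db.records[2].sequence[100:250])
        res = classify_ribotag(read, db)
        assert res.taxonomy == db.records[2].taxonomy.ranks
        assert res.n_tied_hits == 1

    def test_tie_truncates_to_lca(self):
        """A read equidistant from two references that share ranks down to
        class is truncated at the class rank; verified by brute-force
        difference counting against every reference."""
        rng = np.random.default_rng(5)
        base = _random_seq(rng, 400)
        a = list(base)
        b = list(base)
        # two references differing from the read region by exactly 2 each
        a[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[50]]
        a[60] = {"A": "C", "C": "G", "G": "T", "T": "A"}[a[60]]
        b[70] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[70]]
        b[80] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[80]]
        shared = ("Eukaryota", "Stramenopiles", "Bacillariophyta")
        db = ReferenceDatabase(
            gene="rRNA_18S",
            records=[
                MarkerRecord("rA", "rRNA_18S", TaxonomyPath(shared + ("Naviculales",), "diatoms"), "".join(a)),
                MarkerRecord("rB", "rRNA_18S", TaxonomyPath(shared + ("Bacillariales",), "diatoms"), "".join(b)),
            ],
        )
        read = Read("r", base[20:140])  # covers both mutation sites
        # brute force: differences to each reference by direct count
        diffs = {
            rec.record_id: sum(
                1 for x, y in zip(read.sequence, rec.sequence[20:140]) if x != y
            )
            for rec in db.records
        }
        assert diffs == {"rA": 2, "rB": 2}
        res = classify_ribotag(read, db)
        assert res.n_tied_hits == 2
        assert res.taxonomy == shared

    def test_distant_read_no_hit(self, rng):
        db = self._ribo_db(rng)
        assert classify_ribotag(Read("r", _random_seq(rng, 150)), db) == "no_hit"


def test_read_reads_fasta_and_fastq():
    fa = ">a desc\nACGT\nACGT\n>b\nTTTT\n"
    reads = read_reads(fa, "fasta")
    assert [(r.read_id, r.sequence) for r in reads] == [("a", "ACGTACGT"), ("b", "TTTT")]
    fq = "@a\nACGTACGT\n+\nIIIIIIII\n"
    assert read_reads(fq, "fastq")[0].sequence == "ACGTACGT"
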