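"""Genome mapping, precursor extraction, duplex scoring, star validation."""

import numpy as np
import pytest

from srnakit.discover import (
    GenomicLocus,
    discover_novel,
    evaluate_duplex,
    extract_precursor,
    find_star,
    make_candidate,
    map_unannotated,
)
from srnakit.annotate import LibraryReads
from srnakit.fold import fold_back
from srnakit.seq import revcomp


class TestMapUnannotated:
    def test_planted_reads_map_to_their_locus(self, sim10):
        _cfg, refs, truth, _libs = sim10
        reads = [h.mature for h in truth.planted_hairpins]
        mapped, repetitive = map_unannotated(reads, refs.genome)
        assert not repetitive
        for h in truth.planted_hairpins:
            assert mapped[h.mature] == [h.mature_locus]

    def test_absent_read_maps_nowhere(self, sim10):
        _cfg, refs, _truth, _libs = sim10
        mapped, _ = map_unannotated(["TGCA" * 6], refs.genome)
        assert mapped["TGCA" * 6] == []

    def test_repetitive_read_discarded(self):
        mapped, repetitive = map_unannotated(["A" * 21], {"chr1": "A" * 100})
        assert "A" * 21 in repetitive and "A" * 21 not in mapped


class TestExtractPrecursor:
    def test_full_window_length(self):
        genome = {"chr1": "G" * 2000}
        loc = GenomicLocus("chr1", 1000, 1021, "+")
        pre, window = extract_precursor(loc, genome)
        assert len(pre) == 21 + 300
        assert (window.start, window.end) == (850, 1171)

    def test_clipped_at_chromosome_start(self):
        genome = {"chr1": "G" * 500}
        pre, window = extract_precursor(GenomicLocus("chr1", 10, 31, "+"), genome)
        assert window.start == 0 and window.end == 181
        assert len(pre) == 181

    def test_minus_strand_is_reverse_complemented(self):
        genome = {"chr1": "ACGTA" * 100}
        loc = GenomicLocus("chr1", 200, 221, "-")
        pre_plus, _ = extract_precursor(GenomicLocus("chr1", 200, 221, "+"), genome)
        pre_minus, window = extract_precursor(loc, genome)
        assert pre_minus == revcomp(pre_plus)
        assert window.strand == "-" and (window.start, window.end) == (50, 371)


def _synthetic_hairpin_candidate():
    """Hand-built perfect hairpin in a random-flank window."""
    rng = np.random.default_rng(123)
    bases = np.array(list("ACGT"))
    mature = "".join(bases[rng.integers(0, 4, 21)])
    # star pairs mature[0..18] with a 2-nt 3' overhang on each strand
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    star = "".join(comp[mature[18 - j]] for j in range(19)) + "GG"
    basal = "".join(bases[rng.integers(0, 4, 20)])
    body = basal + mature + "CAAACAAA" + star + revcomp(basal)
    flank5 = "".join(bases[rng.integers(0, 4, 150)])
    flank3 = "".join(bases[rng.integers(0, 4, 150)])
    genome = {"chr1": flank5 + body + flank3}
    ms = 150 + 20
    locus = GenomicLocus("chr1", ms, ms + 21, "+")
    return make_candidate(mature, locus, genome), mature, star


class TestEvaluateDuplex:
    def test_perfect_hairpin_passes_with_zero_mismatches(self):
        c, _mature, star = _synthetic_hairpin_candidate()
        rep = evaluate_duplex(c, fold_back(c.precursor))
        assert rep.passed and rep.mismatches == 0 and rep.bulge == 0
        assert rep.mature_arm == "5p"
        assert c.precursor[rep.star_start : rep.star_end] == star

    def test_planted_hairpins_pass(self, sim10):
        cfg, refs, truth, _libs = sim10
        for h in truth.planted_hairpins:
            c = make_candidate(h.mature, h.mature_locus, refs.genome)
            rep = evaluate_duplex(c, fold_back(c.precursor))
            assert rep.passed and rep.mismatches == cfg.duplex_mismatches

    def test_read_across_loop_fails(self):
        c, _m, _s = _synthetic_hairpin_candidate()
        # shift the "mature" annotation to span the loop region
        loop_read_start = c.mature_start + 12
        c2 = make_candidate(
            c.precursor[loop_read_start : loop_read_start + 21],
            GenomicLocus("chr1", loop_read_start, loop_read_start + 21, "+"),
            {"chr1": c.precursor},
        )
        rep = evaluate_duplex(c2, fold_back(c2.precursor))
        assert not rep.passed

    def test_random_windows_fail(self):
        rng = np.random.default_rng(77)
        bases = np.array(list("ACGT"))
        n_pass = 0
        for _ in range(20):
            g = "".join(bases[rng.integers(0, 4, 400)])
            c = make_candidate(
                g[180:201], GenomicLocus("chr1", 180, 201, "+"), {"chr1": g}
            )
            rep = evaluate_duplex(c, fold_back(c.precursor))
            n_pass += rep.passed
        assert n_pass == 0


class TestFindStar:
    def test_recovers_emitted_star(self, sim10):
        _cfg, refs, truth, libs = sim10
        h = next(x for x in truth.planted_hairpins if x.emits_star)
        c = make_candidate(h.mature, h.mature_locus, refs.genome)
        c.structure = fold_back(c.precursor)
        c.duplex = evaluate_duplex(c, c.structure)
        star = find_star(c, libs)
        assert star is not None and star[0] == h.star
        assert sum(star[1].values()) > 0

    def test_absent_star_returns_none(self, sim10):
        _cfg, refs, truth, libs = sim10
        h = next(x for x in truth.planted_hairpins if not x.emits_star)
        c = make_candidate(h.mature, h.mature_locus, refs.genome)
        c.structure = fold_back(c.precursor)
        c.duplex = evaluate_duplex(c, c.structure)
        assert find_star(c, libs) is None

    def test_star_offset_by_three_rejected(self):
        c, _m, star = _synthetic_hairpin_candidate()
        c.structure = fold_back(c.precursor)
        c.duplex = evaluate_duplex(c, c.structure)
        ss = c.duplex.star_start
        shifted = c.precursor[ss - 3 : ss - 3 + 21]
        lib_shift = LibraryReads("l", "control", 1, {shifted: 50})
        assert find_star(c, [lib_shift]) is None
        exact = LibraryReads("l", "control", 1, {star: 50})
        got = find_star(c, [exact])
        assert got is not None and got[0] == star


class TestCallNovel:
    def test_recovers_exactly_star_supported_hairpins(self, sim10, annotated10):
        _cfg, refs, truth, _libs = sim10
        filtered, results = annotated10
        calls, _cands = discover_novel(filtered, results, refs.genome)
        expected = {h.mature for h in truth.planted_hairpins if h.emits_star}
        assert {c.mature for c in calls} == expected

    def test_overlapping_candidates_merge(self, sim10, annotated10):
        """IsomiR-like duplicates (mature and its star both candidate reads)
        collapse to one call per hairpin locus."""
        _cfg, refs, truth, _libs = sim10
        filtered, results = annotated10
        _calls, cands = discover_novel(filtered, results, refs.genome)
        from srnakit.discover import call_novel

        calls = call_novel(cands)
        loci = [(c.window.chrom, c.window.strand, c.window.start) for c in calls]
        assert len(loci) == len(set(loci))
        # star reads of abundant hairpins are candidates too, yet no hairpin
        # yields two calls
        per_hairpin = [
            sum(
                1
                for c in calls
                if c.locus.start >= h.locus.start - 160
                and c.locus.end <= h.locus.end + 160
            )
            for h in truth.planted_hairpins
        ]
        assert max(per_hairpin) == 1

    def test_star_evidence_required(self, sim10, annotated10):
        _cfg, refs, truth, _libs = sim10
        filtered, results = annotated10
        _calls, cands = discover_novel(filtered, results, refs.genome)
        from srnakit.discover import call_novel

        for c in cands:
            c.star_read, c.star_counts = None, {}
        assert call_novel(cands) == []

    def test_strand_consistency(self, sim10, annotated10):
        """Discovery on the reverse-complemented genome yields the same
        mature set with mirrored coordinates."""
        _cfg, refs, _truth, _libs = sim10
        filtered, results = annotated10
        calls_fwd, _ = discover_novel(filtered, results, refs.genome)
        n = len(refs.genome["chr1"])
        rc_genome = {"chr1": revcomp(refs.genome["chr1"])}
        import warnings

        from srnakit.annotate import ReferenceSet, annotate_waterfall

        rc_refs = ReferenceSet(genome=rc_genome)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rc_results = {
                f.library_id: annotate_waterfall(f, rc_refs) for f in filtered
            }
        calls_rc, _ = discover_novel(filtered, rc_results, rc_genome)
        assert {c.mature for c in calls_rc} == {c.mature for c in calls_fwd}
        mirrored = {(n - c.locus.end, n - c.locus.start) for c in calls_rc}
        assert mirrored == {(c.locus.start, c.locus.end) for c in calls_fwd}

    def test_determinism(self, sim10, annotated10):
        _cfg, refs, _truth, _libs = sim10
        filtered, results = annotated10
        a, _ = discover_novel(filtered, results, refs.genome)
        b, _ = discover_novel(filtered, results, refs.genome)
        assert [(c.name, c.mature, c.locus) for c in a] == [
            (c.name, c.mature, c.locus) for c in b
        ]
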