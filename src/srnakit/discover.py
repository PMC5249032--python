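"""Novel miRNA discovery from genome-mapped, otherwise-unannotated reads.

Each candidate read is mapped exactly to the genome (both strands, reads
hitting more than ``max_loci`` positions discarded as repeat-derived), a
precursor window of ±150 nt is excised around each locus, folded by
base-pair maximization, and the mature:star duplex implied by the
structure is scored.  A locus is called a novel miRNA only when the duplex
passes the hairpin criteria (≤4 unpaired mature positions outside the
2-nt 3' overhang, no asymmetric bulge >2 nt) AND a sequenced miRNA* read —
the strand pairing the mature read with 2-nt 3' overhangs — is found in
the libraries with both ends within ±2 nt of the predicted star region.
Overlapping candidate windows are merged into one call, keeping the most
abundant mature read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotate import AnnotationResult, LibraryReads
from .fold import FoldResult, fold_back
from .seq import find_all, revcomp


@dataclass(frozen=True)
class GenomicLocus:
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad locus coordinates {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class DuplexReport:
    """Duplex metrics for one folded candidate."""

    mature_arm: str  # 5p / 3p / undetermined
    mismatches: int
    bulge: int
    star_start: int  # precursor coordinates, may be clipped-invalid
    star_end: int
    passed: bool
    reason: str = ""


@dataclass
class HairpinCandidate:
    read_sequence: str
    locus: GenomicLocus
    window: GenomicLocus
    precursor: str
    mature_start: int  # precursor coordinates
    mature_end: int
    structure: FoldResult | None = None
    duplex: DuplexReport | None = None
    star_read: str | None = None
    star_counts: dict[str, int] = field(default_factory=dict)
    read_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return sum(self.read_counts.values())

    @property
    def pass_flags(self) -> dict[str, bool]:
        return {
            "hairpin": self.duplex is not None and self.duplex.passed,
            "star_sequenced": self.star_read is not None,
        }


def map_unannotated(
    reads: Iterable[str], genome: Mapping[str, str], max_loci: int = 5
) -> tuple[dict[str, list[GenomicLocus]], set[str]]:
    """Exact both-strand genome loci per read.

    Returns (loci map, repetitive set).  Reads with more than ``max_loci``
    loci are reported in the repetitive set and excluded from the map;
    reads absent from the genome map to an empty list.
    """
    mapped: dict[str, list[GenomicLocus]] = {}
    repetitive: set[str] = set()
    for read in reads:
        loci: list[GenomicLocus] = []
        rc = revcomp(read)
        for chrom in sorted(genome):
            text = genome[chrom]
            for pos in find_all(text, read):
                loci.append(GenomicLocus(chrom, pos, pos + len(read), "+"))
            for pos in find_all(text, rc):
                loci.append(GenomicLocus(chrom, pos, pos + len(read), "-"))
            if len(loci) > max_loci:
                break
        if len(loci) > max_loci:
            repetitive.add(read)
        else:
            mapped[read] = loci
    return mapped, repetitive


def extract_precursor(
    locus: GenomicLocus, genome: Mapping[str, str], flank: int = 150
) -> tuple[str, GenomicLocus]:
    """±flank window around a locus; minus-strand loci are reverse-complemented.

    The window locus is recorded on the forward strand (carrying the
    original strand flag); clipping at chromosome bounds is silent but
    visible in the recorded coordinates.
    """
    chrom_seq = genome[locus.chrom]
    start = max(0, locus.start - flank)
    end = min(len(chrom_seq), locus.end + flank)
    window = chrom_seq[start:end]
    if locus.strand == "-":
        window = revcomp(window)
    return window, GenomicLocus(locus.chrom, start, end, locus.strand)


def make_candidate(
    read: str,
    locus: GenomicLocus,
    genome: Mapping[str, str],
    flank: int = 150,
    read_counts: Mapping[str, int] | None = None,
) -> HairpinCandidate:
    """Build an unfolded candidate with mature coordinates in the precursor."""
    precursor, window = extract_precursor(locus, genome, flank)
    if locus.strand == "+":
        ms = locus.start - window.start
    else:
        ms = window.end - locus.end
    return HairpinCandidate(
        read_sequence=read,
        locus=locus,
        window=window,
        precursor=precursor,
        mature_start=ms,
        mature_end=ms + len(read),
        read_counts=dict(read_counts or {}),
    )


_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def evaluate_duplex(
    candidate: HairpinCandidate,
    structure: FoldResult,
    max_mismatch: int = 4,
    max_bulge: int = 2,
    overhang: int = 2,
) -> DuplexReport:
    """Score the mature:star duplex implied by a fold.

    The structure determines the hairpin arm of the mature read and the
    duplex register: the partner offset ``q[i] + (i − mature_start)`` is
    constant along a clean antiparallel helix, and its consensus (median
    over paired mature positions on the majority side) locates the star
    region, shifted for the 2-nt 3' overhangs.  Mature "mismatches" are
    read positions (excluding the 3' ``overhang`` nt, unpaired in a
    canonical duplex) that cannot pair — Watson-Crick or G:U — with their
    register partner; scoring mismatches at sequence level against the
    structure-implied register makes the call robust to co-optimal
    traceback noise in the base-pair-maximization fold.  The asymmetric
    bulge is the largest offset jump between consecutive near-register
    paired positions.
    """
    q = structure.partner
    pre = candidate.precursor
    n = len(pre)
    ms, me = candidate.mature_start, candidate.mature_end
    L = me - ms
    core = list(range(ms, me - overhang))
    arm = "undetermined"

    partners = {i: int(q[i]) for i in core if q[i] >= 0}
    if len(partners) < len(core) / 2:
        return DuplexReport(arm, L, L, -1, -1, False, "insufficient-pairing")
    up = {i: j for i, j in partners.items() if j < ms}
    down = {i: j for i, j in partners.items() if j >= me}
    inside = len(partners) - len(up) - len(down)
    if inside >= max(len(up), len(down)):
        return DuplexReport(arm, L, L, -1, -1, False, "loop-spanning")
    side = down if len(down) >= len(up) else up
    arm = "5p" if side is down else "3p"

    offs = {i: j + (i - ms) for i, j in side.items()}

    def _mm_at(register: int) -> int:
        mm = 0
        for i in core:
            j = register - (i - ms)
            if not (0 <= j < n) or (pre[i], pre[j]) not in _PAIRS:
                mm += 1
        return mm

    # candidate registers are the offsets the structure actually realized;
    # the duplex register is the one with the cleanest complementarity
    # (structural support, then position, break ties)
    support: dict[int, int] = {}
    for o in offs.values():
        support[o] = support.get(o, 0) + 1
    consensus = min(support, key=lambda o: (_mm_at(o), -support[o], o))
    star_start = consensus - (L - overhang - 1)
    star_end = star_start + L
    if not (0 <= star_start < star_end <= n):
        return DuplexReport(arm, L, L, star_start, star_end, False,
                            "star-out-of-bounds")
    if not (star_end <= ms or star_start >= me):
        return DuplexReport(arm, L, L, star_start, star_end, False,
                            "loop-spanning")

    mismatches = _mm_at(consensus)

    bulge = 0
    near = sorted(i for i, o in offs.items() if abs(o - consensus) <= max_bulge)
    for a, b in zip(near, near[1:]):
        bulge = max(bulge, abs(offs[a] - offs[b]))

    passed = mismatches <= max_mismatch and bulge <= max_bulge
    reason = "" if passed else "duplex-criteria"
    return DuplexReport(arm, mismatches, bulge, star_start, star_end, passed, reason)


def find_star(
    candidate: HairpinCandidate,
    libraries: Sequence[LibraryReads],
    tolerance: int = 2,
    min_count: int = 2,
) -> tuple[str, dict[str, int]] | None:
    """Most abundant sequenced read matching the predicted star region.

    A read is star evidence when it occurs in the precursor with start and
    end each within ±``tolerance`` nt of the predicted star region and was
    sequenced at least ``min_count`` times across the libraries (a single
    stray read at the right position is treated as background degradation,
    not processing evidence).
    """
    if candidate.duplex is None or candidate.duplex.star_start < 0:
        return None
    ss, se = candidate.duplex.star_start, candidate.duplex.star_end
    pre = candidate.precursor
    best: tuple[int, str] | None = None
    seen: dict[str, dict[str, int]] = {}
    for p in range(max(0, ss - tolerance), ss + tolerance + 1):
        for e in range(max(p + 1, se - tolerance), min(len(pre), se + tolerance) + 1):
            sub = pre[p:e]
            if sub == candidate.read_sequence or sub in seen:
                continue
            counts = {
                lib.library_id: lib.counts[sub]
                for lib in libraries
                if sub in lib.counts
            }
            total = sum(counts.values())
            if total >= min_count:
                seen[sub] = counts
                key = (total, sub)
                if best is None or key > best:
                    best = key
    if best is None:
        return None
    return best[1], seen[best[1]]


@dataclass
class NovelCall:
    name: str
    mature: str
    mature_arm: str
    star: str
    locus: GenomicLocus
    window: GenomicLocus
    precursor: str
    dot_bracket: str
    mismatches: int
    bulge: int
    mature_counts: dict[str, int]
    star_counts: dict[str, int]


def call_novel(candidates: Sequence[HairpinCandidate]) -> list[NovelCall]:
    """Novel set: all hairpin criteria passed AND star evidence sequenced.

    One call per distinct precursor locus: candidates whose windows overlap
    on the same chromosome and strand are merged, keeping the most abundant
    mature read.  Output order is genomic, which makes the call list
    deterministic for identical inputs.
    """
    passing = [
        c for c in candidates
        if all(c.pass_flags.values()) and c.duplex is not None
    ]
    passing.sort(key=lambda c: (-c.total_count, c.read_sequence,
                                c.locus.chrom, c.locus.start))
    kept: list[HairpinCandidate] = []
    for c in passing:
        merged = False
        for k in kept:
            if (
                c.window.chrom == k.window.chrom
                and c.window.strand == k.window.strand
                and c.window.start < k.window.end
                and k.window.start < c.window.end
            ):
                merged = True
                break
        if not merged:
            kept.append(c)
    kept.sort(key=lambda c: (c.locus.chrom, c.locus.start, c.locus.strand))
    calls = []
    for i, c in enumerate(kept, start=1):
        calls.append(
            NovelCall(
                name=f"novel-miR-{i}",
                mature=c.read_sequence,
                mature_arm=c.duplex.mature_arm,
                star=c.star_read or "",
                locus=c.locus,
                window=c.window,
                precursor=c.precursor,
                dot_bracket=c.structure.dot_bracket() if c.structure else "",
                mismatches=c.duplex.mismatches,
                bulge=c.duplex.bulge,
                mature_counts=dict(c.read_counts),
                star_counts=dict(c.star_counts),
            )
        )
    return calls


def discover_novel(
    libraries: Sequence[LibraryReads],
    annotations: Mapping[str, AnnotationResult],
    genome: Mapping[str, str],
    flank: int = 150,
    min_read_count: int = 5,
    max_loci: int = 5,
    max_mismatch: int = 4,
    max_bulge: int = 2,
    star_tolerance: int = 2,
    min_star_count: int = 2,
    min_loop: int = 3,
    gu_weight: float = 1.0,
) -> tuple[list[NovelCall], list[HairpinCandidate]]:
    """End-to-end novel miRNA discovery over annotated libraries.

    Candidate reads are those assigned to the genome tier in any library
    with a summed count of at least ``min_read_count`` (abundance evidence;
    singleton background reads are not folded).
    """
    totals: dict[str, int] = {}
    per_lib: dict[str, dict[str, int]] = {}
    for lib in libraries:
        res = annotations[lib.library_id]
        for seq, cat in res.category_of_read.items():
            if cat != "genome":
                continue
            c = lib.counts.get(seq, 0)
            totals[seq] = totals.get(seq, 0) + c
            per_lib.setdefault(seq, {})[lib.library_id] = c
    cand_reads = sorted(
        (s for s, t in totals.items() if t >= min_read_count),
        key=lambda s: (-totals[s], s),
    )
    loci_map, _repetitive = map_unannotated(cand_reads, genome, max_loci)
    candidates: list[HairpinCandidate] = []
    for read in cand_reads:
        for locus in loci_map.get(read, []):
            c = make_candidate(read, locus, genome, flank, per_lib[read])
            c.structure = fold_back(c.precursor, min_loop=min_loop, gu_weight=gu_weight)
            c.duplex = evaluate_duplex(c, c.structure, max_mismatch, max_bulge)
            star = find_star(c, libraries, star_tolerance, min_star_count)
            if star is not None:
                c.star_read, c.star_counts = star
            candidates.append(c)
    return call_novel(candidates), candidates
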