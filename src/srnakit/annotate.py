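"""Read loading, collapsing, length filtering and hierarchical annotation.

Each unique read is assigned to exactly one category by screening, in
order, against structural noncoding RNAs (rRNA/tRNA/snRNA/snoRNA decoy
set), transposon/mRNA sequences, the mature miRNA catalog, and finally the
genome; reads matching nothing are "unmapped".  The first matching tier
wins, so the categories form a disjoint partition of the retained reads.
A separate "genome-mappable at any tier" figure is also reported, since
overlapping per-category genome counts are sometimes wanted.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .seq import normalize, revcomp

CATEGORY_ORDER = ("mirbase", "noncoding", "repeats_mrna", "genome", "unmapped")

CONTROL = "control"
WATER_STRESS = "water_stress"


@dataclass
class LibraryReads:
    """One sequencing library as a collapsed sequence→count map."""

    library_id: str
    condition: str
    replicate: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def unique_reads(self) -> int:
        return len(self.counts)


@dataclass
class ReferenceSet:
    """Named reference sequences used by the annotation waterfall."""

    genome: dict[str, str] = field(default_factory=dict)
    structural_ncrna: dict[str, str] = field(default_factory=dict)
    repeats_mrna: dict[str, str] = field(default_factory=dict)
    mature_catalog: dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotationResult:
    """Per-read category assignment plus per-library tallies."""

    library_id: str
    category_of_read: dict[str, str]
    matched_mirna_ids: dict[str, list[str]]
    counts: dict[str, int]
    genome_any: set[str] = field(default_factory=set)

    def tally(self) -> dict[str, dict[str, int]]:
        """Total/unique counts per category; categories are disjoint."""
        out = {c: {"total": 0, "unique": 0} for c in CATEGORY_ORDER}
        for seq, cat in self.category_of_read.items():
            out[cat]["total"] += self.counts[seq]
            out[cat]["unique"] += 1
        out["total"] = {
            "total": sum(v["total"] for k, v in out.items() if k != "total"),
            "unique": sum(v["unique"] for k, v in out.items() if k != "total"),
        }
        out["genome_any"] = {
            "total": sum(self.counts[s] for s in self.genome_any),
            "unique": len(self.genome_any),
        }
        return out


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_reads(
    path: str | Path,
    fmt: str = "fasta_collapsed",
    library_id: str | None = None,
    condition: str = CONTROL,
    replicate: int = 1,
) -> LibraryReads:
    """Load a small-RNA library from FASTA/FASTQ and collapse identical reads.

    ``fasta_collapsed`` expects the ``name_xCOUNT`` header dialect; ``fasta_raw``
    and ``fastq`` count each record once.  Sequences are uppercased and U→T
    normalized before collapsing.
    """
    path = Path(path)
    if fmt not in {"fasta_collapsed", "fasta_raw", "fastq"}:
        raise ValueError(f"unknown read format: {fmt!r}")
    counts: dict[str, int] = {}
    n_records = 0
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq" if fmt == "fastq" else "fasta")
        for i, rec in enumerate(parser):
            n_records += 1
            seq = normalize(str(rec.seq))
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"malformed record {i} in {path}: bad sequence")
            if fmt == "fasta_collapsed":
                name = rec.id
                try:
                    count = int(name.rsplit("_x", 1)[1])
                except (IndexError, ValueError):
                    raise ValueError(
                        f"malformed record {i} in {path}: header {name!r} "
                        "lacks an _xCOUNT suffix"
                    ) from None
                if count < 1:
                    raise ValueError(f"malformed record {i} in {path}: count < 1")
            else:
                count = 1
            counts[seq] = counts.get(seq, 0) + count
    if n_records == 0:
        warnings.warn(f"{path} contained no reads", stacklevel=2)
    return LibraryReads(
        library_id=library_id or path.name.split(".")[0],
        condition=condition,
        replicate=replicate,
        counts=counts,
    )


def length_filter(
    reads: LibraryReads, min_len: int = 18, max_len: int = 28
) -> tuple[LibraryReads, dict[str, int]]:
    """Keep reads with min_len ≤ length ≤ max_len; report the removed mass."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = {s: c for s, c in reads.counts.items() if min_len <= len(s) <= max_len}
    removed = {
        "total": reads.total_reads - sum(kept.values()),
        "unique": reads.unique_reads - len(kept),
    }
    filtered = LibraryReads(reads.library_id, reads.condition, reads.replicate, kept)
    return filtered, removed


def _match_substring_tier(
    reads_by_len: Mapping[int, set[str]], refs: Iterable[str]
) -> set[str]:
    """Reads occurring as an exact substring of any reference, either strand."""
    found: set[str] = set()
    for ref in refs:
        for text in (ref, revcomp(ref)):
            for L, rset in reads_by_len.items():
                if L > len(text):
                    continue
                for i in range(len(text) - L + 1):
                    w = text[i : i + L]
                    if w in rset:
                        found.add(w)
    return found


class _CatalogMatcher:
    """Bounded-substitution full-length matching of reads against the catalog.

    A read matches a catalog entry when it aligns, without indels, inside the
    entry with at most ``max_mm`` substitutions.  A pigeonhole k-mer seed
    prefilter keeps the scan fast: a read with ≤ max_mm substitutions must
    share at least one of its max_mm+1 equal chunks exactly with the entry.
    """

    def __init__(self, catalog: Mapping[str, str], max_mm: int):
        self.max_mm = max_mm
        self.entries = {
            mid: np.frombuffer(normalize(s).encode(), dtype=np.uint8)
            for mid, s in catalog.items()
        }
        self.seed_len = 18 // (max_mm + 1) if max_mm > 0 else 0
        self.seeds: set[str] = set()
        if self.seed_len:
            for s in catalog.values():
                s = normalize(s)
                for i in range(len(s) - self.seed_len + 1):
                    self.seeds.add(s[i : i + self.seed_len])

    def _passes_seed(self, read: str) -> bool:
        if not self.seed_len:
            return True
        k = self.seed_len
        n_chunks = self.max_mm + 1
        step = len(read) // n_chunks
        for c in range(n_chunks):
            chunk = read[c * step : c * step + k]
            if len(chunk) == k and chunk in self.seeds:
                return True
        return False

    def match(self, read: str) -> list[str]:
        if self.max_mm > 0 and not self._passes_seed(read):
            return []
        rb = np.frombuffer(read.encode(), dtype=np.uint8)
        hits = []
        for mid, arr in self.entries.items():
            if arr.size < rb.size:
                continue
            for off in range(arr.size - rb.size + 1):
                if int(np.count_nonzero(arr[off : off + rb.size] != rb)) <= self.max_mm:
                    hits.append(mid)
                    break
        return hits


def annotate_waterfall(
    reads: LibraryReads,
    refs: ReferenceSet,
    mirbase_max_mismatch: int = 2,
) -> AnnotationResult:
    """Assign every read to its first matching tier.

    Tier order: structural noncoding → transposons/mRNA → mature miRNA
    catalog (≤ ``mirbase_max_mismatch`` substitutions, no indels) → genome
    (exact substring, either strand) → unmapped.  An empty reference
    component is skipped with a warning.  Matching is done per tier over the
    full read set and resolved by precedence afterwards, so reference
    insertion order can never influence assignments.
    """
    seqs = list(reads.counts)
    reads_by_len: dict[int, set[str]] = {}
    for s in seqs:
        reads_by_len.setdefault(len(s), set()).add(s)

    def tier_or_warn(component: dict[str, str], name: str) -> set[str]:
        if not component:
            warnings.warn(f"empty reference component {name!r}: tier skipped",
                          stacklevel=3)
            return set()
        return _match_substring_tier(reads_by_len, component.values())

    nc_hits = tier_or_warn(refs.structural_ncrna, "structural_ncrna")
    rep_hits = tier_or_warn(refs.repeats_mrna, "repeats_mrna")
    genome_hits = tier_or_warn(refs.genome, "genome")

    matched_ids: dict[str, list[str]] = {}
    if refs.mature_catalog:
        matcher = _CatalogMatcher(refs.mature_catalog, mirbase_max_mismatch)
        for s in seqs:
            if s in nc_hits or s in rep_hits:
                continue
            ids = matcher.match(s)
            if ids:
                matched_ids[s] = sorted(ids)
    else:
        warnings.warn("empty reference component 'mature_catalog': tier skipped",
                      stacklevel=2)

    category: dict[str, str] = {}
    for s in seqs:
        if s in nc_hits:
            category[s] = "noncoding"
        elif s in rep_hits:
            category[s] = "repeats_mrna"
        elif s in matched_ids:
            category[s] = "mirbase"
        elif s in genome_hits:
            category[s] = "genome"
        else:
            category[s] = "unmapped"

    return AnnotationResult(
        library_id=reads.library_id,
        category_of_read=category,
        matched_mirna_ids=matched_ids,
        counts=dict(reads.counts),
        genome_any=genome_hits,
    )


TALLY_ROWS = ("mirbase", "noncoding", "repeats_mrna", "genome", "unmapped",
              "total", "genome_any")


def tally_table(results: Mapping[str, AnnotationResult]) -> pd.DataFrame:
    """Per-library total/unique counts per category (disjoint partition).

    Rows follow ``TALLY_ROWS``; the ``genome_any`` row is supplementary
    (reads mappable to the genome regardless of their assigned tier) and is
    not part of the partition, which sums to ``total``.
    """
    cols = {}
    for lib_id, res in results.items():
        t = res.tally()
        cols[(lib_id, "total")] = [t[r]["total"] for r in TALLY_ROWS]
        cols[(lib_id, "unique")] = [t[r]["unique"] for r in TALLY_ROWS]
    df = pd.DataFrame(cols, index=list(TALLY_ROWS))
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["library", "measure"])
    return df
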