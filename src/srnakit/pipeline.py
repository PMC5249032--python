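"""End-to-end small-RNA analysis over one fixture directory.

Annotates every library, writes the category tally, per-miRNA and
per-family RPTM profiles with abundance tiers, the star summary, family
and per-miRNA differential-expression tables, and the novel-miRNA call
list.  All outputs are TSV with fixed float formatting and sorted rows,
so identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import annotate, de, discover, quantify
from .annotate import LibraryReads, ReferenceSet
from .simulate import load_fixture

FLOAT_FORMAT = "%.6g"


def run_pipeline(
    refs: ReferenceSet,
    libraries: Sequence[LibraryReads],
    out_dir: str | Path,
    min_len: int = 18,
    max_len: int = 28,
    mirbase_max_mismatch: int = 2,
    denominator: str = "filtered",
    discover_novel_mirnas: bool = True,
    novel_min_count: int = 5,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> dict[str, Path]:
    """Run annotation → quantification → DE → discovery; write TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    filtered: dict[str, LibraryReads] = {}
    results: dict[str, annotate.AnnotationResult] = {}
    denominators: dict[str, float] = {}
    conditions: dict[str, str] = {}
    for lib in libraries:
        flib, _removed = annotate.length_filter(lib, min_len, max_len)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = annotate.annotate_waterfall(flib, refs, mirbase_max_mismatch)
        filtered[lib.library_id] = flib
        results[lib.library_id] = res
        conditions[lib.library_id] = lib.condition
        if denominator == "filtered":
            denominators[lib.library_id] = flib.total_reads
        elif denominator == "genome":
            denominators[lib.library_id] = sum(
                flib.counts[s] for s in res.genome_any
            )
        else:
            raise ValueError(f"unknown denominator mode {denominator!r}")

    tally = annotate.tally_table(results)
    paths["tally"] = out / "tally.tsv"
    tally.to_csv(paths["tally"], sep="\t")

    profiles = quantify.build_mirna_profiles(
        refs.mature_catalog, results, denominators
    )
    families = quantify.build_family_profiles(profiles, conditions)
    paths["mirna_profiles"] = out / "mirna_profiles.tsv"
    quantify.mirna_table(profiles).to_csv(
        paths["mirna_profiles"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    paths["family_profiles"] = out / "family_profiles.tsv"
    quantify.family_table(families).to_csv(
        paths["family_profiles"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    paths["star_summary"] = out / "star_summary.tsv"
    quantify.star_summary(profiles).to_csv(
        paths["star_summary"], sep="\t", index=False, float_format=FLOAT_FORMAT
    )

    lib_ids = sorted(filtered)
    for level, items in (("families", families), ("mirnas", profiles)):
        if not items:
            continue
        counts = pd.DataFrame(
            {
                lid: [
                    (f.raw_counts if level == "families" else f.raw_counts)[lid]
                    for f in items
                ]
                for lid in lib_ids
            },
            index=[
                f.family_id if level == "families" else f.mirna_id for f in items
            ],
        )
        cm = de.CountMatrix(
            counts=counts,
            conditions=conditions,
            library_sizes={l: denominators[l] for l in lib_ids},
        )
        try:
            table = de.run_de(cm, lfc_min=lfc_min, fdr_max=fdr_max)
        except ValueError:
            continue  # e.g. no replication in a hand-built fixture
        paths[f"de_{level}"] = out / f"de_{level}.tsv"
        table.sort_index().to_csv(
            paths[f"de_{level}"], sep="\t", float_format=FLOAT_FORMAT
        )

    if discover_novel_mirnas:
        calls, _cands = discover.discover_novel(
            list(filtered.values()), results, refs.genome,
            min_read_count=novel_min_count,
        )
        rows = []
        for c in calls:
            row = {
                "name": c.name,
                "chrom": c.locus.chrom,
                "start": c.locus.start,
                "end": c.locus.end,
                "strand": c.locus.strand,
                "arm": c.mature_arm,
                "mature": c.mature,
                "star": c.star,
                "mismatches": c.mismatches,
                "bulge": c.bulge,
            }
            row.update({f"count_{l}": c.mature_counts.get(l, 0) for l in lib_ids})
            rows.append(row)
        paths["novel"] = out / "novel_mirnas.tsv"
        pd.DataFrame(rows).to_csv(paths["novel"], sep="\t", index=False)
        with open(out / "novel_precursors.fa", "w") as fh:
            for c in calls:
                fh.write(f">{c.name}\n{c.precursor}\n")
        with open(out / "novel_structures.txt", "w") as fh:
            for c in calls:
                fh.write(f">{c.name}\n{c.precursor}\n{c.dot_bracket}\n")
        paths["novel_precursors"] = out / "novel_precursors.fa"
        paths["novel_structures"] = out / "novel_structures.txt"
    return paths


def run_pipeline_from_dir(fixture_dir: str | Path, out_dir: str | Path,
                          **kwargs) -> dict[str, Path]:
    refs, libraries = load_fixture(fixture_dir)
    return run_pipeline(refs, libraries, out_dir, **kwargs)
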