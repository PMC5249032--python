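"""Synthetic genome, hairpin and library simulation with planted truth.

The generator emulates the study design every downstream stage is tested
against: a toy genome carrying planted miRNA hairpins (mature arm, 8–15 nt
loop, star arm built as the reverse complement of the mature with ≤2
planted mismatches and 2-nt 3' overhangs), structural-ncRNA and
transposon/mRNA decoy sequences, and two conditions × two replicate
libraries of 18–28 nt reads whose length histogram peaks at 21 and 24 nt.
Per-family read counts are drawn negative-binomially (variance μ + φμ²)
around means scaled by per-family log2 fold changes in the water-stress
condition; miRNA* reads are emitted by binomial thinning of the mature
counts; background reads are sampled 70% from decoys and 30% uniformly
from the genome.  Everything is reproducible from (config, seed): the
planted truth gives downstream ground truth for annotation, recovery,
quantification and differential calling.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotate import LibraryReads, ReferenceSet, CONTROL, WATER_STRESS
from .discover import GenomicLocus
from .seq import ALPHABET, revcomp

DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    18: 0.02, 19: 0.03, 20: 0.07, 21: 0.30, 22: 0.08, 23: 0.08,
    24: 0.28, 25: 0.06, 26: 0.04, 27: 0.02, 28: 0.02,
}


class CapacityError(ValueError):
    """The configured genome is too small to place every feature."""


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic dataset."""

    n_hairpins: int = 20
    n_decoy_ncrna: int = 8
    n_decoy_mrna: int = 8
    genome_length: int = 50_000
    mature_length: int = 21
    star_overhang: int = 2
    n_families: int = 10
    condition_lfc: dict[str, float] = field(default_factory=dict)
    replicates_per_condition: int = 2
    library_depth: int = 2_000_000
    nb_dispersion: float = 0.1
    length_peak_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    seed: int = 0
    # generator design knobs (not part of the study contrast)
    mirna_fraction: float = 0.25
    star_fraction: float = 0.1
    n_star_hairpins: int | None = None  # None: every hairpin emits star reads
    duplex_mismatches: int = 2
    loop_length: tuple[int, int] = (8, 15)
    basal_stem: int = 20
    minus_strand_fraction: float = 0.5
    background_decoy_fraction: float = 0.7
    decoy_ncrna_length: tuple[int, int] = (70, 160)
    decoy_mrna_length: tuple[int, int] = (300, 800)

    def validate(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 18 <= self.mature_length <= 28:
            raise ValueError("mature_length must lie in [18, 28]")
        total = sum(self.length_peak_weights.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"length weights sum to {total}, expected 1")
        if min(self.length_peak_weights) < 1 or any(
            w < 0 for w in self.length_peak_weights.values()
        ):
            raise ValueError("length weights must be a probability map")
        if self.n_hairpins < 0 or self.n_families < 0:
            raise ValueError("counts must be non-negative")
        if not 0 <= self.mirna_fraction < 1:
            raise ValueError("mirna_fraction must lie in [0, 1)")
        if self.duplex_mismatches > 2 * self.star_overhang:
            raise ValueError("too many planted duplex mismatches for the criteria")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("loop_length", "decoy_ncrna_length", "decoy_mrna_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "length_peak_weights" in raw:
            raw["length_peak_weights"] = {
                int(k): float(v) for k, v in raw["length_peak_weights"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        for key in ("loop_length", "decoy_ncrna_length", "decoy_mrna_length"):
            raw[key] = list(raw[key])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class HairpinTruth:
    locus: GenomicLocus          # precursor span on the genome
    mature_locus: GenomicLocus   # mature arm span on the genome
    precursor: str               # transcript orientation
    mature: str
    star: str
    mature_arm: str              # 5p / 3p
    family_id: str
    mature_id: str
    star_id: str
    emits_star: bool


@dataclass
class SimTruth:
    planted_hairpins: list[HairpinTruth]
    true_family_of_read: dict[str, str]
    true_lfc: dict[str, float]
    family_mean_fraction: dict[str, float]  # of depth, control condition
    per_library_expected_counts: dict[str, dict[str, float]] = field(
        default_factory=dict
    )


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(ALPHABET))[rng.integers(0, 4, size=length)])


# star bases that pair (Watson-Crick or G:U wobble) with a mature base;
# a planted duplex mismatch must avoid all of them
_PAIRING_PARTNERS = {"A": "T", "C": "G", "G": "CT", "T": "AG"}


def _non_pairing(rng: np.random.Generator, mature_base: str) -> str:
    choices = [b for b in ALPHABET if b not in _PAIRING_PARTNERS[mature_base]]
    return rng.choice(choices)


def _build_hairpin(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[str, str, str, str, int]:
    """Return (precursor_body, mature, star, arm, mature_offset).

    The star arm is the reverse complement of the mature with
    ``duplex_mismatches`` planted substitutions in the duplex core and a
    free 2-nt 3' overhang.  As in real pre-miRNAs the miRNA:miRNA* duplex
    sits on an extended stem: a perfectly complementary basal stem of
    ``basal_stem`` nt flanks the duplex, which also makes the planted
    fold-back the dominant structure under base-pair maximization.
    """
    L = cfg.mature_length
    oh = cfg.star_overhang
    mature = _rand_seq(rng, L)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # duplex core: star[j] pairs mature[L-1-oh-j] for j in 0..L-1-oh
    star = [comp[mature[L - 1 - oh - j]] for j in range(L - oh)]
    mm_pos = rng.choice(L - oh, size=cfg.duplex_mismatches, replace=False)
    for j in mm_pos:
        star[j] = _non_pairing(rng, mature[L - 1 - oh - j])
    star += [rng.choice(list(ALPHABET)) for _ in range(oh)]
    star = "".join(star)
    loop = _rand_seq(rng, int(rng.integers(cfg.loop_length[0], cfg.loop_length[1] + 1)))
    basal5 = _rand_seq(rng, cfg.basal_stem)
    basal3 = revcomp(basal5)
    if rng.random() < 0.5:
        body = basal5 + mature + loop + star + basal3
        return body, mature, star, "5p", len(basal5)
    body = basal5 + star + loop + mature + basal3
    return body, mature, star, "3p", len(basal5) + len(star) + len(loop)


def _occurrences(genome: Mapping[str, str], seq: str) -> int:
    n = 0
    rc = revcomp(seq)
    for text in genome.values():
        for pat in {seq, rc}:
            i = text.find(pat)
            while i != -1:
                n += 1
                i = text.find(pat, i + 1)
    return n


def generate_genome(config: SimConfig) -> tuple[ReferenceSet, SimTruth]:
    """Build the toy genome, decoys, mature catalog and planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_fam = max(1, config.n_families) if config.n_hairpins else config.n_families
    fam_ids = [f"MIR{9001 + f}" for f in range(n_fam)]
    members_seen: dict[str, int] = {f: 0 for f in fam_ids}

    hairpins = []
    for h in range(config.n_hairpins):
        fam = fam_ids[h % n_fam]
        letter = chr(ord("a") + members_seen[fam])
        members_seen[fam] += 1
        for _attempt in range(50):
            body, mature, star, arm, m_off = _build_hairpin(rng, config)
            if body.count(mature) == 1 and star != mature:
                break
        mature_id = f"sim-miR{fam[3:]}{letter}-{arm}"
        star_id = f"sim-miR{fam[3:]}{letter}-{'3p' if arm == '5p' else '5p'}*"
        hairpins.append((body, mature, star, arm, m_off, fam, mature_id, star_id))

    min_gap = 30
    total_feat = sum(len(h[0]) for h in hairpins)
    free = config.genome_length - total_feat - (config.n_hairpins + 1) * min_gap
    if free < 0:
        raise CapacityError(
            f"genome_length {config.genome_length} cannot hold "
            f"{config.n_hairpins} hairpins"
        )
    extra = (
        rng.multinomial(free, np.ones(config.n_hairpins + 1) / (config.n_hairpins + 1))
        if config.n_hairpins
        else np.array([free])
    )

    chrom = "chr1"
    parts = []
    pos = 0
    truth_hairpins: list[HairpinTruth] = []
    catalog: dict[str, str] = {}
    n_star = (
        config.n_hairpins if config.n_star_hairpins is None else config.n_star_hairpins
    )
    for h, (body, mature, star, arm, m_off, fam, mid, sid) in enumerate(hairpins):
        gap = int(extra[h]) + min_gap
        parts.append(_rand_seq(rng, gap))
        pos += gap
        on_minus = rng.random() < config.minus_strand_fraction
        genomic = revcomp(body) if on_minus else body
        strand = "-" if on_minus else "+"
        locus = GenomicLocus(chrom, pos, pos + len(body), strand)
        # mature arm span on the genome (forward coordinates)
        if on_minus:
            m_start = locus.end - m_off - len(mature)
        else:
            m_start = locus.start + m_off
        mature_locus = GenomicLocus(chrom, m_start, m_start + len(mature), strand)
        parts.append(genomic)
        pos += len(body)
        truth_hairpins.append(
            HairpinTruth(
                locus=locus,
                mature_locus=mature_locus,
                precursor=body,
                mature=mature,
                star=star,
                mature_arm=arm,
                family_id=fam,
                mature_id=mid,
                star_id=sid,
                emits_star=h < n_star,
            )
        )
        catalog[mid] = mature
        catalog[sid] = star
    tail = int(extra[-1]) + min_gap if config.n_hairpins else config.genome_length
    parts.append(_rand_seq(rng, tail))
    genome = {chrom: "".join(parts)}

    planted = {h.mature for h in truth_hairpins} | {h.star for h in truth_hairpins}

    def clean_decoy(length: int) -> str:
        for _ in range(50):
            s = _rand_seq(rng, length)
            if not any(p in s or revcomp(p) in s for p in planted):
                return s
        raise RuntimeError("could not draw a decoy free of planted sequences")

    nc_roles = ("rRNA", "tRNA", "snRNA", "snoRNA")
    structural = {
        f"{nc_roles[i % 4]}_{i + 1}": clean_decoy(
            int(rng.integers(*config.decoy_ncrna_length))
        )
        for i in range(config.n_decoy_ncrna)
    }
    rep_roles = ("TE", "mRNA")
    repeats = {
        f"{rep_roles[i % 2]}_{i + 1}": clean_decoy(
            int(rng.integers(*config.decoy_mrna_length))
        )
        for i in range(config.n_decoy_mrna)
    }

    # verify planted-mature uniqueness in the genome; collisions are
    # vanishingly rare at these lengths but must not pass silently
    for h in truth_hairpins:
        if _occurrences(genome, h.mature) != 1:
            raise RuntimeError(f"planted mature {h.mature_id} is not unique in genome")

    fam_weights: dict[str, float] = {}
    active = sorted({h.family_id for h in truth_hairpins})
    if active:
        w = np.exp(rng.uniform(np.log(1.0), np.log(100.0), size=len(active)))
        w /= w.sum()
        fam_weights = {f: float(x) for f, x in zip(active, w)}

    true_lfc = {f: float(config.condition_lfc.get(f, 0.0)) for f in active}
    truth = SimTruth(
        planted_hairpins=truth_hairpins,
        true_family_of_read={
            **{h.mature: h.family_id for h in truth_hairpins},
            **{h.star: h.family_id for h in truth_hairpins},
        },
        true_lfc=true_lfc,
        family_mean_fraction={
            f: config.mirna_fraction * w for f, w in fam_weights.items()
        },
    )
    refs = ReferenceSet(
        genome=genome,
        structural_ncrna=structural,
        repeats_mrna=repeats,
        mature_catalog=catalog,
    )
    return refs, truth


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi == 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mean)))


def _sample_background(
    rng: np.random.Generator,
    n: int,
    seqs: Sequence[str],
    weights_lengths: Sequence[int],
    weights_p: Sequence[float],
    counts: dict[str, int],
    both_strands: bool,
) -> None:
    if n == 0 or not seqs:
        return
    lens = rng.choice(weights_lengths, size=n, p=weights_p)
    seq_lens = np.array([len(s) for s in seqs])
    for L, c in zip(*np.unique(lens, return_counts=True)):
        valid = np.maximum(seq_lens - int(L) + 1, 0)
        if valid.sum() == 0:
            continue
        picks = rng.integers(0, valid.sum(), size=int(c))
        cum = np.cumsum(valid)
        idx = np.searchsorted(cum, picks, side="right")
        offs = picks - (cum[idx] - valid[idx])
        strands = (
            rng.integers(0, 2, size=int(c)) if both_strands else np.zeros(int(c), int)
        )
        for i, o, st in zip(idx, offs, strands):
            s = seqs[int(i)][int(o) : int(o) + int(L)]
            if st:
                s = revcomp(s)
            counts[s] = counts.get(s, 0) + 1


def simulate_libraries(
    refs: ReferenceSet, truth: SimTruth, config: SimConfig
) -> list[LibraryReads]:
    """Simulate replicated two-condition libraries with planted effects.

    Per hairpin, the expected mature count is depth × family fraction /
    family size, scaled by 2^lfc in the stress condition; replicate counts
    are NB(μ, φ).  Star reads are binomially thinned from the mature
    counts.  The background fills the library to exactly ``library_depth``
    reads, split 70/30 between decoy features and uniform genome windows
    with the configured length distribution.
    """
    config.validate()
    fam_sizes: dict[str, int] = {}
    for h in truth.planted_hairpins:
        fam_sizes[h.family_id] = fam_sizes.get(h.family_id, 0) + 1

    lengths = sorted(config.length_peak_weights)
    weights_p = np.array([config.length_peak_weights[k] for k in lengths], float)
    weights_p = weights_p / weights_p.sum()
    decoy_seqs = list(refs.structural_ncrna.values()) + list(refs.repeats_mrna.values())
    # genomic background emulates degradation and siRNA-like reads from
    # non-miRNA loci: sample from the genome with the hairpin spans excised
    genome_seqs: list[str] = []
    for chrom, text in refs.genome.items():
        spans = sorted(
            (h.locus.start, h.locus.end)
            for h in truth.planted_hairpins
            if h.locus.chrom == chrom
        )
        pos = 0
        for s, e in spans:
            if s > pos:
                genome_seqs.append(text[pos:s])
            pos = max(pos, e)
        if pos < len(text):
            genome_seqs.append(text[pos:])

    libraries = []
    lib_index = 0
    truth.per_library_expected_counts = {}
    for condition in (CONTROL, WATER_STRESS):
        for rep in range(1, config.replicates_per_condition + 1):
            rng = np.random.default_rng([config.seed, 7919, lib_index])
            lib_id = f"{condition}_{rep}"
            counts: dict[str, int] = {}
            expected: dict[str, float] = {}
            feature_total = 0
            for h in truth.planted_hairpins:
                frac = truth.family_mean_fraction.get(h.family_id, 0.0)
                mu = config.library_depth * frac / fam_sizes[h.family_id]
                if condition == WATER_STRESS:
                    mu *= 2.0 ** truth.true_lfc.get(h.family_id, 0.0)
                expected[h.mature_id] = mu
                c = _nb_draw(rng, mu, config.nb_dispersion)
                if c:
                    counts[h.mature] = counts.get(h.mature, 0) + c
                    feature_total += c
                if h.emits_star and c:
                    sc = int(rng.binomial(c, config.star_fraction))
                    if sc:
                        counts[h.star] = counts.get(h.star, 0) + sc
                        feature_total += sc
            background = config.library_depth - feature_total
            if background < 0:
                raise ValueError(
                    "library_depth too small for the simulated miRNA reads; "
                    "lower mirna_fraction or the condition effects"
                )
            n_decoy = int(rng.binomial(background, config.background_decoy_fraction))
            _sample_background(
                rng, n_decoy, decoy_seqs, lengths, weights_p, counts, False
            )
            _sample_background(
                rng, background - n_decoy, genome_seqs, lengths, weights_p, counts, True
            )
            libraries.append(
                LibraryReads(
                    library_id=lib_id,
                    condition=condition,
                    replicate=rep,
                    counts=counts,
                )
            )
            truth.per_library_expected_counts[lib_id] = expected
            lib_index += 1
    return libraries


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n{records[name]}\n")


def write_fixture(
    refs: ReferenceSet,
    truth: SimTruth,
    libraries: Sequence[LibraryReads],
    out_dir: str | Path,
    config: SimConfig | None = None,
) -> dict[str, Path]:
    """Write the fixture as FASTA/FASTQ/TSV files under one directory.

    Libraries are written both as gzipped collapsed FASTA (``seq_N_xCOUNT``
    headers) and as plain FASTQ (Phred+33, constant quality).  Reads are
    written in sorted sequence order so fixtures are byte-stable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, records in (
        ("genome", refs.genome),
        ("ncrna", refs.structural_ncrna),
        ("repeats_mrna", refs.repeats_mrna),
        ("mature", refs.mature_catalog),
    ):
        paths[name] = out / f"{name}.fa"
        _write_fasta(paths[name], records)

    for lib in libraries:
        fa = out / f"{lib.library_id}.collapsed.fa.gz"
        with gzip.open(fa, "wt") as fh:
            for i, seq in enumerate(sorted(lib.counts)):
                fh.write(f">seq_{i}_x{lib.counts[seq]}\n{seq}\n")
        fq = out / f"{lib.library_id}.fastq"
        with open(fq, "w") as fh:
            i = 0
            for seq in sorted(lib.counts):
                for _ in range(lib.counts[seq]):
                    fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                    i += 1
        paths[f"reads_{lib.library_id}"] = fa
        paths[f"fastq_{lib.library_id}"] = fq

    hp = out / "hairpins.tsv"
    with open(hp, "w") as fh:
        fh.write(
            "family_id\tmature_id\tstar_id\tchrom\tstart\tend\tstrand\t"
            "mature_start\tmature_end\tarm\tmature\tstar\tprecursor\temits_star\n"
        )
        for h in truth.planted_hairpins:
            fh.write(
                f"{h.family_id}\t{h.mature_id}\t{h.star_id}\t{h.locus.chrom}\t"
                f"{h.locus.start}\t{h.locus.end}\t{h.locus.strand}\t"
                f"{h.mature_locus.start}\t{h.mature_locus.end}\t{h.mature_arm}\t"
                f"{h.mature}\t{h.star}\t{h.precursor}\t{int(h.emits_star)}\n"
            )
    paths["hairpins"] = hp

    fam = out / "families.tsv"
    with open(fam, "w") as fh:
        fh.write("family_id\ttrue_lfc\tmean_fraction\n")
        for f in sorted(truth.true_lfc):
            fh.write(
                f"{f}\t{truth.true_lfc[f]}\t{truth.family_mean_fraction.get(f, 0.0)}\n"
            )
    paths["families"] = fam

    if config is not None:
        cfg_path = out / "config.yaml"
        config.to_yaml(cfg_path)
        paths["config"] = cfg_path
    return paths


def load_fixture(fixture_dir: str | Path) -> tuple[ReferenceSet, list[LibraryReads]]:
    """Read back a written fixture (references + collapsed libraries)."""
    from .annotate import load_reads

    d = Path(fixture_dir)

    def read_fasta(path: Path) -> dict[str, str]:
        records: dict[str, str] = {}
        name = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if name is not None:
                        records[name] = "".join(chunks)
                    name = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line.upper())
        if name is not None:
            records[name] = "".join(chunks)
        return records

    refs = ReferenceSet(
        genome=read_fasta(d / "genome.fa"),
        structural_ncrna=read_fasta(d / "ncrna.fa"),
        repeats_mrna=read_fasta(d / "repeats_mrna.fa"),
        mature_catalog=read_fasta(d / "mature.fa"),
    )
    libraries = []
    for fa in sorted(d.glob("*.collapsed.fa.gz")):
        lib_id = fa.name.split(".")[0]
        condition, rep = lib_id.rsplit("_", 1)
        libraries.append(
            load_reads(
                fa,
                "fasta_collapsed",
                library_id=lib_id,
                condition=condition,
                replicate=int(rep),
            )
        )
    return refs, libraries
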