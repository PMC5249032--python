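"""miRNA target scanning and annotation-term enrichment.

Target sites are found by sliding the reverse complement of the miRNA
along each transcript and counting mismatching positions; no indels or
bulges are allowed, which keeps the scan exactly checkable against naive
per-offset counting.  G:U wobble pairs (miRNA G opposite transcript U, or
miRNA U opposite transcript G) are scored separately with a configurable
penalty — 0.5 mismatch-equivalents by default, common plant-miRNA
practice; set 0 to ignore wobbles or 1 to count them as full mismatches.
Sites whose penalty total is at most ``max_mismatch`` (default 3, i.e.
"fewer than four mismatches") are reported.

Enrichment of a predicted target set against flat annotation terms uses
the one-sided hypergeometric over-representation test with BH-FDR across
terms; no term-hierarchy propagation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_fdr
from .seq import normalize, revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    position: int  # 0-based start of the site on the transcript
    mismatches: int
    wobbles: int
    matched: int
    score: float

    def __post_init__(self):
        if self.mismatches + self.wobbles + self.matched <= 0:
            raise ValueError("empty alignment")


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, -1) for c in normalize(seq)], dtype=np.int8)


def predict_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: Mapping[str, str],
    max_mismatch: float = 3,
    gu_penalty: float = 0.5,
) -> list[TargetSite]:
    """All bounded-mismatch complementary sites of one miRNA.

    Returns sites grouped by transcript (input order), best score first
    within each transcript.
    """
    mirna_seq = normalize(mirna_seq)
    if not 18 <= len(mirna_seq) <= 28:
        raise ValueError("miRNA length must lie in [18, 28]")
    if not transcripts:
        raise ValueError("no transcripts supplied")
    rc = _encode(revcomp(mirna_seq))
    # transcript base expected at alignment column p is rc[p]; a wobble is
    # miRNA G : transcript T or miRNA T : transcript G, which in reverse-
    # complement space means the observed base pairs rc[p] via G/T swap
    wobble_partner = np.full(4, -2, dtype=np.int8)
    wobble_partner[_CODE["A"]] = _CODE["G"]  # expected A (miRNA T) -> G wobbles
    wobble_partner[_CODE["C"]] = _CODE["T"]  # expected C (miRNA G) -> T wobbles
    L = rc.size
    sites: list[TargetSite] = []
    for tid, tseq in transcripts.items():
        enc = _encode(tseq)
        n = enc.size - L + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        is_match = windows == rc[None, :]
        is_wobble = windows == wobble_partner[rc][None, :]
        n_match = is_match.sum(axis=1)
        n_wob = is_wobble.sum(axis=1)
        n_mm = L - n_match - n_wob
        score = n_mm + gu_penalty * n_wob
        hits = np.nonzero(score <= max_mismatch + 1e-9)[0]
        tsites = [
            TargetSite(
                mirna_id=mirna_id,
                transcript_id=tid,
                position=int(p),
                mismatches=int(n_mm[p]),
                wobbles=int(n_wob[p]),
                matched=int(n_match[p]),
                score=float(score[p]),
            )
            for p in hits
        ]
        tsites.sort(key=lambda s: (s.score, s.position))
        sites.extend(tsites)
    return sites


def target_table(sites: Iterable[TargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "position": s.position,
                "mismatches": s.mismatches,
                "wobbles": s.wobbles,
                "score": s.score,
            }
            for s in sites
        ]
    )


def hypergeom_enrichment(
    target_genes: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of terms in a gene set.

    ``annotations`` maps gene → terms (flat, no hierarchy).  P(X ≥ k) is
    computed per term over the universe of N genes with K annotated, for a
    target set of n genes containing k annotated; BH-FDR across terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes)
    if not targets <= universe:
        raise ValueError("target genes must be a subset of the universe")
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        if gene not in universe:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    N, n = len(universe), len(targets)
    rows = []
    for term in sorted(term_genes):
        K = len(term_genes[term])
        k = len(term_genes[term] & targets)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, ""),
                "k_targets": k,
                "K_universe": K,
                "n_set": n,
                "N_universe": N,
                "pvalue": min(1.0, p),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_fdr(df["pvalue"].to_numpy())
        df = df.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(
            drop=True
        )
    return df
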