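"""RPTM quantification, family pooling and abundance-tier classification.

Abundances are normalized to reads per ten million (RPTM):
``count × 1e7 / library denominator``.  The denominator is, by default, the
total number of length-filtered reads in the library (a switch to
genome-mapped totals is available at the call sites that compute
denominators).  Family counts pool raw member counts; miRNA* members are
excluded from family pooling by default and summarized separately.

Families are classified into four abundance tiers by their mean RPTM under
control conditions: high (≥100,000), moderate ([10,000, 100,000)), low
([1,000, 10,000)) and extremely low ([0, 1,000)); every tier is closed at
its lower edge.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

TIERS = ("extremely_low", "low", "moderate", "high")

_FAMILY_RE = re.compile(
    r"^(?:[A-Za-z]{2,5}-)?miR(?P<num>\d+)(?P<var>[a-z]+)?(?:-(?P<arm>[35]p?))?(?P<star>\*)?$",
    re.IGNORECASE,
)


def family_of(mirna_id: str, overrides: Mapping[str, str] | None = None) -> str:
    """Collapse a mature miRNA name to its family id.

    ``gma-miR156b-5p`` → ``MIR156``; already-canonical ``MIR1512`` is left
    unchanged.  Species prefix, variant letters, arm suffix and a trailing
    ``*`` (star) are stripped.  An id the convention cannot parse is returned
    unchanged with a warning, so it forms a singleton family; ``overrides``
    (id→family) wins over the convention when supplied.
    """
    if overrides and mirna_id in overrides:
        return overrides[mirna_id]
    m = _FAMILY_RE.match(mirna_id.strip())
    if not m:
        warnings.warn(f"unparseable miRNA id {mirna_id!r}; kept as its own family",
                      stacklevel=2)
        return mirna_id
    return f"MIR{m.group('num')}"


def arm_of(mirna_id: str) -> str:
    m = _FAMILY_RE.match(mirna_id.strip())
    arm = m.group("arm") if m else None
    if arm in ("5p", "5"):
        return "5p"
    if arm in ("3p", "3"):
        return "3p"
    return "unknown"


def is_star_id(mirna_id: str) -> bool:
    return mirna_id.rstrip().endswith("*")


def rptm_normalize(
    raw_counts: Mapping[str, float], denominators: Mapping[str, float]
) -> dict[str, float]:
    """count × 1e7 / denominator, per library."""
    out = {}
    for lib, c in raw_counts.items():
        den = denominators[lib]
        if den <= 0:
            raise ValueError(f"non-positive RPTM denominator for library {lib!r}")
        out[lib] = c * 1e7 / den
    return out


def classify_tier(mean_rptm: float) -> str:
    if mean_rptm < 0:
        raise ValueError(f"negative RPTM: {mean_rptm}")
    if mean_rptm >= 100_000:
        return "high"
    if mean_rptm >= 10_000:
        return "moderate"
    if mean_rptm >= 1_000:
        return "low"
    return "extremely_low"


@dataclass
class MiRNAProfile:
    mirna_id: str
    family_id: str
    arm: str
    is_star: bool
    raw_counts: dict[str, int]
    rptm: dict[str, float]


@dataclass
class FamilyProfile:
    family_id: str
    member_ids: list[str]
    raw_counts: dict[str, int]
    rptm: dict[str, float]
    mean_rptm_control: float
    mean_rptm_stress: float
    tier: str


def build_mirna_profiles(
    catalog: Mapping[str, str],
    annotations: Mapping[str, "AnnotationResult"],
    denominators: Mapping[str, float],
    family_overrides: Mapping[str, str] | None = None,
) -> list[MiRNAProfile]:
    """Per-catalog-entry raw counts and RPTM across libraries.

    A read contributes its count to every catalog id it matched (multi-hit
    reads keep all ids); unmatched catalog entries get zero rows so absent
    miRNAs are still reported.
    """
    libs = list(annotations)
    counts: dict[str, dict[str, int]] = {mid: {l: 0 for l in libs} for mid in catalog}
    for lib, res in annotations.items():
        for seq, ids in res.matched_mirna_ids.items():
            if res.category_of_read.get(seq) != "mirbase":
                continue
            c = res.counts[seq]
            for mid in ids:
                if mid in counts:
                    counts[mid][lib] += c
    profiles = []
    for mid in sorted(catalog):
        profiles.append(
            MiRNAProfile(
                mirna_id=mid,
                family_id=family_of(mid, family_overrides),
                arm=arm_of(mid),
                is_star=is_star_id(mid),
                raw_counts=counts[mid],
                rptm=rptm_normalize(counts[mid], denominators),
            )
        )
    return profiles


def build_family_profiles(
    profiles: Iterable[MiRNAProfile],
    conditions: Mapping[str, str],
    include_star: bool = False,
    tier_condition: str = "control",
) -> list[FamilyProfile]:
    """Pool member counts into family profiles and classify abundance tiers.

    ``conditions`` maps library id → condition label.  The tier statistic is
    the family's mean RPTM over the libraries of ``tier_condition``
    (``"all"`` averages every library).
    """
    by_family: dict[str, list[MiRNAProfile]] = {}
    for p in profiles:
        if p.is_star and not include_star:
            continue
        by_family.setdefault(p.family_id, []).append(p)
    out = []
    for fam in sorted(by_family):
        members = by_family[fam]
        libs = list(members[0].raw_counts)
        raw = {l: sum(m.raw_counts[l] for m in members) for l in libs}
        rptm = {l: sum(m.rptm[l] for m in members) for l in libs}
        ctrl = [rptm[l] for l in libs if conditions[l] == "control"]
        strs = [rptm[l] for l in libs if conditions[l] == "water_stress"]
        mean_ctrl = float(np.mean(ctrl)) if ctrl else float("nan")
        mean_strs = float(np.mean(strs)) if strs else float("nan")
        if tier_condition == "all":
            tier_stat = float(np.mean(list(rptm.values())))
        else:
            tier_stat = mean_ctrl if tier_condition == "control" else mean_strs
        out.append(
            FamilyProfile(
                family_id=fam,
                member_ids=sorted(m.mirna_id for m in members),
                raw_counts=raw,
                rptm=rptm,
                mean_rptm_control=mean_ctrl,
                mean_rptm_stress=mean_strs,
                tier=classify_tier(tier_stat),
            )
        )
    return out


def star_summary(profiles: Iterable[MiRNAProfile]) -> pd.DataFrame:
    """Per-family mature vs star mean RPTM and their ratio.

    The ratio is star/mature mean RPTM; families with no mature signal get a
    NaN ratio and ``ratio_defined=False`` rather than an exception.
    """
    mature: dict[str, list[float]] = {}
    star: dict[str, list[float]] = {}
    for p in profiles:
        bucket = star if p.is_star else mature
        bucket.setdefault(p.family_id, []).append(float(np.mean(list(p.rptm.values()))))
    fams = sorted(set(mature) | set(star))
    rows = []
    for fam in fams:
        m = sum(mature.get(fam, []))
        s = sum(star.get(fam, []))
        defined = m > 0
        rows.append(
            {
                "family_id": fam,
                "mature_rptm": m,
                "star_rptm": s,
                "ratio": s / m if defined else float("nan"),
                "ratio_defined": defined,
            }
        )
    return pd.DataFrame(rows)


def mirna_table(profiles: Iterable[MiRNAProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"mirna_id": p.mirna_id, "family_id": p.family_id,
               "arm": p.arm, "is_star": p.is_star}
        row.update({f"count_{l}": c for l, c in sorted(p.raw_counts.items())})
        row.update({f"rptm_{l}": v for l, v in sorted(p.rptm.items())})
        rows.append(row)
    return pd.DataFrame(rows)


def family_table(families: Iterable[FamilyProfile]) -> pd.DataFrame:
    rows = []
    for f in families:
        row = {"family_id": f.family_id, "members": ",".join(f.member_ids)}
        row.update({f"count_{l}": c for l, c in sorted(f.raw_counts.items())})
        row.update({f"rptm_{l}": v for l, v in sorted(f.rptm.items())})
        row.update(
            {
                "mean_rptm_control": f.mean_rptm_control,
                "mean_rptm_stress": f.mean_rptm_stress,
                "tier": f.tier,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
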