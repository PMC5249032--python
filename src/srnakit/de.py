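"""Negative-binomial exact-test differential expression with BH-FDR.

Counts are modeled NB with variance μ + φμ²; a single common dispersion φ
is estimated by maximizing the replicate-conditional (qCML) likelihood
after library-size equalization, and each feature is tested with the
condition-pooled exact test: conditional on the pooled total, the
first-condition sum follows a ratio of NB probabilities, and the two-sided
p-value sums every outcome whose conditional probability does not exceed
the observed one.  At φ = 0 the conditional law is exactly binomial.

The reported log2 fold change is computed from pooled RPTM across the
replicates of each condition (stress over control), with a 0.5 pseudocount
applied only when one of the pooled sums is zero.  Calls use the stringent
rule |logFC| ≥ 1 and FDR < 0.05, plus a relaxed fold-change-only list.

This is a self-contained reimplementation of the classic exact-test scheme
for small-replicate count data; p-values approximate, rather than
duplicate, other implementations of the same scheme (library sizes are
equalized by total-count scaling, not quantile adjustment, and the
dispersion is a single common value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

_DISP_LO, _DISP_HI = 1e-6, 10.0


@dataclass
class CountMatrix:
    """Raw counts (features × libraries) with condition labels."""

    counts: pd.DataFrame
    conditions: dict[str, str]
    library_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.library_sizes:
            self.library_sizes = self.counts.sum(axis=0).to_dict()
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"libraries without condition labels: {sorted(missing)}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def libraries_of(self, condition: str) -> list[str]:
        return [l for l in self.counts.columns if self.conditions[l] == condition]


def log_fold_change(
    control_rptm: Sequence[float],
    stress_rptm: Sequence[float],
    pseudocount: float = 0.5,
) -> float:
    """log2 of pooled stress over pooled control abundance.

    The pseudocount is added to both sums only when either sum is zero;
    both-zero features are undefined and return NaN (flagged, not raised).
    """
    if len(control_rptm) == 0 or len(stress_rptm) == 0:
        raise ValueError("empty abundance list")
    c = float(np.sum(control_rptm))
    s = float(np.sum(stress_rptm))
    if c < 0 or s < 0:
        raise ValueError("abundances must be non-negative")
    if c == 0 and s == 0:
        return float("nan")
    if c == 0 or s == 0:
        c += pseudocount
        s += pseudocount
    return float(np.log2(s / c))


def _equalized_counts(cm: CountMatrix) -> tuple[pd.DataFrame, float]:
    sizes = np.array([cm.library_sizes[l] for l in cm.counts.columns], dtype=float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    common = float(np.exp(np.mean(np.log(sizes))))
    scaled = cm.counts.values * (common / sizes)[None, :]
    out = pd.DataFrame(np.rint(scaled).astype(np.int64),
                       index=cm.counts.index, columns=cm.counts.columns)
    return out, common


def _cond_loglik(y: np.ndarray, phi: float) -> float:
    """qCML log-likelihood of replicate splits given group totals.

    ``y`` is features × replicates for one condition (equalized sizes);
    conditional on the row total z, the split likelihood depends only on φ.
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - y.shape[1] * gammaln(r)
        - gammaln(z + n * r)
        + gammaln(n * r)
    )
    return float(ll.sum())


def estimate_dispersion(cm: CountMatrix) -> float:
    """Common NB dispersion by 1-D conditional-likelihood maximization.

    Returns 0 when the likelihood is maximized at the lower search bound
    (under-dispersed counts).  Raises when no condition has ≥2 replicates.
    """
    eq, _ = _equalized_counts(cm)
    groups = []
    for cond in sorted(set(cm.conditions.values())):
        libs = cm.libraries_of(cond)
        if len(libs) >= 2:
            y = eq[libs].values.astype(float)
            y = y[y.sum(axis=1) > 0]
            if y.size:
                groups.append(y)
    if not groups:
        raise ValueError(
            "no condition has replicates: supply a fixed dispersion instead "
            "of estimating one"
        )

    def neg_ll(log_phi: float) -> float:
        phi = 10.0 ** log_phi
        return -sum(_cond_loglik(y, phi) for y in groups)

    res = minimize_scalar(
        neg_ll,
        bounds=(np.log10(_DISP_LO), np.log10(_DISP_HI)),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(10.0 ** res.x)
    if phi <= _DISP_LO * 3:
        return 0.0
    return phi


def exact_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    dispersion: float,
    library_sizes_a: Sequence[float] | None = None,
    library_sizes_b: Sequence[float] | None = None,
) -> float:
    """Two-sided condition-pooled exact NB test for one feature.

    Counts are scaled to the geometric-mean common library size and summed
    per condition; conditioning on the total, the group-a sum is NB/NB
    (binomial when dispersion = 0) and the p-value accumulates every
    outcome at most as probable as the observed split.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    na, nb_ = len(a), len(b)
    sizes = np.concatenate(
        [
            np.asarray(library_sizes_a if library_sizes_a is not None else np.ones(na), float),
            np.asarray(library_sizes_b if library_sizes_b is not None else np.ones(nb_), float),
        ]
    )
    common = np.exp(np.mean(np.log(sizes)))
    scale = common / sizes
    ya = int(round(float((a * scale[:na]).sum())))
    yb = int(round(float((b * scale[na:]).sum())))
    t = ya + yb
    if t == 0:
        return 1.0
    y = np.arange(t + 1)
    if dispersion == 0:
        logp = binom.logpmf(y, t, na / (na + nb_))
    else:
        r = 1.0 / dispersion
        mu = t / (na + nb_)  # per-library mean at the common size under H0
        p = r / (r + mu)
        logp = nbinom.logpmf(y, na * r, p) + nbinom.logpmf(t - y, nb_ * r, p)
    logz = logsumexp(logp)
    obs = logp[ya]
    keep = logp <= obs + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[keep]) - logz)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    results: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Add stringent (|logFC| and FDR) and relaxed (|logFC| only) calls."""
    out = results.copy()
    lfc = out["logFC"]
    sig = out["fdr"] < fdr_max

    def _lab(up, down):
        return np.where(up, "up", np.where(down, "down", "ns"))

    out["call"] = _lab((lfc >= lfc_min) & sig, (lfc <= -lfc_min) & sig)
    out["call_relaxed"] = _lab(lfc >= lfc_min, lfc <= -lfc_min)
    out.loc[lfc.isna(), ["call", "call_relaxed"]] = "ns"
    return out


def run_de(
    cm: CountMatrix,
    control_label: str = "control",
    stress_label: str = "water_stress",
    dispersion: float | None = None,
    pseudocount: float = 0.5,
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Full exact-test differential-expression table for a count matrix.

    Columns: per-library RPTM, logFC (pooled RPTM, stress/control), a mean
    log2 counts-per-million abundance column, PValue, fdr and the two call
    columns.  Features are returned in the input row order.
    """
    libs_c = cm.libraries_of(control_label)
    libs_s = cm.libraries_of(stress_label)
    if not libs_c or not libs_s:
        raise ValueError("both conditions must have at least one library")
    if dispersion is None:
        dispersion = estimate_dispersion(cm)
    sizes_c = [cm.library_sizes[l] for l in libs_c]
    sizes_s = [cm.library_sizes[l] for l in libs_s]
    rptm = cm.counts.astype(float).copy()
    for l in cm.counts.columns:
        rptm[l] = cm.counts[l] * 1e7 / cm.library_sizes[l]
    rows = []
    for feat in cm.counts.index:
        c = cm.counts.loc[feat, libs_c].to_numpy(dtype=float)
        s = cm.counts.loc[feat, libs_s].to_numpy(dtype=float)
        lfc = log_fold_change(
            rptm.loc[feat, libs_c].tolist(), rptm.loc[feat, libs_s].tolist(),
            pseudocount,
        )
        pval = 1.0 if np.isnan(lfc) else exact_test(s, c, dispersion, sizes_s, sizes_c)
        total_size = sum(sizes_c) + sum(sizes_s)
        logcpm = float(np.log2((c.sum() + s.sum() + 0.5) / total_size * 1e6))
        row = {"feature_id": feat}
        row.update({f"rptm_{l}": rptm.loc[feat, l] for l in libs_c + libs_s})
        row.update({"logFC": lfc, "logCPM": logcpm, "PValue": pval})
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    out["fdr"] = bh_fdr(out["PValue"].to_numpy())
    out = call_de(out, lfc_min=lfc_min, fdr_max=fdr_max)
    out.attrs["dispersion"] = dispersion
    return out
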