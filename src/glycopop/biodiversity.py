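"""Ecological diversity statistics for glycoform abundance distributions.

Site-specific glycoform populations behave statistically like
ecological communities: a few dominant "species" and a long tail of
rare ones.  This module provides the standard community descriptors —
richness, Shannon entropy, the inverse Simpson index, evenness
(Pielou's J and the Hill ratio), Fisher's log-series alpha, and Renyi
diversity profiles — plus rank-abundance/octave tables and simple
abundance-model comparisons.

Inputs are abundance vectors of proportions (percent-of-total columns)
or integer counts.  Fisher's alpha needs counts; percentages are
converted to pseudo-counts by scaling to a configurable total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize as _opt
from scipy import stats as _stats

DEFAULT_RENYI_ORDERS = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, math.inf)


def _as_proportions(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("abundances must be non-negative")
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("abundance vector has no positive entries")
    p = v / v.sum()
    return p[p > 0]  # guard against underflow of extreme ratios


def richness(values: Sequence[float]) -> int:
    """Number of glycoforms with positive abundance."""
    v = np.asarray(values, dtype=float)
    return int(np.sum(v > 0))


def shannon(values: Sequence[float]) -> float:
    """Shannon entropy H = -sum p ln p (natural log)."""
    p = _as_proportions(values)
    return float(-(p * np.log(p)).sum())


def inverse_simpson(values: Sequence[float]) -> float:
    """Inverse Simpson index 1 / sum p_i^2.

    Equals the number of glycoforms for a perfectly even population
    and 1 when a single glycoform dominates completely.
    """
    p = _as_proportions(values)
    return float(1.0 / np.sum(p**2))


def pielou_evenness(values: Sequence[float]) -> float:
    """Pielou's J = H / ln S; 1 for uniform, undefined (NaN) for S=1."""
    s = richness(values)
    if s <= 1:
        return float("nan")
    return shannon(values) / math.log(s)


def hill_evenness(values: Sequence[float]) -> float:
    """Hill-ratio evenness: inverse Simpson / richness, in (0, 1]."""
    return inverse_simpson(values) / richness(values)


def renyi_entropy(values: Sequence[float], order: float) -> float:
    """Renyi entropy H_a = ln(sum p^a) / (1-a), with analytic limits.

    a=0 gives ln(richness), a=1 the Shannon limit, a=inf the dominance
    limit -ln(max p).  H_a is non-increasing in a.
    """
    p = _as_proportions(values)
    if order < 0:
        raise ValueError("Renyi order must be >= 0")
    if order == 0:
        return float(math.log(p.size))
    if order == 1:
        return float(-(p * np.log(p)).sum())
    if math.isinf(order):
        return float(-math.log(p.max()))
    # factor out the dominant proportion so p**order cannot underflow
    pmax = p.max()
    ratio_sum = np.sum((p / pmax) ** order)
    return float((order * math.log(pmax) + math.log(ratio_sum)) / (1.0 - order))


def renyi_profile(
    values: Sequence[float], orders: Sequence[float] = DEFAULT_RENYI_ORDERS
) -> pd.Series:
    """Renyi entropies over a grid of orders, as a pandas Series."""
    return pd.Series(
        {a: renyi_entropy(values, a) for a in orders}, name="renyi"
    )


def fisher_alpha(counts: Sequence[int], total: Optional[int] = None) -> float:
    """Fisher's log-series alpha: the solution of S = alpha ln(1 + N/alpha).

    ``counts`` are per-glycoform integer abundances (S = number of
    positive entries, N their sum, or an explicit ``total``).  Solved
    by bracketed root finding to 1e-8.  When every glycoform is a
    singleton (S == N) the relation diverges; +inf is returned.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0) or np.any(c != np.round(c)):
        raise ValueError("counts must be non-negative integers")
    s = int(np.sum(c > 0))
    n = int(total) if total is not None else int(c.sum())
    if s < 1:
        raise ValueError("need at least one species")
    if n < s:
        raise ValueError("total count cannot be below richness")
    if s == n:
        return float("inf")

    def f(alpha: float) -> float:
        return alpha * math.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return float("inf")
    return float(_opt.brentq(f, lo, hi, xtol=1e-8, rtol=1e-12))


def counts_from_percentages(values: Sequence[float], total: int = 1000) -> np.ndarray:
    """Convert a percentage/proportion vector to pseudo-counts.

    Proportions are scaled to ``total`` individuals and rounded;
    glycoforms present at any positive level keep at least one count so
    richness is preserved.
    """
    p = _as_proportions(values)
    counts = np.rint(p * total).astype(int)
    counts[counts == 0] = 1
    return counts


def rank_abundance(values: Sequence[float]) -> pd.DataFrame:
    """Descending abundances with ranks (Whittaker plot input)."""
    v = np.asarray(values, dtype=float)
    v = np.sort(v[v > 0])[::-1]
    if v.size == 0:
        raise ValueError("abundance vector has no positive entries")
    return pd.DataFrame({"rank": np.arange(1, v.size + 1), "abundance": v})


def octave_table(counts: Sequence[int]) -> pd.DataFrame:
    """Preston octave binning: species per doubling abundance class.

    Octave k collects species with counts in [2^k, 2^(k+1)).
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("no positive counts")
    octaves = np.floor(np.log2(c)).astype(int)
    rows = []
    for k in range(octaves.min(), octaves.max() + 1):
        rows.append(
            {
                "octave": k,
                "lower": 2.0**k,
                "upper": 2.0 ** (k + 1),
                "n_species": int(np.sum(octaves == k)),
            }
        )
    return pd.DataFrame(rows)


def log_series_expected_species(alpha: float, n: int, max_count: Optional[int] = None) -> pd.DataFrame:
    """Expected species with abundance k under the log series: alpha x^k / k."""
    x = n / (n + alpha)
    kmax = max_count if max_count is not None else n
    k = np.arange(1, kmax + 1)
    return pd.DataFrame({"abundance": k, "expected_species": alpha * x**k / k})


@dataclass
class DiversityProfile:
    """Per-sample summary of the standard diversity descriptors."""

    sample: str
    richness: int
    shannon: float
    inverse_simpson: float
    pielou_evenness: float
    hill_evenness: float
    fisher_alpha: float
    renyi: pd.Series

    def as_row(self) -> Dict[str, float]:
        row = {
            "sample": self.sample,
            "richness": self.richness,
            "shannon": self.shannon,
            "inverse_simpson": self.inverse_simpson,
            "pielou_evenness": self.pielou_evenness,
            "hill_evenness": self.hill_evenness,
            "fisher_alpha": self.fisher_alpha,
        }
        row.update({f"renyi_{a}": v for a, v in self.renyi.items()})
        return row


def diversity_profile(
    values: Sequence[float],
    sample: str = "sample",
    pseudo_count_total: int = 1000,
    orders: Sequence[float] = DEFAULT_RENYI_ORDERS,
) -> DiversityProfile:
    counts = counts_from_percentages(values, pseudo_count_total)
    return DiversityProfile(
        sample=sample,
        richness=richness(values),
        shannon=shannon(values),
        inverse_simpson=inverse_simpson(values),
        pielou_evenness=pielou_evenness(values),
        hill_evenness=hill_evenness(values),
        fisher_alpha=fisher_alpha(counts),
        renyi=renyi_profile(values, orders),
    )


def diversity_table(
    matrix: pd.DataFrame, pseudo_count_total: int = 1000
) -> pd.DataFrame:
    """Diversity descriptors for every sample (column) of a matrix."""
    rows = []
    for sample in matrix.columns:
        v = matrix[sample].dropna().to_numpy()
        if not np.any(v > 0):
            continue
        rows.append(diversity_profile(v, sample, pseudo_count_total).as_row())
    return pd.DataFrame(rows).set_index("sample")


def diversity_timecourse(
    matrices: Mapping[object, pd.DataFrame], index: str = "inverse_simpson"
) -> pd.DataFrame:
    """Simpson-family indices per sample over an ordered series of matrices.

    ``matrices`` maps timepoint labels to glycoform x sample abundance
    matrices sharing row ids.  Samples (columns) with no positive
    signal at a timepoint are skipped and recorded in
    ``attrs['flagged']``.
    """
    rows = []
    flagged = []
    for t, matrix in matrices.items():
        if matrix.empty:
            flagged.append((t, None))
            continue
        for sample in matrix.columns:
            v = matrix[sample].dropna().to_numpy()
            if not np.any(v > 0):
                flagged.append((t, sample))
                continue
            rows.append(
                {
                    "time": t,
                    "sample": sample,
                    "inverse_simpson": inverse_simpson(v),
                    "richness": richness(v),
                    "shannon": shannon(v),
                }
            )
    df = pd.DataFrame(rows, columns=["time", "sample", "inverse_simpson", "richness", "shannon"])
    if index not in ("inverse_simpson", "richness", "shannon"):
        raise ValueError(f"unknown index {index!r}")
    df.attrs["flagged"] = flagged
    return df


# ---------------------------------------------------------------------------
# Abundance-model comparison (exploratory)

def compare_abundance_models(counts: Sequence[int]) -> pd.DataFrame:
    """AIC comparison of three classical species-abundance models.

    Fits Fisher's log series (1 parameter, via alpha), a discretized
    lognormal (2 parameters, normal MLE on log counts), and the broken
    stick (0 parameters) to the observed per-species counts, scoring
    each by its log likelihood of the count vector.  Intended as an
    exploratory check that a log-series-like skew dominates, not as a
    formal model selection.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    s, n = c.size, c.sum()
    rows = []
    # log series: P(k) = -x^k / (k ln(1-x))
    alpha = fisher_alpha(c.astype(int))
    if math.isfinite(alpha):
        x = n / (n + alpha)
        ll = np.sum(c * np.log(x) - np.log(c) - math.log(-math.log1p(-x)))
        rows.append({"model": "log-series", "k_params": 1, "log_lik": float(ll)})
    # lognormal: normal MLE on ln(counts)
    mu, sigma = float(np.mean(np.log(c))), float(np.std(np.log(c)))
    if sigma > 0:
        ll = float(np.sum(_stats.norm.logpdf(np.log(c), mu, sigma) - np.log(c)))
        rows.append({"model": "lognormal", "k_params": 2, "log_lik": ll})
    # broken stick: expected proportion of rank-i species
    ranks = np.sort(c)[::-1]
    expected = np.array([np.sum(1.0 / np.arange(i, s + 1)) / s for i in range(1, s + 1)])
    expected = expected / expected.sum()
    obs_p = ranks / n
    ll = float(n * np.sum(obs_p * np.log(expected)))
    rows.append({"model": "broken-stick", "k_params": 0, "log_lik": ll})
    df = pd.DataFrame(rows)
    df["aic"] = 2 * df["k_params"] - 2 * df["log_lik"]
    return df.sort_values("aic").reset_index(drop=True)
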