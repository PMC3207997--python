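"""Negative-binomial exact test of observed vs simulated family counts.

The observed libraries and the simulated uniform-transcription datasets are
treated as two conditions of a count experiment.  Per-sample sequencing depth
is normalized by median-of-ratios size factors; per-condition variance is
estimated from the data as a raw-variance function w(q) of the base mean
(method of moments per family, pooled across families by isotonic
regression, floored at shot noise); each family's split of its count total
between the two conditions is then tested with a two-sided exact test on
negative-binomial masses, summing the probabilities of all splits no more
likely than the observed one.  P-values are Benjamini–Hochberg adjusted
across families.  All masses are computed in log space so that the
astronomically small p-values that arise at sequencing depth survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import nbinom, poisson
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

_TIE_REL = 1e-8  # relative tolerance when comparing log-masses for the tail sum


def estimate_size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over families f of k_fj / geometric-mean_j(k_f.), computed in
    log space; families containing any zero are excluded from the median
    (their geometric mean is zero).  ``pseudocount`` may be added to all
    counts when no family is all-positive.
    """
    k = counts.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        logk = np.log(k)
    all_pos = np.isfinite(logk).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no family has nonzero counts in every sample; "
            "consider estimate_size_factors(..., pseudocount=0.5)")
    geomean = np.exp(logk[all_pos].mean(axis=1))
    sf = np.median(k[all_pos] / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns)


@dataclass
class DispersionModel:
    """Raw-variance function v(q): extra-Poisson variance of normalized counts.

    ``method`` is "isotonic" (monotone pooling of per-family method-of-moments
    estimates across families, interpolated in q) or "per-family" (no
    pooling).  Raw variance is floored at zero, i.e. total variance never
    falls below shot noise.
    """

    q: np.ndarray                 # base means, ascending
    v: np.ndarray                 # fitted raw variances at q
    method: str
    per_family: pd.Series | None = None

    def __call__(self, q0: float, family: str | None = None) -> float:
        if self.method == "per-family":
            if family is None or family not in self.per_family.index:
                raise KeyError("per-family dispersion model needs a known family")
            return float(self.per_family[family])
        if len(self.q) == 1:
            return float(self.v[0])
        return float(np.interp(q0, self.q, self.v))


def fit_dispersion(counts: pd.DataFrame, size_factors: pd.Series,
                   method: str = "isotonic") -> DispersionModel:
    """Fit the raw-variance function for one condition's samples.

    Per family: base mean q_f = mean_j(k_fj/s_j); the raw variance is the
    sample variance of normalized counts minus the shot-noise term
    z_f = q_f * mean_j(1/s_j), floored at zero.  With only a dozen families a
    local regression is unstable, so pooling uses isotonic regression of raw
    variance on base mean.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    s = size_factors[counts.columns].to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / s
    q = norm.mean(axis=1)
    w = norm.var(axis=1, ddof=1)
    z = q * np.mean(1.0 / s)
    v_raw = np.maximum(w - z, 0.0)

    per_family = pd.Series(v_raw, index=counts.index)
    order = np.argsort(q)
    q_sorted, v_sorted = q[order], v_raw[order]
    if method == "isotonic" and len(q) >= 2:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        v_fit = iso.fit_transform(q_sorted, v_sorted)
    else:
        v_fit = v_sorted
        method = "per-family" if method == "per-family" else method
    return DispersionModel(q=q_sorted, v=v_fit, method=method, per_family=per_family)


def _log_pmf(mu: float, var: float):
    """Log-mass function for mean/variance, NB when var > mu else Poisson."""
    if var > mu * (1.0 + 1e-8):
        r = mu * mu / (var - mu)
        p = r / (r + mu)
        return lambda k: nbinom.logpmf(k, r, p)
    return lambda k: poisson.logpmf(k, mu)


def nb_exact_test(k_a: int, k_b: int, s_a: np.ndarray, s_b: np.ndarray,
                  v_a: float, v_b: float, max_enumeration: int = 2_000_000):
    """Two-sided exact test of the split of S = k_a + k_b between conditions.

    Condition sums are modeled as K_A ~ NB(mu_A, var_A) with
    mu_A = q0 * sum(s_a), var_A = mu_A + v_a * sum(s_a^2) (likewise B), where
    q0 is the pooled per-unit mean.  The p-value sums Pr(a)Pr(b) over all
    splits a+b=S whose joint mass does not exceed the observed one, divided by
    the total mass on a+b=S.  For very large S the enumeration is windowed to
    the region carrying all but a negligible (<1e-12) share of the mass.

    Returns ``(p, log10_p)``; the log10 p-value stays informative after the
    linear-scale value underflows to 0.
    """
    k_a, k_b = int(k_a), int(k_b)
    S = k_a + k_b
    if S == 0:
        return 1.0, 0.0
    sa, sb = float(np.sum(s_a)), float(np.sum(s_b))
    q0 = S / (sa + sb)
    mu_a, mu_b = q0 * sa, q0 * sb
    var_a = mu_a + v_a * float(np.sum(np.square(s_a)))
    var_b = mu_b + v_b * float(np.sum(np.square(s_b)))
    lp_a, lp_b = _log_pmf(mu_a, var_a), _log_pmf(mu_b, var_b)

    if S + 1 <= max_enumeration:
        ks = np.arange(S + 1)
    else:
        sd = np.sqrt(var_a) + np.sqrt(var_b)
        half = max(12.0 * sd, 1000.0)
        lo = max(0, int(min(mu_a - half, k_a - half)))
        hi = min(S, int(max(mu_a + half, k_a + half)))
        ks = np.arange(lo, hi + 1)

    lt = lp_a(ks) + lp_b(S - ks)
    l_obs = float(lp_a(np.array([k_a]))[0] + lp_b(np.array([k_b]))[0])
    l_total = float(logsumexp(lt))
    in_tail = lt <= l_obs + _TIE_REL * abs(l_obs)
    l_num = float(logsumexp(lt[in_tail])) if in_tail.any() else -np.inf
    log_p = min(l_num - l_total, 0.0)
    return float(np.exp(log_p)), log_p / np.log(10.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a nonempty 1-d vector")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_table1(observed, simulated, size_factor_mode: str = "joint",
               dispersion_method: str = "isotonic") -> pd.DataFrame:
    """Full family-level test: observed libraries vs simulated null datasets.

    ``observed`` and ``simulated`` are FamilyCountMatrix objects (or plain
    count frames) sharing family order.  Size factors are estimated jointly
    across all columns by default.  Returns one row per family with base
    means, fold change (simulated/observed — an overexpressed family has fold
    change < 1), raw and BH-adjusted p-values, and log10 p-values.
    """
    obs = observed.counts if hasattr(observed, "counts") else observed
    sim = simulated.counts if hasattr(simulated, "counts") else simulated
    if list(obs.index) != list(sim.index):
        raise ValueError("observed and simulated matrices disagree on families")
    # disambiguate column names so both conditions may reuse sample ids
    obs = obs.rename(columns=lambda c: f"A:{c}")
    sim = sim.rename(columns=lambda c: f"B:{c}")

    joint = pd.concat([obs, sim], axis=1)
    if size_factor_mode == "joint":
        sf = estimate_size_factors(joint)
        sf_a, sf_b = sf[obs.columns], sf[sim.columns]
    elif size_factor_mode == "per-condition":
        sf_a, sf_b = estimate_size_factors(obs), estimate_size_factors(sim)
    else:
        raise ValueError(f"unknown size_factor_mode {size_factor_mode!r}")

    disp_a = fit_dispersion(obs, sf_a, method=dispersion_method)
    disp_b = fit_dispersion(sim, sf_b, method=dispersion_method)

    s_a, s_b = sf_a.to_numpy(), sf_b.to_numpy()
    rows = []
    for family in obs.index:
        k_a = int(obs.loc[family].sum())
        k_b = int(sim.loc[family].sum())
        base_a = float((obs.loc[family] / sf_a).mean())
        base_b = float((sim.loc[family] / sf_b).mean())
        S = k_a + k_b
        q0 = S / (s_a.sum() + s_b.sum())
        v_a = disp_a(q0, family)
        v_b = disp_b(q0, family)
        p, log10_p = nb_exact_test(k_a, k_b, s_a, s_b, v_a, v_b)
        fold = base_b / base_a if base_a > 0 else np.inf
        rows.append({"family": family,
                     "base_mean_observed": base_a,
                     "base_mean_simulated": base_b,
                     "fold_change": fold,
                     "p_raw": p,
                     "log10_p_raw": log10_p})
    result = pd.DataFrame(rows).set_index("family")
    result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
    # log-space BH mirrors the linear one and survives underflow
    n = len(result)
    order = np.argsort(result["log10_p_raw"].to_numpy(), kind="stable")
    ranked = result["log10_p_raw"].to_numpy()[order] + np.log10(n) - np.log10(np.arange(1, n + 1))
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    log_adj = np.empty(n)
    log_adj[order] = np.minimum(ranked, 0.0)
    result["log10_p_adj"] = log_adj
    return result


def write_results(result: pd.DataFrame, path):
    """Results TSV in report column layout."""
    out = result.reset_index().rename(columns={
        "family": "Repeat Family", "fold_change": "Fold Change",
        "p_raw": "p-value", "p_adj": "Adjusted for multiple comparisons p-value"})
    out.to_csv(path, sep="\t", index=False)
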