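"""Inferential layer for the habitat comparison.

Per-property two-group comparison (rank-sum), correlation structure among
properties (Kendall tau-b), a Mantel permutation test relating genomic
similarity to habitat co-membership, and generalized least squares whose
residual covariance is the fingerprint similarity matrix itself — the
relatedness-corrected estimate of the habitat effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .fingerprint import SimilarityMatrix

__all__ = [
    "TestResult",
    "GlsFit",
    "wilcoxon_rank_sum",
    "kendall_tau",
    "correlation_matrix",
    "mantel",
    "similarity_to_covariance",
    "pgls_fit",
    "five_number_summary",
    "benjamini_hochberg",
    "habitat_report",
]

HABITATS = ("sediment", "water")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# Rank-sum (Mann-Whitney) habitat comparison


def _rank_sum_distribution(n1: int, n: int) -> dict[int, int]:
    """Counts of subsets of {1..n} of size n1 by rank sum (exact null)."""
    # dp[k][s] = number of size-k subsets with sum s
    max_sum = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return {s: int(c) for s, c in enumerate(dp[n1]) if c > 0}


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided rank-sum test for a location difference between two groups.

    Midranks handle ties.  The p-value is exact (full enumeration of rank
    splits) for tie-free samples with n1+n2 <= 12; otherwise the normal
    approximation with tie and continuity corrections is used.  Two groups
    holding the identical constant give p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    if np.all(pooled == pooled[0]):
        return TestResult(w, 1.0, n1, n2, "rank-sum (degenerate)")
    has_ties = np.unique(pooled).size < pooled.size
    n = n1 + n2
    if not has_ties and n <= 12:
        dist = _rank_sum_distribution(n1, n)
        total = math.comb(n, n1)
        w_int = int(round(w))
        cdf = sum(c for s, c in dist.items() if s <= w_int) / total
        sf = sum(c for s, c in dist.items() if s >= w_int) / total
        p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(w, p, n1, n2, "rank-sum (exact)")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic", use_continuity=True)
    return TestResult(w, float(res.pvalue), n1, n2, "rank-sum (normal approx.)")


# ---------------------------------------------------------------------------
# Kendall correlation


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Kendall tau-b with two-sided p (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least three paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Kendall tau undefined for a constant vector")
    no_ties = np.unique(x).size == x.size and np.unique(y).size == y.size
    method = "exact" if (no_ties and x.size <= 8) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return TestResult(float(res.statistic), float(res.pvalue), x.size, x.size, f"kendall-tau-b ({method})")


def correlation_matrix(
    table: pd.DataFrame,
    properties: Sequence[str] | None = None,
    habitat: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Kendall correlations among property columns.

    Rows with a missing value are dropped pairwise; a constant (or too
    short) column yields NaN entries.  Returns (tau, p) DataFrames.
    """
    if habitat is not None:
        table = table[table["habitat"] == habitat]
    if properties is None:
        properties = [c for c in table.columns if c != "habitat"]
    k = len(properties)
    tau = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    np.fill_diagonal(tau, 1.0)
    np.fill_diagonal(pval, 0.0)
    for i in range(k):
        for j in range(i + 1, k):
            pair = table[[properties[i], properties[j]]].dropna()
            if len(pair) < 3:
                continue
            try:
                r = kendall_tau(pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy())
            except ValueError:
                continue
            tau[i, j] = tau[j, i] = r.statistic
            pval[i, j] = pval[j, i] = r.p_value
    return (
        pd.DataFrame(tau, index=properties, columns=properties),
        pd.DataFrame(pval, index=properties, columns=properties),
    )


# ---------------------------------------------------------------------------
# Mantel test


def mantel(
    s: SimilarityMatrix,
    habitat: Sequence[str],
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
    coding: str = "comembership",
) -> TestResult:
    """Permutation test for association between similarity and habitat.

    The habitat structure matrix uses co-membership coding by default
    (H_ij = 1 when strains share a habitat), so a positive statistic reads
    "similarity is larger within habitat"; ``coding="distance"`` flips it.
    r is the Pearson correlation over the strictly-upper-triangle entries;
    the p-value permutes strains jointly over rows and columns and includes
    the observed statistic in the count (+1/+1 rule).
    """
    habitat = np.asarray(habitat)
    n = len(s)
    if habitat.size != n:
        raise ValueError("habitat labels do not match the similarity matrix")
    levels, inverse = np.unique(habitat, return_inverse=True)
    if levels.size < 2:
        raise ValueError("need at least two habitat levels")
    same = (inverse[:, None] == inverse[None, :]).astype(float)
    if coding == "distance":
        same = 1.0 - same
    elif coding != "comembership":
        raise ValueError("coding must be 'comembership' or 'distance'")
    iu = np.triu_indices(n, k=1)
    h_vec = same[iu]
    if np.all(h_vec == h_vec[0]):
        raise ValueError("habitat structure matrix is constant")
    s_vec = s.values[iu]

    def _pearson(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r_obs = _pearson(s_vec, h_vec)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_p = _pearson(s.values[np.ix_(p, p)][iu], h_vec)
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError("alternative must be 'greater' or 'two-sided'")
    p_value = (1 + count) / (1 + n_perm)
    n1 = int(np.sum(inverse == 0))
    return TestResult(r_obs, p_value, n1, n - n1, f"mantel ({alternative}, {coding})")


# ---------------------------------------------------------------------------
# Similarity matrix as residual covariance


def similarity_to_covariance(
    s: SimilarityMatrix | np.ndarray,
    eps_factor: float = 1e-8,
    return_info: bool = False,
):
    """Repair a similarity matrix into a symmetric positive-definite covariance.

    Symmetrize, force a unit diagonal, then clip eigenvalues below
    ``eps_factor * lambda_max`` up to that floor and reconstruct.  Returns the
    SPD matrix, plus (min eigenvalue before, after) when ``return_info``.
    """
    a = s.values if isinstance(s, SimilarityMatrix) else np.asarray(s, dtype=float)
    a = (a + a.T) / 2.0
    a = a.copy()
    np.fill_diagonal(a, 1.0)
    w, q = np.linalg.eigh(a)
    if not np.all(np.isfinite(w)):
        raise ValueError("similarity matrix is not repairable (non-finite spectrum)")
    eps = eps_factor * w.max()
    w_clipped = np.clip(w, eps, None)
    v = (q * w_clipped) @ q.T
    v = (v + v.T) / 2.0
    if return_info:
        return v, (float(w.min()), float(w_clipped.min()))
    return v


@dataclass
class GlsFit:
    """Generalized least squares fit of property ~ habitat with fixed V."""

    beta: np.ndarray  # (intercept, habitat effect for sediment)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    sigma2: float
    df: int
    names: tuple[str, str] = ("intercept", "habitat[sediment]")
    v_conditioning: tuple[float, float] | None = None  # min eigenvalue before/after repair

    @property
    def habitat_effect(self) -> float:
        return float(self.beta[1])

    @property
    def habitat_p(self) -> float:
        return float(self.p[1])

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        tq = sps.t.ppf(0.5 + level / 2.0, self.df)
        return np.column_stack([self.beta - tq * self.se, self.beta + tq * self.se])

    def as_dict(self) -> dict:
        return {
            "beta": [float(b) for b in self.beta],
            "se": [float(v) for v in self.se],
            "t": [float(v) for v in self.t],
            "p": [float(v) for v in self.p],
            "sigma2": float(self.sigma2),
            "df": self.df,
            "names": list(self.names),
        }


def pgls_fit(
    y: Sequence[float],
    habitat: Sequence[str],
    v: np.ndarray,
    v_conditioning: tuple[float, float] | None = None,
) -> GlsFit:
    """GLS of a property on habitat with residual covariance sigma^2 * V.

    V encodes pairwise genomic relatedness (a repaired similarity matrix),
    so the habitat coefficient is estimated net of the tendency of related
    strains to resemble one another.  Computed by whitening through the
    Cholesky factor of V; the habitat coefficient gets a two-sided t-test
    on n − 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    habitat = np.asarray(habitat)
    n = y.size
    if habitat.size != n or v.shape != (n, n):
        raise ValueError("y, habitat and V dimensions do not match")
    ind = (habitat == "sediment").astype(float)
    if ind.sum() == 0 or ind.sum() == n:
        raise ValueError("both habitat levels must be present")
    if n < 3:
        raise ValueError("need at least three strains for a two-parameter fit")
    x = np.column_stack([np.ones(n), ind])
    c, low = linalg.cho_factor(v, lower=True)
    xw = linalg.solve_triangular(c, x, lower=True)
    yw = linalg.solve_triangular(c, y, lower=True)
    xtx = xw.T @ xw
    beta = linalg.solve(xtx, xw.T @ yw, assume_a="pos")
    resid = yw - xw @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return GlsFit(beta=beta, se=se, t=t, p=p, sigma2=sigma2, df=df, v_conditioning=v_conditioning)


# ---------------------------------------------------------------------------
# Reporting


def five_number_summary(values: Sequence[float]) -> dict:
    """Boxplot five numbers: whiskers at Q25 − 1.5·IQR and Q75 + 1.5·IQR.

    Quantiles use linear interpolation (R's default type 7).  Observations
    beyond the whisker fences are listed as outliers.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no observations")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q75 - q25
    lo = q25 - 1.5 * iqr
    hi = q75 + 1.5 * iqr
    outliers = v[(v < lo) | (v > hi)]
    return {
        "whisker_low": float(lo),
        "q25": float(q25),
        "median": float(med),
        "q75": float(q75),
        "whisker_high": float(hi),
        "outliers": [float(o) for o in np.sort(outliers)],
        "n": int(v.size),
    }


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj


def _subset_similarity(s: SimilarityMatrix, ids: Sequence[str]) -> SimilarityMatrix:
    pos = {lab: i for i, lab in enumerate(s.labels)}
    idx = [pos[i] for i in ids]
    return SimilarityMatrix(list(ids), s.values[np.ix_(idx, idx)])


def habitat_report(
    table: pd.DataFrame,
    s: SimilarityMatrix,
    n_perm: int = 9999,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> dict:
    """Full inferential summary of a property table + similarity matrix.

    Per property: group boxplot five-number summaries, the rank-sum habitat
    comparison, and the similarity-corrected GLS habitat test.  Plus Kendall
    correlation matrices for all / sediment-only / water-only strains, the
    Mantel similarity-vs-habitat test, and the hydrophobicity vs EPS-protein
    contrast per habitat.  Failures for one property are recorded and do not
    abort the others.  Raw p-values are reported; a Benjamini-Hochberg
    adjusted column is provided alongside for reference.
    """
    missing = set(table.index) ^ set(s.labels)
    if missing:
        raise ValueError(f"table and similarity matrix disagree on strains: {sorted(missing)[:5]}")
    s = _subset_similarity(s, list(table.index))
    properties = [c for c in table.columns if c != "habitat"]
    habitat = table["habitat"].to_numpy()
    v_full, cond = similarity_to_covariance(s, return_info=True)

    out: dict = {"alpha": alpha, "n_perm": n_perm, "properties": {}}
    raw_p: dict[str, float] = {}
    for prop in properties:
        entry: dict = {}
        try:
            col = table[prop]
            sed = col[table["habitat"] == "sediment"].dropna().to_numpy()
            wat = col[table["habitat"] == "water"].dropna().to_numpy()
            entry["sediment"] = five_number_summary(sed)
            entry["water"] = five_number_summary(wat)
            wres = wilcoxon_rank_sum(sed, wat)
            entry["wilcoxon"] = wres.as_dict()
            entry["wilcoxon"]["significant"] = bool(wres.p_value < alpha)
            raw_p[prop] = wres.p_value
            ok = col.notna()
            if ok.all():
                fit = pgls_fit(col.to_numpy(), habitat, v_full, v_conditioning=cond)
            else:
                sub = _subset_similarity(s, list(table.index[ok]))
                v_sub, cond_sub = similarity_to_covariance(sub, return_info=True)
                fit = pgls_fit(col[ok].to_numpy(), habitat[ok.to_numpy()], v_sub, v_conditioning=cond_sub)
            entry["pgls"] = fit.as_dict()
            entry["pgls"]["habitat_p"] = fit.habitat_p
            entry["pgls"]["significant"] = bool(fit.habitat_p < alpha)
        except (ValueError, linalg.LinAlgError) as exc:  # pragma: no cover - defensive
            entry["error"] = str(exc)
        out["properties"][prop] = entry

    if raw_p:
        names = list(raw_p)
        adj = benjamini_hochberg([raw_p[k] for k in names])
        out["wilcoxon_bh_adjusted"] = {k: float(a) for k, a in zip(names, adj)}

    out["correlations"] = {}
    for label, hab in (("all", None), ("sediment", "sediment"), ("water", "water")):
        tau, pv = correlation_matrix(table, properties, habitat=hab)
        out["correlations"][label] = {
            "properties": properties,
            "tau": tau.to_numpy().tolist(),
            "p": pv.to_numpy().tolist(),
        }

    out["mantel"] = mantel(s, habitat, n_perm=n_perm, seed=seed).as_dict()

    pair: dict = {}
    for hab in HABITATS:
        sub = table[table["habitat"] == hab][["hydrophobicity", "eps_protein"]].dropna()
        try:
            r = kendall_tau(sub["hydrophobicity"].to_numpy(), sub["eps_protein"].to_numpy())
            pair[hab] = r.as_dict()
            pair[hab]["significant"] = bool(r.p_value < alpha)
        except ValueError as exc:
            pair[hab] = {"error": str(exc)}
    out["hydrophobicity_vs_eps_protein"] = pair
    return out
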