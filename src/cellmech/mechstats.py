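"""Elasticity-map cleaning, summary statistics, adhesion energy and the
group-comparison tests used for cell-mechanics data.

Quantile convention: median and quartiles use linear interpolation
(numpy default).  The inverse-Gaussian fit uses the closed-form MLE
(mu_hat = sample mean, lambda_hat = n / sum(1/x_i - 1/mu_hat)), appropriate
for positive right-skewed elasticity distributions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .curves import ElasticityMap

DESIGNS = ("kw_dunn", "welch_anova_gh", "mann_whitney", "welch_t")


# ---------------------------------------------------------------------------
# map cleaning and summaries
# ---------------------------------------------------------------------------

def clean_elasticity_map(emap: ElasticityMap,
                         bounds_Pa: tuple = (10.0, 1.0e5),
                         cell_mask: Optional[np.ndarray] = None
                         ) -> tuple[np.ndarray, float]:
    """Outlier removal for an elasticity map.

    Keeps valid-mask pixels whose modulus lies inside ``bounds_Pa``
    (non-contacting points and glass-like substrate responses fall outside),
    optionally restricted to a supplied cell mask.  Returns the flat value
    array and the kept fraction (relative to all map pixels).
    """
    lo, hi = bounds_Pa
    if not lo < hi:
        raise ValueError("bounds must satisfy low < high")
    keep = emap.valid & (emap.modulus_Pa >= lo) & (emap.modulus_Pa <= hi)
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != emap.shape:
            raise ValueError("cell mask shape does not match the map")
        keep &= cell_mask
    values = emap.modulus_Pa[keep]
    if values.size == 0:
        raise ValueError("no elasticity values survive cleaning")
    return values, float(keep.sum() / emap.valid.size)


def invgauss_mle(values: np.ndarray) -> tuple[float, float]:
    """Closed-form inverse-Gaussian MLE (mu_hat, lambda_hat)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("inverse-Gaussian fit requires n >= 2")
    if np.any(x <= 0):
        raise ValueError("inverse-Gaussian support is the positive reals")
    mu = x.mean()
    denom = np.sum(1.0 / x - 1.0 / mu)
    if denom <= 0:
        raise ValueError("degenerate sample for inverse-Gaussian fit")
    return float(mu), float(x.size / denom)


@dataclass(frozen=True)
class MechanicsSummary:
    """Per-cell (or per-group) elasticity summary."""
    n: int
    median_Pa: float
    iqr_Pa: float
    inv_gauss_mu_Pa: Optional[float] = None
    inv_gauss_lambda_Pa: Optional[float] = None
    lilliefors_p: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "n": self.n, "median_Pa": self.median_Pa, "iqr_Pa": self.iqr_Pa,
            "inv_gauss_mu_Pa": self.inv_gauss_mu_Pa,
            "inv_gauss_lambda_Pa": self.inv_gauss_lambda_Pa,
            "lilliefors_p": self.lilliefors_p,
        }


def summarize(values, fit_invgauss: bool = True,
              lilliefors: bool = False, lilliefors_seed: int = 0
              ) -> MechanicsSummary:
    """Median, inter-quartile range and inverse-Gaussian MLE of a sample.

    The Lilliefors normality p-value is computed on request (it needs a
    seeded Monte-Carlo null table and n >= 5).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ValueError("summarize needs at least one value")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    mu = lam = None
    if fit_invgauss:
        try:
            mu, lam = invgauss_mle(x)
        except ValueError as exc:
            if "positive reals" in str(exc):
                raise
            # constant / too-small samples carry no distribution fit
            mu = lam = None
    p = None
    if lilliefors and x.size >= 5:
        p = lilliefors_normality(x, seed=lilliefors_seed)
    return MechanicsSummary(n=int(x.size), median_Pa=float(med),
                            iqr_Pa=float(q3 - q1), inv_gauss_mu_Pa=mu,
                            inv_gauss_lambda_Pa=lam, lilliefors_p=p)


# ---------------------------------------------------------------------------
# Lilliefors normality test (Monte-Carlo p)
# ---------------------------------------------------------------------------

_LILLIEFORS_TABLES: dict = {}


def _lilliefors_statistic(x: np.ndarray) -> float:
    n = x.size
    s = np.std(x, ddof=1)
    if s == 0:
        raise ValueError("constant sample: s.d. is zero")
    z = np.sort((x - x.mean()) / s)
    cdf = stats.norm.cdf(z)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - cdf)
    d_minus = np.max(cdf - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _null_table(n: int, reps: int, seed: int) -> np.ndarray:
    key = (n, reps, seed)
    if key not in _LILLIEFORS_TABLES:
        rng = np.random.default_rng(seed)
        out = np.empty(reps)
        i_over_n = np.arange(1, n + 1) / n
        im1_over_n = np.arange(n) / n
        chunk = max(1, int(5e6 // n))
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            x = rng.standard_normal((m, n))
            z = (x - x.mean(axis=1, keepdims=True)) \
                / x.std(axis=1, ddof=1, keepdims=True)
            z.sort(axis=1)
            cdf = stats.norm.cdf(z)
            d = np.maximum((i_over_n - cdf).max(axis=1),
                           (cdf - im1_over_n).max(axis=1))
            out[done:done + m] = d
            done += m
        out.sort()
        _LILLIEFORS_TABLES[key] = out
    return _LILLIEFORS_TABLES[key]


def lilliefors_normality(values, reps: int = 10_000, seed: int = 0) -> float:
    """Lilliefors (KS with estimated mean and s.d.) normality test.

    The p-value is simulation-based: the null distribution of the statistic
    is built from ``reps`` seeded standard-normal samples of the same size
    (cached per sample size), and p is the fraction of null statistics at
    or above the observed one (with the +1 finite-sample correction).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise ValueError("Lilliefors test requires n >= 5")
    d = _lilliefors_statistic(x)
    table = _null_table(x.size, reps, seed)
    n_ge = table.size - np.searchsorted(table, d, side="left")
    return float((n_ge + 1) / (table.size + 1))


# ---------------------------------------------------------------------------
# representative sampling and adhesion energy
# ---------------------------------------------------------------------------

def select_representative_sample(values, n: int) -> np.ndarray:
    """The ``n`` values closest to the sample median.

    Ties are broken by the smaller value, then by input order.
    """
    x = np.asarray(values, dtype=float)
    if n > x.size:
        raise ValueError("cannot select more values than available")
    med = np.median(x)
    order = np.lexsort((np.arange(x.size), x, np.abs(x - med)))
    return x[order[:n]]


def equivalent_contact_radius(area: float) -> float:
    """Radius of the circle covering the same area: a = sqrt(area / pi).

    Works in any consistent unit system (m^2 -> m, um^2 -> um).
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    return float(np.sqrt(area / np.pi))


@dataclass(frozen=True)
class AdhesionEnergyInput:
    """Inputs of the zero-load JKR adhesion-energy relation.

    a is the equivalent zero-load contact radius of the adherent cell (m),
    R the measured floating-cell radius (m), E the elastic modulus (Pa).
    """
    a_m: float
    R_m: float
    E_Pa: float
    nu: float = 0.5

    def __post_init__(self):
        if self.a_m <= 0 or self.R_m <= 0 or self.E_Pa <= 0:
            raise ValueError("a, R and E must all be > 0")
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1)")


def adhesion_energy(inp: AdhesionEnergyInput) -> float:
    """Zero-external-load JKR adhesion energy, J/m^2.

    From the JKR zero-load contact radius a^3 = 6*pi*gamma*R^2 / K with the
    effective modulus K = (4/3) * E / (1 - nu^2):

        gamma = 2 a^3 E / (9 pi R^2 (1 - nu^2)).
    """
    return float(2.0 * inp.a_m ** 3 * inp.E_Pa
                 / (9.0 * np.pi * inp.R_m ** 2 * (1.0 - inp.nu ** 2)))


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    """Omnibus + pairwise comparison result."""
    design: str
    statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame     # group1, group2, statistic, p_unadj, p_adj, reject
    groups: list
    alpha: float

    def pairwise_matrix(self) -> pd.DataFrame:
        """Symmetric matrix of adjusted pairwise p-values."""
        m = pd.DataFrame(np.ones((len(self.groups), len(self.groups))),
                         index=self.groups, columns=self.groups)
        for _, r in self.pairwise.iterrows():
            m.loc[r["group1"], r["group2"]] = r["p_adj"]
            m.loc[r["group2"], r["group1"]] = r["p_adj"]
        return m


def _extract_groups(data, group_col="group", value_col="value"):
    if isinstance(data, pd.DataFrame):
        labels = list(pd.unique(data[group_col]))
        groups = {g: np.asarray(data.loc[data[group_col] == g, value_col],
                                dtype=float) for g in labels}
    else:  # mapping label -> values
        labels = list(data.keys())
        groups = {g: np.asarray(v, dtype=float) for g, v in data.items()}
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    return labels, groups


def _dunn_pairwise(labels, groups, alpha):
    """Tie-corrected Dunn z-tests on pooled ranks, Holm-adjusted."""
    pooled = np.concatenate([groups[g] for g in labels])
    ranks = stats.rankdata(pooled)
    N = pooled.size
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        n = groups[g].size
        mean_ranks[g] = ranks[start:start + n].mean()
        sizes[g] = n
        start += n
    rows = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append([g1, g2, z, min(p, 1.0)])
    df = pd.DataFrame(rows, columns=["group1", "group2", "statistic",
                                     "p_unadj"])
    reject, p_adj, *_ = multipletests(df["p_unadj"], alpha=alpha,
                                      method="holm")
    df["p_adj"] = p_adj
    df["reject"] = reject
    return df


def compare_groups(data, design: str = "kw_dunn", alpha: float = 0.05,
                   group_col: str = "group", value_col: str = "value"
                   ) -> GroupComparison:
    """Group comparison with the designs used for cell-mechanics data.

    Designs
    -------
    kw_dunn
        Tie-corrected Kruskal-Wallis omnibus followed by Dunn's pairwise
        z-tests with Holm family-wise adjustment.
    welch_anova_gh
        Welch's heteroscedastic ANOVA (Welch-Satterthwaite df) followed by
        Games-Howell pairwise tests (studentized-range distribution).
    mann_whitney
        Two groups; exact enumeration when n*m <= 400 and there are no
        ties, otherwise the normal approximation with tie correction.
    welch_t
        Two groups, unpaired two-tailed Welch's t-test.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {DESIGNS}")
    labels, groups = _extract_groups(data, group_col, value_col)
    arrays = [groups[g] for g in labels]

    if design in ("welch_anova_gh", "welch_t"):
        for g in labels:
            if np.var(groups[g], ddof=1) == 0:
                raise ValueError(
                    f"group {g!r} has zero variance; Welch-type tests are "
                    "undefined")

    if design in ("mann_whitney", "welch_t") and len(labels) != 2:
        raise ValueError(f"{design} requires exactly two groups")

    pooled = np.concatenate(arrays)
    all_identical = np.all(pooled == pooled[0])

    if design == "kw_dunn":
        if all_identical:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.kruskal(*arrays)
        pairwise = _dunn_pairwise(labels, groups, alpha)
        if all_identical:
            pairwise["reject"] = False

    elif design == "welch_anova_gh":
        import pingouin as pg
        long = pd.DataFrame({
            "value": pooled,
            "group": np.repeat(labels, [a.size for a in arrays]),
        })
        aov = pg.welch_anova(data=long, dv="value", between="group")
        stat = float(aov["F"].iloc[0])
        p = float(aov["p_unc"].iloc[0])
        gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
        pairwise = pd.DataFrame({
            "group1": gh["A"], "group2": gh["B"],
            "statistic": gh["T"], "p_unadj": gh["pval"],
            "p_adj": gh["pval"],     # GH is already family-wise (q dist)
        })
        pairwise["reject"] = pairwise["p_adj"] < alpha

    elif design == "mann_whitney":
        x, y = arrays
        has_ties = np.unique(pooled).size < pooled.size
        if all_identical:
            stat, p = x.size * y.size / 2.0, 1.0
        else:
            method = "exact" if (x.size * y.size <= 400 and not has_ties) \
                else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        pairwise = pd.DataFrame([{
            "group1": labels[0], "group2": labels[1], "statistic": stat,
            "p_unadj": p, "p_adj": p, "reject": p < alpha}])

    else:  # welch_t
        x, y = arrays
        res = stats.ttest_ind(x, y, equal_var=False)
        stat, p = float(res.statistic), float(res.pvalue)
        pairwise = pd.DataFrame([{
            "group1": labels[0], "group2": labels[1], "statistic": stat,
            "p_unadj": p, "p_adj": p, "reject": p < alpha}])

    return GroupComparison(design=design, statistic=float(stat),
                           p_omnibus=float(p), pairwise=pairwise,
                           groups=labels, alpha=alpha)
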