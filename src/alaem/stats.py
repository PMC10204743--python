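"""Axial-orientation statistics for genotype x environment experiments.

Row-relative leaf azimuths live on [0, 90] degrees (0 = parallel to the
rows, 90 = perpendicular).  This module provides:

* ``fraction_perpendicular`` — fp, the fraction of leaves whose relative
  azimuth exceeds a threshold (60 or 45 degrees in practice); the robust
  summary used to compare detector output with field annotations.
* Kolmogorov–Smirnov tests — one-sample against Uniform(0, 90) (is there a
  preferential orientation at all?) and two-sample between sites.
* ``AMMI`` — the Additive Main effects and Multiplicative Interaction model:
  ANOVA main effects plus an SVD of the double-centered interaction matrix,
  with Gollob degrees of freedom for the multiplicative axes.
* ``rdpi`` — the relative distance plasticity index, a scale-invariant
  summary of how strongly a genotype's phenotype shifts across environments.
* ``validation_metrics`` — RMSE / R^2 / correlation p for paired estimated
  vs observed fp values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

__all__ = [
    "FpRecord",
    "KSResult",
    "RDPIResult",
    "ValidationMetrics",
    "fraction_perpendicular",
    "ks_uniform",
    "ks_two_sample",
    "AMMI",
    "ammi_fit",
    "gollob_df",
    "rdpi",
    "rdpi_table",
    "HEADLINE_PAIRS",
    "validation_metrics",
]

#: The headline environment contrasts: extreme vs square sowing patterns.
HEADLINE_PAIRS: tuple[tuple[str, str], ...] = (("R1", "R8"), ("R2", "R8"))


@dataclass(frozen=True)
class FpRecord:
    """Fraction of leaves oriented perpendicular to the rows."""

    fp: float
    n_leaves: int
    threshold_deg: float


@dataclass(frozen=True)
class KSResult:
    statistic: float
    p_value: float
    mode: str                     # "one_sample_uniform" | "two_sample"
    n: int
    m: int | None = None


@dataclass(frozen=True)
class RDPIResult:
    rdpi: float
    n_pairs: int
    pairs: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class ValidationMetrics:
    rmse: float
    r2: float
    p_value: float


def _check_range(a: np.ndarray, name: str = "azimuths") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.size and (a.min() < 0 or a.max() > 90):
        raise ValueError(f"{name} must lie in [0, 90] degrees")
    return a


def fraction_perpendicular(azimuths, threshold_deg: float = 45.0) -> FpRecord:
    """fp = (# relative azimuths strictly greater than the threshold) / n.

    Ties at exactly the threshold count as parallel (strict inequality).
    """
    a = _check_range(azimuths)
    if a.size == 0:
        raise ValueError("fp is undefined for an empty sample")
    if not 0 < threshold_deg < 90:
        raise ValueError("threshold_deg must be in (0, 90)")
    return FpRecord(fp=float(np.mean(a > threshold_deg)),
                    n_leaves=int(a.size), threshold_deg=float(threshold_deg))


def ks_uniform(azimuths, upper: float = 90.0, exact_max_n: int = 25) -> KSResult:
    """One-sample KS test of relative azimuths against Uniform(0, upper).

    D = sup_x |ECDF(x) - x/upper|; the p-value uses the exact small-sample
    distribution for n <= ``exact_max_n`` and the asymptotic Kolmogorov
    distribution otherwise.
    """
    a = _check_range(azimuths)
    if a.size == 0:
        raise ValueError("KS test requires at least one observation")
    method = "exact" if a.size <= exact_max_n else "asymp"
    res = sps.kstest(a, sps.uniform(loc=0, scale=upper).cdf, method=method)
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    mode="one_sample_uniform", n=int(a.size))


def ks_two_sample(a, b) -> KSResult:
    """Two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p-value."""
    a = _check_range(a, "sample a")
    b = _check_range(b, "sample b")
    if a.size == 0 or b.size == 0:
        raise ValueError("KS test requires non-empty samples")
    res = sps.ks_2samp(a, b, method="asymp")
    return KSResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                    mode="two_sample", n=int(a.size), m=int(b.size))


def gollob_df(g: int, e: int, k: int) -> int:
    """Gollob degrees of freedom for the k-th multiplicative AMMI axis."""
    return g + e - 1 - 2 * k


class AMMI(BaseEstimator):
    """Additive Main effects and Multiplicative Interaction decomposition.

    Fits Y_ij = mu + G_i + R_j + sum_k lambda_k b_ik z_jk + eps on a complete
    genotype x environment table: mu is the grand mean, G and R the marginal
    deviations, and the multiplicative terms come from the SVD of the
    double-centered interaction matrix (lambda_k the singular values, b and z
    unit-norm genotype and environment scores).

    The ANOVA table assigns e-1 df to the environment main effect, g-1 to
    genotypes, (g-1)(e-1) to the interaction, g+e-1-2k to the k-th
    multiplicative axis (Gollob's rule) and the remainder to the residual.
    Main effects are tested against the interaction mean square; each
    multiplicative axis against the residual mean square left after the
    retained axes.

    Parameters
    ----------
    n_components : number of multiplicative axes K to retain
        (default: the full interaction rank, min(g-1, e-1)).
    genotype_col, env_col, value_col, replicate_col : column names used when
        ``fit`` is given a long-format DataFrame.
    env_label : row label of the environment main effect in the ANOVA table
        (e.g. "Rectangularity" for a sowing-pattern factor).

    Attributes (after ``fit``)
    --------------------------
    mu_, genotype_effects_, env_effects_, interaction_, singular_values_,
    genotype_scores_, env_scores_, variance_ratio_, anova_, n_replicates_.
    """

    def __init__(self, n_components: int | None = None,
                 genotype_col: str = "genotype", env_col: str = "environment",
                 value_col: str = "value", replicate_col: str = "replicate",
                 env_label: str = "Environment"):
        self.n_components = n_components
        self.genotype_col = genotype_col
        self.env_col = env_col
        self.value_col = value_col
        self.replicate_col = replicate_col
        self.env_label = env_label

    # -- input handling -----------------------------------------------------

    def _cell_means(self, table):
        """Return (means DataFrame g x e, n_replicates, pooled error SS/df)."""
        if isinstance(table, pd.DataFrame):
            df = table
            for col in (self.genotype_col, self.env_col, self.value_col):
                if col not in df.columns:
                    raise ValueError(f"table lacks required column {col!r}")
            counts = df.pivot_table(index=self.genotype_col,
                                    columns=self.env_col,
                                    values=self.value_col, aggfunc="count")
            if counts.isna().any().any() or (counts == 0).any().any():
                missing = [(i, j) for i in counts.index for j in counts.columns
                           if not counts.loc[i, j] > 0]
                raise ValueError(f"incomplete table; missing cells: {missing}")
            r = int(counts.iloc[0, 0])
            if not (counts == r).all().all():
                raise ValueError("replicates must be balanced across cells")
            means = df.pivot_table(index=self.genotype_col,
                                   columns=self.env_col,
                                   values=self.value_col, aggfunc="mean")
            err_ss = err_df = 0.0
            if r > 1:
                within = df.groupby([self.genotype_col, self.env_col],
                                    observed=True)[self.value_col]
                err_ss = float((within.var(ddof=1) * (r - 1)).sum())
                err_df = means.size * (r - 1)
            return means, r, err_ss, err_df
        arr = np.asarray(table, dtype=float)
        if arr.ndim != 2:
            raise ValueError("array input must be a 2-D genotype x env table")
        if np.isnan(arr).any():
            raise ValueError("incomplete table; NaN cells are not imputed")
        means = pd.DataFrame(arr,
                             index=[f"G{i + 1}" for i in range(arr.shape[0])],
                             columns=[f"E{j + 1}" for j in range(arr.shape[1])])
        return means, 1, 0.0, 0.0

    # -- fitting ------------------------------------------------------------

    def fit(self, table, y=None) -> "AMMI":
        means, r, err_ss, err_df = self._cell_means(table)
        g, e = means.shape
        if g < 2 or e < 2:
            raise ValueError("AMMI needs at least 2 genotypes and 2 "
                             "environments")
        full_rank = min(g - 1, e - 1)
        k = full_rank if self.n_components is None else int(self.n_components)
        if not 0 <= k <= full_rank:
            raise ValueError(f"n_components must be in [0, {full_rank}]")

        y_mat = means.to_numpy()
        mu = y_mat.mean()
        g_eff = y_mat.mean(axis=1) - mu
        e_eff = y_mat.mean(axis=0) - mu
        inter = y_mat - mu - g_eff[:, None] - e_eff[None, :]
        u, s, vt = np.linalg.svd(inter, full_matrices=False)
        s = s[:full_rank]
        u = u[:, :full_rank]
        vt = vt[:full_rank]

        # SS on the observation scale: cell-mean SS times replicate count
        ss_g = r * e * float(np.sum(g_eff ** 2))
        ss_e = r * g * float(np.sum(e_eff ** 2))
        ss_int = r * float(np.sum(inter ** 2))
        ss_pc = r * s ** 2

        df_g, df_e, df_int = g - 1, e - 1, (g - 1) * (e - 1)
        df_pc = [gollob_df(g, e, kk) for kk in range(1, k + 1)]
        df_resid = df_int - sum(df_pc)
        ss_resid = ss_int - float(ss_pc[:k].sum())
        ms_int = ss_int / df_int
        ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

        def f_row(ss, df, ms_den, df_den):
            ms = ss / df
            if not np.isfinite(ms_den) or ms_den <= 0 or df_den <= 0:
                return ms, np.nan, np.nan
            fval = ms / ms_den
            return ms, fval, float(sps.f.sf(fval, df, df_den))

        rows = []
        ms, fval, p = f_row(ss_e, df_e, ms_int, df_int)
        rows.append((self.env_label, df_e, ss_e, ms, fval, p))
        ms, fval, p = f_row(ss_g, df_g, ms_int, df_int)
        rows.append(("Genotype", df_g, ss_g, ms, fval, p))
        rows.append(("Interactions", df_int, ss_int, ms_int, np.nan, np.nan))
        for kk in range(k):
            ms, fval, p = f_row(float(ss_pc[kk]), df_pc[kk],
                                ms_resid, df_resid)
            rows.append((f"PC{kk + 1}", df_pc[kk], float(ss_pc[kk]),
                         ms, fval, p))
        rows.append(("Residuals", df_resid, ss_resid,
                     ms_resid, np.nan, np.nan))
        if err_df > 0:
            rows.append(("Error", int(err_df), err_ss, err_ss / err_df,
                         np.nan, np.nan))
        anova = pd.DataFrame(rows, columns=["source", "df", "sum_sq",
                                            "mean_sq", "F", "p_value"])

        self.genotypes_ = list(means.index)
        self.environments_ = list(means.columns)
        self.cell_means_ = means
        self.n_replicates_ = r
        self.mu_ = float(mu)
        self.genotype_effects_ = pd.Series(g_eff, index=means.index,
                                           name="G_i")
        self.env_effects_ = pd.Series(e_eff, index=means.columns, name="R_j")
        self.interaction_ = pd.DataFrame(inter, index=means.index,
                                         columns=means.columns)
        self.singular_values_ = s
        self.genotype_scores_ = u
        self.env_scores_ = vt.T
        total = float(np.sum(s ** 2))
        self.variance_ratio_ = (s ** 2 / total if total > 0
                                else np.zeros_like(s))
        self.n_components_ = k
        self.anova_ = anova
        return self

    # -- derived outputs ----------------------------------------------------

    def reconstruct(self, n_components: int | None = None) -> pd.DataFrame:
        """Cell-mean table implied by mu + G + R + the first K axes."""
        k = self.n_components_ if n_components is None else int(n_components)
        approx = (self.mu_
                  + self.genotype_effects_.to_numpy()[:, None]
                  + self.env_effects_.to_numpy()[None, :])
        if k > 0:
            approx = approx + (self.genotype_scores_[:, :k]
                               * self.singular_values_[:k]
                               ) @ self.env_scores_[:, :k].T
        return pd.DataFrame(approx, index=self.genotypes_,
                            columns=self.environments_)

    def biplot_coordinates(self) -> pd.DataFrame:
        """Symmetric-scaling biplot coordinates (sqrt(lambda)-weighted scores)
        for the first two multiplicative axes, for external plotting."""
        if self.n_components_ < 1:
            raise ValueError("no multiplicative axes retained")
        k = min(2, self.n_components_)
        w = np.sqrt(self.singular_values_[:k])
        rows = []
        for i, gname in enumerate(self.genotypes_):
            rows.append({"label": gname, "kind": "genotype",
                         **{f"PC{a + 1}": self.genotype_scores_[i, a] * w[a]
                            for a in range(k)}})
        for j, ename in enumerate(self.environments_):
            rows.append({"label": ename, "kind": "environment",
                         **{f"PC{a + 1}": self.env_scores_[j, a] * w[a]
                            for a in range(k)}})
        return pd.DataFrame(rows)


def ammi_fit(table, n_components: int | None = None, **kwargs) -> AMMI:
    """Convenience wrapper: fit an :class:`AMMI` model on a table."""
    return AMMI(n_components=n_components, **kwargs).fit(table)


def rdpi(values_by_env, pairs=None) -> RDPIResult:
    """Relative distance plasticity index for one genotype.

    RDPI = (1/n) * sum over environment pairs (i, i') of
    |X_i - X_i'| / (X_i + X_i'), where X is the phenotype of the genotype in
    each environment (here typically the mean row-relative azimuth).  It is
    scale-invariant and lies in [0, 1] for positive phenotypes.

    ``pairs`` defaults to all unordered environment pairs; pass
    :data:`HEADLINE_PAIRS` for the extreme-vs-square sowing contrasts.
    """
    values = dict(values_by_env)
    if pairs is None:
        pairs = list(itertools.combinations(sorted(values), 2))
    pairs = [tuple(p) for p in pairs]
    if not pairs:
        raise ValueError("RDPI requires at least one environment pair")
    terms = []
    for e1, e2 in pairs:
        if e1 not in values or e2 not in values:
            raise ValueError(f"environment pair ({e1}, {e2}) not in data")
        x1, x2 = float(values[e1]), float(values[e2])
        if x1 <= 0 or x2 <= 0:
            raise ValueError("RDPI requires strictly positive phenotypes")
        terms.append(abs(x1 - x2) / (x1 + x2))
    return RDPIResult(rdpi=float(np.mean(terms)), n_pairs=len(pairs),
                      pairs=tuple(pairs))


def rdpi_table(df: pd.DataFrame, value_col: str, env_col: str,
               genotype_col: str = "genotype", pairs=None) -> pd.DataFrame:
    """Per-genotype RDPI from a tidy table of phenotype-by-environment means."""
    rows = []
    for gname, sub in df.groupby(genotype_col, observed=True):
        by_env = sub.groupby(env_col, observed=True)[value_col].mean()
        res = rdpi(by_env.to_dict(), pairs=pairs)
        rows.append({genotype_col: gname, "rdpi": res.rdpi,
                     "n_pairs": res.n_pairs})
    return pd.DataFrame(rows)


def validation_metrics(estimated, observed) -> ValidationMetrics:
    """RMSE, squared Pearson correlation and correlation-test p-value for
    paired estimated vs observed values (e.g. fp from images vs field)."""
    est = np.asarray(estimated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if est.shape != obs.shape:
        raise ValueError("estimated and observed must have the same length")
    if est.size < 3:
        raise ValueError("validation metrics need at least 3 pairs")
    rmse = float(np.sqrt(np.mean((est - obs) ** 2)))
    if np.std(est) == 0 or np.std(obs) == 0:
        warnings.warn("zero variance: R^2 undefined", stacklevel=2)
        return ValidationMetrics(rmse=rmse, r2=float("nan"),
                                 p_value=float("nan"))
    r, p = sps.pearsonr(est, obs)
    return ValidationMetrics(rmse=rmse, r2=float(r ** 2), p_value=float(p))
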