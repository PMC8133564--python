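"""Population statistics: variance components, heritability, ANOVA, correlations, PCA.

Broad-sense heritability on genotype means is

    h² = σ_g² / (σ_g² + σ_e²/r)

with σ_g² the genetic and σ_e² the residual variance and r the number of
replicates per genotype (the arithmetic mean replicate count under
missingness, with the harmonic mean available as an alternative).

The default variance-component estimator is method-of-moments from the
one-way genotype ANOVA expected mean squares: σ_e² = MS_residual and
σ_g² = (MS_genotype − MS_residual)/r̄, truncated at 0 (the raw moment
estimate is kept in the result for diagnostics). A REML backend
(random-intercept mixed model) is available as an alternative.

Genotype × concentration interaction is tested with a fixed-effects
two-way ANOVA (plus an optional block term) using Type II sums of squares,
which are robust to the unbalance that failed chambers introduce.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ValidationError


@dataclass
class VarianceComponents:
    """One-trait genotype variance decomposition."""

    trait: str
    sigma_g2: float
    sigma_e2: float
    r: float
    h2: float
    method: str
    ms_genotype: float
    ms_residual: float
    df_genotype: int
    df_residual: int
    sigma_g2_raw: float  # untruncated moment estimate


def heritability(sigma_g2: float, sigma_e2: float, r: float) -> float:
    """Broad-sense heritability h² = σ_g²/(σ_g² + σ_e²/r)."""
    if r <= 0:
        raise ValidationError(f"replication count must be > 0, got {r}")
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValidationError("variance components must be >= 0")
    denom = sigma_g2 + sigma_e2 / r
    if denom == 0:
        return 0.0
    return sigma_g2 / denom


def _one_way_mean_squares(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """MS_genotype, MS_residual and their dfs from grouped observations."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n = len(all_vals)
    g = len(groups)
    ss_between = sum(len(x) * (x.mean() - grand) ** 2 for x in groups)
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in groups)
    df_b, df_w = g - 1, n - g
    if df_w <= 0:
        raise ValidationError("no residual degrees of freedom")
    return ss_between / df_b, ss_within / df_w, df_b, df_w


def variance_components(
    df: pd.DataFrame,
    value: str,
    genotype: str = "genotype",
    method: str = "moments",
    r_mode: str = "mean",
    r_override: float | None = None,
) -> VarianceComponents:
    """Estimate (σ_g², σ_e²) and h² for one trait.

    ``r_mode`` selects how the replication count entering h² is summarized
    under missingness: ``'mean'`` (arithmetic mean replicates per genotype,
    the default) or ``'harmonic'``. ``r_override`` pins r explicitly.
    """
    sub = df[[genotype, value]].dropna()
    groups = [
        np.asarray(g[value], dtype=float) for _, g in sub.groupby(genotype)
    ]
    if len(groups) < 2:
        raise ValidationError("need at least 2 genotypes")
    sizes = np.array([len(g) for g in groups], dtype=float)
    if np.concatenate(groups).std() == 0:
        raise ValidationError("zero total variance: trait is constant")

    if r_override is not None:
        r = float(r_override)
    elif r_mode == "mean":
        r = float(sizes.mean())
    elif r_mode == "harmonic":
        r = float(len(sizes) / np.sum(1.0 / sizes))
    else:
        raise ValidationError(f"unknown r_mode {r_mode!r}")

    ms_g, ms_e, df_g, df_e = _one_way_mean_squares(groups)

    if method == "moments":
        sigma_e2 = ms_e
        sigma_g2_raw = (ms_g - ms_e) / r
    elif method == "reml":
        model = sm.MixedLM.from_formula(
            f"{value} ~ 1", groups=sub[genotype], data=sub
        )
        fit = model.fit(reml=True)
        sigma_g2_raw = float(fit.cov_re.iloc[0, 0])
        sigma_e2 = float(fit.scale)
    else:
        raise ValidationError(f"unknown method {method!r}")

    sigma_g2 = max(sigma_g2_raw, 0.0)
    return VarianceComponents(
        trait=value,
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        r=r,
        h2=heritability(sigma_g2, sigma_e2, r),
        method=method,
        ms_genotype=ms_g,
        ms_residual=ms_e,
        df_genotype=df_g,
        df_residual=df_e,
        sigma_g2_raw=sigma_g2_raw,
    )


def heritability_table(
    df: pd.DataFrame,
    traits: list[str],
    genotype: str = "genotype",
    method: str = "moments",
    r_mode: str = "mean",
) -> pd.DataFrame:
    """Per-trait variance components and h² as a tidy DataFrame."""
    rows = []
    for trait in traits:
        try:
            vc = variance_components(
                df, trait, genotype=genotype, method=method, r_mode=r_mode
            )
        except ValidationError:
            continue
        rows.append(vars(vc))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotype x concentration ANOVA
# ---------------------------------------------------------------------------


def anova_gxc(
    df: pd.DataFrame,
    value: str,
    genotype: str = "genotype",
    concentration: str = "treatment",
    block: str | None = "block",
) -> pd.DataFrame:
    """Fixed-effects genotype × concentration ANOVA (Type II SS).

    Returns the statsmodels ANOVA table with rows for genotype,
    concentration, their interaction and (if supplied) block. With a
    single-level concentration factor this reduces to the one-way genotype
    table.
    """
    sub = df.dropna(subset=[value]).copy()
    for factor in filter(None, (genotype, concentration, block)):
        if factor not in sub.columns:
            raise ValidationError(f"missing factor column {factor!r}")
        sub[factor] = sub[factor].astype(str)
    if sub[value].nunique() <= 1:
        raise ValidationError(f"{value}: zero variance, ANOVA undefined")

    n_g = sub[genotype].nunique()
    n_c = sub[concentration].nunique()
    if n_g < 2:
        raise ValidationError("need >= 2 genotype levels")

    terms = [f"C(Q('{genotype}'))"]
    if n_c >= 2:
        terms += [
            f"C(Q('{concentration}'))",
            f"C(Q('{genotype}')):C(Q('{concentration}'))",
        ]
    if block is not None and sub[block].nunique() >= 2:
        # aliased block: identical grouping to another factor is unusable
        for factor, n_lev in ((genotype, n_g), (concentration, n_c)):
            if (
                sub.groupby(block)[factor].nunique().eq(1).all()
                and sub.groupby(factor)[block].nunique().eq(1).all()
                and sub[block].nunique() == n_lev
            ):
                raise ValidationError(
                    f"block factor is aliased with {factor!r}"
                )
        terms.append(f"C(Q('{block}'))")
    formula = f"Q('{value}') ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=sub).fit()
    if fit.df_resid < 1:
        raise ValidationError("no residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=2)
    rename = {
        f"C(Q('{genotype}'))": "genotype",
        f"C(Q('{concentration}'))": "concentration",
        f"C(Q('{genotype}')):C(Q('{concentration}'))": "genotype:concentration",
    }
    if block is not None:
        rename[f"C(Q('{block}'))"] = "block"
    table = table.rename(index=rename)
    return table


# ---------------------------------------------------------------------------
# Correlations and PCA
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flags: dict[str, str]


def correlation_matrix(
    df: pd.DataFrame,
    traits: list[str],
    adjust: str | None = None,
) -> CorrelationResult:
    """Pairwise-complete Pearson correlations with t-test p-values.

    ``adjust='bh'`` applies a Benjamini–Hochberg correction across the
    off-diagonal p-values; the default reports raw p-values. Constant
    traits yield missing correlations with a flag.
    """
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=traits, columns=traits)
    flags: dict[str, str] = {}
    pvals = []
    pairs = list(itertools.combinations(traits, 2))
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(sub)
        if len(sub) < 3:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            flags[f"{a}|{b}"] = "insufficient_pairs"
            pvals.append(np.nan)
            continue
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            flags[f"{a}|{b}"] = "constant_trait"
            pvals.append(np.nan)
            continue
        res = stats.pearsonr(sub[a], sub[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
        pvals.append(res.pvalue)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        mask = ~np.isnan(pvals)
        if mask.any():
            adj = np.full(len(pvals), np.nan)
            adj[mask] = multipletests(np.asarray(pvals)[mask], method="fdr_bh")[1]
            for (a, b), q in zip(pairs, adj):
                p.loc[a, b] = p.loc[b, a] = q
    elif adjust is not None:
        raise ValidationError(f"unknown adjustment {adjust!r}")
    return CorrelationResult(r=r, p=p, n=n, flags=flags)


@dataclass
class PCASummary:
    loadings: pd.DataFrame  # traits x components
    explained_variance_ratio: np.ndarray
    n_rows: int


def pca_summary(
    df: pd.DataFrame, traits: list[str], scale: bool = True
) -> PCASummary:
    """PCA of the trait table (listwise deletion, unit-variance scaling default).

    Returns loadings per component and variance-explained fractions which
    sum to 1 over the full component set.
    """
    from sklearn.decomposition import PCA
    from sklearn.preprocessing import StandardScaler

    if len(traits) < 2:
        raise ValidationError("need at least 2 traits for PCA")
    X = df[traits].dropna()
    if len(X) < 2:
        raise ValidationError("need at least 2 complete rows for PCA")
    values = X.to_numpy(dtype=float)
    if scale:
        keep = values.std(axis=0) > 0
        if not keep.all():
            dropped = [t for t, k in zip(traits, keep) if not k]
            raise ValidationError(f"constant trait(s) under scaling: {dropped}")
        values = StandardScaler().fit_transform(values)
    pca = PCA()
    pca.fit(values)
    comps = [f"PC{i + 1}" for i in range(pca.n_components_)]
    loadings = pd.DataFrame(pca.components_.T, index=traits, columns=comps)
    return PCASummary(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_rows=len(X),
    )
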