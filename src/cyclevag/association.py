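"""Hormone-taxa and visit-trend association models.

Three model groups, all on covariate-residualized CLR abundances of taxa
passing the prevalence/abundance filter:

1. Visit trend:      taxa_adj ~ visit_number + (1|woman)
2. Phase differences: ordernorm(delta hormone) ~ ordernorm(delta taxa_adj),
   fitted per consecutive-phase transition (one observation per woman per
   transition, hence ordinary least squares within transition).
3. Overall:          hormone ~ visit_number + taxa_adj + (1|woman)
                               + pregnancy_category

Asymptotic Wald p-values (normal approximation on beta/SE) are reported
together with permutation-based empirical p-values: the abundance column is
permuted across all rows, the model refitted ``n_perm`` times, and the
empirical p is the exact proportion of permutation p-values at or below the
observed one (zero attainable; resolution 1/n_perm).  BH false-discovery-
rate q-values are computed from the asymptotic p-values within each
declared family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .lmm import RandomInterceptModel

__all__ = [
    "TRANSITIONS",
    "fit_visit_model",
    "empirical_pvalue",
    "empirical_from_perm",
    "fdr_adjust",
    "icc",
    "remove_hormone_outliers",
    "consecutive_differences",
    "ordernorm",
    "fit_difference_model",
    "fit_overall_hormone_model",
]

_PHASE_CODE = {1: "F", 2: "O", 3: "EL", 4: "LL"}

#: consecutive-phase transitions, keyed by starting visit
TRANSITIONS = {1: "F-O", 2: "O-EL", 3: "EL-LL"}


@dataclass
class ICCResult:
    taxon: str
    sigma_b2: float
    sigma_e2: float
    icc: float
    singular: bool


def _visit_design(design: pd.DataFrame, index) -> tuple[np.ndarray, np.ndarray]:
    meta = design.loc[index]
    X = np.column_stack([np.ones(len(meta)), meta["visit_number"].to_numpy(dtype=float)])
    return X, meta["woman"].to_numpy()


def fit_visit_model(
    adj: pd.DataFrame,
    design: pd.DataFrame,
    model_id: int,
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-intercept visit-trend model per taxon.

    ``adj`` holds CLR abundances residualized with ladder step
    ``model_id``; visit_number enters numerically (1-4).  Returns one row
    per taxon with the visit slope, SE, 95% CI, asymptotic p, ICC from the
    fit's variance components and (if ``n_perm``>0) the permutation
    empirical p.
    """
    X, groups = _visit_design(design, adj.index)
    model = RandomInterceptModel(X, groups)
    rows = []
    for taxon in adj.columns:
        y = adj[taxon].to_numpy(dtype=float)
        fit = model.fit(y)
        ci = fit.ci()
        row = {
            "taxon": taxon,
            "model_id": model_id,
            "beta": fit.beta[1],
            "se": fit.se[1],
            "ci_lo": ci[1, 0],
            "ci_hi": ci[1, 1],
            "p": fit.p[1],
            "icc": fit.icc,
            "n": len(y),
            "singular": fit.singular,
        }
        if n_perm > 0:
            row["p_empirical"] = empirical_pvalue(
                model, y, fit.p[1], coef_index=1, n_perm=n_perm,
                seed=seed, label=("visit", model_id, taxon),
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("taxon")
    out["q"] = fdr_adjust(out["p"].to_numpy())
    return out


def empirical_pvalue(
    model: RandomInterceptModel,
    y: np.ndarray,
    p_obs: float,
    coef_index: int,
    n_perm: int = 1000,
    seed: int = 0,
    label: tuple = (),
    within_woman: bool = False,
) -> float:
    """Permutation empirical p for one fitted outcome column.

    By default the outcome (taxa-abundance) column is permuted across all
    rows -- deliberately breaking the woman/visit structure, which is how
    the procedure is defined -- the model refitted, and the proportion of
    permutation p-values <= ``p_obs`` returned as the exact fraction over
    ``n_perm`` (0 attainable; resolution 1/n_perm).  ``within_woman``
    restricts permutations to shuffling each woman's values among her own
    visits; this preserves the repeated-measures structure and is offered
    for sensitivity analysis only, as a deviation from the default scheme.
    The permutation stream is derived from ``seed`` and ``label`` so each
    (taxon, model) pair has an independent, reproducible stream.
    """
    rng = substream(seed, "perm", *label)
    y = np.asarray(y, dtype=float)
    if within_woman:
        # group slices in the model's internal (sorted) order
        bounds = np.r_[model.boundaries, model.n]
        y_sorted = y[model.order]
        inverse = np.argsort(model.order)
    perm_p = np.empty(n_perm)
    for b in range(n_perm):
        if within_woman:
            yp = y_sorted.copy()
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                yp[lo:hi] = rng.permutation(yp[lo:hi])
            yp = yp[inverse]
        else:
            yp = rng.permutation(y)
        fit = model.fit(yp)
        perm_p[b] = fit.p[coef_index]
    return empirical_from_perm(p_obs, perm_p)


def empirical_from_perm(p_obs: float, perm_pvalues: np.ndarray) -> float:
    """Exact proportion of permutation p-values <= observed p."""
    perm_pvalues = np.asarray(perm_pvalues, dtype=float)
    return float(np.mean(perm_pvalues <= p_obs))


def fdr_adjust(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one declared family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    mask = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if mask.any():
        q[mask] = multipletests(p[mask], method=method)[1]
    return q


def icc(values: pd.Series, design: pd.DataFrame) -> ICCResult:
    """Intraclass correlation of one taxon from the visit-trend model.

    sigma_b^2/(sigma_b^2+sigma_e^2) from the random-intercept variance
    components; quantifies within-woman stability across visits.
    """
    X, groups = _visit_design(design, values.index)
    fit = RandomInterceptModel(X, groups).fit(values.to_numpy(dtype=float))
    return ICCResult(
        taxon=str(values.name),
        sigma_b2=fit.sigma_b2,
        sigma_e2=fit.sigma_e2,
        icc=fit.icc,
        singular=fit.singular,
    )


def remove_hormone_outliers(
    hormones: pd.DataFrame, k: float = 4.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank hormone values beyond k SD from that hormone's mean.

    Mean and SD are computed once over all samples of each hormone (single
    pass, visits pooled); flagged values become NaN.  Returns the cleaned
    panel and a removal log (sample_id, hormone, value, z).
    """
    cleaned = hormones.copy().astype(float)
    log_rows = []
    for col in hormones.columns:
        x = hormones[col].astype(float)
        if x.notna().sum() < 3:
            raise ValueError(f"hormone {col!r} has fewer than 3 non-missing values")
        mu, sd = x.mean(), x.std(ddof=1)
        if sd == 0:
            continue
        z = (x - mu) / sd
        out = z.abs() > k
        for sid in x.index[out.fillna(False)]:
            log_rows.append({"sample_id": sid, "hormone": col, "value": x[sid], "z": z[sid]})
        cleaned.loc[out.fillna(False), col] = np.nan
    return cleaned, pd.DataFrame(log_rows, columns=["sample_id", "hormone", "value", "z"])


def consecutive_differences(values: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """Per-woman differences between consecutive available visits.

    Only visit pairs (t, t+1) both present contribute; gap pairs such as
    (1, 3) are skipped.  Returns columns woman, transition (F-O, O-EL,
    EL-LL) and delta = value(t+1) - value(t).
    """
    design = design.loc[values.index]
    frame = pd.DataFrame(
        {"woman": design["woman"], "visit": design["visit_number"], "value": values}
    )
    rows = []
    for woman, grp in frame.groupby("woman", sort=True):
        by_visit = grp.set_index("visit")["value"]
        for t in (1, 2, 3):
            if t in by_visit.index and (t + 1) in by_visit.index:
                rows.append(
                    {
                        "woman": woman,
                        "transition": TRANSITIONS[t],
                        "delta": by_visit[t + 1] - by_visit[t],
                    }
                )
    return pd.DataFrame(rows, columns=["woman", "transition", "delta"])


def ordernorm(values) -> np.ndarray:
    """Rank-based inverse-normal (ordered quantile) transform.

    y_i = Phi^-1(rank_i / (n + 1)) with mid-ranks for ties, computed over
    non-missing entries; NaNs propagate.  An all-constant input maps to
    all zeros (with a warning), since ranks carry no information there.
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    mask = ~np.isnan(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("ordernorm requires at least 3 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        import warnings

        warnings.warn("ordernorm input is constant; returning zeros", stacklevel=2)
        out[mask] = 0.0
        return out
    ranks = stats.rankdata(obs, method="average")
    out[mask] = stats.norm.ppf(ranks / (n + 1))
    return out


def fit_difference_model(
    delta_hormone: pd.DataFrame,
    delta_taxa: pd.DataFrame,
    transition: str,
    robust: bool = False,
    min_pairs: int = 10,
    n_perm: int = 0,
    seed: int = 0,
    label: tuple = (),
) -> dict:
    """Regress a hormone change on a taxon change within one transition.

    Both inputs are `consecutive_differences` outputs (columns woman,
    transition, delta), already ordernorm-transformed by the caller or
    raw (the wrapper in the pipeline transforms them).  Each woman
    contributes at most one observation per transition, so the model is
    OLS with an intercept; ``robust`` switches to HC1 standard errors.
    """
    dh = delta_hormone.loc[delta_hormone["transition"] == transition].set_index("woman")["delta"]
    dt = delta_taxa.loc[delta_taxa["transition"] == transition].set_index("woman")["delta"]
    merged = pd.concat([dh.rename("dh"), dt.rename("dt")], axis=1, join="inner").dropna()
    n = len(merged)
    result = {"transition": transition, "n": n, "flag": ""}
    if n < 3:
        result.update(beta=np.nan, se=np.nan, p=np.nan, flag="insufficient_pairs")
        return result
    if merged["dt"].nunique() == 1:
        result.update(beta=np.nan, se=np.nan, p=np.nan, flag="zero_variance_predictor")
        return result
    if n < min_pairs:
        result["flag"] = "low_n"
    import statsmodels.api as sm

    X = sm.add_constant(merged["dt"].to_numpy())
    fit = sm.OLS(merged["dh"].to_numpy(), X).fit(
        cov_type="HC1" if robust else "nonrobust"
    )
    result.update(
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        ci_lo=float(fit.conf_int()[1][0]),
        ci_hi=float(fit.conf_int()[1][1]),
    )
    if n_perm > 0 and np.isfinite(result["p"]):
        # slope p of a simple regression == Pearson correlation p, so the
        # permutation refits reduce to correlation tests on shuffled dt
        rng = substream(seed, "perm_diff", transition, *label)
        dh_arr = merged["dh"].to_numpy()
        dt_arr = merged["dt"].to_numpy()
        perm_p = np.empty(n_perm)
        for b in range(n_perm):
            perm_p[b] = stats.pearsonr(dh_arr, rng.permutation(dt_arr)).pvalue
        result["p_empirical"] = empirical_from_perm(result["p"], perm_p)
    return result


def fit_overall_hormone_model(
    hormone: pd.Series,
    taxa_adj: pd.Series,
    design: pd.DataFrame,
    n_perm: int = 0,
    seed: int = 0,
) -> dict:
    """Whole-cycle hormone model: hormone ~ visit + taxa_adj + (1|woman)
    + pregnancy_category, with the taxa_adj coefficient as focal term.

    The hormone must already be outlier-cleaned; rows with missing hormone
    values are dropped.  ``n_perm`` > 0 adds a permutation empirical p
    obtained by permuting the taxa_adj column.
    """
    common = hormone.index.intersection(taxa_adj.index)
    h = hormone.loc[common]
    keep = h.notna()
    h = h[keep]
    t = taxa_adj.loc[h.index].to_numpy(dtype=float)
    if np.all(t == t[0]):
        raise ValueError("zero-variance taxa predictor")
    meta = design.loc[h.index]
    preg = (meta["Pregnancy_category"] == "ever").astype(float).to_numpy()
    X = np.column_stack(
        [np.ones(len(h)), meta["visit_number"].to_numpy(dtype=float), t, preg]
    )
    groups = meta["woman"].to_numpy()
    model = RandomInterceptModel(X, groups)
    y = h.to_numpy(dtype=float)
    fit = model.fit(y)
    ci = fit.ci()
    result = {
        "beta": float(fit.beta[2]),
        "se": float(fit.se[2]),
        "ci_lo": float(ci[2, 0]),
        "ci_hi": float(ci[2, 1]),
        "p": float(fit.p[2]),
        "n": len(y),
        "singular": fit.singular,
    }
    if n_perm > 0:
        # permute the taxa column (column 3 of X), not the outcome
        rng = substream(seed, "perm_overall", str(hormone.name), str(taxa_adj.name))
        perm_p = np.empty(n_perm)
        Xp = X.copy()
        for b in range(n_perm):
            Xp[:, 2] = rng.permutation(t)
            perm_fit = RandomInterceptModel(Xp, groups).fit(y)
            perm_p[b] = perm_fit.p[2]
        result["p_empirical"] = empirical_from_perm(result["p"], perm_p)
    return result
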