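"""Compositional transforms and taxa-level summaries.

The pipeline moves between three representations of a sample x taxa table:
raw counts, relative abundances (rows sum to 1) and centered log-ratio
(CLR) coordinates (rows sum to 0).  Downstream models operate on CLR
abundances residualized on a cumulative ladder of covariate sets
(model 1 = none, model 2 adds the technical covariates, models 3-10 add
one host covariate each).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "LADDER",
    "covariate_ladder",
    "to_relative_abundance",
    "clr_transform",
    "default_pseudocount",
    "filter_taxa",
    "design_matrix",
    "residualize",
    "dominance_summary",
]

# Cumulative covariate ladder: model k uses the union of steps 2..k.
_LADDER_STEPS = [
    ("Qubit_DNA", "Qubit_Library", "Total_counts"),  # model 2: technical
    ("Age",),
    ("sex_less_than_two_days",),
    ("Pregnancy_category",),
    ("Pill_use",),
    ("Swab_after_feces",),
    ("Bristol_stool_scale",),
    ("Swab_morning_or_not",),
    ("WHR_ranges",),
]

LADDER: dict[int, tuple[str, ...]] = {1: ()}
for _k, _step in enumerate(_LADDER_STEPS, start=2):
    LADDER[_k] = LADDER[_k - 1] + _step

_CATEGORICAL = {
    "sex_less_than_two_days",
    "Pregnancy_category",
    "Pill_use",
    "Swab_after_feces",
    "Swab_morning_or_not",
    "WHR_ranges",
    "smoking",
}


def covariate_ladder(model_id: int) -> tuple[str, ...]:
    """Covariate names used by ladder step ``model_id`` (1..10, cumulative)."""
    if model_id not in LADDER:
        raise ValueError(f"model_id must be in 1..{max(LADDER)}, got {model_id}")
    return LADDER[model_id]


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize counts to fractions; errors on an all-zero sample."""
    totals = counts.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample row: {zero.index[0]!r}")
    return counts.div(totals, axis=0)


def default_pseudocount(rel: pd.DataFrame) -> float:
    """Half the minimum nonzero relative abundance of the table."""
    arr = rel.to_numpy()
    nonzero = arr[arr > 0]
    if nonzero.size == 0:
        raise ValueError("table has no nonzero entries")
    return float(nonzero.min() / 2.0)


def clr_transform(rel: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Centered log-ratio transform: ln(x+eps) minus its per-sample mean.

    ``pseudocount=None`` uses half the minimum nonzero abundance of the
    table; an explicit 0 is only valid on strictly positive tables.
    """
    arr = rel.to_numpy(dtype=float)
    if pseudocount is None:
        pseudocount = default_pseudocount(rel) if (arr == 0).any() else 0.0
    if pseudocount == 0 and (arr == 0).any():
        raise ValueError("zero entries require a positive pseudocount")
    logx = np.log(arr + pseudocount)
    clr = logx - logx.mean(axis=1, keepdims=True)
    out = pd.DataFrame(clr, index=rel.index, columns=rel.columns)
    out.attrs["pseudocount"] = float(pseudocount)
    return out


def filter_taxa(
    rel: pd.DataFrame, min_prevalence: float = 0.20, min_mean_abund: float = 0.001
) -> list[str]:
    """Taxa with prevalence strictly >20% and mean abundance strictly >0.10%.

    Both thresholds are strict inequalities; prevalence counts samples with
    nonzero abundance.
    """
    prevalence = (rel > 0).mean(axis=0)
    mean_abund = rel.mean(axis=0)
    keep = (prevalence > min_prevalence) & (mean_abund > min_mean_abund)
    return [t for t in rel.columns if keep[t]]


def design_matrix(metadata: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    """Numeric design (no intercept column) for a covariate list.

    Categorical covariates expand to treatment-coded indicators with the
    most frequent level as reference.
    """
    cols = {}
    for cov in covariates:
        if cov not in metadata.columns:
            raise ValueError(f"covariate missing from metadata: {cov}")
        series = metadata[cov]
        if cov in _CATEGORICAL or series.dtype == object:
            reference = series.value_counts().idxmax()
            for level in sorted(series.dropna().unique()):
                if level == reference:
                    continue
                cols[f"{cov}[{level}]"] = (series == level).astype(float)
        else:
            cols[cov] = series.astype(float)
    return pd.DataFrame(cols, index=metadata.index, dtype=float)


def residualize(
    clr: pd.DataFrame, metadata: pd.DataFrame, covariate_set_id: int
) -> pd.DataFrame:
    """OLS-residualize each taxon's CLR abundance on a ladder step's design.

    Model 1 is centering only.  Residuals are orthogonal to the (centered)
    design columns; sample order is preserved.  Samples with missing
    covariate values are dropped listwise.
    """
    covs = covariate_ladder(covariate_set_id)
    meta = metadata.loc[clr.index]
    if not covs:
        res = clr - clr.mean(axis=0)
        res.attrs["model_id"] = covariate_set_id
        return res
    X = design_matrix(meta, covs)
    complete = X.notna().all(axis=1)
    X = X.loc[complete]
    Y = clr.loc[complete].to_numpy(dtype=float)
    Xc = X.to_numpy(dtype=float)
    Xc = np.column_stack([np.ones(len(Xc)), Xc])
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        raise ValueError(
            f"rank-deficient design for model {covariate_set_id}: columns {list(X.columns)}"
        )
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    resid = Y - Xc @ beta
    res = pd.DataFrame(resid, index=X.index, columns=clr.columns)
    res.attrs["model_id"] = covariate_set_id
    res.attrs["n_dropped_missing"] = int((~complete).sum())
    return res


def dominance_summary(
    rel: pd.DataFrame, design: pd.DataFrame, threshold: float = 0.60
) -> pd.DataFrame:
    """Per-taxon dominance and prevalence summary.

    A sample is *dominated* by a taxon when its relative abundance strictly
    exceeds ``threshold``; a woman counts as ever-dominated if any of her
    samples is.  ``design`` must carry ``woman`` and ``phase`` columns
    aligned to the samples.  Returns one row per taxon with sample- and
    woman-level dominance fractions, overall prevalence/mean abundance and
    per-phase prevalence and mean abundance.
    """
    design = design.loc[rel.index]
    dominated = rel > threshold
    women = design["woman"]
    n_women = women.nunique()
    rows = {}
    for taxon in rel.columns:
        row = {
            "frac_samples_dominated": dominated[taxon].mean(),
            "frac_women_ever_dominated": dominated[taxon].groupby(women).any().sum() / n_women,
            "prevalence": (rel[taxon] > 0).mean(),
            "mean_abundance": rel[taxon].mean(),
        }
        for phase, idx in design.groupby("phase", sort=False).groups.items():
            row[f"prevalence_{phase}"] = (rel.loc[idx, taxon] > 0).mean()
            row[f"mean_abundance_{phase}"] = rel.loc[idx, taxon].mean()
        rows[taxon] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "taxon"
    out.attrs["threshold"] = threshold
    return out
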