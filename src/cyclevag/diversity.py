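"""Alpha/beta diversity, ordination, covariate screening, and the two
beta-diversity comparison procedures (per-phase and self-vs-random).

Beta diversity is computed two ways: Bray-Curtis on relative abundances
and Euclidean distance on covariate-residualized CLR abundances.  The
self-vs-random procedure contrasts each woman's mean distance among her
own collections against pseudo-women assembled from her first collection
plus random other-women samples from the remaining phases; a strong
individual signature (high ICC) makes Self systematically smaller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.diversity.alpha import simpson as _skbio_simpson
from skbio.stats.distance import DistanceMatrix as _SkbioDM
from skbio.stats.distance import permanova as _skbio_permanova
from skbio.stats.ordination import pcoa as _skbio_pcoa

from ._rng import child_seed, substream
from .composition import design_matrix

__all__ = [
    "shannon",
    "simpson",
    "alpha_diversity_table",
    "bray_curtis",
    "euclidean_clr",
    "OrdinationResult",
    "pcoa",
    "screen_covariates_per_visit",
    "adjust_axes",
    "permanova",
    "friedman_alpha",
    "BetaComparisonResult",
    "per_phase_beta",
    "self_vs_random",
]

_PHASE_OF_VISIT = {1: "follicular", 2: "ovulatory", 3: "early_luteal", 4: "late_luteal"}


def shannon(counts_row) -> float:
    """Shannon-Weiner H = -sum p ln p (natural log)."""
    arr = np.asarray(counts_row, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("all-zero sample row")
    return float(_skbio_shannon(arr, base=np.e))


def simpson(counts_row) -> float:
    """Simpson diversity as the complement 1 - sum p^2.

    The raw concentration sum p^2 is also exposed via
    :func:`alpha_diversity_table`.
    """
    arr = np.asarray(counts_row, dtype=float)
    if arr.sum() <= 0:
        raise ValueError("all-zero sample row")
    return float(_skbio_simpson(arr))


def alpha_diversity_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon H, Simpson D (=1-sum p^2) and raw concentration."""
    rel = counts.div(counts.sum(axis=1), axis=0).to_numpy()
    conc = (rel**2).sum(axis=1)
    out = pd.DataFrame(
        {
            "shannon": [shannon(row) for row in counts.to_numpy()],
            "simpson": 1.0 - conc,
            "simpson_concentration": conc,
        },
        index=counts.index,
    )
    out.index.name = "sample_id"
    return out


def _distance_frame(values: np.ndarray, ids, metric: str) -> pd.DataFrame:
    out = pd.DataFrame(values, index=ids, columns=ids)
    out.attrs["metric"] = metric
    return out


def bray_curtis(rel: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity on relative abundances."""
    if len(rel) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(rel.to_numpy(dtype=float), metric="braycurtis"))
    return _distance_frame(d, rel.index, "bray_curtis")


def euclidean_clr(adj: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance on (residualized) CLR abundances (Aitchison-type)."""
    if len(adj) < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(adj.to_numpy(dtype=float), metric="euclidean"))
    return _distance_frame(d, adj.index, "euclidean_clr")


@dataclass
class OrdinationResult:
    """PCoA axis scores (first axes), full eigenvalue spectrum, and the
    record of covariate adjustments applied to each axis."""

    samples: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # full spectrum, descending (negatives retained)
    adjusted_with: dict[str, list[str]] = field(default_factory=dict)


def pcoa(dist: pd.DataFrame, n_axes: int = 5) -> OrdinationResult:
    """Classical MDS of a distance matrix.

    Axes are taken from positive eigenvalues only; negative eigenvalues
    are retained in the reported spectrum.  If fewer positive eigenvalues
    than ``n_axes`` exist, the available axes are returned with a warning.
    """
    import warnings as _warnings

    dm = _SkbioDM(dist.to_numpy(dtype=float), ids=[str(i) for i in dist.index])
    with _warnings.catch_warnings():
        # full-spectrum eigh is intentional: the report keeps all eigenvalues
        _warnings.filterwarnings("ignore", category=RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh", warn_neg_eigval=False)
    eig = res.eigvals.to_numpy()
    n_pos = int((eig > 1e-12).sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        import warnings

        warnings.warn(
            f"only {k} positive eigenvalues available (requested {n_axes})",
            stacklevel=2,
        )
    scores = res.samples.iloc[:, :k].copy()
    scores.index = dist.index
    scores.columns = [f"PCo{i + 1}" for i in range(k)]
    return OrdinationResult(samples=scores, eigenvalues=eig)


def screen_covariates_per_visit(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    variables: list[str],
    n_bins: int = 3,
    min_level_size: int = 2,
) -> pd.DataFrame:
    """Kruskal-Wallis screen of axis scores against covariates, per visit.

    Longitudinal dependence is avoided by testing within each visit
    separately.  Continuous variables are binned (tertiles by default);
    levels with fewer than ``min_level_size`` observations are dropped.
    Returns a tidy table (axis, variable, visit, p, note).
    """
    scores = ordination.samples
    meta = metadata.loc[scores.index]
    rows = []
    for var in variables:
        series = meta[var]
        if pd.api.types.is_numeric_dtype(series):
            binned = pd.qcut(series, n_bins, duplicates="drop")
        else:
            binned = series.astype("category")
        for visit in sorted(meta["visit_number"].unique()):
            sel = meta["visit_number"] == visit
            groups_here = binned[sel]
            for axis in scores.columns:
                vals = scores.loc[sel, axis]
                note = ""
                grouped = [
                    vals[groups_here == lev].to_numpy()
                    for lev in groups_here.dropna().unique()
                ]
                sizes = [len(g) for g in grouped]
                dropped = sum(s < min_level_size for s in sizes)
                grouped = [g for g in grouped if len(g) >= min_level_size]
                if dropped:
                    note = f"dropped_{dropped}_small_levels"
                if len(grouped) < 2:
                    rows.append(
                        {"axis": axis, "variable": var, "visit": visit,
                         "p": np.nan, "note": note or "constant_within_visit"}
                    )
                    continue
                if all(np.all(g == grouped[0][0]) for g in grouped):
                    p = 1.0
                else:
                    try:
                        p = stats.kruskal(*grouped).pvalue
                    except ValueError:  # all values identical
                        p = 1.0
                rows.append({"axis": axis, "variable": var, "visit": visit, "p": p, "note": note})
    return pd.DataFrame(rows)


def adjust_axes(
    ordination: OrdinationResult,
    metadata: pd.DataFrame,
    significant_pairs: dict[str, list[str]],
) -> OrdinationResult:
    """Residualize each axis on only the covariates it screened significant.

    ``significant_pairs`` maps axis name -> covariate names; axes without
    an entry pass through unchanged.
    """
    scores = ordination.samples.copy()
    meta = metadata.loc[scores.index]
    record: dict[str, list[str]] = {}
    for axis, covs in significant_pairs.items():
        if axis not in scores.columns or not covs:
            continue
        X = design_matrix(meta, tuple(covs))
        Xc = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
        y = scores[axis].to_numpy(dtype=float)
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        scores[axis] = y - Xc @ beta
        record[axis] = list(covs)
    return OrdinationResult(
        samples=scores, eigenvalues=ordination.eigenvalues, adjusted_with=record
    )


def permanova(
    dist: pd.DataFrame, grouping: pd.Series, n_perm: int = 999, seed: int = 0
) -> dict:
    """PERMANOVA of a distance matrix against a categorical grouping.

    Pseudo-F from the partitioned sums of squared distances; the p-value
    uses the add-one permutation rule p = (1 + #{F* >= F}) / (1 + n_perm).
    R^2 is the between-group fraction of the total sum of squares.
    """
    grouping = grouping.loc[dist.index]
    levels = grouping.value_counts()
    if len(levels) < 2:
        raise ValueError("grouping must have at least 2 levels")
    if (levels < 2).any():
        raise ValueError("every group needs at least 2 samples")
    dm = _SkbioDM(dist.to_numpy(dtype=float), ids=[str(i) for i in dist.index])
    res = _skbio_permanova(
        dm, grouping.astype(str).to_numpy(), permutations=n_perm,
        seed=np.random.default_rng(child_seed(seed, "permanova")),
    )
    f = float(res["test statistic"])
    n = len(dist)
    a = len(levels)
    r2 = (f * (a - 1)) / (f * (a - 1) + (n - a))
    return {"pseudo_F": f, "R2": r2, "p": float(res["p-value"]), "n_perm": n_perm}


def friedman_alpha(alpha: pd.Series, design: pd.DataFrame) -> float:
    """Friedman test of a per-sample metric across the 4 visits.

    Uses complete cases only (women with all four visits present).
    """
    design = design.loc[alpha.index]
    wide = pd.DataFrame(
        {"woman": design["woman"], "visit": design["visit_number"], "value": alpha}
    ).pivot(index="woman", columns="visit", values="value").dropna()
    if len(wide) < 2:
        raise ValueError("need at least 2 women with complete visits")
    if np.allclose(wide.to_numpy().std(axis=1), 0):
        return 1.0
    return float(stats.friedmanchisquare(*[wide[c] for c in wide.columns]).pvalue)


@dataclass
class BetaComparisonResult:
    """Per-group beta-diversity summaries and the pairwise tests on them.

    ``summaries`` carries the per-unit summary statistic; ``tests`` one row
    per comparison with raw and Bonferroni-corrected p-values (corrected
    p = min(1, raw * m) with m recorded in ``n_comparisons``).
    """

    summaries: pd.DataFrame
    tests: pd.DataFrame
    n_comparisons: int
    procedure: str
    summary_stat: str


def _summary_fn(summary: str):
    if summary not in ("mean", "median"):
        raise ValueError("summary must be 'mean' or 'median'")
    return np.mean if summary == "mean" else np.median


def per_phase_beta(
    dist: pd.DataFrame, design: pd.DataFrame, summary: str = "mean"
) -> BetaComparisonResult:
    """Within-phase beta diversity, compared pairwise across phases.

    Each sample is summarized by the mean (or median) of its distances to
    all other samples of the same phase; phase distributions are compared
    for all 6 phase pairs with a Wilcoxon signed-rank test and a paired
    t-test, both paired by woman over women present in both phases, with
    Bonferroni correction over the 6 pairs.
    """
    fn = _summary_fn(summary)
    design = design.loc[dist.index]
    d = dist.to_numpy(dtype=float)
    pos = {sid: i for i, sid in enumerate(dist.index)}
    phase_members: dict[int, list[str]] = {
        v: list(idx) for v, idx in design.groupby("visit_number").groups.items()
    }
    for v, members in phase_members.items():
        if len(members) < 2:
            raise ValueError(f"phase {v} has fewer than 2 samples")
    summaries = []
    for v, members in phase_members.items():
        rows = np.array([pos[s] for s in members])
        sub = d[np.ix_(rows, rows)]
        for k, sid in enumerate(members):
            others = np.delete(sub[k], k)
            summaries.append(
                {
                    "sample_id": sid,
                    "woman": design.loc[sid, "woman"],
                    "visit_number": v,
                    "phase": _PHASE_OF_VISIT.get(v, str(v)),
                    "summary": fn(others),
                }
            )
    summ = pd.DataFrame(summaries).set_index("sample_id")
    visits = sorted(phase_members)
    pairs = [(a, b) for i, a in enumerate(visits) for b in visits[i + 1 :]]
    m = len(pairs)
    tests = []
    for a, b in pairs:
        sa = summ.loc[summ["visit_number"] == a].set_index("woman")["summary"]
        sb = summ.loc[summ["visit_number"] == b].set_index("woman")["summary"]
        common = sa.index.intersection(sb.index)
        xa, xb = sa.loc[common].to_numpy(), sb.loc[common].to_numpy()
        if len(common) < 2 or np.allclose(xa, xb):
            pw = pt = 1.0
        else:
            pw = float(stats.wilcoxon(xa, xb).pvalue)
            pt = float(stats.ttest_rel(xa, xb).pvalue)
        tests.append(
            {
                "comparison": f"{_PHASE_OF_VISIT.get(a, a)}_vs_{_PHASE_OF_VISIT.get(b, b)}",
                "n_pairs": len(common),
                "p_wilcoxon": pw,
                "p_ttest": pt,
                "p_wilcoxon_bonf": min(1.0, pw * m),
                "p_ttest_bonf": min(1.0, pt * m),
            }
        )
    return BetaComparisonResult(
        summaries=summ,
        tests=pd.DataFrame(tests),
        n_comparisons=m,
        procedure="per_phase",
        summary_stat=summary,
    )


def self_vs_random(
    dist: pd.DataFrame,
    design: pd.DataFrame,
    n_random: int = 10,
    seed: int = 0,
    summary: str = "mean",
) -> BetaComparisonResult:
    """Self vs random-pseudo-woman beta-diversity comparison.

    Self: for each woman with >=2 samples, the mean (or median) pairwise
    distance among her own collections.  Random replicate r: for each
    woman, her first collection (visit 1) is combined with one sample per
    remaining phase, each drawn uniformly from *other* women (without
    replacement within the pseudo-woman), and the same summary computed.
    Self is compared to each replicate with an unpaired Wilcoxon
    (Mann-Whitney) test, Bonferroni-corrected over the ``n_random`` tests.
    The Self distribution does not depend on the seed.
    """
    fn = _summary_fn(summary)
    design = design.loc[dist.index]
    d = dist.to_numpy(dtype=float)
    pos = {sid: i for i, sid in enumerate(dist.index)}
    women = design.groupby("woman").groups
    multi = {w: list(ids) for w, ids in women.items() if len(ids) >= 2}
    if len(women) < 4:
        raise ValueError("need at least 4 women")
    self_vals = {}
    for w, ids in multi.items():
        rows = np.array([pos[s] for s in ids])
        sub = d[np.ix_(rows, rows)]
        self_vals[w] = fn(sub[np.triu_indices(len(rows), k=1)])
    self_series = pd.Series(self_vals, name="self")

    by_visit: dict[int, pd.Index] = {
        v: idx for v, idx in design.groupby("visit_number").groups.items()
    }
    first = {
        w: sid
        for w, ids in women.items()
        for sid in ids
        if design.loc[sid, "visit_number"] == 1
    }
    rng = substream(seed, "self_vs_random")
    rep_rows = []
    tests = []
    for r in range(1, n_random + 1):
        rand_vals = {}
        for w, anchor in first.items():
            members = [anchor]
            for v in (2, 3, 4):
                donors = [
                    s for s in by_visit.get(v, []) if design.loc[s, "woman"] != w and s not in members
                ]
                if not donors:
                    raise ValueError(f"no donor samples available in phase {v}")
                members.append(donors[rng.integers(len(donors))])
            rows = np.array([pos[s] for s in members])
            sub = d[np.ix_(rows, rows)]
            rand_vals[w] = fn(sub[np.triu_indices(len(rows), k=1)])
        rand_series = pd.Series(rand_vals)
        for w, val in rand_series.items():
            rep_rows.append({"replicate": r, "woman": w, "summary": val})
        if np.allclose(self_series.to_numpy(), self_series.iloc[0]) and np.allclose(
            rand_series.to_numpy(), self_series.iloc[0]
        ):
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(
                    self_series.to_numpy(), rand_series.to_numpy(), alternative="two-sided"
                ).pvalue
            )
        tests.append(
            {
                "comparison": f"self_vs_random_{r}",
                "n_self": len(self_series),
                "n_random": len(rand_series),
                "p_wilcoxon": p,
                "p_wilcoxon_bonf": min(1.0, p * n_random),
            }
        )
    summaries = pd.concat(
        [
            self_series.rename("summary").to_frame().assign(replicate=0).rename_axis("woman").reset_index(),
            pd.DataFrame(rep_rows)[["replicate", "woman", "summary"]],
        ],
        ignore_index=True,
    )
    return BetaComparisonResult(
        summaries=summaries,
        tests=pd.DataFrame(tests),
        n_comparisons=n_random,
        procedure="self_vs_random",
        summary_stat=summary,
    )
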