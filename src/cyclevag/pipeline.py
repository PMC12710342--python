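"""End-to-end analysis pipeline over a cohort's tables.

``run_all`` takes the cohort tables (counts, hormones, metadata, read
stats, centroids), applies QC and compositional preprocessing, and runs
every analysis stage: alpha/beta diversity with the Friedman and pairwise
phase tests, PCoA with per-visit covariate screening and PERMANOVA
follow-up, the per-phase and self-vs-random beta comparisons, the
10-model visit-trend ladder with permutation empirical p-values and ICC,
the consecutive-phase hormone-difference models, the whole-cycle hormone
models, and CST assignment with transition bookkeeping.  All result tables
are written as TSV with a fixed float format, so identical inputs and seed
produce byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import association, composition, cst, diversity, io
from .synthetic import HORMONES

__all__ = ["run_all", "load_cohort_dir"]

_HOST_VARIABLES = [
    "Age",
    "sex_less_than_two_days",
    "Pregnancy_category",
    "Pill_use",
    "Swab_after_feces",
    "Bristol_stool_scale",
    "Swab_morning_or_not",
    "WHR_ranges",
    "smoking",
]


def load_cohort_dir(in_dir) -> dict:
    """Load the TSV tables written by ``cyclevag simulate``."""
    in_dir = Path(in_dir)
    tables = {
        "counts": io.read_counts(in_dir / "counts.tsv"),
        "hormones": io.read_table(in_dir / "hormones.tsv"),
        "metadata": io.read_table(in_dir / "metadata.tsv"),
    }
    rs = in_dir / "read_stats.tsv"
    tables["read_stats"] = io.read_table(rs) if rs.exists() else None
    cen = in_dir / "centroids.tsv"
    tables["centroids"] = io.read_table(cen, index_col="CST") if cen.exists() else None
    return tables


def run_all(
    counts: pd.DataFrame,
    hormones: pd.DataFrame,
    metadata: pd.DataFrame,
    read_stats: pd.DataFrame | None = None,
    centroids: pd.DataFrame | None = None,
    out_dir=None,
    seed: int = 0,
    n_perm: int = 200,
    model_ids: tuple[int, ...] = tuple(range(1, 11)),
    n_random: int = 10,
    fdr_threshold: float = 0.2,
    screen_alpha: float = 0.05,
) -> dict:
    """Run every analysis stage; return (and optionally write) result tables."""
    results: dict[str, pd.DataFrame] = {}

    # --- sample QC ------------------------------------------------------
    if read_stats is not None:
        kept, removed = io.qc_filter_samples(read_stats)
        results["qc_removed"] = removed.set_index("sample_id")
        keep_ids = [s for s in counts.index if s in set(kept)]
        counts = counts.loc[keep_ids]
    counts = io.apply_rare_asv_filter(counts)
    hormones = hormones.loc[hormones.index.intersection(counts.index)]
    metadata = metadata.loc[counts.index]
    design = metadata[["woman", "visit_number", "phase"]]

    # --- composition ----------------------------------------------------
    rel = composition.to_relative_abundance(counts)
    clr = composition.clr_transform(rel)
    adj_tech = composition.residualize(clr, metadata, 2)  # technical covariates
    kept_taxa = composition.filter_taxa(rel)
    results["dominance"] = composition.dominance_summary(rel, design)

    # --- alpha diversity ------------------------------------------------
    alpha = diversity.alpha_diversity_table(counts)
    results["alpha"] = alpha
    alpha_tests = []
    for metric in ("shannon", "simpson"):
        alpha_tests.append(
            {
                "metric": metric,
                "test": "friedman",
                "p": diversity.friedman_alpha(alpha[metric], design),
            }
        )
    results["alpha_tests"] = pd.DataFrame(alpha_tests)

    # --- beta diversity and ordination ----------------------------------
    d_bray = diversity.bray_curtis(rel)
    d_eucl = diversity.euclidean_clr(adj_tech)
    ord_bray = diversity.pcoa(d_bray, n_axes=5)
    screen = diversity.screen_covariates_per_visit(
        ord_bray, metadata, [v for v in _HOST_VARIABLES if v in metadata.columns]
    )
    results["covariate_screen"] = screen
    sig = screen.loc[screen["p"] < screen_alpha]
    sig_pairs: dict[str, list[str]] = {}
    for axis, grp in sig.groupby("axis"):
        sig_pairs[axis] = sorted(grp["variable"].unique())
    ord_adj = diversity.adjust_axes(ord_bray, metadata, sig_pairs)
    results["pcoa_scores"] = ord_adj.samples

    permanova_rows = []
    for (variable, visit), _ in sig.groupby(["variable", "visit"]):
        sel = metadata.index[metadata["visit_number"] == visit]
        sub = d_bray.loc[sel, sel]
        grouping = metadata.loc[sel, variable]
        if pd.api.types.is_numeric_dtype(grouping):
            grouping = pd.qcut(grouping, 3, duplicates="drop").astype(str)
        sizes = grouping.value_counts()
        if len(sizes) < 2 or (sizes < 2).any():
            continue
        res = diversity.permanova(sub, grouping, n_perm=999, seed=seed)
        permanova_rows.append({"variable": variable, "visit": visit, **res})
    results["permanova"] = pd.DataFrame(
        permanova_rows, columns=["variable", "visit", "pseudo_F", "R2", "p", "n_perm"]
    )

    # --- beta comparison procedures --------------------------------------
    per_phase = diversity.per_phase_beta(d_eucl, design, summary="mean")
    results["per_phase_beta"] = per_phase.tests
    svr = diversity.self_vs_random(d_eucl, design, n_random=n_random, seed=seed)
    results["self_vs_random"] = svr.tests
    results["self_vs_random_summaries"] = svr.summaries

    # --- visit-trend ladder and ICC --------------------------------------
    visit_frames = []
    for mid in model_ids:
        adj = composition.residualize(clr[kept_taxa], metadata, mid)
        fits = association.fit_visit_model(adj, design, mid)
        # permutation empirical p for nominally significant taxa
        emp = {}
        from .lmm import RandomInterceptModel

        X = np.column_stack(
            [np.ones(len(adj)), design.loc[adj.index, "visit_number"].to_numpy(float)]
        )
        model = RandomInterceptModel(X, design.loc[adj.index, "woman"].to_numpy())
        for taxon, row in fits.iterrows():
            if row["p"] < 0.05:
                emp[taxon] = association.empirical_pvalue(
                    model,
                    adj[taxon].to_numpy(float),
                    row["p"],
                    coef_index=1,
                    n_perm=n_perm,
                    seed=seed,
                    label=("visit", mid, taxon),
                )
        fits["p_empirical"] = pd.Series(emp).reindex(fits.index)
        visit_frames.append(fits.reset_index())
    results["visit_models"] = pd.concat(visit_frames, ignore_index=True)

    adj2 = composition.residualize(clr[kept_taxa], metadata, 2)
    icc_rows = [
        vars(association.icc(adj2[t], design)) for t in kept_taxa
    ]
    results["icc"] = pd.DataFrame(icc_rows).set_index("taxon")

    # --- hormone models ---------------------------------------------------
    hormones_clean, removal_log = association.remove_hormone_outliers(hormones)
    results["hormone_outliers"] = removal_log.set_index("sample_id") if len(removal_log) else removal_log

    diff_rows = []
    hsub = hormones_clean.loc[hormones_clean.index.intersection(adj_tech.index)]
    for hormone in [h for h in HORMONES if h in hsub.columns]:
        dh = association.consecutive_differences(hsub[hormone], design)
        dh["delta"] = _safe_ordernorm(dh["delta"])
        for taxon in kept_taxa:
            dt = association.consecutive_differences(adj_tech[taxon], design)
            dt["delta"] = _safe_ordernorm(dt["delta"])
            for transition in ("F-O", "O-EL", "EL-LL"):
                res = association.fit_difference_model(
                    dh,
                    dt,
                    transition,
                    n_perm=n_perm if n_perm > 0 else 0,
                    seed=seed,
                    label=(hormone, taxon),
                )
                diff_rows.append({"hormone": hormone, "taxon": taxon, **res})
    diff = pd.DataFrame(diff_rows)
    diff["q"] = association.fdr_adjust(diff["p"].to_numpy())
    results["difference_models"] = diff

    overall_rows = []
    for hormone in [h for h in HORMONES if h in hsub.columns]:
        for taxon in kept_taxa:
            res = association.fit_overall_hormone_model(
                hsub[hormone], adj_tech[taxon], metadata, n_perm=0, seed=seed
            )
            overall_rows.append({"hormone": hormone, "taxon": taxon, **res})
    overall = pd.DataFrame(overall_rows)
    overall["q"] = association.fdr_adjust(overall["p"].to_numpy())
    # permutation empirical p for the nominally significant pairs
    emp_vals = np.full(len(overall), np.nan)
    for i, row in overall.iterrows():
        if row["p"] < 0.05 and n_perm > 0:
            res = association.fit_overall_hormone_model(
                hsub[row["hormone"]],
                adj_tech[row["taxon"]],
                metadata,
                n_perm=n_perm,
                seed=seed,
            )
            emp_vals[i] = res["p_empirical"]
    overall["p_empirical"] = emp_vals
    overall["significant_fdr"] = overall["q"] < fdr_threshold
    results["overall_models"] = overall

    # --- CST --------------------------------------------------------------
    if centroids is not None:
        harmonized, flagged = cst.harmonize_taxa(rel, list(centroids.columns))
        assignments = cst.assign_cst(harmonized, centroids, unclassifiable=flagged)
        assign_df = pd.DataFrame(
            [
                {"sample_id": a.sample_id, "cst": a.label, "tie": a.tie,
                 **{f"theta_{k}": v for k, v in sorted(a.scores.items())}}
                for a in assignments
            ]
        ).set_index("sample_id")
        results["cst_assignments"] = assign_df
        trans = cst.cst_transitions(assign_df["cst"], design)
        results["cst_transitions"] = trans.transitions
        results["cst_phase_pair_changes"] = trans.phase_pair_changes.rename("n_changes").to_frame()
        results["cst_woman_class"] = trans.woman_class.rename("class").to_frame()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in results.items():
            if isinstance(table, pd.DataFrame):
                label = table.index.name or "row"
                io.write_table(table, out_dir / f"{name}.tsv", index_label=label)
    return results


def _safe_ordernorm(series: pd.Series) -> pd.Series:
    vals = series.to_numpy(dtype=float)
    if np.isnan(vals).all() or len(vals) < 3:
        return series
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pd.Series(association.ordernorm(vals), index=series.index)
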