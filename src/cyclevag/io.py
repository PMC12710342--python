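"""Table I/O, sample-level QC, count subsampling and taxa relabeling.

All tables are plain UTF-8 TSV with a header row and a first column
``sample_id`` (or a label column for centroid tables); counts round-trip
losslessly.  The QC rules mirror a 16S sequencing workflow: samples fail on
low input reads, low post-trimming reads, or membership in a library batch
whose negative control shows contamination.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "read_counts",
    "write_counts",
    "read_table",
    "write_table",
    "validate_counts",
    "qc_filter_samples",
    "subsample_counts",
    "apply_rare_asv_filter",
    "relabel_taxa",
]

_TSV = dict(sep="\t", encoding="utf-8")


def validate_counts(counts: pd.DataFrame) -> None:
    """Raise ValueError on duplicate ids/taxa or negative/non-integer cells."""
    if counts.shape[1] == 0:
        raise ValueError("no taxa columns")
    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    if counts.columns.duplicated().any():
        dups = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon names: {dups}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("counts must be numeric")
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at sample {counts.index[i]!r}, taxon {counts.columns[j]!r}"
        )
    frac = np.argwhere(arr != np.floor(arr))
    if frac.size:
        i, j = frac[0]
        raise ValueError(
            f"non-integer count at sample {counts.index[i]!r}, taxon {counts.columns[j]!r}"
        )


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, index_col="sample_id", **_TSV)
    validate_counts(counts)
    return counts.astype(np.int64)


def write_counts(counts: pd.DataFrame, path) -> None:
    validate_counts(counts)
    counts.to_csv(path, sep="\t", index_label="sample_id")


def read_table(path, index_col: str = "sample_id") -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col, **_TSV)


def write_table(table: pd.DataFrame, path, index_label: str = "sample_id") -> None:
    table.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def qc_filter_samples(
    stats: pd.DataFrame,
    min_input: int = 80_000,
    min_survived: int = 60_000,
    neg_ctrl_max: int = 500,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three sample-removal rules of the sequencing QC.

    A (non-control) sample is removed iff its input reads fall below
    ``min_input``, its post-trimming reads fall below ``min_survived``, or
    any negative control in its batch carries more than ``neg_ctrl_max``
    reads.  Returns (kept sample ids, removals table with columns
    ``sample_id``/``reason`` using machine-readable codes ``low_input``,
    ``low_survived``, ``contaminated_batch``).
    """
    if (stats["survived_reads"] > stats["input_reads"]).any():
        bad = stats.index[stats["survived_reads"] > stats["input_reads"]][0]
        raise ValueError(f"survived_reads exceeds input_reads for sample {bad!r}")
    is_neg = stats["is_negative_control"].astype(bool)
    samples = stats.loc[~is_neg]
    controls = stats.loc[is_neg]
    contaminated = set(controls.loc[controls["input_reads"] > neg_ctrl_max, "batch"])
    batches_without_control = set(samples["batch"]) - set(controls["batch"])
    if batches_without_control:
        warnings.warn(
            f"batches without a negative control, contamination rule skipped: "
            f"{sorted(batches_without_control)}",
            stacklevel=2,
        )
    removed: list[tuple[str, str]] = []
    kept: list[str] = []
    for sid, row in samples.iterrows():
        if row["input_reads"] < min_input:
            removed.append((sid, "low_input"))
        elif row["survived_reads"] < min_survived:
            removed.append((sid, "low_survived"))
        elif row["batch"] in contaminated:
            removed.append((sid, "contaminated_batch"))
        else:
            kept.append(sid)
    removed_df = pd.DataFrame(removed, columns=["sample_id", "reason"])
    return kept, removed_df


def subsample_counts(counts: pd.DataFrame, depth: int, seed: int = 0) -> pd.DataFrame:
    """Rarefy each sample to ``depth`` reads without replacement.

    Rows with total <= depth are left untouched; the rest are replaced by a
    multivariate-hypergeometric draw of exactly ``depth`` reads from the
    observed count vector (the count-space analogue of subsampling FASTQ
    reads).  Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    validate_counts(counts)
    out = counts.copy()
    for i, sid in enumerate(counts.index):
        row = counts.iloc[i].to_numpy(dtype=np.int64)
        if row.sum() > depth:
            rng = substream(seed, "subsample", sid)
            out.iloc[i] = rng.multivariate_hypergeometric(row, depth)
    return out


def apply_rare_asv_filter(
    counts: pd.DataFrame, min_reads: int = 5, min_samples: int = 2
) -> pd.DataFrame:
    """Keep taxa with >= min_reads reads in >= min_samples samples (inclusive)."""
    validate_counts(counts)
    keep = (counts >= min_reads).sum(axis=0) >= min_samples
    return counts.loc[:, keep]


def relabel_taxa(
    counts: pd.DataFrame, mapping: dict[str, str], strict: bool = True
) -> pd.DataFrame:
    """Rename taxa; columns mapped to the same name are summed.

    Used both for subgenus-level renaming of *Lactobacillus* species and
    for collapsing ambiguous ASVs into an "unclassified" bucket.  With
    ``strict`` the mapping may not name unknown taxa.
    """
    validate_counts(counts)
    unknown = set(mapping) - set(counts.columns)
    if unknown and strict:
        raise ValueError(f"mapping keys not present in table: {sorted(unknown)}")
    new_names = [mapping.get(c, c) for c in counts.columns]
    out = counts.copy()
    out.columns = new_names
    out = out.T.groupby(level=0, sort=False).sum().T
    return out
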