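"""Community State Type (CST) assignment and longitudinal transitions.

Samples are assigned to the CST whose reference centroid composition they
most resemble under the Yue-Clayton similarity; a dominance-rule fallback
labels samples by their >60% marker species.  Reference centroids are an
external input (a TSV with one row per CST over a taxa vocabulary); the
repository's tests use synthetic centroids only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "harmonize_taxa",
    "yue_clayton_similarity",
    "assign_cst",
    "dominance_cst",
    "cst_transitions",
    "CSTAssignment",
]

_DOMINANCE_MARKERS = {
    "CST-I": "Lactobacillus crispatus",
    "CST-II": "Lactobacillus gasseri",
    "CST-III": "Lactobacillus iners",
    "CST-V": "Lactobacillus jensenii",
}

_PHASE_PAIR = {1: "F-O", 2: "O-EL", 3: "EL-LL"}


@dataclass
class CSTAssignment:
    sample_id: str
    label: str | None
    scores: dict[str, float]
    method: str
    tie: bool = False
    unclassifiable: bool = False


def harmonize_taxa(
    rel: pd.DataFrame,
    vocabulary: list[str],
    rename_map: dict[str, str] | None = None,
    unmapped: str = "drop",
    max_unmapped_mass: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Re-express compositions on a centroid vocabulary and renormalize.

    Source taxa are renamed via ``rename_map`` (several may map to one
    target and are summed); taxa absent from the vocabulary are dropped
    (``unmapped='drop'``) or pooled into an ``Other`` column if the
    vocabulary carries one (``unmapped='other'``).  Returns the aligned
    table plus a per-sample flag marking samples whose unmapped mass
    exceeds ``max_unmapped_mass`` (unclassifiable).
    """
    if unmapped not in ("drop", "other"):
        raise ValueError("unmapped policy must be 'drop' or 'other'")
    renamed = rel.copy()
    if rename_map:
        renamed.columns = [rename_map.get(c, c) for c in renamed.columns]
        renamed = renamed.T.groupby(level=0, sort=False).sum().T
    vocab = list(vocabulary)
    in_vocab = [c for c in renamed.columns if c in vocab]
    out_vocab = [c for c in renamed.columns if c not in vocab]
    unmapped_mass = renamed[out_vocab].sum(axis=1) if out_vocab else pd.Series(0.0, index=renamed.index)
    aligned = pd.DataFrame(0.0, index=renamed.index, columns=vocab)
    aligned[in_vocab] = renamed[in_vocab]
    if unmapped == "other" and "Other" in vocab:
        aligned["Other"] += unmapped_mass
    totals = aligned.sum(axis=1)
    flagged = unmapped_mass > max_unmapped_mass
    safe = totals.where(totals > 0, 1.0)
    aligned = aligned.div(safe, axis=0)
    aligned.attrs["unmapped_mass"] = unmapped_mass
    return aligned, flagged


def yue_clayton_similarity(x, y) -> float:
    """Yue-Clayton theta = sum(xy) / (sum x^2 + sum y^2 - sum(xy))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not x.any() or not y.any():
        raise ValueError("zero composition vector")
    num = float(x @ y)
    return num / (float(x @ x) + float(y @ y) - num)


def assign_cst(
    samples: pd.DataFrame, centroids: pd.DataFrame, unclassifiable: pd.Series | None = None
) -> list[CSTAssignment]:
    """Nearest-centroid assignment under Yue-Clayton similarity.

    Vocabularies must already be harmonized (same columns).  Ties are
    broken lexicographically on the CST label and flagged.  Samples marked
    unclassifiable keep a null label with their score vector.
    """
    missing = set(centroids.columns) ^ set(samples.columns)
    if missing:
        raise ValueError(f"sample/centroid vocabularies differ: {sorted(missing)}")
    cents = centroids[samples.columns]
    labels = sorted(cents.index)
    out = []
    for sid, row in samples.iterrows():
        x = row.to_numpy(dtype=float)
        scores = {lab: yue_clayton_similarity(x, cents.loc[lab].to_numpy()) for lab in labels}
        best = max(scores.values())
        winners = [lab for lab in labels if scores[lab] == best]
        flagged = bool(unclassifiable is not None and unclassifiable.get(sid, False))
        out.append(
            CSTAssignment(
                sample_id=str(sid),
                label=None if flagged else winners[0],
                scores=scores,
                method="centroid",
                tie=len(winners) > 1,
                unclassifiable=flagged,
            )
        )
    return out


def dominance_cst(samples: pd.DataFrame, threshold: float = 0.60) -> list[CSTAssignment]:
    """Dominance-rule fallback: label by the marker species exceeding the
    threshold (strict), else CST-IV."""
    markers = {
        lab: sp for lab, sp in _DOMINANCE_MARKERS.items() if sp in samples.columns
    }
    if len(markers) < 4:
        missing = set(_DOMINANCE_MARKERS.values()) - set(samples.columns)
        raise ValueError(f"dominance rule needs the Lactobacillus markers; missing {sorted(missing)}")
    out = []
    for sid, row in samples.iterrows():
        label = "CST-IV"
        scores = {}
        for lab, sp in markers.items():
            scores[lab] = float(row[sp])
            if row[sp] > threshold:
                label = lab
        out.append(CSTAssignment(sample_id=str(sid), label=label, scores=scores, method="dominance"))
    return out


@dataclass
class CSTTransitions:
    transitions: pd.DataFrame  # one row per consecutive visit pair per woman
    phase_pair_changes: pd.Series  # change counts per F-O / O-EL / EL-LL
    woman_changes: pd.Series  # number of changes per woman
    woman_class: pd.Series  # CH / CH+NA / NO CH / NO CH+NA
    n_women_changed: int = field(init=False)

    def __post_init__(self):
        self.n_women_changed = int((self.woman_changes > 0).sum())


def cst_transitions(assignments: pd.Series, design: pd.DataFrame) -> CSTTransitions:
    """Longitudinal CST-change bookkeeping.

    ``assignments`` maps sample_id -> CST label.  Changes are counted
    between consecutive *available* visits; women are classed CH / CH+NA /
    NO CH / NO CH+NA by whether any change occurred and whether all four
    visits are present.
    """
    design = design.loc[assignments.index]
    frame = pd.DataFrame(
        {
            "woman": design["woman"],
            "visit": design["visit_number"],
            "label": assignments,
        }
    )
    rows = []
    woman_changes = {}
    woman_class = {}
    for woman, grp in frame.groupby("woman", sort=True):
        by_visit = grp.set_index("visit")["label"].dropna()
        changes = 0
        for t in (1, 2, 3):
            if t in by_visit.index and (t + 1) in by_visit.index:
                changed = by_visit[t] != by_visit[t + 1]
                changes += int(changed)
                rows.append(
                    {
                        "woman": woman,
                        "phase_pair": _PHASE_PAIR[t],
                        "from_label": by_visit[t],
                        "to_label": by_visit[t + 1],
                        "changed": bool(changed),
                    }
                )
        complete = all(v in by_visit.index for v in (1, 2, 3, 4))
        woman_changes[woman] = changes
        if changes > 0:
            woman_class[woman] = "CH" if complete else "CH+NA"
        else:
            woman_class[woman] = "NO CH" if complete else "NO CH+NA"
    transitions = pd.DataFrame(rows, columns=["woman", "phase_pair", "from_label", "to_label", "changed"])
    if len(transitions):
        pair_counts = (
            transitions.loc[transitions["changed"]].groupby("phase_pair")["changed"].count()
        )
    else:
        pair_counts = pd.Series(dtype=int)
    pair_counts = pair_counts.reindex(["F-O", "O-EL", "EL-LL"], fill_value=0)
    return CSTTransitions(
        transitions=transitions,
        phase_pair_changes=pair_counts,
        woman_changes=pd.Series(woman_changes).sort_index(),
        woman_class=pd.Series(woman_class).sort_index(),
    )
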