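"""Synthetic menstrual-cycle cohort generator.

Emulates the data structure of a short-term longitudinal vaginal-microbiota
study: ~61 women sampled at four visits timed to the menstrual-cycle phases
(follicular, ovulatory, early luteal, late luteal), each visit yielding a
16S taxa count vector, a five-hormone serum panel (17-beta estradiol, LH,
FSH, progesterone, prolactin) and technical/host metadata.

The generative model is logistic-normal/multinomial: each woman is assigned
a community-state-type (CST) regime; a per-taxon latent log-abundance is

    latent = regime baseline + woman intercept + visit slope * visit
             + hormone coupling * within-woman hormone deviation + noise,

the composition is the softmax of the latents and counts are a multinomial
draw at a lognormally distributed library size.  The woman-intercept and
noise variances are set from ``icc_target`` so the latent intraclass
correlation is known exactly; every random quantity used in generation is
recorded in a :class:`GroundTruth` object so downstream estimators can be
tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream

__all__ = [
    "HORMONES",
    "PHASES",
    "CST_LABELS",
    "CohortConfig",
    "GroundTruth",
    "default_taxa_panel",
    "default_regime_baselines",
    "default_hormone_profiles",
    "default_cst_frequencies",
    "null_config",
    "study_effects",
    "generate_cohort",
    "generate_centroids",
    "generate_read_stats",
]

HORMONES = ("BES17", "LH", "FSH", "PROG", "PRL")

#: visit number -> menstrual-cycle phase
PHASES = {1: "follicular", 2: "ovulatory", 3: "early_luteal", 4: "late_luteal"}

CST_LABELS = ("CST-I", "CST-II", "CST-III", "CST-IV", "CST-V")

# Dominant marker species per Lactobacillus-dominated CST.
CST_MARKERS = {
    "CST-I": "Lactobacillus crispatus",
    "CST-II": "Lactobacillus gasseri",
    "CST-III": "Lactobacillus iners",
    "CST-V": "Lactobacillus jensenii",
}


def default_taxa_panel() -> list[str]:
    """Panel of 24 vaginal taxa typical of 16S profiling of this niche."""
    return [
        "Lactobacillus iners",
        "Lactobacillus crispatus",
        "Lactobacillus gasseri",
        "Lactobacillus jensenii",
        "Bifidobacterium vaginale",
        "Bifidobacterium breve",
        "Prevotella timonensis_A",
        "Prevotella bivia",
        "Fannyhessea vaginae",
        "Streptococcus agalactiae",
        "Streptococcus unclassified",
        "Finegoldia magna",
        "Anaerococcus tetradius",
        "Dialister micraerophilus",
        "Corynebacterium amycolatum",
        "Atopobium deltae",
        "Megasphaera lornae",
        "Sneathia vaginalis",
        "Mobiluncus curtisii",
        "Peptoniphilus harei",
        "Veillonella montpellierensis",
        "Ureaplasma parvum",
        "Aerococcus christensenii",
        "Staphylococcus epidermidis",
    ]


def default_regime_baselines(taxa: list[str] | None = None) -> pd.DataFrame:
    """Baseline latent log-abundances per CST regime (regimes x taxa).

    Dominant species sit ~5 latent-log units above the background so their
    softmax share is typically >60%; the two major lactobacilli are present
    at low level in every regime (their prevalence in healthy cohorts
    exceeds 90%); the CST-IV regime spreads mass over several anaerobes.
    """
    taxa = list(taxa) if taxa is not None else default_taxa_panel()
    base = pd.DataFrame(0.0, index=list(CST_LABELS), columns=taxa)
    for cst, marker in CST_MARKERS.items():
        if marker in base.columns:
            base.loc[cst, marker] = 5.0
    for cst in CST_LABELS:
        if "Lactobacillus iners" in base.columns:
            base.loc[cst, "Lactobacillus iners"] = max(
                base.loc[cst, "Lactobacillus iners"], 2.5
            )
        if "Lactobacillus crispatus" in base.columns:
            base.loc[cst, "Lactobacillus crispatus"] = max(
                base.loc[cst, "Lactobacillus crispatus"], 2.0
            )
    anaerobes = {
        "Bifidobacterium vaginale": 3.5,
        "Prevotella timonensis_A": 3.0,
        "Fannyhessea vaginae": 3.0,
        "Finegoldia magna": 2.5,
        "Anaerococcus tetradius": 2.5,
        "Dialister micraerophilus": 2.5,
        "Prevotella bivia": 2.2,
        "Megasphaera lornae": 2.0,
        "Sneathia vaginalis": 2.0,
    }
    for taxon, level in anaerobes.items():
        if taxon in base.columns:
            base.loc["CST-IV", taxon] = level
    base.loc["CST-IV", "Lactobacillus iners"] = 2.0
    base.loc["CST-IV", "Lactobacillus crispatus"] = 1.5
    return base


def default_hormone_profiles() -> dict[str, dict]:
    """Cyclic serum-hormone profiles: per-visit means plus SDs.

    Units are those of a standard immunoassay panel (BES17 pg/mL, LH/FSH
    IU/L, PROG/PRL ng/mL).  17-beta estradiol and LH peak at the ovulatory
    visit; progesterone peaks in the luteal visits; prolactin is flat.
    Levels are generated lognormally around the per-visit mean (serum
    hormones are positive and right-skewed), so ``between_sd`` (woman-level
    intercept) and ``within_sd`` (visit-to-visit fluctuation) are SDs on
    the log scale, i.e. approximately coefficients of variation.
    """
    return {
        "BES17": {"visit_means": (60.0, 180.0, 130.0, 100.0), "within_sd": 0.30, "between_sd": 0.15},
        "LH": {"visit_means": (6.0, 28.0, 8.0, 6.0), "within_sd": 0.40, "between_sd": 0.15},
        "FSH": {"visit_means": (7.0, 11.0, 4.0, 3.0), "within_sd": 0.30, "between_sd": 0.15},
        "PROG": {"visit_means": (0.6, 1.5, 9.0, 11.0), "within_sd": 0.50, "between_sd": 0.25},
        "PRL": {"visit_means": (12.0, 13.0, 12.5, 12.0), "within_sd": 0.25, "between_sd": 0.20},
    }


def default_cst_frequencies() -> dict[str, float]:
    """Observed CST sample frequencies, renormalized to sum exactly to 1."""
    raw = {"CST-I": 0.316, "CST-II": 0.127, "CST-III": 0.382, "CST-IV": 0.141, "CST-V": 0.033}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Parameters
    ----------
    n_women : int
        Cohort size (default 61).
    n_visits : int
        Number of cycle-phase visits; the study design fixes this at 4.
    seed : int
        Master seed; every random stream is derived from it.
    cst_frequencies : dict
        Probability of each CST regime per woman; must sum to 1 (1e-9).
    icc_target : float
        Latent intraclass correlation sigma_b^2/(sigma_b^2+sigma_e^2) of
        every taxon, in [0, 1).
    latent_total_var : float
        sigma_b^2 + sigma_e^2 of the latent log-abundance (default 1.25,
        so icc_target=0.8 gives sigma_b=1, sigma_e=0.5).
    library_size_mean, library_size_cv : float
        Mean and coefficient of variation of the lognormal sequencing
        library size (reads per sample).
    missing_rate : float
        Per-(woman, visit) probability that a non-first visit is missing;
        visit 1 is never dropped (the self-vs-random resampling anchors on
        each woman's first collection).
    visit_effects : list of (taxon, slope)
        Linear latent-scale slope per visit unit injected into a taxon.
    hormone_effects : list of (hormone, taxon, coupling)
        Latent-scale shift per 1 within-woman SD of the hormone's
        visit-level fluctuation.
    hormone_profiles : dict
        Per-hormone visit means and SDs (see ``default_hormone_profiles``).
    taxa_panel : list of str
        Ordered taxon names.
    regime_baselines : DataFrame
        Regime x taxon latent baselines; rows must cover cst_frequencies.
    """

    n_women: int = 61
    n_visits: int = 4
    seed: int = 0
    cst_frequencies: dict[str, float] = field(default_factory=default_cst_frequencies)
    icc_target: float = 0.8
    latent_total_var: float = 1.25
    library_size_mean: float = 138_000.0
    library_size_cv: float = 0.25
    missing_rate: float = 0.16
    visit_effects: list[tuple[str, float]] = field(default_factory=list)
    hormone_effects: list[tuple[str, str, float]] = field(default_factory=list)
    hormone_profiles: dict[str, dict] = field(default_factory=default_hormone_profiles)
    taxa_panel: list[str] = field(default_factory=default_taxa_panel)
    regime_baselines: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.regime_baselines is None:
            self.regime_baselines = default_regime_baselines(self.taxa_panel)
        self.validate()

    def validate(self) -> None:
        if self.n_women <= 0:
            raise ValueError("n_women must be a positive integer")
        if self.n_visits != 4:
            raise ValueError("the study design fixes n_visits at 4")
        if not self.taxa_panel:
            raise ValueError("taxa_panel must be non-empty")
        total = sum(self.cst_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cst_frequencies must sum to 1 (got {total!r})")
        missing_regimes = set(self.cst_frequencies) - set(self.regime_baselines.index)
        if missing_regimes:
            raise ValueError(f"regimes without baselines: {sorted(missing_regimes)}")
        if not 0.0 <= self.icc_target < 1.0:
            raise ValueError("icc_target must lie in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        panel = set(self.taxa_panel)
        for taxon, _ in self.visit_effects:
            if taxon not in panel:
                raise ValueError(f"visit_effects taxon not in panel: {taxon}")
        for hormone, taxon, _ in self.hormone_effects:
            if hormone not in self.hormone_profiles:
                raise ValueError(f"unknown hormone in hormone_effects: {hormone}")
            if taxon not in panel:
                raise ValueError(f"hormone_effects taxon not in panel: {taxon}")

    @property
    def sigma_b(self) -> float:
        return float(np.sqrt(self.icc_target * self.latent_total_var))

    @property
    def sigma_e(self) -> float:
        return float(np.sqrt((1.0 - self.icc_target) * self.latent_total_var))


def study_effects() -> tuple[list[tuple[str, float]], list[tuple[str, str, float]]]:
    """Injected effects qualitatively mirroring the emulated study.

    Visit trends in the non-*crispatus* lactobacilli, streptococci and
    *Dialister*; negative hormone-taxa couplings concentrated on 17-beta
    estradiol and LH for anaerobe taxa, plus a single prolactin coupling
    with *Bifidobacterium vaginale*.  All couplings use one common
    magnitude (1.0 latent-log unit per within-woman hormone SD,
    i.e. about one latent-total-SD -- large enough that the pattern is
    detectable at the FDR threshold the study design applies); the
    pattern, not the per-pair strength, is what the study design fixes.
    Returns ``(visit_effects, hormone_effects)``.
    """
    visit_effects = [
        ("Lactobacillus iners", -0.20),
        ("Lactobacillus gasseri", 0.25),
        ("Lactobacillus jensenii", 0.20),
        ("Streptococcus agalactiae", 0.25),
        ("Streptococcus unclassified", 0.25),
        ("Dialister micraerophilus", 0.15),
    ]
    hormone_effects = [
        ("BES17", "Prevotella timonensis_A", -1.0),
        ("BES17", "Prevotella bivia", -1.0),
        ("BES17", "Finegoldia magna", -1.0),
        ("BES17", "Anaerococcus tetradius", -1.0),
        ("BES17", "Corynebacterium amycolatum", -1.0),
        ("LH", "Prevotella timonensis_A", -1.0),
        ("LH", "Finegoldia magna", -1.0),
        ("LH", "Anaerococcus tetradius", -1.0),
        ("PRL", "Bifidobacterium vaginale", -1.0),
    ]
    return visit_effects, hormone_effects


def null_config(**overrides) -> CohortConfig:
    """Config under which samples are exchangeable across women and visits.

    A single compositional regime, icc_target=0 and no injected effects:
    the latent field is iid noise, so any within-woman vs between-woman
    contrast is null by construction.  Used for type-I-error calibration.
    """
    defaults = dict(
        cst_frequencies={"CST-III": 1.0},
        icc_target=0.0,
        visit_effects=[],
        hormone_effects=[],
        missing_rate=0.0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@dataclass
class GroundTruth:
    """Exact record of the random quantities used in generation."""

    regimes: dict[str, str]
    woman_intercepts: pd.DataFrame  # woman x taxon latent intercepts
    visit_effects: list[tuple[str, float]]
    hormone_effects: list[tuple[str, str, float]]
    true_icc: dict[str, float]
    library_sizes: dict[str, int]

    def to_json(self, path) -> None:
        payload = {
            "regimes": self.regimes,
            "woman_intercepts": {
                w: self.woman_intercepts.loc[w].to_dict() for w in self.woman_intercepts.index
            },
            "visit_effects": [list(t) for t in self.visit_effects],
            "hormone_effects": [list(t) for t in self.hormone_effects],
            "true_icc": self.true_icc,
            "library_sizes": self.library_sizes,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        wi = pd.DataFrame.from_dict(payload["woman_intercepts"], orient="index").sort_index()
        return cls(
            regimes=payload["regimes"],
            woman_intercepts=wi,
            visit_effects=[tuple(t) for t in payload["visit_effects"]],
            hormone_effects=[tuple(t) for t in payload["hormone_effects"]],
            true_icc=payload["true_icc"],
            library_sizes={k: int(v) for k, v in payload["library_sizes"].items()},
        )


def _woman_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"W{i + 1:0{width}d}" for i in range(n)]


def generate_cohort(config: CohortConfig):
    """Draw one synthetic cohort.

    Returns
    -------
    counts : DataFrame (samples x taxa, int)
    hormones : DataFrame (samples x 5 hormones)
    metadata : DataFrame (samples x covariates)
    truth : GroundTruth
    """
    config.validate()
    seed = config.seed
    women = _woman_ids(config.n_women)
    taxa = list(config.taxa_panel)
    n_taxa = len(taxa)

    rng_regime = substream(seed, "regimes")
    labels = list(config.cst_frequencies)
    probs = np.array([config.cst_frequencies[k] for k in labels])
    regimes = {w: labels[i] for w, i in zip(women, rng_regime.choice(len(labels), size=len(women), p=probs))}

    rng_intercept = substream(seed, "woman_intercepts")
    intercepts = pd.DataFrame(
        rng_intercept.normal(0.0, config.sigma_b, size=(len(women), n_taxa)),
        index=women,
        columns=taxa,
    )

    # visit retention: visit 1 always kept
    rng_miss = substream(seed, "missingness")
    rows: list[tuple[str, int]] = []
    for w in women:
        rows.append((w, 1))
        for v in range(2, config.n_visits + 1):
            if rng_miss.random() >= config.missing_rate:
                rows.append((w, v))
    sample_ids = [f"{w}_{v}" for w, v in rows]

    # hormones: lognormal around the visit-profile mean with a woman-level
    # intercept; the -(sb^2+sw^2)/2 term makes E[level] equal the profile
    rng_h = substream(seed, "hormones")
    h_intercept = {
        h: dict(zip(women, rng_h.normal(0.0, prof["between_sd"], size=len(women))))
        for h, prof in config.hormone_profiles.items()
    }
    h_noise = {
        h: rng_h.normal(0.0, prof["within_sd"], size=len(rows))
        for h, prof in config.hormone_profiles.items()
    }
    hormone_data = {}
    for h, prof in config.hormone_profiles.items():
        means = np.array(prof["visit_means"])
        sb2 = prof["between_sd"] ** 2
        sw2 = prof["within_sd"] ** 2
        log_dev = np.array(
            [h_intercept[h][w] for (w, _) in rows]
        ) + h_noise[h] - (sb2 + sw2) / 2.0
        hormone_data[h] = np.array([means[v - 1] for (_, v) in rows]) * np.exp(log_dev)
    hormones = pd.DataFrame(hormone_data, index=sample_ids)
    hormones = hormones[[h for h in HORMONES if h in hormones.columns]]
    hormones.index.name = "sample_id"

    # latent log-abundances
    rng_eps = substream(seed, "latent_noise")
    latent = np.empty((len(rows), n_taxa))
    base = config.regime_baselines
    for i, (w, v) in enumerate(rows):
        latent[i] = base.loc[regimes[w], taxa].to_numpy() + intercepts.loc[w].to_numpy()
    latent += rng_eps.normal(0.0, config.sigma_e, size=latent.shape)
    visits = np.array([v for _, v in rows])
    taxon_pos = {t: j for j, t in enumerate(taxa)}
    for taxon, slope in config.visit_effects:
        latent[:, taxon_pos[taxon]] += slope * visits
    for hormone, taxon, coupling in config.hormone_effects:
        z = h_noise[hormone] / config.hormone_profiles[hormone]["within_sd"]
        latent[:, taxon_pos[taxon]] += coupling * z

    # composition and counts
    comp = np.exp(latent - latent.max(axis=1, keepdims=True))
    comp /= comp.sum(axis=1, keepdims=True)
    rng_lib = substream(seed, "library_sizes")
    s = np.sqrt(np.log1p(config.library_size_cv**2))
    mu = np.log(config.library_size_mean) - s**2 / 2.0
    libs = np.maximum(np.round(np.exp(rng_lib.normal(mu, s, size=len(rows)))), 1).astype(np.int64)
    rng_counts = substream(seed, "counts")
    counts = np.vstack([rng_counts.multinomial(int(n), p) for n, p in zip(libs, comp)])
    counts = pd.DataFrame(counts, index=sample_ids, columns=taxa)
    counts.index.name = "sample_id"

    metadata = _generate_metadata(config, rows, sample_ids, libs)
    truth = GroundTruth(
        regimes=regimes,
        woman_intercepts=intercepts,
        visit_effects=list(config.visit_effects),
        hormone_effects=list(config.hormone_effects),
        true_icc={t: config.icc_target for t in taxa},
        library_sizes=dict(zip(sample_ids, (int(x) for x in libs))),
    )
    return counts, hormones, metadata, truth


def _generate_metadata(config, rows, sample_ids, libs) -> pd.DataFrame:
    """Technical + host covariates; woman-level fields repeat across visits."""
    seed = config.seed
    women = sorted({w for w, _ in rows})
    rng = substream(seed, "metadata")
    woman_level = pd.DataFrame(
        {
            "Age": rng.integers(18, 46, size=len(women)),
            "Pregnancy_category": rng.choice(["never", "ever"], size=len(women), p=[0.65, 0.35]),
            "Pill_use": rng.choice(["never", "past"], size=len(women), p=[0.6, 0.4]),
            "WHR_ranges": rng.choice(["low", "mid", "high"], size=len(women)),
            "smoking": rng.choice(["no", "yes"], size=len(women), p=[0.75, 0.25]),
        },
        index=women,
    )
    n = len(rows)
    qubit_dna = np.exp(rng.normal(np.log(10.0), 0.5, size=n))
    qubit_lib = np.exp(rng.normal(np.log(20.0), 0.4, size=n))
    meta = pd.DataFrame(
        {
            "woman": [w for w, _ in rows],
            "visit_number": [v for _, v in rows],
            "Qubit_DNA": qubit_dna,
            "Qubit_Library": qubit_lib,
            "Total_counts": libs,
            "sex_less_than_two_days": rng.choice(["no", "yes"], size=n, p=[0.7, 0.3]),
            "Swab_after_feces": rng.choice(["no", "yes"], size=n, p=[0.8, 0.2]),
            "Bristol_stool_scale": rng.integers(2, 6, size=n),
            "Swab_morning_or_not": rng.choice(["no", "yes"], size=n),
        },
        index=sample_ids,
    )
    for col in woman_level.columns:
        meta[col] = woman_level.loc[meta["woman"], col].to_numpy()
    meta["phase"] = meta["visit_number"].map(PHASES)
    meta.index.name = "sample_id"
    return meta


def generate_centroids(config: CohortConfig) -> pd.DataFrame:
    """Reference composition per CST regime (softmax of the regime baselines).

    Rows sum to 1; serves as a synthetic centroid table for the
    nearest-centroid CST classifier.
    """
    if not config.taxa_panel:
        raise ValueError("taxa_panel must be non-empty")
    base = config.regime_baselines.loc[list(config.cst_frequencies), config.taxa_panel]
    comp = np.exp(base.to_numpy())
    comp /= comp.sum(axis=1, keepdims=True)
    out = pd.DataFrame(comp, index=base.index, columns=base.columns)
    out.index.name = "CST"
    return out


def generate_read_stats(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Synthetic sequencing read statistics for the full (woman, visit) grid.

    Per-sample input and post-trimming read counts plus one negative
    control per batch, constructed to span both sides of the QC thresholds
    (80k input / 60k survived / 500-read negative control): the first grid
    sample is forced below the input floor, the second below the survived
    floor, and the last batch's negative control above the contamination
    cutoff.
    """
    seed = config.seed if seed is None else seed
    rng = substream(seed, "read_stats")
    women = _woman_ids(config.n_women)
    sample_ids = [f"{w}_{v}" for w in women for v in range(1, config.n_visits + 1)]
    n = len(sample_ids)
    inputs = np.exp(rng.normal(np.log(160_000.0), 0.25, size=n))
    survived = inputs * rng.uniform(0.85, 0.98, size=n)
    inputs = inputs.astype(np.int64)
    survived = survived.astype(np.int64)
    # force boundary cases on both sides of the thresholds
    inputs[0], survived[0] = 75_000, 58_000
    if n > 1:
        inputs[1], survived[1] = 85_000, 55_000
    # Batches B1/B2 hold the cohort with clean controls; B3 is a small
    # separate plate whose negative control shows contamination, so the
    # batch-level rule fires without gutting the cohort.
    batches = np.array([i % 2 + 1 for i in range(n)])
    n_contam = min(4, n)
    batches[-n_contam:] = 3
    stats = pd.DataFrame(
        {
            "input_reads": inputs,
            "survived_reads": survived,
            "batch": [f"B{b}" for b in batches],
            "is_negative_control": False,
        },
        index=sample_ids,
    )
    neg_inputs = [int(rng.integers(10, 200)), int(rng.integers(10, 200)), 620]
    neg = pd.DataFrame(
        {
            "input_reads": neg_inputs,
            "survived_reads": neg_inputs,
            "batch": ["B1", "B2", "B3"],
            "is_negative_control": True,
        },
        index=["NEG_B1", "NEG_B2", "NEG_B3"],
    )
    out = pd.concat([stats, neg])
    out.index.name = "sample_id"
    return out
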