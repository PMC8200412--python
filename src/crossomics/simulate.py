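"""Synthetic crossover-trial generator with ground-truth bookkeeping.

Generates datasets carrying the statistical structure the analysis
assumes, so every pipeline stage can be exercised and power/calibration
can be measured against a known truth:

* two-arm two-period crossover with stratified block randomisation;
* compositional taxa profiles: per-subject log-normal latent signatures
  (between-subject sd ``subject_signature_sd``) plus within-subject
  log-scale noise, closed to sum 1;
* log-normal metabolite peak areas with a single global detection limit —
  values below the ``detection_limit_quantile`` quantile of all generated
  values are recorded as missing (not detected);
* planted multiplicative treatment effects on chosen features, applied at
  half strength (on the log scale) at T2 and full strength at T3; a
  baseline-dependent effect shrinks with the subject's latent baseline
  level, scaling the log-multiplier by ``1 / (1 + baseline/median)``;
* outcomes: weekly defecation frequency with a placebo drift applied in
  BOTH periods (the regime where a naive before/after contrast within
  either period looks significant but the between-period contrast does
  not), and a blood-folate response at T3 proportional to the subject's
  baseline defecation frequency (``outcome_coupling``).

One master seed feeds independent named substreams (arms, subjects, taxa,
metabolites, outcomes), so adding a component never perturbs another's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataInvariantError
from .trial import FeatureMatrix, SubjectRecord, Timepoint, TrialDataset

__all__ = [
    "PlantedEffect",
    "GeneratorConfig",
    "SyntheticTruth",
    "randomise_arms",
    "generate_trial",
    "plant_baseline_dependent_scfa",
    "plant_metabolite_effects",
    "worked_fixture",
]

_STREAMS = {"arms": 0, "subjects": 1, "taxa": 2, "metabolites": 3, "outcomes": 4}

TIMEPOINTS = [t.value for t in Timepoint]


@dataclass(frozen=True)
class PlantedEffect:
    """A multiplicative treatment effect planted on one feature.

    ``abundance_log_offset`` shifts the feature's latent level (log scale),
    emulating an abundant analyte (e.g. a major SCFA) that sits above the
    detection limit in every sample; it rescales the feature without
    affecting the baseline-dependence factor, which is scale-invariant.
    """

    layer: str  # "taxa" | "metabolites"
    feature: str
    multiplier: float
    baseline_dependent: bool = False
    abundance_log_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise DataInvariantError("effect multiplier must be > 0")


@dataclass
class GeneratorConfig:
    """Trial-generator parameters; defaults mirror the emulated study.

    20 subjects with omics data, ~150 taxa, ~200 metabolites, between-
    subject log-scale signature sd 1.0 against within-subject noise sd 0.3
    (inter-individual variation dominating the intervention), a placebo
    drift of 1 stool/week appearing in both periods, and a 15% global
    detection-limit censoring rate for metabolites.
    """

    n_subjects: int = 20
    n_taxa: int = 150
    n_metabolites: int = 200
    subject_signature_sd: float = 1.0
    noise_sd: float = 0.3
    placebo_drift: float = 1.0
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    detection_limit_quantile: float = 0.15
    outcome_coupling: float = 2.0  # ng/ml folate at T3 per stool/week baseline
    block_size: int = 4
    # outcome scales (weekly defecation frequency, blood folate ng/ml)
    defecation_mean: float = 4.0
    defecation_between_sd: float = 1.2
    defecation_noise_sd: float = 0.7
    folate_mean: float = 9.0
    folate_between_sd: float = 3.0
    folate_noise_sd: float = 0.8
    # Optional shared rank-abundance structure (a feature-level base profile
    # common to all subjects).  Off by default: the emulated null has all
    # between-subject structure in the per-subject signatures, which keeps
    # samples exchangeable at the whole-profile level when the signature sd
    # is zero.  A shared base makes the inter/intra distance comparison
    # anticonservative (see docs), as on real tables.
    taxa_base_sd: float = 0.0
    metabolite_base_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subject_signature_sd < 0 or self.noise_sd <= 0:
            raise DataInvariantError("signature sd must be >= 0 and noise sd > 0")
        if not (0 <= self.detection_limit_quantile < 0.5):
            raise DataInvariantError("detection_limit_quantile must be in [0, 0.5)")
        if self.block_size % 2:
            raise DataInvariantError("block_size must be even")
        if self.n_subjects < 4:
            raise DataInvariantError("need >= 4 subjects")


@dataclass
class SyntheticTruth:
    """Planted-effect bookkeeping for recovery testing."""

    arms: dict[str, str]
    planted: list[dict]  # effect fields + per-subject latent baseline / log-multiplier
    detection_limit: float
    defecation_latent: dict[str, float]
    folate_latent: dict[str, float]

    def planted_features(self, layer: str) -> list[str]:
        return [p["feature"] for p in self.planted if p["layer"] == layer]


def _rng(cfg_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed) % (2**31), _STREAMS[name]])


def randomise_arms(
    subject_ids: list[str],
    strata: dict[str, str] | None = None,
    block_size: int = 4,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Stratified block randomisation of period order (CT vs TC).

    Within each stratum subjects are assigned in blocks of ``block_size``
    containing equal numbers of CT and TC in random order, so the
    within-stratum imbalance never exceeds ``block_size / 2``.
    """
    if block_size % 2:
        raise DataInvariantError("block_size must be even")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strata = strata or {}
    groups: dict[str, list[str]] = {}
    for sid in subject_ids:
        groups.setdefault(strata.get(sid, ""), []).append(sid)
    assignment: dict[str, str] = {}
    for key in sorted(groups):
        members = groups[key]
        for start in range(0, len(members), block_size):
            block = members[start : start + block_size]
            # remainder blocks use a balanced block of their own (even) size,
            # so even-sized strata always balance exactly
            half = (len(block) + 1) // 2
            pattern = ["CT"] * half + ["TC"] * half
            order = rng.permutation(len(pattern))
            for sid, k in zip(block, order):
                assignment[sid] = pattern[k]
    return assignment


def plant_baseline_dependent_scfa(
    feature: str = "met_001",
    multiplier: float = 4.0,
    abundance_log_offset: float = 2.0,
) -> PlantedEffect:
    """The abundant-SCFA scenario: a baseline-dependent response on one
    always-detected metabolite.

    The multiplier is set so the induced score-vs-baseline Spearman
    correlation has the magnitude reported for faecal propionate in the
    emulated trial (about -0.59 at n = 20); the abundance offset keeps the
    feature above the detection limit in every sample, as an abundant SCFA
    is.
    """
    return PlantedEffect(
        "metabolites", feature, multiplier, baseline_dependent=True,
        abundance_log_offset=abundance_log_offset,
    )


def plant_metabolite_effects(
    n: int = 5,
    multiplier: float = 2.0,
    baseline_dependent: bool = False,
    start: int = 0,
) -> list[PlantedEffect]:
    """Convenience: plant ``n`` effects on consecutive metabolite features."""
    return [
        PlantedEffect("metabolites", f"met_{i + 1:03d}", multiplier, baseline_dependent)
        for i in range(start, start + n)
    ]


def _effect_log_matrix(
    cfg: GeneratorConfig,
    layer: str,
    feature_ids: list[str],
    latent: np.ndarray,  # subjects x features latent log level (base + signature)
    truth_rows: list[dict],
) -> np.ndarray:
    """Per-(subject, feature) full-strength log effect; 0 where unplanted."""
    n_sub, n_feat = latent.shape
    eff = np.zeros((n_sub, n_feat))
    index = {f: j for j, f in enumerate(feature_ids)}
    for pe in cfg.planted_effects:
        if pe.layer != layer:
            continue
        if pe.feature not in index:
            raise DataInvariantError(f"planted feature {pe.feature!r} not in {layer}")
        j = index[pe.feature]
        latent[:, j] += pe.abundance_log_offset
        base = np.exp(latent[:, j])
        log_mult = np.log(pe.multiplier)
        if pe.baseline_dependent:
            scale = 1.0 / (1.0 + base / np.median(base))
        else:
            scale = np.ones(n_sub)
        eff[:, j] = log_mult * scale
        truth_rows.append(
            {
                "layer": layer,
                "feature": pe.feature,
                "multiplier": pe.multiplier,
                "baseline_dependent": pe.baseline_dependent,
                "latent_baseline": base.tolist(),
                "log_multiplier_per_subject": (log_mult * scale).tolist(),
            }
        )
    return eff


def _omics_layer(
    cfg: GeneratorConfig,
    layer: str,
    rng: np.random.Generator,
    subject_ids: list[str],
    truth_rows: list[dict],
) -> tuple[pd.DataFrame, np.ndarray]:
    """Raw (uncensored, unclosed) value table for one omics layer.

    Returns (samples x features DataFrame of positive values, latent
    subject-by-feature log levels).  Sample ids are ``<subject>_<tp>``.
    """
    if layer == "taxa":
        n_feat, base_sd, prefix = cfg.n_taxa, cfg.taxa_base_sd, "taxon"
    else:
        n_feat, base_sd, prefix = cfg.n_metabolites, cfg.metabolite_base_sd, "met"
    feature_ids = [f"{prefix}_{j + 1:03d}" for j in range(n_feat)]
    n_sub = len(subject_ids)

    base = rng.normal(0.0, base_sd, size=n_feat)
    signature = rng.normal(0.0, cfg.subject_signature_sd, size=(n_sub, n_feat))
    latent = base[None, :] + signature
    eff = _effect_log_matrix(cfg, layer, feature_ids, latent, truth_rows)

    # effect ramp: none at baseline/week control samples, half at T2, full at T3
    ramp = {"C1": 0.0, "C2": 0.0, "C3": 0.0, "T1": 0.0, "T2": 0.5, "T3": 1.0}
    rows, ids = [], []
    for i, sid in enumerate(subject_ids):
        for tp in TIMEPOINTS:
            noise = rng.normal(0.0, cfg.noise_sd, size=n_feat)
            rows.append(np.exp(latent[i] + ramp[tp] * eff[i] + noise))
            ids.append(f"{sid}_{tp}")
    return pd.DataFrame(np.vstack(rows), index=ids, columns=feature_ids), latent


def generate_trial(cfg: GeneratorConfig) -> tuple[TrialDataset, SyntheticTruth]:
    """Generate one complete synthetic trial plus its ground truth."""
    subject_ids = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]

    # subject latent outcomes (needed before randomisation: strata use them)
    rng_sub = _rng(cfg.seed, "subjects")
    ages = rng_sub.integers(20, 61, size=cfg.n_subjects)
    defec_latent = np.clip(
        rng_sub.normal(cfg.defecation_mean, cfg.defecation_between_sd, cfg.n_subjects),
        1.0,
        None,
    )
    folate_latent = np.clip(
        rng_sub.normal(cfg.folate_mean, cfg.folate_between_sd, cfg.n_subjects),
        0.5,
        None,
    )
    strata = {
        sid: f"age{'<40' if a < 40 else '40+'}|defec{'low' if d < cfg.defecation_mean else 'high'}"
        for sid, a, d in zip(subject_ids, ages, defec_latent)
    }

    arms = randomise_arms(
        subject_ids, strata, block_size=cfg.block_size, seed=_rng(cfg.seed, "arms")
    )
    subjects = [SubjectRecord(s, arms[s], strata[s]) for s in subject_ids]

    truth_rows: list[dict] = []
    taxa_raw, _ = _omics_layer(cfg, "taxa", _rng(cfg.seed, "taxa"), subject_ids, truth_rows)
    taxa = taxa_raw.div(taxa_raw.sum(axis=1), axis=0)

    met_raw, _ = _omics_layer(
        cfg, "metabolites", _rng(cfg.seed, "metabolites"), subject_ids, truth_rows
    )
    detection_limit = float(np.quantile(met_raw.to_numpy(), cfg.detection_limit_quantile))
    met = met_raw.mask(met_raw < detection_limit)

    metadata = pd.DataFrame(
        {
            "sample_id": taxa.index,
            "subject_id": [s.split("_")[0] for s in taxa.index],
            "timepoint": [s.split("_")[1] for s in taxa.index],
        }
    )

    # outcomes: defecation frequency at timepoints 1 and 3 of each period,
    # blood folate at all six draws
    rng_out = _rng(cfg.seed, "outcomes")
    drift = {"1": 0.0, "3": cfg.placebo_drift}
    records = []
    for i, sid in enumerate(subject_ids):
        for tp in ("C1", "C3", "T1", "T3"):
            val = defec_latent[i] + drift[tp[1]] + rng_out.normal(0, cfg.defecation_noise_sd)
            records.append((sid, tp, "defecation_frequency", max(0.0, round(val))))
        for tp in TIMEPOINTS:
            val = folate_latent[i] + rng_out.normal(0, cfg.folate_noise_sd)
            if tp == "T3":
                val += cfg.outcome_coupling * defec_latent[i]
            elif tp == "T2":
                val += 0.5 * cfg.outcome_coupling * defec_latent[i]
            records.append((sid, tp, "blood_folate", max(0.0, val)))
    outcomes = pd.DataFrame(records, columns=["subject_id", "timepoint", "outcome", "value"])

    ds = TrialDataset(
        subjects,
        metadata,
        layers={
            "taxa": FeatureMatrix(taxa, "taxa", "relative abundance"),
            "metabolites": FeatureMatrix(met, "metabolite", "relative peak area"),
        },
        outcomes=outcomes,
    )
    truth = SyntheticTruth(
        arms=arms,
        planted=truth_rows,
        detection_limit=detection_limit,
        defecation_latent=dict(zip(subject_ids, defec_latent.tolist())),
        folate_latent=dict(zip(subject_ids, folate_latent.tolist())),
    )
    return ds, truth


def worked_fixture() -> TrialDataset:
    """A tiny fixed 6-subject trial with hand-computable statistics.

    Defecation quadruples give tie-free period-change differences (so the
    signed-rank test takes the exact path) and simple responder scores —
    subject S1 has (C1=2, C3=3, T1=2, T3=5), hence score 1.0.  The taxa
    layer gives each subject a constant-in-time, subject-specific ranking
    (intra distances 0, inter > 0); the metabolite layer carries one
    non-detection and one mostly-undetected feature for the filters.
    """
    subject_ids = [f"S{i}" for i in range(1, 7)]
    subjects = [
        SubjectRecord(s, "CT" if i % 2 == 0 else "TC")
        for i, s in enumerate(subject_ids)
    ]
    quads = {  # subject: (C1, C3, T1, T3)
        "S1": (2.0, 3.0, 2.0, 5.0),
        "S2": (3.0, 4.0, 3.0, 5.5),
        "S3": (4.0, 4.0, 4.0, 5.0),
        "S4": (5.0, 4.5, 5.0, 7.0),
        "S5": (3.0, 3.5, 3.0, 3.0),
        "S6": (4.0, 5.0, 2.0, 4.75),
    }
    records = [
        (s, tp, "defecation_frequency", v)
        for s, (c1, c3, t1, t3) in quads.items()
        for tp, v in zip(("C1", "C3", "T1", "T3"), (c1, c3, t1, t3))
    ]
    outcomes = pd.DataFrame(records, columns=["subject_id", "timepoint", "outcome", "value"])

    tps = ("C1", "C3", "T1", "T3")
    sample_ids = [f"{s}_{tp}" for s in subject_ids for tp in tps]
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [s.split("_")[0] for s in sample_ids],
            "timepoint": [s.split("_")[1] for s in sample_ids],
        }
    )

    base = np.array([0.40, 0.25, 0.15, 0.12, 0.08])
    taxa_rows = {
        f"{s}_{tp}": np.roll(base, i)
        for i, s in enumerate(subject_ids)
        for tp in tps
    }
    taxa = pd.DataFrame.from_dict(taxa_rows, orient="index")
    taxa.columns = [f"taxon_{j + 1}" for j in range(5)]
    taxa = taxa.loc[sample_ids]

    met = pd.DataFrame(
        index=sample_ids, columns=["met_1", "met_2", "met_3"], dtype=float
    )
    for k, sid in enumerate(sample_ids):
        met.loc[sid, "met_1"] = 1.0 + 0.1 * k
        met.loc[sid, "met_2"] = 0.5 + 0.05 * (k % 4)
    met.loc["S2_C1", "met_2"] = np.nan
    # met_3 detected in only 4 of 24 samples (censored elsewhere)
    met["met_3"] = np.nan
    for sid in ("S1_C1", "S1_T3", "S4_C3", "S6_T1"):
        met.loc[sid, "met_3"] = 2.0

    return TrialDataset(
        subjects,
        metadata,
        layers={
            "taxa": FeatureMatrix(taxa, "taxa", "relative abundance"),
            "metabolites": FeatureMatrix(met, "metabolite", "relative peak area"),
        },
        outcomes=outcomes,
    )
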