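"""Dual-criterion per-feature differential screen.

Each surviving feature is tested twice with the Wilcoxon signed-rank test:

* within the test period — T1 vs T3 paired per subject ("did the feature
  change under the test supplement?"), and
* between periods — the per-subject change T3-T1 against C3-C1 ("did it
  change more than under the control supplement?").

A feature is a *candidate* when both raw p-values fall below alpha, and
*confirmed* when additionally at least one of its Benjamini-Hochberg
q-values (computed per omics layer, separately for each test family) falls
below q*.  Requiring both tests guards against placebo-period drift being
mistaken for a treatment effect.

Pre-filters mirror standard practice for these tables: taxa with mean
relative abundance below 0.001 are excluded; metabolites undetected in at
least 75% of samples are excluded, and remaining non-detections of the
survivors are set to 0 (below detection limit) for the rank tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .errors import StatisticalPreconditionError
from .trial import FeatureMatrix, TrialDataset

__all__ = [
    "ScreenResult",
    "ScreenReport",
    "FilterLog",
    "filter_taxa",
    "filter_metabolites",
    "dual_screen",
    "annotate",
]


@dataclass(frozen=True)
class ScreenResult:
    feature_id: str
    layer: str
    p_within: float   # T1 vs T3
    p_between: float  # (T3 - T1) vs (C3 - C1)
    q_within: float
    q_between: float
    direction: int    # sign of median(T3 - T1)
    n_within: int
    n_between: int
    candidate: bool
    confirmed: bool


@dataclass
class FilterLog:
    kept: list[str]
    dropped: list[str]
    n_imputed: int = 0  # non-detections set to 0 among kept features


@dataclass
class ScreenReport:
    layer: str
    alpha: float
    q_star: float
    results: list[ScreenResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def candidates(self) -> list[str]:
        return [r.feature_id for r in self.results if r.candidate]

    @property
    def confirmed(self) -> list[str]:
        return [r.feature_id for r in self.results if r.confirmed]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.results])
        if len(df):
            with np.errstate(divide="ignore"):
                df["neg_log10_p_within"] = -np.log10(df["p_within"])
                df["neg_log10_p_between"] = -np.log10(df["p_between"])
            df = df.sort_values("p_between", kind="mergesort").reset_index(drop=True)
        return df

    def summary(self) -> dict:
        return {
            "layer": self.layer,
            "alpha": self.alpha,
            "q_star": self.q_star,
            "n_tested": len(self.results),
            "n_skipped": len(self.skipped),
            "n_candidate": len(self.candidates),
            "n_confirmed": len(self.confirmed),
        }


def filter_taxa(
    m: FeatureMatrix, threshold: float = 0.001
) -> tuple[FeatureMatrix, FilterLog]:
    """Keep taxa whose mean relative abundance is at least ``threshold``.

    The mean runs over all retained samples with missing treated as 0.
    The boundary is inclusive: a mean of exactly ``threshold`` is kept.
    """
    means = m.values.fillna(0.0).mean(axis=0)
    keep = means[means >= threshold].index.tolist()
    drop = [f for f in m.feature_ids if f not in set(keep)]
    out = FeatureMatrix(
        m.values[keep], layer=m.layer, unit_note=m.unit_note, check_closure=False
    )
    return out, FilterLog(kept=keep, dropped=drop)


def filter_metabolites(
    m: FeatureMatrix,
    max_missing_fraction: float = 0.75,
    rule: str = "exclude_if_undetected",
) -> tuple[FeatureMatrix, FilterLog]:
    """Detection filter for metabolite tables, then zero-fill survivors.

    Default rule drops a metabolite when its non-detected fraction is
    >= ``max_missing_fraction`` (i.e. it must be detected in more than 25%
    of samples).  The stricter alternative reading,
    ``rule="require_detected"``, keeps only metabolites detected in at
    least ``max_missing_fraction`` of samples.  Remaining non-detections of
    survivors are replaced by 0 (below detection limit) and counted.
    """
    miss = m.values.isna().mean(axis=0)
    if rule == "exclude_if_undetected":
        keep = miss[miss < max_missing_fraction].index.tolist()
    elif rule == "require_detected":
        keep = miss[(1.0 - miss) >= max_missing_fraction].index.tolist()
    else:
        raise ValueError(f"unknown rule {rule!r}")
    drop = [f for f in m.feature_ids if f not in set(keep)]
    kept_vals = m.values[keep]
    n_imputed = int(kept_vals.isna().to_numpy().sum())
    out = FeatureMatrix(kept_vals.fillna(0.0), layer=m.layer, unit_note=m.unit_note)
    return out, FilterLog(kept=keep, dropped=drop, n_imputed=n_imputed)


def dual_screen(
    ds: TrialDataset,
    layer: str,
    alpha: float = 0.05,
    q_star: float = 0.10,
) -> ScreenReport:
    """Run the dual signed-rank screen over every feature of ``layer``.

    Assumes filters have already been applied to the layer.  Features with
    too few usable pairs (or no nonzero differences) are skipped with a
    recorded reason rather than silently dropped.  q-values are BH-adjusted
    over all *tested* features of the layer, separately for the within and
    between families.
    """
    fm = ds.layers[layer]
    wide = ds.layer_wide(layer)
    rows: list[dict] = []
    skipped: list[tuple[str, str]] = []
    for feature in fm.feature_ids:
        sub = wide[feature]
        within = sub[["T1", "T3"]].dropna()
        quads = sub[["C1", "C3", "T1", "T3"]].dropna()
        if len(within) < 3 or len(quads) < 3:
            skipped.append((feature, "fewer than 3 complete pairs"))
            continue
        try:
            within_diffs = (within["T3"] - within["T1"]).to_numpy()
            r_within = stats.wilcoxon_signed_rank(within_diffs)
            # between test: is the T-period change different from the
            # C-period change? differences are (C3-C1) - (T3-T1)
            between_diffs = (
                (quads["C3"] - quads["C1"]) - (quads["T3"] - quads["T1"])
            ).to_numpy()
            r_between = stats.wilcoxon_signed_rank(between_diffs)
        except StatisticalPreconditionError as exc:
            skipped.append((feature, str(exc)))
            continue
        rows.append(
            {
                "feature_id": feature,
                "p_within": r_within.p_value,
                "p_between": r_between.p_value,
                "direction": int(np.sign(np.median(within_diffs))),
                "n_within": r_within.n_effective,
                "n_between": r_between.n_effective,
            }
        )
    results: list[ScreenResult] = []
    if rows:
        q_within = stats.bh_fdr([r["p_within"] for r in rows])
        q_between = stats.bh_fdr([r["p_between"] for r in rows])
        for r, qw, qb in zip(rows, q_within, q_between):
            candidate = r["p_within"] < alpha and r["p_between"] < alpha
            confirmed = candidate and min(qw, qb) < q_star
            results.append(
                ScreenResult(
                    feature_id=r["feature_id"],
                    layer=layer,
                    p_within=r["p_within"],
                    p_between=r["p_between"],
                    q_within=float(qw),
                    q_between=float(qb),
                    direction=r["direction"],
                    n_within=r["n_within"],
                    n_between=r["n_between"],
                    candidate=candidate,
                    confirmed=confirmed,
                )
            )
    return ScreenReport(layer=layer, alpha=alpha, q_star=q_star, results=results, skipped=skipped)


def annotate(report_frame: pd.DataFrame, annotation: pd.DataFrame | None) -> pd.DataFrame:
    """Left-join a feature annotation table (e.g. compound class hierarchy).

    ``annotation`` must carry a ``feature_id`` column; unmatched features
    get "N.A." in every annotation column.  ``None`` or an empty table
    yields all "N.A."-free passthrough (no columns added for None, all
    "N.A." for an empty table with declared columns).
    """
    if annotation is None:
        return report_frame.copy()
    ann = annotation.copy()
    if "feature_id" not in ann.columns:
        raise ValueError("annotation table needs a 'feature_id' column")
    merged = report_frame.merge(ann, on="feature_id", how="left")
    extra = [c for c in ann.columns if c != "feature_id"]
    merged[extra] = merged[extra].fillna("N.A.")
    return merged
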