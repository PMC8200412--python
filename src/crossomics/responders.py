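"""Responder scores and their baseline-dependence screen.

The responder score quantifies, per subject, how much more a measure
changed during the test period than during the control period, relative to
the subject's starting level:

    R = ((T3 - T1) - (C3 - C1)) / Average(C1, T1)

Positive R means the test supplement raised the measure beyond the control
period.  Correlating R against a baseline factor (the same feature's
pre-intervention level, another feature's baseline, or a clinical outcome
at baseline) asks whether the response depends on the subject's starting
gut environment.

Caveat built in as a first-class diagnostic: a change score correlated
against its own noisy baseline is subject to regression to the mean, which
manufactures negative correlation without any real baseline dependence
(most strongly when the baseline is the test-period start T1, which enters
the numerator with a negative sign).  ``rtm_null`` quantifies this by
permuting the period labels (C <-> T) independently per subject — a valid
null because under "no treatment effect" the two periods are exchangeable
while the artifact's machinery is preserved — and locating the observed
correlation within the resulting null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .errors import DataInvariantError, StatisticalPreconditionError
from .trial import TrialDataset

__all__ = [
    "ResponderTable",
    "BaselineCorrelation",
    "RtmNullResult",
    "responder_score",
    "responder_table",
    "baseline_correlation",
    "cross_screen",
    "rtm_null",
]

BASELINE_DEFINITIONS = ("mean_C1_T1", "T1_only", "C1_only")


def responder_score(c1: float, c3: float, t1: float, t3: float) -> float:
    """((T3 - T1) - (C3 - C1)) / Average(C1, T1); scale-invariant."""
    denom = 0.5 * (c1 + t1)
    if denom == 0:
        raise StatisticalPreconditionError("mean(C1, T1) is zero; score undefined")
    return ((t3 - t1) - (c3 - c1)) / denom


@dataclass
class ResponderTable:
    """Per-subject responder scores with aligned baseline values.

    Carries the raw (C1, C3, T1, T3) quadruples so the permutation null can
    recompute scores under period-label swaps.
    """

    subject_ids: list[str]
    scores: np.ndarray
    baselines: np.ndarray
    feature_id: str
    layer: str
    baseline_definition: str
    excluded: list[tuple[str, str]] = field(default_factory=list)
    quads: pd.DataFrame | None = None  # columns C1, C3, T1, T3, index subject

    @property
    def n(self) -> int:
        return len(self.subject_ids)


def _baseline_from_quads(quads: pd.DataFrame, definition: str) -> np.ndarray:
    if definition == "mean_C1_T1":
        return 0.5 * (quads["C1"] + quads["T1"]).to_numpy()
    if definition == "T1_only":
        return quads["T1"].to_numpy()
    if definition == "C1_only":
        return quads["C1"].to_numpy()
    raise ValueError(f"baseline_definition must be one of {BASELINE_DEFINITIONS}")


def responder_table(
    ds: TrialDataset,
    layer: str,
    feature: str,
    baseline_definition: str = "mean_C1_T1",
    subjects: list[str] | None = None,
) -> ResponderTable:
    """Responder scores for one feature or outcome across subjects.

    Subjects missing any of C1, C3, T1, T3, or with mean(C1, T1) = 0, are
    excluded with a recorded reason.  Requires >= 5 valid subjects.
    ``subjects`` restricts the analysis set (e.g. the omics subset).
    """
    if baseline_definition not in BASELINE_DEFINITIONS:
        raise ValueError(f"baseline_definition must be one of {BASELINE_DEFINITIONS}")
    wide = ds.value_table(layer, feature)
    if subjects is not None:
        wide = wide.loc[[s for s in wide.index if s in set(subjects)]]
    quads = wide[["C1", "C3", "T1", "T3"]]
    excluded: list[tuple[str, str]] = []
    complete = quads.dropna()
    for s in quads.index.difference(complete.index):
        excluded.append((s, "missing timepoint"))
    denom = 0.5 * (complete["C1"] + complete["T1"])
    zero = complete.index[denom == 0]
    for s in zero:
        excluded.append((s, "mean(C1, T1) = 0"))
    valid = complete.drop(index=zero)
    if len(valid) < 5:
        raise StatisticalPreconditionError(
            f"{feature!r}: only {len(valid)} subjects with a defined responder score"
        )
    numer = (valid["T3"] - valid["T1"]) - (valid["C3"] - valid["C1"])
    scores = (numer / (0.5 * (valid["C1"] + valid["T1"]))).to_numpy()
    return ResponderTable(
        subject_ids=list(valid.index),
        scores=scores,
        baselines=_baseline_from_quads(valid, baseline_definition),
        feature_id=feature,
        layer=layer,
        baseline_definition=baseline_definition,
        excluded=excluded,
        quads=valid,
    )


@dataclass(frozen=True)
class BaselineCorrelation:
    responder_feature: str
    baseline_feature: str
    rho: float
    p: float
    n: int
    q: float | None = None


def baseline_correlation(rt: ResponderTable) -> BaselineCorrelation:
    """Spearman correlation of responder scores against their own baseline."""
    if rt.n < 5:
        raise StatisticalPreconditionError("need >= 5 subjects for the correlation")
    res = stats.spearman(rt.baselines, rt.scores)
    return BaselineCorrelation(
        responder_feature=f"{rt.layer}:{rt.feature_id}",
        baseline_feature=f"{rt.layer}:{rt.feature_id}@baseline",
        rho=res.rho,
        p=res.p_value,
        n=res.n,
    )


def _factor_baseline(
    ds: TrialDataset, layer: str, feature: str, baseline_definition: str
) -> pd.Series:
    """A factor's per-subject baseline value (missing treated as 0)."""
    wide = ds.value_table(layer, feature)
    quads = wide[["C1", "T1"]].fillna(0.0)
    if baseline_definition == "T1_only":
        return quads["T1"]
    if baseline_definition == "C1_only":
        return quads["C1"]
    return 0.5 * (quads["C1"] + quads["T1"])


def cross_screen(
    ds: TrialDataset,
    responder_targets: list[tuple[str, str]],
    baseline_factors: list[tuple[str, str]],
    baseline_definition: str = "mean_C1_T1",
    subjects: list[str] | None = None,
) -> list[BaselineCorrelation]:
    """Correlate every responder target against every baseline factor.

    Targets and factors are (layer-or-"outcome", feature) pairs.  All
    target x factor Spearman correlations are computed over the subjects
    common to both, BH-FDR is applied over the full list, and results are
    returned sorted by p-value (ties broken by input order).
    """
    raw: list[BaselineCorrelation] = []
    for t_layer, t_feature in responder_targets:
        rt = responder_table(
            ds, t_layer, t_feature, baseline_definition=baseline_definition,
            subjects=subjects,
        )
        score_by_subject = pd.Series(rt.scores, index=rt.subject_ids)
        for f_layer, f_feature in baseline_factors:
            base = _factor_baseline(ds, f_layer, f_feature, baseline_definition)
            common = [s for s in rt.subject_ids if s in base.index and not np.isnan(base[s])]
            if len(common) < 5:
                raise StatisticalPreconditionError(
                    f"factor {f_feature!r}: only {len(common)} subjects overlap"
                )
            res = stats.spearman(base[common].to_numpy(), score_by_subject[common].to_numpy())
            raw.append(
                BaselineCorrelation(
                    responder_feature=f"{t_layer}:{t_feature}",
                    baseline_feature=f"{f_layer}:{f_feature}",
                    rho=res.rho,
                    p=res.p_value,
                    n=res.n,
                )
            )
    if not raw:
        return []
    qs = stats.bh_fdr([r.p for r in raw])
    out = [
        BaselineCorrelation(r.responder_feature, r.baseline_feature, r.rho, r.p, r.n, float(q))
        for r, q in zip(raw, qs)
    ]
    return sorted(out, key=lambda r: r.p)


@dataclass
class RtmNullResult:
    """Permutation null for the score-vs-baseline correlation.

    ``null`` holds the correlation under random per-subject period swaps;
    ``quantile`` is the mid-rank one-sided attained quantile of the
    observed rho within the null; ``p_two_sided`` the add-one two-sided
    permutation p-value.
    """

    observed_rho: float
    null: np.ndarray
    quantile: float
    p_two_sided: float
    n_permutations: int
    seed: int

    def inside_central(self, level: float = 0.95) -> bool:
        lo = np.quantile(self.null, (1 - level) / 2)
        hi = np.quantile(self.null, 1 - (1 - level) / 2)
        return bool(lo <= self.observed_rho <= hi)


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return np.vstack([stats.rank_average(row) for row in a])


def rtm_null(
    rt: ResponderTable, n_permutations: int = 1000, seed: int = 0
) -> RtmNullResult:
    """Period-label permutation null for the baseline correlation.

    Each permutation swaps C and T independently per subject (negating the
    score numerator; the baseline follows its definition — mean(C1, T1) is
    swap-invariant, T1-only becomes C1 for swapped subjects) and recomputes
    the Spearman correlation.  Deterministic given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    if rt.quads is None:
        raise DataInvariantError("ResponderTable lacks raw quadruples")
    q = rt.quads
    c1 = q["C1"].to_numpy(); c3 = q["C3"].to_numpy()
    t1 = q["T1"].to_numpy(); t3 = q["T3"].to_numpy()
    n = c1.size
    numer = (t3 - t1) - (c3 - c1)
    denom = 0.5 * (c1 + t1)  # swap-invariant

    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_permutations, n)).astype(bool)
    signs = np.where(flips, -1.0, 1.0)
    scores = signs * numer / denom  # (B, n)
    if rt.baseline_definition == "T1_only":
        baselines = np.where(flips, c1, t1)
    elif rt.baseline_definition == "C1_only":
        baselines = np.where(flips, t1, c1)
    else:
        baselines = np.broadcast_to(denom, (n_permutations, n))

    rs = _rank_rows(scores)
    rb = _rank_rows(np.ascontiguousarray(baselines))
    rs = rs - rs.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (rs * rb).sum(axis=1)
    den = np.sqrt((rs**2).sum(axis=1) * (rb**2).sum(axis=1))
    ok = den > 0
    null = np.where(ok, num / np.where(ok, den, 1.0), 0.0)

    observed = stats.spearman_rho(rt.baselines, rt.scores)
    below = float((null < observed - 1e-12).sum())
    equal = float((np.abs(null - observed) <= 1e-12).sum())
    quantile = (below + 0.5 * equal) / n_permutations
    extreme = int((np.abs(null) >= abs(observed) - 1e-12).sum())
    p_two = min(1.0, (1 + extreme) / (n_permutations + 1))
    return RtmNullResult(
        observed_rho=observed,
        null=null,
        quantile=quantile,
        p_two_sided=p_two,
        n_permutations=n_permutations,
        seed=seed,
    )
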