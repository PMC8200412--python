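"""Whole-profile Spearman-coefficient distances and inter/intra comparisons.

Beta-diversity here is rank-based: the distance between two samples is
``1 - rho`` where rho is the Spearman correlation of their full feature
profiles (0 = identical ranking, 2 = perfectly reversed).  Because the
measure depends only on within-sample ranks it is invariant to any strictly
monotone transform of a profile, which suits tables mixing relative
abundances and relative peak areas.

The inter/intra comparison asks whether between-subject variation dwarfs
the intervention effect: "inter" distances are taken between different
subjects' calendar-first samples, "intra" among each subject's own samples
across timepoints, compared with a rank-sum test.  The within-period
comparison pairs each subject's start-to-week-k distance in the test period
against the same span in the control period (signed-rank test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .errors import DataInvariantError, StatisticalPreconditionError
from .trial import FeatureMatrix, PairedSeries, TrialDataset

__all__ = [
    "DistanceMatrix",
    "profile_distances",
    "inter_intra_split",
    "inter_intra_test",
    "within_period_comparison",
]


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample Spearman-coefficient distance matrix."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise DataInvariantError("distance matrix shape mismatch")

    def lookup(self, a: str, b: str) -> float:
        i = self.sample_ids.index(a)
        j = self.sample_ids.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def profile_distances(m: FeatureMatrix, missing_as_zero: bool = True) -> DistanceMatrix:
    """Pairwise 1 - Spearman-rho distances between all sample profiles.

    Missing metabolite values are set to 0 for the ranking (non-detection
    sits below the detection limit, hence at the lowest rank); disable with
    ``missing_as_zero=False`` to raise on missing data instead.
    """
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise StatisticalPreconditionError("need >= 2 samples for distances")
    if vals.shape[1] < 3:
        raise StatisticalPreconditionError("need >= 3 features for rank distances")
    if np.isnan(vals).any():
        if not missing_as_zero:
            raise DataInvariantError("missing values present and missing_as_zero=False")
        vals = np.nan_to_num(vals, nan=0.0)
    ranks = np.vstack([stats.rank_average(row) for row in vals])
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        sid = m.sample_ids[int(np.flatnonzero(flat)[0])]
        raise StatisticalPreconditionError(
            f"sample {sid!r} has a constant profile; rank distance undefined"
        )
    rho = (centred @ centred.T) / np.outer(norms, norms)
    d = 1.0 - np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(sample_ids=m.sample_ids, d=d)


def _sample_lookup(ds: TrialDataset, D: DistanceMatrix) -> pd.DataFrame:
    md = ds.metadata.set_index("sample_id")
    missing = [s for s in D.sample_ids if s not in md.index]
    if missing:
        raise DataInvariantError(f"samples absent from metadata: {missing[:5]}")
    return md.loc[D.sample_ids]


def inter_intra_split(
    D: DistanceMatrix,
    ds: TrialDataset,
    intra_pairs: str = "all",
) -> tuple[np.ndarray, np.ndarray]:
    """Split distances into inter-individual and intra-individual sets.

    inter: distances between distinct subjects' first samples, where
    "first" is the calendar-first period start (C1 for arm CT, T1 for TC).
    intra: distances among each subject's own samples — every timepoint
    pair (``intra_pairs="all"``, default) or only calendar-adjacent pairs
    (``"adjacent"``).  Subjects with a single sample contribute nothing to
    the intra set.
    """
    if intra_pairs not in ("all", "adjacent"):
        raise ValueError("intra_pairs must be 'all' or 'adjacent'")
    md = _sample_lookup(ds, D)
    pos = {s: i for i, s in enumerate(D.sample_ids)}

    first_samples = []
    for subj in ds.subjects:
        first_tp = subj.calendar_order()[0].value
        hit = md[(md["subject_id"] == subj.subject_id) & (md["timepoint"] == first_tp)]
        if len(hit):
            first_samples.append(hit.index[0])
    inter = [
        D.d[pos[a], pos[b]]
        for i, a in enumerate(first_samples)
        for b in first_samples[i + 1 :]
    ]

    intra = []
    for subj in ds.subjects:
        rows = md[md["subject_id"] == subj.subject_id]
        if len(rows) < 2:
            continue
        order = {t.value: k for k, t in enumerate(subj.calendar_order())}
        samples = sorted(rows.index, key=lambda s: order[md.loc[s, "timepoint"]])
        if intra_pairs == "all":
            pairs = [
                (a, b) for i, a in enumerate(samples) for b in samples[i + 1 :]
            ]
        else:
            pairs = list(zip(samples, samples[1:]))
        intra.extend(D.d[pos[a], pos[b]] for a, b in pairs)

    return np.asarray(inter, dtype=float), np.asarray(intra, dtype=float)


def inter_intra_test(
    D: DistanceMatrix, ds: TrialDataset, intra_pairs: str = "all"
) -> stats.TestResult:
    """Rank-sum test of inter vs intra distance distributions."""
    inter, intra = inter_intra_split(D, ds, intra_pairs=intra_pairs)
    return stats.wilcoxon_rank_sum(inter, intra)


def within_period_comparison(
    D: DistanceMatrix, ds: TrialDataset, week: int = 4
) -> stats.TestResult:
    """Signed-rank comparison of within-period profile drift, T vs C.

    ``week=2`` compares per-subject d(T1,T2) against d(C1,C2); ``week=4``
    compares d(T1,T3) against d(C1,C3).  If every subject drifts
    identically in both periods (all zero differences) a degenerate
    "no difference" result with p = 1 is returned.
    """
    if week not in (2, 4):
        raise ValueError("week must be 2 or 4")
    k = 2 if week == 2 else 3
    md = _sample_lookup(ds, D)
    pos = {s: i for i, s in enumerate(D.sample_ids)}

    subject_ids, c_dist, t_dist = [], [], []
    for subj in ds.subjects:
        rows = md[md["subject_id"] == subj.subject_id]
        by_tp = dict(zip(rows["timepoint"], rows.index))
        needed = ["C1", f"C{k}", "T1", f"T{k}"]
        if not all(t in by_tp for t in needed):
            continue
        c_dist.append(D.d[pos[by_tp["C1"]], pos[by_tp[f"C{k}"]]])
        t_dist.append(D.d[pos[by_tp["T1"]], pos[by_tp[f"T{k}"]]])
        subject_ids.append(subj.subject_id)
    if len(subject_ids) < 3:
        raise StatisticalPreconditionError(
            f"only {len(subject_ids)} subjects have all four week-{week} samples"
        )
    pairs = PairedSeries(subject_ids, np.array(c_dist), np.array(t_dist))
    if np.all(pairs.diffs == 0.0):
        return stats.TestResult(float("nan"), 1.0, 0, "degenerate")
    return stats.wilcoxon_signed_rank(pairs.x, pairs.y)
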