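"""Data model and TSV I/O for two-period crossover multi-omics trials.

The trial design: each subject receives a control supplement in one
four-week period and a test supplement in the other (order randomised per
subject, arms ``CT`` and ``TC``), separated by a washout.  Samples are
labelled ``C1/C2/C3`` and ``T1/T2/T3`` — supplement letter plus sampling
timepoint (start, week 2, week 4) within that period — independent of
calendar order.  All alignment across measurements goes through the sample
metadata (sample id -> subject, timepoint label); sample ids themselves are
opaque.

Feature tables are samples x features.  Taxa tables hold relative
abundances closing to 1 per sample; metabolite tables hold relative peak
areas where an empty cell means "not detected" (below the instrument
detection limit) — distinct from zero.  Missing values are converted to
zero only inside the differential screen, never at the I/O layer.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataInvariantError, StatisticalPreconditionError

__all__ = [
    "Timepoint",
    "SubjectRecord",
    "FeatureMatrix",
    "TrialDataset",
    "PairedSeries",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_trial",
    "write_trial",
    "extract_pairs",
    "extract_deltas",
]

TAXA_SUM_TOL = 1e-6


class Timepoint(str, enum.Enum):
    """Sample timepoint label: supplement period (C control / T test) + index.

    Index 1 is the period start, 2 is week 2, 3 is week 4; the week mapping
    is fixed (1 -> 0, 2 -> 2, 3 -> 4).  Which period comes first in calendar
    time is the subject's arm, not the label.
    """

    C1 = "C1"
    C2 = "C2"
    C3 = "C3"
    T1 = "T1"
    T2 = "T2"
    T3 = "T3"

    @property
    def period(self) -> str:
        return self.value[0]

    @property
    def index(self) -> int:
        return int(self.value[1])

    @property
    def period_week(self) -> int:
        return {1: 0, 2: 2, 3: 4}[self.index]


ALL_TIMEPOINTS = tuple(Timepoint)


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    arm: str  # "CT" (control period first) or "TC"
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.arm not in ("CT", "TC"):
            raise DataInvariantError(f"arm must be CT or TC, got {self.arm!r}")

    def calendar_order(self) -> tuple[Timepoint, ...]:
        """The subject's six timepoints in calendar order."""
        first, second = (("C", "T") if self.arm == "CT" else ("T", "C"))
        return tuple(
            Timepoint(f"{p}{i}") for p in (first, second) for i in (1, 2, 3)
        )


class FeatureMatrix:
    """Samples x features table of nonnegative values with missingness.

    ``layer`` is one of ``taxa`` (relative abundances, rows close to 1),
    ``metabolite`` (relative peak areas, NaN = not detected) or ``outcome``.
    Backed by a pandas DataFrame (float dtype, NaN for missing).
    """

    VALID_LAYERS = ("taxa", "metabolite", "outcome")

    def __init__(
        self,
        values: pd.DataFrame,
        layer: str,
        unit_note: str = "",
        check_closure: bool = True,
    ):
        """``check_closure=False`` skips the sum-to-1 test for taxa tables —
        used for filtered sub-compositions, which keep their original
        relative abundances rather than being silently renormalised."""
        if layer not in self.VALID_LAYERS:
            raise DataInvariantError(f"unknown layer {layer!r}")
        df = values.astype(float)
        df.index = df.index.astype(str).rename("sample_id")
        df.columns = df.columns.astype(str).rename(None)
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise DataInvariantError(f"duplicated sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise DataInvariantError(f"duplicated feature ids: {dups}")
        arr = df.to_numpy()
        if np.nanmin(arr, initial=0.0) < 0:
            bad = df.index[(arr < 0).any(axis=1)].tolist()
            raise DataInvariantError(f"negative values in samples {bad}")
        if layer == "taxa" and check_closure:
            sums = np.nansum(arr, axis=1)
            off = np.abs(sums - 1.0) > TAXA_SUM_TOL
            if off.any():
                sid = df.index[off][0]
                raise DataInvariantError(
                    f"taxa sample {sid!r} sums to {sums[off][0]:.6g}, not 1"
                )
        self.values = df
        self.layer = layer
        self.unit_note = unit_note

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of missing (not-detected) samples."""
        return self.values.isna().mean(axis=0)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FeatureMatrix(layer={self.layer!r}, "
            f"{self.n_samples} samples x {self.n_features} features)"
        )


@dataclass
class PairedSeries:
    """Subject-aligned value pairs for one feature at two conditions.

    ``x`` holds condition A, ``y`` condition B; subjects missing either
    member are dropped and counted in ``n_dropped``.
    """

    subject_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    n_dropped: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.subject_ids) == self.x.size == self.y.size):
            raise DataInvariantError("PairedSeries arrays are misaligned")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def diffs(self) -> np.ndarray:
        """Differences y - x (later minus earlier by convention)."""
        return self.y - self.x


class TrialDataset:
    """All measurements of one crossover trial, keyed by (subject, timepoint).

    ``metadata`` maps each sample id to its subject and timepoint label;
    ``layers`` holds the omics FeatureMatrix objects; ``outcomes`` is a long
    table (subject_id, timepoint, outcome, value) for clinical scalars such
    as weekly defecation frequency and blood analytes.
    """

    def __init__(
        self,
        subjects: Sequence[SubjectRecord],
        metadata: pd.DataFrame,
        layers: Mapping[str, FeatureMatrix] | None = None,
        outcomes: pd.DataFrame | None = None,
    ):
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise DataInvariantError("duplicate subject ids")
        self.subjects = list(subjects)
        self._subject_map = {s.subject_id: s for s in self.subjects}

        md = metadata.copy()
        required = {"sample_id", "subject_id", "timepoint"}
        if not required.issubset(md.columns):
            raise DataInvariantError(f"metadata needs columns {sorted(required)}")
        md["timepoint"] = md["timepoint"].map(lambda t: Timepoint(t).value)
        if md["sample_id"].duplicated().any():
            raise DataInvariantError("duplicate sample ids in metadata")
        unknown = set(md["subject_id"]) - set(self._subject_map)
        if unknown:
            raise DataInvariantError(f"metadata references unknown subjects {sorted(unknown)}")
        self.metadata = md.reset_index(drop=True)

        self.layers: dict[str, FeatureMatrix] = {}
        for name, fm in (layers or {}).items():
            self.add_layer(name, fm)

        if outcomes is None:
            outcomes = pd.DataFrame(
                columns=["subject_id", "timepoint", "outcome", "value"]
            )
        oc = outcomes.copy()
        needed = {"subject_id", "timepoint", "outcome", "value"}
        if not needed.issubset(oc.columns):
            raise DataInvariantError(f"outcomes needs columns {sorted(needed)}")
        if len(oc):
            oc["timepoint"] = oc["timepoint"].map(lambda t: Timepoint(t).value)
            oc["value"] = oc["value"].astype(float)
            defec = oc[oc["outcome"].str.contains("defecation", case=False)]
            if (defec["value"] < 0).any():
                raise DataInvariantError("defecation frequency values must be >= 0")
            if oc.duplicated(["subject_id", "timepoint", "outcome"]).any():
                raise DataInvariantError("duplicate (subject, timepoint, outcome) rows")
        self.outcomes = oc.reset_index(drop=True)

    # -- structure ---------------------------------------------------------

    def add_layer(self, name: str, fm: FeatureMatrix) -> None:
        known = set(self.metadata["sample_id"])
        missing = set(fm.sample_ids) - known
        if missing:
            raise DataInvariantError(
                f"layer {name!r} has samples absent from metadata: {sorted(missing)[:5]}"
            )
        sub = self.metadata[self.metadata["sample_id"].isin(fm.sample_ids)]
        if sub.duplicated(["subject_id", "timepoint"]).any():
            raise DataInvariantError(
                f"layer {name!r}: more than one sample per (subject, timepoint)"
            )
        self.layers[name] = fm

    def subject(self, subject_id: str) -> SubjectRecord:
        return self._subject_map[subject_id]

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def sample_index(self, layer: str) -> pd.DataFrame:
        """Metadata rows for the samples present in ``layer``."""
        fm = self.layers[layer]
        md = self.metadata.set_index("sample_id")
        return md.loc[fm.sample_ids].reset_index()

    def outcome_names(self) -> list[str]:
        return sorted(self.outcomes["outcome"].unique())

    # -- value lookup ------------------------------------------------------

    def value_table(self, layer: str, feature: str) -> pd.DataFrame:
        """Wide subject x timepoint table of one feature or outcome.

        ``layer`` may be a layer name or ``"outcome"``; missing cells are
        NaN.  This is the single alignment path every paired extraction
        uses, so arm (calendar order) can never influence values.
        """
        if layer == "outcome":
            oc = self.outcomes[self.outcomes["outcome"] == feature]
            if oc.empty:
                raise DataInvariantError(f"unknown outcome {feature!r}")
            wide = oc.pivot(index="subject_id", columns="timepoint", values="value")
        else:
            if layer not in self.layers:
                raise DataInvariantError(f"unknown layer {layer!r}")
            fm = self.layers[layer]
            if feature not in fm.values.columns:
                raise DataInvariantError(
                    f"feature {feature!r} absent from layer {layer!r}"
                )
            col = fm.values[feature]
            md = self.sample_index(layer)
            tab = pd.DataFrame(
                {
                    "subject_id": md["subject_id"].to_numpy(),
                    "timepoint": md["timepoint"].to_numpy(),
                    "value": col.loc[md["sample_id"]].to_numpy(),
                }
            )
            wide = tab.pivot(index="subject_id", columns="timepoint", values="value")
        return wide.reindex(
            index=[s for s in self.subject_ids if s in wide.index],
            columns=[t.value for t in ALL_TIMEPOINTS],
        )


    def layer_wide(self, layer: str) -> pd.DataFrame:
        """Whole-layer subject table: columns (feature, timepoint), NaN missing.

        One pivot for all features — the bulk path the per-feature screen
        uses instead of per-feature :meth:`value_table` calls.
        """
        fm = self.layers[layer]
        md = self.sample_index(layer)
        df = fm.values.copy()
        df.index = pd.MultiIndex.from_arrays(
            [md["subject_id"].to_numpy(), md["timepoint"].to_numpy()],
            names=["subject_id", "timepoint"],
        )
        wide = df.unstack(level=1)
        return wide.reindex([s for s in self.subject_ids if s in wide.index])


# ---------------------------------------------------------------------------
# paired extraction


def extract_pairs(
    ds: TrialDataset,
    layer: str,
    feature: str,
    a: Timepoint | str,
    b: Timepoint | str,
) -> PairedSeries:
    """Subject-aligned (value at a, value at b) pairs for one feature.

    Subjects lacking either sample are dropped (counted in ``n_dropped``).
    Requires at least 3 complete pairs.
    """
    a = Timepoint(a)
    b = Timepoint(b)
    wide = ds.value_table(layer, feature)
    sub = wide[[a.value, b.value]].dropna()
    if len(sub) < 3:
        raise StatisticalPreconditionError(
            f"{feature!r}: only {len(sub)} complete ({a.value}, {b.value}) pairs"
        )
    return PairedSeries(
        subject_ids=list(sub.index),
        x=sub[a.value].to_numpy(),
        y=sub[b.value].to_numpy(),
        n_dropped=len(wide) - len(sub),
        label=f"{feature}:{a.value}-vs-{b.value}",
    )


def extract_deltas(ds: TrialDataset, layer: str, feature: str) -> PairedSeries:
    """Per-subject period changes: x = T3 - T1, y = C3 - C1.

    Sign convention is later-minus-earlier within each period.  Subjects
    missing any of the four samples are dropped.
    """
    wide = ds.value_table(layer, feature)
    sub = wide[["C1", "C3", "T1", "T3"]].dropna()
    if len(sub) < 3:
        raise StatisticalPreconditionError(
            f"{feature!r}: only {len(sub)} subjects with all of C1, C3, T1, T3"
        )
    return PairedSeries(
        subject_ids=list(sub.index),
        x=(sub["T3"] - sub["T1"]).to_numpy(),
        y=(sub["C3"] - sub["C1"]).to_numpy(),
        n_dropped=len(wide) - len(sub),
        label=f"{feature}:delta-T-vs-C",
    )


# ---------------------------------------------------------------------------
# TSV I/O
#
# Layout (UTF-8 TSV, header line, empty string = missing):
#   <layer>.tsv     first column "sample_id", remaining columns feature ids
#   metadata.tsv    sample_id, subject_id, arm? (ignored), timepoint
#   subjects.tsv    subject_id, arm, stratum
#   outcomes.tsv    subject_id, timepoint, outcome, value


def read_feature_matrix(path: str | Path, layer: str, unit_note: str = "") -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"sample_id": str})
    df.index = df.index.astype(str)
    return FeatureMatrix(df, layer=layer, unit_note=unit_note)


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    fm.values.to_csv(path, sep="\t", index_label="sample_id", na_rep="")


def write_trial(ds: TrialDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in ds.subjects],
            "arm": [s.arm for s in ds.subjects],
            "stratum": [s.stratum if s.stratum is not None else "" for s in ds.subjects],
        }
    ).to_csv(out / "subjects.tsv", sep="\t", index=False)
    ds.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    ds.outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False)
    for name, fm in ds.layers.items():
        write_feature_matrix(fm, out / f"{name}.tsv")


def read_trial(
    indir: str | Path, layer_files: Mapping[str, str] | None = None
) -> TrialDataset:
    """Read a trial directory written by :func:`write_trial`.

    ``layer_files`` maps layer name -> layer tag; defaults to any of
    ``taxa.tsv`` / ``metabolites.tsv`` present (tagged taxa / metabolite).
    """
    ind = Path(indir)
    subs = pd.read_csv(ind / "subjects.tsv", sep="\t", dtype=str).fillna("")
    subjects = [
        SubjectRecord(r.subject_id, r.arm, r.stratum or None)
        for r in subs.itertuples()
    ]
    metadata = pd.read_csv(ind / "metadata.tsv", sep="\t", dtype=str)
    outcomes_path = ind / "outcomes.tsv"
    outcomes = None
    if outcomes_path.exists():
        outcomes = pd.read_csv(outcomes_path, sep="\t")
        outcomes["subject_id"] = outcomes["subject_id"].astype(str)
    if layer_files is None:
        layer_files = {}
        if (ind / "taxa.tsv").exists():
            layer_files["taxa"] = "taxa"
        if (ind / "metabolites.tsv").exists():
            layer_files["metabolites"] = "metabolite"
    layers = {
        name: read_feature_matrix(ind / f"{name}.tsv", layer=tag)
        for name, tag in layer_files.items()
    }
    return TrialDataset(subjects, metadata, layers, outcomes)
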