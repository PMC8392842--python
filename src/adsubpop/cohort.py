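"""Reading, validation and preprocessing of ADNIMERGE-style clinical tables.

The analysis consumes a wide visit-level table (one row per patient clinic
visit) with sociodemographics, cognitive test scores and regional brain
volumes.  This module turns the raw CSV — which may contain censored strings
such as ``"<200"``, free-form categorical tokens and missing cells — into a
fully numeric, deskewed, standardized and imputed analysis matrix, recording
every transformation in a :class:`PreprocessReport`.

The fixed pipeline order is::

    filter diagnoses -> drop high-missingness features -> strip inequalities
    -> encode categoricals -> deskew -> standardize -> KNN-impute
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIAGNOSES = ("AD", "CN", "EMCI", "LMCI", "SMC")

#: Clinical direction of the standard features: ``benefit`` means a higher
#: value indicates a better clinical state (e.g. MMSE, brain volumes),
#: ``deficit`` the opposite (e.g. ADAS scores, trail-making time).
BENEFIT_FEATURES = frozenset({
    "MMSE", "MMSE_bl",
    "mPACCdigit", "mPACCdigit_bl", "mPACCtrailsB", "mPACCtrailsB_bl",
    "RAVLT_immediate", "RAVLT_immediate_bl",
    "RAVLT_learning", "RAVLT_learning_bl",
})
DEFICIT_FEATURES = frozenset({
    "ADAS11", "ADAS11_bl", "ADAS13", "ADAS13_bl", "ADASQ4", "ADASQ4_bl",
    "TRABSCOR", "TRABSCOR_bl",
    "RAVLT_perc_forgetting", "RAVLT_perc_forgetting_bl",
    "RAVLT_forgetting", "RAVLT_forgetting_bl",
    "CDRSB", "CDRSB_bl", "FAQ", "FAQ_bl",
})
VOLUME_STEMS = ("WholeBrain", "Hippocampus", "Fusiform", "MidTemp",
                "Entorhinal", "Ventricles", "ICV")

_CENSORED_RE = re.compile(r"^\s*([<>])\s*(\S+)\s*$")


@dataclass(frozen=True)
class FeatureSpec:
    """Typed metadata for one feature column.

    Parameters
    ----------
    name : str
        Column name (ADNIMERGE dialect, e.g. ``"ADAS13_bl"``).
    kind : {"continuous", "categorical"}
    group : {"cognition", "volume", "sociodemographic", "other"}
    direction : {"benefit", "deficit", "neutral"}
        ``benefit`` = higher value means better clinical state.  Cognition
        and volume features must not be ``neutral``.
    """

    name: str
    kind: str = "continuous"
    group: str = "other"
    direction: str = "neutral"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown kind {self.kind!r} for {self.name}")
        if self.group not in ("cognition", "volume", "sociodemographic", "other"):
            raise ValueError(f"unknown group {self.group!r} for {self.name}")
        if self.direction not in ("benefit", "deficit", "neutral"):
            raise ValueError(f"unknown direction {self.direction!r} for {self.name}")
        if self.group in ("cognition", "volume") and self.direction == "neutral":
            raise ValueError(
                f"{self.name}: {self.group} features must have a clinical "
                "direction (benefit or deficit)"
            )


def infer_feature_spec(name: str, kind: str = "continuous") -> FeatureSpec:
    """Build the default :class:`FeatureSpec` for a standard column name."""
    stem_is_volume = any(name == s or name == f"{s}_bl" for s in VOLUME_STEMS)
    if stem_is_volume:
        return FeatureSpec(name, "continuous", "volume", "benefit")
    if name in BENEFIT_FEATURES:
        return FeatureSpec(name, kind, "cognition", "benefit")
    if name in DEFICIT_FEATURES:
        return FeatureSpec(name, kind, "cognition", "deficit")
    if name in ("AGE", "PTEDUCAT"):
        return FeatureSpec(name, "continuous", "sociodemographic", "neutral")
    if name in ("PTGENDER", "PTRACCAT", "PTETHCAT", "PTMARRY"):
        return FeatureSpec(name, "categorical", "sociodemographic", "neutral")
    return FeatureSpec(name, kind, "other", "neutral")


@dataclass
class PreprocessReport:
    """Record of everything the preprocessing pipeline did."""

    dropped_features: list[tuple[str, float]] = field(default_factory=list)
    transforms_applied: dict[str, str] = field(default_factory=dict)
    n_imputed_cells: int = 0
    n_censored_values_converted: int = 0
    codebooks: dict[str, dict[str, int]] = field(default_factory=dict)
    constant_features: list[str] = field(default_factory=list)
    pipeline_log: list[str] = field(default_factory=list)
    feature_means: dict[str, float] = field(default_factory=dict)
    feature_sds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "dropped_features": [
                {"name": n, "missing_fraction": f} for n, f in self.dropped_features
            ],
            "transforms_applied": dict(self.transforms_applied),
            "n_imputed_cells": self.n_imputed_cells,
            "n_censored_values_converted": self.n_censored_values_converted,
            "codebooks": self.codebooks,
            "constant_features": list(self.constant_features),
            "pipeline_log": list(self.pipeline_log),
        }


class CohortTable:
    """A rectangular patient-visit dataset with typed feature metadata.

    Thin wrapper around a :class:`pandas.DataFrame` holding one row per
    visit, with dedicated ``patient_id``, ``visit_id`` and ``diagnosis``
    columns plus one column per feature listed in ``feature_specs``.
    Raw (pre-numeric) values, including censored strings, are kept as-is
    until :func:`preprocess` runs.
    """

    ID_COL = "PTID"
    VISIT_COL = "VISCODE"
    DX_COL = "DX"

    def __init__(self, frame: pd.DataFrame, feature_specs: Sequence[FeatureSpec]):
        names = [s.name for s in feature_specs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature specs: {dup}")
        for col in (self.ID_COL, self.DX_COL):
            if col not in frame.columns:
                raise ValueError(f"required column {col!r} missing")
        missing = [n for n in names if n not in frame.columns]
        if missing:
            raise ValueError(f"feature columns missing from table: {missing}")
        if frame[self.ID_COL].isna().any():
            bad = int(frame.index[frame[self.ID_COL].isna()][0])
            raise ValueError(f"row {bad}: missing patient id")
        if frame[self.DX_COL].isna().any():
            bad = int(frame.index[frame[self.DX_COL].isna()][0])
            raise ValueError(f"row {bad}: missing diagnosis")
        self.frame = frame.reset_index(drop=True)
        self.feature_specs = list(feature_specs)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.feature_specs]

    def spec_for(self, name: str) -> FeatureSpec:
        for s in self.feature_specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def diagnosis_counts(self) -> dict[str, int]:
        return self.frame[self.DX_COL].value_counts().to_dict()

    def with_frame(self, frame: pd.DataFrame,
                   specs: Sequence[FeatureSpec] | None = None) -> "CohortTable":
        return CohortTable(frame, self.feature_specs if specs is None else specs)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_cohort(path, specs: Sequence[FeatureSpec] | None = None,
                alias_map: Mapping[str, str] | None = None) -> CohortTable:
    """Read an ADNIMERGE-dialect CSV into a :class:`CohortTable`.

    Values stay raw: censored strings like ``"<200"`` are preserved until
    :func:`strip_inequalities` runs.  Empty strings and ``"NA"`` are
    missing.  ``alias_map`` renames non-standard headers to the expected
    ADNIMERGE names before validation.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                        na_values=["", "NA"])
    if alias_map:
        frame = frame.rename(columns=dict(alias_map))
    for col in (CohortTable.ID_COL, CohortTable.DX_COL):
        if col not in frame.columns:
            raise ValueError(f"required column {col!r} not found in {path}")
    bad_dx = ~frame[CohortTable.DX_COL].isin(DIAGNOSES)
    if bad_dx.any():
        row = int(frame.index[bad_dx][0])
        raise ValueError(
            f"row {row}: unparseable diagnosis "
            f"{frame[CohortTable.DX_COL].iloc[row]!r} (expected one of {DIAGNOSES})"
        )
    if specs is None:
        reserved = {CohortTable.ID_COL, CohortTable.VISIT_COL, CohortTable.DX_COL}
        specs = [infer_feature_spec(c) for c in frame.columns if c not in reserved]
    return CohortTable(frame, specs)


def filter_diagnosis(cohort: CohortTable, keep: Iterable[str]) -> CohortTable:
    """Restrict the cohort to rows whose diagnosis is in ``keep``."""
    keep = set(keep)
    if not keep:
        raise ValueError("keep must be non-empty")
    mask = cohort.frame[CohortTable.DX_COL].isin(keep)
    return cohort.with_frame(cohort.frame[mask].reset_index(drop=True))


def _missing_fraction(col: pd.Series) -> float:
    return float(col.isna().mean()) if len(col) else 0.0


def drop_high_missingness(cohort: CohortTable, threshold: float = 0.20
                          ) -> tuple[CohortTable, PreprocessReport]:
    """Drop features missing in strictly more than ``threshold`` of rows."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    report = PreprocessReport()
    keep_specs = []
    for spec in cohort.feature_specs:
        frac = _missing_fraction(cohort.frame[spec.name])
        if frac > threshold:
            report.dropped_features.append((spec.name, frac))
        else:
            keep_specs.append(spec)
    dropped = {n for n, _ in report.dropped_features}
    frame = cohort.frame.drop(columns=sorted(dropped))
    report.pipeline_log.append(
        f"drop_high_missingness(threshold={threshold}): dropped {sorted(dropped)}"
    )
    return CohortTable(frame, keep_specs), report


def strip_inequalities(value):
    """Convert a raw cell to a float, mapping ``"<x"``/``">x"`` to ``x``.

    Returns ``(number_or_nan, was_censored)``; non-numeric, non-censored
    tokens become NaN (lossy by design, counted by the caller).
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan, False
    if isinstance(value, (int, float, np.floating, np.integer)):
        return float(value), False
    text = str(value)
    m = _CENSORED_RE.match(text)
    if m:
        try:
            return float(m.group(2)), True
        except ValueError:
            return math.nan, False
    try:
        return float(text), False
    except ValueError:
        return math.nan, False


def encode_categoricals(cohort: CohortTable,
                        codebooks: Mapping[str, Mapping[str, int]] | None = None
                        ) -> tuple[CohortTable, dict[str, dict[str, int]]]:
    """Map categorical levels to integer codes ``0..L-1``.

    Codes are assigned in lexicographic level order.  Supplying fitted
    ``codebooks`` reuses them; an unseen level then raises.
    """
    frame = cohort.frame.copy()
    books: dict[str, dict[str, int]] = {}
    for spec in cohort.feature_specs:
        if spec.kind != "categorical":
            continue
        col = frame[spec.name]
        if codebooks is not None and spec.name in codebooks:
            book = dict(codebooks[spec.name])
            unseen = sorted(set(col.dropna()) - set(book))
            if unseen:
                raise ValueError(
                    f"{spec.name}: unseen categorical level(s) {unseen}"
                )
        else:
            levels = sorted(set(col.dropna()))
            if len(levels) == 1:
                logger.warning("%s: single-level categorical, encoded all-zero",
                               spec.name)
            book = {lvl: i for i, lvl in enumerate(levels)}
        frame[spec.name] = col.map(book).astype(float)
        books[spec.name] = book
    return cohort.with_frame(frame), books


_DESKEW_TAGS = ("identity", "log", "cube_root", "rank_linearized")

#: Parametric transforms are preferred; the rank-based linearization discards
#: all spacing information, so it is reserved for severe residual skew —
#: cases where the best parametric candidate still leaves |skewness| above
#: this bound.
RANK_FALLBACK_SKEW = 2.0


def _sample_skew(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.skew(x, bias=False))


def deskew(values: np.ndarray, rank_fallback_skew: float = RANK_FALLBACK_SKEW
           ) -> tuple[np.ndarray, str]:
    """Reduce skewness of a numeric vector, choosing among fixed transforms.

    Candidates: identity, ``log(x - min + 1)``, cube root, and (as a last
    resort) rank-based piecewise linearization to uniform scores.  The
    parametric transform minimizing bias-corrected \\|sample skewness\\| is
    applied; the rank transform is substituted only when that minimum still
    exceeds ``rank_fallback_skew``.  Missing entries pass through untouched.
    """
    values = np.asarray(values, dtype=float)
    obs = ~np.isnan(values)
    x = values[obs]
    if x.size < 3 or np.ptp(x) == 0:
        return values.copy(), "identity"

    candidates = {
        "identity": x,
        "log": np.log(x - x.min() + 1.0),
        "cube_root": np.cbrt(x),
    }
    skews = {tag: abs(_sample_skew(v)) for tag, v in candidates.items()}
    best = min(_DESKEW_TAGS[:3], key=lambda t: skews[t])
    if skews[best] > rank_fallback_skew:
        ranks = stats.rankdata(x, method="average")
        candidates["rank_linearized"] = (ranks - 0.5) / x.size
        skews["rank_linearized"] = abs(_sample_skew(candidates["rank_linearized"]))
        if skews["rank_linearized"] < skews[best]:
            best = "rank_linearized"
    out = values.copy()
    out[obs] = candidates[best]
    return out, best


def standardize(matrix: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[int]]:
    """Z-score columns using the population standard deviation (divide by n).

    Constant columns (sd = 0) are centered only and reported in the returned
    flag list.  Missing cells are ignored in the moments and left missing.
    """
    X = np.asarray(matrix, dtype=float)
    means = np.nanmean(X, axis=0)
    sds = np.nanstd(X, axis=0)  # ddof=0: population sd
    flagged = [j for j in range(X.shape[1]) if sds[j] == 0]
    safe = np.where(sds == 0, 1.0, sds)
    Z = (X - means) / safe
    return Z, means, sds, flagged


def knn_impute(matrix: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill missing cells with the mean over the k nearest rows.

    Distance between rows is Euclidean over mutually observed features,
    rescaled by ``sqrt(d / n_shared)`` so rows sharing few features are not
    artificially close.  Only rows with the target feature observed are
    candidate neighbors; observed cells are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(matrix, dtype=float).copy()
    n, d = X.shape
    miss = np.isnan(X)
    if not miss.any():
        return X
    all_missing = np.where(miss.all(axis=1))[0]
    if all_missing.size:
        raise ValueError(f"row {int(all_missing[0])} has all values missing")

    obs = ~miss
    Xz = np.where(miss, 0.0, X)
    # squared distances over shared features, scaled by d / n_shared
    shared = obs.astype(float) @ obs.astype(float).T
    sq = (Xz**2) @ obs.T.astype(float)
    sqd = sq + sq.T - 2.0 * (Xz @ Xz.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist2 = np.where(shared > 0, sqd * (d / np.maximum(shared, 1)), np.inf)
    np.fill_diagonal(dist2, np.inf)
    dist2 = np.maximum(dist2, 0.0)

    out = X.copy()
    for i, f in zip(*np.where(miss)):
        cand = np.where(obs[:, f] & np.isfinite(dist2[i]))[0]
        if cand.size == 0:
            out[i, f] = np.nanmean(X[:, f])
            continue
        order = cand[np.argsort(dist2[i, cand], kind="stable")]
        out[i, f] = float(np.mean(X[order[:k], f]))
    return out


def preprocess(cohort: CohortTable, *, diagnosis_filter: Iterable[str] | None = None,
               missingness_threshold: float = 0.20, knn_k: int = 5,
               deskew_enabled: bool = True,
               exclude_features: Iterable[str] = (),
               ) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full fixed-order preprocessing pipeline.

    Returns the analysis-ready numeric matrix (one column per retained
    feature, rows aligned with the filtered cohort) and the report.  The
    result is deterministic: identical input and options give an identical
    matrix.
    """
    if diagnosis_filter:
        cohort = filter_diagnosis(cohort, diagnosis_filter)
    exclude = set(exclude_features)
    if exclude:
        keep = [s for s in cohort.feature_specs if s.name not in exclude]
        cohort = CohortTable(
            cohort.frame.drop(columns=[c for c in exclude
                                       if c in cohort.frame.columns]),
            keep)
    cohort, report = drop_high_missingness(cohort, missingness_threshold)
    report.pipeline_log.insert(
        0, f"filter_diagnosis({sorted(diagnosis_filter) if diagnosis_filter else 'none'})")

    frame = cohort.frame.copy()
    for spec in cohort.feature_specs:
        if spec.kind != "continuous":
            continue
        parsed = [strip_inequalities(v) for v in frame[spec.name]]
        report.n_censored_values_converted += sum(c for _, c in parsed)
        frame[spec.name] = [v for v, _ in parsed]
    report.pipeline_log.append(
        f"strip_inequalities: {report.n_censored_values_converted} censored values converted")

    cohort, books = encode_categoricals(cohort.with_frame(frame))
    report.codebooks = books
    report.pipeline_log.append(f"encode_categoricals: {sorted(books)}")

    frame = cohort.frame
    cols = cohort.feature_names
    X = frame[cols].to_numpy(dtype=float)
    if deskew_enabled:
        for j, spec in enumerate(cohort.feature_specs):
            if spec.kind != "continuous":
                report.transforms_applied[spec.name] = "identity"
                continue
            X[:, j], tag = deskew(X[:, j])
            report.transforms_applied[spec.name] = tag
        report.pipeline_log.append("deskew: applied")
    else:
        report.transforms_applied = {c: "identity" for c in cols}

    Z, means, sds, flagged = standardize(X)
    report.constant_features = [cols[j] for j in flagged]
    report.feature_means = dict(zip(cols, means.tolist()))
    report.feature_sds = dict(zip(cols, sds.tolist()))
    report.pipeline_log.append(
        f"standardize: population sd; constant columns {report.constant_features}")

    report.n_imputed_cells = int(np.isnan(Z).sum())
    if report.n_imputed_cells:
        Z = knn_impute(Z, k=knn_k)
    report.pipeline_log.append(
        f"knn_impute(k={knn_k}): {report.n_imputed_cells} cells imputed")

    return pd.DataFrame(Z, columns=cols, index=frame.index), report
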