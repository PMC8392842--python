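"""Post-hoc characterization of clusters.

For each cluster and feature a Welch two-sample t-test (continuous) or
Pearson chi-squared test (categorical) compares the cluster against the
rest of the cohort, with a Tukey-style studentized-range adjustment across
the per-feature cluster comparisons and Bonferroni across features for a
family-wise alpha.  Percent fold changes are computed on the original
feature scale, then direction-standardized (deficit features sign-flipped)
so a positive value always reads "less severe disease", and aggregated into
per-cluster cognition/volume severity axes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureSpec

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    feature: str
    cluster: int
    statistic: float
    p_value: float
    test: str                   # {"welch_t", "chi_squared"}
    df: float
    p_adjusted: float | None = None
    threshold: float | None = None
    significant: bool | None = None


def cluster_feature_ttest(values: np.ndarray, labels: np.ndarray, cluster: int,
                          include_self: bool = False) -> TestResult:
    """Welch t-test of a cluster's feature values against the rest.

    By default the comparison group is the cluster's complement; with
    ``include_self=True`` it is the full cohort (the literal "cluster vs
    overall" reading, which violates independence between the groups).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    in_c = (labels == cluster) & ~np.isnan(values)
    out_c = (np.ones_like(in_c, bool) if include_self else labels != cluster) \
        & ~np.isnan(values)
    x, y = values[in_c], values[out_c]
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"cluster {cluster}: need >=2 non-missing values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / len(x) + vy / len(y)
    if se2 == 0:
        t = 0.0 if x.mean() == y.mean() else math.inf * np.sign(x.mean() - y.mean())
        df = float(len(x) + len(y) - 2)
        p = 1.0 if t == 0 else 0.0
    else:
        t = float((x.mean() - y.mean()) / math.sqrt(se2))
        df = se2**2 / ((vx / len(x))**2 / (len(x) - 1)
                       + (vy / len(y))**2 / (len(y) - 1))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return TestResult("", cluster, t, p, "welch_t", float(df))


def cluster_feature_chisq(counts_in_cluster: dict, counts_overall: dict,
                          cluster: int = 0) -> TestResult:
    """Pearson chi-squared test of a cluster's category frequencies.

    Expected counts are the overall relative frequencies scaled to the
    cluster size; categories with zero expected count are dropped with a
    warning.  Degrees of freedom: number of retained categories − 1.
    """
    n_cluster = sum(counts_in_cluster.values())
    if n_cluster == 0:
        raise ValueError("cluster is empty")
    n_overall = sum(counts_overall.values())
    cats = [c for c in counts_overall if counts_overall[c] > 0]
    dropped = [c for c in counts_overall if counts_overall[c] == 0]
    if dropped:
        logger.warning("chi-squared: dropping zero-expectation categories %s",
                       dropped)
    obs = np.array([counts_in_cluster.get(c, 0) for c in cats], dtype=float)
    exp = np.array([counts_overall[c] / n_overall * n_cluster for c in cats])
    stat = float(((obs - exp)**2 / exp).sum())
    df = len(cats) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else 1.0
    return TestResult("", cluster, stat, p, "chi_squared", float(df))


def familywise_adjust(results: list[TestResult], alpha: float = 0.05
                      ) -> list[TestResult]:
    """Set significance flags under a family-wise alpha.

    Welch comparisons within a feature get a Tukey-HSD-style adjustment via
    the studentized range (q = \\|t\\|·√2 over the k cluster comparisons);
    chi-squared comparisons get Bonferroni within the feature.  A Bonferroni
    factor across features then yields the family-wise threshold, which is
    stored on every result alongside the raw p.
    """
    by_feature: dict[str, list[TestResult]] = {}
    for r in results:
        by_feature.setdefault(r.feature, []).append(r)
    n_features = max(1, len(by_feature))
    threshold = alpha / n_features
    for group in by_feature.values():
        k = len(group)
        for r in group:
            if r.test == "welch_t" and k >= 2 and math.isfinite(r.statistic):
                p_adj = float(stats.studentized_range.sf(
                    abs(r.statistic) * math.sqrt(2.0), k, r.df))
            elif r.test == "chi_squared" and k >= 2:
                p_adj = min(1.0, r.p_value * k)
            else:
                p_adj = r.p_value
            r.p_adjusted = p_adj
            r.threshold = threshold
            r.significant = bool(p_adj < threshold)
    return results


def fold_change(values: np.ndarray, labels: np.ndarray, cluster: int) -> float:
    """Signed percent change of the cluster mean versus the overall mean.

    ``100 · (mean_cluster − mean_overall) / |mean_overall|``, computed on
    the original (pre-standardization) feature scale.  Returns NaN when the
    overall mean is zero (percent change undefined).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    obs = ~np.isnan(values)
    overall = float(values[obs].mean())
    mean_c = float(values[obs & (labels == cluster)].mean())
    if overall == 0.0:
        logger.warning("fold_change: overall mean is zero for cluster %s", cluster)
        return math.nan
    if mean_c == overall:
        return 0.0
    return 100.0 * (mean_c - overall) / abs(overall)


@dataclass
class FoldChangeTable:
    """Per-(cluster, feature) signed percent fold changes.

    ``direction_standardized`` flips the sign of deficit-direction features
    so positive always means "less severe disease".
    """

    entries: pd.DataFrame  # columns: cluster, feature, percent_fold_change,
                           #          direction_standardized

    @classmethod
    def from_profile(cls, profile: dict[str, tuple[float, ...]],
                     specs: list[FeatureSpec]) -> "FoldChangeTable":
        """Build a table from a feature → per-cluster percent mapping."""
        spec_map = {s.name: s for s in specs}
        rows = []
        for feature, per_cluster in profile.items():
            s = spec_map.get(feature)
            if s is None:
                raise KeyError(f"no FeatureSpec for feature {feature!r}")
            sign = -1.0 if s.direction == "deficit" else 1.0
            for c, pct in enumerate(per_cluster):
                rows.append((c, feature, float(pct), sign * float(pct)))
        return cls(pd.DataFrame(
            rows, columns=["cluster", "feature", "percent_fold_change",
                           "direction_standardized"]))

    @classmethod
    def compute(cls, frame: pd.DataFrame, labels: np.ndarray,
                specs: list[FeatureSpec],
                features: list[str] | None = None) -> "FoldChangeTable":
        """Compute fold changes of every cluster for the given raw features."""
        labels = np.asarray(labels)
        clusters = sorted(int(c) for c in np.unique(labels) if c >= 0)
        feats = features if features is not None else [
            s.name for s in specs if s.kind == "continuous"
            and s.name in frame.columns]
        profile = {
            f: tuple(fold_change(frame[f].to_numpy(dtype=float), labels, c)
                     for c in clusters)
            for f in feats
        }
        table = cls.from_profile(profile, specs)
        table.entries["cluster"] = table.entries["cluster"].map(
            dict(enumerate(clusters)))
        return table

    def pivot(self, standardized: bool = False) -> pd.DataFrame:
        col = "direction_standardized" if standardized else "percent_fold_change"
        return self.entries.pivot(index="feature", columns="cluster", values=col)


@dataclass
class SeveritySummary:
    """Per-cluster mean ± sd of direction-standardized fold changes per axis."""

    clusters: list[int]
    cognition_mean: dict[int, float]
    cognition_sd: dict[int, float]
    volume_mean: dict[int, float]
    volume_sd: dict[int, float]
    cognition_features: list[str]
    volume_features: list[str]

    def to_dict(self) -> dict:
        return {
            "clusters": self.clusters,
            "cognition": {c: {"mean": self.cognition_mean[c],
                              "sd": self.cognition_sd[c]} for c in self.clusters},
            "volume": {c: {"mean": self.volume_mean[c],
                           "sd": self.volume_sd[c]} for c in self.clusters},
            "cognition_features": self.cognition_features,
            "volume_features": self.volume_features,
        }


def severity_summary(fold_table: FoldChangeTable, specs: list[FeatureSpec],
                     cognition_features: list[str] | None = None,
                     volume_features: list[str] | None = None
                     ) -> SeveritySummary:
    """Aggregate direction-standardized fold changes into two severity axes.

    Default axis membership comes from the feature groups in ``specs``:
    ``volume`` features form the brain-volume axis, ``cognition`` features
    the cognitive-performance axis.  Positive axis means = less severe
    disease.  The sd is the population sd of the per-feature standardized
    fold changes within the axis.
    """
    spec_map = {s.name: s for s in specs}
    present = set(fold_table.entries["feature"])
    unknown = sorted(present - set(spec_map))
    if unknown:
        raise KeyError(f"fold table contains unknown feature(s): {unknown}")
    if volume_features is None:
        volume_features = [f for f in present if spec_map[f].group == "volume"]
    if cognition_features is None:
        cognition_features = [f for f in present
                              if spec_map[f].group == "cognition"]
    if not cognition_features or not volume_features:
        raise ValueError("both axis feature lists must be non-empty")

    df = fold_table.entries
    clusters = sorted(df["cluster"].unique().tolist())
    out = SeveritySummary(clusters, {}, {}, {}, {},
                          sorted(cognition_features), sorted(volume_features))
    for c in clusters:
        sub = df[df["cluster"] == c].set_index("feature")["direction_standardized"]
        for axis, feats in (("cognition", cognition_features),
                            ("volume", volume_features)):
            vals = sub.reindex(feats).to_numpy(dtype=float)
            getattr(out, f"{axis}_mean")[c] = float(np.mean(vals))
            getattr(out, f"{axis}_sd")[c] = float(np.std(vals))
    return out


def select_top_features(fold_table: FoldChangeTable,
                        results: list[TestResult], n: int = 10
                        ) -> tuple[dict[int, list[str]], list[str]]:
    """Rank features by their strongest (minimum) p-value across clusters.

    Ties break by \\|percent fold change\\| descending.  Returns the top-n
    list per cluster and the union across clusters (rank order preserved).
    """
    fc = {(r.cluster, r.feature): r for r in results}
    df = fold_table.entries
    per_cluster: dict[int, list[str]] = {}
    min_p: dict[str, float] = {}
    max_fc: dict[str, float] = {}
    for c in sorted(df["cluster"].unique().tolist()):
        sub = df[df["cluster"] == c]
        scored = []
        for _, row in sub.iterrows():
            r = fc.get((c, row["feature"]))
            p = r.p_value if r is not None else 1.0
            scored.append((p, -abs(row["percent_fold_change"]), row["feature"]))
            min_p[row["feature"]] = min(min_p.get(row["feature"], 1.0), p)
            max_fc[row["feature"]] = max(max_fc.get(row["feature"], 0.0),
                                         abs(row["percent_fold_change"]))
        scored.sort()
        per_cluster[c] = [f for _, _, f in scored[:n]]
    union = sorted(min_p, key=lambda f: (min_p[f], -max_fc[f]))[:n]
    return per_cluster, union


def rank_clusters(summary: SeveritySummary) -> dict[str, list[int]]:
    """Order clusters from least to most severe disease.

    Two orderings are emitted rather than silently choosing one: by the
    unweighted mean of the two axis scores, and by the brain-volume axis
    (the brain-reserve reading, under which larger volume tolerates more
    pathology).  Exact ties within an ordering are flagged in the log.
    """
    combined = {c: (summary.cognition_mean[c] + summary.volume_mean[c]) / 2.0
                for c in summary.clusters}
    volume_first = {c: summary.volume_mean[c] for c in summary.clusters}
    orders = {}
    for name, score in (("combined_mean", combined),
                        ("volume_weighted", volume_first)):
        vals = sorted(score.values(), reverse=True)
        if len(set(vals)) != len(vals):
            logger.warning("rank_clusters: tie in %s ordering", name)
        orders[name] = sorted(score, key=lambda c: -score[c])
    return orders
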