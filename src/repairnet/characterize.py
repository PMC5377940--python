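"""Statistical characterization of the positive set against the background.

Compares feature distributions (degree, core number, RNR) between the
positive set, the remaining nodes, and per-pathway subsets using the
two-sample Kolmogorov–Smirnov test, and produces group-mean summaries,
binned frequency distributions, and pathway overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_COLUMNS
from .io import GeneSetAnnotation


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov–Smirnov result.

    D is the supremum of the absolute difference between the two
    empirical CDFs; it lies in [0, 1], is 0 iff the empirical CDFs agree
    at every sample point, and is symmetric in the two samples.
    """

    D: float
    p_value: float
    n1: int
    n2: int


def ks_two_sample(x, y, method: str = "asymp") -> KSResult:
    """Two-sample KS test, sensitive to location and shape differences.

    The p-value comes by default from the asymptotic Kolmogorov
    distribution with effective size n1*n2/(n1+n2) — appropriate for the
    large positive-vs-background comparisons this pipeline makes; pass
    ``method="exact"`` for small samples. Ties are handled exactly by
    evaluating the empirical CDFs at the pooled sample points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(x, y, method=method)
    return KSResult(D=float(res.statistic),
                    p_value=float(min(res.pvalue, 1.0)),
                    n1=int(x.size), n2=int(y.size))


SUMMARY_COLUMNS = ["group", "size", "mean_degree", "mean_kcore", "mean_rnr"]


def summarize_groups(table: pd.DataFrame, annotation: GeneSetAnnotation,
                     min_group_size: int = 4) -> pd.DataFrame:
    """Group means of the three features for positives, negatives, and
    each pathway.

    Pathways with fewer than ``min_group_size`` members in the table are
    listed with their size only; their means are suppressed (NaN), since
    an average over a handful of proteins is not meaningful. The default
    of 4 keeps 8-member groups in and 1–3-member groups out.
    """
    if min_group_size < 1:
        raise ValueError("min_group_size must be >= 1")
    is_pos = table["label"] == "positive"
    rows = []

    def _row(name, sub, suppress=False):
        if len(sub) == 0:
            return
        if suppress:
            means = (np.nan, np.nan, np.nan)
        else:
            means = (sub["degree"].mean(), sub["k_core"].mean(),
                     sub["rnr"].mean())
        rows.append({"group": name, "size": len(sub),
                     "mean_degree": means[0], "mean_kcore": means[1],
                     "mean_rnr": means[2]})

    for pw in sorted(annotation.pathways):
        members = [m for m in annotation.pathways[pw] if m in table.index]
        sub = table.loc[members]
        _row(pw, sub, suppress=len(sub) < min_group_size)
    _row("positives", table[is_pos])
    _row("negatives", table[~is_pos])
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def ks_report(table: pd.DataFrame, annotation: GeneSetAnnotation,
              per_pathway: bool = False, method: str = "asymp") -> dict:
    """KS comparison of each feature between positives and negatives,
    optionally also each pathway vs the non-positive background.

    Returns a nested dict ``{feature: {group: {"D", "p_value", "n1",
    "n2"}}}`` ready for JSON serialization.
    """
    is_pos = table["label"] == "positive"
    neg = table[~is_pos]
    report: dict = {}
    for feat in FEATURE_COLUMNS:
        entry = {}
        res = ks_two_sample(table.loc[is_pos, feat], neg[feat],
                            method=method)
        entry["positives_vs_negatives"] = vars(res)
        if per_pathway:
            for pw in sorted(annotation.pathways):
                members = [m for m in annotation.pathways[pw]
                           if m in table.index]
                if not members:
                    continue
                res = ks_two_sample(table.loc[members, feat], neg[feat],
                                    method=method)
                entry[f"{pw}_vs_negatives"] = vars(res)
        report[feat] = entry
    return report


def pathway_overlap(annotation: GeneSetAnnotation, pathway_names) -> dict:
    """Counts for every region of the inclusion–exclusion partition of
    the named pathways (the numbers a Venn diagram displays).

    Keys are tuples of the pathway names a region belongs to exactly;
    only nonempty regions are returned. The counts sum to the size of
    the union of the named sets.
    """
    pathway_names = list(pathway_names)
    unknown = [n for n in pathway_names if n not in annotation.pathways]
    if unknown:
        raise KeyError(f"unknown pathway name(s): {unknown}")
    sets = {n: set(annotation.pathways[n]) for n in pathway_names}
    counts = {}
    for r in range(1, len(pathway_names) + 1):
        for combo in combinations(pathway_names, r):
            exact = set.intersection(*(sets[n] for n in combo))
            for other in pathway_names:
                if other not in combo:
                    exact -= sets[other]
            if exact:
                counts[tuple(combo)] = len(exact)
    return counts


def binned_distribution(values, bin_edges) -> np.ndarray:
    """Percentage of a sample falling in each bin; percentages sum to 100.

    Bins are half-open [lo, hi) except the last, which is closed, so a
    strictly increasing edge sequence covering the data range partitions
    it exactly. Values outside the bins are an error — the caller chose
    edges that fail to cover the range.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise ValueError(
            f"bins [{edges[0]}, {edges[-1]}] do not cover the data range "
            f"[{values.min()}, {values.max()}]")
    counts, _ = np.histogram(values, bins=edges)
    return counts / values.size * 100.0


def default_bin_edges(values, feature: str, n_bins: int = 10) -> np.ndarray:
    """Heuristic edges: logarithmic for heavy-tailed degree, linear
    otherwise."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.array([lo, lo + 1.0])
    if feature == "degree" and lo >= 0:
        return np.unique(np.concatenate(
            [[lo], np.geomspace(max(lo, 1.0), hi, n_bins), [hi]]))
    return np.linspace(lo, hi, n_bins + 1)


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write the group summary as TSV, means to 2 decimals, '—' for
    suppressed groups."""
    out = summary.copy()
    for col in ("mean_degree", "mean_kcore", "mean_rnr"):
        out[col] = out[col].map(
            lambda v: "—" if pd.isna(v) else f"{v:.2f}")
    out.to_csv(path, sep="\t", index=False)
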