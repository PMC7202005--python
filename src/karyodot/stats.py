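"""Comparative statistics across Drosophila species.

Operates on per-oocyte measurement tables and on per-species summary rows
(heterochromatin fraction, inversion status, mean dot-dot distance, oocyte
counts, proportion out, mean dot area). Implements:

* species summaries from per-oocyte tables;
* pairwise contrasts between closely related species pairs that diverge in
  inversion type (Δ = polymorphic − monomorphic), Welch t-tests when
  per-oocyte samples exist, and the study-specific False Discovery Rate
  procedure with cutoff_i = (i/m)·Q and the conservative Q = 1/(2m);
* the inversion-group comparison on species means (Welch t);
* Pearson correlations with the regression-t two-sided p,
  t = r·sqrt(n−2)/sqrt(1−r²);
* phylogenetic pair-averaging: each close pair of species is collapsed to
  the midpoint of its two means before correlating, a coarse guard
  against treating related species as independent observations.

Summary-only mode exists because every correlation and group comparison
is a function of species means alone; per-oocyte distance samples are
needed only for the pairwise t-tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpeciesSummary",
    "PairContrast",
    "CorrelationResult",
    "GroupComparison",
    "summarize_species",
    "pairwise_contrasts",
    "fdr_evaluate",
    "group_mean_comparison",
    "pearson_correlation",
    "pair_averaged_correlation",
    "round_sig",
]

#: Minimum distance-eligible oocytes the survey protocol aims for per species.
MIN_OOCYTES_TARGET = 30
#: Minimum measured chromosome areas per species.
MIN_AREAS_TARGET = 20


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    decimals = sig - 1 - int(math.floor(math.log10(abs(x))))
    return float(np.round(x, decimals))


@dataclass
class SpeciesSummary:
    """One species' row of the comparative table."""

    species: str
    abbreviation: str
    pct_heterochromatin: float | None
    has_common_inversions: bool
    mean_distance_um: float | None
    n_out: int
    n_total: int
    proportion_out: float
    mean_dot_area_um2: float | None


@dataclass
class PairContrast:
    """One polymorphic-vs-monomorphic species contrast."""

    poly: str
    mono: str
    delta_um: float
    p_value: float | None = None
    rank: int | None = None
    fdr_cutoff: float | None = None
    significant: bool | None = None

    @property
    def delta_printed(self) -> float:
        """Δ to 2 significant figures, the table-reporting precision."""
        return round_sig(self.delta_um, 2)


@dataclass
class CorrelationResult:
    """Pearson correlation with regression-t significance."""

    x: str
    y: str
    n: int
    r: float
    p_value: float
    excluded: tuple[str, ...] = ()
    pair_averaged: bool = False


@dataclass
class GroupComparison:
    """Unweighted group means of species means plus a Welch t-test."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t_statistic: float
    p_value: float

    @property
    def delta(self) -> float:
        return self.mean_a - self.mean_b


def summarize_species(
    table: pd.DataFrame,
    species: str,
    abbreviation: str = "",
    pct_heterochromatin: float | None = None,
    has_common_inversions: bool = False,
) -> SpeciesSummary:
    """Collapse one species' per-oocyte table to a summary row.

    ``table`` uses the per-oocyte schema (columns ``out_flag``,
    ``configuration``, ``distance_um``, ``area1_um2``, ``area2_um2``).
    Mean distance is taken over distance-eligible rows only; the
    proportion out counts every oocyte with any chromosome out over all
    post-Prophase oocytes. Warns when the survey targets (30
    distance-eligible oocytes, 20 measured areas) are unmet; a species
    with no eligible rows gets a missing mean distance, not an error.
    """
    n_total = len(table)
    if n_total == 0:
        raise ValueError(f"{species}: empty per-oocyte table")
    out = table["out_flag"].astype(bool)
    n_out = int(out.sum())

    eligible = table["distance_um"].notna()
    if "configuration" in table.columns:
        eligible &= table["configuration"].isin(
            ["both_out", "one_out_other_locatable"]
        )
    distances = table.loc[eligible, "distance_um"]
    if len(distances) < MIN_OOCYTES_TARGET:
        warnings.warn(
            f"{species}: only {len(distances)} distance-eligible oocytes "
            f"(target {MIN_OOCYTES_TARGET})",
            stacklevel=2,
        )
    areas = pd.concat(
        [table.get("area1_um2", pd.Series(dtype=float)),
         table.get("area2_um2", pd.Series(dtype=float))]
    ).dropna()
    if len(areas) < MIN_AREAS_TARGET:
        warnings.warn(
            f"{species}: only {len(areas)} measured dot areas (target {MIN_AREAS_TARGET})",
            stacklevel=2,
        )
    return SpeciesSummary(
        species=species,
        abbreviation=abbreviation or species,
        pct_heterochromatin=pct_heterochromatin,
        has_common_inversions=has_common_inversions,
        mean_distance_um=float(distances.mean()) if len(distances) else None,
        n_out=n_out,
        n_total=n_total,
        proportion_out=n_out / n_total,
        mean_dot_area_um2=float(areas.mean()) if len(areas) else None,
    )


def fdr_evaluate(
    pvalues: "list[float] | np.ndarray", Q: float | None = None
) -> pd.DataFrame:
    """The study's False Discovery Rate procedure.

    With m tests ranked by ascending p, the cutoff for rank i is
    (i/m)·Q; by default Q = 1/(2m), so cutoff_i = i/(2m²). Significance is
    a step-up rule: find the largest rank whose p-value lies strictly
    below its cutoff; that test and every smaller-ranked test are
    significant. Ties in p are ranked in stable input order.

    Returns a DataFrame indexed like the input with columns ``p_value``,
    ``rank``, ``cutoff``, ``significant``; empty input gives an empty
    frame.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    cols = ["p_value", "rank", "cutoff", "significant"]
    if m == 0:
        return pd.DataFrame(columns=cols)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if Q is None:
        Q = 1.0 / (2 * m)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    cutoffs = ranks / m * Q
    sorted_p = p[order]
    passing = sorted_p < (np.arange(1, m + 1) / m * Q)
    k = int(np.max(np.nonzero(passing)[0]) + 1) if passing.any() else 0
    significant = ranks <= k
    return pd.DataFrame(
        {"p_value": p, "rank": ranks, "cutoff": cutoffs, "significant": significant}
    )


def pairwise_contrasts(
    summary: pd.DataFrame,
    pairs: "list[tuple[str, str]]",
    distances: "dict[str, np.ndarray] | None" = None,
    pvalues: "list[float] | None" = None,
    Q: float | None = None,
) -> list[PairContrast]:
    """Contrasts between inversion-type divergent species pairs.

    ``summary`` is the species table (indexed or keyed by abbreviation,
    with ``mean_distance_um``); each pair is (polymorphic, monomorphic)
    and Δ = mean(poly) − mean(mono). p-values come from Welch two-sample
    t-tests when per-oocyte ``distances`` are supplied, else from
    ``pvalues`` (e.g. published values) in pair order; with neither, the
    contrasts carry Δ only. FDR flags are attached across the m pairs.
    """
    table = summary.set_index("abbreviation") if "abbreviation" in summary.columns else summary
    for a, b in pairs:
        for sp in (a, b):
            if sp not in table.index:
                raise KeyError(f"unknown species {sp!r} in pairs")
    contrasts = []
    for poly, mono in pairs:
        if distances is not None:
            xa, xb = np.asarray(distances[poly]), np.asarray(distances[mono])
            delta = float(xa.mean() - xb.mean())
            p = float(sps.ttest_ind(xa, xb, equal_var=False).pvalue)
            if math.isnan(p) and np.isclose(delta, 0.0):
                p = 1.0  # two degenerate (zero-variance) equal samples
        else:
            delta = float(
                table.loc[poly, "mean_distance_um"] - table.loc[mono, "mean_distance_um"]
            )
            p = None
        contrasts.append(PairContrast(poly=poly, mono=mono, delta_um=delta, p_value=p))
    if distances is None and pvalues is not None:
        if len(pvalues) != len(contrasts):
            raise ValueError("need one p-value per pair")
        for c, p in zip(contrasts, pvalues):
            c.p_value = p
    ps = [c.p_value for c in contrasts]
    if all(p is not None for p in ps) and contrasts:
        fdr = fdr_evaluate(ps, Q=Q)
        for c, (_, row) in zip(contrasts, fdr.iterrows()):
            c.rank = int(row["rank"])
            c.fdr_cutoff = float(row["cutoff"])
            c.significant = bool(row["significant"])
    return contrasts


def group_mean_comparison(
    summary: pd.DataFrame,
    group_col: str = "has_common_inversions",
    value_col: str = "mean_distance_um",
) -> GroupComparison:
    """Compare inversion-polymorphic vs monomorphic species means.

    Unweighted means of the per-species means (species lacking a value,
    e.g. one without a free dot chromosome, drop out), with a Welch
    two-sided t-test on the species means.
    """
    d = summary.dropna(subset=[value_col])
    a = d.loc[d[group_col].astype(bool), value_col].to_numpy(float)
    b = d.loc[~d[group_col].astype(bool), value_col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two species with values")
    res = sps.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        group_a="polymorphic",
        group_b="monomorphic",
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=len(a),
        n_b=len(b),
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def pearson_correlation(
    summary: pd.DataFrame,
    x: str,
    y: str,
    exclude: "tuple[str, ...]" = (),
) -> CorrelationResult:
    """Pearson r between two species-level variables.

    Species named in ``exclude`` (by abbreviation) are dropped, then rows
    missing either variable are dropped pairwise. The two-sided p-value is
    the regression t transform t = r·sqrt(n−2)/sqrt(1−r²) on n−2 degrees
    of freedom (scipy's exact equivalent).
    """
    d = summary
    if exclude:
        key = "abbreviation" if "abbreviation" in d.columns else None
        if key is None:
            raise ValueError("summary needs an 'abbreviation' column to exclude species")
        d = d[~d[key].isin(exclude)]
    d = d.dropna(subset=[x, y])
    if len(d) < 3:
        raise ValueError(f"need at least 3 complete observations, got {len(d)}")
    xv = d[x].to_numpy(float)
    yv = d[y].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(x=x, y=y, n=len(d), r=float(r), p_value=float(p), excluded=tuple(exclude))


def pair_averaged_correlation(
    summary: pd.DataFrame,
    x: str,
    y: str,
    pairs: "list[tuple[str, str]]",
    singletons: "tuple[str, ...]" = (),
) -> CorrelationResult:
    """Correlation after collapsing each close species pair to its midpoint.

    Every species must appear in exactly one pair or singleton; each pair
    contributes the mean of its two species' values, each singleton its
    own values. A blunt control for phylogenetic non-independence.
    """
    seen: set[str] = set()
    for a, b in pairs:
        for sp in (a, b):
            if sp in seen:
                raise ValueError(f"species {sp!r} appears in more than one pair")
            seen.add(sp)
    for sp in singletons:
        if sp in seen:
            raise ValueError(f"species {sp!r} is both paired and singleton")
        seen.add(sp)
    table = summary.set_index("abbreviation") if "abbreviation" in summary.columns else summary
    pts_x, pts_y = [], []
    for a, b in pairs:
        pts_x.append((table.loc[a, x] + table.loc[b, x]) / 2)
        pts_y.append((table.loc[a, y] + table.loc[b, y]) / 2)
    for sp in singletons:
        pts_x.append(table.loc[sp, x])
        pts_y.append(table.loc[sp, y])
    xv = np.asarray(pts_x, float)
    yv = np.asarray(pts_y, float)
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    if len(xv) < 3:
        raise ValueError("need at least 3 pair-averaged points")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined: a variable has zero variance")
    r, p = sps.pearsonr(xv, yv)
    return CorrelationResult(
        x=x, y=y, n=len(xv), r=float(r), p_value=float(p), pair_averaged=True
    )
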