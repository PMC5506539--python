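"""Coevolution-graph connectivity and its relation to conservation.

Builds per-site degrees from spatially filtered significant pairs, bins
degree against conservation index, fits ordinary least squares on bin
means, draws the matched null ensembles (non-coevolved pairs within 10 A,
more than 6 positions apart, redrawn 10 times), contrasts structural
environments, and runs the family-level and annotation-stratified cohort
regressions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .conservation import ConservationProfile, family_average_conservation
from .scoring import SignificantPair
from .secondary import EnvironmentAnnotation
from .structure import ColumnResidueMap, StructureModel, distance_matrix

HCC_THRESHOLD = 3


def site_degrees(pairs: Sequence[SignificantPair]) -> dict[int, int]:
    """Number of significant partners per column; only connected sites appear."""
    seen = set()
    deg: dict[int, int] = {}
    for p in pairs:
        key = (p.i, p.j)
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        seen.add(key)
        deg[p.i] = deg.get(p.i, 0) + 1
        deg[p.j] = deg.get(p.j, 0) + 1
    return deg


def classify_hcc_lcc(
    degrees: dict[int, int], threshold: int = HCC_THRESHOLD
) -> dict[int, str]:
    """HCC (> threshold connections) vs LCC (<= threshold)."""
    return {c: ("HCC" if d > threshold else "LCC") for c, d in degrees.items()}


@dataclass
class BinnedSeries:
    bin_width: int
    labels: list[str]
    n: np.ndarray
    mean_x: np.ndarray
    mean_y: np.ndarray


def bin_and_average(
    x: Sequence[float], y: Sequence[float], bin_width: int
) -> BinnedSeries:
    """Left-closed integer bins starting at 1: value v -> floor((v-1)/w)."""
    if bin_width <= 0:
        raise ValueError("bin width must be a positive integer")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    idx = np.floor((x - 1) / bin_width).astype(int)
    labels, ns, mxs, mys = [], [], [], []
    for b in sorted(set(idx.tolist())):
        sel = idx == b
        lo = b * bin_width + 1
        labels.append(f"{lo}" if bin_width == 1 else f"{lo}-{lo + bin_width - 1}")
        ns.append(int(sel.sum()))
        mxs.append(float(x[sel].mean()))
        mys.append(float(y[sel].mean()))
    return BinnedSeries(bin_width, labels, np.array(ns), np.array(mxs), np.array(mys))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n_points: int


def linear_fit(
    series: BinnedSeries, weighting: str = "unweighted"
) -> RegressionResult:
    """OLS of bin-mean y on bin-mean x; R^2 = 1 - SS_res/SS_tot."""
    x, y = series.mean_x, series.mean_y
    if x.size < 2:
        raise ValueError("need at least 2 bins for a regression")
    if weighting == "by_n":
        w = series.n.astype(float)
    elif weighting == "unweighted":
        w = np.ones_like(x)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    wsum = w.sum()
    xbar = (w * x).sum() / wsum
    ybar = (w * y).sum() / wsum
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in x: regression undefined")
    syy = (w * (y - ybar) ** 2).sum()
    if syy == 0:
        return RegressionResult(0.0, float(ybar), 0.0, int(x.size))
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = (w * (y - intercept - slope * x) ** 2).sum()
    return RegressionResult(
        float(slope), float(intercept), float(1.0 - ss_res / syy), int(x.size)
    )


def scatter_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """OLS over raw points (no binning).

    Used for the real-vs-null control: a binned fit over two occupied
    degree bins has R^2 = 1 by construction, so only the unbinned fit can
    discriminate a real degree-conservation relationship from a matched
    null."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a scatter fit")
    sxx = ((x - x.mean()) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in x: regression undefined")
    syy = ((y - y.mean()) ** 2).sum()
    if syy == 0:
        return RegressionResult(0.0, float(y.mean()), 0.0, int(x.size))
    slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    return RegressionResult(float(slope), float(intercept),
                            float(1.0 - ss_res / syy), int(x.size))


def degree_ci_scatter(
    degrees: dict[int, int], profile: ConservationProfile
) -> RegressionResult:
    """Unbinned site-level fit of CI on degree."""
    cols = [c for c in degrees if not profile.gap_mask[c]]
    return scatter_fit([degrees[c] for c in cols], [profile.ci[c] for c in cols])


def degree_ci_regression(
    degrees: dict[int, int],
    profile: ConservationProfile,
    bin_width: int = 1,
    weighting: str = "unweighted",
) -> RegressionResult:
    """Site-level fit of conservation index on coevolutionary degree."""
    cols = [c for c in degrees if not profile.gap_mask[c]]
    if len(cols) < 2:
        raise ValueError("need at least 2 connected sites with CI")
    series = bin_and_average(
        [degrees[c] for c in cols], [profile.ci[c] for c in cols], bin_width
    )
    return linear_fit(series, weighting)


@dataclass
class NullEnsemble:
    draws: list[list[tuple[int, int]]]
    regressions: list[Optional[RegressionResult]]  # binned fits
    scatter_regressions: list[Optional[RegressionResult]]  # unbinned fits
    seed: int
    pool_size: int


def eligible_null_pairs(
    m: ColumnResidueMap,
    dmat: np.ndarray,
    significant: Iterable[SignificantPair],
    max_distance: float = 10.0,
    min_separation: int = 6,
) -> tuple[list[tuple[int, int]], set[int]]:
    """All (i, j) column pairs usable by the null: mapped, < max_distance,
    |i - j| > min_separation, not significant, anchor sites non-coevolved."""
    sig_pairs = {(p.i, p.j) for p in significant}
    sig_sites = {c for p in significant for c in (p.i, p.j)}
    cols = m.mapped_columns()
    pool = []
    for ai, i in enumerate(cols):
        if i in sig_sites:
            continue
        for j in cols[ai + 1:]:
            if j - i <= min_separation or (i, j) in sig_pairs:
                continue
            d = dmat[m.col_to_res[i], m.col_to_res[j]]
            if np.isfinite(d) and d < max_distance:
                pool.append((i, j))
    return pool, sig_sites


def sample_null_pairs(
    m: ColumnResidueMap,
    s: StructureModel,
    significant: Sequence[SignificantPair],
    n_pairs: int,
    n_draws: int = 10,
    seed: int = 0,
    profile: Optional[ConservationProfile] = None,
    bin_width: int = 1,
    max_distance: float = 10.0,
    min_separation: int = 6,
    dmat: Optional[np.ndarray] = None,
) -> NullEnsemble:
    """Draw ``n_draws`` sets of ``n_pairs`` non-coevolved close pairs.

    When a conservation profile is supplied, each draw carries the
    degree-vs-CI regression of its null graph (None when degenerate).
    """
    if dmat is None:
        dmat = distance_matrix(s)
    pool, _ = eligible_null_pairs(m, dmat, significant, max_distance, min_separation)
    if len(pool) < n_pairs:
        raise ValueError(
            f"only {len(pool)} eligible null pairs; {n_pairs} requested"
        )
    rng = np.random.default_rng(seed)
    draws, regs, scatter_regs = [], [], []
    for _ in range(n_draws):
        idx = rng.choice(len(pool), size=n_pairs, replace=False)
        draw = [pool[k] for k in sorted(idx.tolist())]
        draws.append(draw)
        if profile is not None:
            deg = site_degrees(
                [SignificantPair(i, j, "null", 0.0) for i, j in draw]
            )
            try:
                regs.append(degree_ci_regression(deg, profile, bin_width))
            except ValueError:
                regs.append(None)
            try:
                scatter_regs.append(degree_ci_scatter(deg, profile))
            except ValueError:
                scatter_regs.append(None)
        else:
            regs.append(None)
            scatter_regs.append(None)
    return NullEnsemble(draws, regs, scatter_regs, seed, len(pool))


@dataclass
class EnvironmentContrast:
    """Pair counts and HCC-LCC conservation gaps per environment class."""

    pair_counts: dict[str, int]
    delta_ci: dict[str, Optional[float]]
    site_counts: dict[str, dict[str, int]]  # class -> {"HCC": n, "LCC": n}


def _pair_class(label_i: str, label_j: str, labels: tuple[str, str]) -> str:
    a, b = labels
    if label_i == a and label_j == a:
        return f"{a.upper()}_{a.upper()}"
    if label_i == b and label_j == b:
        return f"{b.upper()}_{b.upper()}"
    return "MIXED"


def environment_contrast(
    pairs: Sequence[SignificantPair],
    m: ColumnResidueMap,
    env: EnvironmentAnnotation,
    profile: ConservationProfile,
    feature: str = "burial",
    hcc_threshold: int = HCC_THRESHOLD,
) -> EnvironmentContrast:
    """Contrast pair environments (both-X vs both-Y vs mixed).

    feature: 'burial' (acc/bur), 'hbond' (hb/nhb) or 'ss' (helix/strand;
    coil residues make a pair MIXED).
    """
    def residue_label(col: int) -> Optional[str]:
        ridx = m.col_to_res.get(col)
        if ridx is None:
            return None
        if feature == "burial":
            if np.isnan(env.relative_accessibility[ridx]):
                return None
            return "bur" if env.buried[ridx] else "acc"
        if feature == "hbond":
            return "hb" if env.hbonded[ridx] else "nhb"
        if feature == "ss":
            return {"helix": "helix", "strand": "strand"}.get(
                str(env.ss_class[ridx]), "other"
            )
        raise ValueError(f"unknown feature {feature!r}")

    names = {
        "burial": ("acc", "bur"),
        "hbond": ("hb", "nhb"),
        "ss": ("helix", "strand"),
    }[feature]
    degrees = site_degrees(pairs)
    hcc = classify_hcc_lcc(degrees, hcc_threshold)

    class_sites: dict[str, set[int]] = {}
    pair_counts: dict[str, int] = {}
    for p in pairs:
        li, lj = residue_label(p.i), residue_label(p.j)
        if li is None or lj is None:
            continue
        cls = _pair_class(li, lj, names)
        pair_counts[cls] = pair_counts.get(cls, 0) + 1
        class_sites.setdefault(cls, set()).update((p.i, p.j))

    delta: dict[str, Optional[float]] = {}
    site_counts: dict[str, dict[str, int]] = {}
    for cls, sites in class_sites.items():
        usable = [c for c in sites if not profile.gap_mask[c]]
        hi = [profile.ci[c] for c in usable if hcc[c] == "HCC"]
        lo = [profile.ci[c] for c in usable if hcc[c] == "LCC"]
        site_counts[cls] = {"HCC": len(hi), "LCC": len(lo)}
        delta[cls] = (
            float(np.mean(hi) - np.mean(lo)) if hi and lo else None
        )
    return EnvironmentContrast(pair_counts, delta, site_counts)


@dataclass
class FamilySummary:
    family_id: str
    method: str
    n_pairs: int
    n_coevolved_sites: int
    mean_ci: float


def family_summary(
    family_id: str,
    method: str,
    pairs: Sequence[SignificantPair],
    profile: ConservationProfile,
    gapless: Iterable[int],
) -> FamilySummary:
    """Per-family record: pair count, distinct coevolved sites, mean CI
    over gapless columns."""
    sites = {c for p in pairs for c in (p.i, p.j)}
    mean_ci = family_average_conservation(profile, gapless)
    return FamilySummary(family_id, method, len(pairs), len(sites), mean_ci)


def cohort_regression(
    summaries: Sequence[FamilySummary],
    bin_width: int = 40,
    weighting: str = "unweighted",
) -> RegressionResult:
    """Family-level fit of mean CI on coevolved-site count (binned)."""
    if len(summaries) < 2:
        raise ValueError("need at least 2 families")
    series = bin_and_average(
        [s.n_coevolved_sites for s in summaries],
        [s.mean_ci for s in summaries],
        bin_width,
    )
    if len(series.labels) < 2:
        raise ValueError("fewer than 2 non-empty bins")
    return linear_fit(series, weighting)


def write_binned_series_tsv(series: BinnedSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tn\tmean_x\tmean_y\n")
        for lbl, n, mx, my in zip(series.labels, series.n,
                                  series.mean_x, series.mean_y):
            fh.write(f"{lbl}\t{n}\t{mx:.6g}\t{my:.6g}\n")


def write_null_report_tsv(ensemble: NullEnsemble, path) -> None:
    """One row per draw: pair count and the fitted regressions (1-based
    seed recorded in the header for reproducibility)."""
    with open(path, "w") as fh:
        fh.write(f"# seed={ensemble.seed} pool_size={ensemble.pool_size}\n")
        fh.write("draw\tn_pairs\tbinned_r2\tbinned_slope\t"
                 "scatter_r2\tscatter_slope\n")
        for k, draw in enumerate(ensemble.draws):
            b = ensemble.regressions[k]
            s = ensemble.scatter_regressions[k]
            fh.write(
                f"{k + 1}\t{len(draw)}\t"
                f"{'' if b is None else f'{b.r_squared:.4g}'}\t"
                f"{'' if b is None else f'{b.slope:.4g}'}\t"
                f"{'' if s is None else f'{s.r_squared:.4g}'}\t"
                f"{'' if s is None else f'{s.slope:.4g}'}\n"
            )


def read_go_table(path) -> pd.DataFrame:
    """TSV with columns family_id, domain, label (families may repeat)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "domain", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    return df


def stratified_regression(
    summaries: Sequence[FamilySummary],
    go: pd.DataFrame,
    domain: str,
    bin_width: int = 40,
    min_families: int = 5,
    weighting: str = "unweighted",
) -> pd.DataFrame:
    """Per-class cohort regressions within one annotation domain.

    Families with several labels enter each of their classes.  Classes with
    fewer than ``min_families`` summarised families are omitted.  Returns a
    table with columns class, n_families, r_squared, slope.
    """
    sub = go[go["domain"] == domain]
    by_id: dict[str, list[FamilySummary]] = {}
    for s in summaries:
        by_id.setdefault(s.family_id, []).append(s)
    rows = []
    for label, grp in sub.groupby("label"):
        members = [
            s for fid in grp["family_id"].unique() for s in by_id.get(fid, [])
        ]
        if len({s.family_id for s in members}) < min_families:
            continue
        try:
            reg = cohort_regression(members, bin_width, weighting)
        except ValueError:
            continue
        rows.append(
            {
                "class": label,
                "n_families": len({s.family_id for s in members}),
                "r_squared": reg.r_squared,
                "slope": reg.slope,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_families", "r_squared", "slope"])
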