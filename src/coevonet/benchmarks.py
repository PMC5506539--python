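"""Recovery and calibration benchmarks.

Self-contained routines that measure, on synthetic data, the properties
the pipeline is supposed to have: false-positive calibration of the Z >= 4
rule on coupling-free alignments, ranked recovery of planted contacts,
and the two cohort-level trends (site-level degree-conservation slope with
its matched null control, and the family-level count-conservation slope).
All randomness is controlled by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import Alignment
from .connectivity import bin_and_average, cohort_regression, linear_fit
from .dca import PottsCouplings, dca_direct_information
from .pipeline import RunConfig, run_family
from .psicov import psicov_score
from .scoring import (
    ScoreMatrix,
    mcbasc_score,
    mip_score,
    sequence_weights,
    zscore_standardize,
)
from .synthetic import CohortSpec, make_cohort, make_family

METHODS = ("MIp", "McBASC", "DCA", "PSICOV")


def _field_profile(L: int, scale: float, seed: int) -> np.ndarray:
    """Per-column single-site fields like a mid-gradient family core."""
    rng = np.random.default_rng(seed)
    h = np.zeros((L, 20))
    for c in range(L):
        h[c, rng.integers(0, 20)] = scale * rng.uniform(0.85, 1.15)
    return h


def _score_all(a: Alignment, cfg: Optional[RunConfig] = None) -> dict[str, ScoreMatrix]:
    cfg = cfg or RunConfig()
    w, _ = sequence_weights(a, cfg.identity_threshold)
    return {
        "MIp": mip_score(a, w, cfg.mi_min_joint_count),
        "McBASC": mcbasc_score(a),
        "DCA": dca_direct_information(a, weights=w),
        "PSICOV": psicov_score(a, weights=w),
    }


def null_calibration(
    n_replicates: int = 20,
    L: int = 30,
    N: int = 500,
    field_scale: float = 1.3,
    z_cutoff: float = 4.0,
    seed: int = 1000,
) -> dict[str, float]:
    """Fraction of column pairs reaching Z >= cutoff on coupling-free
    alignments, pooled over replicates, per method."""
    exceed = {m: 0 for m in METHODS}
    total = 0
    for r in range(n_replicates):
        h = _field_profile(L, field_scale, seed + 7 * r)
        params = PottsCouplings(L=L, q=20, h=h)
        a = make_null_alignment(params, N, seed + 7 * r + 1)
        total += L * (L - 1) // 2
        for m, raw in _score_all(a).items():
            z = zscore_standardize(raw)
            _, _, scores = z.upper_valid()
            exceed[m] += int((scores >= z_cutoff).sum())
    return {m: exceed[m] / total for m in METHODS}


def make_null_alignment(params: PottsCouplings, N: int, seed: int) -> Alignment:
    from .synthetic import sample_potts_alignment

    return sample_potts_alignment(params.L, N, params, seed=seed)


def planted_recovery(
    n_replicates: int = 20,
    L: int = 30,
    N: int = 500,
    n_couplings: int = 15,
    seed: int = 5000,
) -> dict[str, float]:
    """Mean fraction of planted contact pairs among the top-n ranked pairs.

    Families are generated with couplings placed uniformly over structure
    contacts (no gapped flanks, no hub bias — hub concentration is a
    cohort-trend feature, not a recovery condition); ranking uses the raw
    score matrices.
    """
    spec = CohortSpec(
        L=L, N=N, flank_fraction=0.0, hub_bias=0.0, sweeps=150,
    )
    hits = {m: [] for m in METHODS}
    for r in range(n_replicates):
        fam = make_family(
            f"R{r}", L, N, field_scale=1.0, n_couplings=n_couplings,
            spec=spec, seed=seed + 97 * r,
        )
        planted = {(i, j) for i, j, _ in fam.planted_pairs}
        k = len(planted)
        for m, raw in _score_all(fam.alignment).items():
            iu, ju, scores = raw.upper_valid()
            order = np.argsort(-scores)[:k]
            top = {(int(iu[t]), int(ju[t])) for t in order}
            hits[m].append(len(top & planted) / k)
    return {m: float(np.mean(hits[m])) for m in METHODS}


@dataclass
class CohortTrends:
    site_slope: dict[str, float]
    site_r_squared: dict[str, float]
    family_slope: dict[str, float]
    family_r_squared: dict[str, float]
    null_control_wins: dict[str, tuple[int, int]]  # (wins, comparable)
    n_connected_sites: dict[str, int]


def cohort_trends(
    spec: Optional[CohortSpec] = None,
    cfg: Optional[RunConfig] = None,
    site_bin_width: int = 1,
    family_bin_width: int = 5,
) -> CohortTrends:
    """Run the full pipeline on a synthetic cohort and measure the two
    headline trends plus the non-coevolved control.

    The family-level regression uses the given bin width on coevolved-site
    counts (the published bins of 40 scale to 5 at cohort size 24); the
    null control compares unbinned site-level fits (two-bin binned fits
    are degenerate, see connectivity.scatter_fit).
    """
    spec = spec or CohortSpec(seed=1)
    cfg = cfg or RunConfig(min_length=50, seed=spec.seed)
    cohort = make_cohort(spec)
    results = []
    for fam in cohort:
        results.append(
            run_family(fam.to_family_record(), cfg, structure=fam.structure)
        )

    site_slope, site_r2, fam_slope, fam_r2 = {}, {}, {}, {}
    wins_d, n_sites_d = {}, {}
    for m in cfg.methods:
        xs, ys = [], []
        wins = comparable = 0
        for res in results:
            deg = res.degrees[m]
            for c, d in deg.items():
                if not res.profile.gap_mask[c]:
                    xs.append(d)
                    ys.append(res.profile.ci[c])
            real = res.site_scatter[m]
            ne = res.null_ensembles[m]
            if real is not None and ne is not None:
                null_r2 = [
                    r.r_squared for r in ne.scatter_regressions if r is not None
                ]
                if null_r2:
                    comparable += 1
                    if real.r_squared > float(np.mean(null_r2)):
                        wins += 1
        n_sites_d[m] = len(xs)
        wins_d[m] = (wins, comparable)
        try:
            fit = linear_fit(bin_and_average(xs, ys, site_bin_width))
            site_slope[m] = fit.slope
            site_r2[m] = fit.r_squared
        except ValueError:  # degenerate degree distribution at this seed
            site_slope[m] = float("nan")
            site_r2[m] = float("nan")
        try:
            famfit = cohort_regression(
                [res.summaries[m] for res in results], family_bin_width
            )
            fam_slope[m] = famfit.slope
            fam_r2[m] = famfit.r_squared
        except ValueError:
            fam_slope[m] = float("nan")
            fam_r2[m] = float("nan")
    return CohortTrends(site_slope, site_r2, fam_slope, fam_r2, wins_d, n_sites_d)


def determinism_check(seed: int = 4242, tmp_dir=None) -> bool:
    """Regenerate and re-analyse one synthetic family twice under the same
    seed; compare every output file byte for byte."""
    import filecmp
    import tempfile
    from pathlib import Path

    spec = CohortSpec(L=60, N=80, sweeps=60)
    cfg = RunConfig(methods=("MIp", "McBASC"), min_length=50,
                    min_sequences=20, mi_min_joint_count=10, seed=seed)
    base = Path(tmp_dir) if tmp_dir else Path(tempfile.mkdtemp())
    dirs = []
    for tag in ("a", "b"):
        fam = make_family("DEMO", 60, 80, 1.0, 8, spec, seed=seed)
        out = base / tag
        run_family(fam.to_family_record(), cfg, structure=fam.structure,
                   out_dir=out)
        dirs.append(out)
    names = sorted(p.name for p in dirs[0].iterdir())
    if names != sorted(p.name for p in dirs[1].iterdir()):
        return False
    match, mismatch, errors = filecmp.cmpfiles(dirs[0], dirs[1], names,
                                               shallow=False)
    return not mismatch and not errors
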