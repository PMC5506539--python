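"""Per-family and cohort orchestration.

`run_family` executes the full per-family chain in order: score ->
standardise -> select -> map to structure -> spatial filter ->
conservation -> degrees -> environment -> null ensemble -> regressions,
writing TSV outputs along the way.  `run_cohort` aggregates family
summaries into the family-level (and optionally annotation-stratified)
regressions and the method-overlap matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import FamilyRecord, gapless_columns, validate_family
from .conservation import conservation_profile, write_profile_tsv
from .connectivity import (
    FamilySummary,
    NullEnsemble,
    RegressionResult,
    cohort_regression,
    degree_ci_regression,
    degree_ci_scatter,
    environment_contrast,
    family_summary,
    sample_null_pairs,
    site_degrees,
    stratified_regression,
)
from .dca import dca_direct_information
from .psicov import psicov_score
from .scoring import (
    ScoreMatrix,
    SignificantPair,
    mcbasc_score,
    method_overlap,
    mip_score,
    select_significant_pairs,
    sequence_weights,
    write_pairs_tsv,
    write_score_tsv,
    zscore_standardize,
)
from .secondary import EnvironmentAnnotation, annotate_environment
from .structure import (
    distance_matrix,
    map_columns_to_residues,
    read_structure,
    spatial_filter,
    write_annotated_structure,
)

log = logging.getLogger("coevonet")

METHOD_ALIASES = {"mip": "MIp", "mcbasc": "McBASC", "dca": "DCA", "psicov": "PSICOV"}


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published protocol."""

    methods: tuple[str, ...] = ("MIp", "McBASC", "DCA", "PSICOV")
    z_cutoff: float = 4.0
    max_distance: float = 10.0
    min_separation: int = 6
    hcc_threshold: int = 3
    site_bin_widths: tuple[int, ...] = (1, 5)
    family_bin_width: int = 40
    null_draws: int = 10
    min_length: int = 100
    min_sequences: int = 51
    identity_threshold: float = 0.8
    dca_pseudocount: float = 0.5
    psicov_regularization: float = 0.003
    psicov_shrinkage: float = 0.3
    mi_min_joint_count: int = 20
    distance_mode: str = "min_heavy"
    conservation_matrix: str = "blosum62"
    seed: int = 0
    out_dir: Optional[Path] = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
        return d


def score_alignment(
    a, methods: Sequence[str], cfg: RunConfig
) -> dict[str, ScoreMatrix]:
    """Raw score matrices for the requested methods (weights shared)."""
    weights, _ = sequence_weights(a, cfg.identity_threshold)
    out: dict[str, ScoreMatrix] = {}
    for m in methods:
        name = METHOD_ALIASES.get(m.lower(), m)
        if name == "MIp":
            out[name] = mip_score(a, weights, cfg.mi_min_joint_count)
        elif name == "McBASC":
            out[name] = mcbasc_score(a)
        elif name == "DCA":
            out[name] = dca_direct_information(
                a, cfg.identity_threshold, cfg.dca_pseudocount, weights=weights
            )
        elif name == "PSICOV":
            out[name] = psicov_score(
                a,
                regularization=cfg.psicov_regularization,
                shrinkage=cfg.psicov_shrinkage,
                weights=weights,
            )
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


@dataclass
class FamilyResult:
    family_id: str
    profile: "ConservationProfile"
    gapless: set[int]
    pairs_raw: dict[str, list[SignificantPair]]
    pairs_filtered: dict[str, list[SignificantPair]]
    filter_counts: dict[str, tuple[int, int]]  # method -> (kept, total)
    degrees: dict[str, dict[int, int]]
    site_regressions: dict[str, dict[int, Optional[RegressionResult]]]
    site_scatter: dict[str, Optional[RegressionResult]]
    environment_contrasts: dict[str, dict[str, "EnvironmentContrast"]]
    null_ensembles: dict[str, Optional[NullEnsemble]]
    summaries: dict[str, FamilySummary]
    environment: Optional[EnvironmentAnnotation]
    column_map: "ColumnResidueMap"


def _has_backbone(s) -> bool:
    full = sum(
        1 for r in s.residues if all(n in r.atoms for n in ("N", "CA", "C", "O"))
    )
    return full >= 0.5 * len(s.residues)


def run_family(
    fam: FamilyRecord,
    cfg: RunConfig,
    structure=None,
    out_dir: Optional[Path] = None,
) -> FamilyResult:
    """Full per-family analysis; raises on validation or mapping failure."""
    a = fam.alignment
    report = validate_family(a, cfg.min_length, cfg.min_sequences, fam.family_id)
    if not report.passed:
        raise ValueError(
            f"family {fam.family_id} fails admission: {report.reasons}"
        )
    if structure is None:
        structure = read_structure(fam.structure_path, fam.chain)
    cmap = map_columns_to_residues(a, fam.representative_id, structure)
    dmat = distance_matrix(structure, cfg.distance_mode)

    profile = conservation_profile(
        a, cfg.conservation_matrix, cfg.identity_threshold
    )
    gapless = gapless_columns(a)
    environment = annotate_environment(structure) if _has_backbone(structure) else None

    raw_scores = score_alignment(a, cfg.methods, cfg)
    pairs_raw, pairs_filtered, counts = {}, {}, {}
    degrees, site_regs, site_scatter, nulls, summaries = {}, {}, {}, {}, {}
    env_contrasts: dict[str, dict] = {}
    for name, raw in raw_scores.items():
        z = zscore_standardize(raw)
        sel = select_significant_pairs(z, cfg.z_cutoff, cfg.min_separation)
        pairs_raw[name] = sel
        filt = spatial_filter(sel, cmap, structure, cfg.max_distance,
                              cfg.distance_mode, dmat)
        pairs_filtered[name] = filt.kept
        counts[name] = (filt.n_kept, filt.total)
        deg = site_degrees(filt.kept)
        degrees[name] = deg
        regs: dict[int, Optional[RegressionResult]] = {}
        for w in cfg.site_bin_widths:
            try:
                regs[w] = degree_ci_regression(deg, profile, w)
            except ValueError:
                regs[w] = None
        site_regs[name] = regs
        try:
            site_scatter[name] = degree_ci_scatter(deg, profile)
        except ValueError:
            site_scatter[name] = None
        if environment is not None and filt.kept:
            env_contrasts[name] = {
                feature: environment_contrast(
                    filt.kept, cmap, environment, profile, feature,
                    cfg.hcc_threshold,
                )
                for feature in ("burial", "hbond", "ss")
            }
        if filt.kept:
            try:
                nulls[name] = sample_null_pairs(
                    cmap, structure, filt.kept, n_pairs=len(filt.kept),
                    n_draws=cfg.null_draws, seed=cfg.seed,
                    profile=profile, bin_width=cfg.site_bin_widths[0],
                    max_distance=cfg.max_distance,
                    min_separation=cfg.min_separation, dmat=dmat,
                )
            except ValueError as exc:
                log.warning("family %s %s: null unavailable (%s)",
                            fam.family_id, name, exc)
                nulls[name] = None
        else:
            nulls[name] = None
        summaries[name] = family_summary(
            fam.family_id, name, filt.kept, profile, gapless
        )
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_score_tsv(raw, z, out_dir / f"{name}_scores.tsv")
            write_pairs_tsv(
                filt.kept,
                out_dir / f"{name}_pairs.tsv",
                header_note=(
                    f"{filt.n_kept} (out of {filt.total}) significant pairs "
                    f"within {cfg.max_distance} A"
                ),
            )
    if out_dir is not None:
        write_profile_tsv(profile, a, out_dir / "conservation.tsv")
        if environment is not None:
            from .secondary import write_environment_tsv

            write_environment_tsv(environment, structure,
                                  out_dir / "environment.tsv")
        from .connectivity import write_null_report_tsv

        for name, ne in nulls.items():
            if ne is not None:
                write_null_report_tsv(ne, out_dir / f"{name}_null.tsv")
        all_pairs = [p for ps in pairs_filtered.values() for p in ps]
        write_annotated_structure(
            structure, profile, cmap, all_pairs,
            out_dir / "annotated.pdb", out_dir / "edges.tsv",
        )
        _write_site_table(out_dir / "sites.tsv", fam.family_id, degrees,
                          profile, cmap, environment, cfg.hcc_threshold)
    return FamilyResult(
        fam.family_id, profile, gapless, pairs_raw, pairs_filtered, counts,
        degrees, site_regs, site_scatter, env_contrasts, nulls, summaries,
        environment, cmap,
    )


def _write_site_table(path, family_id, degrees, profile, cmap, env, hcc_thr):
    with open(path, "w") as fh:
        fh.write(
            "family\tmethod\tcolumn\tresidue\tdegree\tci\trel_acc\tstate\t"
            "ss\thbonded\thcc_lcc\n"
        )
        for method, deg in degrees.items():
            for col in sorted(deg):
                ridx = cmap.col_to_res.get(col)
                ci = "" if profile.gap_mask[col] else f"{profile.ci[col]:.4g}"
                if env is not None and ridx is not None:
                    rel = env.relative_accessibility[ridx]
                    rel_s = "" if np.isnan(rel) else f"{rel:.3f}"
                    state = env.state(ridx) if not np.isnan(rel) else ""
                    ss = str(env.ss_class[ridx])
                    hb = str(int(env.hbonded[ridx]))
                else:
                    rel_s = state = ss = hb = ""
                label = "HCC" if deg[col] > hcc_thr else "LCC"
                fh.write(
                    f"{family_id}\t{method}\t{col + 1}\t"
                    f"{'' if ridx is None else ridx + 1}\t{deg[col]}\t{ci}\t"
                    f"{rel_s}\t{state}\t{ss}\t{hb}\t{label}\n"
                )


@dataclass
class CohortResult:
    families: list[FamilyResult]
    failed: dict[str, str]
    summaries: dict[str, list[FamilySummary]]
    regressions: dict[str, RegressionResult]
    stratified: Optional[dict[str, pd.DataFrame]]
    overlap: Optional[pd.DataFrame]


def run_cohort(
    records: Sequence[FamilyRecord],
    cfg: RunConfig,
    structures: Optional[dict[str, object]] = None,
    go_table: Optional[pd.DataFrame] = None,
    out_dir: Optional[Path] = None,
) -> CohortResult:
    """Analyse every family, then the cohort-level regressions."""
    results, failed = [], {}
    summaries: dict[str, list[FamilySummary]] = {}
    for rec in records:
        try:
            fam_out = (
                Path(out_dir) / rec.family_id if out_dir is not None else None
            )
            structure = (structures or {}).get(rec.family_id)
            res = run_family(rec, cfg, structure=structure, out_dir=fam_out)
        except Exception as exc:  # noqa: BLE001 - cohort continues
            log.warning("family %s failed: %s", rec.family_id, exc)
            failed[rec.family_id] = str(exc)
            continue
        results.append(res)
        for m, s in res.summaries.items():
            summaries.setdefault(m, []).append(s)
    if not results:
        raise RuntimeError("no family succeeded")

    regressions = {}
    for m, summ in summaries.items():
        try:
            regressions[m] = cohort_regression(summ, cfg.family_bin_width)
        except ValueError as exc:
            log.warning("cohort regression for %s unavailable: %s", m, exc)

    stratified = None
    if go_table is not None:
        stratified = {}
        for domain in sorted(go_table["domain"].unique()):
            for m, summ in summaries.items():
                stratified[f"{domain}:{m}"] = stratified_regression(
                    summ, go_table, domain, cfg.family_bin_width
                )

    overlap = None
    if len(cfg.methods) >= 2:
        pooled: dict[str, list[SignificantPair]] = {m: [] for m in summaries}
        for res in results:
            for m, ps in res.pairs_filtered.items():
                pooled[m].extend(
                    SignificantPair(p.i, p.j, p.method, p.z) for p in ps
                )
        overlap = method_overlap(pooled)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "family_id": s.family_id, "method": s.method,
                "n_pairs": s.n_pairs, "n_coevolved_sites": s.n_coevolved_sites,
                "mean_ci": s.mean_ci,
            }
            for ss in summaries.values() for s in ss
        ]
        pd.DataFrame(rows).to_csv(out_dir / "family_summaries.tsv",
                                  sep="\t", index=False)
        reg_rows = [
            {"method": m, "slope": r.slope, "intercept": r.intercept,
             "r_squared": r.r_squared, "n_bins": r.n_points}
            for m, r in regressions.items()
        ]
        pd.DataFrame(reg_rows).to_csv(out_dir / "cohort_regressions.tsv",
                                      sep="\t", index=False)
        if overlap is not None:
            overlap.to_csv(out_dir / "method_overlap.tsv", sep="\t")
        manifest = {
            "config": cfg.to_dict(),
            "n_families": len(results),
            "failed": failed,
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2)
        )
    return CohortResult(results, failed, summaries, regressions, stratified, overlap)
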