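"""End-to-end orchestration: samples -> individuals -> dyads -> tests -> report.

The report structure follows the analysis battery: individual and dyad
summaries, crossing-proportion tests (with the random-direction null),
distance ANOVA + Tukey, direction and angle tests, the multi-location
Fisher table, and per-sex spatial PCA summaries. Identical seeds and inputs
produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import identity, relatedness, spatial, stats
from .geometry import RiverSet
from .records import Dyad, Individual, Panel, SampleRecord
from .io import json_default, write_dyads_table, write_individuals_table

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Thresholds and replicate counts for a full analysis run."""

    max_mismatch: int = 12
    min_comparable_loci: int = 60
    r_threshold: float = 0.4
    min_shared_loci: int = 40
    long_dispersal_km: float = 25.0
    null_reps: int = 1000
    spca_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    reference_azimuth_deg: float | None = None  # override river-file value
    run_spca: bool = True

    def validate(self) -> None:
        if min(self.max_mismatch, self.min_comparable_loci, self.min_shared_loci) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.null_reps < 1 or self.spca_permutations < 19:
            raise ValueError("replicate counts too small")


def _report(t: stats.TestReport) -> dict:
    return asdict(t)


def run_analysis(
    records: list[SampleRecord],
    rivers: RiverSet,
    config: PipelineConfig,
    panel: Panel | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full pipeline and return (and optionally write) the report."""
    config.validate()
    if config.reference_azimuth_deg is not None:
        rivers = RiverSet(
            names=rivers.names,
            lines=rivers.lines,
            reference_azimuth_deg=config.reference_azimuth_deg,
            extent=rivers.extent,
        )
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": asdict(config),
        "n_samples": len(records),
    }

    # --- identification ---------------------------------------------------
    individuals, sample_map = identity.cluster_samples(
        records,
        max_mismatch=config.max_mismatch,
        min_comparable_loci=config.min_comparable_loci,
    )
    by_sex = {
        s: [i for i in individuals if i.sex == s] for s in ("M", "F", "ambiguous")
    }
    report["individuals"] = {
        "total": len(individuals),
        "males": len(by_sex["M"]),
        "females": len(by_sex["F"]),
        "sex_ambiguous": len(by_sex["ambiguous"]),
        "multi_sample": sum(i.n_samples > 1 for i in individuals),
    }

    # --- dyads ------------------------------------------------------------
    freqs = relatedness.estimate_allele_frequencies(individuals)
    dyads = relatedness.build_dyads(
        individuals,
        freqs,
        rivers,
        r_threshold=config.r_threshold,
        min_shared_loci=config.min_shared_loci,
    )
    classes = {c: [d for d in dyads if d.sex_class == c] for c in ("MM", "FF", "MF")}
    report["dyads"] = {c: len(v) for c, v in classes.items()} | {"total": len(dyads)}

    # --- H1: crossing proportions + random-direction null ------------------
    def crossing_summary(ds: list[Dyad]) -> dict:
        n = len(ds)
        crossed = sum(d.rivers_crossed >= 1 for d in ds)
        by_count = {}
        for d in ds:
            by_count[str(d.rivers_crossed)] = by_count.get(str(d.rivers_crossed), 0) + 1
        return {
            "n": n,
            "n_crossed": crossed,
            "proportion_crossed": crossed / n if n else None,
            "by_crossing_count": dict(sorted(by_count.items())),
        }

    report["crossings"] = {c: crossing_summary(classes[c]) for c in ("MM", "FF", "MF")}
    mm, ff = classes["MM"], classes["FF"]
    if mm and ff:
        report["h1_yates_chi2"] = _report(
            stats.crossing_proportion_test(
                sum(d.rivers_crossed >= 1 for d in mm), len(mm),
                sum(d.rivers_crossed >= 1 for d in ff), len(ff),
            )
        )
    else:
        report["h1_yates_chi2"] = None

    if ff and len(rivers):
        centers = {i.individual_id: i.center for i in individuals}
        # known female dispersers: members of FF dyads, both endpoints
        pool_ids = sorted({d.id_a for d in ff} | {d.id_b for d in ff})
        pool = np.array([centers[i] for i in pool_ids])
        ff_pos = [d for d in ff if d.distance_km > 0]
        if ff_pos:
            obs_prop = sum(d.rivers_crossed >= 1 for d in ff) / len(ff)
            null = stats.simulate_null_crossings(
                pool,
                [d.distance_km for d in ff_pos],
                rivers,
                n_dyads=len(ff_pos),
                observed_proportion=obs_prop,
                reps=config.null_reps,
                seed=config.seed,
                extent=rivers.extent,
            )
            nd = asdict(null)
            nd["replicate_proportions"] = None  # keep the report compact
            nd["observed_below_lower_2p5"] = bool(
                null.observed_proportion < null.lower_2p5_percentile
            )
            report["h1_null_simulation"] = nd
        else:
            report["h1_null_simulation"] = None
    else:
        report["h1_null_simulation"] = None

    # --- H1 follow-up: multiply-located individuals (Fisher) ---------------
    table = stats.multilocation_crossing_table(individuals, rivers)
    report["multilocation_table"] = table.tolist()
    margins_ok = table.sum() > 0 and all(
        m not in (0, table.sum()) for m in (table[0].sum(), table[:, 0].sum())
    )
    if margins_ok:
        report["h1_fisher_exact"] = asdict(stats.fisher_exact_or(table))
    else:
        report["h1_fisher_exact"] = None

    # --- H2: distances ------------------------------------------------------
    groups = {
        c: np.array([d.distance_km for d in classes[c]]) for c in ("MM", "FF", "MF")
    }
    try:
        anova, tukey = stats.distance_anova_tukey(groups)
        report["h2_anova"] = _report(anova)
        report["h2_tukey"] = tukey
    except ValueError as e:
        logger.warning("distance ANOVA skipped: %s", e)
        report["h2_anova"] = report["h2_tukey"] = None

    # --- H3/H4: directions and angles --------------------------------------
    def directed(ds: list[Dyad]):
        return [d for d in ds if d.direction is not None]

    mm_dir, ff_dir = directed(mm), directed(ff)
    report["h3_direction_mm"] = (
        _report(
            stats.direction_proportion_test(
                sum(d.direction == "D1" for d in mm_dir), len(mm_dir), "two-sided"
            )
        )
        if mm_dir
        else None
    )
    report["h4_direction_ff"] = (
        _report(
            stats.direction_proportion_test(
                sum(d.direction == "D1" for d in ff_dir), len(ff_dir), "less"
            )
        )
        if ff_dir
        else None
    )
    if mm_dir and ff_dir:
        mm_ang = [d.angle_deg for d in mm_dir]
        ff_ang = [d.angle_deg for d in ff_dir]
        mm_d = [d.distance_km for d in mm_dir]
        ff_d = [d.distance_km for d in ff_dir]
        report["h4_ks_all"] = _report(stats.angle_distribution_test(mm_ang, ff_ang))
        try:
            report["h4_ks_long"] = _report(
                stats.angle_distribution_test(
                    mm_ang, ff_ang, mm_d, ff_d, min_distance_km=config.long_dispersal_km
                )
            )
        except ValueError as e:
            logger.warning("long-dispersal KS skipped: %s", e)
            report["h4_ks_long"] = None
    else:
        report["h4_ks_all"] = report["h4_ks_long"] = None

    # --- H5: spatial PCA per sex -------------------------------------------
    report["h5_spca"] = {}
    for sex in ("M", "F") if config.run_spca else ():
        inds = by_sex[sex]
        if len(inds) < 10:
            report["h5_spca"][sex] = None
            continue
        coords = np.array([i.center for i in inds])
        X = np.stack([i.consensus for i in inds]).astype(float)
        net = spatial.build_network(coords, seed=config.seed)
        res = spatial.spca(X, net)
        gp, lp = spatial.global_local_tests(
            X, net, n_permutations=config.spca_permutations, seed=config.seed
        )
        lead = int(np.argmax(res.eigenvalues))
        report["h5_spca"][sex] = {
            "n_individuals": len(inds),
            "leading_eigenvalue": float(res.eigenvalues[lead]),
            "leading_axis_moran_i": float(res.axis_moran[lead]),
            "pct_variance_axis1": float(
                100.0 * res.axis_variance[lead] / res.axis_variance.sum()
            ),
            "global_p": gp,
            "local_p": lp,
            "n_permutations": config.spca_permutations,
        }

    # --- outputs ------------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_individuals_table(individuals, out / "individuals.csv")
        write_dyads_table(dyads, out / "dyads.csv")
        with open(out / "sample_to_individual.json", "w") as fh:
            json.dump(sample_map, fh, indent=1, sort_keys=True)
        _export_dapc_inputs(individuals, rivers, out)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=json_default)
    return report


def _export_dapc_inputs(individuals: list[Individual], rivers: RiverSet, out: Path) -> None:
    """Genotype matrix + river-band region labels for external multivariate
    tools (e.g. discriminant analyses run off-the-shelf elsewhere)."""
    from .geometry import band_index
    import pandas as pd

    rows = []
    for ind in individuals:
        rows.append(
            {
                "individual_id": ind.individual_id,
                "sex": ind.sex,
                "region": band_index(ind.center, rivers) + 1,
                **{
                    f"L{l + 1:03d}": (int(c) if c >= 0 else "")
                    for l, c in enumerate(ind.consensus)
                },
            }
        )
    pd.DataFrame(rows).to_csv(out / "genotype_matrix_regions.csv", index=False)
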