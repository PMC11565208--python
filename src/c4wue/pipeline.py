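"""End-to-end orchestration of the three phenotyping phases.

Ties the stages together the way the greenhouse campaign was run:
(1) leaf-level gas exchange and stomatal patterning on young fully
expanded leaves, (2) a gravimetric dry-down with daily pot weighings,
(3) harvest traits.  ``simulate_dataset`` writes a complete synthetic
dataset (CSVs + manifest); ``analyze_dataset`` runs fits, limitation
summaries, water budgets, stomatal summaries, and the statistics,
writing per-stage CSVs and a plain-text report.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from c4wue import __version__
from c4wue.c4_model import (
    C4Params,
    GS_H2O_TO_CO2,
    OperatingPoint,
    OperatingPointSource,
    solve_operating_point,
    stomatal_limitation,
)
from c4wue.aci_fit import (
    FitConfig,
    curves_from_frame,
    fit_aci,
    fits_to_frame,
    read_gas_exchange_csv,
    validate_protocol,
)
from c4wue.expstats import lsmeans_se, one_way_anova, per_day_posthoc, tukey_hsd, two_way_anova
from c4wue.stomata import read_counts_csv, read_measures_csv, summarize_counts, complex_size_summary
from c4wue.synthdata import (
    DEFAULT_EFFECTS,
    BASE_PARAMS,
    DryDownConfig,
    SimConfig,
    sim_aci_panel,
    sim_drydown,
    sim_leaf_areas,
    sim_stomatal_fields,
)
from c4wue.water_budget import (
    read_leaf_area_csv,
    read_pot_mass_csv,
    read_pot_reference_csv,
    rswc_series,
    series_to_frame,
)

logger = logging.getLogger("c4wue")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    ambient_ca: float = 400.0
    kp: float = 80.0
    rd: float = 2.0
    alpha: float = 0.05
    n_plants: int = 10
    noise_cv_a: float = 0.02
    noise_cv_gs: float = 0.05

    def __post_init__(self) -> None:
        if self.kp <= 0:
            raise ValueError(f"kp must be positive, got {self.kp}")
        if self.rd < 0:
            raise ValueError(f"rd must be non-negative, got {self.rd}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def simulate_dataset(config: RunConfig) -> dict[str, Path]:
    """Write a full synthetic experiment to ``config.output_dir``.

    Produces gas-exchange, pot-mass, pot-reference, stomatal-count,
    complex-measure, and leaf-area CSVs plus a JSON manifest carrying
    the seed and parameters needed to reproduce the run bit-for-bit.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = C4Params(vpmax=BASE_PARAMS.vpmax, vmax=BASE_PARAMS.vmax, kp=config.kp, rd=config.rd)
    sim_cfg = SimConfig(
        seed=config.seed, n_plants=config.n_plants, noise_cv_a=config.noise_cv_a,
        noise_cv_gs=config.noise_cv_gs, ambient_ca=config.ambient_ca,
    )
    paths: dict[str, Path] = {}

    gas = sim_aci_panel(DEFAULT_EFFECTS, base, sim_cfg)
    paths["gas_exchange"] = out / "gas_exchange.csv"
    gas.to_csv(paths["gas_exchange"], index=False)

    masses, refs = sim_drydown(DEFAULT_EFFECTS, DryDownConfig(n_pots=config.n_plants), seed=config.seed + 1)
    paths["pot_mass"] = out / "pot_mass.csv"
    pd.DataFrame([m.__dict__ for m in masses]).to_csv(paths["pot_mass"], index=False)
    paths["pot_reference"] = out / "pot_reference.csv"
    pd.DataFrame([r.__dict__ for r in refs]).to_csv(paths["pot_reference"], index=False)

    rng = np.random.default_rng(config.seed + 2)
    all_counts, all_measures = [], []
    for effect in DEFAULT_EFFECTS:
        c, m = sim_stomatal_fields(effect, n_plants=config.n_plants, rng=rng)
        all_counts.extend(c)
        all_measures.extend(m)
    paths["stomatal_counts"] = out / "stomatal_counts.csv"
    pd.DataFrame([c.__dict__ for c in all_counts]).to_csv(paths["stomatal_counts"], index=False)
    paths["complex_measures"] = out / "complex_measures.csv"
    pd.DataFrame([m.__dict__ for m in all_measures]).to_csv(paths["complex_measures"], index=False)

    paths["leaf_area"] = out / "leaf_area.csv"
    sim_leaf_areas(DEFAULT_EFFECTS, n_plants=config.n_plants, seed=config.seed + 3).to_csv(
        paths["leaf_area"], index=False
    )

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "ambient_ca": config.ambient_ca,
        "kp": config.kp,
        "rd": config.rd,
        "n_plants": config.n_plants,
        "noise_cv_a": config.noise_cv_a,
        "noise_cv_gs": config.noise_cv_gs,
        "genotypes": [e.name for e in DEFAULT_EFFECTS],
        "files": {k: p.name for k, p in paths.items()},
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("simulated dataset written to %s", out)
    return paths


def analyze_dataset(data_dir: Path, config: RunConfig) -> dict[str, Path]:
    """Run the full analysis over a dataset directory.

    Stages: A/ci fits -> limitation summaries -> water budgets ->
    stomatal summaries -> statistics.  A missing pot-reference file
    skips the water stage with a warning; everything else completes.
    """
    data_dir = Path(data_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: list[str] = [f"c4wue analysis report (v{__version__})", "=" * 40, ""]
    outputs: dict[str, Path] = {}

    # ---- Stage 1: A/ci fits and limitation summaries -------------------
    gas = read_gas_exchange_csv(data_dir / "gas_exchange.csv")
    curves = curves_from_frame(gas)
    fit_cfg = FitConfig(kp_fixed=config.kp, rd_fixed=config.rd, seed=config.seed)
    fits, genotypes, lim_rows = {}, {}, []
    for plant_id, curve in curves.items():
        _, msgs = validate_protocol(curve)
        for m in msgs:
            logger.warning("%s: %s", plant_id, m)
            report.append(f"WARNING {plant_id}: {m}")
        fit = fit_aci(curve, fit_cfg)
        fits[plant_id] = fit
        genotypes[plant_id] = curve[0].genotype
        if not fit.identifiable_vmax:
            msg = f"{plant_id}: saturation never observed; vmax not identifiable, excluded from vmax comparisons"
            logger.warning(msg)
            report.append(f"WARNING {msg}")
        amb = [o for o in curve if abs(o.ca_sample - config.ambient_ca) <= 0.05 * config.ambient_ca]
        if amb:
            ci_op = float(np.mean([o.ci for o in amb]))
            a_op = float(np.mean([o.a_n for o in amb]))
            gs_op = float(np.mean([o.gs for o in amb]))
            op = OperatingPoint(ci_op=ci_op, a_op=a_op, source=OperatingPointSource.OBSERVED_MEAN)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lim = stomatal_limitation(op, fit.params, config.ambient_ca, gs=gs_op)
            lim_rows.append({
                "plant_id": plant_id, "genotype": genotypes[plant_id],
                "sl": lim.sl, "ci_op": ci_op, "a_op": a_op, "gs_op": gs_op,
                "iwue": lim.iwue, "ci_inflection": lim.ci_inflection,
                "above_inflection": lim.above_inflection,
            })
    fits_df = fits_to_frame(fits, genotypes)
    outputs["fits"] = out / "aci_fits.csv"
    fits_df.to_csv(outputs["fits"], index=False)
    lim_df = pd.DataFrame(lim_rows)
    outputs["limitation"] = out / "limitation.csv"
    lim_df.to_csv(outputs["limitation"], index=False)

    report.append("A/ci fits: one row per plant in aci_fits.csv")
    report.append("\nStomatal limitation (SL) per genotype:")
    for g, sub in lim_df.groupby("genotype"):
        report.append(f"  {g}: SL = {sub['sl'].mean():.3f} (n={len(sub)}), iWUE = {sub['iwue'].mean():.1f}")

    # Genotype comparisons of fitted parameters and iWUE.
    report.append("\nGenotype comparisons (one-way ANOVA + Tukey HSD):")
    stats_rows = []
    for trait, frame in [("vpmax", fits_df), ("vmax", fits_df[fits_df["identifiable_vmax"]]), ("iwue", lim_df), ("sl", lim_df)]:
        if frame["genotype"].nunique() < 2 or len(frame) - frame["genotype"].nunique() < 1:
            continue
        aov = one_way_anova(frame, trait, "genotype")
        tk = tukey_hsd(frame, trait, "genotype", alpha=config.alpha)
        ls = lsmeans_se(frame, trait, ["genotype"])
        p = aov.loc["genotype", "p"]
        report.append(f"  {trait}: F = {aov.loc['genotype', 'F']:.2f}, p = {p:.3g}; letters: {tk.letters}")
        for r in ls.itertuples():
            stats_rows.append({"trait": trait, "genotype": r.genotype, "lsmean": r.lsmean, "se": r.se,
                               "letter": tk.letters.get(r.genotype, "")})
    outputs["genotype_lsmeans"] = out / "genotype_lsmeans.csv"
    pd.DataFrame(stats_rows).to_csv(outputs["genotype_lsmeans"], index=False)

    # ---- Stage 2: water budget -----------------------------------------
    ref_path = data_dir / "pot_reference.csv"
    mass_path = data_dir / "pot_mass.csv"
    if mass_path.exists() and ref_path.exists():
        pots = read_pot_mass_csv(mass_path)
        refs = read_pot_reference_csv(ref_path)
        series = []
        for pot_id, recs in pots.items():
            if pot_id not in refs:
                logger.warning("pot %s has no reference masses; skipped", pot_id)
                report.append(f"WARNING pot {pot_id}: no reference masses; skipped")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                series.append(rswc_series(recs, refs[pot_id]))
        water_df = series_to_frame(series)
        outputs["water"] = out / "soil_water.csv"
        water_df.to_csv(outputs["water"], index=False)
        posthoc = per_day_posthoc(water_df[water_df["day"] > 0], "rswc", "genotype", alpha=config.alpha)
        outputs["water_posthoc"] = out / "soil_water_posthoc.csv"
        posthoc.to_csv(outputs["water_posthoc"], index=False)
        sig_days = sorted(int(d) for d in posthoc.loc[posthoc["significant"], "day"].unique())
        report.append(f"\nDry-down: per-day Tukey flags; genotypes differ in rSWC on days {sig_days}")
    else:
        logger.warning("pot mass/reference files missing; water-budget stage skipped")
        report.append("\nWARNING water-budget stage skipped (missing pot mass or reference CSV)")

    # ---- Stage 3: stomatal patterning ----------------------------------
    counts_path = data_dir / "stomatal_counts.csv"
    if counts_path.exists():
        counts = read_counts_csv(counts_path)
        dens = summarize_counts(counts)
        outputs["stomatal_density"] = out / "stomatal_density.csv"
        dens.to_csv(outputs["stomatal_density"], index=False)
        if dens["genotype"].nunique() >= 2:
            aov2 = two_way_anova(dens, "density", "genotype", "surface")
            report.append("\nStomatal density two-way ANOVA (genotype x surface):")
            for term in aov2.index[:-1]:
                report.append(f"  {term}: F = {aov2.loc[term, 'F']:.2f}, p = {aov2.loc[term, 'p']:.3g}")
        mpath = data_dir / "complex_measures.csv"
        if mpath.exists():
            sizes = complex_size_summary(read_measures_csv(mpath))
            outputs["complex_sizes"] = out / "complex_sizes.csv"
            sizes.to_csv(outputs["complex_sizes"], index=False)

    # ---- Stage 4: leaf area --------------------------------------------
    la_path = data_dir / "leaf_area.csv"
    if la_path.exists():
        areas = read_leaf_area_csv(la_path)
        outputs["leaf_area"] = out / "total_leaf_area.csv"
        areas.to_csv(outputs["leaf_area"], index=False)

    outputs["report"] = out / "report.txt"
    outputs["report"].write_text("\n".join(report) + "\n")
    manifest = {
        "version": __version__, "seed": config.seed, "ambient_ca": config.ambient_ca,
        "kp": config.kp, "rd": config.rd, "alpha": config.alpha,
        "inputs": str(data_dir), "outputs": {k: p.name for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return outputs


def sl_scenario(
    params: C4Params, gs_reduction: float, *, ca: float = 400.0, gs_co2: float | None = None,
    initial_ci: float | None = None,
) -> dict[str, float]:
    """Stomatal limitation before and after a fractional g_s reduction.

    Starting from ``gs_co2`` (or the conductance that puts the
    operating ci at ``initial_ci``), the operating point is re-solved
    at gs_co2·(1 − reduction) and SL reported at both, together with
    the change ΔSL.  This is the leaf-level "how much g_s can be
    removed for free" experiment: while both operating points sit on
    the saturated branch of the A/ci curve, ΔSL is exactly zero.
    """
    if not 0.0 <= gs_reduction < 1.0:
        raise ValueError(f"gs_reduction must be in [0, 1), got {gs_reduction}")
    if (gs_co2 is None) == (initial_ci is None):
        raise ValueError("provide exactly one of gs_co2 or initial_ci")
    if gs_co2 is None:
        from c4wue.c4_model import predict_a

        a0 = predict_a(initial_ci, params)
        if a0 <= 0 or initial_ci >= ca:
            raise ValueError("initial_ci must give positive assimilation below ca")
        gs_co2 = a0 / (ca - initial_ci)
    op0 = solve_operating_point(gs_co2, ca, params)
    op1 = solve_operating_point(gs_co2 * (1.0 - gs_reduction), ca, params)
    if not (op0.positive_a and op1.positive_a):
        raise ValueError("operating point at or below compensation; SL undefined")
    sl0 = stomatal_limitation(op0, params, ca).sl
    sl1 = stomatal_limitation(op1, params, ca).sl
    return {
        "gs_co2_before": gs_co2, "gs_co2_after": gs_co2 * (1.0 - gs_reduction),
        "ci_before": op0.ci_op, "ci_after": op1.ci_op,
        "a_before": op0.a_op, "a_after": op1.a_op,
        "sl_before": sl0, "sl_after": sl1, "delta_sl": sl1 - sl0,
    }
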