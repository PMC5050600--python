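"""Pipeline stages: file-to-file steps shared by the CLI and the numbered
analysis scripts.  Every stage reads and writes plain CSV so any stage can
be re-run standalone."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import config as cfgmod
from . import defaults, icpms, ionome_stats, roots, simulate
from .discriminant import canonical_projection, forward_select, steps_frame
from .io import (
    ICPMS_SCHEMA, ROOT_SCHEMA, TRAIT_MATRIX_SCHEMA, read_table, write_table,
)
from .panel import assemble_panel, panel_frame
from .varcomp import (
    composition_model_spec, fit_varcomp, genotype_means, root_model_spec,
)

log = logging.getLogger("napus_phenomics")


def stage_simulate(cfg: dict, seed: int, outdir: str | Path) -> dict[str, Path]:
    """Generate the full synthetic study: panel, root screen, polytunnel
    pots with TSW/seed yield, and leaf + seed ICP-MS run tables."""
    outdir = Path(outdir)
    rng = np.random.default_rng(seed)
    model = simulate.GenerativeModel(
        drift_amplitude=float(cfg["icpms"]["drift_amplitude"]),
        attrition_rate=float(cfg["attrition_rate"]),
    )
    panel = assemble_panel(cfgmod.panel_config(cfg))
    paths: dict[str, Path] = {}
    paths["genotypes"] = write_table(panel_frame(panel),
                                     outdir / "genotypes.csv")

    # Root screen: core genotypes only (the polytunnel fillers are not sown)
    core = [g for g in panel if g.role.value != "filler"]
    layout = simulate.build_pouch_layout(cfgmod.pouch_design(cfg))
    records = simulate.simulate_root_traits(
        layout, model, seed=int(rng.integers(2**31)), panel=core)
    paths["root_records"] = write_table(records, outdir / "root_records.csv")

    pots = simulate.build_polytunnel_layout(
        panel, cfgmod.polytunnel_design(cfg), seed=int(rng.integers(2**31)))
    plant = simulate.simulate_plant_traits(
        pots, model, seed=int(rng.integers(2**31)))
    paths["pots"] = write_table(plant, outdir / "pots.csv")

    ic = cfg["icpms"]
    for tissue, n_runs, n_samples in (
        ("leaf", int(ic["leaf_runs"]), int(ic["leaf_samples"])),
        ("seed", int(ic["seed_runs"]), int(ic["seed_samples"])),
    ):
        run_size = cfgmod.run_size_for(n_samples, n_runs)
        runs = simulate.simulate_icpms_runs(
            pots, model, run_size=run_size, seed=int(rng.integers(2**31)),
            tissue=tissue, n_samples=n_samples,
        )
        paths[f"icpms_{tissue}"] = write_table(
            runs, outdir / f"icpms_{tissue}.csv")
    return paths


def stage_root_traits(
    root_csv: str | Path, outdir: str | Path, min_radicle_cm: float | None = None
) -> dict[str, Path]:
    """Seedling QC, trait derivation and the attrition report."""
    outdir = Path(outdir)
    records = read_table(root_csv, ROOT_SCHEMA)
    kwargs = {} if min_radicle_cm is None else {"min_radicle_cm": min_radicle_cm}
    kept, exclusions = roots.qc_seedlings(records, **kwargs)
    traits = roots.derive_root_traits(kept)
    report = roots.attrition_report(records, exclusions)
    return {
        "root_traits": write_table(traits, outdir / "root_traits.csv"),
        "exclusions": write_table(exclusions, outdir / "root_exclusions.csv"),
        "attrition": write_table(report, outdir / "root_attrition.csv"),
    }


def stage_icpms_qc(
    icpms_csv: str | Path, tissue: str, outdir: str | Path, cfg: dict | None = None
) -> tuple[icpms.QcResult, dict[str, Path]]:
    """Full ICP-MS QC chain for one tissue; writes the concentration matrix,
    per-element QC report and LOD table."""
    cfg = cfg or cfgmod.load_config()
    outdir = Path(outdir)
    runs = read_table(icpms_csv, ICPMS_SCHEMA)
    monitored = (defaults.LEAF_ELEMENTS if tissue == "leaf"
                 else defaults.SEED_ELEMENTS)
    panel = icpms.ElementPanel(
        tissue=tissue, monitored=monitored,
        excluded=tuple(cfg["exclusion"][tissue]),
    )
    proto = defaults.PROTOCOLS[tissue]
    result = icpms.process_tissue(runs, panel, proto.notional_mass_g)
    conc = result.matrix.meta.join(result.matrix.values)
    conc.insert(0, "sample_id", result.matrix.values.index)
    lods = pd.DataFrame({"element": list(result.lods.lod),
                         "lod_mg_per_kg": list(result.lods.lod.values())})
    paths = {
        "concentrations": write_table(conc, outdir / f"{tissue}_conc.csv"),
        "qc_report": write_table(result.report,
                                 outdir / f"{tissue}_qc_report.csv"),
        "lods": write_table(lods, outdir / f"{tissue}_lods.csv"),
    }
    return result, paths


def stage_varcomp(
    traits_csv: str | Path,
    traits: list[str],
    model: str,
    outdir: str | Path,
    out_name: str = "varcomp.csv",
) -> pd.DataFrame:
    """REML decomposition for each trait; table in percent-of-variance
    layout (genotype, habit, experimental, seed diameter, residual)."""
    data = pd.read_csv(traits_csv)
    rows = []
    for trait in traits:
        spec = (root_model_spec(trait) if model == "root"
                else composition_model_spec(trait))
        dec = fit_varcomp(data, spec)
        row = {"trait": trait, **{k: round(v, 1)
                                  for k, v in dec.grouped_percents().items()},
               "n_iter": dec.n_iter}
        rows.append(row)
        log.info("varcomp %s: %s", trait, row)
    table = pd.DataFrame(rows)
    write_table(table, Path(outdir) / out_name)
    return table


def stage_genotype_means(
    root_csv: str | Path | None,
    leaf_csv: str | Path | None,
    seed_csv: str | Path | None,
    pots_csv: str | Path | None,
    outdir: str | Path,
) -> pd.DataFrame:
    """Genotype x trait matrix: fixed-genotype-model means for root and leaf
    traits, arithmetic means for seed traits and seed-weight traits."""
    pieces: list[pd.DataFrame] = []
    habit_maps: list[pd.Series] = []
    pots = pd.read_csv(pots_csv) if pots_csv is not None else None

    if root_csv is not None:
        root = pd.read_csv(root_csv)
        habit_maps.append(root.groupby("genotype_id")["habit"].first())
        cols = {}
        for trait in defaults.ROOT_TRAITS:
            cols[trait] = genotype_means(root, root_model_spec(trait),
                                         method="fixed_genotype_model")
        pieces.append(pd.DataFrame(cols))
    for tissue, path, wanted in (("leaf", leaf_csv, "fixed_genotype_model"),
                                 ("seed", seed_csv, "arithmetic_mean")):
        if path is None:
            continue
        conc = pd.read_csv(path)
        conc = conc[conc["genotype_id"].notna()]
        if pots is not None and "polytunnel" not in conc.columns:
            design = pots[["pot_id", "habit", "polytunnel", "replicate",
                           "sub_block"]]
            conc = conc.merge(design, on="pot_id", how="left")
        method = wanted
        if method == "fixed_genotype_model" and "polytunnel" not in conc.columns:
            method = "arithmetic_mean"
        elements = [c for c in conc.columns
                    if c in (defaults.LEAF_ELEMENTS + defaults.SEED_ELEMENTS)]
        cols = {}
        for el in elements:
            cols[f"{tissue}_{el}"] = genotype_means(
                conc, composition_model_spec(el), method=method)
        pieces.append(pd.DataFrame(cols))
    if pots is not None:
        habit_maps.append(pots.groupby("genotype_id")["habit"].first())
        cols = {}
        for trait in defaults.SEED_WEIGHT_TRAITS:
            if trait in pots.columns:
                spec = composition_model_spec(trait)
                cols[trait] = genotype_means(pots, spec,
                                             method="arithmetic_mean")
        pieces.append(pd.DataFrame(cols))

    matrix = pd.concat(pieces, axis=1)
    matrix.index.name = "genotype_id"
    habit = pd.concat(habit_maps).groupby(level=0).first() if habit_maps else None
    out = matrix.reset_index()
    if habit is not None:
        out.insert(1, "habit", out["genotype_id"].map(habit))
    ordered = [t for t in defaults.TRAIT_ORDER if t in out.columns]
    extras = [c for c in out.columns
              if c not in ordered and c not in ("genotype_id", "habit")]
    out = out[["genotype_id", "habit"] + ordered + extras]
    write_table(out, Path(outdir) / "genotype_means.csv")
    return out


def _load_matrix(matrix_csv: str | Path) -> pd.DataFrame:
    return read_table(matrix_csv, TRAIT_MATRIX_SCHEMA)


def stage_ratios(matrix_csv: str | Path, outdir: str | Path) -> pd.DataFrame:
    """Translocation ratios for the four element pairs, with habit
    box-plot summaries."""
    matrix = _load_matrix(matrix_csv).set_index("genotype_id")
    habits = matrix["habit"]
    frames = []
    for num, den in defaults.RATIO_PAIRS:
        spec = ionome_stats.RatioSpec(num, den)
        frames.append(ionome_stats.translocation_ratio(matrix, spec))
    ratios = pd.concat(frames)
    ratios.insert(0, "genotype_id", ratios.index)
    ratios.insert(1, "habit", habits.reindex(ratios.index).to_numpy())
    write_table(ratios, Path(outdir) / "translocation_ratios.csv")
    summary = ionome_stats.habit_ratio_summary(
        ratios.set_index("genotype_id").drop(columns=["habit"]), habits)
    write_table(summary, Path(outdir) / "translocation_habit_summary.csv")
    return ratios


def stage_correlate(matrix_csv: str | Path, outdir: str | Path) -> pd.DataFrame:
    """All-pairs Pearson correlations of the genotype-mean traits."""
    matrix = _load_matrix(matrix_csv).set_index("genotype_id")
    traits = [t for t in defaults.TRAIT_ORDER if t in matrix.columns]
    long = ionome_stats.correlation_matrix(matrix[traits])
    write_table(long, Path(outdir) / "correlations.csv")
    square = ionome_stats.correlation_square(long, traits)
    square.insert(0, "trait", square.index)
    write_table(square, Path(outdir) / "correlation_matrix.csv")
    return long


def stage_discriminate(
    matrix_csv: str | Path,
    variate_set: str,
    outdir: str | Path,
    max_steps: int | None = None,
) -> pd.DataFrame:
    """Stepwise discriminant analysis of crop habit for one variate set."""
    matrix = _load_matrix(matrix_csv).set_index("genotype_id")
    traits = [t for t in defaults.variate_sets()[variate_set]
              if t in matrix.columns]
    groups = matrix["habit"]
    steps = forward_select(matrix, groups, traits, max_steps=max_steps)
    table = steps_frame(steps)
    write_table(table, Path(outdir) / f"discriminant_{variate_set}_steps.csv")
    if steps:
        selected = [s.trait for s in steps]
        proj = canonical_projection(matrix, groups, selected)
        scores = proj.scores.reset_index().rename(
            columns={"index": "genotype_id"})
        write_table(scores,
                    Path(outdir) / f"discriminant_{variate_set}_scores.csv")
    return table
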