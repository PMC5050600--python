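"""Synthetic-data generators for the two experiments.

Emulates (i) the pouch-and-wick seedling root screen (runs, frames, tray
columns, trays, paper sides; 32 genotypes x 24 individuals per run) and
(ii) the polytunnel randomised block ionomics experiment (2 polytunnels,
5 replicate blocks of 12 sub-blocks x 36 pots) analysed by ICP-MS in runs
with operational blanks and interleaved reference material.

Quantitative traits are generated from variance-decomposition models: one
zero-mean effect per factor level plus residual noise.  Per-level effects
are drawn normal and then centred/rescaled so that their ddof=1 variance
across levels equals the configured component exactly; this makes the
configured variance shares the realized ones even for factors with very few
levels (habit has 6, the seed-diameter sieve 4), so that downstream
variance-component recovery measures estimation error, not draw luck.  The
seed-diameter effect is a deterministic monotone gradient in class midpoint
with the same scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import defaults
from .types import (
    DesignError, ElementModel, Genotype, PolytunnelDesign, PouchDesign,
    SeedLot, TraitModel,
)

ROOT_DESIGN_CHAIN = ("run", "frame", "column", "tray", "paper_side")
TUNNEL_DESIGN_CHAIN = ("polytunnel", "replicate", "sub_block")


@dataclass
class GenerativeModel:
    """All generator settings for both experiments."""

    root_traits: dict[str, TraitModel] = field(
        default_factory=defaults.default_root_trait_models)
    plant_traits: dict[str, TraitModel] = field(
        default_factory=defaults.default_seed_weight_models)
    elements: dict[str, dict[str, ElementModel]] = field(
        default_factory=defaults.default_element_models)
    drift_amplitude: float = 0.05     # fractional within-run signal drift
    attrition_rate: float = defaults.ATTRITION_RATE
    reference_noise_sd: float = 0.0   # measurement noise on reference rows


def default_generative_model() -> GenerativeModel:
    return GenerativeModel()


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

def build_pouch_layout(design: PouchDesign) -> pd.DataFrame:
    """One row per potential plant position in the root screen."""
    rows: list[tuple] = []
    tray_counts = design.tray_pouch_counts()
    trays_per_column = design.trays_per_frame // design.tray_columns
    for run in range(1, design.n_runs + 1):
        for frame in range(1, design.frames_per_run + 1):
            for tray_idx, n_pouches in enumerate(tray_counts):
                column = tray_idx // trays_per_column + 1
                tray = tray_idx % trays_per_column + 1
                for pouch in range(1, n_pouches + 1):
                    for side in ("A", "B"):
                        rows.append((run, frame, column, tray, pouch, side))
    layout = pd.DataFrame(
        rows, columns=["run", "frame", "column", "tray", "pouch", "paper_side"]
    )
    layout.insert(0, "plant_id",
                  [f"r{r:02d}f{f}c{c}t{t}p{p:02d}{s}"
                   for r, f, c, t, p, s in rows])
    return layout


def build_polytunnel_layout(
    panel: list[Genotype], design: PolytunnelDesign, seed: int
) -> pd.DataFrame:
    """One row per pot; each replicate holds every genotype exactly once,
    allocated at random to sub-blocks under the given seed."""
    if len(panel) != design.units_per_replicate:
        raise DesignError(
            f"panel has {len(panel)} genotypes but each replicate holds "
            f"{design.units_per_replicate} units"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, design.n_replicates + 1):
        tunnel = design.replicate_to_tunnel[rep]
        order = rng.permutation(len(panel))
        for unit_idx, panel_idx in enumerate(order):
            g = panel[panel_idx]
            sub_block = unit_idx // design.units_per_subblock + 1
            rows.append(
                (f"T{tunnel}r{rep}u{unit_idx + 1:03d}", g.id, g.habit.value,
                 g.role.value, tunnel, rep, sub_block)
            )
    return pd.DataFrame(
        rows,
        columns=["pot_id", "genotype_id", "habit", "role",
                 "polytunnel", "replicate", "sub_block"],
    )


# ---------------------------------------------------------------------------
# Seed sieving allocation
# ---------------------------------------------------------------------------

class InsufficientSeedError(ValueError):
    pass


def allocate_seed_diameters(lot: SeedLot, n_needed: int) -> dict[float, int]:
    """Allocate `n_needed` seeds targeting 25% per sieve class.

    A shortfall in a class is taken from the next smallest class; when the
    smallest class is exhausted the deficit cascades to whatever remains.
    """
    if n_needed < 0:
        raise ValueError("n_needed must be >= 0")
    classes = sorted(lot.diameter_counts)
    available = {c: int(lot.diameter_counts[c]) for c in classes}
    if sum(available.values()) < n_needed:
        raise InsufficientSeedError(
            f"genotype {lot.genotype_id}: {sum(available.values())} seeds "
            f"available, {n_needed} needed"
        )
    taken = {c: 0 for c in classes}
    base, remainder = divmod(n_needed, len(classes))
    # Largest classes absorb any remainder so targets sum to n_needed
    targets = {c: base for c in classes}
    for c in sorted(classes, reverse=True)[:remainder]:
        targets[c] += 1
    for c in sorted(classes, reverse=True):
        want = targets[c]
        take = min(want, available[c])
        taken[c] += take
        available[c] -= take
        shortfall = want - take
        # "the next smallest diameter category was used instead"
        for smaller in sorted([x for x in classes if x < c], reverse=True):
            if shortfall == 0:
                break
            take = min(shortfall, available[smaller])
            taken[smaller] += take
            available[smaller] -= take
            shortfall -= take
        if shortfall:
            # fall back upwards if everything smaller is exhausted
            for larger in sorted([x for x in classes if x > c]):
                if shortfall == 0:
                    break
                take = min(shortfall, available[larger])
                taken[larger] += take
                available[larger] -= take
                shortfall -= take
    assert sum(taken.values()) == n_needed
    return {c: n for c, n in taken.items() if n > 0}


# ---------------------------------------------------------------------------
# Trait simulation core
# ---------------------------------------------------------------------------

def _level_effects(rng: np.random.Generator, n_levels: int, sd: float) -> np.ndarray:
    """Zero-mean normal effects rescaled to exact ddof=1 variance sd^2."""
    if n_levels <= 1 or sd == 0:
        return np.zeros(n_levels)
    x = rng.standard_normal(n_levels)
    x -= x.mean()
    s = x.std(ddof=1)
    if s == 0:  # pathological draw
        return np.zeros(n_levels)
    return x * (sd / s)


def _seed_diameter_effects(classes: np.ndarray, sd: float) -> np.ndarray:
    """Monotone-in-midpoint deterministic gradient with ddof=1 variance sd^2."""
    if len(classes) <= 1 or sd == 0:
        return np.zeros(len(classes))
    x = classes.astype(float) - classes.mean()
    s = x.std(ddof=1)
    return x * (sd / s)


def _nested_codes(df: pd.DataFrame, chain: tuple[str, ...], depth: int) -> np.ndarray:
    cols = list(chain[: depth + 1])
    if len(cols) == 1:
        codes, _ = pd.factorize(df[cols[0]])
        return codes
    key = pd.MultiIndex.from_frame(df[cols])
    codes, _ = pd.factorize(key)
    return codes


def simulate_trait(
    df: pd.DataFrame,
    model: TraitModel,
    rng: np.random.Generator,
    design_chain: tuple[str, ...] = ROOT_DESIGN_CHAIN,
) -> np.ndarray:
    """Simulate one trait over the rows of `df`.

    `model.fractions` may use the terms 'genotype', 'habit', 'seed_diameter',
    'experimental' (split equally across the nested design terms of
    `design_chain`) and 'residual'.
    """
    total_var = model.sd**2
    n = len(df)
    y = np.full(n, model.mean, dtype=float)

    frac = dict(model.fractions)
    for term in ("genotype", "habit"):
        f = frac.pop(term, 0.0)
        if f > 0:
            col = "genotype_id" if term == "genotype" else "habit"
            codes, levels = pd.factorize(df[col])
            eff = _level_effects(rng, len(levels), np.sqrt(f * total_var))
            y += eff[codes]
    f = frac.pop("seed_diameter", 0.0)
    if f > 0:
        codes, levels = pd.factorize(df["seed_diameter"], sort=True)
        eff = _seed_diameter_effects(np.asarray(levels, dtype=float),
                                     np.sqrt(f * total_var))
        y += eff[codes]
    f = frac.pop("experimental", 0.0)
    if f > 0:
        per_term = f / len(design_chain)
        for depth in range(len(design_chain)):
            codes = _nested_codes(df, design_chain, depth)
            eff = _level_effects(rng, codes.max() + 1,
                                 np.sqrt(per_term * total_var))
            y += eff[codes]
    f_res = frac.pop("residual", 0.0)
    unknown = [t for t in frac if frac[t] > 0]
    if unknown:
        raise ValueError(f"unknown variance terms in model: {unknown}")
    if f_res > 0:
        y += rng.normal(0.0, np.sqrt(f_res * total_var), size=n)
    if model.integer_valued:
        y = np.clip(np.rint(y), 0, None)
    return y


# ---------------------------------------------------------------------------
# Root screen simulation
# ---------------------------------------------------------------------------

def proportional_panel(n_genotypes: int) -> list[Genotype]:
    """A panel of `n_genotypes` with habits in the diversity-panel proportions."""
    habits: list = []
    total = sum(defaults.HABIT_COUNTS.values())
    for habit, count in defaults.HABIT_COUNTS.items():
        habits.extend([habit] * max(1, round(count * n_genotypes / total)))
    habits = habits[:n_genotypes]
    while len(habits) < n_genotypes:
        habits.append(list(defaults.HABIT_COUNTS)[0])
    return [Genotype(id=f"G{i:03d}", habit=h)
            for i, h in enumerate(habits, start=1)]


def assign_genotypes(
    layout: pd.DataFrame,
    panel: list[Genotype],
    rng: np.random.Generator,
    genotypes_per_run: int = defaults.GENOTYPES_PER_RUN,
) -> pd.DataFrame:
    """Assign genotypes to plant positions: `genotypes_per_run` genotypes per
    run, equal replication within a run, randomised to positions."""
    if not panel:
        raise DesignError("empty panel")
    out = layout.copy()
    out["genotype_id"] = ""
    out["habit"] = ""
    gmap = {g.id: g.habit.value for g in panel}
    ids = [g.id for g in panel]
    ids = [ids[i] for i in rng.permutation(len(ids))]  # mix habits across runs
    cursor = 0
    for run, idx in layout.groupby("run").groups.items():
        idx = np.asarray(idx)
        chosen = [ids[(cursor + i) % len(ids)] for i in range(genotypes_per_run)]
        cursor = (cursor + genotypes_per_run) % len(ids)
        reps = int(np.ceil(len(idx) / genotypes_per_run))
        slots = np.tile(np.asarray(chosen, dtype=object), reps)[: len(idx)]
        rng.shuffle(slots)
        out.loc[idx, "genotype_id"] = slots
        out.loc[idx, "habit"] = [gmap[g] for g in slots]
    return out


def _assign_seed_diameters(
    assigned: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """25% of each genotype-within-run allocation per sieve class, using the
    sieving fallback rule on a generous synthetic seed lot."""
    classes = defaults.SIEVE_CLASSES_MM
    diam = np.empty(len(assigned), dtype=float)
    for (_, _), idx in assigned.groupby(["run", "genotype_id"]).groups.items():
        idx = np.asarray(idx)
        n = len(idx)
        lot = SeedLot(genotype_id="synthetic", tsw=4.0,
                      diameter_counts={c: n for c in classes})
        alloc = allocate_seed_diameters(lot, n)
        values = np.concatenate([np.full(k, c) for c, k in sorted(alloc.items())])
        rng.shuffle(values)
        diam[assigned.index.get_indexer(idx)] = values
    return diam


def simulate_root_traits(
    layout: pd.DataFrame,
    model: GenerativeModel,
    seed: int,
    panel: list[Genotype] | None = None,
) -> pd.DataFrame:
    """Generate the per-plant root screen table (RootRecord rows).

    Measured components PRL, LRL (cm) and LRN (count) are each generated
    under their own variance decomposition on shared factor levels; a
    configurable fraction of seedlings is flagged non-germinated /
    non-emerged / deformed / stunted so downstream QC has work to do.
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = proportional_panel(
            defaults.GENOTYPES_PER_RUN * layout["run"].nunique())
    records = assign_genotypes(layout, panel, rng)
    records["seed_diameter"] = _assign_seed_diameters(records, rng)

    for trait, tm in model.root_traits.items():
        records[trait] = simulate_trait(records, tm, rng, ROOT_DESIGN_CHAIN)
    for trait in ("prl", "lrl"):
        records[trait] = records[trait].clip(lower=0.0)
    records["lrn"] = records["lrn"].astype(int)
    records.loc[records["lrn"] == 0, "lrl"] = 0.0

    n = len(records)
    records["germinated"] = True
    records["emerged"] = True
    records["deformed"] = False
    if model.attrition_rate > 0:
        u = rng.random(n)
        lost = u < model.attrition_rate
        # reason mix within the attrition fraction
        kind = rng.random(n)
        non_germ = lost & (kind < 0.50)
        non_emerge = lost & (kind >= 0.50) & (kind < 0.70)
        deformed = lost & (kind >= 0.70) & (kind < 0.85)
        stunted = lost & (kind >= 0.85)
        records.loc[non_germ, ["germinated", "emerged"]] = False
        records.loc[non_germ, ["prl", "lrl"]] = 0.0
        records.loc[non_germ, "lrn"] = 0
        records.loc[non_emerge, "emerged"] = False
        records.loc[deformed, "deformed"] = True
        records.loc[stunted, "prl"] = rng.uniform(0.5, 2.9, int(stunted.sum()))
    return records


# ---------------------------------------------------------------------------
# Polytunnel plant traits (TSW, indicative seed yield)
# ---------------------------------------------------------------------------

def simulate_plant_traits(
    pots: pd.DataFrame, model: GenerativeModel, seed: int
) -> pd.DataFrame:
    """Per-pot thousand-seed weight and seed yield under the block design."""
    rng = np.random.default_rng(seed)
    out = pots.copy()
    for trait, tm in model.plant_traits.items():
        out[trait] = np.clip(
            simulate_trait(out, tm, rng, TUNNEL_DESIGN_CHAIN), 1e-3, None
        )
    return out


# ---------------------------------------------------------------------------
# ICP-MS run simulation
# ---------------------------------------------------------------------------

def run_sample_capacity(run_size: int) -> int:
    """Samples fitting in a run of `run_size` interleaved slots, where every
    tenth slot is a reference (a reference after every ninth sample)."""
    if run_size < 10:
        raise DesignError("run_size < 10 cannot hold a reference after "
                          "every ninth sample")
    return run_size - run_size // 10


def simulate_icpms_runs(
    pots: pd.DataFrame,
    model: GenerativeModel,
    run_size: int,
    seed: int,
    tissue: str = "leaf",
    n_samples: int | None = None,
    return_truth: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Generate raw ICP-MS run tables for one tissue.

    Each run holds samples with a reference-material row after every ninth
    sample and two operational blanks appended at the end.  Raw readings are
    true tissue concentrations back-converted to the solution scale,
    multiplied by a within-run linear drift factor, plus blank-distributed
    background; a configurable per-element fraction of true values is forced
    below the nominal LOD.
    """
    rng = np.random.default_rng(seed)
    proto = defaults.PROTOCOLS[tissue]
    elements = model.elements[tissue]
    el_names = list(elements)

    pots = pots.reset_index(drop=True)
    if n_samples is not None and n_samples < len(pots):
        keep = np.sort(rng.choice(len(pots), size=n_samples, replace=False))
        pots = pots.iloc[keep].reset_index(drop=True)
    n = len(pots)

    # True tissue concentrations (mg/kg) per pot x element, log-normal
    true_conc = np.empty((n, len(el_names)))
    for j, el in enumerate(el_names):
        em = elements[el]
        tm = TraitModel(mean=np.log10(em.geometric_mean), sd=em.log10_sd,
                        fractions=dict(em.fractions))
        true_conc[:, j] = 10.0 ** simulate_trait(pots, tm, rng,
                                                 TUNNEL_DESIGN_CHAIN)
        if em.censor_fraction > 0:
            conv = proto.dilution * proto.digest_volume_l / proto.notional_mass_g
            nominal_lod = 3.0 * em.blank_sd * conv  # mg/kg
            censored = rng.random(n) < em.censor_fraction
            true_conc[censored, j] = nominal_lod * rng.uniform(
                0.05, 0.8, int(censored.sum()))

    dry_mass = proto.dry_mass_g * np.exp(rng.normal(0, 0.05, n))
    solution_true = (true_conc * dry_mass[:, None]
                     / (proto.digest_volume_l * proto.dilution))  # ug/L

    # Reference material: pooled digest, constant solution concentration
    ref_solution = {
        el: elements[el].geometric_mean * proto.dry_mass_g
        / (proto.digest_volume_l * proto.dilution)
        for el in el_names
    }

    capacity = run_sample_capacity(run_size)
    order = rng.permutation(n)
    rows: list[dict] = []
    run_no = 0
    for start in range(0, n, capacity):
        run_no += 1
        run_id = f"{tissue}_run{run_no:02d}"
        batch = order[start:start + capacity]
        # Build the interleaved sequence slot by slot
        seq: list[tuple[str, int | None]] = []
        sample_iter = iter(batch)
        slot = 0
        placed = 0
        while placed < len(batch):
            slot += 1
            if slot % 10 == 0:
                seq.append(("reference", None))
            else:
                seq.append(("sample", int(next(sample_iter))))
                placed += 1
        # trailing reference if the run ended exactly on a ninth sample
        if (slot + 1) % 10 == 0:
            seq.append(("reference", None))
        total_rows = len(seq) + defaults.BLANKS_PER_RUN
        for b in range(defaults.BLANKS_PER_RUN):
            seq.append(("blank", None))
        span = max(total_rows - 1, 1)
        for pos, (role, pot_idx) in enumerate(seq, start=1):
            drift = 1.0 + model.drift_amplitude * 2.0 * ((pos - 1) / span - 0.5)
            row: dict = {
                "run_id": run_id, "position": pos, "role": role,
                "tissue": tissue, "genotype_id": None, "pot_id": None,
                "dry_mass_g": None,
                "digest_volume_l": proto.digest_volume_l,
                "dilution": proto.dilution,
            }
            if role == "sample":
                row["genotype_id"] = pots.at[pot_idx, "genotype_id"]
                row["pot_id"] = pots.at[pot_idx, "pot_id"]
                row["dry_mass_g"] = dry_mass[pot_idx]
                noise = rng.normal(0.0, 1.0, len(el_names))
                for j, el in enumerate(el_names):
                    em = elements[el]
                    reading = (solution_true[pot_idx, j] * drift
                               + em.blank_mean + em.blank_sd * noise[j])
                    row[el] = max(reading, 0.0)
            elif role == "reference":
                noise = rng.normal(0.0, 1.0, len(el_names))
                for j, el in enumerate(el_names):
                    reading = ref_solution[el] * drift
                    if model.reference_noise_sd > 0:
                        reading *= 1.0 + model.reference_noise_sd * noise[j]
                    row[el] = max(reading, 0.0)
            else:  # blank
                noise = rng.normal(0.0, 1.0, len(el_names))
                for j, el in enumerate(el_names):
                    em = elements[el]
                    row[el] = max(em.blank_mean + em.blank_sd * noise[j], 0.0)
            rows.append(row)
    out = pd.DataFrame(rows)
    if return_truth:
        truth = pd.DataFrame(true_conc, columns=el_names)
        truth.insert(0, "pot_id", pots["pot_id"].to_numpy())
        return out, truth
    return out
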