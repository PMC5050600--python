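"""Default parameter values for the B. napus diversity-panel pipeline.

Panel composition, experimental design sizes, ICP-MS element panels and
exclusion lists, digestion protocol constants, and the per-trait variance
decompositions used as generating truths by the synthetic-data module.
"""

from __future__ import annotations

from dataclasses import dataclass

from .types import ElementModel, Habit, PanelConfig, TraitModel

# ---------------------------------------------------------------------------
# Panel composition
# ---------------------------------------------------------------------------

HABIT_COUNTS: dict[Habit, int] = {
    Habit.WINTER_OSR: 163,
    Habit.SPRING_OSR: 127,
    Habit.SEMIWINTER_OSR: 7,
    Habit.SWEDE: 35,
    Habit.WINTER_FODDER: 15,
    Habit.EXOTIC: 40,
}
N_REFERENCE = 16
N_FILLER = 29


def default_panel_config() -> PanelConfig:
    return PanelConfig(
        habit_counts=dict(HABIT_COUNTS),
        n_reference=N_REFERENCE,
        n_filler=N_FILLER,
    )


# Pouch-and-wick root screen
ROOT_RUNS = 16
GENOTYPES_PER_RUN = 32
INDIVIDUALS_PER_GENOTYPE = 24
ATTRITION_RATE = 0.29
MIN_RADICLE_CM = 3.0

# Seed sieving: the four sieve mesh categories used for allocation, and the
# five diameters observed in the screened seed (an extra 1.18 mm class).
SIEVE_CLASSES_MM: tuple[float, ...] = (1.4, 1.7, 2.0, 2.36)
OBSERVED_DIAMETERS_MM: tuple[float, ...] = (1.18, 1.4, 1.7, 2.0, 2.36)

# ---------------------------------------------------------------------------
# ICP-MS element panels
# ---------------------------------------------------------------------------

LEAF_ELEMENTS: tuple[str, ...] = (
    "Ag", "Al", "As", "B", "Ba", "Ca", "Cd", "Cr", "Co", "Cs", "Cu", "Fe",
    "K", "Mg", "Mn", "Mo", "Na", "Ni", "P", "Pb", "Rb", "S", "Se", "Sr",
    "Ti", "U", "V", "Zn",
)
SEED_ELEMENTS: tuple[str, ...] = (
    "Li", "B", "Na", "Mg", "P", "S", "K", "Ca", "Mn", "Fe", "Co", "Ni",
    "Cu", "Zn", "As", "Se", "Rb", "Sr", "Mo", "Cd",
)

# Elements dropped as at-or-near the limit of detection.  The seed list keeps
# Cr and Pb even though they were never monitored in seed; retention is the
# set difference against the monitored panel.
LEAF_EXCLUDED: tuple[str, ...] = ("Ag", "Co", "Cr", "Ni", "Pb", "U", "V")
SEED_EXCLUDED: tuple[str, ...] = ("As", "Co", "Cr", "Fe", "Ni", "Pb", "Se")

# ---------------------------------------------------------------------------
# Digestion / dilution protocols (solution ug/L -> tissue mg/kg conversion)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigestionProtocol:
    dilution: float          # dilution of digestate before analysis
    digest_volume_l: float   # final digest volume, litres
    dry_mass_g: float        # typical starting dry mass, g
    notional_mass_g: float   # notional dry mass used for LOD reporting


LEAF_PROTOCOL = DigestionProtocol(
    dilution=5.0, digest_volume_l=0.015, dry_mass_g=0.200, notional_mass_g=0.200
)
SEED_PROTOCOL = DigestionProtocol(
    dilution=1.0, digest_volume_l=0.0115, dry_mass_g=0.015, notional_mass_g=0.015
)

PROTOCOLS = {"leaf": LEAF_PROTOCOL, "seed": SEED_PROTOCOL}

LEAF_ICPMS_RUNS = 14
SEED_ICPMS_RUNS = 4
LEAF_SAMPLE_TARGET = 2096   # analysed leaf solutions
SEED_SAMPLE_TARGET = 1986   # analysed seed solutions
REFERENCE_EVERY = 9         # reference material after every ninth sample
BLANKS_PER_RUN = 2

# ---------------------------------------------------------------------------
# Generating variance decompositions (percent of total variance).
# Root rows carry genotype/habit/experimental/seed-diameter shares; the
# residual is always the complement so the shares sum to exactly 100.
# ---------------------------------------------------------------------------

ROOT_TRAIT_SHARES: dict[str, dict[str, float]] = {
    "trl":  {"genotype": 9,  "habit": 1, "experimental": 4, "seed_diameter": 44},
    "prl":  {"genotype": 11, "habit": 6, "experimental": 3, "seed_diameter": 35},
    "lrl":  {"genotype": 9,  "habit": 1, "experimental": 5, "seed_diameter": 41},
    "mlrl": {"genotype": 6,  "habit": 1, "experimental": 5, "seed_diameter": 6},
    "lrn":  {"genotype": 9,  "habit": 4, "experimental": 5, "seed_diameter": 41},
    "lrd":  {"genotype": 13, "habit": 2, "experimental": 8, "seed_diameter": 3},
}

SEED_WEIGHT_SHARES: dict[str, dict[str, float]] = {
    "tsw":        {"genotype": 8,  "habit": 3, "experimental": 3},
    "seed_yield": {"genotype": 10, "habit": 5, "experimental": 10},
}

LEAF_ELEMENT_SHARES: dict[str, dict[str, float]] = {
    "Al": {"genotype": 3,  "habit": 0,  "experimental": 44},
    "As": {"genotype": 4,  "habit": 2,  "experimental": 67},
    "B":  {"genotype": 22, "habit": 3,  "experimental": 42},
    "Ba": {"genotype": 23, "habit": 1,  "experimental": 42},
    "Ca": {"genotype": 26, "habit": 12, "experimental": 27},
    "Cd": {"genotype": 11, "habit": 1,  "experimental": 59},
    "Cs": {"genotype": 2,  "habit": 1,  "experimental": 74},
    "Cu": {"genotype": 17, "habit": 5,  "experimental": 29},
    "Fe": {"genotype": 13, "habit": 6,  "experimental": 43},
    "K":  {"genotype": 35, "habit": 4,  "experimental": 30},
    "Mg": {"genotype": 36, "habit": 17, "experimental": 14},
    "Mn": {"genotype": 15, "habit": 5,  "experimental": 48},
    "Mo": {"genotype": 22, "habit": 10, "experimental": 6},
    "Na": {"genotype": 37, "habit": 21, "experimental": 6},
    "P":  {"genotype": 21, "habit": 8,  "experimental": 17},
    "Rb": {"genotype": 30, "habit": 7,  "experimental": 35},
    "S":  {"genotype": 40, "habit": 15, "experimental": 17},
    "Se": {"genotype": 0,  "habit": 0,  "experimental": 85},
    "Sr": {"genotype": 24, "habit": 7,  "experimental": 41},
    "Ti": {"genotype": 9,  "habit": 3,  "experimental": 65},
    "Zn": {"genotype": 24, "habit": 6,  "experimental": 30},
}

SEED_ELEMENT_SHARES: dict[str, dict[str, float]] = {
    "B":  {"genotype": 13, "habit": 2,  "experimental": 40},
    "Ca": {"genotype": 16, "habit": 9,  "experimental": 26},
    "Cd": {"genotype": 9,  "habit": 8,  "experimental": 40},
    "Cu": {"genotype": 32, "habit": 0,  "experimental": 6},
    "K":  {"genotype": 21, "habit": 1,  "experimental": 25},
    "Li": {"genotype": 10, "habit": 5,  "experimental": 16},
    "Mg": {"genotype": 6,  "habit": 18, "experimental": 52},
    "Mn": {"genotype": 12, "habit": 1,  "experimental": 55},
    "Mo": {"genotype": 41, "habit": 21, "experimental": 7},
    "Na": {"genotype": 12, "habit": 3,  "experimental": 26},
    "P":  {"genotype": 12, "habit": 5,  "experimental": 50},
    "Rb": {"genotype": 14, "habit": 3,  "experimental": 36},
    "S":  {"genotype": 31, "habit": 13, "experimental": 37},
    "Sr": {"genotype": 9,  "habit": 8,  "experimental": 27},
    "Zn": {"genotype": 21, "habit": 12, "experimental": 14},
}

# ---------------------------------------------------------------------------
# Element concentration scales (geometric means, mg/kg dry tissue).
# Chosen to reproduce the reported orders of magnitude (leaf As 0.01 up to
# K > 50,000 mg/kg; seed Cd 0.01 up to K > 13,000 mg/kg) and leaf element
# ratios of the right magnitude (Ca:Sr ~ 500:1, K:Rb ~ 3,000:1).
# ---------------------------------------------------------------------------

LEAF_GEOMETRIC_MEANS: dict[str, float] = {
    "Ag": 0.005, "Al": 40.0, "As": 0.01, "B": 30.0, "Ba": 20.0,
    "Ca": 20000.0, "Cd": 0.3, "Cr": 0.05, "Co": 0.05, "Cs": 0.03,
    "Cu": 4.0, "Fe": 100.0, "K": 55000.0, "Mg": 3500.0, "Mn": 40.0,
    "Mo": 1.5, "Na": 2000.0, "Ni": 0.5, "P": 5000.0, "Pb": 0.05,
    "Rb": 15.0, "S": 12000.0, "Se": 0.05, "Sr": 40.0, "Ti": 2.0,
    "U": 0.001, "V": 0.01, "Zn": 35.0,
}

SEED_GEOMETRIC_MEANS: dict[str, float] = {
    "Li": 0.2, "B": 10.0, "Na": 80.0, "Mg": 3000.0, "P": 7000.0,
    "S": 4000.0, "K": 13000.0, "Ca": 4000.0, "Mn": 30.0, "Fe": 60.0,
    "Co": 0.05, "Ni": 1.0, "Cu": 4.0, "Zn": 40.0, "As": 0.005,
    "Se": 0.03, "Rb": 4.0, "Sr": 8.0, "Mo": 2.0, "Cd": 0.01,
}

# Genotypic spread on log10 scale; Se is far more variable (> 40-fold range).
DEFAULT_LOG10_SD = 0.12
LOG10_SD_OVERRIDES: dict[str, float] = {"Se": 0.45, "Na": 0.3, "Cd": 0.25}

# Element-pair translocation ratios (numerator, denominator)
RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("S", "Mo"), ("Ca", "Sr"), ("K", "Rb"), ("Zn", "Cd"),
)

# ---------------------------------------------------------------------------
# Trait naming and variate sets (heat-map / discriminant ordering)
# ---------------------------------------------------------------------------

ROOT_TRAITS: tuple[str, ...] = ("lrd", "lrl", "lrn", "mlrl", "prl", "trl")
SEED_WEIGHT_TRAITS: tuple[str, ...] = ("tsw", "seed_yield")


def leaf_trait(element: str) -> str:
    return f"leaf_{element}"


def seed_trait(element: str) -> str:
    return f"seed_{element}"


def retained(monitored: tuple[str, ...], excluded: tuple[str, ...]) -> list[str]:
    return [e for e in monitored if e not in excluded]


LEAF_RETAINED: list[str] = retained(LEAF_ELEMENTS, LEAF_EXCLUDED)
SEED_RETAINED: list[str] = retained(SEED_ELEMENTS, SEED_EXCLUDED)

# Correlation-matrix trait ordering: TSW, seed yield, the six root traits
# alphabetically, then leaf and seed element concentrations alphabetically.
TRAIT_ORDER: list[str] = (
    list(SEED_WEIGHT_TRAITS)
    + list(ROOT_TRAITS)
    + [leaf_trait(e) for e in sorted(LEAF_RETAINED)]
    + [seed_trait(e) for e in sorted(SEED_RETAINED)]
)


def variate_sets() -> dict[str, list[str]]:
    """The five discriminant variate sets (root, leaf, seed, seed_weight, combined)."""
    sets = {
        "root": list(ROOT_TRAITS),
        "leaf": [leaf_trait(e) for e in sorted(LEAF_RETAINED)],
        "seed": [seed_trait(e) for e in sorted(SEED_RETAINED)],
        "seed_weight": list(SEED_WEIGHT_TRAITS),
    }
    sets["combined"] = [t for t in TRAIT_ORDER]
    return sets


# ---------------------------------------------------------------------------
# Generator assembly helpers
# ---------------------------------------------------------------------------


def _shares_to_fractions(shares: dict[str, float]) -> dict[str, float]:
    return {term: share / 100.0 for term, share in shares.items()}


def default_root_trait_models() -> dict[str, TraitModel]:
    """Generators for the three measured root components (cm / counts)."""
    scale = {
        "prl": (12.0, 3.0, False),
        "lrl": (15.0, 5.0, False),
        "lrn": (15.0, 5.0, True),
    }
    return {
        trait: TraitModel(
            mean=mean, sd=sd,
            fractions=_shares_to_fractions(ROOT_TRAIT_SHARES[trait]),
            integer_valued=integer,
        )
        for trait, (mean, sd, integer) in scale.items()
    }


def root_trait_model(trait: str) -> TraitModel:
    """Generator for any root trait directly on its own measurement scale."""
    scale = {
        "trl": (27.0, 7.0), "prl": (12.0, 3.0), "lrl": (15.0, 5.0),
        "lrn": (15.0, 5.0), "mlrl": (1.0, 0.3), "lrd": (1.3, 0.4),
    }
    mean, sd = scale[trait]
    return TraitModel(
        mean=mean, sd=sd,
        fractions=_shares_to_fractions(ROOT_TRAIT_SHARES[trait]),
    )


def default_seed_weight_models() -> dict[str, TraitModel]:
    return {
        "tsw": TraitModel(
            mean=4.0, sd=1.0,
            fractions=_shares_to_fractions(SEED_WEIGHT_SHARES["tsw"]),
        ),
        "seed_yield": TraitModel(
            mean=20.0, sd=6.0,
            fractions=_shares_to_fractions(SEED_WEIGHT_SHARES["seed_yield"]),
        ),
    }


def _element_model(tissue: str, element: str) -> ElementModel:
    gms = LEAF_GEOMETRIC_MEANS if tissue == "leaf" else SEED_GEOMETRIC_MEANS
    shares = LEAF_ELEMENT_SHARES if tissue == "leaf" else SEED_ELEMENT_SHARES
    excluded = LEAF_EXCLUDED if tissue == "leaf" else SEED_EXCLUDED
    proto = PROTOCOLS[tissue]
    gm = gms[element]
    # Solution-scale signal for a typical sample, ug/L
    solution_gm = gm * proto.dry_mass_g / (proto.digest_volume_l * proto.dilution)
    if element in excluded:
        # Excluded elements sit at or near the LOD: blank noise scaled so the
        # tissue-scale LOD (3 x blank SD, notional mass) lands above the mean.
        conv = proto.dilution * proto.digest_volume_l / proto.notional_mass_g
        blank_sd = 1.2 * gm / (3.0 * conv)
        blank_mean = 2.0 * blank_sd
        censor = 0.3
    else:
        blank_sd = 0.001 * solution_gm + 0.02
        blank_mean = 2.0 * blank_sd
        censor = 0.1 if element == "Se" else 0.0
    fractions = _shares_to_fractions(shares.get(element, {"genotype": 10, "habit": 2,
                                                          "experimental": 30}))
    return ElementModel(
        geometric_mean=gm,
        log10_sd=LOG10_SD_OVERRIDES.get(element, DEFAULT_LOG10_SD),
        fractions=fractions,
        blank_mean=blank_mean,
        blank_sd=blank_sd,
        censor_fraction=censor,
    )


def default_element_models() -> dict[str, dict[str, ElementModel]]:
    return {
        "leaf": {e: _element_model("leaf", e) for e in LEAF_ELEMENTS},
        "seed": {e: _element_model("seed", e) for e in SEED_ELEMENTS},
    }
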