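"""Core domain types for the B. napus phenotyping pipeline.

The panel groups genotypes by *crop habit* (winter / spring / semiwinter
oilseed rape, swede, winter fodder, exotic).  Two experiments are modelled:
a 'pouch and wick' seedling root screen (runs x frames x tray columns x
trays x paper sides) and a polytunnel randomised block design for leaf and
seed ionomics (polytunnels, replicate blocks, sub-blocks).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Habit(str, enum.Enum):
    WINTER_OSR = "winter_osr"
    SPRING_OSR = "spring_osr"
    SEMIWINTER_OSR = "semiwinter_osr"
    SWEDE = "swede"
    WINTER_FODDER = "winter_fodder"
    EXOTIC = "exotic"


class Role(str, enum.Enum):
    CORE = "core"
    REFERENCE = "reference"
    FILLER = "filler"


@dataclass(frozen=True)
class Genotype:
    id: str
    habit: Habit
    role: Role = Role.CORE


@dataclass
class SeedLot:
    """Seed stock for one genotype: thousand-seed weight and per-sieve counts."""

    genotype_id: str
    tsw: float  # g per 1000 seeds
    diameter_counts: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tsw > 0:
            raise ValueError(f"tsw must be > 0, got {self.tsw}")
        for diam, count in self.diameter_counts.items():
            if int(count) != count or count < 0:
                raise ValueError(
                    f"diameter class {diam}: count must be a non-negative "
                    f"integer, got {count}"
                )


@dataclass
class PanelConfig:
    """How many genotypes of each habit, plus reference and filler lines."""

    habit_counts: dict[Habit, int]
    n_reference: int = 0
    n_filler: int = 0

    def __post_init__(self) -> None:
        for habit, count in self.habit_counts.items():
            if count < 0:
                raise ValueError(f"habit count for {habit} must be >= 0")
        if self.n_reference < 0 or self.n_filler < 0:
            raise ValueError("n_reference and n_filler must be >= 0")

    @property
    def n_core(self) -> int:
        return sum(self.habit_counts.values())

    @property
    def n_total(self) -> int:
        return self.n_core + self.n_reference + self.n_filler


class DesignError(ValueError):
    """Raised when an experimental design description is inconsistent."""


@dataclass
class PouchDesign:
    """Pouch-and-wick screen layout.

    Each run holds `frames_per_run` frames; a frame holds 9 drip trays in a
    3 x 3 arrangement (3 tray columns), trays hold 10 or 11 pouches summing
    to `pouches_per_frame`, and every pouch carries one plant per paper side.
    """

    n_runs: int = 16
    frames_per_run: int = 4
    trays_per_frame: int = 9
    pouches_per_frame: int = 96
    plants_per_pouch: int = 2
    tray_columns: int = 3

    def __post_init__(self) -> None:
        if self.plants_per_pouch != 2:
            raise DesignError("one plant per paper side: plants_per_pouch must be 2")
        counts = self.tray_pouch_counts()
        if sum(counts) != self.pouches_per_frame:
            raise DesignError(
                f"{self.trays_per_frame} trays of 10 or 11 pouches cannot hold "
                f"{self.pouches_per_frame} pouches"
            )
        if self.trays_per_frame % self.tray_columns != 0:
            raise DesignError("trays_per_frame must divide into tray_columns")

    def tray_pouch_counts(self) -> list[int]:
        """Per-tray pouch counts: as even a 10/11 split as possible."""
        base, extra = divmod(self.pouches_per_frame, self.trays_per_frame)
        if base not in (10, 11) and self.pouches_per_frame > 0:
            raise DesignError(
                f"trays would need {base} or {base + 1} pouches; expected 10 or 11"
            )
        return [base + 1 if i < extra else base for i in range(self.trays_per_frame)]

    @property
    def plants_per_frame(self) -> int:
        return self.pouches_per_frame * self.plants_per_pouch

    @property
    def plants_per_run(self) -> int:
        return self.plants_per_frame * self.frames_per_run


@dataclass
class PolytunnelDesign:
    """Randomised block design for the compost-grown ionomics experiment."""

    n_replicates: int = 5
    replicate_to_tunnel: dict[int, str] = field(
        default_factory=lambda: {1: "A", 2: "A", 3: "A", 4: "B", 5: "B"}
    )
    subblocks_per_replicate: int = 12
    units_per_subblock: int = 36

    def __post_init__(self) -> None:
        missing = [r for r in range(1, self.n_replicates + 1)
                   if r not in self.replicate_to_tunnel]
        if missing:
            raise DesignError(f"replicates without a tunnel allocation: {missing}")

    @property
    def units_per_replicate(self) -> int:
        return self.subblocks_per_replicate * self.units_per_subblock

    @property
    def n_units(self) -> int:
        return self.units_per_replicate * self.n_replicates


# ---------------------------------------------------------------------------
# Generative model for the synthetic experiments
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """Variance-decomposition generator for one quantitative trait.

    `fractions` maps variance terms to fractions of total variance; terms not
    listed get 0 and `residual` is taken as the complement of the others, so
    the fractions always sum to 1.
    """

    mean: float
    sd: float  # total (all components + residual) standard deviation
    fractions: dict[str, float] = field(default_factory=dict)
    integer_valued: bool = False  # e.g. lateral root counts

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        non_resid = sum(v for k, v in self.fractions.items() if k != "residual")
        if non_resid > 1 + 1e-9:
            raise ValueError(
                f"non-residual variance fractions sum to {non_resid:.4f} > 1"
            )
        self.fractions = {k: v for k, v in self.fractions.items() if k != "residual"}
        self.fractions["residual"] = 1.0 - non_resid


@dataclass
class ElementModel:
    """Log-normal generator for one element in one tissue.

    Concentrations are log-normal within an element (ionomes span several
    orders of magnitude across elements); `geometric_mean` is in mg/kg dry
    tissue and `log10_sd` is the total SD on the log10 scale, partitioned by
    `fractions` over genotype / habit / design terms / residual.
    """

    geometric_mean: float
    log10_sd: float = 0.15
    fractions: dict[str, float] = field(default_factory=dict)
    blank_mean: float = 0.05   # solution-scale ug/L
    blank_sd: float = 0.02     # solution-scale ug/L
    censor_fraction: float = 0.0  # fraction of true values forced below LOD
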