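"""Assemble the diversity panel from habit counts."""

from __future__ import annotations

import pandas as pd

from .types import Genotype, Habit, PanelConfig, Role

# Stable habit ordering for id assignment
_HABIT_ORDER = [
    Habit.WINTER_OSR, Habit.SPRING_OSR, Habit.SEMIWINTER_OSR,
    Habit.SWEDE, Habit.WINTER_FODDER, Habit.EXOTIC,
]

_HABIT_PREFIX = {
    Habit.WINTER_OSR: "W", Habit.SPRING_OSR: "S", Habit.SEMIWINTER_OSR: "SW",
    Habit.SWEDE: "SD", Habit.WINTER_FODDER: "F", Habit.EXOTIC: "X",
}


def assemble_panel(config: PanelConfig) -> list[Genotype]:
    """One Genotype per configured slot, with unique ids.

    Core genotypes take the configured habit; reference lines are winter OSR
    (normalisation lines); filler lines are recorded as exotic/unspecified.
    """
    panel: list[Genotype] = []
    for habit in _HABIT_ORDER:
        count = config.habit_counts.get(habit, 0)
        prefix = _HABIT_PREFIX[habit]
        for i in range(1, count + 1):
            panel.append(Genotype(id=f"{prefix}{i:03d}", habit=habit))
    for i in range(1, config.n_reference + 1):
        panel.append(Genotype(id=f"REF{i:02d}", habit=Habit.WINTER_OSR,
                              role=Role.REFERENCE))
    for i in range(1, config.n_filler + 1):
        panel.append(Genotype(id=f"FILL{i:02d}", habit=Habit.EXOTIC,
                              role=Role.FILLER))
    ids = [g.id for g in panel]
    assert len(set(ids)) == len(ids)
    return panel


def panel_frame(panel: list[Genotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "genotype_id": [g.id for g in panel],
            "habit": [g.habit.value for g in panel],
            "role": [g.role.value for g in panel],
        }
    )
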