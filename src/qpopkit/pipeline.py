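"""Convenience drivers that wire the modules into the standard workflow:
design -> plates -> per-line quadratic surface -> pair ranking -> cohort
frequency table."""

from __future__ import annotations

import pandas as pd

from .design import DrugDoseSpec, OACDDesign
from .qpop import (
    CombinationRanking,
    FrequencyTable,
    QuadraticSurface,
    aggregate_plate_outputs,
    fit_quadratic_surface,
    rank_frequency,
    score_two_drug_combinations,
)

__all__ = ["rank_cohort"]


def rank_cohort(
    design: OACDDesign,
    plates: pd.DataFrame,
    specs: list[DrugDoseSpec],
    tumor_lines: list[str],
    normal_line: str = "THLE-2",
    objective: str = "delta",
    top_n: int = 25,
    backward_eliminate: bool = False,
) -> tuple[dict[str, QuadraticSurface], list[CombinationRanking], FrequencyTable]:
    """Fit one surface per tumor line and aggregate the pair rankings.

    ``plates`` is the long viability table (run_id, cell_line, replicate,
    viability) covering every tumor line and the shared normal line.
    """
    surfaces: dict[str, QuadraticSurface] = {}
    rankings: list[CombinationRanking] = []
    for line in tumor_lines:
        sub = plates[plates.cell_line.isin([line, normal_line])]
        delta = aggregate_plate_outputs(sub, tumor_line=line, normal_line=normal_line)
        surface = fit_quadratic_surface(
            design, delta.to_numpy(), backward_eliminate=backward_eliminate
        )
        surfaces[line] = surface
        rankings.append(
            score_two_drug_combinations(surface, specs, objective, cell_line=line)
        )
    return surfaces, rankings, rank_frequency(rankings, top_n=top_n)
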