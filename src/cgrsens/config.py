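"""Run configuration: the fixed constants of the analysis in one place."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Analysis constants.

    Parameters
    ----------
    window_years:
        Length of the moving regression window on annual series (calendar years).
    highfreq_window_months:
        Length of the sliding block used for the high-frequency CO2 growth rate.
    bootstrap_reps:
        Number of case-resampling bootstrap replicates per window.
    surrogate_reps:
        Number of Monte-Carlo surrogates in the random-phase significance test.
    excluded_years:
        Calendar years flagged out of all sensitivity fits (Mt Pinatubo eruption
        perturbs the growth rate through diffuse light, cooling and drying).
    conversion_ppm_to_pgc:
        Mass of carbon corresponding to 1 ppm of atmospheric CO2, PgC per ppm.
    sigma_bin_edges:
        Interior edges of the dryness categories on the standardized scale.
    band_limits_deg:
        Northern and southern latitude limits of the tropical band.
    """

    window_years: int = 20
    highfreq_window_months: int = 12
    bootstrap_reps: int = 500
    surrogate_reps: int = 1000
    excluded_years: tuple[int, ...] = (1992, 1993)
    conversion_ppm_to_pgc: float = 2.124
    sigma_bin_edges: tuple[float, float, float] = (-1.0, 0.0, 1.0)
    seed: int = 0
    band_limits_deg: tuple[float, float] = (24.0, -24.0)

    def __post_init__(self) -> None:
        if self.window_years < 2:
            raise ValueError("window_years must be >= 2")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        edges = tuple(self.sigma_bin_edges)
        if any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError("sigma_bin_edges must be strictly increasing")
        self.excluded_years = tuple(int(y) for y in self.excluded_years)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})
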