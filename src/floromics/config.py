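"""Pipeline configuration: thresholds, isotope constants, flux parameters.

Defaults reproduce the analysis conditions of the anthesis study this
package reimplements: Pearson thresholds of 0.65 (metabolite network),
0.80 (transcript–metabolite network) and 0.82 (transcript network), raw
P <= 0.05 edge significance, FDR 0.05 for the developmental-trend filter,
and a minimum of 10 total counts per gene.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "NATURAL_ABUNDANCE"]

#: Default natural heavy-isotope abundances by element, expressed as the
#: probability of each +1, +2 ... mass shift for a single atom.  P is treated
#: as monoisotopic.  All configurable through PipelineConfig.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.0107,),
    "H": (0.000115,),
    "N": (0.00364,),
    "O": (0.00038, 0.00205),
    "Si": (0.04685, 0.03092),
    "S": (0.0075, 0.0425),
    "P": (),
}


@dataclass
class PipelineConfig:
    """Bag of tunables shared by the pipeline stages.

    Attributes
    ----------
    r_metabolite, r_transcript_metabolite, r_transcript
        Pearson-r edge thresholds for the three network flavours (strict
        inequalities; ties at the threshold are excluded).
    p_correlation
        Raw two-sided p-value cutoff for calling a correlation significant.
    fdr_trend
        Benjamini–Hochberg level for the quadratic stage-trend filter.
    min_counts
        Genes with fewer total counts than this across all samples are
        dropped before normalization.
    c13_abundance
        Natural abundance of carbon-13 used in isotopologue correction.
    tracer_purity
        Isotopic purity of the fed tracer glucose (fraction of tracer
        carbons that are actually heavy).
    specific_activity
        Specific activity of the labelled hexose pool, Bq per nmol hexose.
        Default is the feeding-solution value (7 MBq per mmol glucose =
        7 Bq/nmol); fluxes computed with it are lower-bound-biased because
        dilution of the internal hexose-phosphate pool is ignored.
    duration_h
        Labelling duration in hours.
    seed
        Seed for every stochastic component.
    """

    r_metabolite: float = 0.65
    r_transcript_metabolite: float = 0.80
    r_transcript: float = 0.82
    p_correlation: float = 0.05
    fdr_trend: float = 0.05
    min_counts: int = 10
    c13_abundance: float = 0.0107
    tracer_purity: float = 1.0
    specific_activity: float = 7.0
    duration_h: float = 5.0
    seed: int = 0
    natural_abundance: dict = field(default_factory=lambda: dict(NATURAL_ABUNDANCE))

    def __post_init__(self) -> None:
        for name in ("r_metabolite", "r_transcript_metabolite", "r_transcript"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        for name in ("p_correlation", "fdr_trend", "tracer_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.c13_abundance < 0.5:
            raise ValueError("c13_abundance must lie in (0, 0.5)")
        if self.min_counts < 0:
            raise ValueError("min_counts must be >= 0")
        if self.specific_activity <= 0 or self.duration_h <= 0:
            raise ValueError("specific_activity and duration_h must be positive")
        if not isinstance(self.seed, int):
            raise TypeError("seed must be an integer")
        self.natural_abundance = {
            el: tuple(float(x) for x in v) for el, v in self.natural_abundance.items()
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from YAML or JSON; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix == ".json":
            path.write_text(json.dumps(data, indent=2))
        else:
            path.write_text(yaml.safe_dump(data))
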