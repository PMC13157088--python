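"""Run-wide configuration with the pipeline's default thresholds and constants.

Every tunable named by the other modules lives here so that a run can be
described (and reproduced) by a single object.  Unknown keys are rejected at
construction time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

#: Reference maximum accessible surface area for cysteine, in A^2, from the
#: theoretical Gly-X-Gly tripeptide normalisation of Tien et al. (2013).
#: Used to turn absolute SASA into % buried.
CYS_MAX_ASA = 167.0

#: Default organism keywords for the mammalian taxonomy filter
#: (case-insensitive substring match on source-organism strings).
MAMMAL_KEYWORDS = (
    "homo sapiens",
    "mus musculus",
    "rattus",
    "bos taurus",
    "sus scrofa",
    "canis",
    "felis catus",
    "oryctolagus",
    "macaca",
    "pan troglodytes",
    "cricetulus",
    "mesocricetus",
    "ovis aries",
    "equus",
    "capra hircus",
)


@dataclass
class RunConfig:
    """Defaults for the proximal-cysteine screen and Redox Score pipeline."""

    #: S gamma - S gamma screening threshold in A (pairs strictly closer pass).
    pair_distance_max: float = 10.0
    #: Geometric cutoff in A below which a pair is considered disulphide-bound.
    ss_max: float = 2.5
    #: Half-sphere exposure neighbour radius in A.
    hse_radius: float = 12.0
    #: Solvent probe radius in A for Shrake-Rupley SASA.
    sasa_probe: float = 1.4
    #: Number of sphere sample points per atom for SASA.
    sasa_points: int = 960
    #: Reference maximum ASA for CYS in A^2.
    cys_max_asa: float = CYS_MAX_ASA
    #: |Spearman r| at or above which descriptors are grouped.
    group_threshold: float = 0.80
    #: Flank half-widths tried in order when mapping to reference numbering.
    flank_halfwidths: Sequence[int] = (10, 15, 20)
    #: Min-max scale descriptors to [0, 1] before weighting.  Raw mode applies
    #: the variance-proportional weights to unscaled descriptor values.
    scale_descriptors: bool = True
    #: Organism keywords used by the taxonomy filter when none are given.
    taxa: Sequence[str] = MAMMAL_KEYWORDS
    #: Keep pairs spanning two different protein entities.
    keep_hetero_entity: bool = True
    #: Random seed threaded through fixture generation.
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flank_halfwidths"] = list(self.flank_halfwidths)
        d["taxa"] = list(self.taxa)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


DEFAULT_CONFIG = RunConfig()
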