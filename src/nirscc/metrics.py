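"""Channel-level scalp-cortex correlation metrics and probe-design zoning.

Four metrics summarise what a source-detector channel "sees":

* **NCBR** - number of corresponding brain regions: parcels whose normalized
  partial pathlength Lnorm exceeds 0.05 (strict inequality).
* **MLCBR** - the most likely corresponding brain region: argmax of Lnorm;
  its Lnorm value is the channel's *selectivity*.
* **sensitivity** - the absolute partial pathlength (mm) of the MLCBR.
* **consistency** - whether the MLCBR of the same scalp point agrees across
  the 0/1/2-year-old head models (five categories).

Channels are further zoned for probe design: *red* if sensitivity < 3 mm
(too little brain signal regardless of specificity), otherwise *green* if
selectivity > 0.4 and *yellow* if not.  Equality at a boundary goes to the
non-extreme class.  A robustness variant uses thresholds (4, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sensitivity import RegionPathlengths

__all__ = [
    "SCCConfig",
    "SCCRecord",
    "CONSISTENCY_LABELS",
    "ncbr",
    "mlcbr",
    "consistency",
    "zone_classify",
    "zone_ratios",
    "records_to_frame",
]

CONSISTENCY_LABELS = (
    "completely_consistent",
    "consistent_0_1",
    "consistent_0_2",
    "consistent_1_2",
    "inconsistent",
)


@dataclass(frozen=True)
class SCCConfig:
    """Thresholds of the channel metrics."""

    ncbr_threshold: float = 0.05
    sensitivity_threshold: float = 3.0  # mm
    selectivity_threshold: float = 0.4
    alt_thresholds: tuple = (4.0, 0.5)

    def __post_init__(self):
        if min(self.ncbr_threshold, self.sensitivity_threshold, self.selectivity_threshold) <= 0:
            raise ValueError("all thresholds must be > 0")

    def robustness_variant(self) -> "SCCConfig":
        s, q = self.alt_thresholds
        return SCCConfig(
            ncbr_threshold=self.ncbr_threshold,
            sensitivity_threshold=s,
            selectivity_threshold=q,
            alt_thresholds=self.alt_thresholds,
        )


@dataclass
class SCCRecord:
    """All channel metrics for one (fiducial, orientation, distance, age)."""

    fiducial_label: str
    orientation: str
    distance: float
    age_label: str
    ncbr: int
    mlcbr: int
    selectivity: float
    sensitivity: float
    zone: str
    mlcbr_name: str = ""
    pmdf_extent: int = 0  # nodes with PMDF above 1% of its maximum


def ncbr(L: RegionPathlengths, cfg: SCCConfig = SCCConfig()) -> int:
    """Count of parcels whose Lnorm is strictly above the threshold."""
    return int(sum(1 for v in L.L_norm.values() if v > cfg.ncbr_threshold))


def mlcbr(L: RegionPathlengths) -> tuple:
    """(parcel id, selectivity) of the largest Lnorm; ties -> smallest id."""
    items = [(rid, v) for rid, v in L.L_norm.items() if v > 0]
    if not items:
        raise ValueError("all normalized pathlengths are zero")
    best = max(items, key=lambda kv: (kv[1], -kv[0]))
    return int(best[0]), float(best[1])


def consistency(mlcbr_0yo: int, mlcbr_1yo: int, mlcbr_2yo: int) -> str:
    """Five-way consistency of the MLCBR across the three ages.

    All three equal -> completely consistent (takes precedence); exactly one
    matching pair -> the corresponding pairwise category; otherwise
    inconsistent.
    """
    a, b, c = mlcbr_0yo, mlcbr_1yo, mlcbr_2yo
    if a == b == c:
        return "completely_consistent"
    if a == b:
        return "consistent_0_1"
    if a == c:
        return "consistent_0_2"
    if b == c:
        return "consistent_1_2"
    return "inconsistent"


def zone_classify(sensitivity: float, selectivity: float, cfg: SCCConfig = SCCConfig()) -> str:
    """red / yellow / green zoning of a channel.

    Red if sensitivity < threshold (sensitivity takes precedence); among the
    rest, green if selectivity > threshold, else yellow.  Boundary equality is
    non-red / non-green respectively.
    """
    if not (np.isfinite(sensitivity) and np.isfinite(selectivity)):
        raise ValueError("sensitivity and selectivity must be finite")
    if sensitivity < cfg.sensitivity_threshold:
        return "red"
    return "green" if selectivity > cfg.selectivity_threshold else "yellow"


def zone_ratios(records: list) -> pd.DataFrame:
    """Per-distance fraction of channels in each zone (rows sum to 1)."""
    df = records_to_frame(records)
    out = (
        df.groupby("distance")["zone"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=["green", "yellow", "red"], fill_value=0.0)
    )
    out.columns.name = None
    return out


def records_to_frame(records: list) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])
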