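"""Model-free survey summaries: per-site detection proportions and effort.

The per-site detection proportion y_i/n_i is the "naive" detection
probability of a site — the fraction of active occasions on which the
species was recorded.  It is also how the large-predator covariate is built
from a tiger/leopard detection matrix.  Trap nights are accounted as
active occasions x days per occasion (weekly occasions by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import DetectionHistory

__all__ = ["NaiveSiteStats", "DatasetSummary", "site_detection_proportions", "dataset_summary"]


@dataclass
class NaiveSiteStats:
    table: pd.DataFrame  # site_id, detection_proportion, detected

    def values(self) -> np.ndarray:
        return self.table["detection_proportion"].to_numpy()

    def to_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.table.to_csv(fh, index=False)


@dataclass
class DatasetSummary:
    total_detections: int
    n_detected_sites: int
    n_sites: int
    total_trap_occasions: int
    trap_nights: int
    days_per_occasion: int

    @property
    def naive_occupancy(self) -> float:
        return self.n_detected_sites / self.n_sites

    def __str__(self) -> str:
        return (
            f"{self.total_detections} detections across {self.n_detected_sites} "
            f"of {self.n_sites} sites (naive occupancy "
            f"{self.naive_occupancy:.3f}); {self.total_trap_occasions} "
            f"trap-occasions = {self.trap_nights} trap nights at "
            f"{self.days_per_occasion} days/occasion"
        )


def site_detection_proportions(history: DetectionHistory) -> NaiveSiteStats:
    """y_i / n_i per site, with a detected indicator."""
    prop = history.y / history.n
    return NaiveSiteStats(
        pd.DataFrame(
            {
                "site_id": history.site_ids,
                "detection_proportion": prop,
                "detected": history.y > 0,
            }
        )
    )


def dataset_summary(history: DetectionHistory, days_per_occasion: int = 7) -> DatasetSummary:
    """Detection and effort totals; trap nights = active occasions x days."""
    if days_per_occasion < 1:
        raise ValueError("days_per_occasion must be >= 1")
    occasions = int(history.n.sum())
    return DatasetSummary(
        total_detections=int(history.y.sum()),
        n_detected_sites=int((history.y > 0).sum()),
        n_sites=history.n_sites,
        total_trap_occasions=occasions,
        trap_nights=occasions * days_per_occasion,
        days_per_occasion=days_per_occasion,
    )
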