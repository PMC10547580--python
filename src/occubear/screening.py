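"""Collinearity screening of the occupancy predictors.

Pairwise Pearson correlation over all C(7,2) = 21 unordered predictor
pairs; pairs with |r| strictly above the threshold (default 0.7, the
conventional collinearity rule in the occupancy literature) are flagged.
Flagging is advisory — the pipeline proceeds and leaves predictor choice to
the analyst.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .data_io import PREDICTOR_COLUMNS, SiteCovariates

__all__ = ["CorrelationReport", "correlation_screen"]


@dataclass
class CorrelationReport:
    pairs: pd.DataFrame  # columns: var_a, var_b, r, flagged
    threshold: float

    @property
    def flagged(self) -> pd.DataFrame:
        return self.pairs[self.pairs["flagged"]].reset_index(drop=True)

    @property
    def any_flagged(self) -> bool:
        return bool(self.pairs["flagged"].any())

    def to_csv(self, path, header: str | None = None) -> None:
        with open(path, "w") as fh:
            if header:
                fh.write(f"# {header}\n")
            self.pairs.to_csv(fh, index=False)

    def __str__(self) -> str:
        lines = [f"correlation screen (|r| > {self.threshold:g} flagged)"]
        for row in self.pairs.itertuples(index=False):
            mark = "  <-- flagged" if row.flagged else ""
            lines.append(f"  {row.var_a:>12s} ~ {row.var_b:<12s} r = {row.r:+.3f}{mark}")
        return "\n".join(lines)


def correlation_screen(
    cov: SiteCovariates,
    threshold: float = 0.7,
    columns: list[str] | None = None,
) -> CorrelationReport:
    """Pearson r for every unordered predictor pair, flagged at |r| > threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cols = columns if columns is not None else PREDICTOR_COLUMNS
    if cov.n_sites < 3:
        raise ValueError("correlation screening needs at least 3 sites")
    sub = cov.table[cols]
    dead = sub.columns[sub.std(ddof=1) == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance predictor(s) {dead}: correlation undefined")
    corr = sub.corr(method="pearson")
    rows = [
        {"var_a": a, "var_b": b, "r": corr.loc[a, b],
         "flagged": bool(np.abs(corr.loc[a, b]) > threshold)}
        for a, b in combinations(cols, 2)
    ]
    return CorrelationReport(pairs=pd.DataFrame(rows), threshold=threshold)
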