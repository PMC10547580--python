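"""Reading, validation, and standardization of camera-trap survey data.

This module is the single source of truth for the site/occasion data model
used everywhere else in the package: a site-by-occasion binary detection
matrix (``DetectionHistory``) and a per-site covariate table
(``SiteCovariates``).  Detection data are collapsed to the per-site
sufficient statistics ``(y_i, n_i)`` — the number of occasions with a
detection and the number of active (non-missing) occasions — which is exact
for a detection probability that is constant across occasions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PREDICTOR_COLUMNS",
    "COORD_COLUMNS",
    "DetectionHistory",
    "SiteCovariates",
    "StandardizationSpec",
    "read_detection_matrix",
    "read_covariates",
    "write_detection_matrix",
    "write_covariates",
    "standardize",
]

#: The seven occupancy predictors, in the order they enter the logit-linear
#: occupancy equation (after the intercept).
PREDICTOR_COLUMNS = [
    "cc",
    "livestock",
    "predators",
    "human",
    "d_settlement",
    "d_road",
    "d_water",
]

COORD_COLUMNS = ["x", "y"]

_COVARIATE_COLUMNS = ["site_id", *COORD_COLUMNS, *PREDICTOR_COLUMNS]


@dataclass
class DetectionHistory:
    """Per-site detection counts with effort bookkeeping.

    Attributes
    ----------
    site_ids : np.ndarray
        Ordered site identifiers (order preserved from input).
    occasion_matrix : pd.DataFrame
        Site x occasion values in {0, 1, NaN}; NaN marks an inactive occasion.
    y : np.ndarray
        Per-site count of occasions with a detection (sum of non-missing 1s).
    n : np.ndarray
        Per-site count of active occasions.
    """

    site_ids: np.ndarray
    occasion_matrix: pd.DataFrame
    y: np.ndarray = field(init=False)
    n: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        mat = self.occasion_matrix.to_numpy(dtype=float)
        bad = ~(np.isnan(mat) | (mat == 0) | (mat == 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"detection matrix cell must be 0, 1 or NA: site "
                f"{self.site_ids[r]!r}, column {self.occasion_matrix.columns[c]!r} "
                f"has value {mat[r, c]!r}"
            )
        self.y = np.nansum(mat, axis=1).astype(np.int64)
        self.n = np.sum(~np.isnan(mat), axis=1).astype(np.int64)
        if (self.n == 0).any():
            dead = self.site_ids[self.n == 0]
            raise ValueError(
                f"sites with no usable occasions (all NA): {list(dead)}"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_occasions(self) -> int:
        return self.occasion_matrix.shape[1]


@dataclass
class SiteCovariates:
    """Validated per-site covariate table.

    ``table`` carries site_id, projected coordinates (metres), and the seven
    occupancy predictors.  ``standardized`` records whether the predictor
    columns have been z-scored.
    """

    table: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _COVARIATE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"covariate table missing columns: {missing}")
        t = self.table
        if t["site_id"].duplicated().any():
            dup = t.loc[t["site_id"].duplicated(), "site_id"].tolist()
            raise ValueError(f"duplicate site_id in covariates: {dup}")
        num = t[[*COORD_COLUMNS, *PREDICTOR_COLUMNS]]
        if num.isna().any().any():
            col = num.columns[num.isna().any()][0]
            sites = t.loc[num[col].isna(), "site_id"].tolist()
            raise ValueError(f"missing values in {col!r} at sites {sites}")
        if not self.standardized:
            self._check_ranges()

    def _check_ranges(self) -> None:
        t = self.table

        def _fail(col: str, mask: pd.Series, why: str) -> None:
            if mask.any():
                sites = t.loc[mask, "site_id"].tolist()
                raise ValueError(f"{col} {why} at sites {sites}")

        _fail("cc", (t["cc"] < 0) | (t["cc"] > 100), "outside [0, 100]")
        _fail("predators", (t["predators"] < 0) | (t["predators"] > 1),
              "outside [0, 1]")
        for col in ("human", "livestock"):
            _fail(col, t[col] < 0, "negative count")
        for col in ("d_settlement", "d_road", "d_water"):
            _fail(col, t[col] < 0, "negative distance")

    @property
    def site_ids(self) -> np.ndarray:
        return self.table["site_id"].to_numpy()

    @property
    def n_sites(self) -> int:
        return len(self.table)

    def predictor_matrix(self) -> np.ndarray:
        """(n_sites, 7) array of predictors in canonical column order."""
        return self.table[PREDICTOR_COLUMNS].to_numpy(dtype=float)

    def coords(self) -> np.ndarray:
        return self.table[COORD_COLUMNS].to_numpy(dtype=float)


@dataclass(frozen=True)
class StandardizationSpec:
    """Per-covariate (mean, SD) used for z-scoring; SD uses the n-1 denominator."""

    means: pd.Series
    sds: pd.Series

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.means.index:
            out[col] = (out[col] - self.means[col]) / self.sds[col]
        return out


def read_detection_matrix(path) -> DetectionHistory:
    """Read a site x occasion CSV (site_id, occ_1..occ_J; cells 0/1/NA)."""
    df = pd.read_csv(path, comment="#")
    if "site_id" not in df.columns:
        raise ValueError("detection CSV must have a site_id column")
    occ_cols = [c for c in df.columns if c != "site_id"]
    if not occ_cols:
        raise ValueError("detection CSV must have at least one occasion column")
    return DetectionHistory(
        site_ids=df["site_id"].to_numpy(),
        occasion_matrix=df[occ_cols].astype(float),
    )


def read_covariates(path, history: DetectionHistory | None = None) -> SiteCovariates:
    """Read and validate a covariate CSV; optionally align 1:1 with detection sites."""
    df = pd.read_csv(path, comment="#")
    cov = SiteCovariates(df)
    if history is not None:
        cov = align_covariates(cov, history)
    return cov


def align_covariates(cov: SiteCovariates, history: DetectionHistory) -> SiteCovariates:
    """Reorder covariate rows to match detection sites; error on any mismatch."""
    t = cov.table.set_index("site_id")
    want = pd.Index(history.site_ids, name="site_id")
    orphans = want.difference(t.index)
    if len(orphans):
        raise ValueError(f"covariate table missing detection sites: {list(orphans)}")
    extra = t.index.difference(want)
    if len(extra):
        raise ValueError(f"covariate table has sites with no detection row: {list(extra)}")
    out = t.loc[want].reset_index()
    return SiteCovariates(out, standardized=cov.standardized)


def write_detection_matrix(history: DetectionHistory, path, header: str | None = None) -> None:
    df = history.occasion_matrix.copy()
    df.insert(0, "site_id", history.site_ids)
    _write_csv(df, path, header, float_format="%.0f")


def write_covariates(cov: SiteCovariates, path, header: str | None = None) -> None:
    _write_csv(cov.table, path, header)


def _write_csv(df: pd.DataFrame, path, header: str | None, **kw) -> None:
    buf = io.StringIO()
    if header:
        buf.write(f"# {header}\n")
    df.to_csv(buf, index=False, na_rep="NA", **kw)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def standardize(cov: SiteCovariates) -> tuple[SiteCovariates, StandardizationSpec]:
    """Z-score the seven predictors (sample SD, n-1 denominator).

    Returns the standardized table plus the ``StandardizationSpec`` needed to
    standardize prediction inputs or back-transform coefficients.  Raises on
    a zero-variance predictor, which cannot be scaled (remove it instead).
    """
    if cov.n_sites < 2:
        raise ValueError("standardization needs at least 2 sites")
    sub = cov.table[PREDICTOR_COLUMNS]
    means = sub.mean()
    sds = sub.std(ddof=1)
    dead = sds.index[(sds == 0) | ~np.isfinite(sds)].tolist()
    if dead:
        raise ValueError(
            f"zero-variance covariate(s) {dead}: cannot standardize; "
            "remove them from the model"
        )
    spec = StandardizationSpec(means=means, sds=sds)
    return SiteCovariates(spec.apply(cov.table), standardized=True), spec
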