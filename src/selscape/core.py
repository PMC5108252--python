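"""Trait tables and scaling transforms shared by every analysis stage.

Phenotypes enter the pipeline as an individuals-by-traits table.  Three
scalings are supported: variance standardization (the Lande–Arnold
convention for selection-gradient regressions), mean standardization
(dimensionless trait values in units of a reference taxon's means, used
for all P/D/γ comparisons), and the natural log.  Every transform records
a :class:`ScalingSpec` so results can be mapped back to the raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical trait order used by all packaged fixtures.
DEFAULT_TRAITS = ("PN", "MD", "ML")
DEFAULT_UNITS = ("mm", "darkness (0-255)", "darkness (0-255)")

VALID_SCALE_TAGS = frozenset(
    {"raw", "variance_standardized", "mean_standardized", "log"}
)


@dataclass(frozen=True)
class ScalingSpec:
    """Record of a scaling applied to a trait table.

    Parameters
    ----------
    scheme : {"variance", "mean", "log", "none"}
    reference_means, reference_sds : ndarray or "internal"
        The constants used, kept for exact back-transformation.
    """

    scheme: str = "none"
    reference_means: object = "internal"
    reference_sds: object = "internal"

    def __post_init__(self):
        if self.scheme not in {"variance", "mean", "log", "none"}:
            raise ValueError(f"unknown scaling scheme {self.scheme!r}")
        for attr in ("reference_means", "reference_sds"):
            val = getattr(self, attr)
            if isinstance(val, str):
                if val != "internal":
                    raise ValueError(f"{attr} must be a vector or 'internal'")
            else:
                arr = np.asarray(val, dtype=float)
                if self.scheme in {"mean", "log"} and attr == "reference_means":
                    if np.any(arr <= 0):
                        raise ValueError(
                            f"{attr} must be strictly positive for scheme "
                            f"{self.scheme!r}"
                        )
                object.__setattr__(self, attr, arr)


@dataclass
class TraitMatrix:
    """Individuals-by-traits numeric table with labels, units and scale tag.

    ``group`` and ``sex`` are optional per-row factors (e.g. rearing year,
    taxon) used by pooled estimators.
    """

    values: np.ndarray
    trait_labels: tuple = DEFAULT_TRAITS
    units: tuple = DEFAULT_UNITS
    scale_tag: str = "raw"
    group: np.ndarray | None = None
    sex: np.ndarray | None = None
    scaling: ScalingSpec = field(default_factory=ScalingSpec)

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        n, p = self.values.shape
        if p < 2:
            raise ValueError(f"need at least 2 traits, got {p}")
        if len(self.trait_labels) != p:
            raise ValueError("trait_labels length does not match columns")
        if self.scale_tag not in VALID_SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if np.isnan(self.values).any():
            raise ValueError("TraitMatrix may not contain missing values")
        for attr in ("group", "sex"):
            val = getattr(self, attr)
            if val is not None:
                val = np.asarray(val)
                if val.shape[0] != n:
                    raise ValueError(f"{attr} length does not match rows")
                setattr(self, attr, val)

    # -- basic views -----------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.trait_labels))
        if self.group is not None:
            df.insert(0, "group", self.group)
        if self.sex is not None:
            df.insert(0, "sex", self.sex)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait_labels=DEFAULT_TRAITS,
        units=DEFAULT_UNITS,
        scale_tag: str = "raw",
        group: str | None = None,
        sex: str | None = None,
    ) -> "TraitMatrix":
        """Build a TraitMatrix from a dataframe, dropping incomplete rows.

        Rows with any missing trait value are dropped with a logged count
        (no imputation).
        """
        sub = df[list(trait_labels)]
        ok = sub.notna().all(axis=1)
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("dropping %d rows with missing trait values", n_drop)
        kept = df.loc[ok]
        return cls(
            values=kept[list(trait_labels)].to_numpy(dtype=float),
            trait_labels=tuple(trait_labels),
            units=tuple(units),
            scale_tag=scale_tag,
            group=None if group is None else kept[group].to_numpy(),
            sex=None if sex is None else kept[sex].to_numpy(),
        )


def variance_standardize(X: TraitMatrix) -> TraitMatrix:
    """Center each trait and divide by its sample SD (n−1 denominator).

    The standard pre-processing for selection-gradient regressions: the
    resulting columns have mean 0 and variance 1, so β and γ are in units
    of phenotypic standard deviations.
    """
    vals = X.values
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    bad = np.flatnonzero(sds <= 0)
    if bad.size:
        names = ", ".join(X.trait_labels[i] for i in bad)
        raise ValueError(f"zero-variance trait column(s): {names}")
    out = (vals - means) / sds
    return replace(
        X,
        values=out,
        scale_tag="variance_standardized",
        scaling=ScalingSpec("variance", means, sds),
    )


def mean_standardize(X: TraitMatrix, ref: ScalingSpec | None = None) -> TraitMatrix:
    """Divide each trait by a reference mean (default: its own column mean).

    With the internal reference every column mean becomes exactly 1;
    with an external reference (e.g. the *P. a. americana* museum means)
    values are expressed as proportions of that taxon's trait means,
    making selection, variance and divergence directly comparable.
    """
    vals = X.values
    if ref is None or (isinstance(ref.reference_means, str)):
        ref_means = vals.mean(axis=0)
    else:
        ref_means = np.asarray(ref.reference_means, dtype=float)
        if ref_means.shape != (X.p,):
            raise ValueError("reference means length does not match traits")
    if np.any(ref_means <= 0):
        bad = np.flatnonzero(ref_means <= 0)
        names = ", ".join(X.trait_labels[i] for i in bad)
        raise ValueError(f"non-positive reference mean for: {names}")
    out = vals / ref_means
    return replace(
        X,
        values=out,
        scale_tag="mean_standardized",
        scaling=ScalingSpec("mean", ref_means, "internal"),
    )


def log_transform(X: TraitMatrix) -> TraitMatrix:
    """Natural-log transform; errors on non-positive values naming row/trait."""
    vals = X.values
    bad = np.argwhere(vals <= 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-positive value at row {r}, trait {X.trait_labels[c]}: "
            f"{vals[r, c]}"
        )
    return replace(X, values=np.log(vals), scale_tag="log",
                   scaling=ScalingSpec("log"))


# -- CSV interfaces ------------------------------------------------------

INDIVIDUAL_COLUMNS = ("id", "taxon", "sex", "year", "PN", "MD", "ML", "fitness")


def read_individual_table(path) -> pd.DataFrame:
    """Read an individual-level table (id, taxon, sex, year, PN, MD, ML, fitness)."""
    df = pd.read_csv(path)
    missing = [c for c in ("PN", "MD", "ML") if c not in df.columns]
    if missing:
        raise ValueError(f"individual table missing trait columns: {missing}")
    return df


def read_taxon_table(path) -> pd.DataFrame:
    """Read a taxon-mean table (taxon, n, <trait>_mean, <trait>_sd columns)."""
    df = pd.read_csv(path)
    if "taxon" not in df.columns or "n" not in df.columns:
        raise ValueError("taxon table must have 'taxon' and 'n' columns")
    return df
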