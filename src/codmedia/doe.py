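"""Central composite designs (CCD) for fermentation-medium optimization.

A circumscribed CCD for k factors combines a two-level factorial core
(full, or a resolution-V half fraction for k=5), 2k axial ("star") points
at coded distance ±alpha along each factor axis, and replicated center
points.  Factor values are handled in two unit systems:

* *uncoded*: physical concentrations (g/50 mL; mL/50 mL for glycerol),
* *coded*: dimensionless levels where the factorial levels are ±1 and the
  center is 0, via ``coded = (uncoded - center) / half_range``.

Star levels that would fall at or below zero concentration are floored at
a small positive ``low_clip`` so that every design point remains a
physically realizable medium.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "InvalidFactorError",
    "FixtureIntegrityError",
    "generate_ccd",
    "code_values",
    "decode_values",
    "load_paper_fixture",
    "cod_factors",
]


class InvalidFactorError(ValueError):
    """A factor specification violates its invariants."""


class FixtureIntegrityError(RuntimeError):
    """The bundled design fixture does not match its recorded checksum."""


@dataclass(frozen=True)
class FactorSpec:
    """One medium component's position in the design space.

    Parameters
    ----------
    name : str
        Column name of the component (e.g. ``"soybean"``).
    center : float
        Concentration at the design center (coded 0).
    half_range : float
        Distance from the center to the ±1 factorial levels, in the same
        units as ``center``.  Must be positive.
    alpha : float
        Star-point distance in coded units (≥ 1).
    low_clip : float
        Minimum allowed uncoded value; star levels falling below it are
        floored here.
    units : str
        Physical units, for reporting only.
    """

    name: str
    center: float
    half_range: float
    alpha: float = 2.0
    low_clip: float = 0.0
    units: str = "g/50 mL"

    def __post_init__(self) -> None:
        if not self.half_range > 0:
            raise InvalidFactorError(
                f"factor {self.name!r}: half_range must be > 0, got {self.half_range}"
            )
        if self.alpha < 1:
            raise InvalidFactorError(
                f"factor {self.name!r}: alpha must be >= 1, got {self.alpha}"
            )

    @property
    def star_low(self) -> float:
        return max(self.center - self.alpha * self.half_range, self.low_clip)

    @property
    def star_high(self) -> float:
        return self.center + self.alpha * self.half_range

    @property
    def bounds(self) -> tuple[float, float]:
        """The design box for this factor: [low star, high star]."""
        return (self.star_low, self.star_high)


#: Factor specifications of the cholesterol-oxidase production medium.
#: Star distance alpha=2 is implied by the star-to-factorial level spacing;
#: lower star levels that would reach 0 are floored at 0.0005.
def cod_factors() -> list[FactorSpec]:
    return [
        FactorSpec("soybean", 0.75, 0.375, 2.0, 0.0005, "g/50 mL"),
        FactorSpec("glycerol", 0.75, 0.375, 2.0, 0.0005, "mL/50 mL"),
        FactorSpec("maltose", 0.75, 0.375, 2.0, 0.0005, "g/50 mL"),
        FactorSpec("mgso4", 0.025, 0.0125, 2.0, 0.0005, "g/50 mL"),
        FactorSpec("nacl", 0.15, 0.075, 2.0, 0.0005, "g/50 mL"),
    ]


CSV_COLUMNS = (
    "run,soybean,glycerol,maltose,mgso4,nacl,point_type,split,observed"
).split(",")

_FIXTURE_NAME = "ccd_cod_table.csv"
_FIXTURE_SHA256 = "db3792181c647985dbd8d209ab197d7ef1fe9b7842d1d1141c323c2b521ee672"


@dataclass
class DesignTable:
    """A run × factor design with optional observed responses.

    The underlying :class:`pandas.DataFrame` has one row per run and
    columns ``run``, one per factor (uncoded values), ``point_type``
    (factorial | star | center), ``split`` (train | test | validation)
    and ``observed`` (response, NaN when not measured).  Reference
    prediction columns (``predicted_rsm``, ``predicted_ann``) may be
    attached by fixture loaders.
    """

    factors: list[FactorSpec]
    df: pd.DataFrame
    coded_exact: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def uncoded(self) -> np.ndarray:
        """(n_runs, k) matrix of physical concentrations."""
        return self.df[self.factor_names].to_numpy(dtype=float)

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) matrix of coded levels.

        For generated designs this is the exact pre-clipping coded matrix;
        for loaded designs it is recomputed from the uncoded values.
        """
        if self.coded_exact is not None:
            return self.coded_exact
        return code_values(self.uncoded, self.factors)

    @property
    def observed(self) -> np.ndarray:
        return self.df["observed"].to_numpy(dtype=float)

    def subset(self, split: str) -> "DesignTable":
        sub = self.df[self.df["split"] == split].reset_index(drop=True)
        coded = None
        if self.coded_exact is not None:
            coded = self.coded_exact[(self.df["split"] == split).to_numpy()]
        return DesignTable(self.factors, sub, coded)

    def with_observed(self, y: np.ndarray) -> "DesignTable":
        df = self.df.copy()
        df["observed"] = np.asarray(y, dtype=float)
        return DesignTable(self.factors, df, self.coded_exact)

    def to_csv(self, path: str | Path) -> None:
        cols = [c for c in self.df.columns if c in CSV_COLUMNS or c.startswith("predicted")]
        self.df[cols].to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, factors: Sequence[FactorSpec]) -> "DesignTable":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS[:-1] if c not in df.columns]
        if missing:
            raise ValueError(f"design CSV is missing columns: {missing}")
        if "observed" not in df.columns:
            df["observed"] = np.nan
        return cls(list(factors), df)


def _as_matrix(values: np.ndarray | Sequence[float], k: int, what: str) -> tuple[np.ndarray, bool]:
    arr = np.asarray(values, dtype=float)
    was_vector = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != k:
        raise ValueError(f"{what} has length {arr.shape[1]}, expected {k} factors")
    return arr, was_vector


def code_values(
    uncoded: np.ndarray | Sequence[float], factors: Sequence[FactorSpec]
) -> np.ndarray:
    """Convert physical concentrations to coded levels.

    ``coded_i = (uncoded_i - center_i) / half_range_i``.  Accepts a single
    composition vector or an (n, k) matrix; returns the same shape.
    """
    arr, was_vector = _as_matrix(uncoded, len(factors), "uncoded vector")
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    coded = (arr - centers) / halves
    return coded[0] if was_vector else coded


def decode_values(
    coded: np.ndarray | Sequence[float], factors: Sequence[FactorSpec]
) -> np.ndarray:
    """Convert coded levels to physical concentrations, flooring at low_clip."""
    arr, was_vector = _as_matrix(coded, len(factors), "coded vector")
    centers = np.array([f.center for f in factors])
    halves = np.array([f.half_range for f in factors])
    clips = np.array([f.low_clip for f in factors])
    uncoded = np.maximum(centers + arr * halves, clips)
    return uncoded[0] if was_vector else uncoded


def _factorial_core(k: int, fraction: Literal["half", "full"]) -> np.ndarray:
    if fraction == "full":
        return np.array(list(itertools.product((-1.0, 1.0), repeat=k)))
    if fraction != "half":
        raise ValueError(f"fraction must be 'half' or 'full', got {fraction!r}")
    # Resolution-V half fraction: defining relation x_k = x_1 x_2 ... x_{k-1}.
    base = np.array(list(itertools.product((-1.0, 1.0), repeat=k - 1)))
    last = np.prod(base, axis=1, keepdims=True)
    return np.hstack([base, last])


def generate_ccd(
    factors: Sequence[FactorSpec],
    n_center: int = 10,
    fraction: Literal["half", "full"] = "half",
) -> DesignTable:
    """Build a circumscribed central composite design.

    Runs are ordered as: factorial core (standard order, first factor
    slowest), star points (per factor, low then high), center replicates.

    Parameters
    ----------
    factors
        Between 2 and 10 factor specifications with unique names.
    n_center
        Number of replicated center points (≥ 1).
    fraction
        ``"full"`` for the 2^k factorial core, ``"half"`` for the 2^(k-1)
        half fraction generated by x_k = x_1···x_{k-1}.
    """
    factors = list(factors)
    k = len(factors)
    if not 2 <= k <= 10:
        raise InvalidFactorError(f"number of factors must be in [2, 10], got {k}")
    if n_center < 1:
        raise ValueError(f"n_center must be >= 1, got {n_center}")
    names = [f.name for f in factors]
    if len(set(names)) != k:
        raise InvalidFactorError(f"duplicate factor names in {names}")

    core = _factorial_core(k, fraction)
    alphas = np.array([f.alpha for f in factors])
    star = np.zeros((2 * k, k))
    for i in range(k):
        star[2 * i, i] = -alphas[i]
        star[2 * i + 1, i] = alphas[i]
    center = np.zeros((n_center, k))
    coded = np.vstack([core, star, center])

    point_type = (
        ["factorial"] * len(core) + ["star"] * (2 * k) + ["center"] * n_center
    )
    uncoded = decode_values(coded, factors)
    df = pd.DataFrame(uncoded, columns=names)
    df.insert(0, "run", np.arange(1, len(df) + 1))
    df["point_type"] = point_type
    df["split"] = "train"
    df["observed"] = np.nan
    return DesignTable(factors, df, coded_exact=coded)


def load_paper_fixture() -> DesignTable:
    """Load the bundled 36-run COD production design and responses.

    Returns the published five-factor CCD with observed activities,
    train/test/validation split labels (24/6/6), and the published
    RSM and ANN prediction columns attached as ``predicted_rsm`` /
    ``predicted_ann`` reference vectors.  The file's SHA-256 checksum is
    verified on load.
    """
    ref = resources.files("codmedia.data").joinpath(_FIXTURE_NAME)
    text = ref.read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise FixtureIntegrityError(
            f"fixture {_FIXTURE_NAME} checksum mismatch: {digest}"
        )
    from io import StringIO

    df = pd.read_csv(StringIO(text))
    return DesignTable(cod_factors(), df)
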