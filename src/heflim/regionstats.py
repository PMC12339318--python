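"""Region statistics: quadrant segmentation, group tests, normalized ratios,
and correlation with clinical liver-function indicators.

The analysis compares per-pixel mean fluorescence lifetimes between cancerous
and adjacent peritumoral tissue.  Each lifetime image is split into four
quadrants, numbered clockwise from the top-left (1 = top-left, 2 = top-right,
3 = bottom-right, 4 = bottom-left), and the quadrant means feed a two-sample
Student t-test.  Within each patient sample, lifetimes are normalized so the
peritumoral mean is 1, making the cancerous/peritumoral ratio comparable
across patients; that ratio is then correlated (Pearson) against clinical
indicators such as bilirubin fractions, transaminases and AFP.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    EmptyRegionError,
    InvalidParameterError,
    NormalizationError,
    UndefinedStatisticError,
)
from .fitting import LifetimeImage

__all__ = [
    "RegionMeasurement",
    "CorrelationResult",
    "quadrant_split",
    "quadrant_means",
    "region_mean_tau",
    "normalize_to_peritumoral",
    "two_sample_ttest",
    "pearson_r",
    "correlate_table",
    "boxplot_summary",
    "load_clinical_table",
    "INDICATOR_COLUMNS",
]

REGIONS = ("peritumoral", "cancerous")

#: Numeric clinical-indicator columns, in the order of the packaged table.
INDICATOR_COLUMNS = [
    "prothrombin_time_s",
    "total_bilirubin_umol_l",
    "direct_bilirubin_umol_l",
    "indirect_bilirubin_umol_l",
    "alt_u_l",
    "ast_u_l",
    "total_plasma_protein_g_l",
    "albumin_g_l",
    "globulin_g_l",
    "afp_ng_ml",
]


@dataclass(frozen=True)
class RegionMeasurement:
    """Mean lifetime of one quadrant of one region of one sample."""

    sample_id: str
    region: str
    quadrant: int
    mean_tau_m: float  # ps

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InvalidParameterError(f"region must be one of {REGIONS}")
        if self.quadrant not in (1, 2, 3, 4):
            raise InvalidParameterError("quadrant must be 1-4")
        if not self.mean_tau_m > 0:
            raise InvalidParameterError("mean_tau_m must be positive")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of lifetime ratio against one indicator."""

    indicator: str
    r: float
    n: int


def quadrant_split(image: np.ndarray | LifetimeImage) -> dict[int, np.ndarray]:
    """Split an image into four quadrants numbered clockwise from top-left.

    1 = top-left, 2 = top-right, 3 = bottom-right, 4 = bottom-left.  Odd
    dimensions use a floor split: the top row block and left column block get
    the smaller halves.  The quadrants partition the image exactly.

    For a ``LifetimeImage`` the tau_m map is split with masked-out pixels as
    NaN; a bare 2-D array is split as-is.
    """
    if isinstance(image, LifetimeImage):
        arr = np.where(image.mask, image.tau_m_map, np.nan)
    else:
        arr = np.asarray(image)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InvalidParameterError("image must be 2-D with both dimensions >= 2")
    r0, c0 = arr.shape[0] // 2, arr.shape[1] // 2
    return {
        1: arr[:r0, :c0],  # top-left
        2: arr[:r0, c0:],  # top-right
        3: arr[r0:, c0:],  # bottom-right
        4: arr[r0:, :c0],  # bottom-left
    }


def region_mean_tau(
    image: LifetimeImage | np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Arithmetic mean lifetime over the masked-in pixels of a region, ps."""
    if isinstance(image, LifetimeImage):
        arr, m = image.tau_m_map, image.mask
    else:
        arr = np.asarray(image, dtype=float)
        m = ~np.isnan(arr)
    if mask is not None:
        m = m & np.asarray(mask, dtype=bool)
    if not m.any():
        raise EmptyRegionError("no pixels in region")
    return float(np.mean(arr[m]))


def quadrant_means(
    image: LifetimeImage | np.ndarray, sample_id: str, region: str
) -> list[RegionMeasurement]:
    """Mean lifetime of each clockwise quadrant, as measurement records."""
    out = []
    for q, sub in quadrant_split(image).items():
        vals = sub[~np.isnan(sub)]
        if vals.size == 0:
            raise EmptyRegionError(f"quadrant {q} has no analyzed pixels")
        out.append(RegionMeasurement(sample_id, region, q, float(vals.mean())))
    return out


def normalize_to_peritumoral(
    measurements: list[RegionMeasurement],
) -> pd.DataFrame:
    """Normalize one sample's measurements by its peritumoral mean.

    The sample's peritumoral quadrant means average to exactly 1 after
    normalization; cancerous values become the lifetime ratio relative to
    that reference.  Scale-invariant: multiplying all of the sample's
    lifetimes by c > 0 changes nothing.
    """
    if not measurements:
        raise InvalidParameterError("no measurements given")
    samples = {m.sample_id for m in measurements}
    if len(samples) != 1:
        raise InvalidParameterError("normalize one sample at a time")
    peri = [m.mean_tau_m for m in measurements if m.region == "peritumoral"]
    if not peri:
        raise NormalizationError(
            f"sample {samples.pop()!r} has no peritumoral measurements"
        )
    ref = float(np.mean(peri))
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in measurements],
            "region": [m.region for m in measurements],
            "quadrant": [m.quadrant for m in measurements],
            "mean_tau_m_ps": [m.mean_tau_m for m in measurements],
            "normalized": [m.mean_tau_m / ref for m in measurements],
        }
    )


def lifetime_ratio(measurements: list[RegionMeasurement]) -> float:
    """One sample's cancerous/peritumoral mean-lifetime ratio."""
    df = normalize_to_peritumoral(measurements)
    canc = df.loc[df.region == "cancerous", "normalized"]
    if canc.empty:
        raise InvalidParameterError("sample has no cancerous measurements")
    return float(canc.mean())


def two_sample_ttest(group_a, group_b) -> tuple[float, float]:
    """Classical two-sided Student t-test with pooled variance.

    Returns (t, p).  Two identical constant groups give t = 0, p = 1 by
    convention (zero pooled variance with equal means).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need two equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


def correlate_table(
    table: pd.DataFrame, indicators: list[str] | None = None
) -> list[CorrelationResult]:
    """Pearson r of the lifetime ratio against each clinical indicator.

    Indicators default to every known numeric indicator column present in the
    table, in canonical order.  Columns where the correlation is undefined
    (constant values) are reported with r = NaN.
    """
    if "lifetime_ratio" not in table.columns:
        raise InvalidParameterError("table must contain a 'lifetime_ratio' column")
    if len(table) < 3:
        raise InvalidParameterError("need at least 3 patients")
    if indicators is None:
        indicators = [c for c in INDICATOR_COLUMNS if c in table.columns]
        extra = [
            c
            for c in table.columns
            if c not in INDICATOR_COLUMNS
            and c not in ("sample", "cnlc_stage", "lifetime_ratio")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
        indicators += extra
    ratio = table["lifetime_ratio"].to_numpy(dtype=float)
    out = []
    for col in indicators:
        vals = table[col].to_numpy(dtype=float)
        try:
            r = pearson_r(ratio, vals)
        except UndefinedStatisticError:
            r = float("nan")
        out.append(CorrelationResult(indicator=col, r=r, n=len(table)))
    return out


def boxplot_summary(values) -> dict[str, float]:
    """Median, quartiles (linear interpolation), IQR and mean of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidParameterError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(q3 - q1),
        "mean": float(v.mean()),
    }


def load_clinical_table() -> pd.DataFrame:
    """The packaged 4-patient hepatocellular-carcinoma clinical table.

    Per-patient China Liver Cancer (CNLC) stage, measured cancerous/
    peritumoral lifetime ratio, and the preoperative liver-function panel.
    """
    ref = importlib.resources.files("heflim.data").joinpath("table1.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
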