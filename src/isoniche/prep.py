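"""Preprocessing and univariate niche metrics for isotope tables.

Covers three steps that precede ellipsoid fitting:

* arithmetic lipid normalization of delta13C from the tissue C:N ratio
  (lipids are depleted in 13C relative to protein, so fatty muscle reads
  artificially negative);
* Layman-style per-group isotope ranges CR, NR, SR (max minus min of
  delta13C, delta15N, delta34S);
* Mardia's multivariate normality test (skewness and kurtosis), with the
  small-sample skewness correction for n < 20.

Input tables are pandas DataFrames with columns
``species, area, total_length_mm, d13C, d15N, d34S, CN_ratio``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError, DegenerateCovarianceError

__all__ = [
    "REQUIRED_COLUMNS",
    "ISOTOPE_COLUMNS",
    "LaymanRanges",
    "MardiaResult",
    "lipid_correct",
    "lipid_correct_table",
    "layman_ranges",
    "mardia_test",
    "validate_table",
]

REQUIRED_COLUMNS = (
    "species",
    "area",
    "total_length_mm",
    "d13C",
    "d15N",
    "d34S",
    "CN_ratio",
)
ISOTOPE_COLUMNS = ("d13C", "d15N", "d34S")
AREAS = ("inner", "outer")

#: C:N above which muscle delta13C is lipid-corrected; also the assumed
#: C:N of pure protein in the mass-balance correction.
CN_THRESHOLD = 3.7
CN_PROTEIN = 3.7

# delta34S outside this range is implausible for marine fish muscle and
# triggers a soft warning, not an exclusion.
_D34S_PLAUSIBLE = (0.0, 40.0)


@dataclasses.dataclass(frozen=True)
class LaymanRanges:
    """Per-group isotope ranges (permil): CR = delta13C, NR = delta15N,
    SR = delta34S, each max minus min."""

    cr: float
    nr: float
    sr: float


@dataclasses.dataclass(frozen=True)
class MardiaResult:
    """Mardia's multivariate skewness and kurtosis test.

    ``normal`` is True when both component p-values exceed ``alpha``.
    ``skew_corrected`` records whether the small-sample correction factor
    was applied to the skewness statistic.
    """

    skew_stat: float
    skew_p: float
    kurt_stat: float
    kurt_p: float
    normal: bool
    n: int
    skew_corrected: bool
    alpha: float = 0.05


def lipid_correct(
    d13c_sample,
    c_to_n,
    threshold: float = CN_THRESHOLD,
    c_to_n_protein: float = CN_PROTEIN,
):
    """Mass-balance lipid correction of delta13C from the C:N ratio.

    When ``c_to_n > threshold`` returns

        ((d13C_sample * C:N_sample) + 7 * (C:N_sample - C:N_protein))
        / C:N_sample

    otherwise the input unchanged.  Accepts scalars or arrays; returns
    ``(corrected, applied)`` where ``applied`` flags rows the correction
    touched.  Not idempotent on the corrected branch — callers must track
    the flag rather than re-apply.
    """
    d13c = np.asarray(d13c_sample, dtype=float)
    cn = np.asarray(c_to_n, dtype=float)
    if np.any(cn <= 0):
        raise ValidationError("C:N ratio must be positive")
    applied = cn > threshold
    corrected = np.where(
        applied,
        (d13c * cn + 7.0 * (cn - c_to_n_protein)) / cn,
        d13c,
    )
    if np.isscalar(d13c_sample) or np.ndim(d13c_sample) == 0:
        return float(corrected), bool(applied)
    return corrected, applied


def lipid_correct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply the lipid correction to a table's ``d13C`` column, once.

    Adds (or respects) a ``lipid_corrected`` flag column so that running
    the step twice cannot re-apply the correction to already corrected
    rows.
    """
    out = table.copy()
    if "lipid_corrected" not in out.columns:
        out["lipid_corrected"] = False
    todo = ~out["lipid_corrected"].to_numpy(dtype=bool)
    if todo.any():
        corrected, applied = lipid_correct(
            out.loc[todo, "d13C"].to_numpy(),
            out.loc[todo, "CN_ratio"].to_numpy(),
        )
        out.loc[todo, "d13C"] = corrected
        out.loc[todo, "lipid_corrected"] = applied
    return out


def layman_ranges(data) -> LaymanRanges:
    """Isotope ranges CR/NR/SR (max minus min per axis) for one group.

    ``data`` is either an ``n x 3`` array in (d13C, d15N, d34S) order or a
    DataFrame carrying those columns.  Undefined for singleton groups.
    """
    if isinstance(data, pd.DataFrame):
        data = data.loc[:, list(ISOTOPE_COLUMNS)].to_numpy(dtype=float)
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValidationError(
            f"expected an n x 3 matrix, got shape {data.shape}"
        )
    if data.shape[0] < 2:
        raise ValidationError(
            "range undefined: need at least 2 rows per group"
        )
    spans = data.max(axis=0) - data.min(axis=0)
    return LaymanRanges(cr=float(spans[0]), nr=float(spans[1]), sr=float(spans[2]))


def mardia_test(
    data: np.ndarray,
    corrected_skewness: bool | None = None,
    alpha: float = 0.05,
) -> MardiaResult:
    """Mardia's multivariate normality test for trivariate data.

    With ``g_ij`` the doubly centred Mahalanobis inner products (using
    the maximum-likelihood covariance), multivariate skewness is
    ``b1 = mean_{ij}(g_ij^3)`` and kurtosis ``b2 = mean_i(g_ii^2)``.  The
    skewness statistic ``n b1 / 6`` is chi-square with
    ``p(p+1)(p+2)/6 = 10`` degrees of freedom; for small samples it is
    multiplied by the correction factor
    ``(p+1)(n+1)(n+3) / (n ((n+1)(p+1) - 6))``.  Kurtosis is compared to
    its normal limit ``p(p+2) = 15`` with variance ``8p(p+2)/n``.

    ``corrected_skewness=None`` applies the correction automatically when
    ``n < 20``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 3:
        raise ValidationError(
            f"expected an n x 3 matrix, got shape {data.shape}"
        )
    n, p = data.shape
    if n < 5:
        raise ValidationError("Mardia's test needs at least 5 rows")
    centered = data - data.mean(axis=0)
    cov_ml = centered.T @ centered / n
    try:
        inv = np.linalg.inv(cov_ml)
    except np.linalg.LinAlgError as err:
        raise DegenerateCovarianceError(str(err)) from err
    g = centered @ inv @ centered.T
    b1 = float((g**3).mean())
    b2 = float((np.diag(g) ** 2).mean())

    if corrected_skewness is None:
        corrected_skewness = n < 20
    skew_stat = n * b1 / 6.0
    if corrected_skewness:
        skew_stat *= (p + 1) * (n + 1) * (n + 3) / (
            n * ((n + 1) * (p + 1) - 6)
        )
    df_skew = p * (p + 1) * (p + 2) // 6
    skew_p = float(stats.chi2.sf(skew_stat, df=df_skew))

    kurt_mean = p * (p + 2)
    kurt_var = 8.0 * p * (p + 2) / n
    kurt_stat = (b2 - kurt_mean) / np.sqrt(kurt_var)
    kurt_p = float(2.0 * stats.norm.sf(abs(kurt_stat)))

    return MardiaResult(
        skew_stat=float(skew_stat),
        skew_p=skew_p,
        kurt_stat=float(kurt_stat),
        kurt_p=kurt_p,
        normal=bool(skew_p > alpha and kurt_p > alpha),
        n=n,
        skew_corrected=bool(corrected_skewness),
        alpha=alpha,
    )


def validate_table(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Validate an isotope table, excluding (and reporting) bad rows.

    Checks the required columns exist, drops rows with missing isotope
    values, non-positive C:N, or an area outside {inner, outer}, and
    warns (without excluding) on delta34S outside the plausible 0-40
    permil window.  Returns the clean table and a list of
    ``(row_label, reason)`` exclusions.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    exclusions: list[tuple[int, str]] = []
    keep = pd.Series(True, index=table.index)

    iso_missing = table[list(ISOTOPE_COLUMNS) + ["CN_ratio"]].isna().any(axis=1)
    for idx in table.index[iso_missing]:
        exclusions.append((idx, "missing isotope or C:N value"))
    keep &= ~iso_missing

    bad_cn = (~iso_missing) & (table["CN_ratio"] <= 0)
    for idx in table.index[bad_cn]:
        exclusions.append((idx, "non-positive C:N ratio"))
    keep &= ~bad_cn

    bad_area = ~table["area"].isin(AREAS)
    for idx in table.index[bad_area]:
        exclusions.append((idx, f"area not in {AREAS}"))
    keep &= ~bad_area

    clean = table.loc[keep].copy()
    lo, hi = _D34S_PLAUSIBLE
    implausible = (clean["d34S"] < lo) | (clean["d34S"] > hi)
    if implausible.any():
        warnings.warn(
            f"{int(implausible.sum())} rows have delta34S outside the "
            f"plausible range {lo}-{hi} permil; retained",
            UserWarning,
            stacklevel=2,
        )
    return clean, exclusions
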