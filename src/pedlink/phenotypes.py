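"""Social Responsiveness Scale (SRS) phenotype processing.

The SRS is a quantitative measure of autistic social traits.  Raw total
scores are used two ways:

* qualitatively, via published raw-score cutoffs — below 54 unaffected,
  54 to below 87 "spectrum", 87 or above "affected", missing unknown;
* quantitatively, as the residual of the square-root-transformed score
  after regressing out age and sex (males score higher on average).

Rater-quality rules: a score produced by a rater who themselves has an
ASD is dropped entirely; a score from a rater flagged as a poor reporter
is dropped from quantitative analysis only, because under-reporting does
not move the score across a category boundary in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

UNAFFECTED = "unaffected"
SPECTRUM = "spectrum"
AFFECTED = "affected"
UNKNOWN = "unknown"

CATEGORIES = (UNAFFECTED, SPECTRUM, AFFECTED, UNKNOWN)

#: raw-score cutoffs: [0, 54) unaffected, [54, 87) spectrum, [87, inf) affected
SPECTRUM_CUTOFF = 54.0
AFFECTED_CUTOFF = 87.0

PHENOTYPE_COLUMNS = [
    "indiv_id",
    "family_id",
    "raw_srs",
    "version",
    "age",
    "sex",
    "rater_has_asd",
    "rater_poor",
    "clinical_dx",
]


class PhenotypeError(ValueError):
    pass


def categorize(raw_srs: float | None) -> str:
    """Map a raw SRS total score to its qualitative category."""
    if raw_srs is None or (isinstance(raw_srs, float) and np.isnan(raw_srs)):
        return UNKNOWN
    if raw_srs < 0:
        raise PhenotypeError(f"raw SRS score must be non-negative, got {raw_srs}")
    if raw_srs < SPECTRUM_CUTOFF:
        return UNAFFECTED
    if raw_srs < AFFECTED_CUTOFF:
        return SPECTRUM
    return AFFECTED


def read_phenotype_table(path: str) -> pd.DataFrame:
    """Read the delimited phenotype table (header required).

    Tab- and comma-delimited files keep empty fields; otherwise any run
    of whitespace separates columns.
    """
    with open(path) as fh:
        first = fh.readline()
    if "\t" in first:
        sep = "\t"
    elif "," in first:
        sep = ","
    else:
        sep = r"\s+"
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeError(f"{path}: missing columns {missing}")
    df["indiv_id"] = df["indiv_id"].astype(str)
    df["family_id"] = df["family_id"].astype(str)
    for c in ("rater_has_asd", "rater_poor"):
        df[c] = df[c].astype(bool)
    return df


def apply_rater_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Set inclusion flags and categories from the rater-quality flags.

    ``rater_has_asd`` drops the score from every analysis (category becomes
    unknown); ``rater_poor`` drops it from quantitative use only — the
    qualitative category is retained.
    """
    df = records.copy()
    has_score = df["raw_srs"].notna()
    asd_rater = df["rater_has_asd"].astype(bool)
    poor = df["rater_poor"].astype(bool)
    df["included_qualitative"] = has_score & ~asd_rater
    df["included_quantitative"] = has_score & ~asd_rater & ~poor
    df["category"] = [
        categorize(s) if inc else UNKNOWN
        for s, inc in zip(df["raw_srs"], df["included_qualitative"])
    ]
    return df


@dataclass
class AdjustmentFit:
    """OLS fit of sqrt(raw SRS) on age and sex (intercept included)."""

    intercept: float
    beta_age: float
    beta_male: float
    se_age: float
    se_male: float
    n: int


def transform_adjust(records: pd.DataFrame) -> tuple[pd.DataFrame, AdjustmentFit]:
    """Square-root transform and partial out age and sex by OLS.

    Sex is coded 0 = female, 1 = male so a positive male coefficient means
    males score higher.  The residual is the quantitative trait value;
    records excluded from quantitative analysis get NaN but keep their
    qualitative category.
    """
    df = records.copy()
    if "included_quantitative" not in df.columns:
        df = apply_rater_exclusions(df)
    use = (
        df["included_quantitative"]
        & df["raw_srs"].notna()
        & df["age"].notna()
        & df["sex"].isin(["male", "female"])
    )
    n = int(use.sum())
    if n < 3:
        raise PhenotypeError(f"need at least 3 complete records to adjust, have {n}")
    y = np.sqrt(df.loc[use, "raw_srs"].to_numpy(dtype=float))
    age = df.loc[use, "age"].to_numpy(dtype=float)
    male = (df.loc[use, "sex"] == "male").to_numpy(dtype=float)
    x = sm.add_constant(np.column_stack([age, male]), has_constant="add")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise PhenotypeError("singular design: age or sex is constant across records")
    fit = sm.OLS(y, x).fit()
    df["quantitative_value"] = np.nan
    df.loc[use, "quantitative_value"] = fit.resid
    info = AdjustmentFit(
        intercept=float(fit.params[0]),
        beta_age=float(fit.params[1]),
        beta_male=float(fit.params[2]),
        se_age=float(fit.bse[1]),
        se_male=float(fit.bse[2]),
        n=n,
    )
    return df, info


def spouse_correlation(pairs: np.ndarray | list[tuple[float, float]]) -> tuple[float, float]:
    """Pearson correlation between spouses' adjusted scores.

    Returns (r, two-sided p from the t distribution with n-2 df).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise PhenotypeError("pairs must be an (n, 2) array")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if len(arr) < 3:
        raise PhenotypeError("need at least 3 complete spouse pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise PhenotypeError("correlation undefined: a member of the pairs has zero variance")
    r, p = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(r), float(p)


def spouse_pairs(pedigree_members, processed: pd.DataFrame) -> np.ndarray:
    """Extract (value, value) couples from one family's processed table.

    A couple is any (father, mother) pair appearing on a child; each couple
    contributes once, ordered (father, mother).
    """
    seen = set()
    out = []
    vals = processed.set_index("indiv_id")["quantitative_value"]
    for m in pedigree_members:
        if m.father_id is None:
            continue
        key = (m.father_id, m.mother_id)
        if key in seen:
            continue
        seen.add(key)
        if m.father_id in vals.index and m.mother_id in vals.index:
            out.append((vals[m.father_id], vals[m.mother_id]))
    return np.asarray(out, dtype=float).reshape(-1, 2)
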