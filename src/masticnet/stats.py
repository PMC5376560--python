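"""Brain-behavior association statistics.

Hub identification and edge screening use partial correlation controlling
for age and gender: each variable is residualised by OLS on
[intercept | covariates] and the Pearson correlation of the residuals is
tested with ``t = r sqrt(df / (1 - r^2))``, ``df = n - 2 - k``.  Following
the exploratory design being reproduced, edge screening applies *no*
multiple-testing adjustment; hubs are nodes whose degree centrality is
positively and significantly correlated with the behavioral score.

Demographic comparisons use Welch/pooled two-sample t tests (also computable
from printed summary statistics), a continuity-corrected chi-square for
gender balance, Pearson correlations for age-behavior decline, and a
median split on age to form older/younger subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AssociationResult",
    "GroupSplit",
    "GENDER_CODING",
    "partial_correlation",
    "identify_hubs",
    "screen_edges",
    "median_split",
    "two_sample_t",
    "chi_square_2x2",
    "pearson_correlation",
    "phenotype_covariates",
]

#: gender indicator used as a covariate (dummy coding)
GENDER_CODING = {"F": 0.0, "M": 1.0}


@dataclass(frozen=True)
class AssociationResult:
    """One (target, behavior) partial-correlation test."""

    r_partial: float
    t_stat: float
    df: int
    p_two_tailed: float
    covariate_names: tuple[str, ...]
    target_label: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_partial <= 1.0:
            raise ValueError("r_partial outside [-1, 1]")
        if self.df < 0:
            raise ValueError("negative degrees of freedom")
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p outside [0, 1]")


@dataclass(frozen=True)
class GroupSplit:
    """Median-split assignment: age above threshold -> older, below -> younger."""

    threshold_age: float
    assignment: dict[str, str]


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def partial_correlation(
    x,
    y,
    covariates=None,
    covariate_names: tuple[str, ...] = (),
    target_label: str = "",
) -> AssociationResult:
    """Partial correlation of x and y given covariates.

    With no covariates this reduces exactly to the ordinary Pearson
    correlation with ``df = n - 2``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != n:
            raise ValueError("covariate rows must match n")
    k = z.shape[1]
    if n < k + 4:
        raise ValueError(f"need n >= k + 4 observations (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate design (with intercept) is rank deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx = np.sqrt(rx @ rx)
    sy = np.sqrt(ry @ ry)
    if sx == 0 or sy == 0:
        which = "x" if sx == 0 else "y"
        raise ValueError(
            f"{which} has zero residual variance after removing covariates"
        )
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) >= 1.0:
        raise ValueError("|r_partial| = 1: degenerate (collinear) inputs")
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df)
    return AssociationResult(
        r_partial=r,
        t_stat=float(t),
        df=int(df),
        p_two_tailed=float(min(p, 1.0)),
        covariate_names=tuple(covariate_names) if covariate_names else tuple(f"z{i}" for i in range(k)),
        target_label=target_label,
    )


def phenotype_covariates(phenotypes: pd.DataFrame) -> np.ndarray:
    """Age and 0/1 gender indicator (F=0, M=1) as an n x 2 covariate matrix."""
    _check_phenotypes(phenotypes, ("subject_id", "age", "gender", "mpi"))
    gender = phenotypes["gender"].map(GENDER_CODING)
    if gender.isna().any():
        bad = phenotypes.loc[gender.isna(), "subject_id"].iloc[0]
        raise ValueError(f"subject {bad!r}: gender must be one of {set(GENDER_CODING)}")
    return np.column_stack([phenotypes["age"].to_numpy(float), gender.to_numpy(float)])


def _check_phenotypes(phenotypes: pd.DataFrame, required) -> None:
    for col in required:
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
        null = phenotypes[col].isna()
        if null.any():
            row = phenotypes.index[null][0]
            sid = phenotypes["subject_id"].iloc[phenotypes.index.get_loc(row)] \
                if "subject_id" in phenotypes.columns else row
            raise ValueError(f"subject {sid!r}: missing value in column {col!r}")


def identify_hubs(
    dc_by_subject: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every node's degree centrality against the behavioral score.

    Parameters
    ----------
    dc_by_subject
        Subjects x nodes table indexed by subject id.
    phenotypes
        Must contain ``subject_id``, ``age``, ``gender``, ``mpi``.
    alpha
        Uncorrected significance level.

    Returns
    -------
    One row per node with columns
    ``label r_partial t df p is_hub`` -- ``is_hub`` is true iff the partial
    correlation (controlling age and gender) is positive with p < alpha.
    All nodes are always reported.
    """
    phenotypes = phenotypes.reset_index(drop=True)
    cov = phenotype_covariates(phenotypes)
    if len(phenotypes) < 8:
        raise ValueError("need at least 8 subjects for hub identification")
    dc = dc_by_subject.loc[phenotypes["subject_id"].to_list()]
    mpi = phenotypes["mpi"].to_numpy(float)
    if np.std(mpi) == 0:
        raise ValueError("behavioral score has zero variance across subjects")
    rows = []
    for node in dc.columns:
        res = partial_correlation(
            dc[node].to_numpy(float), mpi, cov,
            covariate_names=("age", "gender"), target_label=str(node),
        )
        rows.append(
            {
                "label": str(node),
                "r_partial": res.r_partial,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p_two_tailed,
                "is_hub": bool(res.r_partial > 0 and res.p_two_tailed < alpha),
            }
        )
    return pd.DataFrame(rows)


def screen_edges(
    weights_by_subject: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-edge association of connectivity weight with the behavioral score.

    ``weights_by_subject`` is subjects x edges, indexed by subject id, with
    columns named ``"<node_i>--<node_j>"``.  Signed partial correlations are
    reported with uncorrected two-tailed p-values (exploratory screening; no
    multiplicity adjustment).
    """
    phenotypes = phenotypes.reset_index(drop=True)
    cov = phenotype_covariates(phenotypes)
    if len(phenotypes) < 8:
        raise ValueError("need at least 8 subjects for edge screening")
    w = weights_by_subject.loc[phenotypes["subject_id"].to_list()]
    mpi = phenotypes["mpi"].to_numpy(float)
    if np.std(mpi) == 0:
        raise ValueError("behavioral score has zero variance across subjects")
    rows = []
    for col in w.columns:
        node_i, node_j = str(col).split("--")
        res = partial_correlation(
            w[col].to_numpy(float), mpi, cov,
            covariate_names=("age", "gender"), target_label=str(col),
        )
        rows.append(
            {
                "node_i": node_i,
                "node_j": node_j,
                "r_partial": res.r_partial,
                "t": res.t_stat,
                "df": res.df,
                "p": res.p_two_tailed,
                "significant": bool(res.p_two_tailed < alpha),
            }
        )
    return pd.DataFrame(rows)


def median_split(phenotypes: pd.DataFrame) -> GroupSplit:
    """Split subjects into older/younger halves at the median age.

    For even n the threshold is the ordinary median (midpoint of the two
    central ages); for odd n it is the midpoint of the two ages just below
    and at the centre, so the middle subject falls in the older group and
    the halves differ by at most one.  Ages exactly equal to the threshold
    cannot be assigned and raise an error listing the tied subjects.
    """
    _check_phenotypes(phenotypes, ("subject_id", "age"))
    if len(phenotypes) < 2:
        raise ValueError("need at least 2 subjects to split")
    ages = phenotypes["age"].to_numpy(float)
    a = np.sort(ages)
    n = a.size
    threshold = float((a[n // 2 - 1] + a[n // 2]) / 2.0)
    tied = phenotypes.loc[ages == threshold, "subject_id"].tolist()
    if tied:
        raise ValueError(
            f"age tie at the median ({threshold}): subjects {tied} cannot be "
            "assigned to either group"
        )
    assignment = {
        str(sid): ("older" if age > threshold else "younger")
        for sid, age in zip(phenotypes["subject_id"], ages)
    }
    return GroupSplit(threshold_age=threshold, assignment=assignment)


def two_sample_t(
    group_a=None,
    group_b=None,
    mode: str = "welch",
    from_summary=None,
):
    """Two-tailed two-sample t test, from raw data or summary statistics.

    Parameters
    ----------
    group_a, group_b
        Raw observations (ignored when ``from_summary`` is given).
    mode
        ``"welch"`` (unequal variances, default) or ``"pooled"``.
    from_summary
        Optional ``((mean, sd, n), (mean, sd, n))`` pair; the identical
        formulae are evaluated from the summaries.

    Returns
    -------
    ``(t, df, p_two_tailed)``
    """
    if mode not in ("welch", "pooled"):
        raise ValueError(f"mode must be 'welch' or 'pooled', got {mode!r}")
    if from_summary is not None:
        (m1, s1, n1), (m2, s2, n2) = from_summary
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        if s1 <= 0 or s2 <= 0:
            raise ValueError("summary sds must be positive")
    else:
        a = np.asarray(group_a, dtype=float).ravel()
        b = np.asarray(group_b, dtype=float).ravel()
        n1, n2 = a.size, b.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need n >= 2 per group")
        m1, m2 = a.mean(), b.mean()
        s1, s2 = a.std(ddof=1), b.std(ddof=1)
        if s1 == 0 and s2 == 0 and m1 == m2:
            return 0.0, float(n1 + n2 - 2), 1.0
        if s1 == 0 and s2 == 0:
            raise ValueError("both groups are constant with unequal means")
    v1, v2 = s1 * s1 / n1, s2 * s2 / n2
    if mode == "welch":
        t = (m1 - m2) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * s1 * s1 + (n2 - 1) * s2 * s2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def chi_square_2x2(table, continuity_correction: bool = True):
    """Pearson chi-square on a 2x2 count table, Yates-corrected by default.

    The correction term ``|O - E| - 0.5`` is clamped at zero so perfectly
    balanced tables give exactly chi2 = 0.

    Returns ``(chi2, df, p_two_tailed)`` with df = 1.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs < 0) or np.any(obs != np.floor(obs)):
        raise ValueError("counts must be nonnegative integers")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("every row and column marginal must be positive")
    expected = np.outer(row, col) / obs.sum()
    dev = np.abs(obs - expected)
    if continuity_correction:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev * dev / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, 1, p


def pearson_correlation(x, y):
    """Product-moment correlation with a two-tailed t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))
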