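"""Phenotypic association stage.

Pearson chi-square and Woolf odds ratios for 2x2 tables, logistic regression
with family-clustered sandwich (robust) standard errors — the
independence-working-model reduction of GEE, which is what adjusting for the
relatedness of twins amounts to — plus the prevalence/comorbidity and
onset-chronology tables.  Significance is judged at the conservative
alpha = .01 convention throughout; no multiplicity procedure beyond that.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .core import TwinPairRecord, individuals

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "ChronologyRow",
    "PrevalenceRow",
    "pearson_chi2",
    "odds_ratio_woolf",
    "cluster_robust_logistic",
    "symptom_association",
    "chronology_table",
    "prevalence_table",
    "percent_round",
    "ALPHA",
]

#: Conservative significance convention for the association stage.
ALPHA = 0.01


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d) = (exposed+, exposed-; unexposed+, unexposed-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AssociationResult:
    beta: float
    robust_se: float
    odds_ratio: float
    ci95: tuple
    p_value: float
    n_individuals: int
    n_clusters: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def pearson_chi2(table: ContingencyTable2x2, yates: bool = False):
    """Pearson chi-square for a 2x2 table: (stat, df=1, p).

    Uncorrected by default (the convention of the tables this stage
    emulates); ``yates=True`` applies the continuity correction.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    if n == 0:
        raise ValueError("empty table")
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise ValueError("zero margin: chi-square undefined")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2, 0.0)
    stat = n * num ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), 1, float(chi2_dist.sf(stat, 1))


def odds_ratio_woolf(table: ContingencyTable2x2, continuity: Optional[str] = None):
    """Sample odds ratio ad/bc with the Woolf log-scale 95% CI.

    A zero cell is an error unless ``continuity="haldane"`` adds 0.5 to
    every cell (Haldane–Anscombe).
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0:
        if continuity == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        elif continuity is None:
            raise ValueError("zero cell: use continuity='haldane' or larger strata")
        else:
            raise ValueError(f"unknown continuity policy {continuity!r}")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi))


def _logistic_ml(y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-10):
    """Newton–Raphson logistic ML with separation detection."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # name the first column that is linearly dependent on its predecessors
        for j in range(1, p + 1):
            if np.linalg.matrix_rank(X[:, :j]) < j:
                raise ValueError(f"design not full rank: column {j - 1} is collinear")
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        if np.max(np.abs(eta)) > 40:
            raise ValueError(_separation_message(y, X))
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise ValueError(_separation_message(y, X)) from None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        raise ValueError("logistic ML failed to converge")
    return beta


def _separation_message(y, X):
    for j in range(1, X.shape[1]):
        x = X[:, j]
        if len(np.unique(x)) > 1:
            lo, hi = x[y == 0], x[y == 1]
            if lo.size and hi.size and (lo.max() <= hi.min() or hi.max() <= lo.min()):
                return f"separation detected: column {j} perfectly predicts the outcome"
    return "separation detected: no maximum-likelihood optimum"


def cluster_robust_logistic(
    outcome: np.ndarray,
    predictors: np.ndarray,
    cluster_ids: Sequence,
    add_intercept: bool = True,
    term: int = 0,
) -> AssociationResult:
    """Logistic regression with a cluster-aggregated sandwich variance.

    Point estimates are ordinary (independence working model) logistic ML;
    the variance is A^-1 B A^-1 with A the observed information and B the sum
    of outer products of cluster score sums.  With every cluster a singleton
    this reduces to the plain heteroskedasticity-robust estimator.  The
    reported coefficient is ``term`` (indexing the predictor columns, not
    the intercept).
    """
    y = np.asarray(outcome, float)
    X = np.atleast_2d(np.asarray(predictors, float))
    if X.shape[0] != y.size:
        X = X.T
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    cluster_ids = np.asarray(cluster_ids)
    uniq, inv = np.unique(cluster_ids, return_inverse=True)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        term_ix = term + 1
    else:
        term_ix = term

    beta = _logistic_ml(y, X)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    w = mu * (1.0 - mu)
    A = (X * w[:, None]).T @ X
    scores = X * (y - mu)[:, None]
    cluster_scores = np.zeros((uniq.size, X.shape[1]))
    np.add.at(cluster_scores, inv, scores)
    B = cluster_scores.T @ cluster_scores
    Ainv = np.linalg.inv(A)
    cov = Ainv @ B @ Ainv

    b = float(beta[term_ix])
    se = float(math.sqrt(cov[term_ix, term_ix]))
    z = b / se
    return AssociationResult(
        beta=b,
        robust_se=se,
        odds_ratio=float(math.exp(b)),
        ci95=(float(math.exp(b - 1.96 * se)), float(math.exp(b + 1.96 * se))),
        p_value=float(2 * norm.sf(abs(z))),
        n_individuals=int(y.size),
        n_clusters=int(uniq.size),
    )


def _collect(records, columns):
    """Rows (one per individual) of the requested phenotype columns plus
    family id, keeping only individuals complete on all columns."""
    rows, fams = [], []
    for ind in individuals(records):
        vals = [ind.phenotypes.get(c) for c in columns]
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        fams.append(ind.family_id)
    return np.asarray(rows, float), np.asarray(fams)


def symptom_association(
    records: Sequence[TwinPairRecord],
    symptom: str,
    sud: str,
    adjust_for_diagnosis: Optional[str] = None,
) -> AssociationResult:
    """SUD ~ symptom (+ diagnosis covariate), family-clustered.

    The symptom enters as a positive/negative indicator; when a diagnosis
    covariate is given it enters the same model so the symptom's association
    is judged independent of the diagnosis.
    """
    cols = [sud, symptom] + ([adjust_for_diagnosis] if adjust_for_diagnosis else [])
    data, fams = _collect(records, cols)
    if data.size == 0:
        raise ValueError("no complete observations")
    y = data[:, 0]
    Xcols = [(data[:, 1] > 0).astype(float)]
    if adjust_for_diagnosis:
        Xcols.append((data[:, 2] > 0).astype(float))
    X = np.column_stack(Xcols)
    return cluster_robust_logistic(y, X, fams, term=0)


def percent_round(numerator: int, denominator: int) -> int:
    """Integer percent with half-up rounding (13.5 -> 14, not banker's 14/13)."""
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ChronologyRow:
    sud: str
    n_ed_first: int
    n_sud_first: int
    n_same: int
    pct_ed_first: Optional[int]
    pct_sud_first: Optional[int]
    pct_same: Optional[int]
    n_excluded: int = 0

    @property
    def n_total(self) -> int:
        return self.n_ed_first + self.n_sud_first + self.n_same


def chronology_table(
    records: Sequence[TwinPairRecord],
    ed: str,
    suds: Sequence[str],
) -> list[ChronologyRow]:
    """Onset-ordering rows: ED-first / SUD-first / same-age splits per SUD.

    Only individuals positive for both disorders with both onset ages
    recorded enter a row; the excluded comorbid count is tallied.  Percents
    are half-up integers of count/total; an empty comorbid set yields a row
    of ``None`` percents (rendered as dashes).
    """
    rows = []
    for sud in suds:
        counts = {"ED_first": 0, "SUD_first": 0, "same": 0}
        excluded = 0
        pos = lambda v: v is not None and v > 0
        for ind in individuals(records):
            if pos(ind.phenotypes.get(ed)) and pos(ind.phenotypes.get(sud)):
                e, s = ind.onset_ages.get(ed), ind.onset_ages.get(sud)
                if e is None or s is None:
                    excluded += 1
                    continue
                if e < s:
                    counts["ED_first"] += 1
                elif e > s:
                    counts["SUD_first"] += 1
                else:
                    counts["same"] += 1
        total = sum(counts.values())
        pct = {
            k: (percent_round(v, total) if total else None)
            for k, v in counts.items()
        }
        rows.append(ChronologyRow(
            sud=sud,
            n_ed_first=counts["ED_first"],
            n_sud_first=counts["SUD_first"],
            n_same=counts["same"],
            pct_ed_first=pct["ED_first"],
            pct_sud_first=pct["SUD_first"],
            pct_same=pct["same"],
            n_excluded=excluded,
        ))
    return rows


@dataclass
class PrevalenceRow:
    sud: str
    percent: float
    n: int
    odds_ratio: Optional[float]
    ci95: Optional[tuple]
    p_value: Optional[float]


def prevalence_table(
    records: Sequence[TwinPairRecord],
    group: str,
    suds: Sequence[str],
) -> list[PrevalenceRow]:
    """Per-SUD prevalence among group-positive women with the cluster-robust
    OR against group-negative women; OR undefined (None) when the grouping
    column does not vary."""
    rows = []
    for sud in suds:
        data, fams = _collect(records, [sud, group])
        if data.size == 0:
            rows.append(PrevalenceRow(sud, 0.0, 0, None, None, None))
            continue
        y, g = data[:, 0], (data[:, 1] > 0).astype(float)
        pos = g == 1
        n_pos = int((y[pos] == 1).sum())
        pct = 100.0 * n_pos / pos.sum() if pos.any() else 0.0
        if len(np.unique(g)) < 2 or len(np.unique(y)) < 2:
            rows.append(PrevalenceRow(sud, float(pct), n_pos, None, None, None))
            continue
        res = cluster_robust_logistic(y, g[:, None], fams, term=0)
        rows.append(PrevalenceRow(sud, float(pct), n_pos,
                                  res.odds_ratio, res.ci95, res.p_value))
    return rows
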