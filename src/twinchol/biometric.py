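"""Liability-threshold twin models: univariate ACE/AE/CE/E and the bivariate
Cholesky decomposition, fitted by full-information maximum likelihood on
ordinal raw data.

Model
-----
Each trait's liability is standard normal and is cut by fixed increasing
thresholds into the observed categories.  Liability variance decomposes into
additive-genetic (A), shared-environmental (C) and unique-environmental (E,
which also carries measurement error) parts; across co-twins A correlates
1.0 (MZ) / 0.5 (DZ), C correlates 1.0 and E is independent.  For two traits
the A/C/E covariance between them is parameterized by a triangular Cholesky
path matrix per component (paths a11, a21, a22 and likewise for c, e), which
keeps every implied covariance matrix positive semidefinite and yields the
genetic / shared / unique environmental correlations r_a, r_c, r_e.

A pair's likelihood is the rectangle probability of the 2- or 4-dimensional
liability vector between the observed categories' thresholds; singletons and
missing phenotypes drop the corresponding dimensions, which integrates them
out exactly.  Nested models are compared by the likelihood-ratio chi-square
and by AIC differences (delta chi-square minus twice the dropped degrees of
freedom).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import chi2 as chi2_dist

from .core import TwinPairRecord, Zygosity
from .mvn import bvn_rect, genz_rect, norm_rect

__all__ = [
    "CholeskyParameters",
    "VarianceComponents",
    "ModelFit",
    "ComparisonResult",
    "FitOptions",
    "ProfileCI",
    "MODEL_COMPONENTS",
    "cholesky_from_components",
    "implied_correlation",
    "pair_likelihood",
    "cohort_minus2_loglik",
    "fit_model",
    "variance_components",
    "compare_models",
    "profile_ci",
    "polychoric_correlation",
    "collapse_ordinal",
]

MODEL_COMPONENTS = {
    "ACE": frozenset("ACE"),
    "AE": frozenset("AE"),
    "CE": frozenset("CE"),
    "E": frozenset("E"),
}

_KAPPA = {Zygosity.MZ: 1.0, Zygosity.DZ: 0.5}
_TOL_VAR = 1e-12


# ---------------------------------------------------------------------------
# parameters and derived quantities


@dataclass
class CholeskyParameters:
    """Path coefficients and thresholds of the (bi)variate A/C/E model.

    The univariate case uses only the *11 paths; ``thresholds_trait2`` is
    ``None`` then.  Standardization: each trait's paths must give unit
    liability variance.
    """

    a11: float = 0.0
    a21: float = 0.0
    a22: float = 0.0
    c11: float = 0.0
    c21: float = 0.0
    c22: float = 0.0
    e11: float = 1.0
    e21: float = 0.0
    e22: float = 0.0
    thresholds_trait1: np.ndarray = field(default_factory=lambda: np.array([0.0]))
    thresholds_trait2: Optional[np.ndarray] = None

    @property
    def n_traits(self) -> int:
        return 1 if self.thresholds_trait2 is None else 2

    def validate(self, atol: float = 1e-6) -> None:
        v1 = self.a11**2 + self.c11**2 + self.e11**2
        if abs(v1 - 1.0) > atol:
            raise ValueError(f"trait-1 liability variance {v1} != 1")
        if self.e11 <= 0:
            raise ValueError("e11 must be positive (E includes measurement error)")
        t1 = np.asarray(self.thresholds_trait1, float)
        if t1.size and np.any(np.diff(t1) <= 0):
            raise ValueError("trait-1 thresholds must be strictly increasing")
        if self.n_traits == 2:
            v2 = (self.a21**2 + self.a22**2 + self.c21**2 + self.c22**2
                  + self.e21**2 + self.e22**2)
            if abs(v2 - 1.0) > atol:
                raise ValueError(f"trait-2 liability variance {v2} != 1")
            if self.e21 == 0 and self.e22 == 0:
                raise ValueError("trait-2 E paths cannot both be zero")
            t2 = np.asarray(self.thresholds_trait2, float)
            if t2.size and np.any(np.diff(t2) <= 0):
                raise ValueError("trait-2 thresholds must be strictly increasing")

    def thresholds(self, trait_index: int) -> np.ndarray:
        t = self.thresholds_trait1 if trait_index == 0 else self.thresholds_trait2
        return np.asarray(t, float)


@dataclass
class VarianceComponents:
    """Standardized variance shares per trait and cross-trait correlations."""

    a2: tuple
    c2: tuple
    e2: tuple
    r_a: Optional[float] = None
    r_c: Optional[float] = None
    r_e: Optional[float] = None


@dataclass
class ModelFit:
    model_label: str
    parameters: CholeskyParameters
    minus2_loglik: float
    n_free_params: int
    n_pairs_complete: int
    n_pairs_incomplete: int
    converged: bool
    components: VarianceComponents
    _ctx: object = field(default=None, repr=False, compare=False)
    _theta: object = field(default=None, repr=False, compare=False)


@dataclass
class ComparisonResult:
    delta_chi2: float
    delta_df: int
    p_value: float
    aic_delta: float


@dataclass
class ProfileCI:
    low: float
    high: float
    low_at_boundary: bool = False
    high_at_boundary: bool = False


@dataclass
class FitOptions:
    """Tuning knobs for :func:`fit_model`.

    thresholds : "marginal" fixes thresholds at the pooled marginal ML
        (inverse-normal of cumulative frequencies; the two-stage polychoric
        convention); "joint" estimates them together with the paths.
    n_starts : perturbed restarts added on top of the structured start set.
    max_categories : ordinal traits with more observed categories are
        collapsed into a top category before fitting (None disables).
    n_qmc / n_qmc_final : QMC points for 4-D rectangles during optimization
        and for the final reported -2lnL.
    """

    thresholds: str = "marginal"
    n_starts: int = 1
    seed: int = 0
    max_categories: Optional[int] = 7
    n_qmc: int = 256
    n_qmc_final: int = 8192
    maxiter: Optional[int] = None


def cholesky_from_components(
    shares1: Sequence[float],
    thresholds1,
    shares2: Optional[Sequence[float]] = None,
    thresholds2=None,
    r_a: float = 0.0,
    r_c: float = 0.0,
    r_e: float = 0.0,
) -> CholeskyParameters:
    """Build Cholesky paths from variance shares and cross-trait correlations.

    ``shares`` are (a2, c2, e2) summing to one.  Diagonal paths are the
    positive square roots; for trait 2 the cross path of component X is
    ``r_X * sqrt(X2_2)`` so the implied component correlation is exactly
    ``r_X`` whenever both traits carry component-X variance.
    """
    a2, c2, e2 = (float(x) for x in shares1)
    if abs(a2 + c2 + e2 - 1) > 1e-8 or min(a2, c2, e2) < 0 or e2 <= 0:
        raise ValueError("trait-1 shares must be nonnegative, sum to 1, e2 > 0")
    p = CholeskyParameters(
        a11=math.sqrt(a2), c11=math.sqrt(c2), e11=math.sqrt(e2),
        thresholds_trait1=np.asarray(thresholds1, float),
    )
    if shares2 is not None:
        a2b, c2b, e2b = (float(x) for x in shares2)
        if abs(a2b + c2b + e2b - 1) > 1e-8 or min(a2b, c2b, e2b) < 0 or e2b <= 0:
            raise ValueError("trait-2 shares must be nonnegative, sum to 1, e2 > 0")
        for r, nm in ((r_a, "r_a"), (r_c, "r_c"), (r_e, "r_e")):
            if not -1 <= r <= 1:
                raise ValueError(f"{nm} outside [-1, 1]")
        p.a21 = r_a * math.sqrt(a2b)
        p.a22 = math.sqrt(max(a2b - p.a21**2, 0.0))
        p.c21 = r_c * math.sqrt(c2b)
        p.c22 = math.sqrt(max(c2b - p.c21**2, 0.0))
        p.e21 = r_e * math.sqrt(e2b)
        p.e22 = math.sqrt(max(e2b - p.e21**2, 0.0))
        p.thresholds_trait2 = np.asarray(thresholds2, float)
    p.validate(atol=1e-6)
    return p


def _component_cov(params: CholeskyParameters):
    """Per-component within-person covariance matrices (n_traits square)."""
    if params.n_traits == 1:
        mk = lambda d11: np.array([[d11**2]])
        return (mk(params.a11), mk(params.c11), mk(params.e11))
    out = []
    for d11, d21, d22 in (
        (params.a11, params.a21, params.a22),
        (params.c11, params.c21, params.c22),
        (params.e11, params.e21, params.e22),
    ):
        L = np.array([[d11, 0.0], [d21, d22]])
        out.append(L @ L.T)
    return tuple(out)


def implied_correlation(params: CholeskyParameters, zygosity: Zygosity) -> np.ndarray:
    """Liability correlation matrix for a complete pair.

    Dimension order: twin1 traits first, then twin2 traits.  The within-
    person block is A + C + E (unit diagonal after standardization); the
    cross-twin block is kappa * A + C with kappa 1.0 (MZ) or 0.5 (DZ).
    """
    A, C, E = _component_cov(params)
    within = A + C + E
    cross = _KAPPA[zygosity] * A + C
    return np.block([[within, cross], [cross, within]])


def variance_components(params: CholeskyParameters) -> VarianceComponents:
    """Standardized variance shares and (bivariate) component correlations.

    A correlation whose component variance vanishes on either trait is
    undefined and reported as ``None``, not zero.
    """
    a2_1, c2_1, e2_1 = params.a11**2, params.c11**2, params.e11**2
    if params.n_traits == 1:
        return VarianceComponents(a2=(a2_1,), c2=(c2_1,), e2=(e2_1,))
    tots = {
        "a": (a2_1, params.a21**2 + params.a22**2),
        "c": (c2_1, params.c21**2 + params.c22**2),
        "e": (e2_1, params.e21**2 + params.e22**2),
    }
    corrs = {}
    for comp, cross in (("a", params.a21), ("c", params.c21), ("e", params.e21)):
        v1, v2 = tots[comp]
        if v1 > _TOL_VAR and v2 > _TOL_VAR:
            corrs[comp] = float(np.sign(getattr(params, comp + "11")) * cross / math.sqrt(v2))
        else:
            corrs[comp] = None
    return VarianceComponents(
        a2=(a2_1, tots["a"][1]),
        c2=(c2_1, tots["c"][1]),
        e2=(e2_1, tots["e"][1]),
        r_a=corrs["a"], r_c=corrs["c"], r_e=corrs["e"],
    )


# ---------------------------------------------------------------------------
# likelihood


def _category_bounds(cat: int, thresholds: np.ndarray):
    lo = -np.inf if cat == 0 else thresholds[cat - 1]
    hi = np.inf if cat >= thresholds.size else thresholds[cat]
    return lo, hi


def pair_likelihood(
    params: CholeskyParameters,
    pair: TwinPairRecord,
    traits: Sequence[str],
    n_points: int = 8192,
) -> float:
    """Probability of one pair's observed categories under the model.

    The full liability vector has one dimension per (twin, trait); missing
    twins or missing phenotype values drop their dimensions, which is the
    exact marginal likelihood.
    """
    n_traits = len(traits)
    if n_traits != params.n_traits:
        raise ValueError("trait selection does not match parameter dimensionality")
    corr = implied_correlation(params, pair.zygosity)
    if not np.all(np.isfinite(corr)):
        raise ValueError("non-finite liability covariance")
    dims, lows, highs = [], [], []
    twins = [pair.twin1] + ([pair.twin2] if pair.twin2 is not None else [])
    for ti, twin in enumerate(twins):
        for tj, trait in enumerate(traits):
            if trait not in twin.phenotypes:
                raise ValueError(f"trait {trait!r} absent for {twin.person_id}")
            v = twin.phenotypes[trait]
            if v is None:
                continue
            lo, hi = _category_bounds(int(v), params.thresholds(tj))
            dims.append(ti * n_traits + tj)
            lows.append(lo)
            highs.append(hi)
    if not dims:
        return 1.0
    sub = corr[np.ix_(dims, dims)]
    p = genz_rect(np.array([lows]), np.array([highs]), sub, n_points=n_points)
    return float(p[0])


def _pattern_key(pair: TwinPairRecord, traits, n_traits):
    dims, cats = [], []
    twins = [pair.twin1] + ([pair.twin2] if pair.twin2 is not None else [])
    for ti, twin in enumerate(twins):
        for tj, trait in enumerate(traits):
            if trait not in twin.phenotypes:
                raise ValueError(f"trait {trait!r} absent for {twin.person_id}")
            v = twin.phenotypes[trait]
            if v is None:
                continue
            dims.append(ti * n_traits + tj)
            cats.append(int(v))
    return pair.zygosity, tuple(dims), tuple(cats)


def _group_patterns(records, traits, n_traits):
    """Tally unique (zygosity, observed-dims, categories) patterns."""
    counts = Counter()
    rep = {}
    for rec in records:
        key = _pattern_key(rec, traits, n_traits)
        counts[key] += 1
        rep.setdefault(key, rec.family_id)
    groups = {}
    for (zyg, dims, cats), n in counts.items():
        groups.setdefault((zyg, dims), []).append((cats, n, rep[(zyg, dims, cats)]))
    return groups


def _group_probabilities(params, groups, traits, n_points):
    """Probability of every unique pattern, batched per (zygosity, dims)."""
    corrs = {z: implied_correlation(params, z) for z in (Zygosity.MZ, Zygosity.DZ)}
    out = []
    for (zyg, dims), items in groups.items():
        if not dims:
            out.extend((1.0, n, fam) for _, n, fam in items)
            continue
        sub = corrs[zyg][np.ix_(dims, dims)]
        n_traits = params.n_traits
        lows = np.empty((len(items), len(dims)))
        highs = np.empty_like(lows)
        for b, (cats, _, _) in enumerate(items):
            for j, (dim, cat) in enumerate(zip(dims, cats)):
                lo, hi = _category_bounds(cat, params.thresholds(dim % n_traits))
                lows[b, j], highs[b, j] = lo, hi
        if len(dims) == 1:
            p = norm_rect(lows[:, 0], highs[:, 0])
        elif len(dims) == 2:
            p = bvn_rect(lows, highs, float(sub[0, 1]))
        else:
            p = genz_rect(lows, highs, sub, n_points=n_points)
        out.extend((float(pi), n, fam) for pi, (_, n, fam) in zip(p, items))
    return out


def cohort_minus2_loglik(
    params: CholeskyParameters,
    records: Sequence[TwinPairRecord],
    traits: Sequence[str],
    n_points: int = 8192,
) -> float:
    """-2 log-likelihood of the cohort: -2 sum of log pair probabilities.

    Invariant to record order and to which twin is labelled twin1 (the
    implied correlation matrix is exchangeable across co-twins).
    """
    groups = _group_patterns(records, traits, params.n_traits)
    total = 0.0
    for p, n, fam in _group_probabilities(params, groups, traits, n_points):
        if p <= 0.0:
            raise ValueError(f"zero-probability pattern (family {fam!r})")
        total += n * math.log(p)
    return -2.0 * total


# ---------------------------------------------------------------------------
# model fitting


def collapse_ordinal(records, trait: str, top: int) -> None:
    """Collapse categories of ``trait`` above ``top`` into ``top`` (in place)."""
    for rec in records:
        for twin in (rec.twin1, rec.twin2):
            if twin is None:
                continue
            v = twin.phenotypes.get(trait)
            if v is not None and v > top:
                twin.phenotypes[trait] = top


def _copy_records(records):
    out = []
    for rec in records:
        t1 = replace(rec.twin1, phenotypes=dict(rec.twin1.phenotypes))
        t2 = None
        if rec.twin2 is not None:
            t2 = replace(rec.twin2, phenotypes=dict(rec.twin2.phenotypes))
        out.append(TwinPairRecord(rec.family_id, rec.zygosity, t1, t2))
    return out


def _marginal_thresholds(values: np.ndarray, n_cat: int) -> np.ndarray:
    counts = np.bincount(values, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return ndtri(cum)


class _FitContext:
    """Precomputed pattern tallies and marginal thresholds for one cohort."""

    def __init__(self, records, traits, options: FitOptions):
        self.traits = list(traits)
        self.n_traits = len(self.traits)
        recs = _copy_records(records)
        # dense-relabel observed categories per trait (order-preserving),
        # optionally collapsing a long ordinal tail into a top category
        self.n_cat = []
        for tj, trait in enumerate(self.traits):
            vals = sorted(
                {tw.phenotypes[trait]
                 for r in recs for tw in (r.twin1, r.twin2)
                 if tw is not None and tw.phenotypes.get(trait) is not None}
            )
            if len(vals) < 2:
                raise ValueError(f"trait {trait!r} has fewer than 2 observed categories")
            remap = {v: i for i, v in enumerate(vals)}
            for r in recs:
                for tw in (r.twin1, r.twin2):
                    if tw is not None and tw.phenotypes.get(trait) is not None:
                        tw.phenotypes[trait] = remap[tw.phenotypes[trait]]
            k = len(vals)
            if options.max_categories is not None and k > options.max_categories:
                collapse_ordinal(recs, trait, options.max_categories - 1)
                k = options.max_categories
            self.n_cat.append(k)
        self.records = recs
        self.groups = _group_patterns(recs, self.traits, self.n_traits)
        self.n_pairs_complete = sum(1 for r in recs if r.complete)
        self.n_pairs_incomplete = len(recs) - self.n_pairs_complete
        pooled = [
            np.array([tw.phenotypes[t]
                      for r in recs for tw in (r.twin1, r.twin2)
                      if tw is not None and tw.phenotypes.get(t) is not None])
            for t in self.traits
        ]
        self.marginal_thresholds = [
            _marginal_thresholds(v, k) for v, k in zip(pooled, self.n_cat)
        ]
        # Rectangle bounds are fixed whenever thresholds are fixed at their
        # marginal estimates; precomputing them removes the dominant Python
        # cost from every objective evaluation.
        self.prepared = []
        for (zyg, dims), items in self.groups.items():
            lows = np.empty((len(items), len(dims)))
            highs = np.empty_like(lows)
            for b, (cats, _, _) in enumerate(items):
                for j, (dim, cat) in enumerate(zip(dims, cats)):
                    thr = self.marginal_thresholds[dim % self.n_traits]
                    lows[b, j], highs[b, j] = _category_bounds(cat, thr)
            counts = np.array([n for _, n, _ in items], float)
            self.prepared.append((zyg, dims, lows, highs, counts))


def _theta_layout(label: str, n_traits: int):
    comps = MODEL_COMPONENTS[label]
    names = []
    for t in range(n_traits):
        if "A" in comps:
            names.append(f"xa{t+1}")
        if "C" in comps:
            names.append(f"xc{t+1}")
    if n_traits == 2:
        if "A" in comps:
            names.append("zra")
        if "C" in comps:
            names.append("zrc")
        names.append("zre")
    return names


def _shares_from_logits(xa, xc):
    den = 1.0 + (math.exp(xa) if xa is not None else 0.0) \
              + (math.exp(xc) if xc is not None else 0.0)
    a2 = math.exp(xa) / den if xa is not None else 0.0
    c2 = math.exp(xc) / den if xc is not None else 0.0
    return a2, c2, 1.0 - a2 - c2


def _params_from_theta(theta, label, ctx, thresholds, pinned=None):
    """Map the unconstrained vector to standardized CholeskyParameters.

    ``pinned`` optionally maps a layout name to a fixed value (used by the
    profile-likelihood machinery).
    """
    names = _theta_layout(label, ctx.n_traits)
    pinned = pinned or {}
    free = [n for n in names if n not in pinned]
    vals = dict(zip(free, theta))
    vals.update(pinned)

    def get(n):
        return vals.get(n)

    shares1 = _shares_from_logits(get("xa1"), get("xc1"))
    if ctx.n_traits == 1:
        return cholesky_from_components(shares1, thresholds[0])
    shares2 = _shares_from_logits(get("xa2"), get("xc2"))
    r = {k: math.tanh(vals[z]) if z in vals else 0.0
         for k, z in (("r_a", "zra"), ("r_c", "zrc"), ("r_e", "zre"))}
    return cholesky_from_components(
        shares1, thresholds[0], shares2, thresholds[1], **r
    )


def _m2ll_from_groups(params, ctx, n_points):
    fast = params.thresholds_trait1 is ctx.marginal_thresholds[0] and (
        ctx.n_traits == 1 or params.thresholds_trait2 is ctx.marginal_thresholds[1]
    )
    if not fast:  # joint-threshold path: bounds depend on the parameters
        total = 0.0
        for p, n, _ in _group_probabilities(params, ctx.groups, ctx.traits, n_points):
            total += n * math.log(max(p, 1e-300))
        return -2.0 * total
    corrs = {z: implied_correlation(params, z) for z in (Zygosity.MZ, Zygosity.DZ)}
    total = 0.0
    for zyg, dims, lows, highs, counts in ctx.prepared:
        if not dims:
            continue
        sub = corrs[zyg][np.ix_(dims, dims)]
        if len(dims) == 1:
            p = norm_rect(lows[:, 0], highs[:, 0])
        elif len(dims) == 2:
            p = bvn_rect(lows, highs, float(sub[0, 1]))
        else:
            p = genz_rect(lows, highs, sub, n_points=n_points)
        total += float(counts @ np.log(np.maximum(p, 1e-300)))
    return -2.0 * total


def _falconer_init(ctx, label):
    """Polychoric-based starting shares (Falconer-style) per trait."""
    shares = []
    for tj, trait in enumerate(ctx.traits):
        by_z = {}
        for z in (Zygosity.MZ, Zygosity.DZ):
            x1, x2 = [], []
            for r in ctx.records:
                if r.zygosity != z or r.twin2 is None:
                    continue
                v1 = r.twin1.phenotypes.get(trait)
                v2 = r.twin2.phenotypes.get(trait)
                if v1 is None or v2 is None:
                    continue
                x1.append(v1)
                x2.append(v2)
            try:
                by_z[z] = polychoric_correlation(x1, x2)[0]
            except ValueError:
                by_z[z] = 0.3 if z == Zygosity.MZ else 0.15
        rmz, rdz = by_z[Zygosity.MZ], by_z[Zygosity.DZ]
        a2 = float(np.clip(2 * (rmz - rdz), 0.05, 0.90))
        c2 = float(np.clip(2 * rdz - rmz, 0.02, 0.60))
        if a2 + c2 > 0.95:
            s = 0.95 / (a2 + c2)
            a2, c2 = a2 * s, c2 * s
        shares.append((a2, c2, 1 - a2 - c2))
    rp = 0.0
    if ctx.n_traits == 2:
        x1 = [tw.phenotypes[ctx.traits[0]]
              for r in ctx.records for tw in (r.twin1, r.twin2)
              if tw is not None
              and tw.phenotypes.get(ctx.traits[0]) is not None
              and tw.phenotypes.get(ctx.traits[1]) is not None]
        x2 = [tw.phenotypes[ctx.traits[1]]
              for r in ctx.records for tw in (r.twin1, r.twin2)
              if tw is not None
              and tw.phenotypes.get(ctx.traits[0]) is not None
              and tw.phenotypes.get(ctx.traits[1]) is not None]
        try:
            rp = float(np.clip(polychoric_correlation(x1, x2)[0], -0.85, 0.85))
        except ValueError:
            rp = 0.0
    theta = {}
    comps = MODEL_COMPONENTS[label]
    for t, (a2, c2, e2) in enumerate(shares):
        if "A" in comps:
            theta[f"xa{t+1}"] = math.log(max(a2, 1e-3) / e2)
        if "C" in comps:
            theta[f"xc{t+1}"] = math.log(max(c2, 1e-3) / e2)
    if ctx.n_traits == 2:
        z = math.atanh(rp)
        if "A" in comps:
            theta["zra"] = z
        if "C" in comps:
            theta["zrc"] = z
        theta["zre"] = z
    return theta


def _start_points(ctx, label, options):
    names = _theta_layout(label, ctx.n_traits)
    base = _falconer_init(ctx, label)
    starts = [np.array([base[n] for n in names])]
    comps = MODEL_COMPONENTS[label]
    # boundary starts: near-zero C (and near-zero A for CE-flavoured basins)
    if "C" in comps and "A" in comps:
        alt = dict(base)
        for t in range(ctx.n_traits):
            alt[f"xc{t+1}"] = -5.0
        starts.append(np.array([alt[n] for n in names]))
    rng = np.random.default_rng(options.seed)
    for _ in range(max(0, options.n_starts - 1)):
        starts.append(starts[0] + rng.normal(scale=0.5, size=len(names)))
    return names, starts


def fit_model(
    records: Sequence[TwinPairRecord],
    traits: Sequence[str],
    model_label: str,
    options: Optional[FitOptions] = None,
) -> ModelFit:
    """Maximum-likelihood fit of one liability-threshold twin model.

    Variance shares are parameterized through softmax logits (E the
    baseline), and bivariate cross-paths through tanh-mapped component
    correlations; standardization therefore holds exactly for every candidate,
    and dropped components are structurally zero.  Optimization is
    Nelder-Mead from a polychoric/Falconer-based start plus structured
    alternates; non-convergence is reported, never silent.
    """
    if model_label not in MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model_label!r}")
    if not records:
        raise ValueError("empty cohort")
    options = options or FitOptions()
    if options.thresholds not in ("marginal", "joint"):
        raise ValueError("thresholds option must be 'marginal' or 'joint'")
    ctx = _FitContext(records, traits, options)

    names = _theta_layout(model_label, ctx.n_traits)
    n_thr_params = sum(k - 1 for k in ctx.n_cat) if options.thresholds == "joint" else 0

    def unpack_thresholds(theta_thr):
        if options.thresholds == "marginal":
            return ctx.marginal_thresholds
        out, i = [], 0
        for k in ctx.n_cat:
            first = theta_thr[i]
            diffs = np.exp(theta_thr[i + 1: i + k - 1])
            out.append(np.concatenate([[first], first + np.cumsum(diffs)]))
            i += k - 1
        return out

    def pack_marginal_thresholds():
        out = []
        for thr in ctx.marginal_thresholds:
            out.append(thr[0])
            out.extend(np.log(np.maximum(np.diff(thr), 1e-6)))
        return np.array(out)

    def objective(theta, n_points):
        path_theta = theta[: len(names)]
        thr = unpack_thresholds(theta[len(names):])
        try:
            params = _params_from_theta(path_theta, model_label, ctx, thr)
        except (ValueError, OverflowError):
            return 1e12
        return _m2ll_from_groups(params, ctx, n_points)

    _, starts = _start_points(ctx, model_label, options)
    if options.thresholds == "joint":
        thr0 = pack_marginal_thresholds()
        starts = [np.concatenate([s, thr0]) for s in starts]

    best_theta, best_val, converged = None, np.inf, False
    for s in starts:
        if s.size == 0:
            best_theta, best_val, converged = s, objective(s, options.n_qmc), True
            break
        # quasi-Newton on the smooth deterministic objective
        res = optimize.minimize(
            objective, s, args=(options.n_qmc,), method="L-BFGS-B",
            options=dict(eps=1e-5, ftol=1e-9, gtol=1e-6,
                         maxiter=options.maxiter or 300),
        )
        if res.fun < best_val:
            best_theta, best_val = res.x, float(res.fun)
            converged = bool(res.success)
    if best_theta is not None and best_theta.size:
        # small-simplex polish shaves line-search slack: nested-model
        # likelihoods must be ordered to well below the comparison tolerance
        simplex = np.vstack([best_theta, best_theta + 0.02 * np.eye(best_theta.size)])
        res2 = optimize.minimize(
            objective, best_theta, args=(options.n_qmc,), method="Nelder-Mead",
            options=dict(initial_simplex=simplex, xatol=1e-4, fatol=1e-7,
                         maxiter=60 * best_theta.size),
        )
        if res2.fun < best_val:
            best_theta, best_val = res2.x, float(res2.fun)
            converged = converged or bool(res2.success)

    thr = unpack_thresholds(best_theta[len(names):])
    params = _params_from_theta(best_theta[: len(names)], model_label, ctx, thr)
    m2ll = _m2ll_from_groups(params, ctx, options.n_qmc_final)
    return ModelFit(
        model_label=model_label,
        parameters=params,
        minus2_loglik=float(m2ll),
        n_free_params=len(names) + n_thr_params,
        n_pairs_complete=ctx.n_pairs_complete,
        n_pairs_incomplete=ctx.n_pairs_incomplete,
        converged=converged,
        components=variance_components(params),
        _ctx=ctx,
        _theta=best_theta,
    )


def compare_models(full: ModelFit, sub: ModelFit) -> ComparisonResult:
    """Likelihood-ratio comparison of nested fits.

    delta chi-square is the rise in -2lnL when the submodel's dropped paths
    are constrained to zero; AIC difference is delta chi-square minus twice
    the dropped degrees of freedom, so a free parameter that buys no fit
    costs two AIC points.
    """
    cf, cs = MODEL_COMPONENTS[full.model_label], MODEL_COMPONENTS[sub.model_label]
    if not (cs < cf):
        raise ValueError(
            f"{sub.model_label} is not strictly nested in {full.model_label}"
        )
    delta_df = full.n_free_params - sub.n_free_params
    if delta_df <= 0:
        raise ValueError("nested comparison requires a positive df difference")
    delta = sub.minus2_loglik - full.minus2_loglik
    if delta < -1e-4:
        raise ValueError(
            f"submodel fits better by {-delta:.3g}: optimizer failure in the full model"
        )
    delta = max(delta, 0.0)
    return ComparisonResult(
        delta_chi2=delta,
        delta_df=delta_df,
        p_value=float(chi2_dist.sf(delta, delta_df)),
        aic_delta=delta - 2.0 * delta_df,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals

_QUANTITY_DOMAIN = {
    "a2": (0.0, 1.0), "c2": (0.0, 1.0), "e2": (0.0, 1.0),
    "r_a": (-1.0, 1.0), "r_c": (-1.0, 1.0), "r_e": (-1.0, 1.0),
}


def _profile_objective_factory(fit, quantity, options):
    ctx = fit._ctx
    label = fit.model_label
    names = _theta_layout(label, ctx.n_traits)
    comps = MODEL_COMPONENTS[label]
    thr = ctx.marginal_thresholds

    if quantity in ("r_a", "r_c", "r_e"):
        zname = {"r_a": "zra", "r_c": "zrc", "r_e": "zre"}[quantity]
        if zname not in names:
            raise ValueError(f"{quantity} undefined for model {label}")
        free = [n for n in names if n != zname]

        def g(q):
            pin = {zname: math.atanh(np.clip(q, -1 + 1e-9, 1 - 1e-9))}

            def obj(theta):
                try:
                    p = _params_from_theta(theta, label, ctx, thr, pinned=pin)
                except (ValueError, OverflowError):
                    return 1e12
                return _m2ll_from_groups(p, ctx, options.n_qmc)

            x0 = np.array([fit._theta[names.index(n)] for n in free])
            if x0.size == 0:
                return obj(np.array([]))
            res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                    options=dict(xatol=1e-3, fatol=1e-5))
            return res.fun

        return g

    if quantity in ("a2", "c2", "e2"):
        if ctx.n_traits != 1:
            raise ValueError("share profiles are for univariate fits")
        comp = quantity[0].upper()
        if comp != "E" and comp not in comps:
            raise ValueError(f"{quantity} undefined for model {label}")
        others = [c for c in "ACE" if c in comps and c != comp]

        def g(q):
            q = float(np.clip(q, 1e-9, 1 - 1e-9))

            def build(theta):
                # split the remaining 1-q among the other components
                rest = {}
                if len(others) == 2:
                    w = 1.0 / (1.0 + math.exp(-theta[0]))
                    rest[others[0]] = (1 - q) * w
                    rest[others[1]] = (1 - q) * (1 - w)
                elif len(others) == 1:
                    rest[others[0]] = 1 - q
                shares = {"A": 0.0, "C": 0.0, "E": 0.0, comp: q}
                shares.update(rest)
                if shares["E"] <= 0:
                    raise ValueError("E share must stay positive")
                return cholesky_from_components(
                    (shares["A"], shares["C"], shares["E"]), thr[0]
                )

            def obj(theta):
                try:
                    p = build(theta)
                except (ValueError, OverflowError):
                    return 1e12
                return _m2ll_from_groups(p, ctx, options.n_qmc)

            if len(others) == 2:
                res = optimize.minimize_scalar(
                    lambda t: obj(np.array([t])), bounds=(-12, 12), method="bounded",
                    options=dict(xatol=1e-4),
                )
                return res.fun
            return obj(np.array([]))

        return g

    raise ValueError(f"unknown quantity {quantity!r}")


def profile_ci(
    fit: ModelFit,
    quantity: str,
    level: float = 0.95,
    options: Optional[FitOptions] = None,
) -> ProfileCI:
    """Profile-likelihood confidence interval for a share or correlation.

    Bounds are where -2lnL rises by the chi-square(1) quantile above its
    minimum, re-optimizing all nuisance parameters at each pinned value.  A
    profile that never crosses before the quantity's domain edge returns the
    edge flagged as a boundary (the ordinal-data analogue of intervals that
    span the whole admissible range).
    """
    if not fit.converged:
        raise ValueError("profile_ci requires a converged fit")
    if fit._ctx is None:
        raise ValueError("fit carries no data context")
    options = options or FitOptions()
    g = _profile_objective_factory(fit, quantity, options)
    lo_dom, hi_dom = _QUANTITY_DOMAIN[quantity]

    comp = fit.components
    if quantity in ("a2", "c2", "e2"):
        q_hat = getattr(comp, quantity)[0]
    else:
        q_hat = getattr(comp, quantity)
        if q_hat is None:
            raise ValueError(f"{quantity} undefined for this fit")
    target = _m2ll_from_groups(fit.parameters, fit._ctx, options.n_qmc) \
        + chi2_dist.ppf(level, 1)

    def search(direction):
        end = lo_dom if direction < 0 else hi_dom
        grid = np.linspace(q_hat, end, 12)[1:]
        prev = q_hat
        for q in grid:
            if g(q) >= target:
                try:
                    root = optimize.brentq(
                        lambda v: g(v) - target, min(prev, q), max(prev, q),
                        xtol=2e-3,
                    )
                except ValueError:
                    root = q
                return float(root), False
            prev = q
        return float(end), True

    low, low_b = search(-1)
    high, high_b = search(+1)
    return ProfileCI(low=low, high=high, low_at_boundary=low_b, high_at_boundary=high_b)


# ---------------------------------------------------------------------------
# polychoric correlation (two-stage ML; used for starting values and checks)


def polychoric_correlation(x, y):
    """Two-stage ML polychoric correlation between two ordinal vectors.

    Thresholds come from each margin's cumulative frequencies; the
    correlation maximizes the bivariate likelihood of the contingency table.
    Returns ``(rho, thresholds_x, thresholds_y)``; the estimate is capped
    just inside +-1 so downstream arithmetic stays finite.
    """
    x = np.asarray([np.nan if v is None else v for v in x], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in y], dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok].astype(int), y[ok].astype(int)
    if x.size == 0:
        raise ValueError("no complete pairs")
    ux, uy = np.unique(x), np.unique(y)
    if ux.size < 2 or uy.size < 2:
        raise ValueError("degenerate margin: need >=2 observed categories")
    xi = np.searchsorted(ux, x)
    yi = np.searchsorted(uy, y)
    table = np.zeros((ux.size, uy.size))
    np.add.at(table, (xi, yi), 1.0)
    tx = ndtri(np.cumsum(table.sum(axis=1))[:-1] / x.size)
    ty = ndtri(np.cumsum(table.sum(axis=0))[:-1] / x.size)
    lox = np.concatenate([[-np.inf], tx])
    hix = np.concatenate([tx, [np.inf]])
    loy = np.concatenate([[-np.inf], ty])
    hiy = np.concatenate([ty, [np.inf]])
    obs = table > 0
    ii, jj = np.nonzero(obs)
    low = np.column_stack([lox[ii], loy[jj]])
    high = np.column_stack([hix[ii], hiy[jj]])
    n = table[ii, jj]

    def nll(rho):
        p = bvn_rect(low, high, rho)
        return -np.sum(n * np.log(np.maximum(p, 1e-300)))

    cap = 1.0 - 1e-6
    res = optimize.minimize_scalar(nll, bounds=(-cap, cap), method="bounded",
                                   options=dict(xatol=1e-6))
    return float(np.clip(res.x, -cap, cap)), tx, ty
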