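"""Synthetic twin cohorts with liability-threshold A/C/E structure.

The generator draws, per pair, latent additive-genetic factors correlated
1.0 (MZ) / 0.5 (DZ) across co-twins, shared-environment factors identical
within a pair and unique-environment factors independent per twin, combines
them through the Cholesky path matrices, and cuts each trait's standardized
liability at its thresholds to get the observed category.  Onset ages are
drawn only for trait-positive individuals; for individuals positive on both
traits, the ordering of the two onsets is injected directly from a
probability vector over {ED-first, SUD-first, same age}, which is the
structure the chronology tables summarize.

Reproducibility: one master seed; each pair uses a counter-derived
substream, so a cohort is identical no matter how generation is chunked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.special import ndtri

from .biometric import CholeskyParameters, cholesky_from_components
from .core import Individual, PhenotypeSchema, TwinPairRecord, Zygosity

__all__ = [
    "TraitSpec",
    "OnsetModel",
    "GeneratingModel",
    "calibrate_thresholds",
    "simulate_pair",
    "simulate_cohort",
    "load_generating_model",
    "fixture_path",
]

_KAPPA = {Zygosity.MZ: 1.0, Zygosity.DZ: 0.5}

#: Onset ages are rounded normals truncated to this plausible interview range.
ONSET_BOUNDS = (8, 60)


def calibrate_thresholds(target_marginals: Sequence[float]) -> np.ndarray:
    """Thresholds reproducing the target category frequencies in expectation.

    Standard-normal quantiles of the cumulative frequencies; a zero
    frequency would collide two thresholds and is rejected.
    """
    p = np.asarray(target_marginals, float)
    if p.ndim != 1 or p.size < 2:
        raise ValueError("need at least two category frequencies")
    if np.any(p <= 0):
        raise ValueError("zero-frequency category: threshold collision")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("frequencies must sum to 1")
    return ndtri(np.cumsum(p)[:-1])


@dataclass
class TraitSpec:
    schema: PhenotypeSchema
    thresholds: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, float)
        if t.size != self.schema.n_categories - 1:
            raise ValueError(
                f"{self.schema.name}: {t.size} thresholds for "
                f"{self.schema.n_categories} categories"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.schema.name}: thresholds must increase strictly")
        self.thresholds = t


@dataclass
class OnsetModel:
    """Per-trait onset-age normals plus a comorbid ordering distribution.

    ``ordering`` is (P[trait1 first], P[trait2 first], P[same age]) applied
    to individuals positive on both traits of a bivariate model.
    """

    means: dict = field(default_factory=dict)  # trait -> mean age
    sds: dict = field(default_factory=dict)    # trait -> sd
    ordering: Optional[tuple] = None

    def __post_init__(self):
        if self.ordering is not None:
            o = tuple(float(v) for v in self.ordering)
            if len(o) != 3 or min(o) < 0 or abs(sum(o) - 1.0) > 1e-8:
                raise ValueError("ordering must be 3 nonnegative probabilities summing to 1")
            self.ordering = o


@dataclass
class GeneratingModel:
    traits: list  # list[TraitSpec]
    cholesky: CholeskyParameters
    onset_model: Optional[OnsetModel] = None
    missing_pair_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.missing_pair_rate <= 1.0:
            raise ValueError("missing_pair_rate must be a probability")
        if len(self.traits) != self.cholesky.n_traits:
            raise ValueError("trait list does not match Cholesky dimensionality")
        self.cholesky.validate(atol=1e-6)


def _path_matrices(p: CholeskyParameters):
    if p.n_traits == 1:
        return (np.array([[p.a11]]), np.array([[p.c11]]), np.array([[p.e11]]))
    return (
        np.array([[p.a11, 0.0], [p.a21, p.a22]]),
        np.array([[p.c11, 0.0], [p.c21, p.c22]]),
        np.array([[p.e11, 0.0], [p.e21, p.e22]]),
    )


def _draw_onset(rng, mean, sd):
    lo, hi = ONSET_BOUNDS
    return int(np.clip(round(rng.normal(mean, sd)), lo, hi))


def _assign_onsets(model: GeneratingModel, ind: Individual, rng) -> None:
    om = model.onset_model
    if om is None:
        return
    names = [t.schema.name for t in model.traits]
    positive = [n for n in names if ind.phenotypes.get(n, 0) and n in om.means]
    if len(positive) == 2 and om.ordering is not None:
        t1, t2 = positive
        e = _draw_onset(rng, om.means[t1], om.sds[t1])
        cls = rng.choice(3, p=om.ordering)
        gap = max(1, int(round(abs(rng.normal(3.0, 2.0)))))
        lo, hi = ONSET_BOUNDS
        if cls == 0:      # trait1 (ED) first
            s = min(e + gap, hi)
            if s == e:
                e = max(lo, e - 1)
        elif cls == 1:    # trait2 (SUD) first
            s = max(e - gap, lo)
            if s == e:
                e = min(hi, e + 1)
        else:
            s = e
        ind.onset_ages[t1] = e
        ind.onset_ages[t2] = int(s)
    else:
        for n in positive:
            ind.onset_ages[n] = _draw_onset(rng, om.means[n], om.sds[n])


def simulate_pair(
    model: GeneratingModel,
    zygosity: Zygosity,
    rng: np.random.Generator,
    family_id: str = "F0",
) -> TwinPairRecord:
    """Simulate one complete twin pair under the generating model."""
    La, Lc, Le = _path_matrices(model.cholesky)
    k = len(model.traits)
    kappa = _KAPPA[zygosity]
    a_shared = rng.standard_normal(k)
    a_unique = rng.standard_normal((2, k))
    c_shared = rng.standard_normal(k)
    e_unique = rng.standard_normal((2, k))
    twins = []
    for i in range(2):
        a_i = math.sqrt(kappa) * a_shared + math.sqrt(1.0 - kappa) * a_unique[i]
        liab = La @ a_i + Lc @ c_shared + Le @ e_unique[i]
        phen = {
            t.schema.name: int(np.searchsorted(t.thresholds, liab[j], side="left"))
            for j, t in enumerate(model.traits)
        }
        ind = Individual(
            person_id=f"{family_id}_{i+1}",
            family_id=family_id,
            zygosity=zygosity,
            phenotypes=phen,
            onset_ages={t.schema.name: None for t in model.traits},
        )
        _assign_onsets(model, ind, rng)
        twins.append(ind)
    return TwinPairRecord(family_id, zygosity, twins[0], twins[1])


def simulate_cohort(model: GeneratingModel, n_mz: int, n_dz: int) -> list[TwinPairRecord]:
    """Simulate ``n_mz`` MZ and ``n_dz`` DZ pair records.

    Each pair draws from its own counter-derived substream of the master
    seed; with probability ``missing_pair_rate`` a pair is reduced to a
    singleton (twin2 dropped), emulating incomplete participation.
    """
    if n_mz < 0 or n_dz < 0:
        raise ValueError("pair counts must be nonnegative")
    records = []
    zygs = [Zygosity.MZ] * n_mz + [Zygosity.DZ] * n_dz
    for idx, zyg in enumerate(zygs):
        rng = np.random.default_rng(np.random.SeedSequence([int(model.seed), idx]))
        rec = simulate_pair(model, zyg, rng, family_id=f"F{idx:05d}")
        if model.missing_pair_rate > 0 and rng.random() < model.missing_pair_rate:
            rec = TwinPairRecord(rec.family_id, rec.zygosity, rec.twin1, None)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# fixture configuration files


def fixture_path(name: str) -> Path:
    """Path of a shipped fixture YAML (``name`` with or without .yaml)."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    return Path(resources.files("twinchol") / "fixtures" / name)


def _trait_from_config(cfg: dict) -> TraitSpec:
    name = cfg["name"]
    kind = cfg.get("kind", "binary")
    if "marginals" in cfg:
        marg = np.asarray(cfg["marginals"], float)
        marg = marg / marg.sum()  # tolerate rounded tables
    elif "prevalence" in cfg:
        prev = float(cfg["prevalence"])
        marg = np.array([1.0 - prev, prev])
    else:
        raise ValueError(f"trait {name!r}: need 'marginals' or 'prevalence'")
    schema = PhenotypeSchema(name=name, kind=kind, n_categories=marg.size,
                             description=cfg.get("description", ""))
    return TraitSpec(schema=schema, thresholds=calibrate_thresholds(marg))


def load_generating_model(source, seed: Optional[int] = None) -> GeneratingModel:
    """Build a GeneratingModel from a YAML config (path, fixture name or dict).

    The config gives per-trait marginal frequencies (or a prevalence), the
    per-trait variance shares, optional cross-trait component correlations,
    an optional onset block and the singleton rate.  ``seed`` overrides the
    config seed.
    """
    if isinstance(source, dict):
        cfg = source
    else:
        p = Path(source)
        if not p.exists():
            p = fixture_path(str(source))
        cfg = yaml.safe_load(p.read_text())

    traits = [_trait_from_config(tc) for tc in cfg["traits"]]
    comp = cfg["components"]
    sh1 = comp["trait1"]
    shares1 = (sh1["a2"], sh1["c2"], sh1["e2"])
    if len(traits) == 2:
        sh2 = comp["trait2"]
        corr = cfg.get("correlations", {})
        chol = cholesky_from_components(
            shares1, traits[0].thresholds,
            (sh2["a2"], sh2["c2"], sh2["e2"]), traits[1].thresholds,
            r_a=float(corr.get("r_a", 0.0)),
            r_c=float(corr.get("r_c", 0.0)),
            r_e=float(corr.get("r_e", 0.0)),
        )
    else:
        chol = cholesky_from_components(shares1, traits[0].thresholds)

    onset = None
    if "onset" in cfg:
        oc = dict(cfg["onset"])
        ordering = oc.pop("ordering", None)
        means = {k: float(v["mean"]) for k, v in oc.items()}
        sds = {k: float(v["sd"]) for k, v in oc.items()}
        onset = OnsetModel(means=means, sds=sds,
                           ordering=tuple(ordering) if ordering else None)

    return GeneratingModel(
        traits=traits,
        cholesky=chol,
        onset_model=onset,
        missing_pair_rate=float(cfg.get("missing_pair_rate", 0.0)),
        seed=int(cfg.get("seed", 0)) if seed is None else int(seed),
    )
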