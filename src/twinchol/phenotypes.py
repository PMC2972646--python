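"""Analysis-phenotype construction from raw interview items.

Builds the bulimia-nervosa symptom count (BNSC), broad BN/AN diagnoses, the
combined any-illicit-drug disorder variable, the regular-smoking flag
(>= 7 smoking episodes per month) and the onset-chronology classification.

The interview uses an entry question ("have you ever had eating binges...")
whose non-endorsers skip the whole BN section; they score 0 on the symptom
count by construction, so skipped items are absence, not missingness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import TwinPairRecord, individuals

logger = logging.getLogger(__name__)

__all__ = [
    "BNSymptomProfile",
    "DiagnosisFlags",
    "compute_bnsc",
    "classify_broad_bn",
    "classify_broad_an",
    "combine_any_illicit",
    "classify_regular_smoker",
    "classify_chronology",
    "score_cohort",
    "BNSC_MAX",
    "ILLICIT_SUBSTANCES",
]

#: Structural maximum of the symptom count: binge entry (1) + six purge
#: behaviours (6) + loss of control (3) + amount eaten (2) + weight/shape
#: concern (3) + binge-and-vomit co-occurrence (1).
BNSC_MAX = 16

ILLICIT_SUBSTANCES = (
    "cannabis",
    "sedative",
    "stimulant",
    "cocaine",
    "opiate",
    "hallucinogen",
)

_PURGE_ITEMS = (
    "purge_vomit",
    "purge_laxative",
    "purge_waterpill",
    "purge_exercise",
    "purge_fast",
    "purge_strict_diet",
)


@dataclass
class BNSymptomProfile:
    """Raw BN-section interview items for one individual.

    ``binge_entry`` is the section entry question; all other items are
    structurally skipped (scored 0) when it is not endorsed.  Ordinal items
    use the interview anchors: loss of control 0–3, amount eaten 0–2,
    weight/shape concern 0–3.
    """

    binge_entry: Optional[bool]
    purge_vomit: Optional[bool] = False
    purge_laxative: Optional[bool] = False
    purge_waterpill: Optional[bool] = False
    purge_exercise: Optional[bool] = False
    purge_fast: Optional[bool] = False
    purge_strict_diet: Optional[bool] = False
    loss_of_control: Optional[int] = 0
    amount_eaten: Optional[int] = 0
    weight_shape_concern: Optional[int] = 0
    binge_vomit_same_time: Optional[bool] = False

    def __post_init__(self):
        for name, hi in (("loss_of_control", 3), ("amount_eaten", 2),
                         ("weight_shape_concern", 3)):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= hi):
                raise ValueError(f"{name}={v} outside 0..{hi}")


@dataclass
class DiagnosisFlags:
    """Per-individual diagnosis flags and smoking frequency."""

    bn_wave1: Optional[bool] = None
    bn_wave3: Optional[bool] = None
    an_strict: Optional[bool] = None
    an_no_amenorrhea: Optional[bool] = None
    an_no_feeling_fat: Optional[bool] = None
    sud: dict = field(default_factory=dict)  # substance -> Optional[bool]
    smoking_episodes_per_month: Optional[float] = None


def compute_bnsc(profile: BNSymptomProfile, missing_policy: str = "zero") -> int:
    """Bulimia-nervosa symptom count.

    Sum of: binge entry (0/1), each of six purge behaviours (0/1 each),
    loss-of-control (0–3), amount eaten (0–2), weight/shape concern (0–3),
    and binge-and-vomit-at-the-same-time (0/1).  Non-endorsers of the entry
    question score 0.  A missing item inside an endorsed section is zero-filled
    under the default policy (the skip structure reads absence as zero) and an
    error under ``missing_policy="strict"``.
    """
    if missing_policy not in ("zero", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not profile.binge_entry:  # False or None: no endorsed section
        return 0

    def val(name, v):
        if v is None:
            if missing_policy == "strict":
                raise ValueError(f"missing item {name!r} in endorsed BN section")
            logger.warning("compute_bnsc: missing %s treated as 0", name)
            return 0
        return int(v)

    count = 1  # the endorsed entry item itself
    for item in _PURGE_ITEMS:
        count += val(item, getattr(profile, item))
    count += val("loss_of_control", profile.loss_of_control)
    count += val("amount_eaten", profile.amount_eaten)
    count += val("weight_shape_concern", profile.weight_shape_concern)
    count += val("binge_vomit_same_time", profile.binge_vomit_same_time)
    return count


def classify_broad_bn(flags: DiagnosisFlags) -> Optional[bool]:
    """Lifetime broad BN: diagnosis at either interview wave (OR across waves)."""
    if flags.bn_wave1 is None and flags.bn_wave3 is None:
        return None
    return bool(flags.bn_wave1) or bool(flags.bn_wave3)


def classify_broad_an(flags: DiagnosisFlags) -> Optional[bool]:
    """Lifetime broad AN: strict criteria, or criteria without amenorrhea,
    or criteria without the body-image ("feeling fat") item."""
    defs = (flags.an_strict, flags.an_no_amenorrhea, flags.an_no_feeling_fat)
    if all(d is None for d in defs):
        return None
    return any(bool(d) for d in defs)


def combine_any_illicit(flags: DiagnosisFlags) -> bool:
    """Any illicit drug use disorder: OR over the six illicit substances."""
    out = False
    for sub in ILLICIT_SUBSTANCES:
        v = flags.sud.get(sub)
        if v is None:
            logger.warning("combine_any_illicit: %s missing, treated as no", sub)
            v = False
        out = out or bool(v)
    return out


def classify_regular_smoker(episodes_per_month: Optional[float]) -> Optional[bool]:
    """Regular smoker: an average of at least seven smoking episodes a month."""
    if episodes_per_month is None:
        return None
    if episodes_per_month < 0:
        raise ValueError("episodes_per_month must be >= 0")
    return episodes_per_month >= 7


def classify_chronology(ed_onset: int, sud_onset: int) -> str:
    """Order the two onsets: 'ED_first', 'SUD_first' or 'same' (integer years)."""
    if ed_onset is None or sud_onset is None:
        raise ValueError("both onset ages required; exclude incomplete records upstream")
    if ed_onset < sud_onset:
        return "ED_first"
    if ed_onset > sud_onset:
        return "SUD_first"
    return "same"


_CHRONOLOGY_CODE = {"ED_first": 0, "SUD_first": 1, "same": 2}

_BN_ITEM_FIELDS = (
    "binge_entry", "purge_vomit", "purge_laxative", "purge_waterpill",
    "purge_exercise", "purge_fast", "purge_strict_diet", "loss_of_control",
    "amount_eaten", "weight_shape_concern", "binge_vomit_same_time",
)

_AN_DEF_FIELDS = ("an_strict", "an_no_amenorrhea", "an_no_feeling_fat")


def _as_bool(v):
    return None if v is None else bool(v)


def derive_phenotypes(records: Sequence[TwinPairRecord]) -> list[str]:
    """Derive analysis phenotypes from whatever raw item columns are present.

    For every individual: ``bnsc`` from the BN-section items (when the
    ``binge_entry`` column exists), ``bn_broad`` from the two wave
    diagnoses, ``an_broad`` from the three AN definitions, ``any_illicit``
    from the six illicit-substance flags, and ``regular_smoker`` from a
    ``smoking_episodes_per_month`` column.  Returns the names added.
    """
    added: set[str] = set()
    for ind in individuals(records):
        phen = ind.phenotypes
        if "binge_entry" in phen:
            items = {f: phen.get(f) for f in _BN_ITEM_FIELDS}
            entry = items.pop("binge_entry")
            profile = BNSymptomProfile(
                binge_entry=_as_bool(entry),
                loss_of_control=items.pop("loss_of_control"),
                amount_eaten=items.pop("amount_eaten"),
                weight_shape_concern=items.pop("weight_shape_concern"),
                binge_vomit_same_time=_as_bool(items.pop("binge_vomit_same_time")),
                **{k: _as_bool(v) for k, v in items.items()},
            )
            phen["bnsc"] = compute_bnsc(profile)
            added.add("bnsc")
        if "bn_wave1" in phen or "bn_wave3" in phen:
            flags = DiagnosisFlags(bn_wave1=_as_bool(phen.get("bn_wave1")),
                                   bn_wave3=_as_bool(phen.get("bn_wave3")))
            bn = classify_broad_bn(flags)
            phen["bn_broad"] = None if bn is None else int(bn)
            added.add("bn_broad")
        if any(f in phen for f in _AN_DEF_FIELDS):
            flags = DiagnosisFlags(**{f: _as_bool(phen.get(f)) for f in _AN_DEF_FIELDS})
            an = classify_broad_an(flags)
            phen["an_broad"] = None if an is None else int(an)
            added.add("an_broad")
        if any(s in phen for s in ILLICIT_SUBSTANCES):
            flags = DiagnosisFlags(sud={s: _as_bool(phen.get(s))
                                        for s in ILLICIT_SUBSTANCES})
            phen["any_illicit"] = int(combine_any_illicit(flags))
            added.add("any_illicit")
        if "smoking_episodes_per_month" in phen:
            rs = classify_regular_smoker(phen["smoking_episodes_per_month"])
            phen["regular_smoker"] = None if rs is None else int(rs)
            added.add("regular_smoker")
    return sorted(added)


def score_cohort(
    records: Sequence[TwinPairRecord],
    ed: str = "bn_broad",
    suds: Sequence[str] = (),
) -> int:
    """Append chronology phenotypes ``chronology_<sud>`` to every individual.

    For each individual positive on both the ED diagnosis and the SUD with
    both onset ages present, stores the ordering class (0 = ED first,
    1 = SUD first, 2 = same age); otherwise missing.  Returns the number of
    comorbid individuals excluded for incomplete onset information.
    """
    def pos(v):
        return v is not None and v > 0

    excluded = 0
    for ind in individuals(records):
        for sud in suds:
            key = f"chronology_{sud}"
            if pos(ind.phenotypes.get(ed)) and pos(ind.phenotypes.get(sud)):
                e, s = ind.onset_ages.get(ed), ind.onset_ages.get(sud)
                if e is None or s is None:
                    ind.phenotypes[key] = None
                    excluded += 1
                else:
                    ind.phenotypes[key] = _CHRONOLOGY_CODE[classify_chronology(e, s)]
            else:
                ind.phenotypes[key] = None
    return excluded
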