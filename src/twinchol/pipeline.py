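"""Pipeline orchestration: simulate -> score -> associate -> twinfit -> tables.

A YAML pipeline config drives the full analysis reproducibly: the same
config and seed produce byte-identical ``results.json``.  Table renderers
emit the four publication-style tables (prevalence/comorbidity, chronology,
symptom-level associations, bivariate Cholesky summaries) as Markdown and
CSV with dashes for undefined cells.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .association import chronology_table, prevalence_table, symptom_association
from .biometric import FitOptions, compare_models, fit_model
from .core import SPEC_VERSION, read_cohort, write_cohort
from .phenotypes import score_cohort
from .simulate import load_generating_model, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "render_table", "load_config"]

TABLE_IDS = ("T1", "T2", "T3", "T4")


@dataclass
class PipelineConfig:
    """Validated pipeline description (see `load_config` for the YAML shape)."""

    out_dir: Path
    seed: Optional[int] = None
    simulate: Optional[dict] = None   # {model: fixture/path, n_mz, n_dz}
    cohort_path: Optional[Path] = None
    score: Optional[dict] = None      # {ed: name, suds: [names]}
    associate: list = field(default_factory=list)  # [{symptom, sud, adjust_for}]
    twinfit: list = field(default_factory=list)    # [{traits: [..], models: [..]}]
    tables: list = field(default_factory=list)     # subset of TABLE_IDS
    prevalence_groups: list = field(default_factory=list)  # [{group, suds}]

    def validate(self):
        if self.simulate is None and self.cohort_path is None:
            raise ValueError("config needs either a simulate stage or a cohort path")
        if self.simulate is not None and self.seed is None:
            raise ValueError("stochastic stages require an explicit seed")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ValueError(f"cohort file not found: {self.cohort_path}")
        for t in self.tables:
            if t not in TABLE_IDS:
                raise ValueError(f"unknown table id {t!r}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = PipelineConfig(
        out_dir=Path(raw.get("out_dir", "twinchol_out")),
        seed=raw.get("seed"),
        simulate=raw.get("simulate"),
        cohort_path=Path(raw["cohort"]) if "cohort" in raw else None,
        score=raw.get("score"),
        associate=raw.get("associate", []),
        twinfit=raw.get("twinfit", []),
        tables=raw.get("tables", []),
        prevalence_groups=raw.get("prevalence", []),
    )
    cfg.validate()
    return cfg


def _fit_to_dict(fit):
    c = fit.components
    p = fit.parameters
    d = {
        "model": fit.model_label,
        "minus2_loglik": fit.minus2_loglik,
        "n_free_params": fit.n_free_params,
        "n_pairs_complete": fit.n_pairs_complete,
        "n_pairs_incomplete": fit.n_pairs_incomplete,
        "converged": fit.converged,
        "a2": list(c.a2),
        "c2": list(c.c2),
        "e2": list(c.e2),
        "paths": {k: getattr(p, k) for k in
                  ("a11", "a21", "a22", "c11", "c21", "c22", "e11", "e21", "e22")},
    }
    for k in ("r_a", "r_c", "r_e"):
        d[k] = getattr(c, k)
    return d


def _stage(manifest, name, t0):
    manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the results document.

    Writes ``results.json``, a ``manifest.json`` (seeds, versions, per-stage
    wall-clock) and any requested table artifacts into ``config.out_dir``.
    Any stage failure propagates with the stage name attached.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "twinchol_version": __version__,
        "spec_version": SPEC_VERSION,
        "seed": config.seed,
        "stages": [],
    }
    results: dict = {"spec_version": SPEC_VERSION, "seed": config.seed}

    def run_stage(name, fn):
        t0 = time.time()
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        finally:
            _stage(manifest, name, t0)

    # --- cohort ---------------------------------------------------------
    if config.simulate is not None:
        def _sim():
            model = load_generating_model(config.simulate["model"], seed=config.seed)
            recs = simulate_cohort(model, int(config.simulate["n_mz"]),
                                   int(config.simulate["n_dz"]))
            write_cohort(recs, out / "cohort.csv",
                         schema=[t.schema for t in model.traits])
            return recs, [t.schema for t in model.traits]
        records, schema = run_stage("simulate", _sim)
    else:
        from .core import PhenotypeSchema

        def _load():
            raw = yaml.safe_load(Path(config.cohort_path).with_suffix(".schema.yaml").read_text())
            schema = [PhenotypeSchema(**s) for s in raw["phenotypes"]]
            return read_cohort(config.cohort_path, schema), schema
        records, schema = run_stage("load", _load)

    results["cohort"] = {
        "n_pairs": len(records),
        "n_complete": sum(1 for r in records if r.complete),
        "n_individuals": sum(2 if r.complete else 1 for r in records),
    }

    # --- score ----------------------------------------------------------
    if config.score:
        ed = config.score["ed"]
        suds = list(config.score.get("suds", []))
        excluded = run_stage("score", lambda: score_cohort(records, ed=ed, suds=suds))
        results["score"] = {"ed": ed, "suds": suds, "n_onset_excluded": excluded}
        results["chronology"] = {
            ed: [vars(r) for r in run_stage(
                "chronology", lambda: chronology_table(records, ed, suds))]
        }

    # --- prevalence/comorbidity ----------------------------------------
    if config.prevalence_groups:
        prev = {}
        for spec_row in config.prevalence_groups:
            group, suds = spec_row["group"], list(spec_row["suds"])
            rows = run_stage(f"prevalence:{group}",
                             lambda g=group, s=suds: prevalence_table(records, g, s))
            prev[group] = [vars(r) for r in rows]
        results["prevalence"] = prev

    # --- symptom associations ------------------------------------------
    if config.associate:
        assoc = []
        for design in config.associate:
            res = run_stage(
                f"associate:{design['symptom']}~{design['sud']}",
                lambda d=design: symptom_association(
                    records, d["symptom"], d["sud"], d.get("adjust_for")),
            )
            assoc.append({
                "symptom": design["symptom"], "sud": design["sud"],
                "adjust_for": design.get("adjust_for"),
                "beta": res.beta, "robust_se": res.robust_se,
                "odds_ratio": res.odds_ratio, "ci95": list(res.ci95),
                "p_value": res.p_value, "significant": res.significant,
                "n_individuals": res.n_individuals, "n_clusters": res.n_clusters,
            })
        results["associations"] = assoc

    # --- twin model fitting --------------------------------------------
    if config.twinfit:
        fits_out = []
        for job in config.twinfit:
            traits = list(job["traits"])
            labels = list(job.get("models", ["ACE", "AE"]))
            opts = FitOptions(seed=config.seed or 0,
                              **{k: v for k, v in job.get("options", {}).items()})
            fits = {}
            for label in labels:
                fits[label] = run_stage(
                    f"twinfit:{'x'.join(traits)}:{label}",
                    lambda l=label: fit_model(records, traits, l, opts))
            entry = {"traits": traits,
                     "fits": {l: _fit_to_dict(f) for l, f in fits.items()}}
            if "ACE" in fits:
                comps = {}
                for label in labels:
                    if label != "ACE":
                        cr = compare_models(fits["ACE"], fits[label])
                        comps[label] = {
                            "delta_chi2": cr.delta_chi2, "delta_df": cr.delta_df,
                            "p_value": cr.p_value, "aic_delta": cr.aic_delta,
                        }
                entry["comparisons_vs_ACE"] = comps
            fits_out.append(entry)
        results["twin_fits"] = fits_out

    # --- outputs --------------------------------------------------------
    (out / "results.json").write_text(
        json.dumps(results, indent=2, allow_nan=False, default=float) + "\n")
    for tid in config.tables:
        md, csv = render_table(results, tid)
        (out / f"table_{tid}.md").write_text(md)
        (out / f"table_{tid}.csv").write_text(csv)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return results


# ---------------------------------------------------------------------------
# table rendering


def _fmt(v, nd=2):
    if v is None:
        return "—"
    if isinstance(v, float):
        return f"{v:.{nd}f}"
    return str(v)


def _md_table(header, rows):
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines) + "\n"


def _csv_table(header, rows):
    esc = lambda s: f'"{s}"' if "," in s else s
    return "\n".join([",".join(map(esc, header))] + [",".join(map(esc, r)) for r in rows]) + "\n"


def render_table(results: dict, table_id: str):
    """Render one publication-style table as ``(markdown, csv)`` strings."""
    if table_id == "T1":
        prev = results.get("prevalence")
        if not prev:
            raise ValueError("T1 needs the prevalence stage output")
        header = ["Group", "Substance disorder", "%", "N", "OR (95% CI)"]
        rows = []
        for group, entries in prev.items():
            for e in entries:
                orci = "—"
                if e["odds_ratio"] is not None:
                    lo, hi = e["ci95"]
                    orci = f"{e['odds_ratio']:.2f} ({lo:.2f}–{hi:.2f})"
                rows.append([group, e["sud"], _fmt(e["percent"]), str(e["n"]), orci])
        return _md_table(header, rows), _csv_table(header, rows)

    if table_id == "T2":
        chron = results.get("chronology")
        if not chron:
            raise ValueError("T2 needs the chronology stage output")
        header = ["ED", "Substance disorder", "ED precedes", "SUD precedes", "Same age"]
        rows = []
        for ed, entries in chron.items():
            for e in entries:
                cells = []
                for pct, n in ((e["pct_ed_first"], e["n_ed_first"]),
                               (e["pct_sud_first"], e["n_sud_first"]),
                               (e["pct_same"], e["n_same"])):
                    cells.append("—" if pct is None or n == 0 else f"{pct}% (n = {n})")
                rows.append([ed, e["sud"]] + cells)
        return _md_table(header, rows), _csv_table(header, rows)

    if table_id == "T3":
        assoc = results.get("associations")
        if not assoc:
            raise ValueError("T3 needs the associate stage output")
        header = ["Symptom", "Substance disorder", "OR (95% CI)", "p", "sig (p<.01)"]
        rows = []
        for e in assoc:
            lo, hi = e["ci95"]
            rows.append([
                e["symptom"], e["sud"],
                f"{e['odds_ratio']:.2f} ({lo:.2f}–{hi:.2f})",
                f"{e['p_value']:.4f}", "yes" if e["significant"] else "no",
            ])
        return _md_table(header, rows), _csv_table(header, rows)

    if table_id == "T4":
        fits = results.get("twin_fits")
        if not fits:
            raise ValueError("T4 needs the twinfit stage output")
        header = ["Traits", "Model", "r_a", "r_c", "r_e", "Δχ² (p)", "ΔAIC vs ACE"]
        rows = []
        for entry in fits:
            comps = entry.get("comparisons_vs_ACE", {})
            for label, f in entry["fits"].items():
                if label == "ACE" or label not in comps:
                    dchi, daic = "—", "—"
                else:
                    c = comps[label]
                    dchi = f"{c['delta_chi2']:.2f} ({c['p_value']:.2f})"
                    daic = f"{c['aic_delta']:.2f}"
                rows.append([
                    " × ".join(entry["traits"]), label,
                    _fmt(f.get("r_a")), _fmt(f.get("r_c")), _fmt(f.get("r_e")),
                    dchi, daic,
                ])
        return _md_table(header, rows), _csv_table(header, rows)

    raise ValueError(f"unknown table id {table_id!r}")
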