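"""End-to-end orchestration: score -> split -> rates -> correct ->
standardize -> life tables -> reports, from a single YAML config.

The analysis produces two report tables mirroring the study layout: an
age-adjusted mortality table (subjects, person-years, deaths, adjusted
rate per 1000) and a life-expectancy table (point estimate and 95% CI at
each pivot age), for the full six-behavior score and for current smokers
and nonsmokers under the five-behavior score.  A run manifest records the
config hash, seeds, input digests, stratum counts, and every undefined
estimate with its reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (ReadResult, ReferenceLifeTable, SubjectSchema,
                 read_reference_lifetable, read_subjects, write_report,
                 write_reference_lifetable)
from .lifetable import AnalysisConfig, build_life_table, chiang_variance
from .persontime import tabulate
from .rates import (cohort_standard, compute_rates, correct_open_interval,
                    direct_standardize)
from .scoring import group_labels
from .sentinels import UNDEFINED, is_undefined
from .simulate import (SimulationConfig, BehaviorModel, GompertzHazard,
                       reference_from_config, simulate, true_parameter_set)

log = logging.getLogger("lexpect")

#: Report parts: (label, scheme, smoker-filter)
_PARTS = (("full", "full", None),
          ("smoker", "other_than_smoking", True),
          ("nonsmoker", "other_than_smoking", False))


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    input_digests: dict
    version: str
    stratum_counts: dict
    undefined: list = field(default_factory=list)
    rejections: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2,
                          sort_keys=True, ensure_ascii=False)


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    with open(source, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _is_current_smoker(record) -> bool:
    if record.profile is not None:
        return not record.profile.healthy_smoking
    return record.lifestyle.smoking_status == "current"


def analysis_config_from_dict(d: dict | None) -> AnalysisConfig:
    d = d or {}
    kwargs = {}
    if "pivot_ages" in d:
        kwargs["pivot_ages"] = tuple(float(p) for p in d["pivot_ages"])
    for key in ("radix", "confidence_level", "z"):
        if key in d:
            kwargs[key] = float(d[key])
    return AnalysisConfig(**kwargs)


def simulation_config_from_dict(d: dict | None) -> SimulationConfig:
    d = dict(d or {})
    kwargs = {}
    if "n" in d:
        kwargs["n"] = {k: int(v) for k, v in d["n"].items()}
    if "entry_age_range" in d:
        kwargs["entry_age_range"] = tuple(float(x)
                                          for x in d["entry_age_range"])
    if "gompertz" in d:
        kwargs["gompertz"] = {
            sex: GompertzHazard(b=float(g["b"]), theta=float(g["theta"]))
            for sex, g in d["gompertz"].items()}
    if "behaviors" in d:
        kwargs["behaviors"] = tuple(
            BehaviorModel(name=b["name"],
                          prevalence={k: float(v)
                                      for k, v in b["prevalence"].items()},
                          hazard_ratio=float(b["hazard_ratio"]))
            for b in d["behaviors"])
    for key in ("rho", "horizon", "moveout_fraction"):
        if key in d:
            kwargs[key] = float(d[key])
    if "seed" in d:
        kwargs["seed"] = int(d["seed"])
    return SimulationConfig(**kwargs)


def _read_references(io_cfg: dict) -> dict:
    """Per-sex reference tables; a single path serves both sexes."""
    ref = io_cfg["reference"]
    if isinstance(ref, dict):
        return {sex: read_reference_lifetable(path)
                for sex, path in ref.items()}
    table = read_reference_lifetable(ref)
    return {"male": table, "female": table}


class PipelineError(RuntimeError):
    """An analysis stage failed; carries the stage and stratum."""


def run_analysis(config, out_dir, fmt: str = "csv") -> RunManifest:
    """Run the full analysis described by *config* and write reports
    plus a manifest into *out_dir*.  Returns the manifest."""
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_cfg = config.get("io", {})
    lt_cfg = analysis_config_from_dict(config.get("lifetable"))

    log.info("reading subjects from %s", io_cfg.get("subjects"))
    schema = SubjectSchema(dichotomized=bool(io_cfg.get("dichotomized",
                                                        False)))
    result: ReadResult = read_subjects(io_cfg["subjects"], schema)
    refs = _read_references(io_cfg)
    log.info("accepted %d records, rejected %d", len(result.records),
             len(result.rejections))

    mortality_rows = []
    le_rows = []
    undefined: list = []
    stratum_counts: dict = {}

    # standard population: sex-specific whole-cohort person-years
    overall_ptt = tabulate(result.records, scheme=None)
    standards = {}
    for sex in ("male", "female"):
        if (sex, "all") in overall_ptt.groups():
            standards[sex] = cohort_standard(overall_ptt, sex)

    for part, scheme, smoker in _PARTS:
        if smoker is None:
            subset = result.records
        else:
            subset = [r for r in result.records
                      if _is_current_smoker(r) == smoker]
        log.info("part %s: %d subjects", part, len(subset))
        ptt = tabulate(subset, scheme=scheme)
        part_overall = tabulate(subset, scheme=None)
        counts_by_group: dict = {}
        for r in subset:
            key = (r.sex, _stratum_of(r, scheme))
            counts_by_group[key] = counts_by_group.get(key, 0) + 1

        for sex in ("male", "female"):
            strata = list(group_labels(scheme)) + ["overall"]
            for stratum in strata:
                if stratum == "overall":
                    src_ptt, src_label = part_overall, "all"
                    n_subjects = sum(v for (s, _g), v
                                     in counts_by_group.items() if s == sex)
                else:
                    src_ptt, src_label = ptt, stratum
                    n_subjects = counts_by_group.get((sex, stratum), 0)
                stratum_counts[f"{sex}/{part}/{stratum}"] = n_subjects
                try:
                    rt = compute_rates(src_ptt, sex, src_label)
                except KeyError:
                    rt = None
                if rt is None or n_subjects == 0:
                    continue
                corrected = correct_open_interval(rt, refs[sex])
                # age adjustment uses the observed rates (which makes the
                # whole cohort's adjusted rate its crude rate exactly);
                # life tables use the corrected open-interval rate
                adj = direct_standardize(rt, standards[sex])
                if is_undefined(adj):
                    undefined.append({
                        "sex": sex, "part": part, "stratum": stratum,
                        "quantity": "age_adjusted_rate",
                        "reason": "zero person-years in a band with "
                                  "positive standard weight"})
                mortality_rows.append({
                    "sex": sex, "part": part, "stratum": stratum,
                    "number": n_subjects,
                    "person_years": src_ptt.total_person_years(sex,
                                                               src_label),
                    "deaths": src_ptt.total_deaths(sex, src_label),
                    "age_adjusted_per_1000": adj,
                })
                for pivot in lt_cfg.pivot_ages:
                    lt = build_life_table(corrected, refs[sex], lt_cfg,
                                          pivot)
                    chiang_variance(lt, corrected, lt_cfg)
                    if lt.undefined:
                        undefined.append({
                            "sex": sex, "part": part, "stratum": stratum,
                            "quantity": f"life_expectancy_at_{pivot:g}",
                            "reason": lt.reason})
                        e = lo = hi = UNDEFINED
                    else:
                        e = lt.e
                        if is_undefined(lt.ci):
                            undefined.append({
                                "sex": sex, "part": part,
                                "stratum": stratum,
                                "quantity": f"ci_at_{pivot:g}",
                                "reason": "no deaths in the open interval"})
                            lo = hi = UNDEFINED
                        else:
                            lo, hi = lt.ci
                    le_rows.append({
                        "sex": sex, "part": part, "stratum": stratum,
                        "pivot": pivot, "e": e, "ci_low": lo,
                        "ci_high": hi,
                    })

    mort = pd.DataFrame(mortality_rows)
    le = pd.DataFrame(le_rows)
    ext = fmt
    write_report(mort, out / f"mortality_rates.{ext}", format=fmt,
                 rounded_columns=("age_adjusted_per_1000", "person_years"))
    write_report(le, out / f"life_expectancy.{ext}", format=fmt,
                 rounded_columns=("e", "ci_low", "ci_high"))

    manifest = RunManifest(
        config_hash=_config_hash(config),
        seeds={"simulation": config.get("simulation", {}).get("seed")},
        input_digests={
            "subjects": _sha256_file(io_cfg["subjects"]),
            **_reference_digests(io_cfg),
        },
        version=__version__,
        stratum_counts=stratum_counts,
        undefined=undefined,
        rejections=len(result.rejections),
    )
    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    log.info("wrote reports to %s (%d undefined estimates)", out,
             len(undefined))
    return manifest


def _reference_digests(io_cfg: dict) -> dict:
    ref = io_cfg["reference"]
    if isinstance(ref, dict):
        return {f"reference_{sex}": _sha256_file(p)
                for sex, p in ref.items()}
    return {"reference": _sha256_file(ref)}


def _stratum_of(record, scheme: str) -> str:
    from .persontime import stratum_label
    return stratum_label(record, scheme)


def run_simulate(config, out_dir, seed: int | None = None) -> dict:
    """Generate a synthetic cohort plus its ground truth.

    Writes ``subjects.csv``, per-sex reference life tables derived from
    the generating hazards, and ``truth.json`` with the exact band rates
    and life expectancies per stratum.  Returns the paths.
    """
    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulation_config_from_dict(config.get("simulation"))
    if seed is not None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=int(seed))
    log.info("simulating cohort (n=%s, seed=%d)", sim_cfg.n, sim_cfg.seed)
    cohort = simulate(sim_cfg)
    paths = {"subjects": out / "subjects.csv", "truth": out / "truth.json"}
    cohort.write_csv(paths["subjects"])
    for sex in ("male", "female"):
        ref = reference_from_config(sim_cfg, sex)
        p = out / f"reference_{sex}.csv"
        write_reference_lifetable(ref, p)
        paths[f"reference_{sex}"] = p
    truth = true_parameter_set(sim_cfg)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True),
                              encoding="utf-8")
    log.info("wrote %d subjects to %s", cohort.n, paths["subjects"])
    return paths
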