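"""End-to-end orchestration: load -> flag -> score -> estimate -> associate.

One :func:`run` call takes a :class:`RunConfig` (either paths to microdata +
dictionary, or a synthetic-generator config), executes every stage, and
writes five artifacts to the output directory:

* ``exclusion_report.csv`` -- absent(99) accounting;
* ``prevalence_table.csv`` -- score-level prevalences with 95% CIs, both
  variants (the published Table-2 shape);
* ``association_table.csv`` -- per-variable/category prevalences, bivariate
  and final adjusted PRs (the published Table-3 shape);
* ``selection_trace.json`` -- the backward-elimination audit trail;
* ``manifest.json`` -- every tunable affecting the outputs, verbatim, plus
  stage-by-stage sample sizes. Re-running a manifest reproduces the tables
  byte-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import association as assoc
from . import microdata as mio
from . import published
from . import scoring
from . import survey
from .simulate import GeneratorConfig, generate
from .utils import pct

log = logging.getLogger("guia_adherence")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    microdata_path: Optional[str] = None
    dictionary_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    outdir: str = "results/run"
    variants: tuple[str, ...] = ("ideal", "possible")
    ci_method: str = "logit"
    single_psu: str = "error"
    screen_alpha: float = 0.20
    retain_alpha: float = 0.05
    covariates: Optional[tuple[str, ...]] = None  # None = all canonical covariates
    seed: int = 0


def validate_config(config: RunConfig) -> list[str]:
    """All invariant violations at once; an empty list means runnable."""
    errors: list[str] = []
    has_files = config.microdata_path is not None and config.dictionary_path is not None
    if not has_files and config.generator is None:
        errors.append("either microdata_path+dictionary_path or a generator config is required")
    if config.microdata_path is not None and config.dictionary_path is None:
        errors.append("microdata_path given without dictionary_path")
    for name in ("screen_alpha", "retain_alpha"):
        a = getattr(config, name)
        if not 0 < a < 1:
            errors.append(f"{name}={a} outside (0, 1)")
    if config.ci_method not in ("logit", "wald"):
        errors.append(f"unknown ci_method {config.ci_method!r}")
    if config.single_psu not in ("error", "certainty", "collapse"):
        errors.append(f"unknown single_psu policy {config.single_psu!r}")
    for v in config.variants:
        if v not in scoring.VARIANTS:
            errors.append(f"unknown scoring variant {v!r}")
    if config.generator is not None:
        try:
            config.generator.validate()
        except ValueError as exc:
            errors.append(str(exc))
    return errors


@dataclass
class RunResult:
    data: pd.DataFrame
    exclusion: mio.ExclusionReport
    prevalence_table: pd.DataFrame
    association_table: pd.DataFrame
    screen: assoc.ScreenResult
    final_fit: Optional[assoc.PRFit]
    trace: assoc.SelectionTrace
    artifacts: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run(config: RunConfig) -> RunResult:
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid run config: " + "; ".join(errors))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        gen_cfg = dataclasses.replace(config.generator, seed=config.generator.seed)
        synth = generate(gen_cfg)
        table, dictionary = synth.microdata, synth.dictionary
        log.info("generated synthetic microdata: %d records", len(table))
    else:
        table, dictionary = config.microdata_path, config.dictionary_path

    loaded = _stage("load")(mio.load_microdata)(table, dictionary)
    if loaded.errors:
        log.warning("%d record-level recoding errors", len(loaded.errors))
    data, exclusion = _stage("flag_validity")(mio.flag_validity)(loaded.data)
    log.info(
        "n initial=%d valid=%d absent=%d retained=%.1f%%",
        exclusion.n_total,
        exclusion.n_valid,
        exclusion.n_absent,
        exclusion.pct_retained,
    )

    scored = _stage("score")(scoring.score_both_variants)(data)
    data = pd.concat([data, scored.drop(columns=["score_valid"])], axis=1)

    design = survey.SurveyDesign.from_frame(data)
    prevalence = _stage("estimate")(survey.score_prevalence_table)(
        data,
        design,
        variants=config.variants,
        ci_method=config.ci_method,
        single_psu=config.single_psu,
    )

    spec = assoc.RegressionSpec(
        covariates=config.covariates or tuple(mio.CATEGORIES),
        screen_alpha=config.screen_alpha,
        retain_alpha=config.retain_alpha,
        single_psu=config.single_psu,
    )
    screen = _stage("bivariate_screen")(assoc.bivariate_screen)(data, design, spec)
    final_fit, trace = _stage("backward_eliminate")(assoc.backward_eliminate)(
        data, design, spec, screen.included
    )
    report = _stage("report")(assoc.association_report)(
        data, design, spec, screen, final_fit, ci_method=config.ci_method
    )

    artifacts = {
        "exclusion_report": outdir / "exclusion_report.csv",
        "prevalence_table": outdir / "prevalence_table.csv",
        "association_table": outdir / "association_table.csv",
        "selection_trace": outdir / "selection_trace.json",
        "manifest": outdir / "manifest.json",
    }
    exclusion.to_frame().to_csv(artifacts["exclusion_report"], index=False)
    prevalence.to_csv(artifacts["prevalence_table"], index=False)
    report.to_csv(artifacts["association_table"], index=False)
    artifacts["selection_trace"].write_text(
        json.dumps(
            {
                "included_after_screen": list(screen.included),
                "excluded_by_screen": list(screen.excluded),
                "screen_p_values": {k: round(v, 6) for k, v in screen.p_values.items()},
                "steps": trace.to_records(),
                "final_variables": list(trace.final_variables),
            },
            indent=2,
        )
    )
    manifest = {
        "config": _config_dict(config),
        "n": {
            "initial": exclusion.n_total,
            "valid": exclusion.n_valid,
            "absent": exclusion.n_absent,
            "final_model": final_fit.n_obs if final_fit is not None else 0,
        },
        "design": dataclasses.asdict(design.info()),
    }
    artifacts["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return RunResult(
        data=data,
        exclusion=exclusion,
        prevalence_table=prevalence,
        association_table=report,
        screen=screen,
        final_fit=final_fit,
        trace=trace,
        artifacts=artifacts,
    )


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def reproduce_published(
    microdata_path: Union[str, Path, None],
    dictionary_path: Union[str, Path, None],
    outdir: Union[str, Path] = "results/reproduction",
) -> pd.DataFrame:
    """Run the pipeline on real PeNSE 2019 microdata and compare the headline
    estimates side by side with the published reference values.

    Requires the user to have downloaded the public microdata (IBGE's PeNSE
    2019 download area) and to supply a dictionary mapping the raw variable
    codes onto the canonical names (see ``make_dictionary`` for the layout a
    dictionary must have).
    """
    if (
        microdata_path is None
        or dictionary_path is None
        or not Path(microdata_path).exists()
        or not Path(dictionary_path).exists()
    ):
        raise FileNotFoundError(
            "real survey microdata not found. Download the public PeNSE 2019 "
            "microdata from IBGE's download area (estatisticas -> pense -> "
            "microdados), export the student file as delimited text, write a "
            "dictionary YAML mapping its raw columns onto the canonical "
            "variables (guia_adherence.simulate.make_dictionary shows the "
            "expected structure), then pass both paths."
        )
    result = run(
        RunConfig(
            microdata_path=str(microdata_path),
            dictionary_path=str(dictionary_path),
            outdir=str(outdir),
            single_psu="certainty",
        )
    )
    return compare_to_published(result)


def compare_to_published(result: RunResult) -> pd.DataFrame:
    """Side-by-side of computed vs reference values with absolute differences."""
    ref = published.load_reference_values()
    rows = []

    def add(key: str, computed: Optional[float]) -> None:
        if key not in ref:
            return
        target = float(ref[key]["value"])
        rows.append(
            {
                "quantity": key,
                "computed": computed,
                "published": target,
                "abs_diff": None if computed is None else abs(computed - target),
            }
        )

    add("retained_pct", result.exclusion.pct_retained)
    prev = result.prevalence_table
    for variant, key in (
        ("possible", "full_adherence_possible_pct"),
        ("ideal", "full_adherence_ideal_pct"),
    ):
        sel = prev[(prev["variant"] == variant) & (prev["score"] == 10)]
        add(key, float(sel["pct"].iloc[0]) if len(sel) else None)
    fit = result.final_fit
    for (var, cat), key in published.PR_KEYS.items():
        computed = None
        if fit is not None and var in fit.var_blocks:
            try:
                computed = fit.estimate(var, cat).pr
            except KeyError:
                computed = None
        add(key, computed)
    return pd.DataFrame(rows)
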