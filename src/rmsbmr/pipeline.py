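"""End-to-end orchestration: cohort -> renormalization -> mortality -> organs.

`run_full_pipeline` reproduces the whole analysis on synthetic inputs:

1. generate a cohort and its age-binned msBMR/BMI statistics;
2. first-renormalize, fit the decay law F(T) on the per-age means, and
   second-renormalize every subject;
3. generate a noisy mortality series from the configured model, refit
   (C, T_c), and build survival curves with and without the plateau;
4. decompose the exemplar subjects s1-s4 into organ weights.

All randomness flows from one root seed via independent substreams, and a
JSON manifest records the seed, package version and every fitted parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .allometry import SweepConfig, loglog_slope, sweep_body_mass
from .cohort import CohortSpec, generate_cohort, generate_mortality_series
from .metabolic import DEFAULT_DECAY_LAW, DecayLaw, bin_stats
from .mortality import (DEFAULT_PLATEAU_AGE, MortalityModel, fit_mortality,
                        survival_curve)
from .organs import decompose_subject, load_reference_profile
from .renormalize import fit_decay_law, renormalize_cohort

logger = logging.getLogger("rmsbmr")

#: Worked exemplar subjects (height cm, age years, recorded weight kg).
EXEMPLARS: dict[str, tuple[float, float, float | None]] = {
    "s1": (187.7, 50, 114.0),
    "s2": (160.9, 50, 68.1),
    "s3": (170.0, 50, 135.10),
    "s4": (157.7, 80, 64.60),
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_subjects: int = 25_425
    law: DecayLaw = field(default_factory=lambda: DEFAULT_DECAY_LAW)
    mortality_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"US": (1.55, 101.0), "Italy": (1.4, 101.0),
                                 "Japan": (1.5, 102.0)})
    plateau_age: float | None = DEFAULT_PLATEAU_AGE
    n_at_risk: int = 10_000
    fit_age_range: tuple[float, float] = (80, 104)
    include_allometry: bool = True
    outdir: str | Path | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        if "law" in raw:
            raw["law"] = DecayLaw(**raw["law"])
        if "mortality_params" in raw:
            raw["mortality_params"] = {
                k: tuple(v) for k, v in raw["mortality_params"].items()}
        if "fit_age_range" in raw:
            raw["fit_age_range"] = tuple(raw["fit_age_range"])
        return cls(**raw)


def _write(df, outdir: Path | None, name: str, seed: int) -> None:
    if outdir is None:
        return
    path = outdir / name
    with open(path, "w") as fh:
        fh.write(f"# rmsbmr {__version__} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_full_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest dict (also written to disk
    as ``manifest.json`` when ``config.outdir`` is set)."""
    t_start = time.perf_counter()
    outdir = Path(config.outdir) if config.outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    cohort_seed, mortality_seed = (int(s.generate_state(1)[0] % (2**31))
                                   for s in root.spawn(2))
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "stages": {}}

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s ...", name)

        def done():
            manifest["stages"][name] = round(time.perf_counter() - t0, 3)
        return done

    done = stage("cohort")
    spec = CohortSpec(n_subjects=config.n_subjects, seed=cohort_seed)
    cohort = generate_cohort(spec)
    _write(cohort, outdir, "cohort.csv", config.seed)
    stats = bin_stats(cohort)
    _write(stats, outdir, "bin_stats.csv", config.seed)
    done()

    done = stage("renormalization")
    renorm = renormalize_cohort(cohort, config.law)
    per_age = renorm.groupby("age")["first_msbmr"].mean()
    fitted_law = fit_decay_law(per_age.index.to_numpy(), per_age.to_numpy())
    _write(renorm, outdir, "renorm.csv", config.seed)
    manifest["decay_law"] = {"f0": fitted_law.f0, "u": fitted_law.u,
                             "assumed_f0": config.law.f0,
                             "assumed_u": config.law.u}
    done()

    done = stage("mortality")
    manifest["mortality"] = {}
    ages = np.arange(80, 105)
    for label, (c, t_c) in config.mortality_params.items():
        model = MortalityModel(c=c, t_c=t_c, law=config.law,
                               plateau_age=config.plateau_age)
        series = generate_mortality_series(model, ages, config.n_at_risk,
                                           seed=mortality_seed)
        c_fit, tc_fit = fit_mortality(series, config.law,
                                      config.fit_age_range)
        _write(series, outdir, f"mortality_{label}.csv", config.seed)
        surv = survival_curve(model, anchor_age=80, end_age=120)
        surv_np = survival_curve(
            MortalityModel(c=c, t_c=t_c, law=config.law, plateau_age=None),
            anchor_age=80, end_age=120)
        _write(surv, outdir, f"survival_{label}.csv", config.seed)
        manifest["mortality"][label] = {
            "c_true": c, "t_c_true": t_c, "c_fit": c_fit, "t_c_fit": tc_fit,
            "survival_120_over_80": float(surv["survival"].iloc[-1]),
            "survival_120_no_plateau": float(surv_np["survival"].iloc[-1]),
        }
    done()

    done = stage("organs")
    _, reference = load_reference_profile()
    manifest["organs"] = {}
    for name, (h, t, w0) in EXEMPLARS.items():
        table = decompose_subject(h, t, reference, recorded_weight=w0,
                                  law=config.law)
        _write(table, outdir, f"organs_{name}.csv", config.seed)
        manifest["organs"][name] = {
            "height_cm": h, "age": t,
            "renormalized_weight": table.attrs["weight"],
            "organ_weights": dict(zip(table["organ"],
                                      np.round(table["w_k"], 4))),
        }
    done()

    if config.include_allometry:
        done = stage("allometry")
        sweep = sweep_body_mass(reference, SweepConfig())
        _write(sweep, outdir, "allometry.csv", config.seed)
        manifest["allometry"] = {
            "loglog_slope": loglog_slope(sweep),
            "bmr_at_1kg": float(sweep["bmr_kcal_day"].iloc[0]),
            "bmr_at_800kg": float(sweep["bmr_kcal_day"].iloc[-1]),
        }
        done()

    manifest["elapsed_s"] = round(time.perf_counter() - t_start, 3)
    if outdir is not None:
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, default=_jsonify))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
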