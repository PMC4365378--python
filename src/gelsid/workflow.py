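"""End-to-end study workflows on synthetic compression data.

Reproduces, on synthetic stand-ins for the Instron records, the two studies
of the gel-characterization campaign:

* relaxation study — step-relaxation tests at 25% and 50% final strain,
  continuous-time linear identification, time constants from the poles;

* cyclic study — four samples cycled eight times between 15% and 25% strain
  at speeds 1.0/0.5/0.5/0.1 mm/min; the fastest sample (sample 1) is the
  identification record, the others are validation-only; every structure
  (linear, Mooney-Rivlin-inspired, Neo Hookean variant, Hammerstein) is
  identified on sample 1 and scored by FIT on samples 2-4 and by FPE on the
  cycling part of sample 1.

Default generating truths are the fitted parameter sets of the published
gel study, so the default run exercises the self-consistency targets.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import identify as _id
from . import metrics as _metrics
from .models import poles_to_time_constants
from .protocols import ProtocolSpec, generate_dataset

__all__ = [
    "MODEL1_CYCLIC_PARAMS",
    "NEOHOOKEAN_CYCLIC_PARAMS",
    "HAMMERSTEIN_CYCLIC_PARAMS",
    "LINEAR_CYCLIC_TAUS",
    "RELAXATION_TAUS",
    "WorkflowConfig",
    "load_config",
    "run_relaxation_study",
    "run_cyclic_study",
]

# Fitted parameter sets of the published cyclic study, used as the default
# synthetic ground truth (time constants in seconds).
MODEL1_CYCLIC_PARAMS = {
    "C1": -5.61, "C2": 4.4, "g1": 0.63, "g2": 5.21, "tau1": 1.0, "tau2": 20.0,
}
NEOHOOKEAN_CYCLIC_PARAMS = {
    "C1": 0.22, "C2": 0.0, "g1": 5.94, "g2": 31.58, "tau1": 1.0, "tau2": 20.0,
}
HAMMERSTEIN_CYCLIC_PARAMS = {
    "p0": 10.8, "p1": -1.1, "p2": 0.0, "g1": 0.81, "g2": 0.13,
    "tau1": 4.0, "tau2": 70.0,
}
LINEAR_CYCLIC_TAUS = (1.0, 20.0)
# relaxation-test time constants: final strain magnitude -> (tau1, tau2)
RELAXATION_TAUS = {0.25: (11.0, 180.0), 0.50: (20.0, 112.0)}


@dataclass
class WorkflowConfig:
    """Configuration of the synthetic reproduction workflow.

    Sample 1 (the fastest speed) is always the identification sample; the
    remaining speeds define the validation samples.  noise_frac is the load
    noise standard deviation as a fraction of the clean peak load.
    """

    e0: float = 5.0
    A0: float = 700.0
    sample_rate: float = 10.0
    relax_sample_rate: float = 1.0
    speeds: tuple = (1.0, 0.5, 0.5, 0.1)          # mm/min, sample 1 first
    cycle_bounds: tuple = (0.15, 0.25)
    n_cycles: int = 8
    relax_targets: tuple = (0.25, 0.50)
    relax_speed: float = 10.0                      # mm/min
    hold_duration: float = 1800.0
    relax_g: tuple = (0.05, 0.05)                  # N per unit strain
    noise_frac: float = 0.01
    seed: int = 0
    generator: str = "hammerstein"
    generator_params: dict = field(default_factory=lambda: dict(HAMMERSTEIN_CYCLIC_PARAMS))
    structures: tuple = ("linear_tf", "model1", "model1_neohookean", "hammerstein")
    max_iter: int = 100

    def __post_init__(self):
        if len(self.speeds) < 2:
            raise ValueError("need an identification sample and at least one validation sample")

    def cyclic_spec(self, speed: float) -> ProtocolSpec:
        return ProtocolSpec(
            kind="cycles", crosshead_speed=speed, cycle_bounds=tuple(self.cycle_bounds),
            n_cycles=self.n_cycles, sample_rate=self.sample_rate, e0=self.e0, A0=self.A0,
        )

    def relax_spec(self, target: float) -> ProtocolSpec:
        return ProtocolSpec(
            kind="step_relaxation", crosshead_speed=self.relax_speed,
            target_strain=target, hold_duration=self.hold_duration,
            sample_rate=self.relax_sample_rate, e0=self.e0, A0=self.A0,
        )


def load_config(path) -> WorkflowConfig:
    """Read a WorkflowConfig from a YAML file; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(WorkflowConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    for key in ("speeds", "cycle_bounds", "relax_targets", "structures", "relax_g"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return WorkflowConfig(**raw)


def _seed_for(base: int, stream: int) -> int:
    return int((base * 1_000_003 + stream) % (2**31 - 1))


def run_relaxation_study(cfg: WorkflowConfig) -> dict:
    """Step-relaxation generation + linear identification + time constants.

    For each configured final strain, generates a linear two-Maxwell
    relaxation record with the published time constants, fits the
    second-order transfer function and reports the recovered taus and the
    pointwise model-vs-data error trace summary.
    """
    report = {}
    for k, target in enumerate(cfg.relax_targets):
        taus = RELAXATION_TAUS.get(round(target, 2))
        if taus is None:
            raise KeyError(f"no reference time constants for target strain {target}")
        spec = cfg.relax_spec(target)
        if spec.hold_duration <= 0:
            raise ValueError("relaxation protocol needs a hold phase")
        g1, g2 = cfg.relax_g
        ds = generate_dataset(
            "linear", {"g1": g1, "g2": g2, "tau1": taus[0], "tau2": taus[1]},
            spec, relative_noise=cfg.noise_frac or None,
            seed=_seed_for(cfg.seed, 100 + k), label=f"relax{int(target*100)}",
        )
        res = _id.fit_linear_ct(ds)
        tau_hat = poles_to_time_constants(res.params)
        abs_err = np.abs(res.residuals)
        report[ds.label] = {
            "target_strain": target,
            "tau_true": taus,
            "tau_hat": tuple(float(x) for x in tau_hat),
            "max_abs_error": float(abs_err.max()),
            "n_samples": len(ds),
            "converged": res.converged,
        }
    return report


def _ident_input_fitcfg(structure, cfg, tau_linear):
    """Fit configuration per structure, fixing the scale-ridge normalization."""
    if structure == "linear_tf":
        return _id.FitConfig(structure="linear_tf")
    if structure == "model1":
        init = dict(MODEL1_CYCLIC_PARAMS)
        init["tau1"], init["tau2"] = tau_linear
        return _id.FitConfig(
            structure="model1", init=init,
            fixed=frozenset({"C2", "tau1", "tau2"}), max_iter=cfg.max_iter,
        )
    if structure == "model1_neohookean":
        init = {k: v for k, v in NEOHOOKEAN_CYCLIC_PARAMS.items() if k != "C2"}
        init["tau1"], init["tau2"] = tau_linear
        return _id.FitConfig(
            structure="model1_neohookean", init=init,
            fixed=frozenset({"C1", "tau1", "tau2"}), max_iter=cfg.max_iter,
        )
    if structure == "hammerstein":
        return _id.FitConfig(
            structure="hammerstein", init=dict(HAMMERSTEIN_CYCLIC_PARAMS),
            fixed=frozenset({"g1"}), max_iter=cfg.max_iter,
        )
    raise ValueError(structure)


def run_cyclic_study(cfg: WorkflowConfig) -> _metrics.FitReport:
    """Identify every structure on sample 1, validate on samples 2..n.

    Returns a FitReport with per-sample validation FIT, FPE on the cycling
    part of the identification record, and the estimated parameters.  A
    structure whose fit fails is recorded with NaN entries instead of
    aborting the study.
    """
    datasets = []
    for i, speed in enumerate(cfg.speeds, start=1):
        ds = generate_dataset(
            cfg.generator, copy.deepcopy(cfg.generator_params), cfg.cyclic_spec(speed),
            relative_noise=cfg.noise_frac or None,
            seed=_seed_for(cfg.seed, i), label=f"sample{i}",
        )
        datasets.append(ds)
    ident, validation = datasets[0], datasets[1:]
    ident_labels = {ident.label}

    # linear fit first: its time constants seed the model-1 grey-box fits
    lin_res = _id.fit_linear_ct(ident)
    try:
        tau_linear = poles_to_time_constants(lin_res.params)
    except ValueError:
        tau_linear = LINEAR_CYCLIC_TAUS

    lower_bound = cfg.cycle_bounds[0]
    _, cycling_idx = _metrics.split_first_compression(
        ident.kinematics().eps_eng, lower_bound
    )

    report = _metrics.FitReport(meta={
        "identification_sample": ident.label,
        "generator": cfg.generator,
        "seed": cfg.seed,
        "tau_linear": tuple(float(x) for x in tau_linear),
    })
    for structure in cfg.structures:
        try:
            if structure == "linear_tf":
                res = lin_res
                n_free = 4
            else:
                fit_cfg = _ident_input_fitcfg(structure, cfg, tau_linear)
                res = _id.fit_greybox(ident, fit_cfg)
                n_free = len(_id._PARAM_NAMES[structure]) - len(fit_cfg.fixed)
            report.params[structure] = res.params
            cyc_res = res.residuals[cycling_idx]
            report.fpe[structure] = _metrics.fpe(
                float(cyc_res @ cyc_res), n_free, cyc_res.size
            )
            fits = {}
            for ds in validation:
                _, fit_val = _id.validate(structure, res.params, ds, ident_labels)
                fits[ds.label] = fit_val
            report.fit[structure] = fits
        except Exception as exc:  # isolate per-structure failures
            report.params[structure] = None
            report.fpe[structure] = float("nan")
            report.fit[structure] = {ds.label: float("nan") for ds in validation}
            report.meta[f"error_{structure}"] = f"{type(exc).__name__}: {exc}"
    return report
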