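"""Validated run configuration and the end-to-end analysis pipeline.

``run_pipeline`` chains simulate → offset-correct → extract I-V → fit →
relaxation fit → event idealization → HH comparison and returns the result
bundle; with an output directory set, every table is written as delimited
text stamped with the configuration hash and master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ConductanceSet, Environment, PoreEnergetics
from .events import baseline_correct, empirical_open_probability, idealize
from .hh import HHPotassium, compare_open_probabilities
from .relax import fit_biexponential_series
from .steady import correct_offset, detect_negative_slope, extract_iv, fit_iv, fit_linear
from .synth import (GatingKinetics, NoiseModel, TransientParams, VoltageProtocol,
                    build_protocol, simulate_trace)
from .traceio import write_trace

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("lipidpore")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    start_V: float = 0.200
    stop_V: float = -0.200
    step_V: float = -0.025
    step_s: float = 3.1
    pre_step_s: float = 0.05
    sample_rate_Hz: float = 10_000.0
    holding_V: float = 0.0

    def build(self) -> VoltageProtocol:
        return build_protocol(self.start_V, self.stop_V, self.step_V, self.step_s,
                              self.pre_step_s, self.sample_rate_Hz, self.holding_V)


class ConductanceConfig(_Strict):
    g_leak_S: float = 0.37e-9
    n_pores: int = 100
    g_single_S: float = 15e-12

    def build(self) -> ConductanceSet:
        return ConductanceSet.from_pores(self.g_leak_S, self.n_pores, self.g_single_S)


class EnergeticsConfig(_Strict):
    dmu0_kT: float = 4.0
    alpha_kT_per_V2: float = 40.0
    offset_V: float = 0.2

    def build(self) -> PoreEnergetics:
        return PoreEnergetics(self.dmu0_kT, self.alpha_kT_per_V2, self.offset_V)


class EnvironmentConfig(_Strict):
    temperature_K: float = 297.85
    nernst_V: float = 0.0

    def build(self) -> Environment:
        return Environment(temperature_K=self.temperature_K, nernst_V=self.nernst_V)


class GatingConfig(_Strict):
    mean_open_lifetime_s: float = 0.03
    mode: Literal["stochastic", "equilibrium"] = "equilibrium"

    def build(self) -> GatingKinetics:
        return GatingKinetics(self.mean_open_lifetime_s)


class TransientConfig(_Strict):
    tau_fast_s: float = 258e-6
    tau_slow_s: float = 1.74e-3
    amp_fast_A_per_V: float = 2e-9
    amp_slow_A_per_V: float = 5e-10

    def build(self) -> TransientParams:
        return TransientParams(self.tau_fast_s, self.tau_slow_s,
                               self.amp_fast_A_per_V, self.amp_slow_A_per_V)


class NoiseConfig(_Strict):
    current_noise_sd_A: float = 2e-12
    filter_cutoff_Hz: Optional[float] = 2000.0
    filter_order: int = 4

    def build(self) -> NoiseModel:
        return NoiseModel(self.current_noise_sd_A, self.filter_cutoff_Hz,
                          self.filter_order)


class RunConfig(_Strict):
    """Complete, schema-validated description of one pipeline run."""

    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    conductances: ConductanceConfig = Field(default_factory=ConductanceConfig)
    energetics: EnergeticsConfig = Field(default_factory=EnergeticsConfig)
    environment: EnvironmentConfig = Field(default_factory=EnvironmentConfig)
    gating: GatingConfig = Field(default_factory=GatingConfig)
    transient: TransientConfig = Field(default_factory=TransientConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    mode: Literal["patch", "BLM"] = "patch"
    scenario: Literal["pores_only", "fixed_leak", "free_leak", "linear"] = "free_leak"
    fixed_g_leak_S: Optional[float] = None
    depth_mm: Optional[float] = None
    seed: int = 0
    output_dir: Optional[str] = None
    write_traces: bool = False
    verbosity: int = 0

    @model_validator(mode="after")
    def _check_scenario(self):
        if self.scenario == "fixed_leak" and self.fixed_g_leak_S is None:
            raise ValueError("scenario 'fixed_leak' requires fixed_g_leak_S")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, *args, **kwargs):
    logger.info("stage %s", name)
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(name, exc) from exc


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate → extract → fit → detect → compare end-to-end.

    Returns a bundle with the I-V profile, steady-state fit, relaxation fit,
    event tables, HH comparison table, plus the configuration hash and seed.
    With ``n_pores = 0`` the linear scenario is selected automatically and no
    event detection is attempted.
    """
    if config.verbosity:
        logging.basicConfig(level=logging.INFO)
    chash = config.config_hash()
    logger.info("run %s seed %d", chash, config.seed)

    protocol = config.protocol.build()
    cs = config.conductances.build()
    pe = config.energetics.build()
    env = config.environment.build()
    extra = {"config_hash": chash}
    if config.depth_mm is not None:
        extra["depth_mm"] = config.depth_mm

    traces = _stage("simulate", simulate_trace, protocol, cs, pe, env,
                    config.gating.build(), config.transient.build(),
                    config.noise.build(), seed=config.seed, mode=config.mode,
                    gating=config.gating.mode, extra_metadata=extra)
    corrected = _stage("correct-offset", lambda ts: [correct_offset(t) for t in ts], traces)
    profile = _stage("extract-iv", extract_iv, corrected, (1.5, 3.0), True)

    leak_only = cs.n_pores == 0 or cs.g_pores_S == 0
    scenario = "linear" if leak_only else config.scenario
    if scenario == "linear":
        fit = _stage("fit-iv", fit_linear, profile, env.nernst_V)
    else:
        fit = _stage("fit-iv", fit_iv, profile, scenario, config.fixed_g_leak_S,
                     env.nernst_V)
    negative_slope = _stage("detect-negative-slope", detect_negative_slope, profile)

    relax_fit = _stage("fit-relax", fit_biexponential_series, corrected)

    event_lists = {}
    if not leak_only and config.gating.mode == "stochastic":
        def _detect():
            out = {}
            for trace in corrected:
                level = trace.metadata["level_V"]
                if level == protocol.holding_V:
                    continue
                # skip the capacitive transient after the jump (~30 tau_slow)
                skip_s = protocol.pre_step_s + 30 * config.transient.tau_slow_s
                j = int(round(skip_s * trace.sample_rate_Hz))
                from .synth import CurrentTrace
                step_part = CurrentTrace(trace.time_s[j:], trace.current_A[j:],
                                         trace.voltage_V[j:], dict(trace.metadata))
                out[level] = idealize(baseline_correct(step_part))
            return out
        event_lists = _stage("detect-events", _detect)
    p_open_table = (empirical_open_probability(event_lists, cs.n_pores)
                    if event_lists else pd.DataFrame())

    hh_cmp = _stage("hh-table", compare_open_probabilities, HHPotassium(),
                    [pe], np.arange(-0.2, 0.2001, 0.005))

    bundle = {
        "config_hash": chash,
        "seed": config.seed,
        "profile": profile,
        "fit": fit,
        "negative_slope_intervals": negative_slope,
        "relaxation": relax_fit,
        "events": event_lists,
        "empirical_open_probability": p_open_table,
        "hh_comparison": hh_cmp,
    }

    if config.output_dir:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"config_hash": chash, "seed": config.seed}
        profile.to_frame().to_csv(outdir / "iv_profile.tsv", sep="\t", index=False)
        with open(outdir / "iv_fit.json", "w") as fh:
            json.dump({**stamp, "scenario": fit.scenario,
                       "g_leak_pS": fit.g_leak_S * 1e12,
                       "g_pores_pS": fit.g_pores_S * 1e12,
                       "offset_mV": fit.offset_V * 1e3,
                       "dmu0_kT": fit.dmu0_kT,
                       "alpha_kT_per_V2": fit.alpha_kT_per_V2,
                       "rss_A2": fit.residual_sum_squares,
                       "min_open_probability": fit.min_open_probability},
                      fh, indent=2, allow_nan=True)
        relax_fit.jumps.to_csv(outdir / "relaxation.tsv", sep="\t", index=False)
        if len(p_open_table):
            p_open_table.to_csv(outdir / "open_probability.tsv", sep="\t", index=False)
        for level, ev in event_lists.items():
            ev.events.to_csv(outdir / f"events_{level * 1e3:+.0f}mV.tsv",
                             sep="\t", index=False)
        hh_cmp.to_csv(outdir / "hh_comparison.tsv", sep="\t", index=False)
        with open(outdir / "run.json", "w") as fh:
            json.dump({**stamp, "config": config.model_dump()}, fh, indent=2)
        if config.write_traces:
            for trace in traces:
                write_trace(trace, outdir / "traces" /
                            f"trace_{trace.metadata['level_V'] * 1e3:+.0f}mV.tsv")
    return bundle
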