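"""Monte Carlo harness: coverage, power, and p-value calibration studies.

Given a true process (from the zoo) with known measures, the harness
simulates S independent series, runs the requested bootstrap on each, and
evaluates the frequentist performance of the resulting confidence
distributions:

* ``coverage_experiment`` — empirical coverage of equi-tailed intervals at a
  grid of nominal levels, reported as deviations from nominal with binomial
  standard errors sqrt(p(1-p)/S);
* ``null_test_experiment`` — two-sided p-values on a grid of null values
  theta0, giving the p-value ECDF at the truth (calibration) and the
  rejection rate across the grid (power).

Defaults are reduced-scale (S=100, B=200) relative to a full study
(S=2000, B=2000); per-replicate seeds are base seed + replicate index, so
results are bit-reproducible and trivially parallelizable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .confidence import (
    MEASURES,
    bias_corrected_cd,
    cm_bootstrap,
    confidence_interval,
    markov_bootstrap,
    p_value,
    percentile_cd,
)
from .measures import measure_set
from .zoo import ZooSpec, build_zoo_process, sample_sequence

__all__ = ["ExperimentConfig", "ExperimentResult", "coverage_experiment", "null_test_experiment"]

log = logging.getLogger("cmboot")

DEFAULT_LEVELS = (0.5, 0.8, 0.9, 0.95, 0.99)


@dataclass
class ExperimentConfig:
    """Configuration of one Monte Carlo study."""

    process: ZooSpec
    T: int = 10_000
    S: int = 100
    B: int = 200
    families: tuple[str, ...] = ("machine", "markov")
    cd_kinds: tuple[str, ...] = ("percentile",)
    levels: tuple[float, ...] = DEFAULT_LEVELS
    theta0_rel: tuple[float, ...] = (-0.2, -0.1, 0.0, 0.1, 0.2)
    test_alpha: float = 0.05
    seed: int = 0
    alpha_cssr: float = 0.001
    fixed_order: int | None = None

    def __post_init__(self) -> None:
        if self.S < 1 or self.B < 1:
            raise ValueError("S and B must be >= 1")
        if any(not 0 < lv < 1 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["process"] = {"name": self.process.name, "params": self.process.params}
        return d


@dataclass
class ExperimentResult:
    """Tidy records plus failure accounting and the truth used."""

    records: pd.DataFrame
    truth: dict
    config: ExperimentConfig
    n_failures: int = 0
    pvalues: pd.DataFrame | None = field(default=None, repr=False)


def _cd_factory(kind: str):
    if kind == "percentile":
        return percentile_cd
    if kind in ("bc", "bias_corrected"):
        return bias_corrected_cd
    raise ValueError(f"unknown confidence-distribution kind {kind!r}")


def _run_bootstraps(cfg: ExperimentConfig, machine):
    """Yield (replicate, family, {measure: BootstrapSample}) for each series."""
    for s_idx in range(cfg.S):
        series_seed = cfg.seed + s_idx
        x, _ = sample_sequence(machine, cfg.T, series_seed)
        for family in cfg.families:
            boot_seed = cfg.seed + 100_000 + s_idx * 1000
            try:
                if family == "machine":
                    bs = cm_bootstrap(
                        x, cfg.B, alpha=cfg.alpha_cssr, seed=boot_seed, order=cfg.fixed_order
                    )
                else:
                    bs = markov_bootstrap(x, cfg.B, seed=boot_seed, order=cfg.fixed_order)
            except (ValueError, RuntimeError) as e:
                log.warning("replicate %d family %s failed: %s", s_idx, family, e)
                yield s_idx, family, None
                continue
            yield s_idx, family, bs


def coverage_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """Empirical coverage of bootstrap confidence intervals vs nominal.

    One record per (measure, family, cd kind, level) with the empirical
    coverage, its deviation from nominal, and the binomial standard error.
    Per-replicate failures are counted and excluded, never silently dropped.
    """
    machine = build_zoo_process(cfg.process)
    truth = measure_set(machine).as_dict()
    hits: dict = {}
    totals: dict = {}
    n_failures = 0
    for s_idx, family, bs in _run_bootstraps(cfg, machine):
        if bs is None:
            n_failures += 1
            continue
        for kind in cfg.cd_kinds:
            make = _cd_factory(kind)
            for meas in MEASURES:
                C = make(bs[meas])
                for level in cfg.levels:
                    lo, hi = confidence_interval(C, level)
                    key = (meas, family, kind, level)
                    totals[key] = totals.get(key, 0) + 1
                    if lo <= truth[meas] <= hi:
                        hits[key] = hits.get(key, 0) + 1
    rows = []
    for key, n in sorted(totals.items()):
        meas, family, kind, level = key
        p = hits.get(key, 0) / n
        rows.append(
            {
                "measure": meas,
                "family": family,
                "cd": kind,
                "level": level,
                "coverage": p,
                "deviation": p - level,
                "se": float(np.sqrt(p * (1 - p) / n)),
                "n": n,
            }
        )
    return ExperimentResult(pd.DataFrame(rows), truth, cfg, n_failures)


def null_test_experiment(cfg: ExperimentConfig) -> ExperimentResult:
    """p-value calibration at the truth and power across a theta0 grid.

    The theta0 grid is ``truth * (1 + r)`` for each relative offset r in
    ``cfg.theta0_rel`` (the grid always includes the truth at r = 0).
    Records hold the rejection rate at level ``cfg.test_alpha`` per grid
    point; the raw p-values at every grid point are kept in ``pvalues``.
    """
    machine = build_zoo_process(cfg.process)
    truth = measure_set(machine).as_dict()
    if 0.0 not in cfg.theta0_rel:
        raise ValueError("theta0 grid must include the true value (offset 0)")
    pv_rows = []
    n_failures = 0
    for s_idx, family, bs in _run_bootstraps(cfg, machine):
        if bs is None:
            n_failures += 1
            continue
        for kind in cfg.cd_kinds:
            make = _cd_factory(kind)
            for meas in MEASURES:
                C = make(bs[meas])
                for r in cfg.theta0_rel:
                    theta0 = truth[meas] * (1.0 + r)
                    pv_rows.append(
                        {
                            "replicate": s_idx,
                            "measure": meas,
                            "family": family,
                            "cd": kind,
                            "offset": r,
                            "theta0": theta0,
                            "p": p_value(C, theta0, "two_sided"),
                        }
                    )
    pv = pd.DataFrame(pv_rows)
    rows = []
    if not pv.empty:
        grp = pv.groupby(["measure", "family", "cd", "offset"], as_index=False).agg(
            power=("p", lambda s: float(np.mean(s <= cfg.test_alpha))),
            n=("p", "size"),
        )
        for _, g in grp.iterrows():
            p = g["power"]
            rows.append(
                {
                    "measure": g["measure"],
                    "family": g["family"],
                    "cd": g["cd"],
                    "offset": g["offset"],
                    "power": p,
                    "se": float(np.sqrt(p * (1 - p) / g["n"])),
                    "n": int(g["n"]),
                }
            )
    return ExperimentResult(pd.DataFrame(rows), truth, cfg, n_failures, pvalues=pv)
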