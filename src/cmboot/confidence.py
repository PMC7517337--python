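"""Bootstrap confidence distributions for information-dynamic measures.

The computational mechanics bootstrap treats the epsilon-machine estimated
from the observed series (CSSR at a BIC-chosen history length L0) as the
process, repeatedly simulates same-length series from it, re-runs CSSR at
the same L0 on each, and collects the plug-in measures (entropy rate,
excess entropy, statistical complexity).  A Markov-model bootstrap does the
same with a BIC-chosen Markov chain as the simulator.

The empirical CDF of the bootstrap estimates is the *percentile* confidence
distribution C(theta); the *bias-corrected* variant probit-shifts it by
twice z0 = Phi^-1(F_hat(theta_hat)).  Either yields p-values (right-sided:
C(theta0); two-sided: 2 min{C, 1-C}), confidence curves |2C - 1|, and
equi-tailed confidence intervals (C^-1(alpha/2), C^-1(1-alpha/2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cssr import cssr_estimate
from .machines import EpsilonMachine, MarkovChainModel, SymbolSequence, markov_to_machine
from .measures import DEFAULT_LTR, measure_set
from .selection import select_model
from .zoo import sample_sequence

__all__ = [
    "BootstrapSample",
    "ConfidenceDistribution",
    "cm_bootstrap",
    "markov_bootstrap",
    "percentile_cd",
    "bias_corrected_cd",
    "p_value",
    "confidence_curve",
    "confidence_interval",
]

MEASURES = ("h_mu", "E", "C_mu")

#: how many fresh seeds to try when a bootstrap replicate fails to refit
MAX_REDRAWS = 20


@dataclass
class BootstrapSample:
    """Bootstrap estimates of one measure plus the original point estimate."""

    measure: str
    point: float
    estimates: np.ndarray
    family: str
    order: int
    seed: int
    n_redraws: int = 0

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.size < 1:
            raise ValueError("need at least one bootstrap estimate")
        if not np.isfinite(self.estimates).all():
            raise ValueError("non-finite bootstrap estimate")

    @property
    def B(self) -> int:
        return int(self.estimates.size)


def _bootstrap_engine(
    x: SymbolSequence,
    B: int,
    seed: int,
    family: str,
    alpha: float,
    Ltr: int,
    order: int | None,
    reselect: bool = False,
) -> dict[str, BootstrapSample]:
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(set(x.codes.tolist())) < 2:
        raise ValueError("degenerate single-symbol sequence")
    if order is not None:
        model = (
            cssr_estimate(x, order, alpha)
            if family == "machine"
            else _refit_markov(x, order)
        )
        L0 = order
    else:
        sel = select_model(x, family=family, alpha=alpha)
        model, L0 = sel.model, sel.chosen_order
    simulator = model if isinstance(model, EpsilonMachine) else markov_to_machine(model)
    point = measure_set(simulator, Ltr=Ltr)
    T = len(x)
    est = {m: np.empty(B) for m in MEASURES}
    n_redraws = 0
    next_extra_seed = seed + B  # advanced seeds for redraws
    for b in range(B):
        rep_seed = seed + b
        for _attempt in range(MAX_REDRAWS + 1):
            try:
                xb, _ = sample_sequence(simulator, T, rep_seed)
                if reselect:
                    # re-run BIC order selection on every bootstrap series
                    sel_b = select_model(xb, family=family, alpha=alpha)
                    refit_model = sel_b.model
                    refit = (
                        refit_model
                        if isinstance(refit_model, EpsilonMachine)
                        else markov_to_machine(refit_model)
                    )
                else:
                    refit = (
                        cssr_estimate(xb, L0, alpha)
                        if family == "machine"
                        else markov_to_machine(_refit_markov(xb, L0))
                    )
                ms = measure_set(refit, Ltr=Ltr)
                break
            except (ValueError, RuntimeError):
                n_redraws += 1
                rep_seed = next_extra_seed
                next_extra_seed += 1
        else:
            raise RuntimeError("bootstrap replicate failed after repeated redraws")
        est["h_mu"][b] = ms.hmu
        est["E"][b] = ms.E
        est["C_mu"][b] = ms.Cmu
    pt = {"h_mu": point.hmu, "E": point.E, "C_mu": point.Cmu}
    return {
        m: BootstrapSample(
            measure=m,
            point=pt[m],
            estimates=est[m],
            family=family,
            order=L0,
            seed=seed,
            n_redraws=n_redraws,
        )
        for m in MEASURES
    }


def _refit_markov(x: SymbolSequence, order: int) -> MarkovChainModel:
    from .selection import fit_markov

    return fit_markov(x, order)


def cm_bootstrap(
    x: SymbolSequence,
    B: int,
    alpha: float = 0.001,
    seed: int = 0,
    Ltr: int = DEFAULT_LTR,
    order: int | None = None,
    reselect: bool = False,
) -> dict[str, BootstrapSample]:
    """Computational mechanics bootstrap: epsilon-machine simulator via CSSR.

    Fits CSSR at the BIC-chosen history length L0 (or a fixed ``order``),
    then for b = 1..B samples a same-length series from the fitted machine
    (stationary start), re-runs CSSR at the same L0, and records the plug-in
    measures.  With ``reselect=True`` each bootstrap series gets its own
    BIC order selection instead (markedly more expensive; off by default).
    Replicates whose refit degenerates are redrawn with an advanced seed;
    the redraw count is recorded on the samples.  Identical arguments give
    identical output.
    """
    return _bootstrap_engine(x, B, seed, "machine", alpha, Ltr, order, reselect)


def markov_bootstrap(
    x: SymbolSequence,
    B: int,
    seed: int = 0,
    Ltr: int = DEFAULT_LTR,
    order: int | None = None,
    reselect: bool = False,
) -> dict[str, BootstrapSample]:
    """Markov-model bootstrap: BIC-chosen Markov chain as the simulator.

    The chain is embedded as an epsilon-machine (one state per context) for
    simulation and for the plug-in measures, which systematically inflates
    the statistical complexity when distinct contexts are predictively
    equivalent.
    """
    return _bootstrap_engine(x, B, seed, "markov", 0.001, Ltr, order, reselect)


class ConfidenceDistribution:
    """A nondecreasing function C(theta) on [0, 1] with a quantile inverse."""

    def __init__(self, bs: BootstrapSample, kind: str) -> None:
        self.kind = kind
        self.sample = bs
        self._sorted = np.sort(bs.estimates)
        self._B = bs.B
        if kind == "bias_corrected":
            b = self._ecdf(bs.point)
            self._z0 = stats.norm.ppf(self._clamp(b))

    def _clamp(self, p: float | np.ndarray) -> float | np.ndarray:
        lo, hi = 1.0 / (self._B + 1), self._B / (self._B + 1.0)
        return np.clip(p, lo, hi)

    def _ecdf(self, theta) -> np.ndarray:
        return np.searchsorted(self._sorted, theta, side="right") / self._B

    def __call__(self, theta):
        F = self._ecdf(np.asarray(theta, dtype=float))
        if self.kind == "percentile":
            return F if F.ndim else float(F)
        z = stats.norm.ppf(self._clamp(F)) - 2.0 * self._z0
        out = stats.norm.cdf(z)
        return out if out.ndim else float(out)

    def quantile(self, q):
        """Inverse CDF with the type-1 (inverse-ECDF) convention: the
        smallest attained estimate theta with C(theta) >= q."""
        q = np.asarray(q, dtype=float)
        if self.kind == "percentile":
            p = q
        else:
            # invert the probit shift: F_hat quantile at Phi(Phi^-1(q) + 2 z0)
            p = stats.norm.cdf(stats.norm.ppf(np.clip(q, 1e-15, 1 - 1e-15)) + 2.0 * self._z0)
        idx = np.ceil(np.asarray(p) * self._B).astype(int) - 1
        idx = np.clip(idx, 0, self._B - 1)
        out = self._sorted[idx]
        return out if out.ndim else float(out)


def percentile_cd(bs: BootstrapSample) -> ConfidenceDistribution:
    """Percentile bootstrap confidence distribution: the empirical CDF of
    the bootstrap estimates, C(theta) = #{b : theta*_b <= theta} / B."""
    return ConfidenceDistribution(bs, "percentile")


def bias_corrected_cd(bs: BootstrapSample) -> ConfidenceDistribution:
    """Bias-corrected bootstrap confidence distribution.

    C(theta) = Phi(Phi^-1(F_hat(theta)) - 2 z0) with z0 = Phi^-1(F_hat(theta_hat));
    F_hat arguments are clamped to [1/(B+1), B/(B+1)] before the probit so a
    degenerate bootstrap distribution cannot produce infinite z-scores.
    When F_hat(theta_hat) = 0.5 (no median bias), z0 = 0 and the distribution
    coincides with the percentile one up to the clamping at the extremes.
    """
    return ConfidenceDistribution(bs, "bias_corrected")


def p_value(C: ConfidenceDistribution, theta0: float, alternative: str = "two_sided") -> float:
    """p-value for H0 at theta0: right-sided C(theta0), left-sided
    1 - C(theta0), or two-sided 2 min{C, 1 - C}."""
    c = float(C(theta0))
    if alternative == "right":
        return c
    if alternative == "left":
        return 1.0 - c
    if alternative == "two_sided":
        return 2.0 * min(c, 1.0 - c)
    raise ValueError("alternative must be 'right', 'left' or 'two_sided'")


def confidence_curve(C: ConfidenceDistribution, theta: float) -> float:
    """cc(theta) = |2 C(theta) - 1|; its sublevel set at 1 - alpha is the
    equi-tailed (1 - alpha) confidence interval."""
    return float(np.abs(2.0 * np.asarray(C(theta)) - 1.0))


def confidence_interval(C: ConfidenceDistribution, level: float) -> tuple[float, float]:
    """Equi-tailed interval (C^-1(alpha/2), C^-1(1 - alpha/2)), alpha = 1 - level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = 1.0 - level
    return float(C.quantile(a / 2.0)), float(C.quantile(1.0 - a / 2.0))
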