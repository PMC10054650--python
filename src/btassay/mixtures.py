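"""Mixture interaction statistics under the simple-similar-action model.

For a mixture of similarly acting toxins present at mass fractions r_i with
individual median lethal concentrations LC50_i, the no-interaction null
(Tabashnik's simple similar action, SSA) predicts

    LC50(mix) = ( sum_i r_i / LC50_i )^-1,

a proportion-weighted harmonic combination, assuming parallel
concentration-response lines.  The synergism factor SF = expected / observed
LC50 measures departure from the null; components with a censored
("> bound") LC50 enter at their bound, making the expected value — and SF —
a lower bound.  A Cyt protein that confers activity on an individually
non-toxic partner is an *enabler*; its effect is quantified by the enabling
factor (active component's LC50 over the mixture LC50).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .errors import UnsupportedCensorError
from .types import InteractionAssessment, LethalConcentration, MixtureComponent, QuantalFit

_PROPORTION_TOL = 1e-9


def _component_lc50(component: MixtureComponent) -> tuple[float, bool]:
    lc = component.lc50
    if lc.censored:
        if lc.censor_direction != "greater_than":
            raise UnsupportedCensorError(
                f"component {component.label!r}: a less-than censor cannot enter the SSA sum"
            )
        return lc.censor_bound, True
    return lc.estimate, False


def expected_lc50_ssa(components: Sequence[MixtureComponent]) -> tuple[float, bool]:
    """Expected mixture LC50 under simple similar action.

    Returns the harmonic combination and a flag that is True when any
    component entered at its censoring bound (the result is then a lower
    bound on the true expected LC50).
    """
    if len(components) < 2:
        raise ValueError("a mixture needs at least 2 components")
    total = sum(c.proportion for c in components)
    if abs(total - 1.0) > _PROPORTION_TOL:
        raise ValueError(f"proportions must sum to 1, got {total!r}")
    inv = 0.0
    lower_bound = False
    for comp in components:
        lc50, bounded = _component_lc50(comp)
        if lc50 <= 0:
            raise ValueError(f"component {comp.label!r}: LC50 must be > 0, got {lc50}")
        lower_bound = lower_bound or bounded
        inv += comp.proportion / lc50
    return 1.0 / inv, lower_bound


def synergism_factor(expected: float, observed: float) -> float:
    """SF = expected LC50 / observed LC50; SF >> 1 indicates synergy."""
    if expected <= 0 or observed <= 0:
        raise ValueError(f"LC50s must be > 0, got expected={expected}, observed={observed}")
    return expected / observed


def enabling_factor(active_component_lc50: float, mixture_lc50: float) -> float:
    """Fold-increase of activity over the single active component, for
    mixtures whose partner is individually non-toxic."""
    if active_component_lc50 <= 0 or mixture_lc50 <= 0:
        raise ValueError("LC50s must be > 0")
    return active_component_lc50 / mixture_lc50


def classify_interaction(
    assessment: InteractionAssessment,
    components: Sequence[MixtureComponent],
    *,
    synergy_threshold: float = 2.0,
    antagonism_threshold: float = 0.5,
) -> str:
    """Classify a mixture as enabling / synergistic / additive / antagonistic.

    'Enabling' is reserved for mixtures whose every component is
    individually censored non-active yet whose mixture LC50 is finite and
    below the screening bound.
    """
    all_censored = all(c.lc50.censored for c in components)
    if all_censored:
        min_bound = min(c.lc50.censor_bound for c in components)
        if assessment.observed_lc50 < min_bound:
            return "enabling"
    sf = assessment.synergism_factor
    if sf > synergy_threshold:
        return "synergistic"
    if sf < antagonism_threshold:
        return "antagonistic"
    return "additive"


def assess_mixture(
    components: Sequence[MixtureComponent],
    observed_lc50: float,
    *,
    synergy_threshold: float = 2.0,
    antagonism_threshold: float = 0.5,
) -> InteractionAssessment:
    """Full interaction assessment: SSA expectation, SF, enabling factor
    (when exactly one component is active and the rest are censored), and
    interaction class."""
    expected, lower_bound = expected_lc50_ssa(components)
    sf = synergism_factor(expected, observed_lc50)
    active = [c for c in components if not c.lc50.censored]
    ef: Optional[float] = None
    if len(active) == 1 and len(active) < len(components):
        ef = enabling_factor(active[0].lc50.estimate, observed_lc50)
    assessment = InteractionAssessment(
        expected_lc50=expected,
        expected_is_lower_bound=lower_bound,
        observed_lc50=observed_lc50,
        synergism_factor=sf,
        enabling_factor=ef,
    )
    assessment.interaction_class = classify_interaction(
        assessment,
        components,
        synergy_threshold=synergy_threshold,
        antagonism_threshold=antagonism_threshold,
    )
    return assessment


def sf_bootstrap_interval(
    component_fits: Sequence[tuple[float, QuantalFit]],
    mixture_fit: QuantalFit,
    *,
    n_draws: int = 2000,
    confidence: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric-bootstrap percentile interval for the synergism factor.

    An extension beyond the classical SSA analysis (which reports SF as a
    point ratio): parameters of every fit are resampled from a bivariate
    normal at their estimate/covariance, the SF recomputed per draw, and
    the percentile interval returned.  Draws with a non-positive slope are
    discarded.  Only uncensored components are supported.
    """
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    rng = np.random.default_rng(seed)

    def lc50_draws(fit: QuantalFit) -> np.ndarray:
        beta = rng.multivariate_normal(
            [fit.intercept, fit.slope], fit.covariance, size=n_draws
        )
        a, b = beta[:, 0], beta[:, 1]
        out = np.full(n_draws, np.nan)
        ok = b > 0
        out[ok] = 10.0 ** (-a[ok] / b[ok])
        return out

    inv_expected = np.zeros(n_draws)
    for r, fit in component_fits:
        inv_expected += r / lc50_draws(fit)
    sf = (1.0 / inv_expected) / lc50_draws(mixture_fit)
    sf = sf[np.isfinite(sf)]
    if len(sf) < n_draws // 2:
        raise ValueError("too many degenerate bootstrap draws for a stable interval")
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.percentile(sf, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def mortality_synergy_screen(
    mix_mortality: float, individual_mortalities: Sequence[float]
) -> bool:
    """Preliminary screen on a single shared dose: potential synergy when
    the mixture's mortality strictly exceeds the summed individual
    mortalities (sum capped at 1)."""
    for p in (mix_mortality, *individual_mortalities):
        if not 0 <= p <= 1:
            raise ValueError(f"mortality proportions must be in [0, 1], got {p}")
    return mix_mortality > min(1.0, sum(individual_mortalities))
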