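"""Domain containers for quantal bioassay analysis.

Conventions used throughout the package:

* concentrations are in ng/mL of spore-and-crystal mixture;
* the dose metameter is log10(concentration);
* fitted parameters are ordered (intercept, slope) on the link scale, so a
  mortality probability is F(intercept + slope * log10(dose)) with F the
  logistic (logit link) or standard-normal (probit link) CDF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import logistic, norm

#: Supported link functions, each a scipy frozen distribution providing
#: cdf (F), ppf (F^-1) and pdf (density of the latent tolerance distribution).
LINKS = {"logit": logistic, "probit": norm}


@dataclass(frozen=True)
class BioassayObservation:
    """One well: larvae exposed to one concentration of toxin preparation.

    ``n_dead`` may be fractional after Abbott's correction rescales the
    observed deaths by control mortality.
    """

    treatment: str
    concentration: float  # ng/mL; 0 for control wells
    n_exposed: int
    n_dead: float
    replicate: str = "1"
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.n_exposed < 1:
            raise ValueError(f"n_exposed must be >= 1, got {self.n_exposed}")
        if not 0 <= self.n_dead <= self.n_exposed:
            raise ValueError(
                f"n_dead must be in [0, n_exposed], got {self.n_dead}/{self.n_exposed}"
            )
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")
        if self.is_control != (self.concentration == 0):
            raise ValueError(
                "is_control must be set exactly for zero-concentration wells "
                f"(concentration={self.concentration}, is_control={self.is_control})"
            )

    @property
    def mortality(self) -> float:
        return self.n_dead / self.n_exposed


@dataclass
class QuantalFit:
    """Maximum-likelihood quantal dose-response fit on log10 dose.

    ``covariance`` is the 2x2 inverse observed information for
    (intercept, slope); ``heterogeneity`` is Finney's h = max(1, chi2/df),
    used to inflate variances when replicate variation exceeds binomial.
    """

    link: str
    slope: float
    intercept: float
    covariance: np.ndarray
    k_doses: int
    chi2: float
    df: int
    heterogeneity: float
    converged: bool
    iterations: int
    loglik: float = float("nan")

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; choose from {sorted(LINKS)}")
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.covariance.shape != (2, 2):
            raise ValueError("covariance must be 2x2 for (intercept, slope)")

    @property
    def slope_se(self) -> float:
        return math.sqrt(self.covariance[1, 1])

    @property
    def intercept_se(self) -> float:
        return math.sqrt(self.covariance[0, 0])

    def predict(self, concentration) -> np.ndarray | float:
        """Predicted mortality probability at the given concentration(s)."""
        x = np.log10(np.asarray(concentration, dtype=float))
        return LINKS[self.link].cdf(self.intercept + self.slope * x)


@dataclass
class LethalConcentration:
    """An LCp point estimate with confidence limits, or a censored bound.

    A censored value (no measurable dose-response) carries only
    ``censor_bound`` and ``censor_direction`` ('greater_than' for
    "LC50 > bound", the paper-style report for non-active preparations).
    """

    p_level: float = 0.5
    estimate: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    confidence: float = 0.95
    method: Optional[str] = None  # 'fieller' | 'delta'
    censored: bool = False
    censor_bound: Optional[float] = None
    censor_direction: Optional[str] = None  # 'greater_than' | 'less_than'

    def __post_init__(self) -> None:
        if self.censored:
            if self.censor_bound is None or self.censor_direction not in (
                "greater_than",
                "less_than",
            ):
                raise ValueError("censored LC needs a bound and a direction")
            if self.estimate is not None or self.lower is not None or self.upper is not None:
                raise ValueError("censored LC carries no point estimate or limits")
        else:
            if self.estimate is None or self.estimate <= 0:
                raise ValueError("uncensored LC needs a positive estimate")
            if self.lower is not None and self.upper is not None:
                if not (0 < self.lower <= self.estimate <= self.upper):
                    raise ValueError(
                        f"limits must bracket the estimate: "
                        f"{self.lower} <= {self.estimate} <= {self.upper}"
                    )

    @classmethod
    def censored_above(cls, bound: float, p_level: float = 0.5) -> "LethalConcentration":
        return cls(p_level=p_level, censored=True, censor_bound=bound,
                   censor_direction="greater_than")

    @classmethod
    def censored_below(cls, bound: float, p_level: float = 0.5) -> "LethalConcentration":
        return cls(p_level=p_level, censored=True, censor_bound=bound,
                   censor_direction="less_than")

    @classmethod
    def point(cls, estimate: float, p_level: float = 0.5) -> "LethalConcentration":
        return cls(p_level=p_level, estimate=estimate)

    def __str__(self) -> str:
        if self.censored:
            op = ">" if self.censor_direction == "greater_than" else "<"
            return f"{op}{self.censor_bound:.3g}"
        return f"{self.estimate:.3g}"


@dataclass(frozen=True)
class MixtureComponent:
    """One toxin in a mixture: its mass fraction and its individual LC50."""

    label: str
    proportion: float
    lc50: LethalConcentration

    def __post_init__(self) -> None:
        if not 0 < self.proportion <= 1:
            raise ValueError(f"proportion must be in (0, 1], got {self.proportion}")


@dataclass
class InteractionAssessment:
    """Mixture interaction summary: SSA-expected LC50, synergism factor and class."""

    expected_lc50: float
    expected_is_lower_bound: bool
    observed_lc50: float
    synergism_factor: float
    enabling_factor: Optional[float] = None
    interaction_class: Optional[str] = None  # synergistic | additive | antagonistic | enabling


@dataclass(frozen=True)
class ScreenResult:
    """Verdict of the high-dose activity screen."""

    verdict: str  # 'active' | 'non_active'
    lc50: Optional[LethalConcentration] = None  # censored, when non_active


@dataclass(frozen=True)
class AssayDesign:
    """Serial-dilution bioassay design: k doses descending from a top dose C1
    chosen to produce 90-100% mortality, with 10-15 larvae per well."""

    c1: float
    dilution_factor: float = 2.0
    n_doses: int = 6
    larvae_min: int = 10
    larvae_max: int = 15
    replicates: int = 3
    include_controls: bool = True

    def __post_init__(self) -> None:
        if self.c1 <= 0:
            raise ValueError(f"c1 must be > 0, got {self.c1}")
        if self.dilution_factor <= 1:
            raise ValueError(f"dilution_factor must be > 1, got {self.dilution_factor}")
        if self.n_doses < 3:
            raise ValueError(f"n_doses must be >= 3, got {self.n_doses}")
        if not 1 <= self.larvae_min <= self.larvae_max:
            raise ValueError("need 1 <= larvae_min <= larvae_max")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    @property
    def doses(self) -> list[float]:
        return [self.c1 / self.dilution_factor**i for i in range(self.n_doses)]


@dataclass(frozen=True)
class TrueModel:
    """Ground-truth dose-response for simulation: P(death | dose d) =
    c + (1 - c) * F(slope * (log10 d - log10 LC50)) with c the control
    mortality.  ``interaction_multiplier`` s shifts a mixture's true LC50 to
    LC50_SSA / s (s = 1 is the no-interaction null)."""

    slope: float
    lc50: float
    link: str = "logit"
    control_mortality: float = 0.0
    interaction_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")
        if self.lc50 <= 0:
            raise ValueError(f"lc50 must be > 0, got {self.lc50}")
        if not 0 <= self.control_mortality < 1:
            raise ValueError("control_mortality must be in [0, 1)")
        if self.interaction_multiplier < 0:
            raise ValueError("interaction_multiplier must be >= 0")
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")

    def mortality(self, concentration) -> np.ndarray | float:
        d = np.asarray(concentration, dtype=float)
        p = LINKS[self.link].cdf(self.slope * (np.log10(d) - math.log10(self.lc50)))
        return self.control_mortality + (1.0 - self.control_mortality) * p
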