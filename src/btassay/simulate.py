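"""Synthetic bioassay generation.

Emulates the standard larvicide bioassay design: 6 concentrations formed by
1:2 serial dilutions from a top dose C1 chosen to produce 90-100%
mortality, 10-15 second-instar larvae per well, and binomial death counts
under a logit (or probit) model on log10 concentration.  Mixtures are
simulated under the simple-similar-action null (shared slope, harmonic-mean
LC50) or with a controlled interaction multiplier s that shifts the true
mixture LC50 to LC50_SSA / s.

Reproducibility: every simulation takes an explicit seed; replicate wells
draw from independent child streams spawned from a single
``numpy.random.SeedSequence``, so increasing the replicate count never
perturbs earlier draws.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import DesignError
from .types import LINKS, AssayDesign, BioassayObservation, TrueModel


def serial_dilution(c1: float, factor: float = 2.0, k: int = 6) -> list[float]:
    """Dose series [c1, c1/factor, ..., c1/factor^(k-1)], full precision."""
    if c1 <= 0:
        raise DesignError(f"c1 must be > 0, got {c1}")
    if factor <= 1:
        raise DesignError(f"dilution factor must be > 1, got {factor}")
    if k < 2:
        raise DesignError(f"need at least 2 doses, got {k}")
    return [c1 / factor**i for i in range(k)]


def design_for_truth(
    truth: TrueModel,
    target_mortality: float = 0.90,
    **design_kwargs,
) -> AssayDesign:
    """Choose C1 so the top dose produces ``target_mortality`` under the
    stated truth, then build the serial-dilution design.

    The default 0.90 is the lower edge of the 90-100% top-dose rule: with a
    1:2 six-dose series it centres the dose range closest to the LC50, so
    the design carries information on both sides of the curve.
    """
    if not 0 < target_mortality < 1:
        raise DesignError("target_mortality must be in (0, 1)")
    z = float(LINKS[truth.link].ppf(target_mortality))
    c1 = truth.lc50 * 10.0 ** (z / truth.slope)
    return AssayDesign(c1=c1, **design_kwargs)


def simulate_assay(
    design: AssayDesign,
    truth: TrueModel,
    seed: int | np.random.SeedSequence,
    treatment: str = "sim",
) -> list[BioassayObservation]:
    """Draw one full assay: for each replicate and dose, a larvae count
    uniform on [larvae_min, larvae_max] and a binomial death count at the
    truth's mortality.  Identical seed, identical output."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(design.replicates)
    doses = design.doses
    p = np.asarray(truth.mortality(doses), dtype=float)
    out: list[BioassayObservation] = []
    for rep, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        for dose, pd in zip(doses, p):
            n = int(rng.integers(design.larvae_min, design.larvae_max + 1))
            out.append(
                BioassayObservation(
                    treatment=treatment,
                    concentration=dose,
                    n_exposed=n,
                    n_dead=int(rng.binomial(n, pd)),
                    replicate=str(rep),
                )
            )
        if design.include_controls:
            n = int(rng.integers(design.larvae_min, design.larvae_max + 1))
            out.append(
                BioassayObservation(
                    treatment=treatment,
                    concentration=0.0,
                    n_exposed=n,
                    n_dead=int(rng.binomial(n, truth.control_mortality)),
                    replicate=str(rep),
                    is_control=True,
                )
            )
    return out


def ssa_lc50(components: Sequence[tuple[float, float]]) -> float:
    """Harmonic SSA combination of (proportion, lc50) pairs."""
    total = sum(r for r, _ in components)
    if abs(total - 1.0) > 1e-9:
        raise DesignError(f"proportions must sum to 1, got {total!r}")
    if any(l <= 0 for _, l in components):
        raise DesignError("component LC50s must be > 0")
    return 1.0 / sum(r / l for r, l in components)


def simulate_mixture_assay(
    design: AssayDesign,
    components: Sequence[tuple[float, float]],
    reference_slope: float,
    s: float = 1.0,
    *,
    seed: int | np.random.SeedSequence,
    treatment: str = "mix",
    link: str = "logit",
    control_mortality: float = 0.0,
) -> list[BioassayObservation]:
    """Simulate a mixture assay under simple similar action.

    All components share ``reference_slope`` (the parallelism assumption);
    the true mixture LC50 is the SSA combination divided by the interaction
    multiplier ``s`` (s = 1: null; s > 1: synergy; s < 1: antagonism).
    """
    if reference_slope <= 0:
        raise DesignError("reference_slope must be > 0")
    if s <= 0:
        raise DesignError("interaction multiplier s must be > 0")
    truth = TrueModel(
        slope=reference_slope,
        lc50=ssa_lc50(components) / s,
        link=link,
        control_mortality=control_mortality,
        interaction_multiplier=s,
    )
    return simulate_assay(design, truth, seed, treatment=treatment)
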