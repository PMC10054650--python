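"""Shared fixtures and independent oracles.

The grid oracle maximises the pooled binomial log-likelihood by iterative
dense grid search over (intercept, slope); it shares no code with the
Newton-Raphson path it is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from btassay.quantal import pool_observations

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from btassay.simulate import design_for_truth, simulate_assay
from btassay.types import LINKS, TrueModel


def grid_ml_oracle(doses, n, y, link="logit", center=None, half_width=5.0,
                   levels=6, points=51):
    """Brute-force ML estimate of (intercept, slope) by zooming grid search."""
    x = np.log10(np.asarray(doses, dtype=float))
    n = np.asarray(n, dtype=float)
    y = np.asarray(y, dtype=float)
    dist = LINKS[link]

    def loglik(a, b):
        p = np.clip(dist.cdf(a[..., None] + b[..., None] * x), 1e-12, 1 - 1e-12)
        return np.sum(y * np.log(p) + (n - y) * np.log(1 - p), axis=-1)

    if center is None:
        pstar = (y + 0.5) / (n + 1.0)
        z = dist.ppf(pstar)
        b0, a0 = np.polyfit(x, z, 1)
    else:
        a0, b0 = center
    wa = wb = half_width
    for _ in range(levels):
        aa = np.linspace(a0 - wa, a0 + wa, points)
        bb = np.linspace(b0 - wb, b0 + wb, points)
        A, B = np.meshgrid(aa, bb, indexing="ij")
        ll = loglik(A.ravel(), B.ravel()).reshape(A.shape)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        a0, b0 = aa[i], bb[j]
        wa = 4.0 * (aa[1] - aa[0])
        wb = 4.0 * (bb[1] - bb[0])
    return a0, b0


@pytest.fixture(scope="session")
def cyt1aa_truth():
    """Ground truth matching a typical Cyt1Aa-grade toxin: LC50 171 ng/mL,
    logit slope 1.85 per log10(ng/mL)."""
    return TrueModel(slope=1.85, lc50=171.0)


@pytest.fixture(scope="session")
def standard_assay(cyt1aa_truth):
    """One fixed-seed assay under the 6-dose 1:2 serial-dilution design,
    12 larvae per well, 3 replicates.  Read-only: tests must not mutate it."""
    design = design_for_truth(cyt1aa_truth, larvae_min=12, larvae_max=12, replicates=3)
    return simulate_assay(design, cyt1aa_truth, seed=20230211, treatment="Cyt1Aa")
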