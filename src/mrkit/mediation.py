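"""Two-step MR mediation analysis.

Three MR estimates feed the decomposition: beta1 (exposure -> mediator),
beta2 (mediator -> outcome, instrumented by the mediator's own SNPs), and
beta3 (total exposure -> outcome). The indirect effect is the product
beta1 * beta2 and the proportion mediated is (beta1 * beta2) / beta3. The
analysis only claims mediation when the first step is itself significant
(``gate_alpha`` on the step-1 p-value); a failed gate still reports the
numbers but flags them as unsupported.
"""
from __future__ import annotations

import logging
import math

import numpy as np

from .datatypes import MediationResult, MREstimate

log = logging.getLogger("mrkit.mediation")


def sobel_se(beta1: float, se1: float, beta2: float, se2: float) -> float:
    """First-order (Sobel) standard error of the product beta1 * beta2."""
    return math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)


def product_se_montecarlo(
    beta1: float, se1: float, beta2: float, se2: float,
    n_draws: int = 10_000, seed: int = 0,
) -> float:
    """Monte-Carlo alternative to the Sobel se (product of independent normals)."""
    rng = np.random.default_rng(seed)
    prod = rng.normal(beta1, se1, n_draws) * rng.normal(beta2, se2, n_draws)
    return float(np.std(prod, ddof=1))


def two_step_mediation(
    step1: MREstimate,
    step2: MREstimate,
    total: MREstimate,
    gate_alpha: float = 0.05,
    *,
    exposure: str = "exposure",
    mediator: str = "mediator",
    outcome: str = "outcome",
) -> MediationResult:
    """Combine the three MR estimates into a mediation decomposition.

    ``proportion`` is NaN (with a warning) when the total effect beta3 is
    exactly zero.
    """
    b1, s1 = step1.theta, step1.se
    b2, s2 = step2.theta, step2.se
    b3, s3 = total.theta, total.se
    indirect = b1 * b2
    indirect_se = sobel_se(b1, s1, b2, s2)
    if b3 == 0:
        log.warning(
            "%s -> %s: total effect is zero; proportion mediated undefined",
            exposure, outcome,
        )
        proportion = math.nan
    else:
        proportion = indirect / b3
    gate_passed = bool(step1.pvalue < gate_alpha)
    return MediationResult(
        exposure=exposure,
        mediator=mediator,
        outcome=outcome,
        beta1=b1,
        se1=s1,
        beta2=b2,
        se2=s2,
        beta3=b3,
        se3=s3,
        indirect=indirect,
        indirect_se=indirect_se,
        proportion=proportion,
        gate_passed=gate_passed,
    )
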