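"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check: the exact
binomial test is re-derived by direct enumeration of the probability mass
function, and the logistic dose fit by a hand-written Newton iteration on
the grouped log-likelihood.
"""

from __future__ import annotations

import io
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def binom_minlike_bruteforce(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial P by direct enumeration."""
    pmf = [math.comb(n, j) * p0**j * (1.0 - p0) ** (n - j) for j in range(n + 1)]
    obs = pmf[k]
    total = sum(p for p in pmf if p <= obs * (1.0 + 1e-12))
    return min(total, 1.0)


def newton_logistic_dose(case_counts, control_counts):
    """Wald test for the dose coefficient by hand-written Newton iteration.

    Maximizes the grouped binomial log-likelihood of
    logit P(case) = b0 + b1 * dose over dose levels 0/1/2 and returns
    (beta, se, two-sided Wald P).
    """
    y1 = np.asarray(case_counts, dtype=float)
    y0 = np.asarray(control_counts, dtype=float)
    keep = (y1 + y0) > 0
    dose = np.array([0.0, 1.0, 2.0])[keep]
    y1, y0 = y1[keep], y0[keep]
    X = np.column_stack([np.ones_like(dose), dose])
    b = np.zeros(2)
    H = np.eye(2)
    for _ in range(200):
        eta = X @ b
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (y1 - (y1 + y0) * mu)
        w = (y1 + y0) * mu * (1.0 - mu)
        H = X.T @ (w[:, None] * X)
        step = np.linalg.solve(H, grad)
        b = b + step
        if np.max(np.abs(step)) < 1e-13:
            break
    se = float(np.sqrt(np.linalg.inv(H)[1, 1]))
    z = b[1] / se
    p = float(2.0 * 0.5 * math.erfc(abs(z) / math.sqrt(2.0)))
    return float(b[1]), se, p


@pytest.fixture()
def catalog_tsv():
    """Tiny hand-built catalog table exercising the parser's edge cases."""
    header = "\t".join(
        [
            "SNPS",
            "DISEASE/TRAIT",
            "STRONGEST SNP-RISK ALLELE",
            "RISK ALLELE FREQUENCY",
            "P-VALUE",
            "INITIAL SAMPLE SIZE",
            "STUDY ACCESSION",
        ]
    )
    rows = [
        "rs0001\tmyopia\trs0001-A\t0.12\t2e-9\t1,000 European individuals\tGCST000001",
        "rs0002\tmyopia\trs0002-T\tNR\t3e-10\t2,000 European cases\tGCST000001",
        "rs0003\theight\trs0003-G\t0.61\t1e-12\t500 East Asian individuals\tGCST000002",
        "rs0004\tasthma\trs0004-C\t0.40\tnot_a_number\t900 European children\tGCST000003",
        "rs0005\tasthma\trs0005-?\t0.55\t4.9e-8\t900 European children\tGCST000003",
    ]
    return io.StringIO(header + "\n" + "\n".join(rows) + "\n")
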