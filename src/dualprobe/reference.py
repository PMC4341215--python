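"""Reported tissue-cohort reference values used for cross-checks.

Group-level summaries from the original dual-probe SERS tissue study
(healthy muscle, U251 and A431 xenografts; n = 9/8/9).  These are inputs
for arithmetic cross-checks — e.g. relative EGFR expression between tumor
lines — not outputs of this package.
"""

from __future__ import annotations

__all__ = [
    "GROUP_N",
    "BP_DPMNS_MEAN",
    "BP_DPMNS_SD",
    "BP_RATIO_MEAN",
    "BP_RATIO_SD",
    "NS_ASSOCIATION_K5",
    "NS_DISSOCIATION_K6",
    "fold_difference",
]

GROUP_N = {"healthy": 9, "U251": 8, "A431": 9}

#: reported group means ± s.d. of the NS-aware kinetic estimator
BP_DPMNS_MEAN = {"healthy": 0.06, "U251": 1.13, "A431": 2.23}
BP_DPMNS_SD = {"healthy": 0.14, "U251": 0.40, "A431": 0.86}

#: reported group means ± s.d. of the ratiometric estimator (final rinse)
BP_RATIO_MEAN = {"healthy": 0.00, "U251": 0.33, "A431": 1.03}
BP_RATIO_SD = {"healthy": 0.06, "U251": 0.18, "A431": 0.11}

#: average nonspecific rate constants fitted across the 26 tissue samples (min^-1)
NS_ASSOCIATION_K5 = 0.16
NS_DISSOCIATION_K6 = 0.06


def fold_difference(means: dict[str, float], numerator: str = "A431", denominator: str = "U251") -> float:
    """Relative receptor expression between two tissue groups, ``mean_a / mean_b``."""
    b = means[denominator]
    if b == 0:
        raise ZeroDivisionError(f"group {denominator!r} mean is zero")
    return means[numerator] / b
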