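"""Worked study designs used throughout the examples and tests.

Four published one-stage case-control designs with the prevalence and
genotype relative risk conventionally assumed for them. The type 1 diabetes
control count is reported inconsistently across sources (9054 in the primary
description, 9045 in a companion figure); the primary value is used here.
"""

from .power import PowerSpec

__all__ = ["STUDIES"]

STUDIES: dict[str, PowerSpec] = {
    "type1_diabetes": PowerSpec(
        n_case=7514, n_control=9054, prevalence=0.002, grr=1.15
    ),
    "type2_diabetes": PowerSpec(
        n_case=4595, n_control=5579, prevalence=0.073, grr=1.2
    ),
    "schizophrenia": PowerSpec(
        n_case=5001, n_control=6243, prevalence=0.01, grr=1.2
    ),
    "myopia": PowerSpec(n_case=190, n_control=1064, prevalence=0.25, grr=1.6),
    "alzheimers_late_onset": PowerSpec(
        n_case=17008, n_control=37154, prevalence=0.05, grr=1.15
    ),
}

#: Alternate control count reported for the type 1 diabetes design.
T1D_ALT_CONTROLS = 9045
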