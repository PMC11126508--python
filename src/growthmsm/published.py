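"""Published survey-weighted annual transition probabilities (UK, ages 3-17).

Point estimates of the annual transition probability matrices between the
four weight states, by age band, as published for the UK Millennium Cohort
Study primary analysis (UK90 population-monitoring cut-offs, survey
weighted, unadjusted).  Rows and columns are ordered underweight, healthy
weight, overweight, obesity; each band spans a pair of adjacent survey
waves.  These matrices are input data for cohort projections and worked
examples; the estimation machinery in this package reproduces their form
from panel data, not their values (which require the restricted microdata).
"""

from __future__ import annotations

import numpy as np

from .trace import MatrixSchedule

#: (age_from, age_to) -> annual transition probability matrix (point estimates).
UK_ANNUAL_MATRICES = {
    (3.0, 5.0): np.array([
        [0.7228, 0.2719, 0.0051, 0.0002],
        [0.0024, 0.9624, 0.0332, 0.0020],
        [0.0003, 0.1928, 0.7132, 0.0937],
        [0.0000, 0.0178, 0.1419, 0.8403],
    ]),
    (5.0, 7.0): np.array([
        [0.7224, 0.2733, 0.0041, 0.0002],
        [0.0039, 0.9677, 0.0267, 0.0017],
        [0.0004, 0.1736, 0.7281, 0.0979],
        [0.0000, 0.0097, 0.0874, 0.9029],
    ]),
    (7.0, 11.0): np.array([
        [0.9326, 0.0669, 0.0005, 0.0000],
        [0.0014, 0.9836, 0.0146, 0.0004],
        [0.0000, 0.0253, 0.9223, 0.0524],
        [0.0000, 0.0002, 0.0168, 0.9830],
    ]),
    (11.0, 14.0): np.array([
        [0.9042, 0.0949, 0.0009, 0.0000],
        [0.0022, 0.9798, 0.0175, 0.0005],
        [0.0002, 0.0758, 0.8716, 0.0524],
        [0.0000, 0.0016, 0.0382, 0.9602],
    ]),
    (14.0, 17.0): np.array([
        [0.9186, 0.0806, 0.0008, 0.0000],
        [0.0023, 0.9787, 0.0183, 0.0007],
        [0.0001, 0.0787, 0.8507, 0.0705],
        [0.0000, 0.0017, 0.0391, 0.9592],
    ]),
}

#: Survey-weighted baseline (age 3) state distribution of the expanded
#: validation cohort: underweight, healthy weight, overweight, obesity.
VALIDATION_BASELINE = np.array([0.0078, 0.7270, 0.1590, 0.1063])

#: Pairwise dataset sizes (children) by band, for side-by-side comparison.
PUBLISHED_DATASET_SIZES = {
    (3.0, 5.0): 10_399,
    (5.0, 7.0): 10_729,
    (7.0, 11.0): 9_685,
    (11.0, 14.0): 8_593,
    (14.0, 17.0): 7_085,
}


def uk_annual_schedule() -> MatrixSchedule:
    """The published age-band matrices as a Markov-trace schedule."""
    return MatrixSchedule([(a0, a1, P) for (a0, a1), P in
                           UK_ANNUAL_MATRICES.items()])
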