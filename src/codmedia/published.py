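"""Published reference values for the COD medium-optimization study.

These constants transcribe the study's printed outputs so they can be
used as *inputs* to re-analysis: the published 21-coefficient quadratic
model (which, evaluated with raw g/50 mL concentrations, generates the
study's predicted-response column), the genetic-algorithm operator
settings it reports, and the experimentally measured activities used for
fold-change bookkeeping.  Nothing here is produced by this package's own
fits; see :mod:`codmedia.rsm` for refitting.
"""

from __future__ import annotations

import numpy as np

from .rsm import QuadraticModel

__all__ = [
    "published_quadratic",
    "UNOPTIMIZED_ACTIVITY",
    "VERIFIED_ACTIVITY_RSM_GA",
    "VERIFIED_ACTIVITY_ANN_GA",
    "GA_SETTINGS",
]

FACTOR_NAMES = ["soybean", "glycerol", "maltose", "mgso4", "nacl"]

#: COD activity (U/mL) of the unoptimized production medium.
UNOPTIMIZED_ACTIVITY = 4.2
#: Experimentally verified activity at the RSM-GA optimum (U/mL).
VERIFIED_ACTIVITY_RSM_GA = 6.04
#: Experimentally verified activity at the ANN-GA optimum (U/mL).
VERIFIED_ACTIVITY_ANN_GA = 9.75

#: Genetic-algorithm operator configuration as reported by the study.
#: Migration settings are no-ops for a single population and are kept
#: for fidelity only.
GA_SETTINGS = {
    "population_size": 200,
    "elite_count": 2,
    "crossover_fraction": 1.0,
    "generations": 100,
    "stall_generation_limit": 50,
    "fitness_scaling": "rank",
    "selection": "stochastic_uniform",
    "crossover": "scattered",
    "migration_interval": 20,
    "migration_fraction": 0.2,
}


def published_quadratic() -> QuadraticModel:
    """The published second-order model for COD activity (U/mL).

    Despite being described in terms of coded variables, the printed
    coefficients reproduce the study's predicted-response column only
    when evaluated with uncoded concentrations, so the model is recorded
    with ``basis="uncoded"``.
    """
    return QuadraticModel(
        intercept=2.0494,
        linear=np.array([3.6784, -0.3495, -3.6367, -36.0494, 6.6486]),
        # pair order: (soy,gly) (soy,mal) (soy,mg) (soy,na)
        #             (gly,mal) (gly,mg) (gly,na) (mal,mg) (mal,na) (mg,na)
        interactions=np.array(
            [
                -1.86133,
                0.040889,
                -8.53333,
                7.75111,
                0.70222,
                -12.26667,
                4.44444,
                136.53333,
                -9.68889,
                -212.0,
            ]
        ),
        quadratic=np.array([-1.5605, 0.9819, 1.1270, -38.9134, -4.6168]),
        basis="uncoded",
        factor_names=list(FACTOR_NAMES),
    )
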