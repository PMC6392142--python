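"""Literature reference values for the four human IgG subclasses.

Published IM-MS and modelling observables for human IgG1-4: native masses and
lowest observed charge states, hinge annotations, projection-approximation
CCS of the extended starting models, Fab-arm-sampling ensemble minima and
ranges, triplicate gas-phase collapse CCS, and experimental travelling-wave
CCS for the glycosylated and deglycosylated proteins.  These serve as inputs
for model-vs-experiment comparisons and for the workflow's summary
arithmetic; nothing in the package fits to them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_igg_table", "SUBCLASSES"]

SUBCLASSES = ["IgG1", "IgG2", "IgG3", "IgG4"]

_TABLE = {
    # per-subclass columns, order IgG1, IgG2, IgG3, IgG4
    "theoretical_mass_kda": [150, 150, 170, 150],
    "experimental_mass": [149328, 154297, 162123, 155758],
    "experimental_mass_sd": [89, 42, 4, 62],
    "lowest_charge": [21, 21, 22, 21],
    "hinge_length": [12, 12, 62, 12],
    "n_hinge_disulfides": [2, 4, 11, 2],
    "upper_hinge_residues": [5, 3, 12, 7],
    "initial_ccs": [9532, 9747, 10958, 9512],
    "sampled_min_ccs": [8756, 8597, 9170, 8484],
    "sampling_delta_ccs": [1102, 929, 1329, 1080],
    "collapsed_ccs_model1": [7226, 7396, 7284, 7017],
    "collapsed_range_model1": [176, 201, 173, 204],
    "collapsed_ccs_model2": [6988, 7197, 7176, 6766],
    "collapsed_range_model2": [196, 184, 197, 268],
    "collapsed_ccs_model3": [7142, 7309, 7588, 6644],
    "collapsed_range_model3": [176, 213, 202, 179],
    "experimental_ccs": [6827, 7030, 7173, 7024],
    "experimental_ccs_sd": [81, 113, 68, 97],
    "deglycosylated_ccs": [6851, 7087, 7202, 7095],
    "deglycosylated_ccs_sd": [61, 56, 43, 51],
}


def reference_igg_table() -> pd.DataFrame:
    """Reference observables for human IgG1-4, one row per subclass.

    CCS columns are in Angstrom^2 (model convention: projection
    approximation x 1.14), masses in Da, hinge columns in residues.
    """
    return pd.DataFrame(_TABLE, index=pd.Index(SUBCLASSES, name="subclass")).astype(float)
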