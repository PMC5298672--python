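"""Reference results and ranges from the device's field evaluation.

The spectrometer was evaluated at the Balruddery Centre for Sustainable
Cropping: 96 crop spectra (four crops × 24, captured in twinned pairs at 48
sample locations under two cropping systems) were used to train
cross-validated neural-network calibrations.  This module records the
published evaluation outputs of that trial:

* the crop and cropping-system confusion matrices (rows = predicted,
  columns = true), from which overall accuracy, user's/producer's accuracy
  and Cohen's kappa are recomputed by :mod:`phylis.evaluation`;
* the observed ranges (min/max/mean) of the eighteen soil properties
  analysed at the sample locations, which parameterise the synthetic
  soil-property generator.

The underlying raw spectra and soil analyses were never deposited, so these
summary tables are the only fixed points available for the field study.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import ConfusionMatrix

#: Four-crop confusion matrix from the field trial (rows predicted, cols true).
CROP_CONFUSION = ConfusionMatrix(
    counts=np.array([
        [20, 1, 2, 1],    # predicted beans
        [1, 22, 2, 1],    # predicted potatoes
        [0, 0, 11, 11],   # predicted barley
        [3, 1, 9, 11],    # predicted wheat
    ]),
    class_names=["beans", "potatoes", "barley", "wheat"],
)

#: Two-system confusion matrix from the field trial (rows predicted, cols true).
SYSTEM_CONFUSION = ConfusionMatrix(
    counts=np.array([
        [30, 20],   # predicted sustainable
        [18, 28],   # predicted conventional
    ]),
    class_names=["sustainable", "conventional"],
)

#: Observed range and mean of the 18 soil properties at the trial's sample
#: locations (original units: ppm unless noted; CEC meq/100 g; lime t/ha;
#: available N kg/ha).
SOIL_PROPERTY_RANGES = pd.DataFrame(
    [
        ("pH", 5.5, 6.4, 6.01),
        ("K", 29.0, 71.0, 43.8),
        ("P", 103.0, 459.0, 235.0),
        ("Mg", 113.0, 203.0, 154.0),
        ("Ca", 1385.0, 2142.0, 1727.0),
        ("S", 5.0, 17.0, 9.17),
        ("Mn", 23.0, 61.0, 41.5),
        ("Cu", 7.1, 14.5, 9.89),
        ("B", 0.81, 1.27, 1.0),
        ("Zn", 2.0, 10.7, 4.55),
        ("Mo", 0.01, 0.12, 0.05),
        ("Fe", 509.0, 981.0, 762.0),
        ("Na", 21.0, 80.0, 31.0),
        ("CEC", 11.8, 16.2, 13.6),
        ("lime_required", 3.0, 9.0, 5.25),
        ("NH3", 1.9, 122.0, 8.03),
        ("NO3", 10.8, 117.3, 45.8),
        ("available_N", 39.0, 543.0, 162.0),
    ],
    columns=["property", "minimum", "maximum", "mean"],
).set_index("property")

SOIL_PROPERTIES = list(SOIL_PROPERTY_RANGES.index)
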