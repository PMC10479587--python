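"""Published reference confusion matrices and the metric values derived
from them, used to validate the package's metric conventions end to end
(``glompath verify-tables``).

Matrices are oriented rows = predicted, columns = true, class order
(MCD, MN, TBMN).  The glomerular-level matrix covers 121 held-out
glomeruli; the patient-level matrix covers 15 held-out patients.
"""

from __future__ import annotations

import numpy as np

REFERENCE_GLOMERULAR_CONFUSION = np.array(
    [
        [21, 2, 7],
        [7, 43, 9],
        [9, 0, 23],
    ],
    dtype=np.int64,
)

REFERENCE_PATIENT_CONFUSION = np.array(
    [
        [2, 0, 1],
        [1, 6, 0],
        [2, 0, 3],
    ],
    dtype=np.int64,
)

#: reported values the metric chain must reproduce from the matrices above
REFERENCE_METRICS = {
    "glomerular": {
        "accuracy": 71.90,
        "macro_precision": 71.59,
        "macro_recall": 70.43,
        "f1": 71.01,
        "per_class_recall": {"MCD": 57, "MN": 96, "TBMN": 59},  # integer-rounded
    },
    "patient": {
        "accuracy": 73.33,
        "macro_precision": 70.79,
        "macro_recall": 71.67,
        "f1": 71.23,
        "per_class_recall": {"MCD": 40, "MN": 100, "TBMN": 75},
    },
}
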