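"""Published MIT-BIH confusion matrices used as metric-arithmetic inputs.

These count matrices are reported results of beat classifiers evaluated on
the MIT-BIH arrhythmia test sets; the evaluation module recomputes their
per-predicted-class misclassification errors and overall accuracies from
the raw counts.  Rows are ground truth, columns predictions.

``BASIC_5CLASS`` / ``EXPANDED_5CLASS`` are the five-class results of the
1-D inception network with basic [1, 3, 5] and expanded [10, 50, 100]
branch kernels.  The three-class comparison matrices restrict to NSR, APC
and PVC: ``COMPARISON_CNN`` is a patient-specific 1-D CNN baseline,
``COMPARISON_DAE`` a denoising-autoencoder baseline, and
``COMPARISON_EXPANDED`` the expanded-kernel inception network on the same
three classes.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .io import CLASS_ORDER, ClassLabel

__all__ = [
    "BASIC_5CLASS",
    "EXPANDED_5CLASS",
    "COMPARISON_CNN",
    "COMPARISON_DAE",
    "COMPARISON_EXPANDED",
    "THREE_CLASS_ORDER",
]

THREE_CLASS_ORDER = (ClassLabel.NSR, ClassLabel.APC, ClassLabel.PVC)

BASIC_5CLASS = ConfusionMatrix(
    class_order=CLASS_ORDER,
    counts=np.array(
        [
            [4788, 51, 39, 66, 56],
            [19, 1973, 3, 3, 2],
            [21, 2, 1371, 5, 1],
            [41, 3, 6, 541, 9],
            [10, 6, 1, 14, 1169],
        ]
    ),
)

EXPANDED_5CLASS = ConfusionMatrix(
    class_order=CLASS_ORDER,
    counts=np.array(
        [
            [4794, 81, 33, 29, 63],
            [26, 1968, 2, 0, 4],
            [25, 3, 1363, 5, 4],
            [62, 14, 15, 489, 20],
            [19, 4, 1, 4, 1172],
        ]
    ),
)

COMPARISON_CNN = ConfusionMatrix(
    class_order=THREE_CLASS_ORDER,
    counts=np.array(
        [
            [73539, 824, 368],
            [837, 1568, 178],
            [230, 72, 5277],
        ]
    ),
)

COMPARISON_DAE = ConfusionMatrix(
    class_order=THREE_CLASS_ORDER,
    counts=np.array(
        [
            [41873, 300, 947],
            [1520, 282, 9],
            [1240, 13, 1943],
        ]
    ),
)

COMPARISON_EXPANDED = ConfusionMatrix(
    class_order=THREE_CLASS_ORDER,
    counts=np.array(
        [
            [4794, 29, 63],
            [62, 489, 20],
            [19, 4, 1172],
        ]
    ),
)
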