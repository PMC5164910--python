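"""Published reference values for a 20-slice liver-CT vessel benchmark.

A published evaluation of GA-optimized fuzzy C-means against classical FCM
on twenty 512x512 contrast-enhanced liver CT slices reports, per slice,
the pixel confusion counts (TP/TN/FP/FN) and the derived percent metrics
for both methods.  Those printed values are reproduced here as reference
inputs so the metric formulas in :mod:`gafcm.evaluation` can be checked
against an independent, published computation.

Two caveats, verified programmatically:

* the printed specificity values agree with the quotient recomputed from
  the printed counts only to ~3e-4 (last-digit rounding noise in the
  source tables), and the printed sensitivity/accuracy columns are *not*
  consistent with the printed counts at all;
* the source's per-column "mean" row of the counts table is corrupted
  (its FP mean exceeds every per-image FP) and is therefore not included.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["reference_counts", "reference_metrics"]

# per-slice TP, TN, FP, FN — GA-FCM ("gafcm") and classical FCM ("fcm")
_COUNTS = {
    "gafcm": [
        (50437, 137872, 7480, 11238),
        (50619, 131672, 9357, 9686),
        (49061, 139806, 8737, 8078),
        (50634, 140655, 7876, 8821),
        (50072, 138102, 6852, 13666),
        (49002, 138892, 6578, 12031),
        (49364, 138746, 8478, 10404),
        (49901, 135237, 10154, 7267),
        (50722, 137870, 10301, 6831),
        (50737, 133027, 9442, 7088),
        (49123, 138375, 7096, 12821),
        (50749, 131633, 9358, 7341),
        (50722, 134084, 6993, 10152),
        (49778, 131777, 9417, 11194),
        (50408, 132286, 6396, 14292),
        (49091, 139549, 9462, 9204),
        (49651, 138263, 10104, 5407),
        (50639, 134486, 9575, 9944),
        (50392, 140817, 8278, 9572),
        (50726, 131659, 8374, 11555),
    ],
    "fcm": [
        (49685, 134828, 20977, 26230),
        (49570, 131166, 13782, 21769),
        (50338, 136374, 19007, 25168),
        (50398, 138306, 16970, 23974),
        (49181, 136224, 21150, 26220),
        (49787, 133908, 16510, 23627),
        (49699, 136787, 19581, 25369),
        (50100, 132701, 15033, 22609),
        (50226, 132808, 14699, 22431),
        (50317, 133190, 14237, 22193),
        (49359, 132722, 17972, 24371),
        (50167, 131158, 21065, 26379),
        (50118, 132458, 20335, 25956),
        (49133, 130750, 12617, 20981),
        (49045, 130608, 21356, 26311),
        (49804, 134815, 13570, 21714),
        (50727, 133281, 16254, 23510),
        (49488, 133826, 11832, 20576),
        (49978, 137475, 21697, 26732),
        (49255, 131048, 17581, 24047),
    ],
}

# per-slice percent accuracy, specificity, sensitivity as printed
_METRICS = {
    "gafcm": [
        (90.8162, 94.8538, 81.4028),
        (90.6447, 93.3653, 84.0966),
        (91.7966, 94.1179, 85.9281),
        (91.8856, 94.6972, 85.1578),
        (90.0606, 95.2727, 78.7255),
        (90.9693, 95.4779, 80.4873),
        (90.8368, 94.2416, 82.9291),
        (91.4389, 93.0159, 87.4726),
        (91.6281, 93.0479, 87.8618),
        (91.7641, 93.3725, 87.616),
        (90.3281, 95.1222, 79.2888),
        (91.5391, 93.3628, 86.8553),
        (91.4653, 95.0429, 82.8265),
        (89.9878, 93.3306, 81.8539),
        (89.8570, 95.3878, 77.7472),
        (90.9951, 93.6500, 84.6546),
        (92.3792, 93.1898, 90.2483),
        (90.5212, 93.3533, 83.6607),
        (91.2558, 94.4481, 83.7154),
        (90.1714, 94.0199, 81.2759),
    ],
    "fcm": [
        (79.9731, 86.8731, 66.0423),
        (83.7657, 90.6657, 69.3967),
        (80.8673, 87.7673, 66.0162),
        (82.1712, 89.0712, 67.5289),
        (79.9939, 86.8939, 65.8467),
        (82.6119, 89.5119, 68.2596),
        (80.5778, 87.4778, 66.2105),
        (82.9245, 89.8245, 68.2476),
        (83.1353, 90.0353, 68.6122),
        (83.4889, 90.3889, 69.1785),
        (81.7032, 88.6032, 66.7889),
        (79.5029, 86.4029, 65.4594),
        (80.3739, 87.2739, 66.2031),
        (84.4800, 91.3800, 70.3916),
        (79.9143, 86.8143, 65.8231),
        (83.9549, 90.8549, 69.4204),
        (82.2301, 89.1301, 67.8824),
        (84.9768, 91.8768, 70.8854),
        (79.4691, 86.3691, 64.8601),
        (81.6561, 88.5561, 67.0796),
    ],
}


def _check_method(method: str) -> str:
    if method not in _COUNTS:
        raise ValueError(f"method must be one of {sorted(_COUNTS)}, got {method!r}")
    return method


def reference_counts(method: str = "gafcm") -> pd.DataFrame:
    """Published per-slice confusion counts (columns TP, TN, FP, FN)."""
    data = np.asarray(_COUNTS[_check_method(method)], dtype=np.int64)
    return pd.DataFrame(
        data, columns=["TP", "TN", "FP", "FN"], index=pd.RangeIndex(1, 21, name="image")
    )


def reference_metrics(method: str = "gafcm") -> pd.DataFrame:
    """Published per-slice percent metrics (accuracy, specificity, sensitivity)."""
    data = np.asarray(_METRICS[_check_method(method)], dtype=float)
    return pd.DataFrame(
        data,
        columns=["accuracy", "specificity", "sensitivity"],
        index=pd.RangeIndex(1, 21, name="image"),
    )
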