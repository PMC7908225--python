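"""Published reference values for the Weinstein Noise Sensitivity Scale.

A published GPCM calibration of the 21-item traditional Chinese WNSS on a
community telephone sample (n = 569): per-item discriminations, per-item
integrated information, integrated test-information totals over the entire
ability range and over (-3, 3), and the memberships of the two short forms
(the OTA-derived 8-item form and the 5-item EFA-derived comparator).
These printed values support the in-table arithmetic checks - summing the
information column, ranking discriminations, anchor selection, and
information-retention percentages - without any raw respondent data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "WNSS_DISCRIMINATION",
    "WNSS_ITEM_INFORMATION",
    "WNSS8_ITEMS",
    "NSS_SF_ITEMS",
    "TEST_INFORMATION_TOTALS",
    "load_wnss_calibration",
]

# per-item GPCM discriminations, items 1..21
WNSS_DISCRIMINATION = np.array(
    [
        0.235, 0.329, 0.227, 0.348, 0.655, 0.832, 1.090, 0.214, 0.458, 1.688,
        0.605, 0.123, 0.671, 0.298, 0.148, 0.345, 0.539, 1.206, 1.214, 0.229,
        0.775,
    ]
)

# per-item integrated information over the entire ability range, items 1..21
WNSS_ITEM_INFORMATION = np.array(
    [
        1.06, 1.55, 0.97, 1.63, 3.26, 4.15, 5.45, 0.84, 2.23, 8.44,
        3.00, 0.38, 3.33, 1.33, 0.54, 1.62, 2.64, 6.03, 6.07, 0.96,
        3.86,
    ]
)

# 1-based item numbers of the two short forms
WNSS8_ITEMS = (6, 7, 10, 11, 13, 18, 19, 21)
NSS_SF_ITEMS = (7, 8, 18, 19, 21)

# integrated test-information totals of the full scale and the two short
# forms, over the entire ability range and over (-3, 3)
TEST_INFORMATION_TOTALS = {
    "full_range": {"wnss21": 59.36, "wnss8": 39.89, "nss_sf": 22.93},
    "theta_-3_3": {"wnss21": 43.42, "wnss8": 31.72, "nss_sf": 18.75},
}


def load_wnss_calibration() -> pd.DataFrame:
    """Published calibration as a DataFrame (item, a, information, form
    memberships)."""
    items = np.arange(1, 22)
    return pd.DataFrame(
        {
            "item": items,
            "discrimination": WNSS_DISCRIMINATION,
            "information": WNSS_ITEM_INFORMATION,
            "in_wnss8": np.isin(items, WNSS8_ITEMS),
            "in_nss_sf": np.isin(items, NSS_SF_ITEMS),
        }
    )
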