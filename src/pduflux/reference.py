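"""Published specific-rate measurements used as calibration and check data.

Measured specific production/consumption rates (mean ± SD of duplicate
runs, mg/g_CDW.h) for resting-cell glycerol biotransformation by
*L. reuteri* DSM 20016 ("wt") and the *pdu*-overexpressing strain RPRB3007
("mutant"), in batch operation with carbohydrazide scavenger ("B", overall
and linear-phase rows) and multi-step variable-volume fed-batch operation
("FB", one row per feeding rate).  Consumption rates carry a negative sign.

These numbers are inputs to the analysis (calibration targets and
node-balance worked examples); nothing in the package fits to them at run
time.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["measured_rates", "BATCH_SUMMARY"]

_ROWS = [
    # mode, phase/feed, pH, strain, q_S, sd, q_3HPA, sd, q_3HP, sd, q_1,3PDO, sd
    ("B", "overall", 7, "wt", -1583.2, 204.8, 889.0, 65.6, 233.8, 43.7, 197.5, 36.9),
    ("B", "overall", 7, "mutant", -2842.0, 324.8, 1718.2, 98.3, 426.5, 40.5, 360.3, 34.2),
    ("B", "linear", 7, "wt", -1474.3, 182.8, 856.2, 79.3, 200.5, 41.2, 169.3, 34.8),
    ("B", "linear", 7, "mutant", -2101.3, 252.3, 1122.6, 108.8, 330.2, 36.1, 291.6, 48.4),
    ("FB", 0.6, 7, "wt", -108.0, 1.6, 0.0, 0.0, 49.3, 3.5, 41.7, 3.0),
    ("FB", 0.6, 7, "mutant", -98.7, 5.8, 0.0, 0.0, 49.8, 1.6, 42.1, 1.3),
    ("FB", 1.6, 7, "wt", -266.2, 15.7, 29.0, 5.8, 110.8, 3.0, 93.7, 2.5),
    ("FB", 1.6, 7, "mutant", -256.9, 3.2, 0.0, 0.0, 113.5, 2.3, 95.9, 2.0),
    ("FB", 2.5, 7, "mutant", -420.8, 5.8, 36.2, 2.2, 179.2, 5.3, 151.4, 4.5),
    ("FB", 0.6, 5, "wt", -101.5, 3.8, 0.0, 0.0, 43.0, 3.7, 36.3, 3.1),
    ("FB", 0.6, 5, "mutant", -100.5, 2.4, 0.0, 0.0, 49.9, 4.3, 42.2, 3.7),
    ("FB", 1.0, 5, "wt", -150.0, 18.0, 25.9, 1.2, 62.4, 4.1, 52.7, 3.4),
    ("FB", 1.0, 5, "mutant", -164.6, 2.2, 0.0, 0.0, 76.6, 2.8, 64.7, 2.3),
    ("FB", 1.9, 5, "mutant", -313.5, 5.3, 44.4, 5.1, 139.0, 9.4, 117.4, 7.9),
]

_COLUMNS = [
    "mode", "feed", "ph", "strain",
    "q_s", "q_s_sd", "q_hpa", "q_hpa_sd", "q_hp", "q_hp_sd", "q_pdo", "q_pdo_sd",
]


def measured_rates() -> pd.DataFrame:
    """The measured specific-rate table as a DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def fedbatch_row(strain: str, ph: int, feed: float) -> dict:
    """One fed-batch row as a plain dict (raises if absent/not determined)."""
    df = measured_rates()
    sel = df[(df["mode"] == "FB") & (df["strain"] == strain)
             & (df["ph"] == ph) & (df["feed"] == feed)]
    if sel.empty:
        raise KeyError(f"no measured FB row for {strain}, pH {ph}, {feed} g/h")
    return sel.iloc[0].to_dict()


#: Batch 3HPA-production summary quantities (scavenger mode, pH 7).
BATCH_SUMMARY = {
    "mutant_hpa_titer_g_L": 26.2,       # 3HPA (as complex) after complete conversion
    "mutant_conversion_time_h": 3.0,    # 50 g/L glycerol consumed
    "mutant_volumetric_rate_g_L_h": 8.7,
    "wt_conversion_time_h": 6.0,
    "wt_q_hpa": 889.0,
    "mutant_q_hpa": 1718.2,
}
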