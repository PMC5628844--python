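"""Published roster of northeastern U.S. hawk moths (Sphingidae) with traits
and 1900–2012 trend status.

Twenty-five taxa (the *Sphinx gordius*/*S. poecila* complex is treated as one)
that breed in New England, eastern New York and northern New Jersey and feed
as adults.  For each taxon: adult activity (crepuscular counted as nocturnal),
larval host-plant habit collapsed to tree/vine vs shrub/herb, flight period
(first/last month; northern populations fly somewhat later), whether it is a
solanaceous crop pest, the number of collection lists it appears on, and
whether its detection probability declined over 1900–2012 in the
effort-corrected analysis of the compiled records.

``declined`` is NA for taxa on fewer than ten lists (too sparse for a model
fit).  The direction for non-declining species (increase vs no trend) is not
encoded because only the declined/not margin enters the trait tests.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["load_hawkmoth_roster", "MIN_LISTS"]

MIN_LISTS = 10

# species, activity, host_habit, flight_start, flight_end, pest, lists, declined
_ROSTER = [
    ("Amphion floridensis",        "diurnal",   "tree/vine",  5, 7, False,  27, False),
    ("Darapsa choerilus",          "nocturnal", "shrub/herb", 6, 8, False, 367, False),
    ("Darapsa myron",              "nocturnal", "tree/vine",  6, 7, False, 155, False),
    ("Darapsa versicolor",         "nocturnal", "shrub/herb", 6, 7, False,  29, False),
    ("Deidamia inscriptum",        "nocturnal", "tree/vine",  5, 6, False, 191, False),
    ("Eumorpha achemon",           "nocturnal", "tree/vine",  7, 9, False,  30, True),
    ("Eumorpha pandorus",          "nocturnal", "tree/vine",  7, 8, False, 107, True),
    ("Hemaris diffinis",           "diurnal",   "shrub/herb", 5, 8, False,  44, False),
    ("Hemaris gracilis",           "diurnal",   "shrub/herb", 5, 7, False,  12, False),
    ("Hemaris thysbe",             "diurnal",   "shrub/herb", 5, 8, False,  52, False),
    ("Hyles gallii",               "nocturnal", "shrub/herb", 6, 7, False,  26, False),
    ("Hyles lineata",              "nocturnal", "shrub/herb", 7, 9, False,  32, True),
    ("Proserpinus flavofasciata",  "diurnal",   "shrub/herb", 5, 6, False,   1, None),
    ("Sphecodina abbottii",        "nocturnal", "tree/vine",  5, 6, False, 132, False),
    ("Dolba hyloeus",              "nocturnal", "shrub/herb", 6, 8, False, 118, False),
    ("Lintneria eremitus",         "nocturnal", "shrub/herb", 7, 8, False,  36, False),
    ("Manduca jasminearum",        "nocturnal", "tree/vine",  7, 8, False,   8, None),
    ("Manduca quinquemaculatus",   "nocturnal", "shrub/herb", 6, 9, True,   24, True),
    ("Manduca sexta",              "nocturnal", "shrub/herb", 7, 8, True,   57, False),
    ("Sphinx canadensis",          "nocturnal", "tree/vine",  6, 8, False,   4, None),
    ("Sphinx chersis",             "nocturnal", "tree/vine",  6, 8, False,  36, True),
    ("Sphinx drupiferarum",        "nocturnal", "tree/vine",  5, 7, False,  50, True),
    ("Sphinx gordius/S. poecila",  "nocturnal", "shrub/herb", 5, 7, False, 402, False),
    ("Sphinx kalmiae",             "nocturnal", "tree/vine",  6, 7, False,  94, True),
    ("Sphinx luscitiosa",          "diurnal",   "tree/vine",  5, 6, False,   2, None),
]


def load_hawkmoth_roster() -> pd.DataFrame:
    """Roster as a DataFrame; ``declined`` is a nullable boolean (NA = too few
    lists to fit a trend model)."""
    df = pd.DataFrame(
        _ROSTER,
        columns=[
            "species", "activity", "host_habit", "flight_start_month",
            "flight_end_month", "pest", "lists", "declined",
        ],
    )
    df["declined"] = df["declined"].astype("boolean")
    return df
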