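"""Published survey data for the red knobby newt (*Tylototriton shanjing*).

A range-wide mitochondrial survey of this Yunnan salamander sampled 146
individuals from 19 populations and found 58 haplotypes (144 polymorphic
sites over 2373 aligned bp of cyt b, control region, tRNA-Phe and 12S
rRNA) falling into four geographic lineages, A-D.  The per-population
haplotype counts printed in that survey's sampling table are reproduced
here: they are the inputs for the diversity statistics and define the
sampling design that the synthetic-data generator emulates.  The sequences
themselves are not bundled.

``PUBLISHED_DIVERSITY`` holds the survey's printed gene-diversity values
(point estimate and standard error) for cross-validation; populations with
a single individual have no defined diversity and are omitted there.
"""

from __future__ import annotations

import pandas as pd

from .seqdata import HaplotypeTable

#: survey constants
SEQUENCE_LENGTH = 2373          # aligned sites (753 + 734 + 69 + 817)
SUBSTITUTION_RATE = 1.086       # % substitutions / site / My (mean clock rate)
GENERATION_TIME = 4.0           # years
TOTAL_SEGREGATING_SITES = 144

#: (lineage, population, {haplotype: count}) in survey order
_SURVEY_ROWS: list[tuple[str, str, dict[str, int]]] = [
    ("A", "JP",  {"H1": 2, "H2": 2, "H3": 5, "H4": 1}),
    ("A", "LC",  {"H5": 4, "H6": 3, "H7": 1, "H8": 3, "H9": 1}),
    ("A", "ZB",  {"H10": 1}),
    ("B", "PL",  {"H26": 9, "H27": 1}),
    ("B", "SHZ", {"H28": 8, "H29": 2}),
    ("C", "GF",  {"H43": 5, "H44": 2, "H45": 1}),
    ("C", "PM",  {"H43": 7, "H45": 5, "H46": 2}),
    ("C", "GY",  {"H55": 1}),
    ("D", "WBL", {"H11": 1, "H12": 3}),
    ("D", "SB",  {"H13": 10, "H14": 2, "H15": 1}),
    ("D", "JD",  {"H13": 7, "H16": 1, "H17": 1, "H18": 1}),
    ("D", "NJ",  {"H19": 1}),
    ("D", "DY",  {"H13": 4, "H20": 1, "H21": 3, "H22": 1, "H23": 3,
                  "H24": 1, "H25": 1}),
    ("D", "YD",  {"H30": 2, "H31": 5, "H32": 1, "H33": 3, "H34": 1, "H35": 1}),
    ("D", "CJ",  {"H36": 1, "H37": 1, "H38": 1, "H39": 1, "H40": 1}),
    ("D", "SJ",  {"H41": 3, "H42": 1}),
    ("D", "LL",  {"H47": 2, "H48": 2, "H49": 1, "H50": 2, "H51": 3,
                  "H52": 1, "H53": 1, "H54": 1}),
    ("D", "MC",  {"H56": 1, "H57": 1}),
    ("D", "HS",  {"H58": 1}),
]

#: printed gene diversity h +/- se per population (n >= 2) and overall
PUBLISHED_DIVERSITY: dict[str, tuple[float, float]] = {
    "JP": (0.7333, 0.1199), "LC": (0.8182, 0.0703), "PL": (0.2000, 0.1541),
    "SHZ": (0.3556, 0.1591), "GF": (0.6071, 0.1640), "PM": (0.6484, 0.0813),
    "WBL": (0.5000, 0.2652), "SB": (0.4103, 0.1539), "JD": (0.5333, 0.1801),
    "DY": (0.8681, 0.0594), "YD": (0.8205, 0.0817), "CJ": (1.0000, 0.1265),
    "SJ": (0.5000, 0.2652), "LL": (0.9231, 0.0500), "MC": (1.0000, 0.5000),
    "Total": (0.9608, 0.0078),
}

#: published expansion-model parameters and dates for the expanding lineage
PUBLISHED_EXPANSION = {
    "D": {"tau": 6.156, "t_mya": 0.119},
    "D2": {"tau": 6.648, "t_mya": 0.129},
}


def survey_haplotype_table() -> HaplotypeTable:
    """The published haplotype x population count table (no sequences)."""
    counts: dict[str, dict[str, int]] = {}
    for _, pop, haps in _SURVEY_ROWS:
        for h, c in haps.items():
            counts.setdefault(h, {})[pop] = counts.get(h, {}).get(pop, 0) + c
    order = [f"H{i}" for i in range(1, 59)]
    t = HaplotypeTable.from_counts(counts, L=SEQUENCE_LENGTH)
    t.counts = t.counts.reindex(order).fillna(0).astype(int)
    t.counts = t.counts[[pop for _, pop, _ in _SURVEY_ROWS]]
    t.haplotypes = {h: t.haplotypes.get(h) for h in order}
    t.meta = survey_population_meta()
    return t


def survey_population_meta() -> pd.DataFrame:
    """Per-population lineage assignment and sample size."""
    rows = [{"population": pop, "lineage": lin, "n": sum(h.values())}
            for lin, pop, h in _SURVEY_ROWS]
    return pd.DataFrame(rows).set_index("population")


def survey_sample_sizes() -> dict[str, int]:
    return {pop: sum(h.values()) for _, pop, h in _SURVEY_ROWS}
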