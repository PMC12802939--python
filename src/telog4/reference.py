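"""Published reference values for the rNMP-substituted telomeric constructs.

These are the experimental summary tables for the (TTAGGG)4 construct series:
CD-derived conformations and melting temperatures, smFRET trace-type
percentages and histogram peak parameters, and RNase H2 cleavage time courses
in potassium and sodium.  They serve as inputs (worked-example operands,
generator targets) — the package never claims to regenerate them from raw
instrument data, which were not deposited.

Conventions: Tm in °C; trace-type and cleavage values in percent; ``None`` in
a cleavage series means not detected (below the assay floor); a cleavage SD of
``None`` marks a single-replicate entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

__all__ = [
    "MELT_TABLE",
    "FRET_TABLE",
    "CLEAVAGE_K",
    "CLEAVAGE_NA",
    "CLEAVAGE_TIMEPOINTS_MIN",
    "melt_table",
    "fret_table",
    "cleavage_table",
    "construct_summaries",
    "substitution_sites",
]

#: time grid of the cleavage assays, minutes
CLEAVAGE_TIMEPOINTS_MIN = (1.0, 5.0, 15.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class MeltRow:
    sample: str
    sequence: str
    conformation: tuple[str, ...]
    wavelength_nm: Optional[float]  # monitored wavelength when a dual-Tm row
    tm: float
    delta_tm: float


# Conformation labels: parallel, antiparallel_chair, antiparallel_basket,
# hybrid_3plus1.  Dual-wavelength constructs have two rows.
MELT_TABLE: tuple[MeltRow, ...] = (
    MeltRow("TEL", "TTAGGGTTAGGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 58.86, 0.0),
    MeltRow("TELR3", "TTrAGGGTTAGGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 61.17, 2.31),
    MeltRow("TELR4", "TTArGGGTTAGGGTTAGGGTTAGGG",
            ("antiparallel_basket", "hybrid_3plus1"), 290.0, 55.69, -3.16),
    MeltRow("TELR4", "TTArGGGTTAGGGTTAGGGTTAGGG",
            ("antiparallel_basket", "hybrid_3plus1"), 275.0, 59.33, 0.48),
    MeltRow("TELR5", "TTAGrGGTTAGGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 57.35, -1.51),
    MeltRow("TELR6", "TTAGGrGTTAGGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 59.86, 1.01),
    MeltRow("TELR9", "TTAGGGTTrAGGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 60.77, 1.92),
    MeltRow("TELR10", "TTAGGGTTArGGGTTAGGGTTAGGG", ("antiparallel_basket",), None, 46.99, -11.87),
    MeltRow("TELR11", "TTAGGGTTAGrGGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 57.16, -1.70),
    MeltRow("TELR12", "TTAGGGTTAGGrGTTAGGGTTAGGG", ("hybrid_3plus1",), None, 61.42, 2.56),
    MeltRow("TELR15", "TTAGGGTTAGGGTTrAGGGTTAGGG", ("hybrid_3plus1",), None, 60.34, 1.48),
    MeltRow("TELR16", "TTAGGGTTAGGGTTArGGGTTAGGG",
            ("parallel", "antiparallel_chair"), 270.0, 58.33, -0.53),
    MeltRow("TELR16", "TTAGGGTTAGGGTTArGGGTTAGGG",
            ("parallel", "antiparallel_chair"), 295.0, 57.95, -0.91),
    MeltRow("TELR17", "TTAGGGTTAGGGTTAGrGGTTAGGG", ("hybrid_3plus1",), None, 57.49, -1.37),
    MeltRow("TELR18", "TTAGGGTTAGGGTTAGGrGTTAGGG", ("hybrid_3plus1",), None, 61.38, 2.52),
    MeltRow("TELR21", "TTAGGGTTAGGGTTAGGGTTrAGGG", ("hybrid_3plus1",), None, 61.26, 2.40),
    MeltRow("TELR22", "TTAGGGTTAGGGTTAGGGTTArGGG", ("hybrid_3plus1", "parallel"), None, 58.37, -0.49),
    MeltRow("TELR23", "TTAGGGTTAGGGTTAGGGTTAGrGG", ("hybrid_3plus1",), None, 59.12, 0.27),
    MeltRow("TELR24", "TTAGGGTTAGGGTTAGGGTTAGGrG", ("hybrid_3plus1",), None, 59.40, 0.54),
)


@dataclass(frozen=True)
class FretRow:
    construct: str
    folded_pct: float
    folded_sd: float
    dynamic_pct: float
    dynamic_sd: float
    unfolded_pct: float
    unfolded_sd: float
    peak_center: float
    peak_center_sd: float
    half_width: float
    half_width_sd: float


FRET_TABLE: tuple[FretRow, ...] = (
    FretRow("TELR9", 73.1, 9.43, 19.6, 2.88, 7.28, 5.28, 0.68, 0.01, 0.14, 0.01),
    FretRow("TELR10", 58.8, 4.87, 34.6, 4.87, 6.19, 3.11, 0.68, 0.02, 0.15, 0.01),
    FretRow("TELR11", 56.0, 3.87, 38.9, 2.96, 5.05, 2.68, 0.67, 0.01, 0.14, 0.01),
    FretRow("TELR12", 65.2, 3.05, 29.0, 4.57, 5.74, 3.75, 0.67, 0.01, 0.15, 0.01),
    FretRow("TELR21", 71.8, 3.45, 25.8, 2.7, 2.48, 1.41, 0.66, 0.01, 0.13, 0.01),
    FretRow("TELR22", 66.8, 2.79, 29.2, 2.79, 3.99, 1.84, 0.664, 0.012, 0.14, 0.01),
    FretRow("TELR23", 54.9, 2.48, 39.6, 1.95, 5.51, 1.27, 0.65, 0.01, 0.14, 0.01),
    FretRow("TELR24", 48.2, 4.87, 46.1, 2.36, 5.72, 4.16, 0.68, 0.01, 0.16, 0.01),
    FretRow("TEL", 74.3, 2.50, 17.8, 5.13, 7.89, 3.29, 0.67, 0.01, 0.14, 0.01),
    FretRow("TEL-TTAG", 67.9, 1.74, 29.6, 1.24, 2.25, 0.69, 0.65, 0.01, 0.12, 0.02),
)


# Cleavage tables: construct -> ((mean, sd) or None per timepoint).
# None = not detected; sd None = bare single-replicate entry; a (None, None)
# inside an otherwise-detected sodium series (TELR18) is a missing cell.
_ND = None

CLEAVAGE_K: dict[str, tuple] = {
    "dsTELR10": ((96.0, 0.0), (98.0, 0.0), (99.0, 0.0), (99.0, 0.0), (99.0, 0.0), (99.0, 0.0)),
    "TELR3": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR4": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR5": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR6": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR9": ((6.5, 1.1), (7.0, 1.8), (6.8, 1.1), (6.7, 1.0), (7.6, 2.7), (7.4, 2.1)),
    "TELR10": ((2.4, 0.7), (2.9, 0.5), (3.8, 0.3), (4.5, 0.6), (6.3, 0.3), (9.8, 0.3)),
    "TELR11": ((1.9, 1.2), (1.9, 1.1), (1.4, 0.7), (2.1, 1.2), (2.1, 1.1), (2.1, 1.2)),
    "TELR12": ((0.6, 1.0), (0.8, 1.1), (0.7, 1.0), (0.6, 1.0), (1.0, 1.4), (0.7, 1.1)),
    "TELR15": ((6.0, 0.1), (6.1, 0.2), (6.6, 0.3), (6.9, 0.3), (8.0, 0.4), (9.4, 0.5)),
    "TELR16": ((2.3, 1.2), (2.5, 1.2), (3.3, 1.6), (4.0, 1.9), (5.4, 2.4), (7.2, 2.8)),
    "TELR17": ((1.8, 1.1), (1.7, 1.0), (1.9, 1.0), (2.1, 1.4), (2.3, 1.4), (2.7, 1.4)),
    "TELR18": ((0.2, 0.3), _ND, _ND, _ND, (0.2, 0.3), (0.2, 0.4)),
    "TELR21": ((4.6, 2.2), (4.7, 2.0), (4.7, 2.3), (4.9, 2.2), (5.2, 2.2), (5.5, 2.2)),
    "TELR22": ((1.8, 1.3), (2.9, 1.8), (5.2, 3.0), (8.6, 2.9), (13.4, 4.4), (20.7, 4.0)),
    "TELR23": ((1.4, 2.3), (1.4, 1.9), (2.1, 3.0), (1.1, 1.5), (1.1, 1.9), (1.2, 2.0)),
    "TELR24": (_ND, _ND, _ND, _ND, _ND, _ND),
}

CLEAVAGE_NA: dict[str, tuple] = {
    "dsTELR10": ((97.0, 0.0), (98.0, 0.0), (98.0, 0.0), (99.0, 0.0), (99.0, 0.0), (99.0, 0.0)),
    "TELR3": ((5.3, 8.2), (9.4, 4.6), (21.4, 2.6), (29.2, 2.3), (42.9, 1.0), (58.5, 0.6)),
    "TELR4": ((7.2, 6.4), (10.4, 9.0), (18.1, 4.0), (26.2, 2.7), (39.5, 1.4), (54.1, 5.2)),
    "TELR5": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR6": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR9": ((13.5, 5.7), (15.5, 6.0), (20.6, 6.4), (25.7, 5.5), (33.5, 4.5), (42.1, 4.4)),
    "TELR10": ((7.4, 3.9), (20.9, 3.0), (43.6, 1.4), (63.4, 1.0), (81.4, 3.3), (92.6, 2.9)),
    "TELR11": ((3.8, 5.2), (3.5, 4.4), (3.8, 4.3), (12.9, 12.8), (10.6, 9.4), (10.3, 7.9)),
    "TELR12": ((7.5, 6.6), (0.3, None), (0.6, None), (0.6, None), (9.0, 7.2), (6.6, 4.6)),
    "TELR15": ((14.8, 6.5), (19.7, 5.1), (30.9, 3.4), (44.7, 1.4), (61.2, 0.6), (75.7, 1.8)),
    "TELR16": ((4.4, 3.0), (8.1, 2.9), (14.6, 3.2), (19.4, 3.7), (26.6, 3.8), (38.4, 5.8)),
    "TELR17": ((3.3, 3.7), (3.8, 4.1), (3.8, 3.6), (4.7, 3.6), (6.5, 3.3), (9.0, 3.2)),
    "TELR18": ((11.1, 9.6), (None, None), (None, None), (None, None), (13.3, 12.4), (9.3, 8.1)),
    "TELR21": ((13.4, 10.4), (16.7, 10.4), (12.6, 5.6), (15.7, 5.1), (20.7, 5.6), (22.9, 12.9)),
    "TELR22": ((12.4, 3.9), (51.4, 1.5), (87.9, 4.1), (99.3, 0.6), (99.9, 0.1), (99.3, 1.1)),
    "TELR23": (_ND, _ND, _ND, _ND, _ND, _ND),
    "TELR24": (_ND, _ND, _ND, _ND, _ND, _ND),
}


def melt_table() -> pd.DataFrame:
    """Melting table as a DataFrame (one row per reported Tm)."""
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "sequence": r.sequence,
                "conformation": "+".join(r.conformation),
                "wavelength_nm": r.wavelength_nm,
                "tm_C": r.tm,
                "delta_tm_C": r.delta_tm,
            }
            for r in MELT_TABLE
        ]
    )


def fret_table() -> pd.DataFrame:
    """smFRET trace-type and histogram-peak table as a DataFrame."""
    return pd.DataFrame([vars(r) for r in FRET_TABLE])


def cleavage_table(cation: str) -> pd.DataFrame:
    """Long-format cleavage table for cation 'K' or 'Na'.

    Columns: construct, time_min, mean_pct, sd_pct, detected.
    """
    source = {"K": CLEAVAGE_K, "Na": CLEAVAGE_NA}[cation]
    rows = []
    for construct, series in source.items():
        for t, cell in zip(CLEAVAGE_TIMEPOINTS_MIN, series):
            detected = cell is not None and cell[0] is not None
            rows.append(
                {
                    "construct": construct,
                    "time_min": t,
                    "mean_pct": cell[0] if detected else float("nan"),
                    "sd_pct": (cell[1] if detected and cell[1] is not None else float("nan")),
                    "detected": detected,
                }
            )
    return pd.DataFrame(rows)


def construct_summaries(cation: str) -> dict[str, pd.DataFrame]:
    """Published per-construct cleavage summaries keyed by construct name,
    in the schema of cleavage.summarize_timecourse (excludes the duplex
    activity control, which has no quadruplex position class)."""
    long = cleavage_table(cation)
    out = {}
    for construct, grp in long.groupby("construct", sort=False):
        if construct == "dsTELR10":
            continue
        out[construct] = grp[["time_min", "mean_pct", "sd_pct", "detected"]].reset_index(drop=True)
    return out


def substitution_sites() -> dict:
    """Substitution sites of the 16 single-rNMP constructs, derived from
    their sequence strings by the sequence model."""
    from .sequences import classify_position, parse_sequence

    sites = {}
    for row in MELT_TABLE:
        if row.sample == "TEL" or row.sample in sites:
            continue
        sites[row.sample] = classify_position(parse_sequence(row.sequence, name=row.sample))
    return sites
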