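"""Packaged reference-cohort values.

The published per-profile descriptive statistics and glycemic-variability
outcomes for a cohort of 19 open-source AID users ship with the package as
two small CSVs.  They anchor the metric implementations (GMI and J-index are
closed-form functions of the printed mean and SD, so the printed GV columns
pin those formulas exactly) and parameterise cohort-scale simulations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .gv import GVReport
from .profiles import ProfileStats, count_to_days


def _read(name: str) -> pd.DataFrame:
    with resources.files("glucovar.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def cohort_profiles() -> pd.DataFrame:
    """Per-profile descriptive statistics (count, mean, SD, quartiles, CV,
    skewness, skewness class) for the 19 reference profiles."""
    return _read("cohort_profiles.csv")


def cohort_gv() -> pd.DataFrame:
    """Per-profile GV outcomes (SD-ROC, TBR/TIR/TAR, LBGI/HBGI, GMI,
    J-index) for the 19 reference profiles."""
    return _read("cohort_gv.csv")


def cohort_fixture() -> list[tuple[ProfileStats, GVReport]]:
    """The 19 reference rows as structured (ProfileStats, GVReport) pairs.

    Every profile in the reference cohort tested stationary and
    non-seasonal, so those labels are fixed here.
    """
    profiles = cohort_profiles()
    gv = cohort_gv().set_index("id")
    out: list[tuple[ProfileStats, GVReport]] = []
    for row in profiles.to_dict("records"):
        st = ProfileStats(
            count=int(row["count"]),
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            q1=float(row["q1"]),
            q2=float(row["q2"]),
            q3=float(row["q3"]),
            cv=float(row["cv"]),
            skewness=float(row["skewness"]),
            distribution_label=str(row["distribution"]),
            days=count_to_days(int(row["count"])),
            stationarity_label="stationary",
            seasonal=False,
            id=str(row["id"]),
        )
        g = gv.loc[row["id"]]
        rep = GVReport(
            mean=float(row["mean"]),
            sd=float(row["sd"]),
            cv=float(row["cv"]),
            tbr=float(g.tbr),
            tir=float(g.tir),
            tar=float(g.tar),
            sd_roc=float(g.sd_roc),
            lbgi=float(g.lbgi),
            hbgi=float(g.hbgi),
            gmi=float(g.gmi),
            j_index=float(g.j_index),
            id=str(row["id"]),
        )
        out.append((st, rep))
    return out
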