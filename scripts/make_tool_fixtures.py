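"""One-off generator for the packaged synthetic stand-in data files."""
import os

import numpy as np
import yaml

OUT = os.path.join(os.path.dirname(__file__), "..", "src", "cvdscreen", "data")
os.makedirs(OUT, exist_ok=True)

HEADER = (
    "# Synthetic stand-in tool parameters: structurally faithful to the published\n"
    "# tool family but NOT the published coefficients.\n"
)


def dump(name, doc):
    with open(os.path.join(OUT, name), "w") as fh:
        fh.write(HEADER)
        yaml.safe_dump(doc, fh, sort_keys=False)


def eq_doc(tool_id, mode, outcomes):
    return {"tool_id": tool_id, "mode": mode, "kind": "equation", "outcomes": outcomes}


def block(s0, preds):
    return {"s0": s0, "predictors": [dict(p) for p in preds]}


def pred(name, beta, mean, transform="identity", lo=None, hi=None):
    d = {"name": name, "beta": beta, "mean": mean, "transform": transform}
    if lo is not None:
        d["lo"] = lo
    if hi is not None:
        d["hi"] = hi
    return d


# WHO-2019-style: separate CHD and stroke equations, sex-specific.
def who2019(mode):
    lipid = (
        pred("total_cholesterol", 0.0042, 200.0, lo=80.0, hi=450.0)
        if mode == "lab"
        else pred("bmi", 0.030, 24.5, lo=14.0, hi=50.0)
    )
    chd = {
        "male": block(0.972, [
            pred("age", 0.072, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.016, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.58, 0.20),
            pred("diabetes", 0.62, 0.12),
            lipid,
        ]),
        "female": block(0.984, [
            pred("age", 0.078, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.015, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.70, 0.02),
            pred("diabetes", 0.70, 0.12),
            lipid,
        ]),
    }
    stroke = {
        "male": block(0.988, [
            pred("age", 0.083, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.021, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.42, 0.20),
            pred("diabetes", 0.48, 0.12),
        ]),
        "female": block(0.991, [
            pred("age", 0.086, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.022, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.50, 0.02),
            pred("diabetes", 0.55, 0.12),
        ]),
    }
    return eq_doc("who2019", mode, {"chd": chd, "stroke": stroke})


dump("eq_who2019_lab.yaml", who2019("lab"))
dump("eq_who2019_office.yaml", who2019("office"))


# Framingham-style: combined CVD, log-transformed age.
def framingham(mode):
    lipid = (
        pred("total_cholesterol", 0.95, 200.0, transform="log", lo=80.0, hi=450.0)
        if mode == "lab"
        else pred("bmi", 0.55, 24.5, transform="log", lo=14.0, hi=50.0)
    )
    cvd = {
        "male": block(0.900, [
            pred("age", 3.10, 52.0, transform="log", lo=35.0, hi=95.0),
            pred("sbp", 1.90, 128.0, transform="log", lo=85.0, hi=240.0),
            pred("smoker", 0.65, 0.20),
            pred("diabetes", 0.57, 0.12),
            lipid,
        ]),
        "female": block(0.945, [
            pred("age", 3.35, 52.0, transform="log", lo=35.0, hi=95.0),
            pred("sbp", 2.10, 128.0, transform="log", lo=85.0, hi=240.0),
            pred("smoker", 0.75, 0.02),
            pred("diabetes", 0.68, 0.12),
            lipid,
        ]),
    }
    return eq_doc("framingham", mode, {"combined_cvd": cvd})


dump("eq_framingham_lab.yaml", framingham("lab"))
dump("eq_framingham_office.yaml", framingham("office"))


# Globorisk-style: combined CVD, identity transforms, steeper age slope.
def globorisk(mode):
    lipid = (
        pred("total_cholesterol", 0.0051, 200.0, lo=80.0, hi=450.0)
        if mode == "lab"
        else pred("bmi", 0.042, 24.5, lo=14.0, hi=50.0)
    )
    cvd = {
        "male": block(0.930, [
            pred("age", 0.081, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.017, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.52, 0.20),
            pred("diabetes", 0.60, 0.12),
            lipid,
        ]),
        "female": block(0.958, [
            pred("age", 0.088, 52.0, lo=35.0, hi=95.0),
            pred("sbp", 0.018, 128.0, lo=85.0, hi=240.0),
            pred("smoker", 0.62, 0.02),
            pred("diabetes", 0.72, 0.12),
            lipid,
        ]),
    }
    return eq_doc("globorisk", mode, {"combined_cvd": cvd})


dump("eq_globorisk_lab.yaml", globorisk("lab"))
dump("eq_globorisk_office.yaml", globorisk("office"))


# WHO-ISH-style charts: banded categories generated from a smooth
# underlying gradient, then discretised.
AGE_EDGES = [35, 45, 55, 65, 75, 85]
SBP_EDGES = [100, 120, 140, 160, 180, 220]
CHOL_EDGES = [120, 160, 200, 240, 280, 340]
CATS = ["lt10", "r10to20", "r20to30", "r30to40", "ge40"]
MIDS = {"lt10": 0.05, "r10to20": 0.15, "r20to30": 0.25, "r30to40": 0.35, "ge40": 0.45}
THRESH = [0.10, 0.20, 0.30, 0.40]


def centers(edges):
    e = np.asarray(edges, dtype=float)
    return (e[:-1] + e[1:]) / 2


def categorize(risk):
    return int(np.searchsorted(THRESH, risk, side="right"))


def chart(mode):
    axes = {"age": AGE_EDGES, "sbp": SBP_EDGES}
    if mode == "lab":
        axes["total_cholesterol"] = CHOL_EDGES
    cells = {}
    for sex, sex_b in (("female", 0.0), ("male", 0.35)):
        for smoker in (0, 1):
            for diab in (0, 1):
                key = f"{sex}|{smoker}|{diab}"
                grid = []
                for a in centers(AGE_EDGES):
                    row = []
                    for s in centers(SBP_EDGES):
                        lp = (
                            sex_b
                            + 0.074 * (a - 52.0)
                            + 0.0165 * (s - 128.0)
                            + 0.50 * smoker
                            + 0.58 * diab
                        )
                        if mode == "lab":
                            col = []
                            for c in centers(CHOL_EDGES):
                                lpc = lp + 0.0042 * (c - 200.0)
                                col.append(categorize(1.0 - 0.965 ** np.exp(lpc)))
                            row.append(col)
                        else:
                            row.append(categorize(1.0 - 0.965 ** np.exp(lp)))
                    grid.append(row)
                cells[key] = grid
    return {
        "tool_id": "who_ish", "mode": mode, "kind": "chart",
        "axes": axes, "categorical": ["sex", "smoker", "diabetes"],
        "categories": CATS, "midpoints": MIDS, "cells": cells,
    }


dump("chart_who_ish_office.yaml", chart("office"))
dump("chart_who_ish_lab.yaml", chart("lab"))


# Synthetic Gompertz-Makeham life table by sex, single year of age.
with open(os.path.join(OUT, "life_table_synthetic.csv"), "w") as fh:
    fh.write("sex,age,q\n")
    for sex, factor in (("female", 1.0), ("male", 1.35)):
        for age in range(18, 101):
            q = min(1.0, factor * (2.2e-5 * np.exp(0.093 * age) + 8e-4))
            fh.write(f"{sex},{age},{q:.6f}\n")

# Synthetic case-fatality fractions by condition, sex, 5-year band.
with open(os.path.join(OUT, "case_fatality_synthetic.csv"), "w") as fh:
    fh.write("condition,sex,age_lo,fraction\n")
    for cond, base, slope in (("chd", 0.15, 0.006), ("stroke", 0.20, 0.005)):
        for sex, factor in (("female", 0.92), ("male", 1.0)):
            for lo in range(30, 100, 5):
                f = min(0.75, factor * (base + slope * (lo - 30)))
                fh.write(f"{cond},{sex},{lo},{f:.4f}\n")

print("written to", os.path.abspath(OUT))
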