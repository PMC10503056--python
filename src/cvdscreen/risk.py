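"""10-year cardiovascular risk scoring and probability utilities.

Two families of risk tools are supported, mirroring how published CVD
calculators are distributed:

* **Equation tools** — sex-specific proportional-hazards survival
  equations ``risk = 1 - S0 ** exp(sum(beta * g(x)) - sum(beta * g(xbar)))``
  with a 10-year baseline survival ``S0``, the functional form shared by
  the Framingham, Globorisk and WHO-2019 families.
* **Chart tools** — banded lookup charts (age x blood pressure
  [x cholesterol], split by sex / smoking / diabetes) that return a risk
  *category*, mapped to a point probability through category midpoints;
  this is how the WHO-ISH paper charts work.

Tool parameters are shipped as versioned YAML data files and loaded
through :func:`load_tool`.  The packaged files are synthetic stand-ins
with the right structure and plausible gradients; they do not claim
fidelity to any one publication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRANSFORMS = {"identity": lambda x: x, "log": np.log}


class RiskModelError(ValueError):
    """Malformed tool definition or invalid input to a risk model."""


# ---------------------------------------------------------------------------
# equation tools
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Predictor:
    name: str
    beta: float
    mean: float
    transform: str = "identity"
    lo: float | None = None
    hi: float | None = None

    def value(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.lo is not None or self.hi is not None:
            clipped = np.clip(x, self.lo, self.hi)
            if np.any(clipped != x):
                logger.warning(
                    "predictor %s: %d value(s) outside validity range [%s, %s]; clamped",
                    self.name, int(np.sum(clipped != x)), self.lo, self.hi,
                )
            x = clipped
        return TRANSFORMS[self.transform](x)


@dataclass(frozen=True)
class PHSexBlock:
    s0: float
    predictors: tuple[Predictor, ...]

    def __post_init__(self):
        if not 0.0 < self.s0 < 1.0:
            raise RiskModelError(f"baseline survival S0 must be in (0,1), got {self.s0}")


@dataclass(frozen=True)
class PHModelCoefficients:
    """Sex-specific proportional-hazards risk equation for one outcome."""

    tool_id: str
    mode: str
    outcome: str
    blocks: dict[str, PHSexBlock]

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Vectorised 10-year risk for every row of ``data``."""
        risk = np.empty(len(data), dtype=float)
        sex = data["sex"].to_numpy()
        for s, block in self.blocks.items():
            mask = sex == s
            if not mask.any():
                continue
            lp = np.zeros(int(mask.sum()))
            for p in block.predictors:
                if p.name not in data.columns:
                    raise RiskModelError(
                        f"{self.tool_id}/{self.outcome}: missing predictor {p.name!r}"
                    )
                g = TRANSFORMS[p.transform]
                lp += p.beta * (p.value(data.loc[mask, p.name].to_numpy()) - g(p.mean))
            risk[mask] = 1.0 - block.s0 ** np.exp(lp)
        unknown = ~np.isin(sex, list(self.blocks))
        if unknown.any():
            raise RiskModelError(f"no coefficient block for sex values {set(sex[unknown])}")
        return np.clip(risk, 0.0, 1.0)


def predict_10yr_risk_equation(individual, model: PHModelCoefficients) -> float:
    """10-year event probability for one individual under ``model``."""
    df = pd.DataFrame([dict(individual)])
    return float(model.predict(df)[0])


# ---------------------------------------------------------------------------
# chart tools
# ---------------------------------------------------------------------------


def _bin_index(x: np.ndarray, edges: np.ndarray, label: str) -> np.ndarray:
    """Half-open bins [edges[i], edges[i+1]); out-of-range values clamp."""
    idx = np.searchsorted(edges, x, side="right") - 1
    n_bins = len(edges) - 1
    out = (idx < 0) | (idx >= n_bins)
    if out.any():
        logger.warning("chart axis %s: %d value(s) outside range; clamped", label, int(out.sum()))
    return np.clip(idx, 0, n_bins - 1)


@dataclass(frozen=True)
class RiskChart:
    """Banded risk chart: category lookup plus category midpoints."""

    tool_id: str
    mode: str
    axes: dict[str, np.ndarray]          # ordered continuous axes -> bin edges
    categorical: tuple[str, ...]         # sex, smoker, diabetes
    categories: tuple[str, ...]          # ordered risk categories
    midpoints: dict[str, float]
    cells: dict[str, np.ndarray]         # "female|0|1" -> int array over axis bins

    def __post_init__(self):
        mids = [self.midpoints[c] for c in self.categories]
        if not all(b > a for a, b in zip(mids, mids[1:])):
            raise RiskModelError("category midpoints must be strictly increasing")

    def _key(self, row: dict) -> str:
        parts = []
        for c in self.categorical:
            v = row[c]
            parts.append(str(v) if c == "sex" else str(int(bool(v))))
        return "|".join(parts)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        idx = {
            name: _bin_index(data[name].to_numpy(dtype=float), edges, name)
            for name, edges in self.axes.items()
        }
        risk = np.empty(len(data), dtype=float)
        keys = [
            "|".join(
                str(data[c].iat[i]) if c == "sex" else str(int(bool(data[c].iat[i])))
                for c in self.categorical
            )
            for i in range(len(data))
        ]
        mid = np.array([self.midpoints[c] for c in self.categories])
        axis_names = list(self.axes)
        for i, key in enumerate(keys):
            try:
                cell = self.cells[key]
            except KeyError:
                raise RiskModelError(f"chart {self.tool_id}: no cell block for {key!r}")
            cat = cell[tuple(idx[a][i] for a in axis_names)]
            risk[i] = mid[cat]
        return risk


def predict_10yr_risk_chart(individual, chart: RiskChart) -> float:
    df = pd.DataFrame([dict(individual)])
    return float(chart.predict(df)[0])


# ---------------------------------------------------------------------------
# probability utilities
# ---------------------------------------------------------------------------


def annualize_probability(p10, horizon_years: int = 10):
    """Convert a cumulative ``horizon_years`` probability to an annual one.

    Uses the constant-hazard identity ``p1 = 1 - (1 - p10)**(1/h)``, so
    recompounding over the horizon recovers ``p10`` exactly.
    """
    p = np.asarray(p10, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise RiskModelError("p10 must lie in [0, 1]")
    out = 1.0 - (1.0 - p) ** (1.0 / horizon_years)
    return float(out) if np.isscalar(p10) else out


def combine_risks(p_a, p_b):
    """Combined probability of at least one of two independent events."""
    return 1.0 - (1.0 - np.asarray(p_a)) * (1.0 - np.asarray(p_b))


# ---------------------------------------------------------------------------
# case fatality
# ---------------------------------------------------------------------------


class CaseFatalityTable:
    """Fraction of incident events fatal in the event year.

    Rows keyed by (condition, sex, 5-year age band).  Bands are half-open
    ``[age_lo, age_lo + 5)``; a lookup outside the covered range raises
    (no extrapolation).
    """

    BAND = 5

    def __init__(self, table: pd.DataFrame):
        required = {"condition", "sex", "age_lo", "fraction"}
        if not required.issubset(table.columns):
            raise RiskModelError(f"case-fatality table needs columns {sorted(required)}")
        if ((table["fraction"] < 0) | (table["fraction"] > 1)).any():
            raise RiskModelError("case-fatality fractions must lie in [0, 1]")
        self._frac: dict[tuple[str, str], np.ndarray] = {}
        self._lo: dict[tuple[str, str], int] = {}
        for (cond, sex), grp in table.groupby(["condition", "sex"]):
            grp = grp.sort_values("age_lo")
            lo = grp["age_lo"].to_numpy(dtype=int)
            if not np.all(np.diff(lo) == self.BAND):
                raise RiskModelError(f"age bands for ({cond},{sex}) must be contiguous 5-year")
            self._frac[(cond, sex)] = grp["fraction"].to_numpy(dtype=float)
            self._lo[(cond, sex)] = int(lo[0])

    def fraction(self, condition: str, sex, age) -> np.ndarray:
        """Fatal fraction for arrays of ``sex`` / ``age`` (broadcast)."""
        sex = np.atleast_1d(np.asarray(sex))
        age = np.atleast_1d(np.asarray(age, dtype=float))
        sex, age = np.broadcast_arrays(sex, age)
        out = np.empty(age.shape, dtype=float)
        for s in np.unique(sex):
            key = (condition, str(s))
            if key not in self._frac:
                raise RiskModelError(f"case-fatality table does not cover {key}")
            frac, lo = self._frac[key], self._lo[key]
            idx = np.floor((age[sex == s] - lo) / self.BAND).astype(int)
            if np.any(idx < 0) or np.any(idx >= len(frac)):
                bad = age[sex == s][(idx < 0) | (idx >= len(frac))]
                raise RiskModelError(
                    f"case-fatality table for {key} does not cover ages {sorted(set(bad))}"
                )
            out[sex == s] = frac[idx]
        return out

    def scaled(self, multiplier: float) -> "CaseFatalityTable":
        """New table with every fraction multiplied (clipped to [0, 1])."""
        rows = []
        for (cond, sex), frac in self._frac.items():
            lo = self._lo[(cond, sex)]
            for i, f in enumerate(frac):
                rows.append(
                    {"condition": cond, "sex": sex, "age_lo": lo + self.BAND * i,
                     "fraction": min(1.0, f * multiplier)}
                )
        return CaseFatalityTable(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "CaseFatalityTable":
        return cls(pd.read_csv(path))


def split_fatal_nonfatal(p_event, condition: str, age, sex, table: CaseFatalityTable):
    """Split an annual event probability into (fatal, non-fatal) parts.

    The two parts sum to ``p_event`` exactly.
    """
    p = np.asarray(p_event, dtype=float)
    frac = table.fraction(condition, sex, age)
    if np.isscalar(p_event) and frac.size == 1:
        p_fatal = float(p) * float(frac[0])
        return p_fatal, float(p) - p_fatal
    p_fatal = p * frac
    return p_fatal, p - p_fatal


# ---------------------------------------------------------------------------
# tool registry
# ---------------------------------------------------------------------------


class EquationTool:
    """One or more outcome equations under a single tool id + mode."""

    kind = "equation"

    def __init__(self, tool_id: str, mode: str, models: dict[str, PHModelCoefficients]):
        self.tool_id, self.mode, self.models = tool_id, mode, models

    def risk(self, data: pd.DataFrame, outcome: str) -> np.ndarray:
        return self.models[outcome].predict(data)

    def combined_risk(self, data: pd.DataFrame) -> np.ndarray:
        """Total CVD risk used for high-risk classification."""
        if "combined_cvd" in self.models:
            return self.models["combined_cvd"].predict(data)
        return np.asarray(
            combine_risks(self.models["chd"].predict(data), self.models["stroke"].predict(data))
        )


class ChartTool:
    kind = "chart"

    def __init__(self, chart: RiskChart):
        self.tool_id, self.mode, self.chart = chart.tool_id, chart.mode, chart

    def combined_risk(self, data: pd.DataFrame) -> np.ndarray:
        return self.chart.predict(data)


def _parse_equation(doc: dict) -> EquationTool:
    models = {}
    for outcome, blocks in doc["outcomes"].items():
        parsed = {}
        for sex, blk in blocks.items():
            preds = tuple(
                Predictor(
                    name=p["name"], beta=float(p["beta"]), mean=float(p["mean"]),
                    transform=p.get("transform", "identity"),
                    lo=p.get("lo"), hi=p.get("hi"),
                )
                for p in blk["predictors"]
            )
            parsed[sex] = PHSexBlock(s0=float(blk["s0"]), predictors=preds)
        models[outcome] = PHModelCoefficients(doc["tool_id"], doc["mode"], outcome, parsed)
    return EquationTool(doc["tool_id"], doc["mode"], models)


def _parse_chart(doc: dict) -> ChartTool:
    chart = RiskChart(
        tool_id=doc["tool_id"],
        mode=doc["mode"],
        axes={k: np.asarray(v, dtype=float) for k, v in doc["axes"].items()},
        categorical=tuple(doc["categorical"]),
        categories=tuple(doc["categories"]),
        midpoints={k: float(v) for k, v in doc["midpoints"].items()},
        cells={k: np.asarray(v, dtype=int) for k, v in doc["cells"].items()},
    )
    return ChartTool(chart)


def parse_tool(doc: dict):
    kind = doc.get("kind", "equation")
    return _parse_chart(doc) if kind == "chart" else _parse_equation(doc)


def load_tool_file(path):
    with open(path) as fh:
        return parse_tool(yaml.safe_load(fh))


#: tool_id -> {mode: data file}
_PACKAGED_TOOLS = {
    "who_ish": {"office": "chart_who_ish_office.yaml", "lab": "chart_who_ish_lab.yaml"},
    "who2019": {"office": "eq_who2019_office.yaml", "lab": "eq_who2019_lab.yaml"},
    "framingham": {"office": "eq_framingham_office.yaml", "lab": "eq_framingham_lab.yaml"},
    "globorisk": {"office": "eq_globorisk_office.yaml", "lab": "eq_globorisk_lab.yaml"},
}


def available_tools() -> list[tuple[str, str]]:
    return [(t, m) for t, modes in _PACKAGED_TOOLS.items() for m in modes]


def load_tool(tool_id: str, mode: str):
    """Load a packaged (synthetic stand-in) risk tool by id and mode."""
    try:
        fname = _PACKAGED_TOOLS[tool_id][mode]
    except KeyError:
        raise RiskModelError(f"unknown tool {tool_id!r} mode {mode!r}") from None
    ref = resources.files("cvdscreen.data").joinpath(fname)
    return parse_tool(yaml.safe_load(ref.read_text()))
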