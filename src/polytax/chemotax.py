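"""Chemotaxonomic numerics: calibration curves, quinone molar ratios and
profile correlations, FAME similarity, and binary phenotype similarity."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

ND = "ND"

__all__ = [
    "ChemProfile",
    "CalibrationCurve",
    "fit_calibration",
    "invert_calibration",
    "molar_ratio",
    "profile_correlation",
    "fame_similarity",
    "api_similarity",
    "read_profiles_tsv",
]


@dataclass
class ChemProfile:
    """Per-strain measured components keyed by (condition, component).

    ``values`` holds means; ``sds`` optional standard deviations (display
    only); components absent from ``values`` but listed in ``nd`` were not
    detected.
    """

    strain: str
    values: dict[tuple[str, str], float] = field(default_factory=dict)
    sds: dict[tuple[str, str], float] = field(default_factory=dict)
    nd: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative value for {key} in {self.strain!r}")

    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.values} | {c for c, _ in self.nd})


@dataclass
class CalibrationCurve:
    slope: float
    intercept: float
    range_low: float
    range_high: float
    r_squared: float
    lod: float | None = None
    loq: float | None = None

    def __post_init__(self) -> None:
        if not self.range_high > self.range_low > 0:
            raise ValueError("linear range must satisfy high > low > 0")
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 must be in [0, 1]")


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def fit_calibration(
    points: list[tuple[float, float]], noise_sd: float | None = None
) -> CalibrationCurve:
    """OLS fit Y = a*x + b over (concentration, response) points.

    With a supplied baseline noise estimate, LOD and LOQ are the
    concentrations whose net signal equals 3x and 10x the noise
    (signal-to-noise rule), so LOQ/LOD = 10/3 exactly.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 calibration points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentrations")
    res = stats.linregress(x, y)
    lod = loq = None
    if noise_sd is not None:
        if noise_sd <= 0:
            raise ValueError("noise estimate must be positive")
        lod = 3.0 * noise_sd / res.slope
        loq = 10.0 * noise_sd / res.slope
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        range_low=float(x.min()),
        range_high=float(x.max()),
        r_squared=float(res.rvalue**2),
        lod=lod,
        loq=loq,
    )


def invert_calibration(
    curve: CalibrationCurve, response: float, concentration_factor: float = 1.0
) -> tuple[float | str, bool]:
    """Invert Y = a*x + b to a concentration in mg/L.

    ``concentration_factor`` is the dimensionless enrichment from extraction
    bookkeeping (sample volume / final volume).  Returns (value, extrapolated);
    concentrations below the curve's LOD are reported as the string "<LOD".
    """
    if response < curve.intercept:
        raise ValueError("response below the curve intercept")
    if response == curve.intercept:
        return 0.0, True  # zero net signal, below the linear range
    x_ng_ml = (response - curve.intercept) / curve.slope
    extrapolated = not (curve.range_low <= x_ng_ml <= curve.range_high)
    if curve.lod is not None and x_ng_ml < curve.lod:
        return "<LOD", extrapolated
    mg_l = x_ng_ml / concentration_factor / 1000.0  # ng/mL == ug/L
    return mg_l, extrapolated


# ---------------------------------------------------------------------------
# quinone profiles
# ---------------------------------------------------------------------------


def molar_ratio(amounts: dict[str, float | None]) -> dict[str, float | str]:
    """Normalize detected amounts to percent of their total; None stays ND
    and is excluded from the total."""
    detected = {k: v for k, v in amounts.items() if v is not None}
    total = sum(detected.values())
    if not detected or total == 0:
        raise ValueError("no detectable amounts to normalize")
    out: dict[str, float | str] = {
        k: (ND if v is None else 100.0 * v / total) for k, v in amounts.items()
    }
    return out


def profile_correlation(
    a: ChemProfile, b: ChemProfile, pairing: list[tuple[str, str]]
) -> float | str:
    """Pearson r over paired mean values in the given (condition, component)
    order.  Any ND cell in either profile makes the correlation ND; zero
    variance also reports ND."""
    if len(pairing) < 3:
        raise ValueError("need at least 3 paired cells")
    va, vb = [], []
    for key in pairing:
        for prof, vec in ((a, va), (b, vb)):
            if key in prof.nd or key not in prof.values:
                return ND
            vec.append(prof.values[key])
    if np.std(va) == 0 or np.std(vb) == 0:
        return ND
    return float(stats.pearsonr(va, vb).statistic)


def fame_similarity(a: ChemProfile, b: ChemProfile, condition: str = "") -> float:
    """Pearson r over the union of FAME components; a component missing from
    one profile (and not ND-masked) is treated as 0 percent."""
    comps = sorted(
        {c for cond, c in a.values if cond == condition}
        | {c for cond, c in b.values if cond == condition}
    )
    if len(comps) < 3:
        raise ValueError("need at least 3 shared FAME components")
    va = [a.values.get((condition, c), 0.0) for c in comps]
    vb = [b.values.get((condition, c), 0.0) for c in comps]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise ValueError("zero variance in a FAME composition vector")
    return float(stats.pearsonr(va, vb).statistic)


def api_similarity(a: list[str], b: list[str], method: str = "simple") -> float:
    """Similarity of binary phenotype vectors over {+,-,V,ND}.

    V and ND positions are excluded.  ``simple``: matches / compared tests;
    ``jaccard``: shared positives / positions positive in either.
    """
    if len(a) != len(b):
        raise ValueError("vectors must have equal length")
    skip = {"V", ND}
    pairs = [(x, y) for x, y in zip(a, b) if x not in skip and y not in skip]
    for x, y in pairs:
        if x not in "+-" or y not in "+-":
            raise ValueError(f"unexpected symbols in phenotype vectors: {x!r}/{y!r}")
    if not pairs:
        raise ValueError("no comparable positions")
    if method == "simple":
        return sum(x == y for x, y in pairs) / len(pairs)
    if method == "jaccard":
        either = [(x, y) for x, y in pairs if "+" in (x, y)]
        if not either:
            raise ValueError("no positive positions for Jaccard")
        return sum(x == y == "+" for x, y in either) / len(either)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def parse_profiles(lines: list[str], source: str = "<memory>") -> dict[str, ChemProfile]:
    """Parse profile TSV lines: strain, condition, component, mean, sd, flag."""
    profiles: dict[str, ChemProfile] = {}
    header = lines[0].rstrip("\n").split("\t")
    expected = ["strain", "condition", "component", "mean", "sd", "flag"]
    if header[: len(expected)] != expected:
        raise ValueError(f"unexpected profile TSV header in {source}")
    for line in lines[1:]:
        if not line.strip():
            continue
        strain, cond, comp, mean, sd, flag = (
            line.rstrip("\n").split("\t") + [""] * 6
        )[:6]
        prof = profiles.setdefault(strain, ChemProfile(strain))
        key = (cond, comp)
        if flag == ND or mean == "":
            prof.nd.add(key)
        else:
            prof.values[key] = float(mean)
            if sd:
                prof.sds[key] = float(sd)
    return profiles


def read_profiles_tsv(path: str | Path) -> dict[str, ChemProfile]:
    with open(path, encoding="utf-8") as fh:
        return parse_profiles(fh.readlines(), str(path))


def quinone_pairing(
    conditions: tuple[str, str] = ("aerobic", "anaerobic"),
    components: tuple[str, ...] = ("Q8", "DMK8", "MK8"),
) -> list[tuple[str, str]]:
    """Canonical condition x component pairing order for quinone profiles."""
    return [(cond, comp) for cond in conditions for comp in components]
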