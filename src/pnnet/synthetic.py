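"""Synthetic cohort generator with a known conditional-dependence structure.

The real cohort behind this analysis is access-restricted, so the package
ships a generator that emulates its statistical shape: a Gaussian copula
whose latent multivariate normal has a *known sparse partial-correlation
matrix*, with each column pushed through a marginal quantile transform
anchored to the published per-variable summaries (median and quartiles,
or mean and SD), plus per-variable completely-at-random missingness at
the published rates and raw four-sample saliva profiles for the cortisol
slope. Because the ground-truth network is known, the whole estimation
pipeline can be tested for structure recovery without any data download.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import SalivaProfile
from .variables import VARIABLES

__all__ = [
    "MarginalSpec",
    "NetworkSpec",
    "MissingnessSpec",
    "CohortSample",
    "make_default_spec",
    "default_marginals",
    "default_network",
    "default_missingness",
    "sample_cohort",
    "apply_missingness",
    "sample_saliva_profiles",
]


# --------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class MarginalSpec:
    """Marginal distribution of one panel variable, pinned to quantile anchors.

    kind:
        ``"normal"``    -- mean/sd anchors, Gaussian marginal (age, BMI).
        ``"lognormal"`` -- median/quartile anchors interpolated on the log
                           scale with exponential tails (CRP, cytokines).
        ``"quantile"``  -- median/quartile anchors interpolated on the
                           natural scale with exponential tails; optional
                           bounds and rounding step for instrument scores.
    anchors:
        ``{"mean": m, "sd": s}`` for ``"normal"``; otherwise
        ``{"q25": a, "median": b, "q75": c}`` with strictly increasing values.
    """

    name: str
    kind: str
    anchors: dict[str, float]
    bounds: tuple[float, float] | None = None
    step: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal", "quantile"):
            raise ValueError(f"{self.name}: unknown marginal kind {self.kind!r}")
        if self.kind == "normal":
            if not {"mean", "sd"} <= self.anchors.keys():
                raise ValueError(f"{self.name}: normal marginal needs mean and sd")
            if self.anchors["sd"] <= 0:
                raise ValueError(f"{self.name}: sd must be positive")
        else:
            try:
                q25, med, q75 = (self.anchors[k] for k in ("q25", "median", "q75"))
            except KeyError as exc:
                raise ValueError(f"{self.name}: needs q25/median/q75 anchors") from exc
            if not (q25 < med < q75):
                raise ValueError(f"{self.name}: quartile anchors must be strictly increasing")
            if self.kind == "lognormal" and q25 <= 0:
                raise ValueError(f"{self.name}: lognormal anchors must be positive")
        if self.bounds is not None:
            lo, hi = self.bounds
            if lo >= hi:
                raise ValueError(f"{self.name}: invalid bounds {self.bounds}")
            if self.kind != "normal":
                q25, q75 = self.anchors["q25"], self.anchors["q75"]
                if not (lo <= q25 and q75 <= hi):
                    raise ValueError(f"{self.name}: bounds must contain the anchors")

    def quantile(self, u: np.ndarray) -> np.ndarray:
        """Evaluate the quantile function at probabilities ``u`` in (0, 1)."""
        u = np.asarray(u, dtype=float)
        if self.kind == "normal":
            x = self.anchors["mean"] + self.anchors["sd"] * stats.norm.ppf(u)
        else:
            q25, med, q75 = (self.anchors[k] for k in ("q25", "median", "q75"))
            if self.kind == "lognormal":
                q25, med, q75 = np.log(q25), np.log(med), np.log(q75)
            x = _anchored_quantile(u, q25, med, q75)
            if self.kind == "lognormal":
                x = np.exp(x)
        if self.bounds is not None:
            x = np.clip(x, *self.bounds)
        if self.step is not None:
            x = np.round(x / self.step) * self.step
        return x


def _anchored_quantile(u: np.ndarray, q25: float, med: float, q75: float) -> np.ndarray:
    """Piecewise-linear quantile function through the three anchors.

    Linear between the quartiles; exponential tails outside them, with the
    tail scale matched to the adjacent inter-quartile slope so the density
    is continuous at the quartiles.
    """
    s_lo = med - q25  # tail scale = adjacent linear slope * 0.25
    s_hi = q75 - med
    x = np.empty_like(u)
    lo = u < 0.25
    mid1 = (u >= 0.25) & (u < 0.5)
    mid2 = (u >= 0.5) & (u < 0.75)
    hi = u >= 0.75
    with np.errstate(divide="ignore"):
        x[lo] = q25 - s_lo * np.log(0.25 / u[lo])
    x[mid1] = q25 + (med - q25) * (u[mid1] - 0.25) / 0.25
    x[mid2] = med + (q75 - med) * (u[mid2] - 0.5) / 0.25
    with np.errstate(divide="ignore"):
        x[hi] = q75 + s_hi * np.log(0.25 / (1.0 - u[hi]))
    return x


@dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth partial-correlation structure of the latent Gaussian.

    ``pcor`` is the symmetric unit-diagonal partial-correlation matrix of
    the latent multivariate normal.  The implied precision matrix
    (unit diagonal, off-diagonal ``-pcor``) must be positive definite.
    """

    variable_names: tuple[str, ...]
    pcor: np.ndarray

    def __post_init__(self) -> None:
        p = len(self.variable_names)
        P = np.asarray(self.pcor, dtype=float)
        if P.shape != (p, p):
            raise ValueError(f"pcor must be {p}x{p}, got {P.shape}")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("pcor must be symmetric")
        if not np.allclose(np.diag(P), 1.0):
            raise ValueError("pcor must have unit diagonal")
        off = P - np.diag(np.diag(P))
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal partial correlations must lie in (-1, 1)")
        object.__setattr__(self, "pcor", P)
        if np.linalg.eigvalsh(self.precision()).min() <= 0:
            raise ValueError(
                "implied precision matrix is not positive definite; "
                "reduce the partial-correlation magnitudes in the NetworkSpec"
            )

    def precision(self) -> np.ndarray:
        """Implied precision: unit diagonal, off-diagonal ``-pcor``."""
        return 2.0 * np.eye(len(self.variable_names)) - self.pcor

    def latent_correlation(self) -> np.ndarray:
        """Correlation matrix of the latent normal implied by ``pcor``."""
        sigma = np.linalg.inv(self.precision())
        d = 1.0 / np.sqrt(np.diag(sigma))
        return sigma * np.outer(d, d)

    def edge_set(self, tol: float = 1e-12) -> set[tuple[str, str]]:
        names = self.variable_names
        p = len(names)
        return {
            (names[i], names[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(self.pcor[i, j]) > tol
        }


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable completely-at-random missingness rates."""

    rates: dict[str, float]

    def __post_init__(self) -> None:
        for name, r in self.rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missing rate for {name} must be in [0, 1], got {r}")


@dataclass
class CohortSample:
    """A generated cohort: observed panel plus the latent normal draw."""

    panel: pd.DataFrame
    latent: np.ndarray
    seed: int


# --------------------------------------------------------------------------
# defaults: the study conditions

# Published marginal anchors per variable (complete-data group):
# median (IQR) for skewed scores and biomarkers, mean (SD) for age and BMI.
_DEFAULT_MARGINALS: dict[str, MarginalSpec] = {
    "sleep": MarginalSpec("sleep", "quantile",
                          {"q25": 3.0, "median": 5.0, "q75": 7.0},
                          bounds=(0.0, 21.0), step=1.0),
    "depression": MarginalSpec("depression", "quantile",
                               {"q25": 1.0, "median": 3.0, "q75": 6.0},
                               bounds=(0.0, 21.0), step=1.0),
    "anxiety": MarginalSpec("anxiety", "quantile",
                            {"q25": 3.0, "median": 5.0, "q75": 7.8},
                            bounds=(0.0, 21.0), step=1.0),
    "oral_pain": MarginalSpec("oral_pain", "quantile",
                              {"q25": 8.3, "median": 16.7, "q75": 33.3},
                              bounds=(0.0, 100.0), step=0.1),
    "fatigue": MarginalSpec("fatigue", "quantile",
                            {"q25": 5.0, "median": 9.0, "q75": 13.0},
                            bounds=(4.0, 20.0), step=1.0),
    "cortisol_slope": MarginalSpec("cortisol_slope", "quantile",
                                   {"q25": 0.25, "median": 0.47, "q75": 0.78}),
    "crp": MarginalSpec("crp", "lognormal",
                        {"q25": 2.5, "median": 2.8, "q75": 5.5}),
    "il6": MarginalSpec("il6", "lognormal",
                        {"q25": 0.66, "median": 1.03, "q75": 1.72}),
    "il10": MarginalSpec("il10", "lognormal",
                         {"q25": 0.18, "median": 0.24, "q75": 0.36}),
    "tnfa": MarginalSpec("tnfa", "lognormal",
                         {"q25": 2.32, "median": 2.72, "q75": 3.37}),
    "age": MarginalSpec("age", "normal", {"mean": 65.0, "sd": 8.2}),
    "bmi": MarginalSpec("bmi", "normal", {"mean": 26.1, "sd": 4.5}),
}

# Ground-truth edge support: the 18-edge structure of the published network
# (all partial correlations positive except sleep--cortisol, which is the
# single negative edge: poorer sleep goes with a flatter diurnal slope).
_DEFAULT_EDGES: dict[tuple[str, str], float] = {
    ("sleep", "depression"): 0.2,
    ("sleep", "anxiety"): 0.2,
    ("sleep", "oral_pain"): 0.2,
    ("sleep", "fatigue"): 0.2,
    ("sleep", "cortisol_slope"): -0.2,
    ("depression", "anxiety"): 0.2,
    ("depression", "fatigue"): 0.2,
    ("depression", "age"): 0.2,
    ("anxiety", "fatigue"): 0.2,
    ("oral_pain", "fatigue"): 0.2,
    ("oral_pain", "crp"): 0.2,
    ("fatigue", "crp"): 0.2,
    ("crp", "il6"): 0.2,
    ("il6", "il10"): 0.2,
    ("il6", "tnfa"): 0.2,
    ("il6", "age"): 0.2,
    ("il10", "tnfa"): 0.2,
    ("tnfa", "bmi"): 0.2,
}

# Published per-variable missingness: counts of missing values out of the
# 739 enrolled patients (age was available for everyone).
_MISSING_COUNTS = {
    "sleep": 179, "depression": 142, "anxiety": 144, "oral_pain": 142,
    "fatigue": 177, "cortisol_slope": 340, "crp": 93, "il6": 93,
    "il10": 93, "tnfa": 93, "age": 0, "bmi": 169,
}
_ENROLLED = 739


def default_marginals() -> dict[str, MarginalSpec]:
    return dict(_DEFAULT_MARGINALS)


def default_network() -> NetworkSpec:
    p = len(VARIABLES)
    idx = {v: i for i, v in enumerate(VARIABLES)}
    P = np.eye(p)
    for (a, b), w in _DEFAULT_EDGES.items():
        P[idx[a], idx[b]] = P[idx[b], idx[a]] = w
    return NetworkSpec(VARIABLES, P)


def default_missingness() -> MissingnessSpec:
    return MissingnessSpec({v: _MISSING_COUNTS[v] / _ENROLLED for v in VARIABLES})


def make_default_spec() -> tuple[dict[str, MarginalSpec], NetworkSpec, MissingnessSpec]:
    """Marginals, true network and missingness mirroring the study conditions."""
    return default_marginals(), default_network(), default_missingness()


# --------------------------------------------------------------------------
# sampling

def _substream(seed: int, name: str) -> np.random.Generator:
    # named, independent substreams derived from one master seed
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def sample_cohort(
    n: int,
    marginals: dict[str, MarginalSpec] | None = None,
    network: NetworkSpec | None = None,
    seed: int = 0,
) -> CohortSample:
    """Draw a cohort of ``n`` patients from the Gaussian copula model.

    The latent rows come from a zero-mean multivariate normal whose
    partial-correlation matrix equals ``network.pcor``; each column is then
    pushed through its marginal's quantile transform.  Identical
    ``(seed, spec)`` pairs give bit-identical panels.
    """
    if n < 2:
        raise ValueError("need at least two patients")
    if marginals is None:
        marginals = default_marginals()
    if network is None:
        network = default_network()
    names = network.variable_names
    missing_specs = [v for v in names if v not in marginals]
    if missing_specs:
        raise ValueError(f"no marginal spec for {missing_specs}")
    R = network.latent_correlation()
    chol = np.linalg.cholesky(R)
    rng = _substream(seed, "latent")
    latent = rng.standard_normal((n, len(names))) @ chol.T
    u = stats.norm.cdf(latent)
    cols = {v: marginals[v].quantile(u[:, j]) for j, v in enumerate(names)}
    panel = pd.DataFrame(cols, columns=list(names))
    return CohortSample(panel=panel, latent=latent, seed=seed)


def apply_missingness(
    sample: CohortSample | pd.DataFrame,
    miss: MissingnessSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mask entries independently per variable at the spec's rates."""
    panel = sample.panel if isinstance(sample, CohortSample) else sample
    if miss is None:
        miss = default_missingness()
    rng = _substream(seed, "missingness")
    out = panel.copy()
    for col in out.columns:
        rate = miss.rates.get(col, 0.0)
        if rate > 0:
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = np.nan
    return out


def sample_saliva_profiles(
    n: int,
    seed: int = 0,
    flat: bool = False,
    loq: float = 1.0,
) -> list[SalivaProfile]:
    """Generate raw four-point diurnal saliva cortisol profiles.

    Each profile carries samples at awakening, +30 min, +60 min and 22:00
    with a morning rise and an evening decline.  The evening value is set
    so that the implied slope (awakening minus evening, per hour) follows
    the published slope distribution.  Concentrations below the assay's
    lower limit of quantitation (1.0 nmol/L) are kept but flagged.

    With ``flat=True`` every sample equals the awakening value, so the
    slope is exactly zero (useful as a degenerate test case).
    """
    if n < 1:
        raise ValueError("need at least one profile")
    rng = _substream(seed, "saliva")
    slope_spec = _DEFAULT_MARGINALS["cortisol_slope"]
    wake = np.clip(rng.normal(7.0, 0.75, size=n), 5.0, 10.0)
    evening = np.exp(rng.normal(np.log(2.0), 0.45, size=n))
    slopes = slope_spec.quantile(rng.uniform(1e-9, 1 - 1e-9, size=n))
    hours = 22.0 - wake
    awake = np.maximum(evening + slopes * hours, 0.2)
    peak = awake * rng.uniform(1.2, 1.6, size=n)
    post60 = awake + (peak - awake) * rng.uniform(0.3, 0.9, size=n)
    profiles = []
    for i in range(n):
        if flat:
            conc = (awake[i],) * 4
        else:
            conc = (awake[i], peak[i], post60[i], evening[i])
        profiles.append(
            SalivaProfile(
                times=(wake[i], wake[i] + 0.5, wake[i] + 1.0, 22.0),
                concentrations=conc,
                below_loq=tuple(c < loq for c in conc),
            )
        )
    return profiles


# --------------------------------------------------------------------------
# I/O

def write_cohort_csv(panel: pd.DataFrame, path) -> None:
    """One row per patient, one column per variable, empty cell = missing."""
    panel.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def spec_to_dict(
    marginals: dict[str, MarginalSpec],
    network: NetworkSpec,
    miss: MissingnessSpec,
) -> dict:
    """JSON/YAML-serializable description of a generator configuration."""
    return {
        "marginals": {
            v: {
                "kind": m.kind,
                "anchors": dict(m.anchors),
                "bounds": list(m.bounds) if m.bounds else None,
                "step": m.step,
            }
            for v, m in marginals.items()
        },
        "network": {
            "variables": list(network.variable_names),
            "pcor": network.pcor.tolist(),
        },
        "missingness": dict(miss.rates),
    }
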