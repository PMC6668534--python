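"""One-way MANOVA test statistics and a Monte Carlo type-I error engine.

The module is organised in the order the method runs:

1.  errors and constants
2.  ``GroupedSample`` — grouped p-variate data and CSV input
3.  SSCP decomposition (between-groups B, within-groups W)
4.  the eigenvalue spectrum of W^{-1}B
5.  the four test statistics (Wilks' Λ, Pillai's V, Hotelling–Lawley U,
    Roy's θ) with their F approximations, plus Bartlett's chi-square
6.  ``manova_test`` — the one-shot four-statistic test
7.  simulation scenarios (gamma / Student-t / normal generators)
8.  the Monte Carlo engine (per-scenario rejection rates)
9.  reporting: deviation-from-nominal summaries and table writers

All randomness flows through :class:`numpy.random.Generator` substreams
derived from ``(seed, scenario, replicate_index)`` so every grid cell is
reproducible and order-independent.
"""

from __future__ import annotations

import logging
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import integrate, special
from scipy import linalg as sla
from scipy import stats as sps

logger = logging.getLogger("manovasim")

# ---------------------------------------------------------------------------
# errors and constants
# ---------------------------------------------------------------------------

#: canonical internal test order
TESTS = ("wilks", "pillai", "hotelling", "roy")

#: single-letter labels in the order the study's tables print them (R P H W)
TABLE_TEST_ORDER = ("roy", "pillai", "hotelling", "wilks")
TEST_LETTER = {"roy": "R", "pillai": "P", "hotelling": "H", "wilks": "W"}

#: eigenvalues below RELATIVE_EIG_TOL * (1 + lambda_max) are treated as zero
RELATIVE_EIG_TOL = 1e-10

#: condition number of W above which the within matrix is declared singular
MAX_W_CONDITION = 1e12

#: default nominal level, replication count and root seed of the study design
DEFAULT_ALPHA = 0.05
DEFAULT_REPS = 10_000
DEFAULT_SEED = 12345

#: the ten balanced/unbalanced group-size patterns of the study design
SIZE_PRESETS: dict[str, tuple[int, int, int]] = {
    "10-10-10": (10, 10, 10),
    "20-20-20": (20, 20, 20),
    "50-50-50": (50, 50, 50),
    "10-10-20": (10, 10, 20),
    "10-10-50": (10, 10, 50),
    "10-20-20": (10, 20, 20),
    "10-20-50": (10, 20, 50),
    "10-50-50": (10, 50, 50),
    "20-20-50": (20, 20, 50),
    "20-50-50": (20, 50, 50),
}


class InvalidInputError(ValueError):
    """Raised when grouped data or a statistic value violates a precondition."""


class SingularWithinError(ValueError):
    """Raised when the within-groups SSCP matrix W is (numerically) singular."""


class InsufficientErrorDfError(ValueError):
    """Raised when an F approximation's denominator degrees of freedom are <= 0."""


class ValidationError(ValueError):
    """Raised when a scenario configuration field is invalid; names the field."""


class InvalidAggregationError(ValueError):
    """Raised when cells with mixed nominal levels are aggregated."""


class CellAbortedError(RuntimeError):
    """Raised when a simulation cell exceeds the re-draw budget (>1% of reps)."""


# ---------------------------------------------------------------------------
# grouped multivariate data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupedSample:
    """g groups of p-variate observations.

    Parameters
    ----------
    groups
        One ``(n_i, p)`` float array per group, in group order.
    labels
        Optional group labels (defaults to ``"g1"…``).
    """

    groups: tuple[np.ndarray, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        groups = tuple(np.asarray(a, dtype=float) for a in self.groups)
        if len(groups) < 2:
            raise InvalidInputError(f"need at least 2 groups, got {len(groups)}")
        fixed = []
        for i, a in enumerate(groups):
            if a.ndim == 1:
                a = a[:, None]
            if a.ndim != 2:
                raise InvalidInputError(f"group {i} is not a 2-D block")
            if a.shape[0] < 1:
                raise InvalidInputError(f"group {i} is empty")
            if not np.all(np.isfinite(a)):
                raise InvalidInputError(f"group {i} contains non-finite values")
            fixed.append(a)
        p = fixed[0].shape[1]
        if p < 1:
            raise InvalidInputError("p = 0: no response variables")
        for i, a in enumerate(fixed):
            if a.shape[1] != p:
                raise InvalidInputError(
                    f"group {i} has {a.shape[1]} variables, expected {p}"
                )
        object.__setattr__(self, "groups", tuple(fixed))
        labels = self.labels or tuple(f"g{i + 1}" for i in range(len(fixed)))
        if len(labels) != len(fixed):
            raise InvalidInputError("labels length does not match group count")
        object.__setattr__(self, "labels", tuple(str(l) for l in labels))

    @property
    def g(self) -> int:
        return len(self.groups)

    @property
    def p(self) -> int:
        return self.groups[0].shape[1]

    @property
    def n_i(self) -> tuple[int, ...]:
        return tuple(a.shape[0] for a in self.groups)

    @property
    def N(self) -> int:
        return sum(self.n_i)

    def stacked(self) -> np.ndarray:
        """All N observations as one ``(N, p)`` array."""
        return np.vstack(self.groups)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GroupedSample":
        """First column = group label, remaining columns numeric responses.

        Groups are ordered by first appearance of their label.
        """
        if df.shape[1] < 2:
            raise InvalidInputError("need a label column plus >= 1 numeric column")
        labels_col = df.iloc[:, 0].astype(str)
        values = df.iloc[:, 1:].apply(pd.to_numeric, errors="raise").to_numpy(float)
        order = labels_col.drop_duplicates().tolist()
        blocks = tuple(values[(labels_col == lab).to_numpy()] for lab in order)
        return cls(groups=blocks, labels=tuple(order))

    @classmethod
    def from_csv(cls, path, sep: str | None = None) -> "GroupedSample":
        """Read a delimited table (CSV/TSV, header row required)."""
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        return cls.from_dataframe(df)


# ---------------------------------------------------------------------------
# SSCP decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSCPPair:
    """Between-groups (B) and within-groups (W) sums of squares and
    cross-products matrices; B + W equals the total centered SSCP."""

    B: np.ndarray
    W: np.ndarray


def sscp_matrices(sample: GroupedSample) -> SSCPPair:
    """Decompose total variation into between- and within-group SSCP matrices.

    B = Σ_i n_i (x̄_i − x̄)(x̄_i − x̄)' and W = Σ_i (n_i − 1) S_i, where x̄ is
    the observation-weighted grand mean of all N rows and S_i the i-th group
    covariance matrix. By construction B + W equals the pooled centered SSCP.
    """
    grand = sample.stacked().mean(axis=0)
    p = sample.p
    B = np.zeros((p, p))
    W = np.zeros((p, p))
    for block in sample.groups:
        mean_i = block.mean(axis=0)
        d = mean_i - grand
        B += block.shape[0] * np.outer(d, d)
        centered = block - mean_i
        W += centered.T @ centered
    # enforce exact symmetry against round-off
    B = (B + B.T) / 2.0
    W = (W + W.T) / 2.0
    return SSCPPair(B=B, W=W)


# ---------------------------------------------------------------------------
# eigenvalue spectrum of W^{-1} B
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EigenSpectrum:
    """The s = min(g−1, p) non-negative eigenvalues of W⁻¹B, sorted
    descending, with the hypothesis/error degrees of freedom they carry."""

    lambdas: tuple[float, ...]
    s: int
    q: int  # hypothesis df, g - 1
    v: int  # error df, N - g
    p: int  # number of response variables

    @property
    def lambda_max(self) -> float:
        return self.lambdas[0]


def eigen_spectrum(sscp: SSCPPair, g: int, N: int) -> EigenSpectrum:
    """Solve the generalized eigenproblem B x = λ W x and keep the s largest
    roots (clipped at zero).

    Raises
    ------
    SingularWithinError
        If W is singular or numerically near-singular: error df v = N − g
        below p, a within-groups constant variable, or cond(W) > 1e12.
    """
    B, W = sscp.B, sscp.W
    p = B.shape[0]
    q = g - 1
    v = N - g
    if v < p:
        raise SingularWithinError(
            f"within matrix W is singular: error df v = N - g = {v} < p = {p}"
        )
    cond = np.linalg.cond(W)
    if not np.isfinite(cond) or cond > MAX_W_CONDITION:
        raise SingularWithinError(
            f"within matrix W is numerically singular (condition number {cond:.3g} "
            f"exceeds {MAX_W_CONDITION:.0e}); a variable may be constant within groups"
        )
    try:
        lam = sla.eigh(B, W, eigvals_only=True)
    except (sla.LinAlgError, ValueError) as exc:  # W not positive definite
        raise SingularWithinError(
            f"within matrix W is not positive definite: {exc}"
        ) from exc
    lam = np.sort(lam)[::-1]
    tol = RELATIVE_EIG_TOL * (1.0 + max(lam[0], 0.0))
    lam = np.where(np.abs(lam) < tol, 0.0, lam)
    lam = np.clip(lam, 0.0, None)
    s = min(q, p)
    return EigenSpectrum(lambdas=tuple(lam[:s]), s=s, q=q, v=v, p=p)


# ---------------------------------------------------------------------------
# the four test statistics
# ---------------------------------------------------------------------------


def wilks_lambda(spec: EigenSpectrum) -> float:
    """Wilks' Λ = Π 1/(1+λ_i) = det(W)/det(B+W); 1 means identical means."""
    return float(np.prod([1.0 / (1.0 + lam) for lam in spec.lambdas]))


def pillai_trace(spec: EigenSpectrum) -> float:
    """Pillai's V = Σ λ_i/(1+λ_i), bounded in [0, s]."""
    return float(sum(lam / (1.0 + lam) for lam in spec.lambdas))


def hotelling_lawley(spec: EigenSpectrum) -> float:
    """Hotelling–Lawley trace U = Σ λ_i = tr(W⁻¹B)."""
    return float(sum(spec.lambdas))


def roy_largest_root(spec: EigenSpectrum) -> float:
    """Roy's statistic θ = λ_max/(1+λ_max) ∈ [0, 1)."""
    lam = spec.lambda_max
    return float(lam / (1.0 + lam))


@lru_cache(maxsize=64)
def _roy_null_grid(two_m: int, two_n: int, npts: int = 4097) -> tuple[np.ndarray, np.ndarray]:
    """Null CDF of Roy's θ = λ_max/(1+λ_max) for s = 2 on a fine grid.

    Under H0 the two nonzero roots θ1 ≥ θ2 follow the (real) Jacobi ensemble
    with density ∝ θ1^m θ2^m (1−θ1)^n (1−θ2)^n (θ1−θ2), where
    m = (|p−q|−1)/2 and n = (v−p−1)/2 — the parameters Heck's charts are
    indexed by. Integrating out the smaller root reduces
    P(θ_max ≤ x) to a single integral of

        g(t) = t^m (1−t)^n [ t·B(m+1,n+1)·I_t(m+1,n+1)
                             − B(m+2,n+1)·I_t(m+2,n+1) ]

    which is accumulated by trapezoid on the substitution t = sin²φ (the
    substitution absorbs the integrable t^{−1/2}/(1−t)^{−1/2} endpoint
    singularities). Cached per (2m, 2n); the two arguments are doubled so
    the half-integer parameters hash as exact ints.
    """
    m = two_m / 2.0
    n = two_n / 2.0
    phi = np.linspace(0.0, np.pi / 2.0, npts)
    t = np.sin(phi) ** 2
    b1 = special.beta(m + 1.0, n + 1.0)
    b2 = special.beta(m + 2.0, n + 1.0)
    bracket = t * b1 * special.betainc(m + 1.0, n + 1.0, t) - b2 * special.betainc(
        m + 2.0, n + 1.0, t
    )
    # g(t) dt = 2 t^{m+1/2} (1-t)^{n+1/2} * bracket dphi ; exponents >= 0
    with np.errstate(invalid="ignore"):
        f = 2.0 * t ** (m + 0.5) * (1.0 - t) ** (n + 0.5) * bracket
    f[~np.isfinite(f)] = 0.0
    cum = integrate.cumulative_trapezoid(f, phi, initial=0.0)
    cdf = cum / cum[-1]
    return t, cdf


def roy_null_cdf(theta: float | np.ndarray, p: int, q: int, v: int) -> float | np.ndarray:
    """Exact null CDF of Roy's largest-root statistic θ for s = min(p,q) ≤ 2.

    s = 1 reduces to a Beta(df1/2, df2/2) law, equivalent to the (then exact)
    F form; s = 2 uses the Jacobi-ensemble integral of :func:`_roy_null_grid`.
    """
    s, m, n = _aux_mn(p, q, v)
    if s == 1:
        return sps.beta.cdf(theta, m + 1.0, n + 1.0)
    if s == 2:
        grid_t, grid_cdf = _roy_null_grid(int(round(2 * m)), int(round(2 * n)))
        return np.interp(theta, grid_t, grid_cdf)
    raise InvalidInputError(f"exact Roy null CDF implemented for s <= 2, got s = {s}")


@dataclass(frozen=True)
class TestResult:
    """One statistic's value, its F (or chi-square) approximation,
    degrees of freedom and p-value."""

    statistic_name: str
    statistic_value: float
    approx_kind: str  # "F" or "chi2"
    F_or_chi2: float
    df1: float
    df2: float | None
    p_value: float
    exact_flag: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


def _aux_mn(p: int, q: int, v: int) -> tuple[int, float, float]:
    """s, m, n* auxiliaries shared by the Pillai and Hotelling–Lawley
    approximations: s = min(p,q), m = (|p−q|−1)/2, n* = (v−p−1)/2."""
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nstar = (v - p - 1) / 2.0
    return s, m, nstar


def f_approximation(statistic_name: str, spec: EigenSpectrum, p: int) -> TestResult:
    """F approximation and upper-tail p-value for one of the four statistics.

    Wilks uses Rao's transformation; Pillai uses
    F = ((2n*+s+1)/(2m+s+1)) · V/(s−V) with df1 = s(2m+s+1),
    df2 = s(2n*+s+1); Hotelling–Lawley uses df1 = s(2m+s+1),
    df2 = 2(s·n*+1), F = df2·U/(s·df1); Roy reports the classical bound
    F = df2·λ_max/df1 with df1 = max(p,q), df2 = v − df1 + q, but for
    s ≤ 2 its p-value comes from the exact largest-root null distribution
    (:func:`roy_null_cdf`) — the F bound's own tail is anti-conservative
    for s ≥ 2 and is only used as the p-value when s ≥ 3. When s = 1 all
    four approximations are the same exact F test (``exact_flag``).
    """
    if statistic_name not in TESTS:
        raise InvalidInputError(f"unknown statistic {statistic_name!r}")
    q, v = spec.q, spec.v
    s, m, nstar = _aux_mn(p, q, v)

    if statistic_name == "wilks":
        lam_stat = wilks_lambda(spec)
        den = p * p + q * q - 5
        t = math.sqrt((p * p * q * q - 4) / den) if den > 0 else 1.0
        w = v - (p - q + 1) / 2.0
        df1 = float(p * q)
        df2 = w * t - (p * q - 2) / 2.0
        if df2 <= 0:
            raise InsufficientErrorDfError(
                f"Wilks F approximation has df2 = {df2:.3g} <= 0 (N too small)"
            )
        lam_t = lam_stat ** (1.0 / t)
        F = (1.0 - lam_t) / lam_t * (df2 / df1) if lam_t > 0 else math.inf
        value = lam_stat
    elif statistic_name == "pillai":
        V = pillai_trace(spec)
        df1 = s * (2.0 * m + s + 1.0)
        df2 = s * (2.0 * nstar + s + 1.0)
        if df2 <= 0:
            raise InsufficientErrorDfError(
                f"Pillai F approximation has df2 = {df2:.3g} <= 0 "
                f"(requires N - g >= p + 1)"
            )
        F = (df2 / df1) * V / (s - V) if V < s else math.inf
        value = V
    elif statistic_name == "hotelling":
        U = hotelling_lawley(spec)
        df1 = s * (2.0 * m + s + 1.0)
        df2 = 2.0 * (s * nstar + 1.0)
        if df2 <= 0:
            raise InsufficientErrorDfError(
                f"Hotelling-Lawley F approximation has df2 = {df2:.3g} <= 0 "
                f"(requires N - g >= p + 1)"
            )
        F = df2 * U / (s * df1)
        value = U
    else:  # roy
        lam_max = spec.lambda_max
        df1 = float(max(p, q))
        df2 = v - df1 + q
        if df2 <= 0:
            raise InsufficientErrorDfError(
                f"Roy F bound has df2 = {df2:.3g} <= 0 (N too small)"
            )
        F = df2 * lam_max / df1
        value = roy_largest_root(spec)
        if s <= 2:
            # exact largest-root p-value; the classical F bound above is
            # anti-conservative for s >= 2 and is reported for reference only
            p_value = float(1.0 - roy_null_cdf(value, p, q, v))
            return TestResult(
                statistic_name="roy",
                statistic_value=value,
                approx_kind="F",
                F_or_chi2=float(F),
                df1=float(df1),
                df2=float(df2),
                p_value=min(max(p_value, 0.0), 1.0),
                exact_flag=(s == 1),
            )

    p_value = float(sps.f.sf(F, df1, df2)) if math.isfinite(F) else 0.0
    return TestResult(
        statistic_name=statistic_name,
        statistic_value=value,
        approx_kind="F",
        F_or_chi2=float(F),
        df1=float(df1),
        df2=float(df2),
        p_value=p_value,
        exact_flag=(s == 1),
    )


def bartlett_chi2(
    wilks_value: float, N: int, p: int, g: int, mode: str = "standard"
) -> TestResult:
    """Bartlett's chi-square approximation for Wilks' Λ.

    ``mode="standard"`` uses the conventional correction
    L = −(N − 1 − (p+g)/2)·ln Λ; ``mode="as_printed"`` uses the literal
    L = −((N − 1 − (p+g))/2)·ln Λ. Both are referred to chi-square with
    p(g−1) degrees of freedom.
    """
    if not (0.0 < wilks_value <= 1.0):
        raise InvalidInputError(f"Wilks lambda {wilks_value} outside (0, 1]")
    if mode == "standard":
        scale = N - 1 - (p + g) / 2.0
    elif mode == "as_printed":
        scale = (N - 1 - (p + g)) / 2.0
    else:
        raise InvalidInputError(f"unknown Bartlett mode {mode!r}")
    L = -scale * math.log(wilks_value)
    df = p * (g - 1)
    return TestResult(
        statistic_name="wilks",
        statistic_value=float(wilks_value),
        approx_kind="chi2",
        F_or_chi2=float(L),
        df1=float(df),
        df2=None,
        p_value=float(sps.chi2.sf(L, df)),
        exact_flag=False,
    )


# ---------------------------------------------------------------------------
# one-shot MANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManovaResult:
    """All four test results on one sample, with per-test reject flags
    (strict rule: reject iff p-value < alpha)."""

    results: dict[str, TestResult]
    rejects: dict[str, bool]
    alpha: float
    sscp: SSCPPair
    spectrum: EigenSpectrum

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in TESTS:
            r = self.results[name]
            rows.append(
                {
                    "test": name,
                    "statistic": r.statistic_value,
                    "approx": r.approx_kind,
                    "F": r.F_or_chi2,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p_value": r.p_value,
                    "reject": self.rejects[name],
                }
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = [
            f"One-way MANOVA, alpha = {self.alpha:g} "
            f"(s = {self.spectrum.s}, q = {self.spectrum.q}, v = {self.spectrum.v})",
            f"{'test':<12}{'statistic':>12}{'F':>12}{'df1':>8}{'df2':>10}"
            f"{'p-value':>12}  decision",
        ]
        for name in TESTS:
            r = self.results[name]
            dec = "reject H0" if self.rejects[name] else "retain H0"
            lines.append(
                f"{name:<12}{r.statistic_value:>12.6f}{r.F_or_chi2:>12.4f}"
                f"{r.df1:>8.1f}{r.df2:>10.2f}{r.p_value:>12.6f}  {dec}"
            )
        return "\n".join(lines)


def manova_test(sample: GroupedSample, alpha: float = DEFAULT_ALPHA) -> ManovaResult:
    """Test H0: equal group mean vectors with all four MANOVA statistics.

    Chains the SSCP decomposition, the eigenvalue spectrum of W⁻¹B and the
    four F approximations; a test rejects iff its p-value is strictly below
    ``alpha``.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha {alpha} outside (0, 1)")
    sscp = sscp_matrices(sample)
    spec = eigen_spectrum(sscp, sample.g, sample.N)
    results = {name: f_approximation(name, spec, sample.p) for name in TESTS}
    rejects = {name: results[name].p_value < alpha for name in TESTS}
    return ManovaResult(
        results=results, rejects=rejects, alpha=alpha, sscp=sscp, spectrum=spec
    )


# ---------------------------------------------------------------------------
# simulation scenarios
# ---------------------------------------------------------------------------

FAMILIES = ("gamma", "student_t", "normal")

#: distribution presets of the study design: three distribution pairs, each
#: in a homogeneous- and a heterogeneous-variance flavour.  Gamma groups are
#: centered by their mean shape*scale so H0 (zero mean vectors) holds; the
#: heterogeneous t/normal scale multipliers (1, 1.5, 3) give variance ratios
#: 1 : 2.25 : 9, mirroring the gamma scenario.
DISTRIBUTION_PRESETS: dict[str, dict] = {
    "gamma-homogeneous": dict(
        family="gamma", shapes=(4.0, 4.0, 4.0), scale=0.5, center_to_zero_mean=True
    ),
    "gamma-heterogeneous": dict(
        family="gamma", shapes=(4.0, 9.0, 36.0), scale=0.5, center_to_zero_mean=True
    ),
    "t-homogeneous": dict(family="student_t", df=2.0, scales=(1.0, 1.0, 1.0)),
    "t-heterogeneous": dict(family="student_t", df=2.0, scales=(1.0, 1.5, 3.0)),
    "normal-homogeneous": dict(family="normal", scales=(1.0, 1.0, 1.0)),
    "normal-heterogeneous": dict(family="normal", scales=(1.0, 1.5, 3.0)),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell: a distribution family with per-group parameters,
    group sizes, variable count, nominal level, replication count and seed.

    Every preset keeps H0 (equal — zero — group mean vectors) true by
    construction: gamma draws are shifted by −shape·scale when
    ``center_to_zero_mean`` is set, and t/normal draws have mean zero.
    """

    name: str
    family: str
    group_sizes: tuple[int, ...]
    p: int
    shapes: tuple[float, ...] | None = None  # gamma, per group
    scale: float | None = None  # gamma, common
    df: float | None = None  # student_t
    scales: tuple[float, ...] | None = None  # t/normal per-group multipliers
    center_to_zero_mean: bool = False
    alpha: float = DEFAULT_ALPHA
    reps: int = DEFAULT_REPS
    seed: int = DEFAULT_SEED
    distribution: str = ""  # preset key, for reporting
    sizes_name: str = ""  # size-pattern label, for reporting

    @property
    def g(self) -> int:
        return len(self.group_sizes)

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "family": self.family,
            "group_sizes": list(self.group_sizes),
            "p": self.p,
            "center_to_zero_mean": self.center_to_zero_mean,
            "alpha": self.alpha,
            "reps": self.reps,
            "seed": self.seed,
            "distribution": self.distribution,
            "sizes_name": self.sizes_name,
        }
        if self.family == "gamma":
            d["shapes"] = list(self.shapes)
            d["scale"] = self.scale
        elif self.family == "student_t":
            d["df"] = self.df
            d["scales"] = list(self.scales)
        else:
            d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return make_scenario(**d)


def make_scenario(
    name: str,
    family: str,
    group_sizes: Sequence[int],
    p: int,
    shapes: Sequence[float] | None = None,
    scale: float | None = None,
    df: float | None = None,
    scales: Sequence[float] | None = None,
    center_to_zero_mean: bool = False,
    alpha: float = DEFAULT_ALPHA,
    reps: int = DEFAULT_REPS,
    seed: int = DEFAULT_SEED,
    distribution: str = "",
    sizes_name: str = "",
) -> ScenarioConfig:
    """Validate raw fields into a :class:`ScenarioConfig`.

    Raises :class:`ValidationError` naming the offending field.
    """
    if family not in FAMILIES:
        raise ValidationError(f"family: {family!r} not one of {FAMILIES}")
    group_sizes = tuple(int(n) for n in group_sizes)
    if len(group_sizes) < 2:
        raise ValidationError(f"group_sizes: need >= 2 groups, got {group_sizes}")
    if any(n < 1 for n in group_sizes):
        raise ValidationError(f"group_sizes: all sizes must be >= 1, got {group_sizes}")
    if p < 1:
        raise ValidationError(f"p: must be >= 1, got {p}")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha: must be in (0, 1), got {alpha}")
    if reps < 1:
        raise ValidationError(f"reps: must be >= 1, got {reps}")
    g = len(group_sizes)
    if family == "gamma":
        if shapes is None or scale is None:
            raise ValidationError("shapes/scale: required for the gamma family")
        shapes = tuple(float(a) for a in shapes)
        if len(shapes) != g:
            raise ValidationError(f"shapes: need {g} per-group shapes, got {len(shapes)}")
        if any(a <= 0 for a in shapes):
            raise ValidationError(f"shapes: must be positive, got {shapes}")
        if scale <= 0:
            raise ValidationError(f"scale: must be positive, got {scale}")
        df_, scales_ = None, None
    elif family == "student_t":
        if df is None:
            raise ValidationError("df: required for the student_t family")
        if df <= 0:
            raise ValidationError(f"df: must be positive, got {df}")
        scales = tuple(float(c) for c in (scales if scales is not None else (1.0,) * g))
        if len(scales) != g or any(c <= 0 for c in scales):
            raise ValidationError(f"scales: need {g} positive multipliers, got {scales}")
        shapes, scale, df_, scales_ = None, None, float(df), scales
    else:  # normal
        scales = tuple(float(c) for c in (scales if scales is not None else (1.0,) * g))
        if len(scales) != g or any(c <= 0 for c in scales):
            raise ValidationError(f"scales: need {g} positive multipliers, got {scales}")
        shapes, scale, df_, scales_ = None, None, None, scales
    return ScenarioConfig(
        name=str(name),
        family=family,
        group_sizes=group_sizes,
        p=int(p),
        shapes=shapes,
        scale=float(scale) if scale is not None else None,
        df=df_,
        scales=scales_,
        center_to_zero_mean=bool(center_to_zero_mean),
        alpha=float(alpha),
        reps=int(reps),
        seed=int(seed),
        distribution=str(distribution),
        sizes_name=str(sizes_name),
    )


def scenario_preset(
    distribution: str,
    sizes: str | Sequence[int],
    p: int,
    alpha: float = DEFAULT_ALPHA,
    reps: int = DEFAULT_REPS,
    seed: int = DEFAULT_SEED,
) -> ScenarioConfig:
    """Build one study-design cell from a distribution preset key
    (e.g. ``"gamma-heterogeneous"``) and a size pattern (``"10-10-50"`` or an
    explicit size tuple)."""
    if distribution not in DISTRIBUTION_PRESETS:
        raise ValidationError(
            f"distribution: {distribution!r} not one of "
            f"{sorted(DISTRIBUTION_PRESETS)}"
        )
    if isinstance(sizes, str):
        sizes_name = sizes
        if sizes not in SIZE_PRESETS:
            try:
                group_sizes = tuple(int(tok) for tok in sizes.split("-"))
            except ValueError:
                raise ValidationError(f"sizes: cannot parse pattern {sizes!r}")
        else:
            group_sizes = SIZE_PRESETS[sizes]
    else:
        group_sizes = tuple(int(n) for n in sizes)
        sizes_name = "-".join(str(n) for n in group_sizes)
    name = f"{distribution}/p{p}/{sizes_name}"
    return make_scenario(
        name=name,
        group_sizes=group_sizes,
        p=p,
        alpha=alpha,
        reps=reps,
        seed=seed,
        distribution=distribution,
        sizes_name=sizes_name,
        **DISTRIBUTION_PRESETS[distribution],
    )


def study_grid(
    reps: int = DEFAULT_REPS,
    seed: int = DEFAULT_SEED,
    alpha: float = DEFAULT_ALPHA,
    distributions: Sequence[str] = tuple(DISTRIBUTION_PRESETS),
    ps: Sequence[int] = (2, 3),
) -> list[ScenarioConfig]:
    """The full study grid: 6 distribution presets x p in {2,3} x the ten
    size patterns = 120 cells (fewer if restricted)."""
    return [
        scenario_preset(dist, sizes, p, alpha=alpha, reps=reps, seed=seed)
        for dist in distributions
        for p in ps
        for sizes in SIZE_PRESETS
    ]


def save_scenarios(configs: Iterable[ScenarioConfig], path) -> None:
    """Serialize scenario configs to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"scenarios": [c.to_dict() for c in configs]}, fh, sort_keys=False
        )


def load_scenarios(path) -> list[ScenarioConfig]:
    """Load scenario configs from a YAML file (``scenarios:`` list or a bare
    list of mappings)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    entries = data["scenarios"] if isinstance(data, dict) else data
    return [ScenarioConfig.from_dict(d) for d in entries]


def _scenario_key(name: str) -> int:
    """Stable 32-bit key for a scenario name, used to separate substreams."""
    return zlib.crc32(name.encode("utf-8"))


def sample_groups(config: ScenarioConfig, replicate_index: int) -> GroupedSample:
    """Draw one replicate sample; a deterministic function of
    ``(config.seed, config.name, replicate_index)``.

    Each observation's p variables are drawn independently from the group's
    distribution. Gamma draws are shifted by −shape·scale when
    ``center_to_zero_mean`` so every group mean vector is 0 and H0 holds.
    """
    ss = np.random.SeedSequence(
        (config.seed, _scenario_key(config.name), replicate_index)
    )
    rng = np.random.default_rng(ss)
    blocks = []
    for k, n in enumerate(config.group_sizes):
        shape_ = (n, config.p)
        if config.family == "gamma":
            x = rng.gamma(config.shapes[k], config.scale, size=shape_)
            if config.center_to_zero_mean:
                x -= config.shapes[k] * config.scale
        elif config.family == "student_t":
            x = rng.standard_t(config.df, size=shape_) * config.scales[k]
        else:
            x = rng.normal(0.0, config.scales[k], size=shape_)
        blocks.append(x)
    return GroupedSample(groups=tuple(blocks))


# ---------------------------------------------------------------------------
# Monte Carlo engine
# ---------------------------------------------------------------------------


def mc_stderr(rate: float, R: int) -> float:
    """Binomial Monte Carlo standard error sqrt(rate(1−rate)/R)."""
    if not (0.0 <= rate <= 1.0):
        raise InvalidInputError(f"rate {rate} outside [0, 1]")
    if R < 1:
        raise InvalidInputError(f"R {R} must be >= 1")
    return math.sqrt(rate * (1.0 - rate) / R)


@dataclass(frozen=True)
class TypeIErrorCell:
    """Per-test rejection counts/rates for one simulation cell, with the
    binomial Monte Carlo standard error of each rate."""

    scenario: str
    distribution: str
    sizes_name: str
    p: int
    alpha: float
    reps: int
    seed: int
    counts: dict[str, int]
    rates: dict[str, float]
    stderr: dict[str, float]
    redraws: int = 0
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.error is not None


def run_scenario(config: ScenarioConfig) -> TypeIErrorCell:
    """Estimate per-test type-I error rates for one scenario.

    For r = 1..reps: draw a sample, run the four-statistic MANOVA, record
    strict p < alpha rejections. A replicate whose within matrix is singular
    is re-drawn with the next substream index; more than 1% re-draws aborts
    the cell (:class:`CellAbortedError`).
    """
    counts = dict.fromkeys(TESTS, 0)
    max_redraws = max(1, int(0.01 * config.reps))
    redraws = 0
    draw_index = 0
    for _ in range(config.reps):
        while True:
            sample = sample_groups(config, draw_index)
            draw_index += 1
            try:
                res = manova_test(sample, config.alpha)
                break
            except SingularWithinError:
                redraws += 1
                if redraws > max_redraws:
                    raise CellAbortedError(
                        f"scenario {config.name}: more than 1% of replicates "
                        f"({redraws}/{config.reps}) drew a singular within matrix"
                    )
        for name in TESTS:
            counts[name] += res.rejects[name]
    if redraws:
        logger.info("scenario %s: %d re-draws", config.name, redraws)
    rates = {t: counts[t] / config.reps for t in TESTS}
    return TypeIErrorCell(
        scenario=config.name,
        distribution=config.distribution,
        sizes_name=config.sizes_name or "-".join(map(str, config.group_sizes)),
        p=config.p,
        alpha=config.alpha,
        reps=config.reps,
        seed=config.seed,
        counts=counts,
        rates=rates,
        stderr={t: mc_stderr(rates[t], config.reps) for t in TESTS},
        redraws=redraws,
    )


def run_grid(
    configs: Sequence[ScenarioConfig], progress: bool = False
) -> list[TypeIErrorCell]:
    """Evaluate every cell independently, in input order.

    A failing cell is returned with its ``error`` set instead of aborting the
    remaining cells. Results depend only on each cell's own substreams, so
    they are identical regardless of execution order.
    """
    cells: list[TypeIErrorCell] = []
    for i, cfg in enumerate(configs):
        try:
            cell = run_scenario(cfg)
        except Exception as exc:  # noqa: BLE001 - per-cell isolation is the contract
            logger.error("scenario %s failed: %s", cfg.name, exc)
            cell = TypeIErrorCell(
                scenario=cfg.name,
                distribution=cfg.distribution,
                sizes_name=cfg.sizes_name or "-".join(map(str, cfg.group_sizes)),
                p=cfg.p,
                alpha=cfg.alpha,
                reps=cfg.reps,
                seed=cfg.seed,
                counts={},
                rates={},
                stderr={},
                error=str(exc),
            )
        cells.append(cell)
        if progress:
            status = "FAILED" if cell.failed else (
                " ".join(
                    f"{TEST_LETTER[t]}={cell.rates[t]:.4f}" for t in TABLE_TEST_ORDER
                )
            )
            logger.info(
                "[%d/%d] %s: %s (redraws=%d)",
                i + 1, len(configs), cfg.name, status, cell.redraws,
            )
    return cells


# ---------------------------------------------------------------------------
# reporting: deviation summaries and table export
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeviationSummary:
    """Per-cell absolute deviations |rate − α| and per-cell winners
    (tests with minimal deviation; ties reported, never silently broken)."""

    alpha: float
    deviations: dict[str, dict[str, float]]  # scenario -> test -> |rate - alpha|
    winners: dict[str, tuple[str, ...]]  # scenario -> argmin test(s)
    tally: Counter = field(default_factory=Counter)  # test -> cells won (ties count)

    def to_text(self) -> str:
        lines = [f"Deviation from nominal alpha = {self.alpha:g}"]
        for scenario, devs in self.deviations.items():
            win = self.winners[scenario]
            tie = " (tie)" if len(win) > 1 else ""
            devtxt = "  ".join(f"{t}={devs[t]:.4f}" for t in TESTS)
            lines.append(f"  {scenario}: {devtxt}  -> closest: {', '.join(win)}{tie}")
        lines.append(
            "Cells won: "
            + ", ".join(f"{t}={self.tally.get(t, 0)}" for t in TESTS)
        )
        return "\n".join(lines)


def deviation_summary(
    cells: Sequence[TypeIErrorCell], alpha: float | None = None
) -> DeviationSummary:
    """Which test sits closest to the nominal level in each cell.

    Raises :class:`InvalidAggregationError` if cells carry mixed nominal
    levels (or disagree with an explicitly supplied ``alpha``).
    """
    cells = [c for c in cells]
    if not cells:
        raise InvalidInputError("no cells to summarize")
    alphas = {c.alpha for c in cells}
    if alpha is not None:
        alphas.add(float(alpha))
    if len(alphas) != 1:
        raise InvalidAggregationError(
            f"cells carry mixed nominal levels: {sorted(alphas)}"
        )
    a = alphas.pop()
    deviations: dict[str, dict[str, float]] = {}
    winners: dict[str, tuple[str, ...]] = {}
    tally: Counter = Counter()
    for c in cells:
        if c.failed:
            continue
        devs = {t: abs(c.rates[t] - a) for t in TESTS}
        dmin = min(devs.values())
        win = tuple(t for t in TESTS if devs[t] == dmin)
        deviations[c.scenario] = devs
        winners[c.scenario] = win
        tally.update(win)
    return DeviationSummary(alpha=a, deviations=deviations, winners=winners, tally=tally)


def cells_to_tidy(cells: Sequence[TypeIErrorCell]) -> pd.DataFrame:
    """One row per (cell, test): scenario, distribution, p, size pattern,
    test, rate, count, reps, SE, seed."""
    rows = []
    for c in cells:
        for t in TESTS:
            rows.append(
                {
                    "scenario": c.scenario,
                    "distribution": c.distribution,
                    "p": c.p,
                    "sizes": c.sizes_name,
                    "test": t,
                    "rate": c.rates.get(t, np.nan),
                    "count": c.counts.get(t, np.nan),
                    "reps": c.reps,
                    "se": c.stderr.get(t, np.nan),
                    "alpha": c.alpha,
                    "seed": c.seed,
                    "redraws": c.redraws,
                    "error": c.error or "",
                }
            )
    cols = [
        "scenario", "distribution", "p", "sizes", "test", "rate", "count",
        "reps", "se", "alpha", "seed", "redraws", "error",
    ]
    return pd.DataFrame(rows, columns=cols)


def cells_from_tidy(source) -> list[TypeIErrorCell]:
    """Rebuild cells from a tidy table (inverse of :func:`cells_to_tidy`).

    ``source`` is a DataFrame or a CSV path; paths are parsed with
    ``float_precision="round_trip"`` so rates survive bit-exactly.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, float_precision="round_trip")
    cells = []
    for scenario, grp in df.groupby("scenario", sort=False):
        by_test = grp.set_index("test")
        first = grp.iloc[0]
        err = str(first.get("error", "")) or None
        if err == "nan":
            err = None
        cells.append(
            TypeIErrorCell(
                scenario=str(scenario),
                distribution=str(first["distribution"]),
                sizes_name=str(first["sizes"]),
                p=int(first["p"]),
                alpha=float(first["alpha"]),
                reps=int(first["reps"]),
                seed=int(first["seed"]),
                counts={} if err else {t: int(by_test.loc[t, "count"]) for t in TESTS},
                rates={} if err else {t: float(by_test.loc[t, "rate"]) for t in TESTS},
                stderr={} if err else {t: float(by_test.loc[t, "se"]) for t in TESTS},
                redraws=int(first["redraws"]),
                error=err,
            )
        )
    return cells


def cells_to_wide_layout(cells: Sequence[TypeIErrorCell]) -> pd.DataFrame:
    """Wide table in the study's layout: rows = size patterns, column blocks
    p=2 then p=3, test order R, P, H, W, one row-group per distribution."""
    ok = [c for c in cells if not c.failed]
    ps = sorted({c.p for c in ok})
    dists = list(dict.fromkeys(c.distribution for c in ok))
    by_key = {(c.distribution, c.p, c.sizes_name): c for c in ok}
    size_order = [s for s in SIZE_PRESETS] + sorted(
        {c.sizes_name for c in ok} - set(SIZE_PRESETS)
    )
    rows = []
    for dist in dists:
        seen_sizes = [
            s for s in size_order if any((dist, p, s) in by_key for p in ps)
        ]
        for s in seen_sizes:
            row: dict = {"distribution": dist, "sizes": s}
            for p in ps:
                cell = by_key.get((dist, p, s))
                for t in TABLE_TEST_ORDER:
                    col = f"p{p}_{TEST_LETTER[t]}"
                    row[col] = cell.rates[t] if cell is not None else np.nan
            rows.append(row)
    cols = ["distribution", "sizes"] + [
        f"p{p}_{TEST_LETTER[t]}" for p in ps for t in TABLE_TEST_ORDER
    ]
    return pd.DataFrame(rows, columns=cols)


def write_table(cells: Sequence[TypeIErrorCell], path, layout: str = "tidy") -> None:
    """Write cells as CSV; ``layout="tidy"`` (full precision, round-trips via
    :func:`cells_from_tidy`) or ``layout="wide"`` (wide, rates to 4 decimals
    as the study's tables print them). Byte-identical for identical inputs.
    """
    if layout == "tidy":
        # default float formatting is the shortest round-trip repr: exact
        df = cells_to_tidy(cells)
        df.to_csv(path, index=False)
    elif layout == "wide":
        df = cells_to_wide_layout(cells)
        df.to_csv(path, index=False, float_format="%.4f")
    else:
        raise InvalidInputError(f"unknown layout {layout!r}")
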