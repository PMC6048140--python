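"""Random connection-weight ensembles with mean 1 and variance sigma^2.

Three distribution families are supported, each parameterised directly by
the target variance ``sigma2`` (the mean is always fixed at 1):

lognormal
    ``sigma_LN^2 = ln(sigma^2 + 1)``, ``mu_LN = -sigma_LN^2 / 2``.
    Fully connected: every entry is strictly positive.

sparse_gaussian
    A point mass ``(1-a)`` at zero plus, with probability ``a``, a
    half-Gaussian (truncated at zero, peaked at zero) of width
    ``sigma_SG = sqrt(2/pi) (sigma^2 + 1)``; the sparseness is
    ``a = (pi/2)/(sigma^2 + 1)``.  Requires ``a <= 1``, i.e.
    ``sigma^2 >= pi/2 - 1``.

sparse_lognormal
    The same point mass at zero plus a lognormal with
    ``sigma_SLN^2 = ln[a (sigma^2 + 1)]`` (= ln(pi/2), independent of
    sigma^2).  Moment matching to mean 1 requires
    ``mu_SLN = ln(1/a) - ln[a (sigma^2+1)]/2``; the algebraically
    inconsistent variant ``ln(1/a) - ln(sigma^2+1)/2`` (which yields mean
    sqrt(a)) is available behind ``literal_mu=True`` for comparison.

In the network, excitatory outgoing blocks (E->E and E->I) use variance
``sigma_E^2`` while inhibitory outgoing blocks (I->E and I->I) use
variance 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "WeightEnsemble",
    "WeightMatrix",
    "MomentReport",
    "sample_weights",
    "sample_weight_matrix",
    "validate_moments",
    "SPARSE_MIN_SIGMA2",
]

Family = Literal["lognormal", "sparse_gaussian", "sparse_lognormal"]

#: smallest admissible variance for the sparse families (a <= 1)
SPARSE_MIN_SIGMA2 = np.pi / 2.0 - 1.0


@dataclass(frozen=True)
class WeightEnsemble:
    """A weight distribution family pinned to mean 1, variance sigma2."""

    family: Family
    sigma2: float
    literal_mu: bool = False  # sparse_lognormal only: uncorrected legacy mu

    def __post_init__(self):
        if self.family not in ("lognormal", "sparse_gaussian", "sparse_lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.family != "lognormal" and self.sigma2 < SPARSE_MIN_SIGMA2:
            raise ValueError(
                f"sparse families require sigma2 >= pi/2 - 1 ~= "
                f"{SPARSE_MIN_SIGMA2:.4f} so that the sparseness a <= 1 "
                f"(got sigma2={self.sigma2})"
            )

    # ---- derived family parameters (closed forms) ----

    @property
    def sparseness(self) -> float:
        """Probability a of a nonzero entry (sparse families; 1 otherwise)."""
        if self.family == "lognormal":
            return 1.0
        return (np.pi / 2.0) / (self.sigma2 + 1.0)

    @property
    def derived(self) -> dict:
        s2 = self.sigma2
        if self.family == "lognormal":
            s2ln = np.log(s2 + 1.0)
            return {"mu_LN": -0.5 * s2ln, "sigma_LN": np.sqrt(s2ln)}
        a = self.sparseness
        if self.family == "sparse_gaussian":
            return {"a": a, "sigma_SG": np.sqrt(2.0 / np.pi) * (s2 + 1.0)}
        s2sln = np.log(a * (s2 + 1.0))  # == ln(pi/2) identically
        if self.literal_mu:
            mu = np.log(1.0 / a) - 0.5 * np.log(s2 + 1.0)
        else:
            mu = np.log(1.0 / a) - 0.5 * s2sln
        return {"a": a, "mu_SLN": mu, "sigma_SLN": np.sqrt(s2sln)}

    @property
    def mean(self) -> float:
        """Analytic mean of the ensemble (1 except literal-mu variant)."""
        if self.family == "sparse_lognormal" and self.literal_mu:
            return float(np.sqrt(self.sparseness))
        return 1.0


def sample_weights(
    ensemble: WeightEnsemble,
    shape,
    seed,
) -> np.ndarray:
    """Draw an i.i.d. block of non-negative weights.

    ``seed`` may be an int, a SeedSequence or a Generator; draws are
    reproducible for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = ensemble.derived
    if ensemble.family == "lognormal":
        return rng.lognormal(d["mu_LN"], d["sigma_LN"], size=shape)
    a = d["a"]
    nz = rng.random(size=shape) < a
    out = np.zeros(shape if isinstance(shape, tuple) else (shape,), dtype=float)
    n_nz = int(nz.sum())
    if ensemble.family == "sparse_gaussian":
        out[nz] = np.abs(rng.normal(0.0, d["sigma_SG"], size=n_nz))
    else:
        out[nz] = rng.lognormal(d["mu_SLN"], d["sigma_SLN"], size=n_nz)
    return out


@dataclass
class MomentReport:
    """Empirical-moment check of a sampled block against its ensemble."""

    n: int
    mean: float
    variance: float
    zero_fraction: float
    target_mean: float
    target_variance: float
    mean_ok: bool
    variance_ok: bool

    @property
    def ok(self) -> bool:
        return self.mean_ok and self.variance_ok


def validate_moments(
    block: np.ndarray,
    target: WeightEnsemble,
    tol_mean_se: float = 5.0,
    tol_var_se: float = 5.0,
) -> MomentReport:
    """Check a sampled block's mean and variance against the ensemble.

    Tolerances are multiples of the standard error of each estimator (both
    shrink as 1/sqrt(n)); the variance SE uses the normal-theory
    approximation with the empirical fourth moment.
    """
    x = np.asarray(block, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty weight block")
    n = x.size
    m = float(x.mean())
    v = float(x.var(ddof=1)) if n > 1 else 0.0
    zf = float(np.mean(x == 0.0))
    tm, tv = target.mean, target.sigma2
    se_mean = np.sqrt(tv / n)
    mu4 = float(np.mean((x - m) ** 4))
    se_var = np.sqrt(max(mu4 - v**2, 0.0) / n) if n > 1 else np.inf
    mean_ok = abs(m - tm) <= tol_mean_se * se_mean
    var_ok = (se_var > 0) and abs(v - tv) <= tol_var_se * se_var
    return MomentReport(
        n=n, mean=m, variance=v, zero_fraction=zf,
        target_mean=tm, target_variance=tv,
        mean_ok=bool(mean_ok), variance_ok=bool(var_ok),
    )


@dataclass
class WeightMatrix:
    """The four recurrent connection blocks of an E/I network.

    ``EE``/``IE`` are drawn with variance sigma_E^2; ``EI``/``II`` with
    variance 1 (fixed).  All entries are non-negative; the sign of a
    connection's effect is carried by the receptor reversal potentials,
    not by J.  Self-connections are included (their effect is O(1/N)).
    """

    EE: np.ndarray  # (N_E, N_E): E <- E
    EI: np.ndarray  # (N_E, N_I): E <- I
    IE: np.ndarray  # (N_I, N_E): I <- E
    II: np.ndarray  # (N_I, N_I): I <- I
    family: Family = "lognormal"
    sigma_E2: float = 1.0
    seed: int | None = field(default=None)

    def __post_init__(self):
        NE = self.EE.shape[0]
        NI = self.II.shape[0]
        expected = {"EE": (NE, NE), "EI": (NE, NI), "IE": (NI, NE), "II": (NI, NI)}
        for name, shape in expected.items():
            blk = getattr(self, name)
            if blk.shape != shape:
                raise ValueError(f"block {name} has shape {blk.shape}, expected {shape}")
            if np.any(blk < 0):
                raise ValueError(f"block {name} contains negative weights")

    @property
    def N_E(self) -> int:
        return self.EE.shape[0]

    @property
    def N_I(self) -> int:
        return self.II.shape[0]


def sample_weight_matrix(
    N_E: int,
    N_I: int,
    family: Family,
    sigma_E2: float,
    seed,
) -> WeightMatrix:
    """Sample all four blocks; EE/IE at sigma_E^2, EI/II at variance 1."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    kids = ss.spawn(4)
    ens_E = WeightEnsemble(family, sigma_E2)
    ens_I = WeightEnsemble(family, 1.0)
    EE = sample_weights(ens_E, (N_E, N_E), np.random.default_rng(kids[0]))
    IE = sample_weights(ens_E, (N_I, N_E), np.random.default_rng(kids[1]))
    EI = sample_weights(ens_I, (N_E, N_I), np.random.default_rng(kids[2]))
    II = sample_weights(ens_I, (N_I, N_I), np.random.default_rng(kids[3]))
    return WeightMatrix(EE=EE, EI=EI, IE=IE, II=II, family=family, sigma_E2=sigma_E2)
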