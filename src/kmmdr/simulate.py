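"""Synthetic data generation for the simulation study.

Emulated conditions
-------------------
Datasets of n subjects genotyped at p independent SNPs in Hardy-Weinberg
equilibrium, where exactly one SNP pair carries a purely epistatic effect:
a 3×3 penetrance table f_ij = P(high risk | SNP1 = i, SNP2 = j) with **no
marginal effects** (HWE-weighted row and column means all equal the
prevalence K) and a prescribed heritability

    h² = Σ_ij p_i p_j (f_ij − K)² / (K (1 − K)),    K = Σ_ij p_i p_j f_ij,

with p_i the HWE genotype frequencies at the scenario's minor allele
frequency.  The latent high-risk state x ~ Bernoulli(f) then drives
survival through either a proportional-hazards model with Weibull baseline
(shape a = 5, scale b = 2; hazard multiplier exp(xβ + zγ), β = 1.2) or a
log-normal accelerated-failure-time model log T = μ + xβ + zγ + σε
(μ = 0, β = −1, σ = 1, ε ~ N(0,1)).  The optional covariate z is standard
normal with effect γ ∈ {0, 1}.  Censoring times are Uniform(0, c) with c
calibrated by Monte-Carlo bisection so the expected censored fraction hits
a target in {0, 0.1, 0.3, 0.5}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classifiers import GenotypeMatrix
from .errors import CalibrationError, InvalidInputError
from .survival_core import SurvivalSample

__all__ = [
    "PenetranceModel",
    "SimulationConfig",
    "hwe_frequencies",
    "generate_penetrance",
    "penetrance_summaries",
    "sample_genotypes",
    "assign_risk",
    "simulate_cox",
    "simulate_aft",
    "calibrate_censoring",
    "build_dataset",
]


def hwe_frequencies(maf: float) -> np.ndarray:
    """HWE genotype frequencies ((1−m)², 2m(1−m), m²) for codes 0, 1, 2."""
    m = float(maf)
    return np.array([(1 - m) ** 2, 2 * m * (1 - m), m * m])


@dataclass(frozen=True)
class PenetranceModel:
    """Purely epistatic two-locus penetrance table.

    ``f[i, j]`` is the probability of the latent high-risk state given
    genotypes (i, j) at the causal pair.  Valid models have all entries in
    [0, 1], HWE-weighted marginals constant across rows and columns (no
    marginal effects), and realized heritability near the ``h2`` target.
    """

    f: np.ndarray
    maf: float
    h2: float
    model_id: str = ""
    realized_h2: float = field(default=np.nan)

    def __post_init__(self):
        f = np.asarray(self.f, dtype=np.float64)
        if f.shape != (3, 3):
            raise InvalidInputError("penetrance table must be 3x3")
        if np.any(f < 0) or np.any(f > 1):
            raise InvalidInputError("penetrance entries must lie in [0, 1]")
        object.__setattr__(self, "f", f)
        if np.isnan(self.realized_h2):
            object.__setattr__(self, "realized_h2", penetrance_summaries(f, self.maf)[1])


def penetrance_summaries(f: np.ndarray, maf: float) -> tuple[float, float, float]:
    """(K, h², marginal-effect norm) of a table under HWE weights.

    The marginal-effect norm is the largest absolute deviation of any
    HWE-weighted row or column marginal penetrance from K; a purely
    epistatic table has norm ~0.
    """
    p = hwe_frequencies(maf)
    w = np.outer(p, p)
    k = float(np.sum(w * f))
    h2 = float(np.sum(w * (f - k) ** 2) / (k * (1 - k))) if 0 < k < 1 else 0.0
    row = f @ p   # E[f | SNP1 = i]
    col = f.T @ p
    norm = float(max(np.abs(row - k).max(), np.abs(col - k).max()))
    return k, h2, norm


def generate_penetrance(
    maf: float,
    h2: float,
    seed: int,
    prevalence: float = 0.5,
    max_tries: int = 2000,
    rel_tol: float = 0.05,
) -> PenetranceModel:
    """Random purely epistatic penetrance table at a target heritability.

    Zero-marginal tables form a 4-dimensional linear space: with u, v any
    vectors HWE-orthogonal to the genotype frequencies (Σ p_i u_i = 0), the
    perturbation Δ = Σ outer(u_r, v_r) has all HWE-weighted row and column
    marginals exactly zero — and hence leaves the prevalence K unchanged.
    The generator draws a random direction Δ in that space, rescales it so
    that Σ p_i p_j Δ_ij² = h²·K(1−K) exactly, and accepts the draw if
    f = K + Δ stays inside [0, 1].  At low MAF and high h² the box
    constraint binds hard: the requested ``prevalence`` is then treated as
    a preference, and the feasible K closest to it is used instead (large
    penetrance deviations need headroom on both sides of K).
    Deterministic for a fixed seed.
    """
    if not (0 < maf <= 0.5):
        raise InvalidInputError("maf must be in (0, 0.5]")
    if not (0 < h2 < 1):
        raise InvalidInputError("h2 must be in (0, 1)")
    if not (0 < prevalence < 1):
        raise InvalidInputError("prevalence must be in (0, 1)")
    p = hwe_frequencies(maf)
    w = np.outer(p, p)

    # orthonormal basis (w.r.t. the p-weighted inner product) of {u : Σ p_i u_i = 0}
    basis = []
    for cand in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        u = cand - np.sum(p * cand)  # remove weighted mean
        for b in basis:
            u = u - np.sum(p * u * b) * b
        u = u / np.sqrt(np.sum(p * u * u))
        basis.append(u)

    k_grid = np.concatenate(([prevalence], np.linspace(0.02, 0.98, 97)))
    k_grid = k_grid[np.argsort(np.abs(k_grid - prevalence), kind="stable")]

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        coef = rng.standard_normal((2, 2))
        direction = sum(
            coef[r, c] * np.outer(basis[r], basis[c])
            for r in range(2)
            for c in range(2)
        )
        var = np.sum(w * direction**2)
        if var <= 0:
            continue
        direction = direction / np.sqrt(var)
        dmin, dmax = direction.min(), direction.max()
        for k in k_grid:
            s = np.sqrt(h2 * k * (1 - k))
            if k + s * dmin >= 0.0 and k + s * dmax <= 1.0:
                model = PenetranceModel(
                    f=k + s * direction, maf=maf, h2=h2,
                    model_id=f"maf{maf:g}_h2{h2:g}_s{seed}",
                )
                if abs(model.realized_h2 - h2) / h2 <= rel_tol:
                    return model
                break  # numerically off-target direction; redraw
    raise CalibrationError(
        f"no feasible penetrance table after {max_tries} draws (maf={maf}, h2={h2})"
    )


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation scenario (see module docstring for the models)."""

    survival_model: str = "cox"          # "cox" or "aft"
    n: int = 400
    p: int = 10
    causal_pair: tuple[int, int] | None = (0, 1)
    maf: float = 0.2
    h2: float = 0.1
    penetrance: PenetranceModel | None = None
    beta: float | None = None            # default 1.2 (cox) / -1.0 (aft)
    gamma: float = 0.0
    sigma: float = 1.0                   # aft error scale
    mu: float = 0.0                      # aft intercept
    shape: float = 5.0                   # cox Weibull baseline shape a
    scale: float = 2.0                   # cox Weibull baseline scale b
    censoring_fraction: float = 0.0
    censoring_bound: float | None = None  # precomputed c; None = calibrate
    seed: int = 0

    def __post_init__(self):
        if self.survival_model not in ("cox", "aft"):
            raise InvalidInputError("survival_model must be 'cox' or 'aft'")
        if self.n < 1:
            raise InvalidInputError("n must be positive")
        if not (0 <= self.censoring_fraction < 1):
            raise InvalidInputError("censoring_fraction must be in [0, 1)")
        if self.causal_pair is not None:
            a, b = self.causal_pair
            if a == b or not (0 <= a < self.p and 0 <= b < self.p):
                raise InvalidInputError("causal pair indices must be distinct and < p")
        if self.beta is None:
            object.__setattr__(
                self, "beta", 1.2 if self.survival_model == "cox" else -1.0
            )


def sample_genotypes(n: int, p: int, mafs, seed: int) -> GenotypeMatrix:
    """HWE/LE genotypes: entries Binomial(2, maf) independently per SNP."""
    mafs = np.broadcast_to(np.asarray(mafs, dtype=np.float64), (p,))
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise InvalidInputError("each maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    values = rng.binomial(2, mafs, size=(n, p)).astype(np.int8)
    return GenotypeMatrix(
        values,
        tuple(f"SNP{j + 1}" for j in range(p)),
        tuple(f"S{i + 1}" for i in range(n)),
    )


def assign_risk(
    pair_genotypes: np.ndarray, pen: PenetranceModel, seed: int
) -> np.ndarray:
    """Latent high-risk state x_i ~ Bernoulli(f[g1_i, g2_i])."""
    g = np.asarray(pair_genotypes)
    rng = np.random.default_rng(seed)
    probs = pen.f[g[:, 0], g[:, 1]]
    return (rng.random(g.shape[0]) < probs).astype(np.int8)


def _cox_latent(rng, x, z, cfg: SimulationConfig) -> np.ndarray:
    eta = cfg.beta * x + cfg.gamma * z
    u = rng.random(x.shape[0])
    return cfg.scale * (-np.log(u) / np.exp(eta)) ** (1.0 / cfg.shape)


def _aft_latent(rng, x, z, cfg: SimulationConfig) -> np.ndarray:
    eps = rng.standard_normal(x.shape[0])
    return np.exp(cfg.mu + cfg.beta * x + cfg.gamma * z + cfg.sigma * eps)


def _apply_censoring(rng, latent, cfg: SimulationConfig, z) -> SurvivalSample:
    cov = None if cfg.gamma == 0 else z.reshape(-1, 1)
    if cfg.censoring_fraction == 0:
        return SurvivalSample(latent, np.ones(latent.shape[0], dtype=np.int8), cov)
    c = cfg.censoring_bound
    if c is None:
        gen = _cox_latent if cfg.survival_model == "cox" else _aft_latent
        c = calibrate_censoring(
            cfg.censoring_fraction,
            lambda r, size: gen(
                r,
                _marginal_x(r, size, cfg),
                r.standard_normal(size) if cfg.gamma != 0 else np.zeros(size),
                cfg,
            ),
            seed=cfg.seed,
        )
    cens = rng.uniform(0, c, latent.shape[0])
    time = np.minimum(latent, cens)
    status = (latent <= cens).astype(np.int8)
    return SurvivalSample(time, status, cov)


def _marginal_x(rng, size: int, cfg: SimulationConfig) -> np.ndarray:
    """Draws of the high-risk state from its marginal distribution."""
    if cfg.causal_pair is None or cfg.penetrance is None:
        return np.zeros(size)
    p = hwe_frequencies(cfg.maf)
    k = float(np.sum(np.outer(p, p) * cfg.penetrance.f))
    return (rng.random(size) < k).astype(np.float64)


def simulate_cox(x, z, cfg: SimulationConfig) -> SurvivalSample:
    """Survival from λ(t | x, z) = λ₀(t)·exp(xβ + zγ) with Weibull baseline.

    λ₀ is the hazard of a Weibull with shape a and scale b (survival
    exp(−(t/b)^a)), so the latent time is T = b·(−log U / exp(xβ + zγ))^{1/a}.
    """
    if cfg.survival_model != "cox":
        raise InvalidInputError("config must have survival_model='cox'")
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(x, dtype=np.float64)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=np.float64)
    latent = _cox_latent(rng, x, z, cfg)
    return _apply_censoring(rng, latent, cfg, z)


def simulate_aft(x, z, cfg: SimulationConfig) -> SurvivalSample:
    """Survival from log T = μ + xβ + zγ + σε with standard-normal ε."""
    if cfg.survival_model != "aft":
        raise InvalidInputError("config must have survival_model='aft'")
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(x, dtype=np.float64)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=np.float64)
    latent = _aft_latent(rng, x, z, cfg)
    return _apply_censoring(rng, latent, cfg, z)


def calibrate_censoring(
    target_fraction: float,
    latent_sampler,
    seed: int = 0,
    n_draws: int = 100_000,
    tol: float = 0.005,
) -> float | None:
    """Upper bound c of a Uniform(0, c) censoring law hitting a target
    expected censored fraction.

    With C ~ U(0, c), P(censored | T) = min(T, c)/c, so the expected
    fraction is E[min(T, c)]/c — strictly decreasing in c — estimated from
    one batch of latent draws and solved by bisection.  Returns None for a
    target of zero (no censoring).

    ``latent_sampler(rng, size)`` must return latent event times drawn from
    the scenario's marginal time distribution.
    """
    if not (0 <= target_fraction < 1):
        raise InvalidInputError("target fraction must be in [0, 1)")
    if target_fraction == 0:
        return None
    rng = np.random.default_rng(seed)
    t = np.sort(latent_sampler(rng, n_draws))

    def frac(c):
        return float(np.mean(np.minimum(t, c)) / c)

    lo = float(t[0]) * 0.5 + 1e-12
    hi = float(t[-1]) * 2 + 1e-9
    if frac(hi) > target_fraction:
        # heavier censoring than U(0, 2·max T) can produce
        hi *= 1000
    f_lo, f_hi = frac(lo), frac(hi)
    if not (f_hi <= target_fraction <= f_lo):
        raise CalibrationError(
            f"target {target_fraction} outside achievable range",
            achievable=(f_hi, f_lo),
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target_fraction:
            lo = mid
        else:
            hi = mid
        if abs(frac(mid) - target_fraction) < tol * 0.2:
            break
    return 0.5 * (lo + hi)


def build_dataset(cfg: SimulationConfig):
    """Compose genotypes → latent risk → survival for one dataset.

    Returns (GenotypeMatrix, SurvivalSample, truth) where ``truth`` records
    the causal pair, the latent high-risk states, the realized censoring
    bound and the config.  A ``causal_pair`` of None builds a null dataset
    (x ≡ 0, survival independent of every SNP).
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_geno, s_risk, s_surv = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    genotypes = sample_genotypes(cfg.n, cfg.p, cfg.maf, s_geno)

    pen = cfg.penetrance
    if cfg.causal_pair is not None:
        if pen is None:
            pen = generate_penetrance(cfg.maf, cfg.h2, seed=s_risk)
        x = assign_risk(genotypes.values[:, list(cfg.causal_pair)], pen, s_risk)
    else:
        x = np.zeros(cfg.n, dtype=np.int8)

    rng_z = np.random.default_rng(s_surv)
    z = rng_z.standard_normal(cfg.n) if cfg.gamma != 0 else np.zeros(cfg.n)

    sim_cfg = replace(cfg, seed=s_surv, penetrance=pen)
    if cfg.survival_model == "cox":
        sample = simulate_cox(x, z, sim_cfg)
    else:
        sample = simulate_aft(x, z, sim_cfg)

    truth = {
        "causal_pair": cfg.causal_pair,
        "x": x,
        "penetrance": pen,
        "censoring_bound": sim_cfg.censoring_bound,
        "config": cfg,
    }
    return genotypes, sample, truth
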