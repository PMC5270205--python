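"""Synthetic lipid-panel cohorts with the dependence structure the
LDL-window analysis assumes.

Subject-level data for the three study cohorts were never deposited, so
this module generates cohorts that reproduce the published *summary*
structure: per-cohort means/SDs of every panel measure, the healthy-
cohort regression non-HDL-C = 1.404·apoB + 9.48 (R² = 0.94), a
log-normal TG distribution (the printed SD ≈ 0.7 × mean implies strong
right skew), the inverse TG–LDL-size correlation (target r = −0.52 on
the raw TG scale), the positive LDL-C/apoB-ratio–size correlation
(target +0.44), and the accounting hierarchy
sdLDL-C ≤ LDL-C ≤ non-HDL-C < total-C, which holds by construction.

Generation recipe (deterministic given ``(model, n, seed)``):

1. draw correlated standard-normal latents (z_apob, z_logtg, z_hdl,
   z_ratio, z_size) from the model's latent correlation matrix;
2. apoB, HDL-C, LDL size are affine in their latents; TG is
   exp(μ + σ·z_logtg) with (μ, σ) moment-matched to the target mean/SD;
3. non-HDL-C = slope·apoB + intercept + ε, with Var(ε) set so the
   population R² equals the configured value; total-C = non-HDL-C + HDL-C;
4. LDL-C = apoB × (LDL-C/apoB ratio); rows where LDL-C would exceed
   non-HDL-C redraw z_ratio from its conditional distribution given the
   other latents (a mild truncation, ~3–4 % of rows);
5. sdLDL-C = LDL-C × logistic(b0 + b_apob·z_apob + b_tg·z_logtg + noise),
   so 0 < sdLDL-C < LDL-C always;
6. any residual invariant violation (e.g. size outside its plausibility
   band) redraws the whole row, with a bounded retry budget.

Latent cross-correlations not identified by published numbers
(apoB–TG ≈ 0.3, HDL–logTG ≈ −0.4, and the smaller ones below) are
realism defaults, NOT study-derived; they are ordinary model fields and
can be varied in sensitivity analyses.  The sdLDL coupling coefficients
shipped with the presets were produced by :func:`calibrate_sdldl_coupling`
so that each cohort hits its published sdLDL-C mean and the
hyper-TG/-apoB group is strongly enriched in the top sdLDL-C quartile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from . import reference
from .panels import LDL_SIZE_BAND_NM, validate_panels
from .quartiles import compute_quartiles, QuartileScheme, assign_quartile
from .window import WindowConfig, classify_cohort

_MAX_RETRY_ROUNDS = 100


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a target mean and SD → (mu, sigma)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2, math.sqrt(sigma2)


@dataclass(frozen=True)
class SdldlCoupling:
    """Logistic coefficients for the sdLDL fraction of LDL-C:
    fraction = logistic(b0 + b_apob·z_apob + b_tg·z_logtg + N(0, noise_sd))."""

    b0: float
    b_apob: float
    b_tg: float
    noise_sd: float


@dataclass(frozen=True)
class CohortModel:
    """Distributional model of one cohort's lipid panels.

    SDs may be zero (degenerate/noise-free limits are legal and used in
    consistency tests); correlations must lie in (−1, 1) and the implied
    latent correlation matrix must be positive definite, which is
    checked at construction via :meth:`latent_correlation`.
    """

    label: str
    n_default: int
    # marginal moments (mg/dL except size in nm)
    apob_mean: float
    apob_sd: float
    tg_mean: float
    tg_sd: float
    hdl_mean: float
    hdl_sd: float
    size_mean: float
    size_sd: float
    ldl_apob_ratio_mean: float
    ldl_apob_ratio_sd: float
    # non-HDL-C ~ apoB structural link
    reg_slope: float
    reg_intercept: float
    reg_r2: float
    # dependence targets / assumptions (latent-scale unless noted)
    apob_tg_corr: float = 0.30      # assumption, not study-derived
    hdl_tg_corr: float = -0.40      # assumption, not study-derived
    apob_hdl_corr: float = -0.20    # assumption, not study-derived
    apob_ratio_corr: float = -0.15  # assumption, not study-derived
    apob_size_corr: float = -0.25   # assumption, not study-derived
    tg_ratio_corr: float = -0.35    # assumption, not study-derived
    hdl_ratio_corr: float = 0.15    # assumption, not study-derived
    hdl_size_corr: float = 0.25     # assumption, not study-derived
    size_tg_corr: float = -0.52     # target Pearson r on the raw TG scale
    ratio_size_corr: float = 0.44   # target Pearson r
    sdldl_coupling: SdldlCoupling = field(
        default_factory=lambda: SdldlCoupling(-1.29, 0.2, 0.35, 0.2))
    # demographics (do not feed the lipid model)
    p_male: float = 0.5
    age_mean: float = 50.0
    age_sd: float = 12.0
    p_diabetes: float = 0.0
    hba1c_jds_mean: float | None = None
    hba1c_jds_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("apob_sd", "tg_sd", "hdl_sd", "size_sd",
                     "ldl_apob_ratio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.reg_r2 <= 1:
            raise ValueError("reg_r2 must lie in (0, 1]")
        self.latent_correlation()  # raises if not positive definite

    # --- derived generation parameters -------------------------------
    @property
    def log_tg_mean(self) -> float:
        return lognormal_params(self.tg_mean, self.tg_sd)[0]

    @property
    def log_tg_sd(self) -> float:
        return lognormal_params(self.tg_mean, self.tg_sd)[1]

    @property
    def reg_resid_sd(self) -> float:
        """SD of ε in non-HDL-C = slope·apoB + intercept + ε such that
        the population R² equals ``reg_r2``."""
        signal_sd = abs(self.reg_slope) * self.apob_sd
        return signal_sd * math.sqrt((1 - self.reg_r2) / self.reg_r2)

    @property
    def latent_size_tg_corr(self) -> float:
        """Latent z_logtg–z_size correlation producing the target raw-scale
        corr(TG, size): for TG = exp(μ+σZ), corr(TG, size) = ρ·σ/√(e^{σ²}−1),
        so ρ = target · √(e^{σ²}−1)/σ = target · CV/σ."""
        sigma = self.log_tg_sd
        if sigma == 0 or self.size_sd == 0:
            return 0.0
        cv = math.sqrt(math.expm1(sigma ** 2))
        rho = self.size_tg_corr * cv / sigma
        if abs(rho) >= 1:
            raise ValueError("size_tg_corr target infeasible for this TG skew")
        return rho

    def latent_correlation(self) -> np.ndarray:
        """5×5 latent correlation matrix, order
        (z_apob, z_logtg, z_hdl, z_ratio, z_size); checked positive definite."""
        c = np.eye(5)
        pairs = {
            (0, 1): self.apob_tg_corr, (0, 2): self.apob_hdl_corr,
            (0, 3): self.apob_ratio_corr, (0, 4): self.apob_size_corr,
            (1, 2): self.hdl_tg_corr, (1, 3): self.tg_ratio_corr,
            (1, 4): self.latent_size_tg_corr, (2, 3): self.hdl_ratio_corr,
            (2, 4): self.hdl_size_corr, (3, 4): self.ratio_size_corr,
        }
        for (i, j), rho in pairs.items():
            if not -1 < rho < 1:
                raise ValueError(f"latent correlation ({i},{j})={rho} outside (−1, 1)")
            c[i, j] = c[j, i] = rho
        if np.linalg.eigvalsh(c).min() <= 1e-10:
            raise ValueError("latent correlation matrix is not positive definite")
        return c

    def with_coupling(self, coupling: SdldlCoupling) -> "CohortModel":
        return replace(self, sdldl_coupling=coupling)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _conditional_ratio_weights(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Weights and SD of z_ratio | (other four latents)."""
    rest = [0, 1, 2, 4]
    s_rr = corr[np.ix_(rest, rest)]
    s_3r = corr[3, rest]
    w = np.linalg.solve(s_rr, s_3r)
    var = 1.0 - s_3r @ w
    return w, math.sqrt(max(var, 0.0))


def _draw_lipids(model: CohortModel, n: int, rng: np.random.Generator,
                 chol: np.ndarray, corr: np.ndarray) -> pd.DataFrame:
    z = rng.standard_normal((n, 5)) @ chol.T
    apob = model.apob_mean + model.apob_sd * z[:, 0]
    tg = np.exp(model.log_tg_mean + model.log_tg_sd * z[:, 1])
    hdl = model.hdl_mean + model.hdl_sd * z[:, 2]
    size = model.size_mean + model.size_sd * z[:, 4]
    eps = rng.normal(0.0, model.reg_resid_sd, n) if model.reg_resid_sd > 0 else np.zeros(n)
    non_hdl = model.reg_slope * apob + model.reg_intercept + eps
    total = non_hdl + hdl

    # LDL-C = apoB × ratio must not exceed non-HDL-C.  Violating rows
    # redraw z_ratio from its conditional distribution given the other
    # latents, truncated to the feasible ratio interval (exact inverse-CDF
    # sampling).  Rows whose feasible interval carries negligible mass are
    # marked invalid and fall through to the full-row redraw.
    ratio = model.ldl_apob_ratio_mean + model.ldl_apob_ratio_sd * z[:, 3]
    bad = (apob * ratio > non_hdl) | (ratio <= 0)
    if bad.any():
        if model.ldl_apob_ratio_sd == 0:
            raise RuntimeError("cannot satisfy LDL-C ≤ non-HDL-C with a degenerate ratio")
        w, cond_sd = _conditional_ratio_weights(corr)
        cond_mean = (z[:, [0, 1, 2, 4]] @ w)[bad]
        z_hi = ((non_hdl[bad] / apob[bad] - model.ldl_apob_ratio_mean)
                / model.ldl_apob_ratio_sd)
        z_lo = -model.ldl_apob_ratio_mean / model.ldl_apob_ratio_sd
        a = ndtr((z_lo - cond_mean) / cond_sd) if cond_sd > 0 else np.zeros(bad.sum())
        b = ndtr((z_hi - cond_mean) / cond_sd) if cond_sd > 0 else np.zeros(bad.sum())
        mass = b - a
        feasible = mass > 1e-12
        z_new = np.full(int(bad.sum()), np.nan)
        u = rng.random(int(bad.sum()))
        z_new[feasible] = cond_mean[feasible] + cond_sd * ndtri(
            a[feasible] + u[feasible] * mass[feasible])
        new_ratio = model.ldl_apob_ratio_mean + model.ldl_apob_ratio_sd * z_new
        new_ratio[~feasible] = -1.0  # forces full-row redraw via ldl_c <= 0
        ratio[bad] = new_ratio
    ldl = apob * ratio

    cp = model.sdldl_coupling
    noise = rng.normal(0.0, cp.noise_sd, n) if cp.noise_sd > 0 else np.zeros(n)
    frac = expit(cp.b0 + cp.b_apob * z[:, 0] + cp.b_tg * z[:, 1] + noise)
    sdldl = ldl * frac

    return pd.DataFrame({
        "total_c": total, "hdl_c": hdl, "tg": tg, "ldl_c": ldl,
        "sdldl_c": sdldl, "apob": apob, "ldl_size": size,
    })


def _row_violations(frame: pd.DataFrame) -> np.ndarray:
    lo, hi = LDL_SIZE_BAND_NM
    bad = np.zeros(len(frame), dtype=bool)
    for col in ("total_c", "hdl_c", "tg", "ldl_c", "sdldl_c", "apob"):
        bad |= frame[col].to_numpy() <= 0
    bad |= frame["hdl_c"].to_numpy() >= frame["total_c"].to_numpy()
    bad |= (frame["ldl_c"].to_numpy()
            > frame["total_c"].to_numpy() - frame["hdl_c"].to_numpy())
    size = frame["ldl_size"].to_numpy()
    bad |= (size < lo) | (size > hi)
    return bad


def generate_cohort(model: CohortModel, n: int | None = None,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate ``n`` valid lipid panels from a cohort model.

    Returns a frame in canonical panel-column order that passes every
    panel invariant (asserted before returning).  Deterministic given
    ``(model, n, seed)``; ``seed`` defaults to ``model.seed``.
    """
    n = model.n_default if n is None else int(n)
    if n < 1:
        raise ValueError("n must be at least 1")
    seed = model.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    corr = model.latent_correlation()
    chol = np.linalg.cholesky(corr)

    lipids = _draw_lipids(model, n, rng, chol, corr)
    for _ in range(_MAX_RETRY_ROUNDS):
        bad = _row_violations(lipids)
        if not bad.any():
            break
        redraw = _draw_lipids(model, int(bad.sum()), rng, chol, corr)
        lipids.loc[bad, :] = redraw.to_numpy()
    else:
        raise RuntimeError(
            "retry budget exhausted; a panel invariant (positivity, "
            "HDL < total-C, or the LDL size band) is persistently violated")

    sex = np.where(rng.random(n) < model.p_male, "M", "F")
    age = np.clip(np.round(rng.normal(model.age_mean, model.age_sd, n)), 18, 100)
    diabetes = rng.random(n) < model.p_diabetes
    if model.hba1c_jds_mean is not None:
        hba1c = np.round(np.clip(
            rng.normal(model.hba1c_jds_mean, model.hba1c_jds_sd, n), 4.0, 15.0), 1)
    else:
        hba1c = np.full(n, np.nan)

    out = pd.DataFrame({
        "subject_id": [f"{model.label}-{i + 1:05d}" for i in range(n)],
        "cohort": model.label,
        "age": age.astype(int),
        "sex": sex,
        "diabetes": diabetes,
        **{c: lipids[c].to_numpy() for c in
           ("total_c", "hdl_c", "tg", "ldl_c", "sdldl_c", "apob", "ldl_size")},
        "hba1c_jds": hba1c,
    })
    return validate_panels(out)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset(label: str, coupling: SdldlCoupling, reg_intercept: float | None,
            reg_r2: float | None, ratio_mean_shift: float = 0.0,
            hba1c_mean: float | None = None) -> CohortModel:
    s = reference.COHORT_STATS[label]
    slope = reference.NONHDL_ON_APOB["slope"]
    apob_m, apob_sd = s["apob"]
    if reg_intercept is None:  # moment-match the cohort's non-HDL-C mean
        reg_intercept = s["non_hdl_c"][0] - slope * apob_m
    if reg_r2 is None:  # moment-match the cohort's non-HDL-C SD
        reg_r2 = min((slope * apob_sd) ** 2 / s["non_hdl_c"][1] ** 2, 0.99)
    return CohortModel(
        label=label, n_default=s["n"],
        apob_mean=apob_m, apob_sd=apob_sd,
        tg_mean=s["tg"][0], tg_sd=s["tg"][1],
        hdl_mean=s["hdl_c"][0], hdl_sd=s["hdl_c"][1],
        size_mean=s["ldl_size"][0], size_sd=s["ldl_size"][1],
        # the LDL-C ≤ non-HDL-C truncation trims the upper ratio tail and
        # pulls the realised mean ratio below the configured one; the shift
        # (solved by simulation) restores the published cohort mean
        ldl_apob_ratio_mean=s["ldl_apob_ratio"][0] + ratio_mean_shift,
        ldl_apob_ratio_sd=s["ldl_apob_ratio"][1],
        reg_slope=slope, reg_intercept=reg_intercept, reg_r2=reg_r2,
        # latent value chosen so the realised corr(LDL-C/apoB, size) lands
        # near the +0.44 target after the same truncation
        ratio_size_corr=0.48,
        sdldl_coupling=coupling,
        p_male=s["male"] / s["n"],
        age_mean=s["age"][0], age_sd=s["age"][1],
        p_diabetes=s["diabetes_n"] / s["n"],
        hba1c_jds_mean=hba1c_mean,
    )


def cohort_preset(label: str) -> CohortModel:
    """Preset model for ``healthy``, ``diabetes`` or ``cad``.

    The healthy preset carries the published regression (intercept 9.48,
    R² 0.94); the patient presets moment-match their published non-HDL-C
    mean/SD under the same slope.  Coupling coefficients are the output
    of :func:`calibrate_sdldl_coupling` against each cohort's published
    sdLDL-C mean, fraction SD and Q4 enrichment (frozen here so presets
    are static).
    """
    presets = {
        "healthy": dict(coupling=SdldlCoupling(-1.380, 0.10, 0.35, 0.34),
                        reg_intercept=reference.NONHDL_ON_APOB["intercept"],
                        reg_r2=reference.NONHDL_ON_APOB["r_squared"],
                        ratio_mean_shift=0.016),
        "diabetes": dict(coupling=SdldlCoupling(-0.9408, 0.10, 0.45, 0.55),
                         reg_intercept=None, reg_r2=None,
                         ratio_mean_shift=0.025, hba1c_mean=7.2),
        "cad": dict(coupling=SdldlCoupling(-0.9918, 0.05, 0.40, 0.63),
                    reg_intercept=None, reg_r2=None, ratio_mean_shift=0.023),
    }
    if label not in presets:
        raise ValueError(f"unknown cohort preset {label!r}")
    return _preset(label, **presets[label])


def generate_study(n_per_cohort: dict[str, int] | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """All three preset cohorts in one frame (study-sized by default)."""
    frames = []
    for i, label in enumerate(reference.COHORTS):
        model = cohort_preset(label)
        n = (n_per_cohort or {}).get(label, model.n_default)
        frames.append(generate_cohort(model, n=n, seed=seed + i))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    model: CohortModel
    achieved_q4_share: float
    achieved_sdldl_mean: float
    quartile_shares: tuple[float, float, float, float]


def calibrate_intercept(model: CohortModel, target_sdldl_mean: float,
                        n: int = 50_000, seed: int = 12345,
                        tol: float = 0.05) -> CohortModel:
    """Solve the coupling intercept b0 so the simulated cohort hits a
    target mean sdLDL-C (bisection with common random numbers)."""
    def mean_at(b0: float) -> float:
        m = model.with_coupling(replace(model.sdldl_coupling, b0=b0))
        return float(generate_cohort(m, n=n, seed=seed)["sdldl_c"].mean())

    lo, hi = -4.0, 1.0
    if not mean_at(lo) < target_sdldl_mean < mean_at(hi):
        raise ValueError("target sdLDL-C mean outside the reachable range")
    for _ in range(60):
        mid = (lo + hi) / 2
        if mean_at(mid) < target_sdldl_mean:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-4:
            break
    b0 = round((lo + hi) / 2, 4)
    out = model.with_coupling(replace(model.sdldl_coupling, b0=b0))
    achieved = mean_at(b0)
    if abs(achieved - target_sdldl_mean) > tol * target_sdldl_mean:
        raise ValueError(f"calibration did not converge: mean {achieved:.2f} "
                         f"vs target {target_sdldl_mean:.2f}")
    return out


def hyper_group_quartile_shares(panels: pd.DataFrame,
                                scheme: QuartileScheme | None = None,
                                config: WindowConfig = WindowConfig(),
                                ) -> tuple[float, float, float, float]:
    """Q1..Q4 shares (fractions) of the hyper-TG/-apoB group; the scheme
    defaults to quartiles computed from the cohort itself."""
    scheme = scheme or compute_quartiles(panels["sdldl_c"].to_numpy())
    assigned = classify_cohort(panels, config)
    hyper = assigned[assigned["window_group"] == "hyper_tg_b"]
    if len(hyper) == 0:
        return (0.0, 0.0, 0.0, 0.0)
    q = assign_quartile(hyper["sdldl_c"].to_numpy(), scheme)
    return tuple(float((q == lab).mean()) for lab in ("Q1", "Q2", "Q3", "Q4"))


def calibrate_sdldl_coupling(model: CohortModel,
                             target_sdldl_mean: float,
                             q4_share_min: float = 0.85,
                             candidates: list[tuple[float, float, float]] | None = None,
                             n: int = 50_000, seed: int = 12345,
                             scheme: QuartileScheme | None = None,
                             ) -> CalibrationResult:
    """Search coupling slopes (b_apob, b_tg, noise_sd) whose simulated
    hyper-TG/-apoB group is Q4-enriched at least to ``q4_share_min``,
    re-solving b0 at each candidate to preserve the cohort sdLDL-C mean.

    Candidates default to the model's current slopes followed by a small
    outward grid.  Raises with the best-found share if no candidate
    reaches the band; ``q4_share_min = 0`` returns the (recalibrated)
    current coefficients immediately.
    """
    cp = model.sdldl_coupling
    if candidates is None:
        candidates = [(cp.b_apob, cp.b_tg, cp.noise_sd)] + [
            (ba, bt, cp.noise_sd)
            for bt in (0.35, 0.45, 0.55, 0.65)
            for ba in (0.15, 0.20, 0.25, 0.30)
            if (ba, bt) != (cp.b_apob, cp.b_tg)]
    best: CalibrationResult | None = None
    for b_apob, b_tg, noise_sd in candidates:
        trial = model.with_coupling(SdldlCoupling(cp.b0, b_apob, b_tg, noise_sd))
        trial = calibrate_intercept(trial, target_sdldl_mean, n=n, seed=seed)
        panels = generate_cohort(trial, n=n, seed=seed)
        shares = hyper_group_quartile_shares(panels, scheme=scheme)
        result = CalibrationResult(
            model=trial, achieved_q4_share=shares[3],
            achieved_sdldl_mean=float(panels["sdldl_c"].mean()),
            quartile_shares=shares)
        if best is None or result.achieved_q4_share > best.achieved_q4_share:
            best = result
        if result.achieved_q4_share >= q4_share_min:
            return result
    raise ValueError(
        f"no candidate reached Q4 share ≥ {q4_share_min}; "
        f"best found {best.achieved_q4_share:.3f} with coupling {best.model.sdldl_coupling}")
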