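"""FRET analysis of Mg2+-induced k-turn folding.

Folding of a k-turn kinks the helical axis and brings terminally attached
donor (fluorescein) and acceptor (Cy3) fluorophores closer together, raising
the FRET efficiency E_FRET.  Titrating Mg2+ and following E_FRET therefore
reports on ion-induced folding, which is modelled as a simple two-state
process in which the folded fraction tracks single-site binding:

    E_FRET([Mg2+]) = E0 + dE * KA [Mg2+] / (1 + KA [Mg2+])

with E0 the efficiency without added ions, dE the increase at saturation,
and KA the apparent association constant (headline number: apparent
Kd = 1/KA, reported in molar units internally).

The module provides the isotherm itself (:func:`model_efret`), spectral
pre-processing (least-squares deconvolution of a doubly-labelled emission
spectrum onto donor-only/acceptor-only references, and the acceptor
(ratio)A normalization that converts acceptor amplitudes and extinction
ratios into E_FRET), nonlinear fitting (:func:`fit_two_state`, backed by
lmfit Levenberg-Marquardt), an optional bootstrap for Kd intervals, and a
seeded synthetic-titration generator for parameter-recovery studies.

Fits are unweighted by default; a per-point sigma column may be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Model

from .core import KTurnError

__all__ = [
    "FretError",
    "EmissionSpectrum",
    "AbsorbanceRatios",
    "TitrationPoint",
    "TwoStateFit",
    "model_efret",
    "deconvolute_spectrum",
    "efret_acceptor_ratio",
    "fit_two_state",
    "bootstrap_kd",
    "simulate_titration",
    "recovery_study",
    "read_titration_csv",
    "write_titration_csv",
]


class FretError(KTurnError, ValueError):
    """Invalid input to the FRET analysis routines."""


# ---------------------------------------------------------------------------
# data containers


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum with excitation metadata.

    ``label`` distinguishes donor-only / acceptor-only reference species from
    the doubly-labelled construct.  Wavelengths are nm, intensities arbitrary
    units on a strictly increasing grid.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    excitation_nm: float
    label: str = "doubly-labelled"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or it.shape != wl.shape:
            raise FretError("wavelength and intensity must be 1-D arrays of equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise FretError("wavelength grid must be strictly increasing with >= 2 points")
        if not np.all(np.isfinite(it)):
            raise FretError("intensities must be finite")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)


@dataclass(frozen=True)
class AbsorbanceRatios:
    """Relative extinction coefficients needed for acceptor normalization.

    All three are positive and may be given as dimensionless ratios:
    acceptor extinction at the donor-excitation and acceptor-excitation
    wavelengths, and donor extinction at the donor-excitation wavelength.
    """

    eps_A_at_donor_ex: float
    eps_A_at_acceptor_ex: float
    eps_D_at_donor_ex: float

    def __post_init__(self) -> None:
        for name in ("eps_A_at_donor_ex", "eps_A_at_acceptor_ex", "eps_D_at_donor_ex"):
            if not getattr(self, name) > 0:
                raise FretError(f"{name} must be > 0")


@dataclass(frozen=True)
class TitrationPoint:
    """One titration observation: Mg2+ concentration (M) and E_FRET."""

    mg_conc: float
    efret: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.mg_conc < 0:
            raise FretError(f"negative Mg2+ concentration {self.mg_conc}")
        if not (-0.1 <= self.efret <= 1.1):
            raise FretError(f"E_FRET {self.efret} outside the plausible [-0.1, 1.1] band")


@dataclass(frozen=True)
class TwoStateFit:
    """Result of fitting the two-state isotherm.

    ``kd`` is always 1/``ka`` (molar).  ``converged`` is the optimizer flag;
    ``identifiable`` is False when the curvature around the optimum cannot
    support standard errors (e.g. a flat titration).  ``warnings`` carries
    soft diagnostics such as a non-positive fitted dE.
    """

    e0: float
    de: float
    ka: float
    kd: float
    e0_stderr: float | None
    de_stderr: float | None
    ka_stderr: float | None
    rss: float
    converged: bool
    identifiable: bool = True
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "E0": self.e0,
            "dE_FRET": self.de,
            "KA_per_M": self.ka,
            "Kd_M": self.kd,
            "E0_stderr": self.e0_stderr,
            "dE_stderr": self.de_stderr,
            "KA_stderr": self.ka_stderr,
            "rss": self.rss,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# the isotherm


def model_efret(e0: float, de: float, ka: float, mg_conc) -> np.ndarray | float:
    """Two-state folding isotherm: E0 + dE*KA[Mg2+]/(1 + KA[Mg2+]).

    ``mg_conc`` (molar) may be a scalar or array; KA must be positive.
    """
    if not ka > 0:
        raise FretError(f"KA must be > 0, got {ka}")
    mg = np.asarray(mg_conc, dtype=float)
    if np.any(mg < 0):
        raise FretError("Mg2+ concentrations must be >= 0")
    out = e0 + de * ka * mg / (1.0 + ka * mg)
    return float(out) if np.isscalar(mg_conc) else out


# ---------------------------------------------------------------------------
# spectral path


def deconvolute_spectrum(
    doubly: EmissionSpectrum,
    donor_ref: EmissionSpectrum,
    acceptor_ref: EmissionSpectrum,
    collinearity_tol: float = 1e-6,
) -> tuple[float, float, float]:
    """Decompose a doubly-labelled spectrum into reference amplitudes.

    Solves min ||doubly - a_D*donor_ref - a_A*acceptor_ref||^2 over the
    wavelength grid of the doubly-labelled spectrum (references interpolated
    onto it over the common range).  Returns (a_D, a_A, residual_norm).
    """
    lo = max(doubly.wavelength_nm[0], donor_ref.wavelength_nm[0], acceptor_ref.wavelength_nm[0])
    hi = min(doubly.wavelength_nm[-1], donor_ref.wavelength_nm[-1], acceptor_ref.wavelength_nm[-1])
    mask = (doubly.wavelength_nm >= lo) & (doubly.wavelength_nm <= hi)
    if mask.sum() < 3:
        raise FretError("spectra share fewer than 3 wavelength points")
    grid = doubly.wavelength_nm[mask]
    y = doubly.intensity[mask]
    d = np.interp(grid, donor_ref.wavelength_nm, donor_ref.intensity)
    a = np.interp(grid, acceptor_ref.wavelength_nm, acceptor_ref.intensity)
    basis = np.column_stack([d, a])
    # collinear references cannot be separated
    sv = np.linalg.svd(basis / np.linalg.norm(basis), compute_uv=False)
    if sv[-1] < collinearity_tol * sv[0]:
        raise FretError("donor and acceptor reference spectra are collinear; cannot deconvolute")
    coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
    resid = float(np.linalg.norm(y - basis @ coef))
    return float(coef[0]), float(coef[1]), resid


def efret_acceptor_ratio(
    acceptor_amp_donor_ex: float,
    acceptor_em_direct_ex: float,
    ratios: AbsorbanceRatios,
) -> float:
    """E_FRET by acceptor normalization.

    The acceptor emission under donor excitation contains a directly excited
    component plus the transfer component.  Normalizing by the acceptor
    emission under direct (acceptor-band) excitation gives

        (ratio)A = eps_A(d)/eps_A(a) + E * eps_D(d)/eps_A(a)

    where eps_X(y) is the extinction coefficient of fluorophore X at the
    y-excitation wavelength, so

        E = [ (ratio)A - eps_A(d)/eps_A(a) ] * eps_A(a)/eps_D(d).

    Being a ratio of two fluorescence signals from the same sample, the
    method is insensitive to concentration and to joint instrumental scaling.
    """
    if not acceptor_amp_donor_ex > 0 or not acceptor_em_direct_ex > 0:
        raise FretError("fluorescence amplitudes must be > 0")
    ratio_a = acceptor_amp_donor_ex / acceptor_em_direct_ex
    direct_term = ratios.eps_A_at_donor_ex / ratios.eps_A_at_acceptor_ex
    return (ratio_a - direct_term) * ratios.eps_A_at_acceptor_ex / ratios.eps_D_at_donor_ex


# ---------------------------------------------------------------------------
# fitting


def _default_init(mg: np.ndarray, ef: np.ndarray) -> tuple[float, float, float]:
    """Data-driven starting point: E0 = min, dE = range, KA from half-rise."""
    e0 = float(np.min(ef))
    de = float(np.max(ef) - np.min(ef))
    half = e0 + de / 2.0
    order = np.argsort(mg)
    mg_s, ef_s = mg[order], ef[order]
    above = np.nonzero(ef_s >= half)[0]
    if de > 0 and above.size and above[0] > 0:
        i = above[0]
        x0, x1 = mg_s[i - 1], mg_s[i]
        y0, y1 = ef_s[i - 1], ef_s[i]
        c_half = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    else:
        c_half = float(np.median(mg_s[mg_s > 0])) if np.any(mg_s > 0) else 1.0
    c_half = max(c_half, np.finfo(float).tiny)
    return e0, de if de > 0 else 1e-3, 1.0 / c_half


def fit_two_state(
    curve: Sequence[TitrationPoint],
    init: tuple[float, float, float] | None = None,
) -> TwoStateFit:
    """Fit the two-state isotherm to a titration by nonlinear least squares.

    Requires >= 4 points with >= 2 distinct concentrations.  ``init`` is an
    optional (E0, dE, KA) starting point; by default E0 starts at the minimum
    observed E_FRET, dE at the observed range, and KA at the reciprocal of
    the concentration at half-rise (linear interpolation).  Per-point sigmas,
    when present on every point, weight the residuals.  Non-convergence and
    non-identifiability are flagged on the result rather than raised.
    """
    pts = list(curve)
    if len(pts) < 4:
        raise FretError(f"need >= 4 titration points to fit 3 parameters, got {len(pts)}")
    mg = np.array([p.mg_conc for p in pts], dtype=float)
    ef = np.array([p.efret for p in pts], dtype=float)
    if np.unique(mg).size < 2:
        raise FretError("need at least 2 distinct Mg2+ concentrations")
    sigmas = [p.sigma for p in pts]
    weights = None
    if all(s is not None and s > 0 for s in sigmas):
        weights = 1.0 / np.array(sigmas, dtype=float)

    model = Model(lambda mg_conc, e0, de, ka: e0 + de * ka * mg_conc / (1.0 + ka * mg_conc),
                  independent_vars=["mg_conc"])
    if init is not None:
        starts = [init]
    else:
        # multi-start: the half-rise guess plus a log grid of KA spanning the
        # measured concentration range, keeping the lowest-RSS optimum.  The
        # isotherm has shallow side minima when dE is comparable to the noise.
        e0_i, de_i, ka_i = _default_init(mg, ef)
        pos = mg[mg > 0]
        ka_grid = np.geomspace(0.1 / pos.max(), 10.0 / pos.min(), 7) if pos.size else []
        starts = [(e0_i, de_i, ka_i)] + [(e0_i, de_i, ka0) for ka0 in ka_grid]
    result = None
    best_rss = np.inf
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lmfit warns on flat directions; we flag instead
        for e0_i, de_i, ka_i in starts:
            params = model.make_params(e0=e0_i, de=de_i, ka=ka_i)
            params["ka"].set(min=np.finfo(float).tiny)
            cand = model.fit(ef, params, mg_conc=mg, weights=weights)
            cand_rss = float(np.sum(cand.residual**2))
            if result is None or cand_rss < best_rss - 1e-14:
                result, best_rss = cand, cand_rss

    e0 = float(result.params["e0"].value)
    de = float(result.params["de"].value)
    ka = float(result.params["ka"].value)
    stderr = {k: (float(result.params[k].stderr) if result.params[k].stderr is not None else None)
              for k in ("e0", "de", "ka")}
    rss = float(np.sum((ef - model_efret(e0, de, ka, mg)) ** 2))
    notes: list[str] = []
    if de <= 0:
        notes.append("fitted dE_FRET <= 0: no FRET increase on folding")
    identifiable = result.errorbars and stderr["ka"] is not None and np.isfinite(stderr["ka"])
    if identifiable and de != 0 and stderr["ka"] is not None and stderr["ka"] > 10 * abs(ka):
        notes.append("KA poorly constrained (stderr > 10x estimate)")
        identifiable = False
    if not identifiable:
        notes.append("KA unidentifiable from these data")
    if not result.success:
        notes.append("optimizer did not report convergence")
    return TwoStateFit(
        e0=e0,
        de=de,
        ka=ka,
        kd=1.0 / ka,
        e0_stderr=stderr["e0"],
        de_stderr=stderr["de"],
        ka_stderr=stderr["ka"],
        rss=rss,
        converged=bool(result.success),
        identifiable=bool(identifiable),
        warnings=tuple(notes),
    )


def bootstrap_kd(
    curve: Sequence[TitrationPoint],
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> dict:
    """Case-resampling bootstrap confidence interval for the apparent Kd.

    Resamples titration points with replacement, refits, and returns the
    percentile interval of recovered Kd together with the replicate values.
    """
    pts = list(curve)
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(pts), size=len(pts))
        sample = [pts[i] for i in idx]
        if np.unique([p.mg_conc for p in sample]).size < 2:
            continue
        try:
            kds.append(fit_two_state(sample).kd)
        except FretError:
            continue
    kds_arr = np.array(kds)
    alpha = (1.0 - ci) / 2.0
    return {
        "kd_median": float(np.median(kds_arr)),
        "kd_ci_low": float(np.quantile(kds_arr, alpha)),
        "kd_ci_high": float(np.quantile(kds_arr, 1.0 - alpha)),
        "n_successful": int(kds_arr.size),
    }


# ---------------------------------------------------------------------------
# synthetic titrations


def simulate_titration(
    e0: float,
    de: float,
    kd: float,
    concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[TitrationPoint]:
    """Generate a synthetic titration from the isotherm plus Gaussian noise.

    ``kd`` is the apparent dissociation constant (molar); points are drawn
    i.i.d. with standard deviation ``noise_sd`` and are reproducible under
    ``seed``.  Noisy efficiencies are clipped to the [-0.1, 1.1] plausibility
    band that real acceptor-normalized data occupy.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.size == 0:
        raise FretError("empty concentration list")
    if not kd > 0:
        raise FretError(f"Kd must be > 0, got {kd}")
    if noise_sd < 0:
        raise FretError("noise_sd must be >= 0")
    clean = model_efret(e0, de, 1.0 / kd, conc)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, size=conc.size) if noise_sd > 0 else clean
    noisy = np.clip(noisy, -0.1, 1.1)
    return [TitrationPoint(float(c), float(e)) for c, e in zip(conc, noisy)]


def recovery_study(
    e0: float,
    de: float,
    kd: float,
    concentrations: Sequence[float],
    n_replicates: int = 100,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> dict:
    """Generate-and-refit study: how well does fitting recover known truth?

    Simulates ``n_replicates`` titrations from the isotherm at (e0, de, kd)
    with Gaussian noise, refits each, and summarizes the recovered parameter
    distributions by their medians.  Replicate seeds are spawned from
    ``seed``; the whole study is reproducible.
    """
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    fits = [
        fit_two_state(simulate_titration(e0, de, kd, concentrations, noise_sd, int(s)))
        for s in rep_seeds
    ]
    kds = np.array([f.kd for f in fits])
    e0s = np.array([f.e0 for f in fits])
    plateaus = np.array([f.e0 + f.de for f in fits])
    return {
        "kd_median_M": float(np.median(kds)),
        "e0_median": float(np.median(e0s)),
        "plateau_median": float(np.median(plateaus)),
        "n_replicates": n_replicates,
        "n_converged": int(sum(f.converged for f in fits)),
        "truth": {"e0": e0, "de": de, "kd_M": kd},
    }


# ---------------------------------------------------------------------------
# CSV I/O

_UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


def read_titration_csv(path, units: str | None = None) -> list[TitrationPoint]:
    """Read a titration table (columns ``mg_conc``, ``efret``[, ``sigma``]).

    The concentration unit is declared either by a header suffix
    (``mg_conc_uM``) or the ``units`` argument; molar by default.
    """
    df = pd.read_csv(path)
    conc_col = next((c for c in df.columns if c.startswith("mg_conc")), None)
    if conc_col is None or "efret" not in df.columns:
        raise FretError("titration CSV needs columns mg_conc[_unit] and efret")
    scale = 1.0
    suffix = conc_col[len("mg_conc"):].lstrip("_")
    if units is not None:
        if units not in _UNIT_SCALE:
            raise FretError(f"unknown concentration unit {units!r}")
        scale = _UNIT_SCALE[units]
    elif suffix:
        if suffix not in _UNIT_SCALE:
            raise FretError(f"unknown concentration unit {suffix!r} in header")
        scale = _UNIT_SCALE[suffix]
    sig = df["sigma"] if "sigma" in df.columns else [None] * len(df)
    return [
        TitrationPoint(float(c) * scale, float(e), None if s is None or pd.isna(s) else float(s))
        for c, e, s in zip(df[conc_col], df["efret"], sig)
    ]


def write_titration_csv(points: Sequence[TitrationPoint], path, units: str = "M") -> None:
    """Write titration points with the concentration unit in the header."""
    if units not in _UNIT_SCALE:
        raise FretError(f"unknown concentration unit {units!r}")
    scale = _UNIT_SCALE[units]
    col = "mg_conc" if units == "M" else f"mg_conc_{units}"
    df = pd.DataFrame({
        col: [p.mg_conc / scale for p in points],
        "efret": [p.efret for p in points],
    })
    if any(p.sigma is not None for p in points):
        df["sigma"] = [p.sigma for p in points]
    df.to_csv(path, index=False)
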