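"""Nonlinear least-squares fitting of chemical-shift titration series.

Each NMR resonance is fitted independently to the one-pKa or two-pKa
closed form (:mod:`trxpka.models`) by Levenberg-Marquardt least squares with
multi-start initialization over a grid of candidate pKa values, because
double sigmoids have local minima.  Residuals are unweighted (no per-point
uncertainties are available for this kind of data).  Model choice between
the nested one- and two-pKa forms uses the extra-sum-of-squares F-test.

Per-residue pKa values are then aggregated across resonances as an
unweighted mean with the sample standard deviation as the headline
uncertainty — the convention behind "10.6 ± 0.2 (7)"-style reports, where
the parenthesis counts the resonances averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import lmfit
import numpy as np
from scipy import stats

from .models import (
    OnePkaParams,
    TwoPkaParams,
    microscopic_from_macroscopic,
    shift_one_pka,
    shift_two_pka,
)

__all__ = [
    "TitrationSeries",
    "TitrationFit",
    "PkaEstimate",
    "FitError",
    "NoTitrationError",
    "fit_one_pka",
    "fit_two_pka",
    "select_model",
    "aggregate_pka",
    "microscopic_pair_from_fit",
]

#: pKa grid for multi-start initialization.
PKA_START_GRID = tuple(float(p) for p in range(4, 13))

#: Minimum pKa separation between the two starts of a two-pKa fit.
MIN_START_SEPARATION = 0.5

#: Observed amplitude must exceed this multiple of the noise estimate.
#: The expected range of pure Gaussian noise over ~20 points is ~3.7 sigma,
#: while genuine titrations in this domain run >= 10 sigma.
AMPLITUDE_NOISE_FACTOR = 6.0


class FitError(RuntimeError):
    """A titration fit failed to converge or the input is unfittable."""


class NoTitrationError(FitError):
    """The series shows no resolvable titration (amplitude at the noise floor)."""


@dataclass(frozen=True)
class TitrationSeries:
    """One resonance's chemical shift measured across a pH ladder.

    Points are stored sorted by pH; duplicate pH values (repeated
    measurements) are allowed and retained.
    """

    residue_label: str
    nucleus_label: str
    ph: np.ndarray
    shift: np.ndarray
    oxidation_state_label: str = ""

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        shift = np.asarray(self.shift, dtype=float)
        if ph.shape != shift.shape or ph.ndim != 1:
            raise ValueError("ph and shift must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(ph)) and np.all(np.isfinite(shift))):
            raise ValueError("pH and shift values must all be finite")
        order = np.argsort(ph, kind="stable")
        object.__setattr__(self, "ph", ph[order])
        object.__setattr__(self, "shift", shift[order])

    @property
    def n_points(self) -> int:
        return len(self.ph)

    @property
    def amplitude(self) -> float:
        """Observed shift range (max - min, ppm)."""
        return float(self.shift.max() - self.shift.min())

    def noise_estimate(self) -> float:
        """Robust per-point noise estimate (ppm) from second differences.

        Second differencing annihilates the locally-linear part of a smooth
        titration curve, leaving noise inflated by sqrt(6); the median
        absolute value gives a robust scale.
        """
        if self.n_points < 3:
            return 0.0
        d2 = np.diff(self.shift, n=2)
        return float(1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0))


@dataclass(frozen=True)
class TitrationFit:
    """Result of fitting one titration series to one model.

    ``stderr_pka`` holds asymptotic per-fit standard errors (one value per
    pKa parameter); the cross-resonance spread from :func:`aggregate_pka` is
    the headline uncertainty.  ``extrapolated`` is set when a fitted pKa
    falls more than one unit outside the observed pH window, and
    ``non_identifiable`` when the residual profile of a pKa is flat.
    """

    model_kind: Literal["one_pka", "two_pka"]
    params: Union[OnePkaParams, TwoPkaParams]
    rss: float
    dof: int
    stderr_pka: tuple[Optional[float], ...]
    converged: bool
    extrapolated: bool = False
    non_identifiable: bool = False
    series: Optional[TitrationSeries] = field(default=None, repr=False, compare=False)

    @property
    def pka_values(self) -> tuple[float, ...]:
        if isinstance(self.params, OnePkaParams):
            return (self.params.pka,)
        return (self.params.pka1, self.params.pka2)


@dataclass(frozen=True)
class PkaEstimate:
    """Cross-resonance aggregate: mean pKa, sample SD, and resonance count."""

    mean_pka: float
    sd_pka: Optional[float]
    n_resonances: int

    def __post_init__(self) -> None:
        if self.n_resonances < 1:
            raise ValueError("n_resonances must be >= 1")
        if self.sd_pka is not None and self.sd_pka < 0:
            raise ValueError("sd_pka must be >= 0")


def _validate_series(series: TitrationSeries, min_points: int) -> None:
    if series.n_points < min_points:
        raise FitError(
            f"series {series.residue_label}/{series.nucleus_label} has "
            f"{series.n_points} points; at least {min_points} required"
        )
    amp = series.amplitude
    if amp <= 0:
        raise NoTitrationError("no titration detected: series is constant")
    noise = series.noise_estimate()
    if amp < AMPLITUDE_NOISE_FACTOR * noise:
        raise NoTitrationError(
            f"no titration detected: amplitude {amp:.3g} ppm is below "
            f"{AMPLITUDE_NOISE_FACTOR:g}x the noise estimate {noise:.3g} ppm"
        )


def _run_leastsq(params: lmfit.Parameters, residual, args) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(
        residual, params, args=args, method="leastsq", nan_policy="raise"
    )


def fit_one_pka(series: TitrationSeries) -> TitrationFit:
    """Fit a series to the single-pKa curve.

    Multi-start over the pKa grid; limiting shifts start from the first and
    last observed points.  Raises :class:`NoTitrationError` when the
    amplitude is at the noise floor and :class:`FitError` when no start
    converges.
    """
    _validate_series(series, min_points=6)
    ph, shift = series.ph, series.shift

    def residual(p, ph, shift):
        mp = OnePkaParams(p["delta_protonated"].value, p["delta_deprotonated"].value, p["pka"].value)
        return shift_one_pka(ph, mp) - shift

    best = None
    for pka0 in PKA_START_GRID:
        p = lmfit.Parameters()
        p.add("delta_protonated", value=float(shift[0]))
        p.add("delta_deprotonated", value=float(shift[-1]))
        p.add("pka", value=pka0)
        try:
            res = _run_leastsq(p, residual, (ph, shift))
        except Exception:
            continue
        if not res.success:
            continue
        rss = float(np.sum(res.residual**2))
        if best is None or rss < best[0]:
            best = (rss, res)
        if rss < 1e-20 * max(1.0, series.amplitude**2) * series.n_points:
            break
    if best is None:
        raise FitError(
            f"one-pKa fit did not converge for {series.residue_label}/"
            f"{series.nucleus_label} from any start"
        )
    rss, res = best
    pka = float(res.params["pka"].value)
    fitted = OnePkaParams(
        float(res.params["delta_protonated"].value),
        float(res.params["delta_deprotonated"].value),
        pka,
    )
    extrapolated = not (ph.min() - 1.0 <= pka <= ph.max() + 1.0)
    stderr = res.params["pka"].stderr
    return TitrationFit(
        model_kind="one_pka",
        params=fitted,
        rss=rss,
        dof=series.n_points - 3,
        stderr_pka=(float(stderr) if stderr is not None else None,),
        converged=True,
        extrapolated=extrapolated,
        series=series,
    )


def _two_pka_from_lmfit(p: lmfit.Parameters) -> TwoPkaParams:
    pka1 = float(p["pka1"].value)
    return TwoPkaParams(
        float(p["delta_state0"].value),
        float(p["delta_state1"].value),
        float(p["delta_state2"].value),
        pka1,
        pka1 + float(p["dpka"].value),
    )


def _two_pka_residual(p, ph, shift):
    return shift_two_pka(ph, _two_pka_from_lmfit(p)) - shift


def _profile_flat(
    res: lmfit.minimizer.MinimizerResult,
    which: str,
    ph: np.ndarray,
    shift: np.ndarray,
    rss_opt: float,
    tol: float,
) -> bool:
    """True when one pKa can be displaced by 0.5 units (re-optimizing every
    other parameter) with essentially no cost in residual sum of squares.

    A redundant transition is absorbable in at least one direction, so the
    minimum over the two displacement directions is compared to ``tol``.
    """
    best_d_rss = math.inf
    for delta in (-0.5, 0.5):
        p = res.params.copy()
        if which == "pka1":
            p["pka1"].set(value=p["pka1"].value + delta, vary=False)
        else:
            p["dpka"].set(value=max(0.0, p["dpka"].value + delta), vary=False)
        try:
            shifted = _run_leastsq(p, _two_pka_residual, (ph, shift))
        except Exception:
            continue
        best_d_rss = min(best_d_rss, float(np.sum(shifted.residual**2)) - rss_opt)
    return best_d_rss < tol


def fit_two_pka(series: TitrationSeries) -> TitrationFit:
    """Fit a series to the two-pKa (double sigmoid) curve.

    The ordering ``pka1 <= pka2`` is built into the parameterization (pKa1
    and a nonnegative separation are fitted).  Starts pair every grid value
    with every higher value at least :data:`MIN_START_SEPARATION` apart.
    Practical non-identifiability (flat residual profile of either pKa over
    +/-0.5 units) is flagged, as happens when the data really follow a
    single transition.
    """
    _validate_series(series, min_points=8)
    ph, shift = series.ph, series.shift

    best = None
    tiny = 1e-20 * max(1.0, series.amplitude**2) * series.n_points
    for i, p1 in enumerate(PKA_START_GRID):
        for p2 in PKA_START_GRID[i:]:
            if p2 - p1 < MIN_START_SEPARATION:
                continue
            p = lmfit.Parameters()
            p.add("delta_state0", value=float(shift[0]))
            p.add("delta_state1", value=float(0.5 * (shift[0] + shift[-1])))
            p.add("delta_state2", value=float(shift[-1]))
            p.add("pka1", value=p1)
            p.add("dpka", value=p2 - p1, min=0.0)
            try:
                res = _run_leastsq(p, _two_pka_residual, (ph, shift))
            except Exception:
                continue
            if not res.success:
                continue
            rss = float(np.sum(res.residual**2))
            if best is None or rss < best[0]:
                best = (rss, res)
            if rss < tiny:
                break
        if best is not None and best[0] < tiny:
            break
    if best is None:
        raise FitError(
            f"two-pKa fit did not converge for {series.residue_label}/"
            f"{series.nucleus_label} from any start"
        )
    rss, res = best
    fitted = _two_pka_from_lmfit(res.params)
    dof = series.n_points - 5
    in_window = all(
        ph.min() - 1.0 <= v <= ph.max() + 1.0 for v in (fitted.pka1, fitted.pka2)
    )
    # flatness tolerance: the 95% extra-sum-of-squares cost of pinning one
    # parameter, floored for noise-free data
    sigma2 = rss / max(dof, 1)
    f95 = float(stats.f.ppf(0.95, 1, max(dof, 1)))
    tol = max(sigma2 * f95, series.n_points * (1e-6 * series.amplitude) ** 2)
    flat = _profile_flat(res, "pka1", ph, shift, rss, tol) or _profile_flat(
        res, "dpka", ph, shift, rss, tol
    )
    se1 = res.params["pka1"].stderr
    se_d = res.params["dpka"].stderr
    se2 = None
    if se1 is not None and se_d is not None:
        # conservative: ignores covariance between pka1 and the separation
        se2 = math.hypot(se1, se_d)
    return TitrationFit(
        model_kind="two_pka",
        params=fitted,
        rss=rss,
        dof=dof,
        stderr_pka=(float(se1) if se1 is not None else None, se2),
        converged=True,
        extrapolated=not in_window,
        non_identifiable=flat,
        series=series,
    )


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the nested F-test, with both fits retained for audit."""

    chosen: Literal["one_pka", "two_pka"]
    fit_one: TitrationFit
    fit_two: TitrationFit
    f_statistic: float
    p_value: float


def select_model(series: TitrationSeries, alpha: float = 0.05) -> ModelSelection:
    """Choose between the nested one- and two-pKa fits by F-test at ``alpha``.

    The two-pKa model is preferred when its reduction in residual sum of
    squares is significant at ``alpha``.  ``alpha=1`` always accepts the
    richer model (when it improves the fit at all); ``alpha -> 0`` never
    does.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    f1 = fit_one_pka(series)
    f2 = fit_two_pka(series)
    d_dof = f1.dof - f2.dof
    if f2.rss <= 0.0:
        f_stat = math.inf if f1.rss > 0 else 0.0
    else:
        f_stat = ((f1.rss - f2.rss) / d_dof) / (f2.rss / f2.dof)
    p_value = 1.0 if f_stat <= 0 else float(stats.f.sf(f_stat, d_dof, f2.dof))
    chosen = "two_pka" if p_value < alpha else "one_pka"
    return ModelSelection(chosen, f1, f2, f_stat, p_value)


def microscopic_pair_from_fit(fit: TitrationFit) -> tuple[float, float]:
    """Microscopic pKa pair implied by a two-pKa fit of a single-site reporter.

    A resonance reporting one site of a coupled pair titrates as a double
    sigmoid whose fitted constants are the *macroscopic* pKas and whose
    intermediate plateau height gives the fraction of the first transition
    carried by the reported site.  Inverting through
    :func:`~trxpka.models.microscopic_from_macroscopic` recovers the
    microscopic constants; returns ``(pk_first, pk_second)`` — the shared
    first- and second-deprotonation microscopic values for the reported
    site's branch.
    """
    if fit.model_kind != "two_pka":
        raise ValueError("a two-pKa fit is required")
    p = fit.params
    total = p.delta_state2 - p.delta_state0
    if total == 0:
        raise ValueError("degenerate fit: zero total amplitude")
    r = (p.delta_state1 - p.delta_state0) / total
    model = microscopic_from_macroscopic(p.pka1, p.pka2, r)
    return (model.pk_b_first, model.pk_b_given_a)


def _transition_value(fit: TitrationFit, transition: str) -> float:
    if fit.model_kind == "one_pka":
        return fit.params.pka
    if transition == "lower":
        return fit.params.pka1
    if transition == "upper":
        return fit.params.pka2
    raise ValueError(
        "mixed or two-pKa fits require transition='lower' or 'upper'"
    )


def aggregate_pka(
    fits: Sequence[TitrationFit],
    transition: Literal["only", "lower", "upper"] = "only",
) -> PkaEstimate:
    """Average per-resonance pKa values into a single estimate.

    ``transition='only'`` is valid only for a homogeneous list of one-pKa
    fits; for two-pKa fits (or a mixture, where a one-pKa fit contributes
    its single value) select ``'lower'`` or ``'upper'``.  The result is the
    unweighted mean with the sample (n-1) standard deviation; SD is None
    (undefined) for a single resonance.
    """
    if len(fits) == 0:
        raise ValueError("at least one fit is required")
    if transition == "only":
        kinds = {f.model_kind for f in fits}
        if kinds != {"one_pka"}:
            raise ValueError(
                "transition='only' requires all one-pKa fits; "
                "select 'lower' or 'upper' for two-pKa fits"
            )
    values = np.array([_transition_value(f, transition) for f in fits])
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else None
    return PkaEstimate(mean, sd, len(values))
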