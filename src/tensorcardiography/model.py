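"""Beat model: ECG waves as differences of Gaussian cumulative distribution functions.

A heartbeat's R and T waves are modelled as the difference between the
collective action-potential (AP) transition probabilities of two myocardial
groups: one contributing anodic (positive, endocardial-side) and one cathodic
(negative, epicardial-side) electromotive force to the lead.  The timing of
individual AP transitions is treated as a Gaussian point process, so the
fraction of each group that has depolarised by time ``t`` is a Gaussian CDF
:math:`\\Phi((t-\\mu)/\\sigma)` and the fraction still depolarised during
repolarisation is the falling curve :math:`1-\\Phi((t-\\mu)/\\sigma)`.

Four canonical components describe a beat:

========  ========  =========  =======================================
name      polarity  direction  wave
========  ========  =========  =======================================
``Rp``    anodic    rising     R-wave upstroke (endocardial depol.)
``Rn``    cathodic  rising     R-wave downstroke (epicardial depol.)
``Tp``    anodic    falling    T-wave (endocardial repolarisation)
``Tn``    cathodic  falling    T-wave (epicardial repolarisation)
========  ========  =========  =======================================

Two forward evaluations exist.  *RT-separate* treats the QRS and T windows
independently: ``ECG_R = k_Rp Φ_Rp − k_Rn Φ_Rn + β_R`` and
``ECG_T = f'_Tp − f'_Tn + β_T`` with ``f'_X = k_X (1 − Φ_X)``.  *RT-bulk*
joins each anodic and cathodic pair at the depolarised plateau, so each group
traces a trapezoid ``k_Rx Φ_Rx − k_Tx Φ_Tx`` and the ECG is the anodic minus
the cathodic trapezoid plus a single level ``β``.

All times are milliseconds, all amplitudes millivolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "CDFComponent",
    "BeatModel",
    "TCGMetrics",
    "CrossingResult",
    "eval_component",
    "forward_separate",
    "forward_bulk",
    "derive_metrics",
    "find_repolarization_crossing",
    "COMPONENT_NAMES",
]

#: canonical component order used throughout (tensor axis order).
COMPONENT_NAMES = ("Rp", "Rn", "Tp", "Tn")


class InvalidParameterError(ValueError):
    """Raised for physically impossible component parameters."""


@dataclass(frozen=True)
class CDFComponent:
    """One Gaussian-CDF leg of the beat model.

    Parameters
    ----------
    polarity :
        ``"anodic"`` (positive EMF, endocardial side) or ``"cathodic"``.
    direction :
        ``"rising"`` for a depolarisation CDF (0 → k), ``"falling"`` for a
        repolarisation curve (k → 0, i.e. ``k (1 − Φ)``).
    mu :
        Mean transition time in ms relative to the beat reference (QRS onset
        convention is used by the fitting layer; the model itself is
        reference-agnostic).
    sigma :
        Spread of the transition times in ms; strictly positive.
    k :
        Non-negative amplitude weight in mV.
    """

    polarity: str
    direction: str
    mu: float
    sigma: float
    k: float

    def __post_init__(self) -> None:
        if self.polarity not in ("anodic", "cathodic"):
            raise InvalidParameterError(f"unknown polarity {self.polarity!r}")
        if self.direction not in ("rising", "falling"):
            raise InvalidParameterError(f"unknown direction {self.direction!r}")
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if self.k < 0:
            raise InvalidParameterError(f"k must be >= 0, got {self.k}")

    def __call__(self, t):
        return eval_component(self, t)


def eval_component(c: CDFComponent, t):
    """Evaluate one component at time(s) ``t`` (ms) → amplitude (mV).

    Rising: ``k Φ((t−μ)/σ)``; falling: ``k (1 − Φ((t−μ)/σ))``.
    """
    z = (np.asarray(t, dtype=float) - c.mu) / c.sigma
    phi = ndtr(z)
    if c.direction == "rising":
        return c.k * phi
    return c.k * (1.0 - phi)


def _canonical(
    mode: str,
    muRp: float, muRn: float, muTp: float, muTn: float,
    sigmaRp: float, sigmaRn: float, sigmaTp: float, sigmaTn: float,
    kRp: float, kRn: float, kTp: float, kTn: float,
) -> dict[str, CDFComponent]:
    t_dir = "rising" if mode == "bulk" else "falling"
    return {
        "Rp": CDFComponent("anodic", "rising", muRp, sigmaRp, kRp),
        "Rn": CDFComponent("cathodic", "rising", muRn, sigmaRn, kRn),
        # in bulk mode the T components close the trapezoids, i.e. they are
        # subtracted rising CDFs; the evaluated waveform is identical.
        "Tp": CDFComponent("anodic", t_dir, muTp, sigmaTp, kTp),
        "Tn": CDFComponent("cathodic", t_dir, muTn, sigmaTn, kTn),
    }


@dataclass(frozen=True)
class BeatModel:
    """Full parameter set of one beat.

    ``mode`` is ``"separate"`` (independent QRS and T fits, two levels
    ``beta_r``/``beta_t``) or ``"bulk"`` (joint trapezoid fit, single
    ``beta``).  ``extras`` holds optional additional (anodic, cathodic)
    rising pairs used by the extended fit for notched or slurred QRS
    complexes (delta waves, deep S waves); they are empty for canonical fits.

    The physiologic temporal ordering is ``μRp ≤ μRn ≤ μTn ≤ μTp``; it is
    *checked*, never enforced — a violating model evaluates normally but
    reports ``ordering_ok() == False`` so downstream layers can flag it.
    """

    components: dict[str, CDFComponent]
    mode: str = "separate"
    beta_r: float = 0.0
    beta_t: float = 0.0
    beta: float = 0.0
    extras: tuple[tuple[CDFComponent, CDFComponent], ...] = ()

    @classmethod
    def from_params(
        cls,
        mode: str = "separate",
        *,
        muRp: float, muRn: float, muTp: float, muTn: float,
        sigmaRp: float, sigmaRn: float, sigmaTp: float, sigmaTn: float,
        kRp: float, kRn: float, kTp: float, kTn: float,
        beta_r: float = 0.0, beta_t: float = 0.0, beta: float = 0.0,
        extras: tuple = (),
    ) -> "BeatModel":
        if mode not in ("separate", "bulk"):
            raise InvalidParameterError(f"unknown mode {mode!r}")
        comps = _canonical(
            mode, muRp, muRn, muTp, muTn,
            sigmaRp, sigmaRn, sigmaTp, sigmaTn, kRp, kRn, kTp, kTn,
        )
        return cls(components=comps, mode=mode, beta_r=beta_r,
                   beta_t=beta_t, beta=beta, extras=tuple(extras))

    # -- parameter accessors -------------------------------------------------
    def param(self, name: str, metric: str) -> float:
        """Return μ/σ/k of a canonical component, e.g. ``param("Tp", "sigma")``."""
        return getattr(self.components[name], metric)

    def __getattr__(self, item: str):
        # muRp / sigmaTn / kRn style access
        for metric in ("mu", "sigma", "k"):
            if item.startswith(metric):
                name = item[len(metric):]
                comps = object.__getattribute__(self, "components")
                if name in comps:
                    return getattr(comps[name], metric)
        raise AttributeError(item)

    def ordering_ok(self) -> bool:
        """True iff μRp ≤ μRn ≤ μTn ≤ μTp (physiologic ordering)."""
        return self.muRp <= self.muRn <= self.muTn <= self.muTp

    def shift(self, dt: float) -> "BeatModel":
        """Return a copy with every μ translated by ``dt`` ms."""
        comps = {n: replace(c, mu=c.mu + dt) for n, c in self.components.items()}
        extras = tuple(
            (replace(p, mu=p.mu + dt), replace(q, mu=q.mu + dt))
            for p, q in self.extras
        )
        return replace(self, components=comps, extras=extras)


def _extras_sum(m: BeatModel, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for pos, neg in m.extras:
        out += eval_component(pos, t) - eval_component(neg, t)
    return out


def forward_separate(m: BeatModel, t_grid, segment: str) -> np.ndarray:
    """Evaluate the RT-separate model on ``t_grid`` for one segment.

    ``segment="R"`` returns ``f_Rp − f_Rn + β_R`` (plus any extra QRS pairs);
    ``segment="T"`` returns ``f'_Tp − f'_Tn + β_T``.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.size == 0:
        raise ValueError("empty time grid")
    if segment == "R":
        y = (eval_component(m.components["Rp"], t)
             - eval_component(m.components["Rn"], t)
             + m.beta_r + _extras_sum(m, t))
    elif segment == "T":
        cTp, cTn = m.components["Tp"], m.components["Tn"]
        fTp = cTp.k * (1.0 - ndtr((t - cTp.mu) / cTp.sigma))
        fTn = cTn.k * (1.0 - ndtr((t - cTn.mu) / cTn.sigma))
        y = fTp - fTn + m.beta_t
    else:
        raise ValueError(f"segment must be 'R' or 'T', got {segment!r}")
    return y


def forward_bulk(m: BeatModel, t_grid) -> np.ndarray:
    """Evaluate the RT-bulk model: anodic minus cathodic trapezoid plus β.

    Anodic trapezoid ``A(t) = k_Rp Φ_Rp(t) − k_Tp Φ_Tp(t)``, cathodic
    ``C(t) = k_Rn Φ_Rn(t) − k_Tn Φ_Tn(t)``.  With ``k_Tp = k_Rp`` and
    ``k_Tn = k_Rn`` both trapezoids close (return to 0) after the T wave, and
    during the depolarised plateau the waveform sits at the model ST level
    ``k_Rp − k_Rn + β``.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.size == 0:
        raise ValueError("empty time grid")
    c = m.components
    A = c["Rp"].k * ndtr((t - c["Rp"].mu) / c["Rp"].sigma) \
        - c["Tp"].k * ndtr((t - c["Tp"].mu) / c["Tp"].sigma)
    C = c["Rn"].k * ndtr((t - c["Rn"].mu) / c["Rn"].sigma) \
        - c["Tn"].k * ndtr((t - c["Tn"].mu) / c["Tn"].sigma)
    return A - C + m.beta + _extras_sum(m, t)


@dataclass(frozen=True)
class TCGMetrics:
    """Derived per-beat metrics.

    The four interval metrics are signed μ differences:

    * ``muRTp = μTp − μRp`` — anodic (endocardial-side) collective AP duration;
    * ``muRTn = μTn − μRn`` — cathodic (epicardial-side) collective AP duration;
    * ``muRpn = μRn − μRp`` — transmural depolarisation delay;
    * ``muTpn = μTp − μTn`` — transmural repolarisation delay.

    They satisfy ``muRpn + muRTn + muTpn == muRTp`` identically.
    """

    muRTp: float
    muRTn: float
    muRpn: float
    muTpn: float
    sigmas: dict[str, float] = field(default_factory=dict)
    ks: dict[str, float] = field(default_factory=dict)
    betas: dict[str, float] = field(default_factory=dict)
    r2: float | None = None
    residual_sd: float | None = None


def derive_metrics(m: BeatModel, fit_stats: dict | None = None) -> TCGMetrics:
    """Compute interval metrics (and copy through σ, k, β) for a beat model."""
    fit_stats = fit_stats or {}
    betas = ({"beta": m.beta} if m.mode == "bulk"
             else {"betaR": m.beta_r, "betaT": m.beta_t})
    return TCGMetrics(
        muRTp=m.muTp - m.muRp,
        muRTn=m.muTn - m.muRn,
        muRpn=m.muRn - m.muRp,
        muTpn=m.muTp - m.muTn,
        sigmas={n: m.components[n].sigma for n in COMPONENT_NAMES},
        ks={n: m.components[n].k for n in COMPONENT_NAMES},
        betas=betas,
        r2=fit_stats.get("r2"),
        residual_sd=fit_stats.get("residual_sd"),
    )


@dataclass(frozen=True)
class CrossingResult:
    crossed: bool
    time: float | None


def find_repolarization_crossing(
    m: BeatModel, t_grid=None, step: float = 1.0
) -> CrossingResult:
    """Detect a late-repolarisation inversion of the falling T curves.

    Returns the latest time ``t*`` where ``f'_Tp(t*) = f'_Tn(t*)`` with the
    cathodic curve *above* the anodic one afterwards (``f'_Tn > f'_Tp`` for
    ``t > t*``) — the marker of the epicardial tail outlasting the
    endocardial one seen in ischaemia and early-repolarisation cases.  If no
    such inversion exists the result has ``crossed=False``.

    The search scans a dense grid (default 1 ms) over
    ``[μTn − 3 σTn, μTp + 4 σTp]`` for + → − sign changes of
    ``d(t) = f'_Tp − f'_Tn`` and refines the latest one by bisection.
    """
    cTp, cTn = m.components["Tp"], m.components["Tn"]

    def d(t):
        return (cTp.k * (1.0 - ndtr((t - cTp.mu) / cTp.sigma))
                - cTn.k * (1.0 - ndtr((t - cTn.mu) / cTn.sigma)))

    if t_grid is None:
        lo = cTn.mu - 3.0 * cTn.sigma
        hi = cTp.mu + 4.0 * cTp.sigma
        if hi <= lo:
            warnings.warn("degenerate T window; no crossing search possible")
            return CrossingResult(False, None)
        t_grid = np.arange(lo, hi + step, step)
    t = np.asarray(t_grid, dtype=float)
    vals = d(t)
    # + -> - transitions (strict, so identical curves yield none)
    idx = np.nonzero((vals[:-1] > 0) & (vals[1:] < 0))[0]
    if idx.size == 0:
        return CrossingResult(False, None)
    i = idx[-1]
    t_star = brentq(d, t[i], t[i + 1])
    return CrossingResult(True, float(t_star))
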