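"""Enzyme-kinetic model fitting: Michaelis-Menten, allosteric sigmoidal (Hill)
and substrate inhibition, plus initial-rate extraction, Eadie-Hofstee
diagnostics and competition-assay residual activity.

Model forms (v = velocity, S = substrate concentration in µM):

    mm                    v = Vmax * S / (Km + S)
    hill                  v = Vmax * S**h / (Khalf**h + S**h)
    substrate_inhibition  v = Vmax * S / (Km + S * (1 + S / Ki))

The Hill model reduces to Michaelis-Menten at h = 1 and the substrate-
inhibition model converges to it as Ki -> infinity; both identities are the
basis of the module's self-checks.  Cooperativity (h > 1) shows up as
curvature in the Eadie-Hofstee transform (v against v/S), which is linear
with slope -Km and intercept Vmax for a Michaelis-Menten enzyme.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

__all__ = [
    "MODELS",
    "KineticDataset",
    "ProgressCurve",
    "ModelFit",
    "InitialRate",
    "EadieHofstee",
    "model_velocity",
    "initial_rate",
    "fit_model",
    "compare_models",
    "eadie_hofstee",
    "residual_activity",
]


def _v_mm(S, Vmax, Km):
    return Vmax * S / (Km + S)


def _v_hill(S, Vmax, h, Khalf):
    return Vmax * S**h / (Khalf**h + S**h)


def _v_si(S, Vmax, Km, Ki):
    return Vmax * S / (Km + S * (1.0 + S / Ki))


MODELS = {
    "mm": (_v_mm, ("Vmax", "Km")),
    "hill": (_v_hill, ("Vmax", "h", "Khalf")),
    "substrate_inhibition": (_v_si, ("Vmax", "Km", "Ki")),
}


def model_velocity(model: str, S, **params) -> np.ndarray:
    """Evaluate a named kinetic model at substrate concentrations ``S``."""
    func, names = MODELS[model]
    return func(np.asarray(S, dtype=float), **{k: params[k] for k in names})


@dataclass
class KineticDataset:
    """Initial-velocity data: substrate concentrations (µM) and velocities.

    Replicates are stored flattened; ``replicate`` carries the replicate index
    of each point.  Fitting pools replicates (unweighted least squares).
    """

    S: np.ndarray
    v: np.ndarray
    replicate: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.S.shape != self.v.shape or self.S.ndim != 1:
            raise ValueError("S and v must be 1-D arrays of equal length")
        if np.any(self.S <= 0):
            raise ValueError("substrate concentrations must be positive")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate)
            if self.replicate.shape != self.S.shape:
                raise ValueError("replicate labels must match data length")

    def data_hash(self) -> str:
        order = np.lexsort((self.v, self.S))
        h = hashlib.sha256()
        h.update(np.round(self.S[order], 12).tobytes())
        h.update(np.round(self.v[order], 12).tobytes())
        return h.hexdigest()


@dataclass
class ProgressCurve:
    """A reaction progress trace: signal against time (s)."""

    t: np.ndarray
    y: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class InitialRate:
    slope: float
    stderr: float
    r_squared: float
    n_points: int
    fittable: bool


def initial_rate(
    curve: ProgressCurve, max_points: int | None = None, r2_min: float = 0.98
) -> InitialRate:
    """Initial slope of a progress curve (least squares on the initial window).

    The longest initial window of at least 3 points (at most ``max_points``)
    whose linear fit reaches R^2 >= ``r2_min`` is used.  If no window
    qualifies the best window's slope is still reported but flagged
    ``fittable=False`` — mirroring the exclusion of points for which a linear
    initial-slope fit is not possible.
    """
    n = len(curve.t)
    if n < 3:
        raise ValueError("need at least 3 points for an initial-rate fit")
    limit = n if max_points is None else min(max_points, n)
    best: InitialRate | None = None
    chosen: InitialRate | None = None
    for m in range(3, limit + 1):
        res = stats.linregress(curve.t[:m], curve.y[:m])
        r2 = res.rvalue**2
        cand = InitialRate(res.slope, res.stderr, r2, m, r2 >= r2_min)
        if cand.fittable:
            chosen = cand  # keep extending: longest qualifying window wins
        if best is None or r2 > best.r_squared:
            best = cand
    if chosen is not None:
        return chosen
    assert best is not None
    return InitialRate(best.slope, best.stderr, best.r_squared, best.n_points, False)


@dataclass
class ModelFit:
    """Result of fitting one kinetic model to one dataset."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    ssr: float
    aicc: float
    n: int
    n_params: int
    success: bool
    data_hash: str = ""
    message: str = ""

    def predict(self, S) -> np.ndarray:
        return model_velocity(self.model, S, **self.params)

    def __getitem__(self, name: str) -> float:
        return self.params[name]


def _aicc(ssr: float, n: int, p: int) -> float:
    # residual variance counted as an extra parameter, as usual for LSQ AIC
    k = p + 1
    if n - k - 1 <= 0:
        return float("inf")
    # floor SSR so an exact fit keeps AICc finite (ties then go to parsimony)
    ssr = max(ssr, 1e-300)
    return n * np.log(ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _initial_guesses(model: str, S: np.ndarray, v: np.ndarray) -> dict[str, float]:
    vmax0 = float(np.max(v))
    half = vmax0 / 2.0
    # S at half-max velocity (closest observed point)
    s_half = float(S[np.argmin(np.abs(v - half))])
    s_half = max(s_half, float(np.min(S)))
    if model == "mm":
        return {"Vmax": vmax0, "Km": s_half}
    if model == "hill":
        return {"Vmax": vmax0, "h": 1.0, "Khalf": s_half}
    if model == "substrate_inhibition":
        return {"Vmax": vmax0, "Km": s_half, "Ki": float(np.max(S))}
    raise ValueError(f"unknown model {model!r}")


def fit_model(
    data: KineticDataset, model: str, n_restarts: int = 5, weights: np.ndarray | None = None
) -> ModelFit:
    """Fit a kinetic model by (optionally weighted) least squares.

    All parameters are bounded positive.  A deterministic multi-start scheme
    (the plain guesses plus ``n_restarts`` log-jittered variants) guards
    against local minima; the restart with the lowest SSR wins.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {sorted(MODELS)}")
    if np.unique(data.S).size < 4:
        raise ValueError("need at least 4 distinct substrate concentrations")
    func, names = MODELS[model]
    lm_model = lmfit.Model(func, independent_vars=["S"])
    guesses = _initial_guesses(model, data.S, data.v)
    rng = np.random.default_rng(0)  # jitter is part of the algorithm, fixed
    starts = [guesses]
    for _ in range(n_restarts):
        starts.append(
            {k: val * float(np.exp(rng.normal(0.0, 0.7))) for k, val in guesses.items()}
        )
    best = None
    for start in starts:
        params = lmfit.Parameters()
        for name in names:
            params.add(name, value=start[name], min=1e-12)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = lm_model.fit(
                    data.v, params, S=data.S, weights=weights, method="leastsq"
                )
        except Exception:
            continue
        ssr = float(np.sum(res.residual**2))
        if best is None or ssr < best[0]:
            best = (ssr, res)
    if best is None:
        return ModelFit(
            model=model,
            params={},
            stderr={},
            ssr=float("inf"),
            aicc=float("inf"),
            n=len(data.S),
            n_params=len(names),
            success=False,
            data_hash=data.data_hash(),
            message="no restart converged",
        )
    ssr, res = best
    params = {name: float(res.params[name].value) for name in names}
    stderr = {
        name: float(res.params[name].stderr) if res.params[name].stderr is not None else float("nan")
        for name in names
    }
    n = len(data.S)
    return ModelFit(
        model=model,
        params=params,
        stderr=stderr,
        ssr=ssr,
        aicc=_aicc(ssr, n, len(names)),
        n=n,
        n_params=len(names),
        success=bool(res.success),
        data_hash=data.data_hash(),
        message=res.message or "",
    )


def compare_models(fit_a: ModelFit, fit_b: ModelFit, tie_delta: float = 2.0) -> tuple[ModelFit, float]:
    """Pick the preferred model by AICc; near-ties go to the simpler model.

    Returns ``(preferred_fit, delta_aicc)`` where ``delta_aicc`` is
    AICc(a) - AICc(b).  Comparing fits of different datasets is an error.
    """
    if fit_a.data_hash != fit_b.data_hash:
        raise ValueError("fits were made on different datasets")
    delta = fit_a.aicc - fit_b.aicc
    if abs(delta) < tie_delta:
        preferred = fit_a if fit_a.n_params <= fit_b.n_params else fit_b
    else:
        preferred = fit_a if delta < 0 else fit_b
    return preferred, delta


@dataclass
class EadieHofstee:
    """Eadie-Hofstee transform (x = v/S, y = v) with a curvature diagnostic.

    ``curvature`` is the quadratic coefficient of the least-squares parabola
    through the transformed points; it vanishes for Michaelis-Menten data and
    is significantly nonzero under cooperativity.
    """

    x: np.ndarray
    y: np.ndarray
    curvature: float
    curvature_se: float
    defined: bool


def eadie_hofstee(data: KineticDataset) -> EadieHofstee:
    keep = data.v > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} non-positive velocities", stacklevel=2)
    v = data.v[keep]
    S = data.S[keep]
    x = v / S
    # the parabola's covariance needs at least one residual degree of freedom
    if v.size < 4 or np.unique(x).size < 4:
        return EadieHofstee(x=x, y=v, curvature=float("nan"), curvature_se=float("nan"), defined=False)
    coeffs, cov = np.polyfit(x, v, 2, cov=True)
    return EadieHofstee(
        x=x,
        y=v,
        curvature=float(coeffs[0]),
        curvature_se=float(np.sqrt(cov[0, 0])),
        defined=True,
    )


def residual_activity(
    treated: ProgressCurve,
    control: ProgressCurve,
    max_points: int | None = None,
    r2_min: float = 0.98,
) -> float:
    """Residual enzyme activity: initial slope of treated over control trace.

    Used for competition assays where a candidate covalent inhibitor is
    preincubated with the enzyme and a fluorogenic substrate reports the
    remaining turnover.  The treated slope is used even when its linear-window
    fit is flagged (a fully inhibited trace is flat); an unfittable control is
    an error.
    """
    ctrl = initial_rate(control, max_points=max_points, r2_min=r2_min)
    if not ctrl.fittable:
        raise ValueError("control progress curve has no linear initial window")
    if not ctrl.slope > 0:
        raise ValueError("control slope must be positive")
    trt = initial_rate(treated, max_points=max_points, r2_min=r2_min)
    return trt.slope / ctrl.slope
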