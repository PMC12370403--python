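"""Continuous DRL-vs-CBT curves by trust-region nonlinear least squares.

Five candidate families are fitted to the per-bin (CBT, DRL) points:

====== ======================= ========
name   formula (t = CBT, mm)   n_params
====== ======================= ========
linear a + b t                 2
power1 a t^b                   2
power2 a t^b + c               3
exp1   a exp(b t)              2
exp2   a exp(b t) + c exp(d t) 4
====== ======================= ========

Fitting uses scipy's trust-region-reflective least squares with a
deterministic multi-start policy (data-driven heuristic starts, a
variable-projection grid for the bi-exponential, and fixed-seed random
restarts). Models are ranked by SSE with adjusted-R² and parsimony
tie-breaks; the winner is exposed as a :class:`DRLCurve` that evaluates at
any CBT. A statsmodels-style surface is provided by
:class:`DRLCurveModel` / :class:`DRLCurveResults`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FAMILIES",
    "ModelFamily",
    "ModelFit",
    "DRLCurve",
    "fit_model",
    "gof_metrics",
    "rank_models",
    "fit_all",
    "DRLCurveModel",
    "DRLCurveResults",
]

_TOL = 1e-10
_MAX_NFEV = 10_000
_N_RESTARTS = 20


@dataclass(frozen=True)
class ModelFamily:
    name: str
    n_params: int
    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    label: str

    def __call__(self, t: np.ndarray, params: np.ndarray) -> np.ndarray:
        return self.func(np.asarray(t, dtype=float), np.asarray(params, dtype=float))


def _linear(t, p):
    return p[0] + p[1] * t


def _power1(t, p):
    return p[0] * np.power(t, p[1])


def _power2(t, p):
    return p[0] * np.power(t, p[1]) + p[2]


def _exp1(t, p):
    return p[0] * np.exp(p[1] * t)


def _exp2(t, p):
    return p[0] * np.exp(p[1] * t) + p[2] * np.exp(p[3] * t)


FAMILIES: dict[str, ModelFamily] = {
    "linear": ModelFamily("linear", 2, _linear, "a + b·t"),
    "power1": ModelFamily("power1", 2, _power1, "a·t^b"),
    "power2": ModelFamily("power2", 3, _power2, "a·t^b + c"),
    "exp1": ModelFamily("exp1", 2, _exp1, "a·exp(b·t)"),
    "exp2": ModelFamily("exp2", 4, _exp2, "a·exp(b·t) + c·exp(d·t)"),
}


def gof_metrics(y: np.ndarray, yhat: np.ndarray, n_params: int) -> dict[str, float]:
    """SSE, RMSE, R² and adjusted R² under the residual-dof conventions

    RMSE = sqrt(SSE / (n - p)) and adj-R² = 1 - (1 - R²)(n - 1)/(n - p),
    with SST taken about the mean of the fitted y data.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = len(y)
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -np.inf)
    dof = n - n_params
    rmse = float(np.sqrt(sse / dof)) if dof > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    return {"sse": sse, "rmse": rmse, "r2": r2, "adj_r2": adj_r2}


@dataclass
class ModelFit:
    """One fitted family: parameters in natural units plus goodness of fit."""

    family: ModelFamily
    params: np.ndarray
    gof: dict[str, float]
    n_points: int
    converged: bool
    n_restarts_used: int
    tolerances: dict[str, float] = field(
        default_factory=lambda: {"xtol": _TOL, "ftol": _TOL, "gtol": _TOL}
    )

    @property
    def sse(self) -> float:
        return self.gof["sse"]

    def predict(self, t) -> np.ndarray:
        return self.family(np.asarray(t, dtype=float), self.params)

    def equation_string(self, sig: int = 3) -> str:
        p = [float(f"%.{sig}g" % v) for v in self.params]
        name = self.family.name
        if name == "linear":
            return f"{p[0]} + {p[1]}·CBT"
        if name == "power1":
            return f"{p[0]}·CBT^{p[1]}"
        if name == "power2":
            return f"{p[0]}·CBT^{p[1]} + {p[2]}"
        if name == "exp1":
            tau = float(f"%.{sig}g" % (1.0 / self.params[1]))
            return f"{p[0]}·exp(CBT/{tau})"
        a, b, c, d = self.params
        t1 = float(f"%.{sig}g" % (1.0 / b))
        t2 = float(f"%.{sig}g" % (1.0 / d))
        return f"{p[0]}·exp(CBT/{t1}) + {p[2]}·exp(CBT/{t2})"

    def to_dict(self) -> dict:
        d = {
            "family": self.family.name,
            "params": [float(v) for v in self.params],
            "gof": self.gof,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "tolerances": self.tolerances,
            "equation": self.equation_string(),
        }
        if self.family.name in ("exp1", "exp2"):
            amps = self.params[0::2]
            rates = self.params[1::2]
            d["time_constant_form"] = {
                "amplitudes": [float(v) for v in amps],
                "tau_mm": [float(1.0 / r) if r != 0 else np.inf for r in rates],
            }
        return d


def _canonicalize(family: ModelFamily, params: np.ndarray) -> np.ndarray:
    """Resolve the exp2 component-swap symmetry: order rates b <= d."""
    if family.name == "exp2" and params[1] > params[3]:
        return np.array([params[2], params[3], params[0], params[1]])
    return params


def _heuristic_starts(
    t: np.ndarray, y: np.ndarray, family: ModelFamily
) -> list[np.ndarray]:
    """Data-driven starting points per family."""
    ypos = np.maximum(y, 1e-12)
    starts: list[np.ndarray] = []
    # common building block: linear fit of log(y) on t -> exp1 seed
    A = np.column_stack([np.ones_like(t), t])
    coef_exp, *_ = np.linalg.lstsq(A, np.log(ypos), rcond=None)
    a_e, b_e = float(np.exp(coef_exp[0])), float(coef_exp[1])
    if family.name == "linear":
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        starts.append(coef)
    elif family.name == "power1":
        L = np.column_stack([np.ones_like(t), np.log(t)])
        coef, *_ = np.linalg.lstsq(L, np.log(ypos), rcond=None)
        starts.append(np.array([np.exp(coef[0]), coef[1]]))
    elif family.name == "power2":
        # power1 seed with zero offset, plus a shifted variant
        L = np.column_stack([np.ones_like(t), np.log(t)])
        coef, *_ = np.linalg.lstsq(L, np.log(ypos), rcond=None)
        starts.append(np.array([np.exp(coef[0]), coef[1], 0.0]))
        shift = 0.5 * y.min()
        coef2, *_ = np.linalg.lstsq(L, np.log(np.maximum(y - shift, 1e-12)), rcond=None)
        starts.append(np.array([np.exp(coef2[0]), coef2[1], shift]))
    elif family.name == "exp1":
        starts.append(np.array([a_e, b_e]))
    elif family.name == "exp2":
        # exp1 optimum plus a small fast second component
        span = t.max() - t.min()
        starts.append(np.array([a_e, b_e, 1e-4 * a_e, b_e + 3.0 / max(span, 1.0)]))
        # variable projection over a (slow, fast) rate grid: amplitudes solved linearly
        rates = np.geomspace(0.2 / t.max(), 5.0 / t.min() if t.min() > 0 else 1.0, 12)
        best: list[tuple[float, np.ndarray]] = []
        for i, b in enumerate(rates):
            for d in rates[i + 1 :]:
                B = np.column_stack([np.exp(b * t), np.exp(d * t)])
                amp, *_ = np.linalg.lstsq(B, y, rcond=None)
                r = y - B @ amp
                best.append((float(r @ r), np.array([amp[0], b, amp[1], d])))
        best.sort(key=lambda s: s[0])
        starts.extend(p for _, p in best[:4])
    return starts


def _random_starts(
    t: np.ndarray,
    y: np.ndarray,
    family: ModelFamily,
    base: np.ndarray,
    rng: np.random.Generator,
    n: int,
) -> list[np.ndarray]:
    """Multiplicative/additive perturbations of a base start, fixed seed."""
    out = []
    scale = np.where(np.abs(base) > 1e-12, np.abs(base), y.mean())
    for _ in range(n):
        out.append(base + scale * rng.normal(0, 0.5, size=len(base)))
    return out


def fit_model(
    points: Sequence[tuple[float, float]] | tuple[np.ndarray, np.ndarray],
    family: str | ModelFamily,
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
    nested_start: np.ndarray | None = None,
) -> ModelFit:
    """Trust-region least-squares fit of one family to (CBT, DRL) points.

    Multi-start: data-driven heuristic starts plus ``n_restarts`` fixed-seed
    random perturbations; the best SSE wins. Deterministic given ``seed``.
    Non-convergence of every start yields ``converged=False`` with the best
    parameters found, never an exception.

    Parameters
    ----------
    nested_start : optional explicit extra start, e.g. the optimum of a
        nested family padded with zeros — used to guarantee the nested-model
        SSE inequality.
    """
    fam = FAMILIES[family] if isinstance(family, str) else family
    if isinstance(points, tuple) and len(points) == 2 and np.ndim(points[0]) == 1:
        t = np.asarray(points[0], dtype=float)
        y = np.asarray(points[1], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        t, y = arr[:, 0], arr[:, 1]
    if len(t) <= fam.n_params:
        raise ValueError(
            f"{fam.name} needs more than {fam.n_params} points, got {len(t)}"
        )
    if fam.name.startswith("power") and np.any(t <= 0):
        raise ValueError("power families require CBT > 0")

    rng = np.random.default_rng(seed)
    starts = _heuristic_starts(t, y, fam)
    if nested_start is not None:
        starts.append(np.asarray(nested_start, dtype=float))
    starts.extend(_random_starts(t, y, fam, starts[0], rng, n_restarts))

    def resid(p):
        with np.errstate(over="ignore", invalid="ignore"):
            r = fam(t, p) - y
        return np.where(np.isfinite(r), r, 1e150)

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            res = least_squares(
                resid,
                x0,
                method="trf",
                xtol=_TOL,
                ftol=_TOL,
                gtol=_TOL,
                max_nfev=_MAX_NFEV,
            )
        except Exception:
            continue
        sse = 2.0 * res.cost
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res.x, bool(res.status > 0))
    if best is None:  # every start failed outright
        p0 = starts[0]
        return ModelFit(
            family=fam,
            params=_canonicalize(fam, p0),
            gof=gof_metrics(y, fam(t, p0), fam.n_params),
            n_points=len(t),
            converged=False,
            n_restarts_used=n_used,
        )
    _, params, ok = best
    params = _canonicalize(fam, params)
    return ModelFit(
        family=fam,
        params=params,
        gof=gof_metrics(y, fam(t, params), fam.n_params),
        n_points=len(t),
        converged=ok,
        n_restarts_used=n_used,
    )


def rank_models(fits: Iterable[ModelFit]) -> list[ModelFit]:
    """Ascending SSE; ties by higher adj-R² then fewer params; non-converged last."""
    return sorted(
        fits,
        key=lambda f: (
            not f.converged,
            f.gof["sse"],
            -f.gof["adj_r2"],
            f.family.n_params,
        ),
    )


@dataclass
class DRLCurve:
    """The selected continuous DRL-vs-CBT function for one view."""

    view: str
    fit: ModelFit
    domain: tuple[float, float]

    @classmethod
    def from_coefficients(
        cls,
        view: str,
        family: str,
        params: Sequence[float],
        domain: tuple[float, float] = (20.0, 100.0),
        tau_form: bool = False,
    ) -> "DRLCurve":
        """Build a curve from known coefficients (e.g. a published equation).

        With ``tau_form`` the exponential rates are given as time constants
        (a, tau1, c, tau2 for exp2; a, tau for exp1), the published
        presentation a·exp(t/τ).
        """
        p = np.asarray(params, dtype=float)
        if tau_form:
            if family == "exp1":
                p = np.array([p[0], 1.0 / p[1]])
            elif family == "exp2":
                p = np.array([p[0], 1.0 / p[1], p[2], 1.0 / p[3]])
            else:
                raise ValueError("tau_form only applies to exponential families")
        fam = FAMILIES[family]
        p = _canonicalize(fam, p)
        fit = ModelFit(
            family=fam,
            params=p,
            gof={"sse": np.nan, "rmse": np.nan, "r2": np.nan, "adj_r2": np.nan},
            n_points=0,
            converged=True,
            n_restarts_used=0,
        )
        return cls(view=view, fit=fit, domain=tuple(domain))

    def evaluate(self, cbt, with_flag: bool = False):
        """Closed-form curve value in mGy; optionally an extrapolation flag."""
        val = self.fit.predict(cbt)
        val = float(val) if np.ndim(cbt) == 0 else val
        if with_flag:
            return val, self.is_extrapolation(cbt)
        return val

    __call__ = evaluate

    def is_extrapolation(self, cbt):
        c = np.asarray(cbt, dtype=float)
        flag = (c < self.domain[0]) | (c > self.domain[1])
        return bool(flag) if np.ndim(cbt) == 0 else flag

    def is_valid_drl(self, n_grid: int = 201) -> bool:
        """A usable DRL curve must stay positive over its domain."""
        grid = np.linspace(self.domain[0], self.domain[1], n_grid)
        return bool(np.all(self.fit.predict(grid) > 0))

    def to_dict(self) -> dict:
        return {
            "view": self.view,
            "domain_mm": list(self.domain),
            "valid_drl": self.is_valid_drl(),
            **self.fit.to_dict(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


_NESTING = {"exp2": "exp1", "power2": "power1"}


def _pad_nested(family: str, nested_params: np.ndarray) -> np.ndarray:
    """Embed a nested optimum into the richer family's parameter space."""
    if family == "exp2":
        a, b = nested_params
        return np.array([a, b, 0.0, b])
    if family == "power2":
        a, b = nested_params
        return np.array([a, b, 0.0])
    raise KeyError(family)


def fit_all(
    binned_table,
    families: Iterable[str] = tuple(FAMILIES),
    seed: int = 0,
    n_restarts: int = _N_RESTARTS,
) -> tuple[list[ModelFit], DRLCurve]:
    """Fit every family to a binned DRL table's points; return ranked fits
    and the winning curve for the table's view.

    Raises if fewer than 5 non-empty bins are available (merge adjacent
    extreme bins via a wider :class:`~mammodrl.estimator.BinScheme`).
    """
    t, y = binned_table.fit_points()
    if len(t) < 5:
        raise ValueError(
            f"only {len(t)} non-empty bins; need >= 5 — consider merging "
            "adjacent extreme CBT bins (wider BinScheme)"
        )
    fits = _fit_families((t, y), families, seed, n_restarts)
    ranked = rank_models(fits)
    curve = DRLCurve(
        view=binned_table.view,
        fit=ranked[0],
        domain=(float(t.min()), float(t.max())),
    )
    return ranked, curve


def _fit_families(points, families, seed, n_restarts) -> list[ModelFit]:
    by_name: dict[str, ModelFit] = {}
    order = sorted(families, key=lambda n: FAMILIES[n].n_params)  # nested first
    for name in order:
        nested = _NESTING.get(name)
        nested_start = None
        if nested in by_name:
            nested_start = _pad_nested(name, by_name[nested].params)
        by_name[name] = fit_model(
            points, name, seed=seed, n_restarts=n_restarts, nested_start=nested_start
        )
    return [by_name[n] for n in families]


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------


class DRLCurveModel:
    """DRL-vs-CBT curve model over per-bin DRL points.

    Parameters
    ----------
    cbt, drl : array-like
        Representative CBT (mm) and DRL (mGy) per bin.
    view : str
        Mammographic projection label (CC or MLO) carried into outputs.
    families : iterable of str
        Candidate families to fit (default: all five).

    Examples
    --------
    >>> model = DRLCurveModel.from_binned_table(binned)   # doctest: +SKIP
    >>> res = model.fit(seed=0)                           # doctest: +SKIP
    >>> res.predict(58.0)                                 # doctest: +SKIP
    """

    def __init__(self, cbt, drl, view: str = "CC", families: Iterable[str] = tuple(FAMILIES)):
        self.cbt = np.asarray(cbt, dtype=float)
        self.drl = np.asarray(drl, dtype=float)
        if self.cbt.shape != self.drl.shape:
            raise ValueError("cbt and drl must have equal length")
        self.view = view
        self.families = tuple(families)
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    @classmethod
    def from_binned_table(cls, table, families: Iterable[str] = tuple(FAMILIES)) -> "DRLCurveModel":
        t, y = table.fit_points()
        return cls(t, y, view=table.view, families=families)

    def fit(self, seed: int = 0, n_restarts: int = _N_RESTARTS) -> "DRLCurveResults":
        fits = _fit_families((self.cbt, self.drl), self.families, seed, n_restarts)
        ranked = rank_models(fits)
        curve = DRLCurve(
            view=self.view,
            fit=ranked[0],
            domain=(float(self.cbt.min()), float(self.cbt.max())),
        )
        return DRLCurveResults(self, ranked, curve, seed=seed)


class DRLCurveResults:
    """Fitted candidate families, ranked, with the winner as a DRL curve."""

    def __init__(self, model: DRLCurveModel, fits: list[ModelFit], curve: DRLCurve, seed: int):
        self.model = model
        self.fits = fits
        self.curve = curve
        self.seed = seed

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    @property
    def params(self) -> np.ndarray:
        return self.best.params

    def predict(self, cbt) -> np.ndarray:
        return self.curve.evaluate(cbt)

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "family": f.family.name,
                    "n_params": f.family.n_params,
                    "sse": f.gof["sse"],
                    "rmse": f.gof["rmse"],
                    "r2": f.gof["r2"],
                    "adj_r2": f.gof["adj_r2"],
                    "converged": f.converged,
                }
                for f in self.fits
            ]
        )

    def summary(self) -> str:
        lines = [
            f"DRL curve fit — view {self.model.view}, "
            f"n_points={len(self.model.cbt)}, seed={self.seed}",
            f"domain: {self.curve.domain[0]:.0f}-{self.curve.domain[1]:.0f} mm",
            "",
            f"{'family':<8}{'p':>3}{'SSE':>12}{'RMSE':>10}{'R2':>10}{'adjR2':>10}  conv",
        ]
        for f in self.fits:
            g = f.gof
            lines.append(
                f"{f.family.name:<8}{f.family.n_params:>3}"
                f"{g['sse']:>12.4g}{g['rmse']:>10.4g}{g['r2']:>10.4f}"
                f"{g['adj_r2']:>10.4f}  {'yes' if f.converged else 'NO'}"
            )
        lines += ["", f"selected: {self.best.family.name}: DRL(CBT) = {self.best.equation_string()}"]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<DRLCurveResults view={self.model.view} best={self.best.family.name}>"
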