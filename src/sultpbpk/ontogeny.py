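"""Hepatic sulfotransferase (SULT) ontogeny models and regression machinery.

Human cytosolic SULT isoforms mature on very different postnatal schedules:
SULT1A1 and SULT2A1 start low at birth and rise through infancy, SULT1A3 is
high perinatally and declines, SULT1B1 rises then settles.  This module houses

* three-phase piecewise-linear abundance-vs-age models (the fitted equations
  for SULT1A1, SULT1A3, SULT2A1 and SULT1B1, in pmol per mg cytosolic
  protein), plus a constant profile used for SULT1E1,
* the regression machinery used to derive such models from raw abundance
  observations: five candidate functional forms (exponential, Hill, logistic,
  two-phase piecewise-linear and three-phase piecewise-linear), unweighted
  least squares with multi-start breakpoint search, and AIC-based selection.

The statsmodels-style entry point is :class:`OntogenyRegression`; its
``fit``/``fit_all``/``select`` return :class:`OntogenyFit` results objects.
Functional wrappers (:func:`fit_ontogeny`, :func:`select_best`) mirror the
same operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "AbundanceRecord",
    "OntogenyPiecewise3",
    "ConstantOntogeny",
    "OntogenyFit",
    "OntogenyRegression",
    "ADULT_REFERENCE_AGE",
    "CANDIDATE_FORMS",
    "builtin_ontogeny_library",
    "evaluate_abundance",
    "relative_activity",
    "fit_ontogeny",
    "select_best",
]

#: Age (years) used as the adult reference when converting abundance curves
#: into relative-activity multipliers.  All built-in models are in their
#: final (plateau) phase well before this age, and in vitro Vmax values are
#: measured in adult tissue.
ADULT_REFERENCE_AGE = 20.0


@dataclass(frozen=True)
class AbundanceRecord:
    """One measured enzyme abundance: ``enzyme`` at ``age`` years (postnatal),
    ``abundance`` in pmol per mg cytosolic protein."""

    enzyme: str
    age: float
    abundance: float

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"age must be >= 0, got {self.age}")
        if self.abundance <= 0:
            raise ValueError(f"abundance must be > 0, got {self.abundance}")


def records_to_frame(records: Iterable[AbundanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.enzyme, r.age, r.abundance) for r in records],
        columns=["enzyme", "age_years", "abundance_pmol_per_mg"],
    )


def records_from_frame(frame: pd.DataFrame) -> list[AbundanceRecord]:
    """Read abundance records from the CSV dialect
    (columns enzyme, age_years, abundance_pmol_per_mg)."""
    return [
        AbundanceRecord(str(row.enzyme), float(row.age_years), float(row.abundance_pmol_per_mg))
        for row in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Ontogeny model objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OntogenyPiecewise3:
    """Three-phase piecewise-linear abundance-vs-age curve.

    Phase 1 (``age < breakpoint1``):           intercept1 + slope1 * age
    Phase 2 (``breakpoint1 <= age <= breakpoint2``):
                                               anchor2 + slope2 * (age - breakpoint1)
    Phase 3 (``age > breakpoint2``):           plateau (exactly constant)

    The phases are evaluated exactly as parameterised; a jump between the
    phase-1 limit and ``anchor2`` is permitted (no smoothing is applied), so
    the curve is piecewise-continuous but not necessarily continuous at
    ``breakpoint1``.
    """

    intercept1: float
    slope1: float
    breakpoint1: float
    anchor2: float
    slope2: float
    breakpoint2: float
    plateau: float

    def __post_init__(self) -> None:
        if not 0 < self.breakpoint1 < self.breakpoint2:
            raise ValueError("require 0 < breakpoint1 < breakpoint2")
        if self.plateau <= 0:
            raise ValueError("plateau must be > 0")

    def abundance(self, age):
        """Abundance (pmol/mg cytosolic protein) at ``age`` years (scalar or array)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        out = np.where(
            age < self.breakpoint1,
            self.intercept1 + self.slope1 * age,
            np.where(
                age <= self.breakpoint2,
                self.anchor2 + self.slope2 * (age - self.breakpoint1),
                self.plateau,
            ),
        )
        return float(out) if out.ndim == 0 else out

    def relative_activity(self, age, reference_age: float = ADULT_REFERENCE_AGE):
        """Abundance at ``age`` divided by abundance at ``reference_age``."""
        ref = self.abundance(reference_age)
        if ref <= 0:
            raise ValueError("reference abundance must be positive")
        return self.abundance(age) / ref

    def to_dict(self) -> dict:
        return {
            "form": "piecewise3",
            "intercept1": self.intercept1,
            "slope1": self.slope1,
            "breakpoint1": self.breakpoint1,
            "anchor2": self.anchor2,
            "slope2": self.slope2,
            "breakpoint2": self.breakpoint2,
            "plateau": self.plateau,
        }


@dataclass(frozen=True)
class ConstantOntogeny:
    """Age-invariant profile (used for SULT1E1): relative activity is 1 at
    every age."""

    plateau: float = 1.0

    def abundance(self, age):
        age = np.asarray(age, dtype=float)
        if np.any(age < 0):
            raise ValueError("age must be >= 0")
        out = np.full_like(age, self.plateau, dtype=float)
        return float(out) if out.ndim == 0 else out

    def relative_activity(self, age, reference_age: float = ADULT_REFERENCE_AGE):
        age = np.asarray(age, dtype=float)
        out = np.ones_like(age, dtype=float)
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {"form": "constant", "plateau": self.plateau}


def evaluate_abundance(model, age):
    """Evaluate an ontogeny model's abundance at ``age`` (years, >= 0)."""
    return model.abundance(age)


def relative_activity(model, age, reference_age: float = ADULT_REFERENCE_AGE):
    """Abundance ratio ``abundance(age) / abundance(reference_age)``; equals 1
    at the reference age by construction."""
    return model.relative_activity(age, reference_age)


# Fitted three-phase piecewise equations, abundance in pmol/mg cytosolic
# protein, age in postnatal years.  Phase-3 plateaus are the printed values
# (the phase-2 limit at breakpoint2 agrees to rounding).
_BUILTIN = {
    "SULT1A1": OntogenyPiecewise3(107.8, 88.6, 1.83, 370.1, 6.99, 12.6, 445.2),
    "SULT1A3": OntogenyPiecewise3(117.3, -28.7, 2.0, 60.0, 5.66, 8.6, 97.2),
    "SULT2A1": OntogenyPiecewise3(705.3, 975.2, 1.2, 1893.0, -65.5, 13.2, 1095.0),
    "SULT1B1": OntogenyPiecewise3(45.5, 37.3, 2.6, 140.6, -4.69, 8.1, 115.0),
    "SULT1E1": ConstantOntogeny(1.0),
}


def builtin_ontogeny_library() -> dict:
    """The fitted SULT ontogeny models (SULT1A1/1A3/2A1/1B1 three-phase
    piecewise; SULT1E1 constant), keyed by enzyme name.

    SULT1B1 is included for completeness even though acetaminophen carries no
    SULT1B1 pathway.  Non-SULT (UGT/CYP) maturation profiles live in
    :mod:`sultpbpk.physiology`.
    """
    return dict(_BUILTIN)


# ---------------------------------------------------------------------------
# Candidate functional forms
# ---------------------------------------------------------------------------

def _f_exponential(age, a, b, k):
    # A - B*exp(-k*age): rises (or falls) from A-B at birth toward A.
    return a - b * np.exp(-k * age)


def _f_hill(age, base, emax, a50, h):
    age = np.maximum(age, 0.0)
    a50 = abs(a50) + 1e-12
    h = np.clip(h, 0.05, 20.0)
    return base + emax * age**h / (a50**h + age**h)


def _f_logistic(age, base, span, k, x0):
    z = np.clip(-k * (age - x0), -700.0, 700.0)
    return base + span / (1.0 + np.exp(z))


def _f_piecewise_linear(age, c1, s1, bp, s2):
    # Continuous two-phase line with a slope change at bp.
    return c1 + s1 * np.minimum(age, bp) + s2 * np.maximum(age - bp, 0.0)


def _f_piecewise3(age, c1, s1, bp1, a2, s2, bp2):
    return np.where(
        age < bp1,
        c1 + s1 * age,
        np.where(age <= bp2, a2 + s2 * (age - bp1), a2 + s2 * (bp2 - bp1)),
    )


@dataclass(frozen=True)
class _FormSpec:
    name: str
    n_params: int
    func: Callable
    param_names: tuple


CANDIDATE_FORMS: Mapping[str, _FormSpec] = {
    "exponential": _FormSpec("exponential", 3, _f_exponential, ("a", "b", "k")),
    "hill": _FormSpec("hill", 4, _f_hill, ("base", "emax", "a50", "h")),
    "logistic": _FormSpec("logistic", 4, _f_logistic, ("base", "span", "k", "x0")),
    "piecewise_linear": _FormSpec(
        "piecewise_linear", 4, _f_piecewise_linear, ("c1", "s1", "bp", "s2")
    ),
    "piecewise3": _FormSpec(
        "piecewise3", 6, _f_piecewise3, ("intercept1", "slope1", "breakpoint1", "anchor2", "slope2", "breakpoint2")
    ),
}


# ---------------------------------------------------------------------------
# Fit results
# ---------------------------------------------------------------------------


@dataclass
class OntogenyFit:
    """Least-squares fit of one candidate form to abundance-vs-age data.

    AIC uses the least-squares form ``n*ln(RSS/n) + 2*(k+1)`` with ``k`` the
    number of structural parameters (+1 for the error variance).  Only AIC
    differences between candidates fitted to the same records are meaningful.
    """

    form: str
    params: np.ndarray
    rss: float
    aic: float
    r2: float
    n: int
    converged: bool = True
    param_names: tuple = field(default_factory=tuple)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, age):
        return CANDIDATE_FORMS[self.form].func(np.asarray(age, dtype=float), *self.params)

    def as_model(self):
        """Convert a piecewise3 fit into an :class:`OntogenyPiecewise3`."""
        if self.form != "piecewise3":
            raise ValueError(f"cannot convert form {self.form!r} to a piecewise model")
        c1, s1, bp1, a2, s2, bp2 = self.params
        return OntogenyPiecewise3(c1, s1, bp1, a2, s2, bp2, a2 + s2 * (bp2 - bp1))

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "params": dict(zip(self.param_names, [float(p) for p in self.params])),
            "rss": float(self.rss),
            "aic": float(self.aic),
            "r2": float(self.r2),
            "n": int(self.n),
            "converged": bool(self.converged),
        }

    def summary(self) -> str:
        lines = [
            f"Ontogeny fit: {self.form}",
            f"  n obs      : {self.n}",
            f"  RSS        : {self.rss:.6g}",
            f"  R-squared  : {self.r2:.4f}",
            f"  AIC        : {self.aic:.2f}",
            f"  converged  : {self.converged}",
            "  parameters :",
        ]
        for name, val in zip(self.param_names, self.params):
            lines.append(f"    {name:<12} {val:.6g}")
        return "\n".join(lines)


def _fit_statistics(form: str, params, ages, values) -> OntogenyFit:
    spec = CANDIDATE_FORMS[form]
    pred = spec.func(ages, *params)
    resid = values - pred
    rss = float(resid @ resid)
    n = len(values)
    tss = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    k = spec.n_params + 1  # + error variance
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * k
    return OntogenyFit(
        form=form,
        params=np.asarray(params, dtype=float),
        rss=rss,
        aic=float(aic),
        r2=r2,
        n=n,
        param_names=spec.param_names,
    )


# ---------------------------------------------------------------------------
# Regression engine
# ---------------------------------------------------------------------------


class OntogenyRegression:
    """Unweighted, unstratified least-squares regression of enzyme abundance
    on age, over a set of candidate functional forms.

    Parameters
    ----------
    data
        ``AbundanceRecord`` sequence or a DataFrame with columns
        ``age_years`` and ``abundance_pmol_per_mg``.
    forms
        Candidate form names (default: all five).

    Breakpoints of the piecewise forms are free parameters: a grid over age
    quantiles is scanned with the conditional linear least-squares solution
    evaluated in closed form at each grid point, and the best grid point is
    refined by a local simplex search.  The procedure is deterministic.
    """

    def __init__(self, data, forms: Sequence[str] | None = None):
        if isinstance(data, pd.DataFrame):
            ages = data["age_years"].to_numpy(dtype=float)
            values = data["abundance_pmol_per_mg"].to_numpy(dtype=float)
        else:
            recs = list(data)
            ages = np.array([r.age for r in recs], dtype=float)
            values = np.array([r.abundance for r in recs], dtype=float)
        order = np.argsort(ages, kind="stable")
        self.ages = ages[order]
        self.values = values[order]
        self.forms = list(forms) if forms is not None else list(CANDIDATE_FORMS)
        for f in self.forms:
            if f not in CANDIDATE_FORMS:
                raise ValueError(f"unknown candidate form {f!r}")

    # -- preconditions ------------------------------------------------------

    def _check_design(self, form: str) -> None:
        spec = CANDIDATE_FORMS[form]
        n = len(self.ages)
        if n < spec.n_params + 2:
            raise ValueError(
                f"{form} needs at least {spec.n_params + 2} records, got {n}"
            )
        if np.unique(self.ages).size < spec.n_params:
            raise ValueError(
                f"degenerate design: only {np.unique(self.ages).size} distinct ages "
                f"for form {form!r} with {spec.n_params} parameters"
            )

    # -- piecewise conditional least squares --------------------------------

    @property
    def _min_segment(self) -> int:
        # breakpoint segments must hold a minimum share of the data so that
        # free breakpoints cannot isolate one or two high-leverage points
        return max(3, int(np.ceil(0.05 * len(self.ages))))

    def _pw3_profile_rss(self, bp1: float, bp2: float):
        """Closed-form LS solution for the linear coefficients given breakpoints.

        Phase 2 and the plateau share (anchor2, slope2); the plateau is the
        phase-2 value at bp2 (continuity at the second breakpoint only)."""
        a, y = self.ages, self.values
        m1 = a < bp1
        m23 = ~m1
        m2 = m23 & (a <= bp2)
        if m1.sum() < self._min_segment or m2.sum() < 2 or m23.sum() < self._min_segment:
            return np.inf, None
        X1 = np.column_stack([np.ones(m1.sum()), a[m1]])
        beta1, res1, *_ = np.linalg.lstsq(X1, y[m1], rcond=None)
        x2 = np.minimum(a[m23], bp2) - bp1
        X2 = np.column_stack([np.ones(m23.sum()), x2])
        beta2, res2, *_ = np.linalg.lstsq(X2, y[m23], rcond=None)
        rss = float(np.sum((X1 @ beta1 - y[m1]) ** 2) + np.sum((X2 @ beta2 - y[m23]) ** 2))
        params = np.array([beta1[0], beta1[1], bp1, beta2[0], beta2[1], bp2])
        return rss, params

    def _pwl_profile_rss(self, bp: float):
        a, y = self.ages, self.values
        if (a < bp).sum() < self._min_segment or (a > bp).sum() < self._min_segment:
            return np.inf, None
        X = np.column_stack([np.ones_like(a), np.minimum(a, bp), np.maximum(a - bp, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ beta - y) ** 2))
        return rss, np.array([beta[0], beta[1], bp, beta[2]])

    def _fit_piecewise3(self) -> OntogenyFit:
        qs = np.unique(np.quantile(self.ages, np.linspace(0.05, 0.95, 19)))
        best = (np.inf, None)
        for i, b1 in enumerate(qs):
            for b2 in qs[i + 1 :]:
                if b2 <= b1 + 1e-9:
                    continue
                rss, params = self._pw3_profile_rss(b1, b2)
                if rss < best[0]:
                    best = (rss, params)
        if best[1] is None:
            raise ValueError("piecewise3 breakpoint search found no admissible split")

        def objective(bps):
            b1, b2 = bps
            if not (self.ages.min() < b1 < b2 < self.ages.max()):
                return np.inf
            return self._pw3_profile_rss(b1, b2)[0]

        res = optimize.minimize(
            objective,
            x0=[best[1][2], best[1][5]],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
        )
        rss, params = self._pw3_profile_rss(*res.x)
        if not np.isfinite(rss) or rss > best[0]:
            rss, params = best
        return _fit_statistics("piecewise3", params, self.ages, self.values)

    def _fit_piecewise_linear(self) -> OntogenyFit:
        qs = np.unique(np.quantile(self.ages, np.linspace(0.05, 0.95, 37)))
        best = (np.inf, None)
        for bp in qs:
            rss, params = self._pwl_profile_rss(bp)
            if rss < best[0]:
                best = (rss, params)
        if best[1] is None:
            raise ValueError("piecewise_linear breakpoint search found no admissible split")
        res = optimize.minimize_scalar(
            lambda b: self._pwl_profile_rss(b)[0]
            if self.ages.min() < b < self.ages.max()
            else np.inf,
            bracket=None,
            bounds=(self.ages.min() + 1e-9, self.ages.max() - 1e-9),
            method="bounded",
            options={"xatol": 1e-6},
        )
        rss, params = self._pwl_profile_rss(float(res.x))
        if not np.isfinite(rss) or rss > best[0]:
            rss, params = best
        return _fit_statistics("piecewise_linear", params, self.ages, self.values)

    # -- smooth forms: multi-start curve fitting ----------------------------

    def _smooth_starts(self, form: str) -> list[np.ndarray]:
        y, a = self.values, self.ages
        lo, hi = float(y.min()), float(y.max())
        span = max(hi - lo, 1e-6)
        mid_ages = np.quantile(a[a > 0], [0.25, 0.5, 0.75]) if np.any(a > 0) else [1.0]
        starts = []
        if form == "exponential":
            for tau in (0.5, 2.0, 8.0):
                starts.append(np.array([hi, span, 1.0 / tau]))
                starts.append(np.array([lo, -span, 1.0 / tau]))
        elif form == "hill":
            for a50 in mid_ages:
                for h in (1.0, 2.0):
                    starts.append(np.array([lo, span, max(a50, 1e-3), h]))
                    starts.append(np.array([hi, -span, max(a50, 1e-3), h]))
        elif form == "logistic":
            for x0 in mid_ages:
                for k in (0.5, 2.0):
                    starts.append(np.array([lo, span, k, x0]))
                    starts.append(np.array([hi, -span, k, x0]))
        return starts

    def _fit_smooth(self, form: str) -> OntogenyFit:
        spec = CANDIDATE_FORMS[form]
        best_rss, best_params, any_ok = np.inf, None, False
        for p0 in self._smooth_starts(form):
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(
                        spec.func, self.ages, self.values, p0=p0, maxfev=20000
                    )
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            resid = self.values - spec.func(self.ages, *popt)
            rss = float(resid @ resid)
            if np.isfinite(rss) and rss < best_rss:
                best_rss, best_params, any_ok = rss, popt, True
        if not any_ok:
            # Flagged, not raised: return the best constant model as a
            # non-converged placeholder so callers can inspect it.
            const = np.zeros(spec.n_params)
            const[0] = self.values.mean()
            fit = _fit_statistics(form, const, self.ages, self.values)
            fit.converged = False
            return fit
        return _fit_statistics(form, best_params, self.ages, self.values)

    # -- public API ---------------------------------------------------------

    def fit(self, form: str) -> OntogenyFit:
        self._check_design(form)
        if form == "piecewise3":
            return self._fit_piecewise3()
        if form == "piecewise_linear":
            return self._fit_piecewise_linear()
        return self._fit_smooth(form)

    def fit_all(self) -> list[OntogenyFit]:
        return [self.fit(f) for f in self.forms]

    def select(self) -> OntogenyFit:
        return select_best(self.fit_all())


def fit_ontogeny(records, form: str) -> OntogenyFit:
    """Fit one candidate form to abundance records by unweighted least squares."""
    return OntogenyRegression(records, forms=[form]).fit(form)


def select_best(fits: Sequence[OntogenyFit]) -> OntogenyFit:
    """Minimum-AIC fit; AIC ties are broken in favour of fewer parameters."""
    fits = list(fits)
    if not fits:
        raise ValueError("select_best requires at least one fit")
    return min(fits, key=lambda f: (round(f.aic, 9), f.n_params))
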