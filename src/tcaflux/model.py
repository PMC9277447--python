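"""Flux estimation from multiplet ratio tables.

`IsotopomerFluxModel` is the statsmodels-style entry point: construct it from
an observed :class:`~pandas.DataFrame` of multiplet signal ratios (the TSV
dialect of :mod:`tcaflux.tables`), call :meth:`fit` to obtain a
:class:`FluxFitResults` carrying the estimated relative fluxes (PDH, Y_PC,
PK, Ys; citrate synthase = 1), the weighted least-squares objective, the
per-start trace, an AICc for model comparison, and (after
:meth:`FluxFitResults.bootstrap_ci`) residual-bootstrap confidence
intervals.

The constraint pk <= y_pc + y_s (cycling cannot exceed cataplerosis) is
enforced by reparameterization: internally the optimizer searches a
rectangular box over (f_pdh, y_pc, c, y_s) with pk = c * (y_pc + y_s),
c in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .multiplets import CouplingScheme, ZeroAreaError, default_scheme, multiplet_pattern, signal_ratio_table
from .network import FluxParameters, TCANetwork, TracerSpec, build_tca_network
from .tables import TABLE_COLUMNS

__all__ = [
    "DEFAULT_START",
    "IsotopomerFluxModel",
    "FluxFitResults",
    "FailedFit",
    "GroupTestResult",
    "predict_ratios",
    "fit_fluxes",
    "fit_per_sample",
    "condition_summary",
    "bootstrap_ci",
    "compare_models",
    "group_compare",
]

#: conventional initial flux vector (PDH, PK, Y_PC, Ys) = (0.2, 0.3, 0.1, 0.2)
DEFAULT_START = FluxParameters(f_pdh=0.2, y_pc=0.1, pk=0.3, y_s=0.2)

_FLUX_NAMES = ("f_pdh", "y_pc", "pk", "y_s")

# residual value substituted when a candidate flux vector leaves a quantified
# resonance with zero area (fractions undefined); large enough to repel the
# optimizer, finite so the search continues
_PENALTY = 1e3


def predict_ratios(
    fluxes: FluxParameters,
    tracer: TracerSpec | None = None,
    variant: str = "full",
    scheme: CouplingScheme | None = None,
    tolerance: float = 1e-10,
) -> pd.DataFrame:
    """Noise-free model-predicted ratio table: steady state -> multiplets."""
    tracer = tracer or TracerSpec()
    net = build_tca_network(variant)
    state = net.steady_state(fluxes, tracer, tolerance=tolerance)
    return signal_ratio_table(state.distributions, scheme or default_scheme())


# ---------------------------------------------------------------------------
# internal parameterization per model variant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Param:
    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def to_fluxes(self, x: np.ndarray) -> FluxParameters:
        d = dict(zip(self.names, (float(v) for v in x)))
        f_pdh = d["f_pdh"]
        y_pc = d.get("y_pc", 0.0)
        y_s = d["y_s"]
        pk = d.get("c", 0.0) * (y_pc + y_s)
        return FluxParameters(f_pdh=f_pdh, y_pc=y_pc, pk=pk, y_s=y_s)

    def from_fluxes(self, f: FluxParameters) -> np.ndarray:
        c = f.pk / f.pepck if f.pepck > 0 else 0.0
        d = {"f_pdh": f.f_pdh, "y_pc": f.y_pc, "c": min(max(c, 0.0), 1.0), "y_s": f.y_s}
        x = np.array([d[n] for n in self.names])
        return np.clip(x, self.lower, self.upper)


_PARAMS = {
    "full": _Param(("f_pdh", "y_pc", "c", "y_s"),
                   np.zeros(4), np.array([1.0, 5.0, 1.0, 5.0])),
    "no_cycling": _Param(("f_pdh", "y_pc", "y_s"),
                         np.zeros(3), np.array([1.0, 5.0, 5.0])),
    "no_pc": _Param(("f_pdh", "c", "y_s"),
                    np.zeros(3), np.array([1.0, 1.0, 5.0])),
}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FluxFitResults:
    """Estimates and diagnostics from :meth:`IsotopomerFluxModel.fit`."""

    model: "IsotopomerFluxModel"
    params: FluxParameters
    x_internal: np.ndarray
    objective: float
    n_residuals: int
    starts: list[tuple[FluxParameters, float]]
    variant: str
    aicc: float
    n_free: int
    ci: dict[str, tuple[float, float]] | None = None
    ci_level: float | None = None
    converged: bool = True

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    def conf_int(self) -> dict[str, tuple[float, float]]:
        if self.ci is None:
            raise ValueError("no confidence intervals: call bootstrap_ci() first")
        return self.ci

    def bootstrap_ci(self, n_resamples: int = 200, level: float = 0.95, seed: int = 0) -> "FluxFitResults":
        """Parametric bootstrap confidence intervals.

        Each resample regenerates the data from the fitted model through the
        measurement-noise mechanism the tables are assumed to carry:
        independent Gaussian area noise (scale estimated from the residuals
        by moment matching), clipped at zero and renormalized within each
        resonance. Naive residual resampling ignores the per-resonance
        correlation and censoring of that noise and measurably under-covers
        here. Returns a copy of these results with per-flux percentile
        intervals attached; reproducible for a fixed seed; refuses when the
        fit did not converge.
        """
        if not self.converged:
            raise ValueError("cannot bootstrap an unconverged fit")
        if n_resamples < 50:
            raise ValueError("n_resamples must be >= 50")
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        rng = np.random.default_rng(seed)
        self.model._warm = None  # path-independent: identical seeds, identical CIs
        yhat = self.fittedvalues
        sigma, dof = self.model._noise_scale(yhat, self.n_free)
        groups = self.model._resonance_groups()
        n = len(yhat)
        draws = np.empty((n_resamples, 4))
        for b in range(n_resamples):
            # chi-square draw propagates the uncertainty of sigma itself
            sigma_b = sigma * np.sqrt(dof / rng.chisquare(dof)) if sigma > 0 else 0.0
            noisy = np.clip(yhat + rng.normal(0.0, sigma_b, size=n), 0.0, None)
            y_star = noisy.copy()
            for idx in groups:
                total = noisy[idx].sum()
                if total > 0:
                    y_star[idx] = noisy[idx] / total
            # refit from the point estimate; looser tolerances suffice for
            # percentile intervals
            x_b, _sse = self.model._minimize(self.x_internal, y_star, tol=1e-9)
            f_b = self.model._param.to_fluxes(x_b)
            draws[b] = [getattr(f_b, k) for k in _FLUX_NAMES]
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(draws, alpha, axis=0)
        hi = np.quantile(draws, 1.0 - alpha, axis=0)
        est = np.array([getattr(self.params, k) for k in _FLUX_NAMES])
        ci = {
            k: (float(min(lo[i], est[i])), float(max(hi[i], est[i])))
            for i, k in enumerate(_FLUX_NAMES)
        }
        out = replace(self, ci=ci, ci_level=level)
        return out

    def to_dict(self) -> dict:
        d = {
            "variant": self.variant,
            "estimate": self.params.as_dict(),
            "objective": self.objective,
            "n_residuals": self.n_residuals,
            "n_free_parameters": self.n_free,
            "aicc": self.aicc,
            "converged": self.converged,
            "starts": [
                {"initial": f0.as_dict(), "objective": obj} for f0, obj in self.starts
            ],
        }
        if self.ci is not None:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
            d["ci_level"] = self.ci_level
        return d

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = [
            "Isotopomer flux fit (CS = 1)",
            "=" * 46,
            f"model variant:   {self.variant}",
            f"n residuals:     {self.n_residuals}",
            f"free parameters: {self.n_free}",
            f"objective (SSE): {self.objective:.6g}",
            f"AICc:            {self.aicc:.4g}",
            f"starts tried:    {len(self.starts)}",
            "-" * 46,
        ]
        header = f"{'flux':>6} {'estimate':>10}"
        if self.ci is not None:
            header += f" {'ci_low':>10} {'ci_high':>10}"
        lines.append(header)
        for k in _FLUX_NAMES:
            row = f"{k:>6} {getattr(self.params, k):>10.4f}"
            if self.ci is not None:
                lo, hi = self.ci[k]
                row += f" {lo:>10.4f} {hi:>10.4f}"
            lines.append(row)
        lines.append(f"{'cs':>6} {1.0:>10.4f}  (reference)")
        lines.append("=" * 46)
        return "\n".join(lines)


@dataclass(frozen=True)
class FailedFit:
    """Placeholder in a model ranking for a variant whose fit failed."""

    variant: str
    error: str
    aicc: float = math.inf


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class IsotopomerFluxModel:
    """Weighted nonlinear least-squares flux model for one ratio table.

    Parameters
    ----------
    observed : pandas.DataFrame
        Ratio table in the canonical dialect (one sample, or pooled rows; use
        :func:`fit_per_sample` to fit replicates individually).
    tracer : TracerSpec
        Tracer enrichment and glycolytic inflow.
    variant : str
        'full', 'no_cycling' or 'no_pc'.
    include_lactate : bool
        Whether lactate C2 multiplets enter the objective (default True;
        they carry the pyruvate-cycling signature).
    solver_tolerance : float
        L1 tolerance of the steady-state solver.
    """

    def __init__(
        self,
        observed: pd.DataFrame,
        tracer: TracerSpec | None = None,
        variant: str = "full",
        include_lactate: bool = True,
        scheme: CouplingScheme | None = None,
        solver_tolerance: float = 1e-10,
    ):
        if variant not in _PARAMS:
            raise ValueError(f"unknown model variant {variant!r}")
        self.tracer = tracer or TracerSpec()
        self.variant = variant
        self.scheme = scheme or default_scheme()
        self.network: TCANetwork = build_tca_network(variant)
        self.solver_tolerance = solver_tolerance
        self._param = _PARAMS[variant]
        self._warm: dict[str, np.ndarray] | None = None

        df = observed
        keep = df["pool"].isin(("GLU", "LAC") if include_lactate else ("GLU",))
        df = df.loc[keep]
        if len(df) == 0:
            raise ValueError("observed table contains no usable rows")
        self.data = df.reset_index(drop=True)
        self.endog = self.data["ratio"].to_numpy(dtype=float)
        if np.all(self.endog == 0):
            raise ValueError("degenerate table: all ratios are zero")
        sem = pd.to_numeric(self.data["sem"], errors="coerce").to_numpy(dtype=float)
        w = np.ones_like(self.endog)
        usable = np.isfinite(sem) & (sem > 0)
        w[usable] = 1.0 / sem[usable] ** 2
        self.weights = w
        self._sqrtw = np.sqrt(w)
        self._keys = list(zip(self.data["pool"], self.data["position"], self.data["multiplet"]))
        if len(self.endog) < len(self._param.names):
            raise ValueError("fewer informative rows than free parameters")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "IsotopomerFluxModel":
        from .tables import read_ratio_table

        return cls(read_ratio_table(path), **kwargs)

    # -- forward model ------------------------------------------------------

    def predict(self, fluxes: FluxParameters) -> np.ndarray:
        """Predicted ratios aligned with the observed rows."""
        state = self.network.steady_state(
            fluxes, self.tracer, tolerance=self.solver_tolerance, init=self._warm
        )
        self._warm = {p: d.probs for p, d in state.distributions.items()}
        comps: dict[tuple[str, int, str], float] = {}
        pools = {"GLU": "AKG_GLU", "LAC": "LAC"}
        needed = {(k[0], k[1]) for k in self._keys}
        for pool_label, pos in needed:
            pat = multiplet_pattern(state.distributions[pools[pool_label]], pos, self.scheme)
            for lab, frac in pat.components.items():
                comps[(pool_label, pos, lab)] = frac
        return np.array([comps[k] for k in self._keys])

    def _resonance_groups(self) -> list[np.ndarray]:
        """Row indices of each (sample, pool, position) resonance."""
        if not hasattr(self, "_groups_cache"):
            grouped = self.data.groupby(["sample_id", "pool", "position"], sort=False)
            self._groups_cache = [np.asarray(ix) for _, ix in grouped.groups.items()]
        return self._groups_cache

    def _noise_scale(self, yhat: np.ndarray, n_free: int) -> tuple[float, int]:
        """Area-noise sd by moment matching on unclipped rows.

        Renormalization within an m-component resonance turns iid area noise
        of variance s^2 into row variance s^2 (1 - 2 p + m p^2) for a
        component with fraction p; rows with tiny fractions are additionally
        censored by clipping, so only rows with p in [0.05, 0.95] enter.
        Returns (sd estimate, residual degrees of freedom behind it).
        """
        r = self.endog - yhat
        g = np.empty_like(yhat)
        for idx in self._resonance_groups():
            m = len(idx)
            p = yhat[idx]
            g[idx] = 1.0 - 2.0 * p + m * p**2
        use = (yhat >= 0.05) & (yhat <= 0.95)
        if not np.any(use):
            use = np.ones_like(yhat, dtype=bool)
        n_u = int(use.sum())
        dof = max(n_u - n_free, 1)
        sd = float(np.sqrt(np.sum(r[use] ** 2) / np.sum(g[use]) * n_u / dof))
        return sd, dof

    def _residuals(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        fluxes = self._param.to_fluxes(x)
        try:
            pred = self.predict(fluxes)
        except ZeroAreaError:
            return np.full_like(y, _PENALTY)
        return self._sqrtw * (pred - y)

    def _minimize(self, x0: np.ndarray, y: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, float]:
        sol = optimize.least_squares(
            self._residuals,
            np.clip(x0, self._param.lower, self._param.upper),
            bounds=(self._param.lower, self._param.upper),
            args=(y,),
            method="trf",
            ftol=tol,
            xtol=tol,
            gtol=tol,
        )
        return sol.x, float(np.sum(sol.fun**2))

    # -- fitting ------------------------------------------------------------

    def default_starts(self, n_starts: int = 10, seed: int = 0) -> list[FluxParameters]:
        """The conventional start vector plus seeded space-filling restarts
        drawn uniformly from the bounded search box."""
        starts = [DEFAULT_START]
        rng = np.random.default_rng(seed)
        for _ in range(max(0, n_starts - 1)):
            x = rng.uniform(self._param.lower, self._param.upper)
            starts.append(self._param.to_fluxes(x))
        return starts

    def fit(
        self,
        starts: list[FluxParameters] | None = None,
        n_starts: int = 10,
        seed: int = 0,
    ) -> FluxFitResults:
        """Best-of-starts bounded least squares.

        Ties between converged starts (objectives within 1e-10) are broken by
        first-found order; bit-identical results for identical inputs + seed.
        """
        if starts is None:
            starts = self.default_starts(n_starts=n_starts, seed=seed)
        if not starts:
            raise ValueError("at least one start is required")
        self._warm = None
        y = self.endog
        trace: list[tuple[FluxParameters, float]] = []
        best: tuple[np.ndarray, float] | None = None
        errors: list[str] = []
        for f0 in starts:
            try:
                x_hat, sse = self._minimize(self._param.from_fluxes(f0), y)
            except Exception as exc:  # noqa: BLE001 - annotate, try next start
                errors.append(str(exc))
                continue
            trace.append((f0, sse))
            if best is None or sse < best[1] - 1e-10:
                best = (x_hat, sse)
        if best is None:
            raise RuntimeError(
                "no start converged: " + ("; ".join(errors) or "unknown failure")
            )
        x_hat, sse = best
        n = len(y)
        k = len(self._param.names)
        aicc = n * math.log(max(sse, 1e-300) / n) + 2 * k
        if n - k - 1 > 0:
            aicc += 2 * k * (k + 1) / (n - k - 1)
        return FluxFitResults(
            model=self,
            params=self._param.to_fluxes(x_hat),
            x_internal=x_hat,
            objective=sse,
            n_residuals=n,
            starts=trace,
            variant=self.variant,
            aicc=aicc,
            n_free=k,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------


def fit_fluxes(
    observed: pd.DataFrame,
    tracer: TracerSpec | None = None,
    variant: str = "full",
    starts: list[FluxParameters] | None = None,
    n_starts: int = 10,
    seed: int = 0,
    include_lactate: bool = True,
) -> FluxFitResults:
    """Fit the flux vector to an observed ratio table (all rows pooled)."""
    model = IsotopomerFluxModel(
        observed, tracer=tracer, variant=variant, include_lactate=include_lactate
    )
    return model.fit(starts=starts, n_starts=n_starts, seed=seed)


def fit_per_sample(observed: pd.DataFrame, **kwargs) -> dict[str, FluxFitResults]:
    """Fit each sample_id in the table independently."""
    out = {}
    for sample_id, sub in observed.groupby("sample_id", sort=False):
        out[str(sample_id)] = fit_fluxes(sub, **kwargs)
    return out


def condition_summary(fits: dict[str, FluxFitResults], conditions: dict[str, str] | None = None) -> pd.DataFrame:
    """Mean +/- SEM of per-sample flux estimates, by condition."""
    rows = []
    for sample_id, res in fits.items():
        cond = (conditions or {}).get(sample_id)
        if cond is None:
            cond = str(res.model.data["condition"].iloc[0])
        row = {"sample_id": sample_id, "condition": cond}
        row.update(res.params.as_dict())
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    grouped = per_sample.groupby("condition", sort=False)[list(_FLUX_NAMES)]
    mean = grouped.mean()
    sem = grouped.sem(ddof=1)
    out = mean.join(sem, lsuffix="_mean", rsuffix="_sem")
    out.insert(0, "n", grouped.size())
    return out.reset_index()


def bootstrap_ci(
    observed: pd.DataFrame,
    fit: FluxFitResults,
    n_resamples: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> FluxFitResults:
    """Attach residual-bootstrap confidence intervals to a fit."""
    del observed  # the results object already carries its model/data
    return fit.bootstrap_ci(n_resamples=n_resamples, level=level, seed=seed)


def compare_models(
    observed: pd.DataFrame,
    variants: tuple[str, ...] = ("full", "no_cycling"),
    tracer: TracerSpec | None = None,
    n_starts: int = 10,
    seed: int = 0,
    include_lactate: bool = True,
) -> list[FluxFitResults | FailedFit]:
    """Fit each model variant and rank by AICc (most parsimonious first).

    A variant whose fit fails contributes a :class:`FailedFit` entry at the
    end of the ranking instead of aborting the comparison.
    """
    if len(variants) < 1:
        raise ValueError("at least one variant required")
    ranking: list[FluxFitResults | FailedFit] = []
    for variant in variants:
        try:
            ranking.append(
                fit_fluxes(
                    observed,
                    tracer=tracer,
                    variant=variant,
                    n_starts=n_starts,
                    seed=seed,
                    include_lactate=include_lactate,
                )
            )
        except Exception as exc:  # noqa: BLE001 - annotate the ranking
            ranking.append(FailedFit(variant=variant, error=str(exc)))
    ranking.sort(key=lambda r: r.aicc)
    return ranking


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    pvalue: float
    df: float
    alternative: str


def group_compare(
    fits_a,
    fits_b,
    flux_name: str | None = None,
    alternative: str = "two-sided",
) -> GroupTestResult:
    """Welch two-sample t test between two groups of fitted fluxes.

    Groups may be sequences of floats, of :class:`FluxParameters` (then
    ``flux_name`` selects the flux), or of :class:`FluxFitResults`.
    """

    def extract(group):
        vals = []
        for item in group:
            if isinstance(item, FluxFitResults):
                item = item.params
            if isinstance(item, FluxParameters):
                if flux_name is None:
                    raise ValueError("flux_name required for FluxParameters groups")
                item = getattr(item, flux_name)
            vals.append(float(item))
        return np.asarray(vals)

    a, b = extract(fits_a), extract(fits_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 fitted samples")
    if a.min() == a.max() and b.min() == b.max():
        if a[0] == b[0]:
            return GroupTestResult(0.0, 1.0, float(len(a) + len(b) - 2), alternative)
        raise ValueError("zero within-group variance with unequal means: t undefined")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return GroupTestResult(float(res.statistic), float(res.pvalue), float(res.df), alternative)
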