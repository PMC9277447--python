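"""Steady-state carbon-labeling model of the TCA cycle under [U-13C]glucose.

The network follows the classical single-compartment isotopomer model used for
glutamate 13C-NMR flux analysis: uniformly labeled glucose feeds a pyruvate
pool through glycolysis; pyruvate enters the cycle either oxidatively via
pyruvate dehydrogenase (PDH, labeling glutamate C4-C5 on the first turn) or
anaplerotically via pyruvate carboxylase (Y_PC, labeling C2-C3); a second
anaplerotic inflow (Ys) enters at the succinyl-CoA level; cataplerotic efflux
through PEPCK closes the oxaloacetate balance and, combined with pyruvate
kinase, realises pyruvate cycling (PK) whose unique signature is doublet
labeling of lactate C2. All fluxes are expressed relative to citrate synthase
(CS = 1, one cycle turn).

Each metabolite pool with n carbons carries a probability vector over its 2^n
positional isotopomers (bit i-1 set <=> carbon Ci is 13C, C1 = carboxyl end).
The steady state is the fixed point of the stochastic carbon-transfer map and
is solved by damped-free sweep iteration; an independent Monte-Carlo
back-tracing sampler is provided as a cross-validation oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "POOLS",
    "VARIANTS",
    "FluxParameters",
    "TracerSpec",
    "IsotopomerDistribution",
    "SteadyStateResult",
    "TCANetwork",
    "build_tca_network",
    "FluxBoundsError",
    "ConvergenceError",
]

#: pool name -> number of carbons (C1 = carboxyl end, NMR numbering)
POOLS: dict[str, int] = {
    "PYR": 3,
    "LAC": 3,
    "ACCOA": 2,
    "OAA": 4,
    "AKG_GLU": 5,
    "SUC": 4,
    "PEP": 3,
}

#: model variants: full network, pyruvate cycling clamped to zero, or
#: pyruvate carboxylase clamped to zero.
VARIANTS = ("full", "no_cycling", "no_pc")

_ATOL = 1e-9


class FluxBoundsError(ValueError):
    """Flux vector violates the admissibility constraints."""


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass(frozen=True)
class FluxParameters:
    """Relative fluxes, referenced to citrate synthase = 1.

    Parameters
    ----------
    f_pdh : float
        Fraction of acetyl-CoA turnover fed by pyruvate via PDH (in [0, 1];
        the remainder 1 - f_pdh enters from unlabeled sources).
    y_pc : float
        Pyruvate carboxylase anaplerosis into oxaloacetate (>= 0).
    pk : float
        Pyruvate cycling flux realised through PEPCK -> PEP -> pyruvate
        kinase (>= 0, bounded by total cataplerosis y_pc + y_s).
    y_s : float
        Anaplerosis entering at succinyl-CoA (>= 0).
    cs : float
        Citrate synthase reference flux; fixed at 1.
    """

    f_pdh: float
    y_pc: float
    pk: float
    y_s: float
    cs: float = 1.0

    @property
    def pepck(self) -> float:
        """Cataplerotic efflux closing the OAA mass balance."""
        return self.y_pc + self.y_s

    def validate(self) -> None:
        if not (-_ATOL <= self.f_pdh <= 1 + _ATOL):
            raise FluxBoundsError(f"f_pdh={self.f_pdh} outside [0, 1]")
        for name in ("y_pc", "pk", "y_s"):
            if getattr(self, name) < -_ATOL:
                raise FluxBoundsError(f"{name}={getattr(self, name)} negative")
        if self.pk > self.pepck + _ATOL:
            raise FluxBoundsError(
                f"pk={self.pk} exceeds cataplerosis y_pc + y_s = {self.pepck}"
            )
        if abs(self.cs - 1.0) > _ATOL:
            raise FluxBoundsError("cs is the reference flux and must equal 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "f_pdh": self.f_pdh,
            "y_pc": self.y_pc,
            "pk": self.pk,
            "y_s": self.y_s,
        }


@dataclass(frozen=True)
class TracerSpec:
    """Tracer and inflow settings for a [U-13C]glucose experiment.

    enrichment is the probability that a glycolysis-derived pyruvate molecule
    is uniformly 13C-labeled (all three carbons); glycolytic_inflow is the
    glycolytic pyruvate production relative to CS, which sets the recycled
    fraction pk / (g + pk) of the pyruvate pool; natural_abundance optionally
    mixes a per-carbon background labeling probability into every reported
    distribution (off by default).
    """

    enrichment: float = 1.0
    glycolytic_inflow: float = 2.0
    natural_abundance: float = 0.0

    def validate(self) -> None:
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError(f"enrichment={self.enrichment} outside [0, 1]")
        if self.glycolytic_inflow <= 0:
            raise ValueError("glycolytic_inflow must be > 0")
        if not (0.0 <= self.natural_abundance < 1.0):
            raise ValueError("natural_abundance outside [0, 1)")


@dataclass(frozen=True)
class IsotopomerDistribution:
    """Probability vector over the 2^n positional isotopomers of one pool."""

    pool: str
    probs: np.ndarray

    @property
    def n_carbons(self) -> int:
        return int(np.log2(len(self.probs)) + 0.5)

    def validate(self) -> None:
        if np.any(self.probs < -_ATOL):
            raise ValueError(f"{self.pool}: negative isotopomer probability")
        if abs(float(self.probs.sum()) - 1.0) > _ATOL:
            raise ValueError(f"{self.pool}: probabilities sum to {self.probs.sum()}")

    def marginal(self, position: int) -> float:
        """P(carbon `position` is 13C), position 1-based."""
        patterns = np.arange(len(self.probs))
        mask = (patterns >> (position - 1)) & 1 == 1
        return float(self.probs[mask].sum())


@dataclass(frozen=True)
class SteadyStateResult:
    distributions: dict[str, IsotopomerDistribution]
    iterations: int
    converged: bool
    residual: float


# ---------------------------------------------------------------------------
# precomputed index maps (the atom-fate arrows of the network)
# ---------------------------------------------------------------------------

_P3 = np.arange(8)
_P4 = np.arange(16)
_P5 = np.arange(32)


def _bit(p: np.ndarray, i: int) -> np.ndarray:
    return (p >> (i - 1)) & 1


# PDH: ACCOA.C1 <- PYR.C2, ACCOA.C2 <- PYR.C3 (PYR.C1 lost as CO2)
_IDX_ACCOA_FROM_PYR = _bit(_P3, 2) | (_bit(_P3, 3) << 1)
# KGDH: SUC.Ci <- AKG.C(i+1), AKG.C1 lost as CO2
_IDX_SUC_FROM_AKG = _P5 >> 1
# fumarase scrambling: reversal C1<->C4, C2<->C3
_IDX_REV4 = _bit(_P4, 4) | (_bit(_P4, 3) << 1) | (_bit(_P4, 2) << 2) | (_bit(_P4, 1) << 3)
# PEPCK: PEP.Ci <- OAA.Ci (i=1..3, OAA.C4 lost as CO2)
_IDX_PEP_FROM_OAA = _P4 & 0b111
# CS/aconitase/IDH, OAA-derived part: AKG.C1 <- OAA.C4, C2 <- OAA.C3,
# C3 <- OAA.C2 (OAA.C1 lost as CO2)
_IDX_AKG3_FROM_OAA = _bit(_P4, 4) | (_bit(_P4, 3) << 1) | (_bit(_P4, 2) << 2)
# acetyl-derived part: AKG.C4 <- ACCOA.C2 (methyl), AKG.C5 <- ACCOA.C1
_P2 = np.arange(4)
_IDX_AKG2_FROM_ACCOA = _bit(_P2, 2) | (_bit(_P2, 1) << 1)


def _apply(idx: np.ndarray, dist: np.ndarray, size: int) -> np.ndarray:
    return np.bincount(idx, weights=dist, minlength=size)


def _mix_natural_abundance(probs: np.ndarray, n_carbons: int, na: float) -> np.ndarray:
    """Flip each unlabeled carbon to 13C with probability `na`."""
    d = probs
    patterns = np.arange(len(d))
    for b in range(n_carbons):
        unset = (patterns >> b) & 1 == 0
        moved = np.zeros_like(d)
        moved[patterns[unset] | (1 << b)] = na * d[unset]
        d = d.copy()
        d[unset] *= 1.0 - na
        d += moved
    return d


class TCANetwork:
    """Carbon-atom transition network for one model variant.

    Use :func:`build_tca_network` to construct. The variant clamps fluxes:
    ``no_cycling`` fixes pk = 0, ``no_pc`` fixes y_pc = 0; the corresponding
    carbon maps remain in the network but carry zero mixing weight.
    """

    def __init__(self, variant: str):
        if variant not in VARIANTS:
            raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
        self.variant = variant
        self.pools = dict(POOLS)

    # -- flux handling ------------------------------------------------------

    def clamp(self, fluxes: FluxParameters) -> FluxParameters:
        """Apply the variant's flux constraints (pk or y_pc fixed at 0).

        Cycling is capped at the remaining cataplerosis so the clamped
        vector stays admissible.
        """
        if self.variant == "no_cycling":
            fluxes = replace(fluxes, pk=0.0)
        elif self.variant == "no_pc":
            fluxes = replace(fluxes, y_pc=0.0, pk=min(fluxes.pk, fluxes.y_s))
        return fluxes

    def mixing_weights(self, fluxes: FluxParameters, tracer: TracerSpec) -> dict[str, dict[str, float]]:
        """Per-pool source weights implied by the flux vector; each sums to 1."""
        f = self.clamp(fluxes)
        f.validate()
        tracer.validate()
        g = tracer.glycolytic_inflow
        den_oaa = 1.0 + f.y_s + f.y_pc
        return {
            "ACCOA": {"pdh": f.f_pdh, "unlabeled": 1.0 - f.f_pdh},
            "OAA": {"malate": (1.0 + f.y_s) / den_oaa, "pc": f.y_pc / den_oaa},
            "SUC": {"akg": 1.0 / (1.0 + f.y_s), "unlabeled": f.y_s / (1.0 + f.y_s)},
            "PYR": {"tracer": g / (g + f.pk), "pk": f.pk / (g + f.pk)},
            "LAC": {"pyr": 1.0},
            "PEP": {"oaa": 1.0},
            "AKG_GLU": {"cs": 1.0},
        }

    # -- steady state -------------------------------------------------------

    def _sweep(self, state: dict[str, np.ndarray], w, tracer_dist: np.ndarray) -> dict[str, np.ndarray]:
        """One pass through all pools in dependency order."""
        new = {}
        new["PYR"] = w["PYR"]["tracer"] * tracer_dist + w["PYR"]["pk"] * state["PEP"]
        new["LAC"] = new["PYR"]
        accoa = w["ACCOA"]["pdh"] * _apply(_IDX_ACCOA_FROM_PYR, new["PYR"], 4)
        accoa[0] += w["ACCOA"]["unlabeled"]
        new["ACCOA"] = accoa
        oaa_part = _apply(_IDX_AKG3_FROM_OAA, state["OAA"], 8)
        acc_part = _apply(_IDX_AKG2_FROM_ACCOA, accoa, 4)
        new["AKG_GLU"] = (acc_part[:, None] * oaa_part[None, :]).ravel()
        suc = w["SUC"]["akg"] * _apply(_IDX_SUC_FROM_AKG, new["AKG_GLU"], 16)
        suc[0] += w["SUC"]["unlabeled"]
        new["SUC"] = suc
        scrambled = 0.5 * (suc + suc[_IDX_REV4])
        oaa = w["OAA"]["malate"] * scrambled
        oaa[:8] += w["OAA"]["pc"] * new["PYR"]
        new["OAA"] = oaa
        new["PEP"] = _apply(_IDX_PEP_FROM_OAA, oaa, 8)
        return new

    def _tracer_dist(self, tracer: TracerSpec) -> np.ndarray:
        t = np.zeros(8)
        t[0] = 1.0 - tracer.enrichment
        t[7] += tracer.enrichment
        return t

    def steady_state(
        self,
        fluxes: FluxParameters,
        tracer: TracerSpec,
        tolerance: float = 1e-10,
        max_iterations: int = 10_000,
        init: dict[str, np.ndarray] | None = None,
    ) -> SteadyStateResult:
        """Solve the steady-state isotopomer distribution of every pool.

        Deterministic fixed-point iteration; raises :class:`ConvergenceError`
        carrying the last residual if tolerance (L1 change summed over pools)
        is not reached within ``max_iterations`` sweeps.
        """
        if tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        w = self.mixing_weights(fluxes, tracer)  # validates fluxes + tracer
        tr = self._tracer_dist(tracer)
        if init is not None:
            state = {p: np.asarray(init[p], dtype=float).copy() for p in self.pools}
        else:
            state = {p: np.zeros(1 << n) for p, n in self.pools.items()}
            for p in state:
                state[p][0] = 1.0
        residual = np.inf
        iterations = 0
        for iterations in range(1, max_iterations + 1):
            new = self._sweep(state, w, tr)
            residual = sum(float(np.abs(new[p] - state[p]).sum()) for p in new)
            state = new
            if residual <= tolerance:
                break
        converged = residual <= tolerance
        if not converged:
            raise ConvergenceError(
                f"steady state not reached in {max_iterations} sweeps "
                f"(last L1 change {residual:.3e})",
                residual=residual,
                iterations=iterations,
            )
        return SteadyStateResult(
            distributions=self._package(state, tracer),
            iterations=iterations,
            converged=converged,
            residual=residual,
        )

    def first_turn(self, fluxes: FluxParameters, tracer: TracerSpec) -> dict[str, IsotopomerDistribution]:
        """Single-pass evaluation with all cycle intermediates initially
        unlabeled: the 'first turn' labeling pattern (PDH entry marks
        glutamate C4-C5, carboxylase entry marks C2-C3)."""
        w = self.mixing_weights(fluxes, tracer)
        tr = self._tracer_dist(tracer)
        state = {p: np.zeros(1 << n) for p, n in self.pools.items()}
        for p in state:
            state[p][0] = 1.0
        # one ordered pass: the malate arm of OAA sees only the initial
        # (unlabeled) four-carbon pool, so glutamate shows pure entry patterns
        state["PYR"] = w["PYR"]["tracer"] * tr + w["PYR"]["pk"] * state["PEP"]
        state["LAC"] = state["PYR"]
        accoa = w["ACCOA"]["pdh"] * _apply(_IDX_ACCOA_FROM_PYR, state["PYR"], 4)
        accoa[0] += w["ACCOA"]["unlabeled"]
        state["ACCOA"] = accoa
        scrambled = 0.5 * (state["SUC"] + state["SUC"][_IDX_REV4])
        oaa = w["OAA"]["malate"] * scrambled
        oaa[:8] += w["OAA"]["pc"] * state["PYR"]
        state["OAA"] = oaa
        oaa_part = _apply(_IDX_AKG3_FROM_OAA, oaa, 8)
        acc_part = _apply(_IDX_AKG2_FROM_ACCOA, accoa, 4)
        state["AKG_GLU"] = (acc_part[:, None] * oaa_part[None, :]).ravel()
        suc = w["SUC"]["akg"] * _apply(_IDX_SUC_FROM_AKG, state["AKG_GLU"], 16)
        suc[0] += w["SUC"]["unlabeled"]
        state["SUC"] = suc
        state["PEP"] = _apply(_IDX_PEP_FROM_OAA, oaa, 8)
        return self._package(state, tracer)

    def _package(self, state: dict[str, np.ndarray], tracer: TracerSpec) -> dict[str, IsotopomerDistribution]:
        out = {}
        for p, n in self.pools.items():
            d = state[p]
            if tracer.natural_abundance > 0:
                d = _mix_natural_abundance(d, n, tracer.natural_abundance)
            d = d / d.sum()
            dist = IsotopomerDistribution(pool=p, probs=d)
            dist.validate()
            out[p] = dist
        return out

    # -- Monte-Carlo oracle -------------------------------------------------

    def sample_molecules(
        self,
        fluxes: FluxParameters,
        tracer: TracerSpec,
        n_molecules: int,
        max_depth: int = 200,
        seed: int = 0,
        pools: tuple[str, ...] | None = None,
    ) -> dict[str, IsotopomerDistribution]:
        """Empirical isotopomer distributions by back-tracing single molecules.

        Independent of the fixed-point solver: each molecule's carbons are
        traced backwards through the stochastic source choices until they hit
        the tracer or an unlabeled inflow; beyond ``max_depth`` recursion
        levels a carbon is taken as unlabeled (truncation bias decays
        geometrically with depth).
        """
        if n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        w = self.mixing_weights(fluxes, tracer)
        e = tracer.enrichment
        na = tracer.natural_abundance
        rng = random.Random(seed)
        rev4 = [int(x) for x in _IDX_REV4]
        akg3 = [int(x) for x in _IDX_AKG3_FROM_OAA]
        acc2 = [int(x) for x in _IDX_AKG2_FROM_ACCOA]
        w_tr = w["PYR"]["tracer"]
        w_mal = w["OAA"]["malate"]
        w_akg = w["SUC"]["akg"]
        f_pdh = w["ACCOA"]["pdh"]

        def draw(pool: str, depth: int) -> int:
            if depth > max_depth:
                return 0
            r = rng.random()
            if pool == "PYR":
                if r < w_tr:
                    return 0b111 if rng.random() < e else 0
                return draw("PEP", depth + 1)
            if pool == "LAC":
                return draw("PYR", depth + 1)
            if pool == "ACCOA":
                if r < f_pdh:
                    p = draw("PYR", depth + 1)
                    return ((p >> 1) & 1) | (((p >> 2) & 1) << 1)
                return 0
            if pool == "OAA":
                if r < w_mal:
                    s = draw("SUC", depth + 1)
                    return rev4[s] if rng.random() < 0.5 else s
                return draw("PYR", depth + 1) & 0b111  # PC; C4 from CO2
            if pool == "SUC":
                if r < w_akg:
                    return draw("AKG_GLU", depth + 1) >> 1
                return 0
            if pool == "AKG_GLU":
                o = draw("OAA", depth + 1)
                c = draw("ACCOA", depth + 1)
                return akg3[o] | (acc2[c] << 3)
            if pool == "PEP":
                return draw("OAA", depth + 1) & 0b111
            raise KeyError(pool)

        wanted = tuple(self.pools) if pools is None else tuple(pools)
        out = {}
        for pool in wanted:
            n = self.pools[pool]
            counts = np.zeros(1 << n)
            for _ in range(n_molecules):
                pat = draw(pool, 0)
                if na > 0:
                    for b in range(n):
                        if not (pat >> b) & 1 and rng.random() < na:
                            pat |= 1 << b
                counts[pat] += 1
            dist = IsotopomerDistribution(pool=pool, probs=counts / n_molecules)
            dist.validate()
            out[pool] = dist
        return out


def build_tca_network(variant: str = "full") -> TCANetwork:
    """Construct the TCA-cycle carbon transition network.

    variant : 'full', 'no_cycling' (pyruvate cycling pk fixed at 0) or
    'no_pc' (pyruvate carboxylase y_pc fixed at 0).
    """
    return TCANetwork(variant)
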