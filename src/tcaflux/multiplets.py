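"""NMR multiplet area fractions from positional isotopomer distributions.

A 13C resonance of a carbon that is itself labeled splits according to which
of its directly bonded neighbors are also 13C: no labeled neighbor gives a
singlet (S), one labeled neighbor a doublet (D, named by the coupled pair,
e.g. C2D12), and two labeled neighbors a doublet of doublets ("quartet", Q)
-- unless the two one-bond couplings are equal, in which case the quartet
collapses to a 1:2:1 triplet (T) and the two doublets merge into a single D
(the glutamate C3 case). Fractions are conditional probabilities among
molecules labeled at the observed position, i.e. areas relative to the total
area of that carbon's resonance.

Quantified resonances: glutamate C2, C3, C4, C5 and lactate C2 (lactate
multiplet labels carry an L prefix: LC2S, LC2D12, LC2D23, LC2Q).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import IsotopomerDistribution

__all__ = [
    "CouplingScheme",
    "MultipletPattern",
    "ZeroAreaError",
    "default_scheme",
    "multiplet_pattern",
    "signal_ratio_table",
    "TABLE_COLUMNS",
    "CANONICAL_ROWS",
]

#: canonical RatioTable columns (TSV dialect)
TABLE_COLUMNS = ["sample_id", "condition", "pool", "position", "multiplet", "ratio", "sem"]


class ZeroAreaError(ValueError):
    """The observed position carries no 13C label: ratios are undefined."""


@dataclass(frozen=True)
class CouplingScheme:
    """One-bond 13C-13C couplings per pool and the triplet-collapse rule.

    couplings maps pool -> position -> tuple of (neighbor position, J in Hz).
    Two couplings at a position that agree within ``collapse_tol`` Hz are
    unresolved: the two doublets merge into one D and the doubly-coupled
    state reports as a triplet T.
    """

    couplings: dict[str, dict[int, tuple[tuple[int, float], ...]]]
    collapse_tol: float = 0.5

    def __post_init__(self):
        if self.collapse_tol <= 0:
            raise ValueError("collapse_tol must be > 0")

    def neighbors(self, pool: str, position: int) -> tuple[tuple[int, float], ...]:
        try:
            return self.couplings[pool][position]
        except KeyError:
            raise KeyError(f"no coupling entry for {pool} C{position}") from None


@dataclass(frozen=True)
class MultipletPattern:
    """Area fractions of one carbon resonance, keyed by multiplet label."""

    pool: str
    position: int
    components: dict[str, float]

    def validate(self, atol: float = 1e-9) -> None:
        vals = np.array(list(self.components.values()))
        if np.any(vals < -atol):
            raise ValueError("negative multiplet fraction")
        if abs(vals.sum() - 1.0) > atol:
            raise ValueError(f"fractions sum to {vals.sum()}, not 1")


# glutamate J constants are literature-typical one-bond 13C-13C couplings;
# J23 == J34 produces the observed C3 triplet collapse
_GLU_J = {2: ((1, 53.0), (3, 34.0)), 3: ((2, 34.0), (4, 34.0)),
          4: ((3, 34.0), (5, 51.0)), 5: ((4, 51.0),)}
_LAC_J = {2: ((1, 55.0), (3, 35.0))}

#: (table pool label, network pool, positions quantified)
QUANTIFIED = (("GLU", "AKG_GLU", (2, 3, 4, 5)), ("LAC", "LAC", (2,)))

#: network pool name -> table pool label
_POOL_LABEL = {"AKG_GLU": "GLU", "LAC": "LAC"}


def default_scheme() -> CouplingScheme:
    """Coupling topology for glutamate (C1..C5 chain) and lactate (C1..C3)."""
    return CouplingScheme(couplings={"AKG_GLU": _GLU_J, "LAC": _LAC_J})


def _label_prefix(pool: str, position: int) -> str:
    return ("L" if _POOL_LABEL.get(pool, pool) == "LAC" else "") + f"C{position}"


def multiplet_pattern(
    dist: IsotopomerDistribution,
    position: int,
    scheme: CouplingScheme | None = None,
) -> MultipletPattern:
    """Multiplet area fractions of one carbon resonance.

    Fractions are P(neighbor labeling state | observed carbon labeled);
    raises :class:`ZeroAreaError` when the position carries no label.
    """
    scheme = scheme or default_scheme()
    nbrs = scheme.neighbors(dist.pool, position)
    if not 1 <= len(nbrs) <= 2:
        raise ValueError(f"position C{position} must have 1 or 2 coupled neighbors")
    probs = dist.probs
    patterns = np.arange(len(probs))
    on = (patterns >> (position - 1)) & 1 == 1
    total = float(probs[on].sum())
    if total <= 0.0:
        raise ZeroAreaError(
            f"{dist.pool} C{position} has zero 13C area; multiplet ratios undefined"
        )
    prefix = _label_prefix(dist.pool, position)

    if len(nbrs) == 1:
        (nb, _j), = nbrs
        nb_on = (patterns >> (nb - 1)) & 1 == 1
        d = float(probs[on & nb_on].sum()) / total
        pair = "".join(str(i) for i in sorted((position, nb)))
        comps = {f"{prefix}S": 1.0 - d, f"{prefix}D{pair}": d}
    else:
        (nb_a, j_a), (nb_b, j_b) = nbrs
        a_on = (patterns >> (nb_a - 1)) & 1 == 1
        b_on = (patterns >> (nb_b - 1)) & 1 == 1
        p_s = float(probs[on & ~a_on & ~b_on].sum()) / total
        p_a = float(probs[on & a_on & ~b_on].sum()) / total
        p_b = float(probs[on & ~a_on & b_on].sum()) / total
        p_ab = float(probs[on & a_on & b_on].sum()) / total
        if abs(j_a - j_b) <= scheme.collapse_tol:
            comps = {f"{prefix}S": p_s, f"{prefix}D": p_a + p_b, f"{prefix}T": p_ab}
        else:
            pair_a = "".join(str(i) for i in sorted((position, nb_a)))
            pair_b = "".join(str(i) for i in sorted((position, nb_b)))
            comps = {
                f"{prefix}S": p_s,
                f"{prefix}D{pair_a}": p_a,
                f"{prefix}D{pair_b}": p_b,
                f"{prefix}Q": p_ab,
            }
    pattern = MultipletPattern(pool=dist.pool, position=position, components=comps)
    pattern.validate()
    return pattern


def signal_ratio_table(
    distributions: dict[str, IsotopomerDistribution],
    scheme: CouplingScheme | None = None,
    sample_id: str = "model",
    condition: str = "model",
) -> pd.DataFrame:
    """Model-predicted, noise-free multiplet signal-ratio table.

    One row per (position, multiplet) for glutamate C2-C5 and lactate C2;
    fractions sum to 1 within each resonance.
    """
    scheme = scheme or default_scheme()
    rows = []
    for pool_label, pool, positions in QUANTIFIED:
        if pool not in distributions:
            raise KeyError(f"distributions must contain the {pool} pool")
        for pos in positions:
            pat = multiplet_pattern(distributions[pool], pos, scheme)
            for label, frac in pat.components.items():
                rows.append((sample_id, condition, pool_label, pos, label, frac, np.nan))
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def _canonical_rows() -> tuple[tuple[str, int, str], ...]:
    out = []
    scheme = default_scheme()
    for pool_label, pool, positions in QUANTIFIED:
        for pos in positions:
            nbrs = scheme.neighbors(pool, pos)
            prefix = _label_prefix(pool, pos)
            if len(nbrs) == 1:
                (nb, _j), = nbrs
                pair = "".join(str(i) for i in sorted((pos, nb)))
                labels = [f"{prefix}S", f"{prefix}D{pair}"]
            else:
                (na_, ja), (nb_, jb) = nbrs
                if abs(ja - jb) <= scheme.collapse_tol:
                    labels = [f"{prefix}S", f"{prefix}D", f"{prefix}T"]
                else:
                    pa = "".join(str(i) for i in sorted((pos, na_)))
                    pb = "".join(str(i) for i in sorted((pos, nb_)))
                    labels = [f"{prefix}S", f"{prefix}D{pa}", f"{prefix}D{pb}", f"{prefix}Q"]
            out.extend((pool_label, pos, lab) for lab in labels)
    return tuple(out)


#: every (pool, position, multiplet) the dialect knows, in canonical order
CANONICAL_ROWS = _canonical_rows()
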