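"""Rendering and line-fitting of 13C multiplet regions.

Forward model: each multiplet component of a carbon resonance is a sum of
area-normalized Lorentzian lines on a ppm grid -- a singlet is one line, a
doublet two lines split by J (in Hz, converted to ppm via the spectrometer
13C frequency), a quartet (doublet of doublets) four lines at +/-J1/2 +/-J2/2
with equal areas, and a triplet three lines at -J, 0, +J with 1:2:1 areas.
The inverse step recovers component areas by non-negative linear least
squares against the rendered unit-area templates, emulating line-fit
quantification of glutamate/lactate resonances; normalizing the recovered
areas returns a multiplet pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import optimize

from .multiplets import CouplingScheme, MultipletPattern, ZeroAreaError, default_scheme

__all__ = [
    "SpectrumModel",
    "PeakFitResult",
    "render_spectrum",
    "component_lines",
    "fit_areas",
    "areas_to_ratios",
    "read_spectrum",
    "write_spectrum",
    "read_jcampdx",
    "write_jcampdx",
    "DEFAULT_CENTERS",
]

#: chemical-shift centers (ppm), config constants; only relative line
#: positions matter for the fit
DEFAULT_CENTERS = {
    ("GLU", 2): 55.6,
    ("GLU", 3): 27.8,
    ("GLU", 4): 34.3,
    ("GLU", 5): 182.0,
    ("LAC", 2): 69.3,
}


@dataclass(frozen=True)
class SpectrumModel:
    """Rendering settings for one multiplet region.

    axis is a strictly increasing ppm grid; frequency_mhz converts Hz
    couplings to ppm; linewidth_hz is the Lorentzian full width at half
    maximum; noise_sd adds seeded Gaussian intensity noise when > 0.
    """

    axis: np.ndarray
    frequency_mhz: float = 150.13
    linewidth_hz: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        if ax.ndim != 1 or len(ax) < 2 or np.any(np.diff(ax) <= 0):
            raise ValueError("axis must be a strictly increasing 1-D ppm grid")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be > 0")
        object.__setattr__(self, "axis", ax)


@dataclass(frozen=True)
class PeakFitResult:
    """Areas recovered by line fitting one multiplet region."""

    labels: tuple[str, ...]
    areas: np.ndarray
    residual_norm: float
    converged: bool
    warnings: tuple[str, ...] = ()


def _lorentzian(axis: np.ndarray, center: float, hwhm: float) -> np.ndarray:
    """Unit-area Lorentzian on the ppm axis."""
    return (hwhm / np.pi) / ((axis - center) ** 2 + hwhm**2)


def component_lines(
    label: str,
    position: int,
    pool: str,
    scheme: CouplingScheme | None = None,
) -> list[tuple[float, float]]:
    """(offset in Hz, relative area) of each line of one multiplet component."""
    scheme = scheme or default_scheme()
    pool_net = {"GLU": "AKG_GLU"}.get(pool, pool)
    nbrs = dict(scheme.neighbors(pool_net, position))
    kind = label.lstrip("L")[2:] if label.startswith(("L", "C")) else label
    # kind is e.g. "S", "D12", "D", "T", "Q"
    if kind == "S":
        return [(0.0, 1.0)]
    if kind == "T":
        j = next(iter(nbrs.values()))
        return [(-j, 0.25), (0.0, 0.5), (j, 0.25)]
    if kind == "Q":
        (j1, j2) = [j for _, j in sorted(nbrs.items())]
        return [(s1 * j1 / 2 + s2 * j2 / 2, 0.25) for s1 in (-1, 1) for s2 in (-1, 1)]
    if kind == "D":
        j = next(iter(nbrs.values()))
        return [(-j / 2, 0.5), (j / 2, 0.5)]
    if kind.startswith("D"):
        pair = kind[1:]
        nb = int(pair.replace(str(position), "", 1))
        j = nbrs[nb]
        return [(-j / 2, 0.5), (j / 2, 0.5)]
    raise ValueError(f"unrecognized multiplet label {label!r}")


def _templates(
    labels: tuple[str, ...],
    position: int,
    pool: str,
    center_ppm: float,
    model: SpectrumModel,
    scheme: CouplingScheme | None,
) -> tuple[np.ndarray, list[str]]:
    """Unit-area rendered shape per component; also returns any resolution
    warnings (couplings below the grid step)."""
    hwhm_ppm = (model.linewidth_hz / 2.0) / model.frequency_mhz
    step = float(np.min(np.diff(model.axis)))
    cols = []
    warns = []
    for lab in labels:
        shape = np.zeros_like(model.axis)
        lines = component_lines(lab, position, pool, scheme)
        offsets = [off for off, _ in lines]
        if len(offsets) > 1:
            split_ppm = (max(offsets) - min(offsets)) / model.frequency_mhz
            if split_ppm < step:
                warns.append(
                    f"{lab}: splitting {split_ppm:.2e} ppm below grid step {step:.2e}"
                )
        for off_hz, rel in lines:
            shape += rel * _lorentzian(model.axis, center_ppm + off_hz / model.frequency_mhz, hwhm_ppm)
        cols.append(shape)
    return np.column_stack(cols), warns


def render_spectrum(
    pattern: MultipletPattern,
    model: SpectrumModel,
    center_ppm: float | None = None,
    total_area: float = 1.0,
    scheme: CouplingScheme | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Render one resonance's multiplet pattern as an intensity vector.

    Returns (intensity on model.axis, resolution warnings). Total integrated
    area is proportional to total_area times the sum of pattern fractions.
    Seeded Gaussian noise is added when model.noise_sd > 0.
    """
    pattern.validate()
    pool = {"AKG_GLU": "GLU"}.get(pattern.pool, pattern.pool)
    if center_ppm is None:
        center_ppm = DEFAULT_CENTERS[(pool, pattern.position)]
    labels = tuple(pattern.components)
    design, warns = _templates(labels, pattern.position, pool, center_ppm, model, scheme)
    areas = total_area * np.array([pattern.components[k] for k in labels])
    intensity = design @ areas
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        intensity = intensity + rng.normal(0.0, model.noise_sd, size=len(intensity))
    return intensity, warns


def fit_areas(
    spectrum: np.ndarray,
    model: SpectrumModel,
    labels: tuple[str, ...],
    position: int,
    pool: str,
    center_ppm: float | None = None,
    scheme: CouplingScheme | None = None,
    refine_linewidth: bool = False,
    cond_limit: float = 1e8,
) -> PeakFitResult:
    """Recover multiplet component areas by non-negative least squares.

    Line positions and couplings come from the template; areas are the only
    free parameters (optionally the common linewidth is refined by a nested
    1-D nonlinear search). Raises a conditioning error when the component
    shapes are effectively collinear.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape != model.axis.shape:
        raise ValueError("spectrum and model axis differ in length")
    if center_ppm is None:
        center_ppm = DEFAULT_CENTERS[(pool, position)]

    def solve(lw_hz: float) -> tuple[np.ndarray, float, list[str]]:
        m = replace(model, linewidth_hz=lw_hz)
        design, warns = _templates(labels, position, pool, center_ppm, m, scheme)
        cond = np.linalg.cond(design.T @ design)
        if not np.isfinite(cond) or cond > cond_limit**2:
            raise np.linalg.LinAlgError(
                f"singular design: multiplet components overlap (cond {cond:.2e})"
            )
        areas, rnorm = optimize.nnls(design, spectrum)
        return areas, rnorm, warns

    lw = model.linewidth_hz
    if refine_linewidth:
        res = optimize.minimize_scalar(
            lambda w: solve(w)[1], bounds=(lw / 5.0, lw * 5.0), method="bounded"
        )
        lw = float(res.x)
    areas, rnorm, warns = solve(lw)
    return PeakFitResult(
        labels=tuple(labels),
        areas=areas,
        residual_norm=float(rnorm),
        converged=True,
        warnings=tuple(warns),
    )


def areas_to_ratios(result: PeakFitResult, pool: str, position: int) -> MultipletPattern:
    """Normalize recovered areas to multiplet fractions."""
    total = float(result.areas.sum())
    if total <= 0:
        raise ZeroAreaError(f"{pool} C{position}: fitted total area is zero")
    comps = {lab: float(a) / total for lab, a in zip(result.labels, result.areas)}
    return MultipletPattern(pool=pool, position=position, components=comps)


# ---------------------------------------------------------------------------
# spectrum I/O: two-column text and minimal JCAMP-DX (XYPOINTS)
# ---------------------------------------------------------------------------


def write_spectrum(path: str | Path, axis: np.ndarray, intensity: np.ndarray) -> None:
    np.savetxt(path, np.column_stack([axis, intensity]), fmt="%.8g",
               header="ppm intensity")


def read_spectrum(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(path)
    return data[:, 0], data[:, 1]


def write_jcampdx(path: str | Path, axis: np.ndarray, intensity: np.ndarray,
                  title: str = "tcaflux simulated 13C spectrum") -> None:
    """Minimal JCAMP-DX 4.24 file with (X,Y) point pairs."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={len(axis)}",
        f"##FIRSTX={axis[0]:.8g}",
        f"##LASTX={axis[-1]:.8g}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{x:.8g}, {y:.8g}" for x, y in zip(axis, intensity)]
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_jcampdx(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    in_points = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line.startswith("##XYPOINTS"):
            in_points = True
            continue
        if line.startswith("##"):
            in_points = False
            continue
        if in_points and line:
            x, y = line.split(",")
            xs.append(float(x))
            ys.append(float(y))
    if not xs:
        raise ValueError(f"no XYPOINTS data found in {path}")
    return np.asarray(xs), np.asarray(ys)
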