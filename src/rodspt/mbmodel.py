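"""Model of the projected transverse-position distribution in a rod cell.

A molecule uniformly distributed on the membrane circle of radius ``r``
projects onto the transverse axis with the arcsine density
``1/(pi*sqrt(r^2 - x^2))``; one uniform in the cytoplasmic disk projects
with the semicircle density ``2*sqrt(r^2 - x^2)/(pi*r^2)``. The observed
distribution of normalized transverse positions (xNorm) is a mixture of the
two with weight ``m`` (the membrane-bound fraction), distorted by imaging:

* a soft focal cutoff — signal below depth ``-f`` is lost, so the density
  at depth z is weighted by ``Phi((f + z)/sigma)`` with ``Phi`` the
  standard normal CDF;
* Gaussian localization blur of width ``sigma`` applied in x.

Parameters are tied to the bright-field cell geometry: the membrane circle
radius is ``r = R/dilF`` (``dilF`` >= 1 accounts for the fluorescent label
sitting inside the boundary detected in bright-field), the focal offset is
``f = R - fCut`` (``fCut = 0`` means the view of the cell is unobstructed),
and ``sigma = locErr/1000`` converts the localization error from nm to µm.

All computations here are on per-grid-cell masses with exact raw-component
integrals, so the arcsine singularity at ``|x| = r`` is handled without
loss of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

GRID_POINTS = 400  # default grid cells per half-width R


class ModelParameterError(ValueError):
    """Raised for parameter combinations outside the model's domain."""


@dataclass
class ProjectionModelParams:
    """Parameters of the projected mixture model.

    m : membrane fraction in [0, 1]
    dilF : membrane dilation factor (>= 1), membrane circle at r = R/dilF
    locErr : localization error in nm (sigma = locErr/1000 µm)
    fCut : focal cut measured from the cell top, same unit as R;
        the in-focus half-space is z > -(R - fCut)
    """

    m: float
    dilF: float
    locErr: float
    fCut: float

    def validate(self, R: float):
        if not (0.0 <= self.m <= 1.0):
            raise ModelParameterError("m must be in [0, 1]")
        if self.dilF < 1.0:
            raise ModelParameterError("dilF must be >= 1")
        if self.locErr < 0:
            raise ModelParameterError("locErr must be >= 0")
        if not (0.0 <= self.fCut <= 2 * R):
            raise ModelParameterError("fCut must be in [0, 2R]")


# ---------------------------------------------------------------------------
# raw (imaging-free) marginals
# ---------------------------------------------------------------------------

def raw_membrane_marginal(x, r: float):
    """Arcsine density of the transverse position of membrane molecules.

    ``1/(pi*sqrt(r^2 - x^2))`` for |x| < r, zero outside (the density
    diverges integrably at the support boundary).
    """
    x = np.asarray(x, float)
    inside = np.abs(x) < r
    out = np.zeros_like(x)
    out[inside] = 1.0 / (np.pi * np.sqrt(r * r - x[inside] ** 2))
    return out if out.ndim else float(out)


def raw_cytoplasm_marginal(x, r: float):
    """Semicircle density of the transverse position of cytoplasmic molecules.

    ``2*sqrt(r^2 - x^2)/(pi*r^2)`` for |x| <= r; its variance is r^2/4.
    """
    x = np.asarray(x, float)
    inside = np.abs(x) <= r
    out = np.zeros_like(x)
    out[inside] = 2.0 * np.sqrt(r * r - x[inside] ** 2) / (np.pi * r * r)
    return out if out.ndim else float(out)


def defocus_weight(z, f: float, sigma: float):
    """Detection weight at depth z: ``Phi((f + z)/sigma)``.

    With ``sigma -> 0`` this becomes the hard indicator ``z > -f``.
    """
    z = np.asarray(z, float)
    if sigma > 0:
        out = ndtr((f + z) / sigma)
    else:
        out = np.where(z > -f, 1.0, np.where(z == -f, 0.5, 0.0))
    return out if out.ndim else float(out)


# exact antiderivatives of the raw marginals, for per-cell masses
def _arcsine_cdf(x, r):
    return np.arcsin(np.clip(x / r, -1, 1)) / np.pi + 0.5


def _semicircle_cdf(x, r):
    xc = np.clip(x, -r, r)
    return 0.5 + (xc * np.sqrt(r * r - xc * xc) / (r * r)
                  + np.arcsin(xc / r)) / np.pi


def _phi_int(t):
    """Antiderivative of Phi: integral of Phi(u) du = t*Phi(t) + phi(t)."""
    return t * ndtr(t) + np.exp(-0.5 * t * t) / np.sqrt(2 * np.pi)


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def _component_masses(params: ProjectionModelParams, R: float,
                      step: float, eq9_literal: bool = False):
    """Per-grid-cell masses of both components on a signed-x grid.

    Returns ``(edges, mass_memb, mass_cyto)`` where masses are restricted to
    [-R, R] (positions observed outside the cell boundary are rejected by
    the normalization step, so the model conditions on |x| <= R) and each
    component is renormalized to total mass 1.
    """
    r = R / params.dilF
    f = R - params.fCut
    sigma = params.locErr / 1000.0

    # grid with +-R on exact edge points, padded so blur mass that spills
    # past the boundary is representable before truncation
    m_half = max(1, int(round(R / step)))
    step = R / m_half
    n_pad = int(np.ceil(6 * sigma / step)) + 1
    n = m_half + n_pad
    edges = step * np.arange(-n, n + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    zc = np.sqrt(np.maximum(r * r - centers ** 2, 0.0))

    # membrane: exact arcsine mass per cell, weighted by the two-sided
    # defocus factor evaluated at the cell center (mass at depths +-z(x))
    mass_m = np.diff(_arcsine_cdf(edges, r))
    w_m = defocus_weight(zc, f, sigma) + defocus_weight(-zc, f, sigma)
    mass_m = mass_m * w_m

    # cytoplasm: density(x) = (2/(pi r^2)) * integral_{-z}^{z} Phi((f+u)/s) du
    if sigma > 0:
        if eq9_literal:
            # printed form: integrand constant in u
            dens_c = (2.0 / (np.pi * r * r)) * 2 * zc * ndtr((f + zc) / sigma)
        else:
            upper = (f + zc) / sigma
            lower = (f - zc) / sigma
            dens_c = (2.0 / (np.pi * r * r)) * sigma * (_phi_int(upper)
                                                        - _phi_int(lower))
        mass_c = dens_c * step
    else:
        # hard cutoff: in-focus chord length above depth -f
        zlo = np.minimum(np.maximum(-f, -zc), zc)
        mass_c = (2.0 / (np.pi * r * r)) * (zc - zlo) * step

    # Gaussian localization blur in x as mass-preserving discrete convolution
    if sigma > 0:
        kr = int(np.ceil(6 * sigma / step))
        ker = np.exp(-0.5 * (step * np.arange(-kr, kr + 1) / sigma) ** 2)
        ker /= ker.sum()
        mass_m = np.convolve(mass_m, ker, mode="same")
        mass_c = np.convolve(mass_c, ker, mode="same")

    # condition on |x| <= R: observed positions outside the cell boundary
    # are rejected upstream, so the model renormalizes on [-R, R]
    mass_m = mass_m[n_pad:-n_pad]
    mass_c = mass_c[n_pad:-n_pad]
    edges_k = edges[n_pad:-n_pad]
    tm, tc = mass_m.sum(), mass_c.sum()
    if tm > 0:
        mass_m = mass_m / tm
    if tc > 0:
        mass_c = mass_c / tc
    return edges_k, mass_m, mass_c


def predicted_marginal(params: ProjectionModelParams, R: float,
                       x_out_grid=None, step: float | None = None,
                       eq9_literal: bool = False):
    """Model density of the signed transverse position x (same unit as R).

    Evaluates the imaging-distorted mixture
    ``m * P_memb(x) + (1 - m) * P_cyto(x)`` on ``x_out_grid`` (defaults to
    the internal grid centers). ``eq9_literal`` switches the cytoplasmic
    defocus integral to the depth-independent integrand variant.

    Returns ``(x, density)``.
    """
    params.validate(R)
    if R <= 0:
        raise ModelParameterError("R must be positive")
    if R / params.dilF <= 0:
        raise ModelParameterError("membrane radius r = R/dilF must be positive")
    if step is None:
        step = R / GRID_POINTS
    edges, mass_m, mass_c = _component_masses(params, R, step, eq9_literal)
    centers = 0.5 * (edges[:-1] + edges[1:])
    dens = (params.m * mass_m + (1 - params.m) * mass_c) / step
    if x_out_grid is None:
        return centers, dens
    x_out = np.asarray(x_out_grid, float)
    return x_out, np.interp(x_out, centers, dens, left=0.0, right=0.0)


def model_bin_probabilities(params: ProjectionModelParams, R: float,
                            bin_edges, absolute: bool = True,
                            step: float | None = None,
                            eq9_literal: bool = False) -> np.ndarray:
    """Model probability per xNorm histogram bin.

    ``bin_edges`` are in normalized units and must cover [0, 1]
    (``absolute=True``; signed probabilities of +/-|bin| are summed) or
    [-1, 1]. The result sums to 1 to within 1e-9.
    """
    params.validate(R)
    if step is None:
        step = R / GRID_POINTS
    bin_edges = np.asarray(bin_edges, float)
    lo, hi = (0.0, 1.0) if absolute else (-1.0, 1.0)
    if bin_edges[0] > lo + 1e-12 or bin_edges[-1] < hi - 1e-12:
        raise ValueError(f"bin edges must cover [{lo}, {hi}]")

    edges, mass_m, mass_c = _component_masses(params, R, step, eq9_literal)
    mass = params.m * mass_m + (1 - params.m) * mass_c
    cum = np.concatenate([[0.0], np.cumsum(mass)])

    def cum_at(xn):
        # cumulative mixture mass below physical position xn*R
        return np.interp(np.asarray(xn, float) * R, edges, cum)

    if absolute:
        probs = ((cum_at(bin_edges[1:]) - cum_at(bin_edges[:-1]))
                 + (cum_at(-bin_edges[:-1]) - cum_at(-bin_edges[1:])))
    else:
        probs = cum_at(bin_edges[1:]) - cum_at(bin_edges[:-1])
    total = probs.sum()
    if total <= 0:
        raise ValueError("model mass vanished on the given bins")
    return probs / total
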