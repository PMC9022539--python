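"""Layered repression model with exponential distance dampening.

Coordinated biogenesis arranges miRNAs in layers: the primary miRNA sits in
layer 0, the secondary miRNAs whose biogenesis it drives in layer 1, their
own secondaries in layer 2, and so on.  Three coupled pieces describe how
repression propagates down this hierarchy:

* a polynomial *response curve* relating a secondary miRNA's level to the
  primary's (empirically near-quadratic over induction ranges);
* multiplicative *layer propagation*: the miRNA level in layer n is a
  fraction ``c_n`` (coupling strength in [0, 1]) of the level in layer n-1;
* *target prediction* with exponential distance attenuation: an mRNA sitting
  in layer t is repressed by every miRNA layer m <= t, but the contribution
  of a layer at distance x = t - m is attenuated by ``w**x`` with the
  attenuation base w in (0, 1), giving

      level(target) = baseline * exp(-sum_m beta * w**(t-m) * level_m).

The log-linear form keeps target levels strictly positive and bounded by the
baseline, and makes repression additive in the exponent, so the nearest
miRNA layer always dominates when w < 1.

``recover_params`` closes the loop: given dose-response series simulated
from known parameters it refits (baseline, beta, w) by bounded nonlinear
least squares, which is how the model's identifiability is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.optimize import least_squares


@dataclass(frozen=True)
class ResponseCurve:
    """Polynomial fit of secondary-miRNA level against primary level."""

    degree: int
    coefficients: tuple[float, ...]  # ascending power order
    r_squared: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.degree + 1:
            raise ValueError("need degree+1 coefficients in ascending power order")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        return Polynomial(self.coefficients)(x)


@dataclass
class LayerNetwork:
    """Ordered miRNA layers with per-layer coupling and target genes.

    ``layers[0]`` holds the primary miRNA; ``coupling[n-1]`` is the coupling
    coefficient c_n carrying layer n-1's level into layer n.
    """

    layers: list[list[str]]
    coupling: list[float]
    targets: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("network needs at least the primary layer")
        if len(self.coupling) != len(self.layers) - 1:
            raise ValueError("need one coupling coefficient per layer transition")
        for c in self.coupling:
            if not (0.0 <= c <= 1.0):
                raise ValueError(f"coupling coefficient {c} outside [0, 1]")
        if not self.targets:
            self.targets = [[] for _ in self.layers]

    @property
    def depth(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class DampeningParams:
    """Attenuation base w in (0,1), same-layer repression strength beta >= 0,
    and the unrepressed baseline mRNA level (linear scale, positive)."""

    w: float = 0.5
    beta: float = 1.0
    baseline: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.w < 1.0):
            raise ValueError(f"attenuation base w must lie strictly in (0, 1), got {self.w}")
        if self.beta < 0:
            raise ValueError("repression strength beta must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline mRNA level must be positive")


def fit_response_curve(
    primary_levels: Sequence[float],
    secondary_levels: Sequence[float],
    degree: int = 2,
) -> ResponseCurve:
    """Least-squares polynomial fit of secondary level vs primary level.

    Interpolates exactly when the number of distinct points equals degree+1;
    degenerate inputs (too few points, too few distinct abscissae, unequal
    lengths) raise with the deficiency named.
    """
    x = np.asarray(primary_levels, dtype=float)
    y = np.asarray(secondary_levels, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"series lengths differ: {x.size} primary vs {y.size} secondary")
    n_distinct = np.unique(x).size
    if n_distinct < degree + 1:
        raise ValueError(
            f"need >= {degree + 1} distinct primary levels for degree {degree}, got {n_distinct}"
        )
    poly = Polynomial.fit(x, y, deg=degree).convert()
    resid = y - poly(x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    coeffs = np.zeros(degree + 1)
    coeffs[: poly.coef.size] = poly.coef
    return ResponseCurve(degree=degree, coefficients=tuple(coeffs), r_squared=min(r2, 1.0))


def propagate_layers(network: LayerNetwork, primary_level: float) -> dict[int, float]:
    """Cascade the primary level down the layers: level(n) = c_n * level(n-1)."""
    if primary_level < 0:
        raise ValueError("primary miRNA level must be non-negative")
    levels = {0: float(primary_level)}
    for n in range(1, network.depth):
        levels[n] = network.coupling[n - 1] * levels[n - 1]
    return levels


def predict_target_level(
    levels_by_layer: Mapping[int, float],
    target_layer: int,
    params: DampeningParams,
) -> float:
    """mRNA level of a target in ``target_layer`` under dampened repression.

    Every miRNA layer m <= target_layer represses; a layer at distance
    x = target_layer - m contributes ``beta * w**x * level(m)`` to the
    exponent.  Returns baseline when all miRNA levels are zero and stays in
    (0, baseline] otherwise.
    """
    if target_layer < 0 or target_layer not in levels_by_layer:
        raise ValueError(f"target layer {target_layer} outside the simulated network depth")
    exponent = sum(
        params.beta * params.w ** (target_layer - m) * level
        for m, level in levels_by_layer.items()
        if m <= target_layer
    )
    return params.baseline * float(np.exp(-exponent))


def simulate_series(
    params: DampeningParams,
    network: LayerNetwork,
    doses: Sequence[float],
) -> pd.DataFrame:
    """Noiseless forward model: per dose and layer, miRNA and target levels."""
    rows = []
    for dose in doses:
        if dose < 0:
            raise ValueError("doses must be non-negative")
        levels = propagate_layers(network, dose)
        for layer in range(network.depth):
            rows.append(
                {
                    "dose": float(dose),
                    "layer": layer,
                    "mirna_level": levels[layer],
                    "target_level": predict_target_level(levels, layer, params),
                }
            )
    return pd.DataFrame(rows, columns=["dose", "layer", "mirna_level", "target_level"])


def recover_params(
    series: pd.DataFrame,
    degree: int = 2,
    w_bounds: tuple[float, float] = (1e-6, 1.0 - 1e-6),
) -> tuple[ResponseCurve, DampeningParams]:
    """Refit (baseline, beta, w) and the layer-1 response curve from a series.

    ``series`` must carry columns dose, layer, mirna_level, target_level as
    produced by :func:`simulate_series` /
    :func:`coordbio.synthetic.generate_concentration_series`.  The attenuation
    base w only enters through cross-layer distances, so a single-layer
    series is non-identifiable and refused.

    Fitting is bounded trust-region least squares on linear-scale target
    levels; on noiseless input the recovered parameters match the truth to
    numerical precision.
    """
    required = {"dose", "layer", "mirna_level", "target_level"}
    if not required <= set(series.columns):
        raise ValueError(f"series missing column(s): {', '.join(sorted(required - set(series.columns)))}")
    layers = sorted(series["layer"].unique())
    if len(layers) < 2:
        raise ValueError(
            "attenuation base w is not identifiable from a single layer: "
            "distances between layers never vary"
        )

    # response curve: layer-1 miRNA level against primary (layer-0) level
    wide = series.pivot_table(index="dose", columns="layer", values="mirna_level")
    curve = fit_response_curve(wide[layers[0]].to_numpy(), wide[layers[1]].to_numpy(), degree=degree)

    mirna_levels = {
        (row.dose, row.layer): row.mirna_level for row in series.itertuples(index=False)
    }

    targets = series[["dose", "layer", "target_level"]].to_numpy()

    def residuals(theta: np.ndarray) -> np.ndarray:
        baseline, beta, w = theta
        preds = np.empty(len(targets))
        for i, (dose, layer, _) in enumerate(targets):
            t = int(layer)
            exponent = sum(
                beta * w ** (t - m) * mirna_levels[(dose, m)] for m in layers if m <= t
            )
            preds[i] = baseline * np.exp(-exponent)
        return preds - targets[:, 2]

    y = targets[:, 2]
    theta0 = np.array([max(y.max(), 1e-6), 1.0, 0.5])
    fit = least_squares(
        residuals,
        theta0,
        bounds=([1e-9, 0.0, w_bounds[0]], [np.inf, np.inf, w_bounds[1]]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    baseline, beta, w = fit.x
    return curve, DampeningParams(w=float(w), beta=float(beta), baseline=float(baseline))
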