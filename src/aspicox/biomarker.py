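"""Serum thromboxane B2 conversion and trajectory feature extraction.

sTXB2 reflects the maximal enzymatic capacity of platelet COX-1 and is the
measurable proxy of the model's unacetylated-COX-1 output.  The conversion is
an algebraic monotone map with a threshold: essentially no sTXB2 is produced
while unacetylated COX-1 is below ~20% of total, because the residual enzyme
is rate-limiting only at strong inhibition.

The five response features of a treatment trajectory:

=====  =====================================================================
X_ss   pre-dose plateau (mean of the last 48 h before the first dose)
X_1    minimum over the first inter-dose interval; D_1 = X_1 / X_ss
X_2    minimum over the whole treatment window (nadir); D = X_2 / X_ss
PP     peak-to-peak amplitude over the last full inter-dose interval
T_r    recovery time after the last dosing interval: first instant from
       which X stays within 3% of X_ss for good [h]
=====  =====================================================================
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import Field

from .params import Regimen, _Frozen
from .population import PopulationTrajectory

__all__ = ["ConversionCurve", "cox1_to_stxb2", "FeatureSet", "extract_features"]


class ConversionCurve(_Frozen):
    """Monotone map from unacetylated COX-1 (% of total) to sTXB2 (% of baseline).

    A Hill sigmoid in the COX-1 percentage, renormalised so that 100% maps to
    100%.  The defaults encode the spare-capacity behaviour of serum TXB2
    generation: the output stays near baseline while unacetylated COX-1 is
    abundant, collapses steeply as it approaches ~20-30% of total, and is
    < 1% of baseline at 20% COX-1 (the conversion threshold).
    """

    x50: float = Field(gt=0, default=33.0, description="inflection input [% COX-1]")
    steepness: float = Field(gt=0, default=12.0, description="Hill exponent of the map")

    def __call__(self, x_percent):
        x = np.asarray(x_percent, dtype=float)
        if np.any((x < 0) | (x > 100 + 1e-9)):
            raise ValueError("COX-1 percentage must lie in [0, 100]")
        g = x ** self.steepness / (self.x50 ** self.steepness + x ** self.steepness)
        g100 = 100.0 ** self.steepness / (self.x50 ** self.steepness + 100.0 ** self.steepness)
        out = 100.0 * g / g100
        return out if out.ndim else float(out)


def cox1_to_stxb2(x_percent, curve: ConversionCurve | None = None):
    """Convert unacetylated COX-1 [%] to sTXB2 [% of drug-free baseline]."""
    return (curve or ConversionCurve())(x_percent)


@dataclass
class FeatureSet:
    """The five response features plus their raw ingredients (units: % or au, h)."""

    X_ss: float
    X_1: float
    D_1: float
    X_2: float
    D: float
    PP: float
    T_r: float                    # NaN when the trajectory lacks recovery
    recovery_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"X_ss": self.X_ss, "X1": self.X_1, "D1": self.D_1,
                "X2": self.X_2, "D": self.D, "PP": self.PP, "Tr": self.T_r}

    def __getitem__(self, name: str) -> float:
        return {"X_ss": self.X_ss, "X_1": self.X_1, "D_1": self.D_1,
                "X_2": self.X_2, "D": self.D, "PP": self.PP, "T_r": self.T_r}[name]


FEATURE_NAMES = ["X_ss", "D_1", "D", "PP", "T_r"]


def extract_features(traj, regimen: Regimen | None = None, *,
                     tol_recovery: float = 0.03, signal: str = "percent",
                     plateau_window: float = 48.0) -> FeatureSet:
    """Extract the five response features from a treatment trajectory.

    ``traj`` is a :class:`~aspicox.population.PopulationTrajectory` (then
    ``signal`` selects the percent or absolute readout and ``regimen``
    defaults to the trajectory's own) or a plain ``(t, X)`` pair.

    ``T_r`` is measured from the end of the last dosing interval and requires
    X to stay within ``tol_recovery`` (relative) of the plateau at every
    later sample; if the trajectory ends before recovery, ``T_r`` is NaN and
    ``recovery_defined`` is False.
    """
    if isinstance(traj, PopulationTrajectory):
        t = traj.t
        X = traj.X_percent if signal == "percent" else traj.X_amount
        regimen = regimen or traj.regimen
    else:
        t, X = np.asarray(traj[0], float), np.asarray(traj[1], float)
    if regimen is None:
        raise ValueError("a regimen is required to window the features")

    d0 = regimen.start
    d_last = regimen.last_dose
    t_wd = d_last + regimen.interval          # withdrawal: end of last interval

    pre = (t < d0) & (t >= d0 - plateau_window)
    if not pre.any():
        pre = t < d0
    if not pre.any():
        raise ValueError("trajectory does not cover a pre-dose window")
    X_ss = float(X[pre].mean())

    first = (t >= d0) & (t <= d0 + regimen.interval)
    X_1 = float(X[first].min()) if first.any() else math.nan
    treat = (t >= d0) & (t <= t_wd)
    X_2 = float(X[treat].min()) if treat.any() else math.nan
    last_iv = (t >= d_last) & (t <= t_wd)
    PP = float(X[last_iv].max() - X[last_iv].min()) if last_iv.any() else math.nan

    post = t >= t_wd
    T_r = math.nan
    recovered = False
    if post.any() and X_ss > 0:
        dev = np.abs(X[post] / X_ss - 1.0)
        # within tolerance *and stays there*: reverse running maximum
        ok = np.flip(np.maximum.accumulate(np.flip(dev))) <= tol_recovery
        if ok.any():
            T_r = float(t[post][int(np.argmax(ok))] - t_wd)
            recovered = True
    return FeatureSet(X_ss=X_ss, X_1=X_1, D_1=X_1 / X_ss, X_2=X_2, D=X_2 / X_ss,
                      PP=PP, T_r=T_r, recovery_defined=recovered)
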