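"""The genetic diversity-area relationship (GDAR) power law.

Short-term loss of nucleotide diversity after losing a fraction ``A_lost`` of
habitat is well approximated by

    pi_lost = 1 - (1 - A_lost) ** z

where the exponent ``z`` (``z_GDAR``) encodes population structure: ``z = 0``
means diversity is insensitive to where habitat dies, ``z = 1`` means loss is
proportional to area.  The same functional form with allelic richness as the
response is the mutations-area relationship (MAR, exponent ``z_MAR``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["PowerLawFit", "fit_power_law", "predict_loss"]


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted power-law exponent with goodness of fit on the loss scale."""

    z: float
    r_squared: float
    n_points: int
    loss_type: str = "pi"

    def predict(self, a_lost) -> np.ndarray:
        return predict_loss(self.z, a_lost)


def fit_power_law(points, loss_type: str = "pi") -> PowerLawFit:
    """Fit ``loss = 1 - (1 - A_lost)^z`` by least squares through the origin.

    The transform ``log(1 - loss) = z * log(1 - A_lost)`` makes the model
    linear with no intercept (loss must vanish at zero area loss), so

        z = sum(xy) / sum(x^2),  x = log(1 - A_lost),  y = log(1 - loss).

    ``r_squared`` is reported on the untransformed loss scale against the
    fitted curve.  ``z`` is clipped at zero.

    Parameters
    ----------
    points
        Sequence of ``(A_lost, loss)`` pairs with ``0 <= A_lost < 1`` and
        ``0 <= loss < 1``.  Points at ``A_lost == 0`` carry no information
        about ``z`` and are dropped.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (A_lost, loss) pairs")
    a, y = pts[:, 0], pts[:, 1]
    if np.any((a < 0) | (a >= 1)) or np.any((y < 0) | (y >= 1)):
        raise ValueError("A_lost and loss must lie in [0, 1)")
    keep = a > 0
    if not np.any(keep):
        raise ValueError("no informative points: all at A_lost = 0")
    x = np.log1p(-a[keep])
    ly = np.log1p(-y[keep])
    z = max(0.0, float(np.sum(x * ly) / np.sum(x * x)))
    fitted = predict_loss(z, a)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return PowerLawFit(z=z, r_squared=r2, n_points=int(pts.shape[0]), loss_type=loss_type)


def predict_loss(z: float, a_lost) -> np.ndarray | float:
    """Predicted loss fraction ``1 - (1 - A_lost)^z``."""
    if z < 0:
        raise ValueError("z must be non-negative")
    a = np.asarray(a_lost, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("A_lost must lie in [0, 1]")
    if np.any(a == 1):
        warnings.warn("A_lost = 1 destroys all habitat; returning the formula limit of 1")
    out = 1.0 - np.power(1.0 - a, z)
    return float(out) if np.isscalar(a_lost) else out
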