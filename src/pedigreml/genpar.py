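"""Genetic parameters derived from fitted (co)variance components.

Ratios of the phenotypic variance ``sigma2_p = sigma2_a + sigma2_m +
sigma_am + sigma2_c + sigma2_e``:

* ``h2  = sigma2_a / sigma2_p``       direct heritability
* ``m2  = sigma2_m / sigma2_p``       maternal heritability
* ``c2  = sigma2_c / sigma2_p``       maternal permanent-environment ratio
* ``r_am = sigma_am / (sigma_a sigma_m)``  direct-maternal correlation
* ``h2_t = h2 + 0.5 m2 + 1.5 m r_am h``    total heritability (Willham),
  with ``h = sqrt(h2)`` and ``m = sqrt(m2)``.

``cov_am_proportion = sigma_am / sigma2_p`` is reported alongside ``r_am``:
it is the covariance expressed as a share of the phenotypic variance, a
quantity sometimes printed in place of the correlation, but only the true
correlation enters the Willham total-heritability composite.

Ratios of components the model does not fit are undefined (``nan``), never
zero-filled.  Standard errors use the first-order delta method over the
component covariance matrix (the inverse average-information matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixedmodel import VarianceComponents


@dataclass
class GeneticParameters:
    h2: float
    m2: float
    c2: float
    r_am: float
    h2_t: float
    cov_am_proportion: float
    se: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"h2": self.h2, "m2": self.m2, "c2": self.c2,
                "r_am": self.r_am, "h2_t": self.h2_t,
                "cov_am_proportion": self.cov_am_proportion}


def _ratios_from_values(values: dict, fitted: set) -> dict:
    s2a = values.get("sigma2_a", 0.0)
    s2m = values.get("sigma2_m", 0.0)
    sam = values.get("sigma_am", 0.0)
    s2c = values.get("sigma2_c", 0.0)
    s2e = values.get("sigma2_e", 0.0)
    s2p = s2a + s2m + sam + s2c + s2e
    out = {"h2": s2a / s2p}
    out["m2"] = s2m / s2p if "sigma2_m" in fitted else np.nan
    out["c2"] = s2c / s2p if "sigma2_c" in fitted else np.nan
    if "sigma_am" in fitted:
        out["r_am"] = sam / np.sqrt(s2a * s2m)
        out["cov_am_proportion"] = sam / s2p
    else:
        out["r_am"] = np.nan
        out["cov_am_proportion"] = np.nan
    h = np.sqrt(out["h2"])
    if "sigma2_m" in fitted:
        m = np.sqrt(out["m2"])
        r = out["r_am"] if "sigma_am" in fitted else 0.0
        out["h2_t"] = out["h2"] + 0.5 * out["m2"] + 1.5 * m * r * h
    else:
        out["h2_t"] = out["h2"]
    return out


def derive_parameters(vc: VarianceComponents) -> GeneticParameters:
    """Heritabilities and related ratios, with delta-method SEs.

    SEs are computed by propagating the component covariance matrix
    through a numerical Jacobian of each ratio; they are reported only when
    the fit carries a covariance matrix.
    """
    if vc.sigma2_p <= 0:
        raise ValueError(f"non-positive phenotypic variance {vc.sigma2_p}")
    fitted = set(vc.component_order) if vc.component_order else {
        k for k, v in vc.as_dict().items()
        if k != "sigma2_p" and (v != 0.0 or k in ("sigma2_a", "sigma2_e"))}
    values = vc.as_dict()
    ratios = _ratios_from_values(values, fitted)

    se = {}
    if vc.cov is not None and vc.component_order:
        order = list(vc.component_order)
        x0 = np.array([values[k] for k in order])
        cov = np.asarray(vc.cov, dtype=float)
        keys = [k for k in ("h2", "m2", "c2", "r_am", "h2_t",
                            "cov_am_proportion")
                if np.isfinite(ratios[k])]
        J = np.zeros((len(keys), len(order)))
        for j, comp in enumerate(order):
            h = 1e-6 * max(abs(x0[j]), 1e-3 * vc.sigma2_p)
            up = dict(zip(order, x0)); up[comp] += h
            dn = dict(zip(order, x0)); dn[comp] -= h
            r_up = _ratios_from_values(up, fitted)
            r_dn = _ratios_from_values(dn, fitted)
            for i, k in enumerate(keys):
                J[i, j] = (r_up[k] - r_dn[k]) / (2 * h)
        if np.isfinite(cov).all():
            var = np.einsum("ij,jk,ik->i", J, cov, J)
            var[var < 0] = np.nan
            se = dict(zip(keys, np.sqrt(var)))
    return GeneticParameters(h2=ratios["h2"], m2=ratios["m2"],
                             c2=ratios["c2"], r_am=ratios["r_am"],
                             h2_t=ratios["h2_t"],
                             cov_am_proportion=ratios["cov_am_proportion"],
                             se=se)
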