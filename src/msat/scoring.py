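"""Hub-calibrated inference: fused link scoring for CMM-ADR pairs.

The score for a pair (c, a) is a weighted fusion of three views:

    s = w1 * MLP([z_c || z_a || deg_c || deg_a])   (degree-aware, hub-calibrating)
      + w2 * z_c^T W_B z_a                          (bilinear, asymmetric)
      + w3 * sum_k z_c[k] r[k] z_a[k]               (DistMult, symmetric)

mapped to a probability by the logistic function. Degrees enter as log1p
values standardised by the training graph's per-type mean and sd, which keeps
the MLP input stable on heavy-tailed degree distributions. The DistMult term
contracts the elementwise product with a learnable diagonal ``r``
(initialised to ones), the standard reduction for that scorer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import HeteroGraph
from .network import ModelConfig


def init_scorer_params(config: ModelConfig,
                       rng: np.random.Generator) -> dict[str, Tensor]:
    dh = config.hidden_dim
    hid = config.hci_hidden
    p: dict[str, Tensor] = {}
    p["hci.mlp.W1"] = ad.parameter(ad.xavier_uniform(rng, (2 * dh + 2, hid)))
    p["hci.mlp.b1"] = ad.parameter(np.zeros(hid))
    p["hci.mlp.W2"] = ad.parameter(ad.xavier_uniform(rng, (hid, 1)))
    p["hci.mlp.b2"] = ad.parameter(np.zeros(1))
    p["hci.WB"] = ad.parameter(ad.xavier_uniform(rng, (dh, dh)))
    p["hci.r"] = ad.parameter(np.ones(dh))
    p["hci.w1"] = ad.parameter(1.0 / 3.0)
    p["hci.w2"] = ad.parameter(1.0 / 3.0)
    p["hci.w3"] = ad.parameter(1.0 / 3.0)
    return p


def mlp_score(z_c: Tensor, z_a: Tensor, deg_c: Tensor, deg_a: Tensor,
              params: dict[str, Tensor], config: ModelConfig,
              rng: np.random.Generator | None = None,
              training: bool = False) -> Tensor:
    """Degree-aware MLP over [z_c || z_a || deg_c || deg_a] -> (B, 1)."""
    if z_c.shape[-1] != config.hidden_dim or z_a.shape[-1] != config.hidden_dim:
        raise ValueError("embedding width mismatch with config.hidden_dim")
    x = ad.concat([z_c, z_a, deg_c, deg_a], axis=1)
    h = ad.relu(ad.add(ad.matmul(x, params["hci.mlp.W1"]),
                       params["hci.mlp.b1"]))
    h = ad.dropout(h, config.dropout, rng, training)
    return ad.add(ad.matmul(h, params["hci.mlp.W2"]), params["hci.mlp.b2"])


def bilinear_score(z_c: Tensor, z_a: Tensor, w_b: Tensor) -> Tensor:
    """Rowwise z_c^T W_B z_a -> (B, 1); asymmetric in (c, a) in general."""
    if z_c.shape != z_a.shape:
        raise ValueError("z_c and z_a must have matching shapes")
    tmp = ad.matmul(z_c, w_b)
    return ad.sum_(ad.mul(tmp, z_a), axis=1, keepdims=True)


def distmult_score(z_c: Tensor, z_a: Tensor, r: Tensor) -> Tensor:
    """Rowwise sum_k z_c[k] r[k] z_a[k] -> (B, 1); symmetric in (c, a)."""
    if z_c.shape != z_a.shape:
        raise ValueError("z_c and z_a must have matching shapes")
    return ad.sum_(ad.mul(ad.mul(z_c, r), z_a), axis=1, keepdims=True)


def hci_logit(z_c: Tensor, z_a: Tensor, deg_c: Tensor, deg_a: Tensor,
              params: dict[str, Tensor], config: ModelConfig,
              rng: np.random.Generator | None = None,
              training: bool = False) -> Tensor:
    """Fused raw score s = w1*mlp + w2*bilinear + w3*distmult -> (B, 1)."""
    m = mlp_score(z_c, z_a, deg_c, deg_a, params, config, rng, training)
    b = bilinear_score(z_c, z_a, params["hci.WB"])
    dm = distmult_score(z_c, z_a, params["hci.r"])
    return ad.add(ad.add(ad.mul(params["hci.w1"], m),
                         ad.mul(params["hci.w2"], b)),
                  ad.mul(params["hci.w3"], dm))


def hci_score(z_c: Tensor, z_a: Tensor, deg_c: Tensor, deg_a: Tensor,
              params: dict[str, Tensor], config: ModelConfig,
              rng: np.random.Generator | None = None,
              training: bool = False) -> Tensor:
    """Association probability sigmoid(s) in (0, 1)."""
    return ad.sigmoid(hci_logit(z_c, z_a, deg_c, deg_a, params, config,
                                rng, training))


@dataclass
class DegreeStandardizer:
    """log1p degrees standardised by training-graph per-type mean / sd."""

    mean_cmm: float
    sd_cmm: float
    mean_adr: float
    sd_adr: float

    @classmethod
    def fit(cls, graph: HeteroGraph) -> "DegreeStandardizer":
        dc = np.log1p(graph.degree_vector("cmm", scope="all"))
        da = np.log1p(graph.degree_vector("adr", scope="all"))
        return cls(mean_cmm=float(dc.mean()), sd_cmm=float(dc.std()) or 1.0,
                   mean_adr=float(da.mean()), sd_adr=float(da.std()) or 1.0)

    def transform_cmm(self, degrees: np.ndarray) -> np.ndarray:
        return (np.log1p(degrees) - self.mean_cmm) / self.sd_cmm

    def transform_adr(self, degrees: np.ndarray) -> np.ndarray:
        return (np.log1p(degrees) - self.mean_adr) / self.sd_adr

    def to_dict(self) -> dict:
        return {"mean_cmm": self.mean_cmm, "sd_cmm": self.sd_cmm,
                "mean_adr": self.mean_adr, "sd_adr": self.sd_adr}

    @classmethod
    def from_dict(cls, d: dict) -> "DegreeStandardizer":
        return cls(**d)
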