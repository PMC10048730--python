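"""Singly-constrained gravity models of gene flow on a saturated network.

Dyadic gene flow (the proportion of shared alleles, D_PS) is regressed on
log geographic distance (omega), log within-site attraction covariates
(upsilon, attached to the destination node) and log between-site
resistance distances (c), with a random intercept per *origin* node — the
single constraint.  Fits use REML (ML refits are available for nested
model comparisons).  AIC follows the convention

    AIC = 2 k_eff - 2 logL,   k_eff = (covariates beyond distance) + 4,

the +4 covering intercept, distance, origin-node variance and residual
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeTable
from .pairwise import PairwiseMatrix

log = logging.getLogger(__name__)


@dataclass
class GravityNetwork:
    """Saturated ordered-dyad network.

    ``nodes``: indexed by individual id, columns site, x, y and site-level
    attributes.  ``edges``: one row per ordered dyad with columns ``from``,
    ``to``, ``distance``, the response ``dps`` and any resistance-distance
    columns.
    """

    nodes: pd.DataFrame
    edges: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(self.edges) != n * (n - 1):
            raise ValueError(
                f"network not saturated: {len(self.edges)} edges for {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def write_csv(self, nodes_path, edges_path) -> None:
        self.nodes.to_csv(nodes_path)
        self.edges.to_csv(edges_path, index=False)

    @classmethod
    def read_csv(cls, nodes_path, edges_path) -> "GravityNetwork":
        return cls(pd.read_csv(nodes_path, index_col=0),
                   pd.read_csv(edges_path))


def build_network(table: GenotypeTable, attrs: pd.DataFrame,
                  dps: PairwiseMatrix,
                  resistances: dict[str, PairwiseMatrix] | None = None) -> GravityNetwork:
    """Assemble the saturated network from genotypes and site attributes.

    ``attrs`` is indexed by site (locality) id; every individual of a site
    receives that site's within-site conditions.  ``resistances`` adds one
    edge column per named resistance-distance matrix.
    """
    if table.xy is None:
        raise ValueError("genotype table has no coordinates")
    missing_sites = sorted(set(table.localities) - set(attrs.index.astype(str)))
    if missing_sites:
        raise ValueError(f"sites without attributes: {missing_sites}")
    nodes = pd.DataFrame({"id": table.ids, "site": table.localities,
                          "x": table.xy[:, 0], "y": table.xy[:, 1]}).set_index("id")
    for col in attrs.columns:
        nodes[col] = [attrs.loc[s, col] for s in table.localities]

    n = table.n
    dmat = dps.subset(table.ids).values
    frm, to = zip(*[(i, j) for i in range(n) for j in range(n) if i != j])
    frm, to = np.array(frm), np.array(to)
    dist = np.hypot(*(table.xy[frm] - table.xy[to]).T)
    edges = pd.DataFrame({"from": [table.ids[i] for i in frm],
                          "to": [table.ids[j] for j in to],
                          "distance": dist,
                          "dps": dmat[frm, to]})
    for name, rm in (resistances or {}).items():
        edges[name] = rm.subset(table.ids).values[frm, to]
    return GravityNetwork(nodes, edges)


@dataclass
class GravityFit:
    params: pd.DataFrame      # beta, se, df, t, p per covariate
    logL: float
    k_printed: int            # covariates beyond distance
    aic: float
    method: str
    converged: bool

    def to_dict(self) -> dict:
        return {"params": self.params.to_dict(orient="index"),
                "logL": self.logL, "k": self.k_printed, "aic": self.aic,
                "method": self.method}


def gravity_aic(logL: float, n_covariates: int) -> float:
    """AIC from a gravity-model log-likelihood; ``n_covariates`` counts the
    covariates beyond distance (0 for the pure isolation-by-distance null)."""
    return 2.0 * (n_covariates + 4.0) - 2.0 * logL


class GravityModel(BaseEstimator):
    """Estimator for the singly-constrained gravity mixed model.

    Parameters
    ----------
    covariates : names of within-site (node) and/or resistance (edge)
        covariates beyond distance; [] is the isolation-by-distance null.
    method : "REML" (reported fits) or "ML" (cross-model comparisons).
    constraint : "origin" (default) or "destination" random intercept.
    zero_offset : offset for zero responses; None -> half the minimum
        positive response, applied (and logged loudly) only when needed.
    """

    def __init__(self, covariates: tuple = (), method: str = "REML",
                 constraint: str = "origin", zero_offset: float | None = None):
        self.covariates = covariates
        self.method = method
        self.constraint = constraint
        self.zero_offset = zero_offset

    def fit(self, net: GravityNetwork):
        import statsmodels.api as sm

        edges, nodes = net.edges, net.nodes
        y = edges["dps"].to_numpy(dtype=float)
        if (y < 0).any() or (y > 1).any():
            raise ValueError("response dps must lie in [0, 1]")
        if (y == 0).any():
            if self.zero_offset is None:
                pos = y[y > 0]
                if len(pos) == 0:
                    raise ValueError("all responses zero")
                off = 0.5 * pos.min()
            else:
                off = self.zero_offset
            if off <= 0:
                raise ValueError("zero responses present and no positive offset")
            log.warning("gravity: %d zero responses offset by %.3g",
                        int((y == 0).sum()), off)
            y = y + off
        design = {"log_distance": np.log(edges["distance"].to_numpy(dtype=float))}
        node_cov, edge_cov = [], []
        for cov in self.covariates:
            if cov in edges.columns:
                design[f"log_{cov}"] = _safe_log(edges[cov].to_numpy(dtype=float), cov)
                edge_cov.append(cov)
            elif cov in nodes.columns:
                dest = edges["to"].map(nodes[cov]).to_numpy(dtype=float)
                design[f"log_{cov}"] = _safe_log(dest, cov)
                node_cov.append(cov)
            else:
                raise ValueError(f"covariate {cov!r} not found on nodes or edges")
        X = pd.DataFrame(design)
        X.insert(0, "intercept", 1.0)
        group_col = "from" if self.constraint == "origin" else "to"
        groups = edges[group_col].to_numpy()

        model = sm.MixedLM(np.log(y), X, groups=groups)
        res = model.fit(reml=self.method.upper() == "REML", method="lbfgs")

        n_edges, n_nodes = len(edges), net.n_nodes
        p = X.shape[1]
        rows = []
        for name in X.columns:
            beta = float(res.fe_params[name])
            se = float(res.bse_fe[name])
            # node-level covariates carry node-level information
            df = (n_nodes - 2 if name.replace("log_", "") in node_cov
                  else n_edges - p)
            t = beta / se if se > 0 else np.nan
            pval = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
            rows.append((name, beta, se, df, t, pval))
        params = pd.DataFrame(rows, columns=["term", "beta", "se", "df", "t", "p"]
                              ).set_index("term")
        kp = len(self.covariates)
        self.params_ = params
        self.loglik_ = float(res.llf)
        self.sigma2_group_ = float(res.cov_re.iloc[0, 0])
        self.sigma2_e_ = float(res.scale)
        self.aic_ = gravity_aic(self.loglik_, kp)
        self.result_ = GravityFit(params, self.loglik_, kp, self.aic_,
                                  self.method.upper(), bool(res.converged))
        return self


def _safe_log(v: np.ndarray, name: str) -> np.ndarray:
    if (v <= 0).any():
        off = 0.5 * v[v > 0].min() if (v > 0).any() else 1.0
        log.warning("gravity: covariate %r has non-positive values; offset %.3g",
                    name, off)
        v = v + off
    return np.log(v)


def fit_gravity(net: GravityNetwork, covariates: tuple = (),
                method: str = "REML", **kw) -> GravityFit:
    """Fit one gravity model; see :class:`GravityModel`."""
    return GravityModel(covariates=tuple(covariates), method=method, **kw
                        ).fit(net).result_


def gravity_model_table(net: GravityNetwork,
                        formulas: dict[str, tuple],
                        method: str = "REML") -> pd.DataFrame:
    """Model-selection table (K, logL, AIC) over covariate selections.

    ``formulas``: model name -> covariates beyond distance (the
    isolation-by-distance null is ()).  Sorted by log-likelihood.
    """
    if not formulas:
        raise ValueError("no formulas given")
    rows = []
    for name, covs in formulas.items():
        fit = fit_gravity(net, covariates=tuple(covs), method=method)
        # table convention: the distance-only null prints K = 1
        rows.append((name, fit.k_printed or 1, fit.logL, fit.aic))
    df = pd.DataFrame(rows, columns=["model", "K", "logL", "AIC"]).set_index("model")
    return df.sort_values("logL", ascending=False)
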