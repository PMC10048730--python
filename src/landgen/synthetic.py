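"""Synthetic landscapes, genotypes, dyadic distances and gravity networks.

These generators produce inputs with the statistical structure the
pipeline assumes, with the generating truth recorded so downstream
recovery tests close the loop: autocorrelated environmental rasters; a
known "true" resistance transformation; genetic dissimilarities that
follow the MLPE generative model on commute distance through that surface;
microsatellite genotypes whose site allele-frequency correlation decays
with commute distance; and saturated gravity networks with known
coefficients.

Everything is driven by an explicit integer seed; regeneration from the
same seed is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .genotypes import GenotypeTable
from .pairwise import PairwiseMatrix, euclidean_matrix
from .raster import RasterSurface
from .resistance import build_graph, commute_distance_nodes
from .surfaces import TransformSpec, apply_transform, rescale


@dataclass
class SyntheticTruth:
    """The generating configuration behind a simulated dataset."""

    true_spec: TransformSpec
    beta0: float = 0.0
    beta1: float = 1.0
    sigma2_u: float = 0.5
    sigma2_e: float = 1.0
    seed: int = 0
    layout: np.ndarray | None = None   # (m, 2) sampling coordinates

    def to_json(self) -> str:
        return json.dumps({
            "true_spec": json.loads(self.true_spec.to_json()),
            "beta0": self.beta0, "beta1": self.beta1,
            "sigma2_u": self.sigma2_u, "sigma2_e": self.sigma2_e,
            "seed": self.seed,
            "layout": None if self.layout is None else np.asarray(self.layout).tolist(),
        })


def make_landscape(kind: str, shape: tuple[int, int] = (40, 40), seed: int = 0,
                   smoothing: float = 3.0, n_classes: int = 2,
                   cell_size: float = 100.0) -> RasterSurface:
    """Random autocorrelated raster.

    ``smooth``: Gaussian-filtered white noise (generic continuous surface);
    ``dem``: multiscale field with ridging (|.|) so TRI/TPI are non-trivial;
    ``categorical``: quantile-thresholded smooth field with integer class
    labels 1..n_classes.
    """
    nr, nc = shape
    if nr < 20 or nc < 20:
        raise ValueError("landscape must be at least 20x20")
    rng = np.random.default_rng(seed)
    if kind == "smooth":
        vals = gaussian_filter(rng.standard_normal(shape), smoothing)
    elif kind == "dem":
        vals = np.zeros(shape)
        for octave, amp in ((1.0, 1.0), (2.5, 0.5), (6.0, 0.25)):
            vals += amp * gaussian_filter(rng.standard_normal(shape),
                                          smoothing * octave)
        vals = 500.0 + 300.0 * (vals - vals.min()) / np.ptp(vals) \
            + 50.0 * np.abs(gaussian_filter(rng.standard_normal(shape), smoothing))
    elif kind == "categorical":
        base = gaussian_filter(rng.standard_normal(shape), smoothing)
        edges = np.quantile(base, np.linspace(0, 1, n_classes + 1)[1:-1])
        vals = (np.digitize(base, edges) + 1).astype(float)
    else:
        raise ValueError(f"unknown landscape kind {kind!r}")
    return RasterSurface(vals, cell_size=cell_size, origin=(0.0, nr * cell_size),
                         tag=kind)


def sample_locations(raster: RasterSurface, n: int, seed: int = 0,
                     margin: int = 1) -> np.ndarray:
    """n distinct cell-center coordinates away from the border."""
    rng = np.random.default_rng(seed)
    nr, nc = raster.shape
    cells = [(r, c) for r in range(margin, nr - margin)
             for c in range(margin, nc - margin)
             if not np.isnan(raster.values[r, c])]
    idx = rng.choice(len(cells), size=n, replace=False)
    return np.array([raster.cell_center(*cells[i]) for i in idx])


def _true_commute(truth: SyntheticTruth, raster: RasterSurface,
                  locs: np.ndarray) -> np.ndarray:
    resist = apply_transform(rescale(raster), truth.true_spec)
    graph = build_graph(resist, connectivity=8)
    nodes = graph.snap_nodes(locs)
    return commute_distance_nodes(graph, nodes)


def simulate_genetic_distances(truth: SyntheticTruth, raster: RasterSurface,
                               locs: np.ndarray,
                               ids: list[str] | None = None) -> PairwiseMatrix:
    """Dyadic dissimilarities from the MLPE generative model.

    y_ij = b0 + b1 * z(commute_ij) + u_i + u_j + e_ij with the stated
    variances; commute is computed on the true resistance surface and
    z-scored so b1 is on the same scale the fitting step estimates.
    """
    locs = np.asarray(locs, dtype=float)
    m = len(locs)
    rng = np.random.default_rng(truth.seed)
    cm = _true_commute(truth, raster, locs)
    iu = np.triu_indices(m, k=1)
    c = cm[iu]
    z = (c - c.mean()) / c.std() if c.std() > 0 else np.zeros_like(c)
    u = rng.normal(0.0, np.sqrt(truth.sigma2_u), size=m)
    e = rng.normal(0.0, np.sqrt(truth.sigma2_e), size=len(c))
    y = truth.beta0 + truth.beta1 * z + u[iu[0]] + u[iu[1]] + e
    if ids is None:
        ids = [f"ind{k}" for k in range(m)]
    return PairwiseMatrix.from_condensed(ids, y, "rousset_ar")


def simulate_genotypes(truth: SyntheticTruth, raster: RasterSurface,
                       site_locs: np.ndarray, n_per_site: int = 4,
                       n_loci: int = 10, n_alleles: int = 8,
                       decay: float = 1.0, freq_sd: float = 1.0,
                       n_clone_pairs: int = 0,
                       n_parent_offspring: int = 0) -> GenotypeTable:
    """Genotypes with isolation-by-resistance structure.

    Site allele frequencies are logistic-normal deviates around common
    baselines, correlated between sites as exp(-decay * commute / median
    commute); individuals are two independent allele draws per locus.
    ``decay = 0`` gives one panmictic frequency set.  Clone and
    parent-offspring dyads can be planted for relatedness-filter tests.
    """
    if n_loci < 5:
        raise ValueError("need at least 5 loci")
    locs = np.asarray(site_locs, dtype=float)
    s = len(locs)
    rng = np.random.default_rng(truth.seed)
    if decay > 0:
        cm = _true_commute(truth, raster, locs)
        scale = np.median(cm[np.triu_indices(s, k=1)])
        corr = np.exp(-decay * cm / scale)
    else:
        corr = np.ones((s, s))
    corr = corr + 1e-8 * np.eye(s)
    chol = np.linalg.cholesky(corr)

    freqs = np.empty((s, n_loci, n_alleles))
    for l in range(n_loci):
        base = rng.normal(0.0, 0.5, size=n_alleles)
        dev = chol @ rng.standard_normal((s, n_alleles)) * freq_sd
        logits = base[None, :] + dev
        ex = np.exp(logits - logits.max(axis=1, keepdims=True))
        freqs[:, l, :] = ex / ex.sum(axis=1, keepdims=True)

    ids, sites, alleles, xy = [], [], [], []
    for si in range(s):
        for k in range(n_per_site):
            ids.append(f"s{si:02d}i{k:02d}")
            sites.append(f"site{si:02d}")
            g = np.empty((n_loci, 2), dtype=int)
            for l in range(n_loci):
                g[l] = rng.choice(n_alleles, size=2, p=freqs[si, l]) + 1
            alleles.append(g)
            xy.append(locs[si])
    alleles = np.array(alleles)

    def mendelian_child(parent: np.ndarray, site: int) -> np.ndarray:
        child = np.empty_like(parent)
        for l in range(n_loci):
            child[l, 0] = parent[l, rng.integers(2)]
            child[l, 1] = rng.choice(n_alleles, p=freqs[site, l]) + 1
        return child

    extra_a, extra_ids, extra_sites, extra_xy = [], [], [], []
    for k in range(n_clone_pairs):
        src = int(rng.integers(len(ids)))
        extra_a.append(alleles[src].copy())
        extra_ids.append(f"clone{k:02d}")
        extra_sites.append(sites[src])
        extra_xy.append(xy[src])
    for k in range(n_parent_offspring):
        src = int(rng.integers(len(ids)))
        si = int(sites[src][4:])
        extra_a.append(mendelian_child(alleles[src], si))
        extra_ids.append(f"off{k:02d}")
        extra_sites.append(sites[src])
        extra_xy.append(xy[src])
    if extra_a:
        alleles = np.concatenate([alleles, np.array(extra_a)])
        ids += extra_ids
        sites += extra_sites
        xy += extra_xy
    return GenotypeTable(ids, alleles, [f"L{l + 1}" for l in range(n_loci)],
                         sites, np.asarray(xy, dtype=float))


def simulate_gravity_network(n_sites: int = 15, per_site: int = 4,
                             beta: dict | None = None,
                             sigma2_origin: float = 0.1,
                             sigma2_e: float = 0.05,
                             seed: int = 0):
    """Saturated dyad network with known gravity-model coefficients.

    Node (site-level) attributes are log-normal; the log response is
    intercept + beta_distance * log distance + node/edge covariate terms +
    an origin random effect + residual noise, exponentiated back to a
    similarity in (0, 1]-ish range.  Returns (GravityNetwork, truth dict).
    """
    from .gravity import GravityNetwork  # local import to avoid a cycle

    beta = dict(beta or {})
    beta.setdefault("intercept", -1.0)
    beta.setdefault("distance", -0.03)
    rng = np.random.default_rng(seed)
    n = n_sites * per_site
    site_xy = rng.uniform(0, 30000, size=(n_sites, 2))
    attrs = pd.DataFrame({
        "site": [f"site{si:02d}" for si in range(n_sites)],
        "ivi": np.exp(rng.normal(3.0, 0.4, n_sites)),
        "ndvi": np.exp(rng.normal(-0.4, 0.15, n_sites)),
        "canopy_height": np.exp(rng.normal(2.7, 0.3, n_sites)),
    }).set_index("site")

    ids = [f"s{si:02d}i{k:02d}" for si in range(n_sites) for k in range(per_site)]
    site_of = [f"site{si:02d}" for si in range(n_sites) for _ in range(per_site)]
    xy = np.repeat(site_xy, per_site, axis=0)
    # jitter within-site coordinates so saturated dyads have positive distance
    xy = xy + rng.uniform(10, 400, size=xy.shape)

    nodes = pd.DataFrame({"id": ids, "site": site_of,
                          "x": xy[:, 0], "y": xy[:, 1]}).set_index("id")
    for col in attrs.columns:
        nodes[col] = [attrs.loc[s, col] for s in site_of]

    u = rng.normal(0.0, np.sqrt(sigma2_origin), size=n)
    frm, to = zip(*[(i, j) for i in range(n) for j in range(n) if i != j])
    frm = np.array(frm)
    to = np.array(to)
    dist = np.hypot(*(xy[frm] - xy[to]).T) / 1000.0  # km keeps logs tame
    eta = (beta["intercept"] + beta["distance"] * np.log(dist)
           + u[frm] + rng.normal(0.0, np.sqrt(sigma2_e), size=len(frm)))
    for name, b in beta.items():
        if name in attrs.columns and b != 0.0:
            eta = eta + b * np.log(nodes[name].to_numpy()[to])
    dps_vals = np.exp(eta)
    dps_vals = np.clip(dps_vals / max(1.0, dps_vals.max() * 1.001), 1e-6, 1.0)

    edges = pd.DataFrame({
        "from": [ids[i] for i in frm], "to": [ids[j] for j in to],
        "distance": dist, "dps": dps_vals,
    })
    net = GravityNetwork(nodes=nodes, edges=edges)
    truth = {"beta": beta, "sigma2_origin": sigma2_origin,
             "sigma2_e": sigma2_e, "seed": seed}
    return net, truth


def euclidean_from_locs(ids: list[str], locs: np.ndarray) -> PairwiseMatrix:
    return euclidean_matrix(ids, np.asarray(locs, dtype=float))
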