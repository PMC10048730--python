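"""Bootstrap model selection across optimized resistance surfaces.

Each iteration subsamples a fraction of the individuals without
replacement, restricts the genetic and all candidate distance matrices to
the retained dyads, refits the MLPE model per candidate (no
re-optimization of transformations), ranks candidates by AICc, and
accumulates rank, Akaike weight, and a top-model indicator.  Reported per
candidate: parameter count k, average rank, average weight (omega-bar),
and pi-hat — the percentage of iterations in which the candidate ranked
first, the bootstrap analogue of the Akaike weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

from .mlpe import aicc, fit_mlpe
from .pairwise import PairwiseMatrix
from .raster import RasterSurface

log = logging.getLogger(__name__)


@dataclass
class BootstrapSummary:
    table: pd.DataFrame          # index: candidate; columns: k, avg_rank, omega_bar, pi_hat
    iterations: int
    subsample_fraction: float
    n_resampled_iterations: int = 0

    def __str__(self) -> str:
        return self.table.to_string()


class BootstrapSelector(BaseEstimator):
    """Estimator wrapper around :func:`bootstrap_select`.

    ``fit(candidates, genetic)`` stores the summary in ``summary_`` and the
    winner (highest pi-hat) in ``best_candidate_``.
    """

    def __init__(self, frac: float = 0.75, iters: int = 500,
                 seed: int = 0, k: dict | None = None):
        self.frac = frac
        self.iters = iters
        self.seed = seed
        self.k = k

    def fit(self, candidates: dict, genetic: PairwiseMatrix):
        self.summary_ = bootstrap_select(candidates, genetic, frac=self.frac,
                                         iters=self.iters, seed=self.seed,
                                         k=self.k)
        self.best_candidate_ = self.summary_.table["pi_hat"].idxmax()
        return self


def bootstrap_select(candidates: dict[str, PairwiseMatrix],
                     genetic: PairwiseMatrix, frac: float = 0.75,
                     iters: int = 500, seed: int = 0,
                     k: dict[str, int] | None = None) -> BootstrapSummary:
    """Bootstrap AICc model selection over candidate distance matrices.

    Parameters
    ----------
    candidates : name -> distance matrix (should include a Euclidean
        "Distance" null).
    k : name -> parameter count for AICc (defaults to the fitted count:
        intercept + slope + 2 variances).  AICc n is the subsample size.
    frac : fraction of individuals kept per iteration.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    if not candidates:
        raise ValueError("no candidate matrices")
    rng = np.random.default_rng(seed)
    names = list(candidates)
    ids = genetic.ids
    n = len(ids)
    m = math.ceil(frac * n)
    aligned = {nm: candidates[nm].subset(ids) for nm in names}

    ranks = {nm: 0.0 for nm in names}
    weights = {nm: 0.0 for nm in names}
    tops = {nm: 0 for nm in names}
    kmap = dict(k or {})
    n_resampled = 0
    done = 0
    while done < iters:
        pick = sorted(rng.choice(n, size=m, replace=False).tolist())
        sub_ids = [ids[i] for i in pick]
        rows = []
        try:
            for nm in names:
                fitted = fit_mlpe(genetic.subset(sub_ids),
                                  aligned[nm].subset(sub_ids),
                                  method="ML", k=kmap.get(nm))
                kk = kmap.get(nm, fitted.k)
                rows.append((nm, kk, aicc(fitted.logL, kk, m)))
        except ValueError as exc:
            n_resampled += 1
            log.warning("bootstrap iteration resampled (%s)", exc)
            if n_resampled > 10 * iters:
                raise RuntimeError("too many failed bootstrap iterations") from exc
            continue
        # order by AICc, ties by fewer parameters; exact residual ties are
        # permuted randomly so symmetric candidates have symmetric ranks
        shuffled = [rows[i] for i in rng.permutation(len(rows))]
        order = sorted(shuffled, key=lambda t: (round(t[2], 9), t[1]))
        a = np.array([t[2] for t in order])
        w = np.exp(-0.5 * (a - a.min()))
        w /= w.sum()
        for rank0, ((nm, kk, _), wi) in enumerate(zip(order, w)):
            ranks[nm] += rank0 + 1
            weights[nm] += wi
            kmap.setdefault(nm, kk)
        tops[order[0][0]] += 1
        done += 1

    table = pd.DataFrame({
        "k": [kmap[nm] for nm in names],
        "avg_rank": [ranks[nm] / iters for nm in names],
        "omega_bar": [weights[nm] / iters for nm in names],
        "pi_hat": [100.0 * tops[nm] / iters for nm in names],
    }, index=pd.Index(names, name="candidate"))
    return BootstrapSummary(table, iters, frac, n_resampled)


def spearman_correlation(a: RasterSurface, b: RasterSurface) -> float:
    """Spearman rank correlation between two aligned surfaces over cells
    valid in both."""
    if a.shape != b.shape:
        raise ValueError("surfaces are not aligned")
    ok = ~(a.missing | b.missing)
    if ok.sum() < 3:
        raise ValueError("too few co-valid cells")
    rho, _ = spearmanr(a.values[ok], b.values[ok])
    return float(rho)
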