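"""Genetic-algorithm search over resistance-surface parameterizations.

The optimizer searches transformation space (family, shape, maximum) for
continuous surfaces, or per-class resistance values for categorical
surfaces, maximizing the ML log-likelihood of the MLPE model

    genetic distance ~ commute distance on the transformed surface.

GA machinery: tournament selection, uniform crossover, Gaussian mutation
on log-shape and log-maximum (shape searched on a log scale in
[0.01, 100], maximum up to the single-surface bound 5000 or the composite
bound 10000), elitism, and a stall rule (stop after a fixed number of
generations without a 0.1 log-likelihood improvement).  Runs are repeated
independently (>= 2, the usual convergence check for these searches) and
the best run is reported together with per-run results so disagreement is
visible rather than silently merged.

Commute matrices are cached per evaluated surface (hash of the transformed
resistance values), which is what keeps desk-scale runtimes practical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .mlpe import MLPEFit, fit_mlpe
from .pairwise import PairwiseMatrix
from .raster import RasterSurface
from .resistance import build_graph, commute_distance_nodes
from .surfaces import (COMPOSITE_MAX_BOUND, FAMILIES, SINGLE_MAX_BOUND,
                       CategoricalAssignment, TransformSpec, apply_categorical,
                       apply_transform, combine, percent_contribution, rescale)

log = logging.getLogger(__name__)

_CONT_FAMILIES = FAMILIES  # includes the flat "Distance" null


@dataclass
class GAConfig:
    population: int = 30
    max_generations: int = 100
    patience: int = 25          # generations without >= min_improve
    min_improve: float = 0.1    # log-likelihood units
    tournament: int = 3
    crossover_rate: float = 0.7
    mutation_rate: float = 0.3
    mutation_sigma: float = 0.6     # on log-shape / log-maximum
    family_mutation_rate: float = 0.15
    immigrant_rate: float = 0.15    # fresh random genomes per generation
    n_runs: int = 2
    run_tolerance: float = 0.5      # logL disagreement worth flagging
    log_shape_range: tuple = (float(np.log(0.01)), float(np.log(100.0)))


@dataclass
class OptimizationResult:
    best_spec: object                  # TransformSpec | list | CategoricalAssignment
    best_fit: MLPEFit
    history: list                      # per-generation best logL of the best run
    runs: list                         # per-run {"logL", "spec"} dicts
    converged: bool                    # runs agree within tolerance
    percent_contribution: list | None = None
    n_evaluations: int = 0


class ResistanceOptimizer(BaseEstimator):
    """GA optimizer for one surface or a composite of surfaces.

    ``fit(surfaces, genetic, locs)`` with ``surfaces`` a RasterSurface
    (single) or list of RasterSurface (composite); ``genetic`` the dyadic
    genetic-distance matrix (one row/col per location, aligned with
    ``locs``); ``locs`` (m, 2) projected sampling coordinates.

    Fitted attributes: ``result_``, ``best_spec_``, ``best_fit_``.
    """

    def __init__(self, kind: str = "continuous", seed: int = 0,
                 config: GAConfig | None = None, connectivity: int = 8):
        self.kind = kind
        self.seed = seed
        self.config = config
        self.connectivity = connectivity

    # -- objective --------------------------------------------------------
    def _objective_factory(self, rescaled, raw_cat, genetic, locs, n_components):
        cache: dict[bytes, PairwiseMatrix] = {}
        counter = {"n": 0}
        # the larger composite bound only applies to true multi-surface searches,
        # so a one-component composite is identical to the single-surface search
        max_bound = COMPOSITE_MAX_BOUND if n_components > 1 else SINGLE_MAX_BOUND

        def transform_all(genome) -> list[RasterSurface]:
            if self.kind == "continuous":
                return [apply_transform(r, spec)
                        for r, spec in zip(rescaled, genome)]
            return [apply_categorical(raw_cat[0], genome)]

        def evaluate(genome):
            comps = transform_all(genome)
            surf = combine(comps) if len(comps) > 1 else comps[0]
            key = hashlib.sha1(np.ascontiguousarray(surf.values).tobytes()).digest()
            if key not in cache:
                graph = build_graph(surf, connectivity=self.connectivity)
                nodes = graph.snap_nodes(locs)
                cm = commute_distance_nodes(graph, nodes)
                np.fill_diagonal(cm, np.nan)
                cache[key] = PairwiseMatrix(genetic.ids, cm, "commute")
                counter["n"] += 1
            try:
                fit = fit_mlpe(genetic, cache[key], method="ML")
            except ValueError:   # e.g. flat surface -> constant commute
                return -np.inf, None
            return fit.logL, fit

        return evaluate, counter, max_bound

    # -- genomes ----------------------------------------------------------
    def _random_spec(self, rng, max_bound) -> TransformSpec:
        fam = _CONT_FAMILIES[rng.integers(len(_CONT_FAMILIES))]
        lo, hi = self.config_.log_shape_range
        shape = float(np.exp(rng.uniform(lo, hi)))
        maximum = float(np.exp(rng.uniform(np.log(1.1), np.log(max_bound))))
        return TransformSpec(fam, shape, maximum)

    def _mutate_spec(self, spec, rng, max_bound) -> TransformSpec:
        cfg = self.config_
        fam, shape, maximum = spec.family, spec.shape, spec.maximum
        if rng.random() < cfg.family_mutation_rate:
            fam = _CONT_FAMILIES[rng.integers(len(_CONT_FAMILIES))]
        if rng.random() < cfg.mutation_rate:
            lo, hi = cfg.log_shape_range
            shape = float(np.exp(np.clip(np.log(shape) +
                                         rng.normal(0, cfg.mutation_sigma), lo, hi)))
        if rng.random() < cfg.mutation_rate:
            maximum = float(np.exp(np.clip(np.log(maximum) +
                                           rng.normal(0, cfg.mutation_sigma),
                                           np.log(1.1), np.log(max_bound))))
        return TransformSpec(fam, shape, maximum)

    # -- GA loop ----------------------------------------------------------
    def _run_ga(self, evaluate, rng, n_genes, max_bound, labels=None):
        cfg = self.config_

        if self.kind == "continuous":
            def rand_genome(family=None):
                specs = [self._random_spec(rng, max_bound) for _ in range(n_genes)]
                if family is not None:
                    specs[0] = TransformSpec(family, specs[0].shape,
                                             specs[0].maximum)
                return specs

            def mutate(g):
                return [self._mutate_spec(s, rng, max_bound) for s in g]

            def crossover(a, b):
                mask = rng.random(n_genes) < 0.5
                return ([a[i] if m else b[i] for i, m in enumerate(mask)],
                        [b[i] if m else a[i] for i, m in enumerate(mask)])
        else:
            ref = labels[0]   # first label is the reference class, fixed at 1

            def rand_genome():
                vals = {ref: 1.0}
                for lab in labels[1:]:
                    vals[lab] = float(np.exp(rng.uniform(np.log(1e-2),
                                                         np.log(max_bound))))
                return CategoricalAssignment(vals, bound=max_bound)

            def mutate(g):
                vals = dict(g.values)
                for lab in labels[1:]:
                    if rng.random() < cfg.mutation_rate:
                        vals[lab] = float(np.exp(np.clip(
                            np.log(vals[lab]) + rng.normal(0, cfg.mutation_sigma),
                            np.log(1e-2), np.log(max_bound))))
                return CategoricalAssignment(vals, bound=max_bound)

            def crossover(a, b):
                va, vb = dict(a.values), dict(b.values)
                for lab in labels[1:]:
                    if rng.random() < 0.5:
                        va[lab], vb[lab] = vb[lab], va[lab]
                return (CategoricalAssignment(va, bound=max_bound),
                        CategoricalAssignment(vb, bound=max_bound))

        if self.kind == "continuous":
            # stratified start: every family is represented before filling
            # the rest of the population at random
            fams = list(_CONT_FAMILIES)
            pop = [rand_genome(fams[i]) if i < len(fams) else rand_genome()
                   for i in range(cfg.population)]
        else:
            pop = [rand_genome() for _ in range(cfg.population)]
        fits = [evaluate(g) for g in pop]
        best_idx = int(np.argmax([f[0] for f in fits]))
        best = (fits[best_idx][0], pop[best_idx], fits[best_idx][1])
        history = [best[0]]
        stall = 0

        for _gen in range(cfg.max_generations):
            new_pop = [best[1]]  # elitism
            while len(new_pop) < cfg.population:
                def pick():
                    idx = rng.integers(len(pop), size=cfg.tournament)
                    return pop[max(idx, key=lambda i: fits[i][0])]

                if rng.random() < cfg.immigrant_rate:
                    new_pop.append(rand_genome())
                    continue
                a, b = pick(), pick()
                if rng.random() < cfg.crossover_rate:
                    a, b = crossover(a, b)
                new_pop.append(mutate(a))
                if len(new_pop) < cfg.population:
                    new_pop.append(mutate(b))
            pop = new_pop
            fits = [evaluate(g) for g in pop]
            gen_best = int(np.argmax([f[0] for f in fits]))
            if fits[gen_best][0] > best[0]:
                improved = fits[gen_best][0] - best[0]
                best = (fits[gen_best][0], pop[gen_best], fits[gen_best][1])
                stall = 0 if improved >= cfg.min_improve else stall + 1
            else:
                stall += 1
            history.append(best[0])
            if stall >= cfg.patience:
                break
        best = self._polish(best, evaluate, max_bound)
        history.append(best[0])
        return {"logL": best[0], "genome": best[1], "fit": best[2],
                "history": history}

    def _polish(self, best, evaluate, max_bound):
        """Local refinement of the continuous parameters of the best genome
        (families / class labels stay fixed), so independent runs converge
        to their basin's optimum rather than the GA's last step."""
        from scipy.optimize import minimize

        genome = best[1]
        lo, hi = self.config_.log_shape_range
        if self.kind == "continuous":
            active = [i for i, s in enumerate(genome) if s.family != "Distance"]
            if not active:
                return best
            x0 = np.concatenate([[np.log(genome[i].shape),
                                  np.log(genome[i].maximum)] for i in active])

            def rebuild(x):
                specs = list(genome)
                for k, i in enumerate(active):
                    specs[i] = TransformSpec(
                        genome[i].family,
                        float(np.exp(np.clip(x[2 * k], lo, hi))),
                        float(np.exp(np.clip(x[2 * k + 1], np.log(1.1),
                                             np.log(max_bound)))))
                return specs
        else:
            labels = [lab for lab, v in genome.values.items() if v != 1.0]
            if not labels:
                return best
            x0 = np.log([genome.values[lab] for lab in labels])

            def rebuild(x):
                vals = dict(genome.values)
                for k, lab in enumerate(labels):
                    vals[lab] = float(np.exp(np.clip(x[k], np.log(1e-2),
                                                     np.log(max_bound))))
                return CategoricalAssignment(vals, bound=max_bound)

        def neg(x):
            return -evaluate(rebuild(x))[0]

        res = minimize(neg, x0, method="Nelder-Mead",
                       options={"maxiter": 40 * len(x0), "xatol": 1e-4,
                                "fatol": 1e-6})
        if -res.fun > best[0]:
            genome = rebuild(res.x)
            ll, fit = evaluate(genome)
            return (ll, genome, fit)
        return best

    def fit(self, surfaces, genetic: PairwiseMatrix, locs):
        self.config_ = self.config or GAConfig()
        if isinstance(surfaces, RasterSurface):
            surfaces = [surfaces]
        locs = np.asarray(locs, dtype=float)
        if self.kind == "continuous":
            rescaled = [rescale(s) for s in surfaces]
            raw_cat, labels = None, None
        else:
            if len(surfaces) > 1:
                raise ValueError("categorical optimization is single-surface")
            rescaled = None
            raw_cat = surfaces
            v = surfaces[0].values
            labels = sorted(float(x) for x in np.unique(v[~np.isnan(v)]))
        evaluate, counter, max_bound = self._objective_factory(
            rescaled, raw_cat, genetic, locs, len(surfaces))

        cfg = self.config_
        runs = []
        for r in range(max(2, cfg.n_runs)):
            rng = np.random.default_rng((self.seed, r))
            runs.append(self._run_ga(evaluate, rng,
                                     n_genes=len(surfaces), max_bound=max_bound,
                                     labels=labels))
        lls = [r["logL"] for r in runs]
        best_run = runs[int(np.argmax(lls))]
        spread = max(lls) - min(lls)
        converged = spread <= cfg.run_tolerance
        if not converged:
            log.warning("GA runs disagree by %.3f logL (> %.2f): %s",
                        spread, cfg.run_tolerance, [round(l, 3) for l in lls])

        genome = best_run["genome"]
        if self.kind == "continuous" and len(surfaces) == 1:
            best_spec = genome[0]
            pct = None
        elif self.kind == "continuous":
            best_spec = list(genome)
            comps = [apply_transform(r, s) for r, s in zip(rescaled, genome)]
            pct = percent_contribution(comps)
        else:
            best_spec = genome
            pct = None
        self.result_ = OptimizationResult(
            best_spec=best_spec, best_fit=best_run["fit"],
            history=best_run["history"],
            runs=[{"logL": r["logL"], "spec": r["genome"]} for r in runs],
            converged=converged, percent_contribution=pct,
            n_evaluations=counter["n"])
        self.best_spec_ = best_spec
        self.best_fit_ = best_run["fit"]
        return self


def optimize_surface(raw: RasterSurface, genetic: PairwiseMatrix, locs,
                     kind: str = "continuous", cfg: GAConfig | None = None,
                     seed: int = 0) -> OptimizationResult:
    """GA-optimize a single surface; see :class:`ResistanceOptimizer`."""
    return ResistanceOptimizer(kind=kind, seed=seed, config=cfg
                               ).fit(raw, genetic, locs).result_


def optimize_composite(components: list[RasterSurface], genetic: PairwiseMatrix,
                       locs, cfg: GAConfig | None = None,
                       seed: int = 0) -> OptimizationResult:
    """Jointly optimize transformation parameters of several surfaces
    combined by cell-wise summation."""
    return ResistanceOptimizer(kind="continuous", seed=seed, config=cfg
                               ).fit(list(components), genetic, locs).result_
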