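"""Microsatellite genotype tables and individual-level genetic distances.

Implements the genetic side of the pipeline: reading and validating diploid
multilocus genotypes, maximum-likelihood pairwise relatedness over the
Cotterman coefficients (k0, k1, k2), greedy removal of closely related
dyads, Rousset's â individual differentiation, and the proportion of shared
alleles D_PS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .pairwise import PairwiseMatrix

log = logging.getLogger(__name__)

MISSING = -1  # internal allele code for a missing gene copy


class GenotypeParseError(ValueError):
    pass


class GenotypeValidationError(ValueError):
    pass


@dataclass
class GenotypeTable:
    """Diploid genotypes: individuals x loci, two unordered alleles per locus.

    ``alleles`` has shape (n_individuals, n_loci, 2) with positive integer
    allele labels and ``MISSING`` (-1) for missing gene copies; a locus is
    missing for an individual iff both copies are MISSING.
    """

    ids: list[str]
    alleles: np.ndarray
    loci: list[str]
    localities: list[str] = field(default_factory=list)
    xy: np.ndarray | None = None  # (n, 2) easting/northing in meters

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.alleles = np.asarray(self.alleles, dtype=int)
        n, L = len(self.ids), len(self.loci)
        if self.alleles.shape != (n, L, 2):
            raise GenotypeValidationError("alleles array has wrong shape")
        if len(set(self.ids)) != n:
            dup = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise GenotypeValidationError(f"duplicate individual_id: {dup}")
        if not self.localities:
            self.localities = ["site0"] * n
        bad = (self.alleles <= 0) & (self.alleles != MISSING)
        if bad.any():
            raise GenotypeValidationError("allele labels must be positive integers")
        # half-missing genotypes (one copy typed) are not meaningful
        half = (self.alleles == MISSING).sum(axis=2) == 1
        if half.any():
            raise GenotypeValidationError("genotypes with exactly one missing copy")
        typed = self.typed_mask()
        if not typed.any(axis=1).all():
            who = [self.ids[i] for i in np.where(~typed.any(axis=1))[0]]
            raise GenotypeValidationError(f"individuals with no typed locus: {who}")
        if not typed.any(axis=0).all():
            empty = [self.loci[j] for j in np.where(~typed.any(axis=0))[0]]
            raise GenotypeValidationError(f"loci with no observed allele: {empty}")
        if self.xy is not None:
            self.xy = np.asarray(self.xy, dtype=float)
            if self.xy.shape != (n, 2) or not np.isfinite(self.xy).all():
                raise GenotypeValidationError("coordinates must be finite (n, 2)")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self) -> np.ndarray:
        """(n, L) bool: locus typed (both copies observed) for individual."""
        return (self.alleles != MISSING).all(axis=2)

    def subset(self, ids: Sequence[str]) -> "GenotypeTable":
        idx = [self.ids.index(str(i)) for i in ids]
        return GenotypeTable(
            [self.ids[k] for k in idx], self.alleles[idx].copy(), list(self.loci),
            [self.localities[k] for k in idx],
            None if self.xy is None else self.xy[idx].copy())

    def allele_frequencies(self) -> list[dict[int, float]]:
        """Sample allele frequencies per locus from all typed gene copies."""
        out = []
        for j in range(self.n_loci):
            genes = self.alleles[:, j, :].ravel()
            genes = genes[genes != MISSING]
            labels, counts = np.unique(genes, return_counts=True)
            out.append(dict(zip(labels.tolist(), (counts / counts.sum()).tolist())))
        return out

    def summary(self) -> dict:
        typed = self.typed_mask()
        freqs = self.allele_frequencies()
        sites = pd.Series(self.localities)
        per_site = sites.value_counts()
        s = {
            "n_individuals": self.n,
            "n_loci": self.n_loci,
            "n_localities": int(per_site.size),
            "mean_individuals_per_locality": float(self.n / per_site.size),
            "alleles_per_locus": {l: len(f) for l, f in zip(self.loci, freqs)},
            "missingness": float(1.0 - typed.mean()),
        }
        log.info("genotype table: %(n_individuals)d individuals, %(n_loci)d loci, "
                 "%(n_localities)d localities, missingness %(missingness).3f", s)
        return s


# -- I/O ------------------------------------------------------------------

def read_genotypes(path: str | Path, missing_code: str = "0",
                   allele_sep: str = "/") -> GenotypeTable:
    """Read a wide genotype CSV.

    Layout: columns ``individual_id`` (required), ``locality_id``,
    ``easting``/``northing`` (optional), then loci — either one column per
    locus with ``a/b`` tokens, or two columns per locus named ``<locus>_1``
    and ``<locus>_2``.  ``missing_code`` (default "0") marks a missing gene
    copy; "0/0" is a missing genotype, never allele "0".
    """
    df = pd.read_csv(path, dtype=str).fillna(missing_code)
    if "individual_id" not in df.columns:
        raise GenotypeParseError("missing required column 'individual_id'")
    meta = ["individual_id", "locality_id", "easting", "northing"]
    locus_cols = [c for c in df.columns if c not in meta]

    def parse_token(tok: str, row: int, col: str) -> int:
        tok = tok.strip()
        if tok in (missing_code, "NA", ""):
            return MISSING
        try:
            val = int(tok)
        except ValueError:
            raise GenotypeParseError(
                f"malformed allele token {tok!r} at row {row}, column {col!r}") from None
        if val <= 0:
            raise GenotypeParseError(
                f"non-positive allele {tok!r} at row {row}, column {col!r}")
        return val

    # detect dialect: paired "<locus>_1/<locus>_2" columns vs "a/b" tokens
    paired: dict[str, tuple[str, str]] = {}
    for c in locus_cols:
        if c.endswith("_1") and c[:-2] + "_2" in locus_cols:
            paired[c[:-2]] = (c, c[:-2] + "_2")
    if paired and len(paired) * 2 == len(locus_cols):
        loci = list(paired)
        alleles = np.empty((len(df), len(loci), 2), dtype=int)
        for j, locus in enumerate(loci):
            for k, col in enumerate(paired[locus]):
                alleles[:, j, k] = [parse_token(t, i, col)
                                    for i, t in enumerate(df[col])]
    else:
        loci = locus_cols
        alleles = np.empty((len(df), len(loci), 2), dtype=int)
        for j, col in enumerate(loci):
            for i, tok in enumerate(df[col]):
                parts = str(tok).split(allele_sep)
                if len(parts) != 2:
                    raise GenotypeParseError(
                        f"expected 'a{allele_sep}b' token at row {i}, column {col!r}, "
                        f"got {tok!r}")
                alleles[i, j, 0] = parse_token(parts[0], i, col)
                alleles[i, j, 1] = parse_token(parts[1], i, col)
    # a genotype with one missing copy is treated as fully missing
    one = (alleles == MISSING).any(axis=2)
    alleles[one] = MISSING

    localities = (df["locality_id"].tolist() if "locality_id" in df.columns else [])
    xy = None
    if {"easting", "northing"} <= set(df.columns):
        xy = df[["easting", "northing"]].astype(float).to_numpy()
    table = GenotypeTable(df["individual_id"].tolist(), alleles, loci,
                          localities, xy)
    table.summary()
    return table


def write_genotypes(table: GenotypeTable, path: str | Path,
                    missing_code: str = "0", allele_sep: str = "/") -> None:
    """Write the slash-token wide CSV that :func:`read_genotypes` reads."""
    cols: dict[str, list] = {"individual_id": table.ids,
                             "locality_id": table.localities}
    if table.xy is not None:
        cols["easting"] = table.xy[:, 0]
        cols["northing"] = table.xy[:, 1]
    for j, locus in enumerate(table.loci):
        toks = []
        for i in range(table.n):
            a, b = table.alleles[i, j]
            if a == MISSING or b == MISSING:
                toks.append(f"{missing_code}{allele_sep}{missing_code}")
            else:
                toks.append(f"{a}{allele_sep}{b}")
        cols[locus] = toks
    pd.DataFrame(cols).to_csv(path, index=False)


# -- ML relatedness -------------------------------------------------------

_CANONICAL_STARTS = (
    (1.0, 0.0, 0.0),    # unrelated
    (0.5, 0.5, 0.0),    # half sib
    (0.25, 0.5, 0.25),  # full sib
    (0.0, 1.0, 0.0),    # parent-offspring
)


def _pair_locus_coeffs(g1: tuple[int, int], g2: tuple[int, int],
                       freqs: dict[int, float]) -> tuple[float, float, float]:
    """(S0, S1, S2) such that Pr(G1, G2 | k) = k0 S0 + k1 S1 + k2 S2.

    Standard no-inbreeding IBD-sharing likelihoods for unordered diploid
    genotypes; S0 = Pr(G1)Pr(G2), S2 = Pr(G1) iff identical.
    """
    p = freqs.get
    a, b = g1
    c, d = g2

    def pg(x, y):
        return p(x, 0.0) ** 2 if x == y else 2 * p(x, 0.0) * p(y, 0.0)

    s0 = pg(a, b) * pg(c, d)
    s2 = pg(a, b) if {a, b} == {c, d} else 0.0
    # one shared IBD gene: the IBD copy is equally likely either gene of G1;
    # G2 = {ibd, X} with the non-IBD gene X a fresh population draw
    s1 = 0.0
    pr_g1 = pg(a, b)
    for ibd in (a, b):
        if c == d:
            x_needed = c if ibd == c else None
        else:
            x_needed = d if ibd == c else (c if ibd == d else None)
        s1 += pr_g1 * 0.5 * (p(x_needed, 0.0) if x_needed is not None else 0.0)
    return s0, s1, s2


def _dyad_relatedness(coeffs: np.ndarray) -> float:
    """Maximize the multilocus likelihood over the constrained k-simplex.

    ``coeffs``: (L, 3) array of per-locus (S0, S1, S2).  Returns
    r = k2 + k1/2 at the constrained maximum (k in the 2-simplex with the
    genetically feasible region k1^2 >= 4 k0 k2).
    """

    def negll(k):
        lik = coeffs @ np.clip(k, 0.0, 1.0)
        return -np.log(np.maximum(lik, 1e-300)).sum()

    cons = (
        {"type": "eq", "fun": lambda k: k.sum() - 1.0},
        {"type": "ineq", "fun": lambda k: k[1] ** 2 - 4.0 * k[0] * k[2]},
    )
    best_val, best_k = np.inf, np.array([1.0, 0.0, 0.0])
    for start in _CANONICAL_STARTS:
        res = minimize(negll, np.asarray(start), method="SLSQP",
                       bounds=[(0.0, 1.0)] * 3, constraints=cons,
                       options={"maxiter": 200, "ftol": 1e-12})
        k = np.clip(res.x, 0.0, 1.0)
        k /= k.sum()
        val = negll(k)
        if k[1] ** 2 + 1e-9 >= 4 * k[0] * k[2] and val < best_val:
            best_val, best_k = val, k
    return float(best_k[2] + best_k[1] / 2.0)


def estimate_relatedness(table: GenotypeTable,
                         pairs: Sequence[tuple[str, str]] | None = None) -> PairwiseMatrix:
    """Maximum-likelihood pairwise relatedness r-hat in [0, 1].

    Uses sample allele frequencies (accurate only when the table is a
    reasonable frequency sample); per dyad, loci missing in either member
    are dropped.  ``pairs`` restricts estimation to named dyads (other
    entries stay NaN); by default all dyads are estimated.  Raises if no
    locus is polymorphic (r unidentifiable).
    """
    freqs = table.allele_frequencies()
    if all(len(f) < 2 for f in freqs):
        raise GenotypeValidationError(
            "all loci monomorphic: relatedness is unidentifiable")
    typed = table.typed_mask()
    n = table.n
    vals = np.full((n, n), np.nan)
    if pairs is None:
        todo = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        pos = {pid: k for k, pid in enumerate(table.ids)}
        todo = [(pos[str(a)], pos[str(b)]) for a, b in pairs]
    for i, j in todo:
        loci = np.where(typed[i] & typed[j])[0]
        coeffs = np.array([
            _pair_locus_coeffs(tuple(table.alleles[i, l]),
                               tuple(table.alleles[j, l]), freqs[l])
            for l in loci])
        r = _dyad_relatedness(coeffs) if len(coeffs) else np.nan
        vals[i, j] = vals[j, i] = r
    return PairwiseMatrix(table.ids, vals, "relatedness_r")


def filter_related(table: GenotypeTable, r: PairwiseMatrix,
                   threshold: float = 0.5) -> GenotypeTable:
    """Drop individuals until no dyad has relatedness strictly above threshold.

    Greedy: repeatedly remove the individual with the most above-threshold
    partners (ties: lexicographically smallest id), which retains the most
    individuals in practice.  Dyads at exactly the threshold are kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    rmat = r.subset(table.ids)
    above = np.nan_to_num(rmat.values) > threshold
    keep = set(range(table.n))
    while True:
        deg = {i: int(above[i, sorted(keep)].sum()) for i in keep}
        worst = max(deg.values(), default=0)
        if worst == 0:
            break
        cands = [i for i in keep if deg[i] == worst]
        drop = min(cands, key=lambda i: table.ids[i])
        keep.remove(drop)
    kept_ids = [table.ids[i] for i in sorted(keep)]
    if len(kept_ids) < table.n:
        log.info("filter_related: removed %d of %d individuals (r > %.3g)",
                 table.n - len(kept_ids), table.n, threshold)
    return table.subset(kept_ids)


# -- individual genetic distances ----------------------------------------

def rousset_ar(table: GenotypeTable) -> PairwiseMatrix:
    """Rousset's â between individuals.

    Per locus, Q_ij is the probability that one gene drawn from i matches
    one drawn from j, and Qw the mean within-individual gene identity over
    the sample.  â pools loci as a ratio of sums:
    â_ij = Σ_l (Qw_l − Q_ij,l) / Σ_l (1 − Qw_l), with per-dyad missing loci
    dropped from both sums.
    """
    if table.n < 3:
        raise GenotypeValidationError("rousset_ar needs at least 3 individuals")
    typed = table.typed_mask()
    n, L = table.n, table.n_loci
    # within-individual identity per locus (homozygous = 1)
    hom = (table.alleles[:, :, 0] == table.alleles[:, :, 1]) & typed
    qw = np.array([hom[typed[:, l], l].mean() if typed[:, l].any() else np.nan
                   for l in range(L)])
    if np.all(qw[np.isfinite(qw)] >= 1.0 - 1e-12):
        raise GenotypeValidationError(
            "all individuals identically homozygous: â undefined (Qw = 1)")
    # Q_ij per locus: mean over the 4 cross-individual gene draws
    a = table.alleles
    match = np.zeros((n, n, L))
    for k1 in range(2):
        for k2 in range(2):
            match += a[:, None, :, k1] == a[None, :, :, k2]
    q = match / 4.0
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for l in range(L):
        if not np.isfinite(qw[l]):
            continue
        ok = np.outer(typed[:, l], typed[:, l])
        num += np.where(ok, qw[l] - q[:, :, l], 0.0)
        den += np.where(ok, 1.0 - qw[l], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / den
    vals[den == 0] = np.nan
    np.fill_diagonal(vals, np.nan)
    return PairwiseMatrix(table.ids, vals, "rousset_ar")


def dps(table: GenotypeTable) -> PairwiseMatrix:
    """Proportion of shared alleles D_PS in [0, 1].

    Per shared typed locus, sum over alleles of min allele counts, divided
    by 2; averaged over the loci typed in both members.  Dyads with no
    shared typed locus are NaN and logged.
    """
    typed = table.typed_mask()
    n, L = table.n, table.n_loci
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            loci = np.where(typed[i] & typed[j])[0]
            if len(loci) == 0:
                log.warning("dps: dyad (%s, %s) shares no typed locus",
                            table.ids[i], table.ids[j])
                continue
            shares = []
            for l in loci:
                gi = table.alleles[i, l]
                gj = list(table.alleles[j, l])
                shared = 0
                for al in gi:
                    if al in gj:
                        gj.remove(al)
                        shared += 1
                shares.append(shared / 2.0)
            vals[i, j] = vals[j, i] = float(np.mean(shares))
    return PairwiseMatrix(table.ids, vals, "dps")
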