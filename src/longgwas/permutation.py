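"""Monte-Carlo permutation validation of association findings.

Each replicate redistributes the trait values uniformly at random over the
individuals of the sample (covariate rows stay attached to their
individuals; only the trait column is shuffled) and recomputes the identical
test statistic. The Monte-Carlo p-value is k/N, where k counts replicates
with a statistic strictly larger than the observed one — this estimator can
return exactly 0 and is reported alongside the positively-biased
(k+1)/(N+1).

Permutations come from a counter-based Philox stream keyed by the seed and
drawn in fixed-size blocks, so extending N re-uses the earlier replicates
unchanged. Validating several hits shares one replicate stream: the same
permutations are applied to every hit, making their Monte-Carlo p-values
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import GWASResults, TraitTable, ols_fit
from .genotypes import GenotypeMatrix

PERM_BLOCK = 10_000  # fixed block size keeps the stream extension-stable


@dataclass
class PermutationResult:
    snp_id: str  # SNP id, or "snpA:snpB" for a pair
    n_replicates: int
    k: int  # replicates with statistic strictly larger than observed
    n_ties: int
    observed_stat: float
    parametric_p: float
    seed: int

    @property
    def p_mc(self) -> float:
        return self.k / self.n_replicates

    @property
    def p_mc_conservative(self) -> float:
        return (self.k + 1) / (self.n_replicates + 1)


def _perm_blocks(n: int, n_replicates: int, seed: int):
    """Yield (n_used, index-matrix) blocks of uniform permutations of range(n)."""
    rng = np.random.Generator(np.random.Philox(seed))
    remaining = n_replicates
    while remaining > 0:
        block = rng.permuted(
            np.broadcast_to(np.arange(n), (PERM_BLOCK, n)).copy(), axis=1
        )
        use = min(remaining, PERM_BLOCK)
        yield use, block[:use]
        remaining -= use


class _MarkerStat:
    """Squared-t (Wald) statistic of the dosage coefficient, batch-evaluable."""

    def __init__(self, y, dosage, covariates=None):
        ok = ~np.isnan(y) & ~np.isnan(dosage)
        if covariates is not None:
            ok &= ~np.isnan(covariates).any(axis=1)
        self.ok = ok
        x = dosage[ok]
        cols = [np.ones(ok.sum()), x]
        if covariates is not None:
            cols.extend(covariates[ok].T)
        self.X = np.column_stack(cols)
        self.n, self.p = self.X.shape
        self.xtx = self.X.T @ self.X
        if self.n <= self.p or np.linalg.matrix_rank(self.X) < self.p:
            raise ValueError("degenerate design for permutation statistic")
        self.inv_jj = np.linalg.inv(self.xtx)[1, 1]
        self.parametric_df = self.n - self.p

    def observed(self, y):
        fit = ols_fit(self.X, y[self.ok])
        if fit is None or not np.isfinite(fit["t"][1]):
            raise ValueError("observed statistic undefined; refusing to permute")
        return float(fit["t"][1] ** 2), float(fit["p"][1])

    def batch(self, Y):
        """Statistics for an (n_full × R) matrix of permuted trait columns."""
        Yk = Y[self.ok]
        xty = self.X.T @ Yk
        B = np.linalg.solve(self.xtx, xty)
        sse = (Yk**2).sum(axis=0) - (xty * B).sum(axis=0)
        sse = np.maximum(sse, 1e-300)
        return B[1] ** 2 / (sse / (self.n - self.p) * self.inv_jj)


class _PairStat:
    """Standard nested F of the dosage-product term, batch-evaluable."""

    def __init__(self, y, d1, d2, covariates=None):
        ok = ~np.isnan(y) & ~np.isnan(d1) & ~np.isnan(d2)
        if covariates is not None:
            ok &= ~np.isnan(covariates).any(axis=1)
        self.ok = ok
        cols = [np.ones(ok.sum()), d1[ok], d2[ok]]
        if covariates is not None:
            cols.extend(covariates[ok].T)
        self.Xa = np.column_stack(cols)
        self.Xai = np.column_stack(cols + [d1[ok] * d2[ok]])
        self.n = self.Xai.shape[0]
        self.dof = self.n - self.Xai.shape[1]
        if self.dof <= 0 or np.linalg.matrix_rank(self.Xai) < self.Xai.shape[1]:
            raise ValueError("degenerate design for permutation statistic")
        self.xtx_a = self.Xa.T @ self.Xa
        self.xtx_ai = self.Xai.T @ self.Xai

    def observed(self, y):
        yk = y[self.ok]
        f = self._f(yk[:, None])[0]
        if not np.isfinite(f):
            raise ValueError("observed statistic undefined; refusing to permute")
        return float(f), float(stats.f.sf(f, 1, self.dof))

    def _f(self, Yk):
        def sse(X, xtx):
            xty = X.T @ Yk
            B = np.linalg.solve(xtx, xty)
            return (Yk**2).sum(axis=0) - (xty * B).sum(axis=0)

        sse_a = sse(self.Xa, self.xtx_a)
        sse_ai = np.minimum(sse(self.Xai, self.xtx_ai), sse_a)
        sse_ai = np.maximum(sse_ai, 1e-300)
        return (sse_a - sse_ai) / (sse_ai / self.dof)

    def batch(self, Y):
        return self._f(Y[self.ok])


def permute_scan(
    y: np.ndarray,
    dosages,
    covariates: np.ndarray | None = None,
    n_replicates: int = 100_000,
    seed: int = 0,
    snp_id: str = "",
    forced_observed_stat: float | None = None,
) -> PermutationResult:
    """Monte-Carlo p-value for one SNP (1-D dosage) or one pair (2-column).

    ``forced_observed_stat`` substitutes the reference statistic without
    refitting — used to probe estimator boundaries in the test suite.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    y = np.asarray(y, float)
    dosages = np.asarray(dosages, float)
    if dosages.ndim == 1:
        stat = _MarkerStat(y, dosages, covariates)
    elif dosages.ndim == 2 and dosages.shape[1] == 2:
        stat = _PairStat(y, dosages[:, 0], dosages[:, 1], covariates)
    else:
        raise ValueError("dosages must be one SNP (1-D) or one pair (n × 2)")
    if forced_observed_stat is None:
        obs, p_param = stat.observed(y)
    else:
        obs, p_param = float(forced_observed_stat), np.nan

    k = ties = 0
    for use, idx in _perm_blocks(y.size, n_replicates, seed):
        vals = stat.batch(y[idx.T])
        k += int((vals > obs).sum())
        ties += int((vals == obs).sum())
    return PermutationResult(
        snp_id=snp_id,
        n_replicates=n_replicates,
        k=k,
        n_ties=ties,
        observed_stat=obs,
        parametric_p=p_param,
        seed=seed,
    )


def validate_top_hits(
    scan: GWASResults,
    trait: TraitTable,
    geno: GenotypeMatrix,
    n_top: int = 10,
    n_replicates: int = 100_000,
    seed: int = 0,
) -> list[PermutationResult]:
    """Re-evaluate the n_top smallest-p scan hits under one shared stream."""
    if n_top == 0:
        return []
    hits = scan.table.dropna(subset=["p"]).nsmallest(n_top, "p")
    trait_df = trait.df.set_index("ID")
    common = [i for i in geno.individual_ids if i in trait_df.index]
    sub = geno.subset_individuals(
        np.asarray([geno.individual_ids.index(i) for i in common], dtype=int)
    )
    y = trait_df.loc[common, "dsbp_dt"].to_numpy(float)
    cov = (
        trait_df.loc[common, scan.covariates].to_numpy(float)
        if scan.covariates
        else None
    )
    stats_ = {}
    for sid in hits["snp"]:
        j = sub.snp_ids.index(sid)
        stats_[sid] = _MarkerStat(y, sub.dosages[:, j], cov)
    observed = {sid: s.observed(y) for sid, s in stats_.items()}
    counts = {sid: [0, 0] for sid in stats_}
    for use, idx in _perm_blocks(y.size, n_replicates, seed):
        Y = y[idx.T]
        for sid, s in stats_.items():
            vals = s.batch(Y)
            counts[sid][0] += int((vals > observed[sid][0]).sum())
            counts[sid][1] += int((vals == observed[sid][0]).sum())
    return [
        PermutationResult(
            snp_id=sid,
            n_replicates=n_replicates,
            k=counts[sid][0],
            n_ties=counts[sid][1],
            observed_stat=observed[sid][0],
            parametric_p=observed[sid][1],
            seed=seed,
        )
        for sid in hits["snp"]
    ]
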