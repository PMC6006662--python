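"""Model-based population clustering of codominant genotypes.

The model is a finite mixture over K source populations without admixture:
each individual belongs to one (latent) population, and conditional on that
population its two allele copies at every locus are independent draws from
the population's allele-frequency vector (Hardy-Weinberg within
populations, linkage equilibrium across loci). Parameters — mixing
proportions, per-population allele frequencies and soft assignments Q — are
estimated by expectation-maximization, which is deterministic given a seed
and has a monotonically non-decreasing log-likelihood.

The number of populations is selected by the Evanno delta-K statistic over
replicate runs at successive K: with mean log-likelihood L(K) across
replicates and its standard deviation s(K),

    L'(K)  = L(K) - L(K-1)
    L''(K) = |L(K+1) - 2 L(K) + L(K-1)|
    dK(K)  = L''(K) / s(K)

and the K with the largest dK is reported. When no dK rises above a small
threshold the result is flagged low-signal (no detectable structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .diversity import MISSING, GenotypeMatrix

#: Largest delta-K below which model selection is considered uninformative.
LOW_SIGNAL_DELTA_K = 10.0


class AlleleMixtureModel:
    """Finite mixture of populations for a diploid codominant panel.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Individuals x loci diploid calls (fragment sizes; missing allowed).
    K : int
        Number of source populations, 1 <= K <= n_individuals.
    """

    def __init__(self, matrix: GenotypeMatrix, K: int) -> None:
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > matrix.n_individuals:
            raise ValueError(f"K={K} exceeds the {matrix.n_individuals} individuals")
        self.matrix = matrix
        self.K = K
        self.allele_labels: list[np.ndarray] = []
        n, L = matrix.n_individuals, matrix.n_loci
        max_alleles = 0
        per_locus_codes = []
        for j in range(L):
            cell = matrix.calls[:, j, :]
            alleles = np.unique(cell[cell != MISSING])
            self.allele_labels.append(alleles)
            max_alleles = max(max_alleles, len(alleles))
            per_locus_codes.append({a: idx for idx, a in enumerate(alleles.tolist())})
        # allele copy counts C[i, l, a] in {0, 1, 2}; observation mask
        self._counts = np.zeros((n, L, max_alleles))
        self._obs = np.zeros((n, L))
        self._log_het = np.zeros(n)  # sum of log(2) over heterozygous cells
        for i in range(n):
            for j in range(L):
                a1, a2 = matrix.calls[i, j]
                if a1 == MISSING:
                    continue
                self._obs[i, j] = 1.0
                self._counts[i, j, per_locus_codes[j][a1]] += 1
                self._counts[i, j, per_locus_codes[j][a2]] += 1
                if a1 != a2:
                    self._log_het[i] += np.log(2.0)
        self._allele_mask = np.zeros((L, max_alleles), dtype=bool)
        for j, labels in enumerate(self.allele_labels):
            self._allele_mask[j, : len(labels)] = True

    # -- internals ----------------------------------------------------------

    def _component_loglik(self, log_freqs: np.ndarray) -> np.ndarray:
        """log P(individual i | population k), shape (n, K)."""
        ll = np.einsum("ila,kla->ik", self._counts, log_freqs)
        return ll + self._log_het[:, None]

    def _m_step(self, resp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mix = resp.mean(axis=0)
        numer = np.einsum("ik,ila->kla", resp, self._counts)
        denom = 2.0 * np.einsum("ik,il->kl", resp, self._obs)
        freqs = np.where(
            self._allele_mask[None, :, :], numer / np.maximum(denom, 1e-300)[:, :, None], 0.0
        )
        return mix, freqs

    def fit(
        self, seed: int = 0, max_iter: int = 500, tol: float = 1e-6, n_init: int = 10
    ) -> "MixtureResults":
        """Run EM to convergence (absolute log-likelihood change < tol).

        EM converges to a local optimum, so the fit restarts from ``n_init``
        random initializations (sub-seeded deterministically from ``seed``)
        and keeps the highest-likelihood solution.
        """
        best: MixtureResults | None = None
        for sub in np.random.SeedSequence(seed).spawn(n_init):
            res = self._fit_once(np.random.default_rng(sub), max_iter, tol)
            if best is None or res.loglik > best.loglik:
                best = res
        assert best is not None
        return best

    def _fit_once(self, rng: np.random.Generator, max_iter: int, tol: float) -> "MixtureResults":
        n = self.matrix.n_individuals
        resp = rng.dirichlet(np.ones(self.K), size=n)
        mix, freqs = self._m_step(resp)
        history: list[float] = []
        loglik = -np.inf
        converged = False
        for _ in range(max_iter):
            log_freqs = np.log(np.where(freqs > 0, freqs, 1.0)) + np.where(
                freqs > 0, 0.0, -1e10
            )
            log_joint = np.log(np.maximum(mix, 1e-300))[None, :] + self._component_loglik(
                log_freqs
            )
            per_ind = logsumexp(log_joint, axis=1)
            new_loglik = float(per_ind.sum())
            resp = np.exp(log_joint - per_ind[:, None])
            history.append(new_loglik)
            if np.isfinite(loglik) and abs(new_loglik - loglik) < tol:
                converged = True
                loglik = new_loglik
                break
            loglik = new_loglik
            mix, freqs = self._m_step(resp)
        return MixtureResults(
            model=self,
            mixing=mix,
            allele_freqs=freqs,
            Q=pd.DataFrame(
                resp,
                index=self.matrix.individuals,
                columns=[f"pop{k + 1}" for k in range(self.K)],
            ),
            loglik=loglik,
            n_iter=len(history),
            converged=converged,
            loglik_history=np.array(history),
        )


@dataclass(frozen=True)
class MixtureResults:
    """Fitted mixture: soft assignments Q, allele frequencies, likelihood."""

    model: AlleleMixtureModel
    mixing: np.ndarray
    allele_freqs: np.ndarray  # (K, loci, max alleles), zero-padded
    Q: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    loglik_history: np.ndarray

    @property
    def hard_labels(self) -> pd.Series:
        """Maximum-a-posteriori population per individual."""
        return self.Q.idxmax(axis=1).rename("population")

    def summary(self) -> str:
        lines = [
            "Allele mixture model (no admixture, EM)",
            f"  populations (K):     {self.model.K}",
            f"  individuals:         {self.model.matrix.n_individuals}",
            f"  loci:                {self.model.matrix.n_loci}",
            f"  log-likelihood:      {self.loglik:.4f}",
            f"  EM iterations:       {self.n_iter} ({'converged' if self.converged else 'not converged'})",
            "  mixing proportions:  " + ", ".join(f"{m:.3f}" for m in self.mixing),
            "  assignment counts:   "
            + ", ".join(f"{k}={v}" for k, v in self.hard_labels.value_counts().items()),
        ]
        return "\n".join(lines)


def evanno_delta_k(runs: Mapping[int, Sequence[float]]) -> pd.DataFrame:
    """Evanno table from replicate log-likelihoods per K.

    ``runs`` maps each K of a contiguous range to >= 2 replicate
    log-likelihoods. delta_K is NaN at the range ends (second difference
    undefined) and where the replicate standard deviation is zero.
    """
    ks = sorted(runs)
    if len(ks) < 3:
        raise ValueError("need at least three consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K range must be contiguous")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"need >= 2 replicates at K={k}")
    mean_l = {k: float(np.mean(runs[k])) for k in ks}
    sd_l = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        l_prime = mean_l[k] - mean_l[k - 1] if k - 1 in mean_l else np.nan
        if k - 1 in mean_l and k + 1 in mean_l:
            l_pp = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1])
            delta = l_pp / sd_l[k] if sd_l[k] > 0 else np.nan
        else:
            l_pp, delta = np.nan, np.nan
        rows.append(
            {
                "K": k,
                "n_reps": len(runs[k]),
                "mean_L": mean_l[k],
                "sd_L": sd_l[k],
                "L_prime": l_prime,
                "L_doubleprime_abs": l_pp,
                "delta_K": delta,
            }
        )
    return pd.DataFrame(rows)


def best_k(evanno: pd.DataFrame) -> int:
    """K at the delta-K peak (ties: smallest K). Raises if all undefined.

    A K whose replicates all reached the identical optimum (sd_L == 0) with
    non-zero curvature |L''| has delta_K undefined in the table but
    unbounded support in the sd -> 0 limit; such K outrank every finite
    delta_K here.
    """
    effective = []
    for row in evanno.itertuples():
        if np.isnan(row.L_doubleprime_abs):
            continue
        if row.sd_L == 0.0:
            if row.L_doubleprime_abs > 0:
                effective.append((np.inf, row.K))
        elif not np.isnan(row.delta_K):
            effective.append((row.delta_K, row.K))
    if not effective:
        raise ValueError("delta_K is undefined at every K")
    peak = max(d for d, _ in effective)
    return int(min(k for d, k in effective if d == peak))


@dataclass(frozen=True)
class StructureResults:
    """Replicated structure analysis: Evanno table and the chosen model."""

    evanno: pd.DataFrame
    best_k: int
    best_model: MixtureResults
    low_signal: bool
    logliks: dict[int, list[float]] = field(repr=False, default_factory=dict)

    def q_long(self) -> pd.DataFrame:
        """Bar-chart-ready long format: individual, population, membership."""
        q = self.best_model.Q.reset_index(names="individual")
        return q.melt(id_vars="individual", var_name="population", value_name="membership")

    def summary(self) -> str:
        head = [
            "Population structure (EM mixture + Evanno delta-K)",
            f"  K range:    {self.evanno['K'].min()}..{self.evanno['K'].max()}"
            f" x {int(self.evanno['n_reps'].iloc[0])} replicates",
            f"  best K:     {self.best_k}"
            + ("  [low signal: no dominant delta-K peak]" if self.low_signal else ""),
        ]
        return "\n".join(head) + "\n" + self.evanno.to_string(index=False)


def replicate_seed(master_seed: int, K: int, replicate: int) -> np.random.SeedSequence:
    """Deterministic per-run seed from the master seed by counter hashing."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(K, replicate))


def infer_structure(
    matrix: GenotypeMatrix,
    k_max: int = 6,
    replicates: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> StructureResults:
    """Fit K = 1..k_max with replicated EM runs and select K by delta-K.

    Fully reproducible given ``seed``: replicate r at population count K
    uses a seed derived from (seed, K, r). The returned best model is the
    highest-likelihood replicate at the delta-K peak.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3 for the second difference")
    if replicates < 2:
        raise ValueError("need >= 2 replicates per K")
    logliks: dict[int, list[float]] = {}
    fits: dict[int, list[MixtureResults]] = {}
    for K in range(1, k_max + 1):
        model = AlleleMixtureModel(matrix, K)
        fits[K] = []
        for r in range(replicates):
            ss = replicate_seed(seed, K, r)
            res = model.fit(seed=int(ss.generate_state(1)[0] % (2**31)), max_iter=max_iter, tol=tol)
            fits[K].append(res)
        logliks[K] = [f.loglik for f in fits[K]]
    evanno = evanno_delta_k(logliks)
    k_star = best_k(evanno)
    best_model = max(fits[k_star], key=lambda f: f.loglik)
    degenerate_peak = bool(
        ((evanno["sd_L"] == 0.0) & (evanno["L_doubleprime_abs"] > 0)).any()
    )
    max_delta = np.inf if degenerate_peak else float(evanno["delta_K"].max(skipna=True))
    return StructureResults(
        evanno=evanno,
        best_k=k_star,
        best_model=best_model,
        # NaN max_delta (all undefined, unreachable after best_k) is low signal;
        # an infinite (sd -> 0) peak is maximal signal
        low_signal=not (max_delta >= LOW_SIGNAL_DELTA_K),
        logliks=logliks,
    )


def plot_evanno(evanno: pd.DataFrame, axes=None):
    """Four-panel Evanno plot: mean L(K), L'(K), |L''(K)| and delta-K."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(8, 6))
    axes = np.asarray(axes).ravel()
    panels = [
        ("mean_L", "mean L(K)"),
        ("L_prime", "L'(K)"),
        ("L_doubleprime_abs", "|L''(K)|"),
        ("delta_K", "delta K"),
    ]
    for ax, (col, title) in zip(axes, panels):
        sub = evanno.dropna(subset=[col])
        ax.plot(sub["K"], sub[col], marker="o")
        if col == "mean_L":
            ax.errorbar(evanno["K"], evanno["mean_L"], yerr=evanno["sd_L"], fmt="none")
        ax.set_xlabel("K")
        ax.set_title(title)
    return axes
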