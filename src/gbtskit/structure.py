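"""Population structure: GRM-based PCA and the admixture model.

GRM
    entry(i, j) = mean over loci, where both calls are present, of
    (g_i - 2p)(g_j - 2p) / (2 p (1 - p)), with p the pooled ALT frequency;
    monomorphic loci are excluded and missingness is handled pairwise.

PCA
    eigendecomposition of the GRM; sample scores are eigenvectors scaled
    by sqrt(eigenvalue); variance explained is eigenvalue over the sum of
    positive eigenvalues.  Sign convention: the largest-magnitude loading
    of each component is positive.

Admixture
    each individual i carries ancestry proportions q_i over K clusters
    with cluster allele frequencies f_kj; genotypes are Binomial(2, p_ij)
    with p_ij = sum_k q_ik f_kj.  The log-likelihood

        L = sum_ij [ g_ij ln p_ij + (2 - g_ij) ln (1 - p_ij) ]

    is maximised by EM with closed-form M-steps; monotone non-decrease of
    L is asserted on every iteration.  F is clamped to [1e-6, 1 - 1e-6].
    Random restarts (seeded) mitigate local optima.

Cross-validation for K masks non-missing genotype entries in folds,
refits, predicts each masked dosage as g_hat = 2 sum_k q_ik f_kj, and
scores root-mean-square error; the best K is the argmin (smallest-K
tiebreak).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

_F_EPS = 1e-6


def _polymorphic_dosage(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Float dosage matrix and mask, restricted to polymorphic loci."""
    called = matrix.called
    n_called = called.sum(axis=0)
    dos = np.where(called, matrix.dosage, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_called)
    poly = (n_called > 0) & (p > 0) & (p < 1)
    if not np.any(poly):
        raise ValueError("no polymorphic loci")
    return dos[:, poly], called[:, poly].astype(float), p[poly]


def grm(matrix: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix with pairwise-complete missing handling."""
    if matrix.n_samples < 2:
        raise ValueError("need >= 2 samples")
    dos, w, p = _polymorphic_dosage(matrix)
    z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    zw = z * w
    num = zw @ zw.T
    den = w @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        g = num / den
    g[den == 0] = 0.0
    return 0.5 * (g + g.T)


@dataclasses.dataclass
class PCAResult:
    scores: np.ndarray  # (n_samples, n_components)
    variance_explained: np.ndarray  # fraction per component
    n_components: int
    samples: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"PC{i + 1}" for i in range(self.n_components)]
        )
        if self.samples is not None:
            df.insert(0, "sample", self.samples)
        return df


def pca(g: np.ndarray, n_components: int | None = None,
        samples: list[str] | None = None) -> PCAResult:
    """PCA of a (symmetric) genomic relationship matrix."""
    g = np.asarray(g, dtype=float)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("GRM must be square")
    if not np.allclose(g, g.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 0
    total = evals[pos].sum()
    k = int(pos.sum()) if n_components is None else min(n_components, g.shape[0])
    evals_k = evals[:k]
    evecs_k = evecs[:, :k]
    # deterministic sign: largest-magnitude loading positive
    for c in range(k):
        j = np.argmax(np.abs(evecs_k[:, c]))
        if evecs_k[j, c] < 0:
            evecs_k[:, c] = -evecs_k[:, c]
    scores = evecs_k * np.sqrt(np.maximum(evals_k, 0.0))
    varexp = np.maximum(evals_k, 0.0) / total if total > 0 else np.zeros(k)
    return PCAResult(scores=scores, variance_explained=varexp,
                     n_components=k, samples=samples)


@dataclasses.dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_samples, K), rows sum to 1
    F: np.ndarray  # (K, n_loci_polymorphic) clamped to (0, 1)
    log_likelihood: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray | None = None

    def predicted_dosage(self) -> np.ndarray:
        return 2.0 * (self.Q @ self.F)


def _em_run(
    g: np.ndarray, w: np.ndarray, K: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> AdmixtureFit:
    n, m = g.shape
    q = rng.dirichlet(np.ones(K), size=n)
    f = np.clip(rng.uniform(0.1, 0.9, size=(K, m)), _F_EPS, 1 - _F_EPS)
    gw = g * w
    g2w = (2.0 - g) * w
    n_alleles = 2.0 * w.sum(axis=1)  # callable allele draws per sample

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = np.clip(q @ f, _F_EPS, 1 - _F_EPS)
        ll = float(np.sum(gw * np.log(p) + g2w * np.log1p(-p)))
        if trace and ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise AssertionError(
                f"EM log-likelihood decreased: {trace[-1]:.6f} -> {ll:.6f}"
            )
        trace.append(ll)
        if ll - prev < tol and it > 1:
            converged = True
            break
        prev = ll

        # E+M fused, loop over clusters to bound memory
        alt_w = gw / p  # (n, m)
        ref_w = g2w / (1.0 - p)
        q_new = np.empty_like(q)
        f_alt = np.empty_like(f)
        f_tot = np.empty_like(f)
        for k in range(K):
            ea = (q[:, k : k + 1] * f[k]) * alt_w  # expected ALT copies from k
            er = (q[:, k : k + 1] * (1.0 - f[k])) * ref_w
            f_alt[k] = ea.sum(axis=0)
            f_tot[k] = f_alt[k] + er.sum(axis=0)
            q_new[:, k] = (ea + er).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.clip(f_alt / np.maximum(f_tot, 1e-300), _F_EPS, 1 - _F_EPS)
        q = q_new / np.maximum(n_alleles[:, None], 1e-300)
        q = np.clip(q, 0.0, None)
        q /= q.sum(axis=1, keepdims=True)
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise AssertionError("Q rows drifted from simplex")

    return AdmixtureFit(
        K=K, Q=q, F=f, log_likelihood=trace[-1], n_iterations=it,
        converged=converged, loglik_trace=np.asarray(trace),
    )


def admixture_em(
    matrix_or_dosage,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
    restarts: int = 1,
    mask: np.ndarray | None = None,
) -> AdmixtureFit:
    """Fit the K-cluster admixture model by EM; best of ``restarts`` runs.

    Accepts a :class:`GenotypeMatrix` or a raw dosage array (-1 missing).
    ``mask`` (True = use entry) further hides entries, for cross-validation.
    """
    if isinstance(matrix_or_dosage, GenotypeMatrix):
        if K > matrix_or_dosage.n_samples:
            raise ValueError("K exceeds the number of samples")
        dos, w, _ = _polymorphic_dosage(matrix_or_dosage)
    else:
        raw = np.asarray(matrix_or_dosage, dtype=float)
        if K > raw.shape[0]:
            raise ValueError("K exceeds the number of samples")
        w = (raw >= 0).astype(float)
        dos = np.where(raw >= 0, raw, 0.0)
    if K < 1:
        raise ValueError("K must be >= 1")
    if mask is not None:
        w = w * mask.astype(float)
    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(max(1, restarts)):
        fit = _em_run(dos, w, K, rng, max_iter, tol)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    return best  # type: ignore[return-value]


def align_q(q_hat: np.ndarray, q_ref: np.ndarray) -> np.ndarray:
    """Resolve label switching: greedy column matching on Q correlation."""
    k = q_hat.shape[1]
    corr = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            va, vb = q_hat[:, a], q_ref[:, b]
            sa, sb = va.std(), vb.std()
            corr[a, b] = (
                np.corrcoef(va, vb)[0, 1] if sa > 0 and sb > 0 else -np.inf
            )
    perm = np.full(k, -1)
    used_a, used_b = set(), set()
    for _ in range(k):
        best, pair = -np.inf, None
        for a in range(k):
            if a in used_a:
                continue
            for b in range(k):
                if b in used_b:
                    continue
                if corr[a, b] > best:
                    best, pair = corr[a, b], (a, b)
        a, b = pair  # type: ignore[misc]
        perm[b] = a
        used_a.add(a)
        used_b.add(b)
    return q_hat[:, perm]


@dataclasses.dataclass
class CVReport:
    k_values: list[int]
    cv_errors: list[float]
    folds: int
    best_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.k_values, "cv_error": self.cv_errors})


def cv_choose_k(
    matrix: GenotypeMatrix,
    k_min: int = 1,
    k_max: int = 15,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
    restarts: int = 1,
) -> CVReport:
    """Choose K by masked-genotype cross-validation (RMSE of predicted dosage)."""
    if folds < 2:
        raise ValueError("need >= 2 folds")
    if k_min < 1 or k_max < k_min:
        raise ValueError("bad K range")
    dos, w, _ = _polymorphic_dosage(matrix)
    obs = np.argwhere(w > 0)
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(0, folds, size=len(obs))

    k_values = list(range(k_min, k_max + 1))
    errors = []
    for K in k_values:
        sq_sum, n_masked = 0.0, 0
        for fold in range(folds):
            hold = obs[fold_of == fold]
            mask = np.ones_like(w)
            mask[hold[:, 0], hold[:, 1]] = 0.0
            fit = admixture_em(
                dos * w + (w - 1),  # re-encode missing as -1
                K,
                seed=int(rng.integers(0, 2**31 - 1)),
                max_iter=max_iter,
                tol=tol,
                restarts=restarts,
                mask=mask,
            )
            pred = fit.predicted_dosage()[hold[:, 0], hold[:, 1]]
            truth = dos[hold[:, 0], hold[:, 1]]
            sq_sum += float(np.sum((truth - pred) ** 2))
            n_masked += len(hold)
        errors.append(np.sqrt(sq_sum / n_masked))
    best_k = k_values[int(np.argmin(errors))]
    return CVReport(k_values=k_values, cv_errors=errors, folds=folds, best_k=best_k)
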