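"""Population structure: marker pruning, NJ tree, ancestry EM, clade rules.

Markers for structure inference are biallelic SNPs with minor allele
frequency strictly above 5%, LD-pruned plink-style (windows of 50 loci,
step 1, removing the later locus of any pair with dosage r² > 0.5). The
neighbor-joining tree (Saitou–Nei) is built from 1 − IBS distances.
Ancestry proportions come from an EM estimator of the classic admixture
likelihood (binomial sampling of allele copies from K latent components);
an isolate is assigned to a component only when its ancestry fraction is
strictly above 60%, otherwise it is left unassigned as admixed. Superclades
are declarative groupings of components supplied by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from popsaturate.variant_io_filter import MISSING, GenotypeMatrix

ANCESTRY_THRESHOLD = 0.60
F_EPS = 1e-6


# ---------------------------------------------------------------------------
# marker pruning
# ---------------------------------------------------------------------------


def allele_frequencies(matrix: GenotypeMatrix) -> np.ndarray:
    """Alt-allele frequency per locus over observed allele copies."""
    d = matrix.dosage.astype(float)
    m = matrix.effective_ploidy().astype(float)[:, None]
    ok = matrix.dosage != MISSING
    alt = np.where(ok, d, 0.0).sum(axis=0)
    tot = (ok * m).sum(axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(tot > 0, alt / tot, np.nan)


def filter_biallelic_maf(matrix: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Retain loci with minor allele frequency strictly above maf_min.

    The dosage matrix is biallelic by construction; loci that are
    monomorphic or at MAF <= maf_min are dropped.
    """
    p = allele_frequencies(matrix)
    maf = np.minimum(p, 1 - p)
    keep = np.where(np.nan_to_num(maf, nan=0.0) > maf_min)[0]
    return GenotypeMatrix(
        samples=list(matrix.samples),
        loci=matrix.loci.iloc[keep].reset_index(drop=True),
        dosage=matrix.dosage[:, keep].copy(),
        ploidy=matrix.ploidy.copy(),
    )


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_one_vs_block(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² of dosage vector y against each column of X."""
    oky = y != MISSING
    ok = oky[:, None] & (X != MISSING)
    yf = np.where(oky, y, 0).astype(float)
    Xf = np.where(X != MISSING, X, 0).astype(float)
    c = ok.sum(axis=0).astype(float)
    sy = (ok * yf[:, None]).sum(axis=0)
    sx = (ok * Xf).sum(axis=0)
    syy = (ok * yf[:, None] ** 2).sum(axis=0)
    sxx = (ok * Xf**2).sum(axis=0)
    sxy = (ok * yf[:, None] * Xf).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = c * sxy - sx * sy
        den = (c * sxx - sx**2) * (c * syy - sy**2)
        r2 = np.where((den > 0) & (c >= 2), num**2 / den, 0.0)
    return r2


def ld_prune(
    matrix: GenotypeMatrix, window: int = 50, step: int = 1, r2_max: float = 0.5
) -> GenotypeMatrix:
    """plink-style indep-pairwise pruning on coordinate-sorted loci.

    Greedy left-to-right scan: a locus survives only if its dosage r²
    (pairwise-complete) with every already-retained locus among the previous
    ``window − 1`` retained loci is <= r2_max — when a pair violates, the
    later locus is the one dropped. The result satisfies the plink
    indep-pairwise postcondition: no window of ``window`` consecutive
    retained loci holds a pair with r² > r2_max. ``step`` is accepted for
    interface parity; the scan advances locus by locus, which corresponds
    to step 1.
    """
    if step != 1:
        raise NotImplementedError("only step=1 (the survey's setting) is supported")
    order = matrix.loci.sort_values(["chrom", "pos"], kind="stable").index.to_numpy()
    dosage = matrix.dosage[:, order]
    kept: list[int] = []
    for j in range(dosage.shape[1]):
        recent = kept[-(window - 1):] if window > 1 else []
        if recent:
            r2 = _r2_one_vs_block(dosage[:, j], dosage[:, recent])
            if (r2 > r2_max).any():
                continue
        kept.append(j)
    keep_orig = np.sort(order[np.array(kept, dtype=int)]) if kept else np.array([], dtype=int)
    return GenotypeMatrix(
        samples=list(matrix.samples),
        loci=matrix.loci.iloc[keep_orig].reset_index(drop=True),
        dosage=matrix.dosage[:, keep_orig].copy(),
        ploidy=matrix.ploidy.copy(),
    )


# ---------------------------------------------------------------------------
# distances and neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray
    metric: str = "1-ibs"

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True) or not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """d_ij = 1 − mean over comparable loci of (1 − |dose_i − dose_j| / max_dose)."""
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need >= 2 samples")
    d = matrix.dosage
    plo = matrix.effective_ploidy()
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (d[i] != MISSING) & (d[j] != MISSING)
            if not ok.any():
                out[i, j] = out[j, i] = np.nan
                continue
            max_dose = float(max(plo[i], plo[j]))
            sharing = 1 - np.abs(d[i, ok] - d[j, ok]).astype(float) / max_dose
            out[i, j] = out[j, i] = 1 - sharing.mean()
    return DistanceMatrix(list(matrix.samples), out)


@dataclass
class NJNode:
    name: Optional[str] = None
    children: list[tuple["NJNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class NJTree:
    """Unrooted NJ tree, stored rooted at the final join for serialization."""

    root: NJNode
    ids: list[str]

    def to_newick(self) -> str:
        def fmt(node: NJNode) -> str:
            if not node.children:
                return str(node.name)
            inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf patristic distances (equals the input for additive data)."""
        dists: dict[str, dict[str, float]] = {}

        def walk(node: NJNode, acc: float, dist_to: dict[str, float]) -> None:
            if not node.children:
                dist_to[node.name] = acc  # type: ignore[index]
                return
            for child, bl in node.children:
                walk(child, acc + bl, dist_to)

        def collect(node: NJNode) -> dict[str, float]:
            if not node.children:
                return {node.name: 0.0}  # type: ignore[dict-item]
            below: list[dict[str, float]] = []
            for child, bl in node.children:
                d = {k: v + bl for k, v in collect(child).items()}
                below.append(d)
            for a_i in range(len(below)):
                for b_i in range(a_i + 1, len(below)):
                    for la, da in below[a_i].items():
                        for lb, db in below[b_i].items():
                            dists.setdefault(la, {})[lb] = da + db
                            dists.setdefault(lb, {})[la] = da + db
            merged: dict[str, float] = {}
            for d in below:
                merged.update(d)
            return merged

        collect(self.root)
        n = len(self.ids)
        out = np.zeros((n, n))
        for i, a in enumerate(self.ids):
            for j, b in enumerate(self.ids):
                if i != j:
                    out[i, j] = dists[a][b]
        return pd.DataFrame(out, index=self.ids, columns=self.ids)


def neighbor_joining(dm: DistanceMatrix) -> NJTree:
    """Saitou–Nei neighbor joining with deterministic lowest-index tie-breaks.

    Negative branch lengths are clamped to zero. Exact on additive matrices.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains missing entries")
    D = dm.values.astype(float).copy()
    nodes: list[NJNode] = [NJNode(name=s) for s in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima
        flat = np.argwhere(np.isclose(q, q.min()))
        a_i, b_i = min((tuple(sorted(p)) for p in flat))
        i, j = active[a_i], active[b_i]
        dij = D[i, j]
        li = 0.5 * dij + (r[a_i] - r[b_i]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = NJNode(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    root = NJNode(children=[
        (nodes[i], max(li, 0.0)), (nodes[j], max(lj, 0.0)), (nodes[k], max(lk, 0.0))
    ])
    return NJTree(root=root, ids=list(dm.ids))


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------


@dataclass
class AncestryMatrix:
    samples: list[str]
    Q: np.ndarray  # samples x K
    F: np.ndarray  # K x loci
    K: int
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("ancestry rows must sum to 1")
        if (self.Q < -1e-12).any() or (self.Q > 1 + 1e-12).any():
            raise ValueError("ancestry proportions must lie in [0, 1]")


def _spectral_init(
    dosage: np.ndarray, plo: np.ndarray, K: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic warm start: k-means on the top principal components.

    Mean-imputed dosage fractions → SVD → k-means(K) → hard Q (softened),
    F from per-cluster allele frequencies. Avoids the label-symmetric local
    optima that plague random EM starts on small cohorts.
    """
    from scipy.cluster.vq import kmeans2

    n, L = dosage.shape
    X = dosage.astype(float) / plo[:, None]
    X[dosage == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.5)
    X = np.where(np.isnan(X), col_mean[None, :], X) - col_mean[None, :]
    k_pc = min(max(K - 1, 1), min(n, L) - 1)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = u[:, :k_pc] * s[:k_pc]
    _, labels = kmeans2(pcs, K, minit="++", seed=rng.integers(2**31 - 1))
    Q = np.full((n, K), 0.05 / max(K - 1, 1))
    Q[np.arange(n), labels] = 0.95
    Q /= Q.sum(axis=1, keepdims=True)
    F = np.empty((K, L))
    ok = dosage != MISSING
    for k in range(K):
        members = labels == k
        if members.any():
            alt = np.where(ok[members], dosage[members], 0).sum(axis=0)
            tot = (ok[members] * plo[members, None]).sum(axis=0)
            with np.errstate(invalid="ignore"):
                F[k] = np.where(tot > 0, alt / tot, 0.5)
        else:
            F[k] = rng.uniform(0.05, 0.95, L)
    return Q, np.clip(F, F_EPS, 1 - F_EPS)


def _admixture_loglik(G: np.ndarray, M: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    p = Q @ F  # samples x loci, per-copy alt probability
    p = np.clip(p, F_EPS, 1 - F_EPS)
    ok = M > 0
    return float(np.sum(np.where(ok, G * np.log(p) + (M - G) * np.log(1 - p), 0.0)))


def admixture_em(
    matrix: GenotypeMatrix,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
) -> AncestryMatrix:
    """EM for the binomial admixture likelihood over K latent components.

    Sample i draws each of its m_i allele copies at locus l from component k
    with probability q_ik and then the alternate allele with probability
    f_kl; the EM updates keep Q on the simplex and F in (0, 1). The
    log-likelihood is non-decreasing across iterations (asserted); the best
    of ``n_restarts`` seeded starts is kept.
    """
    n, L = matrix.n_samples, matrix.n_loci
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the sample count {n}")
    plo = matrix.effective_ploidy().astype(float)
    G = matrix.dosage.astype(float)
    M = np.where(matrix.dosage != MISSING, plo[:, None], 0.0)
    G = np.where(matrix.dosage != MISSING, G, 0.0)

    if K == 1:
        with np.errstate(invalid="ignore"):
            f = np.where(M.sum(axis=0) > 0, G.sum(axis=0) / M.sum(axis=0), 0.5)
        F = np.clip(f[None, :], F_EPS, 1 - F_EPS)
        Q = np.ones((n, 1))
        return AncestryMatrix(list(matrix.samples), Q, F, 1,
                              _admixture_loglik(G, M, Q, F), 0, True)

    rng = np.random.default_rng(seed)
    best: Optional[AncestryMatrix] = None
    for restart in range(n_restarts):
        if restart == 0:
            Q, F = _spectral_init(matrix.dosage, plo, K, rng)
        else:
            Q = rng.dirichlet(np.ones(K), size=n)
            F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), F_EPS, 1 - F_EPS)
        prev = -np.inf
        it = 0
        converged = False
        for it in range(1, max_iter + 1):
            pa = Q[:, :, None] * F[None, :, :]  # n x K x L, alt-copy joint
            pr = Q[:, :, None] * (1 - F)[None, :, :]
            sa = np.clip(pa.sum(axis=1), F_EPS, None)  # n x L
            sr = np.clip(pr.sum(axis=1), F_EPS, None)
            # expected alt/ref copies attributed to component k
            Ea = pa / sa[:, None, :] * G[:, None, :]
            Er = pr / sr[:, None, :] * (M - G)[:, None, :]
            Q = (Ea + Er).sum(axis=2)
            denom = np.clip(Q.sum(axis=1, keepdims=True), F_EPS, None)
            Q = Q / denom
            A = Ea.sum(axis=0)  # K x L
            B = Er.sum(axis=0)
            F = np.clip(A / np.clip(A + B, F_EPS, None), F_EPS, 1 - F_EPS)
            ll = _admixture_loglik(G, M, Q, F)
            assert ll >= prev - 1e-6 * max(1.0, abs(prev)), "EM log-likelihood decreased"
            if abs(ll - prev) < tol * max(1.0, abs(ll)):
                converged = True
                prev = ll
                break
            prev = ll
        cand = AncestryMatrix(list(matrix.samples), Q, F, K, prev, it, converged)
        if best is None or cand.loglik > best.loglik:
            best = cand
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# clade assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeAssignment:
    sample: str
    component: Optional[int]  # 0-based component index or None (admixed)
    max_ancestry: float
    threshold: float = ANCESTRY_THRESHOLD
    superclade: Optional[str] = None


def assign_clades(
    ancestry: AncestryMatrix, threshold: float = ANCESTRY_THRESHOLD
) -> list[CladeAssignment]:
    """Assign each sample to its argmax component iff max q > threshold."""
    out = []
    for i, s in enumerate(ancestry.samples):
        q = ancestry.Q[i]
        k = int(np.argmax(q))
        mx = float(q[k])
        out.append(
            CladeAssignment(s, k if mx > threshold else None, mx, threshold)
        )
    return out


def group_superclades(
    assignments: Sequence[CladeAssignment], grouping: dict[str, Sequence[int]]
) -> list[CladeAssignment]:
    """Attach superclade labels from a {name: [component, ...]} config."""
    known = {c for comps in grouping.values() for c in comps}
    comp_to_super = {}
    for name, comps in grouping.items():
        for c in comps:
            comp_to_super[int(c)] = name
    seen = {a.component for a in assignments if a.component is not None}
    unknown = known - seen
    if unknown:
        import warnings

        warnings.warn(f"superclade config references unseen components: {sorted(unknown)}")
    return [
        CladeAssignment(
            a.sample, a.component, a.max_ancestry, a.threshold,
            comp_to_super.get(a.component) if a.component is not None else None,
        )
        for a in assignments
    ]


def align_components(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated components to best match truth (Hungarian matching)."""
    from scipy.optimize import linear_sum_assignment

    K = Q_true.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.abs(Q_est[:, a] - Q_true[:, b]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q_est[:, perm]
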