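"""Multivariate structure of species-by-codon RSCU matrices.

A cohort's RSCU profiles are assembled into a species x codon matrix
(missing-family entries imputed as 0 and logged), columns are z-scored, and
structure is examined three ways: correlation-matrix PCA with loading
diagnostics (contrib, cos2), PERMANOVA on Euclidean distances with a
permutation p-value and a companion homogeneity-of-dispersion test, and
complete-linkage hierarchical clustering for heat-map row ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .codon_metrics import RSCUProfile
from .genetic_code import GeneticCode, load_genetic_code
from .selection import DEFAULT_SEED

__all__ = [
    "RSCUMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "assemble_matrix",
    "zscore_columns",
    "pca",
    "permanova",
    "dispersion_test",
    "hierarchical_order",
    "paper_compat_codon_set",
    "code_aware_codon_set",
]


def _aa_grouped(codons: list[str], code: GeneticCode) -> list[str]:
    """Fixed column order: group codons by amino acid, alphabetical."""
    return sorted(codons, key=lambda c: (code.translate_codon(c), c))


def paper_compat_codon_set() -> list[str]:
    """Standard-code sense codons minus ATG: the conventional 60-codon set."""
    code = load_genetic_code(1)
    return _aa_grouped([c for c in code.sense_codons if c != "ATG"], code)


def code_aware_codon_set(code: GeneticCode) -> list[str]:
    """The active code's degenerate sense codons (families with >= 2 synonyms)."""
    return _aa_grouped(list(code.degenerate_codons), code)


@dataclass
class RSCUMatrix:
    """Unit x codon RSCU values with scaling state and imputation audit."""

    values: pd.DataFrame  # rows: unit ids; columns: codons
    scaled: bool = False
    dropped_columns: list[str] = field(default_factory=list)
    imputed_cells: int = 0

    @property
    def codons(self) -> list[str]:
        return list(self.values.columns)

    @property
    def units(self) -> list[str]:
        return list(self.values.index)


def assemble_matrix(
    profiles: list[RSCUProfile],
    *,
    codon_set_mode: str = "paper_compat_60",
    code: GeneticCode | None = None,
) -> RSCUMatrix:
    """Stack RSCU profiles into a unit x codon matrix with a fixed column set.

    ``paper_compat_60`` uses the 60 standard-code sense codons minus ATG
    regardless of translation table; ``code_aware`` uses the active code's
    degenerate sense codons (so e.g. TGA appears as part of the table-5 Trp
    family).  RSCU entries whose family was unobserved are imputed as 0 —
    a species using zero codons of a family genuinely under-uses them —
    and the imputation count is recorded.
    """
    if not profiles:
        raise ValueError("no profiles to assemble")
    if codon_set_mode == "paper_compat_60":
        columns = paper_compat_codon_set()
    elif codon_set_mode == "code_aware":
        columns = code_aware_codon_set(code or profiles[0].code)
    else:
        raise ValueError(f"unknown codon_set_mode {codon_set_mode!r}")
    rows = {}
    imputed = 0
    for prof in profiles:
        row = []
        for codon in columns:
            v = prof.rscu.get(codon)
            if v is None:
                v = 0.0
                imputed += 1
            row.append(v)
        rows[prof.unit_id] = row
    values = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    return RSCUMatrix(values=values, imputed_cells=imputed)


def zscore_columns(matrix: RSCUMatrix) -> RSCUMatrix:
    """Center and scale each codon column (sample SD); drop zero-variance
    columns and record them.  Idempotent on already-scaled matrices."""
    if len(matrix.values) < 2:
        raise ValueError("need >= 2 rows to scale")
    sd = matrix.values.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    dropped = list(matrix.values.columns[~keep])
    kept = matrix.values.loc[:, keep]
    scaled = (kept - kept.mean(axis=0)) / kept.std(axis=0, ddof=1)
    return RSCUMatrix(
        values=scaled,
        scaled=True,
        dropped_columns=matrix.dropped_columns + dropped,
        imputed_cells=matrix.imputed_cells,
    )


# ---------------------------------------------------------------------------
# PCA

@dataclass
class OrdinationResult:
    scores: pd.DataFrame             # units x PCs
    loadings: pd.DataFrame           # codons x PCs (unit-norm eigenvectors)
    explained_variance: pd.Series    # % per PC, non-increasing
    contrib: pd.DataFrame            # codon % contribution per PC (sums to 100)
    cos2: pd.DataFrame               # squared cosine per codon across kept PCs


def pca(matrix: RSCUMatrix) -> OrdinationResult:
    """PCA of the (z-scored) matrix via SVD of the column-centered data.

    Sign convention: within each component the loading of largest magnitude
    is non-negative, making results deterministic across platforms.
    ``contrib`` is ``100 * loading^2`` per component; ``cos2`` is the squared
    correlation of each codon with each component.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 rows")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if k == 0:
        raise ValueError("matrix has no variance")
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # deterministic sign: largest-|loading| coefficient non-negative
    for j in range(k):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigvals = s**2 / (n - 1)
    explained = 100 * eigvals / eigvals.sum()
    pcs = [f"PC{i+1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=matrix.values.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=matrix.values.columns, columns=pcs)
    contrib = 100 * loadings**2
    # codon coordinates = correlation with PCs (for z-scored input)
    coords = loadings * np.sqrt(eigvals)
    cos2 = coords**2
    cos2 = cos2.div(cos2.sum(axis=1), axis=0)
    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        explained_variance=pd.Series(explained, index=pcs),
        contrib=contrib,
        cos2=cos2,
    )


# ---------------------------------------------------------------------------
# PERMANOVA and dispersion

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    permutations: int
    seed: int
    dispersion_p: float | None = None


def _ss_partition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Within- and total sums of squares from squared distances."""
    n = len(labels)
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_within, ss_total


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float]:
    n = len(labels)
    ss_within, ss_total = _ss_partition(d2, labels)
    ss_between = ss_total - ss_within
    f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_between / ss_total


def permanova(
    matrix: RSCUMatrix | pd.DataFrame | np.ndarray,
    labels,
    *,
    permutations: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances.

    ``pseudo-F = (SS_between/(g-1)) / (SS_within/(N-g))`` from the
    squared-distance partition; the p-value counts permuted F >= observed F
    over uniformly random label permutations with the +1 correction.  The
    result is invariant to the ordering of rows/labels (labels are attached
    to rows, then rows permuted).
    """
    X, labels = _canonical_rows(_as_array(matrix), np.asarray(labels))
    if len(labels) != len(X):
        raise ValueError("labels must match rows")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 members")
    d2 = squareform(pdist(X, metric="euclidean")) ** 2
    f_obs, r2 = _pseudo_f(d2, labels, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(len(labels))
        f_perm, _ = _pseudo_f(d2, labels[perm], len(uniq))
        if f_perm >= f_obs:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        permutations=permutations,
        seed=seed,
    )


def dispersion_test(
    matrix: RSCUMatrix | pd.DataFrame | np.ndarray,
    labels,
    *,
    permutations: int = 10_000,
    seed: int = DEFAULT_SEED,
) -> float:
    """Permutation test of homogeneity of multivariate dispersion.

    Each row's Euclidean distance to its own group centroid is computed
    (coordinates are already an embedding of the Euclidean distance matrix,
    so no PCoA step is needed); the one-way ANOVA F on those distances is the
    statistic, and labels are permuted to obtain the p-value.
    """
    X, labels = _canonical_rows(_as_array(matrix), np.asarray(labels))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")

    def anova_f(lbls: np.ndarray) -> float:
        dists = np.empty(len(lbls))
        for g in np.unique(lbls):
            idx = np.flatnonzero(lbls == g)
            centroid = X[idx].mean(axis=0)
            dists[idx] = np.linalg.norm(X[idx] - centroid, axis=1)
        grand = dists.mean()
        ssb = sum(
            len(np.flatnonzero(lbls == g)) * (dists[lbls == g].mean() - grand) ** 2
            for g in np.unique(lbls)
        )
        ssw = sum(
            ((dists[lbls == g] - dists[lbls == g].mean()) ** 2).sum()
            for g in np.unique(lbls)
        )
        dfb = len(np.unique(lbls)) - 1
        dfw = len(lbls) - len(np.unique(lbls))
        return (ssb / dfb) / (ssw / dfw) if ssw > 0 else np.inf

    f_obs = anova_f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if anova_f(labels[rng.permutation(len(labels))]) >= f_obs:
            hits += 1
    return (hits + 1) / (permutations + 1)


# ---------------------------------------------------------------------------
# hierarchical clustering

def hierarchical_order(
    matrix: RSCUMatrix | pd.DataFrame | np.ndarray,
) -> tuple[list[int], np.ndarray]:
    """Complete-linkage agglomeration on Euclidean distances.

    Returns (leaf order for heat-map rows, scipy linkage matrix).  scipy's
    linkage breaks ties by the original observation index, so the ordering
    is deterministic.
    """
    X = _as_array(matrix)
    if len(X) < 2:
        raise ValueError("need >= 2 rows")
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    return list(hierarchy.leaves_list(Z)), Z


def _canonical_rows(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort rows (with their labels) lexicographically so permutation tests
    are invariant to the order in which samples are supplied."""
    order = np.lexsort(X.T[::-1])
    return X[order], labels[order]


def _as_array(matrix) -> np.ndarray:
    if isinstance(matrix, RSCUMatrix):
        return matrix.values.to_numpy(dtype=float)
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float)
    return np.asarray(matrix, dtype=float)
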