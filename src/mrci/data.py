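"""In-memory containers for bivariate GWAS summary data with LD reference.

The analysis-ready object is :class:`SummaryDataset`: for every retained SNP
it holds the standardized marginal effect estimates for both phenotypes
(``tau1``, ``tau2``, on the per-SD-genotype / per-SD-phenotype scale, i.e.
``z / sqrt(n)``), the LD score ``l_k`` (sum of squared LD correlations over
the tagging set, self included), the tagging-set size ``N_k*`` and the
tagging adjacency itself as a sparse symmetric matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

__all__ = ["LdReference", "SnpRecord", "SummaryDataset"]


class LdReference:
    """Per-SNP LD summary: LD score, tag count, and tagging adjacency.

    The tagging relation is symmetric and reflexive (every SNP tags itself,
    contributing r^2 = 1 to its own LD score).
    """

    def __init__(self, snp_ids, ld_score, adjacency: sp.spmatrix):
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.ld_score = np.asarray(ld_score, dtype=float)
        adjacency = sp.csr_matrix(adjacency, dtype=np.int8)
        adjacency.setdiag(1)
        adjacency.eliminate_zeros()
        self.adjacency = adjacency
        k = len(self.snp_ids)
        if self.ld_score.shape != (k,) or adjacency.shape != (k, k):
            raise ValueError("inconsistent LdReference dimensions")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}
        self.validate()

    @property
    def n_tagged(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def validate(self) -> None:
        if np.any(self.ld_score < 1.0 - 1e-9):
            raise ValueError("ld_score must be >= 1 (self r^2 included)")
        asym = (self.adjacency != self.adjacency.T).nnz
        if asym:
            raise ValueError("tagging adjacency is not symmetric")
        if np.any(self.ld_score > self.n_tagged + 1e-9):
            raise ValueError("ld_score exceeds tag count (r^2 <= 1 violated)")

    def index_of(self, snp_id) -> int:
        return self._index[snp_id]

    @classmethod
    def from_pairs(cls, snp_ids, ld_score, pairs) -> "LdReference":
        """Build from a list of tagged ``(snp_i, snp_j)`` id pairs.

        Pairs are symmetrized; self-pairs are implied and need not be listed.
        """
        snp_ids = np.asarray(snp_ids, dtype=object)
        index = {s: i for i, s in enumerate(snp_ids)}
        rows, cols = [], []
        for a, b in pairs:
            if a in index and b in index:
                i, j = index[a], index[b]
                rows += [i, j]
                cols += [j, i]
        k = len(snp_ids)
        adj = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(k, k)
        ).tocsr()
        adj.data[:] = 1
        return cls(snp_ids, ld_score, adj)

    @classmethod
    def self_only(cls, snp_ids) -> "LdReference":
        """Identity LD: every SNP tags only itself (l_k = 1, N_k* = 1)."""
        k = len(snp_ids)
        return cls(snp_ids, np.ones(k), sp.identity(k, dtype=np.int8, format="csr"))


@dataclass(frozen=True)
class SnpRecord:
    """One SNP's bivariate summary data plus its LD context."""

    snp_id: object
    tau1_hat: float
    tau2_hat: float
    ld_score: float
    n_tagged: int
    tag_indices: np.ndarray


class SummaryDataset:
    """K aligned SNP records for a phenotype pair, ready for estimation."""

    def __init__(self, snp_ids, tau1, tau2, ld_score, adjacency, n1, n2):
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.tau1 = np.ascontiguousarray(tau1, dtype=float)
        self.tau2 = np.ascontiguousarray(tau2, dtype=float)
        self.ld_score = np.ascontiguousarray(ld_score, dtype=float)
        adjacency = sp.csr_matrix(adjacency, dtype=np.int8)
        adjacency.setdiag(1)
        adjacency.eliminate_zeros()
        self.adjacency = adjacency
        self.n1 = float(n1)
        self.n2 = float(n2)
        k = len(self.snp_ids)
        if not (
            self.tau1.shape == self.tau2.shape == self.ld_score.shape == (k,)
            and adjacency.shape == (k, k)
        ):
            raise ValueError("inconsistent SummaryDataset dimensions")
        if k < 1:
            raise ValueError("empty dataset")
        self.n_tagged = np.asarray(adjacency.sum(axis=1)).ravel().astype(np.int64)

    @property
    def K(self) -> int:
        return len(self.snp_ids)

    def record(self, k: int) -> SnpRecord:
        row = self.adjacency.indices[
            self.adjacency.indptr[k] : self.adjacency.indptr[k + 1]
        ]
        return SnpRecord(
            snp_id=self.snp_ids[k],
            tau1_hat=float(self.tau1[k]),
            tau2_hat=float(self.tau2[k]),
            ld_score=float(self.ld_score[k]),
            n_tagged=int(self.n_tagged[k]),
            tag_indices=np.array(row, dtype=np.int64),
        )

    def swap_traits(self) -> "SummaryDataset":
        """Exchange the two phenotypes (used for label-symmetry checks)."""
        return SummaryDataset(
            self.snp_ids, self.tau2, self.tau1, self.ld_score,
            self.adjacency, self.n2, self.n1,
        )

    def subset(self, idx) -> "SummaryDataset":
        idx = np.asarray(idx)
        return SummaryDataset(
            self.snp_ids[idx],
            self.tau1[idx],
            self.tau2[idx],
            self.ld_score[idx],
            self.adjacency[idx][:, idx],
            self.n1,
            self.n2,
        )
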