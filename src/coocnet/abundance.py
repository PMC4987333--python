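"""Abundance-based counterpart analyses.

Functional (FDis) and phylogenetic (PDis) dispersion: the abundance-weighted
mean distance of species to the abundance-weighted centroid of each site's
community, computed in the principal-coordinate embedding of the distance
matrix with the usual correction for negative eigenvalues (squared distances
are real-part minus imaginary-part contributions, floored at zero). The
null reassigns whole abundance columns to species labels, preserving local
abundance and diversity while randomizing which species carries which
abundance profile.

Variance partitioning: Hellinger-transformed abundances regressed on three
explanatory sets (agricultural practices, soil, spatial position); the seven
non-overlapping fractions follow by inclusion-exclusion over the adjusted
R² (Ezekiel) of the seven nested RDA models, and the pure fractions are
tested by permuting residuals under the reduced model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .datatypes import DataValidationError, DistanceMatrix, SiteSpeciesMatrix
from .structure import ModulePartition


def hellinger(m: SiteSpeciesMatrix) -> SiteSpeciesMatrix:
    """Hellinger transform: square root of within-site relative abundance.

    Sites with zero total abundance are dropped with a warning. Every
    transformed row has unit sum of squares.
    """
    if m.value_kind != "abundance":
        raise DataValidationError("hellinger requires an abundance matrix")
    arr = m.values.to_numpy(dtype=float)
    totals = arr.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} site(s) with zero total abundance",
            stacklevel=2,
        )
    arr = arr[keep]
    out = np.sqrt(arr / arr.sum(axis=1, keepdims=True))
    assert np.allclose((out**2).sum(axis=1), 1.0)
    return SiteSpeciesMatrix(
        values=pd.DataFrame(out, index=m.values.index[keep], columns=m.values.columns),
        guild=dict(m.guild),
        value_kind="abundance",
    )


def _pcoa_embedding(d: DistanceMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Principal coordinates of a distance matrix.

    Returns (real_coords, imaginary_coords, species): axes with positive
    eigenvalues give real coordinates, axes with negative eigenvalues give
    'imaginary' coordinates whose squared contributions are subtracted when
    measuring distances in the embedding.
    """
    species = d.species_ids
    D2 = d.values.to_numpy() ** 2
    n = D2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    G = (G + G.T) / 2.0
    vals, vecs = np.linalg.eigh(G)
    tol = 1e-10 * max(1.0, np.abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag, species


def dispersion_index(m: SiteSpeciesMatrix, d: DistanceMatrix) -> pd.Series:
    """Per-site abundance-weighted dispersion (FDis / PDis).

    Sites with fewer than two species present score 0.
    """
    missing = [s for s in m.species_ids if s not in d.species_ids]
    if missing:
        raise DataValidationError(f"species missing from distance matrix: {missing[:5]}")
    real, imag, species = _pcoa_embedding(d.subset(m.species_ids))
    order = [species.index(s) for s in m.species_ids]
    return pd.Series(
        _fdis_from_coords(m.values.to_numpy(dtype=float), real[order], imag[order]),
        index=m.values.index,
        name="dispersion",
    )


def _fdis_from_coords(A: np.ndarray, real: np.ndarray, imag: np.ndarray) -> np.ndarray:
    """FDis per site for abundance rows A over species coordinates."""
    totals = A.sum(axis=1, keepdims=True)
    W = np.divide(A, totals, out=np.zeros_like(A), where=totals > 0)
    cr = W @ real  # site centroids, real part
    ci = W @ imag
    # squared distance of species j to site centroid, with imaginary correction
    out = np.zeros(A.shape[0])
    for i in range(A.shape[0]):
        w = W[i]
        present = w > 0
        if present.sum() < 2:
            continue
        dr = ((real[present] - cr[i]) ** 2).sum(axis=1)
        di = ((imag[present] - ci[i]) ** 2).sum(axis=1)
        z = np.sqrt(np.clip(dr - di, 0.0, None))
        out[i] = float((w[present] * z).sum())
    return out


@dataclass
class DispersionResult:
    guild: str
    distance_kind: str
    index_name: str  # FDis or PDis
    per_site: pd.Series
    mean: float
    n_perm: int
    null_mean: float
    null_sd: float
    ses: float | None
    p: float
    seed: int


def dispersion_ses(
    m: SiteSpeciesMatrix,
    d: DistanceMatrix,
    n_perm: int = 9999,
    seed: int = 0,
    guild: str = "",
) -> DispersionResult:
    """SES of mean-over-sites dispersion against species-identity permutation.

    Each null draw reassigns whole abundance columns to species labels
    (equivalently, permutes species positions in the trait/phylogeny
    embedding), preserving every site's abundance vector and richness.
    """
    if len(m.species_ids) < 3:
        raise DataValidationError("need at least 3 species for the dispersion null")
    real, imag, species = _pcoa_embedding(d.subset(m.species_ids))
    order = [species.index(s) for s in m.species_ids]
    real, imag = real[order], imag[order]
    A = m.values.to_numpy(dtype=float)
    per_site = _fdis_from_coords(A, real, imag)
    observed = float(per_site.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_sp = len(m.species_ids)
    for i in range(n_perm):
        perm = rng.permutation(n_sp)
        null[i] = _fdis_from_coords(A, real[perm], imag[perm]).mean()
    sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    ses = (observed - float(null.mean())) / sd if sd > 0 else None
    p = float((1.0 + np.sum(null < observed)) / (1.0 + n_perm))
    index_name = "PDis" if d.kind == "phylogenetic" else "FDis"
    return DispersionResult(
        guild=guild,
        distance_kind=d.kind,
        index_name=index_name,
        per_site=pd.Series(per_site, index=m.values.index),
        mean=observed,
        n_perm=n_perm,
        null_mean=float(null.mean()),
        null_sd=sd,
        ses=ses,
        p=p,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# RDA variance partitioning


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0, keepdims=True)


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (QR pivot on the centered matrix)."""
    Xc = _center(X)
    if Xc.size == 0:
        return Xc
    q, r, piv = scipy.linalg.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    if rank < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - rank} collinear predictor column(s)", stacklevel=3)
    return Xc[:, keep]


def _r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Multivariate redundancy R² of centered Y on centered X, and rank(X)."""
    Yc = _center(Y)
    Xc = _drop_collinear(X)
    total = float((Yc**2).sum())
    if total == 0:
        raise DataValidationError("response matrix has zero variance")
    if Xc.shape[1] == 0:
        return 0.0, 0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fitted = Xc @ beta
    return float((fitted**2).sum()) / total, Xc.shape[1]


def rda_adjusted_r2(Y: np.ndarray | pd.DataFrame, X: np.ndarray | pd.DataFrame) -> float:
    """Adjusted R² (Ezekiel) of the RDA of Y on X.

    R²_adj = 1 − (1 − R²)(n − 1)/(n − m − 1), m = number of (independent)
    predictors.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = Y.shape[0]
    r2, m = _r2(Y, X)
    if n - m - 1 <= 0:
        raise DataValidationError(f"too few sites (n={n}) for {m} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


FRACTION_LABELS = {
    "a": "pure X1",
    "b": "pure X2",
    "c": "pure X3",
    "d": "joint X1&X2",
    "e": "joint X2&X3",
    "f": "joint X1&X3",
    "g": "joint X1&X2&X3",
}


@dataclass
class VarPartResult:
    response: str
    fractions: dict[str, float]  # keys a..g plus "residual"
    full_adj_r2: float
    pure_p: dict[str, float] = field(default_factory=dict)  # keys a, b, c
    n_perm: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in ("a", "b", "c", "d", "e", "f", "g"):
            rows.append(
                {
                    "response": self.response,
                    "fraction": key,
                    "label": FRACTION_LABELS[key],
                    "adj_r2": self.fractions[key],
                    "p": self.pure_p.get(key, np.nan),
                }
            )
        rows.append(
            {
                "response": self.response,
                "fraction": "residual",
                "label": "residual",
                "adj_r2": self.fractions["residual"],
                "p": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _semipartial_r2(Y: np.ndarray, X_test: np.ndarray, X_cond: np.ndarray) -> float:
    r2_full, _ = _r2(Y, np.hstack([X_test, X_cond]))
    r2_red, _ = _r2(Y, X_cond)
    return r2_full - r2_red


def _partial_pseudo_f(Y: np.ndarray, X_test: np.ndarray, X_cond: np.ndarray) -> float:
    """Pseudo-F of X_test conditional on X_cond (the permutation statistic;
    near-pivotal, unlike the raw semipartial R²)."""
    r2_full, m_full = _r2(Y, np.hstack([X_test, X_cond]))
    r2_red, m_red = _r2(Y, X_cond)
    n = Y.shape[0]
    df_test = max(m_full - m_red, 1)
    df_resid = max(n - m_full - 1, 1)
    denom = max(1.0 - r2_full, 1e-12)
    return ((r2_full - r2_red) / df_test) / (denom / df_resid)


def variance_partition(
    Y: pd.DataFrame,
    x1: pd.DataFrame,
    x2: pd.DataFrame,
    x3: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    response_label: str = "whole network",
) -> VarPartResult:
    """Partition of explained variance over three explanatory sets.

    The 7 non-overlapping fractions (pure X1/X2/X3, three pairwise joints,
    triple joint) come from inclusion-exclusion over the adjusted R² of the
    7 possible models; they sum exactly to the full-model adjusted R².
    Joint fractions can be negative. The three pure fractions are tested by
    residual permutation under the reduced model.
    """
    for x in (x1, x2, x3):
        if list(x.index) != list(Y.index):
            raise DataValidationError("explanatory and response site sets differ")
    Ya = np.asarray(Y, dtype=float)
    X = [np.asarray(x, dtype=float) for x in (x1, x2, x3)]
    adj = {}
    adj["1"] = rda_adjusted_r2(Ya, X[0])
    adj["2"] = rda_adjusted_r2(Ya, X[1])
    adj["3"] = rda_adjusted_r2(Ya, X[2])
    adj["12"] = rda_adjusted_r2(Ya, np.hstack([X[0], X[1]]))
    adj["13"] = rda_adjusted_r2(Ya, np.hstack([X[0], X[2]]))
    adj["23"] = rda_adjusted_r2(Ya, np.hstack([X[1], X[2]]))
    adj["123"] = rda_adjusted_r2(Ya, np.hstack(X))
    fr = {}
    fr["a"] = adj["123"] - adj["23"]
    fr["b"] = adj["123"] - adj["13"]
    fr["c"] = adj["123"] - adj["12"]
    fr["d"] = adj["123"] - adj["3"] - fr["a"] - fr["b"]
    fr["e"] = adj["123"] - adj["1"] - fr["b"] - fr["c"]
    fr["f"] = adj["123"] - adj["2"] - fr["a"] - fr["c"]
    fr["g"] = adj["123"] - sum(fr[k] for k in "abcdef")
    fr["residual"] = 1.0 - adj["123"]

    rng = np.random.default_rng(seed)
    pure_p: dict[str, float] = {}
    tests = {"a": (0, (1, 2)), "b": (1, (0, 2)), "c": (2, (0, 1))}
    for key, (ti, cond) in tests.items():
        X_test = X[ti]
        X_cond = np.hstack([X[c] for c in cond])
        obs = _partial_pseudo_f(Ya, X_test, X_cond)
        # Freedman-Lane: permute residuals under the reduced model
        Xc = _drop_collinear(X_cond)
        Yc = _center(Ya)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        fitted = Xc @ beta
        resid = Yc - fitted
        null = np.empty(n_perm)
        n = Ya.shape[0]
        for i in range(n_perm):
            Ystar = fitted + resid[rng.permutation(n)]
            null[i] = _partial_pseudo_f(Ystar, X_test, X_cond)
        pure_p[key] = float((1.0 + np.sum(null >= obs)) / (1.0 + n_perm))
    return VarPartResult(
        response=response_label,
        fractions=fr,
        full_adj_r2=adj["123"],
        pure_p=pure_p,
        n_perm=n_perm,
        seed=seed,
    )


def subset_by_module(
    m: SiteSpeciesMatrix, partition: ModulePartition
) -> dict[int, SiteSpeciesMatrix]:
    """One abundance matrix per module (network species only)."""
    missing = [s for s in partition.membership if s not in m.species_ids]
    if missing:
        raise DataValidationError(f"module species missing from abundance matrix: {missing[:5]}")
    out = {}
    for module in partition.modules():
        species = partition.module_species(module)
        if not species:
            raise DataValidationError(f"module {module} is empty")
        out[module] = m.subset_species(species)
    return out
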