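"""LD scores and LD-score regression: h2, genetic covariance, and the
multi-trait covariance matrix S with its block-jackknife sampling
covariance V.

The regression model per variant j is

    E[z_aj * z_bj] = intercept + slope * x_j,   x_j = sqrt(N_aj N_bj) l_j / M

so the slope is directly the genetic (co)variance (h2 when a == b).  The
intercept absorbs confounding (a == b) or phenotypic covariance of shared
samples (a != b).  Standard errors and the cross-element sampling
covariance come from a leave-one-block-out jackknife over contiguous
variant blocks; every element of vech(S) is re-estimated per left-out
block so V captures cross-element dependence.

vech ordering convention (frozen): column-major over the lower triangle,
i.e. (0,0), (1,0), ..., (K-1,0), (1,1), (2,1), ..., (K-1,K-1).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPanel

__all__ = [
    "LDScoreTable",
    "LdscEstimate",
    "SVMatrices",
    "ReferencePanel",
    "ld_scores",
    "estimate_h2",
    "estimate_gcov",
    "build_S_V",
    "to_correlation",
    "smooth_to_psd",
    "vech",
    "unvech",
    "vech_indices",
    "read_reference_panel",
    "write_sv",
    "read_sv",
]

logger = logging.getLogger(__name__)

DEFAULT_N_BLOCKS = 200


# ---------------------------------------------------------------------------
# half-vectorization helpers

def vech_indices(k: int) -> list[tuple[int, int]]:
    """(row, col) pairs of the lower triangle, column-major."""
    return [(i, j) for j in range(k) for i in range(j, k)]


def vech(mat: np.ndarray) -> np.ndarray:
    k = mat.shape[0]
    return np.array([mat[i, j] for i, j in vech_indices(k)])


def unvech(v: np.ndarray) -> np.ndarray:
    p = len(v)
    k = int((np.sqrt(8 * p + 1) - 1) / 2)
    if k * (k + 1) != 2 * p:
        raise ValueError(f"length {p} is not a triangular number")
    out = np.zeros((k, k))
    for val, (i, j) in zip(v, vech_indices(k)):
        out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# domain types

@dataclass
class LDScoreTable:
    """Per-variant LD scores and the h2 denominator M."""

    variant_id: np.ndarray
    ldscore: np.ndarray
    M: int

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id)
        self.ldscore = np.asarray(self.ldscore, float)
        if len(self.variant_id) != len(self.ldscore):
            raise ValueError("variant_id and ldscore length mismatch")
        if np.any(self.ldscore < 0):
            raise ValueError("negative LD score after truncation")
        if self.M <= 0:
            raise ValueError("M must be positive")

    def __len__(self) -> int:
        return len(self.ldscore)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# M={self.M}\n")
            pd.DataFrame({"variant_id": self.variant_id, "ldscore": self.ldscore}).to_csv(
                fh, sep="\t", index=False
            )

    @classmethod
    def read(cls, path: str | Path) -> "LDScoreTable":
        with open(path) as fh:
            header = fh.readline().strip()
            m = int(header.split("M=")[1])
            df = pd.read_csv(fh, sep="\t", dtype={"variant_id": str})
        return cls(df["variant_id"].to_numpy(), df["ldscore"].to_numpy(), m)


@dataclass
class LdscEstimate:
    kind: str  # "h2" or "gcov"
    estimate: float
    se_jackknife: float
    intercept: float
    intercept_se: float
    n_blocks: int


@dataclass
class SVMatrices:
    """Genetic covariance matrix S and sampling covariance V of vech(S)."""

    traits: list[str]
    S: np.ndarray
    V: np.ndarray
    smoothed: bool = False
    n_blocks: int | None = None
    intercepts: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.traits)
        p = k * (k + 1) // 2
        self.S = np.asarray(self.S, float)
        self.V = np.asarray(self.V, float)
        if self.S.shape != (k, k):
            raise ValueError(f"S must be {k}x{k}")
        if self.V.shape != (p, p):
            raise ValueError(f"V must be {p}x{p}")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ValueError("S not symmetric")
        if not np.allclose(self.V, self.V.T, atol=1e-10):
            raise ValueError("V not symmetric")

    @property
    def k(self) -> int:
        return len(self.traits)

    def smooth(self) -> "SVMatrices":
        """Return a copy with S and V projected to positive semi-definite."""
        return replace(self, S=smooth_to_psd(self.S), V=smooth_to_psd(self.V),
                       smoothed=True)

    def reorder(self, traits: list[str]) -> "SVMatrices":
        """Permute traits (and V accordingly)."""
        idx = [self.traits.index(t) for t in traits]
        s = self.S[np.ix_(idx, idx)]
        old = {pair: p for p, pair in enumerate(vech_indices(self.k))}
        perm = []
        for i, j in vech_indices(self.k):
            a, b = idx[i], idx[j]
            perm.append(old[(max(a, b), min(a, b))])
        v = self.V[np.ix_(perm, perm)]
        inter = None
        if self.intercepts is not None:
            inter = self.intercepts[np.ix_(idx, idx)]
        return SVMatrices(list(traits), s, v, self.smoothed, self.n_blocks, inter)


@dataclass
class ReferencePanel:
    """Reference genotypes: dosages (n_variants x n_samples) in {0,1,2}."""

    variants: pd.DataFrame  # variant_id, chrom, pos, allele_effect, allele_other
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if len(self.variants) != self.dosages.shape[0]:
            raise ValueError("variant map / dosage row mismatch")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.variants.to_csv(prefix.with_suffix(".vars.tsv"), sep="\t", index=False)
        np.savetxt(prefix.with_suffix(".dosage.tsv"), self.dosages, fmt="%d",
                   delimiter="\t")


def read_reference_panel(prefix: str | Path) -> ReferencePanel:
    prefix = Path(prefix)
    variants = pd.read_csv(prefix.with_suffix(".vars.tsv"), sep="\t",
                           dtype={"variant_id": str})
    dosages = np.loadtxt(prefix.with_suffix(".dosage.tsv"), delimiter="\t", ndmin=2)
    return ReferencePanel(variants, dosages)


# ---------------------------------------------------------------------------
# LD scores

def ld_scores(panel: ReferencePanel, window: int = 100) -> LDScoreTable:
    """Per-variant LD scores over a sliding window of neighbouring variants.

    l_j = sum over variants k with |k - j| <= window of r2_adj(j, k), where
    r2_adj = r2 - (1 - r2)/(n_ref - 2) corrects small-sample inflation; the
    self term contributes exactly 1.  Scores are truncated at 0.
    """
    x = np.asarray(panel.dosages, float)
    m, n = x.shape
    if n < 3:
        raise ValueError("reference panel needs at least 3 samples")
    sd = x.std(axis=1)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic variant(s): correlations set to 0")
    xs = np.zeros_like(x)
    ok = ~mono
    xs[ok] = (x[ok] - x[ok].mean(axis=1, keepdims=True)) / sd[ok, None]

    scores = np.ones(m)  # self term
    for d in range(1, min(window, m - 1) + 1):
        r = (xs[:-d] * xs[d:]).sum(axis=1) / n
        r2 = r**2
        r2_adj = r2 - (1.0 - r2) / (n - 2)
        valid = ok[:-d] & ok[d:]
        contrib = np.where(valid, r2_adj, 0.0)
        scores[:-d] += contrib
        scores[d:] += contrib
    return LDScoreTable(panel.variants["variant_id"].to_numpy(),
                        np.maximum(scores, 0.0), m)


# ---------------------------------------------------------------------------
# weighted regression + block jackknife core

def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_blocks > m:
        raise ValueError(f"more blocks ({n_blocks}) than variants ({m})")
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _jackknife_wls(
    y: np.ndarray,          # (m, p) responses
    x: np.ndarray,          # (m, p) regressors
    w: np.ndarray,          # (m, p) weights
    n_blocks: int,
    free_intercept: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted least squares of each column of y on [1, x], with
    leave-one-block-out estimates.

    Returns (theta_hat (2, p), delete_values (B, 2, p), cov of slopes
    (p, p), cov of intercepts diag (p,)).  Without a free intercept the
    intercept row is zero.
    """
    m, p = y.shape
    bounds = _block_bounds(m, n_blocks)
    starts = bounds[:-1]

    # sufficient statistics per block: A = X'WX (2x2), b = X'Wy (2,)
    wx = w * x
    s_w = np.add.reduceat(w, starts, axis=0)          # (B, p)
    s_x = np.add.reduceat(wx, starts, axis=0)
    s_xx = np.add.reduceat(wx * x, starts, axis=0)
    s_y = np.add.reduceat(w * y, starts, axis=0)
    s_xy = np.add.reduceat(wx * y, starts, axis=0)

    def _solve(a11, a12, a22, b1, b2):
        """Per-element solve of [[a11,a12],[a12,a22]] theta = [b1,b2]."""
        if free_intercept:
            det = a11 * a22 - a12**2
            inter = (a22 * b1 - a12 * b2) / det
            slope = (a11 * b2 - a12 * b1) / det
        else:
            inter = np.zeros_like(b1)
            slope = b2 / a22
        return inter, slope

    tw, tx, txx, ty, txy = (s.sum(axis=0) for s in (s_w, s_x, s_xx, s_y, s_xy))
    inter_full, slope_full = _solve(tw, tx, txx, ty, txy)

    inter_del, slope_del = _solve(tw - s_w, tx - s_x, txx - s_xx,
                                  ty - s_y, txy - s_xy)  # (B, p)

    b = n_blocks
    sd = slope_del - slope_del.mean(axis=0)
    cov_slope = (b - 1) / b * (sd.T @ sd)
    idiff = inter_del - inter_del.mean(axis=0)
    var_inter = (b - 1) / b * (idiff**2).sum(axis=0)

    theta = np.vstack([inter_full, slope_full])
    delete = np.stack([inter_del, slope_del], axis=1)
    return theta, delete, cov_slope, var_inter


def _check_inputs(z: np.ndarray, n: np.ndarray, ld: LDScoreTable) -> None:
    if len(z) != len(ld):
        raise ValueError("z array not aligned to LD score table")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z values")


def _provisional_h2(z: np.ndarray, n: np.ndarray, ld: LDScoreTable) -> float:
    """First-pass unweighted slope, clipped to a sane range."""
    x = n * ld.ldscore / ld.M
    xc = x - x.mean()
    denom = (xc**2).sum()
    slope = float((xc * (z**2 - (z**2).mean())).sum() / denom) if denom > 0 else 0.0
    return min(max(slope, 0.0), 1.0)


def _h2_weights(n: np.ndarray, ld: LDScoreTable, h2: float) -> np.ndarray:
    l = np.maximum(ld.ldscore, 1.0)
    return 1.0 / (l * (1.0 + n * h2 * l / ld.M) ** 2)


def _gcov_weights(n_a, n_b, ld: LDScoreTable, h2_a, h2_b, rho, inter) -> np.ndarray:
    l = np.maximum(ld.ldscore, 1.0)
    va = 1.0 + n_a * h2_a * l / ld.M
    vb = 1.0 + n_b * h2_b * l / ld.M
    eab = np.sqrt(n_a * n_b) * rho * l / ld.M + inter
    return 1.0 / (l * (va * vb + eab**2))


def estimate_h2(
    z: np.ndarray,
    n: np.ndarray | float,
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    unit_weights: bool = False,
    free_intercept: bool = True,
) -> LdscEstimate:
    """Heritability by LD-score regression of z^2 on N*l/M.

    Two-pass weighting by default: a provisional unweighted slope feeds the
    heteroskedasticity/overcounting weights 1/(l * (1 + N h2 l/M)^2).
    ``unit_weights=True`` gives the plain OLS used by closed-form checks.
    With ``free_intercept=False`` the intercept is constrained to 1.
    """
    z = np.asarray(z, float)
    n = np.broadcast_to(np.asarray(n, float), z.shape)
    _check_inputs(z, n, ld)
    x = n * ld.ldscore / ld.M
    if unit_weights:
        w = np.ones_like(z)
    else:
        w = _h2_weights(n, ld, _provisional_h2(z, n, ld))
    y = z**2 if free_intercept else z**2 - 1.0
    theta, _, cov_slope, var_inter = _jackknife_wls(
        y[:, None], x[:, None], w[:, None], n_blocks, free_intercept
    )
    inter = theta[0, 0] + (0.0 if free_intercept else 1.0)
    return LdscEstimate(
        kind="h2",
        estimate=float(theta[1, 0]),
        se_jackknife=float(np.sqrt(cov_slope[0, 0])),
        intercept=float(inter),
        intercept_se=float(np.sqrt(var_inter[0])),
        n_blocks=n_blocks,
    )


def estimate_gcov(
    z_a: np.ndarray,
    z_b: np.ndarray,
    n_a: np.ndarray | float,
    n_b: np.ndarray | float,
    ld: LDScoreTable,
    overlap_intercept_free: bool = True,
    n_blocks: int = DEFAULT_N_BLOCKS,
    unit_weights: bool = False,
) -> LdscEstimate:
    """Genetic covariance by cross-trait LD-score regression of z_a*z_b on
    sqrt(N_a N_b)*l/M; a free intercept absorbs sample-overlap covariance."""
    z_a, z_b = np.asarray(z_a, float), np.asarray(z_b, float)
    n_a = np.broadcast_to(np.asarray(n_a, float), z_a.shape)
    n_b = np.broadcast_to(np.asarray(n_b, float), z_b.shape)
    _check_inputs(z_a, n_a, ld)
    _check_inputs(z_b, n_b, ld)
    x = np.sqrt(n_a * n_b) * ld.ldscore / ld.M
    y = z_a * z_b
    if unit_weights:
        w = np.ones_like(y)
    else:
        h2a = _provisional_h2(z_a, n_a, ld)
        h2b = _provisional_h2(z_b, n_b, ld)
        xc = x - x.mean()
        denom = (xc**2).sum()
        rho = float((xc * (y - y.mean())).sum() / denom) if denom > 0 else 0.0
        rho = min(max(rho, -1.0), 1.0)
        w = _gcov_weights(n_a, n_b, ld, h2a, h2b, rho, 0.0)
    theta, _, cov_slope, var_inter = _jackknife_wls(
        y[:, None], x[:, None], w[:, None], n_blocks, overlap_intercept_free
    )
    return LdscEstimate(
        kind="gcov",
        estimate=float(theta[1, 0]),
        se_jackknife=float(np.sqrt(cov_slope[0, 0])),
        intercept=float(theta[0, 0]),
        intercept_se=float(np.sqrt(var_inter[0])),
        n_blocks=n_blocks,
    )


def build_S_V(
    panel: HarmonizedPanel,
    ld: LDScoreTable,
    n_blocks: int = DEFAULT_N_BLOCKS,
    unit_weights: bool = False,
    free_intercept: bool = True,
) -> SVMatrices:
    """Assemble the K x K genetic covariance matrix S (h2 on the diagonal,
    pairwise genetic covariances off it) and the sampling covariance V of
    vech(S) from a single block jackknife over all elements jointly."""
    k = panel.n_traits
    if k < 2:
        raise ValueError("need at least 2 traits")
    m = panel.n_variants
    _check_inputs(panel.z[:, 0], panel.n[:, 0], ld)
    pairs = vech_indices(k)
    p = len(pairs)

    # provisional per-trait h2 for the weights (matches the pairwise
    # estimators exactly so V's diagonal equals their squared SEs)
    h2_prov = np.array([
        _provisional_h2(panel.z[:, t], panel.n[:, t], ld) for t in range(k)
    ])

    y = np.empty((m, p))
    x = np.empty((m, p))
    w = np.empty((m, p))
    for idx, (i, j) in enumerate(pairs):
        zi, zj = panel.z[:, i], panel.z[:, j]
        ni, nj = panel.n[:, i], panel.n[:, j]
        y[:, idx] = zi * zj
        x[:, idx] = np.sqrt(ni * nj) * ld.ldscore / ld.M
        if unit_weights:
            w[:, idx] = 1.0
        elif i == j:
            w[:, idx] = _h2_weights(ni, ld, h2_prov[i])
        else:
            xc = x[:, idx] - x[:, idx].mean()
            denom = (xc**2).sum()
            rho = float((xc * (y[:, idx] - y[:, idx].mean())).sum() / denom) \
                if denom > 0 else 0.0
            rho = min(max(rho, -1.0), 1.0)
            w[:, idx] = _gcov_weights(ni, nj, ld, h2_prov[i], h2_prov[j], rho, 0.0)
    if not free_intercept:
        for idx, (i, j) in enumerate(pairs):
            if i == j:
                y[:, idx] -= 1.0

    try:
        theta, _, cov_slope, _ = _jackknife_wls(y, x, w, n_blocks, free_intercept)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"joint jackknife regression failed: {exc}") from exc
    bad = ~np.isfinite(theta[1])
    if bad.any():
        i, j = pairs[int(np.flatnonzero(bad)[0])]
        raise RuntimeError(
            f"estimation failed for pair ({panel.traits[i]}, {panel.traits[j]})"
        )

    s = unvech(theta[1])
    inter = unvech(theta[0] + (0.0 if free_intercept else
                               np.array([1.0 if i == j else 0.0 for i, j in pairs])))
    return SVMatrices(list(panel.traits), s, cov_slope, smoothed=False,
                      n_blocks=n_blocks, intercepts=inter)


# ---------------------------------------------------------------------------
# standardization and smoothing

def to_correlation(sv: SVMatrices) -> SVMatrices:
    """Standardize S to a correlation matrix, V by the delta method.

    S_std[i,j] = S[i,j] / sqrt(S[i,i] S[j,j]); the Jacobian of that map
    transforms V.  Rows of V for diagonal moments become 0 (they are fixed
    at 1 after standardization).
    """
    s = sv.S
    d = np.diag(s)
    if np.any(d <= 0):
        bad = [sv.traits[i] for i in range(sv.k) if d[i] <= 0]
        raise ValueError(
            f"non-positive heritability on the diagonal for {bad}; "
            "smooth S or drop the trait(s) before standardizing"
        )
    sd = np.sqrt(d)
    s_std = s / np.outer(sd, sd)
    np.fill_diagonal(s_std, 1.0)

    pairs = vech_indices(sv.k)
    pos = {pair: idx for idx, pair in enumerate(pairs)}
    p = len(pairs)
    jac = np.zeros((p, p))
    for idx, (i, j) in enumerate(pairs):
        if i == j:
            continue
        jac[idx, pos[(i, j)]] = 1.0 / (sd[i] * sd[j])
        jac[idx, pos[(i, i)]] = -s_std[i, j] / (2 * d[i])
        jac[idx, pos[(j, j)]] = -s_std[i, j] / (2 * d[j])
    v_std = jac @ sv.V @ jac.T
    v_std = (v_std + v_std.T) / 2
    return SVMatrices(list(sv.traits), s_std, v_std, smoothed=sv.smoothed,
                      n_blocks=sv.n_blocks, intercepts=sv.intercepts)


def smooth_to_psd(matrix: np.ndarray, floor_scale: float = 1e-8) -> np.ndarray:
    """Nearest PSD projection by eigenvalue truncation.

    Eigenvalues are floored at floor_scale times the largest eigenvalue
    (or at floor_scale if all eigenvalues are non-positive).  Already-PSD
    input is returned unchanged.
    """
    matrix = np.asarray(matrix, float)
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise ValueError("input not symmetric")
    eigval, eigvec = np.linalg.eigh(matrix)
    floor = floor_scale * max(eigval.max(), floor_scale)
    if eigval.min() >= floor:
        return matrix
    fixed = (eigvec * np.maximum(eigval, floor)) @ eigvec.T
    fixed = (fixed + fixed.T) / 2
    logger.info("smooth_to_psd: max element change %.3e",
                np.abs(fixed - matrix).max())
    return fixed


# ---------------------------------------------------------------------------
# S/V serialization

def write_sv(sv: SVMatrices, prefix: str | Path) -> None:
    """Write S and V as delimited square matrices plus a JSON sidecar."""
    prefix = Path(prefix)
    pd.DataFrame(sv.S, index=sv.traits, columns=sv.traits).to_csv(
        prefix.parent / (prefix.name + ".S.tsv"), sep="\t")
    pd.DataFrame(sv.V).to_csv(prefix.parent / (prefix.name + ".V.tsv"),
                              sep="\t", index=False, header=False)
    meta = {
        "traits": sv.traits,
        "vech_order": "column-major lower triangle",
        "n_blocks": sv.n_blocks,
        "smoothed": sv.smoothed,
    }
    (prefix.parent / (prefix.name + ".json")).write_text(json.dumps(meta, indent=2))


def read_sv(prefix: str | Path) -> SVMatrices:
    prefix = Path(prefix)
    s_df = pd.read_csv(prefix.parent / (prefix.name + ".S.tsv"), sep="\t",
                       index_col=0)
    v = np.loadtxt(prefix.parent / (prefix.name + ".V.tsv"), delimiter="\t",
                   ndmin=2)
    meta = json.loads((prefix.parent / (prefix.name + ".json")).read_text())
    v = (v + v.T) / 2  # guard against round-off asymmetry in the text file
    s = s_df.to_numpy()
    return SVMatrices(meta["traits"], (s + s.T) / 2, v,
                      smoothed=meta.get("smoothed", False),
                      n_blocks=meta.get("n_blocks"))
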