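"""Synthetic GWAS summary statistics under a known factor-structured
genetic architecture.

Two generation modes:

* ``simulate_sumstats_direct`` draws per-variant Z-score vectors from the
  multivariate normal implied by the bivariate LD-score model, so the
  estimation stack can be validated against exact truth quickly.
* ``simulate_individual`` is a forward simulation: block-autocorrelated
  genotypes, multivariate polygenic effects with per-variant covariance
  Sigma_g / M, phenotypes, then per-variant single-SNP regressions.  It
  also emits a small reference dosage panel, exercising the reader and
  LD-score code paths end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import LDScoreTable, ReferencePanel
from .sumstats import SumstatsTable

__all__ = ["TrueArchitecture", "make_architecture", "make_ld_scores",
           "simulate_sumstats_direct", "simulate_individual"]


@dataclass
class TrueArchitecture:
    """Known multi-trait genetic architecture on the covariance scale.

    ``Lambda`` (K x L), ``Psi`` (L x L) and ``Theta`` (K,) define the
    genetic covariance Sigma_g = Lambda Psi Lambda' + diag(Theta) whose
    diagonal is the per-trait heritability.
    """

    traits: list[str]
    latents: list[str]
    Lambda: np.ndarray
    Psi: np.ndarray
    Theta: np.ndarray
    N: np.ndarray
    M: int
    seed: int = 0
    overlap: np.ndarray | None = None        # pairwise shared-sample counts
    pheno_corr: np.ndarray | None = None     # phenotypic correlations (diag 1)
    binary: list[bool] = field(default_factory=list)
    prevalence: float = 0.1
    #: standardized (correlation-scale) structure, kept for truth checks
    Lambda_std: np.ndarray | None = None
    Psi_std: np.ndarray | None = None
    Theta_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.traits)
        self.Lambda = np.atleast_2d(np.asarray(self.Lambda, float))
        self.Psi = np.atleast_2d(np.asarray(self.Psi, float))
        self.Theta = np.asarray(self.Theta, float)
        self.N = np.broadcast_to(np.asarray(self.N, float), (k,)).copy()
        if self.overlap is None:
            self.overlap = np.zeros((k, k))
        self.overlap = np.asarray(self.overlap, float)
        if self.pheno_corr is None:
            self.pheno_corr = self.sigma_g_std.copy()
            np.fill_diagonal(self.pheno_corr, 1.0)
        if not self.binary:
            self.binary = [False] * k
        eig = np.linalg.eigvalsh(self.sigma_g)
        if eig.min() < -1e-10:
            raise ValueError("implied genetic covariance is not PSD")
        nmin = np.minimum.outer(self.N, self.N)
        if np.any(self.overlap > nmin + 1e-9):
            raise ValueError("overlap exceeds min(N_a, N_b) for some pair")

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def sigma_g(self) -> np.ndarray:
        s = self.Lambda @ self.Psi @ self.Lambda.T + np.diag(self.Theta)
        return (s + s.T) / 2

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.sigma_g)

    @property
    def sigma_g_std(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(self.h2)
            r = self.sigma_g / np.outer(d, d)
        r[~np.isfinite(r)] = 0.0
        np.fill_diagonal(r, 1.0)
        return r

    def to_json(self) -> str:
        payload = {
            "traits": self.traits, "latents": self.latents,
            "Lambda": self.Lambda.tolist(), "Psi": self.Psi.tolist(),
            "Theta": self.Theta.tolist(), "N": self.N.tolist(),
            "M": self.M, "seed": self.seed,
            "overlap": self.overlap.tolist(),
            "binary": self.binary, "prevalence": self.prevalence,
        }
        return json.dumps(payload, indent=2)


# standardized entity correlations for the paper-like preset; entity order
# CI, URG, SUDF, DD, SS, PERSEV, AN with the CI-URG entry fixed at 0
_PAPERLIKE_PHI = np.array([
    #  CI    URG   SUDF  DD    SS    PERSEV AN
    [1.00, 0.00, 0.50, 0.20, 0.30, 0.30, -0.07],
    [0.00, 1.00, 0.25, 0.10, 0.10, 0.20,  0.14],
    [0.50, 0.25, 1.00, 0.30, 0.25, 0.10,  0.07],
    [0.20, 0.10, 0.30, 1.00, 0.10, 0.10, -0.19],
    [0.30, 0.10, 0.25, 0.10, 1.00, 0.10, -0.07],
    [0.30, 0.20, 0.10, 0.10, 0.10, 1.00, -0.15],
    [-0.07, 0.14, 0.07, -0.19, -0.07, -0.15, 1.00],
])

_PAPERLIKE_TRAITS = ["NU", "PU", "PREMED", "ATT", "MOTOR", "NONPLAN",
                     "PAU", "CUD", "OUD", "TUD", "DD", "SS", "PERSEV", "AN"]


def make_architecture(
    preset: str = "paper_like",
    M: int = 10_000,
    N: float = 50_000,
    seed: int = 0,
) -> TrueArchitecture:
    """Presets: ``paper_like`` (14 traits, CI + orthogonal URG + SUDF
    latents, negative outcome-DD and outcome-PERSEV covariances),
    ``small`` (one factor, 3 indicators + 1 correlated single), and
    ``null`` (4 independent traits)."""
    if preset == "null":
        traits = ["T1", "T2", "T3", "T4"]
        k = len(traits)
        h2 = np.full(k, 0.3)
        return TrueArchitecture(
            traits=traits, latents=[], Lambda=np.zeros((k, 1)),
            Psi=np.zeros((1, 1)), Theta=h2, N=N, M=M, seed=seed,
            Lambda_std=np.zeros((k, 1)), Psi_std=np.zeros((1, 1)),
            Theta_std=np.ones(k),
        )
    if preset == "small":
        traits = ["A", "B", "C", "D"]
        lam_std = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0], [0.0, 1.0]])
        psi = np.array([[1.0, 0.3], [0.3, 1.0]])
        theta_std = 1.0 - np.einsum("il,lm,im->i", lam_std, psi, lam_std)
        h2 = np.full(4, 0.4)
        d = np.sqrt(h2)
        return TrueArchitecture(
            traits=traits, latents=["F", "D_g"],
            Lambda=d[:, None] * lam_std, Psi=psi, Theta=h2 * theta_std,
            N=N, M=M, seed=seed,
            Lambda_std=lam_std, Psi_std=psi, Theta_std=theta_std,
        )
    if preset == "paper_like":
        traits = _PAPERLIKE_TRAITS
        latents = ["CI", "URG", "SUDF", "DD_g", "SS_g", "PERSEV_g", "AN_g"]
        lam_std = np.zeros((14, 7))
        lam_std[0:6, 0] = [0.70, 0.60, 0.65, 0.70, 0.60, 0.75]   # CI
        lam_std[0, 1], lam_std[1, 1] = 0.50, 0.50                # URG (equal)
        lam_std[6:10, 2] = [0.70, 0.75, 0.65, 0.60]              # SUDF
        for pos, lat in zip(range(10, 14), range(3, 7)):         # singles
            lam_std[pos, lat] = 1.0
        phi = _PAPERLIKE_PHI
        comm = np.einsum("il,lm,im->i", lam_std, phi, lam_std)
        if comm.max() > 1 + 1e-9:
            raise AssertionError("preset communalities exceed 1")
        theta_std = np.where(comm < 1 - 1e-12, 1.0 - comm, 0.0)
        theta_std[10:] = 0.0  # singles are exact
        h2 = np.array([0.25, 0.25, 0.20, 0.30, 0.30, 0.25,
                       0.30, 0.35, 0.25, 0.30, 0.35, 0.30, 0.20, 0.40])
        d = np.sqrt(h2)
        binary = [t in ("PAU", "CUD", "OUD", "TUD", "AN") for t in traits]
        return TrueArchitecture(
            traits=traits, latents=latents,
            Lambda=d[:, None] * lam_std, Psi=phi, Theta=h2 * theta_std,
            N=N, M=M, seed=seed, binary=binary,
            Lambda_std=lam_std, Psi_std=phi, Theta_std=theta_std,
        )
    raise ValueError(f"unknown preset {preset!r}")


def make_ld_scores(m: int, seed: int = 0, mean_extra: float = 4.0,
                   M: int | None = None) -> LDScoreTable:
    """Synthetic LD-score distribution: 1 + Gamma-distributed excess."""
    rng = np.random.default_rng(seed)
    extra = rng.gamma(shape=2.0, scale=mean_extra / 2.0, size=m)
    ids = np.array([f"rs{i + 1}" for i in range(m)])
    return LDScoreTable(ids, 1.0 + extra, M or m)


def _variant_frame(m: int) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": [f"rs{i + 1}" for i in range(m)],
        "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "allele_effect": "A",
        "allele_other": "G",
    })


def simulate_sumstats_direct(
    arch: TrueArchitecture,
    ld: LDScoreTable,
) -> list[SumstatsTable]:
    """Draw Z-scores from the exact LD-score-model moments.

    Per variant j the K-vector z_j is multivariate normal with

        Cov[z_aj, z_bj] = sqrt(N_a N_b) Sigma_g[a,b] l_j / M
                          + overlap[a,b] * pheno_corr[a,b] / sqrt(N_a N_b)
        Var[z_aj]       = 1 + N_a h2_a l_j / M
    """
    m = len(ld)
    if m < arch.M:
        raise ValueError(f"LD table covers {m} variants < M = {arch.M}")
    rng = np.random.default_rng(arch.seed)
    n = arch.N
    sqrt_nn = np.sqrt(np.outer(n, n))
    slope_mat = sqrt_nn * arch.sigma_g / arch.M
    base = arch.overlap * arch.pheno_corr / sqrt_nn
    np.fill_diagonal(base, 1.0)

    cov = base[None, :, :] + ld.ldscore[:, None, None] * slope_mat[None, :, :]
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        eigmin = np.linalg.eigvalsh(cov).min(axis=1)
        bad = int(np.argmin(eigmin))
        raise ValueError(
            f"per-variant z covariance not PSD at variant {ld.variant_id[bad]}"
        ) from None
    u = rng.standard_normal((m, arch.k))
    z = np.einsum("mij,mj->mi", chol, u)

    variants = _variant_frame(m)
    variants["variant_id"] = ld.variant_id
    tables = []
    for t, label in enumerate(arch.traits):
        df = variants.copy()
        df["z"] = z[:, t]
        df["n"] = float(n[t])
        tables.append(SumstatsTable(label, df))
    return tables


# ---------------------------------------------------------------------------
# forward (individual-level) mode

def _mvn(rng, cov: np.ndarray, size: int) -> np.ndarray:
    """MVN draws tolerant of singular (PSD) covariance."""
    val, vec = np.linalg.eigh(cov)
    root = vec * np.sqrt(np.maximum(val, 0.0))
    return rng.standard_normal((size, cov.shape[0])) @ root.T


def _haplotype_block(rng, n: int, size: int, rho: float) -> np.ndarray:
    """One LD block of dosages for n individuals: two haplotypes, each a
    Markov chain with allele correlation rho between neighbours."""
    stay = (1.0 + rho) / 2.0  # copy-vs-flip chain: corr(h_j, h_{j+1}) = rho
    dosage = np.zeros((n, size), dtype=np.int8)
    for _hap in range(2):
        h = np.empty((n, size), dtype=np.int8)
        h[:, 0] = rng.random(n) < 0.5
        if size > 1:
            keep = rng.random((n, size - 1)) < stay
            for j in range(1, size):
                h[:, j] = np.where(keep[:, j - 1], h[:, j - 1],
                                   1 - h[:, j - 1])
        dosage += h
    return dosage


def _cohort_slices(arch: TrueArchitecture) -> tuple[list[slice], int]:
    """Place trait cohorts in one sample pool so consecutive traits share
    the requested number of samples (chain overlap only)."""
    starts = [0]
    for t in range(1, arch.k):
        ov = arch.overlap[t - 1, t]
        starts.append(starts[-1] + int(round(arch.N[t - 1] - ov)))
    slices = [slice(s, s + int(arch.N[t])) for t, s in enumerate(starts)]
    pool = max(sl.stop for sl in slices)
    return slices, pool


def simulate_individual(
    arch: TrueArchitecture,
    n_ref: int = 500,
    ld_block_size: int = 20,
    ld_rho: float = 0.5,
) -> tuple[ReferencePanel, list[SumstatsTable]]:
    """Forward simulation to per-variant regression summary statistics.

    Genotypes are block-autocorrelated (allele correlation ``ld_rho``
    between neighbours inside blocks of ``ld_block_size`` variants); each
    variant's effect vector across traits is N(0, Sigma_g / M); binary
    traits are thresholded at the architecture's prevalence and analysed
    as 0/1 outcomes with N as the user-supplied effective sample size.
    """
    if not 0 <= ld_rho < 1:
        raise ValueError("ld_rho must be in [0, 1)")
    if n_ref < 50:
        raise ValueError("n_ref must be >= 50")
    m = arch.M
    rng = np.random.default_rng(arch.seed)
    block_seeds = rng.integers(0, 2**63 - 1, size=(m + ld_block_size - 1)
                               // ld_block_size)
    slices, pool = _cohort_slices(arch)
    n_total = pool + n_ref  # last n_ref rows are the reference cohort

    beta = _mvn(rng, arch.sigma_g / m, m)

    bounds = list(range(0, m, ld_block_size)) + [m]

    def _gen_block(bi: int) -> np.ndarray:
        size = bounds[bi + 1] - bounds[bi]
        brng = np.random.default_rng(block_seeds[bi])
        return _haplotype_block(brng, n_total, size, ld_rho)

    # pass 1: genetic values
    g = np.zeros((n_total, arch.k))
    for bi in range(len(bounds) - 1):
        dos = _gen_block(bi).astype(float)
        xs = (dos - 1.0) / np.sqrt(0.5)  # E=1, Var=1/2 under p=0.5
        g += xs @ beta[bounds[bi]:bounds[bi + 1]]

    # environmental covariance on the standardized-trait scale: P - Sigma_g
    env_cov = arch.pheno_corr - arch.sigma_g
    if np.linalg.eigvalsh(env_cov).min() < -1e-8:
        raise ValueError("phenotypic correlations imply non-PSD environmental "
                         "covariance")
    env = _mvn(rng, env_cov, n_total)
    y = g + env

    thresh = stats.norm.ppf(1 - arch.prevalence)
    variants = _variant_frame(m)

    # standardized outcome per trait cohort (binary traits thresholded)
    cohort_y: list[np.ndarray] = []
    for t in range(arch.k):
        yt = y[slices[t], t]
        if arch.binary[t]:
            yt = (yt > thresh).astype(float)
        sd = yt.std()
        cohort_y.append((yt - yt.mean()) / (sd if sd > 0 else 1.0))

    # pass 2: per-variant regressions per trait cohort
    z = np.zeros((m, arch.k))
    ref_rows = []
    for bi in range(len(bounds) - 1):
        dos = _gen_block(bi)
        ref_rows.append(dos[pool:, :].T.astype(np.int8))  # (size, n_ref)
        dosf = dos[:pool].astype(float)
        for t in range(arch.k):
            xt = dosf[slices[t]]
            mu = xt.mean(axis=0)
            sd = xt.std(axis=0)
            sd[sd == 0] = 1.0
            xs = (xt - mu) / sd
            nt = xt.shape[0]
            r = (xs.T @ cohort_y[t]) / nt
            r = np.clip(r, -0.999999, 0.999999)
            z[bounds[bi]:bounds[bi + 1], t] = np.sqrt(max(nt - 2, 1)) * r \
                / np.sqrt(1 - r**2)

    ref = ReferencePanel(variants.copy(), np.vstack(ref_rows))
    tables = []
    for t, label in enumerate(arch.traits):
        df = variants.copy()
        df["z"] = z[:, t]
        df["n"] = float(arch.N[t])
        df["freq_effect"] = 0.5
        tables.append(SumstatsTable(label, df))
    return ref, tables


def write_tables(tables: list[SumstatsTable], outdir: str | Path) -> list[Path]:
    """Write each trait's table in the canonical sumstats dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for tab in tables:
        df = tab.df.rename(columns={
            "variant_id": "SNP", "chrom": "CHR", "pos": "BP",
            "allele_effect": "A1", "allele_other": "A2", "z": "Z", "n": "N",
            "freq_effect": "FRQ", "pvalue": "P",
        })
        path = outdir / f"{tab.trait_label}.sumstats"
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths
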