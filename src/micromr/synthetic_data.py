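"""Synthetic paired exposure/outcome GWAS summary statistics with known truth.

The default "fast" mode draws summary statistics directly from their
sampling distribution on the standardized-genotype scale:

* marginal exposure effects  b_x = R @ gamma  (R the block LD matrix),
  observed effects ~ Normal(b_x, R / n_x), per-variant se_x = 1/sqrt(n_x);
* marginal outcome log-odds effects  b_y = R @ (theta * gamma + phi)
  (roles swapped when ``reverse``), per-variant
  se_y = 1/sqrt(n_y * case_frac * (1 - case_frac)) from the logistic-score
  approximation with standardized genotypes, noise LD-correlated likewise.

Genotypes are standardized throughout, so exposure effects are per SD and
the 2f(1-f) dosage-variance factor is identically 1. Confounder loadings
never shift the expected marginal genetic effects — instruments are
independent of the confounder by construction (the IV premise); they do
enter the individual-level mode through the trait-generating equations.

The "individual" mode generates genotypes, a shared Gaussian confounder,
the quantitative exposure and a Bernoulli outcome, then regresses per
variant (OLS for the exposure, univariate logistic for the outcome). It is
retained solely as a distributional oracle for the fast mode and supports
independent variants only (rho = 0) and forward causation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from scipy.linalg import cholesky, solve

from .errors import DomainError
from .sumstats_io import (
    LDReference,
    SumStats,
    VariantAssociation,
    write_ld,
    write_sumstats,
)

__all__ = ["SimTruth", "SimOutput", "make_ld", "simulate", "make_panel"]

# ordered allele pairs that are not reverse complements of themselves
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_P_FLOOR = 1e-320  # keep p strictly positive for the (0, 1] invariant


@dataclass
class SimTruth:
    """Generative parameters of one simulated exposure/outcome dataset."""

    theta_true: float
    gamma: tuple[float, ...]  # per-variant direct effects (per SD)
    phi: tuple[float, ...] = ()  # horizontal pleiotropy on the outcome
    confounder_effect_x: float = 0.0
    confounder_effect_y: float = 0.0
    reverse: bool = False
    n_x: int = 1800
    n_y: int = 11600
    n_case_frac: float = 0.41
    blocks: int = 3
    block_size: int = 1
    rho: float = 0.0
    bp_spacing: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.blocks * self.block_size
        self.gamma = tuple(float(g) for g in np.broadcast_to(self.gamma, m))
        phi = self.phi if len(tuple(np.atleast_1d(self.phi))) else np.zeros(m)
        self.phi = tuple(float(p) for p in np.broadcast_to(phi, m))
        if self.n_x < 100 or self.n_y < 100:
            raise DomainError("sample sizes must be >= 100")
        if not (abs(self.rho) < 1):
            raise DomainError("|rho| must be < 1")
        if not (0 < self.n_case_frac < 1):
            raise DomainError("n_case_frac must be in (0, 1)")


@dataclass
class SimOutput:
    exposure_sumstats: SumStats
    outcome_sumstats: SumStats
    ld: LDReference
    truth: SimTruth


def make_ld(
    blocks: int,
    block_size: int,
    rho: float,
    bp_spacing: int = 50_000,
    seed: int = 0,
    id_prefix: str = "snp",
    chrom_offset: int = 0,
) -> LDReference:
    """Block-diagonal AR(1) LD: r(i, j) = rho^|i-j| within a block, 0 across.

    Each block sits on its own synthetic chromosome with variants spaced
    ``bp_spacing`` base pairs apart.
    """
    if not (abs(rho) < 1):
        raise DomainError("|rho| must be < 1")
    ref = LDReference()
    for b in range(blocks):
        chrom = str(chrom_offset + b + 1)
        ids = [f"{id_prefix}_{chrom}_{i}" for i in range(block_size)]
        for i, vid in enumerate(ids):
            ref.positions[vid] = (chrom, (i + 1) * bp_spacing)
        for i in range(block_size):
            for j in range(i + 1, block_size):
                r = rho ** (j - i)
                if abs(r) > 1e-12:
                    ref.set_r(ids[i], ids[j], r)
    return ref


def _block_corr(block_size: int, rho: float) -> np.ndarray:
    idx = np.arange(block_size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _correlated_noise(rng, blocks: int, block_size: int, rho: float) -> np.ndarray:
    """Unit-variance noise with the block AR(1) correlation structure."""
    if block_size == 1 or rho == 0.0:
        return rng.standard_normal(blocks * block_size)
    chol = cholesky(_block_corr(block_size, rho), lower=True)
    z = rng.standard_normal((blocks, block_size))
    return (z @ chol.T).ravel()


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)


def _build_records(
    rng,
    ld: LDReference,
    beta: np.ndarray,
    se: np.ndarray,
    eaf: np.ndarray,
    pairs: list[tuple[str, str]],
    n: int,
    n_case: int | None = None,
    n_control: int | None = None,
    scramble: bool = False,
) -> dict[str, VariantAssociation]:
    """Emit records; with ``scramble`` the reported allele orientation and
    strand are randomized (harmonization must undo this downstream)."""
    records = {}
    p = _two_sided_p(beta / se)
    for k, vid in enumerate(ld.positions):
        chrom, pos = ld.positions[vid]
        ea, oa = pairs[k]
        b, f = float(beta[k]), float(eaf[k])
        if scramble:
            if rng.random() < 0.5:  # report the other allele as effect allele
                ea, oa, b, f = oa, ea, -b, 1.0 - f
            if rng.random() < 0.5:  # report the opposite strand
                ea, oa = _COMPLEMENT[ea], _COMPLEMENT[oa]
        records[vid] = VariantAssociation(
            variant_id=vid,
            chrom=chrom,
            pos=pos,
            effect_allele=ea,
            other_allele=oa,
            eaf=f,
            beta=b,
            se=float(se[k]),
            pvalue=float(p[k]),
            n=float(n),
            n_case=float(n_case) if n_case is not None else None,
            n_control=float(n_control) if n_control is not None else None,
        )
    return records


def simulate(truth: SimTruth, mode: str = "fast") -> SimOutput:
    """Generate one paired exposure/outcome dataset under ``truth``."""
    if mode == "fast":
        return _simulate_fast(truth)
    if mode == "individual":
        return _simulate_individual(truth)
    raise DomainError(f"unknown mode {mode!r}")


def _ld_matmul(ld_blocks: int, block_size: int, rho: float, v: np.ndarray) -> np.ndarray:
    if block_size == 1 or rho == 0.0:
        return v.copy()
    corr = _block_corr(block_size, rho)
    return (v.reshape(ld_blocks, block_size) @ corr).ravel()


def _simulate_fast(truth: SimTruth) -> SimOutput:
    rng = np.random.default_rng(truth.seed)
    m = truth.blocks * truth.block_size
    ld = make_ld(truth.blocks, truth.block_size, truth.rho, truth.bp_spacing)
    gamma = np.asarray(truth.gamma)
    phi = np.asarray(truth.phi)

    if not truth.reverse:
        b_x = _ld_matmul(truth.blocks, truth.block_size, truth.rho, gamma)
        b_y = _ld_matmul(
            truth.blocks, truth.block_size, truth.rho, truth.theta_true * gamma + phi
        )
    else:
        # variants act directly on the outcome; the exposure inherits them
        direct_y = _ld_matmul(truth.blocks, truth.block_size, truth.rho, gamma)
        b_y = direct_y + _ld_matmul(truth.blocks, truth.block_size, truth.rho, phi)
        b_x = truth.theta_true * direct_y

    se_x = np.full(m, 1.0 / np.sqrt(truth.n_x))
    v = truth.n_case_frac * (1.0 - truth.n_case_frac)
    se_y = np.full(m, 1.0 / np.sqrt(truth.n_y * v))

    bhat_x = b_x + se_x * _correlated_noise(rng, truth.blocks, truth.block_size, truth.rho)
    bhat_y = b_y + se_y * _correlated_noise(rng, truth.blocks, truth.block_size, truth.rho)

    eaf = rng.uniform(0.05, 0.95, size=m)
    eaf_y = np.clip(eaf + rng.normal(0.0, 0.005, size=m), 0.01, 0.99)
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    pairs = [_NONPALINDROMIC_PAIRS[i] for i in pair_idx]

    n_case = int(round(truth.n_y * truth.n_case_frac))
    exposure = SumStats(
        trait_id="exposure",
        trait_type="quantitative",
        records=_build_records(rng, ld, bhat_x, se_x, eaf, pairs, truth.n_x),
    )
    outcome = SumStats(
        trait_id="outcome",
        trait_type="binary",
        records=_build_records(
            rng, ld, bhat_y, se_y, eaf_y, pairs, truth.n_y,
            n_case=n_case, n_control=truth.n_y - n_case, scramble=True,
        ),
    )
    return SimOutput(exposure, outcome, ld, truth)


def _ols_per_variant(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = g.shape[0]
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    ss_g = (gc**2).sum(axis=0)
    beta = gc.T @ yc / ss_g
    resid_ss = (yc**2).sum() - beta**2 * ss_g
    sigma2 = resid_ss / (n - 2)
    return beta, np.sqrt(sigma2 / ss_g)


def _logit_per_variant(g: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Univariate logistic regression with intercept via Newton-Raphson."""
    X = np.column_stack([np.ones_like(g), g])
    b = np.zeros(2)
    for _ in range(50):
        eta = X @ b
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        hess = X.T @ (X * w[:, None])
        step = solve(hess, X.T @ (y - p), assume_a="pos")
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    cov = np.linalg.inv(hess)
    return float(b[1]), float(np.sqrt(cov[1, 1]))


def _simulate_individual(truth: SimTruth) -> SimOutput:
    if truth.rho != 0.0 and truth.block_size > 1:
        raise DomainError("individual mode supports independent variants only")
    if truth.reverse:
        raise DomainError("individual mode supports forward causation only")
    rng = np.random.default_rng(truth.seed)
    m = truth.blocks * truth.block_size
    ld = make_ld(truth.blocks, truth.block_size, truth.rho, truth.bp_spacing)
    gamma = np.asarray(truth.gamma)
    phi = np.asarray(truth.phi)
    freq = rng.uniform(0.05, 0.95, size=m)
    cx, cy = truth.confounder_effect_x, truth.confounder_effect_y
    sigma_x = np.sqrt(max(1.0 - float(gamma @ gamma) - cx**2, 0.05))

    def standardized_genotypes(n: int) -> np.ndarray:
        raw = rng.binomial(2, freq, size=(n, m)).astype(float)
        return (raw - 2 * freq) / np.sqrt(2 * freq * (1 - freq))

    # exposure sample
    g_x = standardized_genotypes(truth.n_x)
    u_x = rng.standard_normal(truth.n_x)
    x = g_x @ gamma + cx * u_x + sigma_x * rng.standard_normal(truth.n_x)
    beta_x, se_x = _ols_per_variant(g_x, x)

    # outcome sample (non-overlapping)
    g_y = standardized_genotypes(truth.n_y)
    u_y = rng.standard_normal(truth.n_y)
    x_latent = g_y @ gamma + cx * u_y + sigma_x * rng.standard_normal(truth.n_y)
    eta = (
        np.log(truth.n_case_frac / (1 - truth.n_case_frac))
        + truth.theta_true * x_latent
        + cy * u_y
        + g_y @ phi
    )
    y = (rng.random(truth.n_y) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    beta_y = np.empty(m)
    se_y = np.empty(m)
    for j in range(m):
        beta_y[j], se_y[j] = _logit_per_variant(g_y[:, j], y)

    eaf = freq
    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    pairs = [_NONPALINDROMIC_PAIRS[i] for i in pair_idx]
    n_case = int(y.sum())
    exposure = SumStats(
        trait_id="exposure",
        trait_type="quantitative",
        records=_build_records(rng, ld, beta_x, se_x, eaf, pairs, truth.n_x),
    )
    outcome = SumStats(
        trait_id="outcome",
        trait_type="binary",
        records=_build_records(
            rng, ld, beta_y, se_y, eaf, pairs, truth.n_y,
            n_case=n_case, n_control=truth.n_y - n_case,
        ),
    )
    return SimOutput(exposure, outcome, ld, truth)


def make_panel(
    k_taxa: int,
    effects,
    out_dir: str | os.PathLike,
    seed: int = 0,
    n_x: int = 1800,
    n_y: int = 11600,
    n_case_frac: float = 0.41,
    loci_per_taxon: int = 3,
    block_size: int = 2,
    rho: float = 0.5,
    gamma_scale: float | None = None,
) -> dict:
    """Write a k-exposure panel sharing one outcome study, ready for the CLI.

    Emits ``exposure_<taxon>.tsv`` per taxon, one ``outcome.tsv`` covering
    the union of variants, an LD reference directory and ``truth.json``.
    Deterministic: the same seed yields byte-identical files.
    """
    if k_taxa < 1:
        raise DomainError("k_taxa must be >= 1")
    effects = list(np.broadcast_to(effects, k_taxa))
    os.makedirs(out_dir, exist_ok=True)
    root_rng = np.random.default_rng(seed)
    child_seeds = root_rng.integers(0, 2**31 - 1, size=k_taxa)
    if gamma_scale is None:
        gamma_scale = 10.0 / np.sqrt(n_x)  # per-locus F around 100

    ld_all = LDReference()
    outcome_records: dict[str, VariantAssociation] = {}
    truth_dump = {}
    exposure_paths = []
    for k in range(k_taxa):
        taxon = f"taxon{k:02d}"
        m = loci_per_taxon * block_size
        # lead variant per locus carries the signal; the rest tag along via LD
        gamma = np.zeros(m)
        gamma[::block_size] = gamma_scale
        truth = SimTruth(
            theta_true=float(effects[k]),
            gamma=tuple(gamma),
            n_x=n_x,
            n_y=n_y,
            n_case_frac=n_case_frac,
            blocks=loci_per_taxon,
            block_size=block_size,
            rho=rho,
            seed=int(child_seeds[k]),
        )
        sim = simulate(truth)
        # relocate each taxon's loci onto its own chromosomes
        offset = k * loci_per_taxon
        renamed = LDReference()
        mapping = {}
        for vid, (chrom, pos) in sim.ld.positions.items():
            new_chrom = str(int(chrom) + offset)
            new_id = f"{taxon}_{vid}"
            mapping[vid] = (new_id, new_chrom)
            renamed.positions[new_id] = (new_chrom, pos)
        for (a, b), r in sim.ld.pairs():
            renamed.set_r(mapping[a][0], mapping[b][0], r)
        ld_all.update(renamed)

        exp_records = {}
        for vid, rec in sim.exposure_sumstats.records.items():
            new_id, new_chrom = mapping[vid]
            exp_records[new_id] = _rekey(rec, new_id, new_chrom)
        exp = SumStats(trait_id=taxon, trait_type="quantitative", records=exp_records)
        path = os.path.join(out_dir, f"exposure_{taxon}.tsv")
        write_sumstats(exp, path)
        exposure_paths.append(path)

        for vid, rec in sim.outcome_sumstats.records.items():
            new_id, new_chrom = mapping[vid]
            outcome_records[new_id] = _rekey(rec, new_id, new_chrom)
        truth_dump[taxon] = asdict(truth)

    outcome = SumStats(trait_id="outcome", trait_type="binary", records=outcome_records)
    outcome_path = os.path.join(out_dir, "outcome.tsv")
    write_sumstats(outcome, outcome_path)
    ld_dir = os.path.join(out_dir, "ld")
    write_ld(ld_all, ld_dir)
    with open(os.path.join(out_dir, "truth.json"), "w", encoding="utf-8") as fh:
        json.dump(truth_dump, fh, indent=2, sort_keys=True)
    return {
        "exposure_paths": exposure_paths,
        "outcome_path": outcome_path,
        "ld_dir": ld_dir,
        "truth": truth_dump,
    }


def _rekey(rec: VariantAssociation, new_id: str, new_chrom: str) -> VariantAssociation:
    return VariantAssociation(
        variant_id=new_id,
        chrom=new_chrom,
        pos=rec.pos,
        effect_allele=rec.effect_allele,
        other_allele=rec.other_allele,
        eaf=rec.eaf,
        beta=rec.beta,
        se=rec.se,
        pvalue=rec.pvalue,
        n=rec.n,
        n_case=rec.n_case,
        n_control=rec.n_control,
    )
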