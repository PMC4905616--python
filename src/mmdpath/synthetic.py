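"""Synthetic two-condition omics data and a simulation harness for type-I
error and power.

The generative model is deliberately minimal — the weakest model consistent
with the assumptions of the tests under study: each block is multivariate
Gaussian with unit variances and exchangeable (equicorrelated) correlation
rho, and the alternative shifts the means of a designated feature subset by
delta.  Hotelling's T^2 assumes exactly this normal/equal-covariance world;
the MMD and MST tests are model-free, so Gaussian nulls are the conservative
calibration target for all four.

:func:`generate_nutrimouse_like` emulates the 40-mouse nutrigenomic design
(20 wild-type vs 20 PPAR-deficient mice, 5 diets x 8 mice, a 120-gene
expression block and a 21-fatty-acid block): a 17-gene catabolism subset
carries the genotype shift, and three long-chain omega-3 fatty acids carry a
diet contrast (elevated under the fish diet, mildly under linseed).  What
these generators do *not* emulate: macroarray noise (heteroscedastic,
non-Gaussian), compositional constraints on fatty-acid percentages, or any
gene-gene network correlation beyond exchangeability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .io import OmicsBlock, SampleMetadata
from . import datasets as _datasets
from .kernels import combine_kernels, rbf_kernel
from .mmd import TestResult, mmd_test
from .baselines import NotApplicableError, hotelling_t2, ks_test, ww_test

__all__ = [
    "SimulationDesign",
    "RejectionRate",
    "generate_two_condition",
    "generate_nutrimouse_like",
    "rejection_rate",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated two-condition study.

    delta shifts the means of ``n_shifted`` features (default: all) of the
    ``shift_block`` block for group 2; ``rho`` is the exchangeable
    within-block correlation; ``t_perm`` is the permutation count used by the
    permutation tests inside :func:`rejection_rate`.
    """

    m: int = 20
    n: int = 20
    p_genes: int = 16
    p_lipids: int = 0
    delta: float = 0.0
    shift_block: str = "genes"
    n_shifted: int | None = None
    rho: float = 0.0
    n_reps: int = 500
    alpha: float = 0.05
    t_perm: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("group sizes must be >= 2")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.p_genes < 1:
            raise ValueError("p_genes must be >= 1")


def _exchangeable_block(
    rng: np.random.Generator, n: int, p: int, rho: float
) -> np.ndarray:
    """Draw n x p Gaussian rows with unit variance and equicorrelation rho."""
    z = rng.standard_normal((n, p))
    if rho == 0:
        return z
    shared = rng.standard_normal((n, 1))
    return np.sqrt(1.0 - rho) * z + np.sqrt(rho) * shared


def generate_two_condition(
    design: SimulationDesign,
) -> tuple[list[OmicsBlock], SampleMetadata]:
    """Simulate blocks for two conditions under the exchangeable Gaussian model.

    Group 1 ~ N(0, Sigma), group 2 ~ N(delta * s, Sigma) per block, with s the
    indicator of the shifted features.  Pure function of the design (the seed
    is part of it).
    """
    rng = np.random.default_rng(design.seed)
    N = design.m + design.n
    sample_ids = [f"s{i + 1:03d}" for i in range(N)]
    labels = ["A"] * design.m + ["B"] * design.n

    blocks: list[OmicsBlock] = []
    specs = [("genes", design.p_genes)]
    if design.p_lipids > 0:
        specs.append(("lipids", design.p_lipids))
    for bname, p in specs:
        X = _exchangeable_block(rng, N, p, design.rho)
        if design.delta != 0 and bname == design.shift_block:
            k = p if design.n_shifted is None else min(design.n_shifted, p)
            X[design.m:, :k] += design.delta
        prefix = bname[0]
        blocks.append(OmicsBlock(
            bname, sample_ids, [f"{prefix}{j + 1:03d}" for j in range(p)], X))
    meta = SampleMetadata(sample_ids, {"condition": labels})
    return blocks, meta


#: per-genotype diet layout of the emulated nutrigenomic study
_DIETS = ("coc", "fish", "lin", "ref", "sun")


def generate_nutrimouse_like(
    seed: int = 0,
    delta_genotype: float = 1.0,
    delta_diet: float = 2.0,
    rho: float = 0.2,
) -> tuple[OmicsBlock, OmicsBlock, SampleMetadata]:
    """Simulate a dataset with the 40-mouse nutrigenomic study's design.

    Returns a (40 x 120) gene block, a (40 x 21) lipid block and metadata with
    a balanced genotype (20 wt / 20 ppar) x diet (5 x 8) layout.  The 17
    catabolism genes (named as in the real dataset, so the bundled GMT
    applies) are shifted by ``delta_genotype`` in wt mice; the three omega-3
    fatty acids are raised by ``delta_diet`` under the fish diet and by half
    that under linseed.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"m{i + 1:02d}" for i in range(40)]
    genotype = ["wt"] * 20 + ["ppar"] * 20
    diet = [d for d in _DIETS for _ in range(4)] * 2

    path_genes = list(_datasets.CATABOLISM_GENES)
    gene_ids = path_genes + [f"g{j + 1:03d}" for j in range(120 - len(path_genes))]
    G = _exchangeable_block(rng, 40, 120, rho)
    G[:20, : len(path_genes)] += delta_genotype  # wt mice overexpress the pathway

    omega3 = list(_datasets.OMEGA3_LIPIDS)
    lipid_ids = omega3 + [f"fa{j + 1:02d}" for j in range(21 - len(omega3))]
    L = _exchangeable_block(rng, 40, 21, rho)
    fish = np.array([d == "fish" for d in diet])
    lin = np.array([d == "lin" for d in diet])
    L[fish, : len(omega3)] += delta_diet
    L[lin, : len(omega3)] += delta_diet / 2.0

    genes = OmicsBlock("genes", sample_ids, gene_ids, G)
    lipids = OmicsBlock("lipids", sample_ids, lipid_ids, L)
    meta = SampleMetadata(sample_ids, {"genotype": genotype, "diet": diet})
    return genes, lipids, meta


@dataclass
class RejectionRate:
    """Empirical rejection rate with an exact (Clopper-Pearson) 95% CI."""

    test: str
    rate: float
    n_rejections: int
    n_reps: int
    n_not_applicable: int
    alpha: float
    ci_low: float
    ci_high: float


def _clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    a = (1.0 - level) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


_KNOWN_TESTS = ("mmd", "hotelling", "mww", "mks")


def _run_one(test: str, blocks: list[OmicsBlock], mask: np.ndarray,
             t: int, seed: int) -> TestResult:
    if test == "mmd":
        kernels = [rbf_kernel(b) for b in blocks]
        K = combine_kernels(kernels) if len(kernels) > 1 else kernels[0]
        return mmd_test(K, mask, t=t, seed=seed)
    X = np.hstack([b.values for b in blocks])
    if test == "hotelling":
        return hotelling_t2(X[mask], X[~mask])
    if test == "mww":
        return ww_test(X, mask, mode="permutation", t=t, seed=seed)
    if test == "mks":
        return ks_test(X, mask, t=t, seed=seed)
    raise ValueError(f"unknown test {test!r}; known: {_KNOWN_TESTS}")


def rejection_rate(test: str, design: SimulationDesign) -> RejectionRate:
    """Fraction of simulated datasets on which ``test`` rejects at level alpha.

    Each of ``design.n_reps`` replicates draws fresh data (seeds spawned from
    ``design.seed``), runs the named test (``"mmd"``, ``"hotelling"``,
    ``"mww"`` or ``"mks"``) and compares p to ``design.alpha``.  Replicates on
    which a test is structurally not applicable (Hotelling with p > m+n-2)
    are counted separately, not as rejections.
    """
    if test not in _KNOWN_TESTS:
        raise ValueError(f"unknown test {test!r}; known: {_KNOWN_TESTS}")
    if design.n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    child_seeds = np.random.SeedSequence(design.seed).generate_state(2 * design.n_reps)
    child_seeds = (child_seeds % (2**31 - 1)).astype(np.int64)
    rejections = 0
    not_applicable = 0
    for rep in range(design.n_reps):
        rep_design = replace(design, seed=int(child_seeds[2 * rep]))
        blocks, meta = generate_two_condition(rep_design)
        mask = np.array([v == "A" for v in meta.factors["condition"]])
        try:
            res = _run_one(test, blocks, mask,
                           t=design.t_perm, seed=int(child_seeds[2 * rep + 1]))
        except NotApplicableError:
            not_applicable += 1
            continue
        if res.p_value <= design.alpha:
            rejections += 1
    valid = design.n_reps - not_applicable
    rate = rejections / valid if valid else float("nan")
    lo, hi = _clopper_pearson(rejections, valid) if valid else (float("nan"),) * 2
    return RejectionRate(
        test=test, rate=rate, n_rejections=rejections, n_reps=design.n_reps,
        n_not_applicable=not_applicable, alpha=design.alpha,
        ci_low=lo, ci_high=hi,
    )
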