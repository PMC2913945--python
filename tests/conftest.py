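"""Shared fixtures: small synthetic data sets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from pedlink.models import QuantitativeModel
from pedlink.simulate import SimSpec, gene_drop, generate_pedigrees, simulate_phenotypes


@pytest.fixture(scope="session")
def small_spec() -> SimSpec:
    return SimSpec(
        n_large=0,
        n_moderate=2,
        n_small=8,
        disease_model=QuantitativeModel(),
        n_markers=4,
        n_unlinked_markers=2,
        missing_srs_rate=0.05,
        missing_genotype_rate=0.02,
        min_affected=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    rng = np.random.default_rng(7)
    peds = generate_pedigrees(small_spec, rng)
    gm, gmap, truth = gene_drop(peds, small_spec, rng)
    pheno = simulate_phenotypes(peds, truth, small_spec, rng)
    return peds, gm, gmap, truth, pheno


def random_small_pedigree(rng: np.random.Generator, max_members: int = 8):
    """Random loop-free pedigree structure as a parent-index tuple.

    Founder couple, 1-3 children; one child may marry in a spouse and have
    grandchildren while the total stays within ``max_members``."""
    parent_idx: list[tuple[int, int] | None] = [None, None]
    kids = []
    for _ in range(int(rng.integers(1, 4))):
        if len(parent_idx) >= max_members:
            break
        kids.append(len(parent_idx))
        parent_idx.append((0, 1))
    if kids and len(parent_idx) + 2 <= max_members and rng.random() < 0.7:
        child = int(rng.choice(kids))
        spouse = len(parent_idx)
        parent_idx.append(None)
        for _ in range(int(rng.integers(1, 3))):
            if len(parent_idx) >= max_members:
                break
            parent_idx.append((child, spouse))
    return tuple(parent_idx)


def brute_force_loglik(parent_idx, unary, theta):
    """Independent oracle: likelihood by exhaustive summation over all
    joint diplotype assignments (pruned to states with positive weight)."""
    from pedlink import linkage as L

    n = len(parent_idx)
    cands = [np.nonzero(unary[i] > 0)[0] for i in range(n)]
    size = int(np.prod([len(c) for c in cands]))
    if size > 3_000_000:
        raise ValueError("assignment space too large for the oracle")
    t = L.transmission_matrix(theta)
    grids = np.meshgrid(*cands, indexing="ij")
    assign = np.stack([g.ravel() for g in grids], axis=1)  # (P, n)
    prob = np.ones(len(assign))
    for i in range(n):
        prob *= unary[i][assign[:, i]]
        pi = parent_idx[i]
        if pi is not None:
            prob *= t[assign[:, i], assign[:, pi[0]], assign[:, pi[1]]]
    total = prob.sum()
    return -np.inf if total == 0 else float(np.log(total))


def drop_marker_genotypes(parent_idx, rng, freq1=0.5, typed_prob=0.85):
    """Mendelian-consistent single-marker genotype codes for a structure."""
    n = len(parent_idx)
    alleles = np.zeros((n, 2), dtype=int)
    for i, pi in enumerate(parent_idx):
        if pi is None:
            alleles[i] = rng.random(2) >= freq1  # 0 = allele "1"
        else:
            alleles[i, 0] = alleles[pi[0], rng.integers(2)]
            alleles[i, 1] = alleles[pi[1], rng.integers(2)]
    codes = alleles.sum(axis=1) + 1
    codes[rng.random(n) >= typed_prob] = 0
    return codes
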