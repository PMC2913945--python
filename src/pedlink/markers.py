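"""Marker-level quality control.

Pipeline order mirrors common linkage practice: drop failed/monomorphic
markers, prune residual linkage disequilibrium with a sliding-window
variance-inflation-factor rule (window 50 SNPs, step 5, VIF < 1.5, i.e.
multiple R^2 < 1/3), then apply the minor-allele-frequency filter
(MAF >= 0.10 kept) and a Hardy-Weinberg exact test.

The VIF of marker j within a window is 1 / (1 - R^2_j) where R^2_j is
from regressing j's allele dosage on all other markers in the window;
markers are removed greedily (highest VIF first) until all survivors are
below threshold.  Removal is deterministic: ties go to the marker later
in map order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .pedigree import GeneticMap, GenotypeMatrix, Pedigree


class QCError(ValueError):
    pass


@dataclass
class QCParams:
    maf_min: float = 0.10
    hwe_alpha: float = 1e-3  # common linkage-QC choice; not printed anywhere standard
    ld_window: int = 50
    ld_step: int = 5
    ld_vif: float = 1.5
    hwe_founders_only: bool = True


@dataclass
class MarkerStats:
    marker_id: str
    allele_freq: float  # frequency of allele 1
    maf: float
    hwe_p: float
    status: str = "kept"  # kept / removed
    reason: str = ""  # maf / hwe / ld / performance


# ---------------------------------------------------------------------------


def estimate_allele_freqs(gm: GenotypeMatrix) -> np.ndarray:
    """Allele-1 frequency per marker from all observed genotypes.

    Every genotyped individual is counted (founders and non-founders
    alike).  All-missing markers get NaN and must be dropped downstream.
    """
    a = gm.alleles
    observed = a[:, :, 0] > 0
    n_obs = observed.sum(axis=0)
    count1 = ((a == 1).sum(axis=2)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, count1 / (2.0 * n_obs), np.nan)
    return freq


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact conditional Hardy-Weinberg test for a biallelic marker.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts (of matching parity) whose conditional
    probability does not exceed that of the observed count.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise QCError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise QCError("need at least one genotype")
    n_a = 2 * n_aa + n_ab  # rarer-allele orientation is irrelevant by symmetry
    n_b = 2 * n_bb + n_ab
    n_min = min(n_a, n_b)
    hets = np.arange(n_min % 2, n_min + 1, 2)
    # log P(het = h | allele counts) up to a shared constant
    logp = (
        hets * np.log(2.0)
        - gammaln((n_a - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln((n_b - hets) / 2 + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_ab]
    if obs.size == 0:
        raise QCError("heterozygote count inconsistent with allele counts")
    return float(min(1.0, p[p <= obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# LD pruning


def _dosage(gm: GenotypeMatrix, cols: list[int]) -> np.ndarray:
    """Allele-1 dosage 0/1/2 with NaN for missing, shape (n_indiv, k)."""
    a = gm.alleles[:, cols, :]
    d = (a == 1).sum(axis=2).astype(float)
    d[a[:, :, 0] == 0] = np.nan
    return d


def _window_vifs(x: np.ndarray) -> np.ndarray:
    """VIF of each column of x against the others (complete cases)."""
    x = x[~np.isnan(x).any(axis=1)]
    k = x.shape[1]
    if k == 1:
        return np.ones(1)
    if x.shape[0] <= k:
        # not enough complete cases to fit: treat as maximally inflated
        return np.full(k, np.inf)
    xc = x - x.mean(axis=0)
    sst = (xc**2).sum(axis=0)
    vifs = np.empty(k)
    for j in range(k):
        if sst[j] == 0:
            vifs[j] = 1.0  # constant column carries no LD information
            continue
        others = np.delete(xc, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, xc[:, j], rcond=None)
        resid = xc[:, j] - others @ beta
        ssr = (resid**2).sum()
        r2 = max(0.0, 1.0 - ssr / sst[j])
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def ld_prune_vif(
    gm: GenotypeMatrix,
    marker_order: list[str] | None = None,
    window: int = 50,
    step: int = 5,
    vif_threshold: float = 1.5,
) -> list[str]:
    """Sliding-window VIF pruning; returns the kept marker ids in order.

    ``marker_order`` must list markers in map order within chromosome
    (defaults to the matrix's column order).  A marker removed in any
    window stays removed.
    """
    if window < 2:
        raise QCError("LD window must cover at least 2 markers")
    if step < 1:
        raise QCError("LD step must be positive")
    order = list(marker_order) if marker_order is not None else list(gm.marker_ids)
    removed: set[str] = set()
    start = 0
    while True:
        ids = [m for m in order[start : start + window] if m not in removed]
        if len(ids) >= 2:
            cols = [gm.col_of(m) for m in ids]
            x = _dosage(gm, cols)
            alive = list(range(len(ids)))
            while len(alive) >= 2:
                vifs = _window_vifs(x[:, alive])
                worst = vifs.max()
                if worst < vif_threshold:
                    break
                # tie rule: later in map order wins removal
                j = max(i for i, v in enumerate(vifs) if v == worst)
                removed.add(ids[alive[j]])
                del alive[j]
        if start + window >= len(order):
            break
        start += step
    return [m for m in order if m not in removed]


# ---------------------------------------------------------------------------
# driver


@dataclass
class QCResult:
    genotypes: GenotypeMatrix
    genetic_map: GeneticMap
    stats: pd.DataFrame  # one row per input marker
    counts: dict = field(default_factory=dict)


def apply_qc(
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    pedigrees: list[Pedigree] | None = None,
    params: QCParams | None = None,
) -> QCResult:
    """Full marker QC: performance/monomorphic -> LD prune -> MAF -> HWE.

    Returns the filtered genotypes and map (with allele frequencies
    attached) plus a per-marker report.  Removal reasons partition the
    removed set; the first applicable filter wins.
    """
    params = params or QCParams()
    ids = list(gmap.marker_ids)
    freqs = estimate_allele_freqs(gm)
    freq_of = {m: freqs[gm.col_of(m)] for m in ids}

    reason: dict[str, str] = {}
    # stage 1: failed / monomorphic markers
    for m in ids:
        f = freq_of[m]
        if np.isnan(f) or f <= 0.0 or f >= 1.0:
            reason[m] = "performance"
    # stage 2: LD pruning among surviving markers, per chromosome order
    alive = [m for m in ids if m not in reason]
    if np.isfinite(params.ld_vif):
        kept = set(ld_prune_vif(gm, alive, params.ld_window, params.ld_step, params.ld_vif))
        for m in alive:
            if m not in kept:
                reason[m] = "ld"
    # stage 3: MAF (strict inequality: MAF exactly at the cutoff is kept)
    for m in ids:
        if m in reason:
            continue
        if min(freq_of[m], 1 - freq_of[m]) < params.maf_min:
            reason[m] = "maf"
    # stage 4: HWE exact test, founders only by default
    hwe_rows: set[int] | None = None
    if pedigrees is not None and params.hwe_founders_only:
        hwe_rows = set()
        for ped in pedigrees:
            for ind in ped.founders:
                hwe_rows.add(gm.row_of(ped.family_id, ind.indiv_id))
    hwe_p: dict[str, float] = {}
    for m in ids:
        codes = gm.genotype_codes(m)
        if hwe_rows is not None:
            codes = codes[sorted(hwe_rows)]
        n11 = int((codes == 1).sum())
        n12 = int((codes == 2).sum())
        n22 = int((codes == 3).sum())
        hwe_p[m] = hwe_exact_test(n11, n12, n22) if (n11 + n12 + n22) else 1.0
        if m not in reason and params.hwe_alpha > 0 and hwe_p[m] < params.hwe_alpha:
            reason[m] = "hwe"

    stats = pd.DataFrame(
        {
            "marker_id": ids,
            "chrom": gmap.chromosomes,
            "cm": gmap.positions_cm,
            "bp": gmap.positions_bp,
            "freq1": [freq_of[m] for m in ids],
            "maf": [min(freq_of[m], 1 - freq_of[m]) if not np.isnan(freq_of[m]) else np.nan for m in ids],
            "hwe_p": [hwe_p[m] for m in ids],
            "status": ["removed" if m in reason else "kept" for m in ids],
            "reason": [reason.get(m, "") for m in ids],
        }
    )
    keep_ids = [m for m in ids if m not in reason]
    out_map = gmap.subset(keep_ids)
    out_map.allele_freqs = np.array([freq_of[m] for m in keep_ids])
    counts = {
        "input": len(ids),
        "kept": len(keep_ids),
        **{r: int((stats["reason"] == r).sum()) for r in ("performance", "ld", "maf", "hwe")},
    }
    return QCResult(gm.subset_markers(keep_ids), out_map, stats, counts)
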