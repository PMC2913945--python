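"""Exact pedigree likelihoods and linkage statistics.

The parametric engine computes, for one marker position at a time, the
exact likelihood of a pedigree's marker genotypes and phenotypes under a
two-locus disease-marker model with recombination fraction theta.  The
latent state of an individual is their unordered pair of two-locus
haplotypes (disease allele x marker allele): 4 haplotypes, 10 diplotypes.
Founder diplotypes follow Hardy-Weinberg / linkage-equilibrium priors;
transmission applies recombination between the two loci; phenotypes enter
through penetrance vectors over the 0/1/2 risk-allele count.

Likelihoods are evaluated by exact peeling — sum-product variable
elimination over the pedigree's transmission graph, the generalisation of
Elston-Stewart peeling — vectorised over batches of identically
structured families.  The LOD score is log10 L(theta) / L(1/2); the
heterogeneity LOD (HLOD) maximises the Smith admixture likelihood over
the linked proportion alpha and theta.  A nonparametric affected-pair
allele-sharing statistic (an analog of NPL scoring, computed from the
exact inheritance-vector posterior) and the one-sided 50:50 mixture
chi-square LOD <-> p conversions complete the module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pedigree import Pedigree, PedigreeError

LN10 = np.log(10.0)

#: default recombination-fraction grid (must contain 0.5)
THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.15, 0.2, 0.3, 0.4, 0.5)

#: default admixture-proportion grid (2-decimal resolution)
ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))

#: per-family, per-theta LOD floor: keeps pooled sums finite when a family
#: carries an obligate recombinant (likelihood 0 at theta = 0)
LOD_FLOOR = -99.0


class LinkageError(ValueError):
    pass


class ImpossibleDataError(LinkageError):
    """Marker data have zero probability (Mendelian inconsistency)."""


# ---------------------------------------------------------------------------
# map functions


def haldane_theta(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> recombination fraction."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def haldane_cm(theta: float | np.ndarray) -> float | np.ndarray:
    """Inverse Haldane map function: theta -> cM distance."""
    t = np.asarray(theta, dtype=float)
    return -50.0 * np.log(1.0 - 2.0 * t)


# ---------------------------------------------------------------------------
# two-locus diplotype state space

# haplotype = (disease allele in {0,1}, marker allele index in {0,1});
# marker allele index 0 is allele "1", index 1 is allele "2"
HAPLOTYPES: tuple[tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))
DIPLOTYPES: tuple[tuple[int, int], ...] = tuple(
    (i, j) for i in range(4) for j in range(i, 4)
)
N_STATES = len(DIPLOTYPES)  # 10

#: risk-allele count per diplotype state
RISK_COUNT = np.array([HAPLOTYPES[i][0] + HAPLOTYPES[j][0] for i, j in DIPLOTYPES])

#: marker genotype code per state: 1 = 1/1, 2 = 1/2, 3 = 2/2
_MARKER_CODE = np.array([HAPLOTYPES[i][1] + HAPLOTYPES[j][1] + 1 for i, j in DIPLOTYPES])

#: OBS_MATCH[c, s] = 1 if observed genotype code c (0 missing, 1..3) is
#: compatible with state s
OBS_MATCH = np.zeros((4, N_STATES))
OBS_MATCH[0] = 1.0
for _c in (1, 2, 3):
    OBS_MATCH[_c] = (_MARKER_CODE == _c).astype(float)

_PAIR_TO_STATE = np.zeros((4, 4), dtype=np.int64)
for _s, (_i, _j) in enumerate(DIPLOTYPES):
    _PAIR_TO_STATE[_i, _j] = _s
    _PAIR_TO_STATE[_j, _i] = _s


def gamete_probs(theta: float) -> np.ndarray:
    """G[s, h]: probability a parent in diplotype state s transmits
    haplotype h, with recombination theta between the loci."""
    g = np.zeros((N_STATES, 4))
    for s, (i, j) in enumerate(DIPLOTYPES):
        (d1, m1), (d2, m2) = HAPLOTYPES[i], HAPLOTYPES[j]
        for hap, p in (
            ((d1, m1), (1 - theta) / 2),
            ((d2, m2), (1 - theta) / 2),
            ((d1, m2), theta / 2),
            ((d2, m1), theta / 2),
        ):
            g[s, HAPLOTYPES.index(hap)] += p
    return g


def transmission_matrix(theta: float) -> np.ndarray:
    """T[c, f, m]: P(child state c | father state f, mother state m)."""
    g = gamete_probs(theta)
    t = np.zeros((N_STATES, N_STATES, N_STATES))
    for ga in range(4):
        for gb in range(4):
            t[_PAIR_TO_STATE[ga, gb]] += g[:, ga][:, None] * g[:, gb][None, :]
    return t


def founder_prior(disease_allele_freq: float, marker_freq1: float) -> np.ndarray:
    """Diplotype prior for founders: Hardy-Weinberg at the disease locus,
    the estimated marker allele frequencies, linkage equilibrium between
    them."""
    q = disease_allele_freq
    hap = np.array(
        [(q if d else 1 - q) * (marker_freq1 if m == 0 else 1 - marker_freq1)
         for d, m in HAPLOTYPES]
    )
    pr = np.empty(N_STATES)
    for s, (i, j) in enumerate(DIPLOTYPES):
        pr[s] = hap[i] * hap[j] * (1.0 if i == j else 2.0)
    return pr


# ---------------------------------------------------------------------------
# peeling (batched sum-product variable elimination)


class PeelingPlan:
    """Elimination schedule for one pedigree structure.

    Built once per distinct structure; likelihood evaluation is vectorised
    over all families sharing the structure.  Greedy min-fill ordering on
    the moralised transmission graph keeps cliques small (three variables
    on loop-free pedigrees).
    """

    def __init__(self, parent_indices: tuple):
        self.parent_indices = tuple(parent_indices)
        self.n = len(parent_indices)
        self.founder_mask = np.array([p is None for p in parent_indices])
        # moral graph: child-father, child-mother, father-mother
        adj: dict[int, set[int]] = {i: set() for i in range(self.n)}
        for c, pi in enumerate(parent_indices):
            if pi is None:
                continue
            f, m = pi
            for a, b in ((c, f), (c, m), (f, m)):
                adj[a].add(b)
                adj[b].add(a)
        self.order = self._min_fill_order(adj)

    @classmethod
    def from_pedigree(cls, ped: Pedigree) -> "PeelingPlan":
        return cls(tuple(ped.parent_indices()))

    @staticmethod
    def _min_fill_order(adj: dict[int, set[int]]) -> list[int]:
        adj = {v: set(nb) for v, nb in adj.items()}
        order = []
        remaining = set(adj)
        while remaining:
            best, best_key = None, None
            for v in sorted(remaining):
                nb = adj[v]
                fill = sum(
                    1
                    for a, b in itertools.combinations(sorted(nb), 2)
                    if b not in adj[a]
                )
                key = (fill, len(nb), v)
                if best_key is None or key < best_key:
                    best, best_key = v, key
            order.append(best)
            nb = adj[best]
            for a, b in itertools.combinations(sorted(nb), 2):
                adj[a].add(b)
                adj[b].add(a)
            for a in nb:
                adj[a].discard(best)
            del adj[best]
            remaining.discard(best)
        return order


def _einsum_letters(variables: list[int]) -> dict[int, str]:
    return {v: chr(ord("a") + i) for i, v in enumerate(variables)}


def peel_loglik(plan: PeelingPlan, unary: np.ndarray, theta: float) -> np.ndarray:
    """Natural-log likelihood for a batch of families sharing ``plan``.

    ``unary`` has shape (B, n, 10): per family and member, the product of
    the founder prior (founders only), the marker-observation indicator,
    and the penetrance weight.  Returns shape (B,); -inf marks families
    whose data are impossible under the model.
    """
    unary = np.asarray(unary, dtype=float)
    if unary.ndim == 2:
        unary = unary[None]
    b, n, k = unary.shape
    if n != plan.n or k != N_STATES:
        raise LinkageError("unary weight array does not match the peeling plan")

    t = transmission_matrix(theta)
    # factors: (vars tuple, array); batched arrays lead with the B axis
    factors: list[tuple[tuple[int, ...], np.ndarray, bool]] = []
    for i in range(plan.n):
        factors.append(((i,), unary[:, i, :], True))
    for c, pi in enumerate(plan.parent_indices):
        if pi is not None:
            factors.append(((c, pi[0], pi[1]), t, False))

    log_acc = np.zeros(b)
    for v in plan.order:
        involved = [f for f in factors if v in f[0]]
        factors = [f for f in factors if v not in f[0]]
        union: list[int] = []
        for vars_, _, _ in involved:
            for u in vars_:
                if u not in union:
                    union.append(u)
        out_vars = tuple(u for u in union if u != v)
        letters = _einsum_letters(union)
        subs = []
        operands = []
        any_batched = False
        for vars_, arr, batched in involved:
            subs.append(("z" if batched else "") + "".join(letters[u] for u in vars_))
            operands.append(arr)
            any_batched = any_batched or batched
        out_sub = ("z" if any_batched else "") + "".join(letters[u] for u in out_vars)
        res = np.einsum(",".join(subs) + "->" + out_sub, *operands, optimize=True)
        if any_batched:
            state_axes = tuple(range(1, res.ndim))
            scale = res.max(axis=state_axes) if state_axes else res.copy()
            safe = np.where(scale > 0, scale, 1.0)
            res = res / safe.reshape((b,) + (1,) * len(state_axes))
            with np.errstate(divide="ignore"):
                log_acc = log_acc + np.log(scale)
        else:
            scale = res.max() if res.ndim else float(res)
            if scale > 0:
                res = res / scale
                log_acc = log_acc + np.log(scale)
            else:
                log_acc = log_acc + (-np.inf)
        if out_vars or (any_batched and res.ndim > 1):
            factors.append((out_vars, res, any_batched))
        else:
            with np.errstate(divide="ignore"):
                log_acc = log_acc + (np.log(res) if any_batched else np.log(float(res)))
    # any remaining factors are empty-scope scalars from isolated vertices
    for vars_, arr, batched in factors:
        with np.errstate(divide="ignore"):
            log_acc = log_acc + (np.log(arr) if batched else np.log(float(arr)))
    return log_acc


def build_unary(
    plan: PeelingPlan,
    genotype_codes: np.ndarray,
    pen_weights: np.ndarray,
    disease_allele_freq: float,
    marker_freq1: float,
) -> np.ndarray:
    """Per-member diplotype weights, shape (..., n, 10).

    ``genotype_codes``: (..., n) ints (0 missing, 1=1/1, 2=1/2, 3=2/2);
    ``pen_weights``: (..., n, 3) penetrance vectors per member.
    """
    codes = np.asarray(genotype_codes)
    pw = np.asarray(pen_weights, dtype=float)
    u = OBS_MATCH[codes] * pw[..., RISK_COUNT]
    prior = founder_prior(disease_allele_freq, marker_freq1)
    u = np.where(plan.founder_mask[..., :, None], u * prior, u)
    return u


def pedigree_loglik(
    ped: Pedigree,
    genotype_codes: np.ndarray,
    pen_weights: np.ndarray,
    disease_allele_freq: float,
    marker_freq1: float,
    theta: float,
    check_loops: bool = True,
) -> float:
    """Single-family exact log-likelihood (natural log) at one theta.

    Raises :class:`ImpossibleDataError` when the data have probability
    zero even without linkage (Mendelian inconsistency), and
    :class:`PedigreeError` for looped pedigrees.
    """
    if check_loops:
        from .pedigree import validate_pedigree

        rep = validate_pedigree(ped)
        if rep.has_cycle or rep.has_loop:
            raise PedigreeError(
                f"family {ped.family_id}: looped or cyclic pedigrees are not supported"
            )
    plan = PeelingPlan.from_pedigree(ped)
    unary = build_unary(plan, genotype_codes, pen_weights, disease_allele_freq, marker_freq1)
    ll = float(peel_loglik(plan, unary[None], theta)[0])
    if not np.isfinite(ll) and theta == 0.5:
        raise ImpossibleDataError(
            f"family {ped.family_id}: zero-probability marker configuration"
        )
    return ll


def lod_curves(
    plans: list[PeelingPlan],
    unaries: list[np.ndarray],
    theta_grid: tuple[float, ...] = THETA_GRID,
    family_ids: list[str] | None = None,
) -> np.ndarray:
    """Per-family LOD over the theta grid, shape (F, T).

    Families are grouped by identical structure and peeled in batches.
    lod(theta) = log10 L(theta) - log10 L(1/2); the grid must contain 0.5.
    Impossible data (zero likelihood at theta = 1/2) raises, naming the
    family; -inf at linked thetas (obligate recombinants) is floored.
    """
    if 0.5 not in theta_grid:
        raise LinkageError("theta grid must contain 0.5")
    f = len(plans)
    out = np.empty((f, len(theta_grid)))
    groups: dict[tuple, list[int]] = {}
    for i, p in enumerate(plans):
        groups.setdefault(p.parent_indices, []).append(i)
    for key, idx in groups.items():
        plan = plans[idx[0]]
        u = np.stack([unaries[i] for i in idx])
        ll = np.stack([peel_loglik(plan, u, th) for th in theta_grid], axis=1)
        base = ll[:, theta_grid.index(0.5)]
        if not np.all(np.isfinite(base)):
            bad = idx[int(np.argmin(np.isfinite(base)))]
            name = family_ids[bad] if family_ids else str(bad)
            raise ImpossibleDataError(
                f"family {name}: zero-probability marker configuration"
            )
        lods = (ll - base[:, None]) / LN10
        out[idx, :] = np.maximum(lods, LOD_FLOOR)
    return out


# ---------------------------------------------------------------------------
# pooled LOD and heterogeneity LOD


@dataclass
class HlodResult:
    hlod: float
    alpha: float
    theta: float
    pooled_lod: float  # homogeneity LOD maximised over theta
    per_family_lods: np.ndarray  # (F, T)

    @property
    def p_value(self) -> float:
        return lod_to_pvalue(max(self.hlod, 0.0))


def hlod(
    per_family_lods: np.ndarray,
    theta_grid: tuple[float, ...] = THETA_GRID,
    alpha_grid: tuple[float, ...] = ALPHA_GRID,
) -> HlodResult:
    """Smith admixture-model heterogeneity LOD.

    HLOD = max over (alpha, theta) of sum_i log10[alpha 10^lod_i + 1 - alpha].
    With 0 in the alpha grid the HLOD is never negative; alpha = 1 recovers
    the pooled homogeneity LOD.
    """
    lods = np.asarray(per_family_lods, dtype=float)
    if lods.ndim != 2 or lods.shape[0] == 0:
        raise LinkageError("need a non-empty (families x thetas) LOD array")
    lr = np.power(10.0, lods)  # (F, T)
    alphas = np.asarray(alpha_grid, dtype=float)
    mix = alphas[:, None, None] * lr[None] + (1.0 - alphas[:, None, None])
    with np.errstate(divide="ignore"):
        vals = np.log10(mix).sum(axis=1)  # (A, T)
    ai, ti = np.unravel_index(np.argmax(vals), vals.shape)
    pooled = float(lods.sum(axis=0).max())
    return HlodResult(
        hlod=float(vals[ai, ti]),
        alpha=float(alphas[ai]),
        theta=float(theta_grid[ti]),
        pooled_lod=pooled,
        per_family_lods=lods,
    )


# ---------------------------------------------------------------------------
# nonparametric affected-pair sharing


@dataclass
class NplResult:
    z: float
    p: float
    lod_equivalent: float
    n_families_scored: int
    n_families_skipped: int
    per_family_z: list[float]


def _family_npl(
    ped: Pedigree,
    genotype_codes: np.ndarray,
    marker_freq1: float,
    affected: np.ndarray,
    max_bits: int,
) -> float | None:
    """Per-family standardised sharing score, or None if unscorable.

    Enumerates inheritance vectors (2 bits per non-founder), computes the
    exact posterior given the marker data, and scores the expected
    proportion of alleles shared identical-by-descent over all affected
    pairs, standardised by the null (uniform-vector) mean and SD.
    """
    parent_idx = ped.parent_indices()
    n = len(ped)
    founders = [i for i in range(n) if parent_idx[i] is None]
    nonfounders = [i for i in range(n) if parent_idx[i] is not None]
    aff = [i for i in range(n) if affected[i]]
    if len(aff) < 2:
        return None
    bits = 2 * len(nonfounders)
    if bits > max_bits:
        return None

    slot_of_founder = {f: (2 * k, 2 * k + 1) for k, f in enumerate(founders)}
    n_slots = 2 * len(founders)
    freqs = np.array([marker_freq1, 1.0 - marker_freq1])

    # topological order of non-founders
    placed = set(founders)
    topo: list[int] = []
    pending = list(nonfounders)
    while pending:
        rest = []
        for i in pending:
            f, m = parent_idx[i]
            if f in placed and m in placed:
                topo.append(i)
                placed.add(i)
            else:
                rest.append(i)
        if len(rest) == len(pending):
            raise PedigreeError(f"family {ped.family_id}: unresolved parent order")
        pending = rest
    bit_index = {i: 2 * k for k, i in enumerate(topo)}

    typed = [i for i in range(n) if genotype_codes[i] > 0]
    obs_sets = {1: (0, 0), 2: (0, 1), 3: (1, 1)}  # sorted allele indices

    pairs = list(itertools.combinations(aff, 2))
    s_values = np.empty(2**bits)
    weights = np.empty(2**bits)
    for v in range(2**bits):
        slots: dict[int, tuple[int, int]] = dict(slot_of_founder)
        for i in topo:
            f, m = parent_idx[i]
            b = bit_index[i]
            slots[i] = (
                slots[f][(v >> b) & 1],
                slots[m][(v >> (b + 1)) & 1],
            )
        # sharing score
        tot = 0.0
        for a, bdx in pairs:
            pa, qa = slots[a]
            pb, qb = slots[bdx]
            share = max(
                (pa == pb) + (qa == qb),
                (pa == qb) + (qa == pb),
            )
            tot += share / 2.0
        s_values[v] = tot / len(pairs)
        # P(marker data | v): sum over founder-slot alleles, factorised
        # over connected components of the observation-constraint graph
        parent_slot = list(range(n_slots))

        def find(x: int) -> int:
            while parent_slot[x] != x:
                parent_slot[x] = parent_slot[parent_slot[x]]
                x = parent_slot[x]
            return x

        for i in typed:
            a, bslot = slots[i]
            ra, rb = find(a), find(bslot)
            if ra != rb:
                parent_slot[ra] = rb
        comp_slots: dict[int, list[int]] = {}
        for s in range(n_slots):
            comp_slots.setdefault(find(s), []).append(s)
        comp_typed: dict[int, list[int]] = {r: [] for r in comp_slots}
        for i in typed:
            comp_typed[find(slots[i][0])].append(i)
        w = 1.0
        for root, cslots in comp_slots.items():
            members = comp_typed[root]
            if not members:
                continue  # unconstrained slots integrate to 1
            pos = {s: k for k, s in enumerate(cslots)}
            total = 0.0
            for assign in itertools.product((0, 1), repeat=len(cslots)):
                ok = True
                for i in members:
                    a, bslot = slots[i]
                    got = tuple(sorted((assign[pos[a]], assign[pos[bslot]])))
                    if got != obs_sets[genotype_codes[i]]:
                        ok = False
                        break
                if ok:
                    pr = 1.0
                    for al in assign:
                        pr *= freqs[al]
                    total += pr
            w *= total
            if w == 0.0:
                break
        weights[v] = w

    wsum = weights.sum()
    if wsum <= 0:
        raise ImpossibleDataError(
            f"family {ped.family_id}: zero-probability marker configuration"
        )
    mu0 = s_values.mean()
    sd0 = s_values.std()
    if sd0 == 0:
        return None
    post_mean = float((weights / wsum) @ s_values)
    return (post_mean - mu0) / sd0


def npl_statistic(
    pedigrees: list[Pedigree],
    genotype_codes: list[np.ndarray],
    marker_freq1: float,
    affected_masks: list[np.ndarray],
    max_bits: int = 18,
) -> NplResult:
    """Combined nonparametric sharing statistic across families.

    Families combine with equal weights: Z = sum Z_i / sqrt(F).  One-sided
    p from the normal tail; families exceeding the inheritance-vector bit
    cap or with fewer than two affected members are skipped (counted).
    """
    zs = []
    skipped = 0
    for ped, codes, aff in zip(pedigrees, genotype_codes, affected_masks):
        z = _family_npl(ped, np.asarray(codes), marker_freq1, np.asarray(aff), max_bits)
        if z is None:
            skipped += 1
        else:
            zs.append(z)
    if not zs:
        return NplResult(0.0, 0.5, 0.0, 0, skipped, [])
    z_comb = float(np.sum(zs) / np.sqrt(len(zs)))
    p = float(stats.norm.sf(z_comb))
    lod_eq = pvalue_to_lod(min(max(p, 1e-300), 0.5))
    return NplResult(z_comb, p, lod_eq, len(zs), skipped, zs)


# ---------------------------------------------------------------------------
# LOD <-> p conversions


def lod_to_pvalue(lod: float) -> float:
    """One-sided p for a LOD score: p = 0.5 P[chi2_1 >= 2 ln(10) LOD].

    The 50:50 mixture accounts for the boundary at theta = 1/2; LOD 0
    maps to p = 0.5.
    """
    if lod < 0:
        raise LinkageError("LOD must be non-negative for p conversion")
    return float(0.5 * stats.chi2.sf(2.0 * LN10 * lod, df=1))


def pvalue_to_lod(p: float) -> float:
    """Inverse of :func:`lod_to_pvalue`; defined for p in (0, 0.5]."""
    if not 0 < p <= 0.5:
        raise LinkageError("p must be in (0, 0.5] for LOD conversion")
    return float(stats.chi2.isf(2.0 * p, df=1) / (2.0 * LN10))
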