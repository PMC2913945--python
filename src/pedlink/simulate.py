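"""Synthetic pedigrees, genotypes, and SRS-like phenotypes.

The generator emulates the statistical structure the analysis assumes:
multigenerational loop-free pedigrees in three size classes (large 6-9
generations, moderate 4-5, small 2-3, in 19:6:39 proportions by default),
a biallelic trait locus segregating under Hardy-Weinberg founder priors,
markers in linkage equilibrium dropped through the pedigree with Haldane
recombination, genotype-conditional trait distributions, age and sex
effects on the square-root score scale, spouse trait correlation through
a shared couple-level environmental component, and ascertainment of
families with at least two affected members.

Two phenotype mechanisms are supported, matching the two analysis model
families:

* quantitative specs draw an adjusted-scale trait x ~ N(mean_g, sd_g) and
  back-transform to a raw score, raw = max(0, intercept + beta_age*age +
  beta_male*male + x)^2;
* qualitative specs draw the category directly from the coherent
  factorisation P(affected|g) = f_affected[g], P(spectrum|g) =
  f_spectrum[g](1 - f_affected[g]) (the analysis penetrance triples are
  relative weights, not a multinomial), with a synthetic raw score drawn
  uniformly inside the category's score band.

For nuclear-family study designs (type-I-error calibration, locus
recovery) the module provides an *exact* ascertainment-conditioned
sampler: rejection sampling is infeasible at a disease allele frequency
of 0.05, so parent genotype pairs, affected configurations, and offspring
genotypes are drawn from their exact conditional distributions by
enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linkage
from .models import QualitativeModel, QuantitativeModel, recessive_model
from .pedigree import (
    FEMALE,
    MALE,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Pedigree,
)
from .phenotypes import AFFECTED, SPECTRUM, UNAFFECTED, categorize

CATEGORY_CODES = {UNAFFECTED: 0, SPECTRUM: 1, AFFECTED: 2}


class SimSpecError(ValueError):
    pass


@dataclass
class SimSpec:
    """Study-design parameters for the generator.

    Family-class counts default to the cohort composition (19 large, 6
    moderate, 39 small).  Trait-model parameters default to the analysis
    defaults; the spouse correlation targets 0.33 on the adjusted scale
    and the age/sex coefficients are -0.074 per year and +1.6 for males
    on the square-root score scale.
    """

    n_large: int = 19
    n_moderate: int = 6
    n_small: int = 39
    sibship_mean: float = 2.2  # 1 + Poisson(sibship_mean - 1)
    branch_prob: float = 0.2  # chance a non-spine child founds a new branch

    disease_model: QualitativeModel | QuantitativeModel = field(
        default_factory=QuantitativeModel
    )
    trait_chrom: str = "1"
    trait_cm: float = 10.0
    n_markers: int = 6
    spacing_cm: float = 5.0
    marker_freq1: float = 0.5
    n_unlinked_markers: int = 4
    unlinked_chrom: str = "2"
    alpha_sim: float = 1.0  # fraction of families whose trait locus is linked

    age_min: float = 3.0
    age_max: float = 80.0
    adult_age: float = 18.0  # child vs adult SRS version boundary
    sqrt_intercept: float = 10.0
    beta_age: float = -0.074
    beta_male: float = 1.6
    spouse_corr: float = 0.33

    missing_srs_rate: float = 0.1
    missing_genotype_rate: float = 0.0
    rater_asd_rate: float = 0.01
    rater_poor_rate: float = 0.008

    min_affected: int = 2  # ascertainment; 0 disables
    max_ascertainment_tries: int = 200

    def __post_init__(self) -> None:
        if not 0 <= self.alpha_sim <= 1:
            raise SimSpecError("alpha_sim must be in [0, 1]")
        if not 0 <= self.spouse_corr < 1:
            raise SimSpecError("spouse correlation must be in [0, 1)")
        if self.spacing_cm <= 0:
            raise SimSpecError("marker spacing must be positive")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated data set."""

    disease_genotype: dict[tuple[str, str], int]  # (family, indiv) -> 0/1/2
    linked: dict[str, bool]  # family -> trait locus linked to markers
    latent_trait: dict[tuple[str, str], float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family_id": f,
                "indiv_id": i,
                "disease_genotype": g,
                "linked": int(self.linked[f]),
                "latent_trait": self.latent_trait.get((f, i), np.nan),
            }
            for (f, i), g in self.disease_genotype.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pedigree growth


def _sibship(spec: SimSpec, rng: np.random.Generator) -> int:
    return 1 + rng.poisson(max(spec.sibship_mean - 1.0, 0.0))


def _grow_family(
    family_id: str, generations: int, spec: SimSpec, rng: np.random.Generator
) -> Pedigree:
    """Grow one loop-free family top-down to the requested depth.

    A designated "spine" child per generation always marries in a founder
    spouse and reproduces, guaranteeing the generation count; other
    children found branches with probability ``branch_prob`` (branches
    stop short of the full depth at random)."""
    if generations < 2:
        raise SimSpecError("a family needs at least 2 generations")
    members: list[Individual] = []
    counter = itertools.count(1)

    def new_id() -> str:
        return str(next(counter))

    def add_founder(sex: str) -> str:
        iid = new_id()
        members.append(Individual(family_id, iid, None, None, sex))
        return iid

    def add_child(father: str, mother: str, sex: str) -> str:
        iid = new_id()
        members.append(Individual(family_id, iid, father, mother, sex))
        return iid

    def expand(father: str, mother: str, depth_left: int, is_spine: bool) -> None:
        # this couple sits depth_left generations above the deepest target
        k = _sibship(spec, rng)
        sexes = [MALE if rng.random() < 0.5 else FEMALE for _ in range(k)]
        kids = [add_child(father, mother, s) for s in sexes]
        if depth_left <= 1:
            return
        spine_idx = int(rng.integers(k)) if is_spine else -1
        for idx, kid in enumerate(kids):
            if idx == spine_idx:
                reproduce, depth = True, depth_left - 1
            elif rng.random() < spec.branch_prob:
                reproduce = True
                depth = int(rng.integers(1, depth_left))  # branch may stop early
            else:
                reproduce, depth = False, 0
            if reproduce and depth >= 1:
                spouse = add_founder(FEMALE if sexes[idx] == MALE else MALE)
                fa, mo = (kid, spouse) if sexes[idx] == MALE else (spouse, kid)
                expand(fa, mo, depth, idx == spine_idx)

    fa = add_founder(MALE)
    mo = add_founder(FEMALE)
    expand(fa, mo, generations - 1, True)
    return Pedigree(family_id, members)


def generate_pedigrees(spec: SimSpec, rng: np.random.Generator) -> list[Pedigree]:
    """Generate families in the three size classes, ids "F1", "F2", ..."""
    plans = (
        [(6, 9)] * spec.n_large + [(4, 5)] * spec.n_moderate + [(2, 3)] * spec.n_small
    )
    peds = []
    for i, (lo, hi) in enumerate(plans, start=1):
        g = int(rng.integers(lo, hi + 1))
        peds.append(_grow_family(f"F{i}", g, spec, rng))
    return peds


# ---------------------------------------------------------------------------
# gene dropping


def simulated_map(spec: SimSpec) -> GeneticMap:
    """Marker map implied by the spec: a linked chromosome (with the trait
    locus between/at its markers) plus an unlinked chromosome."""
    ids = [f"M{i + 1}" for i in range(spec.n_markers + spec.n_unlinked_markers)]
    chroms = [spec.trait_chrom] * spec.n_markers + [
        spec.unlinked_chrom
    ] * spec.n_unlinked_markers
    cm = np.concatenate(
        [
            np.arange(spec.n_markers) * spec.spacing_cm,
            np.arange(spec.n_unlinked_markers) * spec.spacing_cm,
        ]
    )
    bp = (cm * 1_000_000).astype(np.int64) + 1
    return GeneticMap(ids, chroms, cm, bp, np.full(len(ids), spec.marker_freq1))


def trait_marker_index(spec: SimSpec) -> int:
    """Index of the map marker closest to the trait locus."""
    cm = np.arange(spec.n_markers) * spec.spacing_cm
    return int(np.argmin(np.abs(cm - spec.trait_cm)))


def gene_drop(
    peds: list[Pedigree], spec: SimSpec, rng: np.random.Generator
) -> tuple[GenotypeMatrix, GeneticMap, SimTruth]:
    """Drop founder haplotypes through each pedigree.

    Founder alleles are i.i.d. draws from the allele frequencies; each
    meiosis transmits a haplotype built by a Markov walk along the locus
    order with switch probability given by the Haldane map function.  In
    unlinked families (probability 1 - alpha_sim) the trait locus
    segregates independently of every marker.
    """
    gmap = simulated_map(spec)
    q = spec.disease_model.disease_allele_freq
    n_loci = len(gmap)

    # locus layout: linked chromosome markers (with trait inserted), then
    # unlinked chromosome markers
    linked_cm = list(gmap.positions_cm[: spec.n_markers])
    trait_pos = float(spec.trait_cm)

    all_rows: list[tuple[str, str]] = []
    alleles = []
    truth = SimTruth({}, {})
    for ped in peds:
        linked = bool(rng.random() < spec.alpha_sim)
        truth.linked[ped.family_id] = linked
        # haplotypes[i] = (2, n_loci) marker alleles in {0,1}; disease[i] = (2,)
        haplo: dict[int, np.ndarray] = {}
        dis: dict[int, np.ndarray] = {}
        parent_idx = ped.parent_indices()
        for i, pi in enumerate(parent_idx):
            if pi is None:
                haplo[i] = (rng.random((2, n_loci)) >= spec.marker_freq1).astype(np.int8)
                dis[i] = (rng.random(2) < q).astype(np.int8)
            else:
                h = np.empty((2, n_loci), dtype=np.int8)
                d = np.empty(2, dtype=np.int8)
                for slot, parent in enumerate(pi):
                    h[slot], d[slot] = _meiosis(
                        haplo[parent], dis[parent], linked_cm, trait_pos,
                        spec.n_markers, linked, rng
                    )
                haplo[i] = h
                dis[i] = d
        for i, m in enumerate(ped.members):
            g = int(dis[i].sum())
            truth.disease_genotype[(ped.family_id, m.indiv_id)] = g
            all_rows.append((ped.family_id, m.indiv_id))
            alleles.append(np.sort(haplo[i] + 1, axis=0).T)  # (n_loci, 2)

    arr = np.asarray(alleles, dtype=np.int8)
    if spec.missing_genotype_rate > 0:
        drop = rng.random(arr.shape[:2]) < spec.missing_genotype_rate
        arr[drop] = 0
    gm = GenotypeMatrix(arr, all_rows, list(gmap.marker_ids))
    return gm, gmap, truth


def _meiosis(
    parent_haplo: np.ndarray,
    parent_dis: np.ndarray,
    linked_cm: list[float],
    trait_pos: float,
    n_linked: int,
    linked: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One gamete: marker alleles (n_loci,) and the transmitted disease allele."""
    n_loci = parent_haplo.shape[1]
    out = np.empty(n_loci, dtype=np.int8)
    # linked chromosome: walk along sorted positions incl. the trait locus
    positions = sorted(set(linked_cm) | {trait_pos}) if linked else sorted(linked_cm)
    cur = int(rng.integers(2))
    chain: dict[float, int] = {}
    prev = None
    for pos in positions:
        if prev is not None:
            theta = float(linkage.haldane_theta(pos - prev))
            if rng.random() < theta:
                cur = 1 - cur
        chain[pos] = cur
        prev = pos
    for j in range(n_linked):
        out[j] = parent_haplo[chain[linked_cm[j]], j]
    if linked:
        d = int(parent_dis[chain[trait_pos]])
    else:
        d = int(parent_dis[rng.integers(2)])
    # unlinked chromosome: an independent walk with the same marker spacing
    n_unlinked = n_loci - n_linked
    if n_unlinked:
        spacing = linked_cm[1] - linked_cm[0] if len(linked_cm) > 1 else 5.0
        theta = float(linkage.haldane_theta(spacing))
        cur = int(rng.integers(2))
        for j in range(n_linked, n_loci):
            if j > n_linked and rng.random() < theta:
                cur = 1 - cur
            out[j] = parent_haplo[cur, j]
    return out, d


# ---------------------------------------------------------------------------
# phenotypes


def _category_probs(model: QualitativeModel) -> np.ndarray:
    """Coherent per-genotype category multinomial implied by the model:
    rows g = 0,1,2; columns unaffected/spectrum/affected."""
    fa = np.asarray(model.f_affected)
    fs = np.asarray(model.f_spectrum)
    p_aff = fa
    p_spec = fs * (1 - fa)
    return np.column_stack([1 - p_aff - p_spec, p_spec, p_aff])


_CATEGORY_BANDS = {0: (0.0, 53.0), 1: (54.0, 86.0), 2: (87.0, 165.0)}


def simulate_phenotypes(
    peds: list[Pedigree],
    truth: SimTruth,
    spec: SimSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotype table for simulated families (one row per individual).

    Under a quantitative disease model, draws the latent adjusted trait
    from the genotype's normal distribution (with the couple-shared
    component inducing the spouse correlation) and back-transforms to a
    raw score.  Under a qualitative model, draws the category directly
    and a synthetic raw score uniform inside the category's band.  With
    ascertainment enabled, families are re-drawn until at least
    ``min_affected`` members are affected (capped number of tries).
    """
    rows = []
    for ped in peds:
        for attempt in range(max(spec.max_ascertainment_tries, 1)):
            fam_rows = _simulate_family_phenotypes(ped, truth, spec, rng)
            if spec.min_affected <= 0:
                break
            n_aff = sum(r["category_code"] == 2 for r in fam_rows)
            if n_aff >= spec.min_affected:
                break
        else:
            raise SimSpecError(
                f"family {ped.family_id}: ascertainment (>= {spec.min_affected} "
                f"affected) not met in {spec.max_ascertainment_tries} tries"
            )
        rows.extend(fam_rows)

    df = pd.DataFrame(rows)
    # missingness and rater flags
    n = len(df)
    missing = rng.random(n) < spec.missing_srs_rate
    df.loc[missing, "raw_srs"] = np.nan
    df["rater_has_asd"] = rng.random(n) < spec.rater_asd_rate
    df["rater_poor"] = rng.random(n) < spec.rater_poor_rate
    df = df.drop(columns=["category_code"])
    return df[
        [
            "indiv_id",
            "family_id",
            "raw_srs",
            "version",
            "age",
            "sex",
            "rater_has_asd",
            "rater_poor",
            "clinical_dx",
        ]
    ]


def _simulate_family_phenotypes(
    ped: Pedigree, truth: SimTruth, spec: SimSpec, rng: np.random.Generator
) -> list[dict]:
    n = len(ped)
    ages = rng.uniform(spec.age_min, spec.age_max, size=n)
    male = np.array([m.sex == MALE for m in ped.members], dtype=float)
    g = np.array(
        [truth.disease_genotype[(ped.family_id, m.indiv_id)] for m in ped.members]
    )
    model = spec.disease_model
    if isinstance(model, QuantitativeModel):
        # couple-shared environmental component induces the spouse correlation
        couple_of: dict[int, int] = {}
        couples: list[tuple[int, int]] = []
        seen = {}
        for m in ped.members:
            if m.father_id is None:
                continue
            key = (m.father_id, m.mother_id)
            if key not in seen:
                seen[key] = len(couples)
                couples.append((ped.index_of(m.father_id), ped.index_of(m.mother_id)))
        for ci, (fa, mo) in enumerate(couples):
            couple_of[fa] = ci
            couple_of[mo] = ci
        shared = rng.normal(size=len(couples))
        z = rng.normal(size=n)
        rho = spec.spouse_corr
        e = np.where(
            [i in couple_of for i in range(n)],
            np.sqrt(rho) * np.array([shared[couple_of.get(i, 0)] for i in range(n)])
            + np.sqrt(1 - rho) * z,
            z,
        )
        means = np.asarray(model.means)[g]
        sds = np.asarray(model.sds)[g]
        x = means + sds * e
        s = spec.sqrt_intercept + spec.beta_age * ages + spec.beta_male * male + x
        raw = np.maximum(s, 0.0) ** 2
        codes = np.array([CATEGORY_CODES[categorize(v)] for v in raw])
        latent = x
    else:
        probs = _category_probs(model)
        u = rng.random(n)
        cum = probs[g].cumsum(axis=1)
        codes = (u[:, None] >= cum).sum(axis=1)  # 0 unaff, 1 spec, 2 aff
        raw = np.array(
            [rng.uniform(*_CATEGORY_BANDS[int(c)]) for c in codes]
        )
        latent = np.full(n, np.nan)

    rows = []
    for i, m in enumerate(ped.members):
        truth.latent_trait[(ped.family_id, m.indiv_id)] = float(latent[i])
        dx = "none"
        if codes[i] == 2:
            dx = "autism" if rng.random() < 0.7 else "asd"
        rows.append(
            {
                "indiv_id": m.indiv_id,
                "family_id": ped.family_id,
                "raw_srs": float(raw[i]),
                "version": "child" if ages[i] < spec.adult_age else "adult",
                "age": float(np.round(ages[i], 1)),
                "sex": m.sex,
                "clinical_dx": dx,
                "category_code": int(codes[i]),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(
    peds: list[Pedigree],
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    phenotypes: pd.DataFrame | None,
    truth: SimTruth | None,
    out_dir,
) -> dict[str, str]:
    """Write PED/MAP/phenotype/truth files readable by the package readers."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ped": os.path.join(out_dir, "data.ped"),
        "map": os.path.join(out_dir, "data.map"),
    }
    with open(paths["ped"], "w") as fh:
        for ped in peds:
            for m in ped.members:
                row = genotypes.row_of(ped.family_id, m.indiv_id)
                sex = {"male": "1", "female": "2", "unknown": "0"}[m.sex]
                al = genotypes.alleles[row].ravel()
                fh.write(
                    " ".join(
                        [
                            ped.family_id,
                            m.indiv_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            sex,
                            m.phenotype or "0",
                        ]
                        + [str(int(a)) for a in al]
                    )
                    + "\n"
                )
    with open(paths["map"], "w") as fh:
        for i, mid in enumerate(gmap.marker_ids):
            fh.write(
                f"{gmap.chromosomes[i]} {mid} {gmap.positions_cm[i]:.4f} "
                f"{int(gmap.positions_bp[i])}\n"
            )
    if phenotypes is not None:
        paths["pheno"] = os.path.join(out_dir, "phenotypes.tsv")
        phenotypes.to_csv(paths["pheno"], sep="\t", index=False)
    if truth is not None:
        paths["truth"] = os.path.join(out_dir, "truth.tsv")
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# exact ascertainment-conditioned nuclear families


def _mendelian_table(q: float) -> np.ndarray:
    """T[gf, gm, gc]: offspring genotype distribution given parents."""
    t = np.zeros((3, 3, 3))
    for gf in range(3):
        for gm in range(3):
            af, am = gf / 2.0, gm / 2.0
            t[gf, gm, 0] = (1 - af) * (1 - am)
            t[gf, gm, 1] = af * (1 - am) + (1 - af) * am
            t[gf, gm, 2] = af * am
    return t


@dataclass
class NuclearBatch:
    """Vectorised batch of ascertained nuclear families (fixed sibship)."""

    sibship: int
    parent_g: np.ndarray  # (n, 2) disease genotypes father, mother
    kid_g: np.ndarray  # (n, k)
    categories: np.ndarray  # (n, 2 + k) codes 0/1/2, parents first
    kid_pat: np.ndarray  # (n, k) transmitted paternal disease allele
    kid_mat: np.ndarray  # (n, k)

    @property
    def n(self) -> int:
        return len(self.parent_g)

    @property
    def members(self) -> int:
        return 2 + self.sibship


def sample_ascertained_nuclear(
    n_families: int,
    sibship: int,
    model: QualitativeModel,
    rng: np.random.Generator,
    min_affected: int = 2,
) -> NuclearBatch:
    """Exact sample of nuclear families conditioned on >= ``min_affected``
    affected members (parents count).

    Sampling proceeds by enumeration: parent genotype pairs from their
    exact posterior given ascertainment, then the affected configuration
    from its conditional distribution (members are independent given the
    parent pair), then offspring genotypes given their own affected
    status, then the spectrum/unaffected split.
    """
    q = model.disease_allele_freq
    hw = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
    f_aff = np.asarray(model.f_affected)
    f_spec = np.asarray(model.f_spectrum)
    trans = _mendelian_table(q)
    m_members = 2 + sibship

    combos = [(gf, gm) for gf in range(3) for gm in range(3)]
    config_list = [
        c for c in itertools.product((0, 1), repeat=m_members) if sum(c) >= min_affected
    ]
    cfg_arr = np.array(config_list)  # (C, M)

    combo_w = np.empty(9)
    cfg_probs = np.empty((9, len(config_list)))
    for ci, (gf, gm) in enumerate(combos):
        p_kid = trans[gf, gm] @ f_aff
        p_members = np.array([f_aff[gf], f_aff[gm]] + [p_kid] * sibship)
        probs = np.prod(
            np.where(cfg_arr == 1, p_members, 1 - p_members), axis=1
        )
        a = probs.sum()  # P(>= min_affected | parent pair)
        combo_w[ci] = hw[gf] * hw[gm] * a
        cfg_probs[ci] = probs / a if a > 0 else 0.0

    combo_w /= combo_w.sum()
    combo_idx = rng.choice(9, size=n_families, p=combo_w)
    parent_g = np.array([combos[c] for c in combo_idx])

    aff = np.empty((n_families, m_members), dtype=np.int64)
    for ci in range(9):
        mask = combo_idx == ci
        if not mask.any():
            continue
        picks = rng.choice(len(config_list), size=int(mask.sum()), p=cfg_probs[ci])
        aff[mask] = cfg_arr[picks]

    # offspring genotypes | parent pair and own affected status
    kid_g = np.empty((n_families, sibship), dtype=np.int64)
    for ci, (gf, gm) in enumerate(combos):
        for a in (0, 1):
            w = trans[gf, gm] * (f_aff if a else (1 - f_aff))
            if w.sum() == 0:
                continue
            w = w / w.sum()
            for k in range(sibship):
                mask = (combo_idx == ci) & (aff[:, 2 + k] == a)
                cnt = int(mask.sum())
                if cnt:
                    kid_g[mask, k] = rng.choice(3, size=cnt, p=w)

    # categories: affected -> 2; else spectrum with prob f_spectrum[g]
    all_g = np.concatenate([parent_g, kid_g], axis=1)  # (n, M)
    spec_draw = rng.random((n_families, m_members)) < f_spec[all_g]
    categories = np.where(aff == 1, 2, np.where(spec_draw, 1, 0)).astype(np.int64)

    # transmitted-allele resolution for linked marker dropping:
    # P(pat, mat | kid_g, parents) proportional to P(pat|gf) P(mat|gm)
    kid_pat = np.empty_like(kid_g)
    kid_mat = np.empty_like(kid_g)
    for ci, (gf, gm) in enumerate(combos):
        af, am = gf / 2.0, gm / 2.0
        for gk in range(3):
            pairs = [(p, m) for p in (0, 1) for m in (0, 1) if p + m == gk]
            w = np.array(
                [(af if p else 1 - af) * (am if m else 1 - am) for p, m in pairs]
            )
            if w.sum() == 0:
                continue
            w = w / w.sum()
            for k in range(sibship):
                mask = (combo_idx == ci) & (kid_g[:, k] == gk)
                cnt = int(mask.sum())
                if cnt:
                    pick = rng.choice(len(pairs), size=cnt, p=w)
                    kid_pat[mask, k] = [pairs[i][0] for i in pick]
                    kid_mat[mask, k] = [pairs[i][1] for i in pick]

    return NuclearBatch(sibship, parent_g, kid_g, categories, kid_pat, kid_mat)


def drop_unlinked_marker(
    batch: NuclearBatch, freq1: float, rng: np.random.Generator
) -> np.ndarray:
    """Genotype codes (n, M) for one marker segregating independently of
    the trait: founder alleles i.i.d., offspring alleles by fair meiosis."""
    n, k = batch.n, batch.sibship
    par = (rng.random((n, 2, 2)) >= freq1).astype(np.int64)  # 0 = allele "1"
    pick_p = rng.integers(2, size=(n, k))
    pick_m = rng.integers(2, size=(n, k))
    kid_a = np.take_along_axis(par[:, 0, :], pick_p, axis=1)
    kid_b = np.take_along_axis(par[:, 1, :], pick_m, axis=1)
    codes = np.empty((n, 2 + k), dtype=np.int64)
    codes[:, 0] = par[:, 0].sum(axis=1) + 1
    codes[:, 1] = par[:, 1].sum(axis=1) + 1
    codes[:, 2:] = kid_a + kid_b + 1
    return codes


def drop_linked_markers(
    batch: NuclearBatch,
    positions_cm: np.ndarray,
    trait_cm: float,
    freq1: float,
    rng: np.random.Generator,
    linked: np.ndarray | None = None,
) -> np.ndarray:
    """Genotype codes (n, M, L) for markers on the trait chromosome.

    Parental phase is drawn uniformly; each meiosis is constrained at the
    trait locus to carry the disease allele the offspring actually
    received, and marker inheritance follows a Haldane Markov walk
    outward from the trait locus.  Families flagged False in ``linked``
    segregate the trait independently (free recombination with every
    marker)."""
    n, k = batch.n, batch.sibship
    pos = np.asarray(positions_cm, dtype=float)
    n_loci = len(pos)
    if linked is None:
        linked = np.ones(n, dtype=bool)

    # parent haplotype marker alleles, (n, 2 parents, 2 slots, L)
    hap = (rng.random((n, 2, 2, n_loci)) >= freq1).astype(np.int64)
    # slot carrying the risk allele for heterozygous parents
    het_slot = rng.integers(2, size=(n, 2))
    # disease allele per slot: g=0 -> (0,0), g=2 -> (1,1), g=1 -> one slot
    slot_dis = np.zeros((n, 2, 2), dtype=np.int64)
    for p in (0, 1):
        g = batch.parent_g[:, p]
        slot_dis[g == 2, p, :] = 1
        hz = g == 1
        slot_dis[hz, p, 0] = het_slot[hz, p] == 0
        slot_dis[hz, p, 1] = het_slot[hz, p] == 1

    # meiosis indicator at the trait locus, per (family, kid, parent)
    trans_allele = np.stack([batch.kid_pat, batch.kid_mat], axis=2)  # (n, k, 2)
    start = np.empty((n, k, 2), dtype=np.int64)
    for p in (0, 1):
        g = batch.parent_g[:, p][:, None]
        forced = (g == 1) & linked[:, None]
        choose = np.where(
            trans_allele[:, :, p] == (het_slot[:, p][:, None] == 0).astype(int), 0, 1
        )
        # hom parents (or unlinked families): unconstrained start
        free = rng.integers(2, size=(n, k))
        start[:, :, p] = np.where(forced, choose, free)

    # walk outward from the trait position across sorted marker gaps
    codes = np.empty((n, 2 + k, n_loci), dtype=np.int64)
    ind = np.empty((n, k, 2, n_loci), dtype=np.int64)
    # distance-ordered walk: left and right sequences from the trait locus
    left = sorted([j for j in range(n_loci) if pos[j] <= trait_cm], key=lambda j: -pos[j])
    right = sorted([j for j in range(n_loci) if pos[j] > trait_cm], key=lambda j: pos[j])
    for seq in (left, right):
        prev_pos = trait_cm
        cur = start.copy()
        for j in seq:
            theta = float(linkage.haldane_theta(abs(pos[j] - prev_pos)))
            theta_eff = np.where(linked, theta, 0.5)  # (n,)
            flip = rng.random((n, k, 2)) < theta_eff[:, None, None]
            cur = np.where(flip, 1 - cur, cur)
            ind[:, :, :, j] = cur
            prev_pos = pos[j]

    for j in range(n_loci):
        codes[:, 0, j] = hap[:, 0, :, j].sum(axis=1) + 1
        codes[:, 1, j] = hap[:, 1, :, j].sum(axis=1) + 1
        for p in (0, 1):
            sel = ind[:, :, p, j]  # (n, k) slot choice
            al = np.take_along_axis(hap[:, p, :, j], sel, axis=1)
            if p == 0:
                kid_a = al
            else:
                kid_b = al
        codes[:, 2:, j] = kid_a + kid_b + 1
    return codes


def nuclear_plan(sibship: int) -> linkage.PeelingPlan:
    """Peeling plan for father, mother, then ``sibship`` children."""
    return linkage.PeelingPlan(tuple([None, None] + [(0, 1)] * sibship))


def batch_lod_curves(
    batch: NuclearBatch,
    codes: np.ndarray,
    model: QualitativeModel,
    marker_freq1: float,
    theta_grid: tuple[float, ...] = linkage.THETA_GRID,
    chunk: int = 100_000,
) -> np.ndarray:
    """Per-family LOD curves (n, T) for a batch of nuclear families at one
    marker.  ``codes`` is (n, M) genotype codes."""
    plan = nuclear_plan(batch.sibship)
    weights = np.stack(
        [
            model.category_weights(UNAFFECTED),
            model.category_weights(SPECTRUM),
            model.category_weights(AFFECTED),
        ]
    )
    pw = weights[batch.categories]  # (n, M, 3)
    out = np.empty((batch.n, len(theta_grid)))
    for lo in range(0, batch.n, chunk):
        hi = min(lo + chunk, batch.n)
        unary = linkage.build_unary(
            plan, codes[lo:hi], pw[lo:hi], model.disease_allele_freq, marker_freq1
        )
        ll = np.stack(
            [linkage.peel_loglik(plan, unary, th) for th in theta_grid], axis=1
        )
        base = ll[:, theta_grid.index(0.5)]
        out[lo:hi] = np.maximum((ll - base[:, None]) / linkage.LN10, linkage.LOD_FLOOR)
    return out


# ---------------------------------------------------------------------------
# study designs


def null_lod_exceedance(
    n_replicates: int,
    n_families: int,
    rng: np.random.Generator,
    sibship: int = 3,
    model: QualitativeModel | None = None,
    marker_freq1: float = 0.7,
    threshold: float = 1.88,
    theta_grid: tuple[float, ...] = linkage.THETA_GRID,
) -> dict:
    """Type-I-error calibration: fraction of null replicates whose pooled
    parametric LOD (maximised over theta) reaches ``threshold``.

    Each replicate holds ``n_families`` ascertained nuclear families; the
    test marker (MAF = min(freq1, 1-freq1)) segregates independently of
    the trait, so every exceedance is a false positive.
    """
    model = model or recessive_model()
    total = n_replicates * n_families
    batch = sample_ascertained_nuclear(total, sibship, model, rng)
    codes = drop_unlinked_marker(batch, marker_freq1, rng)
    lods = batch_lod_curves(batch, codes, model, marker_freq1, theta_grid)
    pooled = lods.reshape(n_replicates, n_families, -1).sum(axis=1)
    max_lod = pooled.max(axis=1)
    exceed = float((max_lod >= threshold).mean())
    return {
        "exceedance": exceed,
        "n_replicates": n_replicates,
        "n_exceed": int((max_lod >= threshold).sum()),
        "max_lods": max_lod,
    }


def linked_recovery_study(
    n_families: int,
    rng: np.random.Generator,
    model: QualitativeModel | None = None,
    sibships: tuple[int, ...] = (2, 3, 4),
    n_linked: int = 6,
    spacing_cm: float = 5.0,
    trait_marker: int = 2,
    n_unlinked: int = 4,
    marker_freq1: float = 0.5,
    alpha_sim: float = 1.0,
    theta_grid: tuple[float, ...] = linkage.THETA_GRID,
) -> dict:
    """Planted-locus recovery: ascertained nuclear families segregating
    the trait locus at marker ``trait_marker`` of a ``spacing_cm``-spaced
    map, scanned per marker (plus an unlinked chromosome).

    Returns the per-marker HLOD results, the index of the best marker,
    and the admixture estimate at the trait marker.
    """
    model = model or recessive_model()
    pos = np.arange(n_linked) * spacing_cm
    trait_cm = float(pos[trait_marker])
    sizes = rng.choice(sibships, size=n_families)
    fam_lods = np.empty((n_families, n_linked + n_unlinked, len(theta_grid)))
    row = 0
    for k in sorted(set(sizes.tolist())):
        nk = int((sizes == k).sum())
        if nk == 0:
            continue
        batch = sample_ascertained_nuclear(nk, int(k), model, rng)
        linked = rng.random(nk) < alpha_sim
        codes_linked = drop_linked_markers(
            batch, pos, trait_cm, marker_freq1, rng, linked=linked
        )
        for j in range(n_linked):
            fam_lods[row : row + nk, j] = batch_lod_curves(
                batch, codes_linked[:, :, j], model, marker_freq1, theta_grid
            )
        for j in range(n_unlinked):
            codes_u = drop_unlinked_marker(batch, marker_freq1, rng)
            fam_lods[row : row + nk, n_linked + j] = batch_lod_curves(
                batch, codes_u, model, marker_freq1, theta_grid
            )
        row += nk

    results = [
        linkage.hlod(fam_lods[:, j], theta_grid) for j in range(n_linked + n_unlinked)
    ]
    hlods = np.array([r.hlod for r in results])
    return {
        "results": results,
        "hlods": hlods,
        "best_marker": int(np.argmax(hlods)),
        "trait_marker": trait_marker,
        "alpha_at_trait": results[trait_marker].alpha,
        "n_linked": n_linked,
    }
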