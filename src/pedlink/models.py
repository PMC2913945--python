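"""Disease models: qualitative liability-class penetrances and the
quantitative three-normal penetrance with equal-width discretization.

A penetrance vector gives, per disease-locus genotype g in {0, 1, 2 risk
alleles}, the relative likelihood of the observed phenotype.  Only ratios
matter — the linkage statistic is a likelihood ratio — so vectors are
scale-free.

Qualitative models use two liability classes (the "spectrum" and the
"affected" score categories).  The unaffected category has no published
penetrance row; the default treats "not even spectrum" as the complement
of the spectrum row, 1 - f_spectrum[g].  Set ``unaffected_as_unknown``
to make unaffected individuals uninformative instead.

The quantitative model assigns each genotype a normal trait distribution
(defaults below are the category-derived values for the adjusted
square-root SRS scale).  For speed the density is discretized into 40
equal-width classes spanning mean0 - 3 sd0 to mean2 + 3 sd2, and an
individual's vector is the three densities at the midpoint of the class
containing their trait value.  Values outside the range clamp to the
first/last class: regression residuals can legitimately exceed +-3 sd.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phenotypes import AFFECTED, SPECTRUM, UNAFFECTED, UNKNOWN


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class QualitativeModel:
    name: str
    disease_allele_freq: float
    f_spectrum: tuple[float, float, float]
    f_affected: tuple[float, float, float]
    unaffected_as_unknown: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.disease_allele_freq < 1:
            raise ModelError("disease allele frequency must be in (0, 1)")
        for trip in (self.f_spectrum, self.f_affected):
            if len(trip) != 3 or any(not 0 <= f <= 1 for f in trip):
                raise ModelError("penetrances must be triples in [0, 1]")

    def category_weights(self, category: str) -> np.ndarray:
        """Penetrance vector (length 3) for a qualitative category."""
        if category == SPECTRUM:
            return np.asarray(self.f_spectrum, dtype=float)
        if category == AFFECTED:
            return np.asarray(self.f_affected, dtype=float)
        if category == UNAFFECTED:
            if self.unaffected_as_unknown:
                return np.ones(3)
            return 1.0 - np.asarray(self.f_spectrum, dtype=float)
        if category == UNKNOWN:
            return np.ones(3)
        raise ModelError(f"unknown phenotype category {category!r}")


def recessive_model(**overrides) -> QualitativeModel:
    """Recessive model: allele freq 0.05; spectrum 0.01/0.01/0.5,
    affected 0.0014/0.0014/0.8."""
    kw = dict(
        name="recessive",
        disease_allele_freq=0.05,
        f_spectrum=(0.01, 0.01, 0.5),
        f_affected=(0.0014, 0.0014, 0.8),
    )
    kw.update(overrides)
    return QualitativeModel(**kw)


def dominant_model(**overrides) -> QualitativeModel:
    """Dominant model: allele freq 0.0025; spectrum 0.01/0.5/0.5,
    affected 0.0014/0.8/0.8."""
    kw = dict(
        name="dominant",
        disease_allele_freq=0.0025,
        f_spectrum=(0.01, 0.5, 0.5),
        f_affected=(0.0014, 0.8, 0.8),
    )
    kw.update(overrides)
    return QualitativeModel(**kw)


def qualitative_penetrance(model: QualitativeModel, category: str, genotype: int) -> float:
    """Likelihood weight for one (category, genotype) combination."""
    if genotype not in (0, 1, 2):
        raise ModelError(f"genotype must be 0, 1 or 2 risk alleles, got {genotype}")
    return float(model.category_weights(category)[genotype])


# ---------------------------------------------------------------------------
# quantitative model


@dataclass(frozen=True)
class QuantitativeModel:
    means: tuple[float, float, float] = (-1.552, 1.184, 2.558)
    sds: tuple[float, float, float] = (2.238, 1.581, 1.356)
    n_classes: int = 40
    # genotype priors need an allele frequency; the recessive value is the
    # default and can be overridden in config
    disease_allele_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ModelError("need at least 2 trait classes")
        if any(s <= 0 for s in self.sds):
            raise ModelError("trait standard deviations must be positive")
        if not 0 < self.disease_allele_freq < 1:
            raise ModelError("disease allele frequency must be in (0, 1)")

    @property
    def lower(self) -> float:
        return self.means[0] - 3 * self.sds[0]

    @property
    def upper(self) -> float:
        return self.means[2] + 3 * self.sds[2]

    @property
    def class_width(self) -> float:
        return (self.upper - self.lower) / self.n_classes


@dataclass
class QuantClasses:
    model: QuantitativeModel
    midpoints: np.ndarray  # (n_classes,)
    vectors: np.ndarray  # (n_classes, 3) normal densities at midpoints

    def vector_for(self, x: float | None) -> np.ndarray:
        """Penetrance vector of the class containing x (clamped); missing
        trait values are uninformative, (1, 1, 1)."""
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return np.ones(3)
        k = int(np.floor((x - self.model.lower) / self.model.class_width))
        k = min(max(k, 0), self.model.n_classes - 1)
        return self.vectors[k]


def build_quant_classes(model: QuantitativeModel) -> QuantClasses:
    """Tabulate class midpoints and their three-normal density vectors."""
    k = np.arange(model.n_classes)
    mids = model.lower + (k + 0.5) * model.class_width
    vecs = np.column_stack(
        [stats.norm.pdf(mids, loc=model.means[g], scale=model.sds[g]) for g in range(3)]
    )
    return QuantClasses(model, mids, vecs)


def trait_density_vector(x: float, model: QuantitativeModel) -> np.ndarray:
    """Un-discretized penetrance vector: the three normal densities at x."""
    return np.array(
        [stats.norm.pdf(x, loc=model.means[g], scale=model.sds[g]) for g in range(3)]
    )


def quant_penetrance_vector(x: float | None, classes: QuantClasses) -> np.ndarray:
    return classes.vector_for(x)


# ---------------------------------------------------------------------------
# config plumbing


def genotype_priors(freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype priors (g = 0, 1, 2 risk alleles)."""
    q = freq
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


def model_from_dict(cfg: dict):
    """Build a model from a YAML/JSON-style mapping.

    ``{"name": "recessive"}`` / ``{"name": "dominant"}`` load the default
    qualitative models; ``{"name": "quantitative", ...}`` loads the
    quantitative model.  Any field can be overridden.
    """
    cfg = dict(cfg)
    name = cfg.pop("name", "recessive")
    if name == "recessive":
        return recessive_model(**cfg)
    if name == "dominant":
        return dominant_model(**cfg)
    if name == "quantitative":
        for key in ("means", "sds"):
            if key in cfg:
                cfg[key] = tuple(cfg[key])
        return QuantitativeModel(**cfg)
    raise ModelError(f"unknown model name {name!r}")
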