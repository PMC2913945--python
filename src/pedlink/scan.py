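"""Genome-scan orchestration and reporting.

Runs the full pipeline — pedigree/map/phenotype loading, marker QC,
phenotype processing, per-marker parametric (LOD/HLOD) and nonparametric
scans under up to five models (qualitative dominant, recessive and NPL;
quantitative parametric and NPL) — then calls peaks against the
suggestive (LOD 1.88) and significant (LOD 3.30) thresholds and writes
delimited result tables.

Scans are single-position: each marker is tested on its own, so no
multipoint smoothing is applied between markers.  Testing several models
inflates the genome-wide error rate; the multiple-model penalty
log10(n_models) (0.7 LOD units for five models) is reported alongside
the raw thresholds, which drive default peak calling.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import linkage, markers, models, phenotypes
from .pedigree import (
    GeneticMap,
    GenotypeMatrix,
    Pedigree,
    read_genetic_map,
    read_pedigree_file,
    validate_pedigree,
)

logger = logging.getLogger("pedlink")

SUGGESTIVE_LOD = 1.88
SIGNIFICANT_LOD = 3.30

MODEL_ALIASES = {
    "dom": "qualitative-dominant",
    "rec": "qualitative-recessive",
    "nplq": "qualitative-NPL",
    "quant": "quantitative-parametric",
    "nplquant": "quantitative-NPL",
}
ALL_MODELS = tuple(MODEL_ALIASES.values())


class ScanError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScanConfig:
    ped_path: str
    map_path: str
    pheno_path: str
    out_dir: str
    model_names: tuple[str, ...] = ALL_MODELS
    qc: markers.QCParams = field(default_factory=markers.QCParams)
    theta_grid: tuple[float, ...] = linkage.THETA_GRID
    alpha_grid: tuple[float, ...] = linkage.ALPHA_GRID
    suggestive_lod: float = SUGGESTIVE_LOD
    significant_lod: float = SIGNIFICANT_LOD
    npl_max_bits: int = 18
    npl_quant_quantile: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        names = []
        for m in self.model_names:
            canon = MODEL_ALIASES.get(m, m)
            if canon not in ALL_MODELS:
                raise ValueError(f"unknown model {m!r}")
            names.append(canon)
        if not names:
            raise ValueError("at least one model is required")
        self.model_names = tuple(names)


@dataclass
class Peak:
    model: str
    chrom: str
    position_bp: int
    score: float
    alpha: float | None
    p: float
    tier: str  # suggestive / significant
    extent_bp: tuple[int, int]  # 1-LOD support interval


def adjust_for_models(threshold: float, n_models: int) -> float:
    """Bonferroni-style LOD penalty for testing several models:
    threshold + log10(n_models)."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return threshold + float(np.log10(n_models))


def sex_ratio(n_male: int, n_female: int) -> tuple[str, float | None]:
    """Male:female ratio as printed in cohort tables, e.g. 119:16 -> 7.44.

    With zero females the ratio is undefined; the string sentinel "N:0"
    is returned with ratio None."""
    if n_female == 0:
        return f"{n_male}:0", None
    return f"{n_male}:{n_female}", round(n_male / n_female, 2)


def summarize_cohort(pheno: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table per diagnostic group (plus all-affected pooled)."""
    df = pheno.copy()
    if "category" not in df.columns:
        df = phenotypes.apply_rater_exclusions(df)
    groups = {
        "autism": df[df["clinical_dx"] == "autism"],
        "asd": df[df["clinical_dx"] == "asd"],
        "all_affected": df[df["clinical_dx"].isin(["autism", "asd"])],
        "other_relatives": df[~df["clinical_dx"].isin(["autism", "asd"])],
    }
    rows = []
    for name, g in groups.items():
        n_male = int((g["sex"] == "male").sum())
        n_female = int((g["sex"] == "female").sum())
        counts, ratio = sex_ratio(n_male, n_female)
        scored = g["raw_srs"].dropna()
        cat = g["category"] if len(g) else pd.Series(dtype=object)
        rows.append(
            {
                "group": name,
                "n": len(g),
                "male_female": counts,
                "sex_ratio": ratio,
                "srs_mean": round(float(scored.mean()), 1) if len(scored) else np.nan,
                "srs_sd": round(float(scored.std()), 1) if len(scored) > 1 else np.nan,
                "pct_child_version": (
                    round(100.0 * float((g["version"] == "child").mean()), 1)
                    if len(g)
                    else np.nan
                ),
                "pct_unaffected": _pct(cat, phenotypes.UNAFFECTED),
                "pct_spectrum": _pct(cat, phenotypes.SPECTRUM),
                "pct_affected": _pct(cat, phenotypes.AFFECTED),
            }
        )
    return pd.DataFrame(rows)


def _pct(cat: pd.Series, value: str) -> float:
    known = cat[cat != phenotypes.UNKNOWN]
    if len(known) == 0:
        return np.nan
    return round(100.0 * float((known == value).mean()), 1)


# ---------------------------------------------------------------------------
# peak calling


def call_peaks(
    results: pd.DataFrame,
    suggestive_lod: float = SUGGESTIVE_LOD,
    significant_lod: float = SIGNIFICANT_LOD,
) -> list[Peak]:
    """Local maxima above the suggestive threshold, merged within 1-LOD
    support intervals, per (model, chromosome) track."""
    if results.empty:
        return []
    peaks: list[Peak] = []
    for (model, chrom), track in results.groupby(["model", "chrom"], sort=False):
        track = track.sort_values("position_bp").reset_index(drop=True)
        s = track["score"].to_numpy(dtype=float)
        cand = [i for i in range(len(s)) if s[i] >= suggestive_lod]
        if not cand:
            continue
        clusters: list[list[int]] = [[cand[0]]]
        for prev, cur in zip(cand, cand[1:]):
            top = max(max(s[i] for i in clusters[-1]), s[cur])
            between = s[prev + 1 : cur]
            if between.size == 0 or between.min() >= top - 1.0:
                clusters[-1].append(cur)
            else:
                clusters.append([cur])
        for cluster in clusters:
            imax = max(cluster, key=lambda i: (s[i], -i))
            top = s[imax]
            lo = min(cluster)
            while lo > 0 and s[lo - 1] >= top - 1.0:
                lo -= 1
            hi = max(cluster)
            while hi < len(s) - 1 and s[hi + 1] >= top - 1.0:
                hi += 1
            row = track.iloc[imax]
            peaks.append(
                Peak(
                    model=model,
                    chrom=str(chrom),
                    position_bp=int(row["position_bp"]),
                    score=float(top),
                    alpha=None if pd.isna(row["alpha"]) else float(row["alpha"]),
                    p=float(row["p"]),
                    tier="significant" if top >= significant_lod else "suggestive",
                    extent_bp=(
                        int(track["position_bp"].iloc[lo]),
                        int(track["position_bp"].iloc[hi]),
                    ),
                )
            )
    return peaks


# ---------------------------------------------------------------------------
# full scan


def _stage(name: str):
    logger.info("stage: %s", name)


def scan_models(
    peds: list[Pedigree],
    gm: GenotypeMatrix,
    gmap: GeneticMap,
    pheno: pd.DataFrame,
    config: ScanConfig,
) -> pd.DataFrame:
    """Per-marker, per-model linkage statistics.

    Returns one row per (model, marker) with the HLOD (or NPL LOD
    equivalent), admixture estimate, and p-value.
    """
    if gmap.allele_freqs is None:
        raise ScanError("scan", "map is missing allele frequencies; run QC first")

    # per-family member rows and phenotype lookups
    plan_cache = {}
    fam_rows = []
    for ped in peds:
        rows = [gm.row_of(ped.family_id, m.indiv_id) for m in ped.members]
        fam_rows.append(np.array(rows))
        key = ped.structure_signature()
        if key not in plan_cache:
            plan_cache[key] = linkage.PeelingPlan(key)
    plans = [plan_cache[p.structure_signature()] for p in peds]

    ph = pheno.set_index(["family_id", "indiv_id"])
    categories = []
    traits = []
    for ped in peds:
        cats, vals = [], []
        for m in ped.members:
            key = (ped.family_id, m.indiv_id)
            if key in ph.index:
                rec = ph.loc[key]
                cats.append(rec["category"])
                vals.append(rec.get("quantitative_value", np.nan))
            else:
                cats.append(phenotypes.UNKNOWN)
                vals.append(np.nan)
        categories.append(cats)
        traits.append(np.array(vals, dtype=float))

    quant_model = models.QuantitativeModel()
    classes = models.build_quant_classes(quant_model)
    quant_pw = [
        np.stack([classes.vector_for(v) for v in vals]) for vals in traits
    ]
    # quantitative-NPL "affected" analog: top-quantile trait values
    all_vals = np.concatenate(traits)
    finite = all_vals[np.isfinite(all_vals)]
    q_cut = np.quantile(finite, config.npl_quant_quantile) if finite.size else np.inf

    rows = []
    for j, marker in enumerate(gmap.marker_ids):
        codes_all = gm.genotype_codes(marker)
        codes = [codes_all[r] for r in fam_rows]
        freq1 = float(gmap.allele_freqs[j])
        base = {
            "marker_id": marker,
            "chrom": gmap.chromosomes[j],
            "position_bp": int(gmap.positions_bp[j]),
            "position_cm": float(gmap.positions_cm[j]),
        }
        for name in config.model_names:
            if name in ("qualitative-dominant", "qualitative-recessive"):
                qm = (
                    models.dominant_model()
                    if name == "qualitative-dominant"
                    else models.recessive_model()
                )
                unaries = [
                    linkage.build_unary(
                        plans[i],
                        codes[i],
                        np.stack([qm.category_weights(c) for c in categories[i]]),
                        qm.disease_allele_freq,
                        freq1,
                    )
                    for i in range(len(peds))
                ]
                lods = linkage.lod_curves(
                    plans, unaries, config.theta_grid, [p.family_id for p in peds]
                )
                res = linkage.hlod(lods, config.theta_grid, config.alpha_grid)
                rows.append(
                    base
                    | {
                        "model": name,
                        "score": res.hlod,
                        "alpha": res.alpha,
                        "theta": res.theta,
                        "p": res.p_value,
                    }
                )
            elif name == "quantitative-parametric":
                unaries = [
                    linkage.build_unary(
                        plans[i],
                        codes[i],
                        quant_pw[i],
                        quant_model.disease_allele_freq,
                        freq1,
                    )
                    for i in range(len(peds))
                ]
                lods = linkage.lod_curves(
                    plans, unaries, config.theta_grid, [p.family_id for p in peds]
                )
                res = linkage.hlod(lods, config.theta_grid, config.alpha_grid)
                rows.append(
                    base
                    | {
                        "model": name,
                        "score": res.hlod,
                        "alpha": res.alpha,
                        "theta": res.theta,
                        "p": res.p_value,
                    }
                )
            else:  # NPL models
                if name == "qualitative-NPL":
                    masks = [
                        np.array([c == phenotypes.AFFECTED for c in categories[i]])
                        for i in range(len(peds))
                    ]
                else:
                    masks = [
                        np.isfinite(traits[i]) & (traits[i] >= q_cut)
                        for i in range(len(peds))
                    ]
                res = linkage.npl_statistic(
                    peds, codes, freq1, masks, config.npl_max_bits
                )
                rows.append(
                    base
                    | {
                        "model": name,
                        "score": res.lod_equivalent,
                        "alpha": np.nan,
                        "theta": np.nan,
                        "p": res.p,
                    }
                )
    return pd.DataFrame(rows)


def run_scan(config: ScanConfig) -> dict:
    """Run the full pipeline; writes TSV outputs and returns them in memory.

    Deterministic given the config: parametric statistics are seed-free
    and the seed only labels the run log.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        peds, gm = read_pedigree_file(config.ped_path)
        gmap = read_genetic_map(config.map_path)
        if len(gmap) != len(gm.marker_ids):
            raise ValueError(
                f"map lists {len(gmap)} markers but PED file carries "
                f"{len(gm.marker_ids)}"
            )
        gm = GenotypeMatrix(gm.alleles, gm.row_keys, list(gmap.marker_ids))
        log(f"loaded {len(peds)} families, {len(gmap)} markers")
    except Exception as e:  # noqa: BLE001
        raise ScanError("load", str(e)) from e

    try:
        for ped in peds:
            rep = validate_pedigree(ped)
            if rep.has_cycle or rep.has_loop or rep.sex_violations:
                raise ValueError(f"family {ped.family_id} failed validation: {rep}")
        log("pedigree validation passed")
    except Exception as e:  # noqa: BLE001
        raise ScanError("validate", str(e)) from e

    try:
        qc = markers.apply_qc(gm, gmap, peds, config.qc)
        log(
            "marker QC: "
            + " -> ".join(
                f"{k}={v}" for k, v in qc.counts.items()
            )
        )
        gm2, gmap2 = qc.genotypes, qc.genetic_map
    except Exception as e:  # noqa: BLE001
        raise ScanError("qc", str(e)) from e

    try:
        pheno = phenotypes.read_phenotype_table(config.pheno_path)
        pheno = phenotypes.apply_rater_exclusions(pheno)
        pheno, fit = phenotypes.transform_adjust(pheno)
        log(
            f"phenotypes: n={len(pheno)}, adjustment beta_age={fit.beta_age:.4f} "
            f"beta_male={fit.beta_male:.3f} on {fit.n} records"
        )
    except Exception as e:  # noqa: BLE001
        raise ScanError("phenotype", str(e)) from e

    try:
        results = scan_models(peds, gm2, gmap2, pheno, config)
        peaks = call_peaks(results, config.suggestive_lod, config.significant_lod)
        n_models = len(config.model_names)
        log(
            f"scan: {len(results)} statistics, {len(peaks)} peaks; "
            f"multiple-model penalty log10({n_models}) = "
            f"{np.log10(n_models):.2f} LOD"
        )
    except ScanError:
        raise
    except Exception as e:  # noqa: BLE001
        raise ScanError("scan", str(e)) from e

    summary = summarize_cohort(pheno)
    peaks_df = pd.DataFrame(
        [
            {
                "model": p.model,
                "chrom": p.chrom,
                "position_bp": p.position_bp,
                "score": round(p.score, 4),
                "alpha": "--" if p.alpha is None else f"{p.alpha:.2f}",
                "p": f"{p.p:.3g}",
                "tier": p.tier,
                "extent_lo_bp": p.extent_bp[0],
                "extent_hi_bp": p.extent_bp[1],
            }
            for p in peaks
        ]
    )

    out = {
        "results": results,
        "peaks": peaks,
        "qc": qc.stats,
        "cohort": summary,
        "adjustment": fit,
        "log": log_lines,
    }
    results.round(6).to_csv(os.path.join(config.out_dir, "results.tsv"), sep="\t", index=False)
    peaks_df.to_csv(os.path.join(config.out_dir, "peaks.tsv"), sep="\t", index=False)
    qc.stats.round(6).to_csv(os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False)
    summary.to_csv(os.path.join(config.out_dir, "cohort_summary.tsv"), sep="\t", index=False)
    with open(os.path.join(config.out_dir, "scan.log"), "w") as fh:
        fh.write(f"seed={config.seed}\n")
        fh.write("\n".join(log_lines) + "\n")
    return out
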