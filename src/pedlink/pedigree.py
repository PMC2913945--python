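"""Pedigree, genotype, and genetic-map containers and readers.

File formats are the classic whitespace-delimited LINKAGE conventions:
a pre-makeped PED file (``FAM IND FA MO SEX PHENO A1 B1 A2 B2 ...``) and a
four-column MAP file (``CHR ID CM BP``).  Missing parents and missing
alleles are both coded ``0``.  Markers must be biallelic; allele codes are
remapped to {1, 2} per marker.  The X chromosome is rejected at load:
every analysis in this package is autosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}

#: chromosome labels refused at load (sex chromosomes / mitochondria)
_NON_AUTOSOMES = {"x", "23", "y", "24", "xy", "25", "mt", "26", "m"}


class PedigreeError(ValueError):
    """Structural or parse problem in pedigree input."""


class MapError(ValueError):
    """Problem in genetic-map input."""


@dataclass(frozen=True)
class Individual:
    family_id: str
    indiv_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # male / female / unknown
    phenotype: str = "0"  # raw PED phenotype column, kept verbatim

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    """One family: an ordered collection of individuals.

    Member order is file/creation order; parents are guaranteed (by the
    reader and the simulator) to appear in the same family.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index = {m.indiv_id: i for i, m in enumerate(self.members)}
        if len(self._index) != len(self.members):
            raise PedigreeError(
                f"family {self.family_id}: duplicated individual id"
            )

    def __len__(self) -> int:
        return len(self.members)

    def index_of(self, indiv_id: str) -> int:
        return self._index[indiv_id]

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members if m.is_founder]

    def parent_indices(self) -> list[tuple[int, int] | None]:
        """Per member, (father_idx, mother_idx) or None for founders."""
        out: list[tuple[int, int] | None] = []
        for m in self.members:
            if m.is_founder:
                out.append(None)
            else:
                out.append((self._index[m.father_id], self._index[m.mother_id]))
        return out

    def generation_count(self) -> int:
        """Number of generations = longest founder-to-descendant chain."""
        g = nx.DiGraph()
        g.add_nodes_from(range(len(self.members)))
        for i, pi in enumerate(self.parent_indices()):
            if pi is not None:
                g.add_edge(pi[0], i)
                g.add_edge(pi[1], i)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(f"family {self.family_id}: pedigree contains a cycle")
        return nx.dag_longest_path_length(g) + 1

    def structure_signature(self) -> tuple:
        """Hashable key identifying the transmission structure (used to
        batch likelihood computations over identically shaped families)."""
        return tuple(self.parent_indices())


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for all individuals across all families.

    alleles[i, j] is the unordered pair for individual row i at marker j,
    coded 1/2 with 0 = missing; both entries are 0 or both nonzero.
    Rows are keyed by (family_id, indiv_id).
    """

    alleles: np.ndarray  # (n_indiv, n_markers, 2) int8
    row_keys: list[tuple[str, str]]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self._row = {k: i for i, k in enumerate(self.row_keys)}
        self._col = {m: j for j, m in enumerate(self.marker_ids)}

    def row_of(self, family_id: str, indiv_id: str) -> int:
        return self._row[(family_id, indiv_id)]

    def col_of(self, marker_id: str) -> int:
        return self._col[marker_id]

    def genotype_codes(self, marker_id: str) -> np.ndarray:
        """Per row: 0 missing, 1 = 1/1, 2 = 1/2, 3 = 2/2."""
        a = self.alleles[:, self.col_of(marker_id), :]
        return np.where(a[:, 0] == 0, 0, a[:, 0] + a[:, 1] - 1).astype(np.int64)

    def subset_markers(self, keep_ids: list[str]) -> "GenotypeMatrix":
        cols = [self._col[m] for m in keep_ids]
        return GenotypeMatrix(self.alleles[:, cols, :].copy(), list(self.row_keys), list(keep_ids))


@dataclass
class GeneticMap:
    """Ordered autosomal marker map (sex-averaged cM, bp positions)."""

    marker_ids: list[str]
    chromosomes: list[str]
    positions_cm: np.ndarray
    positions_bp: np.ndarray
    allele_freqs: np.ndarray | None = None  # freq of allele 1 per marker

    def __len__(self) -> int:
        return len(self.marker_ids)

    def markers_on(self, chrom: str) -> list[int]:
        return [i for i, c in enumerate(self.chromosomes) if c == chrom]

    def subset(self, keep_ids: list[str]) -> "GeneticMap":
        keep = set(keep_ids)
        idx = [i for i, m in enumerate(self.marker_ids) if m in keep]
        return GeneticMap(
            [self.marker_ids[i] for i in idx],
            [self.chromosomes[i] for i in idx],
            self.positions_cm[idx],
            self.positions_bp[idx],
            None if self.allele_freqs is None else self.allele_freqs[idx],
        )


@dataclass
class ValidationReport:
    family_id: str
    generation_count: int
    sex_violations: list[str]
    has_cycle: bool
    has_loop: bool
    n_components: int
    mendelian_errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            not self.sex_violations
            and not self.has_cycle
            and not self.has_loop
            and self.n_components <= 1
            and not self.mendelian_errors
        )


# ---------------------------------------------------------------------------
# readers


def _parse_sex(tok: str, path: str, lineno: int) -> str:
    try:
        return _SEX_CODES[tok]
    except KeyError:
        raise PedigreeError(f"{path}:{lineno}: bad sex code {tok!r}") from None


def read_pedigree_file(path: str) -> tuple[list[Pedigree], GenotypeMatrix]:
    """Read a pre-makeped LINKAGE PED file.

    Returns one :class:`Pedigree` per distinct family id (in order of first
    appearance) and the pooled :class:`GenotypeMatrix`.  ``0 0`` genotypes
    are missing; per-marker allele codes are remapped to {1, 2} in sorted
    order, and more than two observed alleles at a marker is an error.
    """
    rows: list[Individual] = []
    raw_alleles: list[list[int]] = []
    n_markers: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) < 6 or (len(toks) - 6) % 2:
                raise PedigreeError(
                    f"{path}:{lineno}: expected 6 columns plus allele pairs, got {len(toks)}"
                )
            nm = (len(toks) - 6) // 2
            if n_markers is None:
                n_markers = nm
            elif nm != n_markers:
                raise PedigreeError(
                    f"{path}:{lineno}: inconsistent marker count ({nm} vs {n_markers})"
                )
            fam, ind, fa, mo, sex, pheno = toks[:6]
            try:
                al = [int(t) for t in toks[6:]]
            except ValueError:
                raise PedigreeError(f"{path}:{lineno}: non-integer allele code") from None
            if any(a < 0 for a in al):
                raise PedigreeError(f"{path}:{lineno}: negative allele code")
            for j in range(nm):
                a, b = al[2 * j], al[2 * j + 1]
                if (a == 0) != (b == 0):
                    raise PedigreeError(
                        f"{path}:{lineno}: half-missing genotype at marker {j + 1}"
                    )
            rows.append(
                Individual(
                    family_id=fam,
                    indiv_id=ind,
                    father_id=None if fa == "0" else fa,
                    mother_id=None if mo == "0" else mo,
                    sex=_parse_sex(sex, path, lineno),
                    phenotype=pheno,
                )
            )
            raw_alleles.append(al)

    if n_markers is None:
        raise PedigreeError(f"{path}: empty pedigree file")

    alleles = np.asarray(raw_alleles, dtype=np.int64).reshape(len(rows), n_markers, 2)
    # remap per-marker allele codes to {1, 2}
    out = np.zeros_like(alleles, dtype=np.int8)
    for j in range(n_markers):
        col = alleles[:, j, :]
        codes = sorted(set(col[col > 0].tolist()))
        if len(codes) > 2:
            raise PedigreeError(
                f"{path}: marker {j + 1} has {len(codes)} alleles; biallelic markers required"
            )
        for new, old in enumerate(codes, start=1):
            out[:, j, :][col == old] = new
    # sort allele pairs so genotypes are canonically unordered
    out = np.sort(out, axis=2)
    out[out[:, :, 0] == 0] = 0  # (0, x) cannot occur; keep missing canonical

    peds: dict[str, list[Individual]] = {}
    for r in rows:
        peds.setdefault(r.family_id, []).append(r)
    pedigrees = []
    for fam, members in peds.items():
        ids = {m.indiv_id for m in members}
        for m in members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in ids:
                    raise PedigreeError(
                        f"family {fam}: individual {m.indiv_id} references "
                        f"nonexistent {role} {pid!r}"
                    )
            if (m.father_id is None) != (m.mother_id is None):
                raise PedigreeError(
                    f"family {fam}: individual {m.indiv_id} has exactly one parent; "
                    "non-founders need both"
                )
        pedigrees.append(Pedigree(fam, members))

    gm = GenotypeMatrix(
        out,
        [(r.family_id, r.indiv_id) for r in rows],
        [f"M{j + 1}" for j in range(n_markers)],
    )
    return pedigrees, gm


def _marriage_graph(ped: Pedigree) -> nx.Graph:
    """Undirected couple graph: partners link through a union node, union
    nodes link to children.  A pedigree loop (two distinct relationship
    paths joining the same pair, e.g. cousin marriage) is a cycle here."""
    g = nx.Graph()
    g.add_nodes_from(m.indiv_id for m in ped.members)
    for m in ped.members:
        if not m.is_founder:
            union = ("U", m.father_id, m.mother_id)
            g.add_edge(m.father_id, union)
            g.add_edge(m.mother_id, union)
            g.add_edge(union, m.indiv_id)
    return g


def validate_pedigree(ped: Pedigree, genotypes: GenotypeMatrix | None = None) -> ValidationReport:
    """Report-only structural validation (never raises on bad structure)."""
    sex_violations = []
    for m in ped.members:
        if m.father_id is not None:
            fa = ped.members[ped.index_of(m.father_id)]
            if fa.sex == FEMALE:
                sex_violations.append(f"father {fa.indiv_id} of {m.indiv_id} is female")
        if m.mother_id is not None:
            mo = ped.members[ped.index_of(m.mother_id)]
            if mo.sex == MALE:
                sex_violations.append(f"mother {mo.indiv_id} of {m.indiv_id} is male")

    dg = nx.DiGraph()
    dg.add_nodes_from(m.indiv_id for m in ped.members)
    for m in ped.members:
        if not m.is_founder:
            dg.add_edge(m.father_id, m.indiv_id)
            dg.add_edge(m.mother_id, m.indiv_id)
    has_cycle = not nx.is_directed_acyclic_graph(dg)

    mg = _marriage_graph(ped)
    has_loop = (not has_cycle) and bool(nx.cycle_basis(mg))
    n_components = nx.number_connected_components(mg) if len(ped) else 0
    gen = 0 if has_cycle else ped.generation_count()

    mend: list[str] = []
    if genotypes is not None and not has_cycle:
        mend = _mendelian_errors(ped, genotypes)

    return ValidationReport(
        family_id=ped.family_id,
        generation_count=gen,
        sex_violations=sex_violations,
        has_cycle=has_cycle,
        has_loop=has_loop,
        n_components=n_components,
        mendelian_errors=mend,
    )


def _mendelian_errors(ped: Pedigree, gm: GenotypeMatrix) -> list[str]:
    """Allele-count transmission checks (child must receive one allele
    from each typed parent); detection only, no cleaning."""
    errs = []
    for m in ped.members:
        if m.is_founder:
            continue
        ci = gm.row_of(ped.family_id, m.indiv_id)
        fi = gm.row_of(ped.family_id, m.father_id)
        mi = gm.row_of(ped.family_id, m.mother_id)
        for j, mid in enumerate(gm.marker_ids):
            c = gm.alleles[ci, j]
            f = gm.alleles[fi, j]
            mo = gm.alleles[mi, j]
            if c[0] == 0 or (f[0] == 0 and mo[0] == 0):
                continue
            ok = False
            for pat, mat in ((c[0], c[1]), (c[1], c[0])):
                pat_ok = f[0] == 0 or pat in f
                mat_ok = mo[0] == 0 or mat in mo
                if pat_ok and mat_ok:
                    ok = True
                    break
            if not ok:
                errs.append(f"{m.indiv_id}@{mid}")
    return errs


def read_genetic_map(path: str) -> GeneticMap:
    """Read a 4-column MAP file (CHR ID CM BP), sorted per chromosome.

    Rows may arrive unsorted; they are ordered by (chromosome, cM, bp).
    Strictly decreasing cM after sorting cannot occur, but duplicated
    marker ids and sex chromosomes are rejected.
    """
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 4:
                raise MapError(f"{path}:{lineno}: expected 4 columns, got {len(toks)}")
            chrom, mid, cm, bp = toks
            if chrom.lower().removeprefix("chr") in _NON_AUTOSOMES:
                raise MapError(
                    f"{path}:{lineno}: chromosome {chrom!r} is not autosomal; "
                    "this package analyses autosomes only"
                )
            try:
                recs.append((chrom, mid, float(cm), int(bp)))
            except ValueError:
                raise MapError(f"{path}:{lineno}: malformed position") from None
    if not recs:
        raise MapError(f"{path}: empty map file")
    ids = [r[1] for r in recs]
    if len(set(ids)) != len(ids):
        dup = sorted({m for m in ids if ids.count(m) > 1})
        raise MapError(f"{path}: duplicated marker id(s): {', '.join(dup)}")

    # stable sort by chromosome (order of first appearance) then position
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r[0] for r in recs))}
    recs.sort(key=lambda r: (chrom_order[r[0]], r[2], r[3]))
    for a, b in zip(recs, recs[1:]):
        if a[0] == b[0] and b[2] == a[2] and b[3] < a[3]:
            raise MapError(f"{path}: bp positions not non-decreasing at {b[1]}")
    return GeneticMap(
        marker_ids=[r[1] for r in recs],
        chromosomes=[r[0] for r in recs],
        positions_cm=np.array([r[2] for r in recs]),
        positions_bp=np.array([r[3] for r in recs], dtype=np.int64),
    )
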