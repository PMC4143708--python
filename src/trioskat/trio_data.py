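"""Pedigree, genotype, phenotype and region I/O, plus trio extraction.

The analysis unit is the trio: two parents and one offspring.  From a
general pedigree we extract *conditionally independent* trios — each
unordered parent pair contributes at most one offspring, chosen uniformly
at random among the fully genotyped offspring of that pair — so that
allelic transmissions are independent across trios given the parental
genotypes.

Dosage matrices use float arrays with NaN as the missing sentinel.
Genotypes are coded as counts of the minor allele *in the parental
sample*; ties at frequency 0.5 keep the ALT allele (VCF input) or allele
"1" (dosage-matrix input).
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import transmission

logger = logging.getLogger(__name__)

MISSING = np.nan

__all__ = [
    "Individual",
    "Pedigree",
    "Trio",
    "GenotypeMatrix",
    "PhenotypeTable",
    "RegionSet",
    "TrioCohort",
    "VariantPartition",
    "read_pedigree",
    "extract_trios",
    "read_genotypes",
    "read_dosage_matrix",
    "read_phenotypes",
    "read_regions",
    "partition_variants",
    "bed_interval_to_vcf",
]


@dataclass
class Individual:
    family_id: str
    individual_id: str
    father_id: str | None
    mother_id: str | None
    sex: int  # 1 male, 2 female, 0 unknown
    has_genotype: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id is None or self.mother_id is None


class Pedigree:
    """A collection of individuals indexed by (family_id, individual_id)."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._index: dict[tuple[str, str], Individual] = {}
        for ind in self.individuals:
            key = (ind.family_id, ind.individual_id)
            if key in self._index:
                raise ValueError(
                    f"duplicate individual {ind.individual_id!r} in family {ind.family_id!r}"
                )
            self._index[key] = ind
        self._check_acyclic()

    def __len__(self) -> int:
        return len(self.individuals)

    def get(self, family_id: str, individual_id: str) -> Individual | None:
        return self._index.get((family_id, individual_id))

    def dangling_parent_refs(self) -> list[tuple[str, str, str]]:
        """(family, individual, parent) triples whose parent id does not resolve."""
        out = []
        for ind in self.individuals:
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and (ind.family_id, pid) not in self._index:
                    out.append((ind.family_id, ind.individual_id, pid))
        return out

    def _check_acyclic(self) -> None:
        # Walk each individual's ancestor chain; a repeat means a cycle.
        for ind in self.individuals:
            seen = {ind.individual_id}
            frontier = [pid for pid in (ind.father_id, ind.mother_id) if pid is not None]
            while frontier:
                pid = frontier.pop()
                if pid in seen:
                    raise ValueError(
                        f"pedigree cycle involving {pid!r} in family {ind.family_id!r}"
                    )
                parent = self._index.get((ind.family_id, pid))
                if parent is None:
                    continue
                seen.add(pid)
                frontier.extend(
                    p for p in (parent.father_id, parent.mother_id) if p is not None
                )


@dataclass
class Trio:
    father_id: str
    mother_id: str
    offspring_id: str
    family_id: str = ""
    index: int = 0  # 0-based position in the cohort


def read_pedigree(path: str) -> Pedigree:
    """Parse a 6+ column whitespace-delimited PED/FAM file.

    Columns: family, individual, father, mother, sex, phenotype.  "0"
    denotes a missing parent.  Dangling parent references produce a
    warning, not an error.
    """
    individuals: list[Individual] = []
    seen: dict[tuple[str, str], int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=6 whitespace-delimited "
                    f"columns, got {len(cols)}"
                )
            fam, iid, fid, mid, sex_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            key = (fam, iid)
            if key in seen:
                raise ValueError(
                    f"{path}: line {lineno}: duplicate individual {iid!r} in family "
                    f"{fam!r} (first seen at line {seen[key]})"
                )
            seen[key] = lineno
            sex = int(sex_s) if sex_s in ("1", "2") else 0
            individuals.append(
                Individual(
                    family_id=fam,
                    individual_id=iid,
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    sex=sex,
                )
            )
    ped = Pedigree(individuals)
    for fam, iid, pid in ped.dangling_parent_refs():
        warnings.warn(
            f"{path}: individual {iid!r} (family {fam!r}) references unknown parent {pid!r}",
            stacklevel=2,
        )
    return ped


def extract_trios(pedigree: Pedigree, genotyped_ids: set[str], seed: int) -> list[Trio]:
    """Extract conditionally independent trios.

    Offspring are grouped by their unordered (father, mother) pair within a
    family; for each pair with at least one offspring where father, mother
    and the offspring are all genotyped, exactly one such offspring is
    drawn uniformly at random.  Deterministic for a fixed seed and input.
    """
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str, str], list[Individual]] = defaultdict(list)
    for ind in pedigree.individuals:
        if ind.father_id is None or ind.mother_id is None:
            continue
        a, b = sorted((ind.father_id, ind.mother_id))
        groups[(ind.family_id, a, b)].append(ind)

    trios: list[Trio] = []
    for key in sorted(groups):
        family_id = key[0]
        children = groups[key]
        father_id = children[0].father_id
        mother_id = children[0].mother_id
        if father_id not in genotyped_ids or mother_id not in genotyped_ids:
            continue
        eligible = sorted(
            (c for c in children if c.individual_id in genotyped_ids),
            key=lambda c: c.individual_id,
        )
        if not eligible:
            continue
        chosen = eligible[int(rng.integers(len(eligible)))]
        trios.append(
            Trio(
                father_id=father_id,
                mother_id=mother_id,
                offspring_id=chosen.individual_id,
                family_id=family_id,
                index=len(trios),
            )
        )
    return trios


@dataclass
class GenotypeMatrix:
    """Aligned offspring and parental dosage matrices for a trio cohort.

    Dosages count the coded (parental-minor) allele, in {0, 1, 2} with NaN
    for missing.  Rows are trios in cohort order; columns are variants in
    input order.
    """

    variant_ids: list[str]
    offspring: np.ndarray
    paternal: np.ndarray
    maternal: np.ndarray
    positions: np.ndarray | None = None  # 1-based coordinates
    chroms: list[str] | None = None
    coded_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.offspring = np.asarray(self.offspring, dtype=float)
        self.paternal = np.asarray(self.paternal, dtype=float)
        self.maternal = np.asarray(self.maternal, dtype=float)
        m = len(self.variant_ids)
        for name in ("offspring", "paternal", "maternal"):
            arr = getattr(self, name)
            if arr.ndim != 2 or arr.shape[1] != m:
                raise ValueError(f"{name} matrix shape {arr.shape} != (N, {m})")
            vals = arr[~np.isnan(arr)]
            if vals.size and (vals.min() < 0 or vals.max() > 2):
                raise ValueError(f"{name} dosages outside {{0, 1, 2}}")
        if self.positions is None:
            self.positions = np.arange(1, m + 1)
        self.positions = np.asarray(self.positions)

    @property
    def n_trios(self) -> int:
        return self.offspring.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def parental_maf(self) -> np.ndarray:
        return transmission.parental_maf(self.paternal, self.maternal)

    def subset(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        """Column subset preserving the original variant order."""
        wanted = set(variant_ids)
        idx = [j for j, v in enumerate(self.variant_ids) if v in wanted]
        return GenotypeMatrix(
            variant_ids=[self.variant_ids[j] for j in idx],
            offspring=self.offspring[:, idx],
            paternal=self.paternal[:, idx],
            maternal=self.maternal[:, idx],
            positions=self.positions[idx],
            chroms=[self.chroms[j] for j in idx] if self.chroms else None,
            coded_allele=[self.coded_allele[j] for j in idx] if self.coded_allele else None,
        )


@dataclass
class PhenotypeTable:
    """Offspring trait values and covariates, row-aligned with the trio list.

    ``covariates`` always includes an intercept column (first).
    """

    traits: pd.DataFrame
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=lambda: ["intercept"])

    def __post_init__(self) -> None:
        n = len(self.traits)
        if self.covariates is None:
            self.covariates = np.ones((n, 1))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows do not match trait rows")
        for name in self.traits.columns:
            vals = self.traits[name].dropna().unique()
            if set(vals) <= {0, 1} and len(vals) > 0:
                continue  # dichotomous OK

    @property
    def n(self) -> int:
        return len(self.traits)

    def trait(self, name: str) -> np.ndarray:
        if name not in self.traits.columns:
            raise KeyError(f"unknown trait {name!r}; available: {list(self.traits.columns)}")
        return self.traits[name].to_numpy(dtype=float)


@dataclass
class RegionSet:
    """Gene -> variant list (SetID dialect) or gene -> interval (BED dialect).

    BED intervals are 0-based half-open; VCF positions are 1-based.
    """

    by_variants: dict[str, list[str]] | None = None
    by_interval: dict[str, tuple[str, int, int]] | None = None

    @property
    def genes(self) -> list[str]:
        src = self.by_variants if self.by_variants is not None else self.by_interval
        return list(src) if src else []

    def variant_ids_for(self, gene: str, genotypes: GenotypeMatrix) -> list[str]:
        """Variant ids of `gene` present in `genotypes`, in matrix order."""
        if self.by_variants is not None:
            wanted = set(self.by_variants[gene])
            return [v for v in genotypes.variant_ids if v in wanted]
        chrom, start, end = self.by_interval[gene]
        lo, hi = bed_interval_to_vcf(start, end)
        out = []
        for j, vid in enumerate(genotypes.variant_ids):
            c = genotypes.chroms[j] if genotypes.chroms else None
            pos = int(genotypes.positions[j])
            if (c is None or c == chrom) and lo <= pos <= hi:
                out.append(vid)
        return out


def bed_interval_to_vcf(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to a 1-based closed VCF range."""
    return start + 1, end


@dataclass
class TrioCohort:
    trios: list[Trio]
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self) -> None:
        n = len(self.trios)
        if self.genotypes.n_trios != n or self.phenotypes.n != n:
            raise ValueError(
                f"inconsistent cohort: {n} trios, {self.genotypes.n_trios} genotype "
                f"rows, {self.phenotypes.n} phenotype rows"
            )

    @property
    def n_trios(self) -> int:
        return len(self.trios)


# ---------------------------------------------------------------------------
# Genotype input


def _decode_gt_types(gt_types: np.ndarray) -> np.ndarray:
    # cyvcf2 with gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
    out = gt_types.astype(float)
    out[gt_types == 3] = np.nan
    return out


def read_genotypes(
    path: str,
    trios: Sequence[Trio],
    region: tuple[str, int, int] | Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read trio dosages from a (possibly gzipped) VCF.

    `region` is either a BED-style (chrom, start, end) interval, a
    collection of variant ids, or None for all records.  Multiallelic
    records are skipped with a warning.  Dosages are recoded so the coded
    allele is the minor allele among the parents (tie: ALT stays coded).
    """
    from cyvcf2 import VCF

    fathers = [t.father_id for t in trios]
    mothers = [t.mother_id for t in trios]
    offspring = [t.offspring_id for t in trios]
    needed = fathers + mothers + offspring

    vcf = VCF(path, gts012=True)
    have = set(vcf.samples)
    missing = sorted(set(needed) - have)
    if missing:
        raise ValueError(f"{path}: samples absent from VCF header: {missing}")
    col = {s: i for i, s in enumerate(vcf.samples)}
    fi = np.array([col[s] for s in fathers])
    mi = np.array([col[s] for s in mothers])
    oi = np.array([col[s] for s in offspring])

    interval = None
    wanted_ids: set[str] | None = None
    if region is not None:
        if isinstance(region, tuple) and len(region) == 3 and isinstance(region[0], str):
            chrom, start, end = region
            lo, hi = bed_interval_to_vcf(int(start), int(end))
            interval = (chrom, lo, hi)
        else:
            wanted_ids = set(region)

    variant_ids: list[str] = []
    positions: list[int] = []
    chroms: list[str] = []
    coded: list[str] = []
    pat_rows, mat_rows, off_rows = [], [], []

    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(
                f"{path}: skipping multiallelic record at {rec.CHROM}:{rec.POS}",
                stacklevel=2,
            )
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if interval is not None:
            chrom, lo, hi = interval
            if rec.CHROM != chrom or not (lo <= rec.POS <= hi):
                continue
        if wanted_ids is not None and vid not in wanted_ids:
            continue
        dose = _decode_gt_types(np.asarray(rec.gt_types))
        pat, mat, off = dose[fi], dose[mi], dose[oi]
        # Minor-allele recoding from the parental sample only.
        parents = np.concatenate([pat, mat])
        obs = parents[~np.isnan(parents)]
        alt_freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        if alt_freq > 0.5:
            pat, mat, off = 2 - pat, 2 - mat, 2 - off
            coded.append(rec.REF)
        else:
            coded.append(rec.ALT[0])
        variant_ids.append(vid)
        positions.append(rec.POS)
        chroms.append(rec.CHROM)
        pat_rows.append(pat)
        mat_rows.append(mat)
        off_rows.append(off)

    n, m = len(trios), len(variant_ids)
    shape = (n, m)
    return GenotypeMatrix(
        variant_ids=variant_ids,
        offspring=np.array(off_rows).T.reshape(shape),
        paternal=np.array(pat_rows).T.reshape(shape),
        maternal=np.array(mat_rows).T.reshape(shape),
        positions=np.array(positions, dtype=int) if m else np.zeros(0, dtype=int),
        chroms=chroms,
        coded_allele=coded,
    )


def read_dosage_matrix(path: str, trios: Sequence[Trio]) -> GenotypeMatrix:
    """Read the plain dosage-matrix alternative to VCF.

    TSV with the variant id in the first column and one column per
    individual; cells in {0, 1, 2, NA}.  Allele "1" is the counted allele;
    recoding to the parental minor allele is applied as for VCF input
    (tie: allele "1" stays coded).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    needed = {t.father_id for t in trios} | {t.mother_id for t in trios} | {
        t.offspring_id for t in trios
    }
    missing = sorted(needed - set(df.columns))
    if missing:
        raise ValueError(f"{path}: individuals absent from dosage matrix: {missing}")
    pat = df[[t.father_id for t in trios]].to_numpy(dtype=float).T
    mat = df[[t.mother_id for t in trios]].to_numpy(dtype=float).T
    off = df[[t.offspring_id for t in trios]].to_numpy(dtype=float).T
    coded = []
    for j in range(pat.shape[1]):
        parents = np.concatenate([pat[:, j], mat[:, j]])
        obs = parents[~np.isnan(parents)]
        freq = obs.sum() / (2 * obs.size) if obs.size else 0.0
        if freq > 0.5:
            pat[:, j] = 2 - pat[:, j]
            mat[:, j] = 2 - mat[:, j]
            off[:, j] = 2 - off[:, j]
            coded.append("0")
        else:
            coded.append("1")
    return GenotypeMatrix(
        variant_ids=list(df.index.astype(str)),
        offspring=off,
        paternal=pat,
        maternal=mat,
        coded_allele=coded,
    )


def read_phenotypes(
    path: str,
    trios: Sequence[Trio],
    covariate_cols: Sequence[str] | None = None,
) -> PhenotypeTable:
    """Read a TSV of offspring traits keyed by the first (id) column.

    All non-covariate columns are traits.  An intercept column is always
    prepended to the covariates.
    """
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    wanted = [t.offspring_id for t in trios]
    missing = sorted(set(wanted) - set(df.index.astype(str)))
    if missing:
        raise ValueError(f"{path}: offspring absent from phenotype table: {missing}")
    df.index = df.index.astype(str)
    df = df.loc[wanted]
    covariate_cols = list(covariate_cols or [])
    trait_cols = [c for c in df.columns if c not in covariate_cols]
    cov = np.ones((len(df), 1 + len(covariate_cols)))
    for k, c in enumerate(covariate_cols, start=1):
        cov[:, k] = df[c].to_numpy(dtype=float)
    return PhenotypeTable(
        traits=df[trait_cols].reset_index(drop=True),
        covariates=cov,
        covariate_names=["intercept"] + covariate_cols,
    )


def read_regions(path: str) -> RegionSet:
    """Read gene definitions: BED (``.bed``) or two-column SetID TSV."""
    if str(path).endswith(".bed"):
        intervals: dict[str, tuple[str, int, int]] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split()
                if len(cols) < 4:
                    raise ValueError(f"{path}: line {lineno}: BED needs >=4 columns (with name)")
                chrom, start, end, name = cols[0], int(cols[1]), int(cols[2]), cols[3]
                intervals[name] = (chrom, start, end)
        return RegionSet(by_interval=intervals)
    mapping: dict[str, list[str]] = defaultdict(list)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 2:
                raise ValueError(f"{path}: line {lineno}: SetID needs 2 columns (gene, variant)")
            gene, vid = cols[0], cols[1]
            if vid in mapping[gene]:
                raise ValueError(f"{path}: line {lineno}: duplicate variant {vid!r} in gene {gene!r}")
            mapping[gene].append(vid)
    return RegionSet(by_variants=dict(mapping))


@dataclass
class VariantPartition:
    """MAF strata: rare (0 < f <= threshold), common (f > threshold), monomorphic."""

    rare: list[str]
    common: list[str]
    monomorphic: list[str]


def partition_variants(
    genotypes: GenotypeMatrix, maf_threshold: float = 0.05
) -> VariantPartition:
    """Split variants by parental MAF at the (rare-inclusive) threshold."""
    freqs = genotypes.parental_maf()
    rare, common, mono = [], [], []
    for vid, f in zip(genotypes.variant_ids, freqs):
        if np.isnan(f):
            logger.warning("variant %s has no parental genotypes; excluded", vid)
            mono.append(vid)
        elif f == 0:
            mono.append(vid)
        elif f <= maf_threshold:
            rare.append(vid)
        else:
            common.append(vid)
    return VariantPartition(rare=rare, common=common, monomorphic=mono)
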