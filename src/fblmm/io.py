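"""Readers and writers for the genotype, pedigree, region and phenotype formats.

This module is the single place where file coordinates (1-based .bim
positions) are converted to internal 0-based indices, and the single
source of truth for sample/variant ID conventions.  Missing dosages are
kept as NaN here; imputation happens downstream in :mod:`fblmm.kernels`
so that I/O stays lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "Pedigree",
    "RegionMap",
    "PhenotypeTable",
    "FormatError",
    "ValidationError",
    "PedigreeError",
    "read_genotypes",
    "write_genotypes",
    "read_pedigree",
    "write_pedigree",
    "read_region_map",
    "write_region_map",
    "read_phenotypes",
    "write_phenotypes",
]

MISSING = np.nan

_PLINK_MAGIC = bytes([0x6C, 0x1B])
_SNP_MAJOR = 0x01


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


class PedigreeError(ValidationError):
    """Pedigree-specific structural problem (e.g. an ancestry cycle)."""


def _compute_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per column, ignoring missing entries.

    Dosages are minor-allele counts, so maf = mean(dosage)/2 and always
    lies in [0, 0.5] for correctly oriented data.
    """
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    return np.where(np.isnan(freq), 0.0, freq)


@dataclass
class GenotypeMatrix:
    """n x p dosage matrix (minor-allele counts) with variant metadata.

    ``dosages`` holds values in {0, 1, 2} or NaN for missing.  ``variants``
    is indexed by variant ID and carries chromosome / position (1-based) /
    allele columns.  ``maf`` is recomputed from the stored dosages.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        if self.variants.index.has_duplicates:
            dup = self.variants.index[self.variants.index.duplicated()][0]
            raise ValidationError(f"duplicate variant ID {dup!r}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            rows, cols = np.where(
                ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
            )
            raise ValidationError(
                f"dosage {self.dosages[rows[0], cols[0]]!r} out of {{0,1,2}} at "
                f"sample {self.samples[rows[0]]!r}, variant "
                f"{self.variants.index[cols[0]]!r}"
            )
        freq = _compute_maf(self.dosages)
        self.maf = np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants.index)

    def sample_indexer(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.samples)}

    def variant_indexer(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants.index)}

    def subset(
        self,
        samples: Optional[Sequence[str]] = None,
        variants: Optional[Sequence[str]] = None,
    ) -> "GenotypeMatrix":
        """Row/column subset by ID, preserving the requested order."""
        si = self.sample_indexer()
        vi = self.variant_indexer()
        rows = [si[s] for s in samples] if samples is not None else list(range(self.n_samples))
        cols = [vi[v] for v in variants] if variants is not None else list(range(self.n_variants))
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            variants=self.variants.iloc[cols].copy(),
            dosages=self.dosages[np.ix_(rows, cols)].copy(),
        )


def _default_variant_table(ids: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * len(ids),
            "pos": np.arange(1, len(ids) + 1),
            "a1": ["A"] * len(ids),
            "a2": ["G"] * len(ids),
        },
        index=pd.Index(ids, name="variant"),
    )


@dataclass
class PedigreeRecord:
    individual: str
    family: str
    father: Optional[str]
    mother: Optional[str]
    mz_group: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Pedigree records stored in topological order (parents first)."""

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        ids = [r.individual for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate individual IDs in pedigree")
        known = set(ids)
        for r in self.records:
            for p in (r.father, r.mother):
                if p is not None and p not in known:
                    raise ValidationError(
                        f"parent {p!r} of {r.individual!r} absent from pedigree"
                    )
        self.records = _toposort(self.records)
        self._check_mz()

    def _check_mz(self) -> None:
        groups: dict[str, list[PedigreeRecord]] = {}
        for r in self.records:
            if r.mz_group is not None:
                groups.setdefault(r.mz_group, []).append(r)
        for gid, members in groups.items():
            parents = {(m.father, m.mother) for m in members}
            if len(parents) > 1:
                raise ValidationError(
                    f"MZ group {gid!r} members do not share both parents"
                )

    @property
    def individuals(self) -> list[str]:
        return [r.individual for r in self.records]

    @property
    def founders(self) -> list[str]:
        return [r.individual for r in self.records if r.is_founder]

    @property
    def families(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for r in self.records:
            fams.setdefault(r.family, []).append(r.individual)
        return fams

    def record_of(self, individual: str) -> PedigreeRecord:
        for r in self.records:
            if r.individual == individual:
                return r
        raise KeyError(individual)

    def merged_with(self, extra: Iterable[PedigreeRecord]) -> "Pedigree":
        return Pedigree(records=self.records + list(extra))


def _toposort(records: list[PedigreeRecord]) -> list[PedigreeRecord]:
    by_id = {r.individual: r for r in records}
    order: list[PedigreeRecord] = []
    state: dict[str, int] = {}  # 0 = visiting, 1 = done

    def visit(ind: str, stack: list[str]) -> None:
        st = state.get(ind)
        if st == 1:
            return
        if st == 0:
            cycle = stack[stack.index(ind):] + [ind]
            raise PedigreeError(f"ancestry cycle detected: {' -> '.join(cycle)}")
        state[ind] = 0
        rec = by_id[ind]
        stack.append(ind)
        for p in (rec.father, rec.mother):
            if p is not None:
                visit(p, stack)
        stack.pop()
        state[ind] = 1
        order.append(rec)

    for r in records:
        visit(r.individual, [])
    return order


@dataclass
class RegionMap:
    """Ordered region -> member-variant lists (each of size p_m >= 1)."""

    regions: dict[str, list[str]]
    report: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.regions.items():
            if len(members) < 1:
                raise ValidationError(f"region {name!r} has no member variants")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def sizes(self) -> dict[str, int]:
        return {name: len(v) for name, v in self.regions.items()}

    def restricted_to(self, genotypes: GenotypeMatrix) -> "RegionMap":
        """Drop variants absent from `genotypes`; drop emptied regions."""
        known = set(genotypes.variants.index)
        kept: dict[str, list[str]] = {}
        report: dict[str, list[str]] = dict(self.report)
        for name, members in self.regions.items():
            present = [v for v in members if v in known]
            missing = [v for v in members if v not in known]
            if missing:
                report.setdefault("skipped_variants", []).extend(
                    f"{name}:{v}" for v in missing
                )
            if present:
                kept[name] = present
            else:
                report.setdefault("dropped_regions", []).append(name)
        return RegionMap(regions=kept, report=report)


@dataclass
class PhenotypeTable:
    """One row per individual: quantitative outcome plus covariates."""

    table: pd.DataFrame  # index individual ID; column 'phenotype'; rest covariates

    def __post_init__(self) -> None:
        if "phenotype" not in self.table.columns:
            raise ValidationError("phenotype column missing")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicate individual IDs in phenotype table")
        y = self.table["phenotype"].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValidationError("non-finite phenotype value")

    @property
    def phenotype(self) -> np.ndarray:
        return self.table["phenotype"].to_numpy(dtype=float)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns=["phenotype"])

    def aligned_to(self, samples: Sequence[str]) -> tuple["PhenotypeTable", list[str]]:
        """Inner-join to `samples`; returns the table plus unmatched IDs."""
        present = [s for s in samples if s in self.table.index]
        unmatched = sorted(
            set(samples).symmetric_difference(self.table.index)
        )
        return PhenotypeTable(self.table.loc[present].copy()), unmatched


# ---------------------------------------------------------------------------
# genotype I/O

def read_genotypes(path: str | Path, format: str = "dosage-tsv") -> GenotypeMatrix:
    """Read genotypes from `plink-bed` (prefix of a bed/bim/fam triple) or
    a `dosage-tsv` file (samples x variants, header of variant IDs).

    Dosages are oriented as minor-allele counts: columns stored on the
    major allele (frequency > 0.5) are flipped and the flip recorded in the
    variant table (``flipped`` column).
    """
    if format == "dosage-tsv":
        return _read_dosage_tsv(Path(path))
    if format == "plink-bed":
        return _read_plink_bed(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _orient_minor(dosages: np.ndarray, variants: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    freq = _compute_maf(dosages)
    flip = freq > 0.5
    if flip.any():
        dosages = dosages.copy()
        dosages[:, flip] = 2.0 - dosages[:, flip]
    variants = variants.copy()
    variants["flipped"] = flip
    return dosages, variants


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: header must name at least one variant")
        variant_ids = header[1:]
        samples: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {len(header)}"
                )
            samples.append(parts[0])
            row: list[float] = []
            for col, tok in zip(variant_ids, parts[1:]):
                if tok in ("", "NA", "nan"):
                    row.append(MISSING)
                    continue
                try:
                    val = float(tok)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}, variant {col!r}: not a number: {tok!r}"
                    ) from exc
                if val not in (0.0, 1.0, 2.0):
                    raise ValidationError(
                        f"{path}: line {lineno} (sample {parts[0]!r}), variant "
                        f"{col!r}: dosage {tok} outside {{0,1,2}}"
                    )
                row.append(val)
            rows.append(row)
    dosages = np.asarray(rows, dtype=float).reshape(len(samples), len(variant_ids))
    dosages, variants = _orient_minor(dosages, _default_variant_table(variant_ids))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_genotypes(
    genotypes: GenotypeMatrix, path: str | Path, format: str = "dosage-tsv"
) -> None:
    if format == "dosage-tsv":
        _write_dosage_tsv(genotypes, Path(path))
    elif format == "plink-bed":
        _write_plink_bed(genotypes, Path(path))
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_dosage_tsv(genotypes: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\t" + "\t".join(genotypes.variants.index) + "\n")
        for i, sample in enumerate(genotypes.samples):
            toks = [
                "NA" if np.isnan(v) else str(int(v)) for v in genotypes.dosages[i]
            ]
            fh.write(sample + "\t" + "\t".join(toks) + "\n")


# PLINK .bed stores genotypes 2 bits per call in SNP-major order:
# 00 = homozygous A1, 10 = heterozygous, 11 = homozygous A2, 01 = missing.
# With A1 the minor allele, dosage = number of A1 alleles.
_BED_DECODE = {0b00: 2.0, 0b01: MISSING, 0b10: 1.0, 0b11: 0.0}
_BED_ENCODE = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _read_plink_bed(prefix: Path) -> GenotypeMatrix:
    prefix = Path(str(prefix).removesuffix(".bed"))
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f)
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["family", "individual", "father", "mother", "sex", "phenotype"],
        dtype=str,
    )
    samples = fam_df["individual"].tolist()
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "variant", "cm", "pos", "a1", "a2"], dtype=str,
    )
    variants = pd.DataFrame(
        {
            "chrom": bim_df["chrom"].to_numpy(),
            "pos": bim_df["pos"].astype(int).to_numpy(),
            "a1": bim_df["a1"].to_numpy(),
            "a2": bim_df["a2"].to_numpy(),
        },
        index=pd.Index(bim_df["variant"], name="variant"),
    )
    n, p = len(samples), len(variants)
    raw = bed.read_bytes()
    if raw[:2] != _PLINK_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes {raw[:2].hex()}")
    if raw[2] != _SNP_MAJOR:
        raise FormatError(f"{bed}: only SNP-major layout supported")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * p:
        raise FormatError(
            f"{bed}: expected {bytes_per_variant * p} data bytes, found {body.size}"
        )
    codes = np.zeros((p, bytes_per_variant * 4), dtype=np.uint8)
    block = body.reshape(p, bytes_per_variant)
    for shift in range(4):
        codes[:, shift::4] = (block >> (2 * shift)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, MISSING, 1.0, 0.0])
    dosages = lut[codes].T  # n x p
    dosages, variants = _orient_minor(dosages, variants)
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def _write_plink_bed(genotypes: GenotypeMatrix, prefix: Path) -> None:
    prefix = Path(str(prefix).removesuffix(".bed"))
    n, p = genotypes.n_samples, genotypes.n_variants
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in genotypes.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for vid, row in genotypes.variants.iterrows():
            fh.write(
                f"{row.get('chrom', '1')}\t{vid}\t0\t{int(row.get('pos', 1))}\t"
                f"{row.get('a1', 'A')}\t{row.get('a2', 'G')}\n"
            )
    bytes_per_variant = (n + 3) // 4
    out = bytearray(_PLINK_MAGIC + bytes([_SNP_MAJOR]))
    for j in range(p):
        buf = bytearray(bytes_per_variant)
        for i in range(n):
            v = genotypes.dosages[i, j]
            code = 0b01 if np.isnan(v) else _BED_ENCODE[float(v)]
            buf[i // 4] |= code << (2 * (i % 4))
        out.extend(buf)
    prefix.with_suffix(".bed").write_bytes(bytes(out))


# ---------------------------------------------------------------------------
# pedigree I/O

def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-style whitespace-delimited pedigree file.

    Columns: family, individual, father, mother, optional mz_group.
    "0" denotes a missing (founder) parent or no MZ group.
    """
    records: list[PedigreeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 4 columns, found {len(parts)}"
                )
            fam, ind, father, mother = parts[:4]
            mz = parts[4] if len(parts) > 4 else "0"
            records.append(
                PedigreeRecord(
                    individual=ind,
                    family=fam,
                    father=None if father == "0" else father,
                    mother=None if mother == "0" else mother,
                    mz_group=None if mz == "0" else mz,
                )
            )
    return Pedigree(records=records)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write(
                f"{r.family}\t{r.individual}\t{r.father or '0'}\t"
                f"{r.mother or '0'}\t{r.mz_group or '0'}\n"
            )


# ---------------------------------------------------------------------------
# region map I/O

def read_region_map(
    path: str | Path, genotypes: Optional[GenotypeMatrix] = None
) -> RegionMap:
    """Read a two-column (region, variant) TSV.

    Regions keep file order; member lists are deduplicated preserving
    order.  When a companion GenotypeMatrix is given, unknown variants are
    skipped (counted in the report) and emptied regions dropped.
    """
    regions: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            region, variant = parts
            members = regions.setdefault(region, [])
            if variant not in members:
                members.append(variant)
    rmap = RegionMap(regions=regions)
    if genotypes is not None:
        rmap = rmap.restricted_to(genotypes)
    return rmap


def write_region_map(rmap: RegionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in rmap.regions.items():
            for v in members:
                fh.write(f"{name}\t{v}\n")


# ---------------------------------------------------------------------------
# phenotype I/O

def read_phenotypes(path: str | Path, phenotype_column: str = "phenotype") -> PhenotypeTable:
    """Read a TSV with an `individual` ID column plus outcome/covariates."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need an ID column and a phenotype column")
    df = df.set_index(df.columns[0])
    df.index.name = "individual"
    if phenotype_column not in df.columns:
        raise FormatError(f"{path}: phenotype column {phenotype_column!r} absent")
    if phenotype_column != "phenotype":
        df = df.rename(columns={phenotype_column: "phenotype"})
    return PhenotypeTable(table=df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index_label="individual")
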