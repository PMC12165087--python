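"""Genotype data model plus VCF/BED/pop-map readers, writers and windowing.

Coordinate contract: VCF positions are 1-based both in memory
(:attr:`HaplotypePanel.positions`) and on disk; BED intervals, genomic
windows and every internal segment are 0-based half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

from .errors import ArgumentError, ContractError, FormatError, MappingError

logger = logging.getLogger(__name__)

MISSING = -1

SV_TYPES = ("DEL", "INS", "DUP", "INV")

#: SVs longer than this are dropped on read.
SV_MAX_LENGTH = 5_000_000


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """Phased 0/1 haplotype-by-site matrix for one chromosome.

    ``alleles`` has shape ``(2 * n_samples, n_sites)`` with values
    ``{0, 1, MISSING}``; haplotype rows ``2i`` and ``2i + 1`` belong to
    ``sample_ids[i]``.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    alleles: np.ndarray  # int8 (2*n_samples, n_sites)
    sample_ids: list[str]
    phased: bool = True
    n_skipped: int = 0  # records skipped on read (multiallelic / non-SNP)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2 or self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ContractError(
                f"allele matrix has {self.alleles.shape[0]} rows, "
                f"expected {2 * len(self.sample_ids)} for {len(self.sample_ids)} samples"
            )
        if self.alleles.shape[1] != self.positions.size:
            raise ContractError("positions/alleles length mismatch")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ContractError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return 2 * len(self.sample_ids)

    def haplotype_labels(self) -> list[tuple[str, int]]:
        """(sample_id, 0|1) label for every haplotype row, in row order."""
        return [(s, k) for s in self.sample_ids for k in (0, 1)]

    def subset_samples(self, sample_ids: list[str]) -> "HaplotypePanel":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise MappingError(f"samples not in panel: {missing}")
        rows = np.concatenate([[2 * index[s], 2 * index[s] + 1] for s in sample_ids])
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions.copy(),
            alleles=self.alleles[rows],
            sample_ids=list(sample_ids),
            phased=self.phased,
        )

    def region(self, start: int, end: int) -> "HaplotypePanel":
        """Sites with 1-based position in the inclusive range [start, end]."""
        keep = (self.positions >= start) & (self.positions <= end)
        return HaplotypePanel(
            chrom=self.chrom,
            positions=self.positions[keep],
            alleles=self.alleles[:, keep],
            sample_ids=list(self.sample_ids),
            phased=self.phased,
        )

    def genotype_dosages(self) -> np.ndarray:
        """Per-sample diploid dosages (n_samples, n_sites); MISSING if either
        allele of a sample is missing at the site."""
        a = self.alleles[0::2].astype(np.int16)
        b = self.alleles[1::2].astype(np.int16)
        dos = a + b
        dos[(a == MISSING) | (b == MISSING)] = MISSING
        return dos.astype(np.int8)


@dataclass
class PopulationMap:
    """Sample-to-population assignment plus per-analysis roles."""

    assignments: dict[str, str]
    roles: dict[str, str] = field(default_factory=dict)  # role -> population

    def samples_of(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def population_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise MappingError(f"sample {sample!r} has no population assignment")

    def require_roles(self, *names: str) -> None:
        missing = [r for r in names if r not in self.roles]
        if missing:
            raise ConfigurationRoleError(missing)


class ConfigurationRoleError(MappingError):
    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"missing population roles: {', '.join(missing)}")


@dataclass
class GenomicWindow:
    """Half-open genomic interval [start, end), 0-based."""

    chrom: str
    start: int
    end: int
    n_sites: int = 0
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ContractError(f"empty window [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class SVRecord:
    """One biallelic structural variant with per-sample diploid dosages."""

    sv_id: str
    svtype: str
    chrom: str
    pos: int  # 1-based
    end: int  # 1-based inclusive; == pos for INS
    genotypes: np.ndarray  # int8 dosages {0,1,2,MISSING} aligned to sample_ids
    sample_ids: list[str]
    maf: float = float("nan")
    missingness: float = float("nan")

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.svtype not in SV_TYPES:
            raise ContractError(f"unknown SVTYPE {self.svtype!r}")
        if self.end < self.pos:
            raise ContractError("SV end precedes pos")
        called = self.genotypes[self.genotypes != MISSING]
        self.missingness = 1.0 - called.size / max(self.genotypes.size, 1)
        if called.size:
            af = called.sum() / (2.0 * called.size)
            self.maf = float(min(af, 1.0 - af))
        else:
            self.maf = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.pos + 1

    def interval(self) -> tuple[int, int]:
        """0-based half-open genomic footprint."""
        return (self.pos - 1, self.end)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _parse_region(region: str | None) -> tuple[str, int, int] | None:
    if region is None:
        return None
    try:
        chrom, span = region.rsplit(":", 1)
        lo, hi = span.split("-")
        return chrom, int(lo), int(hi)
    except ValueError:
        raise ArgumentError(f"malformed region {region!r}, expected chrom:start-end")


def read_phased_vcf(path: str, region: str | None = None,
                    require_phased: bool = True) -> HaplotypePanel:
    """Read biallelic SNP records from a VCF into a :class:`HaplotypePanel`.

    ``region`` uses the 1-based inclusive ``chrom:start-end`` convention.
    Multiallelic and non-SNP records are skipped; the count is logged and
    stored on the returned panel.
    """
    if not os.path.exists(path):
        raise IOError(f"no such VCF: {path}")
    reg = _parse_region(region)
    vcf = VCF(path)
    samples = list(vcf.samples)
    positions: list[int] = []
    rows: list[np.ndarray] = []
    chrom = None
    skipped = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            skipped += 1
            continue
        if reg is not None:
            rchrom, lo, hi = reg
            if variant.CHROM != rchrom or not (lo <= variant.POS <= hi):
                continue
        if chrom is None:
            chrom = variant.CHROM
        gts = variant.genotypes  # [[a, b, phased], ...]
        hap = np.empty(2 * len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            if require_phased and not g[2] and a >= 0 and b >= 0 and a != b:
                raise FormatError(
                    f"unphased heterozygote for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            hap[2 * i] = a if a >= 0 else MISSING
            hap[2 * i + 1] = b if b >= 0 else MISSING
        positions.append(variant.POS)
        rows.append(hap)
    vcf.close()
    if skipped:
        logger.info("read_phased_vcf: skipped %d multiallelic/non-SNP records", skipped)
    alleles = (
        np.stack(rows, axis=1) if rows else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    return HaplotypePanel(
        chrom=chrom or (reg[0] if reg else "chr1"),
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        sample_ids=samples,
        phased=True,
        n_skipped=skipped,
    )


def write_phased_vcf(panel: HaplotypePanel, path: str, contig_length: int | None = None,
                     ref_alt: tuple[np.ndarray, np.ndarray] | None = None) -> None:
    """Write a panel as a minimal phased VCFv4.2 file."""
    length = contig_length if contig_length is not None else int(panel.positions[-1]) if panel.n_sites else 1
    if ref_alt is None:
        refs = np.full(panel.n_sites, "A")
        alts = np.full(panel.n_sites, "C")
    else:
        refs, alts = ref_alt
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={panel.chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.sample_ids) + "\n")
        a = panel.alleles
        for j in range(panel.n_sites):
            gts = []
            for i in range(panel.n_samples):
                x, y = a[2 * i, j], a[2 * i + 1, j]
                xs = "." if x == MISSING else str(int(x))
                ys = "." if y == MISSING else str(int(y))
                gts.append(f"{xs}|{ys}")
            fh.write(
                f"{panel.chrom}\t{panel.positions[j]}\tsnp{j}\t{refs[j]}\t{alts[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_sv_vcf(path: str, max_length: int = SV_MAX_LENGTH) -> list[SVRecord]:
    """Read SV genotypes from a VCF with SVTYPE/END INFO keys.

    Records longer than ``max_length`` and non-{DEL,INS,DUP,INV} records
    (e.g. translocations/BNDs) are dropped with a logged count.
    """
    if not os.path.exists(path):
        raise IOError(f"no such VCF: {path}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    records: list[SVRecord] = []
    dropped_long = dropped_type = 0
    for variant in vcf:
        svtype = variant.INFO.get("SVTYPE")
        if svtype is None:
            raise FormatError(
                f"record at {variant.CHROM}:{variant.POS} has no SVTYPE INFO key"
            )
        if svtype not in SV_TYPES:
            dropped_type += 1
            continue
        end = variant.INFO.get("END")
        if end is None:
            if svtype == "INS":
                end = variant.POS
            else:
                raise FormatError(
                    f"{svtype} record at {variant.CHROM}:{variant.POS} lacks END"
                )
        end = int(end)
        if end - variant.POS + 1 > max_length:
            dropped_long += 1
            continue
        dosages = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            dosages[i] = MISSING if (a < 0 or b < 0) else a + b
        records.append(
            SVRecord(
                sv_id=variant.ID or f"sv_{variant.CHROM}_{variant.POS}",
                svtype=svtype,
                chrom=variant.CHROM,
                pos=variant.POS,
                end=end,
                genotypes=dosages,
                sample_ids=samples,
            )
        )
    vcf.close()
    if dropped_long or dropped_type:
        logger.info(
            "read_sv_vcf: dropped %d records > %d bp and %d unsupported-type records",
            dropped_long, max_length, dropped_type,
        )
    return records


def write_sv_vcf(svs: list[SVRecord], path: str, contig_length: int | None = None) -> None:
    if not svs:
        raise ArgumentError("no SV records to write")
    samples = svs[0].sample_ids
    chrom = svs[0].chrom
    length = contig_length or max(sv.end for sv in svs)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for sv in sorted(svs, key=lambda s: (s.chrom, s.pos)):
            gts = "\t".join(gt_map[int(d)] for d in sv.genotypes)
            alt = f"<{sv.svtype}>"
            info = f"SVTYPE={sv.svtype};END={sv.end};SVLEN={sv.length}"
            fh.write(
                f"{sv.chrom}\t{sv.pos}\t{sv.sv_id}\tN\t{alt}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# windows, BED, pop-map
# ---------------------------------------------------------------------------


def make_windows(chrom_length: int, window: int = 50_000, step: int = 25_000,
                 chrom: str = "chr1") -> list[GenomicWindow]:
    """Sliding windows ``[k*step, k*step + window)`` truncated at the
    chromosome end; the 50 kb / 25 kb defaults match the scan grid."""
    if step <= 0 or window <= 0:
        raise ArgumentError("window and step must be positive")
    if step > window:
        raise ArgumentError(f"step ({step}) exceeds window ({window})")
    if chrom_length <= 0:
        raise ArgumentError("chrom_length must be positive")
    out = []
    start = 0
    while start < chrom_length:
        end = min(start + window, chrom_length)
        out.append(GenomicWindow(chrom, start, end, truncated=end - start < window))
        start += step
    return out


def count_sites(windows: list[GenomicWindow], positions: np.ndarray) -> None:
    """Fill ``n_sites`` for each window from 1-based site positions."""
    pos0 = np.asarray(positions) - 1
    for w in windows:
        w.n_sites = int(np.count_nonzero((pos0 >= w.start) & (pos0 < w.end)))


def write_bed(intervals, path: str) -> None:
    """Write (chrom, start, end, *extra) tuples as sorted BED3+ lines."""
    rows = sorted(intervals, key=lambda r: (str(r[0]), int(r[1]), int(r[2])))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str) -> list[tuple]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2]), *parts[3:]))
    return out


def read_popmap(path: str) -> PopulationMap:
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected sample<TAB>population")
            assignments[parts[0]] = parts[1]
    return PopulationMap(assignments=assignments)


def write_popmap(popmap: PopulationMap, path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")
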