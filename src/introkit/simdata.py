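"""Forward-in-time Wright-Fisher simulator with exact admixture-tract tracking.

Five populations are simulated on one chromosome: two "domestic" focal
populations ``P_A`` and ``P_B``, their conspecific wild backgrounds ``W_A``
and ``W_B``, and a distant outgroup ``OUT``.  Demography (generations before
present, BP)::

    burn-in                 single ancestral population
    t_out  = split * outgroup_split_factor   OUT splits off
    t_ab   = split_generations               A-side / B-side split
    t_dom  = split * domestic_split_fraction P_x splits from W_x on each side
    0                                        sampled panels

Dated admixture pulses copy whole gametes from a donor population into a
recipient; every chromosome segment descending from a pulse donor is tracked
exactly through recombination, yielding base-accurate truth tracts.

Mutations are infinite-sites events at uniform real-valued positions,
integerised at export; globally fixed sites are dropped and the outgroup-major
allele is written as the REF (ancestral) allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, ConfigurationError
from .genio import HaplotypePanel, PopulationMap, SVRecord

POPULATIONS = ("P_A", "P_B", "W_A", "W_B", "OUT")

# internal lineage names used before the present-day populations exist
_ANC, _ING, _SIDE_A, _SIDE_B = "ANC", "ING", "SIDE_A", "SIDE_B"


@dataclass(frozen=True)
class PulseSpec:
    """A dated admixture pulse: at ``generation`` BP, each parent of each
    recipient individual is drawn from the donor population with
    probability ``proportion``."""

    generation: int
    donor: str
    recipient: str
    proportion: float


@dataclass
class SimulationConfig:
    chromosome_length: int = 5_000_000
    n_sites: int = 4_000  # target count of exported segregating sites
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {p: 40 for p in POPULATIONS}
    )
    split_generations: int = 75
    pulse_specs: list[PulseSpec] = field(default_factory=list)
    mutation_rate: float = 5e-7  # per site per generation
    recombination_rate: float = 5e-8  # per bp per generation
    seed: int = 0
    # demography shape knobs (fractions of split_generations)
    outgroup_split_factor: float = 2.0
    domestic_split_fraction: float = 0.6
    burn_in: int = 250
    #: haplotype count of ancestral (pre-split) populations; kept larger than
    #: the tips so splits occur with incomplete lineage sorting
    ancestral_size: int = 60
    #: haplotypes per population exported to the panels; defaults to the full
    #: census (pop_sizes).  A census larger than the exported sample damps
    #: post-pulse drift without changing the panel dimensions.
    sample_sizes: dict[str, int] | None = None

    def validate(self) -> None:
        if self.chromosome_length <= 0:
            raise ConfigurationError("chromosome_length must be positive")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        for pop in POPULATIONS:
            n = self.pop_sizes.get(pop)
            if n is None:
                raise ConfigurationError(f"pop_sizes missing population {pop}")
            if n < 2 or n % 2:
                raise ConfigurationError(
                    f"pop_sizes[{pop}] must be an even number of haplotypes >= 2"
                )
        if self.split_generations < 2:
            raise ConfigurationError("split_generations must be >= 2")
        t_dom = self.t_domestic_split
        for i, pulse in enumerate(self.pulse_specs):
            if not 0.0 <= pulse.proportion <= 1.0:
                raise ConfigurationError(
                    f"pulse_specs[{i}].proportion must be in [0, 1]"
                )
            if not 1 <= pulse.generation < self.split_generations:
                raise ConfigurationError(
                    f"pulse_specs[{i}].generation must satisfy "
                    f"1 <= generation < split_generations"
                )
            if pulse.donor not in POPULATIONS or pulse.recipient not in POPULATIONS:
                raise ConfigurationError(f"pulse_specs[{i}]: unknown population")
            if pulse.donor == pulse.recipient:
                raise ConfigurationError(f"pulse_specs[{i}]: donor == recipient")
            if pulse.generation >= t_dom and {pulse.donor, pulse.recipient} & {
                "P_A", "P_B", "W_A", "W_B"
            }:
                raise ConfigurationError(
                    f"pulse_specs[{i}].generation predates the populations involved"
                )
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.sample_sizes is not None:
            for pop, k in self.sample_sizes.items():
                if pop not in POPULATIONS:
                    raise ConfigurationError(f"sample_sizes: unknown population {pop}")
                if k < 2 or k % 2 or k > self.pop_sizes[pop]:
                    raise ConfigurationError(
                        f"sample_sizes[{pop}] must be even, >= 2 and <= census size"
                    )

    @property
    def t_outgroup_split(self) -> int:
        return int(round(self.split_generations * self.outgroup_split_factor))

    @property
    def t_domestic_split(self) -> int:
        return int(round(self.split_generations * self.domestic_split_fraction))


@dataclass(frozen=True)
class TruthTract:
    """One recipient-haplotype segment descending from a pulse donor."""

    recipient_sample: str
    haplotype_index: int  # 0 or 1
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    donor_pop: str
    pulse_generation: int


# A haplotype is (mutation positions: sorted float64 array,
#                 ancestry: None | list of (start, end, donor, pulse_gen)).
_Hap = tuple[np.ndarray, list | None]


def _gamete(hap0: _Hap, hap1: _Hap, breaks: np.ndarray, first: int) -> _Hap:
    """Recombine two parental haplotypes at the given crossover positions."""
    if breaks.size == 0:
        muts, anc = hap0 if first == 0 else hap1
        return muts, (list(anc) if anc else None)
    parents = (hap0, hap1)
    edges = np.concatenate(([-math.inf], breaks, [math.inf]))
    mut_parts: list[np.ndarray] = []
    anc_parts: list = []
    for seg in range(edges.size - 1):
        lo, hi = edges[seg], edges[seg + 1]
        muts, anc = parents[(first + seg) % 2]
        i = np.searchsorted(muts, lo)
        j = np.searchsorted(muts, hi)
        if j > i:
            mut_parts.append(muts[i:j])
        if anc:
            for (s, e, donor, gen) in anc:
                cs, ce = max(s, lo), min(e, hi)
                if cs < ce:
                    anc_parts.append((cs, ce, donor, gen))
    return (
        np.concatenate(mut_parts) if mut_parts else np.empty(0),
        anc_parts or None,
    )


def _merge_anc(anc: list) -> list:
    """Coalesce abutting ancestry pieces with identical labels."""
    anc = sorted(anc)
    out = [list(anc[0])]
    for s, e, donor, gen in anc[1:]:
        last = out[-1]
        if s <= last[1] and donor == last[2] and gen == last[3]:
            last[1] = max(last[1], e)
        else:
            out.append([s, e, donor, gen])
    return [tuple(x) for x in out]


def simulate_history(
    config: SimulationConfig,
) -> tuple[dict[str, HaplotypePanel], list[TruthTract]]:
    """Run the forward simulation and return present-day phased panels for
    all five populations plus the exact donor-ancestry truth tracts."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = float(config.chromosome_length)
    xover_mean = config.recombination_rate * L
    mut_mean = config.mutation_rate * L

    pulses_by_gen: dict[int, list[PulseSpec]] = {}
    for pulse in config.pulse_specs:
        pulses_by_gen.setdefault(pulse.generation, []).append(pulse)

    t_out = config.t_outgroup_split
    t_ab = config.split_generations
    t_dom = config.t_domestic_split
    t_start = t_out + config.burn_in

    def size_of(pop: str) -> int:
        if pop in config.pop_sizes:
            return config.pop_sizes[pop]
        return max(config.ancestral_size, max(config.pop_sizes.values()))

    def pops_at(t: int) -> dict[str, str]:
        """Populations alive at generation t -> the pool their parents are
        drawn from (differs from the population itself only at a split)."""
        if t >= t_out:
            return {_ANC: _ANC}
        if t >= t_ab:
            return {
                "OUT": "OUT" if t < t_out - 1 else _ANC,
                _ING: _ING if t < t_out - 1 else _ANC,
            }
        if t >= t_dom:
            return {
                "OUT": "OUT",
                _SIDE_A: _SIDE_A if t < t_ab - 1 else _ING,
                _SIDE_B: _SIDE_B if t < t_ab - 1 else _ING,
            }
        first = t == t_dom - 1
        return {
            "OUT": "OUT",
            "P_A": _SIDE_A if first else "P_A",
            "W_A": _SIDE_A if first else "W_A",
            "P_B": _SIDE_B if first else "P_B",
            "W_B": _SIDE_B if first else "W_B",
        }

    # founders: mutation-free
    current: dict[str, list[_Hap]] = {
        _ANC: [(np.empty(0), None) for _ in range(size_of(_ANC))]
    }

    for t in range(t_start - 1, -1, -1):
        layout = pops_at(t)
        nxt: dict[str, list[_Hap]] = {}
        for pop in sorted(layout):
            source = layout[pop]
            n_haps = size_of(pop)
            n_ind = n_haps // 2
            pulse_here = [
                p for p in pulses_by_gen.get(t, []) if p.recipient == pop
            ]
            # per-parent donor choice; at most one pulse per recipient per gen
            pool_names = np.full(2 * n_ind, "", dtype=object)
            pool_names[:] = source
            donor_of_gamete: list[PulseSpec | None] = [None] * (2 * n_ind)
            if pulse_here:
                pulse = pulse_here[0]
                take = rng.random(2 * n_ind) < pulse.proportion
                for k in np.flatnonzero(take):
                    pool_names[k] = pulse.donor
                    donor_of_gamete[k] = pulse
            kids: list[_Hap] = []
            # batched randomness, consumed in fixed order
            for k in range(2 * n_ind):
                pool = current[str(pool_names[k])]
                parent = int(rng.integers(len(pool) // 2))
                n_x = int(rng.poisson(xover_mean))
                breaks = np.sort(rng.uniform(0.0, L, n_x)) if n_x else np.empty(0)
                first = int(rng.integers(2))
                muts, anc = _gamete(pool[2 * parent], pool[2 * parent + 1], breaks, first)
                pulse = donor_of_gamete[k]
                if pulse is not None:
                    anc = [(0.0, L, pulse.donor, pulse.generation)]
                n_new = int(rng.poisson(mut_mean))
                if n_new:
                    new = rng.uniform(0.0, L, n_new)
                    muts = np.sort(np.concatenate((muts, new)))
                kids.append((muts, anc))
            nxt[pop] = kids
        current = nxt

    return _export(config, rng, current)


def _export(
    config: SimulationConfig, rng: np.random.Generator, current: dict[str, list[_Hap]]
) -> tuple[dict[str, HaplotypePanel], list[TruthTract]]:
    L = config.chromosome_length
    chrom = "chr1"
    pop_haps: dict[str, list[_Hap]] = {}
    for pop in POPULATIONS:
        haps = current[pop]
        want = (config.sample_sizes or {}).get(pop, len(haps))
        if want < len(haps):
            inds = np.sort(rng.choice(len(haps) // 2, size=want // 2, replace=False))
            haps = [haps[2 * i + k] for i in inds for k in (0, 1)]
        pop_haps[pop] = haps
    all_muts = [m for haps in pop_haps.values() for (m, _) in haps]
    union = np.unique(np.concatenate(all_muts)) if all_muts else np.empty(0)

    n_total = sum(len(h) for h in pop_haps.values())
    matrix = np.zeros((n_total, union.size), dtype=np.int8)
    row = 0
    row_of_pop: dict[str, slice] = {}
    for pop in POPULATIONS:
        start = row
        for muts, _ in pop_haps[pop]:
            if muts.size:
                matrix[row, np.searchsorted(union, muts)] = 1
            row += 1
        row_of_pop[pop] = slice(start, row)

    counts = matrix.sum(axis=0)
    keep = (counts > 0) & (counts < n_total)
    union = union[keep]
    matrix = matrix[:, keep]

    # integerise positions (1-based); drop collisions
    ipos = np.floor(union).astype(np.int64) + 1
    uniq = np.concatenate(([True], np.diff(ipos) > 0)) if ipos.size else np.empty(0, bool)
    ipos, matrix = ipos[uniq], matrix[:, uniq]

    if ipos.size > config.n_sites:
        pick = np.sort(rng.choice(ipos.size, size=config.n_sites, replace=False))
        ipos, matrix = ipos[pick], matrix[:, pick]

    # polarize: ancestral = outgroup-major allele
    out_rows = matrix[row_of_pop["OUT"]]
    p_out = out_rows.mean(axis=0)
    flip = p_out > 0.5
    matrix[:, flip] = 1 - matrix[:, flip]

    nucs = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, ipos.size)
    alt_idx = (ref_idx + 1 + rng.integers(0, 3, ipos.size)) % 4
    refs, alts = nucs[ref_idx], nucs[alt_idx]

    panels: dict[str, HaplotypePanel] = {}
    for pop in POPULATIONS:
        rows = matrix[row_of_pop[pop]]
        n_samples = rows.shape[0] // 2
        panels[pop] = HaplotypePanel(
            chrom=chrom,
            positions=ipos.copy(),
            alleles=rows.copy(),
            sample_ids=[f"{pop}_{i}" for i in range(n_samples)],
            phased=True,
        )
        panels[pop].ref_alleles = refs  # type: ignore[attr-defined]
        panels[pop].alt_alleles = alts  # type: ignore[attr-defined]

    tracts: list[TruthTract] = []
    for pop in POPULATIONS:
        for h, (_, anc) in enumerate(pop_haps[pop]):
            if not anc:
                continue
            for s, e, donor, gen in _merge_anc(anc):
                si, ei = int(math.floor(s)), int(math.ceil(e))
                si, ei = max(si, 0), min(ei, L)
                if si < ei:
                    tracts.append(
                        TruthTract(
                            recipient_sample=f"{pop}_{h // 2}",
                            haplotype_index=h % 2,
                            chrom=chrom,
                            start=si,
                            end=ei,
                            donor_pop=donor,
                            pulse_generation=gen,
                        )
                    )
    return panels, tracts


def combined_panel(panels: dict[str, HaplotypePanel]) -> tuple[HaplotypePanel, PopulationMap]:
    """Stack per-population panels (identical site grids) into one panel plus
    the matching population map."""
    pops = [p for p in POPULATIONS if p in panels]
    first = panels[pops[0]]
    alleles = np.vstack([panels[p].alleles for p in pops])
    samples: list[str] = []
    assignments: dict[str, str] = {}
    for p in pops:
        for s in panels[p].sample_ids:
            samples.append(s)
            assignments[s] = p
    panel = HaplotypePanel(
        chrom=first.chrom,
        positions=first.positions.copy(),
        alleles=alleles,
        sample_ids=samples,
        phased=True,
    )
    for attr in ("ref_alleles", "alt_alleles"):
        if hasattr(first, attr):
            setattr(panel, attr, getattr(first, attr))
    return panel, PopulationMap(assignments=assignments)


# ---------------------------------------------------------------------------
# SV table simulation
# ---------------------------------------------------------------------------


def simulate_sv_table(
    config: SimulationConfig,
    n_svs: int,
    stratified_fraction: float,
    tracts: list[TruthTract] | None = None,
    co_place: bool = False,
    seed: int | None = None,
) -> list[SVRecord]:
    """Simulate biallelic SV genotypes for the five populations.

    Exactly ``round(n_svs * stratified_fraction)`` SVs are built with a
    realised allele-frequency difference >= 0.5 between P_A and P_B; the
    rest draw genotypes i.i.d. across all samples from one shared frequency
    (exchangeable null).  With ``co_place`` the stratified SVs are placed
    inside truth tracts.  Truth labels live in ``sv._stratified``.
    """
    if n_svs < 1:
        raise ArgumentError("n_svs must be >= 1")
    if not 0.0 <= stratified_fraction <= 1.0:
        raise ArgumentError("stratified_fraction must be in [0, 1]")
    config.validate()
    rng = np.random.default_rng(config.seed + 7_777 if seed is None else seed)
    L = config.chromosome_length
    n_strat = int(round(n_svs * stratified_fraction))
    n_of = {
        pop: (config.sample_sizes or {}).get(pop, config.pop_sizes[pop]) // 2
        for pop in POPULATIONS
    }
    sample_ids = [f"{pop}_{i}" for pop in POPULATIONS for i in range(n_of[pop])]
    pop_of = np.array([pop for pop in POPULATIONS for _ in range(n_of[pop])])
    n_samples = len(sample_ids)

    tract_spans = (
        [(t.start, t.end) for t in tracts if t.end - t.start >= 2_000] if tracts else []
    )
    if co_place and not tract_spans:
        raise ArgumentError("co_place requires non-empty truth tracts")

    svs: list[SVRecord] = []
    svtypes = np.array(["DEL", "INS", "DUP", "INV"])
    for k in range(n_svs):
        stratified = k < n_strat
        if stratified and co_place:
            s, e = tract_spans[int(rng.integers(len(tract_spans)))]
            pos = int(rng.integers(s + 1, max(s + 2, e - 1000)))
        else:
            pos = int(rng.integers(1, L - 1000))
        svtype = str(svtypes[int(rng.integers(4))])
        size = 0 if svtype == "INS" else int(rng.integers(50, 20_000))
        end = pos if svtype == "INS" else min(pos + size, L)
        genotypes = np.empty(n_samples, dtype=np.int8)
        if stratified:
            hi, lo = 0.8 + 0.15 * rng.random(), 0.05 * rng.random()
            for _ in range(100):
                for pop in POPULATIONS:
                    mask = pop_of == pop
                    p = hi if pop == "P_A" else lo if pop == "P_B" else rng.uniform(0.1, 0.9)
                    genotypes[mask] = rng.binomial(2, p, mask.sum())
                pa = genotypes[pop_of == "P_A"].mean() / 2
                pb = genotypes[pop_of == "P_B"].mean() / 2
                if abs(pa - pb) >= 0.5:
                    break
            else:  # pragma: no cover - essentially unreachable
                genotypes[pop_of == "P_A"] = 2
                genotypes[pop_of == "P_B"] = 0
        else:
            p = rng.uniform(0.05, 0.95)
            genotypes = rng.binomial(2, p, n_samples).astype(np.int8)
        sv = SVRecord(
            sv_id=f"sv{k}",
            svtype=svtype,
            chrom="chr1",
            pos=pos,
            end=end,
            genotypes=genotypes,
            sample_ids=sample_ids,
        )
        sv._stratified = stratified  # type: ignore[attr-defined]
        svs.append(sv)
    return svs


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_simulation(
    panels: dict[str, HaplotypePanel],
    tracts: list[TruthTract],
    svs: list[SVRecord],
    out_prefix: str,
    chromosome_length: int,
) -> dict[str, str]:
    """Write phased SNP VCF, SV VCF, truth-tract BED and pop-map TSV.

    Returns the mapping of artifact name to path."""
    from . import genio

    if not panels:
        raise ArgumentError("panels must be non-empty")
    panel, popmap = combined_panel(panels)
    ref_alt = None
    if hasattr(panel, "ref_alleles"):
        ref_alt = (panel.ref_alleles, panel.alt_alleles)  # type: ignore[attr-defined]
    paths = {
        "snp_vcf": f"{out_prefix}.snps.vcf",
        "sv_vcf": f"{out_prefix}.svs.vcf",
        "truth_bed": f"{out_prefix}.truth.bed",
        "popmap": f"{out_prefix}.popmap.tsv",
    }
    genio.write_phased_vcf(panel, paths["snp_vcf"], contig_length=chromosome_length,
                           ref_alt=ref_alt)
    if svs:
        genio.write_sv_vcf(svs, paths["sv_vcf"], contig_length=chromosome_length)
    else:
        paths.pop("sv_vcf")
    genio.write_bed(
        [
            (t.chrom, t.start, t.end, t.donor_pop, t.recipient_sample,
             t.haplotype_index, t.pulse_generation)
            for t in tracts
        ],
        paths["truth_bed"],
    )
    genio.write_popmap(popmap, paths["popmap"])
    return paths
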