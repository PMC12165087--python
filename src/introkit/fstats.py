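"""Frequency-based population statistics.

Windowed Patterson's D and f_d from population allele frequencies, the
weighted block-jackknife Z, the f4-ratio admixture-proportion estimator,
Weir & Cockerham (1984) F_ST, and SV-to-SNP maximum-r2 tagging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, InsufficientDataError
from .genio import MISSING, GenomicWindow, HaplotypePanel, PopulationMap, SVRecord

#: outgroup frequencies inside this band are treated as unpolarizable
POLARIZE_BAND = (0.4, 0.6)

DEFAULT_MIN_SITES = 10


# ---------------------------------------------------------------------------
# allele frequencies and polarization
# ---------------------------------------------------------------------------


def alt_frequencies(panel: HaplotypePanel, sample_ids: list[str]) -> np.ndarray:
    """Per-site ALT-allele frequency over called alleles of the given samples.

    Sites with no called allele yield NaN.
    """
    sub = panel.subset_samples(sample_ids)
    a = sub.alleles
    called = a != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, a, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)


@dataclass
class QuartetFreqs:
    """Per-site derived-allele frequencies for a (P1, P2; P3, O) quartet,
    polarized so that the derived allele is the outgroup-minor allele.
    Sites where the outgroup is ambiguous or missing are already dropped."""

    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p_out: np.ndarray
    positions: np.ndarray  # 1-based bp

    def __post_init__(self) -> None:
        for arr in (self.p1, self.p2, self.p3, self.p_out):
            if arr.shape != self.positions.shape:
                raise ArgumentError("frequency arrays must align with positions")


def quartet_freqs(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    p1_pop: str,
    p2_pop: str,
    p3_pop: str,
    out_pop: str,
) -> QuartetFreqs:
    """Polarized quartet frequencies for one population arrangement.

    The derived allele at each site is the allele with the lower outgroup
    frequency; sites with outgroup frequency inside ``POLARIZE_BAND`` or
    missing are dropped.
    """
    freqs = {
        pop: alt_frequencies(panel, popmap.samples_of(pop))
        for pop in (p1_pop, p2_pop, p3_pop, out_pop)
    }
    p_o = freqs[out_pop]
    lo, hi = POLARIZE_BAND
    keep = ~np.isnan(p_o) & ((p_o < lo) | (p_o > hi))
    for pop in (p1_pop, p2_pop, p3_pop):
        keep &= ~np.isnan(freqs[pop])
    flip = p_o > hi
    arrs = {}
    for pop in (p1_pop, p2_pop, p3_pop, out_pop):
        f = freqs[pop].copy()
        f[flip] = 1.0 - f[flip]
        arrs[pop] = f[keep]
    return QuartetFreqs(
        p1=arrs[p1_pop],
        p2=arrs[p2_pop],
        p3=arrs[p3_pop],
        p_out=arrs[out_pop],
        positions=panel.positions[keep],
    )


# ---------------------------------------------------------------------------
# D and f_d
# ---------------------------------------------------------------------------


def site_patterns(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site ABBA/BABA weights and their donor-surrogate counterparts."""
    abba = (1 - p1) * p2 * p3 * (1 - p_out)
    baba = p1 * (1 - p2) * p3 * (1 - p_out)
    p_d = np.maximum(p2, p3)
    abba_d = (1 - p1) * p_d * p_d * (1 - p_out)
    baba_d = p1 * (1 - p_d) * p_d * (1 - p_out)
    return abba, baba, abba_d, baba_d


def window_dstats(
    freqs: QuartetFreqs,
    window: GenomicWindow,
    min_sites: int = DEFAULT_MIN_SITES,
) -> tuple[float, float, int]:
    """Patterson's D and f_d for one window; f_d is zeroed where D < 0.

    Returns ``(D, f_d, n_informative_sites)``; D and f_d are NaN when the
    window has fewer than ``min_sites`` usable sites or a zero denominator.
    """
    pos0 = freqs.positions - 1
    mask = (pos0 >= window.start) & (pos0 < window.end)
    n = int(mask.sum())
    if n < min_sites:
        return float("nan"), float("nan"), n
    abba, baba, abba_d, baba_d = site_patterns(
        freqs.p1[mask], freqs.p2[mask], freqs.p3[mask], freqs.p_out[mask]
    )
    num = float(np.sum(abba - baba))
    den = float(np.sum(abba + baba))
    den_d = float(np.sum(abba_d - baba_d))
    d = num / den if den != 0.0 else float("nan")
    if np.isnan(d):
        return d, float("nan"), n
    if d < 0:
        return d, 0.0, n
    fd = num / den_d if den_d != 0.0 else float("nan")
    return d, fd, n


def dstat_scan(
    freqs: QuartetFreqs,
    windows: list[GenomicWindow],
    min_sites: int = DEFAULT_MIN_SITES,
) -> pd.DataFrame:
    """Per-window D/f_d table with columns chrom, start, end, n_sites, D, fd."""
    rows = []
    for w in windows:
        d, fd, n = window_dstats(freqs, w, min_sites=min_sites)
        rows.append((w.chrom, w.start, w.end, n, d, fd))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "D", "fd"])


def genomewide_d(freqs: QuartetFreqs) -> float:
    abba, baba, _, _ = site_patterns(freqs.p1, freqs.p2, freqs.p3, freqs.p_out)
    den = float(np.sum(abba + baba))
    return float(np.sum(abba - baba)) / den if den != 0.0 else float("nan")


def block_d_values(
    freqs: QuartetFreqs, block_size: int, chrom_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block D values and block spans (bp) on a fixed non-overlapping
    grid, for the block jackknife; blocks without informative sites are NaN."""
    abba, baba, _, _ = site_patterns(freqs.p1, freqs.p2, freqs.p3, freqs.p_out)
    pos0 = freqs.positions - 1
    n_blocks = max(1, int(np.ceil(chrom_length / block_size)))
    d_vals = np.full(n_blocks, np.nan)
    spans = np.empty(n_blocks)
    for b in range(n_blocks):
        lo, hi = b * block_size, min((b + 1) * block_size, chrom_length)
        spans[b] = hi - lo
        mask = (pos0 >= lo) & (pos0 < hi)
        den = float(np.sum(abba[mask] + baba[mask]))
        if den != 0.0:
            d_vals[b] = float(np.sum(abba[mask] - baba[mask])) / den
    return d_vals, spans


def jackknife_z(per_block_d: np.ndarray, block_spans: np.ndarray) -> float:
    """Weighted delete-one block-jackknife Z for a genome-wide D.

    Blocks with NaN D are dropped; needs at least five usable blocks.
    With all blocks identical and non-zero the SE is 0 and a signed
    infinity sentinel is returned.
    """
    d = np.asarray(per_block_d, dtype=float)
    w = np.asarray(block_spans, dtype=float)
    keep = ~np.isnan(d)
    d, w = d[keep], w[keep]
    g = d.size
    if g < 5:
        raise InsufficientDataError(f"need >= 5 non-missing blocks, got {g}")
    total_w = w.sum()
    theta = float(np.sum(w * d) / total_w)
    loo = (np.sum(w * d) - w * d) / (total_w - w)
    h = total_w / w
    theta_j = g * theta - float(np.sum((1.0 - w / total_w) * loo))
    pseudo = h * theta - (h - 1.0) * loo
    var = float(np.sum((pseudo - theta_j) ** 2 / (h - 1.0)) / g)
    se = np.sqrt(max(var, 0.0))
    # identical blocks: zero jackknife variance up to float error
    if se <= abs(theta) * 1e-9:
        return 0.0 if theta == 0.0 else float(np.sign(theta)) * float("inf")
    return theta / se


# ---------------------------------------------------------------------------
# f4 ratio
# ---------------------------------------------------------------------------


def f4(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """f4(P1, P2; P3, P4) = mean over sites of (p1 - p2)(p3 - p4)."""
    return float(np.mean((p1 - p2) * (p3 - p4)))


def f4_ratio(
    p_a: np.ndarray,
    p_o: np.ndarray,
    p_x: np.ndarray,
    p_b: np.ndarray,
    p_c: np.ndarray,
    eps: float = 1e-12,
) -> float:
    """Admixture proportion alpha = f4(A,O;X,C) / f4(A,O;B,C).

    X is the putatively admixed population, B the donor-side reference
    (sister of A), C the recipient-side reference.  NaN on a degenerate
    denominator.
    """
    den = f4(p_a, p_o, p_b, p_c)
    if abs(den) < eps:
        return float("nan")
    return f4(p_a, p_o, p_x, p_c) / den


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------


def wc_fst_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WC84 variance components (a, b, c) for one biallelic site.

    ``n``: called diploids per population; ``p``: ALT frequency per
    population; ``h``: observed heterozygote proportion per population.
    Arrays may carry a trailing site axis.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    h = np.asarray(h, dtype=float)
    r = n.shape[0]
    if r < 2:
        raise ArgumentError("need >= 2 populations")
    n_bar = n.mean(axis=0)
    n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum(axis=0) / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=0) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


def wc_fst(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Single-site WC84 theta = a / (a + b + c); NaN if undefined."""
    a, b, c = wc_fst_components(n, p, h)
    den = a + b + c
    return float(a / den) if den != 0.0 else float("nan")


def _pop_site_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n called diploids, ALT freq, het proportion) per site from a
    (n_samples, n_sites) dosage matrix with MISSING entries."""
    called = dosages != MISSING
    n = called.sum(axis=0).astype(float)
    dos = np.where(called, dosages, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dos.sum(axis=0) / (2 * np.maximum(n, 1)), np.nan)
        h = np.where(
            n > 0, ((dosages == 1) & called).sum(axis=0) / np.maximum(n, 1), np.nan
        )
    return n, p, h


def fst_scan(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    pops: list[str],
    windows: list[GenomicWindow],
) -> pd.DataFrame:
    """Windowed ratio-of-sums WC84 F_ST between the given populations.

    Per-window estimates are reported as computed (``fst_raw``) and floored
    at zero (``fst``); sites monomorphic across all populations, or with a
    zero-called population, are skipped.
    """
    stats = [
        _pop_site_stats(panel.subset_samples(popmap.samples_of(pop)).genotype_dosages())
        for pop in pops
    ]
    n = np.stack([s[0] for s in stats])
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])
    usable = (n >= 1).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled = (n * p).sum(axis=0) / np.maximum(n.sum(axis=0), 1)
    usable &= (pooled > 0) & (pooled < 1)
    a = np.full(usable.shape, np.nan)
    b = np.full(usable.shape, np.nan)
    c = np.full(usable.shape, np.nan)
    if usable.any():
        a_u, b_u, c_u = wc_fst_components(n[:, usable], p[:, usable], h[:, usable])
        a[usable], b[usable], c[usable] = a_u, b_u, c_u
    pos0 = panel.positions - 1
    rows = []
    for w in windows:
        mask = (pos0 >= w.start) & (pos0 < w.end) & usable
        den = float(np.nansum(a[mask] + b[mask] + c[mask]))
        raw = float(np.nansum(a[mask])) / den if den != 0.0 else float("nan")
        rows.append(
            (w.chrom, w.start, w.end, int(mask.sum()), raw, max(raw, 0.0) if not np.isnan(raw) else raw)
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "fst_raw", "fst"]
    )


# ---------------------------------------------------------------------------
# SV-SNP LD tagging
# ---------------------------------------------------------------------------


def sv_snp_max_r2(
    sv: SVRecord, panel: HaplotypePanel, flank: int = 50_000
) -> tuple[float, int | None]:
    """Maximum squared Pearson correlation between the SV dosage and any SNP
    dosage within ``flank`` bp of the SV footprint.

    Returns ``(max_r2, best_snp_position)``; ties break toward the smallest
    position.  NaN/None when the SV is monomorphic over jointly-called
    samples or no SNP lies in the flank.
    """
    shared = [s for s in sv.sample_ids if s in panel.sample_ids]
    if not shared:
        return float("nan"), None
    sv_idx = {s: i for i, s in enumerate(sv.sample_ids)}
    sv_dos = sv.genotypes[[sv_idx[s] for s in shared]].astype(float)
    sub = panel.subset_samples(shared)
    lo, hi = sv.pos - flank, sv.end + flank
    keep = (sub.positions >= lo) & (sub.positions <= hi)
    if not keep.any():
        return float("nan"), None
    snp_dos = sub.genotype_dosages()[:, keep].astype(float)
    positions = sub.positions[keep]
    best_r2, best_pos = float("nan"), None
    for j in range(positions.size):
        col = snp_dos[:, j]
        ok = (sv_dos != MISSING) & (col != MISSING)
        if ok.sum() < 2:
            continue
        x, y = sv_dos[ok], col[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2 = float(r * r)
        if np.isnan(best_r2) or r2 > best_r2 + 1e-15:
            best_r2, best_pos = r2, int(positions[j])
    return best_r2, best_pos
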