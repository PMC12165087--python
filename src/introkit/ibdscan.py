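"""Pairwise haplotype IBD detection and the windowed rIBD scan.

IBD here is a deterministic seed-and-extend identity-run matcher with a
small mismatch budget (GERMLINE-style), not an HMM with posterior scores:
it is exact and reproducible on simulated phased data, which is what this
toolkit consumes.  The scan statistic per window is

    rIBD = nIBD(recipient, donor) - nIBD(recipient, background)

with nIBD = cIBD / tIBD, where cIBD counts cross-group haplotype pairs
sharing at least one tract overlapping the window and tIBD is the total
number of cross-group haplotype pairs; nIBD is 0 when no IBD is detected
and 1 when every pair shares the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ArgumentError, ContractError
from .genio import MISSING, GenomicWindow, HaplotypePanel, PopulationMap

DEFAULT_MIN_LENGTH = 200_000
DEFAULT_MIN_SITES = 50
DEFAULT_MAX_MISMATCH = 1

#: an absorbed mismatch must sit at least this many sites from a run end
EDGE_BUFFER = 10


@dataclass(frozen=True)
class IBDTract:
    hap_a: tuple[str, int]
    hap_b: tuple[str, int]
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    n_sites: int


@dataclass
class RibdWindow:
    window: GenomicWindow
    nibd_rd: float
    nibd_rb: float
    ribd: float


def _identity_runs(
    mismatches: np.ndarray,
    n_sites: int,
    max_mismatch: int,
    edge_buffer: int,
    min_run_sites: int = 1,
) -> list[tuple[int, int, int]]:
    """Maximal identity runs as (first_site, last_site, n_absorbed) site-index
    triples, absorbing up to ``max_mismatch`` mismatches per run, none of
    which may lie within ``edge_buffer`` sites of either run end.  Runs with
    fewer than ``min_run_sites`` concordant sites are discarded."""
    m = np.concatenate(([-1], mismatches, [n_sites]))
    k = int(mismatches.size)
    cand_s: list[np.ndarray] = []
    cand_e: list[np.ndarray] = []
    cand_t: list[np.ndarray] = []
    for t in range(min(max_mismatch, k) + 1):
        n_runs = k - t + 1
        s = m[:n_runs] + 1
        e = m[t + 1 : t + 1 + n_runs] - 1
        valid = (e - s + 1 - t) >= max(min_run_sites, 1)
        for i in range(1, t + 1):
            inner = m[i : i + n_runs]
            valid &= (inner - s >= edge_buffer) & (e - inner >= edge_buffer)
        if valid.any():
            cand_s.append(s[valid])
            cand_e.append(e[valid])
            cand_t.append(np.full(int(valid.sum()), t))
    if not cand_s:
        return []
    s_all = np.concatenate(cand_s)
    e_all = np.concatenate(cand_e)
    t_all = np.concatenate(cand_t)
    order = np.lexsort((-e_all, s_all))
    out: list[tuple[int, int, int]] = []
    max_e = -1
    for idx in order:
        if e_all[idx] > max_e:
            out.append((int(s_all[idx]), int(e_all[idx]), int(t_all[idx])))
            max_e = int(e_all[idx])
    return out


def _snap(
    s: int, e: int, positions0: np.ndarray, chrom_length: int
) -> tuple[int, int]:
    """Physical tract bounds: midpoints to the flanking discordant sites,
    or the chromosome edges."""
    if s == 0:
        start = 0
    else:
        start = int((positions0[s - 1] + positions0[s]) // 2) + 1
    if e == positions0.size - 1:
        end = chrom_length
    else:
        end = int((positions0[e] + positions0[e + 1]) // 2) + 1
    return start, end


def detect_ibd(
    panel: HaplotypePanel,
    group_a: list[str],
    group_b: list[str],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_sites: int = DEFAULT_MIN_SITES,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    chrom_length: int | None = None,
    edge_buffer: int = EDGE_BUFFER,
) -> list[IBDTract]:
    """All cross-group IBD tracts between the haplotypes of two sample groups.

    A site where either haplotype is missing counts as a mismatch, so IBD
    is never asserted across missing data.
    """
    if not panel.phased:
        raise ContractError("IBD detection requires a phased panel")
    if set(group_a) & set(group_b):
        raise ArgumentError("groups must be disjoint at the sample level")
    if chrom_length is None:
        chrom_length = int(panel.positions[-1]) if panel.n_sites else 0
    positions0 = panel.positions - 1
    index = {s: i for i, s in enumerate(panel.sample_ids)}
    rows_a = [(s, k, panel.alleles[2 * index[s] + k]) for s in group_a for k in (0, 1)]
    rows_b = [(s, k, panel.alleles[2 * index[s] + k]) for s in group_b for k in (0, 1)]
    n_sites_total = panel.n_sites
    tracts: list[IBDTract] = []
    for sa, ka, alle_a in rows_a:
        miss_a = alle_a == MISSING
        for sb, kb, alle_b in rows_b:
            mism = np.flatnonzero((alle_a != alle_b) | miss_a | (alle_b == MISSING))
            runs = _identity_runs(
                mism, n_sites_total, max_mismatch, edge_buffer, min_run_sites=min_sites
            )
            for s, e, t in runs:
                n_run = e - s + 1 - t
                if n_run < min_sites:
                    continue
                start, end = _snap(s, e, positions0, chrom_length)
                if end - start < min_length:
                    continue
                tracts.append(
                    IBDTract(
                        hap_a=(sa, ka),
                        hap_b=(sb, kb),
                        chrom=panel.chrom,
                        start=start,
                        end=end,
                        n_sites=n_run,
                    )
                )
    return tracts


def nibd(
    tracts: list[IBDTract],
    window: GenomicWindow,
    group_a: list[str],
    group_b: list[str],
) -> float:
    """cIBD / tIBD for one window: the fraction of cross-group haplotype
    pairs with at least one tract overlapping the window (a pair with
    several tracts in the window still counts once)."""
    if not group_a or not group_b:
        raise ArgumentError("both groups must be non-empty")
    t_ibd = (2 * len(group_a)) * (2 * len(group_b))
    pairs = {
        (t.hap_a, t.hap_b)
        for t in tracts
        if t.start < window.end and window.start < t.end
    }
    return len(pairs) / t_ibd


def _window_pair_counts(
    tracts: list[IBDTract], windows: list[GenomicWindow]
) -> np.ndarray:
    """Distinct overlapping pairs per window, via a per-window sweep."""
    if not tracts:
        return np.zeros(len(windows), dtype=np.int64)
    starts = np.array([t.start for t in tracts])
    ends = np.array([t.end for t in tracts])
    pair_key: dict[tuple, int] = {}
    pair_ids = np.empty(len(tracts), dtype=np.int64)
    for i, t in enumerate(tracts):
        pair_ids[i] = pair_key.setdefault((t.hap_a, t.hap_b), len(pair_key))
    counts = np.empty(len(windows), dtype=np.int64)
    for i, w in enumerate(windows):
        mask = (starts < w.end) & (ends > w.start)
        counts[i] = np.unique(pair_ids[mask]).size
    return counts


def ribd_scan(
    panel: HaplotypePanel,
    popmap: PopulationMap,
    windows: list[GenomicWindow],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_sites: int = DEFAULT_MIN_SITES,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    chrom_length: int | None = None,
    min_window_sites: int = 10,
) -> list[RibdWindow]:
    """Windowed rIBD between the roles set on ``popmap``.

    Requires the roles ``recipient``, ``donor`` and ``background``; windows
    with fewer than ``min_window_sites`` panel sites get NaN rIBD.
    """
    popmap.require_roles("recipient", "donor", "background")
    recipient = popmap.samples_of(popmap.roles["recipient"])
    donor = popmap.samples_of(popmap.roles["donor"])
    background = popmap.samples_of(popmap.roles["background"])
    for name, grp in (("recipient", recipient), ("donor", donor), ("background", background)):
        if not grp:
            raise ArgumentError(f"role {name!r} maps to an empty population")
    kwargs = dict(
        min_length=min_length,
        min_sites=min_sites,
        max_mismatch=max_mismatch,
        chrom_length=chrom_length,
    )
    tracts_rd = detect_ibd(panel, recipient, donor, **kwargs)
    tracts_rb = detect_ibd(panel, recipient, background, **kwargs)
    t_rd = (2 * len(recipient)) * (2 * len(donor))
    t_rb = (2 * len(recipient)) * (2 * len(background))
    c_rd = _window_pair_counts(tracts_rd, windows)
    c_rb = _window_pair_counts(tracts_rb, windows)
    pos0 = panel.positions - 1
    out: list[RibdWindow] = []
    for i, w in enumerate(windows):
        n_in_window = int(np.count_nonzero((pos0 >= w.start) & (pos0 < w.end)))
        w.n_sites = n_in_window
        n_rd = c_rd[i] / t_rd
        n_rb = c_rb[i] / t_rb
        ribd = n_rd - n_rb if n_in_window >= min_window_sites else float("nan")
        out.append(RibdWindow(window=w, nibd_rd=n_rd, nibd_rb=n_rb, ribd=ribd))
    return out


def ribd_table(rows: list[RibdWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.window.chrom, r.window.start, r.window.end, r.nibd_rd, r.nibd_rb, r.ribd)
            for r in rows
        ],
        columns=["chrom", "start", "end", "nibd_rd", "nibd_rb", "ribd"],
    )


def tract_table(tracts: list[IBDTract]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                f"{t.hap_a[0]}:{t.hap_a[1]}",
                f"{t.hap_b[0]}:{t.hap_b[1]}",
                t.chrom,
                t.start,
                t.end,
                t.n_sites,
            )
            for t in tracts
        ],
        columns=["hap_a", "hap_b", "chrom", "start", "end", "n_sites"],
    )
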